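"""Multilevel multinomial behaviour models (MMBMs).

The observation model is a multinomial (categorical) logit over the six
behaviour categories with resting as the reference: for observation row
``r`` (one individual in one scan) and non-reference category ``k``,

    eta[r, k] = alpha_k + x_r . beta[:, k] + sum_levels u[level, unit(r), k]
    P(category k | r) = exp(eta[r, k]) / (1 + sum_j exp(eta[r, j]))
    P(rest | r)       = 1 / (1 + sum_j exp(eta[r, j]))

Random effects at each level (individual, and for Model 3 also scan, litter
and group) are drawn from a 5-variate normal with per-category SDs sigma and
correlation matrix Omega, parameterized noncentred through the Cholesky
factor: u = diag(sigma) . L . zeta with zeta ~ N(0, I). The within-individual
correlations Omega_individual are the quantity of scientific interest: a
significantly negative correlation between two cooperative behaviours is the
signature of task specialization.

Model variants:

* M1 - intercepts + individual-level random effects only;
* M2 - M1 plus fixed covariates (age polynomial to cubic, group-size
  polynomial to quadratic, pup presence, relative mass; all z-scored);
* M3 - M2 plus random effects for scan, litter and group.

Posteriors are sampled with the in-package NUTS sampler
(:mod:`mmbm.sampler`); gradients of the joint log density are analytic except
for the correlation-Cholesky transform, which is differentiated by complex
step. All events of one scan share covariates and random effects, so the
likelihood is evaluated on per-(individual, scan) category counts - the
sufficient statistics of the event-level categorical model.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from . import data_model
from .data_model import (
    CATEGORIES,
    FIXED_TERMS,
    NONREFERENCE_CATEGORIES,
    REFERENCE_CATEGORY,
)
from .sampler import nuts

K = len(NONREFERENCE_CATEGORIES)  # non-reference categories
N_CORR = K * (K - 1) // 2

M3_LEVELS = ("individual", "scan", "litter", "group")


# --------------------------------------------------------------------------
# Specs
# --------------------------------------------------------------------------


@dataclass
class PriorConfig:
    """Weakly informative priors for all sampled parameters.

    intercepts ~ Normal(0, intercept_scale), slopes ~ Normal(0, beta_scale),
    random-effect SDs ~ Exponential(sd_rate), correlation Cholesky factors
    ~ LKJ(lkj_eta).
    """

    beta_scale: float = 2.0
    intercept_scale: float = 5.0
    sd_rate: float = 1.0
    lkj_eta: float = 2.0

    def __post_init__(self):
        for name in ("beta_scale", "intercept_scale", "sd_rate", "lkj_eta"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be finite and positive, got {v}")
        if self.lkj_eta < 1:
            raise ValueError("lkj_eta must be >= 1")


@dataclass
class SamplerConfig:
    """MCMC settings; defaults mirror the study design (3 chains of 1000
    iterations, half warmup)."""

    chains: int = 3
    iterations: int = 1000
    warmup: int | None = None  # defaults to iterations // 2
    seed: int = 0
    target_accept: float = 0.8
    max_treedepth: int = 10

    @property
    def n_warmup(self) -> int:
        return self.iterations // 2 if self.warmup is None else self.warmup

    @property
    def n_keep(self) -> int:
        return self.iterations - self.n_warmup


@dataclass
class ModelSpec:
    """Which model variant to fit, for which sex, with which settings.

    ``scan_effect_grain`` controls the unit of the scan-level effect in M3:
    ``"individual_scan"`` (one effect per individual per scan, the default)
    or ``"group_scan"`` (shared by all individuals observed in a session).
    ``correlated_secondary_levels=False`` drops the correlation matrices of
    the scan/litter/group levels (diagonal covariance) for speed.
    """

    variant: str = "M1"
    sex: str = "F"
    reference_category: str = REFERENCE_CATEGORY
    priors: PriorConfig = field(default_factory=PriorConfig)
    sampler: SamplerConfig = field(default_factory=SamplerConfig)
    scan_effect_grain: str = "individual_scan"
    correlated_secondary_levels: bool = True

    def __post_init__(self):
        if self.variant not in ("M1", "M2", "M3"):
            raise ValueError("variant must be one of M1, M2, M3")
        if self.sex not in ("F", "M"):
            raise ValueError("sex must be 'F' or 'M'")
        if self.reference_category not in CATEGORIES:
            raise ValueError(f"unknown reference category {self.reference_category!r}")
        if self.scan_effect_grain not in ("individual_scan", "group_scan"):
            raise ValueError("scan_effect_grain must be individual_scan or group_scan")

    @property
    def fixed_terms(self) -> tuple[str, ...]:
        return () if self.variant == "M1" else FIXED_TERMS

    @property
    def re_levels(self) -> tuple[str, ...]:
        return ("individual",) if self.variant in ("M1", "M2") else M3_LEVELS

    def to_dict(self) -> dict:
        return asdict(self)


# --------------------------------------------------------------------------
# Elementary model operations
# --------------------------------------------------------------------------


def category_probabilities(eta: np.ndarray) -> np.ndarray:
    """Multinomial-logit probabilities from non-reference linear predictors.

    ``eta`` has shape ``(..., 5)``; returns ``(..., 6)`` probabilities in
    :data:`CATEGORIES` order (reference first), computed via log-sum-exp so
    that extreme predictors do not overflow.
    """
    eta = np.asarray(eta, dtype=float)
    if eta.shape[-1] != K:
        raise ValueError(f"eta must have {K} non-reference components")
    full = np.concatenate([np.zeros(eta.shape[:-1] + (1,)), eta], axis=-1)
    return np.exp(full - logsumexp(full, axis=-1, keepdims=True))


def linear_predictors(x, alpha, beta=None, unit_effects=()) -> np.ndarray:
    """Linear predictors eta_k for one covariate row.

    ``x`` is the covariate vector in :attr:`ModelSpec.fixed_terms` order
    (may be empty for M1), ``alpha`` the 5 intercepts, ``beta`` a (P, 5)
    slope matrix, and ``unit_effects`` a sequence of 5-vectors (one per
    active random-effect level). The reference category contributes an
    implicit eta = 0 and is not returned.
    """
    alpha = np.asarray(alpha, dtype=float)
    if alpha.shape != (K,):
        raise ValueError(f"alpha must have shape ({K},)")
    eta = alpha.copy()
    x = np.asarray(x, dtype=float)
    if beta is None:
        if x.size:
            raise ValueError("covariates supplied but beta is None")
    else:
        beta = np.asarray(beta, dtype=float)
        if beta.shape != (x.size, K):
            raise ValueError(
                f"dimension mismatch: x has {x.size} covariates, beta is {beta.shape}"
            )
        eta = eta + x @ beta
    for u in unit_effects:
        u = np.asarray(u, dtype=float)
        if u.shape != (K,):
            raise ValueError(f"unit effects must have shape ({K},)")
        eta = eta + u
    return eta


def noncentred_effects(zeta: np.ndarray, sigma: np.ndarray, L: np.ndarray) -> np.ndarray:
    """Noncentred random effects u = diag(sigma) . L . zeta per unit.

    ``zeta`` is (n_units, 5) standard normal, ``sigma`` the 5 per-category
    SDs, ``L`` the lower-triangular Cholesky factor of the correlation
    matrix. Returns (n_units, 5) effects whose covariance is
    diag(sigma) . L L' . diag(sigma).
    """
    zeta = np.atleast_2d(np.asarray(zeta, dtype=float))
    sigma = np.asarray(sigma, dtype=float)
    L = np.asarray(L, dtype=float)
    if L.shape != (K, K):
        raise ValueError(f"L must be {K}x{K}")
    if not np.allclose(L, np.tril(L)):
        raise ValueError("L must be lower-triangular")
    if np.any(np.diag(L) <= 0):
        raise ValueError("L must have a positive diagonal")
    if sigma.shape != (K,) or np.any(sigma < 0):
        raise ValueError(f"sigma must be {K} nonnegative SDs")
    M = sigma[:, None] * L
    return zeta @ M.T


def event_log_likelihood(eta: np.ndarray, category_idx: np.ndarray) -> np.ndarray:
    """Pointwise log-likelihood of observed categories given eta rows.

    ``eta`` is (n, 5) and ``category_idx`` indexes :data:`CATEGORIES`
    (0 = reference). Returns the n per-event log probabilities.
    """
    eta = np.atleast_2d(np.asarray(eta, dtype=float))
    category_idx = np.asarray(category_idx, dtype=int)
    full = np.concatenate([np.zeros((eta.shape[0], 1)), eta], axis=1)
    lse = logsumexp(full, axis=1)
    return full[np.arange(eta.shape[0]), category_idx] - lse


def log_likelihood(events: pd.DataFrame, params: dict, covariates=None) -> np.ndarray:
    """Per-event log-likelihood under explicit parameter values.

    ``events`` needs columns individual_id and behaviour; ``params`` holds
    ``alpha`` (5,), optionally ``beta`` (P, 5), and optionally per-level unit
    effects ``u_<level>`` as ``{unit_id: 5-vector}``. ``covariates`` (a
    DataFrame indexed like events or keyed by (individual_id, scan_id)) is
    required whenever beta is present.
    """
    alpha = np.asarray(params["alpha"], dtype=float)
    beta = params.get("beta")
    n = len(events)
    eta = np.tile(alpha, (n, 1))
    if beta is not None:
        beta = np.asarray(beta, dtype=float)
        if covariates is None:
            raise ValueError("covariates are required when beta is supplied")
        cov = covariates.set_index(["individual_id", "scan_id"])
        X = cov.loc[
            list(zip(events["individual_id"], events["scan_id"])),
            list(FIXED_TERMS)[: beta.shape[0]],
        ].to_numpy(dtype=float)
        eta = eta + X @ beta
    for level in M3_LEVELS:
        umap = params.get(f"u_{level}")
        if umap is None:
            continue
        key = {"individual": "individual_id", "scan": "scan_id",
               "litter": "litter_id", "group": "group_id"}[level]
        if key not in events.columns:
            raise ValueError(f"events lack column {key} needed for {level} effects")
        missing = set(events[key].unique()) - set(umap)
        if missing:
            raise ValueError(f"events reference unknown {level} units: {sorted(missing)}")
        eta = eta + np.stack([np.asarray(umap[v], dtype=float) for v in events[key]])
    cat_idx = events["behaviour"].map(data_model.category_index).to_numpy()
    return event_log_likelihood(eta, cat_idx)


# --------------------------------------------------------------------------
# Correlation-Cholesky transform (unconstrained z -> L, with LKJ prior)
# --------------------------------------------------------------------------

_CS_H = 1e-20  # complex-step size; exact to machine precision


def _corr_chol_terms(z: np.ndarray, k: int, eta: float):
    """Cholesky factor of a correlation matrix from unconstrained z, plus the
    log prior density.

    The map follows the canonical-partial-correlation construction: hyperbolic
    tangents of z fill L row by row, each entry scaled by the remaining norm.
    Returns ``(L, logdens)`` where ``logdens`` is the (unnormalized) LKJ(eta)
    log density of L plus log|det d L / d z|, so adding it to the target makes
    the prior on L exactly LKJ. Supports batched and complex inputs (for
    complex-step differentiation).
    """
    z = np.asarray(z)
    w = np.tanh(z)
    batch = z.shape[:-1]
    L = np.zeros(batch + (k, k), dtype=z.dtype)
    L[..., 0, 0] = 1.0
    logdens = np.zeros(batch, dtype=z.dtype)
    idx = 0
    for i in range(1, k):
        rem = np.ones(batch, dtype=z.dtype)
        for j in range(i):
            wij = w[..., idx]
            idx += 1
            L[..., i, j] = wij * np.sqrt(rem)
            logdens = logdens + 0.5 * np.log(rem) + np.log(1.0 - wij**2)
            rem = rem - L[..., i, j] ** 2
        L[..., i, i] = np.sqrt(rem)
        # LKJ-Cholesky log density: (k - i - 1 + 2(eta - 1)) * log L_ii
        logdens = logdens + (k - i - 1 + 2.0 * (eta - 1.0)) * 0.5 * np.log(rem)
    return L, logdens


try:  # optional compiled fast path; the numpy implementation is the reference
    import numba as _numba

    @_numba.njit(cache=False)
    def _corr_chol_terms_jit(Z, k, eta):  # pragma: no cover - numerics mirror
        B, m = Z.shape
        L = np.zeros((B, k, k), dtype=np.complex128)
        logdens = np.zeros(B, dtype=np.complex128)
        for b in range(B):
            L[b, 0, 0] = 1.0
            idx = 0
            for i in range(1, k):
                rem = 1.0 + 0j
                for j in range(i):
                    w = np.tanh(Z[b, idx])
                    idx += 1
                    L[b, i, j] = w * np.sqrt(rem)
                    logdens[b] += 0.5 * np.log(rem) + np.log(1.0 - w * w)
                    rem -= L[b, i, j] * L[b, i, j]
                L[b, i, i] = np.sqrt(rem)
                logdens[b] += (k - i - 1 + 2.0 * (eta - 1.0)) * 0.5 * np.log(rem)
        return L, logdens

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False


def _corr_transform_with_grads(z: np.ndarray, k: int, eta: float):
    """L(z), prior term f(z), df/dz and the Jacobian dL/dz via complex step."""
    m = z.size
    Z = z[None, :] + 1j * _CS_H * np.eye(m)
    if _HAVE_NUMBA:
        L_b, f_b = _corr_chol_terms_jit(np.ascontiguousarray(Z), k, float(eta))
    else:
        L_b, f_b = _corr_chol_terms(Z, k, eta)
    L = L_b[0].real
    f = float(f_b[0].real)
    df_dz = f_b.imag / _CS_H
    J = L_b.imag / _CS_H  # (m, k, k)
    return L, f, df_dz, J


# --------------------------------------------------------------------------
# Joint posterior density with analytic gradient
# --------------------------------------------------------------------------


class _PosteriorDensity:
    """Log posterior and gradient on the unconstrained parameter vector.

    Data enter as per-row multinomial counts ``Y`` (rows x 6, reference
    category in column 0), fixed-effect design ``X`` (rows x P) and, per
    random-effect level, an integer unit index per row.

    Unconstrained layout: alpha (5) | beta (P*5) | per level:
    log sigma (5), z_corr (10, if correlated), zeta (n_units*5).
    """

    def __init__(
        self,
        Y: np.ndarray,
        X: np.ndarray,
        level_index: dict[str, np.ndarray],
        priors: PriorConfig,
        correlated: dict[str, bool] | None = None,
        likelihood_weight: float = 1.0,
    ):
        self.Y = np.asarray(Y, dtype=float)
        if self.Y.ndim != 2 or self.Y.shape[1] != K + 1:
            raise ValueError(f"Y must be (rows, {K + 1})")
        self.Yk = self.Y[:, 1:]
        self.N = self.Y.sum(axis=1)
        self.X = np.asarray(X, dtype=float)
        self.P = self.X.shape[1] if self.X.size else 0
        self.levels = list(level_index)
        self.index = {lv: np.asarray(ix, dtype=int) for lv, ix in level_index.items()}
        self.n_units = {lv: int(ix.max()) + 1 if ix.size else 0
                        for lv, ix in self.index.items()}
        self.priors = priors
        self.correlated = {lv: True for lv in self.levels}
        if correlated:
            self.correlated.update(correlated)
        self.w = float(likelihood_weight)

        offset = K + self.P * K
        self.slices: dict[str, dict[str, slice]] = {}
        for lv in self.levels:
            sl = {"log_sigma": slice(offset, offset + K)}
            offset += K
            if self.correlated[lv]:
                sl["z_corr"] = slice(offset, offset + N_CORR)
                offset += N_CORR
            sl["zeta"] = slice(offset, offset + self.n_units[lv] * K)
            offset += self.n_units[lv] * K
            self.slices[lv] = sl
        self.dim = offset

    # -- parameter access ---------------------------------------------------

    def unpack(self, theta: np.ndarray) -> dict:
        out = {
            "alpha": theta[:K],
            "beta": theta[K : K + self.P * K].reshape(self.P, K),
        }
        for lv in self.levels:
            sl = self.slices[lv]
            out[f"log_sigma_{lv}"] = theta[sl["log_sigma"]]
            if self.correlated[lv]:
                out[f"z_corr_{lv}"] = theta[sl["z_corr"]]
            out[f"zeta_{lv}"] = theta[sl["zeta"]].reshape(self.n_units[lv], K)
        return out

    def constrained(self, theta: np.ndarray) -> dict:
        """Natural-scale parameters (sigma, L, Omega, u) for one draw."""
        p = self.unpack(theta)
        out = {"alpha": p["alpha"].copy(), "beta": p["beta"].copy()}
        for lv in self.levels:
            sigma = np.exp(p[f"log_sigma_{lv}"])
            if self.correlated[lv]:
                L, _ = _corr_chol_terms(p[f"z_corr_{lv}"], K, self.priors.lkj_eta)
            else:
                L = np.eye(K)
            out[f"sigma_{lv}"] = sigma
            out[f"L_{lv}"] = L
            out[f"corr_{lv}"] = L @ L.T
            out[f"u_{lv}"] = noncentred_effects(p[f"zeta_{lv}"], sigma, L)
        return out

    def eta(self, con: dict) -> np.ndarray:
        eta = np.tile(con["alpha"], (self.Y.shape[0], 1))
        if self.P:
            eta += self.X @ con["beta"]
        for lv in self.levels:
            eta += con[f"u_{lv}"][self.index[lv]]
        return eta

    def pointwise_loglik(self, con: dict) -> np.ndarray:
        """Per-row multinomial log-likelihood (multinomial coefficient
        dropped; it is constant across parameters and model variants)."""
        eta = self.eta(con)
        full = np.concatenate([np.zeros((eta.shape[0], 1)), eta], axis=1)
        lse = logsumexp(full, axis=1)
        return (self.Yk * eta).sum(axis=1) - self.N * lse

    # -- density ------------------------------------------------------------

    def logp_grad(self, theta: np.ndarray) -> tuple[float, np.ndarray]:
        pr = self.priors
        grad = np.zeros_like(theta)
        alpha = theta[:K]
        beta = theta[K : K + self.P * K].reshape(self.P, K)

        # build L, sigma, u per level (keeping transform grads for later)
        level_data = {}
        if self.P:
            eta = self.X @ beta
            eta += alpha
        else:
            eta = np.broadcast_to(alpha, (self.Y.shape[0], K)).copy()
        lp = 0.0
        for lv in self.levels:
            sl = self.slices[lv]
            log_sigma = theta[sl["log_sigma"]]
            sigma = np.exp(log_sigma)
            zeta = theta[sl["zeta"]].reshape(self.n_units[lv], K)
            if self.correlated[lv]:
                z = theta[sl["z_corr"]]
                L, f, df_dz, Jz = _corr_transform_with_grads(z, K, pr.lkj_eta)
                lp += f
            else:
                L, df_dz, Jz = np.eye(K), None, None
            M = sigma[:, None] * L
            U = zeta @ M.T
            eta += U[self.index[lv]]
            level_data[lv] = (log_sigma, sigma, zeta, L, M, df_dz, Jz)
            # priors: sigma ~ Exp(rate) with log-jacobian, zeta ~ N(0,1)
            lp += float(np.sum(-pr.sd_rate * sigma + log_sigma))
            lp += -0.5 * float(np.sum(zeta**2))

        # likelihood (stable softmax; exponentials computed once)
        m = np.maximum(eta.max(axis=1), 0.0)
        E = np.exp(eta - m[:, None])
        sumexp = np.exp(-m) + E.sum(axis=1)
        lse = m + np.log(sumexp)
        lp += self.w * (float(np.einsum("rk,rk->", self.Yk, eta)) - float(self.N @ lse))
        p = E / sumexp[:, None]
        G = self.w * (self.Yk - self.N[:, None] * p)  # d loglik / d eta

        # priors on alpha, beta
        lp += -0.5 * float(np.sum(alpha**2)) / pr.intercept_scale**2
        lp += -0.5 * float(np.sum(beta**2)) / pr.beta_scale**2
        grad[:K] = G.sum(axis=0) - alpha / pr.intercept_scale**2
        if self.P:
            grad[K : K + self.P * K] = (self.X.T @ G - beta / pr.beta_scale**2).ravel()

        for lv in self.levels:
            sl = self.slices[lv]
            log_sigma, sigma, zeta, L, M, df_dz, Jz = level_data[lv]
            dU = np.zeros((self.n_units[lv], K))
            np.add.at(dU, self.index[lv], G)
            grad[sl["zeta"]] = (dU @ M - zeta).ravel()
            dM = dU.T @ zeta  # (K, K)
            dsigma = (dM * L).sum(axis=1)
            grad[sl["log_sigma"]] = dsigma * sigma + (1.0 - pr.sd_rate * sigma)
            if self.correlated[lv]:
                dL = sigma[:, None] * dM
                grad[sl["z_corr"]] = np.einsum("mab,ab->m", Jz, dL) + df_dz
        return lp, grad


# --------------------------------------------------------------------------
# Event aggregation and design building
# --------------------------------------------------------------------------


def aggregate_counts(events: pd.DataFrame, covariates: pd.DataFrame) -> pd.DataFrame:
    """Collapse events to per-(individual, scan) category counts aligned with
    covariate rows; returns the covariate table with count columns
    ``n_<category>`` appended."""
    counts = (
        events.groupby(["individual_id", "scan_id"])["behaviour"]
        .value_counts()
        .unstack(fill_value=0)
        .reindex(columns=list(CATEGORIES), fill_value=0)
    )
    counts.columns = [f"n_{c}" for c in counts.columns]
    counts = counts.reset_index()
    merged = covariates.merge(counts, on=["individual_id", "scan_id"], how="inner")
    # every observed pair of an individual in the covariate table must match
    relevant = counts[counts["individual_id"].isin(covariates["individual_id"])]
    if len(merged) < len(relevant):
        raise ValueError(
            "some observed (individual, scan) pairs have no covariate row"
        )
    return merged


# --------------------------------------------------------------------------
# Posterior container
# --------------------------------------------------------------------------


@dataclass
class PosteriorResult:
    """Posterior draws plus metadata from one fitted MMBM.

    ``draws`` maps parameter names to arrays indexed (chain, draw, ...):
    ``alpha`` (5,), ``beta`` (P, 5), and per level ``sigma_<level>`` (5,),
    ``corr_<level>`` (5, 5) and ``u_<level>`` (n_units, 5). ``log_lik`` holds
    the pointwise log-likelihood per (individual, scan) row. ``rhat`` is the
    split-R-hat per scalar parameter block; ``divergences`` counts post-warmup
    divergent transitions per chain.
    """

    spec: ModelSpec
    categories: tuple[str, ...]
    draws: dict[str, np.ndarray]
    log_lik: np.ndarray
    rhat: dict[str, float]
    divergences: list[int]
    unit_labels: dict[str, list]
    scaling: dict = field(default_factory=dict)
    ranges: dict = field(default_factory=dict)

    @property
    def n_chains(self) -> int:
        return self.draws["alpha"].shape[0]

    @property
    def n_draws(self) -> int:
        return self.draws["alpha"].shape[1]

    def stacked(self, name: str) -> np.ndarray:
        """Draws for one parameter with chains flattened."""
        a = self.draws[name]
        return a.reshape((-1,) + a.shape[2:])

    def to_inference_data(self):
        """Export to an :class:`arviz.InferenceData` (posterior + log_lik)."""
        import arviz as az

        return az.from_dict(
            posterior={k: v for k, v in self.draws.items()},
            log_likelihood={"obs": self.log_lik},
        )

    def save(self, path) -> None:
        """Write draws (npz) with a JSON sidecar of spec and diagnostics."""
        path = str(path)
        np.savez_compressed(path if path.endswith(".npz") else path + ".npz",
                            log_lik=self.log_lik,
                            **{k: v for k, v in self.draws.items()})
        meta = {
            "spec": self.spec.to_dict(),
            "categories": list(self.categories),
            "rhat": self.rhat,
            "divergences": self.divergences,
            "unit_labels": {k: [str(x) for x in v] for k, v in self.unit_labels.items()},
            "scaling": self.scaling,
            "ranges": self.ranges,
        }
        with open((path[:-4] if path.endswith(".npz") else path) + ".json", "w") as fh:
            json.dump(meta, fh)

    @classmethod
    def load(cls, path) -> "PosteriorResult":
        path = str(path)
        base = path[:-4] if path.endswith(".npz") else path
        arrays = dict(np.load(base + ".npz"))
        log_lik = arrays.pop("log_lik")
        with open(base + ".json") as fh:
            meta = json.load(fh)
        spec_d = meta["spec"]
        spec = ModelSpec(
            variant=spec_d["variant"],
            sex=spec_d["sex"],
            reference_category=spec_d["reference_category"],
            priors=PriorConfig(**spec_d["priors"]),
            sampler=SamplerConfig(**spec_d["sampler"]),
            scan_effect_grain=spec_d["scan_effect_grain"],
            correlated_secondary_levels=spec_d["correlated_secondary_levels"],
        )
        return cls(
            spec=spec,
            categories=tuple(meta["categories"]),
            draws=arrays,
            log_lik=log_lik,
            rhat=meta["rhat"],
            divergences=meta["divergences"],
            unit_labels=meta["unit_labels"],
            scaling=meta["scaling"],
            ranges=meta["ranges"],
        )


# --------------------------------------------------------------------------
# Fitting
# --------------------------------------------------------------------------


def _level_key(level: str, grain: str) -> str:
    return {
        "individual": "individual_id",
        "scan": "scan_id" if grain == "group_scan" else "__row__",
        "litter": "litter_id",
        "group": "group_id",
    }[level]


def fit(
    spec: ModelSpec,
    events: pd.DataFrame,
    covariates,
    likelihood_weight: float = 1.0,
    progress: bool = False,
) -> PosteriorResult:
    """Fit one MMBM variant by NUTS.

    Parameters
    ----------
    spec : the model variant/sex/prior/sampler specification.
    events : long-format sampling events (individual_id, scan_id, behaviour).
    covariates : a :class:`mmbm.data_model.Covariates` or its table; rows for
        the requested sex are selected automatically.
    likelihood_weight : multiplies the log-likelihood (0 gives a
        prior-predictive run; used for prior checks).

    Raises a warning (not an error) if any split-R-hat exceeds 1.05.
    """
    cov_obj = covariates
    table = covariates.table if isinstance(covariates, data_model.Covariates) else covariates
    scaling = cov_obj.scaling.get(spec.sex, {}) if isinstance(cov_obj, data_model.Covariates) else {}
    ranges = cov_obj.ranges.get(spec.sex, {}) if isinstance(cov_obj, data_model.Covariates) else {}
    if "sex" in table.columns:
        table = table[table["sex"] == spec.sex]
    if table.empty:
        raise ValueError(f"no covariate rows for sex {spec.sex!r}")

    rows = aggregate_counts(events, table)
    Y = rows[[f"n_{c}" for c in CATEGORIES]].to_numpy(dtype=float)
    X = (
        rows[list(spec.fixed_terms)].to_numpy(dtype=float)
        if spec.fixed_terms
        else np.empty((len(rows), 0))
    )

    level_index = {}
    unit_labels = {}
    for lv in spec.re_levels:
        key = _level_key(lv, spec.scan_effect_grain)
        if key == "__row__":
            codes = np.arange(len(rows))
            labels = [f"{i}:{s}" for i, s in zip(rows["individual_id"], rows["scan_id"])]
        else:
            cat = pd.Categorical(rows[key])
            codes = cat.codes.astype(int)
            labels = list(cat.categories)
        level_index[lv] = codes
        unit_labels[lv] = labels
        if lv == "litter" and len(labels) < 2:
            warnings.warn(
                "only one litter in the data; the litter-level variance is "
                "weakly identified",
                stacklevel=2,
            )

    correlated = {lv: True for lv in spec.re_levels}
    if not spec.correlated_secondary_levels:
        for lv in spec.re_levels:
            if lv != "individual":
                correlated[lv] = False

    density = _PosteriorDensity(
        Y, X, level_index, spec.priors, correlated, likelihood_weight
    )

    sc = spec.sampler
    n_keep, n_warm = sc.n_keep, sc.n_warmup
    seed_seq = np.random.SeedSequence(sc.seed)
    chain_draws = []
    divergences = []
    for c, child in enumerate(seed_seq.spawn(sc.chains)):
        rng = np.random.default_rng(child)
        theta0 = 0.1 * rng.standard_normal(density.dim)
        draws, stats = nuts(
            density.logp_grad,
            theta0,
            n_samples=n_keep,
            warmup=n_warm,
            rng=rng,
            target_accept=sc.target_accept,
            max_treedepth=sc.max_treedepth,
        )
        if progress:  # pragma: no cover - console feedback only
            print(
                f"chain {c + 1}/{sc.chains}: step={stats.step_size:.3g} "
                f"accept={stats.mean_accept:.2f} divergent={stats.divergences}"
            )
        chain_draws.append(draws)
        divergences.append(stats.divergences)
    if all(d >= n_keep for d in divergences):
        raise RuntimeError(
            f"sampler failure: every post-warmup transition diverged "
            f"(divergences per chain: {divergences})"
        )

    # constrain draws and collect outputs
    P = density.P
    out = {
        "alpha": np.empty((sc.chains, n_keep, K)),
        "beta": np.empty((sc.chains, n_keep, P, K)),
    }
    for lv in spec.re_levels:
        out[f"sigma_{lv}"] = np.empty((sc.chains, n_keep, K))
        out[f"corr_{lv}"] = np.empty((sc.chains, n_keep, K, K))
        out[f"u_{lv}"] = np.empty((sc.chains, n_keep, density.n_units[lv], K))
    log_lik = np.empty((sc.chains, n_keep, Y.shape[0]))
    for c in range(sc.chains):
        for d in range(n_keep):
            con = density.constrained(chain_draws[c][d])
            out["alpha"][c, d] = con["alpha"]
            out["beta"][c, d] = con["beta"]
            for lv in spec.re_levels:
                out[f"sigma_{lv}"][c, d] = con[f"sigma_{lv}"]
                out[f"corr_{lv}"][c, d] = con[f"corr_{lv}"]
                out[f"u_{lv}"][c, d] = con[f"u_{lv}"]
            log_lik[c, d] = density.pointwise_loglik(con)

    rhat = _split_rhat(out, spec)
    worst = max(rhat.values()) if rhat else 1.0
    if worst > 1.05:
        warnings.warn(
            f"convergence warning: max split-R-hat = {worst:.3f} > 1.05; "
            "consider more iterations",
            stacklevel=2,
        )

    return PosteriorResult(
        spec=spec,
        categories=CATEGORIES,
        draws=out,
        log_lik=log_lik,
        rhat=rhat,
        divergences=divergences,
        unit_labels=unit_labels,
        scaling=scaling,
        ranges=ranges,
    )


def _split_rhat(draws: dict[str, np.ndarray], spec: ModelSpec) -> dict[str, float]:
    """Max split-R-hat per scalar parameter block (via arviz)."""
    import arviz as az

    if draws["alpha"].shape[0] < 2:
        return {}  # R-hat needs at least two chains
    subset = {"alpha": draws["alpha"]}
    if draws["beta"].shape[2]:
        subset["beta"] = draws["beta"]
    for lv in spec.re_levels:
        subset[f"sigma_{lv}"] = draws[f"sigma_{lv}"]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rh = az.rhat(az.from_dict(posterior=subset))
    out = {}
    for name in subset:
        vals = np.asarray(rh[name]).ravel()
        vals = vals[np.isfinite(vals)]
        if vals.size:
            out[name] = float(np.max(vals))
    return out
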