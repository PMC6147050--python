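"""Derived quantities from fitted MMBMs.

* WAIC for relative model fit (used as a general indicator, not a selection
  tool, since each variant answers a different question);
* posterior summaries of the within-individual random-effect correlations
  with the credible-interval significance rule — the task-specialization
  test: specialization requires a significantly *negative* correlation
  between two cooperative behaviours;
* fixed-effects-only predicted-probability curves over a covariate grid;
* draw-wise contrasts for the binary pup-presence covariate.

"Significant" throughout means the equal-tailed 95% credible interval
excludes zero. Curve bands are 89% percentile intervals.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from itertools import combinations

import numpy as np
import pandas as pd

from .data_model import (
    COOPERATIVE_CATEGORIES,
    FIXED_TERMS,
    NONREFERENCE_CATEGORIES,
)
from .mmbm_core import PosteriorResult, category_probabilities

K = len(NONREFERENCE_CATEGORIES)


# --------------------------------------------------------------------------
# WAIC
# --------------------------------------------------------------------------


@dataclass
class WaicResult:
    """Widely applicable information criterion: waic = -2 (lppd - p_waic)."""

    lppd: float
    p_waic: float
    waic: float
    se: float
    pointwise: np.ndarray = field(repr=False, default=None)


def waic(pointwise_loglik) -> WaicResult:
    """WAIC from a draws x observations pointwise log-likelihood array.

    Accepts (draws, obs) or (chain, draw, obs); chains are flattened. The
    log pointwise predictive density uses log-sum-exp over draws; the
    effective parameter count is the sum of pointwise posterior variances of
    the log-likelihood; the standard error comes from the dispersion of the
    pointwise WAIC contributions.
    """
    ll = np.asarray(pointwise_loglik, dtype=float)
    if ll.ndim == 3:
        ll = ll.reshape(-1, ll.shape[-1])
    if ll.ndim != 2:
        raise ValueError("pointwise log-likelihood must be (draws, obs) or (chain, draw, obs)")
    S, n = ll.shape
    if S < 2:
        raise ValueError("WAIC needs at least 2 draws (pointwise variance is undefined)")
    if not np.all(np.isfinite(ll)):
        raise ValueError("pointwise log-likelihood contains non-finite values")
    from scipy.special import logsumexp

    lppd_i = logsumexp(ll, axis=0) - np.log(S)
    p_i = ll.var(axis=0, ddof=1)
    waic_i = -2.0 * (lppd_i - p_i)
    se = float(np.sqrt(n * np.var(waic_i, ddof=1))) if n > 1 else 0.0
    return WaicResult(
        lppd=float(lppd_i.sum()),
        p_waic=float(p_i.sum()),
        waic=float(waic_i.sum()),
        se=se,
        pointwise=waic_i,
    )


def waic_table(results: dict[str, PosteriorResult]) -> pd.DataFrame:
    """WAIC comparison across fitted variants, sorted ascending with deltas."""
    rows = []
    for name, res in results.items():
        w = waic(res.log_lik)
        rows.append({"model": name, "waic": w.waic, "se": w.se,
                     "lppd": w.lppd, "p_waic": w.p_waic})
    df = pd.DataFrame(rows).sort_values("waic", kind="stable").reset_index(drop=True)
    df["delta_waic"] = df["waic"] - df["waic"].iloc[0]
    return df


# --------------------------------------------------------------------------
# Random-effect correlations & the specialization test
# --------------------------------------------------------------------------


@dataclass
class CorrelationSummary:
    """Posterior summary of one behaviour-pair random-effect correlation."""

    level: str
    pair: tuple[str, str]
    mean: float
    sd: float
    cri_low: float
    cri_high: float
    significant: bool

    @property
    def is_cooperative_pair(self) -> bool:
        return all(c in COOPERATIVE_CATEGORIES for c in self.pair)

    def formatted(self) -> str:
        """Table-style rendering: mean (SD), bolded when significant."""
        s = f"{self.mean:.2f} ({self.sd:.2f})"
        return f"**{s}**" if self.significant else s


def summarize_correlations(
    posterior: PosteriorResult, level: str = "individual", cri: float = 0.95
) -> list[CorrelationSummary]:
    """Posterior mean, SD and credible interval for each of the 10 pairs of
    non-reference behaviours at one random-effect level.

    Correlations are taken directly from the draw-wise correlation matrices
    (not from correlating point estimates of the unit effects, which inflates
    them). Pairs involving the reference category are not estimable in this
    parameterization and are not reported. A pair is flagged significant when
    its equal-tailed credible interval excludes zero.
    """
    key = f"corr_{level}"
    if key not in posterior.draws:
        raise ValueError(
            f"level {level!r} has no correlation draws in this model variant "
            f"({posterior.spec.variant})"
        )
    draws = posterior.stacked(key)  # (S, K, K)
    lo_q, hi_q = (1 - cri) / 2, 1 - (1 - cri) / 2
    out = []
    for i, j in combinations(range(K), 2):
        r = draws[:, i, j]
        lo, hi = np.quantile(r, [lo_q, hi_q])
        out.append(
            CorrelationSummary(
                level=level,
                pair=(NONREFERENCE_CATEGORIES[i], NONREFERENCE_CATEGORIES[j]),
                mean=float(r.mean()),
                sd=float(r.std(ddof=1)),
                cri_low=float(lo),
                cri_high=float(hi),
                significant=bool(lo > 0 or hi < 0),
            )
        )
    return out


def correlations_frame(summaries: list[CorrelationSummary]) -> pd.DataFrame:
    """Correlation summaries as a flat table (one row per pair)."""
    return pd.DataFrame(
        [
            {
                "level": s.level,
                "category_a": s.pair[0],
                "category_b": s.pair[1],
                "mean": s.mean,
                "sd": s.sd,
                "cri_low": s.cri_low,
                "cri_high": s.cri_high,
                "significant": s.significant,
            }
            for s in summaries
        ]
    )


def correlation_matrix_table(
    upper: list[CorrelationSummary], lower: list[CorrelationSummary] | None = None
) -> pd.DataFrame:
    """Render correlations as a matrix of "mean (SD)" strings.

    ``upper`` fills the upper triangle and ``lower`` (e.g. a second model
    variant) the lower one, the layout used for side-by-side reporting of the
    intercepts-only and covariate-adjusted models.
    """
    cats = list(NONREFERENCE_CATEGORIES)
    tab = pd.DataFrame("", index=cats, columns=cats)
    for s in upper:
        tab.loc[s.pair[0], s.pair[1]] = s.formatted()
    for s in lower or []:
        tab.loc[s.pair[1], s.pair[0]] = s.formatted()
    return tab


@dataclass
class SpecializationReport:
    """Verdict of the task-specialization test.

    Specialization (a caste-like trade-off) is detected iff some pair of
    cooperative behaviours has a significantly negative within-individual
    correlation; otherwise the sign pattern of the cooperative pairs is
    reported.
    """

    detected: bool
    verdict: str
    negative_significant_pairs: list
    positive_significant_pairs: list
    cooperative_pattern: dict

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


def specialization_verdict(summaries: list[CorrelationSummary]) -> SpecializationReport:
    """Apply the trade-off rule to individual-level correlation summaries."""
    coop = [s for s in summaries if s.is_cooperative_pair]
    neg = [s.pair for s in coop if s.significant and s.mean < 0]
    pos = [s.pair for s in coop if s.significant and s.mean > 0]
    pattern = {
        " x ".join(s.pair): {
            "mean": s.mean,
            "significant": s.significant,
            "sign": "negative" if s.mean < 0 else "positive",
        }
        for s in coop
    }
    if neg:
        verdict = (
            "specialization detected: significantly negative correlation(s) "
            "between cooperative behaviours: "
            + ", ".join(" x ".join(p) for p in neg)
        )
    elif pos and len(pos) == len(coop):
        verdict = (
            "no specialization; generalist helpers (all cooperative pairs "
            "significantly positive)"
        )
    else:
        verdict = (
            "no specialization detected; cooperative pair signs: "
            + ", ".join(f"{k}: {v['sign']}" for k, v in pattern.items())
        )
    return SpecializationReport(
        detected=bool(neg),
        verdict=verdict,
        negative_significant_pairs=[list(p) for p in neg],
        positive_significant_pairs=[list(p) for p in pos],
        cooperative_pattern=pattern,
    )


# --------------------------------------------------------------------------
# Predicted probabilities and contrasts (fixed effects only)
# --------------------------------------------------------------------------

#: focal covariate -> (z-scored model columns, powers of the base z value)
_FOCAL_TERMS = {
    "age": (("age_z", 1), ("age_z2", 2), ("age_z3", 3)),
    "group_size": (("groupsize_z", 1), ("groupsize_z2", 2)),
    "relative_mass": (("relative_mass_z", 1),),
}


@dataclass
class PredictedCurves:
    """Per-category posterior-mean probability curves with percentile bands.

    ``grid`` is on the original covariate scale; ``mean``, ``low`` and
    ``high`` have shape (grid, 6) in category order.
    """

    focal: str
    grid: np.ndarray
    grid_z: np.ndarray
    mean: np.ndarray
    low: np.ndarray
    high: np.ndarray
    categories: tuple[str, ...]
    cri: float

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for gi, g in enumerate(self.grid):
            for ci, cat in enumerate(self.categories):
                rows.append(
                    {
                        "focal": self.focal,
                        "value": float(g),
                        "category": cat,
                        "mean": float(self.mean[gi, ci]),
                        "low": float(self.low[gi, ci]),
                        "high": float(self.high[gi, ci]),
                    }
                )
        return pd.DataFrame(rows)


def _draw_probabilities(posterior: PosteriorResult, Xgrid: np.ndarray) -> np.ndarray:
    """(S, grid, 6) fixed-effects-only probabilities per posterior draw."""
    alpha = posterior.stacked("alpha")  # (S, K)
    beta = posterior.stacked("beta")  # (S, P, K)
    eta = alpha[:, None, :] + np.einsum("gp,spk->sgk", Xgrid, beta)
    return category_probabilities(eta)


def predicted_probabilities(
    posterior: PosteriorResult,
    focal: str,
    grid: np.ndarray | None = None,
    n_grid: int = 50,
    cri: float = 0.89,
) -> PredictedCurves:
    """Predicted category probabilities along one covariate, from the fixed
    effects only (random effects excluded), all other covariates held at
    their sample mean (zero on the z scale; pups absent).

    ``focal`` is "age", "group_size" or "relative_mass". The default grid is
    50 even points over the observed covariate range, reported back on the
    original scale.
    """
    if posterior.draws["beta"].shape[2] == 0:
        raise ValueError("model variant has no fixed effects (M1); fit M2 or M3")
    if focal not in _FOCAL_TERMS:
        raise ValueError(f"focal covariate must be one of {sorted(_FOCAL_TERMS)}")
    terms = _FOCAL_TERMS[focal]
    if grid is None:
        if focal not in posterior.ranges:
            raise ValueError(f"no observed range recorded for {focal!r}; pass grid=")
        lo, hi = posterior.ranges[focal]
        grid = np.linspace(lo, hi, n_grid)
    grid = np.asarray(grid, dtype=float)
    if focal in posterior.scaling:
        mean, sd = posterior.scaling[focal]
        grid_z = (grid - mean) / sd
    else:  # no scaling recorded: treat the grid as already z-scored
        grid_z = grid.copy()

    Xgrid = np.zeros((grid.size, len(FIXED_TERMS)))
    for col, power in terms:
        Xgrid[:, FIXED_TERMS.index(col)] = grid_z**power

    probs = _draw_probabilities(posterior, Xgrid)  # (S, G, 6)
    lo_q, hi_q = (1 - cri) / 2, 1 - (1 - cri) / 2
    return PredictedCurves(
        focal=focal,
        grid=grid,
        grid_z=grid_z,
        mean=probs.mean(axis=0),
        low=np.quantile(probs, lo_q, axis=0),
        high=np.quantile(probs, hi_q, axis=0),
        categories=posterior.categories,
        cri=cri,
    )


@dataclass
class ContrastResult:
    """Draw-wise predicted-probability contrast for a binary fixed effect."""

    factor: str
    categories: tuple[str, ...]
    draws: np.ndarray  # (S, 6) probability differences (level 1 - level 0)
    mean: np.ndarray
    cri_low: np.ndarray
    cri_high: np.ndarray
    significant: np.ndarray  # per category: 95% CrI excludes 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "category": self.categories,
                "mean": self.mean,
                "cri_low": self.cri_low,
                "cri_high": self.cri_high,
                "significant": self.significant,
            }
        )


def categorical_contrast(
    posterior: PosteriorResult, factor: str = "pups_present", cri: float = 0.95
) -> ContrastResult:
    """Contrast of fixed-effects predicted probabilities between the two
    levels of a binary covariate, evaluated draw by draw.

    For each posterior draw the six category probabilities are computed at
    factor = 1 and factor = 0 (all other covariates at their sample mean) and
    differenced; significance uses the draw-wise distribution of contrasts
    rather than overlapping prediction intervals.
    """
    if posterior.draws["beta"].shape[2] == 0:
        raise ValueError("model variant has no fixed effects (M1); fit M2 or M3")
    if factor not in FIXED_TERMS:
        raise ValueError(f"factor {factor!r} is not a model fixed effect")
    X = np.zeros((2, len(FIXED_TERMS)))
    X[1, FIXED_TERMS.index(factor)] = 1.0
    probs = _draw_probabilities(posterior, X)  # (S, 2, 6)
    diff = probs[:, 1, :] - probs[:, 0, :]
    lo_q, hi_q = (1 - cri) / 2, 1 - (1 - cri) / 2
    lo = np.quantile(diff, lo_q, axis=0)
    hi = np.quantile(diff, hi_q, axis=0)
    return ContrastResult(
        factor=factor,
        categories=posterior.categories,
        draws=diff,
        mean=diff.mean(axis=0),
        cri_low=lo,
        cri_high=hi,
        significant=(lo > 0) | (hi < 0),
    )


# --------------------------------------------------------------------------
# Optional plotting
# --------------------------------------------------------------------------


def plot_predicted_curves(curves: PredictedCurves, path=None):
    """Plot per-category probability curves with their percentile bands."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4.5))
    for ci, cat in enumerate(curves.categories):
        (line,) = ax.plot(curves.grid, curves.mean[:, ci], label=cat)
        ax.fill_between(
            curves.grid, curves.low[:, ci], curves.high[:, ci],
            alpha=0.2, color=line.get_color(),
        )
    ax.set_xlabel(curves.focal)
    ax.set_ylabel("predicted probability")
    ax.legend(fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
        plt.close(fig)
    return fig
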