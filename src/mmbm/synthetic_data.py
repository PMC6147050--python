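"""Synthetic scan-sampling datasets from a known ground-truth MMBM.

The generator emulates the captive mole-rat study design: 35 groups holding
60 nonreproductive females and 56 nonreproductive males (plus a breeding pair
per group), observed in 12 h scan sessions every ~64 days; each individual is
observed in 10 sessions, entering observation at ~136 days old and leaving at
~716 days; 180 sampling events per individual per session. Body masses follow
the log-log growth model with a group-level intercept. Events are drawn from
the multinomial-logit model given fixed effects on the z-scored covariates
and correlated random effects per individual (and optionally per scan, litter
and group), so every downstream stage can be tested against known truth.

Scenario presets encode qualitatively different social organisations:

* ``no_specialization`` - positively correlated individual effects across the
  nonresting behaviours with a shared hump-shaped age trajectory (generalist
  helpers whose overall commitment changes with age);
* ``temporal_caste`` - age-behaviour trajectories that cross (different
  behaviours peak at different ages) with near-zero correlations;
* ``permanent_caste`` - a strong negative correlation between work and food
  carrying (a developmental trade-off between cooperative tasks);
* ``null`` - no fixed effects and uncorrelated individual effects.

Events are conditionally independent given the random effects; real
behavioural sequences are autocorrelated within a scan, which this generator
(like the fitted model) deliberately ignores.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import data_model
from .data_model import (
    CATEGORIES,
    EVENTS_PER_SCAN,
    FIXED_TERMS,
    NONREFERENCE_CATEGORIES,
    PUP_AGE_DAYS,
)
from .relative_mass import RelativeMassFit

K = len(NONREFERENCE_CATEGORIES)
RE_LEVELS = ("individual", "scan", "litter", "group")

SCENARIOS = ("no_specialization", "temporal_caste", "permanent_caste", "null")

_COOP_IDX = tuple(
    NONREFERENCE_CATEGORIES.index(c) for c in ("food_carry", "nest_building", "work")
)

# Default time-budget intercepts: rest ~40%, active ~20%, eat ~10%,
# food carry ~5%, nest build ~5%, work ~20% (log odds vs rest).
_DEFAULT_INTERCEPTS = (
    np.log(0.20 / 0.40),
    np.log(0.10 / 0.40),
    np.log(0.05 / 0.40),
    np.log(0.05 / 0.40),
    np.log(0.20 / 0.40),
)


def _compound_corr(rho: float) -> np.ndarray:
    m = np.full((K, K), rho)
    np.fill_diagonal(m, 1.0)
    return m


def _betas(rows: dict[str, list[float]]) -> np.ndarray:
    """Fixed-effect matrix (7 covariates x 5 categories) from sparse rows."""
    B = np.zeros((len(FIXED_TERMS), K))
    for term, vals in rows.items():
        B[FIXED_TERMS.index(term)] = vals
    return B


# columns: active_nonhelping, eat, food_carry, nest_building, work
_NO_SPEC_BETAS = _betas(
    {
        "age_z": [0.4, 0.0, 0.8, 0.8, 0.8],
        "age_z2": [-0.3, 0.0, -0.6, -0.6, -0.6],
        "groupsize_z": [0.15, 0.0, 0.1, 0.1, 0.2],
        "groupsize_z2": [0.0, 0.0, 0.0, 0.0, -0.1],
        "relative_mass_z": [0.0, 0.0, 0.3, -0.2, 0.4],
    }
)

# crossing age trajectories: nest building peaks early, food carrying mid,
# work late in the observed age range
_TEMPORAL_BETAS = _betas(
    {
        "age_z": [0.3, 0.0, 0.0, -1.2, 1.2],
        "age_z2": [-0.2, 0.0, -0.6, -0.6, -0.6],
        "relative_mass_z": [0.0, 0.0, 0.2, 0.0, 0.2],
    }
)

_PERMANENT_BETAS = _betas(
    {
        "age_z": [0.3, 0.0, 0.2, 0.2, 0.2],
        "age_z2": [-0.2, 0.0, -0.1, -0.1, -0.1],
    }
)


def scenario_preset(name: str) -> dict:
    """TruthConfig overrides for a named social-organisation scenario."""
    if name not in SCENARIOS:
        raise ValueError(f"unknown scenario {name!r}; valid scenarios: {SCENARIOS}")
    sd = {
        "individual": (0.4, 0.3, 0.8, 0.9, 0.5),
        "scan": (0.3,) * K,
        "litter": (0.2,) * K,
        "group": (0.2,) * K,
    }
    identity = {lv: np.eye(K) for lv in RE_LEVELS}
    if name == "no_specialization":
        corr = dict(identity)
        corr["individual"] = _compound_corr(0.4)
        return {"fixed_betas": _NO_SPEC_BETAS.copy(), "re_sd": sd, "re_corr": corr}
    if name == "temporal_caste":
        return {"fixed_betas": _TEMPORAL_BETAS.copy(), "re_sd": sd, "re_corr": identity}
    if name == "permanent_caste":
        corr = dict(identity)
        m = np.eye(K)
        i, j = NONREFERENCE_CATEGORIES.index("food_carry"), NONREFERENCE_CATEGORIES.index("work")
        m[i, j] = m[j, i] = -0.8
        corr["individual"] = m
        sd = dict(sd)
        sd["individual"] = (0.4, 0.3, 0.9, 0.9, 0.9)
        return {"fixed_betas": _PERMANENT_BETAS.copy(), "re_sd": sd, "re_corr": corr}
    # null: no effects, uncorrelated individual variation only
    return {
        "fixed_betas": np.zeros((len(FIXED_TERMS), K)),
        "re_sd": {
            "individual": (0.5,) * K,
            "scan": (0.0,) * K,
            "litter": (0.0,) * K,
            "group": (0.0,) * K,
        },
        "re_corr": identity,
    }


@dataclass
class TruthConfig:
    """Ground-truth generating parameters for a synthetic dataset."""

    n_groups: int = 35
    n_females: int = 60
    n_males: int = 56
    n_scans_per_individual: int = 10
    events_per_scan: int = EVENTS_PER_SCAN
    intercepts: np.ndarray = field(
        default_factory=lambda: np.array(_DEFAULT_INTERCEPTS)
    )
    fixed_betas: np.ndarray = field(default_factory=lambda: _NO_SPEC_BETAS.copy())
    re_sd: dict = field(
        default_factory=lambda: scenario_preset("no_specialization")["re_sd"]
    )
    re_corr: dict = field(
        default_factory=lambda: scenario_preset("no_specialization")["re_corr"]
    )
    mass_params: tuple = (2.2, 0.42, 0.10, 0.05)  # a, b, sigma_group, sigma_resid
    scenario: str = "no_specialization"
    seed: int = 0
    age_first_scan_days: float = 136.0
    age_first_scan_sd: float = 9.0
    inter_scan_days: float = 64.5
    scan_effect_grain: str = "individual_scan"

    def __post_init__(self):
        if min(self.n_groups, self.n_females + self.n_males,
               self.n_scans_per_individual, self.events_per_scan) < 1:
            raise ValueError("all design counts must be >= 1")
        self.intercepts = np.asarray(self.intercepts, dtype=float)
        self.fixed_betas = np.asarray(self.fixed_betas, dtype=float)
        if self.intercepts.shape != (K,):
            raise ValueError(f"intercepts must have shape ({K},)")
        if self.fixed_betas.shape != (len(FIXED_TERMS), K):
            raise ValueError(
                f"fixed_betas must be ({len(FIXED_TERMS)}, {K}) in {FIXED_TERMS} order"
            )
        self.re_sd = {lv: np.asarray(self.re_sd[lv], dtype=float) for lv in RE_LEVELS}
        self.re_corr = {lv: np.asarray(self.re_corr[lv], dtype=float) for lv in RE_LEVELS}
        for lv in RE_LEVELS:
            if self.re_sd[lv].shape != (K,) or np.any(self.re_sd[lv] < 0):
                raise ValueError(f"re_sd[{lv!r}] must be {K} nonnegative SDs")
            _validate_corr(self.re_corr[lv], lv)
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}; valid: {SCENARIOS}")

    @classmethod
    def from_scenario(cls, name: str, **overrides) -> "TruthConfig":
        preset = scenario_preset(name)
        preset.update(overrides)
        return cls(scenario=name, **preset)

    def to_json(self) -> str:
        d = asdict(self)
        d["intercepts"] = self.intercepts.tolist()
        d["fixed_betas"] = self.fixed_betas.tolist()
        d["re_sd"] = {lv: v.tolist() for lv, v in self.re_sd.items()}
        d["re_corr"] = {lv: v.tolist() for lv, v in self.re_corr.items()}
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "TruthConfig":
        return cls(**json.loads(text))


def _validate_corr(m: np.ndarray, name: str) -> None:
    if m.shape != (K, K):
        raise ValueError(f"re_corr[{name!r}] must be {K}x{K}")
    if not np.allclose(m, m.T):
        raise ValueError(f"re_corr[{name!r}] is not symmetric")
    if not np.allclose(np.diag(m), 1.0):
        raise ValueError(f"re_corr[{name!r}] does not have a unit diagonal")
    eig = np.linalg.eigvalsh(m)
    if eig.min() < -1e-10:
        raise ValueError(
            f"re_corr[{name!r}] is not positive semi-definite (min eigenvalue {eig.min():.3g})"
        )


# --------------------------------------------------------------------------
# Population generation
# --------------------------------------------------------------------------


@dataclass
class Population:
    """Generated individuals, scan sessions, masses and observation pairs."""

    individuals: pd.DataFrame  # incl. a breeding pair per group (is_breeder)
    scans: pd.DataFrame
    masses: pd.DataFrame
    pairs: pd.DataFrame  # observed (individual_id, scan_id)
    group_effects_mass: dict


def generate_population(config: TruthConfig, rng: np.random.Generator | None = None) -> Population:
    """Generate groups, litters, individuals, scan sessions and mass records.

    Litters within a group are staggered by one inter-scan interval, so that
    each litter enters observation (at ~136 days old) on a later group
    session; the youngest litters are pups (< 40 days) during the earliest
    sessions of their older groupmates, which makes ``pups_present`` vary.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    delta = config.inter_scan_days
    origin = pd.Timestamp("2014-01-01")

    sexes = np.array(["F"] * config.n_females + ["M"] * config.n_males)
    rng.shuffle(sexes)
    n_ind = sexes.size
    if n_ind < config.n_groups:
        raise ValueError("need at least one nonreproductive individual per group")
    # random partition of individuals across groups (every group nonempty);
    # uneven sizes mirror real colonies and give the group-size covariate
    # within-dataset variance
    sizes = 1 + rng.multinomial(n_ind - config.n_groups,
                                np.full(config.n_groups, 1.0 / config.n_groups))

    ind_rows, scan_rows, pair_rows = [], [], []
    counter = 0
    group_start = {}
    for g in range(config.n_groups):
        gid = f"g{g + 1:02d}"
        start = origin + pd.Timedelta(days=int(rng.integers(0, 365)))
        group_start[gid] = start
        members = sizes[g]
        # consecutive litters of up to 3, one inter-scan interval apart
        litter_sizes = []
        left = members
        while left > 0:
            take = int(min(left, rng.integers(1, 4)))
            litter_sizes.append(take)
            left -= take
        max_k = len(litter_sizes) - 1
        n_sessions = max_k + config.n_scans_per_individual
        session_dates = [start + pd.Timedelta(days=round(j * delta)) for j in range(n_sessions)]
        for j, date in enumerate(session_dates):
            scan_rows.append(
                {"scan_id": f"{gid}_s{j:02d}", "group_id": gid, "date": date}
            )
        # breeding pair, excluded from analysis but counted in group size
        for bs in ("F", "M"):
            ind_rows.append(
                {
                    "individual_id": f"{gid}_b{bs}",
                    "sex": bs,
                    "birth_date": start - pd.Timedelta(days=1200),
                    "group_id": gid,
                    "litter_id": f"{gid}_l00",
                    "is_breeder": True,
                }
            )
        for m, lsize in enumerate(litter_sizes):
            jitter = float(rng.normal(0.0, config.age_first_scan_sd))
            birth = session_dates[m] - pd.Timedelta(
                days=round(config.age_first_scan_days + jitter)
            )
            lid = f"{gid}_l{m + 1:02d}"
            for _ in range(lsize):
                counter += 1
                iid = f"i{counter:03d}"
                ind_rows.append(
                    {
                        "individual_id": iid,
                        "sex": sexes[counter - 1],
                        "birth_date": birth,
                        "group_id": gid,
                        "litter_id": lid,
                        "is_breeder": False,
                    }
                )
                for j in range(m, m + config.n_scans_per_individual):
                    pair_rows.append(
                        {"individual_id": iid, "scan_id": f"{gid}_s{j:02d}"}
                    )

    individuals = pd.DataFrame(ind_rows)
    scans = pd.DataFrame(scan_rows)
    pairs = pd.DataFrame(pair_rows)

    # group size = living members (incl. breeders) at the session date
    sizes_col, pups_col = [], []
    by_group = dict(tuple(individuals.groupby("group_id")))
    for _, scan in scans.iterrows():
        members = by_group[scan["group_id"]]
        ages = (scan["date"] - members["birth_date"]).dt.days
        sizes_col.append(int((ages >= 0).sum()))
        pups_col.append(bool(((ages >= 0) & (ages < PUP_AGE_DAYS)).any()))
    scans["group_size"] = sizes_col
    scans["pups_present"] = pups_col

    # body masses from the log-log growth model, every 14 days
    a, b, sg, se = config.mass_params
    geff = {gid: float(rng.normal(0.0, sg)) for gid in sorted(group_start)}
    mass_rows = []
    focal = individuals[~individuals["is_breeder"]]
    last_age = config.age_first_scan_days + (config.n_scans_per_individual - 1) * delta
    ages = np.arange(PUP_AGE_DAYS, last_age + 14, 14.0)
    for row in focal.itertuples(index=False):
        noise = rng.normal(0.0, se, size=ages.size)
        logm = a + b * np.log(ages) + geff[row.group_id] + noise
        for age, lm in zip(ages, logm):
            mass_rows.append(
                {
                    "individual_id": row.individual_id,
                    "date": row.birth_date + pd.Timedelta(days=int(age)),
                    "mass_g": float(np.exp(lm)),
                }
            )
    masses = pd.DataFrame(mass_rows)
    return Population(
        individuals=individuals,
        scans=scans,
        masses=masses,
        pairs=pairs,
        group_effects_mass=geff,
    )


# --------------------------------------------------------------------------
# Event generation
# --------------------------------------------------------------------------


def _draw_effects(n: int, sd: np.ndarray, corr: np.ndarray, rng) -> np.ndarray:
    """n draws from N(0, diag(sd) corr diag(sd)) via Cholesky."""
    if n == 0 or np.all(sd == 0):
        return np.zeros((n, K))
    # PSD guaranteed by TruthConfig validation; jitter handles semidefinite cases
    try:
        L = np.linalg.cholesky(corr)
    except np.linalg.LinAlgError:
        L = np.linalg.cholesky(corr + 1e-10 * np.eye(K))
    z = rng.standard_normal((n, K))
    return (z @ L.T) * sd


def true_covariates(population: Population, config: TruthConfig) -> data_model.Covariates:
    """Covariate rows built with the true mass-growth parameters."""
    a, b, _, _ = config.mass_params
    fits = {
        sex: RelativeMassFit(
            sex=sex, intercept=a, slope=b,
            group_effects=dict(population.group_effects_mass),
            sigma_group=config.mass_params[2], sigma_resid=config.mass_params[3],
        )
        for sex in ("F", "M")
    }
    return data_model.build_covariates(
        population.individuals,
        population.scans,
        population.masses,
        fits,
        pairs=population.pairs,
    )


def generate_events(
    population: Population,
    truth: TruthConfig,
    rng: np.random.Generator | None = None,
    covariates: data_model.Covariates | None = None,
) -> pd.DataFrame:
    """Draw sampling events from the ground-truth MMBM.

    Every event is an independent categorical draw with probabilities
    softmax(eta) where eta stacks intercepts, fixed effects on the z-scored
    covariates and the random effects of each level; random effects are drawn
    once per unit.
    """
    rng = np.random.default_rng(truth.seed + 1) if rng is None else rng
    cov = covariates if covariates is not None else true_covariates(population, truth)
    table = cov.table

    X = table[list(FIXED_TERMS)].to_numpy(dtype=float)
    eta = truth.intercepts[None, :] + X @ truth.fixed_betas

    ind_codes = pd.Categorical(table["individual_id"])
    u_ind = _draw_effects(
        len(ind_codes.categories), truth.re_sd["individual"],
        truth.re_corr["individual"], rng,
    )
    eta = eta + u_ind[ind_codes.codes]

    if truth.scan_effect_grain == "group_scan":
        scan_codes = pd.Categorical(table["scan_id"]).codes
        n_scan = scan_codes.max() + 1
    else:
        scan_codes = np.arange(len(table))
        n_scan = len(table)
    eta = eta + _draw_effects(n_scan, truth.re_sd["scan"], truth.re_corr["scan"], rng)[scan_codes]

    for lv, key in [("litter", "litter_id"), ("group", "group_id")]:
        codes = pd.Categorical(table[key])
        eff = _draw_effects(len(codes.categories), truth.re_sd[lv], truth.re_corr[lv], rng)
        eta = eta + eff[codes.codes]

    # softmax over [reference 0, eta]
    full = np.concatenate([np.zeros((eta.shape[0], 1)), eta], axis=1)
    full -= full.max(axis=1, keepdims=True)
    probs = np.exp(full)
    probs /= probs.sum(axis=1, keepdims=True)

    E = truth.events_per_scan
    cats = np.asarray(CATEGORIES)
    recs = []
    for r, row in enumerate(table.itertuples(index=False)):
        draws = rng.choice(len(CATEGORIES), size=E, p=probs[r])
        recs.append(
            pd.DataFrame(
                {
                    "individual_id": row.individual_id,
                    "scan_id": row.scan_id,
                    "event_index": np.arange(1, E + 1),
                    "behaviour": cats[draws],
                }
            )
        )
    return pd.concat(recs, ignore_index=True)


# --------------------------------------------------------------------------
# One-call dataset
# --------------------------------------------------------------------------


@dataclass
class SyntheticDataset:
    truth: TruthConfig
    population: Population
    covariates: data_model.Covariates
    events: pd.DataFrame

    @property
    def tables(self) -> data_model.EventTables:
        return data_model.EventTables(
            events=self.events,
            individuals=self.population.individuals[
                ~self.population.individuals["is_breeder"]
            ].reset_index(drop=True),
            scans=self.population.scans,
        )


def generate_dataset(truth: TruthConfig) -> SyntheticDataset:
    """Generate a complete dataset (population, covariates, events) from one
    seed; identical seeds give identical tables."""
    rng = np.random.default_rng(truth.seed)
    population = generate_population(truth, rng)
    covariates = true_covariates(population, truth)
    events = generate_events(population, truth, rng, covariates)
    return SyntheticDataset(
        truth=truth, population=population, covariates=covariates, events=events
    )


def write_dataset(dataset: SyntheticDataset, outdir) -> None:
    """Write events.csv, masses.csv and truth.json to a directory."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    data_model.write_events(dataset.tables, outdir / "events.csv")
    data_model.write_masses(dataset.population.masses, outdir / "masses.csv")
    (outdir / "truth.json").write_text(dataset.truth.to_json())
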