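"""Domain types, IO and covariate construction for scan-sampling behavioural data.

The data describe instantaneous scan sampling of social groups: each group is
watched for a 12 h session (a "scan"), and the behaviour of every individually
marked, nonreproductive group member is recorded at 4 min intervals, giving
180 sampling events per individual per scan. Behaviours are collapsed onto a
six-category ethogram with resting as the multinomial reference category.

Tables are plain pandas DataFrames; light dataclasses carry metadata that does
not fit a column (standardization constants, the behaviour vocabulary).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

# --------------------------------------------------------------------------
# Behaviour vocabulary
# --------------------------------------------------------------------------

#: The six modelled behaviour categories. ``rest`` is the reference category
#: of the multinomial logit (its linear predictor is fixed at zero).
CATEGORIES: tuple[str, ...] = (
    "rest",
    "active_nonhelping",
    "eat",
    "food_carry",
    "nest_building",
    "work",
)

REFERENCE_CATEGORY = "rest"

#: Categories modelled relative to the reference, in fixed order.
NONREFERENCE_CATEGORIES: tuple[str, ...] = tuple(
    c for c in CATEGORIES if c != REFERENCE_CATEGORY
)

#: Cooperative (helping) behaviours; trade-offs among these are what the
#: task-specialization test interrogates.
COOPERATIVE_CATEGORIES: tuple[str, ...] = ("food_carry", "nest_building", "work")

SCAN_HOURS = 12
SAMPLING_INTERVAL_MIN = 4
#: Sampling events per individual per 12 h scan at 4 min intervals.
EVENTS_PER_SCAN = SCAN_HOURS * 60 // SAMPLING_INTERVAL_MIN

#: Age (days) below which a group member counts as a pup.
PUP_AGE_DAYS = 40

#: Fixed-effect covariates, in the column order used throughout modelling.
FIXED_TERMS: tuple[str, ...] = (
    "age_z",
    "age_z2",
    "age_z3",
    "groupsize_z",
    "groupsize_z2",
    "pups_present",
    "relative_mass_z",
)

EVENT_FILE_COLUMNS = [
    "individual_id",
    "sex",
    "birth_date",
    "group_id",
    "litter_id",
    "scan_id",
    "scan_date",
    "event_index",
    "behaviour",
]
# group_size / pups_present are written by write_events and used if present;
# otherwise they are derived from the observed individuals.
OPTIONAL_EVENT_COLUMNS = ["group_size", "pups_present"]

MASS_FILE_COLUMNS = ["individual_id", "date", "mass_g"]


@dataclass(frozen=True)
class BehaviourCategory:
    """One category of the collapsed ethogram."""

    label: str
    is_reference: bool
    is_cooperative: bool


BEHAVIOUR_CATEGORIES: dict[str, BehaviourCategory] = {
    label: BehaviourCategory(
        label=label,
        is_reference=(label == REFERENCE_CATEGORY),
        is_cooperative=(label in COOPERATIVE_CATEGORIES),
    )
    for label in CATEGORIES
}


def category_index(label: str) -> int:
    """Index of a category in :data:`CATEGORIES` (reference is 0)."""
    try:
        return CATEGORIES.index(label)
    except ValueError:
        raise ValueError(
            f"unknown behaviour category {label!r}; valid: {CATEGORIES}"
        ) from None


# --------------------------------------------------------------------------
# Ethogram collapse
# --------------------------------------------------------------------------


def validate_ethogram_mapping(mapping: dict[str, str]) -> None:
    """Check a raw-label -> category mapping is a surjection onto the six
    modelled categories."""
    bad = {r: c for r, c in mapping.items() if c not in CATEGORIES}
    if bad:
        raise ValueError(f"mapping targets outside the category set: {bad}")
    image = set(mapping.values())
    missing = set(CATEGORIES) - image
    if missing:
        raise ValueError(
            f"mapping is not onto the six categories; unreached: {sorted(missing)}"
        )


def collapse_ethogram(raw_labels, mapping: dict[str, str]):
    """Map raw ethogram labels onto the six modelled categories.

    Parameters
    ----------
    raw_labels : iterable or pandas Series of raw behaviour labels.
    mapping : dict mapping every raw label to one of the six categories.

    Returns the collapsed labels in the same container type (Series in,
    Series out). Raises ``KeyError`` naming any unmapped raw label.
    """
    validate_ethogram_mapping(mapping)
    if isinstance(raw_labels, pd.Series):
        unmapped = set(raw_labels.unique()) - set(mapping)
        if unmapped:
            raise KeyError(f"raw labels missing from the ethogram mapping: {sorted(unmapped)}")
        return raw_labels.map(mapping)
    out = []
    for lab in raw_labels:
        if lab not in mapping:
            raise KeyError(f"raw labels missing from the ethogram mapping: [{lab!r}]")
        out.append(mapping[lab])
    return out


def read_ethogram_mapping(path) -> dict[str, str]:
    """Read a ``raw_label,category`` CSV mapping file."""
    df = pd.read_csv(path)
    if not {"raw_label", "category"} <= set(df.columns):
        raise ValueError("ethogram mapping file needs columns raw_label,category")
    mapping = dict(zip(df["raw_label"].astype(str), df["category"].astype(str)))
    validate_ethogram_mapping(mapping)
    return mapping


# --------------------------------------------------------------------------
# Event file IO
# --------------------------------------------------------------------------


@dataclass
class EventTables:
    """Typed tables parsed from a long-format events file.

    events : one row per sampling event
        (individual_id, scan_id, event_index, behaviour)
    individuals : one row per individual
        (individual_id, sex, birth_date, group_id, litter_id, is_breeder)
    scans : one row per scan session
        (scan_id, group_id, date, group_size, pups_present)
    """

    events: pd.DataFrame
    individuals: pd.DataFrame
    scans: pd.DataFrame


def read_events(path, mapping: dict[str, str] | None = None) -> EventTables:
    """Read a long-format events CSV and split it into typed tables.

    The file must carry the header ``individual_id,sex,birth_date,group_id,
    litter_id,scan_id,scan_date,event_index,behaviour`` (ISO-8601 dates).
    ``group_size`` and ``pups_present`` columns are honoured when present and
    derived from the observed individuals otherwise. If ``mapping`` is given,
    the behaviour column is first collapsed through it.
    """
    df = pd.read_csv(path, dtype={"individual_id": str, "group_id": str,
                                  "litter_id": str, "scan_id": str})
    missing = [c for c in EVENT_FILE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"events file {path} is missing columns {missing}")
    if mapping is not None:
        df["behaviour"] = collapse_ethogram(df["behaviour"], mapping)

    bad = ~df["behaviour"].isin(CATEGORIES)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValueError(
            f"unknown behaviour label {df['behaviour'].iloc[row]!r} at data row "
            f"{row} of {path}; valid labels: {CATEGORIES}"
        )
    dup = df.duplicated(subset=["individual_id", "scan_id", "event_index"])
    if dup.any():
        row = int(np.flatnonzero(dup.to_numpy())[0])
        key = df.loc[df.index[row], ["individual_id", "scan_id", "event_index"]]
        raise ValueError(
            "duplicate (individual_id, scan_id, event_index) = "
            f"({key.iloc[0]}, {key.iloc[1]}, {key.iloc[2]}) at data row {row}"
        )

    df["birth_date"] = pd.to_datetime(df["birth_date"])
    df["scan_date"] = pd.to_datetime(df["scan_date"])

    events = df[["individual_id", "scan_id", "event_index", "behaviour"]].copy()

    individuals = (
        df[["individual_id", "sex", "birth_date", "group_id", "litter_id"]]
        .drop_duplicates("individual_id")
        .reset_index(drop=True)
    )
    individuals["is_breeder"] = False  # analysis files contain nonbreeders only

    scans = (
        df[["scan_id", "group_id", "scan_date"]]
        .drop_duplicates("scan_id")
        .rename(columns={"scan_date": "date"})
        .reset_index(drop=True)
    )
    if "group_size" in df.columns:
        gs = df[["scan_id", "group_size"]].drop_duplicates("scan_id")
        scans = scans.merge(gs, on="scan_id")
    else:
        n_obs = df.groupby("scan_id")["individual_id"].nunique()
        scans["group_size"] = scans["scan_id"].map(n_obs).astype(int)
    if "pups_present" in df.columns:
        pp = df[["scan_id", "pups_present"]].drop_duplicates("scan_id")
        scans = scans.merge(pp, on="scan_id")
        scans["pups_present"] = scans["pups_present"].astype(bool)
    else:
        scans["pups_present"] = _derive_pups_present(individuals, scans)
    return EventTables(events=events, individuals=individuals, scans=scans)


def _derive_pups_present(individuals: pd.DataFrame, scans: pd.DataFrame) -> pd.Series:
    """pups_present is true iff any group member is under 40 days at the scan."""
    flags = []
    by_group = dict(tuple(individuals.groupby("group_id")))
    for _, scan in scans.iterrows():
        members = by_group.get(scan["group_id"])
        if members is None:
            flags.append(False)
            continue
        ages = (scan["date"] - members["birth_date"]).dt.days
        flags.append(bool(((ages >= 0) & (ages < PUP_AGE_DAYS)).any()))
    return pd.Series(flags, index=scans.index)


def write_events(tables: EventTables, path) -> None:
    """Write typed tables back to the denormalized long-format events CSV.

    ``read_events(write_events(t)) == t`` on valid tables.
    """
    df = tables.events.merge(
        tables.individuals[
            ["individual_id", "sex", "birth_date", "group_id", "litter_id"]
        ],
        on="individual_id",
    ).merge(
        tables.scans.rename(columns={"date": "scan_date"})[
            ["scan_id", "scan_date", "group_size", "pups_present"]
        ],
        on="scan_id",
    )
    cols = EVENT_FILE_COLUMNS + OPTIONAL_EVENT_COLUMNS
    df = df[cols].sort_values(
        ["individual_id", "scan_id", "event_index"], kind="stable"
    )
    df["birth_date"] = pd.to_datetime(df["birth_date"]).dt.strftime("%Y-%m-%d")
    df["scan_date"] = pd.to_datetime(df["scan_date"]).dt.strftime("%Y-%m-%d")
    df.to_csv(path, index=False)


def read_masses(path) -> pd.DataFrame:
    """Read a ``individual_id,date,mass_g`` CSV of body-mass records."""
    df = pd.read_csv(path, dtype={"individual_id": str})
    missing = [c for c in MASS_FILE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"mass file {path} is missing columns {missing}")
    df["date"] = pd.to_datetime(df["date"])
    if (df["mass_g"] <= 0).any():
        raise ValueError("mass records must be positive (grams)")
    return df


def write_masses(masses: pd.DataFrame, path) -> None:
    df = masses[MASS_FILE_COLUMNS].copy()
    df["date"] = pd.to_datetime(df["date"]).dt.strftime("%Y-%m-%d")
    df.to_csv(path, index=False)


# --------------------------------------------------------------------------
# Scan selection
# --------------------------------------------------------------------------


def select_scans(scans: pd.DataFrame, n: int = 10, seed=None) -> pd.DataFrame:
    """Select ``n`` scan sessions for one individual.

    The chronologically first and last scans are always retained (to maximise
    age coverage); the remaining ``n - 2`` are drawn uniformly without
    replacement. ``seed`` may be an int or a numpy Generator; the same seed
    always yields the same subset.

    If the individual has ``n`` or fewer scans, all are returned with a
    warning. ``n < 2`` is an error.
    """
    if n < 2:
        raise ValueError("n must be >= 2 (first and last scan are always kept)")
    if not {"scan_id", "date"} <= set(scans.columns):
        raise ValueError("scans must have columns scan_id and date")
    ordered = scans.sort_values(["date", "scan_id"], kind="stable").reset_index(drop=True)
    if len(ordered) <= n:
        if len(ordered) < n:
            warnings.warn(
                f"only {len(ordered)} scans available; returning all of them",
                stacklevel=2,
            )
        return ordered
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    middle = np.arange(1, len(ordered) - 1)
    chosen = rng.choice(middle, size=n - 2, replace=False)
    keep = np.sort(np.concatenate([[0], chosen, [len(ordered) - 1]]))
    return ordered.iloc[keep].reset_index(drop=True)


# --------------------------------------------------------------------------
# Covariate construction
# --------------------------------------------------------------------------


@dataclass
class Covariates:
    """Covariate rows plus the standardization constants used to build them.

    ``table`` has one row per (individual, scan) with ids, raw covariates
    (age_days, group_size, relative_mass) and the z-scored modelling columns
    of :data:`FIXED_TERMS`. ``scaling[sex][var] = (mean, sd)`` maps raw to
    z-scored values; ``ranges[sex][var] = (min, max)`` records the observed
    raw range (used for prediction grids).
    """

    table: pd.DataFrame
    scaling: dict = field(default_factory=dict)
    ranges: dict = field(default_factory=dict)


def _zscore(x: np.ndarray, name: str) -> tuple[np.ndarray, float, float]:
    mean = float(np.mean(x))
    sd = float(np.std(x, ddof=1))
    if not np.isfinite(sd) or sd == 0.0:
        raise ValueError(f"cannot standardize {name}: zero variance")
    return (x - mean) / sd, mean, sd


def nearest_mass(masses: pd.DataFrame, individual_id: str, date) -> float:
    """Mass record for an individual nearest in time to ``date``.

    Equidistant records resolve to the earlier one.
    """
    recs = masses[masses["individual_id"] == individual_id]
    if recs.empty:
        raise ValueError(f"no mass records for individual {individual_id}")
    delta = (recs["date"] - pd.Timestamp(date)).dt.days.to_numpy()
    order = np.lexsort((delta, np.abs(delta)))  # ties -> earlier (negative delta)
    return float(recs["mass_g"].to_numpy()[order[0]])


def build_covariates(
    individuals: pd.DataFrame,
    scans: pd.DataFrame,
    masses: pd.DataFrame,
    relative_mass_fit,
    pairs: pd.DataFrame | None = None,
) -> Covariates:
    """Build the modelling covariates for every observed (individual, scan).

    Parameters
    ----------
    individuals, scans, masses : tables as produced by :func:`read_events` /
        :func:`read_masses`.
    relative_mass_fit : a ``RelativeMassFit`` or a dict ``{sex: fit}`` from
        :mod:`mmbm.relative_mass`.
    pairs : optional DataFrame with columns individual_id, scan_id restricting
        which combinations are built (e.g. the pairs actually observed).
        Defaults to every individual crossed with every scan of its group.

    Continuous covariates (age in days, group size, relative mass) are
    z-scored within sex using the sample (n-1) SD; polynomial terms are raw
    powers of the z-scored base variable.
    """
    ind = individuals[~individuals.get("is_breeder", pd.Series(False, index=individuals.index)).astype(bool)]
    if pairs is None:
        pairs = ind[["individual_id", "group_id"]].merge(
            scans[["scan_id", "group_id"]], on="group_id"
        )[["individual_id", "scan_id"]]

    df = pairs.merge(
        ind[["individual_id", "sex", "birth_date", "group_id", "litter_id"]],
        on="individual_id",
        validate="many_to_one",
    ).merge(
        scans.rename(columns={"date": "scan_date"})[
            ["scan_id", "scan_date", "group_size", "pups_present"]
        ],
        on="scan_id",
        validate="many_to_one",
    )
    df["age_days"] = (df["scan_date"] - df["birth_date"]).dt.days
    if (df["age_days"] < 0).any():
        bad = df.loc[df["age_days"] < 0, "individual_id"].unique()
        raise ValueError(f"negative age at scan for individuals: {list(bad)}")

    have_mass = set(masses["individual_id"].unique())
    need_mass = set(df["individual_id"].unique())
    lacking = sorted(need_mass - have_mass)
    if lacking:
        raise ValueError(f"missing mass records for individuals: {lacking}")

    # nearest-in-time mass per (individual, scan); ties break to earlier record
    mass_at_scan = np.empty(len(df))
    by_ind = {k: v.sort_values("date") for k, v in masses.groupby("individual_id")}
    for i, (iid, sdate) in enumerate(zip(df["individual_id"], df["scan_date"])):
        recs = by_ind[iid]
        delta = (recs["date"] - sdate).dt.days.to_numpy()
        order = np.lexsort((delta, np.abs(delta)))
        mass_at_scan[i] = recs["mass_g"].to_numpy()[order[0]]
    df["mass_g"] = mass_at_scan

    fits = relative_mass_fit if isinstance(relative_mass_fit, dict) else None
    relmass = np.empty(len(df))
    for i, row in enumerate(df.itertuples(index=False)):
        fit = fits[row.sex] if fits is not None else relative_mass_fit
        relmass[i] = fit.residual(row.mass_g, float(row.age_days), row.group_id)
    df["relative_mass"] = relmass

    scaling: dict = {}
    ranges: dict = {}
    parts = []
    for sex, sub in df.groupby("sex", sort=True):
        sub = sub.copy()
        scaling[sex] = {}
        ranges[sex] = {}
        for raw, z in [("age_days", "age"), ("group_size", "group_size"),
                       ("relative_mass", "relative_mass")]:
            x = sub[raw].to_numpy(dtype=float)
            xz, mean, sd = _zscore(x, f"{raw} ({sex})")
            scaling[sex][z] = (mean, sd)
            ranges[sex][z] = (float(x.min()), float(x.max()))
            sub[f"_{z}_z"] = xz
        sub["age_z"] = sub["_age_z"]
        sub["age_z2"] = sub["_age_z"] ** 2
        sub["age_z3"] = sub["_age_z"] ** 3
        sub["groupsize_z"] = sub["_group_size_z"]
        sub["groupsize_z2"] = sub["_group_size_z"] ** 2
        sub["relative_mass_z"] = sub["_relative_mass_z"]
        parts.append(sub.drop(columns=[c for c in sub.columns if c.startswith("_")]))
    out = pd.concat(parts, axis=0).sort_values(
        ["individual_id", "scan_id"], kind="stable"
    ).reset_index(drop=True)
    out["pups_present"] = out["pups_present"].astype(int)
    return Covariates(table=out, scaling=scaling, ranges=ranges)
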