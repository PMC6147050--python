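"""Tests for event IO, ethogram collapse, scan selection and covariates."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mmbm import data_model
from mmbm.data_model import (
    CATEGORIES,
    EVENTS_PER_SCAN,
    REFERENCE_CATEGORY,
    build_covariates,
    collapse_ethogram,
    read_events,
    select_scans,
    write_events,
)
from mmbm.relative_mass import RelativeMassFit


def test_category_vocabulary():
    assert len(CATEGORIES) == 6
    assert REFERENCE_CATEGORY == "rest"
    refs = [c for c in data_model.BEHAVIOUR_CATEGORIES.values() if c.is_reference]
    assert [c.label for c in refs] == ["rest"]
    coop = {c.label for c in data_model.BEHAVIOUR_CATEGORIES.values() if c.is_cooperative}
    assert coop == {"food_carry", "nest_building", "work"}


def test_events_per_scan_is_180():
    # 12 h of sampling at 4 min intervals
    assert EVENTS_PER_SCAN == 12 * 60 // 4 == 180


# --------------------------------------------------------------------------
# IO
# --------------------------------------------------------------------------


def test_events_roundtrip(small_dataset, tmp_path):
    path = tmp_path / "events.csv"
    tables = small_dataset.tables
    write_events(tables, path)
    back = read_events(path)
    ev0 = tables.events.sort_values(
        ["individual_id", "scan_id", "event_index"], kind="stable"
    ).reset_index(drop=True)
    ev1 = back.events.sort_values(
        ["individual_id", "scan_id", "event_index"], kind="stable"
    ).reset_index(drop=True)
    pd.testing.assert_frame_equal(ev0, ev1, check_dtype=False)
    ind0 = tables.individuals.sort_values("individual_id").reset_index(drop=True)
    ind1 = back.individuals.sort_values("individual_id").reset_index(drop=True)
    pd.testing.assert_frame_equal(ind0[ind1.columns], ind1, check_dtype=False)
    sc0 = tables.scans.sort_values("scan_id").reset_index(drop=True)
    sc1 = back.scans.sort_values("scan_id").reset_index(drop=True)
    pd.testing.assert_frame_equal(sc0[sc1.columns], sc1, check_dtype=False)


def _toy_event_file(tmp_path, behaviours, event_index=None):
    n = len(behaviours)
    df = pd.DataFrame(
        {
            "individual_id": ["i1"] * n,
            "sex": ["F"] * n,
            "birth_date": ["2014-01-01"] * n,
            "group_id": ["g1"] * n,
            "litter_id": ["g1_l1"] * n,
            "scan_id": ["g1_s1"] * n,
            "scan_date": ["2014-06-01"] * n,
            "event_index": event_index if event_index is not None else range(1, n + 1),
            "behaviour": behaviours,
        }
    )
    path = tmp_path / "toy.csv"
    df.to_csv(path, index=False)
    return path


def test_read_events_valid_file(tmp_path):
    path = _toy_event_file(tmp_path, ["rest", "work", "eat"])
    tables = read_events(path)
    assert len(tables.events) == 3
    assert len(tables.individuals) == 1
    assert len(tables.scans) == 1


def test_read_events_rejects_unknown_behaviour(tmp_path):
    path = _toy_event_file(tmp_path, ["rest", "fly", "eat"])
    with pytest.raises(ValueError, match="fly") as err:
        read_events(path)
    assert "row 1" in str(err.value)


def test_read_events_rejects_duplicates(tmp_path):
    path = _toy_event_file(tmp_path, ["rest", "work"], event_index=[1, 1])
    with pytest.raises(ValueError, match="duplicate"):
        read_events(path)


# --------------------------------------------------------------------------
# Ethogram collapse
# --------------------------------------------------------------------------


def _sixteen_label_mapping():
    raw = {
        "sleeping": "rest", "huddling": "rest", "inactive_alert": "rest",
        "locomotion": "active_nonhelping", "self_groom": "active_nonhelping",
        "allo_groom": "active_nonhelping", "sparring": "active_nonhelping",
        "drinking": "eat", "feeding": "eat",
        "carry_food": "food_carry", "hoarding": "food_carry",
        "carry_nest_material": "nest_building", "arranging_nest": "nest_building",
        "digging": "work", "sweeping": "work", "gnawing": "work",
    }
    assert len(raw) == 16
    return raw


def test_collapse_sixteen_onto_six():
    mapping = _sixteen_label_mapping()
    out = collapse_ethogram(pd.Series(sorted(mapping)), mapping)
    assert set(out) == set(CATEGORIES)
    assert len(set(out)) == 6


def test_collapse_identity_mapping():
    mapping = {c: c for c in CATEGORIES}
    assert collapse_ethogram(list(CATEGORIES), mapping) == list(CATEGORIES)


def test_collapse_missing_raw_label_errors():
    mapping = _sixteen_label_mapping()
    with pytest.raises(KeyError, match="burrowing"):
        collapse_ethogram(pd.Series(["digging", "burrowing"]), mapping)


def test_collapse_rejects_non_surjective_mapping():
    mapping = {c: c for c in CATEGORIES if c != "work"}
    with pytest.raises(ValueError, match="work"):
        collapse_ethogram(["rest"], mapping)


# --------------------------------------------------------------------------
# Scan selection
# --------------------------------------------------------------------------


def _scan_frame(n):
    return pd.DataFrame(
        {
            "scan_id": [f"s{i:02d}" for i in range(n)],
            "date": pd.date_range("2015-01-01", periods=n, freq="60D"),
        }
    )


def test_select_scans_keeps_extremes():
    scans = _scan_frame(15)
    out = select_scans(scans, n=10, seed=4)
    assert len(out) == 10
    assert "s00" in set(out.scan_id) and "s14" in set(out.scan_id)


def test_select_scans_exact_count_returns_all():
    scans = _scan_frame(10)
    out = select_scans(scans, n=10, seed=0)
    assert list(out.scan_id) == list(scans.scan_id)


def test_select_scans_deterministic():
    scans = _scan_frame(20)
    a = select_scans(scans, n=10, seed=99)
    b = select_scans(scans, n=10, seed=99)
    pd.testing.assert_frame_equal(a, b)


def test_select_scans_too_few_warns():
    scans = _scan_frame(4)
    with pytest.warns(UserWarning, match="returning all"):
        out = select_scans(scans, n=10, seed=0)
    assert len(out) == 4


def test_select_scans_rejects_small_n():
    with pytest.raises(ValueError):
        select_scans(_scan_frame(5), n=1)


@settings(max_examples=40, derandomize=True, deadline=None)
@given(
    n_scans=st.integers(min_value=3, max_value=40),
    n=st.integers(min_value=2, max_value=12),
    seed=st.integers(min_value=0, max_value=2**31 - 1),
)
def test_select_scans_properties(n_scans, n, seed):
    """Selection size, chronological extremes and seed-reproducibility."""
    scans = _scan_frame(n_scans)
    if n_scans < n:
        with pytest.warns(UserWarning):
            out = select_scans(scans, n=n, seed=seed)
    else:
        out = select_scans(scans, n=n, seed=seed)
    assert len(out) == min(n, n_scans)
    assert scans.scan_id.iloc[0] in set(out.scan_id)
    assert scans.scan_id.iloc[-1] in set(out.scan_id)
    if n_scans >= n:
        again = select_scans(scans, n=n, seed=seed)
        assert list(out.scan_id) == list(again.scan_id)


# --------------------------------------------------------------------------
# Covariates
# --------------------------------------------------------------------------


def test_covariates_are_standardized_within_sex(small_dataset):
    table = small_dataset.covariates.table
    for sex, sub in table.groupby("sex"):
        for col in ("age_z", "groupsize_z", "relative_mass_z"):
            assert abs(sub[col].mean()) < 1e-10
            assert abs(sub[col].std(ddof=1) - 1) < 1e-10
        # polynomial columns are raw powers of the z-scored base
        np.testing.assert_allclose(sub["age_z2"], sub["age_z"] ** 2, atol=1e-12)
        np.testing.assert_allclose(sub["age_z3"], sub["age_z"] ** 3, atol=1e-12)
        np.testing.assert_allclose(sub["groupsize_z2"], sub["groupsize_z"] ** 2, atol=1e-12)


def test_pups_present_matches_forty_day_rule(small_dataset):
    scans = small_dataset.population.scans
    derived = data_model._derive_pups_present(
        small_dataset.population.individuals, scans
    )
    assert list(scans["pups_present"]) == list(derived)
    assert scans["pups_present"].any()  # staggered litters create pup scans


def _manual_setup(ages_days, one_group=False):
    """Hand-set ages; each individual in its own group/scan unless
    ``one_group`` (which makes the group-size covariate degenerate)."""
    n = len(ages_days)
    scan_date = pd.Timestamp("2015-06-01")
    groups = ["g1"] * n if one_group else [f"g{j}" for j in range(n)]
    individuals = pd.DataFrame(
        {
            "individual_id": [f"i{j}" for j in range(n)],
            "sex": ["F"] * n,
            "birth_date": [scan_date - pd.Timedelta(days=int(a)) for a in ages_days],
            "group_id": groups,
            "litter_id": ["l1"] * n,
            "is_breeder": [False] * n,
        }
    )
    scans = pd.DataFrame(
        {
            "scan_id": ["s1"] if one_group else [f"s{j}" for j in range(n)],
            "group_id": ["g1"] if one_group else groups,
            "date": [scan_date] * (1 if one_group else n),
            "group_size": [n] if one_group else list(range(2, n + 2)),
            "pups_present": [False] * (1 if one_group else n),
        }
    )
    masses = pd.DataFrame(
        {
            "individual_id": individuals.individual_id,
            "date": [scan_date] * n,
            "mass_g": np.linspace(90.0, 110.0, n),
        }
    )
    fit = RelativeMassFit(sex="F", intercept=0.0, slope=0.0, group_effects={})
    return individuals, scans, masses, fit


def test_symmetric_age_triple_standardizes_to_unit_steps():
    individuals, scans, masses, fit = _manual_setup([100, 400, 700])
    cov = build_covariates(individuals, scans, masses, fit)
    assert sorted(np.round(cov.table["age_z"], 10)) == [-1.0, 0.0, 1.0]


def test_constant_group_size_rejected():
    individuals, scans, masses, fit = _manual_setup([100, 400, 700], one_group=True)
    with pytest.raises(ValueError, match="group_size"):
        build_covariates(individuals, scans, masses, fit)


def test_nearest_mass_tie_breaks_to_earlier_record():
    scan_date = pd.Timestamp("2015-06-01")
    masses = pd.DataFrame(
        {
            "individual_id": ["i0", "i0"],
            "date": [scan_date - pd.Timedelta(days=4), scan_date + pd.Timedelta(days=4)],
            "mass_g": [80.0, 120.0],
        }
    )
    assert data_model.nearest_mass(masses, "i0", scan_date) == 80.0
    # strictly nearer later record wins
    masses.loc[1, "date"] = scan_date + pd.Timedelta(days=2)
    assert data_model.nearest_mass(masses, "i0", scan_date) == 120.0


def test_missing_mass_records_error_names_individual():
    individuals, scans, masses, fit = _manual_setup([100, 400, 700])
    masses = masses[masses.individual_id != "i1"]
    with pytest.raises(ValueError, match="i1"):
        build_covariates(individuals, scans, masses, fit)
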