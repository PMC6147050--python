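"""Shared fixtures: small synthetic datasets and session-scoped fits."""

import warnings

import numpy as np
import pytest

import mmbm


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_truth():
    """Reduced-scale generalist-helper ground truth for fast tests."""
    return mmbm.TruthConfig.from_scenario(
        "no_specialization",
        n_groups=8,
        n_females=12,
        n_males=12,
        n_scans_per_individual=6,
        events_per_scan=30,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_dataset(small_truth):
    return mmbm.generate_dataset(small_truth)


@pytest.fixture(scope="session")
def m1_fit(small_dataset):
    """M1 fit on the small dataset (females)."""
    spec = mmbm.ModelSpec(
        variant="M1",
        sex="F",
        sampler=mmbm.SamplerConfig(chains=2, iterations=400, seed=21),
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return mmbm.fit(spec, small_dataset.events, small_dataset.covariates)


@pytest.fixture(scope="session")
def m2_fit(small_dataset):
    """M2 fit on the small dataset (females)."""
    spec = mmbm.ModelSpec(
        variant="M2",
        sex="F",
        sampler=mmbm.SamplerConfig(chains=2, iterations=400, seed=22),
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return mmbm.fit(spec, small_dataset.events, small_dataset.covariates)


def make_posterior(draws: dict, spec=None, scaling=None, ranges=None):
    """Assemble a PosteriorResult directly from draw arrays (for tests of
    posterior summaries that do not need a real fit)."""
    spec = spec or mmbm.ModelSpec(variant="M2", sex="F")
    n_chain, n_draw = next(iter(draws.values())).shape[:2]
    return mmbm.PosteriorResult(
        spec=spec,
        categories=mmbm.CATEGORIES,
        draws=draws,
        log_lik=np.zeros((n_chain, n_draw, 1)),
        rhat={},
        divergences=[0] * n_chain,
        unit_labels={},
        scaling=scaling or {},
        ranges=ranges or {},
    )
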