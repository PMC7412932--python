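"""Shared fixtures: small paradigms and cohorts sized for fast tests."""

import numpy as np
import pytest
from hypothesis import settings

import rsvpcar as rc
from rsvpcar.synthetic_cohort import ClusterDispersion

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_paradigm() -> rc.ParadigmConfig:
    """2 blocks x 3 trials x 2 rounds x 6 symbols = 72 epochs."""
    return rc.ParadigmConfig(
        n_symbols=6, rounds_per_trial=2, trials_per_block=3, n_blocks=2
    )


@pytest.fixture(scope="session")
def archetype() -> rc.SubjectArchetype:
    return rc.SubjectArchetype(
        subject_id="S1",
        cluster_id=0,
        p300_latency=350.0,
        p300_amplitude=5.0,
        p300_width=150.0,
        topography=np.array([0.55, 0.85, 1.0, 0.45, 0.45, 0.6]),
        noise_sd=10.0,
    )


@pytest.fixture(scope="session")
def small_epochs(archetype, small_paradigm) -> rc.EpochSet:
    return rc.generate_subject_epochs(archetype, small_paradigm, seed=7)


def two_cluster_spec(
    n_subjects=8,
    noise_sd=0.0,
    seed=0,
    paradigm=None,
    within=ClusterDispersion(),
    latencies=(300.0, 450.0),
):
    """Two well-separated latency clusters; noiseless by default so cluster
    membership is exactly recoverable from ERP correlations."""
    paradigm = paradigm or rc.ParadigmConfig(
        n_symbols=6, rounds_per_trial=2, trials_per_block=3, n_blocks=4
    )
    return rc.CohortSpec(
        n_subjects=n_subjects,
        n_clusters=2,
        seed=seed,
        paradigm=paradigm,
        noise_sd=noise_sd,
        base_latency=float(np.mean(latencies)),
        between=ClusterDispersion(),
        within=within,
        cluster_latencies=tuple(latencies),
    )


@pytest.fixture(scope="session")
def noiseless_two_cluster_cohort():
    spec = two_cluster_spec()
    return rc.generate_cohort(spec)
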