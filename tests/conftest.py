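"""Shared fixtures: one desk-scale synthetic cohort and its joint ICA run.

Heavy artifacts are session-scoped so every module reuses them.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from neuraxis import pipeline, synthetic
from neuraxis.io_core import AnalysisConfig

COHORT_SEED = 11
ANALYSIS_SEED = 5


@pytest.fixture(scope="session")
def cohort():
    """Six-subject default cohort with planted ground truth."""
    return synthetic.simulate_cohort(n_sub=6, seed=COHORT_SEED)


@pytest.fixture(scope="session")
def cfg():
    """Desk-scale analysis configuration (smaller PCA/ICA orders)."""
    return AnalysisConfig(n_pca=20, n_ica=12, rng_seed=ANALYSIS_SEED)


@pytest.fixture(scope="session")
def jica_run(cohort, cfg):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return pipeline.run_joint_ica(cohort, cfg)


@pytest.fixture(scope="session")
def truth_maps(cohort):
    first = cohort.subjects[0]
    return synthetic.network_joint_maps(
        cohort.networks,
        np.ones(first.brain.shape, dtype=bool),
        np.ones(first.cord.shape, dtype=bool),
    )


@pytest.fixture(scope="session")
def laterality_run(cohort, cfg):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return pipeline.run_laterality(cohort, cfg)
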