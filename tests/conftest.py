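"""Shared fixtures: random models, mini phantoms, and the full-size LOOCV run.

The expensive 64^3 five-control/three-patient LOOCV is session-scoped and
shared by the acceptance tests; unit tests use fast 32^3 phantoms.
"""

import numpy as np
import pytest

from puv_fcd import classifiers as clf
from puv_fcd import evaluation, phantom
from puv_fcd.config import PipelineConfig

ACCEPTANCE_SEED = 7  # same default seed as the phantom CLI command


def random_gaussian_data(rng, n=400, d=3, sep=4.0):
    """Two Gaussian classes with random full covariances; y=1 is class w1."""
    a1 = rng.standard_normal((d, d))
    a2 = rng.standard_normal((d, d))
    cov1 = a1 @ a1.T + d * np.eye(d)
    cov2 = a2 @ a2.T + d * np.eye(d)
    mu1 = rng.standard_normal(d)
    mu2 = mu1 + sep * rng.standard_normal(d) / np.sqrt(d)
    n1 = n // 3
    x1 = rng.multivariate_normal(mu1, cov1, size=n1)
    x2 = rng.multivariate_normal(mu2, cov2, size=n - n1)
    X = np.vstack([x1, x2])
    y = np.concatenate([np.ones(n1, dtype=int), np.zeros(n - n1, dtype=int)])
    return X, y


def fit_all_kinds(rng, n=400, d=3, **kwargs):
    X, y = random_gaussian_data(rng, n=n, d=d, **kwargs)
    return {kind: clf.fit(kind, X, y) for kind in clf.KINDS}, X, y


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def mini_phantom_config(**overrides):
    base = dict(grid_shape=(32,) * 3, wm_radius_mm=8.0,
                ribbon_thickness_mm=2.0, csf_thickness_mm=1.0)
    base.update(overrides)
    return phantom.PhantomConfig(**base)


MINI_COHORT_CFG = phantom.CohortConfig(lesion_radius_range=(4.0, 5.0))


@pytest.fixture(scope="session")
def mini_cohort():
    """2 controls + 2 patients on a 32^3 grid; fast enough for unit tests."""
    return phantom.generate_cohort(2, 2, mini_phantom_config(), seed=11,
                                   cohort_cfg=MINI_COHORT_CFG)


@pytest.fixture(scope="session")
def acceptance_cohort():
    """5 controls + 3 patients, 64^3, study-condition lesions."""
    return phantom.generate_cohort(5, 3, phantom.PhantomConfig(),
                                   seed=ACCEPTANCE_SEED)


@pytest.fixture(scope="session")
def acceptance_loocv(acceptance_cohort):
    config = PipelineConfig(seed=ACCEPTANCE_SEED)
    return evaluation.loocv_run(acceptance_cohort, config)
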