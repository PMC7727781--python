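import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import ventphen as vp
from ventphen.preprocess import ChainedImputer, apply_scaler, fit_scaler
from ventphen.simulate import features_frame

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def panel():
    return vp.default_feature_panel()


@pytest.fixture(scope="session")
def small_cohort():
    """800-patient synthetic cohort with the default phenotype structure."""
    return vp.simulate_cohort(vp.CohortSpec(800, seed=7))


@pytest.fixture(scope="session")
def prepared_cohort():
    """2000-patient cohort taken through imputation and scaling once."""
    cohort = vp.simulate_cohort(vp.CohortSpec(2000, seed=11))
    feats = features_frame(cohort)
    completed = ChainedImputer(seed=12).fit_transform(feats)
    scaler = fit_scaler(completed)
    return cohort, completed, apply_scaler(completed, scaler), scaler


def two_cluster_data(n=1000, sep=5.0, w=0.6, d=2, seed=0):
    """Two unit-SD spherical clusters at ±sep/2 along every axis."""
    rng = np.random.default_rng(seed)
    z = rng.random(n) < w
    mu = np.where(z[:, None], sep / 2.0, -sep / 2.0) * np.ones((n, d))
    X = rng.normal(mu, 1.0)
    return pd.DataFrame(X, columns=[f"f{i}" for i in range(d)]), z
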