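import numpy as np
import pandas as pd
import pytest

import adaptscan as a


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_study():
    """A compact three-pair adult-stage study with known truth."""
    params = a.StudySimParams(n_genes=400, stages=("adult",),
                              frac_differentiated=0.15, effect_lfc=2.0,
                              frac_parallel=0.5, lib_size_mean=2e5)
    return a.simulate_study(params, seed=2024)


@pytest.fixture(scope="session")
def null_study():
    """No true differentiation anywhere."""
    params = a.StudySimParams(n_genes=400, stages=("adult",),
                              frac_differentiated=0.0, effect_lfc=0.0,
                              lib_size_mean=2e5)
    return a.simulate_study(params, seed=77)


def pst_pipeline(expr, pair, cutoff=0.05, normalize=True):
    """Standard trait pipeline: filter, proportion scale, normalize, P_ST."""
    totals = expr.sample_totals()
    filtered = a.filter_features(expr, 200)
    traits = a.standardize_by_sample_total(filtered, totals)
    if normalize:
        traits, _ = a.normalize_warm_by_median_ratio(traits, pair)
    tab = a.pst_table(traits, pair)
    return a.assign_quantiles_and_outliers(tab, cutoff)
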