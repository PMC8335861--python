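"""Shared fixtures: small synthetic panels built once per session."""

import numpy as np
import pytest

import dalytraj as dt
from dalytraj.scoring import attach_scores


@pytest.fixture(scope="session")
def weight_table():
    return dt.build_weight_table()


@pytest.fixture(scope="session")
def small_panel():
    """Mode-A panel, 300 persons, default study conditions."""
    cfg = dt.truth_config("model1", n_individuals=300, seed=7)
    return dt.generate_panel(cfg)


@pytest.fixture(scope="session")
def scored_panel(small_panel, weight_table):
    scores = dt.score_panel(small_panel, weight_table)
    return attach_scores(small_panel, scores)


@pytest.fixture(scope="session")
def coded_panel(scored_panel):
    return dt.code_panel(scored_panel)


@pytest.fixture(scope="session")
def model1_sim(coded_panel):
    """Mode-B outcome simulated from the model1 preset on the coded design."""
    cfg = dt.truth_config("model1", n_individuals=300, seed=7)
    spec = dt.model_spec("model1")
    return dt.simulate_from_model(cfg, coded_panel, spec), spec


def fit_mixedlm_oracle(dm, reml=False):
    """Independent mixed-model fit (statsmodels MixedLM), best likelihood
    across several optimisers — small instances can defeat any single one."""
    import warnings

    import statsmodels.api as sm

    best = None
    for method in ("lbfgs", "bfgs", "cg", "powell"):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.MixedLM(
                    dm.y, dm.X, groups=dm.group_codes, exog_re=dm.Z
                ).fit(reml=reml, method=method, maxiter=5000)
        except Exception:
            continue
        if best is None or res.llf > best.llf:
            best = res
    return best


def make_toy_design(n_persons=80, n_waves=4, seed=0, covariates=("cohort",)):
    """Small hand-rolled coded frame for focused LMM tests."""
    import pandas as pd

    rng = np.random.default_rng(seed)
    rows = []
    for pid in range(n_persons):
        cohort = int(rng.integers(1, 5))
        female = int(rng.random() < 0.5)
        base_age = float(rng.uniform(-6, 6))
        for k in range(n_waves):
            rows.append(
                dict(person_id=pid, cohort=cohort, female=female,
                     age_c=base_age + 2.0 * k)
            )
    df = pd.DataFrame(rows)
    df["age_c2"] = df["age_c"] ** 2
    return df
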