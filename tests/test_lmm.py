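"""Growth-curve model: design construction, estimation, comparison."""


import numpy as np
import pandas as pd
import pytest

import dalytraj as dt
from dalytraj.errors import ConfigurationError, ModelSpecError
from dalytraj.synthetic import simulate_outcome

from conftest import make_toy_design

#: Fixed-effect rows printed for the full cross-level interaction model
#: (reference education levels excluded), mapped to design column names.
MODEL3_COLUMNS = {
    "intercept", "age", "age2",
    "age*cohort", "age*edu_illiterate", "age*edu_elementary", "age*urban",
    "age*log_income",
    "age*cohort*edu_illiterate", "age*cohort*edu_elementary",
    "age*cohort*urban", "age*cohort*log_income",
    "age2*cohort", "age2*edu_illiterate", "age2*edu_elementary", "age2*urban",
    "age2*log_income",
    "age2*cohort*edu_illiterate", "age2*cohort*edu_elementary",
    "age2*cohort*urban", "age2*cohort*log_income",
    "died_or_lost", "female", "urban", "edu_illiterate", "edu_elementary",
    "log_income", "cohort", "hosp_oop_pct", "doctor_oop_pct",
    "hosp_oop_q2", "hosp_fee_q2", "doctor_oop_q2", "doctor_fee_q2",
    "no_spouse", "drinking", "smoking",
}


def _toy_fit(seed=0, n_persons=80, beta=(1.5, 0.5, -0.05, -0.3),
             cov=((4.0, 0.3), (0.3, 0.25)), resid=1.0, estimation="ML",
             covs=("cohort",)):
    df = make_toy_design(n_persons=n_persons, seed=seed)
    spec = dt.GrowthModelSpec(outcome="y", intercept_covariates=covs)
    dm = dt.build_design(df, spec, require_outcome=False)
    rng = np.random.default_rng(seed + 1000)
    y = simulate_outcome(dm.X, dm.Z, dm.group_codes, beta[: len(dm.columns)],
                         cov, resid, rng)
    return dm.with_outcome(y), spec


class TestBuildDesign:
    def test_minimal_spec_columns(self):
        df = make_toy_design(n_persons=10)
        spec = dt.GrowthModelSpec(outcome="y", intercept_covariates=("cohort",))
        dm = dt.build_design(df, spec, require_outcome=False)
        assert dm.columns == ["intercept", "age", "age2", "cohort"]

    def test_model3_columns_match_published_row_labels(self, coded_panel):
        dm = dt.build_design(coded_panel, dt.model_spec("model3"),
                             require_outcome=False)
        assert set(dm.columns) == MODEL3_COLUMNS

    def test_product_columns_equal_elementwise_products(self, coded_panel):
        spec = dt.model_spec("model3")
        dm = dt.build_design(coded_panel, spec, require_outcome=False)
        df = dm.frame
        cols = {c: i for i, c in enumerate(dm.columns)}
        base = {
            "age": df["age_c"].to_numpy(), "age2": df["age_c2"].to_numpy(),
        }
        for name, idx in cols.items():
            parts = name.split("*")
            if len(parts) == 1:
                continue
            expected = np.ones(len(df))
            for p in parts:
                expected = expected * base.get(p, df.get(p, np.nan))
            np.testing.assert_allclose(dm.X[:, idx], expected)

    def test_rank_deficiency_names_columns(self):
        df = make_toy_design(n_persons=30)
        df["cohort_copy"] = df["cohort"]
        spec = dt.GrowthModelSpec(
            outcome="y", intercept_covariates=("cohort", "cohort_copy")
        )
        with pytest.raises(ModelSpecError, match="cohort"):
            dt.build_design(df, spec, require_outcome=False)

    def test_missing_moderator_column_named(self):
        df = make_toy_design(n_persons=10)
        spec = dt.GrowthModelSpec(outcome="y", slope_moderators=("nonexistent",))
        with pytest.raises(ModelSpecError, match="nonexistent"):
            dt.build_design(df, spec, require_outcome=False)


class TestFit:
    def test_noise_free_data_recovered_exactly(self):
        dm, spec = _toy_fit(seed=1, cov=((0.0, 0.0), (0.0, 0.0)), resid=0.0)
        res = dt.fit(dm, spec, compute_vc_se=False)
        np.testing.assert_allclose(
            res.fixed_effects["estimate"], [1.5, 0.5, -0.05, -0.3], atol=1e-8
        )

    @pytest.mark.parametrize("estimation", ["ML", "REML"])
    def test_agrees_with_independent_mixed_model_fit(self, estimation):
        from conftest import fit_mixedlm_oracle

        dm, spec = _toy_fit(seed=3, n_persons=90)
        res = dt.fit(dm, spec, estimation=estimation, compute_vc_se=False)
        oracle = fit_mixedlm_oracle(dm, reml=(estimation == "REML"))
        rel = np.abs(
            res.fixed_effects["estimate"].to_numpy() - oracle.fe_params
        ) / np.maximum(np.abs(oracle.fe_params), 0.01)
        assert rel.max() < 1e-4
        np.testing.assert_allclose(res.random_cov, np.asarray(oracle.cov_re),
                                   atol=1e-3)
        assert res.residual_var == pytest.approx(oracle.scale, abs=1e-4)

    def test_information_criteria_consistent(self):
        dm, spec = _toy_fit(seed=4)
        res = dt.fit(dm, spec, compute_vc_se=False)
        k = res.param_count
        assert k == len(res.columns) + 4
        assert res.aic == pytest.approx(res.neg2ll + 2 * k)
        assert res.bic == pytest.approx(res.neg2ll + np.log(res.n_obs) * k)
        assert res.converged
        # Wald CIs bracket the estimate symmetrically
        fe = res.fixed_effects
        np.testing.assert_allclose(
            fe["ci_high"] - fe["estimate"], fe["estimate"] - fe["ci_low"]
        )

    def test_random_cov_estimate_is_psd_and_se_finite(self):
        dm, spec = _toy_fit(seed=5)
        res = dt.fit(dm, spec)
        assert np.linalg.eigvalsh(res.random_cov).min() >= -1e-10
        assert res.residual_var > 0
        assert np.isfinite(res.random_cov_se).all()
        assert np.isfinite(res.residual_se)

    def test_nested_ml_likelihood_monotone(self):
        dm, spec = _toy_fit(seed=6)
        res_full = dt.fit(dm, spec, compute_vc_se=False)
        small_spec = dt.GrowthModelSpec(outcome="y", intercept_covariates=())
        dm_small = dt.build_design(dm.frame, small_spec, require_outcome=False)
        res_small = dt.fit(dm_small.with_outcome(dm.y), small_spec,
                           compute_vc_se=False)
        assert res_full.neg2ll <= res_small.neg2ll + 1e-6

    def test_centering_shift_transforms_analytically(self):
        # shifting all ages by c reparameterises the quadratic: curvature
        # terms unchanged, slope terms pick up 2c*curvature, intercepts pick
        # up c*slope + c^2*curvature (within each moderator group)
        c = 3.0
        dm, spec = _toy_fit(seed=7, n_persons=150)
        df = dm.frame.copy()
        res = dt.fit(dm, spec, compute_vc_se=False)
        df["age_c"] = df["age_c"] + c
        df["age_c2"] = df["age_c"] ** 2
        df["y"] = dm.y
        dm2 = dt.build_design(df, spec)
        res2 = dt.fit(dm2, spec, compute_vc_se=False)
        b = {t: res.coef(t) for t in res.columns}
        b2 = {t: res2.coef(t) for t in res2.columns}
        assert b2["age2"] == pytest.approx(b["age2"], abs=1e-5)
        assert b2["age"] == pytest.approx(b["age"] - 2 * c * b["age2"], abs=1e-4)
        assert b2["intercept"] == pytest.approx(
            b["intercept"] - c * b["age"] + c ** 2 * b["age2"], abs=1e-3
        )
        assert b2["cohort"] == pytest.approx(b["cohort"], abs=1e-4)

    def test_row_order_invariance(self):
        dm, spec = _toy_fit(seed=8)
        df = dm.frame.copy()
        df["y"] = dm.y
        shuffled = df.sample(frac=1.0, random_state=0)
        res_a = dt.fit(dt.build_design(df, spec), spec, compute_vc_se=False)
        res_b = dt.fit(dt.build_design(shuffled, spec), spec, compute_vc_se=False)
        np.testing.assert_allclose(
            res_a.fixed_effects["estimate"], res_b.fixed_effects["estimate"],
            atol=1e-6,
        )


class TestCompareFits:
    def test_identical_fits_zero_deltas(self):
        dm, spec = _toy_fit(seed=9)
        res = dt.fit(dm, spec, compute_vc_se=False)
        tab = dt.compare_fits([res, res], names=["a", "b"])
        assert (tab["delta_aic"] == 0).all()
        assert (tab["delta_bic"] == 0).all()
        assert (tab["delta_neg2ll"] == 0).all()

    def test_reml_with_different_fixed_effects_refused(self):
        dm, spec = _toy_fit(seed=10)
        res_full = dt.fit(dm, spec, estimation="REML", compute_vc_se=False)
        small_spec = dt.GrowthModelSpec(outcome="y", intercept_covariates=())
        dm_small = dt.build_design(dm.frame, small_spec, require_outcome=False)
        res_small = dt.fit(dm_small.with_outcome(dm.y), small_spec,
                           estimation="REML", compute_vc_se=False)
        with pytest.raises(ConfigurationError, match="REML"):
            dt.compare_fits([res_full, res_small])

    def test_different_samples_refused(self):
        dm, spec = _toy_fit(seed=11, n_persons=40)
        dm2, _ = _toy_fit(seed=11, n_persons=50)
        res_a = dt.fit(dm, spec, compute_vc_se=False)
        res_b = dt.fit(dm2, spec, compute_vc_se=False)
        with pytest.raises(ConfigurationError, match="sample"):
            dt.compare_fits([res_a, res_b])
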