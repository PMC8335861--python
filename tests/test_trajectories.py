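"""Trajectory prediction, gender-stratified fits, descriptive tables."""

import numpy as np
import pandas as pd
import pytest

import dalytraj as dt
from dalytraj.errors import ConfigurationError, DataError
from dalytraj.lmm import FitResult
from dalytraj.synthetic import simulate_outcome


def _manual_result(columns, beta, cov_scale=0.0):
    """Construct a FitResult directly from a coefficient vector."""
    beta = np.asarray(beta, float)
    fe = pd.DataFrame(
        {"estimate": beta, "se": 0.0, "ci_low": beta, "ci_high": beta, "p": 0.0},
        index=pd.Index(columns, name="term"),
    )
    p = len(columns)
    return FitResult(
        fixed_effects=fe, random_cov=np.eye(2), random_cov_se=np.zeros(3),
        residual_var=1.0, residual_se=0.0,
        cov_beta=cov_scale * np.eye(p), neg2ll=0.0, aic=0.0, bic=0.0,
        n_obs=0, n_groups=0, param_count=p, converged=True, boundary=False,
        gradient_norm=0.0, estimation="ML", columns=list(columns),
    )


MODEL1_COLS = ["intercept", "age", "age2", "age*cohort", "age2*cohort", "cohort"]
MODEL1_BETA = [1.55, 0.49, -0.005, -0.143, -0.001, -0.232]


class TestPredictTrajectories:
    def test_zero_coefficients_give_flat_zero(self):
        res = _manual_result(MODEL1_COLS, np.zeros(6))
        grid = dt.predict_trajectories(
            res, {"c1": {"cohort": 1.0, "_median_age": 60}}, range(50, 71)
        )
        assert (grid.data["predicted"] == 0).all()

    def test_matches_dot_product_oracle(self):
        rng = np.random.default_rng(3)
        beta = rng.normal(size=6)
        res = _manual_result(MODEL1_COLS, beta, cov_scale=0.01)
        profile = {"cohort": 3.0, "_median_age": 58.0}
        grid = dt.predict_trajectories(res, {"c3": profile}, [50, 58, 66])
        for _, row in grid.data.iterrows():
            a = row["age"] - 58.0
            x = np.array([1.0, a, a ** 2, a * 3.0, a ** 2 * 3.0, 3.0])
            assert row["predicted"] == pytest.approx(float(x @ beta), abs=1e-12)
            half = 1.959963984540054 * np.sqrt(0.01 * float(x @ x))
            assert row["upper"] - row["predicted"] == pytest.approx(half)

    def test_second_differences_equal_curvature(self):
        res = _manual_result(MODEL1_COLS, MODEL1_BETA)
        step = 2.0
        grid = dt.predict_trajectories(
            res, {"c2": {"cohort": 2.0, "_median_age": 60.0}},
            np.arange(48, 72, step),
        )
        second = np.diff(grid.data["predicted"].to_numpy(), 2)
        curvature = -0.005 + (-0.001) * 2.0  # age2 + age2*cohort at cohort 2
        np.testing.assert_allclose(second, 2 * curvature * step ** 2, atol=1e-10)

    def test_cohort_slope_gap_at_center_is_three_interactions(self):
        # central difference at the cohort median kills the even (quadratic)
        # terms, so the cohort-4 minus cohort-1 slope gap is 3 * (age x cohort)
        res = _manual_result(MODEL1_COLS, MODEL1_BETA)
        slopes = {}
        for cohort in (1.0, 4.0):
            grid = dt.predict_trajectories(
                res, {"c": {"cohort": cohort, "_median_age": 60.0}}, [59, 61]
            )
            y = grid.data.sort_values("age")["predicted"].to_numpy()
            slopes[cohort] = (y[1] - y[0]) / 2.0
        assert slopes[4.0] - slopes[1.0] == pytest.approx(3 * (-0.143), abs=1e-12)

    def test_missing_profile_term_named(self):
        res = _manual_result(MODEL1_COLS, MODEL1_BETA)
        with pytest.raises(ConfigurationError, match="cohort"):
            dt.predict_trajectories(res, {"c": {"_median_age": 60.0}}, [60])


@pytest.fixture(scope="module")
def sim_panel(coded_panel):
    cfg = dt.truth_config("model1", n_individuals=300, seed=21)
    spec = dt.model_spec("model1")
    return dt.simulate_from_model(cfg, coded_panel, spec), spec


class TestStratifiedFit:
    def test_strata_partition_the_sample(self, sim_panel):
        sim, spec = sim_panel
        male = dt.stratified_fit(sim, spec, "male")
        female = dt.stratified_fit(sim, spec, "female")
        assert male.n_obs + female.n_obs == len(sim.data)
        assert "female" not in male.columns

    def test_identical_truth_gives_compatible_estimates(self, sim_panel):
        # the generating parameters are gender-invariant, so the two strata
        # estimate the same age coefficient up to Monte-Carlo error
        sim, spec = sim_panel
        male = dt.stratified_fit(sim, spec, "male")
        female = dt.stratified_fit(sim, spec, "female")
        gap = abs(male.coef("age") - female.coef("age"))
        se = np.hypot(male.se("age"), female.se("age"))
        assert gap < 4 * se

    def test_empty_stratum_rejected(self, coded_panel):
        df = coded_panel.data
        males_only = dt.PanelDataset(df[df["female"] == 0].copy(), coded_panel.meta)
        spec = dt.model_spec("model1")
        with pytest.raises(DataError, match="female"):
            dt.stratified_fit(males_only, spec, "female")

    def test_gender_specific_interaction_sign_pattern(self):
        # truth: the age x cohort x urban narrowing exists for women only;
        # the stratified refits should find it significant for women more
        # often than for men across replications
        big = dt.code_panel(
            dt.generate_panel(dt.truth_config("model1", n_individuals=6000,
                                              seed=77))
        )
        spec_f, spec_m = dt.model_spec("female"), dt.model_spec("male")
        base = {c: 0.0 for c in dt.FIXED_EFFECTS["female"]}
        base.update({"intercept": 1.9, "age": 0.98, "age2": -0.013,
                     "age*cohort": -0.315, "cohort": -0.321, "urban": -0.541})
        female_truth = dict(base); female_truth["age*cohort*urban"] = 0.075
        male_truth = dict(base); male_truth["age*cohort*urban"] = 0.0
        term = "age*cohort*urban"
        hits_f, hits_m = 0, 0
        reps = 5
        for r in range(reps):
            parts = []
            for sex, truth, sp in ((1, female_truth, spec_f),
                                   (0, male_truth, spec_m)):
                sub = big.data[big.data["female"] == sex].reset_index(drop=True)
                cfg = dt.truth_config("model3", n_individuals=6000,
                                      seed=400 + r + 1000 * sex,
                                      fixed_effects=truth)
                sim = dt.simulate_from_model(cfg, dt.PanelDataset(sub), sp)
                parts.append(sim.data)
            both = dt.PanelDataset(
                pd.concat(parts, ignore_index=True)
                .sort_values(["person_id", "wave_year"])
                .reset_index(drop=True)
            )
            res_f = dt.stratified_fit(both, dt.model_spec("model3"), "female")
            res_m = dt.stratified_fit(both, dt.model_spec("model3"), "male")
            hits_f += res_f.fixed_effects.loc[term, "p"] < 0.05
            assert res_f.coef(term) > res_m.coef(term) - 0.05  # sign pattern
            hits_m += res_m.fixed_effects.loc[term, "p"] < 0.05
        assert hits_f > hits_m


class TestDescriptiveTable:
    def test_matches_groupby_oracle(self, coded_panel):
        tab = dt.descriptive_table(coded_panel)
        df = coded_panel.data
        # DALY mean (SD) for one cohort and wave
        cohort, wave = 2, 2013
        sub = df[(df["cohort"] == cohort) & (df["wave_year"] == wave)]["dalys"]
        expected = f"{sub.mean():.2f} ({sub.std(ddof=1):.2f})"
        row = tab[(tab["variable"] == "dalys") & (tab["level"] == f"wave {wave}")]
        assert row[f"cohort_{cohort}"].iloc[0] == expected
        # categorical N (%) per cohort
        persons = df[df["cohort"] == cohort].drop_duplicates("person_id")
        n_f = int((persons["female"] == 1).sum())
        expected_f = f"{n_f} ({100 * n_f / len(persons):.2f})"
        row = tab[(tab["variable"] == "female") & (tab["level"] == "1")]
        assert row[f"cohort_{cohort}"].iloc[0] == expected_f

    def test_category_percentages_sum_to_100(self, coded_panel):
        tab = dt.descriptive_table(coded_panel)
        fem = tab[tab["variable"] == "female"]
        for col in [c for c in tab.columns if c.startswith("cohort_")]:
            pcts = fem[col].str.extract(r"\(([\d.]+)\)")[0].astype(float)
            assert pcts.sum() == pytest.approx(100.0, abs=0.051)

    def test_single_observation_sd_reported_absent(self):
        df = pd.DataFrame(
            {"person_id": [1], "wave_year": [2011], "cohort": [1],
             "dalys": [1.0], "female": [1], "log_income": [4.3]}
        )
        tab = dt.descriptive_table(df)
        cell = tab[(tab["variable"] == "dalys")
                   & (tab["level"] == "wave 2011")]["cohort_1"].iloc[0]
        assert cell.startswith("1.00")
        assert "NA" in cell

    def test_daly_means_monotone_across_waves(self, coded_panel):
        # absorbing diseases make per-cohort mean burden non-decreasing
        df = coded_panel.data
        for _, g in df.groupby("cohort"):
            means = g.groupby("wave_year")["dalys"].mean()
            assert (np.diff(means.to_numpy()) >= -1e-9).all()
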