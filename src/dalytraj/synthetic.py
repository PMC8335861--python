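"""CHARLS-like longitudinal panel simulation.

Two modes:

* **Mode A** (:func:`generate_panel`): disease-level histories.  Persons are
  drawn from four birth cohorts (1942–1964) with cohort-specific education,
  income and residence mixes; each of 13 chronic conditions follows an
  absorbing discrete annual-hazard onset process; death and loss to
  follow-up occur between waves.  This exercises the scoring and coding
  pipeline end to end.

* **Mode B** (:func:`simulate_from_model`): a continuous outcome is drawn
  exactly from the two-level quadratic growth model — fixed effects on the
  coded covariates, per-person random intercept/slope from a given
  covariance, i.i.d. Gaussian residuals — on top of a coded design panel.
  This is the harness for parameter-recovery experiments.

Defaults emulate the reference study conditions: ~15,000 individuals over
waves 2011/2013/2015/2018, ~80% rural, per-wave attrition inside the
0.07–6.8% range, cohort mixes and SES distributions matching the published
descriptives.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .coding import DEFAULT_BOUNDARIES
from .errors import ConfigurationError, ModelSpecError
from .panel import PanelDataset
from .scoring import DISEASES


def _validate_probs(name, probs, tol=1e-6):
    arr = np.asarray(probs, dtype=float)
    if (arr < 0).any() or abs(arr.sum() - 1.0) > tol:
        raise ConfigurationError(f"{name} must be a probability vector summing to 1")
    return arr


@dataclass
class AttritionConfig:
    """Between-wave exit probabilities (one entry per wave gap).

    The default is outcome-independent.  For informative (MNAR) dropout in
    mode B, ``outcome_coef`` tilts the exit log-odds by the person's
    systematic next-wave outcome level (centered), so sicker-by-covariates
    persons leave more often, and ``dropout_shift`` elevates the outcome of
    everyone destined to exit — a pattern-mixture mechanism in which those
    lost to death or non-response carry a higher disease burden than
    survivors with complete follow-up.  The died/lost indicator is exactly
    the dropout class, so entering it as a covariate absorbs the shift.
    """

    death: tuple = (0.010, 0.012, 0.015)
    loss: tuple = (0.040, 0.050, 0.001)
    outcome_coef: float = 0.0
    dropout_shift: float = 0.0

    def validate(self, n_gaps: int) -> "AttritionConfig":
        if len(self.death) != n_gaps or len(self.loss) != n_gaps:
            raise ConfigurationError(
                f"attrition.death/loss must each have {n_gaps} per-gap entries"
            )
        for d, l in zip(self.death, self.loss):
            if not (0 <= d <= 1 and 0 <= l <= 1 and d + l <= 1):
                raise ConfigurationError(
                    "attrition: per-gap death+loss probabilities must lie in [0, 1]"
                )
        return self


@dataclass
class SesMix:
    """Cohort-specific socioeconomic composition (cohorts 1..4)."""

    urban_fraction: float = 0.20
    female_fraction: float = 0.527
    # P(illiterate, elementary, middle-or-higher) by cohort
    education_probs: tuple = (
        (0.303, 0.465, 0.232),
        (0.294, 0.498, 0.208),
        (0.249, 0.371, 0.380),
        (0.125, 0.316, 0.559),
    )
    log10_income_mean: tuple = (4.17, 4.29, 4.41, 4.54)
    log10_income_sd: tuple = (0.61, 0.59, 0.59, 0.52)
    no_spouse: tuple = (0.200, 0.163, 0.150, 0.145)
    smoking: float = 0.398
    drinking: float = 0.251

    def validate(self) -> "SesMix":
        for k, probs in enumerate(self.education_probs, start=1):
            _validate_probs(f"education_probs[cohort {k}]", probs, tol=1e-3)
        for p in (self.urban_fraction, self.female_fraction, self.smoking,
                  self.drinking, *self.no_spouse):
            if not 0 <= p <= 1:
                raise ConfigurationError("SES fractions must lie in [0, 1]")
        return self


#: Annual onset hazards per disease: base hazard at age 60 and a log-linear
#: age slope, h(age) = base * exp(slope * (age - 60)).  Chosen so baseline
#: (2011) mean DALYs sit near 1.1 years with the published weight registry.
DEFAULT_DISEASE_HAZARDS = {
    "hypertension": {"base": 0.0138, "age_slope": 0.04},
    "diabetes": {"base": 0.0055, "age_slope": 0.05},
    "cancer": {"base": 0.0008, "age_slope": 0.07},
    "chronic_pulmonary": {"base": 0.0035, "age_slope": 0.04},
    "hepatic": {"base": 0.0014, "age_slope": 0.01},
    "heart_disease": {"base": 0.0055, "age_slope": 0.05},
    "stroke": {"base": 0.0014, "age_slope": 0.08},
    "kidney_disease": {"base": 0.0021, "age_slope": 0.03},
    "gastric": {"base": 0.0069, "age_slope": 0.01},
    "emotional_mental": {"base": 0.0017, "age_slope": 0.00},
    "memory": {"base": 0.0006, "age_slope": 0.10},
    "arthritis": {"base": 0.0124, "age_slope": 0.02},
    "asthma": {"base": 0.0014, "age_slope": 0.03},
}

#: Age at which the latent onset processes start (diagnoses can predate the
#: baseline wave) and the upper age bound of the study design.
ONSET_START_AGE = 40
MAX_AGE = 90
MIN_AGE = 45


@dataclass
class TruthConfig:
    """Complete generator parameterisation (the simulation 'truth')."""

    n_individuals: int = 15000
    wave_years: tuple = (2011, 2013, 2015, 2018)
    fixed_effects: dict = field(default_factory=dict)
    random_cov: tuple = ((10.34, 0.498), (0.498, 0.035))
    residual_var: float = 0.209
    cohort_mix: tuple = (0.152, 0.300, 0.281, 0.268)
    ses: SesMix = field(default_factory=SesMix)
    disease_hazards: dict = field(default_factory=lambda: dict(DEFAULT_DISEASE_HAZARDS))
    attrition: AttritionConfig = field(default_factory=AttritionConfig)
    cohort_boundaries: tuple = DEFAULT_BOUNDARIES
    truncate_at_zero: bool = False
    seed: int = 0

    def validate(self) -> "TruthConfig":
        if self.n_individuals < 0:
            raise ConfigurationError("n_individuals must be >= 0")
        if len(self.wave_years) < 2:
            raise ConfigurationError("wave_years needs at least two waves")
        _validate_probs("cohort_mix", self.cohort_mix, tol=1e-3)
        cov = np.asarray(self.random_cov, dtype=float)
        if cov.ndim != 2 or cov.shape[0] != cov.shape[1] or cov.shape[0] not in (2, 3):
            raise ConfigurationError("random_cov must be a 2x2 or 3x3 matrix")
        if not np.allclose(cov, cov.T):
            raise ConfigurationError("random_cov must be symmetric")
        if np.linalg.eigvalsh(cov).min() < -1e-10:
            raise ConfigurationError("random_cov must be positive semi-definite")
        if self.residual_var < 0:
            raise ConfigurationError("residual_var must be >= 0")
        for d, hz in self.disease_hazards.items():
            if d not in DISEASES:
                raise ConfigurationError(f"disease_hazards: unknown disease {d!r}")
            if not 0 <= hz["base"] <= 1:
                raise ConfigurationError(f"disease_hazards[{d}].base outside [0, 1]")
        self.ses.validate()
        self.attrition.validate(len(self.wave_years) - 1)
        return self

    # --- serialisation -------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["random_cov"] = np.asarray(self.random_cov, dtype=float).tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TruthConfig":
        d = dict(d)
        if "ses" in d and isinstance(d["ses"], dict):
            ses = {k: tuple(tuple(x) if isinstance(x, list) else x for x in [v])[0]
                   if isinstance(v, list) else v for k, v in d["ses"].items()}
            for key in ("education_probs",):
                if key in ses and isinstance(ses[key], tuple):
                    ses[key] = tuple(tuple(row) for row in ses[key])
            d["ses"] = SesMix(**ses)
        if "attrition" in d and isinstance(d["attrition"], dict):
            att = {k: tuple(v) if isinstance(v, list) else v
                   for k, v in d["attrition"].items()}
            d["attrition"] = AttritionConfig(**att)
        for key in ("wave_years", "cohort_mix"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        if "cohort_boundaries" in d:
            d["cohort_boundaries"] = tuple(tuple(b) for b in d["cohort_boundaries"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "TruthConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# Mode A: disease-level panel generation
# ---------------------------------------------------------------------------

def _empty_panel_frame() -> pd.DataFrame:
    cols = [
        "person_id", "wave_year", "birth_year", "age", "female", "urban",
        "education", "income_pc", "no_spouse", "smoking", "drinking",
        "hosp_oop", "hosp_fee", "doctor_oop", "doctor_fee",
        "hosp_oop_pct", "doctor_oop_pct", "exit_type",
    ] + [f"onset_{d}" for d in DISEASES]
    return pd.DataFrame({c: pd.Series(dtype=float) for c in cols})


def _simulate_onset_ages(rng, hazards, max_age_per_person):
    """First-passage ages of the absorbing annual Bernoulli onset process."""
    n = len(max_age_per_person)
    base = hazards["base"]
    slope = hazards.get("age_slope", 0.0)
    onset_age = np.full(n, np.nan)
    for a in range(ONSET_START_AGE, MAX_AGE + 1):
        h = min(1.0, base * np.exp(slope * (a - 60)))
        eligible = np.isnan(onset_age) & (a <= max_age_per_person)
        if not eligible.any():
            continue
        hit = eligible & (rng.random(n) < h)
        onset_age[hit] = a
    return onset_age


def generate_panel(config: TruthConfig) -> PanelDataset:
    """Mode A: generate a raw long-format panel with disease histories."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_individuals
    waves = tuple(config.wave_years)
    if n == 0:
        return PanelDataset(data=_empty_panel_frame(), meta={"config": config.to_dict()})

    # --- person-level draws -------------------------------------------
    mix = _validate_probs("cohort_mix", config.cohort_mix, tol=1e-3)
    cohort = rng.choice(4, size=n, p=mix / mix.sum())
    bands = np.asarray(config.cohort_boundaries)
    lo, hi = bands[cohort, 0], bands[cohort, 1]
    birth_year = lo + (rng.random(n) * (hi - lo + 1)).astype(int)
    ses = config.ses
    female = (rng.random(n) < ses.female_fraction).astype(int)
    urban = (rng.random(n) < ses.urban_fraction).astype(int)
    edu_probs = np.asarray(ses.education_probs)[cohort]
    edu_probs = edu_probs / edu_probs.sum(axis=1, keepdims=True)
    u = rng.random(n)
    edu_idx = (u[:, None] > np.cumsum(edu_probs, axis=1)).sum(axis=1)
    education = np.array(["illiterate", "elementary", "middle_or_higher"])[edu_idx]
    mu = np.asarray(ses.log10_income_mean)[cohort]
    sd = np.asarray(ses.log10_income_sd)[cohort]
    income_pc = 10.0 ** rng.normal(mu, sd)
    no_spouse = (rng.random(n) < np.asarray(ses.no_spouse)[cohort]).astype(int)
    smoking = (rng.random(n) < ses.smoking).astype(int)
    drinking = (rng.random(n) < ses.drinking).astype(int)

    # --- disease onsets (absorbing) ------------------------------------
    max_age = np.minimum(waves[-1] - birth_year, MAX_AGE)
    onset_year = {}
    for d in DISEASES:
        hz = config.disease_hazards.get(d)
        if hz is None or hz["base"] == 0.0:
            onset_year[d] = np.full(n, np.nan)
        else:
            ages = _simulate_onset_ages(rng, hz, max_age)
            onset_year[d] = birth_year + ages

    # --- between-wave attrition (outcome-independent in mode A) --------
    # exit_gap[i] = k means person i exits between wave k and k+1 (0-based);
    # len(waves)-1 means retained through the final wave.
    n_gaps = len(waves) - 1
    exit_gap = np.full(n, n_gaps)
    exit_kind = np.array(["none"] * n, dtype=object)
    active = np.ones(n, dtype=bool)
    for k in range(n_gaps):
        p_die, p_loss = config.attrition.death[k], config.attrition.loss[k]
        u = rng.random(n)
        die = active & (u < p_die)
        lose = active & (u >= p_die) & (u < p_die + p_loss)
        exit_gap[die | lose] = k
        exit_kind[die] = "died"
        exit_kind[lose] = "lost"
        active &= ~(die | lose)

    # --- assemble person-wave rows -------------------------------------
    rows = []
    for k, wave in enumerate(waves):
        age = wave - birth_year
        keep = (age >= MIN_AGE) & (age <= MAX_AGE) & (exit_gap >= k)
        idx = np.where(keep)[0]
        if idx.size == 0:
            continue
        m = idx.size
        hosp_fee = rng.lognormal(mean=6.0, sigma=1.6, size=m)
        doctor_fee = rng.lognormal(mean=4.5, sigma=1.4, size=m)
        hosp_ratio = rng.beta(2.0, 2.0, size=m)
        doctor_ratio = rng.beta(2.5, 1.8, size=m)
        block = {
            "person_id": idx,
            "wave_year": wave,
            "birth_year": birth_year[idx],
            "age": age[idx],
            "female": female[idx],
            "urban": urban[idx],
            "education": education[idx],
            "income_pc": income_pc[idx],
            "no_spouse": no_spouse[idx],
            "smoking": smoking[idx],
            "drinking": drinking[idx],
            "hosp_fee": hosp_fee,
            "hosp_oop": hosp_fee * hosp_ratio,
            "doctor_fee": doctor_fee,
            "doctor_oop": doctor_fee * doctor_ratio,
            "hosp_oop_pct": hosp_ratio,
            "doctor_oop_pct": doctor_ratio,
            "exit_type": exit_kind[idx],
        }
        for d in DISEASES:
            oy = onset_year[d][idx]
            block[f"onset_{d}"] = np.where(oy <= wave, oy, np.nan)
        rows.append(pd.DataFrame(block))

    df = pd.concat(rows, ignore_index=True) if rows else _empty_panel_frame()
    df = df.sort_values(["person_id", "wave_year"]).reset_index(drop=True)
    meta = {"config": config.to_dict(), "mode": "A"}
    return PanelDataset(data=df, meta=meta).validate()


# ---------------------------------------------------------------------------
# Mode B: outcome simulation from the growth model
# ---------------------------------------------------------------------------

def simulate_outcome(X, Z, group_codes, beta, random_cov, residual_var, rng):
    """Draw y = X beta + Z u_group + e with u ~ N(0, random_cov), e iid."""
    X = np.asarray(X, float)
    Z = np.asarray(Z, float)
    cov = np.asarray(random_cov, float)
    n_groups = int(group_codes.max()) + 1 if len(group_codes) else 0
    if n_groups == 0:
        u = np.zeros((0, cov.shape[0]))
    else:
        try:
            u = rng.multivariate_normal(np.zeros(cov.shape[0]), cov,
                                        size=n_groups, method="cholesky")
        except np.linalg.LinAlgError:  # singular but PSD (e.g. zero) covariance
            u = rng.multivariate_normal(np.zeros(cov.shape[0]), cov,
                                        size=n_groups, method="eigh")
    e = rng.normal(0.0, np.sqrt(residual_var), size=X.shape[0])
    return X @ np.asarray(beta, float) + np.einsum(
        "ij,ij->i", Z, u[group_codes]
    ) + e


def simulate_from_model(
    config: TruthConfig,
    design,
    model_spec,
    outcome: str | None = None,
) -> PanelDataset:
    """Mode B: attach a model-generated outcome to a coded design panel.

    ``design`` must already carry the coded covariates (``age_c`` etc.).
    When ``config.attrition.outcome_coef`` is nonzero, informative dropout is
    applied after the outcome draw: exit between waves depends on the
    would-be next-wave outcome, and the died/lost indicator is recomputed.
    """
    from .lmm import build_design  # local import to avoid a cycle

    config.validate()
    rng = np.random.default_rng(config.seed + 1)
    outcome = outcome or model_spec.outcome
    dm = build_design(design, model_spec, require_outcome=False)
    missing = [c for c in dm.columns if c not in config.fixed_effects]
    if missing:
        raise ModelSpecError(
            f"fixed_effects missing required terms: {missing}"
        )
    beta = np.array([config.fixed_effects[c] for c in dm.columns])
    df = dm.frame.copy()
    mu = dm.X @ beta

    att = config.attrition
    informative = att.outcome_coef != 0.0 or att.dropout_shift != 0.0
    dropout = None
    if informative:
        df, dropout = _informative_dropout_plan(df, mu, att, rng)
        keep = df["_keep"].to_numpy()
    y = simulate_outcome(
        dm.X, dm.Z, dm.group_codes, beta, config.random_cov,
        config.residual_var, rng,
    )
    if informative:
        y = y + att.dropout_shift * df["_dropout"].to_numpy()
    if config.truncate_at_zero:
        y = np.maximum(y, 0.0)
    df[outcome] = y
    if informative:
        df = df[keep].drop(columns=["_keep", "_dropout"]).copy()
        flag = df["exit_type"].isin(("died", "lost"))
        df["died_or_lost"] = (
            flag.groupby(df["person_id"]).transform("max").astype(int)
        )

    meta = dict(design.meta) if isinstance(design, PanelDataset) else {}
    meta.update({"mode": "B", "truth": config.to_dict(), "outcome": outcome})
    return PanelDataset(data=df.reset_index(drop=True), meta=meta)


def _informative_dropout_plan(df, mu, att: AttritionConfig, rng):
    """Decide exits from the systematic outcome level (pattern-mixture MNAR).

    Exit odds between waves tilt with the person's centered systematic
    next-wave outcome; everyone destined to exit is flagged so the outcome
    draw can add ``dropout_shift``.  Returns the frame with ``_keep`` /
    ``_dropout`` helper columns and the per-person dropout indicator.
    """
    df = df.copy()
    df["_mu"] = mu
    waves = sorted(df["wave_year"].unique())
    gamma = att.outcome_coef
    mu_mean = float(np.mean(mu))
    persons = pd.Index(df["person_id"].unique())
    exited = pd.Series(False, index=persons)
    exit_kind = pd.Series("none", index=persons, dtype=object)
    drop_from = pd.Series(np.inf, index=persons)
    for k in range(len(waves) - 1):
        d_base = att.death[min(k, len(att.death) - 1)]
        l_base = att.loss[min(k, len(att.loss) - 1)]
        p_base = min(max(d_base + l_base, 1e-9), 1 - 1e-9)
        nxt = df[df["wave_year"] == waves[k + 1]].set_index("person_id")["_mu"]
        at_risk = nxt.index[~exited.reindex(nxt.index, fill_value=True)]
        if len(at_risk) == 0:
            continue
        logit = np.log(p_base / (1 - p_base)) + gamma * (
            nxt.loc[at_risk] - mu_mean
        )
        p_exit = 1.0 / (1.0 + np.exp(-logit.to_numpy()))
        gone = at_risk[rng.random(len(at_risk)) < p_exit]
        exited.loc[gone] = True
        drop_from.loc[gone] = waves[k + 1]
        share = d_base / (d_base + l_base) if d_base + l_base > 0 else 0.5
        exit_kind.loc[gone] = np.where(
            rng.random(len(gone)) < share, "died", "lost"
        )
    df["_keep"] = df["wave_year"] < df["person_id"].map(drop_from)
    df["_dropout"] = df["person_id"].map(exited).astype(float)
    df["exit_type"] = df["person_id"].map(exit_kind)
    df = df.drop(columns=["_mu"])
    return df, exited
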