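"""Named parameter presets for recovery experiments.

Each preset bundles a :class:`~dalytraj.lmm.GrowthModelSpec` together with
the corresponding published fixed-effect estimates, random-effect
(co)variances and residual variance, so a simulation can use a reported
coefficient set as its ground truth and a refit can be compared against it.

Presets: ``model1`` (cohort moderation only), ``model2`` (adds SES
moderators on the age and age^2 slopes), ``model3`` (adds cohort-by-SES
cross-level interactions), and the gender-stratified ``male``/``female``
variants of model 3 (gender dropped from the covariates).
"""

from __future__ import annotations

import copy

import numpy as np

from .errors import ConfigurationError
from .lmm import GrowthModelSpec
from .synthetic import TruthConfig

_CONTROLS = (
    "died_or_lost",
    "female",
    "urban",
    "edu_illiterate",
    "edu_elementary",
    "log_income",
    "cohort",
    "hosp_oop_pct",
    "doctor_oop_pct",
    "hosp_oop_q2",
    "hosp_fee_q2",
    "doctor_oop_q2",
    "doctor_fee_q2",
    "no_spouse",
    "drinking",
    "smoking",
)

_SES = ("edu_illiterate", "edu_elementary", "urban", "log_income")
_SES_X_COHORT = tuple(f"cohort*{s}" for s in _SES)


def _spec(slope, curvature, stratified=False):
    controls = tuple(c for c in _CONTROLS if not (stratified and c == "female"))
    return GrowthModelSpec(
        outcome="dalys",
        slope_moderators=tuple(slope),
        curvature_moderators=tuple(curvature),
        intercept_covariates=controls,
    )


MODEL_SPECS = {
    # model 1 prints one education moderator on the age slope alongside the
    # cohort moderators; the preset reproduces the printed term set verbatim.
    "model1": _spec(slope=("cohort", "edu_illiterate"), curvature=("cohort",)),
    "model2": _spec(slope=("cohort",) + _SES, curvature=("cohort",) + _SES),
    "model3": _spec(
        slope=("cohort",) + _SES + _SES_X_COHORT,
        curvature=("cohort",) + _SES + _SES_X_COHORT,
    ),
    "male": _spec(
        slope=("cohort",) + _SES + _SES_X_COHORT,
        curvature=("cohort",) + _SES + _SES_X_COHORT,
        stratified=True,
    ),
    "female": _spec(
        slope=("cohort",) + _SES + _SES_X_COHORT,
        curvature=("cohort",) + _SES + _SES_X_COHORT,
        stratified=True,
    ),
}

_CONTROL_EFFECTS_M1 = {
    "died_or_lost": -0.108, "female": -0.011, "urban": -0.228,
    "edu_illiterate": -0.088, "edu_elementary": 0.031, "log_income": -0.014,
    "cohort": -0.232, "hosp_oop_pct": 0.00002, "doctor_oop_pct": 0.007,
    "hosp_oop_q2": -0.116, "hosp_fee_q2": -0.038, "doctor_oop_q2": -0.276,
    "doctor_fee_q2": 0.042, "no_spouse": 0.13, "drinking": 0.002,
    "smoking": -0.045,
}

FIXED_EFFECTS = {
    "model1": {
        "intercept": 1.55, "age": 0.49, "age2": -0.005,
        "age*cohort": -0.143, "age*edu_illiterate": -0.002,
        "age2*cohort": -0.001,
        **_CONTROL_EFFECTS_M1,
    },
    "model2": {
        "intercept": 2.449, "age": 0.575, "age2": -0.004,
        "age*cohort": -0.138, "age*edu_illiterate": 0.035,
        "age*edu_elementary": 0.028, "age*urban": -0.037,
        "age*log_income": -0.021,
        "age2*cohort": -0.002, "age2*edu_illiterate": 0.001,
        "age2*edu_elementary": 0.0002, "age2*urban": 0.000236,
        "age2*log_income": -0.001,
        "died_or_lost": -0.1, "female": -0.007, "urban": -0.666,
        "edu_illiterate": 0.299, "edu_elementary": 0.342, "log_income": -0.235,
        "cohort": -0.301, "hosp_oop_pct": 0.00002, "doctor_oop_pct": 0.007,
        "hosp_oop_q2": -0.118, "hosp_fee_q2": -0.033, "doctor_oop_q2": -0.276,
        "doctor_fee_q2": 0.042, "no_spouse": 0.128, "drinking": 0.001,
        "smoking": -0.046,
    },
    "model3": {
        "intercept": 1.882, "age": 0.982, "age2": -0.013,
        "age*cohort": -0.315, "age*edu_illiterate": 0.128,
        "age*edu_elementary": 0.11, "age*urban": -0.135,
        "age*log_income": -0.108,
        "age*cohort*edu_illiterate": -0.041,
        "age*cohort*edu_elementary": -0.034,
        "age*cohort*urban": 0.039, "age*cohort*log_income": 0.039,
        "age2*cohort": -0.003, "age2*edu_illiterate": -0.001,
        "age2*edu_elementary": -0.002, "age2*urban": 0.004,
        "age2*log_income": 0.001,
        "age2*cohort*edu_illiterate": -0.001,
        "age2*cohort*edu_elementary": -0.00008,
        "age2*cohort*urban": -0.0003, "age2*cohort*log_income": 0.001,
        "died_or_lost": -0.083, "female": 0.000423, "urban": -0.541,
        "edu_illiterate": 0.155, "edu_elementary": 0.216, "log_income": -0.117,
        "cohort": -0.321, "hosp_oop_pct": 0.00003, "doctor_oop_pct": 0.007,
        "hosp_oop_q2": -0.14, "hosp_fee_q2": -0.01, "doctor_oop_q2": -0.271,
        "doctor_fee_q2": 0.032, "no_spouse": 0.127, "drinking": 0.002,
        "smoking": -0.05,
    },
    "male": {
        "intercept": 1.048, "age": 0.978, "age2": -0.015,
        "age*cohort": -0.317, "age*edu_illiterate": 0.09,
        "age*edu_elementary": 0.086, "age*urban": -0.064,
        "age*log_income": -0.116,
        "age*cohort*edu_illiterate": -0.026,
        "age*cohort*edu_elementary": -0.024,
        "age*cohort*urban": 0.014, "age*cohort*log_income": 0.042,
        "age2*cohort": -0.003, "age2*edu_illiterate": 0.001,
        "age2*edu_elementary": -0.001, "age2*urban": 0.002,
        "age2*log_income": 0.002,
        "age2*cohort*edu_illiterate": -0.001,
        "age2*cohort*edu_elementary": -0.00021,
        "age2*cohort*urban": -0.00008, "age2*cohort*log_income": 0.000364,
        "died_or_lost": -0.093, "urban": -0.496, "edu_illiterate": 0.183,
        "edu_elementary": 0.204, "log_income": -0.113, "cohort": -0.343,
        "hosp_oop_pct": -0.00009, "doctor_oop_pct": 0.007,
        "hosp_oop_q2": 0.288, "hosp_fee_q2": -0.133, "doctor_oop_q2": 0.129,
        "doctor_fee_q2": 0.099, "no_spouse": 0.207, "drinking": 0.01,
        "smoking": 0.261,
    },
    "female": {
        "intercept": 2.137, "age": 1.03, "age2": -0.01,
        "age*cohort": -0.325, "age*edu_illiterate": 0.153,
        "age*edu_elementary": 0.127, "age*urban": -0.24,
        "age*log_income": -0.1,
        "age*cohort*edu_illiterate": -0.054,
        "age*cohort*edu_elementary": -0.042,
        "age*cohort*urban": 0.075, "age*cohort*log_income": 0.035,
        "age2*cohort": -0.004, "age2*edu_illiterate": -0.003,
        "age2*edu_elementary": -0.003, "age2*urban": 0.007,
        "age2*log_income": -0.00023,
        "age2*cohort*edu_illiterate": 0.000031,
        "age2*cohort*edu_elementary": 0.000026,
        "age2*cohort*urban": -0.001, "age2*cohort*log_income": 0.001,
        "died_or_lost": -0.051, "urban": -0.632, "edu_illiterate": -0.088,
        "edu_elementary": 0.216, "log_income": -0.133, "cohort": -0.278,
        "hosp_oop_pct": 0.001, "doctor_oop_pct": 0.114,
        "hosp_oop_q2": -0.178, "hosp_fee_q2": 0.308, "doctor_oop_q2": 0.452,
        "doctor_fee_q2": -0.293, "no_spouse": -0.042, "drinking": 0.04,
        "smoking": -0.209,
    },
}

#: (random-effect covariance [intercept, age slope], residual variance).
RANDOM_EFFECTS = {
    "model1": (((10.34, 0.498), (0.498, 0.035)), 0.209),
    "model2": (((10.314, 0.496), (0.496, 0.035)), 0.209),
    "model3": (((10.291, 0.496), (0.496, 0.035)), 0.207),
    "male": (((10.634, 0.521), (0.521, 0.036)), 0.214),
    "female": (((9.675, 0.448), (0.448, 0.034)), 0.192),
}

PRESETS = tuple(MODEL_SPECS)


def model_spec(name: str) -> GrowthModelSpec:
    try:
        return copy.deepcopy(MODEL_SPECS[name])
    except KeyError:
        raise ConfigurationError(
            f"unknown preset {name!r}; choose from {sorted(MODEL_SPECS)}"
        ) from None


def truth_config(name: str, n_individuals: int = 15000, seed: int = 0,
                 **overrides) -> TruthConfig:
    """A :class:`TruthConfig` whose truth is the named published estimate set."""
    if name not in FIXED_EFFECTS:
        raise ConfigurationError(
            f"unknown preset {name!r}; choose from {sorted(MODEL_SPECS)}"
        )
    cov, resid = RANDOM_EFFECTS[name]
    kwargs = dict(
        n_individuals=n_individuals,
        fixed_effects=dict(FIXED_EFFECTS[name]),
        random_cov=tuple(tuple(row) for row in np.asarray(cov, float)),
        residual_var=resid,
        seed=seed,
    )
    kwargs.update(overrides)
    return TruthConfig(**kwargs).validate()
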