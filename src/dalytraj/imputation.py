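"""Multiple imputation of independent variables and Rubin pooling.

Missingness in covariates is filled by chained equations (statsmodels
``MICEData``); the outcome is never imputed — rows with missing outcome are
reported and left for the caller to drop.  Estimates from the m completed
fits are pooled by Rubin's rules: point estimates are averaged, total
variance combines the within-imputation variance W and the
between-imputation variance B as ``T = W + (1 + 1/m) B``, with
Barnard-Rubin degrees of freedom for the reference distribution.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, DataError
from .panel import PanelDataset, as_frame

log = logging.getLogger(__name__)


def impute_missing(panel, columns, m: int = 5, seed: int = 0,
                   outcome: str | None = "dalys"):
    """Return ``m`` completed copies of the panel.

    Only ``columns`` (independent variables) are imputed.  If nothing is
    missing, the copies are identical to the input.
    """
    if m < 1:
        raise ConfigurationError("m must be >= 1")
    df = as_frame(panel)
    missing_cols = [c for c in columns if c not in df.columns]
    if missing_cols:
        raise DataError(f"columns not present in panel: {missing_cols}")
    if outcome and outcome in df.columns and df[outcome].isna().any():
        n_bad = int(df[outcome].isna().sum())
        log.warning(
            "%d rows have missing outcome %r; the outcome is not imputed",
            n_bad, outcome,
        )
    to_impute = [c for c in columns if df[c].isna().any()]
    if not to_impute:
        return [df.copy() for _ in range(m)]

    from statsmodels.imputation.mice import MICEData

    work = df[list(columns)].astype(float).reset_index(drop=True)
    np.random.seed(seed)  # MICEData draws from the global RandomState
    mice = MICEData(work)
    completed = []
    for _ in range(m):
        mice.update_all()
        filled = df.copy()
        for c in to_impute:
            filled[c] = mice.data[c].to_numpy()
        completed.append(filled)
    return completed


def pool_fits(fits) -> pd.DataFrame:
    """Rubin's-rules pooling of fixed effects across m imputation fits."""
    fits = list(fits)
    if not fits:
        raise ConfigurationError("no fits to pool")
    m = len(fits)
    terms = fits[0].fixed_effects.index
    for f in fits[1:]:
        if not f.fixed_effects.index.equals(terms):
            raise ConfigurationError("fits have different fixed-effect terms")
    est = np.column_stack([f.fixed_effects["estimate"].to_numpy() for f in fits])
    ses = np.column_stack([f.fixed_effects["se"].to_numpy() for f in fits])
    qbar = est.mean(axis=1)
    within = (ses ** 2).mean(axis=1)
    between = est.var(axis=1, ddof=1) if m > 1 else np.zeros_like(qbar)
    total = within + (1 + 1 / m) * between
    se = np.sqrt(total)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (1 + 1 / m) * between / within
        df_bar = np.where(between > 0, (m - 1) * (1 + 1 / r) ** 2, np.inf)
        z = np.where(se > 0, qbar / se, np.nan)
    pvals = np.where(
        np.isinf(df_bar),
        2 * stats.norm.sf(np.abs(z)),
        2 * stats.t.sf(np.abs(z), np.maximum(df_bar, 1.0)),
    )
    crit = np.where(
        np.isinf(df_bar),
        stats.norm.ppf(0.975),
        stats.t.ppf(0.975, np.maximum(df_bar, 1.0)),
    )
    return pd.DataFrame(
        {
            "estimate": qbar,
            "se": se,
            "ci_low": qbar - crit * se,
            "ci_high": qbar + crit * se,
            "p": pvals,
            "between_var": between,
            "df": df_bar,
        },
        index=terms,
    )


def fit_imputed(panel, spec, m: int = 5, seed: int = 0, columns=None):
    """Impute, fit the growth model on each completed panel, and pool."""
    from .lmm import build_design, fit

    df = as_frame(panel)
    columns = columns or [
        c for c in spec.fixed_columns()
        if c not in ("intercept", "age", "age2") and "*" not in c
    ]
    completed = impute_missing(panel, columns, m=m, seed=seed,
                               outcome=spec.outcome)
    fits = []
    for comp in completed:
        keep = comp[spec.outcome].notna() if spec.outcome in comp else slice(None)
        dm = build_design(comp[keep] if not isinstance(keep, slice) else comp, spec)
        fits.append(fit(dm, spec, compute_vc_se=False))
    return fits, pool_fits(fits)
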