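"""Longitudinal analysis of tract FA: mixed-effects vs. pooled OLS.

The model for subject i at wave j is

    FA_ij = beta0 + beta1 * Age_ij + b0_i + b1_i * Age_ij + eps_ij,

with fixed effects (beta0, beta1), subject-level random intercepts and
slopes (b0_i, b1_i) ~ N(0, Psi) and iid residuals eps_ij ~ N(0, sigma^2).
Estimation is by restricted maximum likelihood (REML) through
statsmodels' MixedLM, with an unstructured 2x2 random-effect covariance
by default.  The naive comparison is a pooled ordinary least-squares
regression of FA on age that ignores the repeated-measures structure;
with heterogeneous subjects and age-at-entry confounding the two can
disagree substantially, up to a sign flip of the slope.

Age is centered internally for numerical conditioning and all reported
coefficients, standard errors, random-effect (co)variances and BLUPs are
transformed back to the raw-age scale.  AIC/BIC are computed from the
REML criterion with parameter count 2 fixed + 3 covariance + 1 residual,
matching lmer-style output (not comparable across fixed-effect
structures).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.regression.mixed_linear_model import MixedLM

from .exceptions import ValidationError


def _validate_table(table: pd.DataFrame, min_rows: int = 3) -> pd.DataFrame:
    required = {"subject", "age", "fa"}
    missing = required - set(table.columns)
    if missing:
        raise ValidationError(f"longitudinal table missing columns {sorted(missing)}")
    if len(table) < min_rows:
        raise ValidationError(f"need at least {min_rows} observations")
    return table


@dataclass
class OLSFit:
    intercept: float
    slope: float
    se_intercept: float
    se_slope: float
    r2: float
    adj_r2: float
    resid_se: float
    n_obs: int


def fit_ols(table: pd.DataFrame) -> OLSFit:
    """Pooled OLS of FA on age, all observations treated as independent."""
    table = _validate_table(table)
    age = np.asarray(table["age"], float)
    if np.ptp(age) == 0:
        raise ValidationError("age is constant: OLS design is singular")
    X = sm.add_constant(age)
    res = sm.OLS(np.asarray(table["fa"], float), X).fit()
    return OLSFit(
        intercept=float(res.params[0]),
        slope=float(res.params[1]),
        se_intercept=float(res.bse[0]),
        se_slope=float(res.bse[1]),
        r2=float(res.rsquared),
        adj_r2=float(res.rsquared_adj),
        resid_se=float(np.sqrt(res.mse_resid)),
        n_obs=int(res.nobs),
    )


@dataclass
class LMEFit:
    beta0: float
    beta1: float
    se_beta0: float
    se_beta1: float
    var_b0: float
    var_b1: float
    cov_b0_b1: float
    var_resid: float
    blups: pd.DataFrame          # per-subject b0_i, b1_i (raw-age scale)
    loglik: float                # REML criterion at the optimum
    aic: float
    bic: float
    n_obs: int
    n_subjects: int
    converged: bool
    boundary: bool = False
    flags: set = field(default_factory=set)


def fit_lme(table: pd.DataFrame, diagonal_cov: bool = False) -> LMEFit:
    """REML fit of the random-intercept + random-slope model.

    ``diagonal_cov`` restricts the random-effect covariance to independent
    intercepts and slopes; the default estimates the full 2x2 covariance.
    Near-singular variance estimates are flagged ``boundary`` rather than
    hidden, and non-convergence is surfaced in ``converged``.
    """
    table = _validate_table(table, min_rows=4)
    subjects = table["subject"].unique()
    if len(subjects) < 2:
        raise ValidationError("mixed model needs at least 2 subjects")

    age = np.asarray(table["age"], float)
    fa = np.asarray(table["fa"], float)
    abar = age.mean()
    ac = age - abar

    exog = sm.add_constant(ac)
    exog_re = exog  # random intercept + centered-age slope
    groups = np.asarray(table["subject"])
    model = MixedLM(fa, exog, groups, exog_re=exog_re)
    free = None
    if diagonal_cov:
        from statsmodels.regression.mixed_linear_model import MixedLMParams

        free = MixedLMParams.from_components(
            fe_params=np.ones(2), cov_re=np.eye(2)
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(reml=True, free=free, method=["lbfgs", "powell"])

    beta0c, beta1 = res.fe_params
    cov_fe = res.cov_params()[:2, :2] if hasattr(res.cov_params(), "shape") \
        else np.asarray(res.cov_params())[:2, :2]
    # back-transform: beta0 = beta0c - beta1 * abar
    beta0 = beta0c - beta1 * abar
    var_beta0 = cov_fe[0, 0] + abar**2 * cov_fe[1, 1] - 2 * abar * cov_fe[0, 1]
    se_beta0 = float(np.sqrt(max(var_beta0, 0.0)))
    se_beta1 = float(np.sqrt(max(cov_fe[1, 1], 0.0)))

    # random-effect covariance on the raw-age scale:
    # b0_raw = b0_c - abar * b1, b1_raw = b1
    cr = np.asarray(res.cov_re)
    var_b1 = cr[1, 1]
    cov_c = cr[0, 1]
    var_b0 = cr[0, 0] + abar**2 * var_b1 - 2 * abar * cov_c
    cov_raw = cov_c - abar * var_b1

    blup_rows = []
    for subj, re in res.random_effects.items():
        b0c_i, b1_i = float(re.iloc[0]), float(re.iloc[1])
        blup_rows.append((subj, b0c_i - abar * b1_i, b1_i))
    blups = pd.DataFrame(blup_rows, columns=["subject", "b0", "b1"])

    llf = float(res.llf)
    k = 2 + (2 if diagonal_cov else 3) + 1
    n = len(table)
    aic = -2 * llf + 2 * k
    bic = -2 * llf + k * np.log(n)

    scale = float(res.scale)
    boundary = bool(
        min(cr[0, 0], cr[1, 1]) < 1e-10 * max(scale, cr[0, 0], cr[1, 1], 1e-30)
    )
    return LMEFit(
        beta0=float(beta0),
        beta1=float(beta1),
        se_beta0=se_beta0,
        se_beta1=se_beta1,
        var_b0=float(var_b0),
        var_b1=float(var_b1),
        cov_b0_b1=float(cov_raw),
        var_resid=scale,
        blups=blups,
        loglik=llf,
        aic=float(aic),
        bic=float(bic),
        n_obs=n,
        n_subjects=len(subjects),
        converged=bool(res.converged),
        boundary=boundary,
    )


def compare_models(ols: OLSFit, lme: LMEFit) -> pd.DataFrame:
    """Side-by-side summary table of the pooled OLS and LME fits."""
    rows = [
        ("constant", ols.intercept, lme.beta0),
        ("constant_se", ols.se_intercept, lme.se_beta0),
        ("age", ols.slope, lme.beta1),
        ("age_se", ols.se_slope, lme.se_beta1),
        ("observations", ols.n_obs, lme.n_obs),
        ("r2", ols.r2, np.nan),
        ("adj_r2", ols.adj_r2, np.nan),
        ("loglik", np.nan, lme.loglik),
        ("aic", np.nan, lme.aic),
        ("bic", np.nan, lme.bic),
        ("resid_se", ols.resid_se, float(np.sqrt(lme.var_resid))),
    ]
    return pd.DataFrame(rows, columns=["quantity", "ols", "lme"]).set_index("quantity")
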