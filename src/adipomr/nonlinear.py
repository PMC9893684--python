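"""Control-function non-linear Mendelian randomisation.

Tests whether the causal exposure-outcome relation is non-linear within a
stratum.  Stage 1 regresses the exposure on the genetic risk score and
covariates and keeps the residual; stage 2 is a logistic regression of the
outcome on the exposure, its square, the covariates and the stage-1 residual.
Including the residual (the control function) absorbs unmeasured confounding,
so the quadratic term's Wald test is the non-linearity test.

The exposure is mean-centred within the stratum before squaring to limit
collinearity; reported coefficients are mapped back to the raw exposure scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .onesample import StratumFitError, _fit_logit

__all__ = ["CFResult", "control_function_fit", "fitted_curve"]


@dataclass
class CFResult:
    labels: dict
    beta_linear: float  # raw-scale coefficient on exposure (log-odds per unit)
    se_linear: float
    beta_quadratic: float  # log-odds per squared unit
    se_quadratic: float
    p_quadratic: float
    beta_residual: float
    se_residual: float
    n: int
    cov_linear_quadratic: np.ndarray  # 2x2 covariance of raw-scale (linear, quadratic)
    exposure_mean: float
    exposure_range: tuple[float, float]
    collinearity_flag: bool = False


def control_function_fit(
    data: pd.DataFrame,
    grs_col: str,
    exposure_col: str,
    outcome_col: str,
    covariate_cols: list[str] | None = None,
    stratum_mask: np.ndarray | None = None,
    labels: dict | None = None,
    include_quadratic: bool = True,
) -> CFResult:
    """Quadratic control-function fit within one stratum.

    With ``include_quadratic=False`` the squared term is constrained to zero,
    leaving the linear control-function estimator (useful for comparison with
    the two-stage predictor-substitution fit)."""
    covariate_cols = covariate_cols or []
    if stratum_mask is None:
        stratum_mask = np.ones(len(data), dtype=bool)
    sub = data.loc[stratum_mask, [grs_col, exposure_col, outcome_col] + covariate_cols].dropna()
    y = sub[outcome_col].to_numpy(dtype=float)
    if y.sum() < 1 or (1 - y).sum() < 1:
        raise StratumFitError("stratum needs at least one case and one control")
    g = sub[grs_col].to_numpy(dtype=float)
    if g.std(ddof=1) == 0:
        raise StratumFitError("GRS constant within stratum")
    x = sub[exposure_col].to_numpy(dtype=float)
    C = sub[covariate_cols].to_numpy(dtype=float) if covariate_cols else np.empty((len(sub), 0))
    n = len(sub)

    X1 = np.column_stack([np.ones(n), g, C])
    coef1, *_ = np.linalg.lstsq(X1, x, rcond=None)
    resid = x - X1 @ coef1

    fitted_var = np.var(X1 @ coef1)
    collinear = fitted_var / np.var(x) < 1e-6
    if collinear:
        warnings.warn(
            "stage-1 fitted exposure nearly constant: exposure and residual are collinear",
            RuntimeWarning,
        )

    m = x.mean()
    xc = x - m
    if include_quadratic:
        X2 = np.column_stack([np.ones(n), xc, xc**2, C, resid])
    else:
        X2 = np.column_stack([np.ones(n), xc, C, resid])
    res = _fit_logit(y, X2)
    b1 = float(res.params[1])
    cov = np.asarray(res.cov_params())
    if include_quadratic:
        b2 = float(res.params[2])
        cov12 = cov[1:3, 1:3]
    else:
        b2 = 0.0
        cov12 = np.array([[cov[1, 1], 0.0], [0.0, 0.0]])
    # back-transform: with xc = x - m, b1*xc + b2*xc^2 = (b1 - 2 b2 m) x + b2 x^2 + const
    raw_lin = b1 - 2.0 * b2 * m
    J = np.array([[1.0, -2.0 * m], [0.0, 1.0]])
    cov_raw = J @ cov12 @ J.T
    se_lin = float(np.sqrt(cov_raw[0, 0]))
    se_quad = float(np.sqrt(cov_raw[1, 1]))
    resid_idx = X2.shape[1] - 1
    return CFResult(
        labels=labels or {},
        beta_linear=float(raw_lin),
        se_linear=se_lin,
        beta_quadratic=b2,
        se_quadratic=se_quad,
        p_quadratic=(
            float(2.0 * stats.norm.sf(abs(b2 / se_quad))) if include_quadratic else float("nan")
        ),
        beta_residual=float(res.params[resid_idx]),
        se_residual=float(res.bse[resid_idx]),
        n=n,
        cov_linear_quadratic=cov_raw,
        exposure_mean=float(m),
        exposure_range=(float(x.min()), float(x.max())),
        collinearity_flag=bool(collinear),
    )


def fitted_curve(result: CFResult, grid: np.ndarray) -> pd.DataFrame:
    """Predicted log-odds curve b1*x + b2*x^2 over a grid, with pointwise SE.

    The control-function residual term is set to its mean (zero); the pointwise
    variance comes from the covariance of the raw-scale (linear, quadratic)
    coefficients.  Grid points outside the observed exposure range are flagged.
    """
    grid = np.asarray(grid, dtype=float)
    b1, b2 = result.beta_linear, result.beta_quadratic
    curve = b1 * grid + b2 * grid**2
    cov = result.cov_linear_quadratic
    var = (
        grid**2 * cov[0, 0]
        + grid**4 * cov[1, 1]
        + 2.0 * grid**3 * cov[0, 1]
    )
    lo, hi = result.exposure_range
    outside = (grid < lo) | (grid > hi)
    if outside.any():
        warnings.warn(
            f"{int(outside.sum())} grid point(s) outside the observed exposure range",
            RuntimeWarning,
        )
    return pd.DataFrame(
        {
            "exposure": grid,
            "log_odds": curve,
            "se": np.sqrt(np.maximum(var, 0.0)),
            "extrapolated": outside,
        }
    )
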