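"""Two-sample Mendelian-randomisation estimators and instrument diagnostics.

Four estimators over harmonised summary statistics: inverse-variance weighting
(fixed- and multiplicative random-effects), MR-Egger regression, the weighted
median and the penalised weighted median, plus per-variant Wald ratios,
Cochran's Q / I-squared heterogeneity and the median-F instrument-strength
diagnostic.

All causal estimates are on the log-odds-per-exposure-unit scale; p-values are
two-sided normal throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .harmonise import HarmonisedSet

__all__ = [
    "MREstimate",
    "InstrumentStrength",
    "wald_ratios",
    "ivw",
    "mr_egger",
    "weighted_median",
    "penalised_weighted_median",
    "median_f_statistic",
    "run_all_estimators",
]

PWM_PENALTY = 20.0  # penalty constant of the published penalised weighted median
DEFAULT_N_BOOT = 1000


@dataclass
class MREstimate:
    """One causal-effect estimate with heterogeneity / pleiotropy diagnostics."""

    method: str
    beta: float
    se: float
    pval: float
    n_snps: int
    cochran_q: float | None = None
    q_df: int | None = None
    q_p: float | None = None
    i2: float | None = None
    egger_intercept: float | None = None
    intercept_se: float | None = None
    intercept_p: float | None = None

    @property
    def odds_ratio(self) -> float:
        return float(np.exp(self.beta))

    @property
    def ci(self) -> tuple[float, float]:
        half = stats.norm.ppf(0.975) * self.se
        return float(np.exp(self.beta - half)), float(np.exp(self.beta + half))


@dataclass
class InstrumentStrength:
    f_statistics: np.ndarray
    median_f: float


def _normal_p(z: float | np.ndarray) -> float | np.ndarray:
    return 2.0 * stats.norm.sf(np.abs(z))


def _i_squared(q: float, df: int) -> float:
    if df <= 0 or q <= 0:
        return 0.0
    return float(max(0.0, (q - df) / q) * 100.0)


def wald_ratios(hset: HarmonisedSet | pd.DataFrame) -> pd.DataFrame:
    """Per-variant Wald ratios with first-order delta-method SEs.

    ratio = beta_outcome / beta_exposure; se = se_outcome / |beta_exposure|.
    Variants with a zero exposure beta are dropped with a warning.
    """
    table = hset.table if isinstance(hset, HarmonisedSet) else hset
    if len(table) == 0:
        raise ValueError("empty harmonised set")
    zero = table["beta_exposure"] == 0
    if zero.any():
        warnings.warn(
            f"dropping {int(zero.sum())} variant(s) with zero exposure beta", RuntimeWarning
        )
        table = table.loc[~zero]
    bx = table["beta_exposure"].to_numpy(dtype=float)
    by = table["beta_outcome"].to_numpy(dtype=float)
    sey = table["se_outcome"].to_numpy(dtype=float)
    ratio = by / bx
    se = sey / np.abs(bx)
    return pd.DataFrame(
        {"snp": table["snp"].to_numpy(), "ratio": ratio, "se": se, "weight": 1.0 / se**2}
    )


def ivw(ratios: pd.DataFrame, effects_model: str = "fixed") -> MREstimate:
    """Inverse-variance weighted mean of Wald ratios.

    The random-effects variant is multiplicative: the fixed-effects SE is
    scaled by sqrt(max(1, Q/(k-1))), so it can never be smaller than the
    fixed-effects SE.
    """
    if effects_model not in ("fixed", "random"):
        raise ValueError("effects_model must be 'fixed' or 'random'")
    if len(ratios) == 0:
        raise ValueError("empty ratio list")
    r = ratios["ratio"].to_numpy(dtype=float)
    w = ratios["weight"].to_numpy(dtype=float)
    k = r.size
    beta = float(np.sum(w * r) / np.sum(w))
    se = float(1.0 / np.sqrt(np.sum(w)))
    q = float(np.sum(w * (r - beta) ** 2))
    q_df = k - 1
    q_p = float(stats.chi2.sf(q, q_df)) if q_df > 0 else float("nan")
    if effects_model == "random" and k > 1:
        se *= float(np.sqrt(max(1.0, q / q_df)))
    return MREstimate(
        method=f"IVW_{effects_model}",
        beta=beta,
        se=se,
        pval=float(_normal_p(beta / se)),
        n_snps=k,
        cochran_q=q,
        q_df=q_df,
        q_p=q_p,
        i2=_i_squared(q, q_df),
    )


def mr_egger(hset: HarmonisedSet | pd.DataFrame) -> MREstimate:
    """MR-Egger weighted regression with a free pleiotropy intercept.

    Variant pairs are jointly flipped so every exposure beta is positive, then
    outcome betas are regressed on exposure betas with weights 1/se_outcome^2.
    The slope is the causal estimate; the intercept estimates average
    directional pleiotropy.  SEs use multiplicative overdispersion floored at 1.
    """
    table = hset.table if isinstance(hset, HarmonisedSet) else hset
    if len(table) < 3:
        raise ValueError("MR-Egger requires at least 3 variants")
    bx = table["beta_exposure"].to_numpy(dtype=float).copy()
    by = table["beta_outcome"].to_numpy(dtype=float).copy()
    sey = table["se_outcome"].to_numpy(dtype=float)
    flip = bx < 0
    bx[flip] *= -1.0
    by[flip] *= -1.0
    if np.ptp(bx) == 0:
        raise ValueError("all exposure betas equal: Egger slope unidentifiable")
    w = 1.0 / sey**2
    X = np.column_stack([np.ones_like(bx), bx])
    WX = X * w[:, None]
    xtwx = X.T @ WX
    coef = np.linalg.solve(xtwx, WX.T @ by)
    resid = by - X @ coef
    k = bx.size
    sigma2 = float(np.sum(w * resid**2) / (k - 2))
    cov = np.linalg.inv(xtwx) * max(1.0, sigma2)
    inter_se, slope_se = np.sqrt(np.diag(cov))
    return MREstimate(
        method="Egger",
        beta=float(coef[1]),
        se=float(slope_se),
        pval=float(_normal_p(coef[1] / slope_se)),
        n_snps=k,
        egger_intercept=float(coef[0]),
        intercept_se=float(inter_se),
        intercept_p=float(_normal_p(coef[0] / inter_se)),
    )


def _weighted_median_point(r: np.ndarray, w: np.ndarray) -> float:
    """Cumulative-weight-interpolated median of ratios r with weights w."""
    order = np.argsort(r)
    r_s, w_s = r[order], w[order]
    s = (np.cumsum(w_s) - 0.5 * w_s) / np.sum(w_s)
    return float(np.interp(0.5, s, r_s))


def _bootstrap_se(
    r: np.ndarray,
    se: np.ndarray,
    point_fn,
    n_boot: int,
    seed: int | None,
) -> float:
    rng = np.random.default_rng(seed)
    draws = rng.normal(loc=r[None, :], scale=se[None, :], size=(n_boot, r.size))
    ests = np.array([point_fn(d) for d in draws])
    return float(ests.std(ddof=1))


def weighted_median(
    ratios: pd.DataFrame, n_boot: int = DEFAULT_N_BOOT, seed: int | None = None
) -> MREstimate:
    """Weighted median of Wald ratios; SE by seeded parametric bootstrap.

    Consistent when at least half the total weight comes from valid
    instruments.  The bootstrap redraws each ratio from N(ratio, se) and
    recomputes the weighted median, holding the inverse-variance weights fixed.
    """
    if len(ratios) < 3:
        raise ValueError("weighted median requires at least 3 ratios")
    r = ratios["ratio"].to_numpy(dtype=float)
    se = ratios["se"].to_numpy(dtype=float)
    w = ratios["weight"].to_numpy(dtype=float)
    if np.any(w <= 0):
        raise ValueError("non-positive weights")
    beta = _weighted_median_point(r, w)
    se_b = _bootstrap_se(r, se, lambda d: _weighted_median_point(d, w), n_boot, seed)
    return MREstimate(
        method="WM",
        beta=beta,
        se=se_b,
        pval=float(_normal_p(beta / se_b)),
        n_snps=r.size,
    )


def _penalised_weights(r: np.ndarray, w: np.ndarray, penalty: float) -> np.ndarray:
    wm = _weighted_median_point(r, w)
    q_j = w * (r - wm) ** 2
    p_j = stats.chi2.sf(q_j, df=1)
    return w * np.minimum(1.0, penalty * p_j)


def penalised_weighted_median(
    ratios: pd.DataFrame,
    penalty: float = PWM_PENALTY,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int | None = None,
) -> MREstimate:
    """Weighted median with heterogeneity-penalised weights.

    Each variant's contribution Q_j = w_j (ratio_j - WM)^2 is converted to an
    upper-tail chi-square(1) probability p_j and its weight multiplied by
    min(1, penalty * p_j), down-weighting outlying ratios; the weighted median
    is then recomputed.  The penalty is re-derived inside every bootstrap draw.
    """
    if len(ratios) < 3:
        raise ValueError("penalised weighted median requires at least 3 ratios")
    r = ratios["ratio"].to_numpy(dtype=float)
    se = ratios["se"].to_numpy(dtype=float)
    w = ratios["weight"].to_numpy(dtype=float)
    if np.any(w <= 0):
        raise ValueError("non-positive weights")

    def point(d: np.ndarray) -> float:
        return _weighted_median_point(d, _penalised_weights(d, w, penalty))

    beta = point(r)
    se_b = _bootstrap_se(r, se, point, n_boot, seed)
    return MREstimate(
        method="PWM",
        beta=beta,
        se=se_b,
        pval=float(_normal_p(beta / se_b)),
        n_snps=r.size,
    )


def median_f_statistic(exposure: pd.DataFrame) -> InstrumentStrength:
    """Per-variant F = (beta/se)^2 from the exposure GWAS, and its median."""
    if len(exposure) == 0:
        raise ValueError("empty exposure records")
    if (exposure["se"] <= 0).any():
        raise ValueError("non-positive exposure SE")
    f = (exposure["beta"].to_numpy(dtype=float) / exposure["se"].to_numpy(dtype=float)) ** 2
    return InstrumentStrength(f_statistics=f, median_f=float(np.median(f)))


def run_all_estimators(
    hset: HarmonisedSet | pd.DataFrame,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int | None = None,
    heterogeneity_alpha: float = 0.05,
) -> pd.DataFrame:
    """All four estimators on one harmonised set, as a tidy results table.

    Both IVW flavours are reported; the fixed-effects fit is flagged as the
    headline model unless its heterogeneity test rejects at
    ``heterogeneity_alpha``, in which case the random-effects fit is.
    """
    ratios = wald_ratios(hset)
    fixed = ivw(ratios, "fixed")
    random_ = ivw(ratios, "random")
    results = [fixed, random_]
    if len(ratios) >= 3:
        results.append(mr_egger(hset))
        results.append(weighted_median(ratios, n_boot=n_boot, seed=seed))
        results.append(penalised_weighted_median(ratios, n_boot=n_boot, seed=seed))
    headline = "IVW_random" if (fixed.q_p is not None and fixed.q_p < heterogeneity_alpha) else "IVW_fixed"
    rows = []
    for est in results:
        lo, hi = est.ci
        rows.append(
            {
                "method": est.method,
                "n_snps": est.n_snps,
                "beta": est.beta,
                "se": est.se,
                "OR": est.odds_ratio,
                "ci_low": lo,
                "ci_high": hi,
                "pval": est.pval,
                "Q": est.cochran_q,
                "Q_p": est.q_p,
                "I2": est.i2,
                "egger_intercept": est.egger_intercept,
                "intercept_se": est.intercept_se,
                "intercept_p": est.intercept_p,
                "headline": est.method == headline,
            }
        )
    return pd.DataFrame(rows)
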