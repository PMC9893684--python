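"""Conventional observational logistic-regression associations.

The contrasts the MR estimates are judged against: odds ratios per 1-SD of the
continuous adiposity exposure, and category-based odds ratios using the
Working Group on Obesity in China BMI bands (normal 18.5-23.9, overweight
24-27.9, obese >= 28 kg/m^2; underweight < 18.5 excluded from the binary
contrasts).  The printed band edges leave rounding gaps (23.9-24, 27.9-28);
they are implemented as half-open intervals [18.5, 24), [24, 28), [28, inf)
so every value is classified while the conventional labels are retained.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .onesample import _fit_logit, beta_se_to_or_ci

__all__ = [
    "CategorySpec",
    "ObservationalEstimate",
    "logistic_or_per_sd",
    "assign_category",
    "category_or",
]


@dataclass
class ObservationalEstimate:
    label: str
    beta: float
    se: float
    pval: float
    n: int

    @property
    def odds_ratio(self) -> float:
        return float(np.exp(self.beta))

    @property
    def ci(self) -> tuple[float, float]:
        or_, lo, hi = beta_se_to_or_ci(self.beta, self.se)
        return lo, hi


@dataclass
class CategorySpec:
    """Named half-open intervals over BMI with a reference category."""

    intervals: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "underweight": (-np.inf, 18.5),
            "normal": (18.5, 24.0),
            "overweight": (24.0, 28.0),
            "obese": (28.0, np.inf),
        }
    )
    reference: str = "normal"
    excluded: tuple[str, ...] = ("underweight",)

    def __post_init__(self) -> None:
        if self.reference not in self.intervals:
            raise ValueError("reference category not present")
        edges = sorted(self.intervals.values())
        for (a_lo, a_hi), (b_lo, b_hi) in zip(edges, edges[1:]):
            if a_hi > b_lo:
                raise ValueError("intervals must be disjoint")


def logistic_or_per_sd(
    data: pd.DataFrame,
    exposure_col: str,
    outcome_col: str,
    covariate_cols: list[str] | None = None,
    stratum_mask: np.ndarray | None = None,
    exposure_sd: float | None = None,
) -> ObservationalEstimate:
    """Adjusted logistic OR per 1 SD of the exposure.

    The exposure is standardised with ``exposure_sd`` (full-sample SD by
    convention, stratum SD if omitted), making the OR invariant to affine
    rescaling of the raw exposure.
    """
    covariate_cols = covariate_cols or []
    if stratum_mask is None:
        stratum_mask = np.ones(len(data), dtype=bool)
    sub = data.loc[stratum_mask, [exposure_col, outcome_col] + covariate_cols].dropna()
    x = sub[exposure_col].to_numpy(dtype=float)
    if exposure_sd is None:
        exposure_sd = float(x.std(ddof=1))
    xs = (x - x.mean()) / exposure_sd
    y = sub[outcome_col].to_numpy(dtype=float)
    C = sub[covariate_cols].to_numpy(dtype=float) if covariate_cols else np.empty((len(sub), 0))
    X = np.column_stack([np.ones(len(sub)), xs, C])
    res = _fit_logit(y, X)
    beta, se = float(res.params[1]), float(res.bse[1])
    return ObservationalEstimate(
        label=f"{exposure_col}_per_sd",
        beta=beta,
        se=se,
        pval=float(2.0 * stats.norm.sf(abs(beta / se))),
        n=len(sub),
    )


def assign_category(values: np.ndarray | pd.Series, spec: CategorySpec | None = None) -> pd.Series:
    """Map BMI values onto the category labels of ``spec`` (half-open [lo, hi))."""
    spec = spec or CategorySpec()
    v = np.asarray(values, dtype=float)
    out = pd.Series(pd.NA, index=range(v.size), dtype="object")
    for name, (lo, hi) in spec.intervals.items():
        out[(v >= lo) & (v < hi)] = name
    return out


def category_or(
    data: pd.DataFrame,
    exposure_col: str,
    outcome_col: str,
    spec: CategorySpec | None = None,
    covariate_cols: list[str] | None = None,
) -> pd.DataFrame:
    """Per-category ORs versus the reference category.

    Each non-reference, non-excluded category is contrasted against the
    reference in its own logistic fit (individuals in other categories are
    dropped for that contrast; excluded categories, by default underweight,
    never enter).
    """
    spec = spec or CategorySpec()
    covariate_cols = covariate_cols or []
    cats = assign_category(data[exposure_col].to_numpy(), spec)
    cats.index = data.index
    if (cats == spec.reference).sum() == 0:
        raise ValueError("reference category is empty")
    rows = []
    for name in spec.intervals:
        if name == spec.reference or name in spec.excluded:
            continue
        mask = ((cats == name) | (cats == spec.reference)).to_numpy()
        sub = data.loc[mask, [outcome_col] + covariate_cols].dropna()
        ind = (cats.loc[sub.index] == name).to_numpy(dtype=float)
        if ind.sum() == 0:
            raise ValueError(f"category '{name}' is empty")
        y = sub[outcome_col].to_numpy(dtype=float)
        C = sub[covariate_cols].to_numpy(dtype=float) if covariate_cols else np.empty((len(sub), 0))
        X = np.column_stack([np.ones(len(sub)), ind, C])
        res = _fit_logit(y, X)
        beta, se = float(res.params[1]), float(res.bse[1])
        or_, lo, hi = beta_se_to_or_ci(beta, se)
        rows.append(
            {
                "category": name, "reference": spec.reference, "n": len(sub),
                "n_category": int(ind.sum()), "beta": beta, "se": se,
                "OR": or_, "ci_low": lo, "ci_high": hi,
                "pval": float(2.0 * stats.norm.sf(abs(beta / se))),
            }
        )
    return pd.DataFrame(rows)
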