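"""One-sample Mendelian randomisation: stratified two-stage IV estimation,
fixed-effects meta-analysis and subgroup contrast tests.

Stage 1 regresses the exposure on the genetic risk score plus covariates
within a stratum; stage 2 substitutes the fitted exposure into a logistic model
of the binary depression outcome.  Stratum estimates are pooled by
inverse-variance fixed-effects meta-analysis with Cochran's Q and I-squared,
and male/female or urban/rural estimates are contrasted with the Fisher
z-score test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.tools.sm_exceptions import PerfectSeparationError

__all__ = [
    "StratumEstimate",
    "MetaResult",
    "StratumFitError",
    "two_stage_estimate",
    "fixed_effects_meta",
    "fisher_z_compare",
    "or_ci_to_beta_se",
    "beta_se_to_or_ci",
    "run_stratified_onesample",
]

_Z975 = 1.959964


class StratumFitError(RuntimeError):
    """Raised when a stratum's IV fit is degenerate (separation, zero slope...)."""


@dataclass
class StratumEstimate:
    labels: dict
    beta: float  # log-odds per 1-SD exposure
    se: float
    pval: float
    n_cases: int
    n_controls: int

    @property
    def odds_ratio(self) -> float:
        return float(np.exp(self.beta))

    @property
    def ci(self) -> tuple[float, float]:
        return (
            float(np.exp(self.beta - _Z975 * self.se)),
            float(np.exp(self.beta + _Z975 * self.se)),
        )


@dataclass
class MetaResult:
    beta: float
    se: float
    pval: float
    q: float
    df: int
    q_p: float
    i2: float
    strata: list[dict] = field(default_factory=list)

    @property
    def odds_ratio(self) -> float:
        return float(np.exp(self.beta))

    @property
    def ci(self) -> tuple[float, float]:
        return (
            float(np.exp(self.beta - _Z975 * self.se)),
            float(np.exp(self.beta + _Z975 * self.se)),
        )


def _fit_logit(y: np.ndarray, X: np.ndarray) -> sm.Logit:
    """Bounded-iteration logistic fit with separation / convergence guards."""
    try:
        with np.errstate(all="ignore"):
            res = sm.Logit(y, X).fit(disp=0, maxiter=100)
    except (np.linalg.LinAlgError, PerfectSeparationError) as exc:
        raise StratumFitError(f"logistic fit failed: {exc}") from exc
    if not res.mle_retvals.get("converged", False):
        raise StratumFitError("logistic fit did not converge (possible separation)")
    if not np.all(np.isfinite(res.bse)):
        raise StratumFitError("non-finite SEs in logistic fit (possible separation)")
    return res


def two_stage_estimate(
    data: pd.DataFrame,
    grs_col: str,
    exposure_col: str,
    outcome_col: str,
    covariate_cols: list[str] | None = None,
    stratum_mask: np.ndarray | None = None,
    labels: dict | None = None,
    exposure_sd: float | None = None,
    n_boot: int = 0,
    seed: int | None = None,
) -> StratumEstimate:
    """Two-stage predictor-substitution IV estimate within one stratum.

    Stage 1: OLS of the exposure on the GRS and covariates.  Stage 2: logistic
    regression of the outcome on the stage-1 fitted exposure and covariates.
    The fitted-exposure coefficient is rescaled to log-odds per 1 SD of the
    exposure, where the SD is computed once in the full analysis sample and
    passed in via ``exposure_sd`` (defaults to the stratum SD if omitted).

    Stage-2 model-based SEs ignore stage-1 sampling error; pass ``n_boot`` > 0
    for a seeded nonparametric bootstrap SE instead.
    """
    covariate_cols = covariate_cols or []
    if stratum_mask is None:
        stratum_mask = np.ones(len(data), dtype=bool)
    sub = data.loc[stratum_mask, [grs_col, exposure_col, outcome_col] + covariate_cols].dropna()
    y = sub[outcome_col].to_numpy(dtype=float)
    n_cases, n_controls = int(y.sum()), int((1 - y).sum())
    if n_cases < 1 or n_controls < 1:
        raise StratumFitError("stratum needs at least one case and one control")
    g = sub[grs_col].to_numpy(dtype=float)
    if g.std(ddof=1) == 0:
        raise StratumFitError("zero stage-1 slope: GRS constant within stratum")
    x = sub[exposure_col].to_numpy(dtype=float)
    C = sub[covariate_cols].to_numpy(dtype=float) if covariate_cols else np.empty((len(sub), 0))
    if exposure_sd is None:
        exposure_sd = float(x.std(ddof=1))

    def _fit(idx: np.ndarray) -> float:
        X1 = np.column_stack([np.ones(idx.size), g[idx], C[idx]])
        coef1, *_ = np.linalg.lstsq(X1, x[idx], rcond=None)
        if coef1[1] == 0:
            raise StratumFitError("zero stage-1 slope")
        fitted = X1 @ coef1
        X2 = np.column_stack([np.ones(idx.size), fitted, C[idx]])
        res = _fit_logit(y[idx], X2)
        return res, float(res.params[1])

    all_idx = np.arange(len(sub))
    res2, coef = _fit(all_idx)
    beta = coef * exposure_sd
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        draws = []
        for _ in range(n_boot):
            bidx = rng.integers(0, all_idx.size, size=all_idx.size)
            try:
                draws.append(_fit(bidx)[1] * exposure_sd)
            except StratumFitError:
                continue
        se = float(np.std(draws, ddof=1))
    else:
        se = float(res2.bse[1]) * exposure_sd
    return StratumEstimate(
        labels=labels or {},
        beta=float(beta),
        se=se,
        pval=float(2.0 * stats.norm.sf(abs(beta / se))),
        n_cases=n_cases,
        n_controls=n_controls,
    )


def fixed_effects_meta(estimates: list[StratumEstimate]) -> MetaResult:
    """Inverse-variance fixed-effects pooling with Q and I-squared."""
    if not estimates:
        raise ValueError("no estimates to pool")
    b = np.array([e.beta for e in estimates])
    se = np.array([e.se for e in estimates])
    if np.any(~np.isfinite(b)) or np.any(~np.isfinite(se)) or np.any(se <= 0):
        raise ValueError("estimates must have finite betas and positive SEs")
    w = 1.0 / se**2
    pooled = float(np.sum(w * b) / np.sum(w))
    pooled_se = float(1.0 / np.sqrt(np.sum(w)))
    q = float(np.sum(w * (b - pooled) ** 2))
    df = len(estimates) - 1
    q_p = float(stats.chi2.sf(q, df)) if df > 0 else float("nan")
    i2 = float(max(0.0, (q - df) / q) * 100.0) if (df > 0 and q > 0) else 0.0
    return MetaResult(
        beta=pooled,
        se=pooled_se,
        pval=float(2.0 * stats.norm.sf(abs(pooled / pooled_se))),
        q=q,
        df=df,
        q_p=q_p,
        i2=i2,
        strata=[e.labels for e in estimates],
    )


def fisher_z_compare(
    a: StratumEstimate | MetaResult, b: StratumEstimate | MetaResult
) -> tuple[float, float]:
    """Fisher z-score test of equality of two independent estimates."""
    if a.se <= 0 or b.se <= 0:
        raise ValueError("SEs must be positive")
    z = (a.beta - b.beta) / np.sqrt(a.se**2 + b.se**2)
    return float(z), float(2.0 * stats.norm.sf(abs(z)))


def or_ci_to_beta_se(odds_ratio: float, ci_low: float, ci_high: float) -> tuple[float, float]:
    """Reconstruct (beta, se) on the log-odds scale from an OR and 95% CI."""
    if not (0 < ci_low < odds_ratio < ci_high):
        raise ValueError("require 0 < ci_low < OR < ci_high")
    beta = float(np.log(odds_ratio))
    se = float((np.log(ci_high) - np.log(ci_low)) / (2.0 * _Z975))
    return beta, se


def beta_se_to_or_ci(beta: float, se: float) -> tuple[float, float, float]:
    return (
        float(np.exp(beta)),
        float(np.exp(beta - _Z975 * se)),
        float(np.exp(beta + _Z975 * se)),
    )


def _estimate_from(beta: float, se: float) -> StratumEstimate:
    return StratumEstimate(
        labels={}, beta=beta, se=se,
        pval=float(2.0 * stats.norm.sf(abs(beta / se))), n_cases=0, n_controls=0,
    )


def run_stratified_onesample(
    data: pd.DataFrame,
    grs_col: str,
    exposure_col: str,
    outcome_col: str,
    covariate_cols: list[str] | None = None,
    exposure_sd: float | None = None,
    min_case_prevalence: float | None = None,
) -> pd.DataFrame:
    """Sex-by-region stratified IV fits pooled into the headline subgroup table.

    Fits every (sex, region) stratum, then meta-analyses into all / urban /
    rural by all / male / female cells, with Fisher-z sex contrasts per region
    group and an urban-vs-rural contrast overall.  Strata that fail to fit
    (separation, no cases) or fall below ``min_case_prevalence`` are dropped
    and recorded in the ``n_dropped`` attribute of the returned table.
    """
    if exposure_sd is None:
        exposure_sd = float(data[exposure_col].std(ddof=1))
    cell: dict[tuple[int, int], StratumEstimate] = {}
    dropped = []
    for (sex, region), idx in data.groupby(["sex", "region"]).groups.items():
        mask = np.zeros(len(data), dtype=bool)
        mask[data.index.get_indexer(idx)] = True
        prev = data.loc[idx, outcome_col].mean()
        if min_case_prevalence is not None and prev < min_case_prevalence:
            dropped.append({"sex": sex, "region": region, "reason": "low_prevalence"})
            continue
        try:
            cell[(sex, region)] = two_stage_estimate(
                data, grs_col, exposure_col, outcome_col, covariate_cols,
                stratum_mask=mask, labels={"sex": sex, "region": region},
                exposure_sd=exposure_sd,
            )
        except StratumFitError as exc:
            dropped.append({"sex": sex, "region": region, "reason": str(exc)})

    urban_of = dict(zip(data["region"], data["urban"])) if "urban" in data else {}

    def pool(sexes, regions_pred) -> MetaResult | None:
        ests = [
            e for (s, r), e in cell.items()
            if s in sexes and regions_pred(r)
        ]
        return fixed_effects_meta(ests) if ests else None

    def region_groups():
        yield "both", lambda r: True
        if urban_of:
            yield "urban", lambda r: bool(urban_of.get(r, 0))
            yield "rural", lambda r: not urban_of.get(r, 0)

    rows = []
    for region_label, pred in region_groups():
        metas = {}
        for sex_label, sexes in (("all", (0, 1)), ("male", (0,)), ("female", (1,))):
            m = pool(sexes, pred)
            metas[sex_label] = m
            if m is None:
                continue
            or_, lo, hi = beta_se_to_or_ci(m.beta, m.se)
            rows.append(
                {
                    "strata": sex_label, "region_group": region_label,
                    "beta": m.beta, "se": m.se, "OR": or_, "ci_low": lo, "ci_high": hi,
                    "pval": m.pval, "Q": m.q, "df": m.df, "Q_p": m.q_p, "I2": m.i2,
                    "p_sex": np.nan, "p_region": np.nan,
                }
            )
        if metas.get("male") is not None and metas.get("female") is not None:
            _, p_sex = fisher_z_compare(metas["male"], metas["female"])
            for row in rows:
                if row["region_group"] == region_label and row["strata"] == "male":
                    row["p_sex"] = p_sex

    table = pd.DataFrame(rows)
    if urban_of:
        urban_all = pool((0, 1), lambda r: bool(urban_of.get(r, 0)))
        rural_all = pool((0, 1), lambda r: not urban_of.get(r, 0))
        if urban_all is not None and rural_all is not None:
            _, p_region = fisher_z_compare(urban_all, rural_all)
            table.loc[
                (table["strata"] == "all") & (table["region_group"] == "urban"), "p_region"
            ] = p_region
    table.attrs["n_dropped"] = len(dropped)
    table.attrs["dropped"] = dropped
    return table
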