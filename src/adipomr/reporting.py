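"""Pipeline orchestration, significance conventions and summary tables.

Runs the full analysis from a YAML config, annotates every result row with a
significance tier (none / tentative / corrected) under the conventions used
throughout: P < 0.05 is tentative evidence, with stricter multiple-testing
thresholds of P < 0.025 for the two-sample analyses (two exposure groups) and
P < 0.013 for the one-sample analyses (four exposure-by-residence groups).
Also produces the demographics ("Table 1"-style) case/control summary.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import __version__
from .grs import code_trait_raising_alleles, compute_grs, crossfit_weights, instrument_strength
from .harmonise import align_effect_alleles, apply_exclusion_filters
from .nonlinear import control_function_fit
from .observational import category_or, logistic_or_per_sd
from .onesample import StratumFitError, run_stratified_onesample
from .simulate import SimConfig, simulate_cohort, simulate_sumstats_pair, write_cohort, write_sumstats
from .twosample import median_f_statistic, run_all_estimators

__all__ = [
    "AnalysisConfig",
    "significance_tier",
    "run_pipeline",
    "summarize_demographics",
]

logger = logging.getLogger("adipomr")

TENTATIVE_P = 0.05
TWO_SAMPLE_CORRECTED_P = 0.025
ONE_SAMPLE_CORRECTED_P = 0.013


@dataclass
class AnalysisConfig:
    """Validated run configuration; defaults mirror the package's conventions."""

    seed: int
    n_individuals: int = 20_000
    n_variants: int = 50
    sim: dict = field(default_factory=dict)  # extra SimConfig overrides
    maf_window: tuple[float, float] = (0.45, 0.55)
    named_snps: list[str] = field(default_factory=list)
    n_boot: int = 1000
    pwm_penalty: float = 20.0
    k_blocks: int = 100
    tentative_p: float = TENTATIVE_P
    two_sample_corrected_p: float = TWO_SAMPLE_CORRECTED_P
    one_sample_corrected_p: float = ONE_SAMPLE_CORRECTED_P
    outcome: str = "depressive_symptoms"
    covariates: list[str] = field(default_factory=lambda: ["age"])
    min_case_prevalence: float | None = None

    def __post_init__(self) -> None:
        for name in ("tentative_p", "two_sample_corrected_p", "one_sample_corrected_p"):
            p = getattr(self, name)
            if not 0.0 < p < 1.0:
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.seed is None:
            raise ValueError("seed must be set")
        lo, hi = self.maf_window
        if lo >= hi:
            raise ValueError("maf_window requires lo < hi")
        if self.k_blocks < 2:
            raise ValueError("k_blocks must be >= 2")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValueError("config must be a mapping")
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "maf_window" in raw:
            raw["maf_window"] = tuple(raw["maf_window"])
        return cls(**raw)


def significance_tier(
    p: float, corrected: float, tentative: float = TENTATIVE_P
) -> str:
    """Deterministic tier for one p-value: corrected < tentative < none."""
    if not np.isfinite(p):
        return "none"
    if p < corrected:
        return "corrected"
    if p < tentative:
        return "tentative"
    return "none"


def _stage(name: str, n_in: int | None = None, n_out: int | None = None) -> None:
    msg = f"stage={name}"
    if n_in is not None:
        msg += f" in={n_in}"
    if n_out is not None:
        msg += f" out={n_out}"
    logger.info(msg)


def run_pipeline(config: AnalysisConfig, out_dir: str | Path | None = None) -> dict:
    """Execute the full analysis end-to-end on a simulated cohort.

    Stages in dependency order: simulate (cohort + two-sample summary
    statistics), harmonise + filter, two-sample MR, GRS construction,
    stratified one-sample MR with meta-analysis and contrasts, control-function
    non-linear MR, and the observational per-SD association.  Identical
    config + seed gives byte-identical outputs.
    """
    handler = None
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        handler = logging.FileHandler(out_dir / "run.log", mode="w")
        logger.addHandler(handler)
    if not any(isinstance(h, logging.StreamHandler) for h in logger.handlers):
        logger.addHandler(logging.StreamHandler(sys.stderr))
    logger.setLevel(logging.INFO)

    try:
        sim_kwargs = dict(
            n_individuals=config.n_individuals,
            n_variants=config.n_variants,
            seed=config.seed,
        )
        sim_kwargs.update(config.sim)
        sim = SimConfig(**sim_kwargs)

        cohort = simulate_cohort(sim)
        _stage("simulate_cohort", n_out=len(cohort.data))
        pair = simulate_sumstats_pair(
            SimConfig(**{**sim_kwargs, "seed": sim.seed + 1})
        )
        _stage("simulate_sumstats", n_out=len(pair.exposure_stats))

        hset = align_effect_alleles(pair.exposure_stats, pair.outcome_stats)
        filters = {"maf_window": config.maf_window}
        if config.named_snps:
            filters["named_snps"] = config.named_snps
        hset, counts = apply_exclusion_filters(hset, filters)
        _stage("harmonise", n_in=len(pair.exposure_stats), n_out=hset.n_retained)

        ts = run_all_estimators(hset, n_boot=config.n_boot, seed=config.seed)
        ts["tier"] = [
            significance_tier(p, config.two_sample_corrected_p, config.tentative_p)
            for p in ts["pval"]
        ]
        strength = median_f_statistic(
            pair.exposure_stats[pair.exposure_stats["snp"].isin(hset.table["snp"])]
        )
        _stage("two_sample_mr", n_out=len(ts))

        coding = code_trait_raising_alleles(cohort)
        weights = crossfit_weights(
            cohort, coding, k=config.k_blocks, seed=config.seed,
            pc_cols=[c for c in cohort.data.columns if c.startswith("pc")],
        )
        score = compute_grs(cohort, weights)
        data = cohort.data.loc[score.index].copy()
        data["grs"] = score.to_numpy()
        sex_strata = {
            "male": (data["sex"] == 0).to_numpy(),
            "female": (data["sex"] == 1).to_numpy(),
        }
        strengths = instrument_strength(data["exposure"], data["grs"], sex_strata)
        _stage("grs", n_out=len(score))

        onesample = run_stratified_onesample(
            data, "grs", "exposure", config.outcome,
            covariate_cols=config.covariates,
            min_case_prevalence=config.min_case_prevalence,
        )
        onesample["tier"] = [
            significance_tier(p, config.one_sample_corrected_p, config.tentative_p)
            for p in onesample["pval"]
        ]
        _stage("one_sample_mr", n_out=len(onesample))

        nlmr_rows = []
        for label, mask in (("urban", data["urban"] == 1), ("rural", data["urban"] == 0)):
            try:
                cf = control_function_fit(
                    data, "grs", "exposure", config.outcome,
                    covariate_cols=config.covariates,
                    stratum_mask=mask.to_numpy(), labels={"region_group": label},
                )
            except StratumFitError as exc:
                logger.warning("nlmr stratum %s dropped: %s", label, exc)
                continue
            nlmr_rows.append(
                {
                    "region_group": label, "beta_linear": cf.beta_linear,
                    "se_linear": cf.se_linear, "beta_quadratic": cf.beta_quadratic,
                    "se_quadratic": cf.se_quadratic, "p_quadratic": cf.p_quadratic,
                    "beta_residual": cf.beta_residual, "n": cf.n,
                    "tier": significance_tier(
                        cf.p_quadratic, config.one_sample_corrected_p, config.tentative_p
                    ),
                }
            )
        nlmr = pd.DataFrame(nlmr_rows)
        _stage("nonlinear_mr", n_out=len(nlmr))

        obs = logistic_or_per_sd(
            data, "exposure", config.outcome, covariate_cols=config.covariates + ["sex"]
        )
        _stage("observational", n_out=obs.n)

        results = {
            "cohort": cohort,
            "sumstats": pair,
            "harmonised": hset,
            "filter_counts": counts,
            "two_sample": ts,
            "median_f": strength.median_f,
            "grs_weights": weights,
            "grs_strength": strengths,
            "one_sample": onesample,
            "nonlinear": nlmr,
            "observational": obs,
        }

        if out_dir is not None:
            write_cohort(cohort, out_dir)
            write_sumstats(pair, out_dir)
            hset.write(out_dir / "harmonised.tsv", out_dir / "exclusions.tsv")
            ts.to_csv(out_dir / "two_sample_mr.tsv", sep="\t", index=False)
            onesample.to_csv(out_dir / "one_sample_mr.tsv", sep="\t", index=False)
            nlmr.to_csv(out_dir / "nonlinear_mr.tsv", sep="\t", index=False)
            manifest = {
                "package_version": __version__,
                "seed": config.seed,
                "config": {k: (list(v) if isinstance(v, tuple) else v)
                           for k, v in asdict(config).items()},
                "settings": {
                    "grs_fallback": "non-derivation individuals scored with full-sample weights",
                    "rint_offset": "Blom (3/8)",
                    "wald_se": "first-order delta method",
                    "exposure_centred_in_nlmr": True,
                },
            }
            with open(out_dir / "manifest.json", "w") as fh:
                json.dump(manifest, fh, indent=2, sort_keys=True)
        return results
    finally:
        if handler is not None:
            handler.close()
            logger.removeHandler(handler)


def summarize_demographics(
    data: pd.DataFrame,
    case_col: str,
    continuous: list[str] | None = None,
    binary: list[str] | None = None,
    categorical: list[str] | None = None,
) -> pd.DataFrame:
    """Case/control demographics summary with group-comparison p-values.

    Continuous variables report mean (SD) per group with the p-value from a
    linear regression of the variable on case status; binary variables report
    N (% of column total) with a logistic-regression p; categorical variables
    report per-level N (%) with a single likelihood-ratio p from a logistic
    regression of case status on the category indicators.
    """
    import statsmodels.api as sm

    case = data[case_col].to_numpy(dtype=float)
    if not set(np.unique(case)) <= {0.0, 1.0}:
        raise ValueError("case indicator must be binary")
    n_case, n_ctrl = int(case.sum()), int((1 - case).sum())
    if n_case == 0 or n_ctrl == 0:
        raise ValueError("both groups must be non-empty")
    is_case = case == 1.0
    rows = [{"variable": "N", "level": "", "cases": str(n_case),
             "controls": str(n_ctrl), "pval": np.nan}]

    for var in continuous or []:
        v = data[var].to_numpy(dtype=float)
        if np.ptp(v) == 0:  # no variation: no group difference by construction
            p = 1.0
        else:
            X = np.column_stack([np.ones(v.size), case])
            p = float(sm.OLS(v, X).fit().pvalues[1])
        rows.append(
            {
                "variable": var, "level": "mean (SD)",
                "cases": f"{v[is_case].mean():.2f} ({v[is_case].std(ddof=1):.2f})",
                "controls": f"{v[~is_case].mean():.2f} ({v[~is_case].std(ddof=1):.2f})",
                "pval": p,
            }
        )

    for var in binary or []:
        v = data[var].to_numpy(dtype=float)
        if np.ptp(v) == 0:
            p = 1.0
        else:
            res = sm.Logit(v, np.column_stack([np.ones(v.size), case])).fit(disp=0)
            p = float(res.pvalues[1])
        a, b = int(v[is_case].sum()), int(v[~is_case].sum())
        rows.append(
            {
                "variable": var, "level": "N (%)",
                "cases": f"{a} ({100.0 * a / n_case:.1f})",
                "controls": f"{b} ({100.0 * b / n_ctrl:.1f})",
                "pval": p,
            }
        )

    for var in categorical or []:
        levels = pd.unique(data[var])
        dummies = pd.get_dummies(data[var], drop_first=True).to_numpy(dtype=float)
        full = sm.Logit(case, np.column_stack([np.ones(case.size), dummies])).fit(disp=0)
        null = sm.Logit(case, np.ones((case.size, 1))).fit(disp=0)
        lr = 2.0 * (full.llf - null.llf)
        p = float(stats.chi2.sf(lr, dummies.shape[1]))
        first = True
        for lev in levels:
            v = (data[var] == lev).to_numpy()
            a, b = int(v[is_case].sum()), int(v[~is_case].sum())
            rows.append(
                {
                    "variable": var, "level": str(lev),
                    "cases": f"{a} ({100.0 * a / n_case:.1f})",
                    "controls": f"{b} ({100.0 * b / n_ctrl:.1f})",
                    "pval": p if first else np.nan,
                }
            )
            first = False
    return pd.DataFrame(rows)


def percentage(count: int, total: int, decimals: int = 1) -> float:
    """Column percentage rounded to the table's printed precision."""
    if total <= 0:
        raise ValueError("total must be positive")
    return round(100.0 * count / total, decimals)
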