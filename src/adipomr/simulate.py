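"""Synthetic cohort and GWAS summary-statistic generation.

Emulates the data model of a large population biobank with questionnaire-based
depression phenotyping: biallelic genotype dosages at specified allele
frequencies, a polygenic continuous adiposity exposure with an unmeasured
confounder, a binary depression outcome with optional linear and quadratic
causal effects of the exposure, optional direct (pleiotropic) variant effects
on the outcome, region-structured baseline risk, and CIDI-style depression
items from which case status is re-derivable.

Everything downstream of this module (harmonisation, two-sample MR, genetic
risk scores, one-sample IV estimation, non-linear MR and the observational
contrasts) is exercised on cohorts drawn here, so the generator is first-class,
tested code rather than a fixture.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import norm

__all__ = [
    "SimConfig",
    "CohortDataset",
    "SumStatsPair",
    "simulate_cohort",
    "simulate_sumstats_pair",
    "derive_depression_phenotypes",
    "write_cohort",
    "write_sumstats",
    "read_sumstats",
    "SUMSTAT_COLUMNS",
]

SUMSTAT_COLUMNS = ["snp", "effect_allele", "other_allele", "eaf", "beta", "se", "pval", "n"]

_TRIGGER_COLS = [f"trigger_{i}" for i in range(1, 5)]
_CIDI_COLS = [f"cidi_{i}" for i in range(1, 8)]

# Marginal yes-rates of the four broad-episode trigger items among cases,
# approximating the pattern seen in questionnaire cohorts (the "sad/depressed"
# item dominates).  Controls answer no to every item.
_TRIGGER_RATES_CASES = np.array([0.95, 0.44, 0.30, 0.25])


@dataclass
class SimConfig:
    """Parameters of the synthetic data-generating process.

    Effects are parameterised on the scale the estimators target: the causal
    coefficients are log-odds per 1 SD of the exposure (linear) and per squared
    SD (quadratic); per-variant exposure effects are additive per allele in
    exposure SD units; pleiotropy effects are direct per-allele log-odds on the
    outcome, zero meaning a valid instrument.
    """

    n_individuals: int
    n_variants: int
    maf: np.ndarray | None = None
    variant_effects_exposure: np.ndarray | None = None  # (V,) or (2, V) male/female
    causal_effect_linear: float = 0.0
    causal_effect_quadratic: float = 0.0
    pleiotropy_effects: np.ndarray | None = None
    confounder_effect_exposure: float = 0.0
    confounder_effect_outcome: float = 0.0
    baseline_logit: float = float(logit(0.035))  # ~3.5% case prevalence
    n_regions: int = 10  # 5 urban + 5 rural
    region_intercepts: np.ndarray | None = None
    sex_ratio: float = 0.5  # proportion female
    exposure_noise_sd: float = 1.0
    cidi_symptom_rate: float = 0.25  # per-item yes-rate among cases (free parameter)
    n_pcs: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals < 1 or self.n_variants < 1:
            raise ValueError("n_individuals and n_variants must be positive")
        if self.n_regions < 1:
            raise ValueError("n_regions must be >= 1")
        if not 0.0 <= self.sex_ratio <= 1.0:
            raise ValueError("sex_ratio must lie in [0, 1]")
        V = self.n_variants
        if self.maf is None:
            # frequencies spread over the common-variant range
            self.maf = np.linspace(0.1, 0.5, V)
        self.maf = np.asarray(self.maf, dtype=float)
        if self.maf.shape != (V,):
            raise ValueError("maf must have length n_variants")
        if np.any(self.maf <= 0.0) or np.any(self.maf >= 1.0):
            raise ValueError("all MAFs must lie strictly in (0, 1)")
        if self.variant_effects_exposure is None:
            self.variant_effects_exposure = np.full(V, 0.05)
        self.variant_effects_exposure = np.asarray(self.variant_effects_exposure, dtype=float)
        if self.variant_effects_exposure.shape not in ((V,), (2, V)):
            raise ValueError("variant_effects_exposure must be (n_variants,) or (2, n_variants)")
        if self.pleiotropy_effects is None:
            self.pleiotropy_effects = np.zeros(V)
        self.pleiotropy_effects = np.asarray(self.pleiotropy_effects, dtype=float)
        if self.pleiotropy_effects.shape != (V,):
            raise ValueError("pleiotropy_effects must have length n_variants")
        if self.region_intercepts is None:
            self.region_intercepts = np.zeros(self.n_regions)
        self.region_intercepts = np.asarray(self.region_intercepts, dtype=float)
        if self.region_intercepts.shape != (self.n_regions,):
            raise ValueError("region_intercepts must have length n_regions")
        for name in (
            "causal_effect_linear",
            "causal_effect_quadratic",
            "confounder_effect_exposure",
            "confounder_effect_outcome",
            "baseline_logit",
            "exposure_noise_sd",
        ):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        for name in ("maf", "variant_effects_exposure", "pleiotropy_effects", "region_intercepts"):
            if not np.all(np.isfinite(getattr(self, name))):
                raise ValueError(f"{name} must be finite")
        if self.exposure_noise_sd <= 0 and not np.any(self.variant_effects_exposure):
            raise ValueError("exposure would have zero variance")

    @property
    def sex_specific_effects(self) -> bool:
        return self.variant_effects_exposure.ndim == 2

    def effects_for_sex(self, female: bool) -> np.ndarray:
        if self.sex_specific_effects:
            return self.variant_effects_exposure[1 if female else 0]
        return self.variant_effects_exposure


@dataclass
class CohortDataset:
    """Individual-level table plus variant metadata.

    ``data`` holds one row per individual: dosage columns named by variant id,
    the continuous exposure, the 11 depression item responses, the derived
    binary phenotypes, sex (1 = female), region id, the urban flag, age and
    principal-component columns.  ``variants`` maps variant id to its alleles
    and population allele frequency.
    """

    data: pd.DataFrame
    variants: pd.DataFrame
    config: SimConfig | None = None
    # latent quantities kept for oracle checks in tests; not written to disk
    latent: dict = field(default_factory=dict)

    @property
    def variant_ids(self) -> list[str]:
        return list(self.variants["snp"])

    def dosages(self) -> np.ndarray:
        return self.data[self.variant_ids].to_numpy(dtype=float)


@dataclass
class SumStatsPair:
    """Exposure and outcome GWAS summary statistics from disjoint samples."""

    exposure_stats: pd.DataFrame
    outcome_stats: pd.DataFrame
    true_theta: float


def _variant_table(config: SimConfig) -> pd.DataFrame:
    ids = [f"rs{1000 + j}" for j in range(config.n_variants)]
    # deterministic allele assignment cycling over transitions/transversions
    pairs = [("A", "G"), ("C", "T"), ("A", "C"), ("G", "T")]
    ea, oa = zip(*(pairs[j % 4] for j in range(config.n_variants)))
    return pd.DataFrame(
        {"snp": ids, "effect_allele": ea, "other_allele": oa, "maf": config.maf}
    )


def derive_depression_phenotypes(items: pd.DataFrame | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Derive the binary depression phenotypes from item responses.

    The first four columns are the broad-episode trigger items (feeling
    sad/depressed, worthlessness, loss of interest, loss of appetite); the
    remaining seven are the CIDI-SF symptom items.  An individual is a
    depressive-symptoms case if they answered yes to one or more trigger
    items, and a major-depression case if additionally at least 3 of the 7
    CIDI-SF symptoms are endorsed.
    """
    arr = np.asarray(items, dtype=float)
    if arr.ndim == 1:
        arr = arr[None, :]
    if arr.shape[1] != 11:
        raise ValueError("expected 11 item columns (4 trigger + 7 CIDI-SF)")
    if not np.all(np.isin(arr, (0.0, 1.0))):
        raise ValueError("item responses must be binary")
    triggers, cidi = arr[:, :4], arr[:, 4:]
    depressive_symptoms = (triggers.sum(axis=1) >= 1).astype(int)
    major_depression = (depressive_symptoms.astype(bool) & (cidi.sum(axis=1) >= 3)).astype(int)
    return depressive_symptoms, major_depression


def _draw_items(case: np.ndarray, rate_cidi: float, rng: np.random.Generator) -> np.ndarray:
    """Item responses consistent with the case indicator.

    Cases endorse at least one trigger item (the first item is forced when a
    draw yields none) and endorse each CIDI-SF symptom independently; controls
    answer no throughout, so derivation reproduces the case indicator exactly.
    """
    n = case.shape[0]
    items = np.zeros((n, 11), dtype=int)
    idx = np.flatnonzero(case)
    if idx.size:
        trig = (rng.random((idx.size, 4)) < _TRIGGER_RATES_CASES[None, :]).astype(int)
        none = trig.sum(axis=1) == 0
        trig[none, 0] = 1
        cidi = (rng.random((idx.size, 7)) < rate_cidi).astype(int)
        items[idx, :4] = trig
        items[idx, 4:] = cidi
    return items


def simulate_cohort(config: SimConfig, rng: np.random.Generator | None = None) -> CohortDataset:
    """Draw one cohort from the generative model.

    Dosages are hard allele counts Binomial(2, maf).  The exposure is the
    additive genetic value plus a shared standard-normal confounder U scaled by
    ``confounder_effect_exposure`` plus Gaussian noise.  The outcome is
    Bernoulli with logit equal to baseline + region intercept + linear and
    quadratic effects of the within-sample standardised exposure + direct
    variant effects + ``confounder_effect_outcome``·U.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n, V = config.n_individuals, config.n_variants

    variants = _variant_table(config)
    G = rng.binomial(2, config.maf[None, :], size=(n, V)).astype(float)

    female = (rng.random(n) < config.sex_ratio).astype(int)
    region = rng.integers(0, config.n_regions, size=n)
    urban = (region < (config.n_regions + 1) // 2).astype(int)
    age = np.clip(rng.normal(53.0, 11.0, size=n), 30.0, 79.0)
    pcs = rng.normal(size=(n, config.n_pcs))

    U = rng.normal(size=n)
    if config.sex_specific_effects:
        gamma = np.where(
            female[:, None].astype(bool),
            config.variant_effects_exposure[1][None, :],
            config.variant_effects_exposure[0][None, :],
        )
        genetic_value = (G * gamma).sum(axis=1)
    else:
        genetic_value = G @ config.variant_effects_exposure
    exposure = (
        genetic_value
        + config.confounder_effect_exposure * U
        + rng.normal(scale=config.exposure_noise_sd, size=n)
    )
    sd = exposure.std(ddof=1)
    if sd == 0:
        raise ValueError("simulated exposure has zero variance")
    x_std = (exposure - exposure.mean()) / sd

    eta = (
        config.baseline_logit
        + config.region_intercepts[region]
        + config.causal_effect_linear * x_std
        + config.causal_effect_quadratic * x_std**2
        + G @ config.pleiotropy_effects
        + config.confounder_effect_outcome * U
    )
    p = expit(eta)
    case = rng.binomial(1, p)

    items = _draw_items(case, config.cidi_symptom_rate, rng)
    ds, md = derive_depression_phenotypes(items)
    assert np.array_equal(ds, case)

    data = pd.DataFrame(G, columns=variants["snp"])
    data.insert(0, "iid", [f"ID{i:07d}" for i in range(n)])
    data["sex"] = female
    data["region"] = region
    data["urban"] = urban
    data["age"] = age
    for k in range(config.n_pcs):
        data[f"pc{k + 1}"] = pcs[:, k]
    data["exposure"] = exposure
    for j, c in enumerate(_TRIGGER_COLS + _CIDI_COLS):
        data[c] = items[:, j]
    data["depressive_symptoms"] = ds
    data["major_depression"] = md

    return CohortDataset(
        data=data,
        variants=variants,
        config=config,
        latent={"confounder": U, "linear_predictor": eta, "case_probability": p},
    )


def _marginal_linear(y: np.ndarray, G: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-variant simple linear regression slopes and SEs, vectorised."""
    n = y.shape[0]
    Gc = G - G.mean(axis=0, keepdims=True)
    yc = y - y.mean()
    sxx = (Gc**2).sum(axis=0)
    if np.any(sxx == 0):
        raise ValueError("monomorphic variant in exposure sample")
    beta = (Gc * yc[:, None]).sum(axis=0) / sxx
    sse = (yc**2).sum() - beta**2 * sxx
    se = np.sqrt(np.maximum(sse, 0.0) / (n - 2) / sxx)
    return beta, se


def _marginal_logistic(
    y: np.ndarray, G: np.ndarray, max_iter: int = 40, tol: float = 1e-10
) -> tuple[np.ndarray, np.ndarray]:
    """Per-variant univariate logistic regressions (intercept + dosage).

    Newton iterations are run simultaneously for all variants; each variant's
    2x2 information matrix is solved in closed form.  Agrees with a one-at-a-
    time maximum-likelihood fit to full convergence.
    """
    n, V = G.shape
    ybar = y.mean()
    if ybar in (0.0, 1.0):
        raise ValueError("outcome sample has no cases or no controls")
    if np.any(G.std(axis=0) == 0):
        raise ValueError("monomorphic variant in outcome sample")
    b0 = np.full(V, logit(ybar))
    b1 = np.zeros(V)
    for _ in range(max_iter):
        eta = b0[None, :] + G * b1[None, :]
        mu = expit(eta)
        w = mu * (1.0 - mu)
        r = y[:, None] - mu
        s0 = r.sum(axis=0)
        s1 = (G * r).sum(axis=0)
        i00 = w.sum(axis=0)
        i01 = (G * w).sum(axis=0)
        i11 = (G * G * w).sum(axis=0)
        det = i00 * i11 - i01**2
        d0 = (i11 * s0 - i01 * s1) / det
        d1 = (-i01 * s0 + i00 * s1) / det
        b0 += d0
        b1 += d1
        if max(np.abs(d0).max(), np.abs(d1).max()) < tol:
            break
    else:
        warnings.warn("marginal logistic fits did not fully converge", RuntimeWarning)
    se1 = np.sqrt(i00 / det)
    return b1, se1


def simulate_sumstats_pair(
    config: SimConfig, rng: np.random.Generator | None = None
) -> SumStatsPair:
    """Two-sample GWAS summary statistics from two disjoint cohorts.

    Sample 1 yields per-variant linear-regression effects of each dosage on
    the standardised exposure (betas in exposure-SD units per allele); sample 2
    yields per-variant logistic-regression log-odds effects on the binary
    outcome.  Using the standardised exposure in sample 1 puts the Wald ratio
    directly on the log-odds-per-1-SD scale of ``causal_effect_linear``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    variants = _variant_table(config)

    cohort1 = simulate_cohort(config, rng=rng)
    cohort2 = simulate_cohort(config, rng=rng)

    G1 = cohort1.dosages()
    x = cohort1.data["exposure"].to_numpy()
    x_std = (x - x.mean()) / x.std(ddof=1)
    beta_x, se_x = _marginal_linear(x_std, G1)
    eaf1 = G1.mean(axis=0) / 2.0

    G2 = cohort2.dosages()
    y = cohort2.data["depressive_symptoms"].to_numpy(dtype=float)
    beta_y, se_y = _marginal_logistic(y, G2)
    eaf2 = G2.mean(axis=0) / 2.0

    n = config.n_individuals

    def _records(beta, se, eaf):
        z = beta / se
        return pd.DataFrame(
            {
                "snp": variants["snp"],
                "effect_allele": variants["effect_allele"],
                "other_allele": variants["other_allele"],
                "eaf": eaf,
                "beta": beta,
                "se": se,
                "pval": 2.0 * norm.sf(np.abs(z)),
                "n": n,
            }
        )

    return SumStatsPair(
        exposure_stats=_records(beta_x, se_x, eaf1),
        outcome_stats=_records(beta_y, se_y, eaf2),
        true_theta=config.causal_effect_linear,
    )


# ---------------------------------------------------------------------------
# I/O: headered TSV dialect shared across the package


def write_cohort(cohort: CohortDataset, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort.data.to_csv(out / "cohort.tsv", sep="\t", index=False)
    cohort.variants.to_csv(out / "variants.tsv", sep="\t", index=False)


def write_sumstats(pair: SumStatsPair, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pair.exposure_stats[SUMSTAT_COLUMNS].to_csv(out / "exposure_sumstats.tsv", sep="\t", index=False)
    pair.outcome_stats[SUMSTAT_COLUMNS].to_csv(out / "outcome_sumstats.tsv", sep="\t", index=False)


def read_sumstats(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(SUMSTAT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"summary-statistic file missing columns: {sorted(missing)}")
    return df
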