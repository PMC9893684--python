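"""Genetic risk score construction with cross-fitted weights.

Builds the one-sample instrument: rank-based inverse-normal transformation of
the trait, sex-specific trait-raising-allele coding from joint multivariate
regressions, per-variant weights estimated by leave-block-out cross-fitting
(the derivation subset is split into K random blocks, each block's individuals
are scored with weights estimated with their block excluded, so no phenotype
contributes to its own weights), GRS scoring, and R^2 / F instrument-strength
diagnostics.

Dosages may be fractional in [0, 2] (imputed data); the generator's hard calls
are a special case.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import ndtri
from scipy.stats import rankdata

from .simulate import CohortDataset

__all__ = [
    "VariantCoding",
    "GRSWeights",
    "InstrumentStrengthGRS",
    "rank_inverse_normal",
    "code_trait_raising_alleles",
    "coded_dosages",
    "crossfit_weights",
    "compute_grs",
    "instrument_strength",
]

DEFAULT_K = 100
MAF_MIN = 0.01

_BLOM_NUM = 3.0 / 8.0
_BLOM_DEN = 1.0 / 4.0


def rank_inverse_normal(values: np.ndarray | pd.Series) -> np.ndarray:
    """Blom rank-based inverse-normal transform: Phi^-1((r - 3/8)/(n + 1/4)).

    Ties share the average rank; ranks are computed within the supplied vector.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("need a 1-D vector with at least 2 values")
    if not np.all(np.isfinite(x)):
        raise ValueError("values must be finite")
    if np.ptp(x) == 0:
        raise ValueError("all values identical: transform undefined")
    r = rankdata(x, method="average")
    return ndtri((r - _BLOM_NUM) / (x.size + _BLOM_DEN))


@dataclass
class GRSWeights:
    """Cross-fitted per-variant weights plus full-sample fallback weights.

    ``block`` maps derivation-subset individuals (by position in the cohort) to
    their block; ``weights[sex]`` is a (K, V) array whose row b was estimated
    with block b's individuals excluded; ``full_weights[sex]`` is the
    all-derivation-individuals fit, used for individuals outside the
    derivation subset (an assumption, flagged here and in output metadata).
    """

    variant_ids: list[str]
    coding: pd.DataFrame
    block: pd.Series  # index = cohort row position (derivation subset only)
    weights: dict[int, np.ndarray]  # sex (0 male / 1 female) -> (K, V)
    full_weights: dict[int, np.ndarray]  # sex -> (V,)
    k: int
    excluded_variants: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["snp", "reason"])
    )
    notes: str = "non-derivation individuals scored with full-derivation-sample weights"

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for sex, W in self.weights.items():
            for b in range(self.k):
                for j, snp in enumerate(self.variant_ids):
                    rows.append(
                        {
                            "snp": snp,
                            "coded_allele": self.coding.set_index("snp").loc[snp, "coded_allele"],
                            "sex": sex,
                            "block": b,
                            "weight": W[b, j],
                        }
                    )
        return pd.DataFrame(rows)


VariantCoding = pd.DataFrame  # columns: snp, coded_allele, beta_male, beta_female, ...


@dataclass
class InstrumentStrengthGRS:
    stratum: str
    r_squared: float
    f_statistic: float
    n: int


def _sex_joint_betas(
    cohort: CohortDataset, trait: str, variant_ids: list[str], female: int,
    pc_cols: list[str] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Joint OLS of the within-sex RINT trait on all dosages simultaneously."""
    mask = cohort.data["sex"].to_numpy() == female
    if mask.sum() < len(variant_ids) + 2:
        raise ValueError("too few individuals of one sex for the joint regression")
    y = rank_inverse_normal(cohort.data.loc[mask, trait].to_numpy())
    G = cohort.data.loc[mask, variant_ids].to_numpy(dtype=float)
    covs = [np.ones((mask.sum(), 1))]
    if pc_cols:
        covs.append(cohort.data.loc[mask, pc_cols].to_numpy(dtype=float))
    X = np.hstack([G] + covs)
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        raise ValueError("singular design: collinear variants in joint regression")
    resid = y - X @ coef
    sigma2 = resid @ resid / (mask.sum() - X.shape[1])
    cov = np.linalg.inv(X.T @ X) * sigma2
    se = np.sqrt(np.diag(cov)[: len(variant_ids)])
    return coef[: len(variant_ids)], se


def code_trait_raising_alleles(
    cohort: CohortDataset,
    trait: str = "exposure",
    variant_ids: list[str] | None = None,
    pc_cols: list[str] | None = None,
) -> pd.DataFrame:
    """Determine the coded (trait-raising) allele per variant, shared across sexes.

    The RINT trait is regressed jointly on all variant dosages within each sex.
    The coded allele is the trait-raising allele; when the sexes disagree, the
    sex with the larger absolute effect decides, and the same coded allele is
    applied to both sexes.
    """
    if variant_ids is None:
        variant_ids = cohort.variant_ids
    sexes = set(cohort.data["sex"].unique())
    if sexes != {0, 1}:
        raise ValueError("both sexes must be represented")
    beta_m, se_m = _sex_joint_betas(cohort, trait, variant_ids, female=0, pc_cols=pc_cols)
    beta_f, se_f = _sex_joint_betas(cohort, trait, variant_ids, female=1, pc_cols=pc_cols)

    vmeta = cohort.variants.set_index("snp")
    rows = []
    for j, snp in enumerate(variant_ids):
        ea, oa = vmeta.loc[snp, "effect_allele"], vmeta.loc[snp, "other_allele"]
        raise_m = ea if beta_m[j] > 0 else oa
        raise_f = ea if beta_f[j] > 0 else oa
        if raise_m == raise_f:
            coded, source = raise_m, "concordant"
        elif abs(beta_m[j]) >= abs(beta_f[j]):
            coded, source = raise_m, "male"
        else:
            coded, source = raise_f, "female"
        rows.append(
            {
                "snp": snp,
                "effect_allele": ea,
                "other_allele": oa,
                "coded_allele": coded,
                "beta_male": beta_m[j],
                "se_male": se_m[j],
                "beta_female": beta_f[j],
                "se_female": se_f[j],
                "coding_source_sex": source,
                "flipped": coded != ea,
            }
        )
    return pd.DataFrame(rows)


def coded_dosages(cohort: CohortDataset, coding: pd.DataFrame) -> np.ndarray:
    """Dosage matrix re-oriented to count copies of the coded allele."""
    ids = list(coding["snp"])
    G = cohort.data[ids].to_numpy(dtype=float)
    flip = coding["flipped"].to_numpy(dtype=bool)
    G = G.copy()
    G[:, flip] = 2.0 - G[:, flip]
    return G


def crossfit_weights(
    cohort: CohortDataset,
    coding: pd.DataFrame,
    trait: str = "exposure",
    k: int = DEFAULT_K,
    seed: int | None = None,
    derivation_col: str | None = None,
    pc_cols: list[str] | None = None,
    maf_min: float = MAF_MIN,
) -> GRSWeights:
    """Leave-block-out cross-fitted weights from the derivation subset.

    Within each sex of the derivation subset, individuals are split into ``k``
    uniformly random blocks (seeded).  For each block, the within-sex RINT
    trait is regressed jointly on all coded dosages (plus principal-component
    adjustment covariates whose coefficients are discarded) with that block's
    individuals excluded; the resulting variant coefficients are the weights
    applied to the excluded block.  Variants with cohort MAF below ``maf_min``
    are excluded before weighting.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    ids = list(coding["snp"])
    # MAF screen on the cohort's own dosages
    freq = cohort.data[ids].to_numpy(dtype=float).mean(axis=0) / 2.0
    maf = np.minimum(freq, 1.0 - freq)
    keep = maf >= maf_min
    excluded = pd.DataFrame(
        {"snp": np.array(ids)[~keep], "reason": "maf_below_threshold"}
    )
    coding = coding.loc[keep.tolist()].reset_index(drop=True)
    ids = list(coding["snp"])
    V = len(ids)
    if V == 0:
        raise ValueError("no variants pass the MAF screen")

    G_all = coded_dosages(cohort, coding)
    if derivation_col is None:
        deriv = np.ones(len(cohort.data), dtype=bool)
    else:
        deriv = cohort.data[derivation_col].to_numpy(dtype=bool)
    sex = cohort.data["sex"].to_numpy()

    rng = np.random.default_rng(seed)
    deriv_idx = np.flatnonzero(deriv)
    if deriv_idx.size < k:
        raise ValueError("a block would have zero members; reduce k or enlarge the subset")
    # balanced assignment: block sizes differ by at most 1
    blocks = rng.permutation(np.arange(deriv_idx.size) % k)
    block_series = pd.Series(blocks, index=deriv_idx)

    weights: dict[int, np.ndarray] = {}
    full_weights: dict[int, np.ndarray] = {}
    for s in (0, 1):
        rows = deriv_idx[sex[deriv_idx] == s]
        if rows.size < V + k + 2:
            raise ValueError("derivation subset too small relative to k and variant count")
        y = rank_inverse_normal(cohort.data.loc[rows, trait].to_numpy())
        parts = [G_all[rows], np.ones((rows.size, 1))]
        if pc_cols:
            parts.append(cohort.data.loc[rows, pc_cols].to_numpy(dtype=float))
        X = np.hstack(parts)
        # leave-block-out solves via sufficient-statistic downdating: the
        # held-out block's X'X and X'y contributions are subtracted from the
        # full-sample cross-products, which is algebraically identical to
        # refitting on the remaining rows
        xtx = X.T @ X
        xty = X.T @ y
        full_weights[s] = np.linalg.solve(xtx, xty)[:V]
        W = np.empty((k, V))
        b_of_rows = block_series.loc[rows].to_numpy()
        for b in range(k):
            m = b_of_rows == b
            Xb, yb = X[m], y[m]
            coef = np.linalg.solve(xtx - Xb.T @ Xb, xty - Xb.T @ yb)
            W[b] = coef[:V]
        weights[s] = W

    return GRSWeights(
        variant_ids=ids,
        coding=coding,
        block=block_series,
        weights=weights,
        full_weights=full_weights,
        k=k,
        excluded_variants=excluded,
    )


def compute_grs(cohort: CohortDataset, w: GRSWeights) -> pd.Series:
    """Per-individual genetic risk score.

    Derivation-subset individuals are scored with the weight vector estimated
    without their own block; all others receive the full-derivation-sample
    weights for their sex.  Individuals with any missing dosage are dropped
    (complete-case) and their count recorded via the returned series' length.
    """
    G = coded_dosages(cohort, w.coding)
    complete = ~np.isnan(G).any(axis=1)
    sex = cohort.data["sex"].to_numpy()
    score = np.full(len(cohort.data), np.nan)
    for s in (0, 1):
        rows = np.flatnonzero((sex == s) & complete)
        if rows.size == 0:
            continue
        wt = np.tile(w.full_weights[s], (rows.size, 1))
        in_deriv = np.isin(rows, w.block.index)
        if in_deriv.any():
            b = w.block.loc[rows[in_deriv]].to_numpy()
            wt[in_deriv] = w.weights[s][b]
        score[rows] = np.einsum("ij,ij->i", G[rows], wt)
    out = pd.Series(score, index=cohort.data.index, name="grs")
    return out[complete]


def instrument_strength(
    trait: np.ndarray | pd.Series,
    score: np.ndarray | pd.Series,
    strata: dict[str, np.ndarray] | None = None,
) -> list[InstrumentStrengthGRS]:
    """Per-stratum R^2 and F of the raw trait on the GRS.

    F = R^2 (n - 2) / (1 - R^2), the univariate-regression F statistic.
    """
    trait = np.asarray(trait, dtype=float)
    score = np.asarray(score, dtype=float)
    if strata is None:
        strata = {"all": np.ones(trait.size, dtype=bool)}
    out = []
    for name, mask in strata.items():
        n = int(mask.sum())
        if n < 3:
            raise ValueError(f"stratum '{name}' has fewer than 3 individuals")
        r = np.corrcoef(trait[mask], score[mask])[0, 1]
        r2 = float(r**2)
        f = float(r2 * (n - 2) / (1.0 - r2)) if r2 < 1 else float("inf")
        out.append(InstrumentStrengthGRS(stratum=name, r_squared=r2, f_statistic=f, n=n))
    return out


def write_weights(w: GRSWeights, path: str | Path) -> None:
    w.to_frame().to_csv(path, sep="\t", index=False)


def write_scores(cohort: CohortDataset, score: pd.Series, path: str | Path) -> None:
    df = cohort.data.loc[score.index, ["iid", "sex", "region"]].copy()
    df["grs"] = score.to_numpy()
    df.to_csv(path, sep="\t", index=False)
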