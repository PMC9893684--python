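"""Harmonisation of exposure and outcome GWAS summary statistics.

Aligns the two datasets to a common effect allele and applies the variant
exclusion filters used before two-sample MR: a minor-allele-frequency window
around 0.5 (guarding against harmonisation error for near-palindromic-risk
frequencies), removal of variants whose trait-raising allele is discordant
between two ancestry-specific effect estimates, and removal of named variants.

Strand-complement rescue is deliberately not attempted: alleles that neither
match nor swap are excluded, and the MAF window is the sole guard against
ambiguous alignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["HarmonisedSet", "align_effect_alleles", "apply_exclusion_filters"]

REASON_MISSING = "missing_in_outcome"
REASON_MISMATCH = "allele_mismatch"
REASON_MAF_WINDOW = "maf_window"
REASON_DISCORDANT = "discordant_raising_allele"
REASON_NAMED = "named_snp"

_KNOWN_FILTERS = {"maf_window", "discordant_raising_allele", "named_snps"}


@dataclass
class HarmonisedSet:
    """Aligned exposure/outcome effect pairs plus a machine-readable exclusion log.

    ``table`` has one row per retained variant with both effects expressed for
    the shared effect allele; ``exclusions`` records every removed variant with
    exactly one primary reason code, so filter counts on real inputs can be
    reproduced.
    """

    table: pd.DataFrame
    exclusions: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["snp", "reason"])
    )

    @property
    def n_retained(self) -> int:
        return len(self.table)

    def write(self, table_path, exclusions_path=None) -> None:
        self.table.to_csv(table_path, sep="\t", index=False)
        if exclusions_path is not None:
            self.exclusions.to_csv(exclusions_path, sep="\t", index=False)


def _check_records(df: pd.DataFrame, label: str) -> None:
    if df["snp"].duplicated().any():
        dups = df.loc[df["snp"].duplicated(), "snp"].tolist()
        raise ValueError(f"duplicate variant ids in {label} dataset: {dups[:5]}")
    if (df["se"] <= 0).any():
        raise ValueError(f"non-positive SE in {label} dataset")
    if (df["effect_allele"] == df["other_allele"]).any():
        raise ValueError(f"identical effect and other allele in {label} dataset")


def align_effect_alleles(exposure: pd.DataFrame, outcome: pd.DataFrame) -> HarmonisedSet:
    """Orient outcome effects onto the exposure dataset's effect alleles.

    For each exposure variant found in the outcome dataset: a matching allele
    pair is retained as-is; a swapped pair (outcome effect allele equals the
    exposure other allele and vice versa) has its outcome beta negated and its
    EAF replaced by 1 - EAF; any other pair is excluded as irreconcilable.
    Variants absent from the outcome dataset are logged as missing.
    """
    _check_records(exposure, "exposure")
    _check_records(outcome, "outcome")

    out_idx = outcome.set_index("snp")
    rows, excl = [], []
    for rec in exposure.itertuples(index=False):
        if rec.snp not in out_idx.index:
            excl.append((rec.snp, REASON_MISSING))
            continue
        o = out_idx.loc[rec.snp]
        beta_o, eaf_o = float(o["beta"]), float(o["eaf"])
        if o["effect_allele"] == rec.effect_allele and o["other_allele"] == rec.other_allele:
            pass
        elif o["effect_allele"] == rec.other_allele and o["other_allele"] == rec.effect_allele:
            beta_o = -beta_o
            eaf_o = 1.0 - eaf_o
        else:
            excl.append((rec.snp, REASON_MISMATCH))
            continue
        rows.append(
            {
                "snp": rec.snp,
                "effect_allele": rec.effect_allele,
                "other_allele": rec.other_allele,
                "beta_exposure": float(rec.beta),
                "se_exposure": float(rec.se),
                "eaf_exposure": float(rec.eaf),
                "beta_outcome": beta_o,
                "se_outcome": float(o["se"]),
                "eaf_outcome": eaf_o,
            }
        )
    cols = [
        "snp", "effect_allele", "other_allele",
        "beta_exposure", "se_exposure", "eaf_exposure",
        "beta_outcome", "se_outcome", "eaf_outcome",
    ]
    table = pd.DataFrame(rows, columns=cols)
    exclusions = pd.DataFrame(excl, columns=["snp", "reason"])
    return HarmonisedSet(table=table, exclusions=exclusions)


def _raising_allele(beta: float, effect_allele: str, other_allele: str) -> str:
    return effect_allele if beta > 0 else other_allele


def apply_exclusion_filters(
    hset: HarmonisedSet, filters: dict
) -> tuple[HarmonisedSet, dict[str, int]]:
    """Apply named exclusion filters, returning the filtered set and per-filter counts.

    Supported filters:

    - ``maf_window``: ``(lo, hi)`` — remove variants whose outcome-side MAF,
      computed as min(eaf, 1-eaf), lies strictly inside the open interval.
      Boundary values are retained.
    - ``discordant_raising_allele``: a DataFrame with columns snp,
      effect_allele, other_allele, beta giving an independent ancestry's
      effect estimates; variants whose trait-raising allele differs between
      the exposure dataset and this reference are removed.
    - ``named_snps``: list of variant ids to remove.
    """
    unknown = set(filters) - _KNOWN_FILTERS
    if unknown:
        raise ValueError(f"unknown filter(s): {sorted(unknown)}")

    table = hset.table.copy()
    new_excl: list[tuple[str, str]] = []
    counts: dict[str, int] = {}

    if "maf_window" in filters:
        lo, hi = filters["maf_window"]
        if lo >= hi:
            raise ValueError("maf_window requires lo < hi")
        maf = np.minimum(table["eaf_outcome"], 1.0 - table["eaf_outcome"])
        drop = (maf > lo) & (maf < hi)
        counts["maf_window"] = int(drop.sum())
        new_excl += [(s, REASON_MAF_WINDOW) for s in table.loc[drop, "snp"]]
        table = table.loc[~drop]

    if "discordant_raising_allele" in filters:
        ref = filters["discordant_raising_allele"].set_index("snp")
        drop_ids = []
        for rec in table.itertuples(index=False):
            if rec.snp not in ref.index:
                continue
            r = ref.loc[rec.snp]
            ours = _raising_allele(rec.beta_exposure, rec.effect_allele, rec.other_allele)
            theirs = _raising_allele(float(r["beta"]), r["effect_allele"], r["other_allele"])
            if ours != theirs:
                drop_ids.append(rec.snp)
        counts["discordant_raising_allele"] = len(drop_ids)
        new_excl += [(s, REASON_DISCORDANT) for s in drop_ids]
        table = table.loc[~table["snp"].isin(drop_ids)]

    if "named_snps" in filters:
        names = set(filters["named_snps"])
        drop = table["snp"].isin(names)
        counts["named_snps"] = int(drop.sum())
        new_excl += [(s, REASON_NAMED) for s in table.loc[drop, "snp"]]
        table = table.loc[~drop]

    exclusions = pd.concat(
        [hset.exclusions, pd.DataFrame(new_excl, columns=["snp", "reason"])],
        ignore_index=True,
    )
    return HarmonisedSet(table=table.reset_index(drop=True), exclusions=exclusions), counts
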