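"""RINT, allele coding, cross-fitted weights and GRS scoring."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.stats import norm

from adipomr import (
    SimConfig,
    code_trait_raising_alleles,
    coded_dosages,
    compute_grs,
    crossfit_weights,
    instrument_strength,
    rank_inverse_normal,
    simulate_cohort,
)


# --- rank inverse-normal transform ----------------------------------------

def test_rint_symmetry_and_blom_quantiles():
    out = rank_inverse_normal(np.array([1.0, 2.0, 3.0]))
    assert out[1] == pytest.approx(0.0)
    assert out[0] == pytest.approx(-out[2])
    v5 = rank_inverse_normal(np.array([10.0, 20.0, 30.0, 40.0, 50.0]))
    expected = norm.ppf((np.arange(1, 6) - 3.0 / 8.0) / (5 + 0.25))
    np.testing.assert_allclose(v5, expected)


def test_rint_rank_invariance_and_tie_handling():
    x = np.array([3.0, 1.0, 10.0, 7.0])
    np.testing.assert_allclose(rank_inverse_normal(x), rank_inverse_normal(np.exp(x)))
    tied = rank_inverse_normal(np.array([1.0, 2.0, 2.0, 5.0]))
    assert tied[1] == pytest.approx(tied[2])


def test_rint_output_passes_moment_normality_check():
    rng = np.random.default_rng(0)
    z = rank_inverse_normal(rng.exponential(size=500))  # heavily skewed input
    assert abs(z.mean()) < 0.05
    assert z.std() == pytest.approx(1.0, abs=0.05)
    assert abs(((z - z.mean()) ** 3).mean()) < 0.05  # skewness removed


def test_rint_rejects_degenerate_input():
    with pytest.raises(ValueError, match="identical"):
        rank_inverse_normal(np.ones(10))


# --- trait-raising allele coding ------------------------------------------

@pytest.fixture(scope="module")
def sexed_cohort():
    # variant 0 has opposite effects by sex, male effect larger
    eff = np.full((2, 6), 0.15)
    eff[0, 0], eff[1, 0] = 0.25, -0.10   # male +, female -
    eff[0, 1], eff[1, 1] = -0.05, 0.20   # male -, female + (female larger)
    cfg = SimConfig(
        n_individuals=12_000, n_variants=6, variant_effects_exposure=eff, seed=21,
    )
    return simulate_cohort(cfg)


def test_coded_allele_follows_larger_sex_effect(sexed_cohort):
    coding = code_trait_raising_alleles(sexed_cohort)
    v = sexed_cohort.variants.set_index("snp")
    row0 = coding.iloc[0]
    assert row0["coding_source_sex"] == "male"
    assert row0["coded_allele"] == v.iloc[0]["effect_allele"]
    row1 = coding.iloc[1]
    assert row1["coding_source_sex"] == "female"
    assert row1["coded_allele"] == v.iloc[1]["effect_allele"]
    assert (coding.iloc[2:]["coding_source_sex"] == "concordant").all()


def test_coding_is_idempotent(sexed_cohort):
    c1 = code_trait_raising_alleles(sexed_cohort)
    c2 = code_trait_raising_alleles(sexed_cohort)
    pd.testing.assert_frame_equal(c1, c2)


# --- cross-fitted weights --------------------------------------------------

@pytest.fixture(scope="module")
def fitted(small_cohort):
    coding = code_trait_raising_alleles(small_cohort)
    weights = crossfit_weights(
        small_cohort, coding, k=10, seed=3, pc_cols=["pc1", "pc2", "pc3", "pc4"]
    )
    return coding, weights


def test_crossfit_honesty_by_explicit_refit(small_cohort, fitted):
    """Each block's stored weights equal an independent OLS fit that excludes
    that block's individuals, so no phenotype informs its own weights."""
    coding, w = fitted
    G = coded_dosages(small_cohort, coding)
    sex = small_cohort.data["sex"].to_numpy()
    rng = np.random.default_rng(0)
    for b in rng.choice(w.k, size=5, replace=False):
        for s in (0, 1):
            rows = np.array([i for i in w.block.index if sex[i] == s])
            y = rank_inverse_normal(small_cohort.data.loc[rows, "exposure"].to_numpy())
            in_block = w.block.loc[rows].to_numpy() == b
            keep = rows[~in_block]
            ykeep = y[~in_block]
            X = np.column_stack(
                [G[keep], np.ones(keep.size),
                 small_cohort.data.loc[keep, ["pc1", "pc2", "pc3", "pc4"]].to_numpy()]
            )
            ref = sm.OLS(ykeep, X).fit()
            np.testing.assert_allclose(
                w.weights[s][b], ref.params[: len(w.variant_ids)], atol=1e-8
            )


def test_two_block_weights_agree_and_track_full_sample():
    # strong, varied effects so weight noise is small relative to signal
    gamma = np.linspace(0.08, 0.35, 8)
    cfg = SimConfig(
        n_individuals=30_000, n_variants=8, variant_effects_exposure=gamma, seed=17,
    )
    cohort = simulate_cohort(cfg)
    coding = code_trait_raising_alleles(cohort)
    w = crossfit_weights(cohort, coding, k=2, seed=5)
    for s in (0, 1):
        # homogeneous data: the two leave-half-out weight vectors agree within
        # sampling error of each other
        a, b = w.weights[s]
        se = 1.0 / np.sqrt(len(cohort.data) / 4 * 2 * cfg.maf * (1 - cfg.maf))
        assert np.all(np.abs(a - b) < 6 * se)
        assert np.corrcoef(a, b)[0, 1] > 0.8
    score_cf = compute_grs(cohort, w)
    # full-sample-weighted score as oracle
    G = coded_dosages(cohort, coding)
    sex = cohort.data["sex"].to_numpy()
    full = np.where(sex == 0, G @ w.full_weights[0], G @ w.full_weights[1])
    assert np.corrcoef(score_cf.to_numpy(), full)[0, 1] > 0.99


def test_low_maf_variants_excluded_before_weighting():
    maf = np.array([0.3, 0.005, 0.2, 0.4])
    cfg = SimConfig(
        n_individuals=8000, n_variants=4, maf=maf,
        variant_effects_exposure=np.full(4, 0.1), seed=9,
    )
    cohort = simulate_cohort(cfg)
    coding = code_trait_raising_alleles(cohort)
    w = crossfit_weights(cohort, coding, k=5, seed=1)
    assert len(w.variant_ids) == 3
    assert list(w.excluded_variants["snp"]) == ["rs1001"]
    assert (w.excluded_variants["reason"] == "maf_below_threshold").all()


def test_crossfit_requires_k_at_least_two(small_cohort, fitted):
    coding, _ = fitted
    with pytest.raises(ValueError, match="k must be"):
        crossfit_weights(small_cohort, coding, k=1, seed=0)


# --- GRS scoring -----------------------------------------------------------

def test_grs_linear_in_weights(small_cohort, fitted):
    coding, w = fitted
    score = compute_grs(small_cohort, w)
    assert len(score) == len(small_cohort.data)
    # all-zero weights give all-zero scores
    import copy

    w0 = copy.deepcopy(w)
    for s in (0, 1):
        w0.weights[s][:] = 0.0
        w0.full_weights[s][:] = 0.0
    assert (compute_grs(small_cohort, w0) == 0.0).all()
    # single variant with unit weight reproduces the coded dosage
    w1 = copy.deepcopy(w)
    for s in (0, 1):
        w1.weights[s][:] = 0.0
        w1.full_weights[s][:] = 0.0
        w1.weights[s][:, 0] = 1.0
        w1.full_weights[s][0] = 1.0
    G = coded_dosages(small_cohort, coding)
    np.testing.assert_allclose(compute_grs(small_cohort, w1).to_numpy(), G[:, 0])


def test_allele_coding_coflip_invariance(small_cohort, fitted):
    """Flipping a variant's coded allele (dosage -> 2-dosage, weight -> -weight)
    shifts every score by a constant, leaving R^2 and F unchanged.

    Stated for a shared weight vector: under cross-fitting the shift constant
    is block-specific, so the blocks here are collapsed onto the full-sample
    weights before flipping."""
    import copy

    coding, w = fitted
    w = copy.deepcopy(w)
    for s in (0, 1):
        w.weights[s][:] = w.full_weights[s][None, :]
    score = compute_grs(small_cohort, w)
    wf = copy.deepcopy(w)
    j = 0
    wf.coding = wf.coding.copy()
    wf.coding.loc[j, "flipped"] = not wf.coding.loc[j, "flipped"]
    new_coded = (
        wf.coding.loc[j, "other_allele"]
        if wf.coding.loc[j, "coded_allele"] == wf.coding.loc[j, "effect_allele"]
        else wf.coding.loc[j, "effect_allele"]
    )
    wf.coding.loc[j, "coded_allele"] = new_coded
    for s in (0, 1):
        wf.weights[s][:, j] *= -1.0
        wf.full_weights[s][j] *= -1.0
    flipped = compute_grs(small_cohort, wf)
    trait = small_cohort.data["exposure"]
    # the shift constant is sex-specific (weights are per sex), so R^2 and F
    # are compared within sex strata
    strata = {
        "male": (small_cohort.data["sex"] == 0).to_numpy(),
        "female": (small_cohort.data["sex"] == 1).to_numpy(),
    }
    for s1, s2 in zip(
        instrument_strength(trait, score, strata),
        instrument_strength(trait, flipped, strata),
    ):
        assert s1.r_squared == pytest.approx(s2.r_squared, rel=1e-9)
        assert s1.f_statistic == pytest.approx(s2.f_statistic, rel=1e-9)


# --- instrument strength ---------------------------------------------------

def test_f_closed_form():
    rng = np.random.default_rng(1)
    score = rng.normal(size=102)
    # construct a trait with R^2 exactly 0.5 against the score
    resid = rng.normal(size=102)
    resid -= np.polyval(np.polyfit(score, resid, 1), score)  # orthogonalise
    sc = (score - score.mean()) / score.std()
    rc = (resid - resid.mean()) / resid.std()
    trait = sc + rc
    s = instrument_strength(trait, score)[0]
    assert s.r_squared == pytest.approx(0.5, abs=1e-9)
    assert s.f_statistic == pytest.approx(100.0, abs=1e-6)


def test_r_squared_matches_analytic_variance_decomposition():
    """Strong simulation: R^2 of trait on the true-weighted score approaches
    the analytic share sum(2 p (1-p) gamma^2) / Var(X)."""
    gamma = np.full(20, 0.12)
    maf = np.linspace(0.15, 0.45, 20)
    cfg = SimConfig(
        n_individuals=30_000, n_variants=20, maf=maf,
        variant_effects_exposure=gamma, exposure_noise_sd=1.0, seed=33,
    )
    cohort = simulate_cohort(cfg)
    G = cohort.dosages()
    score = G @ gamma
    var_g = np.sum(2 * maf * (1 - maf) * gamma**2)
    expected_r2 = var_g / (var_g + 1.0)
    s = instrument_strength(cohort.data["exposure"], score)[0]
    assert s.r_squared == pytest.approx(expected_r2, rel=0.1)
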