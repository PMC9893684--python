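"""Two-sample MR estimators against closed forms and independent fits."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st

from adipomr import (
    ivw,
    median_f_statistic,
    mr_egger,
    penalised_weighted_median,
    wald_ratios,
    weighted_median,
)
from adipomr.twosample import _weighted_median_point
from conftest import make_ratios


def make_hset_table(bx, sex, by, sey):
    return pd.DataFrame(
        {
            "snp": [f"rs{i}" for i in range(len(bx))],
            "beta_exposure": bx, "se_exposure": sex,
            "beta_outcome": by, "se_outcome": sey,
        }
    )


# --- Wald ratios -----------------------------------------------------------

def test_wald_ratio_definition_and_sign():
    t = make_hset_table([0.1, -0.1], [0.01, 0.01], [0.05, 0.05], [0.01, 0.01])
    r = wald_ratios(t)
    assert r["ratio"].tolist() == pytest.approx([0.5, -0.5])
    assert r["se"].tolist() == pytest.approx([0.1, 0.1])


def test_wald_ratios_match_elementwise_arithmetic():
    rng = np.random.default_rng(1)
    bx = rng.normal(0.1, 0.03, 10)
    by = rng.normal(0.0, 0.02, 10)
    sey = rng.uniform(0.005, 0.02, 10)
    r = wald_ratios(make_hset_table(bx, np.full(10, 0.01), by, sey))
    np.testing.assert_allclose(r["ratio"], by / bx)
    np.testing.assert_allclose(r["se"], sey / np.abs(bx))
    np.testing.assert_allclose(r["weight"], (np.abs(bx) / sey) ** 2)


def test_zero_exposure_beta_dropped_with_warning():
    t = make_hset_table([0.1, 0.0], [0.01, 0.01], [0.05, 0.05], [0.01, 0.01])
    with pytest.warns(RuntimeWarning, match="zero exposure beta"):
        r = wald_ratios(t)
    assert len(r) == 1


# --- IVW -------------------------------------------------------------------

def test_ivw_single_and_replicated_ratios():
    single = ivw(make_ratios([0.5], [0.1]))
    assert (single.beta, single.se, single.cochran_q) == pytest.approx((0.5, 0.1, 0.0))
    double = ivw(make_ratios([0.5, 0.5], [0.1, 0.1]))
    assert double.beta == pytest.approx(0.5)
    assert double.se == pytest.approx(0.1 / np.sqrt(2))
    assert double.cochran_q == pytest.approx(0.0)
    assert double.i2 == 0.0


def test_ivw_equals_zero_intercept_weighted_regression():
    rng = np.random.default_rng(2)
    bx = rng.normal(0.1, 0.02, 25)
    by = 0.3 * bx + rng.normal(0, 0.01, 25)
    sey = rng.uniform(0.005, 0.02, 25)
    t = make_hset_table(bx, np.full(25, 0.01), by, sey)
    est = ivw(wald_ratios(t))
    wls = sm.WLS(by, bx[:, None], weights=1.0 / sey**2).fit()
    assert est.beta == pytest.approx(wls.params[0], abs=1e-10)


def test_random_effects_se_never_below_fixed():
    r = make_ratios([0.0, 0.4, 0.8], [0.05, 0.05, 0.05])
    fixed, random_ = ivw(r, "fixed"), ivw(r, "random")
    assert random_.se >= fixed.se
    assert random_.se == pytest.approx(fixed.se * np.sqrt(fixed.cochran_q / 2))
    homog = make_ratios([0.5, 0.5, 0.5], [0.1, 0.1, 0.1])
    assert ivw(homog, "random").se == pytest.approx(ivw(homog, "fixed").se)


def test_i_squared_range_and_closed_form():
    r = make_ratios([0.0, 0.4], [0.1, 0.1])
    est = ivw(r)
    assert est.cochran_q == pytest.approx(8.0)
    assert est.i2 == pytest.approx(87.5)
    assert 0.0 <= est.i2 < 100.0


# --- MR-Egger --------------------------------------------------------------

def test_egger_recovers_exact_affine_relation():
    bx = np.array([0.05, 0.10, 0.15, 0.20])
    t = make_hset_table(bx, np.full(4, 0.01), 0.5 * bx, np.full(4, 0.01))
    est = mr_egger(t)
    assert est.beta == pytest.approx(0.5, abs=1e-12)
    assert est.egger_intercept == pytest.approx(0.0, abs=1e-12)
    est2 = mr_egger(make_hset_table(bx, np.full(4, 0.01), 0.5 * bx + 0.02, np.full(4, 0.01)))
    assert est2.beta == pytest.approx(0.5, abs=1e-12)
    assert est2.egger_intercept == pytest.approx(0.02, abs=1e-12)


def test_egger_orientation_flips_pairs_jointly():
    bx = np.array([0.05, -0.10, 0.15, -0.20])
    by = 0.5 * bx + 0.02 * np.sign(bx)  # pleiotropy aligned with orientation
    est = mr_egger(make_hset_table(bx, np.full(4, 0.01), by, np.full(4, 0.01)))
    assert est.beta == pytest.approx(0.5, abs=1e-12)
    assert est.egger_intercept == pytest.approx(0.02, abs=1e-12)


def test_egger_reduces_to_ivw_without_intercept():
    rng = np.random.default_rng(3)
    bx = np.abs(rng.normal(0.1, 0.03, 15))
    by = 0.4 * bx + rng.normal(0, 0.01, 15)
    sey = rng.uniform(0.005, 0.02, 15)
    t = make_hset_table(bx, np.full(15, 0.01), by, sey)
    est_ivw = ivw(wald_ratios(t))
    # refit the Egger regression with the intercept constrained to zero
    wls = sm.WLS(by, bx[:, None], weights=1.0 / sey**2).fit()
    assert wls.params[0] == pytest.approx(est_ivw.beta, abs=1e-10)


def test_egger_requires_three_variants_and_spread():
    t = make_hset_table([0.1, 0.2], [0.01] * 2, [0.05, 0.1], [0.01] * 2)
    with pytest.raises(ValueError, match="at least 3"):
        mr_egger(t)
    t2 = make_hset_table([0.1] * 4, [0.01] * 4, [0.05] * 4, [0.01] * 4)
    with pytest.raises(ValueError, match="unidentifiable"):
        mr_egger(t2)


# --- weighted median -------------------------------------------------------

def test_weighted_median_symmetric_case():
    est = weighted_median(make_ratios([0.4, 0.5, 0.6], [0.1, 0.1, 0.1]), n_boot=200, seed=0)
    assert est.beta == pytest.approx(0.5)


def test_weighted_median_monotone_in_weight_shift():
    r = make_ratios([0.4, 0.5, 0.6], [0.1, 0.1, 0.1])
    r.loc[2, "weight"] *= 3
    est = weighted_median(r, n_boot=200, seed=0)
    assert est.beta > 0.5


@settings(deadline=None, max_examples=30)
@given(st.lists(st.floats(-2, 2), min_size=3, max_size=9).filter(lambda v: len(v) % 2 == 1))
def test_equal_weight_odd_k_equals_sample_median(vals):
    w = np.ones(len(vals))
    assert _weighted_median_point(np.array(vals), w) == pytest.approx(np.median(vals))


def test_pwm_equals_wm_when_ratios_identical():
    r = make_ratios([0.3] * 5, [0.1] * 5)
    wm = weighted_median(r, n_boot=100, seed=1)
    pwm = penalised_weighted_median(r, n_boot=100, seed=1)
    assert pwm.beta == wm.beta == pytest.approx(0.3)


def test_pwm_downweights_outlier():
    from adipomr.twosample import _penalised_weights
    from scipy.stats import chi2

    ratios = [0.5] * 10 + [5.0]
    ses = [0.1] * 11
    r = make_ratios(ratios, ses)
    w = r["weight"].to_numpy()
    w_pen = _penalised_weights(r["ratio"].to_numpy(), w, 20.0)
    # hand computation for the outlier: WM of the concordant mass is 0.5,
    # Q = w (5.0 - 0.5)^2 = 100 * 20.25 = 2025, p = chi2.sf(2025, 1) ~ 0
    q_out = w[-1] * (5.0 - 0.5) ** 2
    assert q_out == pytest.approx(2025.0)
    assert w_pen[-1] == pytest.approx(w[-1] * min(1.0, 20.0 * chi2.sf(q_out, 1)))
    assert w_pen[-1] < w[-1]
    assert w_pen[:-1] == pytest.approx(w[:-1])  # concordant ratios unpenalised
    est = penalised_weighted_median(r, n_boot=100, seed=2)
    assert 0.4 <= est.beta <= 0.6


# --- instrument strength ---------------------------------------------------

def test_median_f_statistic():
    exp = pd.DataFrame({"beta": [0.1], "se": [0.02]})
    assert median_f_statistic(exp).median_f == pytest.approx(25.0)
    exp3 = pd.DataFrame({"beta": [0.4, 0.5, 0.6], "se": [0.1, 0.1, 0.1]})
    assert median_f_statistic(exp3).median_f == pytest.approx(25.0)


def test_median_f_matches_per_variant_regression(sumstats_pair):
    strength = median_f_statistic(sumstats_pair.exposure_stats)
    # oracle: per-variant F from the squared t of an explicit regression is
    # identical to (beta/se)^2, recomputed here from the stored records
    f = (sumstats_pair.exposure_stats["beta"] / sumstats_pair.exposure_stats["se"]) ** 2
    assert strength.median_f == pytest.approx(np.median(f), rel=1e-12)
    assert np.all(strength.f_statistics >= 0)


# --- scale equivariance ----------------------------------------------------

def test_scale_equivariance_of_all_estimators():
    rng = np.random.default_rng(4)
    bx = np.abs(rng.normal(0.1, 0.03, 12))
    by = 0.3 * bx + rng.normal(0, 0.005, 12)
    sey = rng.uniform(0.005, 0.02, 12)
    t1 = make_hset_table(bx, np.full(12, 0.01), by, sey)
    c = 2.5
    t2 = make_hset_table(c * bx, np.full(12, 0.01), by, sey)
    assert ivw(wald_ratios(t2)).beta == pytest.approx(ivw(wald_ratios(t1)).beta / c)
    assert mr_egger(t2).beta == pytest.approx(mr_egger(t1).beta / c)
    wm1 = weighted_median(wald_ratios(t1), n_boot=50, seed=0).beta
    wm2 = weighted_median(wald_ratios(t2), n_boot=50, seed=0).beta
    assert wm2 == pytest.approx(wm1 / c)
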