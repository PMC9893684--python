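import numpy as np
import pandas as pd
import pytest

from adipomr import SimConfig, simulate_cohort, simulate_sumstats_pair


def make_ratios(ratios, ses):
    """Build a Wald-ratio frame from plain lists."""
    r = np.asarray(ratios, dtype=float)
    s = np.asarray(ses, dtype=float)
    return pd.DataFrame(
        {"snp": [f"rs{i}" for i in range(r.size)], "ratio": r, "se": s, "weight": 1.0 / s**2}
    )


@pytest.fixture(scope="session")
def small_cohort():
    cfg = SimConfig(
        n_individuals=6000,
        n_variants=12,
        variant_effects_exposure=np.full(12, 0.08),
        causal_effect_linear=-0.2,
        confounder_effect_exposure=0.4,
        confounder_effect_outcome=0.4,
        seed=11,
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def sumstats_pair():
    cfg = SimConfig(
        n_individuals=8000,
        n_variants=15,
        variant_effects_exposure=np.full(15, 0.08),
        causal_effect_linear=-0.3,
        seed=7,
    )
    return simulate_sumstats_pair(cfg)
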