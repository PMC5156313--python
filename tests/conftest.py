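import numpy as np
import pandas as pd
import pytest

from lrckit import SimConfig, simulate_engraftment, measure_flow


@pytest.fixture
def noiseless_cohort():
    """Small 21-day cohort with a dormant seed and exact label readout."""
    cfg = SimConfig(
        n_injected=20_000,
        homing_prob=0.05,
        r=0.9,
        K=1e5,
        d=0.0,
        p_dormant_seed=0.02,
        cv_mfi=0.0,
        n_days=14,
        seed=7,
    )
    cohort, burden = simulate_engraftment(cfg)
    return cfg, cohort, burden


@pytest.fixture
def noiseless_sample(noiseless_cohort):
    cfg, cohort, _ = noiseless_cohort
    return cfg, measure_flow(cohort, cv_mfi=0.0)


def random_lda_table(rng, f_range=(1e-3, 0.3)):
    """A random informative limiting-dilution table."""
    while True:
        f = np.exp(rng.uniform(np.log(f_range[0]), np.log(f_range[1])))
        doses = rng.choice([1, 3, 10, 30, 100], size=3, replace=False)
        rows = []
        for d in doses:
            n = int(rng.integers(5, 25))
            p = 1 - (1 - f) ** d
            rows.append((int(d), n, int(rng.binomial(n, p))))
        table = pd.DataFrame(rows, columns=["dose", "n_mice", "n_engrafted"])
        k, n = table["n_engrafted"].sum(), table["n_mice"].sum()
        if 0 < k < n:
            return f, table
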