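import numpy as np
import pytest

from carriermod.assoc import prepare_scan_inputs
from carriermod.simulate import AscertainmentScheme, SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A modest ascertained cohort with a real effect (HR 1.3) for fit tests."""
    cfg = SimConfig(
        n_families=800,
        beta=float(np.log(1.3)),
        n_null_snps=20,
        seed=101,
        causal_maf=0.3,
        country_weights={"A": 0.6, "B": 0.4},
        ascertainment=AscertainmentScheme(n_cases=500, n_controls=500),
    )
    data = simulate_cohort(cfg)
    gm = data.selected_genotypes()
    inputs = prepare_scan_inputs(data.selected, cfg.incidence)
    return cfg, data, gm, inputs


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
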