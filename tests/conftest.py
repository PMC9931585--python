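import numpy as np
import pytest

import imctme as it


@pytest.fixture(scope="session")
def conditions8():
    """Eight one-marker cell types with heterogeneous proportions."""
    return it.simple_conditions(8)


@pytest.fixture(scope="session")
def noisy_core(conditions8):
    """One ~520-cell core at the default noise level (log-normal
    sigma 0.3, 5% off-target signal)."""
    panel, rules, props, targets = conditions8
    spec = it.SyntheticSpec(
        type_proportions=props, marker_targets=targets, cell_density=80.0
    )
    return it.generate_core(spec, seed=11)


@pytest.fixture(scope="session")
def noisy_core_table(conditions8, noisy_core):
    panel, rules, props, targets = conditions8
    return it.phenotype_core(noisy_core.stack, noisy_core.seg, panel, rules)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
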