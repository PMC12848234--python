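import numpy as np
import pytest

import photocap as pc


@pytest.fixture(scope="session")
def regression_world():
    """Site-mean table + truth where Vcmax25 is linear in covariates."""
    table, truth = pc.generate(pc.GeneratorConfig(mode="regression_truth", seed=101))
    return pc.prepare_site_table(table), truth


@pytest.fixture(scope="session")
def optimality_world():
    """Site-mean table + truth generated by the dynamic-cost optimality model
    with 5% observation noise and a single measurement per site."""
    table, truth = pc.generate(
        pc.GeneratorConfig(
            mode="optimality_truth",
            seed=202,
            measurements_per_site=1,
            measurement_noise_sd=0.0,
        )
    )
    return pc.prepare_site_table(table), truth


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
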