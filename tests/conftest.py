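import numpy as np
import pandas as pd
import pytest

from umglyco import CohortSimParams, CopyNumberCalls, gen_expression_cohort, load_panel


@pytest.fixture(scope="session")
def panel():
    return load_panel()


@pytest.fixture(scope="session")
def small_cohort():
    """A modest two-group cohort with one planted effect, shared across tests."""
    params = CohortSimParams(
        n_samples=60, monosomy_prob=0.5, delta={"GYG2": -1.2}, seed=11
    )
    return gen_expression_cohort(params)


@pytest.fixture()
def toy_cn():
    """Six samples: three monosomy-3, three disomy-3, no gene aberrations."""
    samples = [f"S{i}" for i in range(6)]
    arm = pd.DataFrame(
        {
            "arm3p_loss": [True, True, True, False, False, False],
            "arm3q_loss": [True, True, True, False, False, False],
        },
        index=samples,
        dtype=object,
    )
    genes = pd.DataFrame("neutral", index=["EPM2A"], columns=samples)
    return CopyNumberCalls(arm_calls=arm, gene_calls=genes)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
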