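import numpy as np
import pytest

from vernal import CONDITIONS, ExpressionDataset, SynthConfig, generate_dataset

H1_TRUTH = {"v0": 0.5, "K0": 1.5, "v1": 0.15, "K1": 3.0, "lambda": 0.2, "tau": 2.0}


def mechanistic_config(seed=42, cv=0.05, sd_floor=0.005, **overrides):
    """Well-identified H1 generating design used by recovery experiments.

    Dense 2-day sampling, a high PIM initial level (so the V- conditions
    show a clean decay pinning lambda) and early SOC1 midpoints (so the
    delayed FTa1 pulse is shape-distinct from the SOC1 rises).
    """
    base = dict(
        timepoints=tuple(np.arange(5.0, 25.1, 2.0)),
        cv=cv,
        sd_floor=sd_floor,
        seed=seed,
        pim_baseline=1.0,
        nonvern_factor=0.05,
        soc1_midpoints={"SOC1a": 11.0, "SOC1b": 13.0, "SOC1c": 15.0},
        pim_mode="mechanistic",
        pim_hypothesis="H1",
        pim_params=dict(H1_TRUTH),
    )
    base.update(overrides)
    return SynthConfig(**base)


@pytest.fixture(scope="session")
def noisefree_mech():
    """Noise-free mechanistic H1 dataset plus its generating truth."""
    config = mechanistic_config(cv=0.0, sd_floor=0.0)
    return generate_dataset(config)


@pytest.fixture(scope="session")
def noisy_mech_dataset():
    return generate_dataset(mechanistic_config()).dataset


@pytest.fixture(scope="session")
def default_dataset():
    """Default phenomenological dataset, fixed seed."""
    return generate_dataset(SynthConfig(seed=0)).dataset


@pytest.fixture
def tiny_dataset():
    """Hand-buildable 3-timepoint dataset with simple values."""
    timepoints = (5.0, 10.0, 15.0)
    mean, sd = {}, {}
    rng = np.random.default_rng(123)
    for gene in ("FTa1", "SOC1a", "SOC1b", "SOC1c", "PIM"):
        for cond in CONDITIONS:
            mean[(gene, cond)] = rng.uniform(0.1, 2.0, size=3)
            sd[(gene, cond)] = rng.uniform(0.05, 0.5, size=3)
    return ExpressionDataset(timepoints, mean, sd)
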