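import numpy as np
import pytest

from sumonmr.synthetic import (
    EnsembleDesign,
    TitrationDesign,
    default_interface,
    gen_ensemble,
    gen_titration,
)


@pytest.fixture
def noiseless_titration():
    """Noiseless fast-exchange titration with a known Kd of 31 uM."""
    design = TitrationDesign(
        true_kd=31.0,
        noise_sd=0.0,
        interface_residues=default_interface(seed=11),
        seed=11,
    )
    return design, gen_titration(design)


@pytest.fixture
def small_ensemble():
    design = EnsembleDesign(
        n_models=5, n_residues=20, flexible_ranges=((1, 4), (17, 20)),
        core_noise_sd=0.2, tail_noise_sd=1.5, seed=3,
    )
    return design, gen_ensemble(design)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
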