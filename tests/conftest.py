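import numpy as np
import pytest

from hydrophys import PVSimSpec, VCSimSpec, VulnerabilityFit, simulate_pv, simulate_vc


@pytest.fixture
def logistic_fit():
    """A fixed logistic curve (p50 = -2 MPa, a = 2 per MPa) for closed-form checks."""
    return VulnerabilityFit(
        p50=-2.0,
        slope_a=2.0,
        p12=-2.0 + np.log(88.0 / 12.0) / 2.0,
        p88=-2.0 + np.log(12.0 / 88.0) / 2.0,
    )


@pytest.fixture
def clean_vc_stem():
    """One noise-free synthetic stem (true p50 = -3, a = 2)."""
    return simulate_vc(
        VCSimSpec(true_p50=-3.0, slope_a=2.0, n_stems=1, noise_sd=0.0, seed=7)
    )[0]


@pytest.fixture
def clean_pv_curve():
    """Noise-free dry-down at the stiff-leaved parameter set."""
    return simulate_pv(PVSimSpec(pi0=-2.15, epsilon=30.58, psi_noise_sd=0.0, seed=3))
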