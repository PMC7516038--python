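import numpy as np
import pytest

from canopyflux import SpectralDistribution


@pytest.fixture
def flat_spectrum():
    """1 µmol m⁻² s⁻¹ nm⁻¹ everywhere on a 380-780 nm grid."""
    wl = np.arange(380.0, 781.0, 1.0)
    return SpectralDistribution(wl, np.ones_like(wl))


@pytest.fixture(scope="session")
def default_experiment():
    """One full four-treatment synthetic experiment under default conditions.

    Session-scoped: the 18-day stream plus daily images is the costly part of
    the suite and several tests only read from it.
    """
    from canopyflux import simulate_experiment

    return simulate_experiment(seed=20260919)


@pytest.fixture(scope="session")
def default_report(default_experiment):
    from canopyflux import analyze_experiment

    return analyze_experiment(default_experiment)
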