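import numpy as np
import pytest

from flimmux import AcquisitionConfig, IRF, SpeciesModel, TCSPCImage
from flimmux.core import expected_decay


@pytest.fixture(scope="session")
def acq() -> AcquisitionConfig:
    """Default acquisition: 80 MHz (12.5 ns period), 256 bins."""
    return AcquisitionConfig(rep_rate=80.0, n_bins=256)


@pytest.fixture(scope="session")
def irf() -> IRF:
    """Gaussian IRF, center 1.5 ns, sigma 0.15 ns."""
    return IRF(kind="gaussian", center=1.5, sigma=0.15)


@pytest.fixture(scope="session")
def delta_irf() -> IRF:
    """Idealized delta IRF at t = 0 (no temporal blur)."""
    return IRF(kind="delta", center=0.0)


@pytest.fixture(scope="session")
def mono_species():
    def make(tau: float, name: str | None = None,
             brightness: float = 1.0) -> SpeciesModel:
        return SpeciesModel.mono(name or f"tau{tau}", tau, brightness)

    return make


@pytest.fixture(scope="session")
def expected_image(acq):
    """One-pixel TCSPCImage holding a noiseless expected histogram."""

    def make(hist: np.ndarray) -> TCSPCImage:
        return TCSPCImage(np.asarray(hist, float)[None, None, :], acq)

    return make


@pytest.fixture(scope="session")
def pure_histograms(acq, irf):
    """Noiseless expected histograms (1e6 photons) keyed by lifetime."""

    def make(taus, n_photons=1e6, use_irf=None):
        the_irf = irf if use_irf is None else use_irf
        return {tau: expected_decay(SpeciesModel.mono(f"t{tau}", tau),
                                    n_photons, the_irf, acq)
                for tau in taus}

    return make
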