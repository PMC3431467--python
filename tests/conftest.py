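import numpy as np
import pytest

from lungqct import CTVolume, LungMask, PhantomParams, generate_phantom, make_annulus_slice


@pytest.fixture(scope="session")
def small_params() -> PhantomParams:
    """Desk-scale phantom parameters used throughout the unit tests."""
    return PhantomParams(grid_shape=(64, 64, 64), seed=3)


@pytest.fixture(scope="session")
def small_phantom(small_params):
    """(insp, exp, truth) for the shared 64-cube phantom."""
    return generate_phantom(small_params)


@pytest.fixture(scope="session")
def annulus():
    """Ideal airway cross-section: (image, spacing, centre_mm)."""
    return make_annulus_slice()


def volume_from_values(values, spacing=(1.0, 1.0, 1.0), label="clean") -> CTVolume:
    """Wrap a 1-D sequence of HU values into a tiny CTVolume."""
    arr = np.asarray(values, dtype=np.float32).reshape(-1, 1, 1)
    return CTVolume(arr, spacing, label)


def full_mask(vol: CTVolume) -> LungMask:
    return LungMask(np.ones(vol.values.shape, dtype=bool), vol.spacing_mm)
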