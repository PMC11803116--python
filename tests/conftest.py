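import numpy as np
import pytest

from dsppol.filtering import StokesImageSet
from dsppol.forward import shg_field
from dsppol.polarization import DSP_STATES, state_jones, stokes_from_field
from dsppol.tensor import MolecularSusceptibility, lab_tensor_2d_from_ratios


@pytest.fixture
def mol_achiral():
    """chi_zzz = 1.6, no chiral component."""
    return MolecularSusceptibility(chi_zzz=1.6)


@pytest.fixture
def mol_chiral():
    """The standard collagen-like tensor: chi_zzz = 1.6, chi_xyz = 0.2 + 0.2i."""
    return MolecularSusceptibility.from_complex_xyz(1.6, 0.2 + 0.2j)


def stokes_images_from_ratios(R, C, delta_phase, delta) -> StokesImageSet:
    """Noise-free Stokes images for effective-ratio arrays (test helper)."""
    t = lab_tensor_2d_from_ratios(R, C, delta_phase, delta)
    stokes = {m: stokes_from_field(shg_field(t, state_jones(m))) for m in DSP_STATES}
    return StokesImageSet(stokes=stokes)


@pytest.fixture
def ratio_grid():
    """Moderate (R, C, Delta, delta) grid covering the physical regime,
    avoiding the R = 3 pole of the linear-dichroism forms."""
    return np.meshgrid(
        [0.5, 1.0, 1.6, 2.0, 3.5],
        [0.0, 0.1, -0.1, 0.3, -0.3],
        [0.0, np.pi / 4, -np.pi / 4, np.pi / 2, -np.pi / 2],
        np.radians([0.0, 10.0, -35.0, 20.0, 44.0]),
        indexing="ij",
    )
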