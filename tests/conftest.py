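import numpy as np
import pytest

from scarpol.synthetic_data import CohortCalibration, synth_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One 36-wound cohort at the default calibration."""
    return synth_cohort(CohortCalibration(), seed=7)


@pytest.fixture(scope="session")
def null_cohort():
    """A cohort whose month-6 outcome is decoupled from every feature."""
    return synth_cohort(CohortCalibration().with_coupling(0.0), seed=11)


def make_random_stokes(rng, shape=(5, 6, 3, 2, 2), spacing=(2.0, 5.0, 5.0)):
    """Random physical Stokes volume: |QUV| <= I by construction."""
    from scarpol.polarimetry import StokesVolume

    I = np.ones(shape)
    direction = rng.standard_normal((3,) + shape)
    direction /= np.linalg.norm(direction, axis=0)
    r = rng.uniform(0.0, 1.0, shape)
    Q, U, V = direction * r * I
    return StokesVolume(
        I=I, Q=Q, U=U, V=V,
        spacing_z=spacing[0], spacing_x=spacing[1], spacing_y=spacing[2],
    )
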