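import numpy as np
import pytest

from npfate.dosimetry import BeamGeometry
from npfate.phantom import CelluloseBackground, ParticleModel, PhantomSpec


@pytest.fixture
def beam() -> BeamGeometry:
    """Small synthetic detector: 64x64 px, q up to ~0.017 1/A."""
    return BeamGeometry(
        energy_kev=20.129,
        sample_detector_mm=8000.0,
        pixel_um=300.0,
        beam_center=(31.5, 31.5),
    )


@pytest.fixture
def dose_beam() -> BeamGeometry:
    """Beamline dosimetry parameters for the live-plant exposure."""
    return BeamGeometry(
        energy_kev=20.129,
        sample_detector_mm=8000.0,
        pixel_um=300.0,
        beam_center=(31.5, 31.5),
        photon_flux=1e13,
        exposure_time_s=0.05,
        spot_area_um2=50.0 * 50.0,
        mass_attenuation_cm2_g=0.56,
    )


@pytest.fixture
def guinier_particle() -> ParticleModel:
    """Baseline nano-hydroxyapatite solution: Rg 297 A, forward intensity 7845."""
    return ParticleModel(shape="guinier", rg=297.0, concentration=7845.0)


@pytest.fixture
def isotropic_spec(beam) -> PhantomSpec:
    """Noiseless isotropic single-point phantom (no background)."""
    return PhantomSpec(
        beam=beam,
        mesh_shape=(1, 1),
        particle=ParticleModel(shape="guinier", rg=100.0, concentration=100.0),
        concentration_field=np.ones((1, 1)),
        frame_shape=(64, 64),
        noise="none",
    )


@pytest.fixture
def anisotropic_spec(beam) -> PhantomSpec:
    """Noiseless phantom with a strongly anisotropic cellulose background."""
    return PhantomSpec(
        beam=beam,
        mesh_shape=(1, 1),
        particle=ParticleModel(shape="guinier", rg=100.0, concentration=0.0),
        concentration_field=np.ones((1, 1)),
        background=CelluloseBackground(
            amplitude=1e-4, power_law_exponent=2.5, anisotropy_fraction=0.8, preferred_orientation=1.2
        ),
        frame_shape=(64, 64),
        noise="none",
    )
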