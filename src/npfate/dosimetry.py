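"""X-ray dosimetry and cone-beam geometry helpers.

Surface-dose estimate for a focused microbeam (thin-sample approximation:
no transmission or depth attenuation factor) plus the cone-beam geometry
relations used for laboratory micro-CT: magnification, effective voxel size
after magnification, and effective propagation distance for near-field
phase contrast.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "BeamGeometry",
    "CTGeometry",
    "dose_per_exposure",
    "magnification",
    "effective_voxel",
    "effective_propagation",
    "scan_time",
]

#: Joules per keV (exact, CODATA definition of the elementary charge).
KEV_TO_J = 1.602176634e-16


@dataclass(frozen=True)
class BeamGeometry:
    """Monochromatic pencil/micro-beam geometry at the sample.

    The scattering-geometry fields (energy, distance, pixel pitch, beam
    center) are required; the dosimetry fields are optional so the same
    object can drive both azimuthal regrouping and dose estimates.

    Parameters
    ----------
    energy_kev : photon energy in keV.
    sample_detector_mm : sample-to-detector distance in mm.
    pixel_um : detector pixel pitch in micrometers.
    beam_center : (row, col) of the direct beam on the detector, pixels.
    photon_flux : incident flux in photons/s (dose only).
    exposure_time_s : exposure per frame in seconds (dose only).
    spot_area_um2 : focal spot area in square micrometers (dose only).
    mass_attenuation_cm2_g : mass attenuation coefficient mu/rho in cm^2/g
        at ``energy_kev`` (dose only; user-supplied, no internal tables).
    """

    energy_kev: float
    sample_detector_mm: float
    pixel_um: float
    beam_center: tuple[float, float]
    photon_flux: float | None = None
    exposure_time_s: float | None = None
    spot_area_um2: float | None = None
    mass_attenuation_cm2_g: float | None = None

    def __post_init__(self) -> None:
        for name in ("energy_kev", "sample_detector_mm", "pixel_um"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)!r}")
        for name in (
            "photon_flux",
            "exposure_time_s",
            "spot_area_um2",
            "mass_attenuation_cm2_g",
        ):
            value = getattr(self, name)
            if value is not None and value < 0:
                raise ValueError(f"{name} must be non-negative, got {value!r}")

    @property
    def wavelength_A(self) -> float:
        """X-ray wavelength in Angstrom, lambda = 12.398 / E[keV]."""
        return 12.398 / self.energy_kev


@dataclass(frozen=True)
class CTGeometry:
    """Cone-beam micro-CT geometry.

    Parameters
    ----------
    source_detector_cm : source-to-detector distance (SDD) in cm.
    source_object_cm : source-to-rotation-center distance (SOD) in cm.
    detector_pixel_um : physical detector pixel size in micrometers.
    """

    source_detector_cm: float
    source_object_cm: float
    detector_pixel_um: float

    def __post_init__(self) -> None:
        if self.source_object_cm <= 0 or self.detector_pixel_um <= 0:
            raise ValueError("distances and pixel size must be positive")
        if self.source_object_cm >= self.source_detector_cm:
            raise ValueError(
                "source-object distance must be smaller than source-detector "
                f"distance (SOD={self.source_object_cm}, SDD={self.source_detector_cm})"
            )


def dose_per_exposure(beam: BeamGeometry) -> float:
    """Dose deposited by one exposure, in gray.

    D = flux * E * t / A * (mu/rho), with flux in photons/s, E converted
    keV -> J, the spot area A converted um^2 -> m^2 and mu/rho converted
    cm^2/g -> m^2/kg.  Linear in flux, energy and exposure time; a thin-
    sample surface dose with no transmission correction.
    """
    missing = [
        name
        for name in (
            "photon_flux",
            "exposure_time_s",
            "spot_area_um2",
            "mass_attenuation_cm2_g",
        )
        if getattr(beam, name) is None
    ]
    if missing:
        raise ValueError(f"beam geometry lacks dosimetry fields: {missing}")
    if beam.spot_area_um2 == 0:
        raise ValueError("spot area must be non-zero")
    energy_j = beam.energy_kev * KEV_TO_J
    area_m2 = beam.spot_area_um2 * 1e-12
    mu_rho_m2_kg = beam.mass_attenuation_cm2_g * 0.1  # 1 cm^2/g = 0.1 m^2/kg
    fluence = beam.photon_flux * beam.exposure_time_s / area_m2  # photons/m^2
    return fluence * energy_j * mu_rho_m2_kg


def magnification(geom: CTGeometry) -> float:
    """Geometric magnification M = SDD / SOD."""
    return geom.source_detector_cm / geom.source_object_cm


def effective_voxel(geom: CTGeometry) -> float:
    """Effective voxel size after magnification, micrometers: pixel / M."""
    return geom.detector_pixel_um / magnification(geom)


def effective_propagation(geom: CTGeometry) -> float:
    """Effective propagation distance for near-field phase contrast, cm.

    z_eff = SOD * (SDD - SOD) / SDD, the defocus distance rescaled by the
    cone-beam magnification.
    """
    sod = geom.source_object_cm
    sdd = geom.source_detector_cm
    return sod * (sdd - sod) / sdd


def scan_time(
    mesh_shape: tuple[int, int],
    exposure_time_s: float,
    overhead_per_point_s: float = 0.0,
) -> float:
    """Total mesh-scan acquisition time in seconds.

    rows * cols * (exposure + per-point overhead); overhead defaults to 0,
    giving a lower bound on wall-clock time.
    """
    rows, cols = mesh_shape
    if rows <= 0 or cols <= 0 or exposure_time_s < 0 or overhead_per_point_s < 0:
        raise ValueError("mesh shape must be positive and times non-negative")
    return rows * cols * (exposure_time_s + overhead_per_point_s)
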