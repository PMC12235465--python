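"""Synthetic phantoms for the correlative SAXS / micro-CT / XRF pipeline.

Generates detector frames, mesh scans, dilution series, CT volumes and
elemental maps with the statistical structure the downstream analysis
assumes, so that every stage can be exercised and validated offline:

* isotropic nanoparticle scattering from orientation-averaged form factors
  (sphere, cylinder, core-shell sphere, or a pure Guinier model) superposed
  on an anisotropic power-law "cellulose" background,
* dilution series obeying the Guinier relation I0 proportional to
  concentration at fixed particle size,
* day-0/1/3 time series in which the per-modality signals follow one of the
  four canonical nanoparticle fates (aggregation, dispersion, dissolution,
  translocation).

All randomness flows from a single integer seed through
``numpy.random.default_rng``; a fixed spec yields bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.special import j1

from .ct_quant import Volume
from .dosimetry import BeamGeometry
from .feature_maps import MeshScan
from .saxs_reduce import DetectorFrame, q_theta_maps
from .xrf_maps import ElementMap

__all__ = [
    "ParticleModel",
    "CelluloseBackground",
    "PhantomSpec",
    "TimepointPhantom",
    "form_factor_intensity",
    "radius_of_gyration",
    "render_frame",
    "render_mesh_scan",
    "dilution_curves",
    "render_timeseries_phantoms",
    "MODES",
]

_SHAPES = ("sphere", "cylinder", "core_shell_sphere", "guinier")

#: Canonical nanoparticle fates of the multimodal decision framework.
MODES = ("aggregation", "dispersion", "dissolution", "translocation")


class InvalidModelError(ValueError):
    """Raised when a particle model has non-positive dimensions."""


@dataclass(frozen=True)
class ParticleModel:
    """A monodisperse nanoparticle scattering model.

    shape : one of ``sphere``, ``cylinder``, ``core_shell_sphere``,
        ``guinier``.
    radius : sphere radius in Angstrom.
    length, cyl_radius : cylinder length and cross-section radius, Angstrom.
    core_radius, shell_thickness : core-shell sphere dimensions, Angstrom.
    rg : radius of gyration for the pure Guinier model, Angstrom.
    contrast : relative electron-density contrast (a.u.); for the
        core-shell shape this is the *core* contrast.
    shell_contrast : shell contrast for the core-shell shape; defaults to
        half the core contrast when unset.
    concentration : relative number density (a.u.); the noiseless forward
        intensity is concentration * contrast**2.
    """

    shape: str
    radius: float | None = None
    length: float | None = None
    cyl_radius: float | None = None
    core_radius: float | None = None
    shell_thickness: float | None = None
    rg: float | None = None
    contrast: float = 1.0
    shell_contrast: float | None = None
    concentration: float = 1.0

    def __post_init__(self) -> None:
        if self.shape not in _SHAPES:
            raise InvalidModelError(f"unknown shape {self.shape!r}; expected one of {_SHAPES}")
        required = {
            "sphere": ("radius",),
            "cylinder": ("length", "cyl_radius"),
            "core_shell_sphere": ("core_radius", "shell_thickness"),
            "guinier": ("rg",),
        }[self.shape]
        for name in required:
            value = getattr(self, name)
            if value is None or value <= 0:
                raise InvalidModelError(f"{self.shape} model requires positive {name}, got {value!r}")
        if self.concentration < 0:
            raise InvalidModelError("concentration must be non-negative")

    def _shell_contrast(self) -> float:
        return self.shell_contrast if self.shell_contrast is not None else 0.5 * self.contrast


@dataclass(frozen=True)
class CelluloseBackground:
    """Anisotropic power-law background mimicking oriented cellulose.

    I_bg(q, theta) = amplitude * q**(-exponent)
                     * [1 - f + f * cos^2(theta - orientation)]

    with anisotropy fraction f in [0, 1]; f = 0 is isotropic, f = 1 fully
    modulated.  ``orientation`` (radians) may be overridden per mesh point.
    """

    amplitude: float = 0.0
    power_law_exponent: float = 2.5
    anisotropy_fraction: float = 0.0
    preferred_orientation: float = 0.0

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")
        if not 0.0 <= self.anisotropy_fraction <= 1.0:
            raise ValueError("anisotropy_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of a synthetic mesh scan.

    concentration_field scales the particle term per mesh point;
    orientation_field (optional, radians, same shape) overrides the
    background orientation per point.  With noise='poisson' all frames
    share one count scale, chosen so the unit-concentration frame has mean
    pixel value ``target_mean_count``; relative intensities across mesh
    points are preserved under the noise.
    """

    beam: BeamGeometry
    mesh_shape: tuple[int, int]
    particle: ParticleModel
    concentration_field: np.ndarray
    background: CelluloseBackground = CelluloseBackground()
    orientation_field: np.ndarray | None = None
    frame_shape: tuple[int, int] = (64, 64)
    noise: str = "none"
    target_mean_count: float = 100.0
    step_mm: tuple[float, float] = (0.05, 0.05)
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "concentration_field", np.asarray(self.concentration_field, dtype=float)
        )
        if self.concentration_field.shape != tuple(self.mesh_shape):
            raise ValueError("concentration_field shape must equal mesh_shape")
        if np.any(self.concentration_field < 0):
            raise ValueError("concentration_field must be non-negative")
        if self.orientation_field is not None:
            ofield = np.asarray(self.orientation_field, dtype=float)
            if ofield.shape != tuple(self.mesh_shape):
                raise ValueError("orientation_field shape must equal mesh_shape")
            object.__setattr__(self, "orientation_field", ofield)
        if self.noise not in ("none", "poisson"):
            raise ValueError(f"unknown noise mode {self.noise!r}")


def _sphere_amplitude(x: np.ndarray) -> np.ndarray:
    """Normalized sphere scattering amplitude 3(sin x - x cos x)/x^3."""
    x = np.asarray(x, dtype=float)
    out = np.ones_like(x)
    small = np.abs(x) < 1e-4
    xs = np.where(small, 1.0, x)
    out = np.where(small, 1.0 - x**2 / 10.0, 3.0 * (np.sin(xs) - xs * np.cos(xs)) / xs**3)
    return out


def _sinc(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    small = np.abs(x) < 1e-8
    xs = np.where(small, 1.0, x)
    return np.where(small, 1.0, np.sin(xs) / xs)


def _j1c(x: np.ndarray) -> np.ndarray:
    """2 J1(x)/x, continued to 1 at x = 0."""
    x = np.asarray(x, dtype=float)
    small = np.abs(x) < 1e-8
    xs = np.where(small, 1.0, x)
    return np.where(small, 1.0, 2.0 * j1(xs) / xs)


# 128-point Gauss-Legendre rule on alpha in (0, pi/2) for the cylinder
# orientation average; accurate to ~1e-10 over the q-ranges used here.
_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(128)
_ALPHA = 0.25 * np.pi * (_GL_NODES + 1.0)
_ALPHA_W = 0.25 * np.pi * _GL_WEIGHTS


def form_factor_intensity(model: ParticleModel, q: np.ndarray) -> np.ndarray:
    """Orientation-averaged scattered intensity of a particle model, a.u.

    I(q) = concentration * contrast^2 * P(q) with P(0) = 1, so the forward
    intensity equals concentration * contrast^2 (set concentration to the
    desired I0 with unit contrast).  Monotonically decreasing through the
    Guinier regime; finite at q -> 0.
    """
    q = np.asarray(q, dtype=float)
    scale = model.concentration * model.contrast**2
    if model.shape == "guinier":
        p = np.exp(-(q**2) * model.rg**2 / 3.0)
    elif model.shape == "sphere":
        p = _sphere_amplitude(q * model.radius) ** 2
    elif model.shape == "cylinder":
        # <|A|^2> over uniformly distributed orientations alpha (angle
        # between cylinder axis and q), weight sin(alpha).
        qc = q[..., None]
        a = _sinc(0.5 * qc * model.length * np.cos(_ALPHA)) * _j1c(
            qc * model.cyl_radius * np.sin(_ALPHA)
        )
        p = np.sum(a**2 * np.sin(_ALPHA) * _ALPHA_W, axis=-1)
    elif model.shape == "core_shell_sphere":
        rc = model.core_radius
        rt = rc + model.shell_thickness
        rho_c = model.contrast
        rho_s = model._shell_contrast()
        vc = rc**3
        vt = rt**3  # 4pi/3 cancels in the normalization
        amp = rho_s * vt * _sphere_amplitude(q * rt) + (rho_c - rho_s) * vc * _sphere_amplitude(
            q * rc
        )
        amp0 = rho_s * vt + (rho_c - rho_s) * vc
        # contrasts shape the amplitude; I(0) stays concentration * contrast^2
        p = (amp / amp0) ** 2
    else:  # pragma: no cover - guarded in __post_init__
        raise InvalidModelError(model.shape)
    return scale * p


def radius_of_gyration(model: ParticleModel) -> float:
    """Closed-form radius of gyration of a particle model, Angstrom.

    sphere: Rg^2 = 3 R^2 / 5; cylinder: Rg^2 = L^2/12 + R^2/2; core-shell
    sphere: contrast-weighted second moment; guinier: its own Rg.
    """
    if model.shape == "sphere":
        return float(np.sqrt(3.0 / 5.0) * model.radius)
    if model.shape == "cylinder":
        return float(np.sqrt(model.length**2 / 12.0 + model.cyl_radius**2 / 2.0))
    if model.shape == "guinier":
        return float(model.rg)
    if model.shape == "core_shell_sphere":
        rc = model.core_radius
        rt = rc + model.shell_thickness
        rho_c = model.contrast
        rho_s = model._shell_contrast()
        num = rho_s * (rt**5 - rc**5) + rho_c * rc**5
        den = rho_s * (rt**3 - rc**3) + rho_c * rc**3
        return float(np.sqrt(0.6 * num / den))
    raise NotImplementedError(f"no closed-form Rg for shape {model.shape!r}")


def _frame_noiseless(
    spec: PhantomSpec, concentration_scale: float, orientation: float
) -> np.ndarray:
    q_map, theta_map = q_theta_maps(spec.beam, spec.frame_shape)
    # clamp q at the beam-center pixel to the half-pixel q so the power-law
    # background stays finite there
    beam = spec.beam
    r_half_mm = 0.5 * beam.pixel_um * 1e-3
    q_floor = (4.0 * np.pi / beam.wavelength_A) * np.sin(
        0.5 * np.arctan2(r_half_mm, beam.sample_detector_mm)
    )
    q_safe = np.maximum(q_map, q_floor)

    particle = replace(
        spec.particle, concentration=spec.particle.concentration * concentration_scale
    )
    img = form_factor_intensity(particle, q_safe)
    bg = spec.background
    if bg.amplitude > 0:
        f = bg.anisotropy_fraction
        theta_safe = np.where(np.isfinite(theta_map), theta_map, 0.0)
        modulation = 1.0 - f + f * np.cos(theta_safe - orientation) ** 2
        img = img + bg.amplitude * q_safe ** (-bg.power_law_exponent) * modulation
    return img


def render_frame(spec: PhantomSpec, point: tuple[int, int]) -> DetectorFrame:
    """Render the detector frame for one mesh point.

    Pixel value = isotropic particle term (the form factor at the pixel's q,
    scaled by the point's concentration) + anisotropic background
    A q^-p [1 - f + f cos^2(theta - theta0)], optionally Poisson sampled.
    Deterministic under a fixed spec seed.
    """
    row, col = point
    if not (0 <= row < spec.mesh_shape[0] and 0 <= col < spec.mesh_shape[1]):
        raise IndexError(f"point {point} outside mesh {spec.mesh_shape}")
    orientation = (
        spec.orientation_field[row, col]
        if spec.orientation_field is not None
        else spec.background.preferred_orientation
    )
    img = _frame_noiseless(spec, spec.concentration_field[row, col], orientation)
    if spec.noise == "poisson":
        # One count scale for the whole scan, anchored to the unit-
        # concentration frame, so relative intensities across mesh points
        # (and across scans sharing particle and beam) are preserved.
        reference = _frame_noiseless(spec, 1.0, spec.background.preferred_orientation)
        ref_mean = reference.mean()
        scaled = img * (spec.target_mean_count / ref_mean) if ref_mean > 0 else img
        rng = np.random.default_rng([spec.seed, row, col])
        img = rng.poisson(scaled).astype(float)
    return DetectorFrame(counts=img, exposure_time_s=0.1)


def render_mesh_scan(spec: PhantomSpec) -> MeshScan:
    """Render every mesh point of a phantom spec into a MeshScan."""
    rows, cols = spec.mesh_shape
    frames = np.empty((rows, cols) + tuple(spec.frame_shape), dtype=float)
    for r in range(rows):
        for c in range(cols):
            frames[r, c] = render_frame(spec, (r, c)).counts
    return MeshScan(frames=frames, beam=spec.beam, step_mm=spec.step_mm)


def dilution_curves(
    base_model: ParticleModel,
    dilution_factors: list[float],
    q: np.ndarray,
    noise_fraction: float = 0.01,
    seed: int = 0,
):
    """Noisy 1D curves for a dilution series of one particle model.

    Returns a list of (dilution_factor, Curve1D); intensities carry
    multiplicative Gaussian noise of relative size ``noise_fraction`` and a
    matching sigma column.
    """
    from .saxs_reduce import Curve1D

    rng = np.random.default_rng(seed)
    out = []
    for factor in dilution_factors:
        if factor < 1:
            raise ValueError("dilution factors must be >= 1")
        model = replace(base_model, concentration=base_model.concentration / factor)
        ideal = form_factor_intensity(model, q)
        noisy = ideal * (1.0 + noise_fraction * rng.standard_normal(q.shape))
        out.append((factor, Curve1D(q=q, intensity=noisy, sigma=noise_fraction * ideal)))
    return out


# ----------------------------------------------------------------------------
# Time-series phantoms for the four canonical nanoparticle fates
# ----------------------------------------------------------------------------


@dataclass
class TimepointPhantom:
    """All modality outputs of one phantom timepoint."""

    day: float
    scan: MeshScan
    volume: Volume
    xrf_mobile: ElementMap
    xrf_immobile: ElementMap
    infiltrated_mask: np.ndarray  # over the SAXS mesh
    xrf_region_mask: np.ndarray  # over the XRF map grid
    q_window: tuple[float, float] = (0.004, 0.022)  # analysis window, 1/A


def _blob_field(shape, centers, sigma, rng=None) -> np.ndarray:
    """Sum of unit-amplitude Gaussian blobs on a 2D grid."""
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    out = np.zeros(shape, dtype=float)
    for cy, cx in centers:
        out += np.exp(-(((yy - cy) ** 2 + (xx - cx) ** 2) / (2.0 * sigma**2)))
    return out


# Per-fate factors applied at day d (relative to day 0):
#   saxs  - multiplies the particle concentration in the mesh scan
#   ct    - multiplies the CT cluster gray amplitude
#   sig   - multiplies the CT cluster width (dispersion spreads clusters)
#   mob   - multiplies the mobile-element (P-like) XRF deposit
#   imm   - multiplies the immobile-tracer (Ce-like) XRF deposit
# Magnitudes are fixed a priori to be well outside the +/-10% stability
# band by day 3 for every non-stable arrow of the decision framework.
_FATE_FACTORS = {
    "dissolution": dict(
        saxs=lambda d: np.exp(-0.8 * d),
        ct=lambda d: 1.0,
        sig=lambda d: 1.0,
        mob=lambda d: np.exp(-0.6 * d),
        imm=lambda d: 1.0,
    ),
    "aggregation": dict(
        saxs=lambda d: np.exp(-0.5 * d),
        ct=lambda d: 1.0 + 0.25 * d,
        sig=lambda d: 1.0,
        mob=lambda d: 1.0,
        imm=lambda d: 1.0,
    ),
    "translocation": dict(
        saxs=lambda d: np.exp(-0.6 * d),
        ct=lambda d: np.exp(-0.25 * d),
        sig=lambda d: 1.0,
        mob=lambda d: np.exp(-0.5 * d),
        imm=lambda d: np.exp(-0.5 * d),
    ),
    "dispersion": dict(
        saxs=lambda d: 1.0 + 0.3 * d,
        ct=lambda d: np.exp(-0.4 * d),
        sig=lambda d: 1.0 + 0.4 * d,
        mob=lambda d: 1.0,
        imm=lambda d: 1.0,
    ),
}


def _default_beam(frame_shape: tuple[int, int]) -> BeamGeometry:
    """Synthetic detector with the beam centered on the frame."""
    return BeamGeometry(
        energy_kev=20.129,
        sample_detector_mm=8000.0,
        pixel_um=300.0,
        beam_center=((frame_shape[0] - 1) / 2.0, (frame_shape[1] - 1) / 2.0),
    )


def _ct_volume(shape, day_amp, day_sigma, rng) -> Volume:
    """Leaf slab in air with high-gray nanoparticle clusters."""
    nz, ny, nx = shape
    gray = rng.normal(0.05, 0.005, size=shape)  # air
    leaf = np.zeros(shape, dtype=bool)
    z0, z1 = int(0.2 * nz), int(0.8 * nz)
    y0, y1 = int(0.15 * ny), int(0.85 * ny)
    x0, x1 = int(0.15 * nx), int(0.85 * nx)
    leaf[z0:z1, y0:y1, x0:x1] = True
    gray[leaf] = rng.normal(0.30, 0.02, size=int(leaf.sum()))

    zz, yy, xx = np.mgrid[0:nz, 0:ny, 0:nx]
    centers = [
        (0.45 * nz, 0.40 * ny, 0.40 * nx),
        (0.55 * nz, 0.60 * ny, 0.55 * nx),
        (0.50 * nz, 0.45 * ny, 0.65 * nx),
    ]
    sigma = 0.05 * min(ny, nx) * day_sigma
    blobs = np.zeros(shape, dtype=float)
    for cz, cy, cx in centers:
        blobs += np.exp(
            -(((zz - cz) ** 2 + (yy - cy) ** 2 + (xx - cx) ** 2) / (2.0 * sigma**2))
        )
    gray = gray + np.where(leaf, 1.0 * day_amp * blobs, 0.0)
    return Volume(gray=gray, voxel_size_um=2.78)


def render_timeseries_phantoms(
    days: list[float],
    mode: str,
    seed: int = 0,
    mesh_shape: tuple[int, int] = (8, 8),
    frame_shape: tuple[int, int] = (64, 64),
    volume_shape: tuple[int, int, int] = (64, 64, 64),
    map_shape: tuple[int, int] = (64, 64),
    noise: str = "poisson",
) -> dict[float, TimepointPhantom]:
    """Render a multi-day phantom for one canonical nanoparticle fate.

    Returns one :class:`TimepointPhantom` per day, with SAXS mesh scan, CT
    volume, and mobile/immobile elemental maps whose signal trends follow
    the decision-framework arrows for ``mode``.  Deterministic per seed.
    """
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")
    if list(days) != sorted(days):
        raise ValueError("days must be sorted ascending")
    factors = _FATE_FACTORS[mode]
    beam = _default_beam(frame_shape)

    # infiltration site: a cluster of mesh points near the center
    conc = _blob_field(mesh_shape, [(mesh_shape[0] * 0.5, mesh_shape[1] * 0.5)], 0.18 * mesh_shape[0])
    infiltrated = conc > 0.3 * conc.max()
    # Freeze-dried regime: particle scattering dominates the cellulose
    # background inside the infiltrated region by roughly an order of
    # magnitude over the analysis q-window (qRg in [0.5, 2]).
    particle = ParticleModel(shape="guinier", rg=297.0, concentration=200.0)
    background = CelluloseBackground(
        amplitude=2e-5, power_law_exponent=2.5, anisotropy_fraction=0.5, preferred_orientation=1.2
    )

    # XRF deposit footprint on the map grid
    deposit = _blob_field(
        map_shape, [(map_shape[0] * 0.5, map_shape[1] * 0.5)], 0.12 * min(map_shape)
    )
    xrf_region = deposit > 0.3 * deposit.max()

    out: dict[float, TimepointPhantom] = {}
    for i, day in enumerate(days):
        day_seed = np.random.default_rng([seed, 7919, i]).integers(0, 2**31 - 1)
        spec = PhantomSpec(
            beam=beam,
            mesh_shape=mesh_shape,
            particle=particle,
            concentration_field=conc * factors["saxs"](day),
            background=background,
            frame_shape=frame_shape,
            noise=noise,
            target_mean_count=200.0,
            seed=int(day_seed),
        )
        scan = render_mesh_scan(spec)
        rng = np.random.default_rng([int(day_seed), 1])
        volume = _ct_volume(volume_shape, factors["ct"](day), factors["sig"](day), rng)
        base = rng.normal(2.0, 0.2, size=map_shape).clip(min=0)
        mobile = ElementMap(
            element="P",
            intensity=(base + 40.0 * factors["mob"](day) * deposit).clip(min=0),
            pixel_size_um=20.0,
        )
        immobile = ElementMap(
            element="Ce",
            intensity=(base + 40.0 * factors["imm"](day) * deposit).clip(min=0),
            pixel_size_um=20.0,
        )
        out[day] = TimepointPhantom(
            day=day,
            scan=scan,
            volume=volume,
            xrf_mobile=mobile,
            xrf_immobile=immobile,
            infiltrated_mask=infiltrated,
            xrf_region_mask=xrf_region,
            q_window=(0.5 / particle.rg, 2.0 / particle.rg),
        )
    return out
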