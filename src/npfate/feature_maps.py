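"""Mesh-scan feature maps: total scattering and scattering anisotropy.

A mesh scan is a raster of detector frames, one per microbeam position.
Two scalar statistics per point assemble the feature-map images:

* total scattering — counts inside a q-window, attributing each cake cell
  its mean intensity times the number of contributing pixels (linear in
  frame intensity);
* scattering anisotropy — the first moment of the azimuthal profile,
  M1 = integral theta * I(theta) dtheta, which vanishes for isotropic
  scatterers on a centered theta grid and grows with preferred orientation
  (oriented cellulose), distinguishing it from isotropic nanoparticle
  clusters of similar total signal.

The literal first moment is origin-dependent on an uncentered grid; a
normalized variant M1 / integral I dtheta is the default for maps.
Invalid mesh points are NaN in exported maps, never zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .dosimetry import BeamGeometry
from .saxs_reduce import (
    AzimuthalProfile,
    Cake,
    DetectorFrame,
    azimuthal_integrate,
    azimuthal_regroup,
)

__all__ = [
    "MeshScan",
    "FeatureMap",
    "total_scattering_map",
    "first_moment",
    "anisotropy_map",
]

#: Default analysis q-window (1/A) for feature maps.
DEFAULT_Q_WINDOW = (0.004, 0.022)


@dataclass
class MeshScan:
    """Raster scan of detector frames over a sample.

    frames : array (rows, cols, ny, nx) of detector counts.
    valid : boolean (rows, cols); invalid points are skipped and their map
        values marked missing.
    beam : shared beam geometry for all points.
    step_mm : (dy, dx) motor step between mesh points.
    """

    frames: np.ndarray
    beam: BeamGeometry
    step_mm: tuple[float, float] = (0.05, 0.05)
    valid: np.ndarray | None = None
    mask: np.ndarray | None = None  # shared detector mask

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 4:
            raise ValueError("frames must be a 4D (rows, cols, ny, nx) array")
        if self.valid is None:
            self.valid = np.ones(self.frames.shape[:2], dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
            if self.valid.shape != self.frames.shape[:2]:
                raise ValueError("valid flags must match mesh shape")

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[:2]

    def frame(self, row: int, col: int) -> DetectorFrame:
        return DetectorFrame(counts=self.frames[row, col], mask=self.mask)

    def cakes(self, n_q: int = 40, n_theta: int = 36) -> np.ndarray:
        """Regroup every valid frame; returns an object array of Cakes."""
        out = np.empty(self.shape, dtype=object)
        for r in range(self.shape[0]):
            for c in range(self.shape[1]):
                if self.valid[r, c]:
                    out[r, c] = azimuthal_regroup(self.frame(r, c), self.beam, n_q, n_theta)
        return out


@dataclass
class FeatureMap:
    """A per-mesh-point scalar statistic rendered as an image.

    values : 2D array over the mesh; NaN marks invalid/missing points.
    statistic : 'total_scattering', 'anisotropy_m1' or
        'anisotropy_m1_normalized'.
    q_window : (q_lo, q_hi) in 1/A used for the statistic.
    """

    values: np.ndarray
    statistic: str
    q_window: tuple[float, float]
    step_mm: tuple[float, float] = (0.05, 0.05)


def total_scattering_map(
    scan: MeshScan,
    q_lo: float = DEFAULT_Q_WINDOW[0],
    q_hi: float = DEFAULT_Q_WINDOW[1],
    n_q: int = 40,
    n_theta: int = 36,
) -> FeatureMap:
    """Windowed total-counts map of a mesh scan.

    Per point: sum over cake cells whose q-center lies in [q_lo, q_hi] of
    (mean intensity x contributing pixels), i.e. the total counts
    attributable to the window.  Linear in frame intensity.  Points with no
    valid cell in the window are NaN.
    """
    if q_hi <= q_lo:
        raise ValueError("q-window must be increasing")
    values = np.full(scan.shape, np.nan)
    cakes = scan.cakes(n_q=n_q, n_theta=n_theta)
    for r in range(scan.shape[0]):
        for c in range(scan.shape[1]):
            cake = cakes[r, c]
            if cake is None:
                continue
            in_window = (cake.q_centers >= q_lo) & (cake.q_centers <= q_hi)
            cells = cake.valid[in_window]
            if not np.any(cells):
                continue
            totals = cake.intensity[in_window] * cake.pixel_counts[in_window]
            values[r, c] = np.nansum(np.where(cells, totals, 0.0))
    return FeatureMap(
        values=values, statistic="total_scattering", q_window=(q_lo, q_hi), step_mm=scan.step_mm
    )


def first_moment(profile: AzimuthalProfile, normalized: bool = True) -> float:
    """First moment of an azimuthal profile as an anisotropy statistic.

    Literal mode (normalized=False): M1 = integral theta I(theta) dtheta by
    trapezoidal quadrature — origin-dependent unless the grid is centered.
    Normalized mode divides by integral I dtheta, giving the
    intensity-weighted mean azimuth.  Both vanish for an isotropic profile
    on a centered grid.
    """
    theta = profile.theta
    intensity = profile.intensity
    ok = np.isfinite(intensity)
    theta, intensity = theta[ok], intensity[ok]
    if theta.size < 2:
        return float("nan")
    centered = abs(theta[0] + theta[-1]) < 1e-9
    if not centered and not normalized:
        warnings.warn(
            "first moment on an uncentered theta grid is origin-dependent", stacklevel=2
        )
    m1 = float(np.trapezoid(theta * intensity, theta))
    if not normalized:
        return m1
    total = float(np.trapezoid(intensity, theta))
    return m1 / total if total != 0 else float("nan")


def anisotropy_map(
    scan: MeshScan,
    q_lo: float = DEFAULT_Q_WINDOW[0],
    q_hi: float = DEFAULT_Q_WINDOW[1],
    normalized: bool = True,
    n_q: int = 40,
    n_theta: int = 36,
) -> FeatureMap:
    """Scattering-anisotropy map: per-point azimuthal first moment."""
    values = np.full(scan.shape, np.nan)
    cakes = scan.cakes(n_q=n_q, n_theta=n_theta)
    for r in range(scan.shape[0]):
        for c in range(scan.shape[1]):
            cake = cakes[r, c]
            if cake is None:
                continue
            try:
                profile = azimuthal_integrate(cake, q_lo, q_hi)
            except ValueError:
                continue
            values[r, c] = first_moment(profile, normalized=normalized)
    statistic = "anisotropy_m1_normalized" if normalized else "anisotropy_m1"
    return FeatureMap(
        values=values, statistic=statistic, q_window=(q_lo, q_hi), step_mm=scan.step_mm
    )
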