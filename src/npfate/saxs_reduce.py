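"""Reduction of 2D SAXS detector frames to polar (q, theta) cakes and 1D curves.

The regrouping is a plain per-pixel rebinning onto a polar grid about the
beam center: each cake cell holds the *mean* of the unmasked pixel counts
whose (q, theta) fall inside it, together with the number of contributing
pixels, so that windowed totals (mean x pixel_counts) are exact and
partially filled corner bins remain well defined.

Conventions
-----------
* q = (4 pi / lambda) * sin(atan(r / D) / 2), lambda[A] = 12.398 / E[keV].
* theta is measured counterclockwise from the detector +x axis (increasing
  column index), with +y along increasing row index; range [-pi, pi).
* Cells with zero contributing pixels are NaN, never zero.
* No polarization or solid-angle corrections are applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .dosimetry import BeamGeometry

__all__ = [
    "DetectorFrame",
    "Cake",
    "Curve1D",
    "AzimuthalProfile",
    "pixel_q_theta",
    "q_theta_maps",
    "azimuthal_regroup",
    "radial_integrate",
    "azimuthal_integrate",
    "subtract_background",
]


class UndefinedAzimuthError(ValueError):
    """Raised for the beam-center pixel, where the azimuth is undefined."""


class EmptyCakeError(ValueError):
    """Raised when every pixel of a frame is masked."""


@dataclass
class DetectorFrame:
    """A single 2D scattering exposure.

    counts : 2D non-negative array of detector counts.
    mask : 2D boolean, True = exclude pixel.
    exposure_time_s : exposure time in seconds.
    """

    counts: np.ndarray
    mask: np.ndarray | None = None
    exposure_time_s: float = 1.0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2D array")
        if not np.all(np.isfinite(self.counts)):
            raise ValueError("counts must be finite")
        if self.mask is None:
            self.mask = np.zeros(self.counts.shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.counts.shape:
                raise ValueError("mask shape must match counts shape")


@dataclass
class Cake:
    """Azimuthally regrouped intensity I(q, theta).

    intensity : 2D array (n_q, n_theta) of per-cell mean counts; NaN where
        no pixel contributes.
    q_edges : strictly increasing bin edges in 1/A, length n_q + 1.
    theta_edges : bin edges in radians covering [-pi, pi), length n_theta + 1.
    pixel_counts : per-cell number of contributing pixels.
    """

    intensity: np.ndarray
    q_edges: np.ndarray
    theta_edges: np.ndarray
    pixel_counts: np.ndarray

    def __post_init__(self) -> None:
        if not np.all(np.diff(self.q_edges) > 0):
            raise ValueError("q_edges must be strictly increasing")

    @property
    def q_centers(self) -> np.ndarray:
        return 0.5 * (self.q_edges[:-1] + self.q_edges[1:])

    @property
    def theta_centers(self) -> np.ndarray:
        return 0.5 * (self.theta_edges[:-1] + self.theta_edges[1:])

    @property
    def valid(self) -> np.ndarray:
        return self.pixel_counts > 0


@dataclass
class Curve1D:
    """A 1D scattering curve I(q) with propagated counting uncertainty."""

    q: np.ndarray
    intensity: np.ndarray
    sigma: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.q.shape != self.intensity.shape:
            raise ValueError("q and intensity must have the same length")
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
            if self.sigma.shape != self.q.shape:
                raise ValueError("sigma must match q length")
            if np.any(self.sigma < 0):
                raise ValueError("sigma must be non-negative")


@dataclass
class AzimuthalProfile:
    """Azimuthal intensity profile I(theta) on a centered grid in [-pi, pi)."""

    theta: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if np.any(self.theta < -np.pi) or np.any(self.theta >= np.pi):
            raise ValueError("theta must lie in [-pi, pi)")


def pixel_q_theta(beam: BeamGeometry, pixel: tuple[float, float]) -> tuple[float, float]:
    """Scattering vector magnitude and azimuth of one detector pixel.

    Returns (q [1/A], theta [rad]).  Raises :class:`UndefinedAzimuthError`
    for the exact beam-center pixel, whose azimuth is undefined (its q is 0).
    """
    row, col = pixel
    dy = (row - beam.beam_center[0]) * beam.pixel_um * 1e-3  # mm
    dx = (col - beam.beam_center[1]) * beam.pixel_um * 1e-3
    r = np.hypot(dy, dx)
    q = (4.0 * np.pi / beam.wavelength_A) * np.sin(0.5 * np.arctan2(r, beam.sample_detector_mm))
    if r == 0.0:
        raise UndefinedAzimuthError("azimuth undefined at the beam center (q = 0)")
    theta = np.arctan2(dy, dx)
    if theta >= np.pi:  # atan2 returns (-pi, pi]; fold pi onto -pi
        theta = -np.pi
    return float(q), float(theta)


def q_theta_maps(beam: BeamGeometry, shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel q and theta maps for a detector of the given shape.

    theta is NaN at the beam-center pixel (undefined azimuth).
    """
    rows = np.arange(shape[0], dtype=float)[:, None]
    cols = np.arange(shape[1], dtype=float)[None, :]
    dy = (rows - beam.beam_center[0]) * beam.pixel_um * 1e-3
    dx = (cols - beam.beam_center[1]) * beam.pixel_um * 1e-3
    r = np.hypot(dy, dx)
    q = (4.0 * np.pi / beam.wavelength_A) * np.sin(0.5 * np.arctan2(r, beam.sample_detector_mm))
    theta = np.arctan2(dy, dx)
    theta = np.where(theta >= np.pi, -np.pi, theta)
    theta = np.where(r == 0.0, np.nan, theta)
    return q, theta


def azimuthal_regroup(
    frame: DetectorFrame,
    beam: BeamGeometry,
    n_q: int,
    n_theta: int,
    q_range: tuple[float, float] | None = None,
) -> Cake:
    """Rebin a detector frame onto a polar (q, theta) grid.

    Each cell is the mean of the unmasked pixel counts falling in it;
    ``pixel_counts`` records how many pixels contributed, so that
    ``intensity * pixel_counts`` summed over cells reproduces the total
    unmasked counts exactly (the beam-center pixel, whose azimuth is
    undefined, is always excluded).
    """
    if n_q < 2 or n_theta < 2:
        raise ValueError("n_q and n_theta must both be at least 2")
    q_map, theta_map = q_theta_maps(beam, frame.counts.shape)
    keep = ~frame.mask & np.isfinite(theta_map)
    if not np.any(keep):
        raise EmptyCakeError("all pixels are masked")
    qs = q_map[keep]
    thetas = theta_map[keep]
    values = frame.counts[keep]

    if q_range is None:
        q_lo, q_hi = qs.min(), qs.max()
    else:
        q_lo, q_hi = q_range
    if q_hi <= q_lo:
        raise ValueError("q_range must be increasing")
    q_edges = np.linspace(q_lo, q_hi, n_q + 1)
    theta_edges = np.linspace(-np.pi, np.pi, n_theta + 1)

    # np.histogram2d treats the last bin as closed, matching "conservation":
    # pixels at q == q_hi and theta == pi-epsilon all land inside the grid.
    sums, _, _ = np.histogram2d(qs, thetas, bins=(q_edges, theta_edges), weights=values)
    counts, _, _ = np.histogram2d(qs, thetas, bins=(q_edges, theta_edges))
    with np.errstate(invalid="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return Cake(
        intensity=mean,
        q_edges=q_edges,
        theta_edges=theta_edges,
        pixel_counts=counts.astype(int),
    )


def radial_integrate(cake: Cake) -> Curve1D:
    """Collapse a cake over theta to I(q), pixel-count weighted.

    sigma assumes Poisson counting statistics on the total counts in each
    q-row: sigma(mean) = sqrt(total counts) / n_pixels.
    """
    n = cake.pixel_counts.astype(float)
    totals = np.where(cake.valid, cake.intensity * n, 0.0)
    row_counts = n.sum(axis=1)
    row_totals = totals.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        intensity = np.where(row_counts > 0, row_totals / row_counts, np.nan)
        sigma = np.where(row_counts > 0, np.sqrt(np.maximum(row_totals, 0.0)) / row_counts, np.nan)
    return Curve1D(q=cake.q_centers, intensity=intensity, sigma=sigma)


def azimuthal_integrate(cake: Cake, q_lo: float, q_hi: float) -> AzimuthalProfile:
    """Collapse a cake over a q-window to I(theta), pixel-count weighted."""
    centers = cake.q_centers
    in_window = (centers >= q_lo) & (centers <= q_hi)
    if q_hi <= q_lo or not np.any(in_window):
        raise ValueError(
            f"q-window [{q_lo}, {q_hi}] does not overlap cake q-range "
            f"[{cake.q_edges[0]}, {cake.q_edges[-1]}]"
        )
    n = cake.pixel_counts[in_window].astype(float)
    totals = np.where(cake.valid[in_window], cake.intensity[in_window] * n, 0.0)
    col_counts = n.sum(axis=0)
    with np.errstate(invalid="ignore"):
        intensity = np.where(col_counts > 0, totals.sum(axis=0) / col_counts, np.nan)
    return AzimuthalProfile(theta=cake.theta_centers, intensity=intensity)


def subtract_background(sample: Curve1D, background: Curve1D, scale: float = 1.0) -> Curve1D:
    """Subtract a scaled background curve from a sample curve.

    The background is linearly interpolated onto the sample q-grid when the
    grids differ; the sample grid must lie inside the background's q-range.
    Negative results are retained (a warning reports how many), and sigmas
    are combined in quadrature.
    """
    if np.array_equal(sample.q, background.q):
        bg_i = background.intensity
        bg_s = background.sigma
    else:
        if sample.q.min() < background.q.min() or sample.q.max() > background.q.max():
            raise ValueError("sample q-grid not covered by background q-grid")
        order = np.argsort(background.q)
        bg_i = np.interp(sample.q, background.q[order], background.intensity[order])
        bg_s = (
            np.interp(sample.q, background.q[order], background.sigma[order])
            if background.sigma is not None
            else None
        )
    intensity = sample.intensity - scale * bg_i
    if sample.sigma is not None and bg_s is not None:
        sigma = np.sqrt(sample.sigma**2 + (scale * bg_s) ** 2)
    else:
        sigma = sample.sigma
    n_negative = int(np.sum(intensity < 0))
    if n_negative:
        warnings.warn(
            f"background subtraction produced {n_negative} negative intensities (retained)",
            stacklevel=2,
        )
    return Curve1D(q=sample.q.copy(), intensity=intensity, sigma=sigma)
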