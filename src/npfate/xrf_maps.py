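"""Fitted X-ray fluorescence elemental maps: registration and histograms.

Elemental maps (e.g. P, Ca, K at their K-edges; Ce, Eu at L-edges) arrive
as fitted 2D intensity grids.  Two operations support the correlative
analysis: a translation-only co-registration (integer-pixel, by normalized
cross-correlation of Otsu-binarized maps, mirroring crop-based alignment of
modalities that share gross morphology but not a coordinate frame), and
common-bin histograms of a time series against a control map, whose
maximum intensity serves as the reference marker separating the
nanoparticle-dosed signal from native background.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve
from skimage.filters import threshold_otsu

__all__ = [
    "ElementMap",
    "AlignmentError",
    "coregister_crop",
    "histogram_vs_control",
]


class AlignmentError(ValueError):
    """Raised when cross-correlation cannot establish a translation."""


@dataclass
class ElementMap:
    """A fitted elemental intensity map.

    element : element symbol (e.g. 'P', 'Ce').
    intensity : 2D non-negative array of fitted counts.
    pixel_size_um : map pixel size in micrometers.
    """

    element: str
    intensity: np.ndarray
    pixel_size_um: float = 20.0

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.ndim != 2:
            raise ValueError("intensity must be a 2D array")
        if np.any(self.intensity < 0):
            raise ValueError("intensity must be non-negative")


def _binarize(img: np.ndarray) -> np.ndarray:
    if np.ptp(img) == 0:
        return np.zeros_like(img)
    return (img > threshold_otsu(img)).astype(float)


def estimate_offset(map_a: ElementMap, map_b: ElementMap) -> tuple[tuple[int, int], float]:
    """Integer-pixel translation of map_b relative to map_a.

    Normalized cross-correlation of the zero-mean Otsu-binarized maps; the
    returned (dy, dx) is the shift that moved content from a to b, and the
    peak value (in [0, 1]) measures alignment confidence.
    """
    a = _binarize(map_a.intensity)
    b = _binarize(map_b.intensity)
    a0 = a - a.mean()
    b0 = b - b.mean()
    denom = np.sqrt((a0**2).sum() * (b0**2).sum())
    if denom == 0:
        return (0, 0), 0.0
    corr = fftconvolve(b0, a0[::-1, ::-1], mode="full")
    peak = np.unravel_index(np.argmax(corr), corr.shape)
    dy = int(peak[0] - (a.shape[0] - 1))
    dx = int(peak[1] - (a.shape[1] - 1))
    return (dy, dx), float(corr[peak] / denom)


def coregister_crop(
    map_a: ElementMap,
    map_b: ElementMap,
    offset: tuple[int, int] | None = None,
    min_correlation: float = 0.2,
) -> tuple[ElementMap, ElementMap, tuple[int, int]]:
    """Align two maps by integer translation and crop to the overlap.

    If ``offset`` (dy, dx, such that b's content equals a's translated by
    that amount) is not given
    it is estimated by normalized cross-correlation; an estimated peak
    below ``min_correlation`` raises :class:`AlignmentError`, in which case
    a manual offset must be supplied.  Returns the two cropped maps plus
    the offset used.
    """
    if offset is None:
        offset, peak = estimate_offset(map_a, map_b)
        if peak < min_correlation:
            raise AlignmentError(
                f"correlation peak {peak:.3f} below {min_correlation}; supply a manual offset"
            )
    dy, dx = offset
    ha, wa = map_a.intensity.shape
    hb, wb = map_b.intensity.shape
    # b[y, x] = a[y - dy, x - dx]: a's pixel j pairs with b's pixel j + d
    a_y0, a_x0 = max(0, -dy), max(0, -dx)
    b_y0, b_x0 = max(0, dy), max(0, dx)
    h = min(ha - a_y0, hb - b_y0)
    w = min(wa - a_x0, wb - b_x0)
    if h <= 0 or w <= 0:
        raise AlignmentError(f"offset {offset} leaves no overlap")
    crop_a = ElementMap(
        element=map_a.element,
        intensity=map_a.intensity[a_y0 : a_y0 + h, a_x0 : a_x0 + w],
        pixel_size_um=map_a.pixel_size_um,
    )
    crop_b = ElementMap(
        element=map_b.element,
        intensity=map_b.intensity[b_y0 : b_y0 + h, b_x0 : b_x0 + w],
        pixel_size_um=map_b.pixel_size_um,
    )
    return crop_a, crop_b, (dy, dx)


def histogram_vs_control(
    maps: list[ElementMap],
    control: ElementMap,
    bins: int = 50,
) -> dict:
    """Common-bin histograms of a time series with the control maximum.

    All maps must share the control's element.  Bin edges are common to the
    whole series and the control, so histograms are directly comparable.
    ``control_max`` is the literal maximum of the control map, and each
    entry reports the fraction of pixels above it — the signal attributable
    to the dosed nanoparticles rather than native background.
    """
    for m in maps:
        if m.element != control.element:
            raise ValueError(
                f"element mismatch: map has {m.element!r}, control has {control.element!r}"
            )
    lo = min(m.intensity.min() for m in [*maps, control])
    hi = max(m.intensity.max() for m in [*maps, control])
    edges = np.linspace(lo, hi, bins + 1)
    control_max = float(control.intensity.max())
    entries = []
    for m in maps:
        counts, _ = np.histogram(m.intensity, bins=edges)
        frac = float(np.mean(m.intensity > control_max))
        entries.append(
            {
                "counts": counts,
                "fraction_above_control_max": frac,
                "peak_bin": int(np.argmax(counts)),
            }
        )
    return {"edges": edges, "control_max": control_max, "entries": entries}
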