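"""Multimodal decision framework for nanoparticle fate.

After foliar infiltration, nanoparticles may aggregate, disperse, dissolve
or translocate.  Each process leaves a distinct joint signature in the
three imaging modalities:

====================  =======  ========  =======
process               SAXS     micro-CT  XRF
====================  =======  ========  =======
aggregation           down     up        stable
dispersion            up       down      stable
dissolution           down     stable    stable
translocation         down     down      down
====================  =======  ========  =======

The XRF column refers to the dosed particle's signature element; for
dissolution the discriminating tracer is the *immobile* dopant (e.g. Ce),
which stays put while the mobile nutrient (e.g. P) is exported — the
mobile element's decline is reported alongside, not used to veto the call.

Trends are first-to-last relative changes with an inclusive +/-10%
stability band by default; classification returns every rule whose pattern
matches (the framework is not claimed to be a partition).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TrendTriplet",
    "ProcessCall",
    "extract_trend",
    "classify_process",
    "correlate_case",
    "RULES",
    "DEFAULT_STABILITY_BAND",
]

DEFAULT_STABILITY_BAND = 0.10

#: process -> (saxs, ct, xrf) trend pattern
RULES: dict[str, tuple[str, str, str]] = {
    "aggregation": ("down", "up", "stable"),
    "dispersion": ("up", "down", "stable"),
    "dissolution": ("down", "stable", "stable"),
    "translocation": ("down", "down", "down"),
}


class UndefinedBaselineError(ValueError):
    """Raised when the first value of a series is non-positive."""


class InsufficientTimepointsError(ValueError):
    """Raised when fewer than two timepoints are available."""


@dataclass
class TrendTriplet:
    """Per-modality trend labels with the relative changes behind them."""

    saxs: str
    ct: str
    xrf: str
    relative_changes: tuple[float, float, float] = (float("nan"),) * 3
    element_role: str = "unspecified"  # 'mobile', 'immobile' or 'unspecified'

    def __post_init__(self) -> None:
        for label in (self.saxs, self.ct, self.xrf):
            if label not in ("up", "down", "stable"):
                raise ValueError(f"trend label must be up/down/stable, got {label!r}")


@dataclass
class ProcessCall:
    """Outcome of the rule-table classification."""

    labels: set[str]
    matched_rules: list[str]
    confidence_note: str = ""


def extract_trend(
    series: Sequence[tuple[float, float]] | Sequence[float],
    band: float = DEFAULT_STABILITY_BAND,
) -> tuple[str, float]:
    """Label a time series up/down/stable by its first-to-last change.

    ``series`` is a list of (time, statistic) pairs (or bare statistics) in
    ascending time order.  r = (last - first) / first; |r| <= band (band
    inclusive) is stable, otherwise the sign decides.
    """
    values = [v[1] if isinstance(v, (tuple, list)) else v for v in series]
    if len(values) < 2:
        raise InsufficientTimepointsError("need at least two timepoints to define a trend")
    first, last = float(values[0]), float(values[-1])
    if first <= 0:
        raise UndefinedBaselineError(f"first value must be positive, got {first}")
    r = (last - first) / first
    if abs(r) <= band:
        return "stable", r
    return ("up" if r > 0 else "down"), r


def classify_process(triplet: TrendTriplet) -> ProcessCall:
    """Match a trend triplet against the fate rule table.

    Every rule consistent with the triplet is returned; an empty label set
    means the observed pattern is inconsistent with the framework.
    """
    pattern = (triplet.saxs, triplet.ct, triplet.xrf)
    labels = {name for name, rule in RULES.items() if rule == pattern}
    if labels:
        note = f"pattern {pattern} matched {sorted(labels)}"
    else:
        note = "inconsistent with framework"
    return ProcessCall(labels=labels, matched_rules=sorted(labels), confidence_note=note)


def correlate_case(
    days: Sequence[float],
    saxs_maps: Sequence,
    ct_np_mean: Sequence[float],
    xrf_maps: Sequence,
    saxs_mask: np.ndarray | None = None,
    xrf_mask: np.ndarray | None = None,
    band: float = DEFAULT_STABILITY_BAND,
    element_role: str = "immobile",
) -> tuple[ProcessCall, pd.DataFrame]:
    """End-to-end fate call from per-day modality products.

    Parameters
    ----------
    days : ascending acquisition days.
    saxs_maps : per-day total-scattering FeatureMaps (or bare 2D arrays).
    ct_np_mean : per-day mean gray value of the nanoparticle CT region
        (e.g. the ``np_mean_gray`` column of a CT time-series report).
    xrf_maps : per-day ElementMaps (or bare 2D arrays) of the signature
        element; pass the immobile tracer to probe dissolution.
    saxs_mask, xrf_mask : region-of-interest masks on the respective grids
        (default: whole map).

    Returns the ProcessCall plus an evidence table listing each modality's
    statistic per timepoint and the extracted trends.
    """
    if len(days) < 2:
        raise InsufficientTimepointsError("insufficient timepoints")
    if not (len(days) == len(saxs_maps) == len(ct_np_mean) == len(xrf_maps)):
        raise ValueError("all modality series must have one entry per day")

    def region_mean(obj, mask):
        arr = np.asarray(getattr(obj, "values", getattr(obj, "intensity", obj)), dtype=float)
        if mask is not None:
            arr = arr[mask]
        return float(np.nanmean(arr))

    saxs_stats = [region_mean(m, saxs_mask) for m in saxs_maps]
    ct_stats = [float(v) for v in ct_np_mean]
    xrf_stats = [region_mean(m, xrf_mask) for m in xrf_maps]

    saxs_trend, r_saxs = extract_trend(saxs_stats, band)
    ct_trend, r_ct = extract_trend(ct_stats, band)
    xrf_trend, r_xrf = extract_trend(xrf_stats, band)
    triplet = TrendTriplet(
        saxs=saxs_trend,
        ct=ct_trend,
        xrf=xrf_trend,
        relative_changes=(r_saxs, r_ct, r_xrf),
        element_role=element_role,
    )
    call = classify_process(triplet)
    evidence = pd.DataFrame(
        {
            "day": list(days),
            "saxs_region_mean": saxs_stats,
            "ct_np_mean_gray": ct_stats,
            "xrf_region_mean": xrf_stats,
        }
    )
    evidence.attrs["trends"] = {
        "saxs": (saxs_trend, r_saxs),
        "ct": (ct_trend, r_ct),
        "xrf": (xrf_trend, r_xrf),
    }
    return call, evidence
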