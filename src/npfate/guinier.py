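"""Guinier analysis of solution small-angle scattering.

In the low-q (Guinier) regime, I(q) ~ I0 exp(-q^2 Rg^2 / 3): a straight
line in ln I versus q^2 whose slope gives the radius of gyration Rg and
whose intercept gives the forward-scattered intensity I0.  I0 is
proportional to particle concentration at fixed size and contrast, so the
ratio of baseline to diluted I0 tracks the dilution factor, while Rg stays
constant until particles start to dissolve or aggregate.

The fit is a weighted linear least squares in (q^2, ln I) with weights
(I/sigma)^2 (the delta-method variance of ln I); when no q-window is
given, the widest low-q window satisfying q_max * Rg <= limit (default
1.3, the standard validity bound for globular scatterers) is found by
iterating fit and window to a fixed point.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .saxs_reduce import Curve1D

__all__ = [
    "GuinierResult",
    "DilutionSeries",
    "guinier_fit",
    "reduction_ratios",
    "rg_stability",
]

DEFAULT_QMAX_RG = 1.3
MIN_POINTS = 5


class FitImpossibleError(ValueError):
    """Raised when no usable points remain for a Guinier fit."""


@dataclass
class GuinierResult:
    """Result of one Guinier fit.

    rg / rg_err : radius of gyration and its standard error, Angstrom.
    i_zero / i_zero_err : forward-scattered intensity (extrapolated I(0),
        not the incident flux) and its standard error, a.u.
    q_window : (q_min, q_max) actually fitted, 1/A.
    q_max_rg : q_max * Rg of the fitted window.
    n_points : points used; n_dropped : non-positive intensities excluded.
    degenerate : True when the slope was non-negative (flat or rising
        curve), in which case rg is reported as 0.
    """

    rg: float
    rg_err: float
    i_zero: float
    i_zero_err: float
    q_window: tuple[float, float]
    q_max_rg: float
    n_points: int
    n_dropped: int = 0
    degenerate: bool = False


@dataclass
class DilutionSeries:
    """Guinier results across a dilution series of one particle type.

    entries : list of (label, dilution_factor, GuinierResult); the
    baseline (factor 1) entry is identified by ``baseline_label``.
    """

    entries: list[tuple[str, float, GuinierResult]]
    baseline_label: str

    def __post_init__(self) -> None:
        labels = [label for label, _, _ in self.entries]
        if self.baseline_label not in labels:
            raise ValueError(f"baseline {self.baseline_label!r} not among entries {labels}")
        for label, factor, _ in self.entries:
            if factor < 1:
                raise ValueError(f"dilution factor must be >= 1, got {factor} for {label!r}")

    def baseline(self) -> GuinierResult:
        for label, _, result in self.entries:
            if label == self.baseline_label:
                return result
        raise AssertionError  # unreachable; checked in __post_init__


def _wls(x: np.ndarray, y: np.ndarray, w: np.ndarray):
    """Weighted least squares y = b + m x; returns (m, b, var_m, var_b)."""
    sw = w.sum()
    xm = (w * x).sum() / sw
    ym = (w * y).sum() / sw
    sxx = (w * (x - xm) ** 2).sum()
    m = (w * (x - xm) * (y - ym)).sum() / sxx
    b = ym - m * xm
    # covariance from the weight model (weights = 1/var)
    var_m = 1.0 / sxx
    var_b = 1.0 / sw + xm**2 / sxx
    return m, b, var_m, var_b


def _fit_points(q: np.ndarray, i: np.ndarray, sigma: np.ndarray | None) -> GuinierResult:
    x = q**2
    y = np.log(i)
    if sigma is not None and np.all(sigma > 0):
        w = (i / sigma) ** 2
    else:
        w = np.ones_like(i)
    m, b, var_m, var_b = _wls(x, y, w)
    i_zero = float(np.exp(b))
    i_zero_err = i_zero * float(np.sqrt(var_b))
    if m >= 0:
        return GuinierResult(
            rg=0.0,
            rg_err=float("nan"),
            i_zero=i_zero,
            i_zero_err=i_zero_err,
            q_window=(float(q.min()), float(q.max())),
            q_max_rg=0.0,
            n_points=int(q.size),
            degenerate=True,
        )
    rg = float(np.sqrt(-3.0 * m))
    rg_err = float(1.5 / rg * np.sqrt(var_m))  # |dRg/dm| = 3/(2 Rg)
    return GuinierResult(
        rg=rg,
        rg_err=rg_err,
        i_zero=i_zero,
        i_zero_err=i_zero_err,
        q_window=(float(q.min()), float(q.max())),
        q_max_rg=float(q.max() * rg),
        n_points=int(q.size),
    )


def guinier_fit(
    curve: Curve1D,
    q_window: tuple[float, float] | None = None,
    qmax_rg_limit: float = DEFAULT_QMAX_RG,
    max_iter: int = 50,
) -> GuinierResult:
    """Fit Rg and I0 to the low-q portion of a scattering curve.

    With an explicit ``q_window`` the fit uses exactly the positive-
    intensity points inside it.  Without one, the window starts from all
    points and is iteratively truncated to q <= limit / Rg until the fit
    and window are mutually consistent (or ``max_iter`` is exceeded).
    """
    keep = np.isfinite(curve.intensity) & (curve.intensity > 0) & np.isfinite(curve.q)
    n_dropped = int(curve.q.size - keep.sum())
    q = curve.q[keep]
    i = curve.intensity[keep]
    sigma = curve.sigma[keep] if curve.sigma is not None else None
    order = np.argsort(q)
    q, i = q[order], i[order]
    sigma = sigma[order] if sigma is not None else None

    if q.size < MIN_POINTS:
        raise FitImpossibleError(
            f"need at least {MIN_POINTS} positive-intensity points, have {q.size}"
        )

    if q_window is not None:
        sel = (q >= q_window[0]) & (q <= q_window[1])
        if sel.sum() < MIN_POINTS:
            raise FitImpossibleError("fewer than 5 positive points inside the q-window")
        result = _fit_points(q[sel], i[sel], sigma[sel] if sigma is not None else None)
        result.n_dropped = n_dropped
        return result

    n = q.size
    for _ in range(max_iter):
        result = _fit_points(q[:n], i[:n], sigma[:n] if sigma is not None else None)
        if result.degenerate:
            result.n_dropped = n_dropped
            return result
        n_new = int(np.searchsorted(q, qmax_rg_limit / result.rg, side="right"))
        n_new = max(n_new, MIN_POINTS)
        if n_new >= n:
            result.n_dropped = n_dropped
            return result
        n = n_new
    raise FitImpossibleError(f"window iteration did not converge within {max_iter} iterations")


def reduction_ratios(series: DilutionSeries, decimals: int | None = 2) -> list[tuple[str, float]]:
    """I0 reduction ratio of each entry relative to the series baseline.

    ratio = I0(baseline) / I0(entry); the baseline row reads 1.  Ratios are
    rounded to ``decimals`` places for table reproduction (None = full
    precision).  Tracks the dilution factor when scattering is linear in
    concentration.
    """
    base = series.baseline().i_zero
    if base <= 0:
        raise ValueError("baseline forward intensity must be positive")
    out = []
    for label, _, result in series.entries:
        if result.i_zero <= 0:
            raise ValueError(f"non-positive forward intensity for entry {label!r}")
        ratio = base / result.i_zero
        out.append((label, round(ratio, decimals) if decimals is not None else ratio))
    return out


def rg_stability(series: DilutionSeries, tolerance: float = 0.05) -> dict:
    """Spread of fitted Rg across a dilution series.

    max_relative_spread = max |rg - median| / median; the series is called
    stable when the spread is within ``tolerance`` (default 5%), the
    particle-size-invariance check for dilution.
    """
    if len(series.entries) < 2:
        raise ValueError("need at least two entries to assess stability")
    rgs = np.array([result.rg for _, _, result in series.entries], dtype=float)
    med = float(np.median(rgs))
    spread = float(np.max(np.abs(rgs - med)) / med)
    return {"max_relative_spread": spread, "stable": spread <= tolerance, "median_rg": med}
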