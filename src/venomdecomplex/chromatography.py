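"""Chromatographic share estimation from a 215 nm RP-HPLC trace.

The whole-venom quantification model is hierarchical: each manually collected
fraction contributes a share ``f_i`` of the total venom protein, estimated as
the fraction's integrated (baseline-corrected) absorbance divided by the total
over all collected fractions.  Uncollected baseline regions are excluded from
the normalising denominator, so collected shares sum to 1.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import maximum_filter1d, minimum_filter1d
from scipy.signal import find_peaks

from .datamodel import (
    Chromatogram,
    FractionBoundary,
    FractionBoundarySet,
    FractionShareTable,
)
from .errors import BoundsError, NoSignal


def correct_baseline(chrom: Chromatogram, method: str = "linear_endpoints",
                     window_min: float = 30.0) -> Chromatogram:
    """Subtract a baseline estimate; negative residuals are clipped to 0.

    ``linear_endpoints`` subtracts the straight line through the first and
    last sample — parameter-free and adequate for slow solvent-gradient drift.
    ``rolling_min`` subtracts a morphological opening (running minimum then
    running maximum over a ``window_min``-minute window), which tracks
    non-linear drift; the window must exceed the widest peak's base or the
    opening will eat into peaks, and the estimator lags on steep ramps.
    """
    y = chrom.absorbance
    t = chrom.time
    if method == "linear_endpoints":
        baseline = y[0] + (y[-1] - y[0]) * (t - t[0]) / (t[-1] - t[0])
    elif method == "rolling_min":
        dt = float(np.median(np.diff(t)))
        size = max(1, int(round(window_min / dt)))
        baseline = maximum_filter1d(
            minimum_filter1d(y, size=size, mode="nearest"), size=size, mode="nearest"
        )
    else:
        raise ValueError(f"unknown baseline method {method!r}")
    return chrom.with_absorbance(np.clip(y - baseline, 0.0, None))


def _segment_area(t: np.ndarray, y: np.ndarray, start: float, end: float) -> float:
    """Trapezoidal area of the trace over [start, end], with interpolated endpoints."""
    inner = (t > start) & (t < end)
    ts = np.concatenate(([start], t[inner], [end]))
    ys = np.concatenate(([np.interp(start, t, y)], y[inner], [np.interp(end, t, y)]))
    return float(np.trapezoid(ys, ts))


def integrate_fractions(chrom: Chromatogram, bounds: FractionBoundarySet) -> FractionShareTable:
    """Trapezoidal area per collected fraction window, normalised to shares.

    Fraction windows are half-open ``[start, end)``; because windows never
    overlap, endpoint interpolation assigns each boundary's measure-zero point
    consistently.
    """
    t, y = chrom.time, chrom.absorbance
    areas: dict[str, float] = {}
    for b in bounds.collected:
        if b.start < t[0] - 1e-9 or b.end > t[-1] + 1e-9:
            raise BoundsError(
                f"fraction {b.fraction_id} [{b.start}, {b.end}) outside trace "
                f"range [{t[0]}, {t[-1]}]"
            )
        areas[b.fraction_id] = max(_segment_area(t, y, b.start, b.end), 0.0)
    total = sum(areas.values())
    if total <= 0:
        raise NoSignal("zero total integrated area over collected fractions")
    return FractionShareTable({fid: a / total for fid, a in areas.items()}).validate()


def detect_peaks(chrom: Chromatogram, min_prominence: float = 5.0) -> FractionBoundarySet:
    """Propose fraction boundaries at the local minima flanking prominent maxima.

    A helper for simulated or unannotated traces; the reference workflow uses
    manually collected boundaries.  Returns an empty set on a flat trace.
    """
    t, y = chrom.time, chrom.absorbance
    peaks, _ = find_peaks(y, prominence=min_prominence)
    if peaks.size == 0:
        return FractionBoundarySet(())
    # internal boundaries at the minimum between consecutive peaks
    cuts = [float(t[0])]
    for left, right in zip(peaks, peaks[1:]):
        k = left + int(np.argmin(y[left:right + 1]))
        cuts.append(float(t[k]))
    cuts.append(float(t[-1]))
    entries = tuple(
        FractionBoundary(f"F{i + 1}", cuts[i], cuts[i + 1], True)
        for i in range(len(cuts) - 1)
    )
    return FractionBoundarySet(entries)
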