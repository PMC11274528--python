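"""Mean tumor diameter (MTD) and velocity of diameter expansion (VDE).

The MTD is the diameter of the sphere equivalent to the tumor under the
halving convention: from the three orthogonal diameters,
``MTD.3D = (D1·D2·D3)^(1/3)``, or from the segmented volume,
``MTD.V = (2·V)^(1/3)`` with V in mm³.  When V is itself the ellipsoid
half-product estimate (D1·D2·D3)/2 the two coincide algebraically.

The VDE is the slope of the linear MTD growth curve over time in years
(mm/year), fitted by ordinary least squares over all scans of an eligible
window: a maximal run of follow-up spanning at least 6 months with no
interfering therapeutic intervention.  Typical surgically managed LGGs
grow around 3–4 mm/year; a VDE at or above 8 mm/year signals impending
anaplastic transformation.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "MTDPair",
    "VDEEstimate",
    "mtd_from_diameters",
    "mtd_from_volume",
    "eligible_windows",
    "vde",
    "DAYS_PER_YEAR",
    "MIN_WINDOW_DAYS",
    "VDE_ALARM_MM_PER_YEAR",
]

DAYS_PER_YEAR = 365.25
MIN_WINDOW_DAYS = 182  # "at least 6 months apart"
VDE_ALARM_MM_PER_YEAR = 8.0


@dataclass(frozen=True)
class MTDPair:
    """Both MTD variants for one scan, mm."""

    mtd_3d: float
    mtd_v: float
    scan_date: date


@dataclass(frozen=True)
class VDEEstimate:
    """OLS slope of MTD against time for one eligible window."""

    vde: float  # mm/year
    window: tuple[date, date]
    n_scans: int
    variant: str  # "3d" | "v"
    excluded_reason: str | None = None


def mtd_from_diameters(d1: float, d2: float, d3: float) -> float:
    """MTD.3D = (D1·D2·D3)^(1/3), diameters in mm."""
    if d1 <= 0 or d2 <= 0 or d3 <= 0:
        raise ValueError("diameters must be positive")
    return float((d1 * d2 * d3) ** (1.0 / 3.0))


def mtd_from_volume(volume_ml: float) -> float:
    """MTD.V = (2·V)^(1/3) with V converted from mL to mm³.

    Note the halving convention's bias on true spheres: for a sphere of
    diameter d, V = (π/6)d³ and MTD.V = (π/3)^(1/3)·d ≈ 1.0156·d.
    """
    if volume_ml < 0:
        raise ValueError("volume must be >= 0")
    return float((2.0 * volume_ml * 1000.0) ** (1.0 / 3.0))


def eligible_windows(
    scan_dates: Sequence[date],
    events: Iterable[date] = (),
) -> list[tuple[date, date, list[int]]]:
    """Treatment-free follow-up windows spanning at least 6 months.

    Scans are cut into maximal segments at each treatment event; a segment
    whose first and last scans are >= 182 days apart yields one window
    ``(start, end, scan indices)``.  A scan falling exactly on an event
    date belongs to both adjacent segments (documented convention).

    Raises if ``scan_dates`` is not sorted — silently sorting would hide
    manifest errors.
    """
    dates = list(scan_dates)
    if any(b < a for a, b in zip(dates, dates[1:])):
        raise ValueError("scan dates must be sorted ascending")
    cuts = sorted(set(events))

    segments: list[list[int]] = []
    current: list[int] = []
    remaining = list(cuts)
    for i, d in enumerate(dates):
        while remaining and remaining[0] < d:
            if current:
                segments.append(current)
            current = []
            remaining.pop(0)
        if remaining and remaining[0] == d:
            # boundary scan closes the segment and opens the next
            current.append(i)
            segments.append(current)
            current = [i]
            remaining.pop(0)
        else:
            current.append(i)
    if current:
        segments.append(current)

    windows = []
    for seg in segments:
        if len(seg) < 2:
            continue
        start, end = dates[seg[0]], dates[seg[-1]]
        if (end - start).days >= MIN_WINDOW_DAYS:
            windows.append((start, end, seg))
    return windows


def vde(
    scans: Sequence[tuple[date, float]],
    variant: str = "v",
    method: str = "ols",
) -> VDEEstimate:
    """VDE of one window: slope of MTD (mm) against time (years).

    ``scans`` are (date, mtd) pairs; time is measured in years of 365.25
    days since the window start.  ``method="ols"`` (default) regresses over
    all scans; ``method="endpoint"`` uses only the first and last scans
    (the two coincide for two-scan windows).
    """
    if len(scans) < 2:
        raise ValueError("VDE needs at least 2 scans")
    dates = [d for d, _ in scans]
    if any(b < a for a, b in zip(dates, dates[1:])):
        raise ValueError("scan dates must be sorted ascending")
    t = np.array([(d - dates[0]).days for d in dates]) / DAYS_PER_YEAR
    y = np.array([m for _, m in scans], dtype=float)
    if t[-1] == t[0]:
        raise ValueError("window has zero time span")
    if method == "endpoint":
        slope = (y[-1] - y[0]) / (t[-1] - t[0])
    elif method == "ols":
        slope = float(np.polyfit(t, y, 1)[0])
    else:
        raise ValueError("method must be 'ols' or 'endpoint'")
    return VDEEstimate(vde=float(slope), window=(dates[0], dates[-1]),
                       n_scans=len(scans), variant=variant)


def pairwise_windows(
    scan_dates: Sequence[date],
    events: Iterable[date] = (),
) -> list[tuple[date, date, list[int]]]:
    """All treatment-free scan pairs >= 6 months apart (per-assessment
    analysis mode, mirroring paired-comparison designs); the default
    maximal-segment windows avoid double-counting correlated pairs."""
    windows = []
    for start, end, seg in eligible_windows(scan_dates, events):
        dates = list(scan_dates)
        for a in range(len(seg)):
            for b in range(a + 1, len(seg)):
                i, j = seg[a], seg[b]
                if (dates[j] - dates[i]).days >= MIN_WINDOW_DAYS:
                    windows.append((dates[i], dates[j], [i, j]))
    return windows
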