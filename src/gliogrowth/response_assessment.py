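"""Baseline selection, measurability filters and progression classification.

Follows the high-grade-glioma response frameworks (RECIST / Macdonald /
RANO) transposed to post-surgical LGG follow-up:

* the baseline is the first MRI between 72 hours and 2 years after
  surgery (earlier scans are confounded by post-surgical changes; a first
  scan later than 2 years excludes the patient), or, for
  chemotherapy-response evaluation, the last scan before chemotherapy
  onset;
* non-measurable baselines are excluded per method: < 10 mm (1D),
  < 100 mm² (2D), < 0.5 mL (3D);
* progression under the RANO-derived thresholds is an increase of
  ≥ 20% (1D), ≥ 25% (2D) or ≥ 40% (3D and segmented volume) from
  baseline; the LGG-optimized mode instead uses the ROC-derived cutoffs
  > 16% (1D), > 33% (2D), > 52% (3D), > 15% (MTD.3D).  The segmented
  volume at ≥ 40% serves as ground truth in both modes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta

import pandas as pd

__all__ = [
    "ThresholdConfig",
    "ResponseLabel",
    "BaselineResult",
    "select_baseline",
    "percent_change",
    "classify",
    "build_response_table",
    "METHODS",
]

METHODS = ("1d", "2d", "3d", "mtd3d", "volume")


@dataclass(frozen=True)
class ThresholdConfig:
    """Progression thresholds (%) and measurability floors.

    ``prog_*`` are the RANO-derived thresholds (inclusive ≥); ``lgg_*``
    the LGG-optimized ROC cutoffs (strict >).  The volume ground truth
    uses ``prog_volume`` in both modes — a documented asymmetry, since
    the reference definition of progression itself stays RANO-based.
    """

    prog_1d: float = 20.0
    prog_2d: float = 25.0
    prog_3d: float = 40.0
    prog_volume: float = 40.0
    prog_mtd3d: float = 20.0  # rano mode: 1D rule applied to the MTD
    lgg_1d: float = 16.0
    lgg_2d: float = 33.0
    lgg_3d: float = 52.0
    lgg_mtd3d: float = 15.0
    min_1d_mm: float = 10.0
    min_2d_mm2: float = 100.0
    min_3d_ml: float = 0.5
    vde_alarm: float = 8.0
    mtd_subgroup_cut_mm: float = 35.0

    def __post_init__(self) -> None:
        for name in ("prog_1d", "prog_2d", "prog_3d", "prog_volume",
                     "lgg_1d", "lgg_2d", "lgg_3d", "lgg_mtd3d",
                     "min_1d_mm", "min_2d_mm2", "min_3d_ml",
                     "vde_alarm", "mtd_subgroup_cut_mm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    def threshold(self, method: str, mode: str) -> tuple[float, bool]:
        """(threshold %, inclusive?) for a method and mode."""
        if method not in METHODS:
            raise ValueError(f"unknown method {method!r}")
        if mode not in ("rano", "lgg"):
            raise ValueError(f"unknown mode {mode!r}")
        if method == "volume":
            return self.prog_volume, True  # ground truth rule, both modes
        if mode == "rano":
            return {"1d": self.prog_1d, "2d": self.prog_2d,
                    "3d": self.prog_3d, "mtd3d": self.prog_mtd3d}[method], True
        return {"1d": self.lgg_1d, "2d": self.lgg_2d,
                "3d": self.lgg_3d, "mtd3d": self.lgg_mtd3d}[method], False


@dataclass(frozen=True)
class ResponseLabel:
    method: str
    pct_change: float
    label: str  # "progression" | "non_progression"
    baseline_date: date
    followup_date: date


@dataclass
class BaselineResult:
    """Outcome of baseline selection: a scan index or an exclusion."""

    index: int | None
    scan_date: date | None = None
    excluded_reason: str | None = None
    dropped_early: list[int] = field(default_factory=list)


def select_baseline(
    scan_dates: list[date],
    surgery_date: date,
    chemo_start: date | None = None,
    mode: str = "progression",
) -> BaselineResult:
    """Choose the baseline scan of a follow-up series.

    ``mode="progression"``: first scan in [surgery + 72 h, surgery + 2
    years]; scans earlier than 72 h post-surgery are dropped (post-surgical
    enhancement/edema/ischemia), and if the first qualifying scan falls
    beyond 2 years the series is excluded.  ``mode="chemo"``: the latest
    scan strictly before chemotherapy onset.  Returns an exclusion record
    rather than raising when no scan qualifies.
    """
    if any(b < a for a, b in zip(scan_dates, scan_dates[1:])):
        raise ValueError("scan dates must be sorted ascending")
    if mode == "chemo":
        if chemo_start is None:
            raise ValueError("chemo mode requires chemo_start")
        prior = [i for i, d in enumerate(scan_dates) if d < chemo_start]
        if not prior:
            return BaselineResult(index=None,
                                  excluded_reason="no scan before "
                                                  "chemotherapy onset")
        i = prior[-1]
        return BaselineResult(index=i, scan_date=scan_dates[i])
    if mode != "progression":
        raise ValueError("mode must be 'progression' or 'chemo'")

    lo = surgery_date + timedelta(hours=72)
    hi = surgery_date + timedelta(days=int(2 * 365.25))
    dropped = [i for i, d in enumerate(scan_dates) if d < lo]
    for i, d in enumerate(scan_dates):
        if lo <= d <= hi:
            return BaselineResult(index=i, scan_date=d,
                                  dropped_early=dropped)
    if any(d > hi for d in scan_dates):
        return BaselineResult(
            index=None, dropped_early=dropped,
            excluded_reason="first postoperative baseline over 2 years "
                            "post-surgery")
    return BaselineResult(index=None, dropped_early=dropped,
                          excluded_reason="no scan 72 h to 2 years "
                                          "post-surgery")


def percent_change(baseline_size: float, followup_size: float) -> float:
    """100 × (follow − baseline) / baseline."""
    if baseline_size == 0:
        raise ValueError("zero baseline size")
    return 100.0 * (followup_size - baseline_size) / baseline_size


def classify(
    change_pct: float,
    method: str,
    thresholds: ThresholdConfig | None = None,
    mode: str = "rano",
) -> str:
    """"progression" or "non_progression" for one percent change.

    RANO-derived thresholds are inclusive (≥); the LGG-optimized ROC
    cutoffs are strict (>), matching how an ROC operating point
    "progression if change > t" reads.
    """
    thresholds = thresholds or ThresholdConfig()
    t, inclusive = thresholds.threshold(method, mode)
    hit = change_pct >= t if inclusive else change_pct > t
    return "progression" if hit else "non_progression"


def build_response_table(
    measurements: pd.DataFrame,
    thresholds: ThresholdConfig | None = None,
    mode: str = "rano",
) -> tuple[pd.DataFrame, dict]:
    """Classify every follow-up scan of a cohort against its baseline.

    ``measurements`` needs one row per scan with columns ``patient_id``,
    ``scan_date`` (datetime-like), ``surgery_date``, optional
    ``chemo_start``, and the per-scan sizes ``size_1d`` (mm), ``size_2d``
    (mm²), ``size_3d`` (mL), ``volume_seg`` (mL), ``mtd_3d`` (mm).

    Returns ``(table, ledger)``: one row per retained follow-up scan with
    the percent change and label per method plus the volume ground-truth
    label, and an exclusion ledger counting dropped scans per reason so
    that retained + excluded = total follow-ups for every method.
    """
    thresholds = thresholds or ThresholdConfig()
    size_cols = {"1d": "size_1d", "2d": "size_2d", "3d": "size_3d",
                 "mtd3d": "mtd_3d", "volume": "volume_seg"}
    ledger: dict[str, dict[str, int]] = {
        m: {"retained": 0, "non_measurable_baseline": 0,
            "no_baseline": 0, "before_baseline": 0}
        for m in METHODS}
    rows = []

    for pid, grp in measurements.groupby("patient_id", sort=True):
        grp = grp.sort_values("scan_date")
        dates = [pd.Timestamp(d).date() for d in grp["scan_date"]]
        surgery = pd.Timestamp(grp["surgery_date"].iloc[0]).date()
        base = select_baseline(dates, surgery)
        n_follow = (len(dates) - base.index - 1
                    if base.index is not None else len(dates))
        if base.index is None:
            for m in METHODS:
                ledger[m]["no_baseline"] += n_follow
            continue
        brow = grp.iloc[base.index]

        measurable = {
            "1d": brow["size_1d"] >= thresholds.min_1d_mm,
            "2d": brow["size_2d"] >= thresholds.min_2d_mm2,
            "3d": brow["size_3d"] >= thresholds.min_3d_ml,
            "mtd3d": brow["size_3d"] >= thresholds.min_3d_ml,
            "volume": True,
        }
        for m in METHODS:
            ledger[m]["before_baseline"] += base.index

        for k in range(base.index + 1, len(grp)):
            frow = grp.iloc[k]
            row: dict = {"patient_id": pid,
                         "baseline_date": dates[base.index],
                         "followup_date": dates[k]}
            for m in METHODS:
                col = size_cols[m]
                if not measurable[m]:
                    ledger[m]["non_measurable_baseline"] += 1
                    row[f"change_{m}"] = float("nan")
                    row[f"label_{m}"] = "excluded_non_measurable"
                    continue
                change = percent_change(float(brow[col]), float(frow[col]))
                row[f"change_{m}"] = change
                row[f"label_{m}"] = classify(change, m, thresholds, mode)
                ledger[m]["retained"] += 1
            row["truth"] = row["label_volume"]
            rows.append(row)

    table = pd.DataFrame(rows)
    ledger["mode"] = mode  # type: ignore[assignment]
    return table, ledger
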