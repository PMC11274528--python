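"""Self-contained validation studies: parameter recovery on synthetic data.

These drive the whole chain — cohort generation, voxel measurement, MTD /
VDE computation, progression classification, ROC analysis — on synthetic
cohorts with known ground truth, and report how well the planted
quantities are recovered.  They are what the acceptance checks and the
reproduction script run.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .agreement_stats import roc_optimal_threshold
from .cli import compute_vde_table
from .growth_metrics import mtd_from_diameters, mtd_from_volume
from .mask_measures import load_mask, measure_mask
from .response_assessment import build_response_table
from .synthetic_cohort import CohortConfig, generate_cohort


def measure_cohort(manifest_path: str | Path,
                   exact: bool = False) -> pd.DataFrame:
    """Run the full measurement protocol over a cohort manifest."""
    mdf = pd.read_csv(manifest_path, dtype=str, keep_default_na=False)
    root = Path(manifest_path).parent
    rows = []
    for _, r in mdf.iterrows():
        mask = load_mask(root / r["mask_path"])
        diam, size = measure_mask(mask, exact=exact)
        rows.append({
            "patient_id": r["patient_id"], "scan_date": r["scan_date"],
            "surgery_date": r["surgery_date"],
            "chemo_start": r["chemo_start"],
            "radio_start": r["radio_start"],
            "W": diam.W, "PW": diam.PW, "D1": diam.D1, "D2": diam.D2,
            "D3": diam.D3,
            "size_1d": size.size_1d, "size_2d": size.size_2d,
            "size_3d": size.size_3d, "volume_seg": size.volume_seg,
            "mtd_3d": mtd_from_diameters(diam.D1, diam.D2, diam.D3),
            "mtd_v": mtd_from_volume(size.volume_seg),
        })
    return pd.DataFrame(rows)


def vde_recovery_study(work_dir: str | Path, seed: int = 1,
                       n_patients: int = 30) -> dict:
    """Plant VDEs in a voxelized cohort and recover them from masks.

    The cohort uses bare ellipsoidal residues (no cavity, no satellites,
    no irregularity) so that voxelization is the only measurement noise,
    and plants growth rates uniform over 0–8 mm/year — indolent disease up
    to the anaplastic alarm level.  Returns the per-window VDE errors of
    the volume-based estimate and summary statistics.
    """
    config = CohortConfig(
        n_patients=n_patients, scans_per_patient=(4, 6),
        image_shape=(96, 96, 96), mtd_range=(22.0, 34.0),
        irregularity_range=(0.0, 0.0), cavity_probability=0.0,
        max_satellites=0, treatment_fraction=0.0,
        vde_range=(0.0, 8.0), seed=seed)
    _, manifest, truth = generate_cohort(config, work_dir)
    measurements = measure_cohort(manifest)
    vde_table = compute_vde_table(measurements)

    errors_v, errors_3d, planted = [], [], []
    for _, row in vde_table.iterrows():
        true_vde = truth.windows[row["patient_id"]]
        planted.append(true_vde)
        errors_v.append(row["vde_v"] - true_vde)
        errors_3d.append(row["vde_3d"] - true_vde)
    return {
        "measurements": measurements,
        "truth": truth,
        "n_windows": len(errors_v),
        "mean_planted_vde": float(np.mean(planted)),
        "mean_vde_v_error": float(np.mean(errors_v)),
        "mean_vde_3d_error": float(np.mean(errors_3d)),
        "mean_abs_vde_v_error": float(np.mean(np.abs(errors_v))),
    }


def threshold_recovery_study(measurements: pd.DataFrame) -> dict:
    """Recover the 3D progression threshold against the volume truth.

    Builds the response table, takes every follow-up with a measurable 3D
    baseline, and finds the Youden-optimal 3D-change cutoff with the
    segmented-volume classification (>= 40% increase) as truth.
    """
    table, _ = build_response_table(measurements)
    keep = table["label_3d"].isin(
        ["progression", "non_progression"]).to_numpy()
    changes = table.loc[keep, "change_3d"].to_numpy()
    truth = (table.loc[keep, "truth"] == "progression").to_numpy()
    auc, thr, sens, spec = roc_optimal_threshold(changes, truth)
    return {"auc": auc, "threshold_pct": thr, "sensitivity_pct": sens,
            "specificity_pct": spec, "changes": changes, "truth": truth,
            "n": int(keep.sum())}


def planted_threshold_study(seed: int = 1, n_patients: int = 60) -> dict:
    """Threshold recovery with a planted Youden optimum.

    Builds a measurement table (one baseline + one follow-up per patient)
    whose 3D-change distributions for progressors and non-progressors are
    separated: non-progressor changes fill up to exactly the planted
    cutoff, progressor changes start above it.  The Youden-optimal
    "change > t" cutoff over observed values is then the planted value,
    and the pipeline must recover it within one grid step.
    """
    rng = np.random.default_rng(np.uint32(seed))
    planted = 35.0
    rows = []
    half = n_patients // 2
    for p in range(n_patients):
        pid = f"S{p:03d}"
        d0 = 25.0 + 10.0 * rng.uniform()
        if p < half:  # non-progressors: 3D change in (0, planted]
            change_3d = planted if p == 0 else rng.uniform(0.0, planted)
            change_vol = min(change_3d + rng.uniform(-5.0, 5.0), 38.0)
        else:  # progressors: clearly separated above the planted cutoff
            change_3d = rng.uniform(planted + 10.0, 90.0)
            change_vol = max(change_3d + rng.uniform(-5.0, 5.0), 42.0)
        v0 = 8.0
        for scan_date, f3, fv in (("2015-02-01", 1.0, 1.0),
                                  ("2016-02-01", (1 + change_3d / 100.0),
                                   (1 + change_vol / 100.0))):
            s = f3 ** (1.0 / 3.0)
            rows.append({
                "patient_id": pid,
                "scan_date": scan_date,
                "surgery_date": "2015-01-01",
                "size_1d": d0 * s, "size_2d": (d0 * s) ** 2,
                "size_3d": d0 ** 3 / 2000.0 * f3,
                "volume_seg": v0 * fv,
                "mtd_3d": d0 * s,
            })
    measurements = pd.DataFrame(rows)
    out = threshold_recovery_study(measurements)
    out["planted_threshold_pct"] = planted
    changes = np.sort(np.unique(out.pop("changes")))
    out.pop("truth")
    # grid distance between the recovered and planted cutoffs
    i = int(np.searchsorted(changes, out["threshold_pct"]))
    j = int(np.searchsorted(changes, planted))
    out["grid_steps_from_planted"] = abs(i - j)
    return out
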