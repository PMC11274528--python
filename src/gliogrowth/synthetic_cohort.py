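"""Synthetic longitudinal cohorts of post-surgical low-grade glioma lesions.

Real LGG follow-up data are delineations of an irregular, infiltrative
residue left after resection, frequently accompanied by a fluid-filled
cavity and a handful of satellite residues, re-imaged every 3–6 months.
This module builds voxelized scenes with exactly that structure, together
with a manifest (patient id, scan dates, treatment dates, mask paths) and
an analytic ground truth (volume, diameters, MTD, VDE) so every downstream
measurement stage can be validated against known geometry.

Geometry model
--------------
The main residue is an ellipsoid with semi-axes (a, b, c), an arbitrary
orientation, and a smooth angular irregularity: a point x belongs to the
lesion iff, in normalized ellipsoid coordinates ``xi = S^-1 R^T (x - c)``,

    ||xi|| <= 1 + amp * f(xi / ||xi||)

where f is a band-limited random field on the sphere (real spherical
harmonics of degree 2–4, normalized to max |f| = 1) and ``amp`` is the
irregularity amplitude as a fraction of the local radius.  Because the
perturbation lives in normalized coordinates, the lesion volume factors as

    V = (4/3) * pi * a * b * c * kappa(field)

with kappa independent of the semi-axes — growth that rescales semi-axes
rescales the volume exactly, which keeps the ground truth closed-form.
Satellites are small unperturbed ellipsoids placed disjoint from the main
residue; the resection cavity is a sphere carved out of the union (label 2)
and is kept analytically enclosed in the main residue at cohort-generation
time so the scene volume stays V_main + sum(V_sat) - V_cavity.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field, replace
from datetime import date, timedelta
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy.special import sph_harm_y

__all__ = [
    "Cavity",
    "Satellite",
    "LesionSpec",
    "CohortConfig",
    "GroundTruth",
    "generate_lesion_mask",
    "grow_spec",
    "generate_cohort",
    "analytic_scene_volume_mm3",
    "analytic_mtd_mm",
    "analytic_extents_mm",
    "perturbation_kappa",
]

LABEL_BACKGROUND = 0
LABEL_TUMOR = 1
LABEL_CAVITY = 2

_HARMONIC_DEGREES = (2, 3, 4)


# ---------------------------------------------------------------------------
# specs


@dataclass(frozen=True)
class Cavity:
    """Spherical resection cavity, mm."""

    center: tuple[float, float, float]
    radius: float

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("cavity radius must be > 0")


@dataclass(frozen=True)
class Satellite:
    """Small unperturbed ellipsoidal residue, mm."""

    center: tuple[float, float, float]
    semi_axes: tuple[float, float, float]

    def __post_init__(self) -> None:
        if min(self.semi_axes) <= 0:
            raise ValueError("satellite semi-axes must be > 0")


@dataclass(frozen=True)
class LesionSpec:
    """Analytic description of one post-surgical lesion scene.

    ``center`` and ``semi_axes`` are in mm in world coordinates (x
    transversal, y antero–posterior, z inferior–superior); ``orientation``
    are intrinsic z-y-x Euler angles in radians.  ``irregularity_amplitude``
    modulates the main residue's radius by up to that fraction;
    ``perturbation_seed`` fixes the random angular field so that a spec is a
    complete, deterministic description of the scene.  ``true_vde`` is the
    planted velocity of diameter expansion of the scene MTD in mm/year.
    """

    center: tuple[float, float, float]
    semi_axes: tuple[float, float, float]
    orientation: tuple[float, float, float] = (0.0, 0.0, 0.0)
    irregularity_amplitude: float = 0.0
    cavity: Cavity | None = None
    satellites: tuple[Satellite, ...] = ()
    true_vde: float = 0.0
    perturbation_seed: int = 0

    def __post_init__(self) -> None:
        if min(self.semi_axes) <= 0:
            raise ValueError("semi-axes must all be > 0")
        if not 0.0 <= self.irregularity_amplitude <= 0.5:
            raise ValueError("irregularity_amplitude must lie in [0, 0.5]")
        if self.true_vde < 0:
            raise ValueError("true_vde must be >= 0")


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of a synthetic longitudinal cohort.

    Defaults mirror a surgically treated LGG follow-up population: imaging
    every 3–6 months, residual tumors of 20–45 mm MTD with a resection
    cavity, 0–3 satellite residues, growth rates spanning indolent disease
    up to the 8 mm/year anaplastic-transformation alarm level.
    """

    n_patients: int = 10
    scans_per_patient: tuple[int, int] = (4, 7)
    scan_interval_days: tuple[int, int] = (90, 180)
    voxel_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    image_shape: tuple[int, int, int] = (128, 128, 128)
    growth_model: str = "isotropic"
    vde_range: tuple[float, float] = (0.0, 8.0)
    seed: int = 0
    mtd_range: tuple[float, float] = (20.0, 45.0)
    irregularity_range: tuple[float, float] = (0.05, 0.15)
    cavity_probability: float = 1.0
    max_satellites: int = 3
    treatment_fraction: float = 0.25

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if self.scans_per_patient[0] < 2:
            raise ValueError("need at least 2 scans per patient")
        lo, hi = self.scan_interval_days
        if not (1 <= lo <= hi):
            raise ValueError("invalid scan interval range")
        if self.growth_model not in ("isotropic", "anisotropic"):
            raise ValueError("growth_model must be 'isotropic' or 'anisotropic'")
        if self.vde_range[0] < 0 or self.vde_range[0] > self.vde_range[1]:
            raise ValueError("invalid vde_range")


@dataclass
class GroundTruth:
    """Analytic truth for every generated scan and follow-up window.

    ``scans`` maps patient id -> list of per-scan records with
    ``true_volume_ml``, ``true_diameters_mm`` (D1, D2, D3 axis-aligned
    extents of the main residue), ``true_mtd_mm`` = (2 V_mm3)^(1/3);
    ``windows`` maps patient id -> planted VDE in mm/year;
    ``progression`` maps patient id -> list of per-follow-up flags (volume
    change from first scan >= 40%).
    """

    scans: dict[str, list[dict]] = field(default_factory=dict)
    windows: dict[str, float] = field(default_factory=dict)
    progression: dict[str, list[bool]] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {"scans": self.scans, "windows": self.windows,
             "progression": self.progression},
            indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# angular perturbation field


def _harmonic_coefficients(seed: int) -> np.ndarray:
    rng = np.random.default_rng(np.uint32(seed))
    n = sum(2 * (ell + 1) for ell in _HARMONIC_DEGREES)
    return rng.standard_normal(n)


def _evaluate_field(coeffs: np.ndarray, theta: np.ndarray,
                    phi: np.ndarray) -> np.ndarray:
    """Real band-limited spherical field at polar angle theta, azimuth phi."""
    out = np.zeros(np.broadcast(theta, phi).shape)
    i = 0
    for ell in _HARMONIC_DEGREES:
        for m in range(ell + 1):
            y = sph_harm_y(ell, m, theta, phi)
            out += coeffs[i] * y.real + coeffs[i + 1] * y.imag
            i += 2
    return out


def _field_normalization(coeffs: np.ndarray) -> float:
    """max |f| over a fine sphere grid, so amp*f/norm stays within +-amp."""
    th = np.linspace(0.0, np.pi, 181)
    ph = np.linspace(0.0, 2 * np.pi, 361, endpoint=False)
    vals = _evaluate_field(coeffs, th[:, None], ph[None, :])
    m = float(np.abs(vals).max())
    return m if m > 0 else 1.0


def perturbation_kappa(amplitude: float, seed: int) -> float:
    """Volume factor of the perturbed unit ball, (3/4pi) * (1/3)∮(1+amp f)^3 dΩ.

    Gauss–Legendre in cos(theta) x trapezoid in phi; exact to machine
    precision for the degree <= 12 integrand (cube of a degree-4 field).
    """
    if amplitude == 0.0:
        return 1.0
    coeffs = _harmonic_coefficients(seed)
    norm = _field_normalization(coeffs)
    nodes, weights = leggauss(16)
    theta = np.arccos(nodes)
    nphi = 64
    phi = 2 * np.pi * np.arange(nphi) / nphi
    f = _evaluate_field(coeffs, theta[:, None], phi[None, :]) / norm
    integrand = (1.0 + amplitude * f) ** 3
    integral = (weights[:, None] * integrand).sum() * (2 * np.pi / nphi)
    return float(integral / (4 * np.pi))


# ---------------------------------------------------------------------------
# analytic ground truth helpers


def _rotation_matrix(angles: Sequence[float]) -> np.ndarray:
    az, ay, ax = angles
    cz, sz = np.cos(az), np.sin(az)
    cy, sy = np.cos(ay), np.sin(ay)
    cx, sx = np.cos(ax), np.sin(ax)
    rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    return rz @ ry @ rx


def _cavity_is_enclosed(spec: LesionSpec) -> bool:
    """Sufficient condition: the cavity sphere fits inside the most eroded
    perturbed surface of the main residue."""
    if spec.cavity is None:
        return True
    rot = _rotation_matrix(spec.orientation)
    offset = np.asarray(spec.cavity.center) - np.asarray(spec.center)
    xi = np.linalg.solve(np.diag(spec.semi_axes), rot.T @ offset)
    reach = np.linalg.norm(xi) + spec.cavity.radius / min(spec.semi_axes)
    return bool(reach <= 1.0 - spec.irregularity_amplitude)


def _tumor_parts_volume_mm3(spec: LesionSpec) -> float:
    a, b, c = spec.semi_axes
    kappa = perturbation_kappa(spec.irregularity_amplitude,
                               spec.perturbation_seed)
    v = 4.0 / 3.0 * np.pi * a * b * c * kappa
    for sat in spec.satellites:
        sa, sb, sc = sat.semi_axes
        v += 4.0 / 3.0 * np.pi * sa * sb * sc
    return v


def analytic_scene_volume_mm3(spec: LesionSpec) -> float:
    """Closed-form tumor volume of the scene in mm^3.

    Requires the cavity (when present) to be enclosed in the main residue
    and satellites to be disjoint from it, which `generate_cohort`
    guarantees by construction.
    """
    if spec.cavity is not None and not _cavity_is_enclosed(spec):
        raise ValueError(
            "analytic volume requires the cavity to be enclosed in the main "
            "residue; use voxel counting for general cavity placements")
    v = _tumor_parts_volume_mm3(spec)
    if spec.cavity is not None:
        v -= 4.0 / 3.0 * np.pi * spec.cavity.radius ** 3
    return float(v)


def analytic_mtd_mm(spec: LesionSpec) -> float:
    """Scene MTD, the equivalent diameter (2 V)^(1/3) with V in mm^3."""
    return float((2.0 * analytic_scene_volume_mm3(spec)) ** (1.0 / 3.0))


def analytic_extents_mm(spec: LesionSpec) -> tuple[float, float, float]:
    """Axis-aligned support widths of the main (unperturbed) ellipsoid.

    For an ellipsoid with shape matrix M = R diag(a²,b²,c²) Rᵀ the width
    along coordinate axis i is 2·sqrt(M_ii); irregularity perturbs the
    measured extents by up to the amplitude fraction.
    """
    rot = _rotation_matrix(spec.orientation)
    m = rot @ np.diag(np.square(spec.semi_axes)) @ rot.T
    return tuple(float(2.0 * np.sqrt(m[i, i])) for i in range(3))


# ---------------------------------------------------------------------------
# voxelization


def generate_lesion_mask(
    spec: LesionSpec,
    spacing: Sequence[float],
    shape: Sequence[int],
) -> np.ndarray:
    """Voxelize a lesion scene into a labeled volume.

    A voxel (center-in convention) gets label 1 when inside the main
    perturbed ellipsoid or a satellite, label 2 when inside the cavity
    sphere (the cavity overrides tumor: carving happens after the union),
    else 0.  Deterministic given the spec — the irregularity field is fixed
    by ``spec.perturbation_seed``.

    Raises ValueError naming the first axis on which the scene (main
    residue bounding sphere, satellites or cavity) exceeds image bounds.
    """
    spacing = np.asarray(spacing, dtype=float)
    shape = tuple(int(s) for s in shape)
    if np.any(spacing <= 0):
        raise ValueError("voxel spacing must be positive")

    _check_bounds(spec, spacing, shape)

    labels = np.zeros(shape, dtype=np.uint8)
    _fill_main(labels, spec, spacing)
    for sat in spec.satellites:
        _fill_ellipsoid(labels, sat.center, sat.semi_axes, spacing)
    if spec.cavity is not None:
        _carve_cavity(labels, spec.cavity, spacing)
    return labels


def _check_bounds(spec: LesionSpec, spacing: np.ndarray,
                  shape: tuple[int, ...]) -> None:
    extent_mm = (np.asarray(shape) - 1) * spacing
    amp = spec.irregularity_amplitude
    reach = max(spec.semi_axes) * (1.0 + amp)
    bodies = [("main residue", np.asarray(spec.center), reach)]
    for k, sat in enumerate(spec.satellites):
        bodies.append((f"satellite {k}", np.asarray(sat.center),
                       max(sat.semi_axes)))
    if spec.cavity is not None:
        bodies.append(("cavity", np.asarray(spec.cavity.center),
                       spec.cavity.radius))
    axes = "xyz"
    for name, center, r in bodies:
        for i in range(3):
            if center[i] - r < 0 or center[i] + r > extent_mm[i]:
                raise ValueError(
                    f"{name} exceeds image bounds along axis "
                    f"{axes[i]}: center {center[i]:.1f} mm, reach "
                    f"{r:.1f} mm, image extent {extent_mm[i]:.1f} mm")


def _voxel_window(center: Sequence[float], reach: float, spacing: np.ndarray,
                  shape: tuple[int, ...]):
    lo = np.maximum(0, np.floor((np.asarray(center) - reach) / spacing)
                    ).astype(int)
    hi = np.minimum(np.asarray(shape) - 1,
                    np.ceil((np.asarray(center) + reach) / spacing)
                    ).astype(int)
    grids = np.meshgrid(*[np.arange(a, b + 1) for a, b in zip(lo, hi)],
                        indexing="ij")
    idx = tuple(grids)
    coords = [g * s for g, s in zip(grids, spacing)]
    return idx, coords


def _fill_main(labels: np.ndarray, spec: LesionSpec,
               spacing: np.ndarray) -> None:
    amp = spec.irregularity_amplitude
    reach = max(spec.semi_axes) * (1.0 + amp) + float(spacing.max())
    idx, coords = _voxel_window(spec.center, reach, spacing, labels.shape)
    rot = _rotation_matrix(spec.orientation)
    rel = np.stack([c - mu for c, mu in zip(coords, spec.center)], axis=-1)
    xi = rel @ rot / np.asarray(spec.semi_axes)  # = S^-1 R^T (x-c), rowwise
    r = np.linalg.norm(xi, axis=-1)
    if amp == 0.0:
        inside = r <= 1.0
    else:
        coeffs = _harmonic_coefficients(spec.perturbation_seed)
        norm = _field_normalization(coeffs)
        with np.errstate(invalid="ignore", divide="ignore"):
            theta = np.arccos(np.clip(np.divide(xi[..., 2], r,
                                                out=np.zeros_like(r),
                                                where=r > 0), -1, 1))
            phi = np.arctan2(xi[..., 1], xi[..., 0])
        f = _evaluate_field(coeffs, theta, phi) / norm
        inside = r <= 1.0 + amp * f
    labels[idx] = np.where(inside, LABEL_TUMOR, labels[idx])


def _fill_ellipsoid(labels: np.ndarray, center: Sequence[float],
                    semi_axes: Sequence[float], spacing: np.ndarray) -> None:
    reach = max(semi_axes) + float(spacing.max())
    idx, coords = _voxel_window(center, reach, spacing, labels.shape)
    q = sum(((c - mu) / ax) ** 2
            for c, mu, ax in zip(coords, center, semi_axes))
    labels[idx] = np.where(q <= 1.0, LABEL_TUMOR, labels[idx])


def _carve_cavity(labels: np.ndarray, cavity: Cavity,
                  spacing: np.ndarray) -> None:
    reach = cavity.radius + float(spacing.max())
    idx, coords = _voxel_window(cavity.center, reach, spacing, labels.shape)
    d2 = sum((c - mu) ** 2 for c, mu in zip(coords, cavity.center))
    labels[idx] = np.where(d2 <= cavity.radius ** 2, LABEL_CAVITY,
                           labels[idx])


# ---------------------------------------------------------------------------
# growth


def grow_spec(spec: LesionSpec, dt_years: float,
              mode: str = "isotropic") -> LesionSpec:
    """Advance a lesion scene by ``dt_years`` at its planted VDE.

    The scene MTD (2·V)^(1/3) increases by exactly ``true_vde * dt``.  The
    cavity does not grow; the required tumor-part volume factor s solves

        (MTD0 + vde·dt)^3 / 2 = s · V_parts − V_cavity

    in closed form.  Isotropic mode scales all semi-axes (main and
    satellites) and satellite offsets by s^(1/3); anisotropic mode — the
    white-matter-tract growth pattern of LGGs — puts the whole factor s on
    the main residue's longest semi-axis (and each satellite's matching
    axis), leaving the others untouched.
    """
    if dt_years < 0:
        raise ValueError("dt must be >= 0")
    if dt_years == 0 or spec.true_vde == 0:
        return spec

    mtd0 = analytic_mtd_mm(spec)
    target = mtd0 + spec.true_vde * dt_years
    v_parts = _tumor_parts_volume_mm3(spec)
    v_cav = (4.0 / 3.0 * np.pi * spec.cavity.radius ** 3
             if spec.cavity is not None else 0.0)
    s = (target ** 3 / 2.0 + v_cav) / v_parts

    center = np.asarray(spec.center)
    if mode == "isotropic":
        lin = s ** (1.0 / 3.0)
        new_axes = tuple(ax * lin for ax in spec.semi_axes)
        sats = tuple(
            Satellite(
                center=tuple(center + lin * (np.asarray(t.center) - center)),
                semi_axes=tuple(ax * lin for ax in t.semi_axes))
            for t in spec.satellites)
    elif mode == "anisotropic":
        j = int(np.argmax(spec.semi_axes))
        new_axes = tuple(ax * s if i == j else ax
                         for i, ax in enumerate(spec.semi_axes))
        sats = tuple(
            Satellite(center=t.center,
                      semi_axes=tuple(ax * s if i == j else ax
                                      for i, ax in enumerate(t.semi_axes)))
            for t in spec.satellites)
    else:
        raise ValueError("mode must be 'isotropic' or 'anisotropic'")
    return replace(spec, semi_axes=new_axes, satellites=sats)


# ---------------------------------------------------------------------------
# cohort generation


def _random_spec(rng: np.random.Generator, config: CohortConfig,
                 follow_up_years: float) -> LesionSpec:
    spacing = np.asarray(config.voxel_spacing)
    extent = (np.asarray(config.image_shape) - 1) * spacing
    center = tuple(extent / 2.0)

    # draw target MTD, translate to semi-axes with mild anisotropy:
    # (2V)^(1/3) = mtd  ->  abc = 3 mtd^3 / (8 pi)
    mtd = rng.uniform(*config.mtd_range)
    ratios = rng.uniform(0.7, 1.4, size=3)
    ratios /= ratios.prod() ** (1.0 / 3.0)
    amp = rng.uniform(*config.irregularity_range)
    orientation = tuple(rng.uniform(0, np.pi, size=3))
    vde = rng.uniform(*config.vde_range)
    pert_seed = int(rng.integers(0, 2 ** 31 - 1))

    # the lesion must still fit at the end of follow-up; semi-axes scale
    # linearly with MTD in isotropic mode, cubically on one axis in
    # anisotropic mode, so cap the drawn MTD accordingly
    semi_unit = max(ratios) * (3.0 / (8.0 * np.pi)) ** (1.0 / 3.0)
    room = float(extent.min()) / 2.0 - 2.0 * float(spacing.max())
    mtd_end = mtd + vde * follow_up_years
    if config.growth_model == "anisotropic":
        mtd_end = mtd * (mtd_end / mtd) ** 3
    allowed_end = room / (semi_unit * (1.0 + amp) * 1.05)
    if mtd_end > allowed_end:
        mtd = max(10.0, mtd - (mtd_end - allowed_end))
        mtd_end = allowed_end
    if mtd * semi_unit * (1.0 + amp) > room:
        raise ValueError(
            "image_shape too small for the requested mtd_range / vde_range "
            "over this follow-up duration")
    growth_headroom = mtd_end / mtd

    abc = 3.0 * mtd ** 3 / (8.0 * np.pi)
    base = abc ** (1.0 / 3.0)
    semi_axes = tuple(base * r for r in ratios)

    spec = LesionSpec(center=center, semi_axes=semi_axes,
                      orientation=orientation, irregularity_amplitude=amp,
                      true_vde=vde, perturbation_seed=pert_seed)

    # enclosed cavity: offset + radius must stay within (1-amp) of the
    # normalized unit ball (sufficient enclosure condition)
    if rng.uniform() < config.cavity_probability:
        amin = min(semi_axes)
        r_cav = rng.uniform(0.15, 0.3) * amin
        max_off = max(0.0, ((1.0 - amp) - r_cav / amin) * amin * 0.8)
        direction = rng.standard_normal(3)
        direction /= np.linalg.norm(direction)
        off = direction * rng.uniform(0, max_off)
        spec = replace(spec, cavity=Cavity(center=tuple(np.asarray(center)
                                                        + off),
                                           radius=r_cav))

    n_sat = int(rng.integers(0, config.max_satellites + 1))
    sats = []
    reach_main = max(semi_axes) * (1.0 + amp)
    g = growth_headroom * 1.02  # offsets and sizes scale with growth
    for _ in range(n_sat):
        r_sat = rng.uniform(3.0, 6.0)
        direction = rng.standard_normal(3)
        direction /= np.linalg.norm(direction)
        dist = reach_main + r_sat + rng.uniform(2.0, 8.0)
        c_end = np.asarray(center) + direction * dist * g
        if np.any(c_end - r_sat * g < 0) or np.any(c_end + r_sat * g
                                                   > extent):
            continue  # skip satellites that would leave the image
        sats.append(Satellite(
            center=tuple(np.asarray(center) + direction * dist),
            semi_axes=(r_sat, r_sat * 0.9, r_sat * 0.8)))
    return replace(spec, satellites=tuple(sats))


def generate_cohort(config: CohortConfig, out_dir: str | Path):
    """Write a full synthetic cohort to ``out_dir``.

    Returns ``(mask_paths, manifest_path, ground_truth)``.  Output layout:
    one NIfTI label mask per scan (``<pid>_<date>.nii.gz``), a
    ``manifest.csv`` with columns patient_id, scan_date, mask_path,
    surgery_date, chemo_start, radio_start, and ``ground_truth.json``.
    Pure function of (config, seed): regeneration is byte-identical for the
    manifest and array-identical for the masks.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {out_dir}: {exc}")

    rng = np.random.default_rng(np.uint32(config.seed))
    truth = GroundTruth()
    manifest_rows = []
    mask_paths: list[Path] = []
    affine = np.diag(list(config.voxel_spacing) + [1.0])

    for p in range(config.n_patients):
        pid = f"P{p + 1:03d}"
        surgery = date(2012, 1, 1) + timedelta(
            days=int(rng.integers(0, 2000)))
        first_scan = surgery + timedelta(days=int(rng.integers(10, 90)))
        n_scans = int(rng.integers(config.scans_per_patient[0],
                                   config.scans_per_patient[1] + 1))
        dates = [first_scan]
        for _ in range(n_scans - 1):
            dates.append(dates[-1] + timedelta(
                days=int(rng.integers(config.scan_interval_days[0],
                                      config.scan_interval_days[1] + 1))))

        chemo: date | None = None
        if rng.uniform() < config.treatment_fraction and n_scans >= 3:
            mid = dates[n_scans // 2]
            chemo = mid + timedelta(days=int(rng.integers(5, 40)))

        follow_up_years = (dates[-1] - dates[0]).days / 365.25
        spec0 = _random_spec(rng, config, follow_up_years)
        truth.scans[pid] = []
        truth.windows[pid] = spec0.true_vde
        vols = []
        for d in dates:
            dt_years = (d - dates[0]).days / 365.25
            spec_t = grow_spec(spec0, dt_years, mode=config.growth_model)
            labels = generate_lesion_mask(spec_t, config.voxel_spacing,
                                          config.image_shape)
            fname = f"{pid}_{d.isoformat()}.nii.gz"
            img = nib.Nifti1Image(labels, affine)
            img.header.set_zooms(config.voxel_spacing)
            nib.save(img, out_dir / fname)
            mask_paths.append(out_dir / fname)

            v_mm3 = analytic_scene_volume_mm3(spec_t)
            vols.append(v_mm3)
            truth.scans[pid].append({
                "scan_date": d.isoformat(),
                "true_volume_ml": v_mm3 / 1000.0,
                "true_diameters_mm": list(analytic_extents_mm(spec_t)),
                "true_mtd_mm": (2.0 * v_mm3) ** (1.0 / 3.0),
            })
            manifest_rows.append({
                "patient_id": pid,
                "scan_date": d.isoformat(),
                "mask_path": fname,
                "surgery_date": surgery.isoformat(),
                "chemo_start": chemo.isoformat() if chemo else "",
                "radio_start": "",
            })
        truth.progression[pid] = [
            (v - vols[0]) / vols[0] * 100.0 >= 40.0 for v in vols[1:]]

    manifest_path = out_dir / "manifest.csv"
    with open(manifest_path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=[
            "patient_id", "scan_date", "mask_path", "surgery_date",
            "chemo_start", "radio_start"])
        writer.writeheader()
        writer.writerows(manifest_rows)

    (out_dir / "ground_truth.json").write_text(truth.to_json())
    return mask_paths, manifest_path, truth
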