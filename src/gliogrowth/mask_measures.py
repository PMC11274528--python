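"""Optimized linear measurements and segmented volume from LGG label masks.

Implements the five-diameter protocol used for post-surgical low-grade
glioma follow-up on FLAIR delineations:

* ``W``  — tumor width, the longest in-plane (axial) diameter in any
  direction;
* ``PW`` — perpendicular width, the largest diameter perpendicular
  (within a small angular tolerance) to W in the same axial slice;
* ``D1`` / ``D2`` / ``D3`` — maximal transversal, antero–posterior and
  inferior–superior extents of the residue along the anatomical axes;

under the two LGG-specific rules: (1) W and PW must avoid crossing the
resection cavity as much as possible, and (2) with multiple residues, the
linear measurements are taken on the largest connected component only.
The segmented volume, by contrast, counts every residue.

Axis convention: after reorientation to canonical (RAS) axes, x is
transversal, y antero–posterior, z inferior–superior; axial slices are
constant-z planes.  Chord lengths and extents use a caliper convention of
voxel-center distance plus one voxel step, so that identities such as
W = D1 = D2 = D3 on a voxelized sphere hold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "LesionMask",
    "DiameterSet",
    "SizeRecord",
    "load_mask",
    "largest_residue",
    "extract_w_pw",
    "extract_d123",
    "segmented_volume",
    "size_estimates",
    "measure_mask",
    "EmptyLesionError",
]

LABEL_TUMOR = 1
LABEL_CAVITY = 2

#: measurability floors: 10 mm (1D), 100 mm² (2D), 0.5 mL (3D)
MIN_1D_MM = 10.0
MIN_2D_MM2 = 100.0
MIN_3D_ML = 0.5


class EmptyLesionError(ValueError):
    """Raised when a measurement is requested on a mask without tumor."""


@dataclass
class LesionMask:
    """A labeled lesion volume: 0 background, 1 tumor, 2 cavity.

    ``spacing`` is the voxel size in mm along (x, y, z) in the canonical
    orientation (x transversal, y antero–posterior, z inferior–superior).
    """

    labels: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3D array")
        if min(self.spacing) <= 0:
            raise ValueError("spacing must be positive")
        bad = set(np.unique(self.labels)) - {0, 1, 2}
        if bad:
            raise ValueError(f"labels must be in {{0,1,2}}, found {bad}")

    @property
    def tumor(self) -> np.ndarray:
        return self.labels == LABEL_TUMOR

    @property
    def n_tumor_voxels(self) -> int:
        return int(self.tumor.sum())


@dataclass
class DiameterSet:
    """The five linear measures of one scan, in mm."""

    W: float
    PW: float
    D1: float
    D2: float
    D3: float
    w_slice_index: int
    w_endpoints: tuple
    pw_endpoints: tuple
    cavity_crossing_fraction: float
    flags: tuple[str, ...] = ()


@dataclass
class SizeRecord:
    """Per-scan 1D/2D/3D size estimates and the segmented volume."""

    size_1d: float  # mm (W)
    size_2d: float  # mm² (W × PW)
    size_3d: float  # mL ((D1·D2·D3)/2, converted)
    volume_seg: float  # mL
    measurable_1d: bool
    measurable_2d: bool
    measurable_3d: bool


def load_mask(path: str | Path) -> LesionMask:
    """Read a NIfTI label volume, reorienting to the canonical axes.

    Any input orientation is accepted; the array is brought to RAS-closest
    orientation from the affine so that axis 0 is transversal, axis 1
    antero–posterior and axis 2 inferior–superior.
    """
    img = nib.as_closest_canonical(nib.load(str(path)))
    labels = np.asarray(img.dataobj).astype(np.uint8)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return LesionMask(labels=labels, spacing=spacing)


# ---------------------------------------------------------------------------
# largest residue


def largest_residue(mask: LesionMask) -> tuple[LesionMask, int]:
    """Restrict the tumor label to its largest connected component.

    Components use 26-connectivity (diffuse FLAIR lesions; stricter
    connectivity would fragment thin infiltrative bridges).  Cavity voxels
    are preserved untouched.  Returns ``(restricted mask, component
    count)``.  An exact voxel-count tie is broken toward the component
    with the smaller lexicographic centroid, with a warning.
    """
    tumor = mask.tumor
    if not tumor.any():
        raise EmptyLesionError("no measurable lesion: mask has no tumor voxels")
    structure = np.ones((3, 3, 3), dtype=bool)
    comp, n = ndimage.label(tumor, structure=structure)
    if n == 1:
        return mask, 1
    counts = np.bincount(comp.ravel())[1:]
    best = int(np.argmax(counts)) + 1
    ties = np.flatnonzero(counts == counts[best - 1]) + 1
    if len(ties) > 1:
        centroids = ndimage.center_of_mass(tumor, comp, ties)
        order = sorted(range(len(ties)), key=lambda i: tuple(centroids[i]))
        best = int(ties[order[0]])
        warnings.warn(
            "largest_residue: exact volume tie between components; "
            "keeping the one with smallest lexicographic centroid",
            stacklevel=2)
    labels = mask.labels.copy()
    labels[(comp != best) & tumor] = 0
    return LesionMask(labels=labels, spacing=mask.spacing), int(n)


# ---------------------------------------------------------------------------
# W / PW chord search


def _boundary_points(slice_tumor: np.ndarray) -> np.ndarray:
    """Tumor pixels with a 4-neighbor outside tumor (or at image edge)."""
    t = slice_tumor
    interior = np.zeros_like(t)
    interior[1:-1, 1:-1] = (t[1:-1, 1:-1] & t[:-2, 1:-1] & t[2:, 1:-1]
                            & t[1:-1, :-2] & t[1:-1, 2:])
    return np.argwhere(t & ~interior)


#: samples per chord for the crossing fraction; fixed so the fraction is a
#: deterministic function of the endpoints (and finer than one sample per
#: half-pixel for any chord that fits a 128-pixel slice)
N_CHORD_SAMPLES = 257


def _crossing_fractions(slice_labels: np.ndarray, p0: np.ndarray,
                        p1: np.ndarray) -> np.ndarray:
    """Fraction of each chord p0[i]->p1[i] overlapping non-tumor pixels.

    Chords are sampled at a fixed count of evenly spaced points looked up
    with nearest-neighbor rounding.  Both cavity and background count as
    crossing (the rule penalizes leaving tumor tissue altogether).
    """
    p0 = np.asarray(p0, float)
    p1 = np.asarray(p1, float)
    t = np.linspace(0.0, 1.0, N_CHORD_SAMPLES)
    samples = p0[:, None, :] + t[None, :, None] * (p1 - p0)[:, None, :]
    ij = np.rint(samples).astype(int)
    vals = slice_labels[ij[..., 0], ij[..., 1]]
    return (vals != LABEL_TUMOR).mean(axis=1)


def _caliper_length(p0: np.ndarray, p1: np.ndarray,
                    spacing2: np.ndarray) -> float:
    """Distance between voxel centers plus one voxel step along the chord
    direction (compensates half-voxel truncation at both ends)."""
    idx_dir = np.asarray(p1, float) - np.asarray(p0, float)
    n_mm = float(np.linalg.norm(idx_dir * spacing2))
    if n_mm == 0.0:
        return float(np.linalg.norm(spacing2))
    idx_dir /= np.linalg.norm(idx_dir)
    return n_mm + float(np.linalg.norm(idx_dir * spacing2))


def _best_chord(slice_labels: np.ndarray, pts: np.ndarray,
                spacing2: np.ndarray, tol: float,
                direction: np.ndarray | None = None,
                angle_tol_deg: float = 5.0):
    """Longest chord between boundary points with crossing fraction <= tol.

    Returns ``(length_mm, (p0, p1), crossing, compliant)``.  When no chord
    satisfies the tolerance, the chord minimizing the crossing fraction is
    returned with ``compliant=False``.  ``direction`` restricts candidates
    to within ``angle_tol_deg`` of perpendicular to that (mm-space) vector.
    """
    npts = len(pts)
    if npts == 0:
        return None
    if npts == 1:
        p = pts[0]
        return (float(np.linalg.norm(spacing2)), (tuple(p), tuple(p)), 0.0,
                True)

    diff = (pts[None, :, :] - pts[:, None, :]).astype(float)
    diff_mm = diff * spacing2
    lengths = np.linalg.norm(diff_mm, axis=-1)
    iu, ju = np.triu_indices(npts, k=1)

    if direction is not None:
        dnorm = direction / np.linalg.norm(direction)
        seg = diff_mm[iu, ju]
        seglen = np.linalg.norm(seg, axis=1)
        with np.errstate(invalid="ignore"):
            cosang = np.abs(seg @ dnorm) / np.where(seglen > 0, seglen, 1.0)
        keep = cosang <= np.sin(np.deg2rad(angle_tol_deg))
        iu, ju = iu[keep], ju[keep]
        if len(iu) == 0:
            return None

    pair_len = lengths[iu, ju]
    order = np.argsort(pair_len, kind="stable")[::-1]

    # evaluate crossing fractions in length-descending chunks; the first
    # compliant chord in chunk order is the winner
    best_noncompliant = None  # (crossing, -length, i, j)
    chunk = 512
    for start in range(0, len(order), chunk):
        sel = order[start:start + chunk]
        i_sel, j_sel = iu[sel], ju[sel]
        fracs = _crossing_fractions(slice_labels, pts[i_sel], pts[j_sel])
        ok = np.flatnonzero(fracs <= tol)
        if len(ok):
            k = int(ok[0])
            i, j = int(i_sel[k]), int(j_sel[k])
            length = _caliper_length(pts[i], pts[j], spacing2)
            return (length, (tuple(pts[i]), tuple(pts[j])),
                    float(fracs[k]), True)
        k = int(np.lexsort((-pair_len[sel], fracs))[0])
        cand = (float(fracs[k]), -float(pair_len[sel][k]),
                int(i_sel[k]), int(j_sel[k]))
        if best_noncompliant is None or cand[:2] < best_noncompliant[:2]:
            best_noncompliant = cand
    frac, _, i, j = best_noncompliant
    length = _caliper_length(pts[i], pts[j], spacing2)
    return length, (tuple(pts[i]), tuple(pts[j])), frac, False


def extract_w_pw(
    mask: LesionMask,
    crossing_tolerance: float = 0.10,
    max_boundary_points: int = 2000,
    exact: bool = False,
) -> tuple[float, float, dict]:
    """Extract W and PW with cavity-crossing avoidance.

    Per axial slice, W candidates are chords between tumor boundary pixels
    whose crossing fraction (fraction of the chord outside tumor tissue —
    cavity or background) does not exceed ``crossing_tolerance``; W is the
    longest such chord over all slices.  PW is the longest chord in W's
    slice within ±5° of perpendicular to W, under the same rule.  If no
    compliant chord exists anywhere, the minimal-crossing chord is used and
    flagged ``"noncompliant"``.  Slices with more than
    ``max_boundary_points`` boundary pixels are uniformly subsampled unless
    ``exact`` is set.

    Expects ``largest_residue`` to have been applied.  Returns
    ``(W, PW, metadata)`` with endpoints, slice index, crossing fraction
    and flags in the metadata dict.
    """
    tumor = mask.tumor
    if not tumor.any():
        raise EmptyLesionError("no measurable lesion")
    spacing2 = np.asarray(mask.spacing[:2], dtype=float)
    flags: list[str] = []

    if tumor.sum() == 1:
        idx = np.argwhere(tumor)[0]
        diag = float(np.linalg.norm(spacing2))
        meta = {"w_slice_index": int(idx[2]),
                "w_endpoints": (tuple(idx[:2]), tuple(idx[:2])),
                "pw_endpoints": (tuple(idx[:2]), tuple(idx[:2])),
                "cavity_crossing_fraction": 0.0,
                "flags": ("degenerate",)}
        return diag, diag, meta

    best = None  # (compliant, length, z, endpoints, crossing)
    for z in range(mask.labels.shape[2]):
        sl = tumor[:, :, z]
        if not sl.any():
            continue
        pts = _boundary_points(sl)
        if len(pts) > max_boundary_points and not exact:
            stride = int(np.ceil(len(pts) / max_boundary_points))
            pts = pts[::stride]
            flags.append(f"subsampled_slice_{z}")
        res = _best_chord(mask.labels[:, :, z], pts, spacing2,
                          crossing_tolerance)
        if res is None:
            continue
        length, endpoints, crossing, compliant = res
        key = (compliant, length)
        if best is None or key > (best[0], best[1]):
            best = (compliant, length, z, endpoints, crossing)

    compliant, w_len, w_z, w_ep, w_cross = best
    if not compliant:
        flags.append("noncompliant")

    # PW: same slice, perpendicular to W within ±5°
    sl = tumor[:, :, w_z]
    pts = _boundary_points(sl)
    if len(pts) > max_boundary_points and not exact:
        stride = int(np.ceil(len(pts) / max_boundary_points))
        pts = pts[::stride]
    w_dir = (np.asarray(w_ep[1], float) - np.asarray(w_ep[0], float)) * spacing2
    if np.linalg.norm(w_dir) == 0:
        pw_len, pw_ep, pw_cross = w_len, w_ep, w_cross
        flags.append("degenerate")
    else:
        res = _best_chord(mask.labels[:, :, w_z], pts, spacing2,
                          crossing_tolerance, direction=w_dir)
        if res is None:
            pw_len = float(np.linalg.norm(spacing2))
            pw_ep = w_ep
            pw_cross = 0.0
            flags.append("no_perpendicular_chord")
        else:
            pw_len, pw_ep, pw_cross, pw_ok = res
            if not pw_ok:
                flags.append("pw_noncompliant")
    pw_len = min(pw_len, w_len)  # PW is constrained; W is the slice max

    meta = {"w_slice_index": int(w_z), "w_endpoints": w_ep,
            "pw_endpoints": pw_ep,
            "cavity_crossing_fraction": float(max(w_cross, pw_cross)),
            "flags": tuple(flags)}
    return float(w_len), float(pw_len), meta


# ---------------------------------------------------------------------------
# axis-aligned extents and volume


def extract_d123(mask: LesionMask) -> tuple[float, float, float]:
    """Maximal transversal (D1), antero–posterior (D2) and height (D3)
    extents of the tumor, in mm.

    Extent along an axis is (max index − min index + 1) voxels converted to
    mm — the full caliper width of the covered voxels.  Apply
    ``largest_residue`` first; extents here span whatever tumor voxels the
    mask contains.
    """
    tumor = mask.tumor
    if not tumor.any():
        raise EmptyLesionError("no measurable lesion")
    idx = np.argwhere(tumor)
    spans = idx.max(axis=0) - idx.min(axis=0) + 1
    return tuple(float(s * z) for s, z in zip(spans, mask.spacing))


def segmented_volume(mask: LesionMask, slice_gap_mm: float = 0.0) -> float:
    """Segmented tumor volume in mL, all residues included.

    The outlined area of each axial slice is extruded across the slice
    pitch; with a declared inter-slice gap, across (thickness + gap).  For
    contiguous acquisitions this is exactly voxel count × voxel volume.
    """
    if slice_gap_mm < 0:
        raise ValueError("slice gap must be >= 0")
    sx, sy, sz = mask.spacing
    areas = mask.tumor.sum(axis=(0, 1)) * sx * sy  # mm² per slice
    return float(areas.sum() * (sz + slice_gap_mm) / 1000.0)


def size_estimates(d: DiameterSet, volume_seg_ml: float) -> SizeRecord:
    """1D/2D/3D tumor-size estimates with measurability flags.

    1D = W (mm); 2D = W × PW (mm²); 3D = (D1·D2·D3)/2 (mm³ → mL), the
    ellipsoid half-product volume approximation.  Measurability follows
    the response-assessment floors: ≥10 mm (1D), ≥100 mm² (2D),
    ≥0.5 mL (3D).
    """
    size_1d = d.W
    size_2d = d.W * d.PW
    size_3d = d.D1 * d.D2 * d.D3 / 2.0 / 1000.0
    return SizeRecord(
        size_1d=size_1d, size_2d=size_2d, size_3d=size_3d,
        volume_seg=volume_seg_ml,
        measurable_1d=size_1d >= MIN_1D_MM,
        measurable_2d=size_2d >= MIN_2D_MM2,
        measurable_3d=size_3d >= MIN_3D_ML,
    )


def measure_mask(mask: LesionMask, crossing_tolerance: float = 0.10,
                 exact: bool = False,
                 slice_gap_mm: float = 0.0) -> tuple[DiameterSet, SizeRecord]:
    """Full measurement of one scan: diameters on the largest residue,
    segmented volume over all residues, size estimates and flags."""
    volume = segmented_volume(mask, slice_gap_mm=slice_gap_mm)
    main, n_comp = largest_residue(mask)
    w, pw, meta = extract_w_pw(main, crossing_tolerance=crossing_tolerance,
                               exact=exact)
    d1, d2, d3 = extract_d123(main)
    diam = DiameterSet(W=w, PW=pw, D1=d1, D2=d2, D3=d3,
                       w_slice_index=meta["w_slice_index"],
                       w_endpoints=meta["w_endpoints"],
                       pw_endpoints=meta["pw_endpoints"],
                       cavity_crossing_fraction=meta[
                           "cavity_crossing_fraction"],
                       flags=meta["flags"] + (f"n_components={n_comp}",))
    return diam, size_estimates(diam, volume)
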