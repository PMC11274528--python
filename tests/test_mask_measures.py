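"""Linear diameters, segmented volume and size estimates from label masks."""

import numpy as np
import pytest

from gliogrowth import mask_measures as mm
from gliogrowth import synthetic_cohort as sc
from conftest import make_mask
from oracles import brute_force_w

CENTER = (48.0, 48.0, 48.0)


# ---------------------------------------------------------------------------
# largest_residue


def test_largest_residue_identity_on_single_component(sphere_spec):
    mask = make_mask(sphere_spec)
    out, n = mm.largest_residue(mask)
    assert n == 1
    assert np.array_equal(out.labels, mask.labels)


def test_largest_residue_keeps_main_drops_satellite():
    spec = sc.LesionSpec(
        center=CENTER, semi_axes=(13.4, 13.4, 13.4),
        satellites=(sc.Satellite(center=(80.0, 48.0, 48.0),
                                 semi_axes=(6.2, 6.2, 6.2)),))
    mask = make_mask(spec)
    total = mask.n_tumor_voxels
    out, n = mm.largest_residue(mask)
    assert n == 2
    # main ~10 mL vs satellite ~1 mL: retained fraction ~ 10/11
    assert out.n_tumor_voxels / total == pytest.approx(10 / 11, abs=0.01)


def test_largest_residue_tie_breaks_lexicographically_with_warning():
    labels = np.zeros((40, 20, 20), dtype=np.uint8)
    labels[5:10, 5:10, 5:10] = 1
    labels[25:30, 5:10, 5:10] = 1  # identical offset block
    mask = mm.LesionMask(labels, (1, 1, 1))
    with pytest.warns(UserWarning, match="tie"):
        out, n = mm.largest_residue(mask)
    assert n == 2
    kept = np.argwhere(out.tumor)
    assert kept[:, 0].max() < 20  # smaller-centroid component retained


def test_empty_mask_raises_explicit_error():
    mask = mm.LesionMask(np.zeros((10, 10, 10), dtype=np.uint8), (1, 1, 1))
    with pytest.raises(mm.EmptyLesionError, match="no measurable lesion"):
        mm.largest_residue(mask)
    with pytest.raises(mm.EmptyLesionError):
        mm.extract_d123(mask)


# ---------------------------------------------------------------------------
# W / PW


def test_w_pw_on_axis_aligned_ellipse():
    spec = sc.LesionSpec(center=CENTER, semi_axes=(20.0, 10.0, 8.0))
    mask = make_mask(spec)
    w, pw, meta = mm.extract_w_pw(mask)
    assert w == pytest.approx(40.0, abs=1.5)
    assert pw == pytest.approx(20.0, abs=1.5)
    assert pw <= w
    assert meta["cavity_crossing_fraction"] <= 0.10


def test_w_endpoints_lie_on_tumor(sphere_spec):
    mask = make_mask(sphere_spec)
    w, pw, meta = mm.extract_w_pw(mask)
    z = meta["w_slice_index"]
    for p in meta["w_endpoints"]:
        assert mask.labels[p[0], p[1], z] == mm.LABEL_TUMOR


def test_w_avoids_central_cavity():
    """Sphere d=30 with a d=10 central cavity: the winning chord stays
    within the 10% crossing tolerance and equals the brute-force search."""
    spec = sc.LesionSpec(center=CENTER, semi_axes=(15.0, 15.0, 15.0),
                         cavity=sc.Cavity(center=CENTER, radius=5.0))
    mask = make_mask(spec, shape=(64, 64, 64))
    w, pw, meta = mm.extract_w_pw(mask)
    assert meta["cavity_crossing_fraction"] <= 0.10
    assert "noncompliant" not in meta["flags"]
    w_oracle, _, _, _ = brute_force_w(mask.labels, mask.spacing[:2])
    assert w == pytest.approx(w_oracle, abs=1e-9)
    assert w < 31.0  # no compliant full-diameter chord exists


def test_c_shape_matches_exhaustive_oracle():
    """Half-annulus slice: tip-to-tip chord only wins if its crossing stays
    within tolerance, else the longest intra-tumor chord."""
    labels = np.zeros((64, 64, 3), dtype=np.uint8)
    yy, xx = np.mgrid[0:64, 0:64]
    r = np.hypot(xx - 32, yy - 32)
    half_annulus = (r >= 18) & (r <= 26) & (yy <= 32)
    labels[half_annulus, 1] = 1
    mask = mm.LesionMask(labels, (1.0, 1.0, 1.0))
    w, pw, meta = mm.extract_w_pw(mask, exact=True)
    w_oracle, z, ep, frac = brute_force_w(labels, (1.0, 1.0))
    assert w == pytest.approx(w_oracle, abs=1e-9)


def test_single_voxel_lesion_degenerate():
    labels = np.zeros((8, 8, 8), dtype=np.uint8)
    labels[4, 4, 4] = 1
    mask = mm.LesionMask(labels, (1.0, 1.0, 1.0))
    w, pw, meta = mm.extract_w_pw(mask)
    assert w == pytest.approx(np.sqrt(2.0))
    assert pw == w
    assert "degenerate" in meta["flags"]


# ---------------------------------------------------------------------------
# D1/D2/D3


def test_d123_axis_aligned_extents():
    spec = sc.LesionSpec(center=CENTER, semi_axes=(15.0, 10.0, 5.0))
    mask = make_mask(spec)
    d1, d2, d3 = mm.extract_d123(mask)
    assert d1 == pytest.approx(30.0, abs=1.0)
    assert d2 == pytest.approx(20.0, abs=1.0)
    assert d3 == pytest.approx(10.0, abs=1.0)


def test_rotation_about_z_swaps_d1_d2():
    spec = sc.LesionSpec(center=CENTER, semi_axes=(15.0, 10.0, 5.0))
    rot = sc.LesionSpec(center=CENTER, semi_axes=(15.0, 10.0, 5.0),
                        orientation=(np.pi / 2.0, 0.0, 0.0))
    m0, m90 = make_mask(spec), make_mask(rot)
    d0 = mm.extract_d123(m0)
    d90 = mm.extract_d123(m90)
    assert d90[0] == pytest.approx(d0[1], abs=1.0)
    assert d90[1] == pytest.approx(d0[0], abs=1.0)
    assert d90[2] == pytest.approx(d0[2], abs=1.0)
    w0, pw0, _ = mm.extract_w_pw(m0)
    w90, pw90, _ = mm.extract_w_pw(m90)
    assert w90 == pytest.approx(w0, abs=1.0)
    assert pw90 == pytest.approx(pw0, abs=1.0)


def test_rotated_ellipsoid_extents_equal_coordinate_scan():
    spec = sc.LesionSpec(center=CENTER, semi_axes=(16.0, 11.0, 8.0),
                         orientation=(0.5, 0.3, 0.9))
    mask = make_mask(spec)
    d = mm.extract_d123(mask)
    idx = np.argwhere(mask.tumor)
    expected = tuple(float(idx[:, i].max() - idx[:, i].min() + 1)
                     for i in range(3))
    assert d == pytest.approx(expected)


def test_sphere_diameter_identity(sphere_spec):
    """On a voxelized sphere the caliper convention makes W = D1 = D2 = D3."""
    mask = make_mask(sphere_spec)
    w, pw, _ = mm.extract_w_pw(mask)
    d1, d2, d3 = mm.extract_d123(mask)
    assert d1 == d2 == d3
    assert w == pytest.approx(d1, abs=1.0)
    assert pw == pytest.approx(d1, abs=1.0)


# ---------------------------------------------------------------------------
# segmented volume


def test_segmented_volume_unit_conversion():
    labels = np.zeros((20, 20, 20), dtype=np.uint8)
    labels[5:15, 5:15, 5:15] = 1  # 1000 voxels
    mask = mm.LesionMask(labels, (1.0, 1.0, 1.0))
    assert mm.segmented_volume(mask) == pytest.approx(1.0)
    assert mm.segmented_volume(mask, slice_gap_mm=1.0) == pytest.approx(2.0)
    with pytest.raises(ValueError):
        mm.segmented_volume(mask, slice_gap_mm=-0.5)


def test_segmented_volume_counts_all_residues():
    spec_main = sc.LesionSpec(center=CENTER, semi_axes=(13.4, 13.4, 13.4))
    spec_both = sc.LesionSpec(
        center=CENTER, semi_axes=(13.4, 13.4, 13.4),
        satellites=(sc.Satellite(center=(80.0, 48.0, 48.0),
                                 semi_axes=(6.2, 6.2, 6.2)),))
    v_main = mm.segmented_volume(make_mask(spec_main))
    v_both = mm.segmented_volume(make_mask(spec_both))
    assert v_both > v_main
    assert v_both - v_main == pytest.approx(1.0, abs=0.05)  # ~1 mL satellite


def test_segmented_volume_anisotropic_spacing():
    labels = np.zeros((20, 20, 10), dtype=np.uint8)
    labels[5:15, 5:15, 2:7] = 1  # 500 voxels of 1x1x2 mm
    mask = mm.LesionMask(labels, (1.0, 1.0, 2.0))
    assert mm.segmented_volume(mask) == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# size estimates


def test_size_estimates_measurability_boundaries():
    d = mm.DiameterSet(W=10.0, PW=10.0, D1=10.0, D2=10.0, D3=10.0,
                       w_slice_index=0, w_endpoints=(), pw_endpoints=(),
                       cavity_crossing_fraction=0.0)
    rec = mm.size_estimates(d, 0.5)
    assert rec.size_3d == pytest.approx(0.5)   # exactly the 3D floor
    assert rec.size_2d == pytest.approx(100.0)  # exactly the 2D floor
    assert rec.measurable_1d and rec.measurable_2d and rec.measurable_3d
    small = mm.DiameterSet(W=9.9, PW=9.9, D1=9.9, D2=9.9, D3=9.9,
                           w_slice_index=0, w_endpoints=(), pw_endpoints=(),
                           cavity_crossing_fraction=0.0)
    rec = mm.size_estimates(small, 0.4)
    assert not (rec.measurable_1d or rec.measurable_2d or rec.measurable_3d)


def test_size_estimates_formulas():
    d = mm.DiameterSet(W=31.0, PW=24.0, D1=30.0, D2=25.0, D3=20.0,
                       w_slice_index=0, w_endpoints=(), pw_endpoints=(),
                       cavity_crossing_fraction=0.0)
    rec = mm.size_estimates(d, 7.0)
    assert rec.size_1d == 31.0
    assert rec.size_2d == pytest.approx(31.0 * 24.0, rel=1e-12)
    assert rec.size_3d == pytest.approx(30.0 * 25.0 * 20.0 / 2.0 / 1000.0,
                                        rel=1e-12)
    assert rec.size_2d <= rec.size_1d ** 2


def test_measure_mask_end_to_end(sphere_spec):
    mask = make_mask(sphere_spec)
    diam, size = mm.measure_mask(mask)
    assert size.volume_seg == pytest.approx(4.0 / 3.0 * np.pi * 15.0 ** 3
                                            / 1000.0, rel=0.03)
    assert size.size_3d == pytest.approx(diam.D1 * diam.D2 * diam.D3 / 2000.0,
                                         rel=1e-12)
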