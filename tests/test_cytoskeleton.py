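"""Stress-fiber/focal-adhesion segmentation and polar localization."""

import numpy as np
import pytest

from cncorr.cytoskeleton import (FiberParams,
                                 StressFiberSegmenter,
                                 extract_cell_and_nucleus_masks,
                                 feature_statistics, normalize_localization,
                                 segment_focal_adhesions,
                                 segment_stress_fibers)
from cncorr.cytoskeleton import _Branch
from cncorr.simulate import GapSpec, generate_cytoskeleton_image


# -- boundary determination -------------------------------------------------

def test_mask_from_background_model():
    rng = np.random.default_rng(0)
    img = rng.normal(100.0, 10.0, (200, 200))
    yy, xx = np.mgrid[:200, :200]
    disk = (xx - 100) ** 2 + (yy - 100) ** 2 <= 60 ** 2
    img[disk] = 1000.0
    mask, nuc = extract_cell_and_nucleus_masks(img)
    assert nuc is None
    assert abs(mask.sum() - disk.sum()) / disk.sum() < 0.02


def test_mask_blank_image_errors():
    with pytest.raises(ValueError, match="no foreground"):
        extract_cell_and_nucleus_masks(
            np.random.default_rng(1).normal(100.0, 10.0, (100, 100)))
    with pytest.raises(ValueError, match="empty"):
        extract_cell_and_nucleus_masks(np.empty((0, 0)))


def test_mask_keeps_largest_component():
    rng = np.random.default_rng(2)
    img = rng.normal(100.0, 10.0, (200, 200))
    yy, xx = np.mgrid[:200, :200]
    big = (xx - 70) ** 2 + (yy - 100) ** 2 <= 40 ** 2
    small = (xx - 170) ** 2 + (yy - 100) ** 2 <= 20 ** 2
    img[big | small] = 1000.0
    mask, _ = extract_cell_and_nucleus_masks(img)
    assert mask[100, 70] and not mask[100, 170]


def test_nucleus_needs_fixed_threshold():
    rng = np.random.default_rng(3)
    img = rng.normal(100.0, 10.0, (100, 100))
    img[40:60, 40:60] = 1000.0
    with pytest.raises(ValueError, match="nucleus_threshold"):
        extract_cell_and_nucleus_masks(img, nucleus_image=img)
    mask, nuc = extract_cell_and_nucleus_masks(img, nucleus_image=img,
                                               nucleus_threshold=500.0)
    assert nuc is not None and nuc.sum() == 400


# -- stress fibers ----------------------------------------------------------

def test_five_fibers_recovered_noise_free():
    img = generate_cytoskeleton_image(5, 0, noise_sd=0.0, seed=0)
    fibers = segment_stress_fibers(img.intensity, img.cell_mask,
                                   pixel_size=img.pixel_size)
    assert len(fibers) == 5
    truth = sorted(img.truth_fibers, key=lambda t: t["orientation_deg"])
    found = sorted(fibers, key=lambda f: f.orientation)
    for t, f in zip(truth, found):
        assert f.length == pytest.approx(t["length_px"] * img.pixel_size,
                                         rel=0.10)
        diff = abs(f.orientation - t["orientation_deg"]) % 180.0
        assert min(diff, 180.0 - diff) < 2.0


def test_fiber_count_stable_at_snr5():
    counts = []
    for seed in range(10):
        img = generate_cytoskeleton_image(5, 0, noise_sd=120.0, seed=seed)
        counts.append(len(segment_stress_fibers(img.intensity, img.cell_mask)))
    assert abs(np.mean(counts) - 5.0) <= 0.5
    assert all(abs(c - 5) <= 1 for c in counts)


def gap_image(**gap_kwargs):
    img = generate_cytoskeleton_image(
        3, 0, gap_spec=GapSpec(fiber_index=0, **gap_kwargs),
        noise_sd=0.0, seed=3)
    return img


def n_fibers(img):
    return len(segment_stress_fibers(img.intensity, img.cell_mask))


def test_collinear_5px_gap_reconnects():
    assert n_fibers(gap_image(gap_px=5.0)) == 3


def test_gap_angle_criterion():
    assert n_fibers(gap_image(gap_px=5.0, angle_offset_deg=30.0)) == 4
    assert n_fibers(gap_image(gap_px=5.0, angle_offset_deg=10.0)) == 3


def test_gap_distance_criterion():
    assert n_fibers(gap_image(gap_px=12.0)) == 4


def test_gap_intensity_criterion():
    assert n_fibers(gap_image(gap_px=5.0, intensity_ratio=1.5)) == 4
    assert n_fibers(gap_image(gap_px=5.0, intensity_ratio=1.1)) == 3


def test_gap_width_criterion():
    assert n_fibers(gap_image(gap_px=5.0, width_ratio=1.5)) == 4
    assert n_fibers(gap_image(gap_px=5.0, width_ratio=1.1)) == 3


def branch(path, intensity=100.0, width=3.0):
    path = np.asarray(path)
    seg = StressFiberSegmenter()
    from cncorr.cytoskeleton import _branch_orientation, _path_length
    return _Branch(path=path, length_px=_path_length(path),
                   orientation=_branch_orientation(path),
                   mean_intensity=intensity, width_px=width)


def test_mergeable_criteria_individually_necessary():
    seg = StressFiberSegmenter()
    a = branch([(50, c) for c in range(10, 30)])
    ok = branch([(50, c) for c in range(34, 54)])           # 4-px gap
    assert seg.mergeable(a, ok)
    far = branch([(50, c) for c in range(40, 60)])          # 10-px gap
    assert not seg.mergeable(a, far)
    steep = branch([(34 + i, 34 + i) for i in range(20)])   # 45 deg off
    assert not seg.mergeable(a, steep)
    bright = branch([(50, c) for c in range(34, 54)], intensity=150.0)
    assert not seg.mergeable(a, bright)                     # 1.5-fold
    wide = branch([(50, c) for c in range(34, 54)], width=4.5)
    assert not seg.mergeable(a, wide)                       # 1.5-fold


def test_reconnection_never_increases_count():
    for seed in (0, 1, 2):
        img = generate_cytoskeleton_image(5, 0, noise_sd=60.0, seed=seed)
        merged = segment_stress_fibers(img.intensity, img.cell_mask)
        no_merge = segment_stress_fibers(
            img.intensity, img.cell_mask,
            params=FiberParams(max_gap_px=1e-6))
        assert len(merged) <= len(no_merge)
        # merging regroups fragments; total fragment count is conserved
        assert (sum(f.n_fragments for f in merged)
                == sum(f.n_fragments for f in no_merge))


def test_fiber_param_validation_and_empty_mask():
    with pytest.raises(ValueError, match="local_block"):
        FiberParams(local_block=10)
    with pytest.raises(ValueError, match="admissible"):
        FiberParams(max_angle_deg=0.0)
    img = generate_cytoskeleton_image(2, 0, noise_sd=0.0, seed=0)
    assert segment_stress_fibers(img.intensity,
                                 np.zeros_like(img.cell_mask)) == []
    with pytest.raises(ValueError, match="shape"):
        segment_stress_fibers(img.intensity, img.cell_mask[:-1])


# -- focal adhesions --------------------------------------------------------

def test_twenty_adhesions_recovered():
    img = generate_cytoskeleton_image(0, 20, noise_sd=0.0, seed=1)
    fas = segment_focal_adhesions(img.intensity, img.cell_mask,
                                  pixel_size=img.pixel_size)
    assert len(fas) == 20
    truth = np.array([t["centroid"] for t in img.truth_adhesions])
    found = np.array([fa.centroid / img.pixel_size for fa in fas])
    for t in truth:
        assert np.min(np.hypot(*(found - t).T)) < 1.0


def test_adhesion_count_stable_at_snr5():
    counts = []
    for seed in range(10):
        img = generate_cytoskeleton_image(0, 20, noise_sd=160.0, seed=seed)
        fas = segment_focal_adhesions(img.intensity, img.cell_mask)
        counts.append(len(fas))
    assert abs(np.mean(counts) - 20.0) <= 2.0


def test_touching_blobs_split_by_watershed():
    shape = (120, 120)
    yy, xx = np.mgrid[:120, :120]
    cell = np.ones(shape, bool)
    img = np.zeros(shape)
    for cx in (52, 60):  # 8 px apart: supports overlap
        img += 800.0 * np.exp(-(((xx - cx) ** 2 + (yy - 60) ** 2)
                                / (2 * 2.0 ** 2)))
    fas = segment_focal_adhesions(img, cell)
    assert len(fas) == 2


def test_blank_adhesion_image():
    assert segment_focal_adhesions(np.zeros((64, 64)),
                                   np.ones((64, 64), bool)) == []
    assert segment_focal_adhesions(np.zeros((64, 64)),
                                   np.zeros((64, 64), bool)) == []


# -- feature statistics -----------------------------------------------------

class _Feat:
    def __init__(self, **kw):
        self.__dict__.update(kw)


def test_feature_statistics_density_arithmetic():
    mask = np.zeros((40, 40), bool)
    mask[:25, :40] = True
    assert mask.sum() == 1000
    adhesions = [_Feat(area=2.0)] * 10
    stats = feature_statistics([], adhesions, mask, pixel_size=1.0)
    assert stats["adhesion_density_per_um2"] == pytest.approx(0.01)
    assert stats["mean_adhesion_area_um2"] == pytest.approx(2.0)
    # doubling cell area halves the density
    big = np.zeros((50, 40), bool)
    big[:, :] = True
    stats2 = feature_statistics([], adhesions, big, pixel_size=1.0)
    assert stats2["adhesion_density_per_um2"] == pytest.approx(0.005)


def test_feature_statistics_fiber_summary():
    fibers = [_Feat(length=12.0), _Feat(length=18.0)]
    mask = np.ones((10, 10), bool)
    stats = feature_statistics(fibers, [], mask, pixel_size=2.0)
    assert stats["mean_fiber_length_um"] == pytest.approx(15.0)
    assert stats["cell_area_um2"] == pytest.approx(400.0)
    assert stats["fiber_density_per_um2"] == pytest.approx(2 / 400.0)
    with pytest.raises(ValueError, match="empty"):
        feature_statistics([], [], np.zeros((5, 5), bool), 1.0)


# -- localization -----------------------------------------------------------

def ellipse_points(mask, radii_frac, angles_deg):
    """Points at given fractional radii along given mask-frame ray angles."""
    from skimage import measure as _measure
    from cncorr.cytoskeleton import _edge_distance

    props = _measure.regionprops(mask.astype(int))[0]
    cy, cx = props.centroid
    pts = []
    for f, a in zip(radii_frac, angles_deg):
        th = np.deg2rad(a)
        edge = _edge_distance(mask, (cx, cy), th)
        pts.append((cx + f * edge * np.cos(th), cy + f * edge * np.sin(th)))
    return np.array(pts)


def test_radius_zero_and_one(ellipse_mask):
    pts = ellipse_points(ellipse_mask, [0.0, 1.0], [0.0, 40.0])
    loc = normalize_localization(pts, ellipse_mask)
    assert loc.radii[0] == pytest.approx(0.0, abs=1e-9)
    assert loc.radii[1] == pytest.approx(1.0, abs=0.02)
    assert loc.polar_frequency.sum() == 2


def test_radii_always_in_unit_interval(ellipse_mask):
    rng = np.random.default_rng(0)
    pts = ellipse_points(ellipse_mask, rng.uniform(0, 1, 200),
                         rng.uniform(0, 360, 200))
    loc = normalize_localization(pts, ellipse_mask)
    assert np.all((loc.radii >= 0.0) & (loc.radii <= 1.0))
    assert loc.polar_frequency.sum() == 200


def test_uniform_angles_give_round_polygon(ellipse_mask):
    angles = np.arange(500) * 360.0 / 500.0   # angularly uniform
    pts = ellipse_points(ellipse_mask, np.full(500, 0.6), angles)
    loc = normalize_localization(pts, ellipse_mask)
    assert 1.0 <= loc.ar <= 1.15


def test_two_opposite_sectors_give_elongated_polygon(ellipse_mask):
    rng = np.random.default_rng(1)
    angles = np.concatenate([rng.uniform(-15, 15, 250),
                             rng.uniform(165, 195, 250)]) % 360.0
    pts = ellipse_points(ellipse_mask, np.full(500, 0.6), angles)
    loc = normalize_localization(pts, ellipse_mask)
    assert loc.ar > 2.0


def test_localization_rotation_invariance():
    """Rotating features and mask together changes ar by < 5%."""
    h = w = 256

    def make(theta_deg):
        yy, xx = np.mgrid[:h, :w]
        cx, cy = (w - 1) / 2, (h - 1) / 2
        th = np.deg2rad(theta_deg)
        u = (xx - cx) * np.cos(th) + (yy - cy) * np.sin(th)
        v = -(xx - cx) * np.sin(th) + (yy - cy) * np.cos(th)
        mask = (u / (0.45 * w)) ** 2 + (v / (0.32 * h)) ** 2 <= 1.0
        rng = np.random.default_rng(5)
        ang = rng.uniform(0, 360, 300)
        rad = rng.uniform(0.2, 0.9, 300)
        pts = ellipse_points(mask, rad, (ang + theta_deg) % 360.0)
        return normalize_localization(pts, mask).ar

    base = make(0.0)
    for theta in (30.0, 60.0, 90.0):
        assert make(theta) == pytest.approx(base, rel=0.05)


def test_centroid_outside_mask_errors():
    ring = np.zeros((100, 100), bool)
    yy, xx = np.mgrid[:100, :100]
    r2 = (xx - 50) ** 2 + (yy - 50) ** 2
    ring[(r2 <= 45 ** 2) & (r2 >= 35 ** 2)] = True
    with pytest.raises(ValueError, match="centroid"):
        normalize_localization(np.array([[50.0, 12.0]]), ring)
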