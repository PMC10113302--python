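"""The three-component objective: intensity sum, ridge-centering penalty,
landmark term."""

import numpy as np
import pytest

from vesselreg.core import CenterlinePoint, IntensityVolume, LandmarkSet
from vesselreg.metric import (
    MetricConfig,
    combined_metric,
    intensity_at,
    m1_intensity_sum,
    m2_gradient_penalty,
    m3_landmark_term,
    radius_weight,
)
from vesselreg.phantom import rasterize
from vesselreg.transform import AffineTransform

from conftest import random_volume, straight_tube_forest

IDENT = AffineTransform.identity()


def _random_points(rng, n, lo, hi):
    pos = rng.uniform(lo, hi, (n, 3))
    radii = rng.uniform(0.5, 2.5, n)
    tangents = rng.normal(size=(n, 3))
    tangents /= np.linalg.norm(tangents, axis=1, keepdims=True)
    return [CenterlinePoint(p, r, t) for p, r, t in zip(pos, radii, tangents)]


# ---------------------------------------------------------------------------
# intensity_at
# ---------------------------------------------------------------------------

def test_intensity_constant_volume_any_sigma():
    vol = IntensityVolume(np.full((10, 10, 10), 5.0), spacing=(1, 1, 1))
    for sigma in (0.0, 0.5, 2.0):
        assert intensity_at(vol, (4.3, 5.1, 4.9), sigma) == pytest.approx(5.0)


def test_intensity_voxel_center_sigma_zero():
    rng = np.random.default_rng(0)
    vol = IntensityVolume(rng.random((6, 6, 6)), spacing=(1.2, 0.8, 1.0),
                          origin=(3.0, -2.0, 1.0))
    p = vol.voxel_to_world([2, 3, 4])
    assert intensity_at(vol, p, 0.0) == pytest.approx(vol.data[2, 3, 4], abs=1e-12)


def test_intensity_on_axis_beats_offset_on_tube():
    forest, vol = straight_tube_forest(), None
    vol = rasterize(forest, 0.7)
    on_axis = intensity_at(vol, (0, 0, 7.5), 1.0)
    off = intensity_at(vol, (1.5, 0, 7.5), 1.0)  # one radius off-axis
    assert on_axis > off


def test_intensity_out_of_bounds_value():
    vol = IntensityVolume(np.full((8, 8, 8), 3.0), spacing=(1, 1, 1))
    assert intensity_at(vol, (100, 100, 100), 0.0) == 0.0
    assert intensity_at(vol, (100, 100, 100), 0.0, oob_intensity=-1.0) == -1.0


# ---------------------------------------------------------------------------
# radius_weight
# ---------------------------------------------------------------------------

def test_radius_weight_modes_and_monotonicity():
    assert radius_weight(2.0, MetricConfig(weight_mode="linear")) == 2.0
    assert radius_weight(7.3, MetricConfig(weight_mode="uniform")) == 1.0
    with pytest.raises(ValueError):
        radius_weight(-1.0, MetricConfig())
    rng = np.random.default_rng(1)
    for mode in ("linear", "uniform"):
        cfg = MetricConfig(weight_mode=mode)
        r = np.sort(rng.uniform(0.1, 5.0, (1000, 2)), axis=1)
        for r1, r2 in r:
            assert radius_weight(r1, cfg) <= radius_weight(r2, cfg)


# ---------------------------------------------------------------------------
# m1
# ---------------------------------------------------------------------------

def test_m1_constant_volume_is_constant():
    vol = IntensityVolume(np.full((10, 10, 10), 2.5), spacing=(1, 1, 1))
    rng = np.random.default_rng(2)
    pts = _random_points(rng, 15, 2, 7)
    assert m1_intensity_sum(pts, vol, IDENT, MetricConfig()) == pytest.approx(2.5)


def test_m1_hand_computed_weighted_mean():
    """Two points with weights 1 and 3 and intensities 0.2 and 0.6 give
    (1*0.2 + 3*0.6) / 4 = 0.5."""
    data = np.zeros((6, 6, 6))
    data[1, 1, 1] = 0.2
    data[4, 4, 4] = 0.6
    vol = IntensityVolume(data, spacing=(1, 1, 1))
    pts = [
        CenterlinePoint((1, 1, 1), 1.0, (0, 0, 1)),
        CenterlinePoint((4, 4, 4), 3.0, (0, 0, 1)),
    ]
    # tiny kappa keeps sigma below the pyramid's first level => raw volume
    cfg = MetricConfig(kappa=1e-3, weight_mode="linear")
    assert m1_intensity_sum(pts, vol, IDENT, cfg) == pytest.approx(0.5, abs=1e-12)


def test_m1_matches_pointwise_oracle_20_random_instances():
    rng = np.random.default_rng(3)
    for _ in range(20):
        vol = random_volume(rng)
        lo = vol.origin + 1
        hi = vol.voxel_to_world(np.array(vol.shape) - 2.0)
        pts = _random_points(rng, int(rng.integers(2, 12)), lo, np.maximum(lo + 1, hi))
        cfg = MetricConfig(kappa=float(rng.uniform(0.2, 1.5)))
        got = m1_intensity_sum(pts, vol, IDENT, cfg)
        # unvectorized oracle looping point by point
        num = den = 0.0
        for p in pts:
            w = p.radius  # linear weight mode
            num += w * intensity_at(vol, p.position, cfg.kappa * p.radius,
                                    cfg.oob_intensity)
            den += w
        assert got == pytest.approx(num / den, abs=1e-10)


def test_m1_normalization_invariance():
    """Scaling all weights by a positive constant leaves m1 unchanged."""
    rng = np.random.default_rng(4)
    vol = random_volume(rng)
    pts = _random_points(rng, 8, vol.origin, vol.origin + 4)
    cfg = MetricConfig()
    base = m1_intensity_sum(pts, vol, IDENT, cfg)
    c = 3.7
    num = den = 0.0
    for p in pts:
        w = c * p.radius
        num += w * intensity_at(vol, p.position, cfg.kappa * p.radius)
        den += w
    assert num / den == pytest.approx(base, abs=1e-12)


def test_m1_empty_points_errors():
    vol = IntensityVolume(np.zeros((5, 5, 5)), spacing=(1, 1, 1))
    with pytest.raises(ValueError):
        m1_intensity_sum([], vol, IDENT, MetricConfig())


def test_m1_centerline_on_axis_beats_lateral_shift_100_tubes():
    rng = np.random.default_rng(5)
    cfg = MetricConfig()
    for _ in range(100):
        radius = float(rng.uniform(0.8, 2.5))
        forest = straight_tube_forest(radius=radius, length=12.0, n=15)
        vol = rasterize(forest, 0.7)
        seg = forest.segments[0]
        pts = (seg.positions, seg.radii, seg.tangents)
        on_axis = m1_intensity_sum(pts, vol, IDENT, cfg)
        shift = AffineTransform(dof=6, translation=(0.7 * rng.choice([-1, 1]),
                                                    0.7 * rng.choice([-1, 1]), 0))
        assert on_axis >= m1_intensity_sum(pts, vol, shift, cfg)


# ---------------------------------------------------------------------------
# m2
# ---------------------------------------------------------------------------

def test_m2_zero_on_constant_volume():
    vol = IntensityVolume(np.full((10, 10, 10), 4.0), spacing=(1, 1, 1))
    p = CenterlinePoint((5, 5, 5), 1.0, (0, 0, 1))
    assert m2_gradient_penalty(p, vol, IDENT, MetricConfig()) == 0.0


def test_m2_all_inward_gradients_zero_penalty():
    """A radially decreasing profile has gradients pointing exactly inward
    on the normal plane -> penalty 0 (the theta = 180 deg case)."""
    n = 21
    c = (n - 1) / 2.0
    ii, jj, kk = np.meshgrid(*[np.arange(n)] * 3, indexing="ij")
    data = -((ii - c) ** 2 + (jj - c) ** 2)  # ridge along k
    vol = IntensityVolume(data.astype(float), spacing=(1, 1, 1))
    p = CenterlinePoint((c, c, c), 2.0, (0, 0, 1))
    cfg = MetricConfig(n_rays=4, n_radii=1, kappa=1e-3)
    assert m2_gradient_penalty(p, vol, IDENT, cfg) == pytest.approx(0.0, abs=1e-9)


def test_m2_on_axis_below_offset_random_tubes():
    rng = np.random.default_rng(6)
    cfg = MetricConfig()
    for _ in range(20):
        radius = float(rng.uniform(0.9, 2.2))
        forest = straight_tube_forest(radius=radius, length=12.0)
        vol = rasterize(forest, 0.7)
        p_on = CenterlinePoint((0, 0, 6.0), radius, (0, 0, 1))
        off = np.array([radius / 2, 0, 0])
        p_off = CenterlinePoint(np.array([0, 0, 6.0]) + off, radius, (0, 0, 1))
        assert (
            m2_gradient_penalty(p_on, vol, IDENT, cfg)
            < m2_gradient_penalty(p_off, vol, IDENT, cfg)
        )


def test_m2_rigid_rotation_invariance():
    """Rotating the whole scene (tube + point + tangent) by 90 degrees
    leaves the penalty unchanged within interpolation error."""
    cfg = MetricConfig()
    f1 = straight_tube_forest(direction=(0, 0, 1))
    v1 = rasterize(f1, 0.7)
    f2 = straight_tube_forest(direction=(0, 1, 0))
    v2 = rasterize(f2, 0.7)
    p1 = CenterlinePoint((0.3, 0, 7.0), 1.5, (0, 0, 1))
    p2 = CenterlinePoint((0.3, 7.0, 0), 1.5, (0, 1, 0))
    a = m2_gradient_penalty(p1, v1, IDENT, cfg)
    b = m2_gradient_penalty(p2, v2, IDENT, cfg)
    assert a == pytest.approx(b, abs=1e-3)


def test_m2_degenerate_tangent_errors():
    vol = IntensityVolume(np.zeros((5, 5, 5)), spacing=(1, 1, 1))
    p = CenterlinePoint((2, 2, 2), 1.0, (0, 0, 1))
    p.tangent = np.zeros(3)  # bypass constructor validation
    with pytest.raises(ValueError, match="tangent"):
        m2_gradient_penalty(p, vol, IDENT, MetricConfig())


# ---------------------------------------------------------------------------
# m3
# ---------------------------------------------------------------------------

def test_m3_matched_pairs_zero():
    pts = np.random.default_rng(7).uniform(-5, 5, (6, 3))
    lm = LandmarkSet(pts, pts.copy(), role="guidance")
    assert m3_landmark_term(lm, IDENT) == 0.0


def test_m3_three_four_five():
    lm = LandmarkSet([[0, 0, 0]], [[3, 4, 0]], role="guidance")
    assert m3_landmark_term(lm, IDENT) == pytest.approx(25.0)


def test_m3_duplicate_pair_invariance():
    rng = np.random.default_rng(8)
    mov, fix = rng.uniform(-5, 5, (4, 3)), rng.uniform(-5, 5, (4, 3))
    lm = LandmarkSet(mov, fix, role="guidance")
    dup = LandmarkSet(
        np.vstack([mov, mov[1:2]]), np.vstack([fix, fix[1:2]]),
        labels=[f"L{i}" for i in range(5)], role="guidance",
    )
    t = AffineTransform(dof=6, translation=(1, -2, 0.5))
    base = m3_landmark_term(lm, t)
    # duplicating one pair changes the mean, but duplicating ALL pairs not
    all_dup = LandmarkSet(
        np.vstack([mov, mov]), np.vstack([fix, fix]),
        labels=[f"L{i}" for i in range(8)], role="guidance",
    )
    assert m3_landmark_term(all_dup, t) == pytest.approx(base, abs=1e-12)
    assert dup is not None  # constructed fine


def test_m3_no_pairs_inert():
    assert m3_landmark_term(None, IDENT) == 0.0
    empty = LandmarkSet(np.empty((0, 3)), np.empty((0, 3)), labels=[], role="guidance")
    assert m3_landmark_term(empty, IDENT) == 0.0


# ---------------------------------------------------------------------------
# combined metric
# ---------------------------------------------------------------------------

def test_combined_reduces_to_m1():
    rng = np.random.default_rng(9)
    cfg = MetricConfig(alpha1=1.0, alpha2=0.0, alpha3=0.0)
    for _ in range(20):
        vol = random_volume(rng)
        pts = _random_points(rng, 6, vol.origin, vol.origin + 4)
        assert combined_metric(pts, vol, IDENT, None, cfg) == pytest.approx(
            m1_intensity_sum(pts, vol, IDENT, cfg), abs=1e-12
        )


def test_combined_decreases_with_worse_landmarks():
    rng = np.random.default_rng(10)
    vol = IntensityVolume(np.full((10, 10, 10), 1.0), spacing=(1, 1, 1))
    pts = _random_points(rng, 5, 2, 7)
    cfg = MetricConfig(alpha3=0.1)
    good = LandmarkSet([[2, 2, 2]], [[2, 2, 2]], role="guidance")
    bad = LandmarkSet([[2, 2, 2]], [[6, 2, 2]], role="guidance")
    assert combined_metric(pts, vol, IDENT, good, cfg) > combined_metric(
        pts, vol, IDENT, bad, cfg
    )


def test_combined_matches_componentwise_oracle(tube_volume):
    """Full combined value equals a point-by-point recomputation of
    alpha1*m1 - alpha2*mean(m2) - alpha3*m3 to 1e-10."""
    forest, vol = tube_volume
    seg = forest.segments[0]
    cfg = MetricConfig()
    lm = LandmarkSet([[0, 0, 0], [0, 0, 15.0]], [[0.5, 0, 0], [0, 0, 14.0]],
                     role="guidance")
    t = AffineTransform(dof=12, translation=(0.2, -0.1, 0.3),
                        rotation=(1.0, -2.0, 0.5), scale=(1.02, 0.98, 1.0),
                        shear=(0.01, 0.0, -0.02), anchor=(0, 0, 7.5))
    got = combined_metric(
        (seg.positions, seg.radii, seg.tangents), vol, t, lm, cfg
    )
    pts = seg.points
    m1 = m1_intensity_sum(pts, vol, t, cfg)
    m2s = [m2_gradient_penalty(p, vol, t, cfg) for p in pts]
    m3 = m3_landmark_term(lm, t)
    expect = cfg.alpha1 * m1 - cfg.alpha2 * float(np.mean(m2s)) - cfg.alpha3 * m3
    assert got == pytest.approx(expect, abs=1e-10)


def test_combined_continuity_in_parameters(tube_volume):
    """Perturbing any transform parameter by 1e-6 changes the value by less
    than 1e-3 on in-bounds configurations."""
    forest, vol = tube_volume
    seg = forest.segments[0]
    cfg = MetricConfig()
    pts = (seg.positions, seg.radii, seg.tangents)
    base_kwargs = dict(
        translation=np.array([0.1, 0.2, -0.1]),
        rotation=np.array([2.0, -1.0, 3.0]),
        scale=np.array([1.01, 0.99, 1.0]),
        shear=np.array([0.02, -0.01, 0.0]),
        anchor=np.array([0.0, 0.0, 7.5]),
    )
    base = combined_metric(pts, vol, AffineTransform(dof=12, **base_kwargs), None, cfg)
    for field in ("translation", "rotation", "scale", "shear"):
        for axis in range(3):
            kw = {k: v.copy() for k, v in base_kwargs.items()}
            kw[field][axis] += 1e-6
            v = combined_metric(pts, vol, AffineTransform(dof=12, **kw), None, cfg)
            assert abs(v - base) < 1e-3
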