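"""Powell driver, rotation grid, refinement, perturbation and the cascade."""

import numpy as np
import pytest

from vesselreg.metric import MetricConfig
from vesselreg.optimize import (
    GridEntry,
    OptimizerConfig,
    build_rotation_grid,
    cascade_register,
    powell_maximize,
    refine_grid,
    score_grid,
    select_and_perturb,
)
from vesselreg.phantom import rasterize
from vesselreg.transform import AffineTransform

from conftest import straight_tube_forest


# ---------------------------------------------------------------------------
# powell_maximize
# ---------------------------------------------------------------------------

def test_powell_concave_quadratic():
    c = np.array([1.5, -2.0, 0.5])
    obj = lambda x: -float(np.sum((x - c) ** 2))  # noqa: E731
    p, v, trace = powell_maximize(obj, np.zeros(3), OptimizerConfig())
    assert np.allclose(p, c, atol=1e-4)
    assert np.all(np.diff(trace) >= 0)


def test_powell_constant_objective_returns_start():
    p, v, trace = powell_maximize(lambda x: 7.0, np.array([1.0, 2.0]),
                                  OptimizerConfig())
    assert v == 7.0
    assert np.allclose(p, [1.0, 2.0])


def test_powell_negated_rosenbrock():
    obj = lambda x: -((1 - x[0]) ** 2 + 100 * (x[1] - x[0] ** 2) ** 2)  # noqa: E731
    cfg = OptimizerConfig(powell_ftol=1e-12)
    p, v, trace = powell_maximize(obj, np.array([-1.2, 1.0]), cfg)
    assert np.allclose(p, [1.0, 1.0], atol=1e-3)
    assert np.all(np.diff(trace) >= 0)


def test_powell_nonfinite_start_errors():
    with pytest.raises(ValueError, match="finite"):
        powell_maximize(lambda x: float("nan"), np.zeros(2), OptimizerConfig())


# ---------------------------------------------------------------------------
# rotation grid
# ---------------------------------------------------------------------------

def test_grid_default_11_angles_per_axis():
    grid = build_rotation_grid(OptimizerConfig())
    for axis in range(3):
        vals = sorted({g[axis] for g in grid})
        assert vals == [float(a) for a in range(0, 33, 3)]
        assert len(vals) == 11


def test_grid_step_15():
    grid = build_rotation_grid(OptimizerConfig(rotation_step=15.0))
    vals = sorted({g[0] for g in grid})
    assert vals == [0.0, 15.0, 30.0]


def test_grid_step_larger_than_range():
    grid = build_rotation_grid(OptimizerConfig(rotation_step=45.0))
    assert len(grid) == 1
    assert np.allclose(grid[0], 0)


def test_grid_full_mode_1331_triples():
    grid = build_rotation_grid(OptimizerConfig(grid_mode="full"))
    assert len(grid) == 11 ** 3


def test_grid_coarse_mode_count():
    grid = build_rotation_grid(OptimizerConfig())
    assert len(grid) == 3 * 11 - 2


def test_grid_mirrored():
    grid = build_rotation_grid(OptimizerConfig(rotation_step=15.0,
                                               mirror_rotations=True))
    vals = sorted({g[2] for g in grid})
    assert vals == [-30.0, -15.0, 0.0, 15.0, 30.0]


# ---------------------------------------------------------------------------
# refine_grid
# ---------------------------------------------------------------------------

def _axis_sweep_entries(angles, scores, axis=0):
    out = []
    for a, s in zip(angles, scores):
        rot = np.zeros(3)
        rot[axis] = a
        out.append(GridEntry(rot, np.array([1.0, 0, 0, 0]), s))
    return out


def test_refine_doubles_axis_resolution():
    cfg = OptimizerConfig()
    angles = [float(a) for a in range(0, 33, 3)]
    scored = _axis_sweep_entries(angles, np.linspace(0, 1, 11))
    refined = refine_grid(scored, cfg)
    vals = sorted({e.rotation[0] for e in refined if np.all(e.rotation[1:] == 0)})
    assert len(vals) == 21  # 11 -> 21 after one refinement


def test_refine_inserts_neighbor_mean():
    cfg = OptimizerConfig()
    scored = _axis_sweep_entries([0.0, 3.0], [0.4, 0.6])
    refined = refine_grid(scored, cfg)
    mid = [e for e in refined if e.rotation[0] == 1.5]
    assert len(mid) == 1
    assert mid[0].score == pytest.approx(0.5)
    assert mid[0].kind == "interpolated"


def test_refine_keeps_original_scores():
    cfg = OptimizerConfig()
    scored = _axis_sweep_entries([0.0, 3.0, 6.0], [0.1, 0.9, 0.3])
    refined = refine_grid(scored, cfg)
    originals = {e.rotation[0]: e.score for e in refined if e.kind == "exact"}
    assert originals == {0.0: 0.1, 3.0: 0.9, 6.0: 0.3}


def test_refine_single_point_unchanged():
    cfg = OptimizerConfig()
    scored = _axis_sweep_entries([0.0], [0.5])
    assert refine_grid(scored, cfg) == scored


# ---------------------------------------------------------------------------
# select_and_perturb
# ---------------------------------------------------------------------------

def test_select_and_perturb_start_count():
    cfg = OptimizerConfig(n_best=1)
    scored = _axis_sweep_entries([0.0, 3.0], [0.9, 0.1])
    starts = select_and_perturb(scored, voxel_size=(0.7, 0.7, 0.7), config=cfg)
    assert len(starts) == 1 + 2 * 7  # unperturbed + 2 per parameter


def test_select_and_perturb_zero_magnitudes():
    cfg = OptimizerConfig(n_best=2)
    scored = _axis_sweep_entries([0.0, 3.0, 6.0], [0.9, 0.1, 0.5])
    starts = select_and_perturb(scored, voxel_size=(0.0, 0.0, 0.0), config=cfg)
    assert len(starts) == 2


def test_select_and_perturb_magnitudes():
    cfg = OptimizerConfig(n_best=1, brain_radius=75.0)
    scored = _axis_sweep_entries([0.0], [1.0])
    starts = select_and_perturb(scored, voxel_size=(0.5, 0.5, 0.7), config=cfg)
    base = starts[0]
    deltas = np.array([np.max(np.abs(s - base)) for s in starts[1:]])
    d_rot = np.degrees(np.arcsin(0.7 / 75.0))
    assert np.allclose(sorted(set(np.round(deltas, 12))),
                       sorted({d_rot, 0.7 / 75.0, 0.7}))


def test_select_tie_break_smaller_rotation_then_order():
    cfg = OptimizerConfig(n_best=1)
    e_big = GridEntry(np.array([30.0, 0, 0]), np.array([1.0, 0, 0, 0]), 0.5)
    e_small = GridEntry(np.array([3.0, 0, 0]), np.array([1.0, 0, 0, 0]), 0.5)
    starts = select_and_perturb([e_big, e_small], (0, 0, 0), cfg)
    assert starts[0][0] == 3.0  # smaller rotation wins the tie
    e_same1 = GridEntry(np.array([3.0, 0, 0]), np.array([1.0, 0, 0, 0]), 0.5)
    e_same2 = GridEntry(np.array([0, 3.0, 0]), np.array([2.0, 0, 0, 0]), 0.5)
    starts = select_and_perturb([e_same1, e_same2], (0, 0, 0), cfg)
    assert starts[0][3] == 1.0  # equal rotation magnitude: input order wins


def test_select_empty_grid_errors():
    with pytest.raises(ValueError, match="empty"):
        select_and_perturb([], (1, 1, 1), OptimizerConfig())


# ---------------------------------------------------------------------------
# score_grid / cascade
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def tube_instance():
    forest = straight_tube_forest(radius=1.5, length=12.0, n=15)
    vol = rasterize(forest, 0.7)
    seg = forest.segments[0]
    pts = (seg.positions, seg.radii, seg.tangents)
    anchor = seg.positions.mean(axis=0)
    return pts, vol, anchor


def test_score_grid_aligned_zero_rotation_wins(tube_instance, fast_config):
    pts, vol, anchor = tube_instance
    cfg = OptimizerConfig(rotation_step=15.0, grid_max_iter=2)
    grid = build_rotation_grid(cfg)
    scored = score_grid(grid, pts, vol, None, np.eye(4), anchor,
                        MetricConfig(), cfg)
    best = max(scored, key=lambda e: e.score)
    assert np.allclose(best.rotation, 0)


def test_score_grid_single_point_and_determinism(tube_instance):
    pts, vol, anchor = tube_instance
    cfg = OptimizerConfig(grid_max_iter=2)
    grid = [np.zeros(3)]
    s1 = score_grid(grid, pts, vol, None, np.eye(4), anchor, MetricConfig(), cfg)
    s2 = score_grid(grid, pts, vol, None, np.eye(4), anchor, MetricConfig(), cfg)
    assert len(s1) == 1
    assert s1[0].score == s2[0].score  # pure map, bit-identical


def test_cascade_identity_recovery(tube_instance, desk_config):
    """An already-aligned tube yields a near-identity transform."""
    pts, vol, anchor = tube_instance
    t, v, trace = cascade_register(pts, vol, None, np.eye(4), anchor,
                                   MetricConfig(), desk_config, final_dof=12)
    assert np.linalg.norm(t.translation) <= 1.0
    assert np.max(np.abs(t.rotation)) <= 2.0


def test_cascade_monotone_stages(tube_instance, desk_config):
    """The final 12-DOF value is at least the seeding 7-DOF value, which is
    at least its 4-DOF seed's value."""
    pts, vol, anchor = tube_instance
    t, v, trace = cascade_register(pts, vol, None, np.eye(4), anchor,
                                   MetricConfig(), desk_config, final_dof=12)
    grid_scores = [val for stage, _, val in trace if stage == "grid"]
    stage7 = [val for stage, _, val in trace if stage == "stage7"]
    stage12 = [val for stage, _, val in trace if stage == "stage12"]
    assert max(stage7) >= max(grid_scores) - 1e-9
    assert v >= max(stage7) - 1e-9
    assert stage12 == sorted(stage12)  # non-decreasing Powell trace


def test_cascade_beats_plain_powell(tube_instance, desk_config):
    """The multi-start cascade is at least as good as one plain 12-DOF
    Powell run from identity, on rotated instances."""
    pts, vol, anchor = tube_instance
    from vesselreg.optimize import _stage3_objective, _stage_bounds
    from vesselreg.metric import MetricEvaluator
    from vesselreg.transform import apply_matrix

    rng = np.random.default_rng(11)
    wins = 0
    for _ in range(3):
        rot = rng.uniform(-25, 25, 3)
        M = AffineTransform(dof=6, rotation=rot, anchor=anchor).to_matrix()
        moved = (apply_matrix(M, pts[0]), pts[1],
                 pts[2] @ M[:3, :3].T)
        t, v_cascade, _ = cascade_register(
            moved, vol, None, np.eye(4), anchor, MetricConfig(), desk_config,
            final_dof=12,
        )
        ev = MetricEvaluator(moved, vol, None, MetricConfig())
        obj = _stage3_objective(ev, anchor)
        start = np.concatenate([np.zeros(3), np.ones(3), np.zeros(3), np.zeros(3)])
        _, v_plain, _ = powell_maximize(
            obj, start, desk_config, bounds=_stage_bounds(desk_config, 3, False)
        )
        # within the stage tolerances the cascade never loses materially
        assert v_cascade >= v_plain - 1e-3
        wins += v_cascade >= v_plain - 1e-3
    assert wins == 3


def test_cascade_rigid_final_dof(tube_instance, desk_config):
    pts, vol, anchor = tube_instance
    t, v, trace = cascade_register(pts, vol, None, np.eye(4), anchor,
                                   MetricConfig(), desk_config, final_dof=6)
    assert t.dof == 6
    assert np.allclose(t.scale, 1.0)
    assert np.allclose(t.shear, 0.0)
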