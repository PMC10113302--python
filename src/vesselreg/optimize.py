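"""Multi-start, parameter-decoupled optimization cascade.

Affine registration is heavily dependent on rotation, so rotations are
resolved first: a rotation grid (0-30 deg in 3 deg steps per Euler axis by
default) spans starting points; at each grid point a 4-DOF Powell run finds
isotropic scale and translation; the grid is refined by interpolation; the
best candidates are perturbed per-parameter (magnitudes derived from brain
radius and voxel size) into starts for a 7-DOF Powell stage; the single
best 7-DOF result seeds the final 12-DOF optimization (anisotropic scale
and shear released).  Powell's conjugate-direction method is used
throughout with an initial step of 0.1 in each parameter's native unit
(degree, mm, unitless).

A rigid variant of the cascade (used for global initialization) locks scale
at 1 and finishes at 6 DOF instead of 12.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .metric import MetricConfig, MetricEvaluator
from .transform import AffineTransform, apply_matrix

__all__ = [
    "OptimizerConfig",
    "GridEntry",
    "powell_maximize",
    "build_rotation_grid",
    "score_grid",
    "refine_grid",
    "select_and_perturb",
    "cascade_register",
]

_BAD_VALUE = -1e12
_MIN_SCALE = 0.05


@dataclass
class OptimizerConfig:
    """Settings of the optimization cascade.

    rotation_range / rotation_step
        Per-axis rotation grid in degrees (default 0..30 in steps of 3,
        i.e. 11 values per axis).  ``mirror_rotations`` extends the grid
        symmetrically to [-range, range].
    grid_mode
        "coarse" varies one Euler axis at a time (3*11 - 2 grid points at
        defaults); "full" takes the Cartesian product (11^3 points).
    n_best
        Candidates kept after grid refinement (default 3).
    powell_step / powell_max_iter / powell_ftol
        Powell initial direction-set step, iteration cap and relative
        objective tolerance for the main (7/12-DOF) stages.
    grid_ftol / grid_max_iter
        Looser settings for the per-grid-point 4-DOF scoring runs, which
        only rank starting points.
    scale_bounds / shear_bounds
        Box constraints on scale and shear parameters during the 4/7/12-DOF
        stages.  Local refinements after the global initialization are
        expected to be modest; the bounds keep the anchored anisotropic
        stages away from the degenerate optimum of contracting a small
        subtree onto its (brighter, thicker) parent ridge.
    brain_radius
        Length scale (mm) used to derive rotation/scale perturbation
        magnitudes from the fixed volume's voxel size.
    """

    rotation_range: tuple[float, float] = (0.0, 30.0)
    rotation_step: float = 3.0
    mirror_rotations: bool = False
    grid_mode: str = "coarse"
    n_best: int = 3
    powell_step: float = 0.1
    powell_max_iter: int = 1000
    powell_ftol: float = 1e-6
    grid_ftol: float = 1e-3
    grid_max_iter: int = 50
    start_max_iter: int | None = None
    scale_bounds: tuple[float, float] = (0.8, 1.25)
    shear_bounds: tuple[float, float] = (-0.15, 0.15)
    brain_radius: float = 75.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rotation_step <= 0:
            raise ValueError("rotation_step must be > 0")
        if self.n_best < 1:
            raise ValueError("n_best must be >= 1")
        if self.powell_max_iter < 1:
            raise ValueError("powell_max_iter must be >= 1")
        if self.grid_mode not in ("coarse", "full"):
            raise ValueError(f"unknown grid_mode {self.grid_mode!r}")

    @classmethod
    def desk_scale(cls, seed: int = 0) -> "OptimizerConfig":
        """Reduced-cost profile used for the synthetic-phantom studies:
        a mirrored 15-degree rotation grid, one kept candidate and short
        multi-start Powell runs before the final full-length polish.  The
        cascade structure is unchanged."""
        return cls(
            rotation_step=15.0,
            mirror_rotations=True,
            n_best=1,
            grid_max_iter=1,
            grid_ftol=1e-2,
            start_max_iter=1,
            powell_max_iter=6,
            powell_ftol=1e-4,
            seed=seed,
        )

    def to_dict(self) -> dict:
        return {
            "rotation_range": list(self.rotation_range),
            "rotation_step": self.rotation_step,
            "mirror_rotations": self.mirror_rotations,
            "grid_mode": self.grid_mode,
            "n_best": self.n_best,
            "powell_step": self.powell_step,
            "powell_max_iter": self.powell_max_iter,
            "powell_ftol": self.powell_ftol,
            "grid_ftol": self.grid_ftol,
            "grid_max_iter": self.grid_max_iter,
            "start_max_iter": self.start_max_iter,
            "scale_bounds": list(self.scale_bounds),
            "shear_bounds": list(self.shear_bounds),
            "brain_radius": self.brain_radius,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "OptimizerConfig":
        d = dict(d)
        for key in ("rotation_range", "scale_bounds", "shear_bounds"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


# ---------------------------------------------------------------------------
# Powell driver
# ---------------------------------------------------------------------------

def powell_maximize(
    objective,
    start,
    config: OptimizerConfig,
    max_iter: int | None = None,
    ftol: float | None = None,
    bounds=None,
):
    """Maximize a scalar objective with Powell's conjugate-direction method.

    Runs scipy's Powell minimizer on the negated objective with the initial
    direction set scaled to ``powell_step``.  Returns ``(params, value,
    trace)`` where the trace records the best value seen so far at the
    start and after every Powell iteration (hence non-decreasing).
    """
    start = np.asarray(start, dtype=np.float64)
    f0 = float(objective(start))
    if not np.isfinite(f0):
        raise ValueError(f"objective is not finite at the start point: {f0}")

    best = {"params": start.copy(), "value": f0}

    def neg(x):
        v = float(objective(x))
        if np.isfinite(v) and v > best["value"]:
            best["value"] = v
            best["params"] = np.asarray(x, dtype=np.float64).copy()
        return -v if np.isfinite(v) else -_BAD_VALUE

    trace = [f0]

    def callback(_xk):
        trace.append(best["value"])

    n = len(start)
    minimize(
        neg,
        start,
        method="Powell",
        callback=callback,
        bounds=bounds,
        options={
            "maxiter": max_iter if max_iter is not None else config.powell_max_iter,
            "ftol": ftol if ftol is not None else config.powell_ftol,
            "xtol": 1e-6,
            "direc": config.powell_step * np.eye(n),
            "disp": False,
        },
    )
    trace.append(best["value"])
    return best["params"], best["value"], np.asarray(trace)


# ---------------------------------------------------------------------------
# Rotation grid
# ---------------------------------------------------------------------------

def _axis_angles(config: OptimizerConfig) -> np.ndarray:
    lo, hi = config.rotation_range
    if config.rotation_step > hi - lo:
        angles = np.array([0.0])
    else:
        angles = np.arange(lo, hi + 1e-9, config.rotation_step)
    if config.mirror_rotations:
        angles = np.unique(np.concatenate([-angles, angles]))
    return angles


def build_rotation_grid(config: OptimizerConfig) -> list[np.ndarray]:
    """Rotation triples (degrees) spanning the multi-start grid.

    "coarse" mode varies one Euler axis at a time (the origin appears
    once); "full" mode returns the Cartesian product of the per-axis angle
    sets.
    """
    angles = _axis_angles(config)
    if config.grid_mode == "full":
        return [
            np.array([a, b, c])
            for a in angles
            for b in angles
            for c in angles
        ]
    grid = [np.zeros(3)]
    for axis in range(3):
        for a in angles:
            if a == 0.0:
                continue
            rot = np.zeros(3)
            rot[axis] = a
            grid.append(rot)
    return grid


@dataclass
class GridEntry:
    """A scored rotation-grid point: the rotation, the 4-DOF parameters
    ([scale, tx, ty, tz]) found at it, the achieved metric, and whether the
    score is exact or refinement-interpolated."""

    rotation: np.ndarray
    params: np.ndarray
    score: float
    kind: str = "exact"


def _transform_points(parent_matrix, pos, tangents):
    M = np.asarray(parent_matrix, dtype=np.float64)
    tp = apply_matrix(M, pos)
    tt = tangents @ M[:3, :3].T
    tt /= np.linalg.norm(tt, axis=1, keepdims=True)
    return tp, tt


def _stage1_objective(evaluator, rotation, anchor, rigid):
    """4-DOF (iso scale + translation) or, for the rigid cascade,
    3-DOF (translation only) objective with the grid rotation held fixed."""
    if rigid:
        def obj(p):
            t = AffineTransform(
                dof=6, rotation=rotation, translation=p, anchor=anchor
            )
            return evaluator(t)
        start = np.zeros(3)
    else:
        def obj(p):
            if p[0] < _MIN_SCALE:
                return _BAD_VALUE * (1.0 + (_MIN_SCALE - p[0]))
            t = AffineTransform(
                dof=4,
                rotation=rotation,
                scale=np.full(3, p[0]),
                translation=p[1:4],
                anchor=anchor,
            )
            return evaluator(t)
        start = np.array([1.0, 0.0, 0.0, 0.0])
    return obj, start


_INF = (-np.inf, np.inf)


def _stage_bounds(config: OptimizerConfig, stage: int, rigid: bool):
    """Box constraints per cascade stage: scale and shear are bounded,
    rotations and translations are free."""
    if rigid:
        return None
    sb, hb = tuple(config.scale_bounds), tuple(config.shear_bounds)
    if stage == 1:  # [s, t3]
        return [sb, _INF, _INF, _INF]
    if stage == 2:  # [r3, s, t3]
        return [_INF] * 3 + [sb] + [_INF] * 3
    return [_INF] * 3 + [sb] * 3 + [hb] * 3 + [_INF] * 3  # [r3, s3, sh3, t3]


def _score_grid(grid, evaluator, anchor, config, rigid=False) -> list[GridEntry]:
    entries = []
    bounds = _stage_bounds(config, 1, rigid)
    for rot in grid:
        obj, start = _stage1_objective(evaluator, rot, anchor, rigid)
        params, value, _ = powell_maximize(
            obj, start, config, max_iter=config.grid_max_iter,
            ftol=config.grid_ftol, bounds=bounds,
        )
        if rigid:
            params = np.concatenate([[1.0], params])  # store as [s, t]
        entries.append(GridEntry(np.asarray(rot, float).copy(), params, value))
    return entries


def score_grid(
    grid,
    segment_points,
    volume,
    landmarks,
    parent_matrix,
    anchor,
    metric_config: MetricConfig,
    config: OptimizerConfig,
) -> list[GridEntry]:
    """For each grid rotation, optimize the remaining 4 DOF (isotropic
    scale + translation) of the anchored local transform and record the
    achieved combined metric."""
    if len(grid) == 0:
        raise ValueError("empty rotation grid")
    pos, radii, tangents = segment_points
    tp, tt = _transform_points(parent_matrix, pos, tangents)
    evaluator = MetricEvaluator((tp, radii, tt), volume, landmarks, metric_config)
    return _score_grid(grid, evaluator, np.asarray(anchor, float), config)


def refine_grid(scored: list[GridEntry], config: OptimizerConfig) -> list[GridEntry]:
    """Insert a grid point between each two adjacent ones along every
    rotation axis; inserted points get the arithmetic mean of their
    neighbors' scores (and parameters) without re-optimization.  Original
    entries keep their exact scores."""
    if len(scored) < 2:
        return list(scored)
    refined = list(scored)
    if config.grid_mode == "full":
        # refine each axis of the lattice; interpolate along that axis
        rots = np.array([e.rotation for e in scored])
        by_rot = {tuple(e.rotation): e for e in scored}
        for axis in range(3):
            vals = np.unique(rots[:, axis])
            mids = (vals[:-1] + vals[1:]) / 2.0
            new = []
            for e in list(refined):
                for lo, hi, mid in zip(vals[:-1], vals[1:], mids):
                    if e.rotation[axis] != lo:
                        continue
                    other_rot = e.rotation.copy()
                    other_rot[axis] = hi
                    other = by_rot.get(tuple(other_rot))
                    if other is None:
                        continue
                    rot = e.rotation.copy()
                    rot[axis] = mid
                    new.append(
                        GridEntry(
                            rot,
                            (e.params + other.params) / 2.0,
                            (e.score + other.score) / 2.0,
                            kind="interpolated",
                        )
                    )
            refined.extend(new)
            rots = np.array([e.rotation for e in refined])
            by_rot = {tuple(e.rotation): e for e in refined}
        return refined

    # coarse axis-wise grid: refine each 1D axis sweep (origin included)
    def axis_of(e):
        nz = np.nonzero(e.rotation)[0]
        return int(nz[0]) if len(nz) == 1 else None

    origin = [e for e in scored if np.all(e.rotation == 0)]
    for axis in range(3):
        sweep = [e for e in scored if axis_of(e) == axis] + origin
        sweep.sort(key=lambda e: e.rotation[axis])
        for a, b in zip(sweep[:-1], sweep[1:]):
            rot = np.zeros(3)
            rot[axis] = (a.rotation[axis] + b.rotation[axis]) / 2.0
            refined.append(
                GridEntry(
                    rot,
                    (a.params + b.params) / 2.0,
                    (a.score + b.score) / 2.0,
                    kind="interpolated",
                )
            )
    return refined


def select_and_perturb(
    refined: list[GridEntry],
    voxel_size,
    config: OptimizerConfig,
    rigid: bool = False,
) -> list[np.ndarray]:
    """Pick the ``n_best`` top-scoring grid entries and perturb every
    transformation parameter.

    Each candidate yields the unperturbed start plus two perturbed copies
    per parameter.  Magnitudes are derived from the fixed volume's voxel
    size v = max(voxel_size) and the brain radius R: translation +/- v mm,
    rotation +/- asin(v / R) (one-voxel displacement at brain-surface
    distance), scale +/- v / R.  Ties in score break toward smaller total
    rotation magnitude, then input order.

    Starts are 7-vectors [rx, ry, rz, s, tx, ty, tz] (6-vectors without s
    for the rigid cascade).
    """
    if not refined:
        raise ValueError("empty scored grid")
    order = sorted(
        range(len(refined)),
        key=lambda i: (
            -refined[i].score,
            float(np.sum(np.abs(refined[i].rotation))),
            i,
        ),
    )
    v = float(np.max(np.asarray(voxel_size, dtype=np.float64)))
    d_rot = float(np.degrees(np.arcsin(min(1.0, v / config.brain_radius))))
    d_scale = v / config.brain_radius
    starts = []
    for i in order[: config.n_best]:
        e = refined[i]
        if rigid:
            base = np.concatenate([e.rotation, e.params[1:4]])
            mags = np.array([d_rot, d_rot, d_rot, v, v, v])
        else:
            base = np.concatenate([e.rotation, e.params[:1], e.params[1:4]])
            mags = np.array([d_rot, d_rot, d_rot, d_scale, v, v, v])
        starts.append(base.copy())
        for j, m in enumerate(mags):
            if m == 0:
                continue
            for sgn in (1.0, -1.0):
                p = base.copy()
                p[j] += sgn * m
                starts.append(p)
    return starts


# ---------------------------------------------------------------------------
# Full cascade
# ---------------------------------------------------------------------------

def _stage2_objective(evaluator, anchor, rigid):
    if rigid:
        def obj(p):  # [r3, t3]
            t = AffineTransform(
                dof=6, rotation=p[:3], translation=p[3:6], anchor=anchor
            )
            return evaluator(t)
    else:
        def obj(p):  # [r3, s, t3]
            if p[3] < _MIN_SCALE:
                return _BAD_VALUE * (1.0 + (_MIN_SCALE - p[3]))
            t = AffineTransform(
                dof=7,
                rotation=p[:3],
                scale=np.full(3, p[3]),
                translation=p[4:7],
                anchor=anchor,
            )
            return evaluator(t)
    return obj


def _stage3_objective(evaluator, anchor):
    def obj(p):  # [r3, s3, sh3, t3]
        if np.min(p[3:6]) < _MIN_SCALE:
            return _BAD_VALUE * (1.0 + (_MIN_SCALE - float(np.min(p[3:6]))))
        t = AffineTransform(
            dof=12,
            rotation=p[:3],
            scale=p[3:6],
            shear=p[6:9],
            translation=p[9:12],
            anchor=anchor,
        )
        return evaluator(t)
    return obj


def cascade_register(
    segment_points,
    volume,
    landmarks,
    parent_matrix,
    anchor,
    metric_config: MetricConfig,
    config: OptimizerConfig,
    final_dof: int = 12,
):
    """Run the full decoupled cascade for one (sub)tree.

    ``segment_points`` is ``(positions, radii, tangents)`` in the original
    moving frame; ``parent_matrix`` (4x4) carries them into the current
    accumulated frame, and the returned local transform (anchored at
    ``anchor``) composes on top of it.  ``final_dof`` 12 runs the standard
    grid -> 4-DOF -> refine -> perturb -> 7-DOF -> 12-DOF cascade; 6 runs
    the rigid variant (scale locked at 1, no shear) used for global
    initialization.

    Returns ``(transform, value, trace)`` with ``trace`` a list of
    ``(stage, iteration, value)`` records.
    """
    if final_dof not in (6, 12):
        raise ValueError("final_dof must be 6 or 12")
    rigid = final_dof == 6
    pos, radii, tangents = segment_points
    if len(pos) == 0:
        raise ValueError("cascade needs at least one represented point")
    anchor = np.asarray(anchor, dtype=np.float64)
    tp, tt = _transform_points(parent_matrix, pos, tangents)
    evaluator = MetricEvaluator((tp, radii, tt), volume, landmarks, metric_config)

    trace: list[tuple[str, int, float]] = []

    grid = build_rotation_grid(config)
    scored = _score_grid(grid, evaluator, anchor, config, rigid=rigid)
    for i, e in enumerate(scored):
        trace.append(("grid", i, e.score))
    refined = refine_grid(scored, config)
    starts = select_and_perturb(refined, volume.spacing, config, rigid=rigid)

    stage2 = _stage2_objective(evaluator, anchor, rigid)
    b2 = _stage_bounds(config, 2, rigid)
    best_params, best_value = None, -np.inf
    n_bad = 0
    for i, s in enumerate(starts):
        if not np.isfinite(stage2(s)):
            n_bad += 1
            continue
        if b2 is not None:  # clip perturbed starts into the box
            s = np.clip(s, [b[0] for b in b2], [b[1] for b in b2])
        p, v, tr = powell_maximize(
            stage2, s, config, max_iter=config.start_max_iter, bounds=b2
        )
        trace.append(("stage7" if not rigid else "stage6", i, v))
        if v > best_value:
            best_params, best_value = p, v
    if best_params is None:
        raise ValueError(f"all {n_bad} cascade starts gave non-finite objectives")

    if rigid:
        # full-length polish of the winning start
        best_params, best_value, tr = powell_maximize(
            stage2, best_params, config, bounds=b2
        )
        for i, v in enumerate(tr):
            trace.append(("stage6_polish", i, float(v)))
        t = AffineTransform(
            dof=6,
            rotation=best_params[:3],
            translation=best_params[3:6],
            anchor=anchor,
        )
        return t, best_value, trace

    start12 = np.concatenate(
        [
            best_params[:3],
            np.full(3, best_params[3]),
            np.zeros(3),
            best_params[4:7],
        ]
    )
    stage3 = _stage3_objective(evaluator, anchor)
    p12, v12, tr12 = powell_maximize(
        stage3, start12, config, bounds=_stage_bounds(config, 3, rigid=False)
    )
    for i, v in enumerate(tr12):
        trace.append(("stage12", i, float(v)))
    t = AffineTransform(
        dof=12,
        rotation=p12[:3],
        scale=p12[3:6],
        shear=p12[6:9],
        translation=p12[9:12],
        anchor=anchor,
    )
    return t, v12, trace
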