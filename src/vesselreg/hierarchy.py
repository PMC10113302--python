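"""Root-to-leaf hierarchical registration with the representation concept.

Segments large enough to be visible in the coarse fixed volume are marked
*represented*; only their points enter the metric.  After a global rigid
initialization over all represented points, the forest is traversed
breadth-first from the roots: at every represented segment the full
cascade optimizes a local affine transform of the subtree rooted there
(anchored at the branch point shared with the parent, so the tree stays
connected), and the result composes onto the accumulated transform of the
whole subtree.  Non-represented segments are never optimized — they
inherit their ancestors' accumulated transforms exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import IntensityVolume, LandmarkSet, VesselForest
from .metric import MetricConfig, _interp_by_level, _radius_weights
from .optimize import OptimizerConfig, cascade_register
from .transform import AffineTransform, apply_matrix, child_anchor

__all__ = [
    "RegistrationResult",
    "assign_representation",
    "global_initialize",
    "hierarchical_register",
]


@dataclass
class RegistrationResult:
    """Per-segment transforms and diagnostics of a hierarchical run."""

    local: dict[int, AffineTransform]
    accumulated: dict[int, np.ndarray]
    global_transform: AffineTransform
    metric_values: dict[int, float]
    traces: dict
    final_metric: float
    initial_errors: dict | None = None
    final_errors: dict | None = None
    config: dict = field(default_factory=dict)

    def transformed_forest(self, forest: VesselForest) -> VesselForest:
        """The moving forest with every segment's accumulated transform
        applied."""
        out = forest.copy()
        for sid, seg in out.segments.items():
            M = self.accumulated[sid]
            seg.positions = apply_matrix(M, seg.positions)
            t = seg.tangents @ M[:3, :3].T
            seg.tangents = t / np.linalg.norm(t, axis=1, keepdims=True)
        return out

    def to_dict(self) -> dict:
        return {
            "global_transform": self.global_transform.to_dict(),
            "local": {str(k): v.to_dict() for k, v in self.local.items()},
            "accumulated": {str(k): v.tolist() for k, v in self.accumulated.items()},
            "metric_values": {str(k): v for k, v in self.metric_values.items()},
            "final_metric": self.final_metric,
            "initial_errors": self.initial_errors,
            "final_errors": self.final_errors,
            "config": self.config,
        }


def assign_representation(
    forest: VesselForest, pc_spacing, factor: float = 1.0
) -> VesselForest:
    """Mark segments visible in the coarse fixed volume.

    A segment is represented when its median point radius is at least
    ``factor * max(pc_spacing)``; visibility is determined by vessel size.
    Roots are always represented (with a warning if below threshold).
    Modifies the forest in place and returns it.
    """
    threshold = factor * float(np.max(np.asarray(pc_spacing, dtype=np.float64)))
    for sid, seg in forest.segments.items():
        seg.represented = seg.median_radius >= threshold
    for rid in forest.root_ids:
        if not forest.segments[rid].represented:
            warnings.warn(
                f"root segment {rid} has median radius below the "
                f"representation threshold {threshold:.3g} mm; forcing it "
                "represented",
                stacklevel=2,
            )
            forest.segments[rid].represented = True
    return forest


def _nearest_segment_ids(forest: VesselForest, points: np.ndarray) -> np.ndarray:
    """Assign each point to the segment with the nearest centerline point
    (in the original moving frame)."""
    pos, _, _, sids = forest.all_points()
    out = np.empty(len(points), dtype=int)
    for i, p in enumerate(np.atleast_2d(points)):
        d = np.linalg.norm(pos - p[None, :], axis=1)
        out[i] = sids[int(np.argmin(d))]
    return out


def _represented_points(forest: VesselForest, sids):
    ps, rs, ts, owner = [], [], [], []
    for sid in sids:
        seg = forest.segments[sid]
        if not seg.represented:
            continue
        ps.append(seg.positions)
        rs.append(seg.radii)
        ts.append(seg.tangents)
        owner.append(np.full(len(seg), sid))
    if not ps:
        return None
    return (
        np.concatenate(ps),
        np.concatenate(rs),
        np.concatenate(ts),
        np.concatenate(owner),
    )


def global_initialize(
    forest: VesselForest,
    volume: IntensityVolume,
    landmarks: LandmarkSet | None,
    metric_config: MetricConfig,
    config: OptimizerConfig,
) -> AffineTransform:
    """Rigid (6-DOF) initialization: one cascade restricted to rotation +
    translation over all represented points jointly, anchored at their
    centroid."""
    pts = _represented_points(forest, sorted(forest.segments))
    if pts is None:
        raise ValueError("no represented segments; run assign_representation")
    pos, radii, tangents, _ = pts
    anchor = pos.mean(axis=0)
    t, _value, _trace = cascade_register(
        (pos, radii, tangents),
        volume,
        landmarks,
        np.eye(4),
        anchor,
        metric_config,
        config,
        final_dof=6,
    )
    return t


def _forest_metric(forest, accumulated, volume, metric_config) -> float:
    """Weighted-mean intensity (m1) over all represented points, each
    carried by its segment's accumulated matrix."""
    num, den = 0.0, 0.0
    for sid, seg in forest.segments.items():
        if not seg.represented:
            continue
        w = _radius_weights(seg.radii, metric_config)
        tp = apply_matrix(accumulated[sid], seg.positions)
        vals = _interp_by_level(
            volume, tp, metric_config.kappa * seg.radii, metric_config.oob_intensity
        )
        num += float(np.sum(w * vals))
        den += float(np.sum(w))
    return num / den


def hierarchical_register(
    forest: VesselForest,
    volume: IntensityVolume,
    guidance: LandmarkSet | None = None,
    validation: LandmarkSet | None = None,
    metric_config: MetricConfig | None = None,
    config: OptimizerConfig | None = None,
) -> RegistrationResult:
    """Register a vessel forest to the intensity ridges of a volume.

    Runs :func:`global_initialize`, then traverses the forest breadth-first
    from the roots (siblings by descending median radius).  At each
    represented segment, the cascade optimizes a local transform evaluated
    on the represented points of the subtree rooted there, anchored at the
    parent's transformed branch point; the local transform composes onto
    the accumulated matrices of the whole subtree.  Guidance landmarks are
    assigned to the nearest segment and travel with it; validation
    landmarks are only used for before/after error reporting.
    """
    from .evaluation import hausdorff, landmark_mse  # local import: no cycle

    metric_config = metric_config or MetricConfig()
    config = config or OptimizerConfig()
    if not any(s.represented for s in forest.segments.values()):
        raise ValueError("forest has zero represented segments")

    guid_sids = (
        _nearest_segment_ids(forest, guidance.moving)
        if guidance is not None and len(guidance)
        else None
    )
    val_sids = (
        _nearest_segment_ids(forest, validation.moving)
        if validation is not None and len(validation)
        else None
    )

    initial_errors = None
    if val_sids is not None:
        initial_errors = {
            "mse": landmark_mse(validation, np.eye(4)),
            "hd": hausdorff(validation.moving, validation.fixed),
        }

    g = global_initialize(forest, volume, guidance, metric_config, config)
    G = g.to_matrix()
    accumulated = {sid: G.copy() for sid in forest.segments}
    local: dict[int, AffineTransform] = {
        sid: AffineTransform.identity(dof=12) for sid in forest.segments
    }
    metric_values: dict[int, float] = {}
    traces: dict = {"global": None}

    for sid in forest.traversal_order():
        seg = forest.segments[sid]
        if not seg.represented:
            continue  # transformed with its parent only
        subtree = forest.subtree_ids(sid)
        pts = _represented_points(forest, subtree)
        pos, radii, tangents, _owner = pts
        parent_matrix = accumulated[sid]
        if seg.parent_id is None:
            anchor = apply_matrix(parent_matrix, seg.positions).mean(axis=0)
        else:
            anchor = child_anchor(seg, accumulated[seg.parent_id])
        lm = None
        if guid_sids is not None:
            in_subtree = np.isin(guid_sids, subtree)
            if np.any(in_subtree):
                lm = LandmarkSet(
                    apply_matrix(parent_matrix, guidance.moving[in_subtree]),
                    guidance.fixed[in_subtree],
                    [guidance.labels[i] for i in np.where(in_subtree)[0]],
                    role="guidance",
                )
        t, value, tr = cascade_register(
            (pos, radii, tangents),
            volume,
            lm,
            parent_matrix,
            anchor,
            metric_config,
            config,
            final_dof=12,
        )
        L = t.to_matrix()
        for tid in subtree:
            accumulated[tid] = L @ accumulated[tid]
        local[sid] = t
        metric_values[sid] = value
        traces[sid] = tr

    final_metric = _forest_metric(forest, accumulated, volume, metric_config)

    final_errors = None
    if val_sids is not None:
        moved = np.array(
            [
                apply_matrix(accumulated[val_sids[i]], validation.moving[i])
                for i in range(len(validation))
            ]
        )
        d = moved - validation.fixed
        final_errors = {
            "mse": float(np.mean(np.sum(d * d, axis=1))),
            "hd": hausdorff(moved, validation.fixed),
        }

    return RegistrationResult(
        local=local,
        accumulated=accumulated,
        global_transform=g,
        metric_values=metric_values,
        traces=traces,
        final_metric=final_metric,
        initial_errors=initial_errors,
        final_errors=final_errors,
        config={
            "metric": metric_config.to_dict(),
            "optimizer": config.to_dict(),
        },
    )
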