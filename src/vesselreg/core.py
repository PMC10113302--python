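"""Core domain types: volumes, centerlines, vessel forests and landmarks.

All registration math lives in world millimetres.  The internal world frame
is axis-aligned LPS; file readers convert on the way in.  Voxel indices are
0-based and refer to voxel centers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

__all__ = [
    "IntensityVolume",
    "CenterlinePoint",
    "VesselSegment",
    "VesselForest",
    "LandmarkSet",
    "compute_tangents",
    "split_at_branchpoints",
    "build_forest",
]

# Tolerance for deciding two segment endpoints are the same branch point (mm).
NODE_MATCH_TOL = 1e-6


# ---------------------------------------------------------------------------
# Volumes
# ---------------------------------------------------------------------------

@dataclass
class IntensityVolume:
    """A 3D scalar image with world geometry.

    Parameters
    ----------
    data
        3D array of intensities, indexed ``data[i, j, k]``.
    spacing
        Per-axis voxel size in mm, all components > 0.
    origin
        World position (mm) of the center of voxel (0, 0, 0).
    direction
        3x3 direction-cosine matrix mapping voxel axes to world axes.
        Defaults to identity (axis-aligned).
    """

    data: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray = None  # type: ignore[assignment]
    direction: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"volume data must be 3D, got shape {self.data.shape}")
        if min(self.data.shape) < 2:
            raise ValueError("volume must have at least 2 voxels per axis")
        self.spacing = np.asarray(self.spacing, dtype=np.float64).reshape(3)
        if np.any(self.spacing <= 0):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        if self.origin is None:
            self.origin = np.zeros(3)
        self.origin = np.asarray(self.origin, dtype=np.float64).reshape(3)
        if self.direction is None:
            self.direction = np.eye(3)
        self.direction = np.asarray(self.direction, dtype=np.float64).reshape(3, 3)
        if abs(np.linalg.det(self.direction)) < 1e-12:
            raise ValueError("direction matrix is singular")
        self._inv_direction = np.linalg.inv(self.direction)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def affine(self) -> np.ndarray:
        """4x4 homogeneous voxel->world map (voxel centers)."""
        A = np.eye(4)
        A[:3, :3] = self.direction * self.spacing[None, :]
        A[:3, 3] = self.origin
        return A

    def world_to_voxel(self, points: np.ndarray) -> np.ndarray:
        """Map world coordinates (mm) to continuous voxel coordinates.

        Out-of-grid coordinates are returned as-is; boundedness is the
        caller's concern.
        """
        p = np.asarray(points, dtype=np.float64)
        return ((p - self.origin) @ self._inv_direction.T) / self.spacing

    def voxel_to_world(self, voxels: np.ndarray) -> np.ndarray:
        v = np.asarray(voxels, dtype=np.float64)
        return (v * self.spacing) @ self.direction.T + self.origin

    def same_geometry(self, other: "IntensityVolume", tol: float = 1e-9) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
            and np.allclose(self.direction, other.direction, atol=tol)
        )


# ---------------------------------------------------------------------------
# Centerlines
# ---------------------------------------------------------------------------

@dataclass
class CenterlinePoint:
    """A centerline sample: position (mm), maximum-inscribed-sphere radius
    (mm) and unit tangent."""

    position: np.ndarray
    radius: float
    tangent: np.ndarray

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=np.float64).reshape(3)
        self.tangent = np.asarray(self.tangent, dtype=np.float64).reshape(3)
        if self.radius <= 0:
            raise ValueError(f"radius must be positive, got {self.radius}")
        n = np.linalg.norm(self.tangent)
        if abs(n - 1.0) > 1e-9:
            raise ValueError(f"tangent must be unit length, |t| = {n}")


def compute_tangents(positions: np.ndarray) -> np.ndarray:
    """Unit tangents along a polyline by central differences (one-sided at
    the ends)."""
    p = np.asarray(positions, dtype=np.float64)
    if len(p) < 2:
        raise ValueError("need at least 2 points for tangents")
    t = np.empty_like(p)
    t[1:-1] = p[2:] - p[:-2]
    t[0] = p[1] - p[0]
    t[-1] = p[-1] - p[-2]
    norms = np.linalg.norm(t, axis=1, keepdims=True)
    if np.any(norms < 1e-12):
        raise ValueError("degenerate tangent: consecutive points coincide")
    return t / norms


@dataclass
class VesselSegment:
    """An ordered run of centerline points between branch points.

    Points are stored as parallel arrays for vectorized math; the
    ``points`` property exposes them as :class:`CenterlinePoint` objects.
    ``represented`` marks whether the segment is large enough to be visible
    in the low-resolution fixed volume and hence counted in the metric; it
    is set by ``assign_representation`` before registration.
    """

    id: int
    positions: np.ndarray
    radii: np.ndarray
    tangents: np.ndarray = None  # type: ignore[assignment]
    parent_id: int | None = None
    child_ids: list[int] = field(default_factory=list)
    represented: bool = False

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.float64).reshape(-1, 3)
        self.radii = np.asarray(self.radii, dtype=np.float64).reshape(-1)
        if len(self.positions) < 2:
            raise ValueError(f"segment {self.id}: needs at least 2 points")
        if len(self.radii) != len(self.positions):
            raise ValueError(f"segment {self.id}: radii/positions length mismatch")
        if np.any(self.radii <= 0):
            raise ValueError(f"segment {self.id}: radii must be positive")
        steps = np.linalg.norm(np.diff(self.positions, axis=0), axis=1)
        if np.any(steps < 1e-12):
            raise ValueError(f"segment {self.id}: consecutive points coincide")
        if self.tangents is None:
            self.tangents = compute_tangents(self.positions)
        self.tangents = np.asarray(self.tangents, dtype=np.float64).reshape(-1, 3)

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def points(self) -> list[CenterlinePoint]:
        return [
            CenterlinePoint(p, r, t)
            for p, r, t in zip(self.positions, self.radii, self.tangents)
        ]

    @property
    def first_point(self) -> np.ndarray:
        return self.positions[0]

    @property
    def last_point(self) -> np.ndarray:
        return self.positions[-1]

    @property
    def median_radius(self) -> float:
        return float(np.median(self.radii))

    def reversed(self) -> "VesselSegment":
        return VesselSegment(
            id=self.id,
            positions=self.positions[::-1].copy(),
            radii=self.radii[::-1].copy(),
            tangents=-self.tangents[::-1].copy(),
            parent_id=self.parent_id,
            child_ids=list(self.child_ids),
            represented=self.represented,
        )

    def copy(self) -> "VesselSegment":
        return VesselSegment(
            id=self.id,
            positions=self.positions.copy(),
            radii=self.radii.copy(),
            tangents=self.tangents.copy(),
            parent_id=self.parent_id,
            child_ids=list(self.child_ids),
            represented=self.represented,
        )


@dataclass
class VesselForest:
    """Vessel segments organized as a forest: roots are inlets, leaves are
    outlets, and every non-root segment has exactly one parent."""

    segments: dict[int, VesselSegment]
    root_ids: list[int]

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for rid in self.root_ids:
            if rid not in self.segments:
                raise ValueError(f"root id {rid} not in segments")
            if self.segments[rid].parent_id is not None:
                raise ValueError(f"root {rid} has a parent")
        for sid, seg in self.segments.items():
            if seg.id != sid:
                raise ValueError(f"segment key {sid} != segment.id {seg.id}")
            for cid in seg.child_ids:
                if cid not in self.segments:
                    raise ValueError(f"segment {sid}: unknown child {cid}")
                if self.segments[cid].parent_id != sid:
                    raise ValueError(f"child {cid} does not point back to {sid}")
            if seg.parent_id is not None:
                if seg.parent_id not in self.segments:
                    raise ValueError(f"segment {sid}: unknown parent {seg.parent_id}")
                if sid not in self.segments[seg.parent_id].child_ids:
                    raise ValueError(f"parent {seg.parent_id} does not list child {sid}")
            if seg.parent_id is None and sid not in self.root_ids:
                raise ValueError(f"segment {sid} has no parent and is not a root")
        # acyclic: every segment reachable from exactly one root, no revisits
        seen: set[int] = set()
        for rid in self.root_ids:
            stack = [rid]
            while stack:
                sid = stack.pop()
                if sid in seen:
                    raise ValueError(f"cycle or shared subtree at segment {sid}")
                seen.add(sid)
                stack.extend(self.segments[sid].child_ids)
        if seen != set(self.segments):
            orphans = sorted(set(self.segments) - seen)
            raise ValueError(f"segments unreachable from any root: {orphans}")

    def subtree_ids(self, seg_id: int) -> list[int]:
        """All segment ids in the subtree rooted at ``seg_id`` (inclusive),
        breadth-first."""
        out, queue = [], [seg_id]
        while queue:
            sid = queue.pop(0)
            out.append(sid)
            queue.extend(self.segments[sid].child_ids)
        return out

    def traversal_order(self) -> list[int]:
        """Breadth-first root-to-leaf order; siblings by descending median
        radius, ties by id."""
        order: list[int] = []
        level = sorted(
            self.root_ids, key=lambda s: (-self.segments[s].median_radius, s)
        )
        queue = list(level)
        while queue:
            sid = queue.pop(0)
            order.append(sid)
            kids = sorted(
                self.segments[sid].child_ids,
                key=lambda s: (-self.segments[s].median_radius, s),
            )
            queue.extend(kids)
        return order

    def all_points(self, represented_only: bool = False):
        """Concatenated (positions, radii, tangents, segment_ids) arrays."""
        ps, rs, ts, ids = [], [], [], []
        for sid, seg in sorted(self.segments.items()):
            if represented_only and not seg.represented:
                continue
            ps.append(seg.positions)
            rs.append(seg.radii)
            ts.append(seg.tangents)
            ids.append(np.full(len(seg), sid))
        if not ps:
            empty = np.empty((0, 3))
            return empty, np.empty(0), empty.copy(), np.empty(0, dtype=int)
        return (
            np.concatenate(ps),
            np.concatenate(rs),
            np.concatenate(ts),
            np.concatenate(ids),
        )

    def copy(self) -> "VesselForest":
        return VesselForest(
            segments={sid: seg.copy() for sid, seg in self.segments.items()},
            root_ids=list(self.root_ids),
        )


# ---------------------------------------------------------------------------
# Landmarks
# ---------------------------------------------------------------------------

@dataclass
class LandmarkSet:
    """Paired landmarks (moving, fixed) in world mm.

    ``role`` is "guidance" (enters the optimized objective) or "validation"
    (held out for error measurement); the two sets must be disjoint.
    """

    moving: np.ndarray
    fixed: np.ndarray
    labels: list[str] = None  # type: ignore[assignment]
    role: str = "validation"

    def __post_init__(self) -> None:
        self.moving = np.asarray(self.moving, dtype=np.float64).reshape(-1, 3)
        self.fixed = np.asarray(self.fixed, dtype=np.float64).reshape(-1, 3)
        if len(self.moving) != len(self.fixed):
            raise ValueError("moving/fixed landmark counts differ")
        if self.labels is None:
            self.labels = [f"L{i}" for i in range(len(self.moving))]
        if len(self.labels) != len(self.moving):
            raise ValueError("label count mismatch")
        if self.role not in ("guidance", "validation"):
            raise ValueError(f"unknown landmark role {self.role!r}")

    def __len__(self) -> int:
        return len(self.moving)

    def copy(self) -> "LandmarkSet":
        return LandmarkSet(
            self.moving.copy(), self.fixed.copy(), list(self.labels), self.role
        )


# ---------------------------------------------------------------------------
# Centerline graph -> segments
# ---------------------------------------------------------------------------

def split_at_branchpoints(
    positions: np.ndarray,
    radii: np.ndarray,
    edges,
) -> list[VesselSegment]:
    """Split a centerline graph into segments at its branching points.

    Each returned segment is a maximal path whose interior points have
    degree 2; endpoints are branch points (degree >= 3), inlets or outlets
    (degree 1).  Branch points are duplicated into each incident segment.

    Parameters
    ----------
    positions, radii
        Per-node world coordinates (mm) and maximum-inscribed-sphere radii.
    edges
        Iterable of (i, j) node-index pairs.
    """
    positions = np.asarray(positions, dtype=np.float64).reshape(-1, 3)
    radii = np.asarray(radii, dtype=np.float64).reshape(-1)
    if len(positions) == 0:
        raise ValueError("empty centerline graph")

    g = nx.Graph()
    g.add_nodes_from(range(len(positions)))
    g.add_edges_from(edges)
    isolated = [n for n in g.nodes if g.degree(n) == 0]
    if isolated:
        raise ValueError(f"isolated centerline points: {isolated}")

    terminals = [n for n in g.nodes if g.degree(n) != 2]
    if not terminals:
        raise ValueError(
            "centerline graph has no endpoints or branch points "
            "(pure cycle); cut it before splitting"
        )

    segments: list[VesselSegment] = []
    visited_edges: set[frozenset[int]] = set()
    for start in sorted(terminals):
        for nb in sorted(g.neighbors(start)):
            e = frozenset((start, nb))
            if e in visited_edges:
                continue
            path = [start, nb]
            visited_edges.add(e)
            while g.degree(path[-1]) == 2:
                prev, cur = path[-2], path[-1]
                nxt = next(n for n in g.neighbors(cur) if n != prev)
                visited_edges.add(frozenset((cur, nxt)))
                path.append(nxt)
            segments.append(
                VesselSegment(
                    id=len(segments),
                    positions=positions[path],
                    radii=radii[path],
                )
            )
    if len(visited_edges) != g.number_of_edges():
        # edges only reachable through all-degree-2 cycles attached nowhere
        raise ValueError("centerline graph contains an unreachable cycle")
    return segments


# ---------------------------------------------------------------------------
# Segments -> forest
# ---------------------------------------------------------------------------

def _node_key(p: np.ndarray) -> tuple[int, int, int]:
    return tuple(np.round(np.asarray(p) / NODE_MATCH_TOL).astype(np.int64))


def build_forest(
    segments: list[VesselSegment],
    root_segment_ids: list[int],
    cut_segment_ids: list[int] | None = None,
) -> VesselForest:
    """Assemble segments sharing endpoints into a forest of vessel trees.

    ``cut_segment_ids`` name segments (communicating-artery analogues) whose
    attachment at the root-farther endpoint is severed so that anatomical
    cycles are eliminated; the segments themselves are retained as children
    on their root-nearer side.  Non-root segments are re-oriented so their
    first point is the branch point shared with the parent.

    Raises
    ------
    ValueError
        If a cycle remains after the declared cuts (the error names the
        segment ids on the cycle).
    """
    cut_ids = set(cut_segment_ids or [])
    by_id = {s.id: s.copy() for s in segments}
    if len(by_id) != len(segments):
        raise ValueError("duplicate segment ids")
    for rid in root_segment_ids:
        if rid not in by_id:
            raise ValueError(f"unknown root segment id {rid}")
    for cid in cut_ids:
        if cid not in by_id:
            raise ValueError(f"unknown cut segment id {cid}")

    # endpoint-node incidence
    incident: dict[tuple, list[int]] = {}
    for s in by_id.values():
        for p in (s.first_point, s.last_point):
            incident.setdefault(_node_key(p), []).append(s.id)

    # cycles among non-cut segments can never be broken by the cuts
    check = nx.MultiGraph()
    for s in by_id.values():
        if s.id in cut_ids:
            continue
        check.add_edge(_node_key(s.first_point), _node_key(s.last_point), sid=s.id)
    try:
        cyc = nx.find_cycle(check)
    except nx.NetworkXNoCycle:
        cyc = None
    if cyc is not None:
        sids = sorted({check.edges[e]["sid"] for e in cyc})
        raise ValueError(f"cycle remains after cuts through segments {sids}")

    parent: dict[int, int | None] = {}
    entry_node: dict[int, tuple | None] = {}
    queue: list[int] = []
    for rid in root_segment_ids:
        parent[rid] = None
        entry_node[rid] = None
        queue.append(rid)

    while queue:
        sid = queue.pop(0)
        seg = by_id[sid]
        ends = [_node_key(seg.first_point), _node_key(seg.last_point)]
        if entry_node[sid] is None:
            exits = ends
        else:
            exits = [n for n in ends if n != entry_node[sid]]
            if sid in cut_ids:
                exits = []  # severed at the root-farther endpoint
        for node in exits:
            for tid in incident.get(node, []):
                if tid == sid:
                    continue
                if tid in parent:
                    if tid in cut_ids:
                        continue  # severed attachment of the cut segment
                    raise ValueError(
                        f"cycle remains after cuts: segment {tid} reachable "
                        f"from both {parent[tid]} and {sid}"
                    )
                parent[tid] = sid
                entry_node[tid] = node
                queue.append(tid)

    unreached = sorted(set(by_id) - set(parent))
    if unreached:
        raise ValueError(
            f"segments unreachable from the declared roots: {unreached}"
        )

    # orient children so their first point is the shared branch point
    for sid, seg in list(by_id.items()):
        node = entry_node[sid]
        if node is not None and _node_key(seg.first_point) != node:
            by_id[sid] = seg.reversed()

    for sid, seg in by_id.items():
        seg.parent_id = parent[sid]
        seg.child_ids = []
    for sid, pid in parent.items():
        if pid is not None:
            by_id[pid].child_ids.append(sid)
    for seg in by_id.values():
        seg.child_ids.sort()

    return VesselForest(segments=by_id, root_ids=list(root_segment_ids))
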