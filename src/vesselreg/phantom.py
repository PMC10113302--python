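"""Synthetic vascular phantoms: bifurcating trees with paired high- and
low-resolution volumes and ground-truth deformations.

A phantom emulates the paired data the registration is built for: a
high-resolution angiography-like scan (fine spacing, low noise) from which
the centerline model originates, and a lower-resolution flow-magnitude-like
scan (coarse spacing, extra blur and noise) whose intensity ridges are the
registration target.  Vessel cross-sections are Gaussian, so the rasterized
centerline is an intensity ridge by construction, and child radii at each
bifurcation follow Murray's law r_p^g = r_c1^g + r_c2^g.

The moving object is always the centerline (points), so Monte-Carlo
deformations are applied analytically to points — never by resampling a
volume.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .core import IntensityVolume, LandmarkSet, VesselForest, VesselSegment
from .transform import AffineTransform

__all__ = [
    "PhantomBundle",
    "generate_tree",
    "rasterize",
    "make_bundle",
    "sample_deformation",
    "deform_forest",
    "temporal_mip",
    "RigidDeformation",
    "SmoothFieldDeformation",
]

MIN_BRANCH_RADIUS = 0.05  # mm; thinner branches are truncated


# ---------------------------------------------------------------------------
# Tree generation
# ---------------------------------------------------------------------------

def _perp_basis(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    helper = np.zeros(3)
    helper[int(np.argmin(np.abs(d)))] = 1.0
    u = np.cross(d, helper)
    u /= np.linalg.norm(u)
    return u, np.cross(d, u)


def _segment_polyline(
    start: np.ndarray,
    direction: np.ndarray,
    length: float,
    radius: float,
    tortuosity: float,
    point_step: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Smooth polyline: a straight run plus a low-frequency sinusoidal
    lateral sweep of amplitude ``tortuosity * radius``."""
    n = max(3, int(np.ceil(length / point_step)) + 1)
    s = np.linspace(0.0, length, n)
    u, v = _perp_basis(direction)
    phase = rng.uniform(0, 2 * np.pi)
    cycles = rng.uniform(0.5, 1.5)
    amp = tortuosity * radius
    # zero lateral offset at both ends keeps branch points shared exactly
    sweep = amp * np.sin(np.pi * s / length) * np.sin(
        2 * np.pi * cycles * s / length + phase
    )
    sweep2 = amp * np.sin(np.pi * s / length) * np.cos(
        2 * np.pi * cycles * s / length + phase
    )
    return (
        start[None, :]
        + s[:, None] * direction[None, :]
        + sweep[:, None] * u[None, :]
        + sweep2[:, None] * v[None, :]
    )


def generate_tree(
    seed: int,
    depth: int = 3,
    root_radius: float = 2.0,
    murray_exponent: float = 3.0,
    tortuosity: float = 0.3,
    length_factor: float = 5.0,
    point_step: float = 0.75,
    asymmetry_range: tuple[float, float] = (0.45, 0.55),
) -> VesselForest:
    """Recursive bifurcating vessel tree with Murray-law radii.

    ``depth`` counts segment generations (depth 1 is a single unbranched
    segment).  Segment length is ``length_factor`` times its radius; radii
    are constant along a segment and split at bifurcations as
    r_p^g = r_c1^g + r_c2^g with g = ``murray_exponent``.  Branches whose
    radius would fall below 0.05 mm are truncated.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if root_radius <= 0:
        raise ValueError("root_radius must be positive")
    rng = np.random.default_rng(seed)
    segments: dict[int, VesselSegment] = {}
    next_id = [0]

    def grow(start, direction, radius, level, parent_id):
        sid = next_id[0]
        next_id[0] += 1
        length = length_factor * radius
        pos = _segment_polyline(
            start, direction, length, radius, tortuosity, point_step, rng
        )
        seg = VesselSegment(
            id=sid,
            positions=pos,
            radii=np.full(len(pos), radius),
            parent_id=parent_id,
        )
        segments[sid] = seg
        if level >= depth:
            return sid
        # Murray split, slightly asymmetric by default
        a = rng.uniform(*asymmetry_range)
        g = murray_exponent
        r1 = radius * a ** (1.0 / g)
        r2 = radius * (1.0 - a) ** (1.0 / g)
        end_dir = pos[-1] - pos[-2]
        end_dir /= np.linalg.norm(end_dir)
        u, v = _perp_basis(end_dir)
        azim = rng.uniform(0, 2 * np.pi)
        plane = np.cos(azim) * u + np.sin(azim) * v
        for r, sign in ((r1, 1.0), (r2, -1.0)):
            if r < MIN_BRANCH_RADIUS:
                continue  # truncated branch
            ang = np.radians(rng.uniform(20.0, 35.0))
            child_dir = np.cos(ang) * end_dir + sign * np.sin(ang) * plane
            child_dir /= np.linalg.norm(child_dir)
            cid = grow(pos[-1], child_dir, r, level + 1, sid)
            seg.child_ids.append(cid)
        return sid

    root = grow(np.zeros(3), np.array([0.0, 0.0, 1.0]), root_radius, 1, None)
    return VesselForest(segments=segments, root_ids=[root])


# ---------------------------------------------------------------------------
# Rasterization
# ---------------------------------------------------------------------------

def _dense_samples(forest: VesselForest, step: float):
    """Resample every segment at arc-length ``step``; returns (points,
    radii) arrays used for distance queries."""
    pts, rads = [], []
    for seg in forest.segments.values():
        d = np.linalg.norm(np.diff(seg.positions, axis=0), axis=1)
        arc = np.concatenate([[0.0], np.cumsum(d)])
        n = max(2, int(np.ceil(arc[-1] / step)) + 1)
        s = np.linspace(0.0, arc[-1], n)
        p = np.stack(
            [np.interp(s, arc, seg.positions[:, c]) for c in range(3)], axis=1
        )
        r = np.interp(s, arc, seg.radii)
        pts.append(p)
        rads.append(r)
    return np.concatenate(pts), np.concatenate(rads)


def rasterize(
    forest: VesselForest,
    spacing,
    profile_sigma_factor: float = 0.5,
    noise_sigma: float = 0.0,
    blur_sigma: float = 0.0,
    fov: tuple | None = None,
    margin: float = 6.0,
    seed: int = 0,
) -> IntensityVolume:
    """Rasterize a vessel forest into a volume of Gaussian tubes.

    Voxel intensity is the maximum over nearby centerline samples of
    exp(-d^2 / (2 (f r)^2)) with d the distance to the centerline, r the
    local radius and f = ``profile_sigma_factor``; peak intensity 1 lies on
    the centerline.  Then Gaussian blur ``blur_sigma`` (mm) and additive
    Gaussian noise ``noise_sigma`` are applied, clipping at 0.

    ``fov``, if given, is (origin, shape); the tree must fit inside it.
    """
    spacing = np.broadcast_to(np.asarray(spacing, dtype=np.float64), (3,)).copy()
    if np.any(spacing <= 0):
        raise ValueError("spacing must be positive")

    if not forest.segments:
        shape = (16, 16, 16) if fov is None else tuple(fov[1])
        origin = np.zeros(3) if fov is None else np.asarray(fov[0], float)
        return IntensityVolume(np.zeros(shape), spacing, origin)

    pts, rads = _dense_samples(forest, float(np.min(spacing)) / 2.0)
    lo, hi = pts.min(axis=0), pts.max(axis=0)
    if fov is None:
        origin = lo - margin
        shape = tuple(np.ceil((hi - lo + 2 * margin) / spacing).astype(int) + 1)
    else:
        origin = np.asarray(fov[0], dtype=np.float64)
        shape = tuple(int(s) for s in fov[1])
        far = origin + (np.array(shape) - 1) * spacing
        if np.any(lo < origin) or np.any(hi > far):
            raise ValueError(
                f"tree bounding box [{lo}, {hi}] exceeds field of view "
                f"[{origin}, {far}]"
            )

    grid = np.stack(
        np.meshgrid(*[np.arange(s) for s in shape], indexing="ij"), axis=-1
    ).reshape(-1, 3)
    centers = grid * spacing[None, :] + origin[None, :]

    tree = cKDTree(pts)
    k = min(8, len(pts))
    dist, idx = tree.query(centers, k=k, workers=-1)
    if k == 1:
        dist, idx = dist[:, None], idx[:, None]
    sig = profile_sigma_factor * rads[idx]
    vals = np.exp(-(dist**2) / (2.0 * sig**2))
    data = vals.max(axis=1).reshape(shape)

    if blur_sigma > 0:
        data = ndimage.gaussian_filter(data, sigma=blur_sigma / spacing)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        data = data + rng.normal(0.0, noise_sigma, size=data.shape)
    return IntensityVolume(np.clip(data, 0.0, None), spacing, origin)


# ---------------------------------------------------------------------------
# Bundles
# ---------------------------------------------------------------------------

@dataclass
class PhantomBundle:
    """A ground-truth tree, its paired volumes and disjoint landmark sets."""

    forest: VesselForest
    tof: IntensityVolume
    pc: IntensityVolume
    guidance: LandmarkSet
    validation: LandmarkSet
    provenance: dict = field(default_factory=dict)


def _landmark_sets(forest: VesselForest):
    """Landmarks at natural peculiarities, split into disjoint sets.

    Guidance landmarks sit at vessel start and end points (inlets and
    outlets) — the locations the landmark term of the metric is meant to
    guide.  Validation landmarks are held out at different peculiarities:
    bifurcations and the midpoints of leaf segments.
    """
    g_pts, g_labels, v_pts, v_labels = [], [], [], []
    for sid in sorted(forest.segments):
        seg = forest.segments[sid]
        if seg.parent_id is None:
            g_pts.append(seg.first_point)
            g_labels.append(f"inlet_{sid}")
        if seg.child_ids:
            v_pts.append(seg.last_point)
            v_labels.append(f"bif_{sid}")
        else:
            g_pts.append(seg.last_point)
            g_labels.append(f"outlet_{sid}")
            v_pts.append(seg.positions[len(seg) // 2])
            v_labels.append(f"mid_{sid}")
    return (np.array(g_pts), g_labels), (np.array(v_pts), v_labels)


def make_bundle(
    seed: int,
    depth: int = 3,
    root_radius: float = 2.0,
    tof_spacing: float = 0.3,
    pc_spacing: float = 0.7,
    tof_noise: float = 0.01,
    pc_noise: float = 0.02,
    pc_blur: float = 0.5,
    margin: float = 12.0,
) -> PhantomBundle:
    """Generate one phantom: tree, fine/coarse volumes and landmark sets.

    The coarse volume gets a generous spatial margin so deformed centerlines
    stay mostly in-frame during Monte-Carlo runs.  Landmarks are placed at
    natural peculiarities and split into disjoint sets: guidance at vessel
    start/end points (inlets, outlets), validation at bifurcations and leaf
    midpoints.  Both sides of each pair coincide because the fixed volume
    is rasterized from the same (undeformed) tree.
    """
    forest = generate_tree(seed, depth=depth, root_radius=root_radius)
    tof = rasterize(
        forest, tof_spacing, noise_sigma=tof_noise, margin=margin / 2, seed=seed + 1
    )
    pc = rasterize(
        forest,
        pc_spacing,
        noise_sigma=pc_noise,
        blur_sigma=pc_blur,
        margin=margin,
        seed=seed + 2,
    )
    (g_pts, g_labels), (v_pts, v_labels) = _landmark_sets(forest)
    guidance = LandmarkSet(g_pts, g_pts.copy(), g_labels, role="guidance")
    validation = LandmarkSet(v_pts, v_pts.copy(), v_labels, role="validation")
    provenance = {
        "seed": seed,
        "depth": depth,
        "root_radius": root_radius,
        "tof_spacing": tof_spacing,
        "pc_spacing": pc_spacing,
        "tof_noise": tof_noise,
        "pc_noise": pc_noise,
        "pc_blur": pc_blur,
    }
    return PhantomBundle(forest, tof, pc, guidance, validation, provenance)


# ---------------------------------------------------------------------------
# Deformations
# ---------------------------------------------------------------------------

class RigidDeformation:
    """Ground-truth rigid (or rigid + isotropic scale) deformation."""

    kind = "rigid"

    def __init__(self, transform: AffineTransform):
        self.transform = transform

    def apply(self, points: np.ndarray) -> np.ndarray:
        return self.transform.apply(points)


class SmoothFieldDeformation:
    """Smooth non-rigid deformation: displacements on a coarse control grid,
    trilinearly interpolated (edge values extend beyond the grid)."""

    kind = "nonrigid"

    def __init__(self, origin, spacing, displacements):
        self.origin = np.asarray(origin, dtype=np.float64)
        self.spacing = np.asarray(spacing, dtype=np.float64)
        self.displacements = np.asarray(displacements, dtype=np.float64)

    def displacement(self, points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(np.asarray(points, dtype=np.float64))
        cont = (p - self.origin) / self.spacing
        n = np.array(self.displacements.shape[:3])
        cont = np.clip(cont, 0.0, n - 1.000001)
        out = np.empty_like(p)
        for c in range(3):
            out[:, c] = ndimage.map_coordinates(
                self.displacements[..., c], cont.T, order=1, mode="nearest"
            )
        return out

    def apply(self, points: np.ndarray) -> np.ndarray:
        p = np.asarray(points, dtype=np.float64)
        return p + self.displacement(p).reshape(p.shape)

    def max_jacobian_violation(self, bbox, n_check: int = 8) -> float:
        """Minimum finite-difference Jacobian determinant over a check grid
        (must stay positive for an invertible field)."""
        lo, hi = bbox
        axes = [np.linspace(lo[c], hi[c], n_check) for c in range(3)]
        pts = np.stack(np.meshgrid(*axes, indexing="ij"), -1).reshape(-1, 3)
        h = 0.5
        J = np.empty((len(pts), 3, 3))
        for c in range(3):
            off = np.zeros(3)
            off[c] = h
            J[:, :, c] = (
                (self.apply(pts + off) - self.apply(pts - off)) / (2 * h)
            )
        return float(np.min(np.linalg.det(J)))


def sample_deformation(
    spec,
    seed: int,
    anchor=(0.0, 0.0, 0.0),
    bbox=None,
):
    """Draw a ground-truth deformation from an MCSpec.

    Rigid family: rotation of uniformly random axis and angle in
    [0, rotation_range] deg, translation of uniform direction and magnitude
    in [0, translation_range] mm (plus isotropic scale within
    1 +/- scale_range if nonzero), acting about ``anchor``.

    Non-rigid family: a smooth control-point displacement field spanning
    ``bbox`` with i.i.d. Gaussian control displacements of std
    ``jitter_mm``, clipped at 3 sigma (so the maximum displacement is
    bounded); fields whose sampled Jacobian determinant goes non-positive
    are redrawn up to 10 times.
    """
    rng = np.random.default_rng(seed)
    if spec.family == "rigid":
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        angle = rng.uniform(0.0, np.radians(spec.rotation_range))
        zyx = Rotation.from_rotvec(axis * angle).as_euler("ZYX", degrees=True)
        tdir = rng.normal(size=3)
        tdir /= np.linalg.norm(tdir)
        tmag = rng.uniform(0.0, spec.translation_range)
        if spec.scale_range > 0:
            s = rng.uniform(1.0 - spec.scale_range, 1.0 + spec.scale_range)
            t = AffineTransform(
                dof=7,
                rotation=zyx[::-1].copy(),
                translation=tmag * tdir,
                scale=np.full(3, s),
                anchor=np.asarray(anchor, dtype=np.float64),
            )
        else:
            t = AffineTransform(
                dof=6,
                rotation=zyx[::-1].copy(),
                translation=tmag * tdir,
                anchor=np.asarray(anchor, dtype=np.float64),
            )
        return RigidDeformation(t)
    if spec.family == "nonrigid":
        if bbox is None:
            raise ValueError("non-rigid deformation sampling needs a bbox")
        lo = np.asarray(bbox[0], dtype=np.float64) - 2.0
        hi = np.asarray(bbox[1], dtype=np.float64) + 2.0
        n = spec.n_control
        # keep control spacing >= 4x jitter so the field stays diffeomorphic
        min_extent = 4.0 * spec.jitter_mm * (n - 1)
        center, extent = (lo + hi) / 2.0, hi - lo
        extent = np.maximum(extent, min_extent)
        lo, hi = center - extent / 2.0, center + extent / 2.0
        spacing = (hi - lo) / (n - 1)
        for _ in range(10):
            disp = np.clip(
                rng.normal(0.0, spec.jitter_mm, size=(n, n, n, 3)),
                -3.0 * spec.jitter_mm,
                3.0 * spec.jitter_mm,
            )
            field = SmoothFieldDeformation(lo, spacing, disp)
            if field.max_jacobian_violation((lo, hi)) > 0.05:
                return field
        raise ValueError(
            "could not sample an invertible non-rigid field in 10 tries; "
            "reduce jitter_mm"
        )
    raise ValueError(f"unknown deformation family {spec.family!r}")


def deform_forest(forest: VesselForest, deformation) -> VesselForest:
    """Apply a deformation analytically to every centerline point; radii
    are kept, tangents recomputed from the deformed polylines."""
    segments = {}
    for sid, seg in forest.segments.items():
        segments[sid] = VesselSegment(
            id=sid,
            positions=deformation.apply(seg.positions),
            radii=seg.radii.copy(),
            parent_id=seg.parent_id,
            child_ids=list(seg.child_ids),
            represented=seg.represented,
        )
    return VesselForest(segments=segments, root_ids=list(forest.root_ids))


def deform_landmarks(landmarks: LandmarkSet, deformation) -> LandmarkSet:
    """Deform the moving side of a landmark set; the fixed side stays."""
    return LandmarkSet(
        deformation.apply(landmarks.moving),
        landmarks.fixed.copy(),
        list(landmarks.labels),
        landmarks.role,
    )


# ---------------------------------------------------------------------------
# Temporal MIP
# ---------------------------------------------------------------------------

def temporal_mip(frames: list[IntensityVolume]) -> IntensityVolume:
    """Voxelwise maximum intensity projection across time frames of
    identical geometry (combines per-phase magnitude images into one)."""
    if not frames:
        raise ValueError("temporal_mip needs at least one frame")
    first = frames[0]
    for f in frames[1:]:
        if not first.same_geometry(f):
            raise ValueError("temporal_mip: frame geometries differ")
    data = np.maximum.reduce([f.data for f in frames])
    return IntensityVolume(data, first.spacing.copy(), first.origin.copy(),
                           first.direction.copy())
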