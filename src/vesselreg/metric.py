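"""The registration objective: fit centerline points to intensity ridges.

The objective has three components, combined as

    alpha1 * m1  -  alpha2 * mean(m2)  -  alpha3 * m3     (maximized)

* m1 — scaled sum of weighted intensities: the radius-weighted mean of the
  fixed volume's intensity, blurred at a per-point scale sigma_i = kappa *
  r_i, sampled at the transformed centerline points.  At the optimum all
  points lie inside intensity ridges.
* m2 — ridge-centering penalty: image gradients sampled on the plane normal
  to the (transformed) centerline tangent, within the vessel radius, should
  point inward toward the centerline; outward-pointing gradients are
  penalized.
* m3 — mean squared distance (mm^2) between transformed guidance landmarks
  and their fixed counterparts.

Per-point Gaussian blur is served from a small pyramid of pre-smoothed
volumes at discrete sigma levels (geometric spacing, factor sqrt(2)); the
level nearest sigma_i is used.  Points mapped outside the grid read
``oob_intensity`` (default 0), which together with the normalization of m1
penalizes transforms that push the model off the image.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import CenterlinePoint, IntensityVolume, LandmarkSet
from .transform import _as_matrix, apply_matrix

__all__ = [
    "MetricConfig",
    "intensity_at",
    "radius_weight",
    "m1_intensity_sum",
    "m2_gradient_penalty",
    "m3_landmark_term",
    "combined_metric",
    "MetricEvaluator",
]

_GRAD_EPS = 1e-12


@dataclass
class MetricConfig:
    """Weights and scales of the registration objective.

    kappa
        Blur-scale factor: each point is read from the volume smoothed at
        sigma_i = kappa * r_i (mm).  Default 1.0 (blur scale equal to the
        vessel radius).
    weight_mode
        "linear" (w(r) = r, default: larger vessels contribute more, since
        visibility is determined by vessel size) or "uniform" (w(r) = 1).
    alpha1, alpha2, alpha3
        Component weights for the intensity sum, gradient penalty and
        landmark term (alpha3 in 1/mm^2).
    n_rays, n_radii
        Normal-plane sampling: n_rays equally spaced directions at n_radii
        radial offsets up to the vessel radius.
    oob_intensity
        Intensity returned for points outside the grid.
    """

    kappa: float = 1.0
    weight_mode: str = "linear"
    alpha1: float = 1.0
    alpha2: float = 0.5
    alpha3: float = 0.01
    n_rays: int = 6
    n_radii: int = 1
    oob_intensity: float = 0.0

    def __post_init__(self) -> None:
        if self.kappa <= 0:
            raise ValueError("kappa must be > 0")
        if self.alpha1 <= 0:
            raise ValueError("alpha1 must be > 0")
        if self.alpha2 < 0 or self.alpha3 < 0:
            raise ValueError("component weights must be >= 0")
        if self.n_rays < 4:
            raise ValueError("n_rays must be >= 4")
        if self.n_radii < 1:
            raise ValueError("n_radii must be >= 1")
        if self.weight_mode not in ("linear", "uniform"):
            raise ValueError(f"unknown weight_mode {self.weight_mode!r}")

    def to_dict(self) -> dict:
        return {
            "kappa": self.kappa,
            "weight_mode": self.weight_mode,
            "alpha1": self.alpha1,
            "alpha2": self.alpha2,
            "alpha3": self.alpha3,
            "n_rays": self.n_rays,
            "n_radii": self.n_radii,
            "oob_intensity": self.oob_intensity,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MetricConfig":
        return cls(**d)


# ---------------------------------------------------------------------------
# Scale-space pyramid
# ---------------------------------------------------------------------------

class _Pyramid:
    """Lazily computed stack of Gaussian-smoothed copies of a volume.

    Level k holds the volume smoothed at sigma_k = sigma0 * sqrt(2)^k mm,
    with sigma0 = max(spacing)/2; level -1 is the raw volume.  A requested
    sigma maps to the nearest level (raw when sigma < sigma0/2).
    """

    def __init__(self, volume: IntensityVolume):
        self.volume = volume
        self.sigma0 = float(np.max(volume.spacing)) / 2.0
        self._levels: dict[int, np.ndarray] = {-1: volume.data}

    def level_index(self, sigma: float) -> int:
        if sigma < self.sigma0 / 2.0:
            return -1
        return max(0, round(math.log(sigma / self.sigma0) / math.log(math.sqrt(2.0))))

    def level_indices(self, sigmas: np.ndarray) -> np.ndarray:
        s = np.asarray(sigmas, dtype=np.float64)
        idx = np.full(s.shape, -1, dtype=np.int64)
        pos = s >= self.sigma0 / 2.0
        idx[pos] = np.maximum(
            0,
            np.round(np.log(s[pos] / self.sigma0) / math.log(math.sqrt(2.0))).astype(
                np.int64
            ),
        )
        return idx

    def level(self, k: int) -> np.ndarray:
        if k not in self._levels:
            sigma_mm = self.sigma0 * math.sqrt(2.0) ** k
            sigma_vox = sigma_mm / self.volume.spacing
            self._levels[k] = ndimage.gaussian_filter(
                self.volume.data, sigma=sigma_vox, mode="nearest"
            )
        return self._levels[k]


def _pyramid(volume: IntensityVolume) -> _Pyramid:
    pyr = getattr(volume, "_pyramid", None)
    if pyr is None or pyr.volume is not volume:
        pyr = _Pyramid(volume)
        volume._pyramid = pyr  # cache on the volume instance
    return pyr


def _interp_by_level(
    volume: IntensityVolume,
    points: np.ndarray,
    sigmas: np.ndarray,
    oob: float,
    groups=None,
) -> np.ndarray:
    """Trilinear interpolation of per-point blurred intensity, grouping
    points by pyramid level.  ``points`` (N, 3) world mm; ``sigmas`` (N,).

    ``groups`` is an optional precomputed [(level, index_array), ...]
    partition (the levels depend only on the sigmas, which are fixed for a
    given point set)."""
    pyr = _pyramid(volume)
    vox = volume.world_to_voxel(points)
    if groups is None:
        groups = _level_groups(pyr, sigmas)
    out = np.empty(len(points), dtype=np.float64)
    for k, sel in groups:
        out[sel] = ndimage.map_coordinates(
            pyr.level(int(k)),
            vox[sel].T,
            order=1,
            mode="constant",
            cval=oob,
        )
    return out


def _level_groups(pyr: _Pyramid, sigmas: np.ndarray):
    levels = pyr.level_indices(sigmas)
    return [(int(k), np.nonzero(levels == k)[0]) for k in np.unique(levels)]


def intensity_at(
    volume: IntensityVolume,
    p: np.ndarray,
    sigma: float,
    oob_intensity: float = 0.0,
) -> float:
    """Blurred, trilinearly interpolated intensity at world point ``p`` (mm).

    ``sigma`` (mm) selects the nearest scale-space pyramid level; sigma = 0
    reads the raw volume.  Points outside the grid return
    ``oob_intensity``.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    p = np.asarray(p, dtype=np.float64).reshape(1, 3)
    return float(_interp_by_level(volume, p, np.array([sigma]), oob_intensity)[0])


# ---------------------------------------------------------------------------
# Components
# ---------------------------------------------------------------------------

def radius_weight(r: float, config: MetricConfig) -> float:
    """Per-point weight as a function of vessel radius (mm)."""
    if r <= 0:
        raise ValueError(f"radius must be positive, got {r}")
    if config.weight_mode == "uniform":
        return 1.0
    return float(r)


def _radius_weights(radii: np.ndarray, config: MetricConfig) -> np.ndarray:
    radii = np.asarray(radii, dtype=np.float64)
    if np.any(radii <= 0):
        raise ValueError("radii must be positive")
    if config.weight_mode == "uniform":
        return np.ones_like(radii)
    return radii.copy()


def _points_arrays(points):
    """Accept a list of CenterlinePoint or (positions, radii, tangents)."""
    if isinstance(points, tuple):
        pos, radii, tangents = points
        return (
            np.asarray(pos, dtype=np.float64).reshape(-1, 3),
            np.asarray(radii, dtype=np.float64).reshape(-1),
            np.asarray(tangents, dtype=np.float64).reshape(-1, 3),
        )
    pos = np.array([p.position for p in points])
    radii = np.array([p.radius for p in points])
    tangents = np.array([p.tangent for p in points])
    return pos.reshape(-1, 3), radii, tangents.reshape(-1, 3)


def m1_intensity_sum(points, volume, T, config: MetricConfig) -> float:
    """Scaled sum of weighted intensities (maximization target).

    m1(T) = sum_i w(r_i) I_{kappa sigma_i}(x_i T) / sum_i w(r_i), with
    sigma_i = kappa * r_i.  The normalization makes it a weighted mean, so
    for in-bounds points the value lies within the volume's intensity range.
    """
    pos, radii, _ = _points_arrays(points)
    if len(pos) == 0:
        raise ValueError("m1 needs at least one centerline point")
    w = _radius_weights(radii, config)
    tp = apply_matrix(_as_matrix(T), pos)
    vals = _interp_by_level(volume, tp, config.kappa * radii, config.oob_intensity)
    return float(np.sum(w * vals) / np.sum(w))


def _plane_basis(tangents: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Orthonormal (u, v) spanning the plane normal to each tangent."""
    t = tangents / np.linalg.norm(tangents, axis=1, keepdims=True)
    helper = np.zeros_like(t)
    helper[np.arange(len(t)), np.argmin(np.abs(t), axis=1)] = 1.0
    u = np.cross(t, helper)
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    v = np.cross(t, u)
    return u, v


def _m2_batch(
    pos: np.ndarray,
    radii: np.ndarray,
    tangents: np.ndarray,
    volume: IntensityVolume,
    M: np.ndarray,
    config: MetricConfig,
    groups=None,
) -> np.ndarray:
    """Per-point ridge-centering penalty, vectorized over points.

    For each point, the plane perpendicular to the transformed tangent is
    sampled at n_rays directions x n_radii radial offsets up to the vessel
    radius.  The central-difference image gradient, projected onto the
    plane, is compared with the outward radial direction: a gradient
    pointing inward toward the centerline (theta = 180 deg, as on the far
    slope of a ridge) contributes 0; an outward gradient contributes 1.
    """
    norms = np.linalg.norm(tangents, axis=1)
    if np.any(norms < 1e-9):
        raise ValueError("degenerate tangent (norm < 1e-9)")
    N = len(pos)
    center = apply_matrix(M, pos)  # (N, 3)
    t = tangents @ M[:3, :3].T
    t /= np.linalg.norm(t, axis=1, keepdims=True)
    u, v = _plane_basis(t)

    phis = 2.0 * np.pi * np.arange(config.n_rays) / config.n_rays
    # directions (N, K, 3)
    dirs = (
        np.cos(phis)[None, :, None] * u[:, None, :]
        + np.sin(phis)[None, :, None] * v[:, None, :]
    )
    fracs = np.arange(1, config.n_radii + 1) / config.n_radii  # (J,)
    rho = radii[:, None] * fracs[None, :]  # (N, J)
    # samples (N, J, K, 3)
    samples = center[:, None, None, :] + rho[:, :, None, None] * dirs[:, None, :, :]

    J, K = config.n_radii, config.n_rays
    flat = samples.reshape(-1, 3)  # (S, 3) with S = N*J*K
    S = len(flat)
    h = float(np.min(volume.spacing)) / 2.0
    # all six central-difference offsets in one interpolation batch
    offsets = np.concatenate([h * np.eye(3), -h * np.eye(3)])  # (6, 3)
    batch = (flat[None, :, :] + offsets[:, None, :]).reshape(-1, 3)
    if groups is None:
        sig = np.repeat(config.kappa * radii, J * K)
        groups = _level_groups(_pyramid(volume), np.tile(sig, 6))
    vals = _interp_by_level(
        volume, batch, None, config.oob_intensity, groups=groups
    ).reshape(6, S)
    grad = ((vals[:3] - vals[3:]) / (2.0 * h)).T  # (S, 3)

    grad = grad.reshape(N, J, K, 3)
    # project onto the normal plane
    gdott = np.einsum("njkc,nc->njk", grad, t)
    gp = grad - gdott[..., None] * t[:, None, None, :]
    gnorm = np.linalg.norm(gp, axis=-1)
    outward = dirs[:, None, :, :]  # unit outward radial direction
    cos_theta = np.einsum("njkc,njkc->njk", gp, np.broadcast_to(outward, gp.shape))
    with np.errstate(invalid="ignore", divide="ignore"):
        cos_theta = np.where(gnorm > _GRAD_EPS, cos_theta / gnorm, -1.0)
    contrib = np.where(gnorm > _GRAD_EPS, 0.5 * (1.0 + cos_theta), 0.0)
    return contrib.reshape(N, J * K).mean(axis=1)


def m2_gradient_penalty(
    point: CenterlinePoint, volume, T, config: MetricConfig
) -> float:
    """Ridge-centering penalty for a single centerline point (see
    :func:`_m2_batch`); in [0, 1], 0 when every sampled gradient points
    inward (or vanishes)."""
    return float(
        _m2_batch(
            point.position.reshape(1, 3),
            np.array([point.radius]),
            point.tangent.reshape(1, 3),
            volume,
            _as_matrix(T),
            config,
        )[0]
    )


def m3_landmark_term(landmarks: LandmarkSet | None, T) -> float:
    """Mean squared distance (mm^2) between transformed moving guidance
    landmarks and their fixed counterparts; 0 when no pairs are given."""
    if landmarks is None or len(landmarks) == 0:
        return 0.0
    moved = apply_matrix(_as_matrix(T), landmarks.moving)
    d = moved - landmarks.fixed
    return float(np.mean(np.sum(d * d, axis=1)))


def combined_metric(points, volume, T, landmarks, config: MetricConfig) -> float:
    """alpha1 * m1 - alpha2 * mean(m2 over points) - alpha3 * m3
    (maximized).  With alpha2 = alpha3 = 0 this equals m1 exactly."""
    pos, radii, tangents = _points_arrays(points)
    if len(pos) == 0:
        raise ValueError("combined_metric needs at least one centerline point")
    M = _as_matrix(T)
    value = config.alpha1 * m1_intensity_sum((pos, radii, tangents), volume, M, config)
    if config.alpha2 > 0:
        value -= config.alpha2 * float(
            np.mean(_m2_batch(pos, radii, tangents, volume, M, config))
        )
    if config.alpha3 > 0:
        value -= config.alpha3 * m3_landmark_term(landmarks, M)
    return value


class MetricEvaluator:
    """Callable wrapper binding (points, volume, landmarks, config) so the
    optimizer only varies the transform.

    The pyramid-level partition of the sample batches depends only on the
    (fixed) radii, so it is computed once here rather than per evaluation.
    """

    def __init__(self, points, volume, landmarks, config: MetricConfig):
        self.pos, self.radii, self.tangents = _points_arrays(points)
        if len(self.pos) == 0:
            raise ValueError("metric needs at least one centerline point")
        self.volume = volume
        self.landmarks = landmarks
        self.config = config
        pyr = _pyramid(volume)  # build the cache eagerly
        self._w = _radius_weights(self.radii, config)
        self._sum_w = float(np.sum(self._w))
        sig = config.kappa * self.radii
        self._m1_groups = _level_groups(pyr, sig)
        m2_sig = np.repeat(sig, config.n_radii * config.n_rays)
        self._m2_groups = _level_groups(pyr, np.tile(m2_sig, 6))
        for k, _sel in self._m1_groups:  # precompute smoothed levels
            pyr.level(k)

    def __call__(self, T) -> float:
        cfg = self.config
        M = _as_matrix(T)
        tp = apply_matrix(M, self.pos)
        vals = _interp_by_level(
            self.volume, tp, None, cfg.oob_intensity, groups=self._m1_groups
        )
        value = cfg.alpha1 * float(np.sum(self._w * vals) / self._sum_w)
        if cfg.alpha2 > 0:
            value -= cfg.alpha2 * float(
                np.mean(
                    _m2_batch(
                        self.pos, self.radii, self.tangents, self.volume, M,
                        cfg, groups=self._m2_groups,
                    )
                )
            )
        if cfg.alpha3 > 0:
            value -= cfg.alpha3 * m3_landmark_term(self.landmarks, M)
        return value
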