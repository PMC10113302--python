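"""Anchored parameterized affine transforms and their composition.

A local transform acts about an anchor point (for child vessels, the branch
point shared with the parent), so that with zero local translation a child
segment stays attached to its transformed parent:

    M = T(translation) . T(anchor) . R(rotation) . Shear . Scale . T(-anchor)

Euler angles use the intrinsic Z-Y-X convention, in degrees.  Degrees of
freedom:

* 4  — isotropic scale + 3 translations (rotation held fixed, e.g. from a
       rotation grid)
* 6  — rigid: 3 rotations + 3 translations
* 7  — 3 rotations + isotropic scale + 3 translations
* 12 — 3 rotations + 3 scales + 3 shears + 3 translations
* 15 — experimental: as 12 but with 6 shear parameters (lower-triangular
       shears released as well)
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .core import VesselSegment

__all__ = ["AffineTransform", "compose", "apply_matrix", "child_anchor"]

_VALID_DOF = (4, 6, 7, 12, 15)


def _shear_matrix(shear: np.ndarray) -> np.ndarray:
    """Unit upper-triangular shear from (xy, xz, yz); a 6-vector adds the
    lower-triangular (yx, zx, zy) entries (experimental 15-parameter mode)."""
    S = np.eye(3)
    S[0, 1], S[0, 2], S[1, 2] = shear[0], shear[1], shear[2]
    if len(shear) == 6:
        S[1, 0], S[2, 0], S[2, 1] = shear[3], shear[4], shear[5]
    return S


@dataclass
class AffineTransform:
    """Anchored affine transform with explicit parameters (mm / degrees)."""

    dof: int = 12
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))
    rotation: np.ndarray = field(default_factory=lambda: np.zeros(3))
    scale: np.ndarray = field(default_factory=lambda: np.ones(3))
    shear: np.ndarray = field(default_factory=lambda: np.zeros(3))
    anchor: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        if self.dof not in _VALID_DOF:
            raise ValueError(f"dof must be one of {_VALID_DOF}, got {self.dof}")
        self.translation = np.asarray(self.translation, dtype=np.float64).reshape(3)
        self.rotation = np.asarray(self.rotation, dtype=np.float64).reshape(3)
        scale = np.asarray(self.scale, dtype=np.float64).reshape(-1)
        if scale.size == 1:
            scale = np.repeat(scale, 3)
        self.scale = scale.reshape(3)
        self.shear = np.asarray(self.shear, dtype=np.float64).reshape(-1)
        if self.shear.size not in (3, 6):
            raise ValueError("shear must have 3 (or experimental 6) components")
        self.anchor = np.asarray(self.anchor, dtype=np.float64).reshape(3)
        if np.any(self.scale <= 0):
            raise ValueError(f"scale components must be positive, got {self.scale}")
        if self.dof in (4, 7) and not np.allclose(self.scale, self.scale[0]):
            raise ValueError(f"dof={self.dof} requires isotropic scale")
        if self.dof in (4, 6, 7) and np.any(self.shear != 0):
            raise ValueError(f"dof={self.dof} does not admit shear")
        if self.dof == 6 and not np.allclose(self.scale, 1.0):
            raise ValueError("dof=6 (rigid) requires unit scale")

    @classmethod
    def identity(cls, dof: int = 12, anchor=(0.0, 0.0, 0.0)) -> "AffineTransform":
        return cls(dof=dof, anchor=np.asarray(anchor, dtype=np.float64))

    def to_matrix(self) -> np.ndarray:
        """4x4 homogeneous matrix; rotation/scale/shear act about the anchor."""
        R = Rotation.from_euler("ZYX", self.rotation[::-1], degrees=True).as_matrix()
        L = R @ _shear_matrix(self.shear) @ np.diag(self.scale)
        M = np.eye(4)
        M[:3, :3] = L
        M[:3, 3] = self.translation + self.anchor - L @ self.anchor
        return M

    @classmethod
    def from_matrix(
        cls, M: np.ndarray, anchor=(0.0, 0.0, 0.0), dof: int = 12
    ) -> "AffineTransform":
        """Recover parameters from a 4x4 matrix (inverse of ``to_matrix``
        within the Euler convention's domain)."""
        M = np.asarray(M, dtype=np.float64)
        anchor = np.asarray(anchor, dtype=np.float64).reshape(3)
        L = M[:3, :3]
        # L = R @ Shear @ Scale with Shear unit upper-triangular and Scale
        # positive-diagonal => QR decomposition with sign fixing.
        Q, U = np.linalg.qr(L)
        signs = np.sign(np.diag(U))
        signs[signs == 0] = 1.0
        Q = Q * signs[None, :]
        U = U * signs[:, None]
        scale = np.diag(U).copy()
        shear = np.array([U[0, 1] / scale[1], U[0, 2] / scale[2], U[1, 2] / scale[2]])
        zyx = Rotation.from_matrix(Q).as_euler("ZYX", degrees=True)
        translation = M[:3, 3] - anchor + L @ anchor
        if dof in (4, 6, 7):
            if np.max(np.abs(shear)) > 1e-8:
                raise ValueError(f"matrix has shear, incompatible with dof={dof}")
            shear = np.zeros(3)
        if dof == 6:
            if np.max(np.abs(scale - 1.0)) > 1e-8:
                raise ValueError("matrix is not rigid (scale != 1)")
            scale = np.ones(3)
        elif dof in (4, 7):
            if np.max(np.abs(scale - scale[0])) > 1e-8:
                raise ValueError(f"anisotropic scale, incompatible with dof={dof}")
            scale = np.full(3, scale.mean())
        return cls(
            dof=dof,
            translation=translation,
            rotation=zyx[::-1].copy(),
            scale=scale,
            shear=shear,
            anchor=anchor,
        )

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Apply to world points, shape (..., 3)."""
        return apply_matrix(self.to_matrix(), points)

    def to_dict(self) -> dict:
        return {
            "dof": self.dof,
            "translation": self.translation.tolist(),
            "rotation_deg": self.rotation.tolist(),
            "scale": self.scale.tolist(),
            "shear": self.shear.tolist(),
            "anchor": self.anchor.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AffineTransform":
        return cls(
            dof=d["dof"],
            translation=d["translation"],
            rotation=d["rotation_deg"],
            scale=d["scale"],
            shear=d["shear"],
            anchor=d["anchor"],
        )


def _as_matrix(t) -> np.ndarray:
    if isinstance(t, AffineTransform):
        return t.to_matrix()
    M = np.asarray(t, dtype=np.float64)
    if M.shape != (4, 4):
        raise ValueError(f"expected AffineTransform or 4x4 matrix, got {M.shape}")
    return M


def compose(outer, inner) -> np.ndarray:
    """Matrix product outer . inner (accepts transforms or 4x4 matrices).

    Used to chain a child's local transform onto the accumulated parent
    transform so children remain anchored to their parents.
    """
    return _as_matrix(outer) @ _as_matrix(inner)


def apply_matrix(M: np.ndarray, points: np.ndarray) -> np.ndarray:
    p = np.asarray(points, dtype=np.float64)
    return p @ M[:3, :3].T + M[:3, 3]


def child_anchor(child: VesselSegment, parent_accumulated: np.ndarray) -> np.ndarray:
    """Anchor of a child's local transform: its first centerline point (the
    branch point shared with the parent) mapped through the parent's
    accumulated transform.  Roots have no parent and anchor at their own
    centroid instead."""
    if child.parent_id is None:
        raise ValueError(
            f"segment {child.id} is a root; roots anchor at their own centroid"
        )
    return apply_matrix(_as_matrix(parent_accumulated), child.first_point)
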