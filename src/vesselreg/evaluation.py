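"""Landmark error measures and the Monte-Carlo validation harness.

Ground-truth registration problems are manufactured by applying random
known deformations (rigid or smooth non-rigid) to the moving centerline
and its landmarks, then registering back to the untransformed fixed
volume.  Mean squared error (MSE, mm^2; an RMS column in mm is also
reported) and the Hausdorff distance (HD, mm) between validation-landmark
sets are recorded before and after registration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .core import LandmarkSet, VesselForest
from .hierarchy import _nearest_segment_ids, assign_representation, hierarchical_register
from .metric import MetricConfig
from .optimize import OptimizerConfig
from .transform import _as_matrix, apply_matrix

__all__ = ["MCSpec", "landmark_mse", "hausdorff", "hausdorff_directed", "run_mcs"]


@dataclass
class MCSpec:
    """Design of a Monte-Carlo simulation run.

    family
        "rigid" (random rotation up to ``rotation_range`` deg and
        translation up to ``translation_range`` mm) or "nonrigid" (smooth
        control-point displacement field with jitter ``jitter_mm``).
    repetitions
        Number of random deformations to register.
    """

    family: str = "rigid"
    repetitions: int = 20
    rotation_range: float = 30.0
    translation_range: float = 10.0
    scale_range: float = 0.0
    jitter_mm: float = 5.0
    n_control: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in ("rigid", "nonrigid"):
            raise ValueError(f"unknown MCS family {self.family!r}")
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")
        for name in ("rotation_range", "translation_range", "scale_range", "jitter_mm"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "repetitions": self.repetitions,
            "rotation_range": self.rotation_range,
            "translation_range": self.translation_range,
            "scale_range": self.scale_range,
            "jitter_mm": self.jitter_mm,
            "n_control": self.n_control,
            "seed": self.seed,
        }


# ---------------------------------------------------------------------------
# Error measures
# ---------------------------------------------------------------------------

def landmark_mse(landmarks: LandmarkSet, transforms, forest: VesselForest = None) -> float:
    """Mean squared Euclidean distance (mm^2) between transformed moving
    landmarks and their fixed counterparts.

    ``transforms`` is either a single transform/4x4 matrix applied to all
    moving landmarks, or a mapping segment id -> accumulated matrix, in
    which case each landmark travels with its nearest segment (``forest``
    required).
    """
    if len(landmarks) == 0:
        raise ValueError("landmark_mse needs at least one pair")
    if isinstance(transforms, dict):
        if forest is None:
            raise ValueError("per-segment transforms need the forest for assignment")
        sids = _nearest_segment_ids(forest, landmarks.moving)
        moved = np.array(
            [
                apply_matrix(_as_matrix(transforms[sids[i]]), landmarks.moving[i])
                for i in range(len(landmarks))
            ]
        )
    else:
        moved = apply_matrix(_as_matrix(transforms), landmarks.moving)
    d = moved - landmarks.fixed
    return float(np.mean(np.sum(d * d, axis=1)))


def hausdorff_directed(setA: np.ndarray, setB: np.ndarray) -> float:
    """max over a in A of min over b in B of ||a - b|| (mm)."""
    A = np.atleast_2d(np.asarray(setA, dtype=np.float64))
    B = np.atleast_2d(np.asarray(setB, dtype=np.float64))
    if len(A) == 0 or len(B) == 0:
        raise ValueError("hausdorff needs non-empty sets")
    return float(cdist(A, B).min(axis=1).max())


def hausdorff(setA: np.ndarray, setB: np.ndarray) -> float:
    """Symmetric Hausdorff distance (mm): the maximum across all minimum
    point-pair distances, taken in both directions."""
    return max(hausdorff_directed(setA, setB), hausdorff_directed(setB, setA))


# ---------------------------------------------------------------------------
# Monte-Carlo harness
# ---------------------------------------------------------------------------

def run_mcs(
    bundle,
    spec: MCSpec,
    metric_config: MetricConfig | None = None,
    config: OptimizerConfig | None = None,
    representation_factor: float = 1.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Monte-Carlo validation: deform, register, measure.

    Per repetition, a deformation sampled from ``spec`` is applied to the
    phantom's tree and landmark moving sides; the deformed tree is
    registered to the (untransformed) coarse volume, and initial/final MSE
    and HD of the validation landmarks are recorded.  A failed registration
    records the failure and does not abort the batch.

    Returns ``(rows, summary)``: the per-repetition table and a summary
    with average/median/std per measure plus the fraction of repetitions
    improved.
    """
    from .phantom import deform_forest, deform_landmarks, sample_deformation

    metric_config = metric_config or MetricConfig()
    config = config or OptimizerConfig.desk_scale(seed=spec.seed)
    pos, _, _, _ = bundle.forest.all_points()
    centroid = pos.mean(axis=0)
    bbox = (pos.min(axis=0), pos.max(axis=0))

    rows = []
    for rep in range(spec.repetitions):
        rep_seed = int((spec.seed * 100003 + 7919 * rep + 1) % (2**31 - 1))
        deformation = sample_deformation(spec, rep_seed, anchor=centroid, bbox=bbox)
        moving = deform_forest(bundle.forest, deformation)
        assign_representation(moving, bundle.pc.spacing, representation_factor)
        guidance = deform_landmarks(bundle.guidance, deformation)
        validation = deform_landmarks(bundle.validation, deformation)
        initial_mse = landmark_mse(validation, np.eye(4))
        initial_hd = hausdorff(validation.moving, validation.fixed)
        row = {
            "rep": rep,
            "family": spec.family,
            "seed": rep_seed,
            "initial_mse": initial_mse,
            "initial_hd": initial_hd,
        }
        try:
            result = hierarchical_register(
                moving,
                bundle.pc,
                guidance=guidance,
                validation=validation,
                metric_config=metric_config,
                config=config,
            )
            row.update(
                final_mse=result.final_errors["mse"],
                final_hd=result.final_errors["hd"],
                final_metric=result.final_metric,
                status="ok",
            )
            row["improved_mse"] = row["final_mse"] < row["initial_mse"]
            row["improved_hd"] = row["final_hd"] < row["initial_hd"]
        except Exception as exc:  # record, do not abort the batch
            row.update(
                final_mse=np.nan,
                final_hd=np.nan,
                final_metric=np.nan,
                status=f"failed: {exc}",
                improved_mse=False,
                improved_hd=False,
            )
        row["initial_rms"] = float(np.sqrt(row["initial_mse"]))
        row["final_rms"] = float(np.sqrt(row["final_mse"]))
        rows.append(row)

    table = pd.DataFrame(rows)
    summary = summarize_mcs(table)
    return table, summary


def summarize_mcs(table: pd.DataFrame) -> pd.DataFrame:
    """Average / median / standard deviation of the error measures per
    deformation family, plus the fraction of repetitions improved."""
    out = []
    for family, grp in table.groupby("family"):
        ok = grp[grp["status"] == "ok"]
        row = {"family": family, "n": len(grp), "n_failed": int((grp["status"] != "ok").sum())}
        for col in ("initial_mse", "final_mse", "initial_hd", "final_hd"):
            row[f"{col}_avg"] = float(ok[col].mean())
            row[f"{col}_median"] = float(ok[col].median())
            row[f"{col}_std"] = float(ok[col].std(ddof=1)) if len(ok) > 1 else 0.0
        row["frac_improved_mse"] = float(grp["improved_mse"].mean())
        row["frac_improved_hd"] = float(grp["improved_hd"].mean())
        out.append(row)
    return pd.DataFrame(out)
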