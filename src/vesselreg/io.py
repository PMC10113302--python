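"""Readers and writers: NIfTI volumes, centerlines (JSON dialect and a
minimal ASCII VTK-XML PolyData subset), landmark CSVs and YAML run
configuration.

The internal world frame is axis-aligned LPS.  NIfTI affines are RAS by
convention and are converted on read and write.  Volumes are stored as
float32 on disk and promoted to float64 in memory.
"""

from __future__ import annotations

import json
import warnings
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .core import IntensityVolume, LandmarkSet, VesselForest, VesselSegment, \
    build_forest, split_at_branchpoints
from .metric import MetricConfig
from .optimize import OptimizerConfig

__all__ = [
    "read_volume",
    "write_volume",
    "read_centerline",
    "write_centerline",
    "read_forest",
    "write_forest",
    "lines_to_forest",
    "read_landmarks",
    "write_landmarks",
    "RunConfig",
]

DEFAULT_RADIUS_ARRAY = "MaximumInscribedSphereRadius"

_RAS_TO_LPS = np.diag([-1.0, -1.0, 1.0, 1.0])


# ---------------------------------------------------------------------------
# Volumes (NIfTI)
# ---------------------------------------------------------------------------

def read_volume(path) -> IntensityVolume:
    """Read a NIfTI-1 volume; geometry (spacing/origin/direction) comes from
    the file's affine, converted from RAS to the package's LPS frame."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D volume, got shape {data.shape}")
    affine = img.affine
    if affine is None or not np.all(np.isfinite(affine)):
        raise ValueError("volume has no usable affine")
    lps = _RAS_TO_LPS @ affine
    L = lps[:3, :3]
    spacing = np.linalg.norm(L, axis=0)
    direction = L / spacing[None, :]
    return IntensityVolume(data, spacing, lps[:3, 3], direction)


def write_volume(volume: IntensityVolume, path) -> None:
    lps = np.eye(4)
    lps[:3, :3] = volume.direction * volume.spacing[None, :]
    lps[:3, 3] = volume.origin
    ras = _RAS_TO_LPS @ lps
    img = nib.Nifti1Image(volume.data.astype(np.float32), ras)
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# Centerlines
# ---------------------------------------------------------------------------

def read_centerline(path, radius_array: str = DEFAULT_RADIUS_ARRAY):
    """Read a centerline as (points (N,3) mm, radii (N,), lines).

    ``lines`` is a list of point-index polylines.  Supported formats:
    VTK-XML PolyData (.vtp, ascii) with a per-point radius array named
    ``radius_array``, and the package's JSON dialect (flat polylines or
    the forest dialect of :func:`read_forest`).
    """
    path = Path(path)
    if path.suffix.lower() == ".vtp":
        return _read_vtp(path, radius_array)
    d = json.loads(path.read_text())
    if "segments" in d:
        forest = _forest_from_dict(d)
        return _forest_to_lines(forest)
    return (
        np.asarray(d["points"], dtype=np.float64),
        np.asarray(d["radii"], dtype=np.float64),
        [list(map(int, ln)) for ln in d["lines"]],
    )


def write_centerline(
    points, radii, lines, path, radius_array: str = DEFAULT_RADIUS_ARRAY
) -> None:
    """Write polylines to .vtp (ascii VTK-XML PolyData) or .json."""
    path = Path(path)
    points = np.asarray(points, dtype=np.float64)
    radii = np.asarray(radii, dtype=np.float64)
    if path.suffix.lower() == ".vtp":
        _write_vtp(points, radii, lines, path, radius_array)
        return
    path.write_text(
        json.dumps(
            {
                "points": points.tolist(),
                "radii": radii.tolist(),
                "lines": [list(map(int, ln)) for ln in lines],
            }
        )
    )


def _read_vtp(path: Path, radius_array: str):
    root = ET.parse(str(path)).getroot()
    piece = root.find("./PolyData/Piece")
    if piece is None:
        raise ValueError(f"{path}: not a VTK PolyData file")

    def _floats(el):
        if el.get("format", "ascii") != "ascii":
            raise ValueError(f"{path}: only ascii-format VTP is supported")
        return np.fromstring(el.text, sep=" ")

    pts_el = piece.find("./Points/DataArray")
    points = _floats(pts_el).reshape(-1, 3)
    radii = None
    for arr in piece.findall("./PointData/DataArray"):
        if arr.get("Name") == radius_array:
            radii = _floats(arr)
    if radii is None:
        raise ValueError(
            f"{path}: missing per-point radius array {radius_array!r}"
        )
    conn = offs = None
    for arr in piece.findall("./Lines/DataArray"):
        if arr.get("Name") == "connectivity":
            conn = _floats(arr).astype(int)
        elif arr.get("Name") == "offsets":
            offs = _floats(arr).astype(int)
    if conn is None or offs is None:
        raise ValueError(f"{path}: PolyData has no line connectivity")
    lines, start = [], 0
    for end in offs:
        lines.append(list(conn[start:end]))
        start = end
    return points, radii, lines


def _write_vtp(points, radii, lines, path: Path, radius_array: str) -> None:
    conn = [i for ln in lines for i in ln]
    offs = np.cumsum([len(ln) for ln in lines])
    fmt = lambda a: " ".join(f"{x:.9g}" for x in np.asarray(a).ravel())  # noqa: E731
    xml = (
        '<?xml version="1.0"?>\n'
        '<VTKFile type="PolyData" version="0.1" byte_order="LittleEndian">\n'
        " <PolyData>\n"
        f'  <Piece NumberOfPoints="{len(points)}" NumberOfVerts="0" '
        f'NumberOfLines="{len(lines)}" NumberOfStrips="0" NumberOfPolys="0">\n'
        "   <PointData>\n"
        f'    <DataArray type="Float64" Name="{radius_array}" format="ascii">'
        f"{fmt(radii)}</DataArray>\n"
        "   </PointData>\n"
        "   <Points>\n"
        '    <DataArray type="Float64" NumberOfComponents="3" format="ascii">'
        f"{fmt(points)}</DataArray>\n"
        "   </Points>\n"
        "   <Lines>\n"
        f'    <DataArray type="Int64" Name="connectivity" format="ascii">'
        f"{fmt(conn)}</DataArray>\n"
        f'    <DataArray type="Int64" Name="offsets" format="ascii">'
        f"{fmt(offs)}</DataArray>\n"
        "   </Lines>\n"
        "  </Piece>\n"
        " </PolyData>\n"
        "</VTKFile>\n"
    )
    path.write_text(xml)


# ---------------------------------------------------------------------------
# Forest JSON dialect
# ---------------------------------------------------------------------------

def write_forest(forest: VesselForest, path) -> None:
    d = {
        "segments": [
            {
                "id": sid,
                "points": seg.positions.tolist(),
                "radii": seg.radii.tolist(),
                "parent": seg.parent_id,
                "children": list(seg.child_ids),
                "represented": bool(seg.represented),
            }
            for sid, seg in sorted(forest.segments.items())
        ],
        "roots": list(forest.root_ids),
    }
    Path(path).write_text(json.dumps(d))


def _forest_from_dict(d: dict) -> VesselForest:
    segments = {}
    for s in d["segments"]:
        segments[int(s["id"])] = VesselSegment(
            id=int(s["id"]),
            positions=np.asarray(s["points"], dtype=np.float64),
            radii=np.asarray(s["radii"], dtype=np.float64),
            parent_id=None if s.get("parent") is None else int(s["parent"]),
            child_ids=[int(c) for c in s.get("children", [])],
            represented=bool(s.get("represented", False)),
        )
    return VesselForest(segments=segments, root_ids=[int(r) for r in d["roots"]])


def read_forest(path) -> VesselForest:
    return _forest_from_dict(json.loads(Path(path).read_text()))


def _forest_to_lines(forest: VesselForest):
    pts, rads, lines = [], [], []
    offset = 0
    for sid in sorted(forest.segments):
        seg = forest.segments[sid]
        pts.append(seg.positions)
        rads.append(seg.radii)
        lines.append(list(range(offset, offset + len(seg))))
        offset += len(seg)
    return np.concatenate(pts), np.concatenate(rads), lines


def lines_to_forest(
    points, radii, lines, root_segment_ids=None, cut_segment_ids=None
) -> VesselForest:
    """Build a forest from polylines: merge coincident points into a graph,
    split at branch points and assemble parent/child relations.  When no
    roots are declared, the segment with the largest median radius becomes
    the root."""
    points = np.asarray(points, dtype=np.float64)
    radii = np.asarray(radii, dtype=np.float64)
    # merge duplicated points shared between polylines
    key = np.round(points / 1e-6).astype(np.int64)
    _, uniq_idx, inverse = np.unique(key, axis=0, return_index=True, return_inverse=True)
    edges = set()
    for ln in lines:
        for a, b in zip(ln[:-1], ln[1:]):
            ia, ib = int(inverse[a]), int(inverse[b])
            if ia != ib:
                edges.add((min(ia, ib), max(ia, ib)))
    segs = split_at_branchpoints(points[uniq_idx], radii[uniq_idx], sorted(edges))
    if root_segment_ids is None:
        root_segment_ids = [max(segs, key=lambda s: s.median_radius).id]
    return build_forest(segs, root_segment_ids, cut_segment_ids)


# ---------------------------------------------------------------------------
# Landmarks
# ---------------------------------------------------------------------------

def read_landmarks(path) -> tuple[LandmarkSet | None, LandmarkSet | None]:
    """Read a landmark CSV (label,mx,my,mz,fx,fy,fz,role; mm) into disjoint
    (guidance, validation) sets; rows without a role default to validation
    with a warning."""
    df = pd.read_csv(path)
    required = ["label", "mx", "my", "mz", "fx", "fy", "fz"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"landmark CSV missing columns {missing}")
    if df["label"].duplicated().any():
        dups = sorted(df.loc[df["label"].duplicated(), "label"].unique())
        raise ValueError(f"duplicate landmark labels: {dups}")
    if "role" not in df.columns:
        warnings.warn("landmark CSV has no 'role' column; defaulting to validation")
        df["role"] = "validation"
    if df["role"].isna().any():
        warnings.warn("landmarks with missing role default to validation")
        df["role"] = df["role"].fillna("validation")
    out = []
    for role in ("guidance", "validation"):
        grp = df[df["role"] == role]
        if len(grp) == 0:
            out.append(None)
            continue
        out.append(
            LandmarkSet(
                grp[["mx", "my", "mz"]].to_numpy(float),
                grp[["fx", "fy", "fz"]].to_numpy(float),
                grp["label"].astype(str).tolist(),
                role=role,
            )
        )
    return out[0], out[1]


def write_landmarks(path, *sets: LandmarkSet) -> None:
    rows = []
    for s in sets:
        if s is None:
            continue
        for i in range(len(s)):
            rows.append(
                {
                    "label": s.labels[i],
                    "mx": s.moving[i, 0],
                    "my": s.moving[i, 1],
                    "mz": s.moving[i, 2],
                    "fx": s.fixed[i, 0],
                    "fy": s.fixed[i, 1],
                    "fz": s.fixed[i, 2],
                    "role": s.role,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Full run configuration; unknown YAML keys are rejected and the
    snapshot is embedded in all outputs."""

    metric: MetricConfig = field(default_factory=MetricConfig)
    optimizer: OptimizerConfig = field(default_factory=OptimizerConfig)
    representation_factor: float = 1.0
    cut_segment_ids: list = field(default_factory=list)
    seed: int = 0
    output_dir: str = "."

    def to_dict(self) -> dict:
        return {
            "metric": self.metric.to_dict(),
            "optimizer": self.optimizer.to_dict(),
            "representation_factor": self.representation_factor,
            "cut_segment_ids": list(self.cut_segment_ids),
            "seed": self.seed,
            "output_dir": self.output_dir,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {
            "metric",
            "optimizer",
            "representation_factor",
            "cut_segment_ids",
            "seed",
            "output_dir",
        }
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(d)
        if "metric" in kwargs:
            kwargs["metric"] = MetricConfig.from_dict(kwargs["metric"])
        if "optimizer" in kwargs:
            kwargs["optimizer"] = OptimizerConfig.from_dict(kwargs["optimizer"])
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as f:
            d = yaml.safe_load(f) or {}
        return cls.from_dict(d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as f:
            yaml.safe_dump(self.to_dict(), f)
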