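"""Readers/writers for landmark point sets and analysis report tables.

Point sets travel as 3D Slicer markups fiducial files (the ``.mrk.json``
dialect) or plain CSV (``label,x,y,z``).  Internally everything is RAS
oriented, in mm; LPS-flagged markups are converted on read (x and y
negated).  Dendrite bundles use a CSV with a ``trace`` grouping column.

Report writers emit deterministic TSV tables at the reporting precisions
used throughout: integer Hz, one-decimal semitones, integer percent.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, InvalidInputError
from .geometry import Centerline3D
from .tonotopy import DendriteTrace, RateProfile, TonotopicMap, semitone_difference

__all__ = [
    "LabeledPointSet",
    "read_markups",
    "write_markups",
    "read_points_csv",
    "write_points_csv",
    "read_dendrites_csv",
    "write_dendrites_csv",
    "to_centerline",
    "write_report",
]


@dataclass(frozen=True)
class LabeledPointSet:
    """Named, ordered set of labeled 3D points (RAS, mm)."""

    name: str
    labels: tuple
    points: np.ndarray
    source: str = "synthetic"

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise InvalidInputError("points must be an (n, 3) array")
        if not np.all(np.isfinite(pts)):
            raise InvalidInputError("point coordinates must be finite")
        labels = tuple(str(l) for l in self.labels)
        if len(labels) != len(pts):
            raise InvalidInputError("labels and points must align")
        if len(set(labels)) != len(labels):
            raise InvalidInputError(f"duplicate labels in point set '{self.name}'")
        object.__setattr__(self, "points", pts)
        object.__setattr__(self, "labels", labels)

    def __len__(self):
        return len(self.points)


def to_centerline(pset: LabeledPointSet, label: str | None = None) -> Centerline3D:
    """View a labeled point set as an ordered centerline."""
    return Centerline3D(pset.points, label=label or pset.name)


def read_markups(path) -> LabeledPointSet:
    """Read a 3D Slicer markups fiducial file (.mrk.json) as RAS mm points."""
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as e:
        raise FormatError(f"{path}: not valid JSON ({e})") from e
    markups = doc.get("markups")
    if not isinstance(markups, list) or not markups:
        raise FormatError(f"{path}: missing 'markups' array")
    mk = markups[0]
    coords = mk.get("coordinateSystem", "LPS")
    if coords not in ("RAS", "LPS"):
        raise FormatError(f"{path}: unsupported coordinateSystem '{coords}'")
    cps = mk.get("controlPoints")
    if not isinstance(cps, list):
        raise FormatError(f"{path}: missing 'controlPoints'")
    labels, pts = [], []
    for i, cp in enumerate(cps):
        pos = cp.get("position")
        if pos is None or len(pos) != 3:
            raise FormatError(f"{path}: controlPoints[{i}] missing 3D 'position'")
        labels.append(cp.get("label", f"P{i}"))
        pts.append([float(v) for v in pos])
    pts = np.asarray(pts, dtype=float)
    if coords == "LPS":
        pts[:, 0] *= -1.0
        pts[:, 1] *= -1.0
    return LabeledPointSet(name=mk.get("name", path.stem), labels=labels,
                           points=pts, source=str(path))


def write_markups(pset: LabeledPointSet, path, coordinate_system: str = "RAS") -> None:
    """Write a point set as a Slicer markups fiducial file."""
    if coordinate_system not in ("RAS", "LPS"):
        raise FormatError(f"unsupported coordinateSystem '{coordinate_system}'")
    pts = pset.points.copy()
    if coordinate_system == "LPS":
        pts[:, 0] *= -1.0
        pts[:, 1] *= -1.0
    doc = {
        "@schema": "https://raw.githubusercontent.com/slicer/slicer/master/Modules/Loadable/Markups/Resources/Schema/markups-schema-v1.0.3.json#",
        "markups": [
            {
                "type": "Fiducial",
                "name": pset.name,
                "coordinateSystem": coordinate_system,
                "controlPoints": [
                    {"id": str(i + 1), "label": lab, "position": [float(v) for v in p]}
                    for i, (lab, p) in enumerate(zip(pset.labels, pts))
                ],
            }
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=1) + "\n")


def read_points_csv(path) -> LabeledPointSet:
    """Read a label,x,y,z CSV (header required; mm, RAS)."""
    path = Path(path)
    df = pd.read_csv(path)
    need = ["label", "x", "y", "z"]
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    return LabeledPointSet(
        name=path.stem,
        labels=[str(l) for l in df["label"]],
        points=df[["x", "y", "z"]].to_numpy(dtype=float),
        source=str(path),
    )


def write_points_csv(pset: LabeledPointSet, path) -> None:
    df = pd.DataFrame(pset.points, columns=["x", "y", "z"])
    df.insert(0, "label", list(pset.labels))
    df.to_csv(path, index=False, float_format="%.9f")


def read_dendrites_csv(path) -> list[DendriteTrace]:
    """Read dendrite traces from a trace,label,x,y,z CSV (grouped by trace)."""
    path = Path(path)
    df = pd.read_csv(path)
    need = ["trace", "label", "x", "y", "z"]
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    out = []
    for name, grp in df.groupby("trace", sort=False):
        out.append(DendriteTrace(grp[["x", "y", "z"]].to_numpy(dtype=float), name=str(name)))
    if not out:
        raise FormatError(f"{path}: no dendrite traces")
    return out


def write_dendrites_csv(dendrites, path) -> None:
    rows = []
    for i, tr in enumerate(dendrites):
        name = tr.name or f"d{i:03d}"
        for j, p in enumerate(tr.points):
            rows.append((name, f"{name}_{j}", p[0], p[1], p[2]))
    pd.DataFrame(rows, columns=["trace", "label", "x", "y", "z"]).to_csv(
        path, index=False, float_format="%.9f"
    )


def _hz(v: float) -> str:
    return str(int(math.floor(v + 0.5)))


def write_report(results: dict, out_dir) -> list:
    """Write the analysis report tables; returns the paths written.

    ``results`` keys: ``oc_map`` (required, :class:`TonotopicMap`),
    ``sg_map`` (optional), ``rates`` (optional list of
    :class:`RateProfile`), ``morphometry`` (optional DataFrame).

    Emits (a) ``tonotopy_by_angle.tsv`` — OC and SG frequencies (integer
    Hz) and their absolute semitone difference (one decimal) at 90-degree
    increments of angular depth, with "N/A" beyond the SG's angular extent;
    (b) ``rate_profiles.tsv``; (c) ``morphometry.tsv``.  Output is
    deterministic: identical inputs give byte-identical files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []

    oc: TonotopicMap = results["oc_map"]
    sg: TonotopicMap | None = results.get("sg_map")
    angles = np.arange(0.0, np.floor(oc.angle_deg[-1] / 90.0) * 90.0 + 1e-9, 90.0)
    rows = []
    for ang in angles:
        oc_f = oc.freq_at_angle(ang)
        if sg is not None and sg.angle_deg[0] - 1e-9 <= ang <= sg.angle_deg[-1] + 1e-9:
            sg_f = sg.freq_at_angle(ang)
            sg_cell = _hz(sg_f)
            diff_cell = f"{semitone_difference(oc_f, sg_f):.1f}"
        else:
            sg_cell, diff_cell = "N/A", "N/A"
        rows.append((int(ang), _hz(oc_f), sg_cell, diff_cell))
    table = pd.DataFrame(
        rows, columns=["angle_deg", "oc_freq_hz", "sg_freq_hz", "abs_semitone_diff"]
    )
    p = out_dir / "tonotopy_by_angle.tsv"
    table.to_csv(p, sep="\t", index=False)
    written.append(p)

    rates = results.get("rates")
    if rates:
        frames = []
        for rp in rates:
            df = pd.DataFrame({"position": rp.position, "rate": rp.rate})
            df.insert(0, "unit", rp.unit)
            frames.append(df)
        p = out_dir / "rate_profiles.tsv"
        pd.concat(frames, ignore_index=True).to_csv(
            p, sep="\t", index=False, float_format="%.6f"
        )
        written.append(p)

    morpho = results.get("morphometry")
    if morpho is not None:
        p = out_dir / "morphometry.tsv"
        morpho.to_csv(p, sep="\t", index=False)
        written.append(p)
    return written
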