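"""Readers and writers for the package's table and landmark formats.

Formats are deliberately plain text:

* muscle tables — CSV with columns ``muscle, volume_mm3, length_mm,
  alpha_deg, beta_deg`` (plus derived force columns on output), or an
  equivalent JSON list of row objects;
* lever tables — CSV with columns ``kind, name, length_mm`` where kind is
  ``inlever`` (name = muscle) or ``outlever`` (name = bite point);
* landmarks — CSV with columns ``taxon, side, muscle, role, anchor, x, y,
  z`` (role in origin/insertion/joint/bite, anchor in
  anterior/posterior/centroid), or a JSON list mirroring the schema;
* jaw models — a JSON object with joints, cylinders and scan settings.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .forces import MuscleName
from .gape import JawModel, MuscleCylinder
from .geometry import MuscleGeometry
from .levers import LeverSet

__all__ = [
    "read_muscle_table",
    "write_muscle_table",
    "read_levers",
    "write_levers",
    "read_landmarks",
    "jaw_model_from_landmarks",
    "read_jaw_model",
    "write_jaw_model",
]

MUSCLE_COLUMNS = ["volume_mm3", "length_mm", "alpha_deg", "beta_deg"]
LANDMARK_COLUMNS = ["taxon", "side", "muscle", "role", "anchor", "x", "y", "z"]


def read_muscle_table(path: str | Path) -> dict[str, MuscleGeometry]:
    """Read a muscle measurement table (CSV or JSON) into geometries."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        df = pd.DataFrame(json.loads(path.read_text()))
    else:
        df = pd.read_csv(path)
    missing = [c for c in ["muscle", *MUSCLE_COLUMNS] if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return {
        str(r.muscle): MuscleGeometry(r.volume_mm3, r.length_mm, r.alpha_deg, r.beta_deg)
        for r in df.itertuples()
    }


def write_muscle_table(frame: pd.DataFrame, path: str | Path) -> None:
    """Write a muscle table (index = muscle) to CSV or JSON by extension."""
    path = Path(path)
    out = frame.reset_index()
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(out.to_dict(orient="records"), indent=2))
    else:
        out.to_csv(path, index=False)


def read_levers(path: str | Path) -> LeverSet:
    path = Path(path)
    if path.suffix.lower() == ".json":
        obj = json.loads(path.read_text())
        return LeverSet(inlever=obj["inlever"], outlever=obj["outlever"])
    df = pd.read_csv(path)
    missing = [c for c in ("kind", "name", "length_mm") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    inlever = {r.name: r.length_mm for r in df.itertuples() if r.kind == "inlever"}
    outlever = {r.name: r.length_mm for r in df.itertuples() if r.kind == "outlever"}
    return LeverSet(inlever=inlever, outlever=outlever)


def write_levers(levers: LeverSet, path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".json":
        obj = dict(
            inlever={k.value: v for k, v in levers.inlever.items()},
            outlever=dict(levers.outlever),
        )
        path.write_text(json.dumps(obj, indent=2))
        return
    rows = [{"kind": "inlever", "name": k.value, "length_mm": v} for k, v in levers.inlever.items()]
    rows += [{"kind": "outlever", "name": k, "length_mm": v} for k, v in levers.outlever.items()]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_landmarks(path: str | Path) -> pd.DataFrame:
    """Read a landmark file (CSV or JSON list of row objects)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        df = pd.DataFrame(json.loads(path.read_text()))
    else:
        df = pd.read_csv(path)
    missing = [c for c in LANDMARK_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing landmark columns {missing}")
    return df


def jaw_model_from_landmarks(
    df: pd.DataFrame,
    resting_gape: float = 5.0,
    step: float = 0.5,
    opening_sign: int | None = None,
) -> JawModel:
    """Assemble a JawModel from a landmark table.

    Joints come from ``role == 'joint'`` rows (side L/R; a single midline
    joint row is expanded to a pure mediolateral axis through that point).
    Each muscle with origin and insertion rows at anterior and posterior
    anchors contributes two cylinders; the depressor (mDM) contributes one
    cylinder per available anchor, excluded from limit detection.
    """
    joints = df[df.role == "joint"]
    if len(joints) == 0:
        raise ValueError("landmarks contain no jaw joint")
    if len(joints) == 1:
        p = joints.iloc[0]
        centre = np.array([p.x, p.y, p.z], dtype=float)
        joint_left = centre + np.array([0.0, 1.0, 0.0])
        joint_right = centre - np.array([0.0, 1.0, 0.0])
    else:
        by_side = {str(r.side): np.array([r.x, r.y, r.z], dtype=float) for r in joints.itertuples()}
        if not {"L", "R"} <= set(by_side):
            raise ValueError("two joint landmarks must be tagged side L and R")
        joint_left, joint_right = by_side["L"], by_side["R"]

    def _anchor(muscle: str, role: str, anchor: str) -> np.ndarray | None:
        sel = df[(df.muscle == muscle) & (df.role == role) & (df.anchor == anchor)]
        if len(sel) == 0:
            return None
        return sel[["x", "y", "z"]].to_numpy(dtype=float).mean(axis=0)

    adductors: list[MuscleCylinder] = []
    depressor = None
    for muscle in df[df.role.isin(["origin", "insertion"])].muscle.unique():
        name = MuscleName.parse(muscle)
        for pos, anchor in ((1, "anterior"), (2, "posterior")):
            o = _anchor(muscle, "origin", anchor)
            i = _anchor(muscle, "insertion", anchor)
            if o is None and i is None and anchor != "centroid":
                o = _anchor(muscle, "origin", "centroid")
                i = _anchor(muscle, "insertion", "centroid")
                if o is None or i is None or pos == 2:
                    continue
            if o is None or i is None:
                continue
            cyl = MuscleCylinder(name, pos, o, i)
            if name is MuscleName.mDM:
                depressor = depressor or cyl
            else:
                adductors.append(cyl)
    return JawModel(
        joint_left=joint_left,
        joint_right=joint_right,
        adductors=adductors,
        depressor=depressor,
        resting_gape=resting_gape,
        step=step,
        opening_sign=opening_sign,
    )


def write_jaw_model(model: JawModel, path: str | Path) -> None:
    def cyl(c: MuscleCylinder) -> dict:
        return dict(
            muscle=c.muscle.value,
            position=c.position,
            origin=list(c.origin),
            insertion=list(c.insertion),
        )

    obj = dict(
        joint_left=list(model.joint_left),
        joint_right=list(model.joint_right),
        adductors=[cyl(c) for c in model.adductors],
        depressor=cyl(model.depressor) if model.depressor is not None else None,
        resting_gape=model.resting_gape,
        step=model.step,
        opening_sign=model.opening_sign,
    )
    Path(path).write_text(json.dumps(obj, indent=2))


def read_jaw_model(path: str | Path) -> JawModel:
    obj = json.loads(Path(path).read_text())

    def cyl(d: dict) -> MuscleCylinder:
        return MuscleCylinder(
            MuscleName.parse(d["muscle"]), int(d["position"]),
            np.asarray(d["origin"], float), np.asarray(d["insertion"], float),
        )

    return JawModel(
        joint_left=np.asarray(obj["joint_left"], float),
        joint_right=np.asarray(obj["joint_right"], float),
        adductors=[cyl(d) for d in obj["adductors"]],
        depressor=cyl(obj["depressor"]) if obj.get("depressor") else None,
        resting_gape=float(obj.get("resting_gape", 5.0)),
        step=float(obj.get("step", 0.5)),
        opening_sign=obj.get("opening_sign"),
    )
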