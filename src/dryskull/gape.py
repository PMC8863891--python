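"""Muscle-strain-constrained gape modelling.

Jaw opening is modelled as rigid rotation of the mandible about the
mediolateral axis through the two jaw-joint centres.  Each adductor muscle
is reduced to two straight cylinders joining the anteriormost ("1") and
posteriormost ("2") extents of its origin (cranium-fixed) and insertion
(mandible-fixed) sites.  As the jaw opens in 0.5-degree increments from a
small resting gape (5 degrees by default — the posture the muscles were
reconstructed in), every cylinder's length is tracked relative to its
resting length.  Sarcomere cross-bridge overlap bounds the strain a muscle
can work at: optimal tension is possible up to 130% of resting length and
tension fails entirely at 170%.  The first sampled angles at which any
adductor cylinder reaches those strains are the optimal and maximum gape
limits.  The depressor (mDM), which shortens during opening, never limits
gape; its elongation at the resting posture is reported as a plausibility
check.

Curved muscle wrapping paths are deliberately not modelled during opening —
straight segments only, as their stretch cannot be tracked objectively.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .forces import MuscleName

__all__ = [
    "MuscleCylinder",
    "JawModel",
    "StrainLimits",
    "GapeResult",
    "GapeModelError",
    "rotate_about_axis",
    "cylinder_strain",
    "find_gape_limits",
    "jaw_clearance",
]

_MAX_SCAN_DEG = 180.0


class GapeModelError(ValueError):
    """Raised for degenerate or ambiguous jaw-model geometry."""


def _pt(p) -> np.ndarray:
    a = np.asarray(p, dtype=float).reshape(3)
    if not np.all(np.isfinite(a)):
        raise ValueError(f"non-finite point: {a!r}")
    return a


@dataclass(frozen=True)
class MuscleCylinder:
    """A straight muscle proxy from a cranial origin to a mandibular insertion.

    ``position`` tags the anteriormost ("1") or posteriormost ("2")
    cylinder of a muscle; the id is e.g. ``"mPTv1"``.
    """

    muscle: MuscleName
    position: int  # 1 = anteriormost, 2 = posteriormost
    origin: np.ndarray  # cranium-fixed, mm
    insertion: np.ndarray  # mandible-fixed, mm

    def __post_init__(self) -> None:
        object.__setattr__(self, "origin", _pt(self.origin))
        object.__setattr__(self, "insertion", _pt(self.insertion))
        if self.position not in (1, 2):
            raise ValueError("cylinder position must be 1 (anterior) or 2 (posterior)")
        if np.allclose(self.origin, self.insertion):
            raise ValueError("cylinder origin and insertion coincide")

    @property
    def id(self) -> str:
        return f"{self.muscle.value}{self.position}"

    @property
    def resting_length(self) -> float:
        return float(np.linalg.norm(self.origin - self.insertion))


def rotate_about_axis(point, axis_a, axis_b, theta_deg: float) -> np.ndarray:
    """Rigidly rotate ``point`` about the line through axis_a, axis_b.

    The sense follows the right-hand rule about the axis direction
    ``axis_b - axis_a``; callers decide which sign opens the jaw.
    """
    a, b = _pt(axis_a), _pt(axis_b)
    d = b - a
    n = np.linalg.norm(d)
    if n == 0:
        raise GapeModelError("degenerate rotation axis: the two axis points coincide")
    rot = Rotation.from_rotvec(np.radians(theta_deg) * d / n)
    return a + rot.apply(_pt(point) - a)


@dataclass
class JawModel:
    """Bilateral jaw with a mediolateral rotation axis through the joints.

    ``resting_gape`` is the open angle (degrees) at which all cylinder
    lengths are defined as unstrained; ``step`` the sampling increment of
    the opening cycle.  ``opening_sign`` (+1/-1) picks the rotation sense
    that opens the jaw; leave ``None`` to auto-detect (the sense in which
    the adductors lengthen).
    """

    joint_left: np.ndarray
    joint_right: np.ndarray
    adductors: list[MuscleCylinder]
    depressor: MuscleCylinder | None = None
    resting_gape: float = 5.0
    step: float = 0.5
    opening_sign: int | None = None

    def __post_init__(self) -> None:
        self.joint_left = _pt(self.joint_left)
        self.joint_right = _pt(self.joint_right)
        if np.allclose(self.joint_left, self.joint_right):
            raise GapeModelError("joint points must be distinct (they define the rotation axis)")
        if self.step <= 0:
            raise ValueError("step must be > 0")
        if self.resting_gape < 0:
            raise ValueError("resting_gape must be >= 0")
        if self.opening_sign is not None and self.opening_sign not in (+1, -1):
            raise ValueError("opening_sign must be +1, -1 or None")

    def _sign(self) -> int:
        if self.opening_sign is not None:
            return self.opening_sign
        if not self.adductors:
            raise GapeModelError("cannot auto-detect opening sense without adductors")
        # Opening stretches the adductors: probe both senses with a small
        # rotation and keep the one that lengthens them on average.
        probe = 1.0
        deltas = {}
        for s in (+1, -1):
            total = 0.0
            for c in self.adductors:
                ins = rotate_about_axis(c.insertion, self.joint_left, self.joint_right, s * probe)
                total += np.linalg.norm(c.origin - ins) - c.resting_length
            deltas[s] = total / len(self.adductors)
        best = max(deltas, key=deltas.get)
        if deltas[best] <= 1e-12 or abs(deltas[+1] - deltas[-1]) <= 1e-12:
            raise GapeModelError(
                "opening sense ambiguous (neither rotation sense lengthens the "
                "adductors); set opening_sign explicitly"
            )
        return best

    def cylinders(self) -> list[MuscleCylinder]:
        out = list(self.adductors)
        if self.depressor is not None:
            out.append(self.depressor)
        return out


@dataclass(frozen=True)
class StrainLimits:
    """Length-tension thresholds relative to resting length."""

    optimal: float = 1.3
    maximum: float = 1.7

    def __post_init__(self) -> None:
        # optimal == 1.0 is a degenerate but legal limit: it is hit at the
        # resting gape itself, since resting strain is 1 by definition
        if not (1.0 <= self.optimal < self.maximum):
            raise ValueError("require 1 <= optimal < maximum")


def _lengths_at(model: JawModel, theta: float, sign: int) -> dict[str, float]:
    """Cylinder lengths (mm) at gape ``theta``; mandible-fixed insertions
    rotate by theta - resting_gape, cranial origins stay put."""
    delta = sign * (theta - model.resting_gape)
    out = {}
    for c in model.cylinders():
        ins = rotate_about_axis(c.insertion, model.joint_left, model.joint_right, delta)
        out[c.id] = float(np.linalg.norm(c.origin - ins))
    return out


def cylinder_strain(model: JawModel, theta: float) -> dict[str, float]:
    """Strain factor (length / resting length) of every cylinder at ``theta``.

    At theta == resting_gape every factor is exactly 1.  The depressor,
    whose insertion sits behind the joint, shortens (< 1) as the jaw opens.
    """
    sign = model._sign()
    rest = {c.id: c.resting_length for c in model.cylinders()}
    for cid, l0 in rest.items():
        if l0 <= 0:
            raise GapeModelError(f"cylinder {cid} has zero resting length")
    if theta == model.resting_gape:
        return {cid: 1.0 for cid in rest}
    lengths = _lengths_at(model, theta, sign)
    return {cid: lengths[cid] / rest[cid] for cid in rest}


@dataclass
class GapeResult:
    """Gape limits with the full per-cylinder strain traces.

    ``theta_optimal`` / ``theta_maximum``: first sampled angles (degrees,
    multiples of the step) at which any adductor cylinder reaches the
    optimal / maximum strain limit; ``None`` if never reached before the
    scan ceiling (``open_ended`` is then True).
    ``constraining_optimal`` / ``constraining_maximum``: ids of the
    cylinder(s) crossing first, smallest id first.
    ``depressor_factors``: (elongation at optimal gape, elongation at
    resting gape), both relative to the depressor's length at maximum gape.
    """

    theta_optimal: float | None
    theta_maximum: float | None
    constraining_optimal: list[str]
    constraining_maximum: list[str]
    thetas: np.ndarray
    strain_trace: dict[str, np.ndarray]
    depressor_factors: tuple[float, float] | None = None
    open_ended: bool = False
    max_scanned: float = field(default=_MAX_SCAN_DEG)

    def trace_frame(self):
        """Strain trace as a DataFrame (theta column + one per cylinder)."""
        import pandas as pd

        df = pd.DataFrame({"theta_deg": self.thetas})
        for cid, tr in self.strain_trace.items():
            df[cid] = tr
        return df


def find_gape_limits(model: JawModel, limits: StrainLimits = StrainLimits()) -> GapeResult:
    """Scan the opening cycle and locate the strain-limited gape angles.

    Theta advances from ``resting_gape`` in increments of ``step``; a limit
    is recorded at the first sampled angle whose adductor strain is at or
    above the threshold (no sub-step interpolation — the detection grid is
    the published procedure's keyframe grid).  The depressor is excluded
    from limit detection; its length change is reported post hoc.
    """
    if not model.adductors:
        raise GapeModelError("model has no adductor cylinders")
    sign = model._sign()
    rest = {c.id: c.resting_length for c in model.cylinders()}
    add_ids = [c.id for c in model.adductors]

    thetas = []
    trace: dict[str, list[float]] = {cid: [] for cid in rest}
    theta_opt = None
    theta_max = None
    cons_opt: list[str] = []
    cons_max: list[str] = []

    theta = model.resting_gape
    while theta <= _MAX_SCAN_DEG + 1e-9:
        lengths = _lengths_at(model, theta, sign)
        thetas.append(theta)
        for cid in rest:
            trace[cid].append(lengths[cid] / rest[cid])
        strains = {cid: trace[cid][-1] for cid in add_ids}
        if theta_opt is None:
            hit = sorted(cid for cid, s in strains.items() if s >= limits.optimal)
            if hit:
                theta_opt, cons_opt = theta, hit
        if theta_max is None:
            hit = sorted(cid for cid, s in strains.items() if s >= limits.maximum)
            if hit:
                theta_max, cons_max = theta, hit
        if theta_max is not None:
            break
        theta = round(theta + model.step, 9)

    open_ended = theta_max is None or theta_opt is None
    arr_thetas = np.asarray(thetas)
    arr_trace = {cid: np.asarray(v) for cid, v in trace.items()}

    depressor_factors = None
    if model.depressor is not None and theta_max is not None and theta_opt is not None:
        dep = model.depressor.id
        l_max = _lengths_at(model, theta_max, sign)[dep]
        l_opt = _lengths_at(model, theta_opt, sign)[dep]
        l_rest = rest[dep]
        if l_max <= 0:
            raise GapeModelError("depressor length vanished at maximum gape")
        depressor_factors = (l_opt / l_max, l_rest / l_max)

    return GapeResult(
        theta_optimal=theta_opt,
        theta_maximum=theta_max,
        constraining_optimal=cons_opt,
        constraining_maximum=cons_max,
        thetas=arr_thetas,
        strain_trace=arr_trace,
        depressor_factors=depressor_factors,
        open_ended=open_ended,
        max_scanned=float(arr_thetas[-1]),
    )


def jaw_clearance(model: JawModel, theta: float, anterior_bite_point_mandible, anterior_bite_point_cranium) -> float:
    """Gap (mm) between the opposing anterior bite points at gape ``theta``.

    The bite points are given in the fully closed (0 degree) posture; the
    mandibular point is rotated open by ``theta``.  For a bite point at
    radius r from the joint axis coincident with its cranial counterpart
    when closed, the clearance is the chord 2 r sin(theta/2).
    """
    if theta < 0:
        raise ValueError("theta must be >= 0")
    sign = model._sign()
    mand = rotate_about_axis(
        anterior_bite_point_mandible, model.joint_left, model.joint_right, sign * theta
    )
    return float(np.linalg.norm(mand - _pt(anterior_bite_point_cranium)))
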