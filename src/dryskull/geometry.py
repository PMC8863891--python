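"""Geometric measurement of reconstructed cranial muscles.

This module turns raw 3D data — closed triangle meshes of muscle volumes and
landmark points on the skull — into the scalar quantities the dry-skull
force chain consumes: muscle volume (mm^3), muscle length (mm), sagittal and
coronal insertion angles (degrees), and lever-arm lengths (mm).

Coordinates are plain millimetres in a skull-fixed anatomical frame.  The
frame convention used throughout the package is: the *dorsoventral* axis is
"vertical" (the direction a jaw adductor pulls the mandible towards the
cranium), the sagittal plane is spanned by the anteroposterior and
dorsoventral axes, and the coronal plane by the mediolateral and
dorsoventral axes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "MeshError",
    "TriMesh",
    "AnatomicalFrame",
    "MuscleGeometry",
    "mesh_volume",
    "path_length",
    "insertion_angles",
    "lever_lengths",
]

log = logging.getLogger(__name__)


class MeshError(ValueError):
    """Raised when a mesh violates the closed/oriented preconditions."""


def _as_point(p) -> np.ndarray:
    a = np.asarray(p, dtype=float).reshape(3)
    if not np.all(np.isfinite(a)):
        raise ValueError(f"non-finite coordinates: {a!r}")
    return a


@dataclass
class TriMesh:
    """A triangle mesh: (n, 3) float vertices and (m, 3) int faces."""

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if not np.all(np.isfinite(self.vertices)):
            raise MeshError("mesh vertices contain non-finite coordinates")
        if self.faces.size and (
            self.faces.min() < 0 or self.faces.max() >= len(self.vertices)
        ):
            raise MeshError("face indices out of range")

    @classmethod
    def from_file(cls, path: str | Path) -> "TriMesh":
        """Load an ASCII OBJ or PLY mesh.

        Quads and larger polygons are fan-triangulated on read (delegated to
        trimesh's loader).  No vertex merging or repair is performed: the
        mesh is taken exactly as stored so that closedness problems in the
        input surface are surfaced, not papered over.
        """
        import trimesh as _tm

        loaded = _tm.load(str(path), process=False, force="mesh")
        return cls(np.asarray(loaded.vertices), np.asarray(loaded.faces))

    def validate_closed(self) -> None:
        """Check every edge is shared by exactly two consistently wound faces.

        For a consistently oriented closed surface each undirected edge
        appears exactly twice, once in each direction.  Violations are
        reported with the offending edges.
        """
        if len(self.faces) == 0:
            raise MeshError("mesh has no faces")
        edges = np.concatenate(
            [self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]]
        )
        directed = {}
        for a, b in edges:
            key = (int(a), int(b))
            directed[key] = directed.get(key, 0) + 1
        bad = []
        for (a, b), n in directed.items():
            n_rev = directed.get((b, a), 0)
            if n != 1 or n_rev != 1:
                bad.append((a, b))
        if bad:
            shown = ", ".join(f"{a}-{b}" for a, b in sorted(bad)[:10])
            more = "" if len(bad) <= 10 else f" (+{len(bad) - 10} more)"
            raise MeshError(f"mesh not closed/consistently oriented at edges: {shown}{more}")


def mesh_volume(mesh: TriMesh) -> float:
    """Enclosed volume of a closed triangle mesh, in mm^3.

    Uses the divergence theorem: the signed volumes of the tetrahedra formed
    by each face and the origin sum to the enclosed volume.  The result is
    orientation-normalised (absolute value), so inward- and outward-wound
    meshes give the same number.

    Raises :class:`MeshError` if the mesh is open or inconsistently
    oriented, naming the offending edges.
    """
    mesh.validate_closed()
    v = mesh.vertices
    f = mesh.faces
    signed = np.einsum("ij,ij->i", v[f[:, 0]], np.cross(v[f[:, 1]], v[f[:, 2]])) / 6.0
    return float(abs(signed.sum()))


def path_length(points: Sequence) -> float:
    """Total length in mm of the polyline through ``points`` (>= 2 points).

    With two points this is the straight-line (chord) muscle length; more
    points measure a curved centreline.
    """
    pts = np.asarray([_as_point(p) for p in points], dtype=float)
    if len(pts) < 2:
        raise ValueError("path_length needs at least 2 points")
    return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())


@dataclass(frozen=True)
class AnatomicalFrame:
    """Right-handed orthonormal skull-fixed frame.

    ``dorsoventral`` is the vertical axis against which insertion angles are
    measured; ``anteroposterior`` + ``dorsoventral`` span the sagittal
    plane, ``mediolateral`` + ``dorsoventral`` the coronal plane.
    """

    anteroposterior: np.ndarray
    mediolateral: np.ndarray
    dorsoventral: np.ndarray
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        for name in ("anteroposterior", "mediolateral", "dorsoventral", "origin"):
            object.__setattr__(self, name, _as_point(getattr(self, name)))
        m = np.stack([self.anteroposterior, self.mediolateral, self.dorsoventral])
        if not np.allclose(m @ m.T, np.eye(3), atol=1e-9):
            raise ValueError("frame axes must be mutually orthonormal")
        if np.linalg.det(m) < 0:
            raise ValueError("frame must be right-handed")

    @classmethod
    def standard(cls) -> "AnatomicalFrame":
        """+x anterior, +y left (mediolateral), +z dorsal."""
        return cls(np.array([1.0, 0, 0]), np.array([0, 1.0, 0]), np.array([0, 0, 1.0]))


def insertion_angles(origin_centroid, insertion_centroid, frame: AnatomicalFrame) -> tuple[float, float]:
    """Sagittal (alpha) and coronal (beta) insertion angles, in degrees.

    The line of action runs from the insertion centroid to the origin
    centroid.  ``alpha`` is the angle between the dorsoventral (vertical)
    axis and the projection of the line of action onto the sagittal plane;
    ``beta`` is the analogous angle in the coronal plane.  Signs are folded
    away (only the cosines matter downstream) so both lie in [0, 90]; 90
    marks a line of action with no vertical component, which cannot adduct
    and is rejected when building a MuscleGeometry.

    A line of action orthogonal to a projection plane projects to nothing
    there; that angle is defined as 0 and logged as degenerate.
    """
    o = _as_point(origin_centroid)
    i = _as_point(insertion_centroid)
    v = o - i
    if np.linalg.norm(v) == 0:
        raise ValueError("origin and insertion centroids coincide")
    a = float(np.dot(v, frame.anteroposterior))
    m = float(np.dot(v, frame.mediolateral))
    d = float(np.dot(v, frame.dorsoventral))

    def _fold(horiz: float, vert: float, plane: str) -> float:
        if horiz == 0.0 and vert == 0.0:
            log.warning("line of action orthogonal to the %s plane; angle defined 0", plane)
            return 0.0
        # abs() folds sign away: only the cosine matters downstream.  A
        # fully horizontal line of action yields 90 (degenerate adductor);
        # MuscleGeometry/resultant_force reject it there.
        return float(np.degrees(np.arctan2(abs(horiz), abs(vert))))

    alpha = _fold(a, d, "sagittal")
    beta = _fold(m, d, "coronal")
    return alpha, beta


def lever_lengths(joint_center, insertion_point, bite_points: Sequence) -> tuple[float, list[float]]:
    """Inlever and outlever moment-arm lengths in mm.

    The inlever is the straight-line 3D distance from the jaw joint to the
    muscle's insertion point; each outlever is the distance from the joint
    to a bite point.  Callers wanting sagittal-projected levers should
    project the points before calling.
    """
    j = _as_point(joint_center)
    ins = _as_point(insertion_point)
    inlever = float(np.linalg.norm(ins - j))
    outlevers = [float(np.linalg.norm(_as_point(b) - j)) for b in bite_points]
    return inlever, outlevers


@dataclass(frozen=True)
class MuscleGeometry:
    """Measured geometry of one reconstructed muscle.

    ``csa`` (physiological cross-sectional area proxy) is always
    volume/length, the dry-skull estimator of force-generating area.
    """

    volume: float  # mm^3
    length: float  # mm
    alpha: float = 0.0  # degrees, sagittal
    beta: float = 0.0  # degrees, coronal

    def __post_init__(self) -> None:
        if self.volume < 0:
            raise ValueError(f"volume must be >= 0, got {self.volume}")
        if self.length <= 0:
            raise ValueError(f"length must be > 0, got {self.length}")
        for name, ang in (("alpha", self.alpha), ("beta", self.beta)):
            if not 0 <= ang < 90:
                raise ValueError(f"{name} must lie in [0, 90), got {ang}")

    @property
    def csa(self) -> float:
        """Cross-sectional area, mm^2 (volume / length)."""
        return self.volume / self.length
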