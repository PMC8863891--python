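"""Synthetic jaw generators with controllable ground truth.

Every stage of the measurement -> force -> lever -> gape chain can be
exercised without any real specimen: :func:`make_taxon` builds a bilateral
jaw whose muscle anchor points and volumes are placed so that running the
full pipeline on its output recovers prescribed target forces exactly
(round-trip identity); :func:`make_planar_gape_model` builds a
single-cylinder planar jaw whose strain has a law-of-cosines closed form,
giving an analytic oracle for the gape scan; :func:`make_muscle_mesh`
builds closed tube meshes of exactly known volume for the mesh volumetrics.

Synthetic muscles are straight cylinders with randomised placement rather
than anatomical shapes: the analysis consumes only volume, length, the two
insertion angles, lever arms and anchor points, so realism beyond those
statistics would add nothing the pipeline can see.  All randomness flows
from a single seeded generator per call; there is no global state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .forces import ADDUCTORS, ForceParameters, MuscleName, build_records, force_table
from .gape import JawModel, MuscleCylinder
from .geometry import MuscleGeometry, TriMesh
from .levers import LeverSet, STANDARD_BITE_POINTS, bite_table

__all__ = [
    "SyntheticTaxonSpec",
    "SyntheticTaxon",
    "make_taxon",
    "make_planar_gape_model",
    "make_muscle_mesh",
]


@dataclass(frozen=True)
class SyntheticTaxonSpec:
    """Recipe for a synthetic taxon.

    Default dimensions emulate a mid-sized oviraptorid-like skull: ~150 mm
    long with ~60 mm between the jaw joints, eight bilateral adductor
    pairs plus one depressor, bite points along the palate with outlevers
    decreasing anterior -> posterior.  ``target_fmus`` (N, bilateral) and
    ``target_bite_anterior`` (N) pin the ground truth the pipeline must
    recover; left None they are drawn from broad plausible ranges.
    """

    n_muscles: int = 8
    target_fmus: tuple[float, ...] | None = None
    target_inlevers: tuple[float, ...] | None = None
    target_outlevers: tuple[float, float, float] | None = None
    target_bite_anterior: float | None = None
    skull_length: float = 150.0  # mm
    joint_separation: float = 60.0  # mm
    gape_geometry: str = "full3d"  # or "planar"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_muscles < 1:
            raise ValueError("n_muscles must be >= 1")
        if self.skull_length <= 0 or self.joint_separation <= 0:
            raise ValueError("dimensions must be positive")
        if self.gape_geometry not in ("planar", "full3d"):
            raise ValueError("gape_geometry must be 'planar' or 'full3d'")
        if self.target_fmus is not None:
            if len(self.target_fmus) != self.n_muscles:
                raise ValueError("target_fmus must have n_muscles entries")
            if any(f <= 0 for f in self.target_fmus):
                raise ValueError("target_fmus must be positive (zero/negative volume implied)")
        if self.target_inlevers is not None and len(self.target_inlevers) != self.n_muscles:
            raise ValueError("target_inlevers must have n_muscles entries")
        if self.target_bite_anterior is not None and self.target_bite_anterior <= 0:
            raise ValueError("target_bite_anterior must be positive")


@dataclass
class SyntheticTaxon:
    """Generated jaw model plus the measurement tables and ground truth."""

    model: JawModel
    muscles: pd.DataFrame  # volume_mm3, length_mm, alpha_deg, beta_deg per muscle
    levers: LeverSet
    bite_points: dict[str, np.ndarray]
    params: ForceParameters
    truth: dict


def _muscle_names(n: int) -> list[MuscleName | str]:
    if n <= len(ADDUCTORS):
        return list(ADDUCTORS[:n])
    return list(ADDUCTORS) + [f"syn{i}" for i in range(n - len(ADDUCTORS))]


def make_taxon(spec: SyntheticTaxonSpec) -> SyntheticTaxon:
    """Build a jaw model and measurement table with exact known truth.

    Anchor coordinates are placed inside a skull-sized bounding box; muscle
    volumes are solved from the target forces so that measuring the
    generated geometry and running the force/lever chain reproduces every
    target to machine precision.
    """
    rng = np.random.default_rng(spec.seed)
    params = ForceParameters()
    L = spec.skull_length
    half_sep = spec.joint_separation / 2.0

    # joints on the mediolateral (y) axis; midline joint centre at origin
    joint_left = np.array([0.0, +half_sep, 0.0])
    joint_right = np.array([0.0, -half_sep, 0.0])
    joint_mid = np.zeros(3)

    # bite points on the palate midline, anterior (+x) of the joint
    if spec.target_outlevers is not None:
        outlevers = tuple(float(v) for v in spec.target_outlevers)
    else:
        outlevers = tuple(sorted(rng.uniform(0.35 * L, 0.7 * L, size=3), reverse=True))
    if not (outlevers[0] > outlevers[1] > outlevers[2] > 0):
        raise ValueError(f"outlevers must strictly decrease and stay positive: {outlevers}")
    bite_points = {
        name: np.array([d, 0.0, 0.0]) for name, d in zip(STANDARD_BITE_POINTS, outlevers)
    }

    names = _muscle_names(spec.n_muscles)
    if spec.target_inlevers is not None:
        inlevers = [float(v) for v in spec.target_inlevers]
    else:
        inlevers = list(rng.uniform(0.08 * L, 0.3 * L, size=spec.n_muscles))
    if spec.target_fmus is not None:
        fmus_targets = [float(v) for v in spec.target_fmus]
    else:
        fmus_targets = list(rng.uniform(10.0, 300.0, size=spec.n_muscles))

    rows = []
    cylinders: list[MuscleCylinder] = []
    scale = params.stress_sigma * params.correction_factor * (2.0 if params.bilateral else 1.0)
    for k, (name, inl, fm) in enumerate(zip(names, inlevers, fmus_targets)):
        # insertion on the mandible, anterodorsal of the joint at distance inl
        elev = rng.uniform(np.radians(5), np.radians(35))
        insertion = joint_mid + inl * np.array([np.cos(elev), 0.0, np.sin(elev)])
        # line of action insertion -> origin with prescribed sagittal/coronal
        # deviations from vertical: direction (tan a, tan b, 1)
        alpha = rng.uniform(5.0, 45.0)
        beta = rng.uniform(0.0, 25.0)
        length = rng.uniform(0.15 * L, 0.4 * L)
        d = np.array([math.tan(math.radians(alpha)), math.tan(math.radians(beta)), 1.0])
        d /= np.linalg.norm(d)
        if rng.random() < 0.5:  # posterodorsal vs anterodorsal pull
            d[0] = -d[0]
        origin = insertion + length * d
        volume = fm * length / scale
        rows.append(
            dict(
                muscle=name.value if isinstance(name, MuscleName) else name,
                volume_mm3=volume,
                length_mm=length,
                alpha_deg=alpha,
                beta_deg=beta,
            )
        )
        if isinstance(name, MuscleName):
            off = np.array([0.06 * L, 0.0, 0.0])  # anterior/posterior anchor offsets
            cylinders.append(MuscleCylinder(name, 1, origin + off, insertion + off * 0.3))
            cylinders.append(MuscleCylinder(name, 2, origin - off * 0.5, insertion - off * 0.2))

    # retroarticular depressor: insertion behind the joint, origin on the occiput
    depressor = MuscleCylinder(
        MuscleName.mDM,
        1,
        origin=np.array([-0.10 * L, 0.0, 0.25 * L]),
        insertion=np.array([-0.08 * L, 0.0, 0.0]),
    )

    muscles = pd.DataFrame(rows).set_index("muscle")
    levers = LeverSet(
        inlever={n: v for n, v in zip(names, inlevers)},
        outlever={n: v for n, v in zip(STANDARD_BITE_POINTS, outlevers)},
    )

    if spec.target_bite_anterior is not None:
        # bite force is linear in volume: one global rescale hits the target
        tbl = bite_table(
            force_table(
                build_records(
                    {n: MuscleGeometry(r.volume_mm3, r.length_mm, r.alpha_deg, r.beta_deg)
                     for n, r in zip(names, muscles.itertuples())},
                    params,
                )
            ).records,
            levers,
        )
        factor = spec.target_bite_anterior / float(tbl.totals["anterior"])
        muscles["volume_mm3"] *= factor
        fmus_targets = [f * factor for f in fmus_targets]

    geoms = {
        n: MuscleGeometry(r.volume_mm3, r.length_mm, r.alpha_deg, r.beta_deg)
        for n, r in zip(names, muscles.itertuples())
    }
    ft = force_table(build_records(geoms, params))
    bt = bite_table(ft.records, levers)

    if spec.gape_geometry == "planar":
        flat = np.array([1.0, 0.0, 1.0])
        cylinders = [
            MuscleCylinder(c.muscle, c.position, c.origin * flat, c.insertion * flat)
            for c in cylinders
        ]

    model = JawModel(
        joint_left=joint_left,
        joint_right=joint_right,
        adductors=cylinders,
        depressor=depressor,
        resting_gape=5.0,
        step=0.5,
    )

    bound = 1.5 * L
    coords = np.concatenate(
        [np.stack([c.origin for c in cylinders + [depressor]]),
         np.stack([c.insertion for c in cylinders + [depressor]]),
         np.stack(list(bite_points.values()))]
    )
    assert np.all(np.abs(coords) <= bound), "generated geometry escaped the skull bounding box"

    truth = dict(
        fmus={(n.value if isinstance(n, MuscleName) else n): f for n, f in zip(names, fmus_targets)},
        fres={r.name.value: r.fres for r in ft.adductors},
        sum_fmus=ft.total_fmus,
        sum_fres=ft.total_fres,
        fbite_totals={pt: float(v) for pt, v in bt.totals.items()},
        inlever={(n.value if isinstance(n, MuscleName) else n): v for n, v in zip(names, inlevers)},
        outlever=dict(zip(STANDARD_BITE_POINTS, outlevers)),
    )
    return SyntheticTaxon(
        model=model, muscles=muscles, levers=levers,
        bite_points=bite_points, params=params, truth=truth,
    )


def make_planar_gape_model(
    r_origin: float,
    r_insertion: float,
    initial_angle: float,
    resting_gape: float = 5.0,
    step: float = 0.5,
) -> JawModel:
    """Single-cylinder sagittal-plane jaw with a closed-form strain law.

    The cranial origin sits at radius ``r_origin`` from the joint axis and
    the mandibular insertion at radius ``r_insertion``, separated by
    ``initial_angle`` (phi0, degrees) at the resting gape.  Opening by
    theta - resting_gape widens the enclosed angle, so the cylinder length
    obeys the law of cosines

        l(theta)^2 = r_o^2 + r_i^2 - 2 r_o r_i cos(phi0 + theta - rest)

    which lets any strain-limit crossing be solved exactly by inversion.
    Geometry with phi0 so large that opening initially shortens the
    cylinder cannot represent an adductor and is rejected.
    """
    if r_origin <= 0 or r_insertion <= 0:
        raise ValueError("radii must be positive")
    if not 0.0 < initial_angle < 180.0:
        raise ValueError(
            f"initial_angle={initial_angle} deg is non-adductor geometry: "
            "opening would not lengthen the cylinder"
        )
    phi0 = math.radians(initial_angle)
    joint_left = np.array([0.0, +10.0, 0.0])
    joint_right = np.array([0.0, -10.0, 0.0])
    origin = np.array([0.0, 0.0, r_origin])
    insertion = np.array([r_insertion * math.sin(phi0), 0.0, r_insertion * math.cos(phi0)])
    cyl = MuscleCylinder(MuscleName.mAMES, 1, origin, insertion)
    # the axis direction runs left -> right (-y); the -1 sense is the
    # right-hand rotation about +y, which carries the insertion from +z
    # towards +x and widens the enclosed angle: that is jaw opening here
    return JawModel(
        joint_left=joint_left,
        joint_right=joint_right,
        adductors=[cyl],
        depressor=None,
        resting_gape=resting_gape,
        step=step,
        opening_sign=-1,
    )


def planar_strain_closed_form(
    r_origin: float, r_insertion: float, initial_angle: float, resting_gape: float, theta: float
) -> float:
    """Law-of-cosines strain of the planar model at gape ``theta``."""
    phi0 = math.radians(initial_angle)
    phi = phi0 + math.radians(theta - resting_gape)
    l0 = math.sqrt(r_origin**2 + r_insertion**2 - 2 * r_origin * r_insertion * math.cos(phi0))
    l = math.sqrt(r_origin**2 + r_insertion**2 - 2 * r_origin * r_insertion * math.cos(phi))
    return l / l0


def planar_crossing_angle(
    r_origin: float, r_insertion: float, initial_angle: float, resting_gape: float, strain: float
) -> float | None:
    """Exact gape angle at which the planar model reaches ``strain``.

    Inverts the law of cosines; returns None when the strain is
    unreachable (the cylinder maxes out at phi = 180 degrees).
    """
    phi0 = math.radians(initial_angle)
    l0sq = r_origin**2 + r_insertion**2 - 2 * r_origin * r_insertion * math.cos(phi0)
    cos_phi = (r_origin**2 + r_insertion**2 - strain**2 * l0sq) / (2 * r_origin * r_insertion)
    if cos_phi < -1.0:
        return None
    cos_phi = min(cos_phi, 1.0)
    phi = math.acos(cos_phi)
    if phi < phi0:
        return None
    return resting_gape + math.degrees(phi - phi0)


def make_muscle_mesh(volume_target: float, length: float, seed: int = 0) -> TriMesh:
    """Closed tube mesh whose enclosed volume equals ``volume_target``.

    An n-gon prism of the requested length whose polygon radius is solved
    so the prism volume is exact; the seed varies the facet count and a
    rigid placement (rotation + translation), which leaves the volume
    untouched while changing every vertex.
    """
    if volume_target <= 0 or length <= 0:
        raise ValueError("volume_target and length must be positive")
    rng = np.random.default_rng(seed)
    n = int(rng.integers(24, 64))
    # inscribed n-gon area = 1/2 n r^2 sin(2 pi / n); solve r for exact volume
    r = math.sqrt(2.0 * volume_target / (n * length * math.sin(2 * math.pi / n)))
    ang = 2 * math.pi * np.arange(n) / n
    ring = np.stack([r * np.cos(ang), r * np.sin(ang)], axis=1)
    bottom = np.column_stack([ring, np.zeros(n)])
    top = np.column_stack([ring, np.full(n, length)])
    c_bot = np.array([[0.0, 0.0, 0.0]])
    c_top = np.array([[0.0, 0.0, length]])
    verts = np.concatenate([bottom, top, c_bot, c_top])
    i_cb, i_ct = 2 * n, 2 * n + 1
    faces = []
    for i in range(n):
        j = (i + 1) % n
        faces.append([i, j, n + i])  # side, outward
        faces.append([j, n + j, n + i])
        faces.append([i_cb, j, i])  # bottom cap, normal -z
        faces.append([i_ct, n + i, n + j])  # top cap, normal +z
    faces = np.asarray(faces)

    from scipy.spatial.transform import Rotation

    rot = Rotation.random(rng=rng).as_matrix()
    shift = rng.uniform(-50, 50, size=3)
    verts = verts @ rot.T + shift
    return TriMesh(verts, faces)
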