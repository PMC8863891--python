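"""Dry-skull muscle force estimation.

Converts measured muscle geometry into contraction force and into the
vertical resultant force acting on the mandible:

    Fmus = CSA * sigma            (CSA = volume / length)
    Fres = Fmus * cos(alpha) * cos(beta)

with ``sigma`` the assumed isometric muscle stress (0.3 N/mm^2 by default)
and a dimensionless correction factor (1.5 by default) compensating for
unmodelled architecture such as pennation.  Forces are reported summed over
both sides of a bilaterally symmetric skull when the ``bilateral`` flag is
set (the default); the doubling happens here, once, and never again
downstream.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .geometry import MuscleGeometry

__all__ = [
    "MuscleName",
    "ADDUCTORS",
    "ForceParameters",
    "MuscleRecord",
    "ForceTable",
    "muscle_force",
    "resultant_force",
    "force_table",
    "build_records",
]


class MuscleName(str, enum.Enum):
    """The eight jaw adductors plus the jaw depressor.

    mAME*: m. adductor mandibulae externus medialis / profundus /
    superficialis; mAMP: m. adductor mandibulae posterior; mPST*: m.
    pseudotemporalis superficialis / profundus; mPT*: m. pterygoideus
    dorsalis / ventralis; mDM: m. depressor mandibulae (jaw opener,
    excluded from all adduction sums).
    """

    mAMEM = "mAMEM"
    mAMEP = "mAMEP"
    mAMES = "mAMES"
    mAMP = "mAMP"
    mPSTs = "mPSTs"
    mPSTp = "mPSTp"
    mPTd = "mPTd"
    mPTv = "mPTv"
    mDM = "mDM"

    @classmethod
    def parse(cls, label: str) -> "MuscleName":
        """Accept labels with or without the leading 'm' (e.g. 'AMEM')."""
        s = str(label).strip()
        for cand in (s, "m" + s):
            try:
                return cls(cand)
            except ValueError:
                continue
        lowered = {m.value.lower(): m for m in cls}
        if s.lower() in lowered:
            return lowered[s.lower()]
        if ("m" + s).lower() in lowered:
            return lowered[("m" + s).lower()]
        raise ValueError(f"unknown muscle label: {label!r}")


ADDUCTORS: tuple[MuscleName, ...] = tuple(m for m in MuscleName if m is not MuscleName.mDM)


@dataclass(frozen=True)
class ForceParameters:
    """Dry-skull force model constants.

    stress_sigma: isometric muscle stress, N/mm^2.
    correction_factor: scalar compensating for pennation etc.; set to 1 to
        obtain uncorrected forces.
    bilateral: when True, forces are summed over both (assumed symmetric)
        sides of the skull, i.e. doubled.
    """

    stress_sigma: float = 0.3
    correction_factor: float = 1.5
    bilateral: bool = True

    def __post_init__(self) -> None:
        if self.stress_sigma <= 0:
            raise ValueError("stress_sigma must be > 0")
        if self.correction_factor < 1:
            raise ValueError("correction_factor must be >= 1")


@dataclass
class MuscleRecord:
    """One muscle's geometry plus its derived forces and contributions."""

    name: MuscleName
    geometry: MuscleGeometry
    fmus: float | None = None  # N
    fres: float | None = None  # N
    contribution_fmus: float | None = None  # %
    contribution_fres: float | None = None  # %


def muscle_force(geometry: MuscleGeometry, params: ForceParameters = ForceParameters()) -> float:
    """Contraction force Fmus in newtons.

    (volume/length) * sigma * correction, doubled if bilateral.
    """
    f = geometry.csa * params.stress_sigma * params.correction_factor
    return 2.0 * f if params.bilateral else f


def resultant_force(fmus: float, alpha: float, beta: float) -> float:
    """Vertical resultant Fres = Fmus * cos(alpha) * cos(beta), in newtons."""
    for name, ang in (("alpha", alpha), ("beta", beta)):
        if not 0 <= ang < 90:
            raise ValueError(f"{name} must lie in [0, 90) for an adducting muscle, got {ang}")
    return float(fmus * np.cos(np.radians(alpha)) * np.cos(np.radians(beta)))


@dataclass
class ForceTable:
    """Per-muscle forces with contributions and adductor totals."""

    records: list[MuscleRecord]
    total_volume: float
    total_fmus: float
    total_fres: float

    def __getitem__(self, name: MuscleName | str) -> MuscleRecord:
        key = MuscleName.parse(name) if not isinstance(name, MuscleName) else name
        for r in self.records:
            if r.name is key:
                return r
        raise KeyError(key)

    @property
    def adductors(self) -> list[MuscleRecord]:
        return [r for r in self.records if r.name is not MuscleName.mDM]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            rows.append(
                dict(
                    muscle=r.name.value,
                    volume_mm3=r.geometry.volume,
                    length_mm=r.geometry.length,
                    alpha_deg=r.geometry.alpha,
                    beta_deg=r.geometry.beta,
                    fmus_N=r.fmus,
                    fres_N=r.fres,
                    contribution_fmus_pct=r.contribution_fmus,
                    contribution_fres_pct=r.contribution_fres,
                )
            )
        return pd.DataFrame(rows).set_index("muscle")


def build_records(
    geometries: Mapping[MuscleName | str, MuscleGeometry],
    params: ForceParameters = ForceParameters(),
) -> list[MuscleRecord]:
    """Create records with Fmus/Fres filled in from geometry."""
    out = []
    for name, geo in geometries.items():
        mname = MuscleName.parse(name) if not isinstance(name, MuscleName) else name
        fm = muscle_force(geo, params)
        fr = resultant_force(fm, geo.alpha, geo.beta)
        out.append(MuscleRecord(mname, geo, fmus=fm, fres=fr))
    return out


def force_table(records: Iterable[MuscleRecord]) -> ForceTable:
    """Attach contribution percentages and adductor totals.

    The depressor (mDM), if present, is carried through but excluded from
    the sums and given no contribution.  Contributions are percentages of
    the adductor totals and sum to 100 by construction.
    """
    recs = [replace(r) for r in records]
    adductors = [r for r in recs if r.name is not MuscleName.mDM]
    if not adductors:
        raise ValueError("force_table needs at least one adductor record")
    for r in recs:
        if r.fmus is None or r.fres is None:
            r.fmus = muscle_force(r.geometry)
            r.fres = resultant_force(r.fmus, r.geometry.alpha, r.geometry.beta)
    tot_v = sum(r.geometry.volume for r in adductors)
    tot_m = sum(r.fmus for r in adductors)
    tot_r = sum(r.fres for r in adductors)
    if tot_m <= 0 or tot_r <= 0:
        # all-zero tables are legal (e.g. zero-volume muscles); contributions undefined
        for r in adductors:
            r.contribution_fmus = 0.0
            r.contribution_fres = 0.0
    else:
        for r in adductors:
            r.contribution_fmus = 100.0 * r.fmus / tot_m
            r.contribution_fres = 100.0 * r.fres / tot_r
    return ForceTable(recs, total_volume=tot_v, total_fmus=tot_m, total_fres=tot_r)
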