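"""Jaw lever mechanics: bite forces, mechanical advantage, scaling.

The mandible is treated as a third-class lever rotating about the jaw
joint.  Each muscle's vertical resultant is transmitted to a bite point by

    Fbite = (Fres * L_inlever) / L_outlever

where the inlever is the joint-to-insertion moment arm and the outlever the
joint-to-bite-point moment arm.  Mechanical advantage at a bite point is
the total bite force divided by the total resultant muscle force — the
Fres-weighted mean of the per-muscle lever ratios.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd

from .forces import MuscleName, MuscleRecord

__all__ = [
    "STANDARD_BITE_POINTS",
    "LeverSet",
    "BiteForceTable",
    "bite_force",
    "bite_table",
    "mechanical_advantage",
    "scaled_comparison",
    "relative_csa",
]

#: Conventional bite positions, anterior to posterior along the palate:
#: beak/tooth tip, mid palate/toothrow, posterior (tooth-like) projection.
STANDARD_BITE_POINTS: tuple[str, ...] = ("anterior", "mid_palate", "posterior")


@dataclass
class LeverSet:
    """Inlever per muscle (mm) and outlever per bite point (mm).

    Outlevers are stored in the order given; for the standard three points
    they decrease anterior -> posterior (the joint is behind the toothrow).
    """

    inlever: dict[MuscleName, float] = field(default_factory=dict)
    outlever: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.inlever = {
            (MuscleName.parse(k) if not isinstance(k, MuscleName) else k): float(v)
            for k, v in self.inlever.items()
        }
        self.outlever = {str(k): float(v) for k, v in self.outlever.items()}
        for k, v in self.inlever.items():
            if v <= 0:
                raise ValueError(f"inlever for {k.value} must be > 0, got {v}")
        for k, v in self.outlever.items():
            if v <= 0:
                raise ValueError(f"outlever for {k!r} must be > 0, got {v}")
        if set(self.outlever) == set(STANDARD_BITE_POINTS):
            seq = [self.outlever[p] for p in STANDARD_BITE_POINTS]
            if not (seq[0] > seq[1] > seq[2]):
                raise ValueError(
                    "outlevers must strictly decrease anterior -> posterior "
                    f"for the standard bite points, got {seq}"
                )

    @property
    def bite_points(self) -> list[str]:
        return list(self.outlever)


def bite_force(fres: float, inlever: float, outlever: float) -> float:
    """Fbite = (Fres * inlever) / outlever, in newtons."""
    if outlever <= 0:
        raise ValueError(f"outlever must be > 0, got {outlever}")
    return float(fres * inlever / outlever)


@dataclass
class BiteForceTable:
    """Per-muscle, per-bite-point bite forces with totals and contributions.

    ``fbite``: DataFrame, muscles (rows) x bite points (columns), newtons.
    ``totals``: per-point column sums, newtons.
    ``contribution``: per-muscle percentage of the total; identical at every
    bite point because the common outlever cancels, so a single column
    suffices.
    ``sum_fres``: total adductor resultant force the table was built from.
    """

    fbite: pd.DataFrame
    totals: pd.Series
    contribution: pd.Series
    sum_fres: float

    def to_frame(self, levers: "LeverSet | None" = None) -> pd.DataFrame:
        df = self.fbite.copy()
        if levers is not None:
            df.insert(0, "inlever_mm", [levers.inlever[MuscleName.parse(m)] for m in df.index])
        df["contribution_pct"] = self.contribution
        return df


def bite_table(records: Iterable[MuscleRecord], levers: LeverSet) -> BiteForceTable:
    """Evaluate the lever chain for every adductor at every bite point.

    ``records`` must carry Fres (already summed over both sides upstream;
    no re-doubling happens here).  The depressor is ignored.  A missing
    inlever raises, naming the muscle.
    """
    adductors = [r for r in records if r.name is not MuscleName.mDM]
    if not adductors:
        raise ValueError("bite_table needs at least one adductor record")
    if not levers.outlever:
        raise ValueError("bite_table needs at least one bite point outlever")
    for r in adductors:
        if r.name not in levers.inlever:
            raise ValueError(f"missing inlever for muscle {r.name.value}")
        if r.fres is None:
            raise ValueError(f"record for {r.name.value} has no Fres; run force_table first")

    points = levers.bite_points
    data = {
        pt: [bite_force(r.fres, levers.inlever[r.name], levers.outlever[pt]) for r in adductors]
        for pt in points
    }
    fb = pd.DataFrame(data, index=[r.name.value for r in adductors])
    totals = fb.sum(axis=0)
    sum_fres = float(sum(r.fres for r in adductors))
    # moment (Fres * inlever) fixes the split between muscles at every point
    moments = pd.Series(
        [r.fres * levers.inlever[r.name] for r in adductors],
        index=fb.index,
    )
    msum = float(moments.sum())
    contribution = 100.0 * moments / msum if msum > 0 else moments * 0.0
    return BiteForceTable(fbite=fb, totals=totals, contribution=contribution, sum_fres=sum_fres)


def mechanical_advantage(table: BiteForceTable) -> dict[str, float]:
    """MA per bite point: total Fbite / total Fres.

    Equivalently the Fres-weighted mean of inlever/outlever over muscles.
    """
    if table.sum_fres <= 0:
        raise ValueError("mechanical advantage undefined for zero total Fres")
    return {pt: float(table.totals[pt] / table.sum_fres) for pt in table.totals.index}


def scaled_comparison(
    fbite_target: float,
    fbite_reference: float,
    area_target: float,
    area_reference: float,
) -> float:
    """How much greater a bite force is than isometric area scaling predicts.

    Returns 100 * (F_target / (F_reference * A_target/A_reference) - 1), in
    percent: 0 means the target is exactly what scaling the reference up by
    cranial surface area would give.
    """
    vals = dict(
        fbite_target=fbite_target,
        fbite_reference=fbite_reference,
        area_target=area_target,
        area_reference=area_reference,
    )
    for k, v in vals.items():
        if v <= 0:
            raise ValueError(f"{k} must be > 0, got {v}")
    predicted = fbite_reference * area_target / area_reference
    return float(100.0 * (fbite_target / predicted - 1.0))


def relative_csa(total_csa: float, cranial_surface_area: float) -> float:
    """Total adductor CSA relative to cranial surface area (dimensionless)."""
    if total_csa <= 0 or cranial_surface_area <= 0:
        raise ValueError("relative_csa needs positive inputs")
    return float(total_csa / cranial_surface_area)
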