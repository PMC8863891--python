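"""Published measurement tables for the four study taxa.

The package ships, as plain CSV data, the printed per-muscle measurement
and force tables, lever arms, bite-force tables, mechanical advantage
values and gape-limit summaries for *Incisivosaurus gauthieri*, *Citipati
osmolskae*, *Khaan mckennai* and *Conchoraptor gracilis*.  These values are
stored exactly as printed (one decimal place for forces and millimetres)
and serve as reference inputs/outputs for the force and lever chain.

Two tolerances apply when comparing recomputed values against them:
single-step recomputations from printed inputs of the same table carry the
output rounding half-width (about 0.05 N), while cross-table chains started
from printed (hence rounded) inputs accumulate the input rounding and need
a relative band (about 1%).  ``CHAIN_TOLERANCE`` records the latter.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

import pandas as pd

__all__ = ["TaxonFixture", "FixtureLibrary", "fixtures", "TAXA", "CHAIN_TOLERANCE"]

TAXA = ("Incisivosaurus", "Citipati", "Khaan", "Conchoraptor")

#: relative tolerance for quantities recomputed across tables (rounded inputs)
CHAIN_TOLERANCE = 0.01


@dataclass(frozen=True)
class TaxonFixture:
    """Printed values for one taxon.

    ``muscle_table``: per-muscle volume, length, Fmus, alpha, beta, Fres and
    contributions.  ``bite_table``: per-muscle inlever, per-point Fbite and
    contribution.  ``outlever``: mm per bite point.  ``sums``: printed
    totals.  ``ma``: mechanical advantage per point.  ``gape``: (optimal,
    maximum) gape limits in degrees with the constraining cylinder id.
    ``scaled_pct``: percent by which bite force exceeds surface-area scaling
    of the reference taxon (None for the reference itself).
    """

    name: str
    muscle_table: pd.DataFrame
    bite_table: pd.DataFrame
    outlever: dict[str, float]
    sums: dict[str, float]
    ma: dict[str, float]
    scaled_pct: dict[str, float] | None
    fres_fmus_ratio: float
    relative_csa: float
    gape: tuple[float, float]
    constraining_cylinder: str
    depressor_factors: tuple[float, float]


class FixtureLibrary(dict):
    """Mapping taxon name -> :class:`TaxonFixture` (attribute access too)."""

    def __getattr__(self, name: str) -> TaxonFixture:
        try:
            return self[name]
        except KeyError as exc:
            raise AttributeError(name) from exc


def _read(name: str) -> pd.DataFrame:
    with resources.files("dryskull.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh)


@lru_cache(maxsize=1)
def fixtures() -> FixtureLibrary:
    """Load the printed tables, verbatim, keyed by taxon."""
    muscles = _read("muscle_table.csv")
    bites = _read("bite_table.csv")
    summary = _read("taxon_summary.csv").set_index("taxon")

    lib = FixtureLibrary()
    for taxon in TAXA:
        mt = muscles[muscles.taxon == taxon].drop(columns="taxon").set_index("muscle")
        bt = bites[bites.taxon == taxon].drop(columns="taxon").set_index("muscle")
        s = summary.loc[taxon]
        points = ("anterior", "mid_palate", "posterior")
        scaled = None
        if not pd.isna(s["scaled_pct_anterior"]):
            scaled = {p: float(s[f"scaled_pct_{p}"]) for p in points}
        lib[taxon] = TaxonFixture(
            name=taxon,
            muscle_table=mt,
            bite_table=bt,
            outlever={p: float(s[f"outlever_{p}_mm"]) for p in points},
            sums=dict(
                volume=float(s["sum_volume_mm3"]),
                fmus=float(s["sum_fmus_N"]),
                fres=float(s["sum_fres_N"]),
                **{f"bite_{p}": float(s[f"bite_sum_{p}_N"]) for p in points},
            ),
            ma={p: float(s[f"ma_{p}"]) for p in points},
            scaled_pct=scaled,
            fres_fmus_ratio=float(s["fres_fmus_ratio"]),
            relative_csa=float(s["relative_csa"]),
            gape=(float(s["gape_optimal_deg"]), float(s["gape_maximum_deg"])),
            constraining_cylinder=str(s["constraining_cylinder"]),
            depressor_factors=(float(s["mdm_factor_optimal"]), float(s["mdm_factor_rest"])),
        )
    return lib


def fixture_geometries(taxon: str):
    """Printed volume/length/angles of one taxon as MuscleGeometry objects."""
    from .geometry import MuscleGeometry

    mt = fixtures()[taxon].muscle_table
    return {
        m: MuscleGeometry(r.volume_mm3, r.length_mm, r.alpha_deg, r.beta_deg)
        for m, r in zip(mt.index, mt.itertuples())
    }


def fixture_levers(taxon: str):
    """Printed inlever/outlever set of one taxon as a LeverSet."""
    from .levers import LeverSet

    fx = fixtures()[taxon]
    return LeverSet(
        inlever=dict(zip(fx.bite_table.index, fx.bite_table.inlever_mm)),
        outlever=fx.outlever,
    )
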