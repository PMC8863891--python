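"""End-to-end analysis runs: measurements -> forces -> bite table -> gape.

A :class:`RunConfig` names the inputs and model constants;``run_pipeline``
executes the stages, writes a report bundle (CSV tables plus one JSON
manifest with provenance) and returns the in-memory
:class:`AnalysisReport`.  ``compare_taxa`` places several reports on a
common footing by scaling a reference taxon's bite force by cranial
surface area.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .forces import ForceParameters, build_records, force_table, ForceTable
from .gape import GapeResult, StrainLimits, find_gape_limits
from .io import read_jaw_model, read_levers, read_muscle_table
from .levers import BiteForceTable, bite_table, mechanical_advantage, scaled_comparison

__all__ = ["RunConfig", "AnalysisReport", "PipelineError", "run_pipeline", "compare_taxa"]

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name."""


@dataclass
class RunConfig:
    """Inputs and constants for one analysis run."""

    muscles: str | Path
    levers: str | Path
    model: str | Path | None = None  # jaw-model JSON; gape stage runs only if set
    taxon: str = "specimen"
    force_params: ForceParameters = field(default_factory=ForceParameters)
    strain_limits: StrainLimits = field(default_factory=StrainLimits)
    resting_gape: float | None = None  # None: keep the model file's value
    step: float | None = None
    out_dir: str | Path | None = None
    seed: int | None = None  # echoed into provenance only

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "RunConfig":
        """Load a YAML or JSON config file; keyword overrides win."""
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        fp = raw.pop("force_params", {})
        sl = raw.pop("strain_limits", {})
        return cls(
            force_params=ForceParameters(**fp),
            strain_limits=StrainLimits(**sl),
            **raw,
        )


@dataclass
class AnalysisReport:
    """Every number regenerable from config + inputs; no hidden state."""

    taxon: str
    force_table: ForceTable
    bite_table: BiteForceTable
    mechanical_advantage: dict[str, float]
    gape: GapeResult | None
    provenance: dict

    def manifest(self) -> dict:
        out = dict(
            taxon=self.taxon,
            totals=dict(
                volume_mm3=self.force_table.total_volume,
                fmus_N=self.force_table.total_fmus,
                fres_N=self.force_table.total_fres,
                fbite_N={k: float(v) for k, v in self.bite_table.totals.items()},
            ),
            mechanical_advantage=self.mechanical_advantage,
            provenance=self.provenance,
        )
        if self.gape is not None:
            out["gape"] = dict(
                theta_optimal_deg=self.gape.theta_optimal,
                theta_maximum_deg=self.gape.theta_maximum,
                constraining_optimal=self.gape.constraining_optimal,
                constraining_maximum=self.gape.constraining_maximum,
                depressor_factors=self.gape.depressor_factors,
                open_ended=self.gape.open_ended,
            )
        return out


def _require(path: str | Path, stage: str) -> Path:
    p = Path(path)
    if not p.exists():
        raise PipelineError(f"stage={stage}: input not found: {p}")
    return p


def run_pipeline(config: RunConfig) -> AnalysisReport:
    """Run forces -> bite -> (optional) gape and write the report bundle."""
    geoms = read_muscle_table(_require(config.muscles, "forces"))
    log.info("stage=forces: %d muscles from %s", len(geoms), config.muscles)
    ft = force_table(build_records(geoms, config.force_params))

    levers = read_levers(_require(config.levers, "bite"))
    log.info("stage=bite: %d bite points", len(levers.outlever))
    try:
        bt = bite_table(ft.records, levers)
    except ValueError as exc:
        raise PipelineError(f"stage=bite: {exc}") from exc
    ma = mechanical_advantage(bt)

    gape = None
    if config.model is not None:
        model = read_jaw_model(_require(config.model, "gape"))
        if config.resting_gape is not None:
            model.resting_gape = config.resting_gape
        if config.step is not None:
            model.step = config.step
        log.info("stage=gape: %d adductor cylinders", len(model.adductors))
        try:
            gape = find_gape_limits(model, config.strain_limits)
        except ValueError as exc:
            raise PipelineError(f"stage=gape: {exc}") from exc

    provenance = dict(
        package_version=__version__,
        config=dataclasses.asdict(
            dataclasses.replace(
                config,
                muscles=str(config.muscles),
                levers=str(config.levers),
                model=None if config.model is None else str(config.model),
                out_dir=None if config.out_dir is None else str(config.out_dir),
            )
        ),
        seed=config.seed,
    )
    report = AnalysisReport(
        taxon=config.taxon,
        force_table=ft,
        bite_table=bt,
        mechanical_advantage=ma,
        gape=gape,
        provenance=provenance,
    )
    if config.out_dir is not None:
        write_report(report, config.out_dir, levers)
    return report


def write_report(report: AnalysisReport, out_dir: str | Path, levers=None) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.force_table.to_frame().to_csv(out / "force_table.csv")
    report.bite_table.to_frame(levers).to_csv(out / "bite_table.csv")
    pd.Series(report.mechanical_advantage, name="mechanical_advantage").rename_axis(
        "bite_point"
    ).to_csv(out / "mechanical_advantage.csv")
    if report.gape is not None:
        report.gape.trace_frame().to_csv(out / "strain_trace.csv", index=False)
    (out / "manifest.json").write_text(json.dumps(report.manifest(), indent=2, default=float))


def compare_taxa(
    reports: list[AnalysisReport],
    surface_areas: dict[str, float],
    reference_taxon: str,
) -> pd.DataFrame:
    """Percent by which each taxon's bite force exceeds area-scaling of the
    reference, per bite point, plus the absolute force ranking.

    Taxa without a surface area are skipped with a warning.
    """
    if len(reports) < 2:
        raise ValueError("compare_taxa needs at least two reports")
    by_name = {r.taxon: r for r in reports}
    if reference_taxon not in by_name:
        raise ValueError(f"reference taxon {reference_taxon!r} not among the reports")
    if reference_taxon not in surface_areas:
        raise ValueError(f"no surface area for reference taxon {reference_taxon!r}")
    ref = by_name[reference_taxon]
    ref_area = surface_areas[reference_taxon]

    rows = []
    for r in reports:
        if r.taxon not in surface_areas:
            log.warning("compare_taxa: no surface area for %s; skipped", r.taxon)
            continue
        row: dict = dict(taxon=r.taxon)
        for pt, total in r.bite_table.totals.items():
            if pt not in ref.bite_table.totals.index:
                continue
            row[f"pct_greater_{pt}"] = scaled_comparison(
                float(total),
                float(ref.bite_table.totals[pt]),
                surface_areas[r.taxon],
                ref_area,
            )
        row["max_bite_N"] = float(r.bite_table.totals.max())
        rows.append(row)
    df = pd.DataFrame(rows).set_index("taxon")
    df["rank_by_force"] = df["max_bite_N"].rank(ascending=False).astype(int)
    return df
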