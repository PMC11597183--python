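"""End-to-end analysis pipeline: calibrate, estimate, validate, report.

Stages
------
1. calibrate — build one calibration point per calibration ligand from its
   wild-type bound trajectories, the free-ligand trajectories and the
   replica-averaged experimental free energy, then fit the LIE weights;
2. estimate — apply the fitted weights to every (ligand, variant) system;
3. validate — optional ordinal concordance of the validation ligand's
   per-variant estimates against assay-derived relations;
4. report — affinity matrix, column-normalized heatmap grid (TSV + SVG),
   per-variant drug rankings and a JSON summary.

The pipeline is deterministic: rerunning the same configuration produces
byte-identical numeric tables.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import io as snp_io
from .calibration import FitResult, check_ordinal_concordance, fit_parameters
from .calibration import CalibrationSystem
from .energetics import (
    BindingEstimate,
    EnergyTrajectory,
    LIEParameters,
    aggregate_replicas,
    estimate_binding,
    trajectory_means,
)
from .reporting import (
    AffinityMatrix,
    extreme_combinations,
    normalize_heatmap,
    plot_heatmap,
    rank_ligands,
)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]

log = logging.getLogger("snplie.pipeline")


@dataclass(frozen=True)
class PipelineConfig:
    energy_table: str
    affinity_table: str
    relations_table: Optional[str] = None
    calibration_ligands: Optional[tuple] = None
    validation_ligand: str = "S1P"
    fit_method: str = "least_squares"
    discard_fraction: float = 0.0
    endogenous_ligand: str = "S1P"
    include_endogenous_in_rankings: bool = False
    occupancy_threshold: float = 0.25

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        text = Path(path).read_text()
        raw = yaml.safe_load(text)  # YAML superset also parses JSON
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        if "calibration_ligands" in raw and raw["calibration_ligands"] is not None:
            raw["calibration_ligands"] = tuple(raw["calibration_ligands"])
        return cls(**raw)


@dataclass
class PipelineResult:
    fit: FitResult
    estimates: list
    matrix: AffinityMatrix
    heatmap: np.ndarray
    rankings: dict
    concordance: Optional[float] = None
    extremes: Optional[tuple] = None
    outputs: dict = field(default_factory=dict)


def _pooled_free_means(free_trajs, discard_fraction):
    per = [trajectory_means(t, discard_fraction) for t in free_trajs]
    n = sum(m.n_frames for m in per)
    return (
        sum(m.mean_vdw * m.n_frames for m in per) / n,
        sum(m.mean_elec * m.n_frames for m in per) / n,
    )


def _build_calibration(
    trajs: list[EnergyTrajectory],
    affinities,
    ligands: tuple,
    discard_fraction: float,
) -> list[CalibrationSystem]:
    """One calibration point per ligand: replica-averaged wild-type bound
    means minus pooled free means, against the replica-averaged
    experimental free energy."""
    systems = []
    for ligand in ligands:
        bound = [t for t in trajs if t.ligand == ligand and t.state == "bound"
                 and t.variant == "WT"]
        free = [t for t in trajs if t.ligand == ligand and t.state == "free"]
        if not bound or not free:
            raise ValueError(
                f"calibration ligand {ligand!r} lacks "
                f"{'bound WT' if not bound else 'free-state'} trajectories"
            )
        dg_values = [a.dg_exp for a in affinities if a.ligand == ligand]
        if not dg_values:
            raise ValueError(f"no experimental affinity for calibration ligand {ligand!r}")
        bmeans = [trajectory_means(t, discard_fraction) for t in bound]
        fvdw, felec = _pooled_free_means(free, discard_fraction)
        systems.append(
            CalibrationSystem(
                ligand=ligand,
                delta_vdw=float(np.mean([m.mean_vdw for m in bmeans]) - fvdw),
                delta_elec=float(np.mean([m.mean_elec for m in bmeans]) - felec),
                dg_exp=aggregate_replicas(dg_values)[0],
            )
        )
    return systems


def run_pipeline(config, out_dir) -> PipelineResult:
    """Execute the full analysis and write the report bundle to ``out_dir``.

    ``config`` is a :class:`PipelineConfig` or a path to a YAML/JSON file.
    Missing input files abort before any computation; a stage failure
    aborts with the stage named in the exception.
    """
    if not isinstance(config, PipelineConfig):
        config = PipelineConfig.from_file(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # Pre-flight: every referenced input must exist before we compute.
    inputs = [config.energy_table, config.affinity_table]
    if config.relations_table:
        inputs.append(config.relations_table)
    missing = [p for p in inputs if not Path(p).is_file()]
    if missing:
        raise FileNotFoundError(f"missing input files: {missing}")

    trajs = snp_io.read_energy_table(config.energy_table)
    affinities = snp_io.read_affinity_table(config.affinity_table)
    if not any(t.state == "free" for t in trajs):
        raise ValueError("energy table contains no free-state trajectories")
    log.info("loaded %d trajectories, %d affinities", len(trajs), len(affinities))

    # Stage 1: calibration.
    try:
        ligands = config.calibration_ligands or tuple(
            dict.fromkeys(a.ligand for a in affinities)
        )
        calib = _build_calibration(trajs, affinities, ligands, config.discard_fraction)
        fit = fit_parameters(calib, method=config.fit_method)
    except Exception as exc:
        raise RuntimeError(f"calibration stage failed: {exc}") from exc
    log.info("calibrated alpha=%.4f beta=%.4f rmse=%.4f on %d systems",
             fit.params.alpha, fit.params.beta, fit.rmse, len(calib))

    # Stage 2: estimation for every bound (ligand, variant) system.
    try:
        estimates: list[BindingEstimate] = []
        groups: dict[tuple, list[EnergyTrajectory]] = {}
        for t in trajs:
            if t.state == "bound":
                groups.setdefault((t.ligand, t.variant), []).append(t)
        for (ligand, variant), bound in sorted(groups.items()):
            free = [t for t in trajs if t.ligand == ligand and t.state == "free"]
            if not free:
                raise ValueError(f"no free-state trajectories for ligand {ligand!r}")
            estimates.append(
                estimate_binding(fit.params, bound, free, config.discard_fraction)
            )
    except Exception as exc:
        raise RuntimeError(f"estimation stage failed: {exc}") from exc
    log.info("estimated %d variant-ligand systems", len(estimates))

    # Stage 3: optional ordinal validation on the validation ligand.
    concordance = None
    if config.relations_table:
        try:
            relations = snp_io.read_relations_table(config.relations_table)
            per_variant = {
                e.variant: e.mean_dg
                for e in estimates
                if e.ligand == config.validation_ligand
            }
            concordance = check_ordinal_concordance(per_variant, relations)
        except Exception as exc:
            raise RuntimeError(f"validation stage failed: {exc}") from exc
        log.info("ordinal concordance %.3f over %d relations",
                 concordance, len(relations))

    # Stage 4: reporting.
    try:
        matrix = AffinityMatrix.from_estimates(estimates)
        heatmap = normalize_heatmap(matrix)
        rankings = {
            v: rank_ligands(matrix, v, config.include_endogenous_in_rankings,
                            config.endogenous_ligand)
            for v in matrix.variants
        }
        extremes = extreme_combinations(matrix)

        est_rows = pd.DataFrame(
            {
                "variant": [e.variant for e in estimates],
                "ligand": [e.ligand for e in estimates],
                "mean_dg_kcal_mol": [round(e.mean_dg, 6) for e in estimates],
                "spread_dg_kcal_mol": [round(e.spread_dg, 6) for e in estimates],
                "n_replicas": [len(e.per_replica_dg) for e in estimates],
            }
        )
        outputs = {
            "fit": out / "fit.json",
            "estimates": out / "binding_estimates.tsv",
            "heatmap_grid": out / "heatmap.tsv",
            "heatmap_image": out / "heatmap.svg",
            "rankings": out / "rankings.tsv",
            "summary": out / "summary.json",
        }
        est_rows.to_csv(outputs["estimates"], sep="\t", index=False)
        pd.DataFrame(
            np.round(heatmap, 6), index=list(matrix.variants),
            columns=list(matrix.ligands)
        ).to_csv(outputs["heatmap_grid"], sep="\t")
        plot_heatmap(matrix, outputs["heatmap_image"])
        pd.DataFrame(
            [
                {"variant": v, "rank": i + 1, "ligand": lig}
                for v, order in rankings.items()
                for i, lig in enumerate(order)
            ]
        ).to_csv(outputs["rankings"], sep="\t", index=False)
        outputs["fit"].write_text(
            json.dumps(
                {
                    "alpha": fit.params.alpha,
                    "beta": fit.params.beta,
                    "rmse": fit.rmse,
                    "residuals": list(fit.residuals),
                    "method": fit.method,
                    "condition_flag": fit.condition_flag,
                },
                indent=2,
            )
        )
        outputs["summary"].write_text(
            json.dumps(
                {
                    "n_trajectories": len(trajs),
                    "n_systems": len(estimates),
                    "alpha": fit.params.alpha,
                    "beta": fit.params.beta,
                    "calibration_rmse": fit.rmse,
                    "ordinal_concordance": concordance,
                    "most_favorable": list(extremes[0]),
                    "least_favorable": list(extremes[1]),
                },
                indent=2,
            )
        )
    except Exception as exc:
        raise RuntimeError(f"reporting stage failed: {exc}") from exc
    log.info("wrote report bundle to %s", out)

    return PipelineResult(
        fit=fit,
        estimates=estimates,
        matrix=matrix,
        heatmap=heatmap,
        rankings=rankings,
        concordance=concordance,
        extremes=extremes,
        outputs={k: str(v) for k, v in outputs.items()},
    )
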