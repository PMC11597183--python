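"""Readers and writers for the plain-text table formats.

Energies are kcal/mol throughout; readers refuse files whose energy or
IC50 columns do not declare their unit in the column name
(``e_vdw_kcal_mol``, ``ic50_molar``, ``temperature_K``).  Floats are
written with at least six significant digits.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .calibration import CalibrationSystem, OrdinalRelation
from .energetics import EnergyTrajectory, ExperimentalAffinity
from .occupancy import InteractionEvent, OccupancyRecord

__all__ = [
    "read_energy_table",
    "write_energy_table",
    "read_affinity_table",
    "read_calibration_table",
    "read_relations_table",
    "read_event_table",
    "write_event_table",
    "write_occupancy_report",
]

_ENERGY_COLUMNS = [
    "system_id", "ligand", "variant", "state", "replica", "frame",
    "e_vdw_kcal_mol", "e_elec_kcal_mol",
]

_FLOAT_FORMAT = "%.8g"


def _require(df: pd.DataFrame, columns: Sequence[str], what: str) -> None:
    missing = set(columns) - set(df.columns)
    if missing:
        raise ValueError(
            f"{what} is missing required columns {sorted(missing)} "
            "(energy/affinity columns must declare units in their names)"
        )


def read_energy_table(path) -> list[EnergyTrajectory]:
    """Read per-frame interaction energies into trajectories.

    One trajectory is returned per (system_id, ligand, variant, state,
    replica) group, frames sorted by frame index.
    """
    # keep_default_na: the free-state variant sentinel "NA" is a value,
    # not a missing entry.
    df = pd.read_csv(path, keep_default_na=False)
    _require(df, _ENERGY_COLUMNS, "energy table")
    trajs = []
    keys = ["system_id", "ligand", "variant", "state", "replica"]
    for (system_id, ligand, variant, state, replica), grp in df.groupby(keys, sort=True):
        grp = grp.sort_values("frame")
        trajs.append(
            EnergyTrajectory(
                system_id=str(system_id),
                ligand=str(ligand),
                variant=str(variant),
                state=str(state),
                replica=int(replica),
                e_vdw=grp["e_vdw_kcal_mol"].to_numpy(dtype=float),
                e_elec=grp["e_elec_kcal_mol"].to_numpy(dtype=float),
            )
        )
    return trajs


def write_energy_table(trajs: Iterable[EnergyTrajectory], path) -> None:
    frames = []
    for t in trajs:
        frames.append(
            pd.DataFrame(
                {
                    "system_id": t.system_id,
                    "ligand": t.ligand,
                    "variant": t.variant,
                    "state": t.state,
                    "replica": t.replica,
                    "frame": np.arange(t.n_frames),
                    "e_vdw_kcal_mol": t.e_vdw,
                    "e_elec_kcal_mol": t.e_elec,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(
        path, index=False, float_format=_FLOAT_FORMAT
    )


def read_affinity_table(path) -> list[ExperimentalAffinity]:
    """Read experimental affinities (ligand, ic50_molar, temperature_K,
    source_label); the free energy is derived on load."""
    df = pd.read_csv(path)
    _require(df, ["ligand", "ic50_molar", "temperature_K"], "affinity table")
    if "source_label" not in df.columns:
        df["source_label"] = ""
    return [
        ExperimentalAffinity.from_ic50(
            ligand=str(r.ligand),
            ic50=float(r.ic50_molar),
            temperature=float(r.temperature_K),
            source_label=str(r.source_label),
        )
        for r in df.itertuples(index=False)
    ]


def read_calibration_table(path) -> list[CalibrationSystem]:
    """Read pre-computed calibration points (ligand, delta_vdw, delta_elec,
    dg_exp), all kcal/mol."""
    df = pd.read_csv(path)
    _require(df, ["ligand", "delta_vdw", "delta_elec", "dg_exp"], "calibration table")
    return [
        CalibrationSystem(
            ligand=str(r.ligand),
            delta_vdw=float(r.delta_vdw),
            delta_elec=float(r.delta_elec),
            dg_exp=float(r.dg_exp),
        )
        for r in df.itertuples(index=False)
    ]


def read_relations_table(path) -> list[OrdinalRelation]:
    df = pd.read_csv(path)
    _require(df, ["better", "worse"], "relations table")
    return [OrdinalRelation(better=str(r.better), worse=str(r.worse))
            for r in df.itertuples(index=False)]


def read_event_table(path) -> list[InteractionEvent]:
    """Read per-frame interaction events (the documented CSV conversion of
    profiler reports): system_id, replica, frame, residue_name,
    residue_number, interaction_type."""
    df = pd.read_csv(path)
    _require(
        df,
        ["system_id", "replica", "frame", "residue_name", "residue_number",
         "interaction_type"],
        "event table",
    )
    return [
        InteractionEvent(
            system_id=str(r.system_id),
            replica=int(r.replica),
            frame=int(r.frame),
            residue_name=str(r.residue_name),
            residue_number=int(r.residue_number),
            interaction_type=str(r.interaction_type),
        )
        for r in df.itertuples(index=False)
    ]


def write_event_table(events: Iterable[InteractionEvent], path) -> None:
    pd.DataFrame(events, columns=InteractionEvent._fields).to_csv(path, index=False)


def write_occupancy_report(
    records: Sequence[OccupancyRecord],
    path,
    threshold: float = 0.25,
    mode: str = "pooled",
) -> None:
    """Write a TSV occupancy report with per-replica fractions, the pooled
    fraction, and the filter verdict at ``threshold``."""
    from .occupancy import filter_occupancy

    kept = {r.key for r in filter_occupancy(records, threshold, mode)}
    rows = []
    for r in sorted(records, key=lambda r: r.key):
        row: Mapping = {
            "residue_number": r.residue_number,
            "residue_name": r.residue_name,
            "interaction_type": r.interaction_type,
            "pooled_occupancy": round(r.pooled_occupancy, 6),
            "pass_filter": r.key in kept,
        }
        row = dict(row)
        for i, occ in enumerate(r.per_replica_occupancy, start=1):
            row[f"occupancy_rep{i}"] = round(occ, 6)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
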