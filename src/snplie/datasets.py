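"""Packaged reference datasets for the S1PR1 variant/drug study system.

These small tables collect published experimental and simulation-derived
reference values for sphingosine-1-phosphate receptor 1 (S1PR1) and the
multiple sclerosis drugs that modulate it:

* experimental IC50 measurements for S1P, fingolimod phosphate and
  ponesimod (radioligand competition assays at body temperature);
* binding-site SNPs of S1PR1 with population frequencies and predicted
  impact labels;
* replica-averaged LIE binding free energies of S1P against binding-site
  mutants used for ordinal validation, with the ordinal relations
  established by independent binding assays;
* the full variant x drug matrix of replica-averaged LIE binding free
  energies.

They serve as fixed inputs for calibration, validation and reporting;
nothing in this module computes.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .calibration import OrdinalRelation
from .energetics import ExperimentalAffinity
from .reporting import AffinityMatrix
from .variants import VariantSpec, load_snp_table

__all__ = [
    "load_experimental_affinities",
    "load_reported_dg_columns",
    "load_snp_variants",
    "load_validation_affinities",
    "load_ordinal_relations",
    "load_variant_affinity_matrix",
]


def _data(name: str):
    return resources.files("snplie.data").joinpath(name)


def load_experimental_affinities() -> list[ExperimentalAffinity]:
    """Experimental IC50 values with their derived free energies."""
    df = pd.read_csv(_data("experimental_affinities.csv"))
    return [
        ExperimentalAffinity.from_ic50(
            ligand=str(r.ligand),
            ic50=float(r.ic50_molar),
            temperature=float(r.temperature_K),
            source_label=str(r.source_label),
        )
        for r in df.itertuples(index=False)
    ]


def load_reported_dg_columns() -> dict[str, list[float]]:
    """The per-assay free energies exactly as reported alongside the IC50
    measurements (two-decimal precision), per ligand.  These are the inputs
    for reproducing the reported per-ligand aggregates; minute differences
    from the exact conversion reflect the source's own rounding."""
    df = pd.read_csv(_data("experimental_affinities.csv"))
    return {
        str(lig): [float(v) for v in grp["dg_exp_reported"]]
        for lig, grp in df.groupby("ligand", sort=False)
    }


def load_snp_variants() -> list[VariantSpec]:
    """The seven binding-site SNPs of S1PR1 with frequencies and impact."""
    with resources.as_file(_data("snp_variants.csv")) as path:
        return load_snp_table(path)


def load_validation_affinities() -> dict[str, tuple[float, float]]:
    """Replica-averaged S1P binding free energies per validation mutant:
    variant -> (mean_dg, spread_dg) in kcal/mol."""
    df = pd.read_csv(_data("s1p_validation_affinities.csv"))
    return {
        str(r.variant): (float(r.mean_dg_kcal_mol), float(r.spread_dg_kcal_mol))
        for r in df.itertuples(index=False)
    }


def load_ordinal_relations() -> list[OrdinalRelation]:
    """Ordinal binding-affinity relations established by binding assays."""
    df = pd.read_csv(_data("ordinal_relations.csv"))
    return [OrdinalRelation(better=str(r.better), worse=str(r.worse))
            for r in df.itertuples(index=False)]


def load_variant_affinity_matrix() -> AffinityMatrix:
    """The full variant x ligand matrix of LIE binding free energies."""
    return AffinityMatrix.from_long_frame(
        pd.read_csv(_data("variant_drug_affinities.csv"))
    )
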