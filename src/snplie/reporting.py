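"""Variant x ligand affinity matrices, heatmap normalization and rankings.

The per-variant binding free energies of all ligands are assembled into a
matrix whose columns (ligands) are normalized independently onto a 0-10
scale for heatmap display: 0 marks the variant where that ligand binds
least favorably, 10 the variant where it binds most favorably.  Drug
rankings per variant are strictly free-energy based; the endogenous
modulator (S1P) is carried in the matrix but excluded from therapeutic
rankings by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .energetics import BindingEstimate

__all__ = [
    "AffinityMatrix",
    "ExtremeCell",
    "normalize_heatmap",
    "rank_ligands",
    "extreme_combinations",
    "plot_heatmap",
]


class ExtremeCell(NamedTuple):
    variant: str
    ligand: str
    dg: float


@dataclass(frozen=True)
class AffinityMatrix:
    """Mean and spread of the binding free energy per variant and ligand."""

    variants: tuple
    ligands: tuple
    mean_dg: np.ndarray
    spread_dg: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "variants", tuple(self.variants))
        object.__setattr__(self, "ligands", tuple(self.ligands))
        mean = np.asarray(self.mean_dg, dtype=float)
        spread = np.asarray(self.spread_dg, dtype=float)
        object.__setattr__(self, "mean_dg", mean)
        object.__setattr__(self, "spread_dg", spread)
        shape = (len(self.variants), len(self.ligands))
        if mean.shape != shape or spread.shape != shape:
            raise ValueError(f"grid shapes must be {shape}")
        if len(set(self.variants)) != len(self.variants):
            raise ValueError("variant labels are not unique")
        if len(set(self.ligands)) != len(self.ligands):
            raise ValueError("ligand labels are not unique")
        if not (np.isfinite(mean).all() and np.isfinite(spread).all()):
            raise ValueError("affinity grids contain non-finite values")

    @classmethod
    def from_estimates(cls, estimates: Sequence[BindingEstimate]) -> "AffinityMatrix":
        """Assemble a matrix from per-system estimates (first-appearance
        order for both axes); every variant x ligand cell must be present."""
        variants = list(dict.fromkeys(e.variant for e in estimates))
        ligands = list(dict.fromkeys(e.ligand for e in estimates))
        mean = np.full((len(variants), len(ligands)), np.nan)
        spread = np.full_like(mean, np.nan)
        for e in estimates:
            mean[variants.index(e.variant), ligands.index(e.ligand)] = e.mean_dg
            spread[variants.index(e.variant), ligands.index(e.ligand)] = e.spread_dg
        if np.isnan(mean).any():
            i, j = np.argwhere(np.isnan(mean))[0]
            raise ValueError(f"missing estimate for ({variants[i]}, {ligands[j]})")
        return cls(variants=tuple(variants), ligands=tuple(ligands),
                   mean_dg=mean, spread_dg=spread)

    @classmethod
    def from_long_frame(cls, df: pd.DataFrame) -> "AffinityMatrix":
        """Build from a long table with columns variant, ligand,
        mean_dg_kcal_mol, spread_dg_kcal_mol."""
        required = {"variant", "ligand", "mean_dg_kcal_mol", "spread_dg_kcal_mol"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"long affinity table missing columns: {sorted(missing)}")
        ests = [
            BindingEstimate.from_values(
                system_id=f"{r.variant}:{r.ligand}",
                ligand=str(r.ligand),
                variant=str(r.variant),
                values=[float(r.mean_dg_kcal_mol)],
            )
            for r in df.itertuples(index=False)
        ]
        mat = cls.from_estimates(ests)
        spread = np.array(
            [
                [
                    float(
                        df[(df.variant == v) & (df.ligand == l)]
                        .spread_dg_kcal_mol.iloc[0]
                    )
                    for l in mat.ligands
                ]
                for v in mat.variants
            ]
        )
        return cls(variants=mat.variants, ligands=mat.ligands,
                   mean_dg=mat.mean_dg, spread_dg=spread)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.mean_dg, index=list(self.variants),
                            columns=list(self.ligands))


def normalize_heatmap(matrix: AffinityMatrix) -> np.ndarray:
    """Column-wise 0-10 normalization of the mean free energies.

    For each ligand column, 0 maps the least favorable (highest) dG and 10
    the most favorable (most negative):
    h = 10 * (v - v_least) / (v_most - v_least).  A degenerate constant
    column maps to all zeros with a warning.  The result is invariant
    under any per-column positive-scale affine transform of the input.
    """
    grid = np.zeros_like(matrix.mean_dg)
    for j in range(len(matrix.ligands)):
        col = matrix.mean_dg[:, j]
        v_least, v_most = col.max(), col.min()
        if v_least == v_most:
            warnings.warn(
                f"ligand column {matrix.ligands[j]!r} is constant; "
                "normalized values set to 0",
                RuntimeWarning,
                stacklevel=2,
            )
            continue
        # "+ 0.0" canonicalizes IEEE negative zero at the column minimum
        grid[:, j] = 10.0 * (col - v_least) / (v_most - v_least) + 0.0
    return grid


def rank_ligands(
    matrix: AffinityMatrix,
    variant: str,
    include_endogenous: bool = False,
    endogenous: str = "S1P",
) -> list[str]:
    """Ligands for one variant, most favorable binding first.

    Sorted by ascending mean dG; ties broken by smaller replica spread,
    then by input column order.  The endogenous modulator is excluded
    unless ``include_endogenous`` is set.
    """
    if variant not in matrix.variants:
        raise KeyError(f"unknown variant {variant!r}")
    i = matrix.variants.index(variant)
    candidates = [
        (matrix.mean_dg[i, j], matrix.spread_dg[i, j], j, lig)
        for j, lig in enumerate(matrix.ligands)
        if include_endogenous or lig != endogenous
    ]
    candidates.sort(key=lambda t: (t[0], t[1], t[2]))
    return [lig for *_, lig in candidates]


def extreme_combinations(matrix: AffinityMatrix) -> tuple[ExtremeCell, ExtremeCell]:
    """Globally most and least favorable (variant, ligand, dG) cells.

    Ties are broken by row-major (variant-then-ligand) order.
    Returns ``(most_favorable, least_favorable)``.
    """
    flat = matrix.mean_dg.ravel()  # row-major; argmin/argmax take first tie
    i_min, j_min = np.unravel_index(int(np.argmin(flat)), matrix.mean_dg.shape)
    i_max, j_max = np.unravel_index(int(np.argmax(flat)), matrix.mean_dg.shape)
    most = ExtremeCell(matrix.variants[i_min], matrix.ligands[j_min],
                       float(matrix.mean_dg[i_min, j_min]))
    least = ExtremeCell(matrix.variants[i_max], matrix.ligands[j_max],
                        float(matrix.mean_dg[i_max, j_max]))
    return most, least


def plot_heatmap(matrix: AffinityMatrix, path=None, annotate: bool = True):
    """Render the normalized matrix as a heatmap (returns the Axes).

    The numeric grid, not the image, is the tested artifact; this is a
    convenience for visual inspection.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import seaborn as sns

    grid = normalize_heatmap(matrix)
    fig, ax = plt.subplots(figsize=(1.6 + len(matrix.ligands), 1 + 0.5 * len(matrix.variants)))
    sns.heatmap(
        grid,
        ax=ax,
        cmap="viridis",
        vmin=0,
        vmax=10,
        annot=annotate,
        fmt=".1f",
        xticklabels=list(matrix.ligands),
        yticklabels=list(matrix.variants),
        cbar_kws={"label": "normalized binding favorability (0-10)"},
    )
    ax.set_xlabel("ligand")
    ax.set_ylabel("receptor variant")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
        plt.close(fig)
    return ax
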