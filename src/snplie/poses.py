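"""Ligand pose RMSD and redocking pose selection.

Redocking validation compares docked poses of a ligand against its
crystallographic (native) pose inside the same receptor frame.  Because
both poses share that frame, the RMSD is computed without superposition by
default; an optimal rigid (Kabsch) alignment is available as an opt-in for
frame-independent comparisons.

By convention only heavy atoms enter the comparison: the file readers drop
atoms whose names begin with ``H`` unless configured otherwise.  No
symmetry correction for topologically equivalent atoms (e.g. ring flips)
is applied; atom correspondence is by identical name order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

__all__ = [
    "LigandPose",
    "pose_rmsd",
    "select_best_poses",
    "read_pose_csv",
    "read_poses_pdb",
]


@dataclass(frozen=True)
class LigandPose:
    """An ordered set of named atom coordinates (Å) with an optional
    docking score (dimensionless; lower is better)."""

    ligand: str
    atom_names: tuple
    coords: np.ndarray
    score: Optional[float] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "atom_names", tuple(self.atom_names))
        coords = np.asarray(self.coords, dtype=float)
        object.__setattr__(self, "coords", coords)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValueError("coords must be an (n_atoms, 3) array")
        if len(self.atom_names) != coords.shape[0]:
            raise ValueError(
                f"{len(self.atom_names)} atom names but {coords.shape[0]} coordinates"
            )
        if len(self.atom_names) == 0:
            raise ValueError("a pose must contain at least one atom")
        if not np.isfinite(coords).all():
            raise ValueError("pose coordinates contain non-finite values")
        if self.score is not None and not math.isfinite(self.score):
            raise ValueError("pose score must be finite")

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)


def _check_compatible(a: LigandPose, b: LigandPose) -> None:
    if a.n_atoms != b.n_atoms:
        raise ValueError(f"atom counts differ: {a.n_atoms} vs {b.n_atoms}")
    for i, (na, nb) in enumerate(zip(a.atom_names, b.atom_names)):
        if na != nb:
            raise ValueError(f"atom name mismatch at index {i}: {na!r} vs {nb!r}")


def pose_rmsd(a: LigandPose, b: LigandPose, align: bool = False) -> float:
    """Root-mean-square deviation between two poses of the same ligand.

    With ``align=True``, ``b`` is first rigidly superposed onto ``a``
    (optimal translation + Kabsch rotation), so any rigid motion of a pose
    yields RMSD 0.  Atom names must match in identical order.
    """
    _check_compatible(a, b)
    xa, xb = a.coords, b.coords
    if align:
        ca, cb = xa.mean(axis=0), xb.mean(axis=0)
        rot, _ = Rotation.align_vectors(xa - ca, xb - cb)
        xb = rot.apply(xb - cb) + ca
        xa = a.coords
    return float(np.sqrt(np.mean(np.sum((xa - xb) ** 2, axis=1))))


def select_best_poses(
    poses: Sequence[LigandPose],
    reference: LigandPose,
    top_n: int = 10,
    keep_k: int = 3,
) -> list[tuple[LigandPose, float]]:
    """Redocking pose selection: best scores first, then lowest RMSD.

    The ``top_n`` best-scoring poses (lower score = better; ties keep
    input order) are retained, their unaligned RMSD to the native
    reference is computed, and the ``keep_k`` lowest-RMSD poses are
    returned ascending by RMSD (RMSD ties broken by the better score).

    Returns
    -------
    list of (pose, rmsd) pairs, RMSDs non-decreasing.
    """
    if not keep_k >= 1:
        raise ValueError("keep_k must be >= 1")
    if not top_n >= keep_k:
        raise ValueError(f"top_n ({top_n}) must be >= keep_k ({keep_k})")
    if len(poses) < keep_k:
        raise ValueError(f"only {len(poses)} poses available, need at least {keep_k}")
    for p in poses:
        if p.score is None:
            raise ValueError("all candidate poses must carry a docking score")
        _check_compatible(reference, p)

    # Stable sort keeps input order among equal scores.
    by_score = sorted(range(len(poses)), key=lambda i: poses[i].score)[:top_n]
    scored = [(poses[i], pose_rmsd(reference, poses[i])) for i in by_score]
    scored.sort(key=lambda pr: (pr[1], pr[0].score))
    return scored[:keep_k]


def read_pose_csv(
    path, ligand: str, score: Optional[float] = None, drop_hydrogens: bool = True
) -> LigandPose:
    """Read a pose from a coordinate CSV with columns atom_name, x, y, z."""
    df = pd.read_csv(path)
    missing = {"atom_name", "x", "y", "z"} - set(df.columns)
    if missing:
        raise ValueError(f"pose CSV missing columns: {sorted(missing)}")
    if drop_hydrogens:
        df = df[~df["atom_name"].str.upper().str.startswith("H")]
    return LigandPose(
        ligand=ligand,
        atom_names=tuple(df["atom_name"]),
        coords=df[["x", "y", "z"]].to_numpy(dtype=float),
        score=score,
    )


def read_poses_pdb(
    path,
    residue_name: str,
    ligand: Optional[str] = None,
    drop_hydrogens: bool = True,
) -> list[LigandPose]:
    """Read ligand poses from the HETATM records of a (multi-model) PDB file.

    Each model yields one pose containing the atoms of ``residue_name``,
    heavy atoms only by default.  Scores are not stored in PDB files; attach
    them separately.
    """
    from biotite.structure.io.pdb import PDBFile

    pdb = PDBFile.read(str(path))
    stack = pdb.get_structure(model=None)  # AtomArrayStack over all models
    mask = (stack.res_name == residue_name) & stack.hetero
    if drop_hydrogens:
        mask &= ~np.char.startswith(np.char.upper(stack.atom_name), "H")
    if not mask.any():
        raise ValueError(f"no HETATM records for residue {residue_name!r} in {path}")
    names = tuple(stack.atom_name[mask])
    return [
        LigandPose(
            ligand=ligand or residue_name,
            atom_names=names,
            coords=np.asarray(stack.coord[m][mask], dtype=float),
        )
        for m in range(stack.stack_depth())
    ]


def write_selection_tsv(
    selection: Sequence[tuple[LigandPose, float]], path
) -> None:
    """Write a redocking selection as a TSV of pose index, score and RMSD."""
    rows = [
        {"pose": i, "score": pose.score, "rmsd_angstrom": round(rmsd, 6)}
        for i, (pose, rmsd) in enumerate(selection)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
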