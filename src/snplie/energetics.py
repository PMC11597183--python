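"""Core LIE data model and binding free-energy arithmetic.

The linear interaction energy (LIE) method estimates an absolute binding
free energy from two end-point simulations of the ligand — one bound in the
solvated receptor, one free in solvent — as a weighted sum of the
bound-minus-free differences of the trajectory-averaged van der Waals and
electrostatic ligand–environment interaction energies:

    dG_bind = alpha * (<E_vdW>_bound - <E_vdW>_free)
            + beta  * (<E_elec>_bound - <E_elec>_free)

Experimental reference affinities are obtained from IC50 values through

    dG_exp = R * T * ln(IC50)

with the IC50 in molar units, so that sub-molar potencies map to negative
free energies.  All energies are kcal/mol throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "GAS_CONSTANT_KCAL",
    "BODY_TEMPERATURE_K",
    "EnergyTrajectory",
    "StateMeans",
    "LIEParameters",
    "ExperimentalAffinity",
    "BindingEstimate",
    "dg_from_ic50",
    "trajectory_means",
    "lie_dg",
    "aggregate_replicas",
    "estimate_binding",
]

#: Universal gas constant in kcal mol^-1 K^-1.
GAS_CONSTANT_KCAL = 1.9872036e-3

#: Physiological temperature used for both the simulations and the IC50
#: conversions, in kelvin.
BODY_TEMPERATURE_K = 310.15

_STATES = ("bound", "free")


@dataclass(frozen=True)
class EnergyTrajectory:
    """Per-frame ligand–environment interaction energies for one replica.

    ``state`` distinguishes the ligand bound in the solvated receptor from
    the ligand free in solvent; free-state records carry ``variant="NA"``
    because no receptor is present.
    """

    system_id: str
    ligand: str
    variant: str
    state: str
    replica: int
    e_vdw: np.ndarray
    e_elec: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "e_vdw", np.asarray(self.e_vdw, dtype=float))
        object.__setattr__(self, "e_elec", np.asarray(self.e_elec, dtype=float))
        if self.state not in _STATES:
            raise ValueError(f"state must be one of {_STATES}, got {self.state!r}")
        if self.replica < 1:
            raise ValueError(f"replica must be >= 1, got {self.replica}")
        if self.e_vdw.ndim != 1 or self.e_elec.ndim != 1:
            raise ValueError("energy series must be one-dimensional")
        if len(self.e_vdw) != len(self.e_elec):
            raise ValueError(
                f"e_vdw and e_elec lengths differ: {len(self.e_vdw)} vs {len(self.e_elec)}"
            )
        if len(self.e_vdw) == 0:
            raise ValueError("energy series must be nonempty")
        if not (np.isfinite(self.e_vdw).all() and np.isfinite(self.e_elec).all()):
            raise ValueError("energy series contain non-finite values")
        if self.state == "free" and self.variant != "NA":
            raise ValueError('free-state trajectories must carry variant="NA"')

    @property
    def n_frames(self) -> int:
        return len(self.e_vdw)


@dataclass(frozen=True)
class StateMeans:
    """Trajectory-averaged interaction energies for one state."""

    mean_vdw: float
    mean_elec: float
    n_frames: int

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if not (math.isfinite(self.mean_vdw) and math.isfinite(self.mean_elec)):
            raise ValueError("state means must be finite")


@dataclass(frozen=True)
class LIEParameters:
    """Empirical weights of the van der Waals (alpha) and electrostatic
    (beta) terms of the LIE estimate.  Both are dimensionless; beta may
    legitimately be small or negative for charged, hydrogen-bond donating
    ligands."""

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.alpha) and math.isfinite(self.beta)):
            raise ValueError("LIE parameters must be finite")


@dataclass(frozen=True)
class ExperimentalAffinity:
    """An experimentally determined IC50 with its derived free energy."""

    ligand: str
    ic50: float
    temperature: float
    dg_exp: float = field(init=False)
    source_label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "dg_exp", dg_from_ic50(self.ic50, self.temperature)
        )

    @classmethod
    def from_ic50(
        cls,
        ligand: str,
        ic50: float,
        temperature: float = BODY_TEMPERATURE_K,
        source_label: str = "",
    ) -> "ExperimentalAffinity":
        return cls(ligand=ligand, ic50=ic50, temperature=temperature,
                   source_label=source_label)


@dataclass(frozen=True)
class BindingEstimate:
    """Replica-resolved LIE binding free energy for one receptor–ligand
    system: one dG per bound replica, with their mean and population
    standard deviation."""

    system_id: str
    ligand: str
    variant: str
    per_replica_dg: tuple
    mean_dg: float
    spread_dg: float

    @classmethod
    def from_values(
        cls, system_id: str, ligand: str, variant: str, values: Sequence[float]
    ) -> "BindingEstimate":
        mean, spread = aggregate_replicas(values)
        return cls(
            system_id=system_id,
            ligand=ligand,
            variant=variant,
            per_replica_dg=tuple(float(v) for v in values),
            mean_dg=mean,
            spread_dg=spread,
        )


def dg_from_ic50(ic50: float, temperature: float = BODY_TEMPERATURE_K) -> float:
    """Convert an IC50 (molar) to a free energy dG = R*T*ln(IC50), kcal/mol.

    The conversion treats the IC50 as the inhibition constant directly,
    without a Cheng–Prusoff correction.  Sub-molar IC50 values give
    negative (favorable) free energies; 1 M maps to exactly zero.

    Raises
    ------
    ValueError
        If ``ic50`` or ``temperature`` is not strictly positive.
    """
    if not ic50 > 0:
        raise ValueError(f"ic50 must be > 0 M, got {ic50}")
    if not temperature > 0:
        raise ValueError(f"temperature must be > 0 K, got {temperature}")
    return GAS_CONSTANT_KCAL * temperature * math.log(ic50)


def trajectory_means(
    traj: EnergyTrajectory, discard_fraction: float = 0.0
) -> StateMeans:
    """Average the per-frame energies of one replica.

    ``discard_fraction`` drops that initial fraction of frames before
    averaging (useful when the input still contains equilibration; the
    default assumes production frames only).
    """
    if not 0.0 <= discard_fraction < 1.0:
        raise ValueError("discard_fraction must be in [0, 1)")
    # Ceil: at least the requested fraction is discarded.
    start = math.ceil(len(traj.e_vdw) * discard_fraction)
    vdw = traj.e_vdw[start:]
    elec = traj.e_elec[start:]
    if len(vdw) == 0:
        raise ValueError("no frames remain after discarding the initial fraction")
    return StateMeans(
        mean_vdw=float(vdw.mean()),
        mean_elec=float(elec.mean()),
        n_frames=len(vdw),
    )


def lie_dg(params: LIEParameters, bound: StateMeans, free: StateMeans) -> float:
    """Evaluate the LIE binding free energy from bound and free state means."""
    return params.alpha * (bound.mean_vdw - free.mean_vdw) + params.beta * (
        bound.mean_elec - free.mean_elec
    )


def aggregate_replicas(values: Iterable[float]) -> tuple[float, float]:
    """Mean and population standard deviation (divisor n) of replica values.

    The population convention (``ddof=0``) is deliberate: it is the spread
    measure used for the replica aggregates throughout this package.
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("cannot aggregate an empty list of replica values")
    if not np.isfinite(arr).all():
        raise ValueError("replica values contain non-finite entries")
    return float(arr.mean()), float(arr.std(ddof=0))


def _pooled_means(trajs: Sequence[EnergyTrajectory], discard_fraction: float) -> StateMeans:
    """Frame-weighted pooled means across replicas."""
    per = [trajectory_means(t, discard_fraction) for t in trajs]
    n = sum(m.n_frames for m in per)
    vdw = sum(m.mean_vdw * m.n_frames for m in per) / n
    elec = sum(m.mean_elec * m.n_frames for m in per) / n
    return StateMeans(mean_vdw=vdw, mean_elec=elec, n_frames=n)


def estimate_binding(
    params: LIEParameters,
    bound_trajs: Sequence[EnergyTrajectory],
    free_trajs: Sequence[EnergyTrajectory],
    discard_fraction: float = 0.0,
    pair_replicas: bool = False,
) -> BindingEstimate:
    """Estimate the binding free energy of one receptor–ligand system.

    By default the free-state means are pooled (frame-weighted) across all
    free-ligand replicas and reused against every bound replica, yielding
    one dG per bound replica; their mean and population standard deviation
    form the estimate.  With ``pair_replicas=True`` each bound replica is
    instead paired with the free replica of the same replica index.

    Raises
    ------
    ValueError
        If bound and free trajectories disagree on the ligand, if either
        list is empty, or (in paired mode) if a bound replica has no
        free-state partner.
    """
    if not bound_trajs:
        raise ValueError("at least one bound-state trajectory is required")
    if not free_trajs:
        raise ValueError("at least one free-state trajectory is required")
    ligands = {t.ligand for t in bound_trajs} | {t.ligand for t in free_trajs}
    if len(ligands) != 1:
        raise ValueError(f"bound and free trajectories mix ligands: {sorted(ligands)}")
    for t in bound_trajs:
        if t.state != "bound":
            raise ValueError(f"replica {t.replica} passed as bound has state {t.state!r}")
    for t in free_trajs:
        if t.state != "free":
            raise ValueError(f"replica {t.replica} passed as free has state {t.state!r}")

    bound_sorted = sorted(bound_trajs, key=lambda t: t.replica)
    if pair_replicas:
        free_by_replica = {t.replica: t for t in free_trajs}
        per_dg = []
        for t in bound_sorted:
            if t.replica not in free_by_replica:
                raise ValueError(f"no free-state replica {t.replica} to pair with")
            per_dg.append(
                lie_dg(
                    params,
                    trajectory_means(t, discard_fraction),
                    trajectory_means(free_by_replica[t.replica], discard_fraction),
                )
            )
    else:
        free_means = _pooled_means(free_trajs, discard_fraction)
        per_dg = [
            lie_dg(params, trajectory_means(t, discard_fraction), free_means)
            for t in bound_sorted
        ]

    ref = bound_sorted[0]
    return BindingEstimate.from_values(ref.system_id, ref.ligand, ref.variant, per_dg)
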