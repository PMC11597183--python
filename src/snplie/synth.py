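"""Synthetic generators for every input the analysis consumes.

The molecular dynamics and docking engines are outside this package; their
outputs are emulated here with known ground truth so every downstream
operation can be exercised end to end:

* interaction-energy time series — stationary AR(1) Gaussian fluctuations
  around configurable means, mimicking equilibrated production trajectories
  with autocorrelated energy noise, five independent replicas per system;
* calibration sets — bound-minus-free energy gaps with experimental free
  energies generated from known LIE weights plus Gaussian noise;
* contact event streams — a two-state (present/absent) Markov chain whose
  stationary on-probability equals the requested occupancy, with a
  configurable mean contact lifetime;
* docked poses — i.i.d. Gaussian coordinate jitter around a reference pose
  with scores monotone in the jitter magnitude plus noise.

All generators are pure functions of (spec, seed): identical inputs give
identical outputs.  Replica ``r`` derives its stream from ``seed ^ r``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np

from .calibration import CalibrationSystem
from .energetics import EnergyTrajectory, LIEParameters, lie_dg, StateMeans
from .occupancy import INTERACTION_TYPES, InteractionEvent
from .poses import LigandPose

__all__ = [
    "EnergyGenSpec",
    "ContactGenSpec",
    "gen_energy_trajectories",
    "gen_calibration_set",
    "gen_contact_stream",
    "gen_jittered_poses",
]


@dataclass(frozen=True)
class EnergyGenSpec:
    """Ground truth for an AR(1) interaction-energy generator.

    The series obeys x_t = mu + phi * (x_{t-1} - mu) + eps_t with
    eps ~ Normal(0, sigma^2 * (1 - phi^2)), so the marginal distribution is
    Normal(mu, sigma^2) for any phi in [0, 1).
    """

    mean_vdw: float
    mean_elec: float
    sd_vdw: float = 2.0
    sd_elec: float = 3.0
    ar1_phi: float = 0.8
    n_frames: int = 10_000
    n_replicas: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sd_vdw < 0 or self.sd_elec < 0:
            raise ValueError("standard deviations must be >= 0")
        if not 0.0 <= self.ar1_phi < 1.0:
            raise ValueError("ar1_phi must lie in [0, 1)")
        if self.n_frames < 1 or self.n_replicas < 1:
            raise ValueError("n_frames and n_replicas must be >= 1")


@dataclass(frozen=True)
class ContactGenSpec:
    """Ground truth for a two-state persistent contact generator.

    ``persistence`` is the mean contact lifetime in frames (geometric
    sojourn).  The off->on and on->off transition probabilities are chosen
    so the chain's stationary on-probability equals ``true_occupancy``.
    """

    true_occupancy: float
    persistence: float = 2.0
    n_frames: int = 10_000
    n_replicas: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.true_occupancy <= 1.0:
            raise ValueError("true_occupancy must lie in [0, 1]")
        if self.persistence < 1.0:
            raise ValueError("persistence (mean lifetime) must be >= 1 frame")
        if self.n_frames < 1 or self.n_replicas < 1:
            raise ValueError("n_frames and n_replicas must be >= 1")
        # Off-state exit probability p_on = pi/(1-pi) * 1/L must not exceed 1.
        pi, L = self.true_occupancy, self.persistence
        if pi < 1.0 and pi / (1.0 - pi) / L > 1.0:
            raise ValueError(
                "infeasible spec: occupancy too high for the requested persistence"
            )


def _replica_rng(seed: int, replica: int) -> np.random.Generator:
    return np.random.default_rng(seed ^ replica)


def _ar1(rng: np.random.Generator, mu: float, sigma: float, phi: float, n: int) -> np.ndarray:
    if sigma == 0.0:
        return np.full(n, mu)
    x = np.empty(n)
    x[0] = rng.normal(mu, sigma)  # stationary initial condition
    innov = rng.normal(0.0, sigma * math.sqrt(1.0 - phi * phi), size=n - 1)
    for t in range(1, n):
        x[t] = mu + phi * (x[t - 1] - mu) + innov[t - 1]
    return x


def gen_energy_trajectories(
    spec: EnergyGenSpec,
    system_id: str,
    ligand: str,
    variant: str = "NA",
    state: str = "free",
) -> list[EnergyTrajectory]:
    """Generate one AR(1) energy trajectory per replica (replicas 1..n)."""
    trajs = []
    for r in range(1, spec.n_replicas + 1):
        rng = _replica_rng(spec.seed, r)
        e_vdw = _ar1(rng, spec.mean_vdw, spec.sd_vdw, spec.ar1_phi, spec.n_frames)
        e_elec = _ar1(rng, spec.mean_elec, spec.sd_elec, spec.ar1_phi, spec.n_frames)
        trajs.append(
            EnergyTrajectory(
                system_id=system_id,
                ligand=ligand,
                variant=variant,
                state=state,
                replica=r,
                e_vdw=e_vdw,
                e_elec=e_elec,
            )
        )
    return trajs


def gen_calibration_set(
    true_params: LIEParameters,
    n_systems: int,
    gap_ranges: tuple[tuple[float, float], tuple[float, float]] = ((-40.0, -10.0), (-30.0, 0.0)),
    noise_sd: float = 0.0,
    seed: int = 0,
) -> list[CalibrationSystem]:
    """Generate calibration points whose dg_exp follows the LIE model.

    Bound-minus-free gaps are drawn uniformly from ``gap_ranges``
    ((vdw_lo, vdw_hi), (elec_lo, elec_hi)); the experimental free energy is
    the exact LIE prediction under ``true_params`` plus Normal(0, noise_sd)
    observation noise.
    """
    if n_systems < 2:
        raise ValueError("n_systems must be >= 2")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    (v_lo, v_hi), (e_lo, e_hi) = gap_ranges
    dvdw = rng.uniform(v_lo, v_hi, size=n_systems)
    delec = rng.uniform(e_lo, e_hi, size=n_systems)
    noise = rng.normal(0.0, noise_sd, size=n_systems) if noise_sd > 0 else np.zeros(n_systems)
    systems = []
    for i in range(n_systems):
        bound = StateMeans(mean_vdw=dvdw[i], mean_elec=delec[i], n_frames=1)
        free = StateMeans(mean_vdw=0.0, mean_elec=0.0, n_frames=1)
        systems.append(
            CalibrationSystem(
                ligand=f"lig{i:03d}",
                delta_vdw=float(dvdw[i]),
                delta_elec=float(delec[i]),
                dg_exp=float(lie_dg(true_params, bound, free) + noise[i]),
            )
        )
    return systems


def _two_state_series(
    rng: np.random.Generator, pi_on: float, persistence: float, n: int
) -> np.ndarray:
    """Boolean presence series from the stationary two-state Markov chain."""
    if pi_on == 0.0:
        return np.zeros(n, dtype=bool)
    if pi_on == 1.0:
        return np.ones(n, dtype=bool)
    p_off = 1.0 / persistence                      # on -> off
    p_on = pi_on / (1.0 - pi_on) / persistence     # off -> on
    # Alternating geometric sojourns reproduce the chain exactly and avoid
    # a per-frame Python loop.
    state = bool(rng.random() < pi_on)             # stationary start
    mean_len = persistence if state else 1.0 / p_on
    est_runs = int(2 * n / min(mean_len, n) + 20)
    out = np.empty(n, dtype=bool)
    pos = 0
    while pos < n:
        lens_on = rng.geometric(p_off, size=est_runs)
        lens_off = rng.geometric(p_on, size=est_runs)
        for k in range(est_runs):
            run = lens_on[k] if state else lens_off[k]
            end = min(pos + int(run), n)
            out[pos:end] = state
            pos = end
            state = not state
            if pos >= n:
                break
    return out


def gen_contact_stream(
    spec: ContactGenSpec,
    residue_name: str = "LEU",
    residue_number: int = 205,
    interaction_type: str = "hydrophobic",
    system_id: str = "synthetic",
) -> tuple[list[InteractionEvent], dict[int, int]]:
    """Generate a persistent contact event stream across replicas.

    Returns the event list together with the frames-per-replica map that
    :func:`snplie.occupancy.compute_occupancy` expects.
    """
    if interaction_type not in INTERACTION_TYPES:
        raise ValueError(f"unknown interaction type {interaction_type!r}")
    events: list[InteractionEvent] = []
    frames = {r: spec.n_frames for r in range(1, spec.n_replicas + 1)}
    for r in range(1, spec.n_replicas + 1):
        rng = _replica_rng(spec.seed, r)
        present = _two_state_series(rng, spec.true_occupancy, spec.persistence, spec.n_frames)
        events.extend(
            InteractionEvent(system_id, r, int(f), residue_name, residue_number, interaction_type)
            for f in np.flatnonzero(present)
        )
    return events, frames


def gen_jittered_poses(
    reference: LigandPose,
    sigma: float,
    n_poses: int,
    score_rule: Optional[Callable[[float, np.random.Generator], float]] = None,
    seed: int = 0,
) -> list[LigandPose]:
    """Generate docked-pose candidates by Gaussian coordinate jitter.

    Each pose displaces every coordinate by i.i.d. Normal(0, sigma^2), so
    for many atoms the expected RMSD to the reference approaches
    sigma * sqrt(3).  ``score_rule(rmsd, rng)`` assigns the docking score
    (default: the RMSD plus Normal(0, 0.1) noise, i.e. near-native poses
    tend to score best).
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if n_poses < 1:
        raise ValueError("n_poses must be >= 1")
    if score_rule is None:
        score_rule = lambda rmsd, rng: rmsd + rng.normal(0.0, 0.1)
    rng = np.random.default_rng(seed)
    poses = []
    for _ in range(n_poses):
        disp = rng.normal(0.0, sigma, size=reference.coords.shape) if sigma > 0 else 0.0
        coords = reference.coords + disp
        rmsd = float(np.sqrt(np.mean(np.sum((coords - reference.coords) ** 2, axis=1))))
        poses.append(
            LigandPose(
                ligand=reference.ligand,
                atom_names=reference.atom_names,
                coords=coords,
                score=float(score_rule(rmsd, rng)),
            )
        )
    return poses
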