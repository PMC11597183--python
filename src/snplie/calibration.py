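"""Empirical calibration of the LIE weights and ordinal validation.

The two LIE weights (alpha for van der Waals, beta for electrostatics) are
fitted so that the predicted binding free energies of a small calibration
set of ligands match their IC50-derived experimental free energies.  Two
fitting routes are provided: a no-intercept ordinary least-squares solve of
the 2-column linear model, and an exhaustive grid scan anchored at the
literature starting point (0.161, 0.48).

Fitted parameters are then sanity-checked against ordinal experimental
evidence — pairs of systems for which binding assays establish which binds
more favorably — rather than against absolute affinities.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .energetics import LIEParameters

__all__ = [
    "CalibrationSystem",
    "FitResult",
    "OrdinalRelation",
    "LITERATURE_START",
    "fit_parameters",
    "check_ordinal_concordance",
]

#: Literature starting values (alpha, beta) for the grid scan.
LITERATURE_START = (0.161, 0.48)

#: Relative singular-value cutoff below which the 2-column design is
#: treated as numerically rank-deficient.
_RANK_RTOL = 1e-10


@dataclass(frozen=True)
class CalibrationSystem:
    """One calibration point: bound-minus-free mean-energy gaps paired with
    the experimental free energy they should predict (all kcal/mol)."""

    ligand: str
    delta_vdw: float
    delta_elec: float
    dg_exp: float

    def __post_init__(self) -> None:
        for name in ("delta_vdw", "delta_elec", "dg_exp"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite for ligand {self.ligand!r}")


@dataclass(frozen=True)
class FitResult:
    params: LIEParameters
    residuals: tuple
    rmse: float
    method: str
    condition_flag: bool = False
    intercept: float = 0.0

    def __post_init__(self) -> None:
        if self.rmse < 0:
            raise ValueError("rmse must be >= 0")


@dataclass(frozen=True)
class OrdinalRelation:
    """An experimentally established ordering: ``better`` binds more
    favorably (more negative dG) than ``worse``."""

    better: str
    worse: str

    def __post_init__(self) -> None:
        if self.better == self.worse:
            raise ValueError(f"relation labels must be distinct, got {self.better!r} twice")


def _design(systems: Sequence[CalibrationSystem], with_intercept: bool):
    X = np.array([[s.delta_vdw, s.delta_elec] for s in systems], dtype=float)
    if with_intercept:
        X = np.hstack([X, np.ones((len(systems), 1))])
    y = np.array([s.dg_exp for s in systems], dtype=float)
    return X, y


def _finalize(
    systems: Sequence[CalibrationSystem],
    alpha: float,
    beta: float,
    intercept: float,
    method: str,
    condition_flag: bool,
) -> FitResult:
    pred = np.array(
        [alpha * s.delta_vdw + beta * s.delta_elec + intercept for s in systems]
    )
    y = np.array([s.dg_exp for s in systems])
    resid = pred - y
    return FitResult(
        params=LIEParameters(alpha=alpha, beta=beta),
        residuals=tuple(float(r) for r in resid),
        rmse=float(np.sqrt(np.mean(resid**2))),
        method=method,
        condition_flag=condition_flag,
        intercept=float(intercept),
    )


def fit_parameters(
    systems: Sequence[CalibrationSystem],
    method: str = "least_squares",
    bounds: tuple[tuple[float, float], tuple[float, float]] = ((-0.5, 1.5), (-0.5, 1.5)),
    grid_step: float = 0.01,
    with_intercept: bool = False,
) -> FitResult:
    """Fit the LIE weights to a calibration set.

    Parameters
    ----------
    systems:
        Calibration points (at least two).
    method:
        ``"least_squares"`` solves the no-intercept linear model
        min ||alpha*dvdw + beta*delec - dg_exp||^2 exactly;
        ``"grid"`` scans a bounded (alpha, beta) lattice anchored at the
        literature start (0.161, 0.48) and returns the lattice minimizer.
    bounds:
        ((alpha_lo, alpha_hi), (beta_lo, beta_hi)) box for the grid scan.
    grid_step:
        Lattice spacing of the grid scan.
    with_intercept:
        Adds a constant offset column (off by default, matching the
        two-parameter LIE model).

    Notes
    -----
    A rank-deficient (collinear) design does not abort the least-squares
    fit: the minimum-norm solution is returned with ``condition_flag``
    set and a warning issued.
    """
    if len(systems) < 2:
        raise ValueError("at least two calibration systems are required")

    if method == "least_squares":
        X, y = _design(systems, with_intercept)
        sol, _, rank, sv = np.linalg.lstsq(X, y, rcond=None)
        flag = rank < X.shape[1] or sv[-1] < _RANK_RTOL * sv[0]
        if flag:
            warnings.warn(
                "calibration design is collinear; returning the minimum-norm "
                "least-squares solution",
                RuntimeWarning,
                stacklevel=2,
            )
        intercept = float(sol[2]) if with_intercept else 0.0
        return _finalize(systems, float(sol[0]), float(sol[1]), intercept,
                         "least_squares", bool(flag))

    if method == "grid":
        (a_lo, a_hi), (b_lo, b_hi) = bounds
        a0, b0 = LITERATURE_START
        # Lattice anchored at the literature start so that it is always a
        # candidate, clipped to the requested box.
        alphas = a0 + grid_step * np.arange(
            math.ceil((a_lo - a0) / grid_step), math.floor((a_hi - a0) / grid_step) + 1
        )
        betas = b0 + grid_step * np.arange(
            math.ceil((b_lo - b0) / grid_step), math.floor((b_hi - b0) / grid_step) + 1
        )
        X, y = _design(systems, with_intercept=False)
        # SSE over the lattice, vectorized: pred[i,j,k] for alpha_i, beta_j.
        pred = alphas[:, None, None] * X[:, 0] + betas[None, :, None] * X[:, 1]
        sse = ((pred - y) ** 2).sum(axis=-1)
        i, j = np.unravel_index(int(np.argmin(sse)), sse.shape)
        return _finalize(systems, float(alphas[i]), float(betas[j]), 0.0, "grid", False)

    raise ValueError(f"unknown fit method {method!r}")


def check_ordinal_concordance(
    estimates: Mapping[str, float], relations: Sequence[OrdinalRelation]
) -> float:
    """Fraction of ordinal relations satisfied by the estimates.

    A relation is satisfied when the ``better`` label's free energy is
    strictly more negative than the ``worse`` label's; ties count as
    violations.  The result is invariant under any common positive-scale
    affine transform of the estimates.
    """
    if len(relations) == 0:
        raise ValueError("relation list is empty")
    hits = 0
    for rel in relations:
        for label in (rel.better, rel.worse):
            if label not in estimates:
                raise KeyError(f"no estimate for label {label!r}")
        if estimates[rel.better] < estimates[rel.worse]:
            hits += 1
    return hits / len(relations)
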