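# Methods

## The model

`snplie` implements end-point binding free-energy analysis by the linear
interaction energy (LIE) method for the sphingosine-1-phosphate receptor 1
(S1PR1) and the multiple sclerosis drugs that modulate it, with particular
attention to nonsynonymous binding-site SNPs. The binding free energy of a
ligand is estimated from two equilibrium simulations — the ligand bound in
the solvated receptor and the ligand free in solvent — as

    ΔG_bind = α (⟨E_vdW⟩_bound − ⟨E_vdW⟩_free) + β (⟨E_elec⟩_bound − ⟨E_elec⟩_free)

where ⟨·⟩ is the trajectory average of the ligand–environment van der Waals
or electrostatic interaction energy and α, β are empirical dimensionless
weights. Experimental reference affinities are derived from IC50 values as
ΔG_exp = R·T·ln(IC50), with R = 1.9872036×10⁻³ kcal·mol⁻¹·K⁻¹,
T = 310.15 K and the IC50 in molar units, taken directly as the inhibition
constant (no Cheng–Prusoff correction). This package consumes per-frame
interaction-energy tables; computing those energies from raw MD
trajectories, and the simulations themselves, are out of scope.

Key modelling assumptions:

* **Stationarity.** Input energy series are production frames of an
  equilibrated simulation; `discard_fraction` (default 0) exists for inputs
  that still contain equilibration and removes `ceil(n·fraction)` initial
  frames (ceiling so that the "nothing left" error state is reachable).
* **Free-state pooling.** The free-ligand state is simulated independently
  of any receptor variant, so its means are pooled frame-weighted across
  all free replicas and reused against every bound replica. Per-replica
  pairing (`pair_replicas=True`) is available but not the default.
* **Replica spread.** Replicas are independent simulations differing only
  in their random seed. Aggregates use the **population** standard
  deviation (divisor n, not n−1) — the convention that reproduces the
  reference experimental aggregates to their printed precision; the sample
  convention does not.

## Parameter calibration

`fit_parameters` solves the no-intercept two-column linear model
min Σ(αΔvdW + βΔelec − ΔG_exp)² exactly via least squares (`numpy.lstsq`;
the minimum-norm solution with a condition flag and warning on collinear
designs), or scans an (α, β) lattice (default box [−0.5, 1.5]², step 0.01)
anchored at the literature starting point (0.161, 0.48), which brackets
both that start and the fitted values reported for this receptor system
(0.46, 0.09). An optional constant offset is available but off by default,
matching the two-parameter model. Negative β values are legitimate for
charged, hydrogen-bond-donating ligands and are not clipped.

The calibration trio for the packaged study is S1P, fingolimod and
ponesimod — the three ligands for which IC50 measurements are packaged.
The reference study's own fitted values (0.46, 0.09) are a plausibility
band only, not a test target: the underlying per-replica mean energies are
not available, so recovery is validated on synthetic calibration sets with
known ground truth instead.

Validation of fitted parameters is ordinal, not absolute:
`check_ordinal_concordance` scores the fraction of assay-established
"binds better than" relations satisfied by the per-variant estimates, with
ties counted as violations. The statistic is invariant under any common
positive-scale affine transform of the estimates.

## Variant model

Mutation codes combine UniProt P21453 sequence numbering with optional
Ballesteros–Weinstein generic numbers. Three input spellings are accepted
(`A293T`, `A293(7.35)T`, `A293^7.35^T`); the canonical output is the
parenthesized form, because superscript notation does not survive plain
text. Silent substitutions and non-canonical residue letters are parse
errors; no renumbering or rsID→coordinate mapping is attempted.

## Interaction occupancy

Occupancy is keyed by (residue number, interaction type) at residue
granularity, ignoring atom-level donor/acceptor identity. Replicas are
pooled frame-weighted by default (`pooled = Σ event frames / Σ frames`,
identically the frame-weighted mean of per-replica occupancies); because
the per-simulation reading of the 25% reporting convention is also
defensible, per-replica occupancies are retained and an
`any_replica` filter mode is provided. The filter threshold is inclusive
(≥). Note that for a contact whose true occupancy sits exactly at the
threshold, sampling noise makes the filter verdict a coin flip no matter
how many frames are observed; the filter separates occupancies reliably
only when they differ from the threshold by a few standard errors.

## Pose analysis

Pose RMSD is computed without superposition by default, since docked and
native poses share the receptor frame in redocking validation; optimal
rigid superposition (Kabsch, via `scipy.spatial.transform.Rotation
.align_vectors`) is opt-in. Readers keep heavy atoms only unless told
otherwise. Atom correspondence is by identical name order; no
graph-automorphism symmetry correction (equivalent ring atoms) is applied —
a known limitation that can overstate RMSD for symmetric ligands.
Redocking selection takes the `top_n = 10` best-scoring poses (lower score
is better, ties keep input order) and returns the `keep_k = 3` lowest-RMSD
ones, RMSD ties broken by the better score.

## Synthetic data

The generators emulate the statistical structure of the real inputs, with
known ground truth:

* **Energies** — stationary AR(1) series x_t = μ + φ(x_{t−1} − μ) + ε,
  ε ~ N(0, σ²(1−φ²)), so the marginal is exactly N(μ, σ²). Defaults:
  5 replicas, 10⁴ frames (a desk-scale stand-in for 100 ns production
  runs), σ_vdW = 2, σ_elec = 3 kcal/mol, φ = 0.8.
* **Calibration sets** — uniform bound-minus-free gaps (vdW in
  [−40, −10], elec in [−30, 0] kcal/mol, the scale typical of drug-sized
  ligands with charged groups) with ΔG_exp generated by the exact LIE
  forward model plus Gaussian observation noise.
* **Contacts** — a two-state Markov chain with stationary on-probability
  equal to the target occupancy and geometric sojourns with mean contact
  lifetime `persistence` (default 2 frames); generated by alternating
  geometric run lengths, which reproduces the chain exactly. High
  occupancies require proportionally long persistence (the off-state exit
  probability must not exceed 1); infeasible combinations are rejected.
* **Poses** — i.i.d. Gaussian jitter per coordinate (RMSD → σ√3 for many
  atoms) with scores monotone in jitter magnitude plus noise.

All generators are pure functions of (spec, seed); replica r draws from
`seed ⊕ r`. What the generators deliberately do **not** reproduce:
force-field physics, slow conformational drift, correlated vdW/elec
fluctuations, and water-mediated contact networks. Passing tests therefore
demonstrate the correctness of the estimators and decision rules, not the
physical accuracy of any simulation engine.

## Reporting

Heatmap normalization is **per ligand column**: h = 10(v − v_least)/(v_most
− v_least), where v_most is the most negative entry, so each column spans
exactly [0, 10]; a constant column degenerates to zeros with a warning.
Variant-wise (row) normalization is deliberately rejected — the scale is
meant to compare mutations within a drug, not drugs within a mutation.
Consequently the normalized values are *not* comparable across a row, and
per-variant drug rankings are computed from the raw free energies
(ascending mean, ties by smaller replica spread, then input order), with
the endogenous modulator S1P excluded from therapeutic rankings by default.
Rankings are strictly ΔG-based; pharmacokinetics and tolerability are out
of scope. Global extremes break ties in row-major order.

The pipeline (`run_pipeline`) wires the stages together from a YAML/JSON
configuration, fails before any computation if an input file is missing,
names the failing stage on error, and writes a plain-text report bundle
(TSVs + JSON summary + SVG heatmap; the numeric grid, not the image, is
the tested artifact). It is deterministic: identical configuration gives
byte-identical numeric tables.

## Numerical choices and scale

* Rank deficiency threshold for the calibration design: smallest singular
  value < 10⁻¹⁰ × largest.
* Floats in written tables carry ≥6 significant digits; energy and IC50
  columns must declare units in their names (`e_vdw_kcal_mol`,
  `ic50_molar`) or the readers refuse the file.
* Test and acceptance problem sizes: 10⁴–10⁵ frames per synthetic series,
  5 replicas, 200-seed Monte-Carlo recovery studies — sizes chosen so the
  statistical assertions (3-standard-error bands, ±0.01 occupancy
  concentration) are sharp at desk scale.
* The exact IC50→ΔG conversion of 1.40×10⁻⁹ M at 310.15 K is
  −12.5651 kcal/mol, which rounds to −12.57; the packaged reported value
  for those assays is −12.56 (the source's own rounding). Aggregates of
  reported columns therefore use the reported two-decimal values as
  inputs.
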