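"""Unit and property tests for the LIE energy model."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from snplie import (
    BODY_TEMPERATURE_K,
    GAS_CONSTANT_KCAL,
    EnergyTrajectory,
    LIEParameters,
    StateMeans,
    aggregate_replicas,
    dg_from_ic50,
    estimate_binding,
    lie_dg,
    trajectory_means,
)
from snplie.synth import EnergyGenSpec, gen_energy_trajectories


def make_traj(e_vdw, e_elec=None, state="bound", variant="WT", replica=1, ligand="lig"):
    e_vdw = np.asarray(e_vdw, dtype=float)
    e_elec = e_vdw * 0.5 if e_elec is None else np.asarray(e_elec, dtype=float)
    return EnergyTrajectory(
        system_id="sys", ligand=ligand, variant=variant if state == "bound" else "NA",
        state=state, replica=replica, e_vdw=e_vdw, e_elec=e_elec,
    )


class TestDgFromIc50:
    @pytest.mark.parametrize(
        "ic50, expected, tol",
        [
            (1.60e-10, -13.90, 0.005),  # strongest S1P assay
            (4.70e-10, -13.24, 0.005),
            (6.70e-10, -13.02, 0.005),
            (1.40e-9, -12.56, 0.01),  # source rounded down; exact is -12.5651
            (2.80e-10, -13.56, 0.005),  # strongest fingolimod assay
            (2.10e-9, -12.31, 0.01),
            (2.20e-9, -12.29, 0.005),
            (1.30e-8, -11.19, 0.005),  # ponesimod
        ],
    )
    def test_reproduces_experimental_conversions(self, ic50, expected, tol):
        assert dg_from_ic50(ic50, BODY_TEMPERATURE_K) == pytest.approx(expected, abs=tol)

    def test_molar_reference_state_is_zero(self):
        assert dg_from_ic50(1.0, BODY_TEMPERATURE_K) == 0.0

    @pytest.mark.parametrize("ic50, temp", [(0.0, 310.15), (-1e-9, 310.15), (1e-9, 0.0)])
    def test_domain_errors(self, ic50, temp):
        with pytest.raises(ValueError):
            dg_from_ic50(ic50, temp)

    @given(
        lo=st.floats(min_value=-12, max_value=0),
        delta=st.floats(min_value=0.01, max_value=6),
        temp=st.floats(min_value=250, max_value=350),
    )
    def test_monotone_and_linear_in_log_ic50(self, lo, delta, temp):
        a, b = 10.0**lo, 10.0 ** (lo + delta)
        dga, dgb = dg_from_ic50(a, temp), dg_from_ic50(b, temp)
        assert dga < dgb
        slope = (dgb - dga) / (math.log(b) - math.log(a))
        assert slope == pytest.approx(GAS_CONSTANT_KCAL * temp, rel=1e-9)


class TestTrajectoryMeans:
    def test_constant_series(self):
        m = trajectory_means(make_traj([-20.0] * 10))
        assert m.mean_vdw == -20.0 and m.n_frames == 10

    def test_two_point_mean(self):
        m = trajectory_means(make_traj([-1.0, -3.0]))
        assert m.mean_vdw == -2.0

    def test_discard_fraction_drops_initial_frames(self):
        m = trajectory_means(make_traj([0.0, 0.0, -4.0, -6.0]), discard_fraction=0.5)
        assert m.mean_vdw == -5.0 and m.n_frames == 2

    def test_empty_after_discard_raises(self):
        with pytest.raises(ValueError, match="discard"):
            trajectory_means(make_traj([-1.0]), discard_fraction=0.99)

    def test_ar1_series_mean_within_three_standard_errors(self):
        mu, sigma, phi, n = -15.0, 2.0, 0.9, 100_000
        spec = EnergyGenSpec(mean_vdw=mu, mean_elec=-40.0, sd_vdw=sigma,
                             sd_elec=sigma, ar1_phi=phi, n_frames=n,
                             n_replicas=1, seed=11)
        traj = gen_energy_trajectories(spec, "sys", "lig")[0]
        se = sigma * math.sqrt((1 + phi) / (1 - phi) / n)
        assert abs(trajectory_means(traj).mean_vdw - mu) < 3 * se


class TestLieDg:
    def test_hand_evaluated_example(self):
        params = LIEParameters(alpha=0.46, beta=0.09)
        bound = StateMeans(mean_vdw=-25.0, mean_elec=-15.0, n_frames=1)
        free = StateMeans(mean_vdw=-5.0, mean_elec=-5.0, n_frames=1)
        assert lie_dg(params, bound, free) == pytest.approx(-10.1)

    def test_zero_coefficients_give_zero(self):
        bound = StateMeans(-30.0, -40.0, 5)
        free = StateMeans(-4.0, -35.0, 5)
        assert lie_dg(LIEParameters(0.0, 0.0), bound, free) == 0.0

    def test_equal_states_give_zero(self):
        m = StateMeans(-12.0, -20.0, 5)
        assert lie_dg(LIEParameters(0.46, 0.09), m, m) == 0.0

    @given(
        alpha=st.floats(-1, 1), beta=st.floats(-1, 1),
        dv=st.floats(-50, 0), de=st.floats(-50, 0),
    )
    def test_linear_in_alpha(self, alpha, beta, dv, de):
        bound = StateMeans(dv, de, 1)
        free = StateMeans(0.0, 0.0, 1)
        double = lie_dg(LIEParameters(2 * alpha, beta), bound, free)
        single = lie_dg(LIEParameters(alpha, beta), bound, free)
        zero = lie_dg(LIEParameters(0.0, beta), bound, free)
        assert double - single == pytest.approx(single - zero, abs=1e-9)


class TestAggregateReplicas:
    def test_s1p_affinity_column_population_convention(self):
        mean, std = aggregate_replicas([-13.90, -13.24, -13.02, -12.56, -12.56, -12.56])
        assert round(mean, 2) == -12.97
        assert round(std, 2) == 0.49

    def test_fingolimod_affinity_column_population_convention(self):
        mean, std = aggregate_replicas([-13.56, -12.31, -12.29])
        assert round(mean, 2) == -12.72
        assert round(std, 2) == 0.59

    def test_identical_values_have_zero_spread(self):
        assert aggregate_replicas([-5.0, -5.0, -5.0]) == (-5.0, 0.0)

    def test_empty_list_raises(self):
        with pytest.raises(ValueError):
            aggregate_replicas([])


class TestEstimateBinding:
    params = LIEParameters(alpha=0.46, beta=0.09)

    def test_identical_replicas_give_zero_spread(self):
        bound = [make_traj([-20.0] * 5, [-10.0] * 5, replica=r) for r in range(1, 6)]
        free = [make_traj([-2.0] * 5, [-1.0] * 5, state="free", replica=1)]
        est = estimate_binding(self.params, bound, free)
        assert est.spread_dg == 0.0
        assert len(est.per_replica_dg) == 5

    def test_matches_direct_substitution_oracle(self):
        # Constant series -> means are exact; dG per replica by hand.
        bound_means = [(-20.0, -10.0), (-24.0, -14.0), (-22.0, -6.0)]
        free_mean = (-2.0, -4.0)
        bound = [
            make_traj([v] * 4, [e] * 4, replica=r + 1)
            for r, (v, e) in enumerate(bound_means)
        ]
        free = [make_traj([free_mean[0]] * 8, [free_mean[1]] * 8, state="free")]
        est = estimate_binding(self.params, bound, free)
        expected = [
            0.46 * (v - free_mean[0]) + 0.09 * (e - free_mean[1])
            for v, e in bound_means
        ]
        assert est.per_replica_dg == pytest.approx(expected)
        assert est.mean_dg == pytest.approx(np.mean(expected))

    def test_single_bound_replica(self):
        bound = [make_traj([-20.0] * 3, [-10.0] * 3)]
        free = [make_traj([0.0] * 3, [0.0] * 3, state="free")]
        est = estimate_binding(self.params, bound, free)
        assert est.mean_dg == pytest.approx(-10.1)
        assert est.spread_dg == 0.0

    def test_ligand_mismatch_raises(self):
        bound = [make_traj([-20.0] * 3, ligand="a")]
        free = [make_traj([0.0] * 3, state="free", ligand="b")]
        with pytest.raises(ValueError, match="ligand"):
            estimate_binding(self.params, bound, free)

    def test_replica_permutation_invariance(self):
        rng = np.random.default_rng(3)
        bound = [
            make_traj(rng.normal(-20, 2, 50), rng.normal(-10, 2, 50), replica=r)
            for r in range(1, 6)
        ]
        free = [make_traj(rng.normal(-2, 1, 50), rng.normal(-1, 1, 50),
                          state="free", replica=r) for r in range(1, 3)]
        fwd = estimate_binding(self.params, bound, free)
        rev = estimate_binding(self.params, bound[::-1], free[::-1])
        assert fwd.mean_dg == pytest.approx(rev.mean_dg)
        assert fwd.spread_dg == pytest.approx(rev.spread_dg)

    def test_paired_mode_requires_partner(self):
        bound = [make_traj([-20.0] * 3, replica=2)]
        free = [make_traj([0.0] * 3, state="free", replica=1)]
        with pytest.raises(ValueError, match="pair"):
            estimate_binding(self.params, bound, free, pair_replicas=True)


class TestEnergyTrajectoryInvariants:
    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            make_traj([-1.0, -2.0], [-1.0])

    def test_free_state_requires_na_variant(self):
        with pytest.raises(ValueError):
            EnergyTrajectory("s", "lig", "WT", "free", 1,
                             np.array([-1.0]), np.array([-1.0]))

    def test_nonfinite_energy_rejected(self):
        with pytest.raises(ValueError):
            make_traj([-1.0, np.nan])
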