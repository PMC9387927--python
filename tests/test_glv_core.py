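"""Core dynamics: derivatives, steady-state solver, extinction resolution."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import helpers
import ktwsim as kw
from ktwsim.glv_core import EXTINCTION_THRESHOLD


def single_bacterium(k=0.5, alpha=0.1):
    return kw.Ecosystem([kw.BacteriumStrain(0, k)], [], np.zeros((0, 1)),
                        kw.GlobalRates(alpha=alpha))


def pair(k=0.5, beta=10.0, eta=0.5):
    return kw.Ecosystem([kw.BacteriumStrain(0, k)], [kw.PhageStrain(1, beta)],
                        np.array([[eta]]))


class TestDerivatives:
    def test_single_bacterium_fixed_point(self):
        # dB/dt = 0 at the closed-form density B* = 1 - alpha/k
        eco = single_bacterium()
        dB, dP = kw.derivatives(eco, kw.CommunityState([0.8], []))
        assert dB == pytest.approx(0.0, abs=1e-15)
        assert dP.size == 0

    def test_zero_density_is_absorbing(self):
        eco = single_bacterium()
        dB, _ = kw.derivatives(eco, kw.CommunityState([0.0], []))
        assert dB[0] == 0.0

    def test_pair_fixed_point(self):
        # B* = delta/(beta*eta) = 0.2, P* = (k(1-B*) - alpha)/eta = 0.6
        eco = pair()
        dB, dP = kw.derivatives(eco, kw.CommunityState([0.2], [0.6]))
        assert np.allclose(dB, 0.0, atol=1e-15)
        assert np.allclose(dP, 0.0, atol=1e-15)

    def test_dimension_mismatch_rejected(self):
        eco = pair()
        with pytest.raises(ValueError):
            kw.derivatives(eco, kw.CommunityState([0.2, 0.3], [0.6]))

    def test_generic_point_matches_direct_formula(self):
        rng = np.random.default_rng(5)
        eco, _ = helpers.random_feasible_ecosystem(rng, n_max=3)
        B = rng.uniform(0.01, 0.5, eco.n_bacteria)
        P = rng.uniform(0.01, 0.5, eco.n_phages)
        dB, dP = kw.derivatives(eco, kw.CommunityState(B, P))
        for i, b in enumerate(eco.bacteria):
            expect = b.k * B[i] * (1 - B.sum()) - 0.1 * B[i] \
                - B[i] * float(eco.eta[:, i] @ P)
            assert dB[i] == pytest.approx(expect, rel=1e-12)
        for q, ph in enumerate(eco.phages):
            expect = P[q] * ph.beta * float(eco.eta[q, :] @ B) - P[q]
            assert dP[q] == pytest.approx(expect, rel=1e-12)


class TestSolveSteadyState:
    def test_single_bacterium_closed_form(self):
        res = kw.solve_steady_state(single_bacterium())
        assert res.feasible and not res.degenerate
        assert res.state.B[0] == pytest.approx(0.8, abs=1e-12)

    def test_pair_closed_form(self):
        res = kw.solve_steady_state(pair())
        assert res.feasible
        assert res.state.B[0] == pytest.approx(0.2, abs=1e-12)
        assert res.state.P[0] == pytest.approx(0.6, abs=1e-12)

    def test_two_bacteria_competitive_exclusion(self):
        eco = kw.Ecosystem([kw.BacteriumStrain(0, 0.8),
                            kw.BacteriumStrain(1, 0.3)], [], np.zeros((0, 2)))
        assert not kw.solve_steady_state(eco).feasible

    def test_more_phages_than_bacteria_infeasible(self):
        # two phages sharing one host: predator exclusion
        eco = kw.Ecosystem([kw.BacteriumStrain(0, 0.8)],
                           [kw.PhageStrain(1, 10), kw.PhageStrain(2, 20)],
                           np.array([[0.4], [0.6]]))
        res = kw.solve_steady_state(eco)
        assert not res.feasible

    def test_n_exceeding_m_plus_one_infeasible(self):
        # three bacteria, one phage: one resource supports at most M+1
        eco = kw.Ecosystem(
            [kw.BacteriumStrain(i, k) for i, k in enumerate((0.9, 0.6, 0.3))],
            [kw.PhageStrain(3, 10)], np.array([[0.5, 0.4, 0.0]]))
        assert not kw.solve_steady_state(eco).feasible

    def test_empty_ecosystem_trivially_feasible(self):
        eco = kw.Ecosystem([], [], np.zeros((0, 0)))
        res = kw.solve_steady_state(eco)
        assert res.feasible and res.state.B.size == 0

    def test_feasible_states_are_fixed_points(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            eco, state = helpers.random_feasible_ecosystem(rng)
            dB, dP = kw.derivatives(eco, state)
            assert np.max(np.abs(np.concatenate([dB, dP]))) < 1e-9


class TestIntegrateUntilExtinction:
    def test_slower_competitor_dies(self):
        eco = kw.Ecosystem([kw.BacteriumStrain(0, 0.8),
                            kw.BacteriumStrain(1, 0.3)], [], np.zeros((0, 2)))
        kind, idx, state, _t = kw.integrate_until_extinction(
            eco, kw.CommunityState([0.5, 0.3], []))
        assert (kind, idx) == ("bacterium", 1)
        assert state.B[1] < EXTINCTION_THRESHOLD

    def test_nonviable_bacterium_dies(self):
        eco = single_bacterium(k=0.05)  # k < alpha: negative net growth
        kind, idx, _state, _t = kw.integrate_until_extinction(
            eco, kw.CommunityState([0.5], []))
        assert (kind, idx) == ("bacterium", 0)

    def test_winner_elimination_triplet(self):
        # interior point of the slower-grower-wins region: the fast grower S
        # is driven extinct by apparent competition through the shared phage
        t = kw.TripletSystem(k_S=0.9, k_R=0.5, eta_S=0.8, eta_R=0.3, beta=20)
        assert kw.classify_triplet(t) is kw.TripletOutcome.R_EXCLUDES_S
        eco = kw.Ecosystem(
            [kw.BacteriumStrain(0, t.k_S), kw.BacteriumStrain(1, t.k_R)],
            [kw.PhageStrain(2, t.beta)], np.array([[t.eta_S, t.eta_R]]))
        # start near the S+phage steady state with R at inoculum density
        bs1 = 1.0 / (t.beta * t.eta_S)
        ps1 = (t.k_S * (1 - bs1) - 0.1) / t.eta_S
        kind, idx, _state, _t = kw.integrate_until_extinction(
            eco, kw.CommunityState([bs1, 1e-6], [ps1]))
        assert (kind, idx) == ("bacterium", 0)
        # independent-integrator cross-check of the surviving set
        out = helpers.simulate_triplet_outcome(t, np.random.default_rng(3))
        assert out == "R_EXCLUDES_S"

    def test_positivity_preserved(self):
        # stiff phage bloom on an abundant host (beta*eta = 36): the
        # trajectory must never hand back negative densities
        eco = kw.Ecosystem([kw.BacteriumStrain(0, 0.9),
                            kw.BacteriumStrain(1, 0.4)],
                           [kw.PhageStrain(2, 40)],
                           np.array([[0.9, 0.3]]))
        assert not kw.solve_steady_state(eco).feasible
        _kind, _idx, state, _t = kw.integrate_until_extinction(
            eco, kw.CommunityState([0.8, 1e-6], [1e-6]))
        assert np.all(state.B >= 0) and np.all(state.P >= 0)

    def test_no_extinction_raises(self):
        eco = pair()
        with pytest.raises(kw.NonConvergenceError):
            kw.integrate_until_extinction(
                eco, kw.CommunityState([0.21], [0.59]), t_max=2e3)


class TestResolveAfterPerturbation:
    def test_feasible_input_is_noop(self):
        eco = pair()
        res = kw.solve_steady_state(eco)
        eco2, state2, extinct = kw.resolve_after_perturbation(eco, res.state)
        assert extinct == []
        assert eco2 is eco or (eco2.n_bacteria, eco2.n_phages) == (1, 1)
        assert np.allclose(state2.B, res.state.B, atol=1e-12)

    def test_two_bacteria_resolve_to_winner(self):
        eco = kw.Ecosystem([kw.BacteriumStrain(0, 0.8),
                            kw.BacteriumStrain(1, 0.3)], [], np.zeros((0, 2)))
        eco2, state2, extinct = kw.resolve_after_perturbation(
            eco, kw.CommunityState([0.5, 0.3], []))
        assert extinct == [1]
        assert eco2.n_bacteria == 1 and eco2.bacteria[0].id == 0
        assert state2.B[0] == pytest.approx(1 - 0.1 / 0.8, abs=1e-12)

    def test_nonviable_invader_leaves_residents_unchanged(self):
        eco = pair()
        base = kw.solve_steady_state(eco).state
        invader = kw.BacteriumStrain(9, 0.05)  # k < alpha
        eco2 = eco.with_bacterium(invader, np.zeros(1))
        init = kw.CommunityState(np.append(base.B, 1e-6), base.P)
        eco3, state3, extinct = kw.resolve_after_perturbation(eco2, init)
        assert extinct == [9]
        assert [b.id for b in eco3.bacteria] == [0]
        assert np.allclose(state3.B, base.B, atol=1e-9)
        assert np.allclose(state3.P, base.P, atol=1e-9)

    def test_orphan_phage_removed_with_host(self):
        # phage 3 only attacks the doomed slower bacterium: both must go
        eco = kw.Ecosystem(
            [kw.BacteriumStrain(0, 0.9), kw.BacteriumStrain(1, 0.2)],
            [kw.PhageStrain(3, 2.0)], np.array([[0.0, 0.002]]))
        eco2, _state2, extinct = kw.resolve_after_perturbation(
            eco, kw.CommunityState([0.5, 1e-4], [1e-4]))
        assert set(extinct) == {1, 3}
        assert eco2.n_phages == 0 and eco2.bacteria[0].id == 0


class TestOracleEquivalence:
    def test_integration_converges_to_linear_steady_state(self):
        """Perturbed trajectories relax to the linear-solver fixed point."""
        rng = np.random.default_rng(99)
        for _ in range(100):
            eco, state = helpers.random_feasible_ecosystem(rng)
            target = np.concatenate([state.B, state.P])
            y = target * rng.uniform(0.9, 1.1, eco.n_strains)
            for t_span in (2e4, 8e4, 3e5):
                y = helpers.integrate_ecosystem(eco, y, t_span)
                err = np.max(np.abs(y - target))
                if err < 1e-6:
                    break
            assert err < 1e-6


class TestSerialization:
    @given(st.integers(0, 2**31 - 1))
    def test_roundtrip_lossless(self, seed):
        rng = np.random.default_rng(seed)
        eco, state = helpers.random_feasible_ecosystem(rng, n_max=3)
        doc = kw.ecosystem_to_json(eco, state)
        eco2, state2 = kw.ecosystem_from_json(doc)
        assert [b.id for b in eco2.bacteria] == [b.id for b in eco.bacteria]
        assert np.array_equal(eco2.eta, eco.eta)
        assert np.array_equal(eco2.k_vec, eco.k_vec)
        assert np.array_equal(eco2.beta_vec, eco.beta_vec)
        assert np.array_equal(state2.B, state.B)
        assert np.array_equal(state2.P, state.P)
        assert eco2.rates == eco.rates


class TestValidation:
    @pytest.mark.parametrize("alpha,delta", [(-0.1, 1.0), (0.1, 0.0)])
    def test_bad_rates_rejected(self, alpha, delta):
        with pytest.raises(ValueError):
            kw.GlobalRates(alpha=alpha, delta=delta)

    def test_bad_strain_parameters_rejected(self):
        with pytest.raises(ValueError):
            kw.BacteriumStrain(0, 1.5)
        with pytest.raises(ValueError):
            kw.PhageStrain(0, 0.5)

    def test_eta_range_enforced(self):
        with pytest.raises(ValueError):
            kw.Ecosystem([kw.BacteriumStrain(0, 0.5)], [kw.PhageStrain(1, 5)],
                         np.array([[1.5]]))
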