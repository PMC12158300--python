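import numpy as np
import pytest

from mesostate import dynamics as dy
from mesostate import synth
from mesostate.types import (
    InvalidConfigError,
    InvalidInputError,
    ObservationMatrix,
    ProcessNoise,
    SessionChain,
    TransitionMatrix,
)


def noiseless_chain(A, seed=0, K=10):
    cfg = synth.SimConfig(
        process_noise_sd=0.0, runs_per_session=K,
        ground_truth_A={"NFT": A, "resting": A},
    )
    return synth.simulate_network_chain(cfg, "resting", seed).chains["resting"]


class TestFuzzyRule:
    def test_neutral_at_zero(self):
        assert dy.FuzzyRule()(0.0) == pytest.approx(1.0)

    def test_saturates_at_category_gains(self):
        rule = dy.FuzzyRule(scale=1.0)
        assert rule(-5.0) == pytest.approx(1.2)
        assert rule(5.0) == pytest.approx(0.7)

    def test_boundary_is_membership_weighted_mean(self):
        # halfway into the improving category: memberships 0.5 / 0.5
        rule = dy.FuzzyRule(scale=1.0)
        assert rule(-0.5) == pytest.approx((0.5 * 1.2 + 0.5 * 1.0) / 1.0)
        assert rule(0.5) == pytest.approx((0.5 * 1.0 + 0.5 * 0.7) / 1.0)

    def test_bounds_clip(self):
        rule = dy.FuzzyRule(improving=3.0, scale=1.0, bounds=(0.5, 1.5))
        assert rule(-10.0) == 1.5

    def test_nonfinite_rejected(self):
        with pytest.raises(InvalidInputError):
            dy.FuzzyRule()(np.nan)

    def test_invalid_bounds(self):
        with pytest.raises(InvalidConfigError):
            dy.FuzzyRule(bounds=(0.0, 1.5))


class TestEstimateTransition:
    def test_fixed_point_identity(self, random_observation):
        A = dy.estimate_transition(random_observation, random_observation)
        assert A.allclose(TransitionMatrix.identity(), atol=1e-10)

    def test_scaling(self, random_observation):
        doubled = 2.0 * random_observation
        A = dy.estimate_transition(random_observation, doubled)
        assert A.allclose(2.0 * TransitionMatrix.identity(), atol=1e-10)

    def test_exact_recovery_against_inverse_oracle(self, rng, random_transition):
        from mesostate.synth import _random_initial_state

        x_prev = _random_initial_state(rng, shrink=0.4)
        x_curr = random_transition.apply(x_prev)
        A = dy.estimate_transition(x_prev, x_curr)
        # oracle for the square blocks: direct matrix inverse
        for name in ("mc", "loc", "mnet"):
            oracle = getattr(x_curr, name) @ np.linalg.inv(getattr(x_prev, name))
            assert np.allclose(getattr(A, name), oracle, atol=1e-10)
        assert A.allclose(random_transition, atol=1e-10)

    def test_zero_previous_block_rejected(self, random_observation):
        zero = ObservationMatrix.zeros()
        with pytest.raises(InvalidInputError, match="unidentifiable"):
            dy.estimate_transition(zero, random_observation)


class TestLinearize:
    def test_identity_layout(self):
        vec = dy.linearize(TransitionMatrix.identity())
        expected = np.concatenate(
            [np.eye(3).ravel(), np.eye(4).ravel(), np.eye(3).ravel(), np.eye(3).ravel()]
        )
        assert np.array_equal(vec, expected)

    def test_round_trip(self, random_transition):
        back = dy.delinearize(dy.linearize(random_transition))
        assert back.allclose(random_transition, atol=0)

    def test_length_43(self, random_transition):
        assert dy.linearize(random_transition).size == 43


class TestF1Loss:
    def test_identical_transitions_zero(self, random_transition):
        assert dy.f1_loss([random_transition] * 5) < 1e-30

    def test_order_invariance(self, rng):
        ts = [
            TransitionMatrix.from_vector(rng.standard_normal(43)) for _ in range(6)
        ]
        assert dy.f1_loss(ts) == pytest.approx(dy.f1_loss(ts[::-1]), rel=1e-12)

    def test_single_position_perturbation(self, random_transition):
        c = 0.3
        vec = dy.linearize(random_transition).copy()
        vec[7] += c
        other = dy.delinearize(vec)
        assert dy.f1_loss([random_transition, other]) == pytest.approx(
            c**2 / 2 / 43, rel=1e-12
        )

    def test_needs_two(self, random_transition):
        with pytest.raises(InvalidInputError):
            dy.f1_loss([random_transition])


class TestUpdateProcessNoise:
    def test_neutral_update(self):
        w = ProcessNoise.from_vector(np.linspace(-1, 1, 46))
        cfg = dy.FitConfig(theta1_rule=dy.FuzzyRule(improving=1.0, worsening=1.0))
        out = dy.update_process_noise(w, 0.0, cfg)
        assert out.allclose(w, atol=0)

    def test_scalar_case(self):
        # w = 0.1, theta1 = 0.9, b0 = 0.01  ->  0.1
        w = ProcessNoise.from_vector(np.full(46, 0.1))
        b0 = ProcessNoise.from_vector(np.full(46, 0.01))
        cfg = dy.FitConfig(
            theta1_rule=dy.FuzzyRule(improving=0.9, flat=0.9, worsening=0.9),
            b0=b0,
        )
        out = dy.update_process_noise(w, 0.0, cfg)
        assert np.allclose(out.to_vector(), 0.1, atol=1e-15)

    def test_nonfinite_delta_rejected(self):
        with pytest.raises(InvalidInputError):
            dy.update_process_noise(ProcessNoise.zeros(), np.inf, dy.FitConfig())


class TestConsensus:
    def test_exact_on_noiseless_chain(self, random_transition):
        chain = noiseless_chain(random_transition, seed=2)
        A = dy.consensus_transition(chain.states)
        assert A.allclose(random_transition, atol=1e-9)


class TestFitSession:
    def test_noiseless_chain_converges_immediately(self, random_transition):
        chain = noiseless_chain(random_transition, seed=4)
        fit = dy.fit_session(chain)
        assert fit.converged
        assert fit.iterations_used <= 2
        assert fit.final_f1 < 1e-20
        assert fit.consensus_A.allclose(random_transition, atol=1e-8)

    def test_noisy_chain_recovery(self):
        cfg = synth.SimConfig(process_noise_sd=0.01)
        sim = synth.simulate_network_chain(cfg, "resting", seed=10)
        fit = dy.fit_session(sim.chains["resting"])
        A_true = sim.truth["resting"].transition
        rel = (
            np.linalg.norm(fit.consensus_A.to_vector() - A_true.to_vector())
            / np.linalg.norm(A_true.to_vector())
        )
        assert rel < 0.1
        assert fit.final_f1 < fit.initial_f1

    def test_f1_trajectory_non_increasing(self):
        cfg = synth.SimConfig(process_noise_sd=0.05)
        for seed in range(5):
            sim = synth.simulate_network_chain(cfg, "NFT", seed=seed)
            fit = dy.fit_session(sim.chains["NFT"])
            traj = fit.per_iteration_f1
            assert all(b <= a + 1e-15 for a, b in zip(traj, traj[1:]))

    def test_recovery_error_decreases_with_noise(self):
        """Median consensus error shrinks as process noise shrinks."""
        medians = []
        for sd in (0.02, 0.01, 0.005):
            errs = []
            cfg = synth.SimConfig(process_noise_sd=sd)
            for seed in range(10):
                sim = synth.simulate_network_chain(cfg, "resting", seed=seed)
                fit = dy.fit_session(sim.chains["resting"])
                A_true = sim.truth["resting"].transition
                errs.append(
                    np.linalg.norm(fit.consensus_A.to_vector() - A_true.to_vector())
                    / np.linalg.norm(A_true.to_vector())
                )
            medians.append(np.median(errs))
        assert medians[0] > medians[1] > medians[2]

    def test_control_terms_fixed_to_zero(self):
        with pytest.raises(InvalidConfigError, match="control"):
            dy.FitConfig(control_matrix_B=1.0)


class TestAlignment:
    @staticmethod
    def _biased_chain(seed, bias_value):
        cfg = synth.SimConfig(process_noise_sd=0.01)
        sim = synth.simulate_network_chain(cfg, "resting", seed)
        states = [
            ObservationMatrix.from_vector(x.to_vector() + bias_value)
            for x in sim.chains["resting"].states
        ]
        return SessionChain(
            session_id=f"s{seed}-{bias_value}", condition="resting", states=states
        )

    def test_identical_sessions_are_a_fixed_point(self):
        chains = [self._biased_chain(7, 0.0) for _ in range(2)]
        for i, c in enumerate(chains):
            c.session_id = f"s{i}"
        fits = [dy.fit_session(c) for c in chains]
        assert dy.f2_loss(fits) == 0.0
        aligned = dy.align_sessions(fits)
        assert all(np.allclose(f.b0_final.to_vector(), 0.0) for f in aligned)

    def test_bias_reduced(self):
        chains = [self._biased_chain(s, 0.0) for s in range(2)] + [
            self._biased_chain(s + 50, 0.2) for s in range(2)
        ]
        fits = [dy.fit_session(c) for c in chains]
        before = dy.f2_loss(fits)
        aligned = dy.align_sessions(fits)
        assert dy.f2_loss(aligned) < before

    def test_f2_order_invariance(self):
        chains = [self._biased_chain(s, 0.0) for s in range(3)]
        fits = [dy.fit_session(c) for c in chains]
        assert dy.f2_loss(fits) == pytest.approx(dy.f2_loss(fits[::-1]), rel=1e-12)

    def test_single_session_warns(self):
        fit = dy.fit_session(self._biased_chain(1, 0.0))
        with pytest.warns(UserWarning, match="at least 2"):
            out = dy.align_sessions([fit])
        assert out == [fit]
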