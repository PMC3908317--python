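"""Basin-hopping components: Metropolis rule, perturbation, minimization,
and the full hop loop."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from fraghop import (AMWLite, BHConfig, EvaluationCounter, compute_lrmsd,
                     evaluate, extended_chain, greedy_minimize,
                     metropolis_accept_probability, minimize, perturb_biased,
                     perturb_unbiased, run_basin_hopping,
                     temperature_from_acceptance, toy_sequence)
from fraghop.sampling import TEMPERATURE_PRESETS


class TestMetropolisRule:
    def test_downhill_always_accepted(self):
        for t in (0.0, 0.1, 5.0):
            assert metropolis_accept_probability(-3.0, t) == 1.0

    def test_zero_temperature_is_strict_descent(self):
        assert metropolis_accept_probability(0.001, 0.0) == 0.0
        assert metropolis_accept_probability(0.0, 0.0) == 0.0

    def test_calibration_probability(self):
        """At the temperature calibrated for p=0.1 at 1.4 kcal/mol, a 1.4
        kcal/mol increase is accepted with probability exactly 0.1."""
        t0 = temperature_from_acceptance(0.1, 1.4)
        assert metropolis_accept_probability(1.4, t0) == pytest.approx(0.1, abs=1e-12)

    def test_preset_temperatures_closed_form(self):
        assert TEMPERATURE_PRESETS["T0"] == pytest.approx(1.4 / math.log(10), rel=1e-12)
        assert TEMPERATURE_PRESETS["T1"] == pytest.approx(1.7 / math.log(10), rel=1e-12)
        assert TEMPERATURE_PRESETS["T2"] == pytest.approx(2.6 / math.log(10), rel=1e-12)
        assert TEMPERATURE_PRESETS["T0"] == pytest.approx(0.6080, abs=1e-3)
        assert TEMPERATURE_PRESETS["T2"] == pytest.approx(1.1291, abs=1e-3)

    @given(p=st.floats(min_value=1e-6, max_value=1 - 1e-6),
           de=st.floats(min_value=1e-3, max_value=50.0))
    def test_round_trip_is_exact(self, p, de):
        t = temperature_from_acceptance(p, de)
        assert metropolis_accept_probability(de, t) == pytest.approx(p, abs=1e-12)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            temperature_from_acceptance(0.0, 1.0)
        with pytest.raises(ValueError):
            temperature_from_acceptance(1.0, 1.0)
        with pytest.raises(ValueError):
            temperature_from_acceptance(0.5, -1.0)
        with pytest.raises(ValueError):
            metropolis_accept_probability(1.0, -0.1)


class TestPerturbation:
    def test_unbiased_changes_one_window_without_evaluation(self, small_system):
        seq, lib, _ = small_system
        conf = extended_chain(seq)
        rng = np.random.default_rng(0)
        out = perturb_unbiased(conf, lib, rng)
        diff_rows = np.flatnonzero((out.angles != conf.angles).any(axis=1))
        assert 1 <= len(diff_rows) <= 3
        assert diff_rows.max() - diff_rows.min() <= 2
        assert out.terms is None  # no energy evaluation happened

    def test_unbiased_reproducible(self, small_system):
        seq, lib, _ = small_system
        conf = extended_chain(seq)
        a = perturb_unbiased(conf, lib, np.random.default_rng(5))
        b = perturb_unbiased(conf, lib, np.random.default_rng(5))
        assert np.array_equal(a.angles, b.angles)

    def test_biased_attempt_cap_and_positive_target(self, small_system):
        seq, lib, _ = small_system
        conf = extended_chain(seq)
        rng = np.random.default_rng(1)
        cfg = BHConfig(target_distance=2.0)
        for _ in range(50):
            _, d, achieved, attempts = perturb_biased(conf, lib, 2.0, cfg, rng)
            assert 1 <= attempts <= cfg.max_attempts
            assert d > 0 and achieved >= 0

    def test_single_attempt_degenerates_to_unbiased(self, small_system):
        seq, lib, _ = small_system
        conf = extended_chain(seq)
        cfg = BHConfig(target_distance=2.0, max_attempts=1)
        cand, _, achieved, attempts = perturb_biased(
            conf, lib, 2.0, cfg, np.random.default_rng(3))
        rng2 = np.random.default_rng(3)
        rng2.normal(2.0, 1.0)  # the d draw consumed first
        twin = perturb_unbiased(conf, lib, rng2)
        assert attempts == 1
        assert np.array_equal(cand.angles, twin.angles)
        assert achieved == pytest.approx(compute_lrmsd(conf, cand))

    def test_tolerance_met_when_library_admits(self, small_system):
        """With a diverse library the achieved distance lands within the
        0.5 A tolerance of the drawn target in the large majority of draws."""
        seq, lib, _ = small_system
        conf = extended_chain(seq)
        rng = np.random.default_rng(7)
        cfg = BHConfig(target_distance=3.0)
        n, hits = 100, 0
        for _ in range(n):
            _, d, achieved, _ = perturb_biased(conf, lib, 3.0, cfg, rng)
            hits += abs(achieved - d) <= cfg.tolerance
        assert hits / n >= 0.8


class TestMinimize:
    def test_greedy_energy_strictly_decreases(self, small_system, model):
        seq, lib, _ = small_system
        counter = EvaluationCounter(budget=10_000)
        conf = extended_chain(seq)
        evaluate(model, conf, counter)
        out, used, truncated = minimize(conf, lib, model, 0.0, 5, counter,
                                        np.random.default_rng(2))
        assert not truncated and used >= 5
        assert out.terms.total < conf.terms.total

    def test_k1_stops_at_first_rejection(self, small_system, model):
        seq, lib, _ = small_system

        class Uphill:
            term_names = ("flat",)

            def evaluate_terms(self, conf):
                # every move looks worse than the start (start scored first)
                from fraghop.energy import TermVector
                self.calls = getattr(self, "calls", 0) + 1
                return TermVector(names=self.term_names,
                                  values=np.array([float(self.calls)]))

        uphill = Uphill()
        counter = EvaluationCounter(budget=100)
        conf = extended_chain(seq)
        evaluate(uphill, conf, counter)
        _, used, _ = minimize(conf, lib, uphill, 0.0, 1, counter,
                              np.random.default_rng(0))
        assert used == 1

    def test_budget_exhaustion_flags_truncated(self, small_system, model):
        seq, lib, _ = small_system
        counter = EvaluationCounter(budget=4)
        conf = extended_chain(seq)
        evaluate(model, conf, counter)
        out, used, truncated = minimize(conf, lib, model, 0.0, 50, counter,
                                        np.random.default_rng(2))
        assert truncated and used == 3 and counter.count == 4

    def test_requires_scored_input(self, small_system, model):
        seq, lib, _ = small_system
        with pytest.raises(ValueError):
            minimize(extended_chain(seq), lib, model, 0.0, 3,
                     EvaluationCounter(budget=10), np.random.default_rng(0))

    @pytest.mark.parametrize("seed", range(5))
    def test_greedy_equals_zero_temperature_metropolis(self, small_system,
                                                       model, seed):
        """The independent strict-descent implementation and the Metropolis
        minimizer at T = 0 produce byte-identical results from one seed."""
        seq, lib, _ = small_system
        conf = extended_chain(seq)
        evaluate(model, conf, EvaluationCounter(budget=10))
        a, ua, ta = minimize(conf, lib, model, 0.0, 6,
                             EvaluationCounter(budget=2_000),
                             np.random.default_rng(seed))
        b, ub, tb = greedy_minimize(conf, lib, model, 6,
                                    EvaluationCounter(budget=2_000),
                                    np.random.default_rng(seed))
        assert np.array_equal(a.angles, b.angles)
        assert (ua, ta) == (ub, tb)
        assert a.terms.total == b.terms.total


class TestRunBasinHopping:
    def test_budget_respected_and_reconciled(self, small_system, model):
        seq, lib, _ = small_system
        traj = run_basin_hopping(seq, lib, model,
                                 BHConfig(budget=500, seed=1, k=4))
        assert traj.evaluations <= 500
        # every evaluation is attributed to exactly one record (the start
        # state's and each hop's perturbed-state evaluation included)
        assert traj.evaluations == sum(r.evaluations for r in traj.records)

    def test_seeded_runs_identical(self, small_system, model):
        seq, lib, _ = small_system
        cfg = BHConfig(budget=600, seed=9, k=4)
        t1 = run_basin_hopping(seq, lib, model, cfg)
        t2 = run_basin_hopping(seq, lib, model, cfg)
        assert len(t1.records) == len(t2.records)
        for a, b in zip(t1.records, t2.records):
            assert np.array_equal(a.angles, b.angles)
            assert a.accepted == b.accepted
            assert np.array_equal(a.mu_prev, b.mu_prev, equal_nan=True)
        assert t1.evaluations == t2.evaluations

    def test_metropolis_minimizer_hops_fewer_than_greedy(self, small_system,
                                                         model):
        """At an equal budget the T > 0 minimizer spends more evaluations per
        minimization, so the trajectory contains fewer hops."""
        seq, lib, _ = small_system
        greedy = run_basin_hopping(seq, lib, model,
                                   BHConfig(budget=1_500, seed=3, k=4))
        t1 = TEMPERATURE_PRESETS["T1"]
        mmc = run_basin_hopping(
            seq, lib, model,
            BHConfig(budget=1_500, seed=3, k=4, min_temperature=t1))
        assert mmc.hops < greedy.hops

    def test_rejected_hops_recorded_and_state_kept(self, small_system, model):
        seq, lib, _ = small_system
        traj = run_basin_hopping(seq, lib, model,
                                 BHConfig(budget=1_200, seed=4, k=4))
        rejected = [r for r in traj.records[1:] if not r.accepted]
        assert rejected, "fixture run should reject at least one hop"
        assert traj.acceptances == sum(r.accepted for r in traj.records[1:])
        assert all(np.isfinite(r.mu_prev) and r.mu_prev >= 0
                   for r in traj.records[1:])

    def test_hop_acceptance_matches_metropolis_statistics(self, small_system,
                                                          model):
        """Among uphill hops, the empirical acceptance frequency agrees with
        the mean Metropolis probability within binomial error."""
        seq, lib, _ = small_system
        cfg = BHConfig(budget=20_000, seed=11, k=3)
        traj = run_basin_hopping(seq, lib, model, cfg)
        current = traj.records[0]
        probs, outcomes = [], []
        for rec in traj.records[1:]:
            delta = rec.total - current.total
            if delta > 0:
                probs.append(math.exp(-delta / cfg.hop_temperature))
                outcomes.append(rec.accepted)
            if rec.accepted:
                current = rec
        probs, outcomes = np.array(probs), np.array(outcomes, dtype=float)
        assert len(probs) >= 50
        se = math.sqrt(np.sum(probs * (1 - probs))) / len(probs)
        assert abs(outcomes.mean() - probs.mean()) < 4 * se + 1e-9

    def test_max_hops_cap(self, small_system, model):
        seq, lib, _ = small_system
        traj = run_basin_hopping(
            seq, lib, model, BHConfig(budget=10**6, max_hops=7, seed=0, k=3))
        assert traj.hops == 7

    def test_mu_bias_trend_on_fixture(self, model):
        """Mean hop distance increases with the perturbation target D."""
        from fraghop import generate_toy_system
        seq, lib, _ = generate_toy_system(14, pool_size=40,
                                          noise_sd=(8.0, 25.0, 60.0), seed=2)
        means = []
        for d in (1.0, 4.0):
            traj = run_basin_hopping(
                seq, lib, model,
                BHConfig(budget=10**6, max_hops=120, seed=21, k=3,
                         target_distance=d))
            means.append(np.nanmean([r.mu_prev for r in traj.records[1:]]))
        assert means[0] < means[1]


def test_config_validation():
    with pytest.raises(ValueError):
        BHConfig(target_distance=-1.0)
    with pytest.raises(ValueError):
        BHConfig(tolerance=0.0)
    with pytest.raises(ValueError):
        BHConfig(k=0)
    with pytest.raises(ValueError):
        BHConfig(budget=0)
    with pytest.raises(ValueError):
        BHConfig(max_hops=0)
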