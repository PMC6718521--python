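"""Ingestion-pattern search: mutation, tournaments, enumeration oracle."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

import glucopt as g
from glucopt.patterns import (
    DEFAULT_SLOTS,
    IngestionPattern,
    ObjectiveSpec,
    OptimizerSettings,
    enumerate_patterns,
    evaluate_objective,
    init_population,
    mutate_pattern,
    optimize,
    pattern_count,
    pattern_to_schedule,
    tournament_scores,
)


class TestPattern:
    def test_bolus_pattern_schedule(self):
        sched = pattern_to_schedule(IngestionPattern.bolus(50))
        assert sched.events == ((0.0, 50.0, 0.5),)
        assert g.ingestion_flux(sched, 0.1) == pytest.approx(100.0)

    def test_endpoint_split_two_events(self):
        sched = pattern_to_schedule(IngestionPattern.endpoint_split(50))
        assert len(sched.events) == 2
        assert sched.events[0][0] == 0.0 and sched.events[1][0] == 60.0

    def test_total_grams_preserved(self):
        p = IngestionPattern((3, 0, 5, 0, 0, 0, 0, 0, 1, 0, 0, 0, 41))
        assert pattern_to_schedule(p).total_grams == pytest.approx(p.total)

    def test_first_slot_constraint_enforced(self):
        with pytest.raises(ValueError, match="first slot"):
            IngestionPattern((0, 50) + (0,) * 11)

    def test_negative_grams_rejected(self):
        with pytest.raises(ValueError):
            IngestionPattern((1, -1) + (0,) * 11)


class TestInitPopulation:
    def test_invariants_and_seeds_present(self):
        rng = np.random.default_rng(0)
        settings = OptimizerSettings(pop_size=40, n_generations=1, trials=1)
        pop = init_population(settings, 50, rng)
        assert len(pop) == 40
        assert all(p.total == 50 and p.grams[0] >= 1 for p in pop)
        assert pop[0].grams == IngestionPattern.bolus(50).grams
        assert pop[1].grams == IngestionPattern.endpoint_split(50).grams

    def test_seeded_reproducibility(self):
        settings = OptimizerSettings(pop_size=30, n_generations=1, trials=1)
        p1 = init_population(settings, 50, np.random.default_rng(9))
        p2 = init_population(settings, 50, np.random.default_rng(9))
        assert [p.grams for p in p1] == [q.grams for q in p2]


class TestMutate:
    @given(st.integers(0, 2**31 - 1), st.integers(0, 25))
    def test_invariants_preserved(self, seed, L):
        rng = np.random.default_rng(seed)
        base = init_population(
            OptimizerSettings(pop_size=3, n_generations=1, trials=1), 50, rng
        )[2]
        out = mutate_pattern(base, L, rng)
        assert out.total == 50
        assert out.grams[0] >= 1
        assert all(v >= 0 for v in out.grams)

    def test_zero_transfers_is_identity(self):
        rng = np.random.default_rng(1)
        p = IngestionPattern((7, 0, 0, 3, 0, 0, 0, 0, 0, 0, 0, 0, 40))
        assert mutate_pattern(p, 0, rng).grams == p.grams

    def test_strict_source_rule_never_empties_slots(self):
        """Under the strict reading a slot holding exactly 1 g cannot donate."""
        rng = np.random.default_rng(3)
        p = IngestionPattern((1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 38))
        for _ in range(50):
            out = mutate_pattern(p, 10, rng, strict=True)
            # slots 1..11 held exactly 1 g (slot 0 is specially handled and
            # slot 12 can donate); none may drop to 0
            assert all(v >= 1 for v in out.grams[1:12])


class TestTournament:
    def test_unique_minimum_scores_m(self):
        j = np.array([5.0, 1.0, 9.0, 7.0, 6.0])
        scores = tournament_scores(j, m=10, rng=np.random.default_rng(0))
        assert scores[1] == 10

    def test_all_equal_scores_zero(self):
        scores = tournament_scores(np.full(8, 3.3), m=5, rng=np.random.default_rng(1))
        assert np.all(scores == 0)

    def test_median_scores_about_half_m(self):
        """The median individual beats ~half its opponents on average."""
        m = 20
        acc = []
        for seed in range(300):
            j = np.arange(21, dtype=float)  # index 10 is the median
            scores = tournament_scores(j, m, np.random.default_rng(seed))
            acc.append(scores[10])
        assert np.mean(acc) == pytest.approx(m / 2, rel=0.1)


class TestEnumerate:
    def test_two_slot_instance(self):
        pats = [p.grams for p in enumerate_patterns(2, (0.0, 30.0))]
        assert sorted(pats) == [(1, 1), (2, 0)]

    @pytest.mark.parametrize("total,n_slots", [(4, 3), (6, 3), (8, 4), (5, 2)])
    def test_count_matches_stars_and_bars(self, total, n_slots):
        slots = tuple(float(5 * i) for i in range(n_slots))
        pats = list(enumerate_patterns(total, slots))
        assert len(pats) == pattern_count(total, n_slots)
        assert len({p.grams for p in pats}) == len(pats)  # each exactly once

    def test_large_instance_guarded(self):
        with pytest.raises(ValueError, match="too large"):
            list(enumerate_patterns(50, DEFAULT_SLOTS))

    def test_printed_search_space_expression(self):
        """62!/(49!·13!) = C(62,13): the count usually quoted for this
        search space (the constraint-faithful count is C(61,12))."""
        value = math.factorial(62) // (math.factorial(49) * math.factorial(13))
        assert value == math.comb(62, 13) == 8_308_281_242_850


class TestObjective:
    def test_representation_invariance(self, subjA):
        """J computed from the pattern equals J computed from its explicit
        schedule representation."""
        p = IngestionPattern((10, 0, 0, 0, 0, 0, 8, 0, 0, 0, 0, 0, 32))
        obj = ObjectiveSpec(target="glucose_peak")
        j_pattern = evaluate_objective(p, subjA, obj)
        traj = g.simulate(subjA, pattern_to_schedule(p), obj.solver)
        assert j_pattern == g.peak_value(traj, "G")

    def test_unknown_target_rejected(self):
        with pytest.raises(KeyError):
            ObjectiveSpec(target="cpeptide_peak")

    def test_dose_monotonicity(self, subjB):
        """Doubling the bolus dose does not decrease the glucose peak."""
        obj = ObjectiveSpec(target="glucose_peak")
        j50 = evaluate_objective(IngestionPattern.bolus(50), subjB, obj)
        j100 = evaluate_objective(IngestionPattern.bolus(100), subjB, obj)
        assert j100 >= j50


class TestOptimize:
    def test_single_slot_returns_bolus(self, subjA):
        """With one slot the bolus is the only feasible pattern."""
        settings = OptimizerSettings(pop_size=4, n_generations=3, trials=1, seed=0)
        res = optimize(subjA, ObjectiveSpec(), settings, total=10, slot_times=(0.0,))
        assert res.best_pattern.grams == (10,)

    def test_l_schedule(self):
        s = OptimizerSettings(l_initial=20, l_decrement=1, l_interval=25)
        assert s.l_at(0) == 20
        assert s.l_at(24) == 20
        assert s.l_at(25) == 19
        assert s.l_at(499) == 1
        assert s.l_at(10_000) == 0

    def test_trace_non_increasing_and_deterministic(self, subjA):
        settings = OptimizerSettings(pop_size=12, n_generations=10, trials=2, seed=4)
        obj = ObjectiveSpec()
        r1 = optimize(subjA, obj, settings, total=6, slot_times=(0.0, 30.0, 60.0))
        r2 = optimize(subjA, obj, settings, total=6, slot_times=(0.0, 30.0, 60.0))
        assert r1.best_pattern.grams == r2.best_pattern.grams
        assert r1.trace == r2.trace
        for trial in r1.trial_results:
            assert np.all(np.diff(trial["trace"]) <= 0)

    def test_best_bounded_by_bolus(self, subjA):
        """The returned optimum is never worse than the bolus (a seeded
        member of every initial population)."""
        settings = OptimizerSettings(pop_size=10, n_generations=5, trials=1, seed=2)
        obj = ObjectiveSpec()
        res = optimize(subjA, obj, settings, total=8, slot_times=(0.0, 20.0, 40.0, 60.0))
        j_bolus = evaluate_objective(
            IngestionPattern.bolus(8, (0.0, 20.0, 40.0, 60.0)), subjA, obj
        )
        assert res.best_j_search <= j_bolus + 1e-12
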