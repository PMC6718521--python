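"""Normalized RSS, evolutionary-programming search, and simplex refinement."""

import math

import numpy as np
import pytest

import glucopt as g
from glucopt.data import DatasetError, ExperimentDataset
from glucopt.fitting import (
    FitSettings,
    RssEvaluator,
    ep_global_search,
    fit,
    rss,
    simplex_refine,
)


def _truth_theta(subject):
    return np.array(
        [getattr(subject.kinetics, n) for n in subject.structure.free_kinetic_names]
        + [getattr(subject.initial, n) for n in subject.structure.free_initial_names]
    )


class TestRss:
    def test_zero_when_simulation_matches_data(self, subjA, clean_datasets):
        """Zero-noise data generated by the same solver settings gives RSS ~ 0."""
        ds = g.generate_dataset(
            g.SyntheticSubjectSpec(
                subject=subjA, noise_fraction=0.0, seed=0,
                solver=g.SolverSettings(method="rk4", step=0.25),
            )
        )
        ev = RssEvaluator(ds, subjA.structure)
        assert ev.rss(_truth_theta(subjA)) < 1e-20

    def test_single_series_arithmetic(self, subjC):
        """A two-point series with range 1: RSS = sum of squared raw
        residuals, i.e. the denominator of the normalization is max-min."""
        import pandas as pd

        rows = [
            {"subject_id": "x", "condition": "50B", "species": "G",
             "time_min": t, "value": v, "included": True}
            for t, v in [(300.0, 0.0), (400.0, 1.0)]
        ]
        ds = ExperimentDataset(pd.DataFrame(rows))
        solver = g.SolverSettings(method="rk4", step=0.25)
        ev = RssEvaluator(ds, subjC.structure, solver)
        proto = next(p for p in g.standard_protocols() if p.name == "50B")
        traj = g.simulate(subjC, proto.schedule(), solver)
        sim = g.sample_at(traj, [300.0, 400.0], "G")
        want = (sim[0] - 0.0) ** 2 / 1.0 + (sim[1] - 1.0) ** 2 / 1.0
        assert ev.rss(_truth_theta(subjC)) == pytest.approx(want, rel=1e-9)

    def test_min_max_normalization_scale_invariance(self, subjB):
        """Scaling one species' data and predictions jointly by 10 leaves
        its RSS contribution unchanged (min-max normalization)."""
        ds = g.generate_dataset(
            g.SyntheticSubjectSpec(subject=subjB, noise_fraction=0.03, seed=9)
        )
        base = rss(ds, subjB.kinetics, subjB.initial, subjB.structure)
        frame = ds.frame.copy()
        sel = frame["species"] == "GIP"
        frame.loc[sel, "value"] *= 10.0
        from dataclasses import replace

        scaled_subj = g.Subject(
            structure=subjB.structure,
            kinetics=replace(subjB.kinetics, k2=subjB.kinetics.k2 * 10,
                             k3=subjB.kinetics.k3,
                             a=subjB.kinetics.a / 10, d=subjB.kinetics.d),
            initial=replace(subjB.initial, GIP0=subjB.initial.GIP0 * 10),
        )
        # scaling GIP data by 10 and the GIP prediction by 10 (k2, GIP0 x10;
        # couplings a/10 keep the insulin equation unchanged; b = 0 here)
        ds10 = ExperimentDataset(frame)
        scaled = rss(ds10, scaled_subj.kinetics, scaled_subj.initial, subjB.structure)
        assert scaled == pytest.approx(base, rel=1e-6)

    def test_degenerate_series_rejected_by_name(self, subjA, clean_datasets):
        frame = clean_datasets["subjA"].frame.copy()
        sel = (frame["condition"] == "25B") & (frame["species"] == "CP")
        frame.loc[sel, "value"] = 123.0
        ds = ExperimentDataset(frame)
        with pytest.raises(DatasetError, match=r"25B.*CP"):
            RssEvaluator(ds, subjA.structure)

    def test_additivity_over_conditions(self, subjA, clean_datasets):
        """Excluding a condition removes exactly its terms."""
        ds = clean_datasets["subjA"]
        theta = _truth_theta(subjA) * 1.02  # slightly off truth: nonzero RSS
        full = RssEvaluator(ds, subjA.structure).rss(theta)
        without = RssEvaluator(ds.with_condition_excluded("75C"), subjA.structure).rss(theta)
        only = RssEvaluator(
            ExperimentDataset(ds.frame[ds.frame.condition == "75C"]),
            subjA.structure,
        ).rss(theta)
        assert full == pytest.approx(without + only, rel=1e-9)

    def test_condition_order_invariance(self, subjA, clean_datasets):
        ds = clean_datasets["subjA"]
        shuffled = ExperimentDataset(
            ds.frame.sample(frac=1.0, random_state=4).reset_index(drop=True)
        )
        theta = _truth_theta(subjA) * 1.05
        assert RssEvaluator(ds, subjA.structure).rss(theta) == pytest.approx(
            RssEvaluator(shuffled, subjA.structure).rss(theta), rel=1e-12
        )


class _Quadratic:
    """1-parameter surrogate objective with a known minimum, duck-typed as
    an evaluator for the EP search."""

    free_names = ("k",)
    x_star = math.log(0.37)

    def rss_log(self, x):
        return float((x[0] - self.x_star) ** 2)

    def log_bounds(self, settings):
        return np.array([math.log(1e-3)]), np.array([math.log(1e3)])

    def data_informed_start(self, settings):
        return np.array([0.0])


class TestEpGlobalSearch:
    def test_quadratic_surrogate_reaches_analytic_minimum(self):
        ev = _Quadratic()
        st = FitSettings(pop_size=30, n_generations=50, seed=0)
        cands, trace = ep_global_search(ev, st)
        x_best, f_best = cands[0]
        assert abs(x_best[0] - ev.x_star) < 0.01 * abs(ev.x_star)

    def test_best_so_far_trace_is_non_increasing(self):
        _, trace = ep_global_search(_Quadratic(), FitSettings(pop_size=20, n_generations=40, seed=1))
        assert np.all(np.diff(trace) <= 0)

    def test_same_seed_identical_traces(self):
        st = FitSettings(pop_size=20, n_generations=30, seed=7)
        rng1 = np.random.default_rng(3)
        rng2 = np.random.default_rng(3)
        _, tr1 = ep_global_search(_Quadratic(), st, rng1)
        _, tr2 = ep_global_search(_Quadratic(), st, rng2)
        assert np.array_equal(tr1, tr2)


class TestSimplexRefine:
    def test_descent_contract(self, subjA):
        ds = g.generate_dataset(
            g.SyntheticSubjectSpec(subject=subjA, noise_fraction=0.05, seed=2)
        )
        ev = RssEvaluator(ds, subjA.structure)
        st = FitSettings(simplex_maxiter=300)
        x0 = ev.data_informed_start(st)
        f0 = ev.rss_log(x0)
        _, f1 = simplex_refine(x0, ev, st)
        assert f1 <= f0

    def test_starting_at_a_local_minimum_returns_it(self):
        """On a surrogate with a known minimum, refinement from the minimum
        leaves both the point and the objective value unchanged."""
        ev = _Quadratic()
        st = FitSettings(simplex_maxiter=500)
        x_star = np.array([ev.x_star])
        x1, f1 = simplex_refine(x_star, ev, st)
        assert f1 == pytest.approx(0.0, abs=1e-12)
        assert x1[0] == pytest.approx(ev.x_star, abs=1e-6)


class TestFit:
    def test_result_best_is_min_of_trials(self, subjA, clean_datasets):
        st = FitSettings(n_trials=2, pop_size=20, n_generations=15,
                         simplex_maxiter=100, polish="none", seed=5)
        res = fit(clean_datasets["subjA"], subjA.structure, st)
        assert res.best_rss == min(res.trial_rss)
        assert res.best_rss >= 0

    def test_near_truth_start_recovers_zero_noise_data(self, subjA, clean_datasets):
        """Refinement seeded near the truth drives RSS to ~0 on clean data."""
        st = FitSettings(n_trials=1, pop_size=10, n_generations=5, seed=0)
        x_warm = np.log(_truth_theta(subjA) * 1.1)
        res = fit(clean_datasets["subjA"], subjA.structure, st, x_warm=x_warm)
        assert res.best_rss < 1e-4

    def test_fitted_subject_reconstruction(self, subjA, clean_datasets):
        st = FitSettings(n_trials=1, pop_size=15, n_generations=10,
                         simplex_maxiter=50, polish="none", seed=1)
        res = fit(clean_datasets["subjA"], subjA.structure, st)
        fitted = res.subject()
        assert fitted.structure == subjA.structure
        assert fitted.species == subjA.species
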