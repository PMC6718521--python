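"""Model family: ingestion input, fluxes, state equations, steady-state closure."""

import numpy as np
import pytest

import glucopt as g
from conftest import random_admissible_subject


class TestIngestionFlux:
    def test_bolus_worked_value(self):
        """A 50-g bolus over 0.5 min delivers 50/0.5 = 100 g/min."""
        sched = g.IngestionSchedule.bolus(50.0)
        assert g.ingestion_flux(sched, 0.25) == pytest.approx(100.0)

    def test_zero_outside_event_windows(self):
        sched = g.IngestionSchedule.bolus(50.0)
        assert g.ingestion_flux(sched, 0.5) == 0.0  # half-open window
        assert g.ingestion_flux(sched, 300.0) == 0.0

    def test_continuous_rate(self):
        """75 g over 2 h flows at 0.625 g/min throughout."""
        sched = g.IngestionSchedule.continuous(75.0, 120.0)
        assert g.ingestion_flux(sched, 60.0) == pytest.approx(0.625)

    def test_integral_equals_total_grams(self):
        sched = g.IngestionSchedule([(0.0, 10.0, 0.5), (30.0, 5.0, 10.0)])
        t = np.linspace(0, 60, 60001)
        flux = np.array([g.ingestion_flux(sched, ti) for ti in t])
        assert np.trapezoid(flux, t) == pytest.approx(sched.total_grams, rel=1e-3)

    def test_overlapping_events_rejected_at_construction(self):
        with pytest.raises(ValueError, match="overlap"):
            g.IngestionSchedule([(0.0, 10.0, 5.0), (3.0, 5.0, 5.0)])

    @pytest.mark.parametrize("bad", [(0.0, -1.0, 0.5), (0.0, 10.0, 0.0)])
    def test_invalid_events_rejected(self, bad):
        with pytest.raises(ValueError):
            g.IngestionSchedule([bad])


class TestClosure:
    def test_k9_direct_substitution(self):
        """k9 = k8 / (G0 X0 (X0 + L8)) with k8=1, G0=2, X0=1, L8=3 gives 1/8."""
        kin = g.KineticParameters(
            k2=1, k3=1, k4=1, k5=1, k6=1, k7=1, k8=1.0, k10=1,
            L2=1, L4=1, L6=1, L8=3.0, L11=1, V=1,
        )
        init = g.InitialState(GIP0=1, GLP10=1, G0=2.0, I0=1, CP0=1, X0=1.0)
        der = g.close_parameters(kin, init, g.ModelStructure())
        assert der.k9 == pytest.approx(0.125)

    def test_basal_incretins_equal_initial_levels(self, subjB):
        der = subjB.derived
        assert der.GIP_B == subjB.initial.GIP0
        assert der.GLP1_B == subjB.initial.GLP10

    def test_closure_domain_error_on_nonpositive_levels(self):
        kin = g.fixture_subjects()["subjC"].kinetics
        bad = g.InitialState(GIP0=1, GLP10=1, G0=-5.0, I0=1, CP0=1, X0=1)
        with pytest.raises(ValueError):
            g.close_parameters(kin, bad, g.ModelStructure())

    def test_closure_zeroes_rhs_for_random_draws(self):
        """Defining property: derivatives vanish at t=0 with no ingestion."""
        rng = np.random.default_rng(11)
        for _ in range(100):
            s = random_admissible_subject(rng)
            dy = g.rhs(s.state_vector(), s.param_vector(), 0.0)
            scale = np.maximum(np.abs(s.state_vector()), 1.0)
            assert np.max(np.abs(dy) / scale) < 1e-9


class TestFluxVector:
    def test_secretion_reduces_to_glucose_term_with_zero_couplings(self, subjA):
        p = subjA.param_vector()
        y = subjA.state_vector()
        v = g.flux_vector(y, p, 0.0)
        k10, G = p[7], y[4]
        assert p[14] == p[16] == p[17] == 0.0  # a, c, d masked by structure
        # with only b active, zeroing GIP leaves v10 = k10 * G
        y2 = y.copy()
        y2[1] = 0.0
        v2 = g.flux_vector(y2, p, 0.0)
        assert v2[9] == pytest.approx(k10 * G)

    def test_uptake_is_bilinear_in_G_and_X(self, subjA):
        p = subjA.param_vector()
        y = subjA.state_vector()
        y2 = y.copy()
        y2[4] *= 2
        y2[7] *= 2
        v, v2 = g.flux_vector(y, p, 0.0), g.flux_vector(y2, p, 0.0)
        assert v2[8] == pytest.approx(4 * v[8])

    def test_gip_secretion_saturates_at_k2(self, subjA):
        p = subjA.param_vector()
        y = subjA.state_vector()
        y[0] = 1e9  # IntestG -> infinity
        v = g.flux_vector(y, p, 0.0)
        assert v[1] == pytest.approx(p[0], rel=1e-6)

    def test_nonnegative_fluxes_on_nonnegative_states(self):
        """All fluxes except the signed basal-relaxation terms (v3, v5) are
        nonnegative whenever the state is nonnegative."""
        rng = np.random.default_rng(5)
        signed = {2, 4}  # v3, v5
        for _ in range(200):
            s = random_admissible_subject(rng)
            y = rng.uniform(0, 1, 8) * np.array([80, 100, 50, 60, 300, 500, 2000, 5])
            v = g.flux_vector(y, s.param_vector(), rng.uniform(0, 100))
            for i, vi in enumerate(v):
                if i not in signed:
                    assert vi >= 0.0

    def test_relaxation_fluxes_restore_basal(self, subjB):
        p = subjB.param_vector()
        y = subjB.state_vector()
        y[1] = p[22] + 10  # GIP above basal
        y[2] = p[23] - 2   # GLP1 below basal
        v = g.flux_vector(y, p, 0.0)
        assert v[2] < 0 and v[4] > 0

    def test_masked_coefficient_has_no_effect(self, subjA):
        """Structure-fixed coefficients are hard zeros: varying the value in
        the kinetics object does not change any flux."""
        from dataclasses import replace

        k1 = subjA.kinetics
        k2 = replace(k1, a=5.0, c=2.0, d=1.0)  # all masked by subjA's structure
        s2 = g.Subject(structure=subjA.structure, kinetics=k2, initial=subjA.initial)
        y = subjA.state_vector() + 1.0
        assert np.allclose(
            g.flux_vector(y, subjA.param_vector(), 3.0),
            g.flux_vector(y, s2.param_vector(), 3.0),
        )


class TestRhs:
    def test_zero_at_closed_steady_state(self, subjC):
        dy = g.rhs(subjC.state_vector(), subjC.param_vector(), 0.0)
        assert np.max(np.abs(dy)) < 1e-12

    def test_cpeptide_minus_insulin_balance(self, subjB):
        """dCP/dt - dI/dt = v11 - v12: both share the secretion source v10."""
        y = subjB.state_vector() * 1.3
        p = subjB.param_vector()
        dy = g.rhs(y, p, 2.0)
        v = g.flux_vector(y, p, 2.0)
        assert dy[6] - dy[5] == pytest.approx(v[10] - v[11], rel=1e-12)

    def test_glp1_free_model_exposes_seven_states(self, subjA):
        assert len(subjA.structure.state_names) == 7
        assert "GLP1" not in subjA.structure.state_names
        traj = g.simulate(subjA, g.IngestionSchedule.bolus(25.0),
                          g.SolverSettings(method="rk4", step=0.25, horizon=60.0))
        assert traj.states.shape[1] == 7


class TestStructure:
    def test_glp1_removal_forces_couplings_to_zero(self):
        s = g.ModelStructure(c_free=True, d_free=True, include_glp1=False)
        assert not s.c_free and not s.d_free

    def test_full_model_free_parameter_counts(self):
        full = g.ModelStructure()
        assert len(full.free_kinetic_names) == 18
        assert full.n_free == 24

    def test_labels(self):
        assert g.ModelStructure().label == "full"
        assert g.ModelStructure(c_free=False, d_free=False).label == "c=d=0"
        assert g.ModelStructure(a_free=False, include_glp1=False).label == "noGLP1,a=0"

    def test_subject_json_round_trip(self, tmp_path, subjB):
        path = tmp_path / "subj.json"
        subjB.to_json(path)
        loaded = g.Subject.from_json(path)
        assert loaded.kinetics == subjB.kinetics
        assert loaded.initial == subjB.initial
        assert loaded.structure == subjB.structure
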