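"""Whole-body ODE system: construction, conservation, linearity, kinetics."""

from dataclasses import replace

import numpy as np
import pytest

from ondapbpk.engine import (N_STATES, DosingRegimen, _IDX, _I_DEPOT,
                             build_model, default_time_grid,
                             mass_balance_audit, simulate_individual)
from ondapbpk.nca import pk_summary
from ondapbpk.physiology import ORGAN_NAMES


class TestConstruction:
    def test_state_count_is_organs_plus_depot_and_audit(self):
        assert N_STATES == len(ORGAN_NAMES) + 2

    def test_liver_inflow_from_physiology(self, drug, ref_phys, iv5):
        m = build_model(drug, ref_phys, iv5)
        q_h = ref_phys.portal_flow + ref_phys.hepatic_arterial_flow
        assert ref_phys.organs["liver"].blood_flow == pytest.approx(q_h)
        assert m.hepatic_cl_blood < q_h

    def test_iv_model_never_populates_depot(self, healthy_iv_profile):
        _, prof = healthy_iv_profile
        assert np.all(prof.states[:, _I_DEPOT] == 0.0)

    def test_mass_conservation_in_system_matrix(self, drug, ref_phys, iv5):
        # column sums vanish: every transfer has an equal opposite entry
        A = build_model(drug, ref_phys, iv5).system_matrix
        assert np.allclose(A.sum(axis=0), 0.0, atol=1e-14)


class TestSimulation:
    def test_zero_dose_zero_profile(self, drug, ref_phys):
        reg = DosingRegimen(route="iv_infusion", dose=0.0, infusion_duration=5.0)
        prof = simulate_individual(build_model(drug, ref_phys, reg), t_end=24.0)
        assert np.all(prof.concentrations == 0.0)

    def test_mass_balance_residual(self, healthy_iv_profile,
                                   healthy_oral_profile):
        for model, prof in (healthy_iv_profile, healthy_oral_profile):
            assert mass_balance_audit(model, prof) <= 1e-6

    def test_auc_equals_dose_over_clearance(self, healthy_iv_profile, iv5):
        model, prof = healthy_iv_profile
        pk = pk_summary(prof, iv5, model.physiology.body_weight)
        analytic = model.dose_ug / (model.plasma_cl * 60.0)  # ug/(L/h)=ng·h/mL
        assert pk.auc_0inf == pytest.approx(analytic, rel=0.005)

    def test_dose_linearity(self, drug, ref_phys, iv5):
        times = np.linspace(0.0, 24.0, 200)
        m1 = build_model(drug, ref_phys, iv5)
        m2 = build_model(drug, ref_phys, replace(iv5, dose=16.0))
        c1 = simulate_individual(m1, times=times).concentrations
        c2 = simulate_individual(m2, times=times).concentrations
        assert np.allclose(c2, 2.0 * c1, rtol=1e-9, atol=1e-12)

    def test_superposition_of_two_doses(self, drug, ref_phys, iv5):
        tau = 8.0
        times = np.round(np.arange(0.0, 48.0 + 1e-9, 0.25), 10)
        single = simulate_individual(build_model(drug, ref_phys, iv5),
                                     times=times)
        double_reg = replace(iv5, n_doses=2, dosing_interval=tau)
        double = simulate_individual(build_model(drug, ref_phys, double_reg),
                                     times=times)
        c1 = single.concentrations
        shifted = np.zeros_like(c1)
        n_shift = int(round(tau / 0.25))
        shifted[n_shift:] = c1[:c1.size - n_shift]
        expected = c1 + shifted
        assert np.max(np.abs(double.concentrations - expected)) \
            <= 1e-6 * expected.max()

    def test_expm_agrees_with_stiff_integrator(self, drug, ref_phys, iv5):
        times = np.linspace(0.0, 24.0, 100)
        m = build_model(drug, ref_phys, iv5)
        a = simulate_individual(m, times=times, method="expm")
        b = simulate_individual(m, times=times, method="lsoda")
        scale = a.concentrations.max()
        assert np.max(np.abs(a.concentrations - b.concentrations)) < 1e-5 * scale

    def test_oral_fully_eliminated_after_ten_half_lives(self, drug, ref_phys,
                                                        oral8):
        m = build_model(drug, ref_phys, oral8)
        prof = simulate_individual(m, t_end=96.0)
        from ondapbpk.engine import _I_ELIM
        eliminated = prof.states[-1, _I_ELIM]
        assert eliminated >= 0.999 * m.fa * m.dose_ug

    def test_zero_clearance_never_eliminates(self, ref_phys, drug, iv5):
        inert = replace(drug, clint_cyp1a2=0.0, clint_cyp3a4=0.0,
                        renal_clearance_specific=0.0)
        m = build_model(inert, ref_phys, iv5)
        prof = simulate_individual(m, t_end=48.0)
        from ondapbpk.engine import _I_ELIM
        assert np.all(prof.states[:, _I_ELIM] == 0.0)
        assert mass_balance_audit(m, prof) <= 1e-6


class TestKinetics:
    def test_terminal_half_life_near_literature(self, healthy_iv_profile, iv5):
        _, prof = healthy_iv_profile
        pk = pk_summary(prof, iv5, 73.0)
        assert 3.8 / 2 <= pk.t_half <= 3.8 * 2

    def test_oral_bioavailability_in_physiologic_range(
            self, healthy_iv_profile, healthy_oral_profile, iv5, oral8):
        _, p_iv = healthy_iv_profile
        _, p_oral = healthy_oral_profile
        auc_iv = pk_summary(p_iv, iv5, 73.0).auc_0inf
        auc_oral = pk_summary(p_oral, oral8, 73.0).auc_0inf
        f = auc_oral / auc_iv
        assert 0.5 <= f <= 0.8      # brackets the known 60-70%

    def test_oral_first_pass_lowers_exposure(self, healthy_iv_profile,
                                             healthy_oral_profile, iv5, oral8):
        _, p_iv = healthy_iv_profile
        _, p_oral = healthy_oral_profile
        assert pk_summary(p_oral, oral8, 73.0).cmax \
            < 0.2 * pk_summary(p_iv, iv5, 73.0).cmax

    def test_time_grid_covers_infusion_end(self, iv5):
        grid = default_time_grid(iv5, 24.0)
        assert np.any(np.isclose(grid, 5.0 / 60.0))
        assert grid[0] == 0.0 and grid[-1] == 24.0
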