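"""Partitioning, binding and clearance arithmetic for the drug model."""

import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ondapbpk.drug import (blood_plasma_ratio, fu_adjusted, fu_blood, log_d,
                           partition_set, poulin_theil_kp, renal_cl_absolute,
                           total_intrinsic_clearance, volume_of_distribution,
                           well_stirred_hepatic_cl)
from ondapbpk.physiology import (OrganSpec, PLASMA_COMPOSITION,
                                 apply_cirrhosis, load_cp_scalers)


def organ(name="tissue", vw=0.76, vnl=0.022, vph=0.0072):
    return OrganSpec(name=name, volume=1.0, blood_flow=0.1,
                     water_fraction=vw, neutral_lipid_fraction=vnl,
                     phospholipid_fraction=vph)


class TestPoulinTheilKp:
    def test_plasma_like_tissue_has_unit_kp(self, drug):
        plasma_like = organ(vw=0.96, vnl=0.0035, vph=0.00225)
        assert poulin_theil_kp(drug, plasma_like) == pytest.approx(1.0)

    def test_kp_increases_with_neutral_lipid(self, drug):
        kps = [poulin_theil_kp(drug, organ(vw=0.6, vnl=v))
               for v in (0.01, 0.02, 0.05, 0.1, 0.3)]
        assert all(b > a for a, b in zip(kps, kps[1:]))

    def test_muscle_kp_matches_direct_formula_evaluation(self, drug):
        # independent arithmetic evaluation of the partition equation
        p = 10.0 ** (2.25 - math.log10(1.0 + 10.0 ** (7.40 - 7.4)))
        num = p * (0.022 + 0.3 * 0.0072) + 0.76 + 0.7 * 0.0072
        den = p * (0.0035 + 0.3 * 0.00225) + 0.96 + 0.7 * 0.00225
        expected = num / den
        got = poulin_theil_kp(drug, organ())
        assert got == pytest.approx(expected, rel=1e-6)

    def test_adipose_uses_olive_oil_coefficient_and_unit_fu(self, drug):
        fat = organ(name="adipose", vw=0.18, vnl=0.79, vph=0.002)
        p = 10.0 ** (1.115 * log_d(drug) - 1.35)
        num = p * (0.79 + 0.3 * 0.002) + 0.18 + 0.7 * 0.002
        den = p * (0.0035 + 0.3 * 0.00225) + 0.96 + 0.7 * 0.00225
        assert poulin_theil_kp(drug, fat) == pytest.approx(
            num / den * drug.fu_plasma, rel=1e-9)

    def test_zero_water_fraction_rejected(self, drug):
        with pytest.raises(ValueError, match="water"):
            poulin_theil_kp(drug, OrganSpec(
                name="weird", volume=1.0, blood_flow=0.1, water_fraction=0.0,
                neutral_lipid_fraction=0.5, phospholipid_fraction=0.0))

    def test_log_d_of_base_at_ph74(self, drug):
        # pKa 7.40 at pH 7.4: half ionized, logD = logP - log10(2)
        assert log_d(drug) == pytest.approx(2.25 - math.log10(2.0))


class TestWellStirred:
    def test_zero_intrinsic_clearance_gives_zero(self):
        assert well_stirred_hepatic_cl(1.5, 0.27, 0.0) == 0.0

    def test_flow_limited_ceiling(self):
        assert well_stirred_hepatic_cl(1.5, 0.27, 1e6) == pytest.approx(
            1.5, rel=1e-3)

    def test_worked_example(self):
        # q=1.5, fu_b=0.27, clint=0.24 -> 1.5*0.0648/1.5648
        assert well_stirred_hepatic_cl(1.5, 0.27, 0.24) == pytest.approx(
            0.0621, abs=5e-5)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(q=st.floats(0.1, 5.0), fu=st.floats(0.01, 1.0),
           cl=st.floats(0.0, 50.0))
    def test_bounded_by_flow_and_monotone(self, q, fu, cl):
        base = well_stirred_hepatic_cl(q, fu, cl)
        assert 0.0 <= base < q
        assert well_stirred_hepatic_cl(q * 1.1, fu, cl) >= base
        assert well_stirred_hepatic_cl(q, min(fu * 1.1, 1.0), cl) >= base
        assert well_stirred_hepatic_cl(q, fu, cl + 0.1) > base

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            well_stirred_hepatic_cl(1.5, -0.1, 0.2)


class TestClearances:
    def test_healthy_uncalibrated_total_clint(self, drug, ref_phys):
        raw = replace(drug, calibration_factor=1.0)
        assert total_intrinsic_clearance(raw, ref_phys) == pytest.approx(0.24)

    def test_calibration_factor_scales_linearly(self, drug, ref_phys):
        assert total_intrinsic_clearance(drug, ref_phys) == pytest.approx(
            0.24 * drug.calibration_factor)

    def test_zero_abundance_gives_zero(self, drug, ref_phys):
        dead = replace(ref_phys, cyp1a2_abundance=0.0, cyp3a4_abundance=0.0)
        assert total_intrinsic_clearance(drug, dead) == 0.0

    def test_cp_c_pathway_scaling(self, drug, ref_phys):
        # CYP1A2 whole-liver activity 0.12; CYP3A4 0.4 per functional mass 0.28
        sick = apply_cirrhosis(ref_phys, load_cp_scalers("C"))
        raw = replace(drug, calibration_factor=1.0)
        expected = 0.21 * 0.12 + 0.03 * 0.4 * 0.28
        assert total_intrinsic_clearance(raw, sick) == pytest.approx(expected)

    def test_renal_clearance(self, drug):
        assert renal_cl_absolute(drug, 70.0) == pytest.approx(9.1)
        assert renal_cl_absolute(drug, 70.0, 0.55) == pytest.approx(5.005)
        assert renal_cl_absolute(drug, 70.0, 0.0) == 0.0


class TestUnboundFractions:
    def test_identity_albumin(self, drug):
        assert fu_adjusted(drug, 1.0) == pytest.approx(0.27)

    def test_cp_c_hypoalbuminemia(self, drug):
        # 0.27 / (0.53*0.73 + 0.27)
        assert fu_adjusted(drug, 0.53) == pytest.approx(0.411, abs=5e-4)

    def test_no_binding_is_invariant(self, drug):
        free = replace(drug, fu_plasma=1.0)
        for alb in (0.3, 0.5, 1.0, 2.0):
            assert fu_adjusted(free, alb) == 1.0

    def test_monotone_decreasing_in_albumin(self, drug):
        vals = [fu_adjusted(drug, a) for a in (0.3, 0.5, 0.8, 1.0, 1.5)]
        assert all(b < a for a, b in zip(vals, vals[1:]))

    def test_nonpositive_albumin_rejected(self, drug):
        with pytest.raises(ValueError, match="albumin"):
            fu_adjusted(drug, 0.0)

    def test_blood_plasma_ratio_from_hematocrit(self, drug):
        bp = blood_plasma_ratio(drug, 0.47)
        assert bp == pytest.approx((1 - 0.47) + 0.47 * 0.63 / 0.96)
        assert fu_blood(drug, 0.47) == pytest.approx(0.27 / bp)


class TestDistributionVolume:
    def test_vss_within_twofold_of_literature(self, drug, ref_phys):
        ps = partition_set(drug, ref_phys)
        vd = volume_of_distribution(ps, ref_phys) / ref_phys.body_weight
        assert 1.8 / 2 <= vd <= 1.8 * 2

    def test_kp_scale_multiplies_tissues_not_blood(self, drug, ref_phys):
        base = partition_set(drug, ref_phys)
        scaled = partition_set(drug, ref_phys, kp_scale=1.3)
        for k in base.kp:
            assert scaled.kp[k] == pytest.approx(1.3 * base.kp[k])
        assert scaled.blood_plasma_ratio == base.blood_plasma_ratio
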