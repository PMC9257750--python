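import math

import numpy as np
import pytest

from ratpbpk.absorption_acat import (
    FormulationSpec,
    GutCompartment,
    SolubilityModel,
    default_acat_config,
    diffusion_coefficient,
    dissolution_rate,
    estimate_solubilization_ratio,
    local_solubility,
    simulate_po,
    simulate_reduced,
)
from ratpbpk.disposition import compute_kp_set, compute_vss, simulate_iv
from ratpbpk.ivive import well_stirred_cl
from ratpbpk.pk_metrics import nca

from conftest import make_compound


class TestSolubilizationRatio:
    def test_no_enhancement(self):
        assert estimate_solubilization_ratio(1.0, s_fassif=1.0) == 0.0

    def test_fassif_worked_value(self):
        assert estimate_solubilization_ratio(1.0, s_fassif=4.0) == pytest.approx(1.0)

    def test_fessif_worked_value(self):
        assert estimate_solubilization_ratio(1.0, s_fessif=16.0) == pytest.approx(1.0)

    def test_max_over_media(self):
        sr = estimate_solubilization_ratio(1.0, s_fassif=4.0, s_fessif=31.0)
        assert sr == pytest.approx(2.0)

    def test_missing_both_warns_and_zero(self):
        with pytest.warns(UserWarning, match="aqueous"):
            assert estimate_solubilization_ratio(1.0) == 0.0

    def test_clipped_at_zero(self):
        assert estimate_solubilization_ratio(10.0, s_fassif=1.0) == 0.0


class TestLocalSolubility:
    def comp(self, ph, bile=0.0):
        return GutCompartment("x", 1.0, ph, 1.0, 0.2, bile)

    def test_neutral_ph_independent(self):
        m = SolubilityModel(s_aq=2.0, solubilization_ratio=0.5)
        assert local_solubility(m, self.comp(2.0)) == pytest.approx(2.0)
        s = local_solubility(m, self.comp(7.0, bile=4.0))
        assert s == pytest.approx(2.0 * (1.0 + 0.5 * 4.0))

    def test_monoprotic_acid_hh_identity(self):
        # at pH == pKa the ionized species doubles the intrinsic solubility
        m = SolubilityModel(s_aq=1.0, ref_ph=3.0, pka_list=((5.0, "acid"),))
        # ref at pH 3: essentially intrinsic (factor 1.01)
        ref_factor = 1.0 + 10.0 ** (3.0 - 5.0)
        s = local_solubility(m, self.comp(5.0))
        assert s == pytest.approx(2.0 / ref_factor, rel=1e-12)

    def test_hand_computed_profile(self):
        m = SolubilityModel(s_aq=1.0, ref_ph=6.5, pka_list=((4.0, "acid"),))
        for ph in (3.0, 5.0, 7.4):
            expected = (1.0 + 10.0 ** (ph - 4.0)) / (1.0 + 10.0 ** (6.5 - 4.0))
            assert local_solubility(m, self.comp(ph)) == pytest.approx(expected, rel=1e-12)

    def test_amplification_cap(self):
        m = SolubilityModel(s_aq=1.0, ref_ph=2.0, pka_list=((3.0, "acid"),), max_amp=100.0)
        assert local_solubility(m, self.comp(8.5)) == pytest.approx(100.0 * 1.0, rel=1e-6)


class TestDissolution:
    def test_saturation_stops_dissolution(self):
        rate = dissolution_rate(1.0, 25e-4, 0.1, 0.1, 5e-5)
        assert rate == 0.0

    def test_rate_positive_below_saturation(self):
        assert dissolution_rate(1.0, 25e-4, 0.1, 0.0, 5e-5) > 0

    def test_diffusion_coefficient_power_law(self):
        assert diffusion_coefficient(400.0) == pytest.approx(9.9e-5 * 400.0 ** -0.453)
        with pytest.raises(ValueError):
            diffusion_coefficient(0.0)

    def test_time_to_dissolve_scales_with_radius_squared(self):
        """In the h = r regime (r0 below the diffusion-layer cap), the
        time to 90% dissolved under sink conditions scales with r0^2;
        checked by numerically integrating the shrinking-sphere rate law."""
        from scipy.integrate import solve_ivp

        d, cs, rho, m0 = 5e-5, 0.01, 1.2, 1.0  # cm^2/s, mg/mL, g/mL, mg

        def t90(r0_cm):
            def rhs(t, y):
                m = max(y[0], 0.0)
                r = r0_cm * (m / m0) ** (1.0 / 3.0) if m > 0 else 0.0
                return [-dissolution_rate(m, r, cs, 0.0, d, density=rho)]

            def hit(t, y):
                return y[0] - 0.1 * m0

            hit.terminal = True
            hit.direction = -1
            sol = solve_ivp(rhs, (0.0, 1e7), [m0], events=hit,
                            rtol=1e-10, atol=1e-14)
            assert sol.t_events[0].size == 1
            return sol.t_events[0][0]

        t_small, t_large = t90(10e-4), t90(20e-4)  # 10 um vs 20 um radius
        assert t_large / t_small == pytest.approx(4.0, rel=0.02)


class TestSimulatePO:
    def test_solution_bypasses_dissolution(self, phys):
        c = make_compound(s_aq=1e-3)  # insoluble, but dosed as solution
        kps = compute_kp_set(c, 0.2, 1.0, phys)
        res = simulate_po(c, 1.0, 100.0, kps, phys,
                          formulation=FormulationSpec(kind="solution"))
        assert np.all(res.extras["lumen_undissolved"] < 1e-12)
        assert res.extras["fabs"] > 0.5

    def test_zero_permeability_no_absorption(self, phys):
        c = make_compound(papp=1e-30)
        kps = compute_kp_set(c, 0.2, 1.0, phys)
        res = simulate_po(c, 1.0, 100.0, kps, phys)
        assert res.extras["fabs"] < 1e-6

    def test_complete_absorption_no_clearance_foral_near_one(self, phys):
        c = make_compound(papp=1e-3, clint=10.0)
        kps = compute_kp_set(c, 0.2, 1.0, phys)
        clint = 0.5  # nearly no first pass
        res = simulate_po(c, 1.0, clint, kps, phys, t_end_h=2000.0)
        iv = simulate_iv(1.0, clint, 0.2, 1.0, kps, phys, t_end_h=2000.0)
        auc_iv = nca(iv.time_h, iv.plasma, 1.0, "IV").aucinf
        ppo = nca(res.time_h, res.plasma, 1.0, "PO", auc_iv_ref=auc_iv, dose_iv_ref=1.0)
        assert ppo.foral == pytest.approx(1.0, abs=0.02)

    def test_foral_close_to_fabs_times_fh(self, phys):
        c = make_compound(papp=3e-5, clint=30.0, fup=0.3)
        kps = compute_kp_set(c, 0.3, 1.0, phys)
        clint = 200.0
        res = simulate_po(c, 1.0, clint, kps, phys, t_end_h=200.0)
        iv = simulate_iv(1.0, clint, 0.3, 1.0, kps, phys, t_end_h=200.0)
        auc_iv = nca(iv.time_h, iv.plasma, 1.0, "IV").aucinf
        ppo = nca(res.time_h, res.plasma, 1.0, "PO", auc_iv_ref=auc_iv, dose_iv_ref=1.0)
        assert ppo.foral == pytest.approx(
            res.extras["fabs"] * res.extras["fh"], rel=0.05
        )

    def test_gut_mass_balance(self, phys):
        for kind in ("solution", "suspension"):
            c = make_compound(s_aq=1.0)
            kps = compute_kp_set(c, 0.2, 1.0, phys)
            res = simulate_po(c, 2.0, 100.0, kps, phys,
                              formulation=FormulationSpec(kind=kind))
            assert res.mass_balance_error() < 1e-6

    def test_fabs_nondecreasing_in_permeability(self, phys):
        fabs = []
        for papp in (1e-7, 1e-6, 1e-5):
            c = make_compound(papp=papp)
            kps = compute_kp_set(c, 0.2, 1.0, phys)
            res = simulate_po(c, 1.0, 100.0, kps, phys)
            fabs.append(res.extras["fabs"])
        assert fabs[0] < fabs[1] < fabs[2]

    def test_fabs_nondecreasing_in_solubility(self, phys):
        fabs = []
        for s_aq in (0.1, 1.0, 100.0):
            c = make_compound(s_aq=s_aq, papp=1e-5)
            kps = compute_kp_set(c, 0.2, 1.0, phys)
            res = simulate_po(c, 10.0, 100.0, kps, phys,
                              formulation=FormulationSpec(kind="suspension"))
            fabs.append(res.extras["fabs"])
        assert fabs[0] <= fabs[1] <= fabs[2]
        assert fabs[0] < fabs[2]

    def test_foral_le_fabs(self, phys):
        c = make_compound(papp=2e-5, clint=50.0)
        kps = compute_kp_set(c, 0.2, 1.0, phys)
        clint = 500.0
        res = simulate_po(c, 1.0, clint, kps, phys, t_end_h=200.0)
        iv = simulate_iv(1.0, clint, 0.2, 1.0, kps, phys, t_end_h=200.0)
        auc_iv = nca(iv.time_h, iv.plasma, 1.0, "IV").aucinf
        ppo = nca(res.time_h, res.plasma, 1.0, "PO", auc_iv_ref=auc_iv, dose_iv_ref=1.0)
        assert ppo.foral <= res.extras["fabs"] + 1e-6
        assert res.extras["fabs"] <= 1.0 + 1e-9


class TestSimulateReduced:
    def test_iv_equals_closed_form(self, phys):
        c = make_compound()
        kps = compute_kp_set(c, 0.2, 1.0, phys)
        vss = compute_vss(kps, phys, 1.0)
        clint = 100.0
        cl = well_stirred_cl(clint, 0.2, 1.0)
        res = simulate_reduced(c, 1.0, "IV", clint, vss, phys)
        expected = 1.0 / (vss * 1000.0) * np.exp(-cl / (vss * 1000.0) * res.time_h * 60.0) * 1e6
        np.testing.assert_allclose(res.plasma, expected, rtol=1e-12)

    def test_po_mass_balance(self, phys):
        c = make_compound()
        kps = compute_kp_set(c, 0.2, 1.0, phys)
        vss = compute_vss(kps, phys, 1.0)
        res = simulate_reduced(c, 1.0, "PO", 100.0, vss, phys)
        assert res.mass_balance_error() < 1e-6

    def test_po_auc_close_to_full_model(self, phys):
        c = make_compound(papp=2e-5)
        kps = compute_kp_set(c, 0.2, 1.0, phys)
        vss = compute_vss(kps, phys, 1.0)
        clint = 150.0
        full = simulate_po(c, 1.0, clint, kps, phys, t_end_h=200.0)
        red = simulate_reduced(c, 1.0, "PO", clint, vss, phys, t_end_h=200.0)
        auc_full = nca(full.time_h, full.plasma, 1.0, "PO").aucinf
        auc_red = nca(red.time_h, red.plasma, 1.0, "PO").aucinf
        assert auc_red == pytest.approx(auc_full, rel=0.05)

    def test_bad_route(self, phys):
        c = make_compound()
        with pytest.raises(ValueError, match="route"):
            simulate_reduced(c, 1.0, "IM", 10.0, 1.0, phys)
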