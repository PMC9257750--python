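import math

import numpy as np
import pytest

from ratpbpk.disposition import (
    KpError,
    KpSet,
    blood_cell_partition,
    compute_kp,
    compute_kp_set,
    compute_vss,
    simulate_iv,
    simulate_reduced_iv,
)
from ratpbpk.ivive import well_stirred_cl
from ratpbpk.physiology import TISSUES, RatPhysiology, TissueComposition, default_physiology
from ratpbpk.pk_metrics import nca

from conftest import make_compound


class TestKpSet:
    def test_requires_all_tissues(self):
        with pytest.raises(KpError, match="missing"):
            KpSet({"liver": 1.0})

    def test_rejects_nonpositive(self):
        vals = {t: 1.0 for t in TISSUES}
        vals["liver"] = 0.0
        with pytest.raises(KpError, match="> 0"):
            KpSet(vals)


class TestComputeKp:
    def test_water_only_limit(self, phys):
        """No lipid affinity, fully unbound, neutral: Kp ~ total water."""
        c = make_compound(logd74=-10.0, fup=1.0, bp=1.0)
        for name in ("muscle", "liver", "brain"):
            t = phys.tissues[name]
            kp = compute_kp(c, t, 1.0, 1.0, phys)
            # residual 0.7*f_np is the water-like phospholipid headgroup term
            assert kp == pytest.approx(t.f_ew + t.f_iw + 0.7 * t.f_np, rel=1e-6)

    def test_monotone_in_logd_for_neutral(self, phys):
        kps = [
            compute_kp(make_compound(logd74=ld), phys.tissues["muscle"], 0.2, 1.0, phys)
            for ld in (0.0, 1.0, 2.0, 3.0)
        ]
        assert all(b > a for a, b in zip(kps, kps[1:]))

    def test_negative_blood_cell_partition_raises(self, phys):
        c = make_compound(category="basic", bp=0.3)
        with pytest.raises(KpError, match="blood-cell"):
            compute_kp(c, phys.tissues["muscle"], c.in_vitro.fup, 0.3, phys)

    def test_strong_base_transcription_oracle(self, phys):
        """Straight-line independent transcription of the monoprotic-base
        partitioning equations, evaluated step by step per tissue."""
        pka, logd, fup, bp = 9.0, 2.0, 0.1, 1.2
        c = make_compound(category="basic", pka=pka, logd74=logd, fup=fup, bp=bp)
        logp = logd + math.log10(1.0 + 10.0 ** (pka - 7.4))
        p = 10.0 ** logp
        y = 1.0 + 10.0 ** (pka - 7.4)  # plasma pH
        # blood-cell calibration of the acidic-phospholipid constant
        kpu_bc = ((bp - (1.0 - 0.46)) / 0.46) / fup
        x_bc = 1.0 + 10.0 ** (pka - 7.22)
        water_bc = 0.603 * x_bc / y
        lipid_bc = (p * 0.0017 + (0.3 * p + 0.7) * 0.0029) / y
        ka = (kpu_bc - water_bc - lipid_bc) * y / (0.5 * 10.0 ** (pka - 7.22))
        for name in ("muscle", "liver", "heart", "brain"):
            t = phys.tissues[name]
            x = 1.0 + 10.0 ** (pka - t.ph_iw)
            expected = fup * (
                t.f_ew
                + t.f_iw * x / y
                + (p * t.f_nl + (0.3 * p + 0.7) * t.f_np) / y
                + ka * t.ap * 10.0 ** (pka - t.ph_iw) / y
            )
            assert compute_kp(c, t, fup, bp, phys) == pytest.approx(expected, rel=1e-12)

    def test_acid_uses_albumin_ratio_neutral_uses_lipoprotein(self, phys):
        acid = make_compound(category="acidic", fup=0.05)
        neutral = make_compound(fup=0.05)
        t = phys.tissues["muscle"]
        kp_acid = compute_kp(acid, t, 0.05, 1.0, phys)
        kp_neutral = compute_kp(neutral, t, 0.05, 1.0, phys)
        assert kp_acid != pytest.approx(kp_neutral)


class TestComputeVss:
    def test_all_kp_one(self, phys):
        kps = KpSet({t: 1.0 for t in TISSUES})
        vss = compute_vss(kps, phys, bp=1.0)
        tissue_vol = sum(phys.tissues[t].volume for t in TISSUES)
        # bp=1 makes the blood-cell partition exactly 1
        assert vss == pytest.approx((phys.v_blood + tissue_vol) / 1000.0, rel=1e-12)

    def test_linearity_in_kp(self, phys):
        kps1 = KpSet({t: 1.5 for t in TISSUES})
        kps2 = KpSet({t: 3.0 for t in TISSUES})
        blood = phys.v_plasma + phys.v_blood * phys.hematocrit * blood_cell_partition(1.0, phys.hematocrit)
        t1 = compute_vss(kps1, phys, 1.0) * 1000.0 - blood
        t2 = compute_vss(kps2, phys, 1.0) * 1000.0 - blood
        assert t2 == pytest.approx(2.0 * t1, rel=1e-12)

    def test_matches_simulated_mrt_cl(self, phys):
        """Vss formula vs CL*MRT from a low-extraction IV profile."""
        for seed_cat in ("neutral", "basic", "acidic"):
            c = make_compound(category=seed_cat, logd74=2.5, fup=0.3, bp=1.1)
            kps = compute_kp_set(c, 0.3, 1.1, phys)
            vss = compute_vss(kps, phys, 1.1)
            clint = 2.0  # low extraction so liver-site elimination bias is negligible
            cl = well_stirred_cl(clint, 0.3, 1.1)
            t_half_h = math.log(2.0) * vss * 1000.0 / cl / 60.0
            res = simulate_iv(1.0, clint, 0.3, 1.1, kps, phys, t_end_h=8 * t_half_h)
            params = nca(res.time_h, res.plasma, 1.0, "IV")
            assert params.vss == pytest.approx(vss, rel=0.02)


class TestSimulateIV:
    def test_auc_cl_identity(self, phys):
        c = make_compound(fup=0.2, bp=1.1)
        kps = compute_kp_set(c, 0.2, 1.1, phys)
        clint = 300.0
        cl = well_stirred_cl(clint, 0.2, 1.1)
        res = simulate_iv(2.0, clint, 0.2, 1.1, kps, phys)
        params = nca(res.time_h, res.plasma, 2.0, "IV")
        assert params.cl == pytest.approx(cl, rel=0.005)
        assert params.aucinf * params.cl * 60.0 == pytest.approx(2.0 * 1e6, rel=0.005)

    def test_mass_balance(self, phys):
        c = make_compound()
        kps = compute_kp_set(c, 0.2, 1.0, phys)
        res = simulate_iv(1.0, 100.0, 0.2, 1.0, kps, phys)
        assert res.mass_balance_error() < 1e-6

    def test_nonnegative_states(self, phys):
        c = make_compound()
        kps = compute_kp_set(c, 0.2, 1.0, phys)
        res = simulate_iv(1.0, 100.0, 0.2, 1.0, kps, phys)
        assert np.all(res.plasma >= 0)
        for arr in res.amounts.values():
            assert np.all(arr >= -1e-12)

    def test_zero_clint_no_elimination_flagged(self, phys):
        c = make_compound()
        kps = compute_kp_set(c, 0.2, 1.0, phys)
        res = simulate_iv(1.0, 0.0, 0.2, 1.0, kps, phys)
        assert np.all(res.eliminated < 1e-12)
        params = nca(res.time_h, res.plasma, 1.0, "IV")
        # no terminal decline: extrapolation must be flagged as unreliable
        assert params.warnings

    def test_closed_form_degenerate_config(self):
        """Well-mixed limit (flows scaled up, all Kp = 1) vs the closed-form
        one-compartment solution."""
        phys = default_physiology()
        scaled = {
            name: TissueComposition(
                name=t.name, volume=t.volume, blood_flow=t.blood_flow * 1e5,
                f_ew=t.f_ew, f_iw=t.f_iw, f_nl=t.f_nl, f_np=t.f_np, ap=t.ap,
                ra_albumin=t.ra_albumin, ra_lipoprotein=t.ra_lipoprotein,
                ph_iw=t.ph_iw,
            )
            for name, t in phys.tissues.items()
        }
        fast = RatPhysiology(tissues=scaled)
        kps = KpSet({t: 1.0 for t in TISSUES})
        clint, fup, dose = 50.0, 0.5, 1.0
        res = simulate_iv(dose, clint, fup, 1.0, kps, fast, t_end_h=6.0)
        v_tot = fast.v_blood + sum(fast.tissues[t].volume for t in TISSUES)
        cl = clint * fup  # no flow limitation in the well-mixed limit
        expected = dose / v_tot * np.exp(-cl * res.time_h * 60.0 / v_tot) * 1e6
        mask = res.time_h > 0.01  # after the (fast) mixing transient
        rel = np.abs(res.plasma[mask] - expected[mask]) / expected[mask]
        assert rel.max() < 1e-4


class TestSimulateReducedIV:
    def test_matches_closed_form_exactly(self):
        res = simulate_reduced_iv(2.0, 30.0, 1.5)
        expected = 2.0 / 1500.0 * np.exp(-30.0 / 1500.0 * res.time_h * 60.0) * 1e6
        np.testing.assert_allclose(res.plasma, expected, rtol=1e-12)

    def test_cmax_is_dose_over_vss(self):
        res = simulate_reduced_iv(2.0, 30.0, 1.5)
        assert res.plasma[0] == pytest.approx(2.0 / 1.5 * 1000.0, rel=1e-12)

    def test_auc_identity_vs_full(self, phys):
        c = make_compound(fup=0.2, bp=1.0)
        kps = compute_kp_set(c, 0.2, 1.0, phys)
        clint = 200.0
        cl = well_stirred_cl(clint, 0.2, 1.0)
        vss = compute_vss(kps, phys, 1.0)
        full = simulate_iv(1.0, clint, 0.2, 1.0, kps, phys, t_end_h=200.0)
        red = simulate_reduced_iv(1.0, cl, vss, t_end_h=200.0)
        auc_full = nca(full.time_h, full.plasma, 1.0, "IV").aucinf
        auc_red = nca(red.time_h, red.plasma, 1.0, "IV").aucinf
        assert auc_red == pytest.approx(auc_full, rel=0.01)
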