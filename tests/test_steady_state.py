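import numpy as np
import pytest

from akglyc import adenylate as aden
from akglyc.dynamics import integrate, rhs
from akglyc.kinetics import AtpaseSpec, v_gpi, v_hk
from akglyc.steady_state import (bifurcation_diagram, characteristic,
                                 characteristic_vs_charge, find_steady_states,
                                 pool_sweep, stabilization_metrics)


class TestCharacteristic:
    def test_flux_equality_at_every_point(self, ery, ery_curve):
        c = ery_curve
        assert c.converged.all()
        vhk = v_hk(c.ATP, c.G6P, ery)
        vgpi = v_gpi(c.G6P, c.F6P, ery)
        assert np.max(np.abs(vhk - vgpi)) < 1e-8
        assert np.max(np.abs(vgpi - c.V_PFK)) < 1e-8
        assert np.allclose(c.production, 2 * c.V_PFK, atol=1e-8)

    def test_normal_operating_point(self, ery_curve):
        assert ery_curve.production_at(1.5) == pytest.approx(2.34, rel=0.03)
        ok = ery_curve.converged
        g6p = np.interp(1.5, ery_curve.ATP[ok], ery_curve.G6P[ok])
        f6p = np.interp(1.5, ery_curve.ATP[ok], ery_curve.F6P[ok])
        assert g6p == pytest.approx(0.0706, rel=0.05)
        assert f6p == pytest.approx(0.0231, rel=0.10)

    def test_bell_shape_with_operating_point_on_descending_branch(self, ery_curve):
        assert ery_curve.classify(operating_atp=1.5) == "bell"
        atp_peak, prod_peak = ery_curve.peak()
        assert atp_peak < 1.5
        assert prod_peak > ery_curve.production_at(1.5)

    def test_production_vanishes_at_low_atp(self, ery):
        c = characteristic(ery, atp_grid=np.linspace(0.005, 0.2, 40))
        assert c.production[c.converged][0] < 0.1 * c.production[c.converged][-1]

    def test_without_ak_is_monotone_increasing(self, ery):
        p = ery.replace(ak_mode="absent")
        c = characteristic(p, atp_grid=np.linspace(0.1, 1.9, 200))
        assert c.classify() == "monotone"

    def test_points_are_dynamic_steady_states(self, ery, ery_curve):
        """Cross-module consistency: each characteristic point, balanced by
        a matching linear load, is a fixed point of the full dynamics."""
        c = ery_curve
        for i in range(10, len(c.ATP), 40):
            atp = c.ATP[i]
            adp, _ = aden.adp_amp_from_atp(atp, ery.A_pool, ery.K_AK)
            balancing = AtpaseSpec("linear", activity=c.production[i] / atp)
            deriv = rhs([c.G6P[i], c.F6P[i], 2 * atp + adp], ery, balancing)
            assert np.max(np.abs(deriv)) < 1e-6

    def test_peak_height_scales_with_hk_activity(self, ery, ery_curve):
        """The bell height tracks HK activity (the pathway's limiting
        enzyme): close to, though slightly below, proportionally."""
        base = ery_curve.peak()[1]
        up = characteristic(ery.replace(A_HK=24.0)).peak()[1]
        down = characteristic(ery.replace(A_HK=6.0)).peak()[1]
        assert 1.5 < up / base < 2.0
        assert 0.5 < down / base < 0.65

    def test_weak_amp_activation_removes_descending_branch(self, ery, ery_curve):
        """Raising the PFK AMP-activation constant suppresses the negative
        feedback: at 100x the bell is flattened to a vestigial bump, at
        1000x the curve is strictly monotone increasing."""
        c100 = characteristic(ery.replace(K_PFK3=1.0))
        _, peak100 = c100.peak()
        drop100 = (peak100 - c100.production[c100.converged][-1]) / peak100
        drop_base = ((ery_curve.peak()[1] - ery_curve.production[ery_curve.converged][-1])
                     / ery_curve.peak()[1])
        assert drop100 < 0.05 < drop_base
        c1000 = characteristic(ery.replace(K_PFK3=10.0))
        assert c1000.classify() == "monotone"


class TestFindSteadyStates:
    def test_linear_default_single_stable_state(self, ery, ery_curve):
        recs = find_steady_states(ery, AtpaseSpec("linear"), curve=ery_curve)
        assert len(recs) == 1
        r = recs[0]
        assert r.stability == "stable" and r.branch == "descending"
        assert r.ATP == pytest.approx(1.5, rel=0.02)
        assert np.all(np.real(r.eigenvalues) < 0)

    def test_hyperbolic_default_stable_unstable_pair(self, ery, ery_curve):
        recs = find_steady_states(ery, AtpaseSpec("hyperbolic"), curve=ery_curve)
        labels = sorted((r.stability, r.branch) for r in recs)
        assert labels == [("stable", "descending"), ("unstable", "ascending")]

    def test_hyperbolic_above_maximum_only_collapse(self, ery, ery_curve):
        vmax = 1.3 * ery_curve.peak()[1]
        recs = find_steady_states(ery, AtpaseSpec("hyperbolic", activity=vmax),
                                  curve=ery_curve)
        assert len(recs) == 1 and recs[0].branch == "collapsed"
        assert recs[0].ATP == 0.0

    def test_stability_confirmed_by_perturbed_integration(self, ery, ery_curve):
        recs = find_steady_states(ery, AtpaseSpec("hyperbolic"), curve=ery_curve)
        for r in recs:
            for sign in (+1, -1):
                atp0 = r.ATP * (1 + sign * 0.01)
                adp0, _ = aden.adp_amp_from_atp(atp0, ery.A_pool, ery.K_AK)
                traj = integrate(ery, [r.G6P, r.F6P, 2 * atp0 + adp0], 5.0,
                                 AtpaseSpec("hyperbolic"),
                                 t_eval=[0.0, 5.0])
                err = abs(traj.ATP[-1] - r.ATP) / r.ATP
                if r.stability == "stable":
                    assert err < 1e-3
                else:
                    assert err > 0.02


class TestBifurcation:
    def test_linear_with_ak_stabilizes_atp(self, ery, ery_curve):
        grid = np.array([0.5, 1.0, 2.0]) * ery.atpase_linear_a
        d = bifurcation_diagram(ery, "linear", grid, curve=ery_curve)
        _, atp = d.branch("stable")
        assert len(atp) == 3
        span = (atp.max() - atp.min()) / atp[1]
        assert span < 0.30  # fourfold load range moves ATP < 30%
        # a twofold step from half-normal to normal load moves ATP ~10%
        half_step = 100.0 * (atp[0] - atp[1]) / atp[0]
        assert 5.0 <= half_step <= 15.0
        assert d.fold_activity is None

    def test_linear_without_ak_tracks_inverse_activity(self, ery):
        p = ery.replace(ak_mode="absent")
        recs1 = find_steady_states(p, AtpaseSpec("linear", scale=1.0))
        recs2 = find_steady_states(p, AtpaseSpec("linear", scale=2.0))
        atp1 = max(r.ATP for r in recs1)
        atp2 = max(r.ATP for r in recs2)
        assert atp2 < 0.6 * atp1  # no stabilization: ~inverse to activity

    def test_hyperbolic_fold_near_characteristic_maximum(self, ery, ery_curve):
        grid = np.linspace(0.5, 2.5, 9) * ery.atpase_hyperbolic_Vmax
        d = bifurcation_diagram(ery, "hyperbolic", grid, curve=ery_curve)
        sa, _ = d.branch("stable")
        ua, _ = d.branch("unstable")
        assert len(sa) > 0 and len(ua) > 0
        peak = ery_curve.peak()[1]
        assert d.fold_activity == pytest.approx(peak, rel=0.05)
        # beyond the fold the nonzero states are gone
        beyond = find_steady_states(
            ery, AtpaseSpec("hyperbolic", activity=1.01 * d.fold_activity),
            curve=ery_curve)
        assert all(r.branch == "collapsed" for r in beyond)


class TestStabilization:
    def test_erythrocyte_q_well_above_one(self, ery, ery_curve):
        m = stabilization_metrics(ery, "linear", curve=ery_curve)
        assert m["Q"] > 5.0
        assert m["C"] == pytest.approx(-1.0 / m["Q"])

    def test_off_stable_branch_raises(self, ery, ery_curve):
        with pytest.raises(ValueError):
            stabilization_metrics(ery, "hyperbolic", activity=6.0, curve=ery_curve)


class TestPoolSweep:
    def test_normalized_curves_nearly_collapse(self, ery):
        res = pool_sweep(ery, [0.9, 1.79, 3.58])
        assert res.max_deviation < 0.10
        # through the peak region the collapse is much tighter
        mid = (res.x_common > 0.7) & (res.x_common < 1.3)
        for i in range(3):
            for j in range(i + 1, 3):
                assert np.max(np.abs(res.normalized[i] - res.normalized[j])[mid]) < 0.02

    def test_absolute_curves_scale_with_pool(self, ery):
        res = pool_sweep(ery, [0.9, 1.79, 3.58])
        peaks = [c.peak() for c in res.curves]
        atp_pos = np.array([p[0] for p in peaks])
        assert np.all(np.diff(atp_pos) > 0)
        rel_pos = atp_pos / np.array([0.9, 1.79, 3.58])
        assert np.max(rel_pos) - np.min(rel_pos) < 0.02  # peak sits at fixed ATP/A

    def test_without_ak_normalized_curves_do_not_collapse(self, ery):
        """Without AK the flux follows absolute ATP, so curves plotted
        against relative ATP separate strongly across pool sizes."""
        p = ery.replace(ak_mode="absent")
        vals = []
        for A in (0.9, 1.79, 3.58):
            c = characteristic(p.replace(A_pool=A),
                               atp_grid=np.linspace(0.05, 0.95, 80) * A)
            vals.append(np.interp(0.5 * A, c.ATP, c.production))
        assert max(vals) > 1.5 * min(vals)


class TestChargeCurve:
    def test_charge_approximates_relative_atp_at_high_charge(self, ery, ery_curve):
        cc = characteristic_vs_charge(ery, curve=ery_curve)
        sel = cc.atp_rel > 0.7
        assert np.all(cc.phi[sel] > cc.atp_rel[sel])
        assert np.max(cc.phi[sel] - cc.atp_rel[sel]) < 0.12
        # at the physiological point the two abscissae agree to ~7 points
        i = np.argmin(np.abs(cc.atp_rel - 1.5 / 1.79))
        assert cc.phi[i] - cc.atp_rel[i] < 0.08

    def test_production_vanishes_at_low_charge(self, ery, ery_curve):
        cc = characteristic_vs_charge(ery, curve=ery_curve)
        i = np.argmin(cc.phi)
        assert cc.production[i] < 0.15 * np.max(cc.production)

    def test_requires_ak_mode(self, ery):
        with pytest.raises(ValueError):
            characteristic_vs_charge(ery.replace(ak_mode="absent"))
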