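"""Force-curve analysis tests: WLC model, baseline, contact point, rupture
detection, WLC fitting and the per-curve round trip."""

from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from smforce import (SimulationConfig, analyze_curve, classify_specificity,
                     correct_baseline, detect_ruptures, find_contact_point,
                     fit_wlc, simulate_experiment, simulate_force_curve,
                     simulate_rupture_forces, wlc_extension, wlc_force)
from smforce.curves import RuptureEvent


class TestWlcModel:
    def test_zero_extension_zero_force(self):
        assert wlc_force(0.0, 0.38, 35.0) == 0.0

    def test_closed_form_value(self):
        # (kB*T / Lp) * [1/(4*(1-0.5)^2) - 1/4 + 0.5] = (kB*T/0.38) * 1.25
        expected = 1.380649e-2 * 298.0 / 0.38 * 1.25
        assert wlc_force(15.0, 0.38, 30.0, 298.0) == pytest.approx(expected)
        assert wlc_force(15.0, 0.38, 30.0, 298.0) == pytest.approx(13.53, abs=0.05)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.floats(0.01, 0.98), st.floats(0.01, 0.97))
    def test_strictly_increasing(self, t1, t2):
        lc = 35.0
        f1, f2 = wlc_force(t1 * lc, 0.38, lc), wlc_force(t2 * lc, 0.38, lc)
        if t1 < t2:
            assert f1 < f2
        elif t1 > t2:
            assert f1 > f2

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            wlc_force(36.0, 0.38, 35.0)
        with pytest.raises(ValueError):
            wlc_force(10.0, -0.1, 35.0)

    def test_extension_inverts_force(self):
        x = wlc_extension(100.0, 0.38, 35.0)
        assert wlc_force(x, 0.38, 35.0) == pytest.approx(100.0, abs=1e-6)


class TestBaseline:
    def test_removes_own_tilt(self, noiseless_config):
        cfg = replace(noiseless_config, baseline_tilt=0.05)
        curve = correct_baseline(simulate_force_curve(cfg, []))
        tail = curve.force_retract[-100:]
        assert abs(tail.mean()) < 0.1

    def test_idempotent_on_flat_curve(self, single_event_curve):
        once = correct_baseline(single_event_curve)
        twice = correct_baseline(once)
        np.testing.assert_allclose(twice.force_retract, once.force_retract,
                                   atol=1e-9)

    def test_tilted_curve_round_trip(self, noiseless_config):
        cfg = replace(noiseless_config, baseline_tilt=0.05)
        curve = simulate_force_curve(cfg, [(100.0, 35.0)])
        events = analyze_curve(curve, noise_sd=0.5, spring_constant=30.0)
        assert len(events) == 1
        assert events[0].rupture_force == pytest.approx(100.0, abs=0.5)


class TestContactPoint:
    def test_noiseless_contact_point(self, single_event_curve):
        curve = correct_baseline(single_event_curve)
        z0 = find_contact_point(curve, noise_sd=0.2)
        assert z0 == pytest.approx(5.0, abs=0.25)

    def test_no_contact_raises(self):
        z = np.arange(100.0)
        zero = np.zeros(100)
        from smforce import ForceCurve
        with pytest.raises(ValueError):
            find_contact_point(ForceCurve("c", z, zero, zero), noise_sd=1.0)

    def test_noisy_contact_point_within_two_samples(self, control_config):
        cfg = replace(control_config, force_noise_sd=2.0)
        errs = []
        for seed in range(30):
            curve = simulate_force_curve(
                cfg, [], np.random.default_rng(seed), curve_id=f"s{seed}")
            curve = correct_baseline(curve)
            errs.append(abs(find_contact_point(curve, noise_sd=2.0) - 5.0))
        dz = cfg.retract_velocity / cfg.sample_rate
        assert np.max(errs) < 2 * dz + 0.2


class TestDetection:
    def test_noiseless_single_event(self, single_event_curve):
        events = detect_ruptures(correct_baseline(single_event_curve), 0.0)
        assert len(events) == 1
        assert events[0].rupture_force == pytest.approx(132.0, abs=1e-6)

    def test_false_positive_rate_on_flat_baselines(self, control_config):
        cfg = replace(control_config, force_noise_sd=5.0)
        fp = 0
        for seed in range(200):
            curve = simulate_force_curve(
                cfg, [], np.random.default_rng(10_000 + seed))
            if detect_ruptures(correct_baseline(curve), 5.0):
                fp += 1
        assert fp / 200 <= 0.05

    def test_two_tethers_two_events(self, noiseless_config):
        curve = simulate_force_curve(noiseless_config, [(66.0, 25.0), (132.0, 42.0)])
        events = detect_ruptures(correct_baseline(curve), 0.0)
        assert len(events) == 2
        assert events[0].rupture_distance < events[1].rupture_distance


class TestWlcFit:
    def test_noiseless_self_consistency(self):
        x = np.linspace(0.5, 31.0, 80)
        f = wlc_force(x, 0.38, 35.0)
        lp, lc, resid = fit_wlc(x, f)
        assert lp == pytest.approx(0.38, rel=1e-4)
        assert lc == pytest.approx(35.0, rel=1e-4)
        assert resid < 1e-6

    def test_noisy_contour_length_within_five_percent(self):
        x = np.linspace(0.5, 31.0, 150)
        f_true = wlc_force(x, 0.38, 35.0)
        errs = []
        for seed in range(25):
            f = f_true + np.random.default_rng(seed).normal(0, 2.0, len(x))
            _, lc, _ = fit_wlc(x, f)
            errs.append(abs(lc - 35.0) / 35.0)
        assert np.mean(errs) < 0.05

    def test_matches_grid_search_oracle(self):
        x = np.linspace(0.5, 30.0, 120)
        f = wlc_force(x, 0.38, 35.0) + np.random.default_rng(42).normal(0, 2.0, len(x))
        lp_fit, lc_fit, _ = fit_wlc(x, f)
        # brute-force oracle on a (Lp, Lc) lattice
        lps = np.arange(0.2, 0.61, 0.02)
        lcs = np.arange(31.0, 45.01, 0.25)
        best = None
        for lp in lps:
            for lc in lcs:
                ssr = np.sum((wlc_force(x, lp, lc) - f) ** 2)
                if best is None or ssr < best[0]:
                    best = (ssr, lp, lc)
        assert abs(lp_fit - best[1]) <= 0.02 + 1e-9
        assert abs(lc_fit - best[2]) <= 0.25 + 1e-9

    def test_too_short_segment_raises(self):
        with pytest.raises(ValueError):
            fit_wlc(np.linspace(1, 10, 10), np.linspace(1, 50, 10))


class TestSpecificity:
    def _event(self, dist, resid=np.nan, lc=np.nan, force=50.0):
        return RuptureEvent(curve_id="c", rupture_force=force,
                            rupture_distance=dist, contour_length=lc,
                            fit_residual=resid)

    def test_inside_window_is_specific(self):
        assert classify_specificity(self._event(35.0))

    def test_surface_adhesion_is_not(self):
        assert not classify_specificity(self._event(2.0))

    def test_permissive_limits_accept_everything(self):
        ev = self._event(200.0, resid=1e9)
        assert classify_specificity(ev, tether_window=(0.0, np.inf),
                                    residual_max=np.inf)

    def test_extension_beyond_contour_rejected(self):
        ev = self._event(35.0, resid=1.0, lc=20.0, force=60.0)
        assert not classify_specificity(ev, spring_constant=30.0)


class TestRoundTrip:
    def test_noiseless_recovery_below_half_piconewton(self, noiseless_config):
        rng = np.random.default_rng(11)
        n_ok = 0
        for _ in range(25):
            force = float(np.clip(simulate_rupture_forces(noiseless_config, 1, rng)[0], 20, None))
            lc = float(rng.normal(35, 5))
            if lc < 15:
                continue
            try:
                curve = simulate_force_curve(noiseless_config, [(force, lc)], rng)
            except ValueError:
                continue
            events = analyze_curve(curve, noise_sd=0.5, spring_constant=30.0)
            assert len(events) == 1
            assert events[0].rupture_force == pytest.approx(force, abs=0.5)
            n_ok += 1
        assert n_ok >= 20

    def test_noisy_mean_absolute_error_below_two_piconewtons(self, control_config):
        cfg = replace(control_config, force_noise_sd=5.0)
        rng = np.random.default_rng(7)
        errs = []
        while len(errs) < 150:
            force = float(np.clip(simulate_rupture_forces(cfg, 1, rng)[0], 20, None))
            lc = float(rng.normal(35, 5))
            if lc < 15:
                continue
            try:
                curve = simulate_force_curve(cfg, [(force, lc)], rng)
            except ValueError:
                continue
            events = analyze_curve(curve, noise_sd=5.0, spring_constant=30.0)
            if len(events) == 1:
                errs.append(abs(events[0].rupture_force - force))
        assert np.mean(errs) < 2.0

    def test_detection_count_matches_truth_on_noiseless_multitether(self):
        cfg = SimulationConfig(seed=21, n_curves=60, force_noise_sd=0.0,
                               baseline_tilt=0.0,
                               specific_event_probability=1.2)
        curves, truth = simulate_experiment(cfg)
        for curve, ct in zip(curves, truth.curves):
            events = detect_ruptures(correct_baseline(curve), 0.0)
            # a second rupture needs its own >= 10-sample monotone rise, so
            # ruptures closer than ~13 samples (2.6 nm + drop span) merge
            zs = sorted(
                5.0 + wlc_extension(f, cfg.persistence_length, lc) + f / 30.0
                for f, lc in zip(ct.forces, ct.contour_lengths))
            resolvable = 1 + sum(b - a > 3.0 for a, b in zip(zs, zs[1:])) \
                if zs else 0
            assert resolvable <= len(events) <= max(len(zs), resolvable)
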