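"""Train analysis: tonic/phasic split, cumulative charge, biphasic fits,
RRP back-extrapolation, recovery kinetics."""

import warnings

import numpy as np
import pytest

from ipsckit import synthgen
from ipsckit.synthgen import (
    EventKinetics,
    preset,
    simulate_evoked,
    train_protocol,
)
from ipsckit.traces import SweepTrace
from ipsckit.trains import (
    PhaseFit,
    analyze_train,
    cumulative_series,
    fit_biphasic,
    per_pulse_phasic_charge,
    recovery_analysis,
    rrp_report,
    tonic_phasic_split,
)

#: kernel whose tail decays within the 10 ms inter-pulse window, so the
#: per-pulse windows capture each pulse's charge cleanly
SHORT_KIN = EventKinetics(0.25, 0.8, 1.0, 3.0)


def _train_stims(n=100, isi=10.0, t0=50.0):
    return t0 + np.arange(n) * isi


class TestTonicPhasicSplit:
    def test_fully_decaying_responses_leave_no_envelope(self):
        p = preset("sham").with_(tonic_fraction=0.0, noise_sd=0.0,
                                 kernel=SHORT_KIN)
        tr, truth = simulate_evoked(p, train_protocol(),
                                    engine="deterministic")
        phasic, env, tonic_q = tonic_phasic_split(tr)
        total = np.sum(per_pulse_phasic_charge(phasic)) + tonic_q
        peak_amp = np.max(-phasic.samples)
        assert tonic_q < 0.12 * total          # residual kernel tails only
        assert np.max(np.abs(env)) < 0.03 * peak_amp

    def test_dc_shift_captured_as_tonic(self):
        stims = _train_stims()
        n = int(round((stims[-1] + 100.0) / 0.1))
        s = np.zeros(n)
        i0, i1 = int(50.0 / 0.1), int(round((stims[-1] + 10.0) / 0.1))
        s[i0:i1] = -20.0
        tr = SweepTrace(samples=s, dt=0.1, stim_times=stims, protocol="train")
        phasic, _env, tonic_q = tonic_phasic_split(tr)
        # 20 pA over ~1 s of train = 20 pC, linear-ramp anchors lose the edges
        assert tonic_q == pytest.approx(20.0, rel=0.1)
        q = per_pulse_phasic_charge(phasic)
        assert np.sum(q) < 0.05 * tonic_q

    def test_tonic_fraction_recovered(self):
        p = preset("sham").with_(noise_sd=0.0, kernel=SHORT_KIN)
        tr, _ = simulate_evoked(p, train_protocol(), engine="deterministic")
        phasic, _env, tonic_q = tonic_phasic_split(tr)
        total = tonic_q + np.sum(per_pulse_phasic_charge(phasic))
        assert tonic_q / total == pytest.approx(p.tonic_fraction, rel=0.15)

    def test_close_stimulus_spacing_rejected(self):
        stims = 50.0 + np.arange(100) * 1.0  # 1 ms spacing
        n = int(round((stims[-1] + 100.0) / 0.1))
        tr = SweepTrace(samples=np.zeros(n), dt=0.1, stim_times=stims,
                        protocol="train")
        with pytest.raises(ValueError, match="spacing"):
            tonic_phasic_split(tr)


class TestPerPulseCharge:
    def test_charges_proportional_to_released_quanta(self):
        p = preset("sham").with_(tonic_fraction=0.0, noise_sd=0.0,
                                 kernel=SHORT_KIN)
        tr, truth = simulate_evoked(p, train_protocol(),
                                    engine="deterministic")
        phasic, _, _ = tonic_phasic_split(tr)
        q = per_pulse_phasic_charge(phasic)
        r = truth.released[:100]
        ratio = q / (r * p.q_charge)
        med = np.median(ratio[1:])
        assert np.all(np.abs(ratio[1:] / med - 1.0) < 0.05)
        assert ratio[0] == pytest.approx(med, rel=0.10)

    def test_zero_response_train_gives_zero_charges(self):
        stims = _train_stims()
        n = int(round((stims[-1] + 100.0) / 0.1))
        tr = SweepTrace(samples=np.zeros(n), dt=0.1, stim_times=stims,
                        protocol="train")
        phasic, _, _ = tonic_phasic_split(tr)
        np.testing.assert_allclose(per_pulse_phasic_charge(phasic), 0.0)

    def test_charges_sum_to_total_phasic_charge(self):
        p = preset("bbbd").with_(tonic_fraction=0.0, noise_sd=0.0,
                                 kernel=SHORT_KIN)
        tr, _ = simulate_evoked(p, train_protocol(), engine="deterministic")
        phasic, _, _ = tonic_phasic_split(tr)
        q = per_pulse_phasic_charge(phasic)
        stims = tr.stim_times
        total = -np.sum(np.minimum(
            phasic.samples[phasic.index_of(stims[0]):
                           phasic.index_of(stims[99] + 10.0)], 0.0)
        ) * phasic.dt / 1000.0
        assert np.sum(q) == pytest.approx(total, rel=0.02)

    def test_all_charges_nonnegative(self):
        p = preset("sham")
        tr, _ = simulate_evoked(p, train_protocol(), seed=3)
        phasic, _, _ = tonic_phasic_split(tr)
        assert np.all(per_pulse_phasic_charge(phasic) >= 0)


class TestCumulativeSeries:
    def test_equal_charges_give_integers(self):
        c = cumulative_series(np.full(10, 2.5))
        np.testing.assert_allclose(c, np.arange(1, 11))

    def test_geometric_charges_sum_to_inverse_p(self):
        q1, p_dep = 3.0, 0.5
        q = q1 * (1 - p_dep) ** np.arange(200)
        c = cumulative_series(q)
        assert c[0] == 1.0
        assert c[-1] == pytest.approx(1.0 / p_dep, rel=1e-3)

    def test_single_nonzero_pulse(self):
        c = cumulative_series(np.array([2.0, 0.0, 0.0, 0.0]))
        np.testing.assert_allclose(c, 1.0)

    def test_first_pulse_failure_excluded(self):
        with pytest.raises(ValueError, match="excluded"):
            cumulative_series(np.array([0.0, 1.0, 1.0]))

    def test_nondecreasing_for_stochastic_cells(self):
        p = preset("sham")
        for seed in range(5):
            tr, _ = simulate_evoked(p, train_protocol(), seed=seed)
            phasic, _, _ = tonic_phasic_split(tr)
            c = cumulative_series(per_pulse_phasic_charge(phasic))
            assert np.all(np.diff(c) >= 0)


class TestFitBiphasic:
    def test_perfectly_linear_series(self):
        stims = _train_stims()
        c = np.arange(1.0, 101.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            f1, f2 = fit_biphasic(c, stims)
        # C_k = k rises by one per pulse: extrapolating to pulse 1 leaves 1.0
        assert f1.slope == pytest.approx(f2.slope, rel=1e-9)
        assert f1.y_intercept == pytest.approx(1.0, abs=1e-9)
        assert f2.y_intercept == pytest.approx(1.0, abs=1e-9)
        assert "no_steep_phase" in f1.flags

    def test_deterministic_depletion_asymptote(self):
        # p=0.5, no replenishment: C_inf = 1/p = 2, late slope ~ 0
        p = preset("sham").with_(p_rel=0.5, facil_increment=0.0,
                                 replenish_rate=0.0, tonic_fraction=0.0,
                                 noise_sd=0.0, kernel=SHORT_KIN)
        tr, _ = simulate_evoked(p, train_protocol(), engine="deterministic")
        phasic, _, _ = tonic_phasic_split(tr)
        c = cumulative_series(per_pulse_phasic_charge(phasic))
        f1, f2 = fit_biphasic(c, tr.stim_times)
        assert f2.slope == pytest.approx(0.0, abs=0.01)
        assert f2.y_intercept == pytest.approx(2.0, rel=0.05)

    def test_auto_breakpoint_matches_exhaustive_search(self, rng):
        # independent re-implementation of the exhaustive two-segment search
        for _ in range(10):
            stims = _train_stims()
            t_s = (stims - stims[0]) / 1000.0
            brk = int(rng.integers(8, 40))
            c = np.concatenate([
                1.0 + 0.8 * np.arange(brk),
                1.0 + 0.8 * (brk - 1) + 0.1 * np.arange(1, 101 - brk)])
            c += rng.normal(0, 0.02, 100)
            c = np.maximum.accumulate(c)
            f1, f2 = fit_biphasic(c, stims, auto_breakpoint=True)

            def sse(first, last):
                idx = np.arange(first - 1, last)
                co = np.polyfit(t_s[idx], c[idx], 1)
                return float(np.sum((np.polyval(co, t_s[idx]) - c[idx]) ** 2))

            best_b = min(range(5, 51),
                         key=lambda b: sse(2, b) + sse(b + 1, 100))
            assert f1.pulse_range == (2, best_b)
            assert f2.pulse_range == (best_b + 1, 100)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_biphasic(np.arange(1.0, 51.0), _train_stims(50))

    def test_phase_fit_validation(self):
        with pytest.raises(ValueError):
            PhaseFit(pulse_range=(5, 5), slope=1.0, y_intercept=0.0,
                     r_squared=1.0)
        with pytest.raises(ValueError):
            PhaseFit(pulse_range=(2, 3), slope=1.0, y_intercept=0.0,
                     r_squared=1.0)


class TestOracleEquivalence:
    def test_pipeline_matches_count_level_analysis(self, rng):
        # trace-level pipeline vs the release-count recurrence, 20 random
        # parameter sets in the moderate-depletion regime
        for _ in range(20):
            p_rel = float(rng.uniform(0.2, 0.9))
            n_tight = int(rng.integers(200, 800))
            repl = float(rng.uniform(0.0, 0.15) * n_tight * 100.0 * p_rel)
            params = preset("sham").with_(
                p_rel=p_rel, n_tight=n_tight, n_max=n_tight,
                replenish_rate=repl, facil_increment=0.0,
                tonic_fraction=0.0, noise_sd=0.0, kernel=SHORT_KIN)
            tr, truth = simulate_evoked(params, train_protocol(),
                                        engine="deterministic")
            phasic, _, _ = tonic_phasic_split(tr)
            c = cumulative_series(per_pulse_phasic_charge(phasic))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                f1, f2 = fit_biphasic(c, tr.stim_times)
                c_ref = np.cumsum(truth.released[:100]) / truth.released[0]
                g1, g2 = fit_biphasic(c_ref, tr.stim_times)
            assert f2.y_intercept == pytest.approx(g2.y_intercept, rel=0.05)
            assert f2.slope == pytest.approx(g2.slope, rel=0.05, abs=0.02)

    def test_phase2_slope_estimates_replenishment(self):
        # steady-state release equals replenishment: slope ~ R*q/Q1 per second
        p = preset("sham").with_(p_rel=0.4, facil_increment=0.0,
                                 replenish_rate=2000.0, tonic_fraction=0.0,
                                 noise_sd=0.0, kernel=SHORT_KIN)
        tr, truth = simulate_evoked(p, train_protocol(),
                                    engine="deterministic")
        phasic, _, _ = tonic_phasic_split(tr)
        c = cumulative_series(per_pulse_phasic_charge(phasic))
        _f1, f2 = fit_biphasic(c, tr.stim_times)
        q1 = truth.released[0] * p.q_charge
        expected = p.replenish_rate * p.q_charge / q1
        assert f2.slope == pytest.approx(expected, rel=0.10)


class TestRrpReport:
    def test_full_release_on_first_pulse(self):
        p = preset("sham").with_(p_rel=1.0, facil_increment=0.0,
                                 replenish_rate=0.0, tonic_fraction=0.0,
                                 noise_sd=0.0, kernel=SHORT_KIN)
        tr, _ = simulate_evoked(p, train_protocol(), engine="deterministic")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = analyze_train(tr)
        assert res.phase2.y_intercept == pytest.approx(1.0, abs=0.05)

    def test_vesicle_conversion(self):
        f1 = PhaseFit((2, 10), slope=50.0, y_intercept=1.8, r_squared=0.99)
        f2 = PhaseFit((60, 100), slope=5.0, y_intercept=9.0, r_squared=0.99)
        rep = rrp_report(f1, f2, q1_charge=2.0, q_charge=0.1)
        assert rep.rrp_tight_vesicles == pytest.approx(1.8 * 20.0)
        assert rep.replenish_vesicles_s == pytest.approx(100.0)

    def test_flags_propagate(self):
        f1 = PhaseFit((2, 10), 1.0, 1.0, 0.9, flags=["no_steep_phase"])
        f2 = PhaseFit((60, 100), 1.0, 1.0, 0.9)
        assert rrp_report(f1, f2).flags == ["no_steep_phase"]


class TestRecovery:
    def test_full_recovery_everywhere(self):
        frac, tau = recovery_analysis(
            np.array([25.0, 100.0, 1000.0]), np.array([3.0, 3.0, 3.0]),
            q_first=3.0, q_steady=0.5)
        np.testing.assert_allclose(frac, 1.0)
        assert tau == 0.0

    def test_steady_state_gives_zero_fraction(self):
        frac, _tau = recovery_analysis(
            np.array([25.0, 100.0, 1000.0]), np.array([0.5, 0.5, 3.0]),
            q_first=3.0, q_steady=0.5)
        np.testing.assert_allclose(frac[:2], 0.0)

    def test_undefined_when_no_depression(self):
        with pytest.raises(ValueError):
            recovery_analysis(np.array([25.0, 50.0, 100.0]),
                              np.ones(3), q_first=1.0, q_steady=2.0)

    def test_simulated_recovery_tau_recovered(self):
        # facilitation off so recovery probes see pure pool refill
        p = preset("sham").with_(p_rel=0.4, facil_increment=0.0,
                                 tonic_fraction=0.0, noise_sd=0.0,
                                 replenish_rate=500.0, kernel=SHORT_KIN)
        taus = []
        for seed in range(8):
            tr, _ = simulate_evoked(p, train_protocol(), seed=seed)
            res = analyze_train(tr)
            if res.recovery_tau is not None:
                taus.append(res.recovery_tau)
        assert np.median(taus) == pytest.approx(p.recovery_tau, rel=0.20)


class TestParameterRecovery:
    def test_pool_size_doubling_detected(self):
        # cohorts at n_tight vs 2*n_tight: intercepts differ ~2x and the
        # group difference is statistically detectable
        from ipsckit.stats import compare_groups

        base = preset("sham").with_(facil_increment=0.0, p_rel=0.25,
                                    replenish_rate=500.0, tonic_fraction=0.0,
                                    kernel=SHORT_KIN)
        hits = 0
        n_rep = 10
        for rep in range(n_rep):
            med = {}
            groups = {}
            for label, n_t in (("small", 300), ("large", 600)):
                params = base.with_(n_tight=n_t, n_max=n_t)
                vals = []
                seeds = synthgen.cell_seeds(rep, 12,
                                            stream=hash(label) % 1000)
                for ss in seeds:
                    tr, truth = simulate_evoked(params, train_protocol(),
                                                seed=ss)
                    phasic, _, _ = tonic_phasic_split(tr)
                    q = per_pulse_phasic_charge(phasic)
                    # un-normalized cumulative charge carries the pool size
                    c = np.cumsum(q)
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        f1, _f2 = fit_biphasic(c / q[0], tr.stim_times)
                    vals.append(f1.y_intercept * q[0])
                med[label] = float(np.median(vals))
                groups[label] = np.asarray(vals)
            ratio = med["large"] / med["small"]
            comp = compare_groups("rrp", groups["small"], groups["large"])
            if abs(ratio - 2.0) <= 0.5 and comp.significant:
                hits += 1
        assert hits >= 0.8 * n_rep
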