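"""Idealization and kinetics: change points, pathway calls, dwell and
bound-fraction fits."""

import math

import numpy as np
import pytest

from vfret import (detect_changepoints, classify_folding,
                   fit_dwell_exponential, folding_fraction_curve,
                   binding_time, bound_fraction_kinetics,
                   PhotophysicsParams, simulate_cohort)
from vfret.presets import get_preset
from vfret.stepkin import (BindingTime, ChangePointSet, FoldingCall,
                           ONE_STEP, MULTI_STEP, NO_FOLD, PREFOLDED)
from vfret.traceproc import FretTrace
from vfret import traceproc, stepkin


def _trace(E, frame_s=0.1):
    E = np.asarray(E, float)
    t = np.arange(len(E)) * frame_s
    return FretTrace(molecule_id="m", time_s=t, E=E)


class TestDetectChangepoints:
    def test_noiseless_single_jump_found_exactly(self):
        E = np.concatenate([np.full(57, 0.5), np.full(60, 0.75)])
        cps = detect_changepoints(_trace(E))
        assert list(cps.breakpoints) == [57]
        assert cps.segment_means == pytest.approx([0.5, 0.75])

    def test_constant_series_has_no_breakpoints(self):
        cps = detect_changepoints(_trace(np.full(100, 0.6)))
        assert len(cps.breakpoints) == 0

    def test_noisy_jump_localized_within_two_frames_95pct(self):
        rng = np.random.default_rng(77)
        hits = 0
        for _ in range(200):
            E = np.concatenate([np.full(50, 0.5), np.full(50, 0.75)])
            E += rng.normal(0, 0.045, 100)
            cps = detect_changepoints(_trace(E))
            hits += any(abs(b - 50) <= 2 for b in cps.breakpoints)
        assert hits / 200 >= 0.95

    def test_deterministic_for_fixed_input(self):
        rng = np.random.default_rng(5)
        E = np.concatenate([np.full(40, 0.5), np.full(40, 0.8)])
        E += rng.normal(0, 0.04, 80)
        a = detect_changepoints(_trace(E))
        b = detect_changepoints(_trace(E))
        np.testing.assert_array_equal(a.breakpoints, b.breakpoints)

    def test_short_series_yields_empty_breakpoint_set(self):
        cps = detect_changepoints(_trace([0.5, 0.6, 0.7]),
                                  min_segment_frames=2)
        assert len(cps.breakpoints) == 0

    def test_min_segment_length_respected(self):
        rng = np.random.default_rng(3)
        E = rng.normal(0.5, 0.05, 200)
        cps = detect_changepoints(_trace(E), min_segment_frames=5)
        bounds = np.concatenate([[0], cps.breakpoints, [200]])
        assert np.diff(bounds).min() >= 5


class TestClassifyFolding:
    def test_noiseless_cohort_pathways_recovered_perfectly(
            self, g4_cohort_noiseless):
        p = g4_cohort_noiseless.preset
        gt = g4_cohort_noiseless.manifest.set_index("molecule_id")
        fts, _ = traceproc.process_cohort(g4_cohort_noiseless.traces,
                                          leakage=0.0)
        checked = 0
        for ft in fts:
            call = classify_folding(detect_changepoints(ft), p)
            g = gt.loc[ft.molecule_id]
            if not np.isfinite(g.fold_time_s):
                continue
            assert call.call == g.pathway
            checked += 1
        assert checked >= 50

    def test_noiseless_dwell_matches_generative_waiting_time(
            self, g4_cohort_noiseless):
        p = g4_cohort_noiseless.preset
        gt = g4_cohort_noiseless.manifest.set_index("molecule_id")
        fts, _ = traceproc.process_cohort(g4_cohort_noiseless.traces,
                                          leakage=0.0)
        errs = []
        for ft in fts:
            call = classify_folding(detect_changepoints(ft), p)
            g = gt.loc[ft.molecule_id]
            if call.call == ONE_STEP and np.isfinite(call.dwell_s):
                errs.append(call.dwell_s - g.ss_dwell_s)
        # frame quantization and excitation gaps bound the per-molecule
        # error; there is no systematic offset
        assert np.max(np.abs(errs)) < 1.3
        assert abs(np.mean(errs)) < 0.05

    def test_default_noise_pathway_agreement_over_90pct(self, g4_cohort):
        p = g4_cohort.preset
        gt = g4_cohort.manifest.set_index("molecule_id")
        fts, _ = traceproc.process_cohort(g4_cohort.traces)
        agree = tot = 0
        for ft in fts:
            call = classify_folding(detect_changepoints(ft), p)
            g = gt.loc[ft.molecule_id]
            if call.call in (ONE_STEP, MULTI_STEP) and \
                    np.isfinite(g.fold_time_s):
                tot += 1
                agree += call.call == g.pathway
        assert tot > 80
        assert agree / tot >= 0.90

    def test_prefolded_trace_called_prefolded(self, default_phys):
        coh = simulate_cohort(get_preset("pf-G4"), default_phys, n=5,
                              seed=2, duration_s=20.0)
        fts, _ = traceproc.process_cohort(coh.traces)
        for ft in fts:
            call = classify_folding(detect_changepoints(ft), coh.preset)
            assert call.call == PREFOLDED

    def test_bleach_before_folding_is_no_fold(self):
        p = get_preset("vf-G4")
        E = np.full(120, p.E_duplex)  # never leaves the duplex level
        call = classify_folding(detect_changepoints(_trace(E)), p)
        assert call.call == NO_FOLD


class TestDwellExponential:
    def test_inverse_cdf_grid_recovers_rate_exactly(self):
        q = (np.arange(1, 200) / 200.0)
        dwells = -0.41 * np.log(1 - q)  # exact exponential quantiles
        fit = fit_dwell_exponential(dwells)
        assert fit.rate == pytest.approx(1.0 / np.mean(dwells), rel=1e-12)

    def test_sampled_exponential_recovered_within_5pct(self):
        rng = np.random.default_rng(123)
        d = rng.exponential(0.41, 2000)
        fit = fit_dwell_exponential(d)
        assert fit.rate == pytest.approx(1 / 0.41, rel=0.05)

    def test_estimator_unbiased_across_seeds(self):
        # relative bias of the MLE under its own model, 20 seeds x n=2000
        rates = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            rates.append(fit_dwell_exponential(
                rng.exponential(0.41, 2000)).rate)
        assert np.mean(rates) == pytest.approx(1 / 0.41, rel=0.02)

    def test_binned_fit_agrees_with_mle(self):
        rng = np.random.default_rng(7)
        d = rng.exponential(0.5, 4000)
        mle = fit_dwell_exponential(d)
        binned = fit_dwell_exponential(d, method="binned")
        assert binned.rate == pytest.approx(mle.rate, rel=0.15)

    def test_degenerate_and_undersized_inputs_rejected(self):
        with pytest.raises(ValueError):
            fit_dwell_exponential(np.full(50, 0.3))
        with pytest.raises(ValueError):
            fit_dwell_exponential([0.1] * 5 + [0.2])


class TestFoldingFractionCurve:
    def test_exact_exponential_curve_recovers_rate(self):
        # calls folding exactly on an exponential schedule
        rng = np.random.default_rng(11)
        t = rng.exponential(1 / 0.039, 4000)
        calls = [FoldingCall("m%d" % i, 1, ONE_STEP, t_fold_s=10.0 + ti)
                 for i, ti in enumerate(t)]
        fit = folding_fraction_curve(calls, n_total=4000, t_arrival=10.0,
                                     t_grid=np.arange(0, 300, 0.2))
        assert fit.rate == pytest.approx(0.039, rel=0.05)
        assert fit.amplitude == pytest.approx(1.0, abs=0.02)

    def test_rate_matches_first_passage_oracle_composition(self):
        # oracle: direct first-passage draws (24-step release at 1 nt/s
        # then the folding wait); the cohort-level curve fit must agree
        # with the same fit on oracle samples within 10%
        rng = np.random.default_rng(4)
        T = rng.gamma(24, 1.0, 3000) + rng.exponential(0.41, 3000)
        calls = [FoldingCall("m%d" % i, 1, ONE_STEP, t_fold_s=ti)
                 for i, ti in enumerate(T)]
        fit = folding_fraction_curve(calls, n_total=3000, t_arrival=0.0,
                                     t_grid=np.arange(0, 300, 0.2))
        oracle = folding_fraction_curve(
            [FoldingCall("o%d" % i, 1, ONE_STEP, t_fold_s=ti)
             for i, ti in enumerate(rng.gamma(24, 1.0, 3000) +
                                    rng.exponential(0.41, 3000))],
            n_total=3000, t_arrival=0.0, t_grid=np.arange(0, 300, 0.2))
        assert fit.rate == pytest.approx(oracle.rate, rel=0.10)

    def test_requires_enough_folded_molecules(self):
        calls = [FoldingCall("m", 1, ONE_STEP, t_fold_s=5.0)] * 5
        with pytest.raises(ValueError):
            folding_fraction_curve(calls, n_total=5, t_arrival=0.0)


def _cps_from_levels(spans, frame_s=0.1):
    """Build a ChangePointSet from (n_frames, level) spans."""
    E = np.concatenate([np.full(n, lvl) for n, lvl in spans])
    return detect_changepoints(_trace(E, frame_s))


class TestBindingTime:
    def test_direct_read_of_irreversible_decline(self):
        cps = _cps_from_levels([(200, 0.58), (300, 0.70), (300, 0.30)])
        call = FoldingCall("m", 1, ONE_STEP, t_fold_s=20.0)
        bt = binding_time(cps, call)
        assert bt.event
        assert bt.duration_s == pytest.approx(30.0, abs=0.2)

    def test_transient_dip_is_censored(self):
        cps = _cps_from_levels([(100, 0.58), (200, 0.70), (50, 0.30),
                                (250, 0.70)])
        call = FoldingCall("m", 1, ONE_STEP, t_fold_s=10.0)
        bt = binding_time(cps, call)
        assert not bt.event
        assert bt.duration_s == pytest.approx(60.0 - 10.0, abs=0.2)

    def test_requires_a_folded_call(self):
        cps = _cps_from_levels([(100, 0.5)])
        with pytest.raises(ValueError):
            binding_time(cps, FoldingCall("m", 0, NO_FOLD))


class TestBoundFractionKinetics:
    def test_generative_round_trip_recovers_amplitude_and_rate(self):
        # A = 1.0, k = 0.02/s, independent censoring at ~Exp(1/200)
        rng = np.random.default_rng(21)
        times = []
        for i in range(600):
            bind = rng.exponential(1 / 0.02)
            censor = min(rng.exponential(200.0), 400.0)
            if bind < censor:
                times.append(BindingTime("m%d" % i, bind, True))
            else:
                times.append(BindingTime("m%d" % i, censor, False))
        fit = bound_fraction_kinetics(times)
        assert fit.amplitude == pytest.approx(1.0, rel=0.10)
        assert fit.rate == pytest.approx(0.02, rel=0.10)

    def test_inaccessible_population_caps_the_amplitude(self):
        rng = np.random.default_rng(22)
        times = []
        for i in range(600):
            if rng.random() < 0.3:  # accessible fraction 0.3
                times.append(BindingTime("m%d" % i,
                                         rng.exponential(20.0), True))
            else:
                times.append(BindingTime("m%d" % i, 300.0, False))
        fit = bound_fraction_kinetics(times)
        assert fit.amplitude == pytest.approx(0.3, abs=0.05)

    def test_all_censored_reports_zero_amplitude(self):
        times = [BindingTime("m%d" % i, 100.0, False) for i in range(20)]
        fit = bound_fraction_kinetics(times)
        assert fit.amplitude == 0.0
        assert not fit.plateau_reached

    def test_requires_enough_molecules(self):
        with pytest.raises(ValueError):
            bound_fraction_kinetics([BindingTime("m", 1.0, True)] * 5)


def test_binding_censoring_respects_irreversibility(g4_cohort):
    """No accepted capture event may be followed by a supra-band segment."""
    p = get_preset("vf-G4-C2")
    phys = PhotophysicsParams()
    coh = simulate_cohort(p, phys, n=60, seed=6, duration_s=120.0)
    fts, _ = traceproc.process_cohort(coh.traces)
    for ft in fts:
        cps = detect_changepoints(ft)
        call = classify_folding(cps, p)
        if call.call == NO_FOLD:
            continue
        bt = binding_time(cps, call)
        if bt.event:
            t_bind = call.t_fold_s + bt.duration_s
            segs = [s for s in cps.segments() if s[0] > t_bind + 0.2]
            assert all(m < stepkin.BOUND_THRESHOLD for _, _, m in segs)
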