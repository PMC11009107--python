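"""Event detection: segmentation, baseline, extraction, features, fits."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cupore._pelt import brute_force_segmentation, pelt_gaussian
from cupore.params import DEFAULT_PARAMS
from cupore.signals import (
    DENSITY_GRID,
    BaselineEstimate,
    CurrentTrace,
    characterize_dwell,
    compute_density_features,
    detect_change_points,
    detect_events,
    estimate_baseline,
    extract_events,
    fit_blockade_distribution,
    polish_trace,
)
from cupore.simulate import TraceConfig, simulate_blank, simulate_trace

S = DEFAULT_PARAMS["S"]


def _trace(samples, rate=2000.0):
    return CurrentTrace(samples=np.asarray(samples, float), sampling_rate=rate)


class TestChangePoints:
    def test_constant_series_has_no_change_points(self):
        cps = detect_change_points(_trace(np.full(500, 100.0)))
        assert len(cps) == 0

    def test_noiseless_step_found_exactly(self):
        x = np.r_[np.full(300, 1.0), np.full(300, 5.0)]
        cps = detect_change_points(_trace(x))
        assert list(cps) == [300]

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_search_oracle(self, seed):
        # noisy 3-segment series <= 200 samples; oracle enumerates every
        # segmentation with <= 2 breaks under the identical cost
        rng = np.random.default_rng(seed)
        x = np.concatenate(
            [
                rng.normal(100.0, 1.0, 70),
                rng.normal(88.0, 1.0, 40),
                rng.normal(100.0, 1.0, 90),
            ]
        )
        penalty = 5.0 * np.log(x.size)
        got = list(pelt_gaussian(x, penalty, min_size=5))
        expected, _ = brute_force_segmentation(x, penalty, max_breaks=2, min_size=5)
        assert got == expected
        assert abs(got[0] - 70) <= 2 and abs(got[1] - 110) <= 2

    def test_variance_only_change_detected(self):
        rng = np.random.default_rng(0)
        x = np.r_[rng.normal(100, 0.5, 200), rng.normal(100, 5.0, 200)]
        cps = detect_change_points(_trace(x))
        assert len(cps) >= 1 and abs(cps[0] - 200) <= 5

    def test_chunked_detection_covers_long_trace(self):
        rng = np.random.default_rng(1)
        x = rng.normal(100, 1.0, 5000)
        x[2400:2600] -= 15
        cps = detect_change_points(_trace(x), chunk_size=1000)
        # event boundaries present despite chunking
        assert any(abs(c - 2400) <= 3 for c in cps)
        assert any(abs(c - 2600) <= 3 for c in cps)


class TestPolish:
    def test_no_change_points_gives_global_mean(self):
        tr = _trace([1.0, 2.0, 3.0, 4.0])
        seg = polish_trace(tr, [])
        assert np.allclose(seg.polished(), 2.5)

    def test_two_segments_polished_to_their_means(self):
        tr = _trace([1.0, 1.0, 3.0, 3.0])
        seg = polish_trace(tr, [2])
        assert np.allclose(seg.polished(), [1, 1, 3, 3])

    def test_invalid_change_points_rejected(self):
        tr = _trace([1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            polish_trace(tr, [0])
        with pytest.raises(ValueError):
            polish_trace(tr, [2, 2])

    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.floats(min_value=-100, max_value=100), min_size=4, max_size=40),
           st.integers(min_value=1, max_value=38))
    def test_polished_mean_conserves_raw_mean(self, vals, k):
        if k >= len(vals):
            k = len(vals) - 1
        tr = _trace(vals)
        seg = polish_trace(tr, [k])
        assert np.mean(seg.polished()) == pytest.approx(np.mean(vals), abs=1e-9)


class TestBaseline:
    def test_dominant_level_is_baseline(self):
        x = np.r_[np.full(900, 100.0), np.full(100, 80.0)]
        seg = polish_trace(_trace(x), [900])
        assert estimate_baseline(seg).I0 == pytest.approx(100.0)

    def test_blank_trace_baseline_is_global_mode(self):
        cfg = TraceConfig.fast(duration=20.0, seed=0)
        trace, _ = simulate_blank(cfg, artifact_rate=0.0)
        seg = polish_trace(trace, detect_change_points(trace))
        assert estimate_baseline(seg).I0 == pytest.approx(100.0, rel=0.01)

    def test_simulated_baseline_recovered_within_one_percent(self):
        cfg = TraceConfig.fast(duration=30.0, seed=4, baseline_current=150.0,
                               copper_excursion_level=165.0)
        trace, _ = simulate_trace([(S, 300.0)], cfg)
        seg = polish_trace(trace, detect_change_points(trace))
        assert estimate_baseline(seg).I0 == pytest.approx(150.0, rel=0.01)

    def test_unstable_baseline_raises(self):
        # many equally weighted distinct levels: no cluster reaches 20%
        means = np.repeat(np.linspace(50, 150, 20), 10)
        tr = _trace(means + np.random.default_rng(0).normal(0, 0.01, means.size))
        seg = polish_trace(tr, list(range(10, 200, 10)))
        with pytest.raises(ValueError, match="stable baseline"):
            estimate_baseline(seg)


class TestExtractEvents:
    def test_blank_trace_yields_no_events(self):
        cfg = TraceConfig.fast(duration=20.0, seed=1)
        trace, _ = simulate_blank(cfg, artifact_rate=0.0)
        events, _, _ = detect_events(trace, with_features=False)
        assert events == []

    def test_blockade_arithmetic_of_single_event(self):
        x = np.full(1000, 100.0)
        x[400:500] = 86.8  # blockade 0.132
        events, baseline, _ = detect_events(_trace(x), with_features=False)
        assert len(events) == 1
        ev = events[0]
        assert ev.mean_level == pytest.approx(86.8, abs=1e-9)
        assert ev.blockade == pytest.approx(0.132, abs=1e-9)
        assert (ev.start, ev.end) == (400, 500)

    def test_detector_completeness_on_clean_trace(self):
        # noiseless, no excursions, no state-2; sampled fast enough that the
        # minimum-dwell cut dominates the segmenter's minimum segment, so
        # every loggable event >= min_dwell is recovered with exact blockade
        cfg = TraceConfig(sampling_rate=20000.0, duration=20.0, noise_sd=0.0,
                          copper_occupancy=1.0, state2_prob=0.0, seed=9)
        trace, log = simulate_trace([(S, 300.0)], cfg)
        events, baseline, _ = detect_events(trace, with_features=False)
        detectable = log[log["dwell_ms"] >= 0.5]
        assert len(events) == len(detectable)
        inj = 1.0 - detectable["level_pA"].to_numpy() / cfg.baseline_current
        got = np.sort([e.blockade for e in events])
        assert np.allclose(np.sort(inj), got, atol=1e-6)

    def test_event_count_monotone_in_blockade_threshold(self):
        cfg = TraceConfig.fast(duration=60.0, seed=2)
        trace, _ = simulate_trace([(S, 300.0)], cfg)
        seg = polish_trace(trace, detect_change_points(trace))
        base = estimate_baseline(seg)
        counts = [
            len(extract_events(seg, base, min_blockade=mb))
            for mb in (0.05, 0.1, 0.12, 0.2)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_state2_events_flagged_as_multilevel(self):
        # long-dwell class so the inner sub-level spans enough samples for
        # its change points to be resolved at the reduced sampling rate
        cfg = TraceConfig.fast(duration=120.0, seed=6, state2_prob=1.0)
        trace, log = simulate_trace([(DEFAULT_PARAMS["His1"], 500.0)], cfg)
        events, _, _ = detect_events(trace, with_features=False)
        long_events = [e for e in events if e.dwell_ms > 40]
        assert long_events
        frac_multi = np.mean([e.n_sublevels > 1 for e in long_events])
        assert frac_multi > 0.8


class TestDensityFeatures:
    def _event_from(self, samples, rate=2000.0):
        # generous flanking baseline so the level mode is unambiguous
        pad = np.full(4 * len(samples), 100.0)
        tr = _trace(np.r_[pad, samples, pad], rate)
        events, baseline, _ = detect_events(tr, with_features=False)
        assert len(events) == 1
        return events[0], tr, baseline

    def test_point_mass_peaks_at_nearest_grid_point(self):
        ev, tr, base = self._event_from(np.full(40, 86.8))
        dens = compute_density_features(ev, tr, base)
        assert dens.shape == (1000,)
        assert DENSITY_GRID[np.argmax(dens)] == pytest.approx(0.868, abs=0.001)
        assert dens[np.abs(DENSITY_GRID - 0.868) > 0.01].max() < 1e-6 * dens.max()

    def test_density_integrates_to_unit_mass(self):
        rng = np.random.default_rng(0)
        ev, tr, base = self._event_from(rng.normal(86.8, 1.0, 200))
        dens = compute_density_features(ev, tr, base)
        assert np.sum(dens) * 0.001 == pytest.approx(1.0, abs=0.02)

    def test_two_level_event_gives_bimodal_density(self):
        samples = np.r_[np.full(60, 85.0), np.full(60, 70.0)]
        ev, tr, base = self._event_from(samples)
        dens = compute_density_features(ev, tr, base)
        i1 = np.argmin(np.abs(DENSITY_GRID - 0.85))
        i2 = np.argmin(np.abs(DENSITY_GRID - 0.70))
        mid = (i1 + i2) // 2
        # modes at the two levels, clear trough between them
        assert min(abs(np.argmax(dens) - i1), abs(np.argmax(dens) - i2)) <= 5
        assert dens[i1] > 5 * dens[mid]
        assert dens[i2] > 5 * dens[mid]

    def test_corrupt_event_rejected(self):
        ev, tr, base = self._event_from(np.full(40, 86.8))
        tr.samples[ev.start] = 200.0  # standardized sample 2.0 > 1.5
        with pytest.raises(ValueError, match="corrupt"):
            compute_density_features(ev, tr, base)

    def test_features_invariant_to_current_gain(self):
        # doubling the gain doubles I0 and all samples: standardized
        # amplitudes, hence features, are unchanged
        rng = np.random.default_rng(3)
        samples = rng.normal(86.8, 1.0, 100)
        ev, tr, base = self._event_from(samples)
        d1 = compute_density_features(ev, tr, base)
        tr2 = _trace(tr.samples * 2.0)
        base2 = BaselineEstimate(
            I0=base.I0 * 2, window_I0=base.window_I0 * 2,
            window_s=base.window_s, coverage=base.coverage,
        )
        d2 = compute_density_features(ev, tr2, base2)
        assert np.allclose(d1, d2, rtol=1e-9)


class TestDwellFit:
    def test_degenerate_sample_raises(self):
        with pytest.raises(ValueError, match="degenerate"):
            characterize_dwell(np.full(100, 5.0))

    def test_exponential_halflife_recovered(self):
        rng = np.random.default_rng(0)
        draws = rng.exponential(5.0 / np.log(2), 5000)
        hl, se = characterize_dwell(draws)
        assert abs(hl - 5.0) < 3 * se

    def test_too_few_events_rejected(self):
        with pytest.raises(ValueError):
            characterize_dwell(np.arange(10.0) + 1)


class TestBlockadeFit:
    def test_point_mass_returns_value_and_zero_sd(self):
        mu, sd, se, diag = fit_blockade_distribution(np.full(100, 0.132))
        assert (mu, sd, se) == (pytest.approx(0.132), 0.0, 0.0)

    def test_gaussian_parameters_recovered(self):
        rng = np.random.default_rng(1)
        draws = rng.normal(0.171, 0.0026, 5000)
        mu, sd, se, _ = fit_blockade_distribution(draws)
        assert abs(mu - 0.171) < 3 * max(se, 1e-5)
        assert sd == pytest.approx(0.0026, rel=0.15)
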