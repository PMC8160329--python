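"""Calcium events, vessel response classification, shuffled null, NVC index."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oxyflow import nvc
from oxyflow.traces import DiameterTrace, FluorescenceTrace


def _trace(values, rate=10.0):
    return FluorescenceTrace(values=np.asarray(values, dtype=float),
                             frame_rate=rate)


def _transient_trace(event_times, amps, rate=10.0, duration=60.0, noise=1.0,
                     f0=100.0, tau=0.4, seed=0):
    rng = np.random.default_rng(seed)
    t = np.arange(int(duration * rate)) / rate
    f = np.full(t.size, f0)
    for te, a in zip(event_times, amps):
        on = t >= te
        f[on] += f0 * a * np.exp(-(t[on] - te) / tau)
    return _trace(f + rng.normal(0, noise, t.size), rate)


class TestNormalization:
    def test_global_minmax(self):
        out = nvc.normalize_global(_trace([0.0, 5.0, 10.0]))
        assert np.allclose(out.values, [0.0, 0.5, 1.0])
        assert out.normalization == "global"

    def test_global_affine_invariance(self):
        a = nvc.normalize_global(_trace([1.0, 3.0, 2.0, 5.0]))
        b = nvc.normalize_global(_trace([10.0, 30.0, 20.0, 50.0]))
        assert np.allclose(a.values, b.values)

    def test_global_constant_raises(self):
        with pytest.raises(ValueError):
            nvc.normalize_global(_trace([2.0, 2.0, 2.0]))

    def test_baseline_positive(self):
        out = nvc.normalize_baseline(np.array([2.0, 4.0]), np.array([2.0, 2.0]))
        assert out[1] == pytest.approx(1.0)

    def test_baseline_negative_uses_abs(self):
        out = nvc.normalize_baseline(np.array([-1.0]), np.array([-2.0, -2.0]))
        assert out[0] == pytest.approx(0.5)

    def test_baseline_zero_raises(self):
        with pytest.raises(ValueError):
            nvc.normalize_baseline(np.array([1.0]), np.array([1e-15]))


class TestEventDetection:
    def test_single_transient_recovered(self):
        tr = _transient_trace([30.0], [1.0], noise=1.0, seed=0)
        events = nvc.detect_calcium_events(tr)
        assert len(events) == 1
        assert events[0].peak_time == pytest.approx(30.0, abs=0.1)  # ±1 frame
        assert events[0].peak_dff == pytest.approx(1.0, abs=0.1)

    def test_two_transients_two_seconds_apart(self):
        tr = _transient_trace([20.0, 22.0], [1.0, 0.8], noise=0.5, seed=1)
        events = nvc.detect_calcium_events(tr)
        times = sorted(e.peak_time for e in events)
        assert len(times) == 2
        assert times[0] == pytest.approx(20.0, abs=0.1)
        assert times[1] == pytest.approx(22.0, abs=0.1)

    def test_edge_events_dropped(self):
        tr = _transient_trace([2.0, 30.0], [1.0, 1.0], noise=0.2, seed=2)
        events = nvc.detect_calcium_events(tr)
        assert all(e.peak_time == pytest.approx(30.0, abs=0.1) for e in events)

    def test_count_invariant_under_affine_rescaling(self):
        tr = _transient_trace([15.0, 40.0], [1.2, 0.9], noise=0.8, seed=3)
        scaled = _trace(5.0 * tr.values + 30.0, tr.frame_rate)
        n0 = len(nvc.detect_calcium_events(tr))
        n1 = len(nvc.detect_calcium_events(scaled))
        assert n0 == n1 == 2

    def test_short_recording_raises(self):
        with pytest.raises(ValueError):
            nvc.detect_calcium_events(_trace(np.random.default_rng(0).normal(size=50)))


class TestClassifyResponse:
    def test_flat_not_responsive(self):
        d = np.ones(150)
        d[0] += 1e-6  # avoid zero baseline SD degeneracy
        rec = nvc.classify_response(d, 10.0)
        assert not rec.responsive

    def test_step_with_latency(self):
        d = np.ones(150) + np.random.default_rng(0).normal(0, 0.01, 150)
        d[70:82] += 0.1  # +2 s, lasting 1.2 s, ≫1 SD
        rec = nvc.classify_response(d, 10.0)
        assert rec.responsive
        assert rec.latency == pytest.approx(2.0, abs=0.15)

    def test_short_blip_rejected(self):
        d = np.ones(150) + np.random.default_rng(1).normal(0, 0.01, 150)
        d[70:74] += 0.1  # 0.4 s < 0.5 s duration rule
        rec = nvc.classify_response(d, 10.0)
        assert not rec.responsive

    def test_missing_samples_invalidate(self):
        d = np.ones(150)
        d[::3] = np.nan
        rec = nvc.classify_response(d, 10.0)
        assert not rec.valid

    def test_false_positive_rate_matches_monte_carlo(self):
        """The 1-SD/0.5-s rule's chance rate on white noise, against a
        brute-force reimplementation of the same rule."""
        rate, n_pre, n_resp = 10.0, 50, 50
        min_run = int(np.floor(0.5 * rate)) + 1
        rng = np.random.default_rng(7)
        n_trials = 2000
        hits_impl = 0
        hits_oracle = 0
        for _ in range(n_trials):
            d = rng.normal(0.0, 1.0, 151)
            if nvc.classify_response(d, rate).responsive:
                hits_impl += 1
            # independent oracle: run-length scan
            base = d[:n_pre]
            thr = base.mean() + base.std()
            above = d[n_pre + 1:n_pre + 1 + n_resp] > thr
            runs = np.diff(np.flatnonzero(np.diff(np.r_[0, above, 0])).reshape(-1, 2),
                           axis=1) if above.any() else np.empty((0, 1))
            if runs.size and runs.max() >= min_run:
                hits_oracle += 1
        p = hits_oracle / n_trials
        ci = 1.96 * np.sqrt(p * (1 - p) / n_trials)
        assert abs(hits_impl / n_trials - p) <= ci + 1e-9


class TestShuffledNull:
    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(0)
        d = DiameterTrace(values=5 + rng.normal(0, 0.1, 1200), rate=10.0)
        r1 = nvc.shuffled_null(d, [20.0, 50.0, 80.0], n_iter=20, seed=3)
        r2 = nvc.shuffled_null(d, [20.0, 50.0, 80.0], n_iter=20, seed=3)
        assert r1 == r2

    def test_white_noise_rate_within_monte_carlo_ci(self):
        """Shuffling white noise gives the rule's analytic chance rate."""
        rng = np.random.default_rng(1)
        d = DiameterTrace(values=5 + rng.normal(0, 0.1, 2400), rate=10.0)
        rate = nvc.shuffled_null(d, [30.0, 90.0, 150.0, 210.0], n_iter=100, seed=5)
        # Monte-Carlo oracle of the same rule on iid windows
        mc_rng = np.random.default_rng(2)
        hits = 0
        trials = 3000
        min_run = int(np.floor(0.5 * 10.0)) + 1
        for _ in range(trials):
            w = mc_rng.normal(0, 1, 151)
            base = w[:50]
            above = w[51:101] > base.mean() + base.std()
            runs = np.diff(np.flatnonzero(np.diff(np.r_[0, above, 0])).reshape(-1, 2),
                           axis=1) if above.any() else np.empty((0, 1))
            hits += bool(runs.size and runs.max() >= min_run)
        p = hits / trials
        ci = 1.96 * np.sqrt(p * (1 - p) / 400) + 1.96 * np.sqrt(p * (1 - p) / trials)
        assert abs(rate - p) <= ci

    def test_locked_responses_exceed_shuffled(self):
        rng = np.random.default_rng(3)
        rate = 10.0
        n = 2400
        d = 5 + rng.normal(0, 0.05, n)
        events = [30.0, 90.0, 150.0, 210.0]
        for te in events:
            i = int(te * rate)
            d[i + 10:i + 30] += 0.5  # reliable dilation 1-3 s post event
        trace = DiameterTrace(values=d, rate=rate)
        aligned = np.mean([
            nvc.classify_response(
                d[int(te * rate) - 50:int(te * rate) + 101], rate).responsive
            for te in events])
        shuffled = nvc.shuffled_null(trace, events, n_iter=50, seed=0)
        assert aligned == 1.0
        assert shuffled < 0.5 * aligned


class TestIndexAndCorrelation:
    def test_index_arithmetic(self):
        assert nvc.nvc_index(0.05, 0.5) == pytest.approx(0.1)

    def test_index_scale_free(self):
        assert nvc.nvc_index(0.05, 0.5) == pytest.approx(nvc.nvc_index(0.5, 5.0))

    def test_index_halves_with_doubled_calcium(self):
        assert nvc.nvc_index(0.05, 1.0) == pytest.approx(0.5 * nvc.nvc_index(0.05, 0.5))

    def test_index_rejects_nonpositive_calcium(self):
        with pytest.raises(ValueError):
            nvc.nvc_index(0.05, 0.0)

    def test_cohort_median_recovers_gain(self):
        rng = np.random.default_rng(4)
        g = 0.2
        ca = rng.uniform(0.5, 2.0, 200)
        dil = g * ca * rng.normal(1.0, 0.05, 200)
        idx = [nvc.nvc_index(d, c) for d, c in zip(dil, ca)]
        assert np.median(idx) == pytest.approx(g, rel=0.05)

    def test_self_correlation_unity(self, rng):
        x = rng.normal(size=(3, 500))
        r, _ = nvc.roi_pairwise_correlation(x)
        assert np.allclose(np.diag(r), 1.0)
        assert np.allclose(r, r.T, equal_nan=True)

    def test_independent_noise_mean_near_zero(self, rng):
        x = rng.normal(size=(6, 2000))
        _, mean_off = nvc.roi_pairwise_correlation(x)
        assert abs(mean_off) < 2 / np.sqrt(2000) * 3

    def test_shared_signal_fraction_recovered(self, rng):
        t_len = 4000
        common = rng.normal(size=t_len)
        rho = 0.5
        x = np.stack([np.sqrt(rho) * common + np.sqrt(1 - rho) * rng.normal(size=t_len)
                      for _ in range(5)])
        _, mean_off = nvc.roi_pairwise_correlation(x)
        assert mean_off == pytest.approx(rho, abs=0.06)

    def test_constant_trace_excluded(self, rng):
        x = rng.normal(size=(3, 300))
        x[1] = 2.0
        r, mean_off = nvc.roi_pairwise_correlation(x)
        assert np.isnan(r[1, 0]) and np.isnan(r[0, 1])
        assert np.isfinite(mean_off)


class TestHolmBonferroni:
    def test_two_pvalues(self):
        assert np.allclose(nvc.holm_bonferroni([0.01, 0.04]), [0.02, 0.04])

    def test_single_unchanged(self):
        assert nvc.holm_bonferroni([0.3])[0] == pytest.approx(0.3)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            nvc.holm_bonferroni([0.1, 1.2])

    def test_against_step_down_oracle(self, rng):
        """Brute-force step-down procedure on 1000 random p-vectors."""
        for _ in range(1000):
            m = int(rng.integers(1, 9))
            p = rng.uniform(0, 1, m)
            adj = nvc.holm_bonferroni(p)
            order = np.argsort(p, kind="stable")
            expect = np.empty(m)
            running = 0.0
            for rank, i in enumerate(order):
                running = max(running, (m - rank) * p[i])
                expect[i] = min(running, 1.0)
            assert np.allclose(adj, expect)

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=12))
    @settings(max_examples=50, deadline=None)
    def test_properties(self, pvals):
        adj = nvc.holm_bonferroni(pvals)
        assert np.all(adj >= np.asarray(pvals) - 1e-12)
        assert np.all((adj >= 0) & (adj <= 1))
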