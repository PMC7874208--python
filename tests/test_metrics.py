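"""Rolling median, difference signal, cycle segmentation and per-cycle metrics."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from vsrkit import (
    Cycle,
    cycle_metrics,
    difference_signal,
    flag_startles,
    rolling_median,
    segment_cycles,
)
from vsrkit.errors import DegenerateCycleError, SegmentationError
from vsrkit.metrics import analyze_trace

from conftest import make_trace


def brute_rolling_median(a, window):
    """Sort-based windowed median with symmetrically shrinking edges."""
    n = len(a)
    out = np.empty(n)
    for i in range(n):
        k = min(window // 2, i, n - 1 - i)
        w = sorted(a[i - k : i + k + 1])
        out[i] = (w[len(w) // 2] + w[(len(w) - 1) // 2]) / 2
    return out


def brute_cycle_metrics(diff, valid, threshold):
    """Per-frame reimplementation of the metric set (no vector shortcuts)."""
    vals = [d for d, v in zip(diff, valid) if v]
    mx = max(vals)
    integral = sum(vals) / len(vals)
    pct = 100.0 * sum(1 for d in vals if d > threshold) / len(vals)
    return mx, integral, pct, mx > threshold


class TestRollingMedian:
    def test_constant_series_unchanged(self):
        np.testing.assert_array_equal(rolling_median(np.full(20, 3.5)), np.full(20, 3.5))

    def test_single_outlier_rejected(self):
        out = rolling_median(np.array([0.0, 0.0, 10.0, 0.0, 0.0]), 5)
        assert out[2] == 0.0

    @given(st.integers(0, 2**31 - 1), st.sampled_from([1, 3, 5, 9]))
    def test_matches_brute_force_oracle(self, seed, window):
        a = np.random.default_rng(seed).normal(size=200)
        np.testing.assert_array_equal(
            rolling_median(a, window), brute_rolling_median(a, window)
        )

    @pytest.mark.parametrize("window", [0, 2, 4, -3])
    def test_even_or_nonpositive_window_rejected(self, window):
        with pytest.raises(ValueError):
            rolling_median(np.zeros(10), window)

    def test_window_longer_than_series_rejected(self):
        with pytest.raises(ValueError):
            rolling_median(np.zeros(3), 5)


class TestDifferenceSignal:
    def test_constant_series_gives_zeros(self):
        np.testing.assert_array_equal(difference_signal(np.full(30, 7.0)), np.zeros(30))

    def test_single_spike_passes_through(self):
        a = np.zeros(31)
        a[15] = 12.0
        d = difference_signal(a, 5)
        assert d[15] == 12.0

    def test_slow_sinusoid_mostly_removed(self):
        """A sway period much longer than the window leaves only the
        per-window curvature residual, bounded well below the 5° threshold."""
        t = np.arange(1280) / 30.0
        a = 5.0 * np.sin(2 * np.pi * 0.53 * t)
        d = difference_signal(a, 5)
        # curvature bound: |a''| * (window/2 / fps)^2 / 2
        bound = 5.0 * (2 * np.pi * 0.53) ** 2 * (2 / 30.0) ** 2 / 2
        assert d.max() <= bound + 1e-9

    def test_invalid_frames_carry_zero(self):
        a = np.full(20, 9.0)
        a[4] = 40.0
        valid = np.ones(20, dtype=bool)
        valid[4] = False
        assert difference_signal(a, 5, valid)[4] == 0.0


class TestSegmentCycles:
    def test_standard_recording_retains_21_cycles(self):
        trace = make_trace(np.zeros(1280), black_every=56)
        cycles = segment_cycles(trace)
        retained = [c for c in cycles if not c.excluded]
        assert len(retained) == 21
        assert len(cycles) == 23  # 22 complete + 1 partial
        assert cycles[0].exclusion_reason == "first"
        assert cycles[-1].exclusion_reason == "last_or_partial"
        assert cycles[-1].n_frames() == 1280 - 1232

    def test_two_black_frames_give_one_excluded_cycle(self):
        trace = make_trace(np.zeros(11), black_every=10)  # blacks at 0 and 10
        cycles = segment_cycles(trace)
        assert len(cycles) == 1
        assert cycles[0].exclusion_reason == "first"

    def test_five_equal_cycles_retain_middle_three(self):
        trace = make_trace(np.zeros(51), black_every=10)
        cycles = segment_cycles(trace)
        retained = [c.index for c in cycles if not c.excluded]
        assert retained == [1, 2, 3]

    def test_fewer_than_two_black_frames_is_error(self):
        with pytest.raises(SegmentationError):
            segment_cycles(make_trace(np.zeros(100)))

    def test_retained_spans_tile_without_overlap(self, wt_trace):
        cycles = segment_cycles(wt_trace)
        for a, b in zip(cycles, cycles[1:]):
            assert a.end == b.start

    def test_multi_epoch_exclusion_is_per_epoch(self):
        from vsrkit import EpochSpan

        epochs = [EpochSpan(0, 51, 0.0, 5.0), EpochSpan(51, 102, 51 / 30 + 5.0, 0.0)]
        angles = np.zeros(102)
        blacks = np.concatenate([np.arange(0, 51, 10), 51 + np.arange(0, 51, 10)])
        valid = np.ones(102, dtype=bool)
        valid[blacks] = False
        from vsrkit import TailTrace

        trace = TailTrace(angles, 30.0, blacks, valid, epochs=epochs)
        cycles = segment_cycles(trace)
        by_epoch = {}
        for c in cycles:
            by_epoch.setdefault(c.epoch, []).append(c)
        for e, cs in by_epoch.items():
            assert cs[0].exclusion_reason == "first"
            assert cs[-1].exclusion_reason == "last_or_partial"
            assert sum(not c.excluded for c in cs) == 3


class TestStartleExclusion:
    def _trace_with_cycle_values(self, peak):
        a = np.zeros(51)
        a[25] = peak  # inside cycle 2 (frames 20-29)
        return make_trace(a, black_every=10)

    def test_cycle_above_45_excluded(self):
        trace = self._trace_with_cycle_values(50.0)
        cycles = flag_startles(trace, segment_cycles(trace))
        assert [c.exclusion_reason for c in cycles if c.index == 2] == ["startle"]

    def test_cycle_just_below_45_retained(self):
        trace = self._trace_with_cycle_values(44.9)
        cycles = flag_startles(trace, segment_cycles(trace))
        assert not [c for c in cycles if c.exclusion_reason == "startle"]

    def test_single_injected_startle_excludes_exactly_one_cycle(self, protocol):
        from vsrkit import phenotype_preset, simulate_trace

        # one startle among the cycles: rate chosen so exactly one fires
        for seed in range(50):
            params = phenotype_preset("wild_type", startle_rate=0.04, seed=seed)
            trace = simulate_trace(params, protocol)
            cycles = flag_startles(trace, segment_cycles(trace))
            n_startle = sum(c.exclusion_reason == "startle" for c in cycles)
            truth = np.max(np.abs(difference_signal(trace.angles, 5, trace.valid)))
            if n_startle == 1:
                assert truth > 45.0
                return
        pytest.fail("no seed produced exactly one startle cycle")


class TestCycleMetrics:
    def test_partial_activity_arithmetic(self):
        """8° on 14 of 56 frames: pct 25, normalized integral 2, max 8."""
        a = np.zeros(57)
        idx = np.arange(1, 15) * 4 - 2  # isolated spikes, median untouched
        a[idx] = 8.0
        trace = make_trace(a, black_every=56)
        cyc = Cycle(index=0, start=0, end=56)
        m = cycle_metrics(trace, cyc, threshold=5.0)
        # black frame 0 is invalid: 55 valid frames, all 14 spikes inside
        assert m.max_tail_angle == pytest.approx(8.0)
        assert m.normalized_integral == pytest.approx(8.0 * 14 / 55)
        assert m.pct_above_threshold == pytest.approx(100.0 * 14 / 55)
        assert m.active

    def test_zero_difference_is_inactive(self):
        trace = make_trace(np.zeros(31), black_every=30)
        m = cycle_metrics(trace, Cycle(index=0, start=0, end=30))
        assert (m.max_tail_angle, m.normalized_integral, m.pct_above_threshold) == (
            0.0,
            0.0,
            0.0,
        )
        assert not m.active

    def test_cycle_without_valid_frames_is_degenerate(self):
        trace = make_trace(np.zeros(31), black_every=30)
        trace.valid[:] = False
        with pytest.raises(DegenerateCycleError):
            cycle_metrics(trace, Cycle(index=0, start=0, end=30))

    def test_exact_threshold_counts_as_not_above(self):
        a = np.zeros(31)
        a[15] = 5.0
        trace = make_trace(a, black_every=30)
        m = cycle_metrics(trace, Cycle(index=0, start=0, end=30), threshold=5.0)
        assert m.pct_above_threshold == 0.0
        assert not m.active

    @given(st.integers(0, 2**31 - 1))
    def test_full_metric_vector_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        trace = make_trace(rng.normal(0, 8, size=200), black_every=25)
        diff = difference_signal(trace.angles, 5, trace.valid)
        for cyc in segment_cycles(trace):
            m = cycle_metrics(trace, cyc)
            mx, integral, pct, active = brute_cycle_metrics(
                diff[cyc.start : cyc.end], trace.valid[cyc.start : cyc.end], 5.0
            )
            assert m.max_tail_angle == mx
            # np.sum (pairwise) vs Python sum differ by summation order only
            np.testing.assert_allclose(m.normalized_integral, integral, rtol=1e-13)
            assert m.pct_above_threshold == pct
            assert m.active == active

    def test_pct_above_threshold_non_increasing_in_threshold(self, wt_trace):
        cycles = segment_cycles(wt_trace)
        cyc = next(c for c in cycles if not c.excluded)
        pcts = [
            cycle_metrics(wt_trace, cyc, threshold=th).pct_above_threshold
            for th in (0.0, 2.0, 5.0, 10.0, 20.0)
        ]
        assert pcts == sorted(pcts, reverse=True)

    def test_metric_ordering_invariant(self, wt_trace):
        """0 ≤ normalized integral ≤ max ≤ 45 after startle exclusion."""
        table = analyze_trace(wt_trace)
        kept = table[~table["excluded"]]
        assert (kept["normalized_integral_deg"] >= 0).all()
        assert (
            kept["normalized_integral_deg"] <= kept["max_tail_angle_deg"] + 1e-12
        ).all()
        assert (kept["max_tail_angle_deg"] <= 45.0).all()
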