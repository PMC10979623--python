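"""Training-control heuristics vs brute-force oracles on fixture traces."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ganbalance.heuristics import (LossTrace, instability_score, select_epoch,
                                   select_lr1, select_lr2, speed_score,
                                   truncate_trace)
from ganbalance.simulate import make_loss_trace_fixture


def _trace(values, epochs=None):
    values = np.asarray(values, dtype=float)
    if epochs is None:
        epochs = np.arange(len(values))
    return LossTrace(epochs, values)


def _brute_force_apexes(values):
    """All local extrema by direct neighbour comparison (plateaus collapsed),
    endpoints included."""
    vals = [values[0]]
    for v in values[1:]:
        if v != vals[-1]:
            vals.append(v)
    if len(vals) < 3:
        return vals
    out = [vals[0]]
    for i in range(1, len(vals) - 1):
        if (vals[i] - vals[i - 1]) * (vals[i + 1] - vals[i]) < 0:
            out.append(vals[i])
    out.append(vals[-1])
    return out


class TestTruncate:
    def test_truncates_before_first_violation(self):
        t = truncate_trace(_trace([1, 2, 16, 3]), 15, -10)
        np.testing.assert_array_equal(t.critic_loss, [1, 2])

    def test_in_bounds_trace_unchanged(self):
        t = _trace([1, -2, 14.9, -9.9])
        out = truncate_trace(t, 15, -10)
        np.testing.assert_array_equal(out.critic_loss, t.critic_loss)

    def test_violation_at_index_zero_empties_trace(self):
        assert len(truncate_trace(_trace([-11, 0, 1]), 15, -10)) == 0

    def test_lower_bound_also_truncates(self):
        t = truncate_trace(_trace([1, -12, 3]), 15, -10)
        np.testing.assert_array_equal(t.critic_loss, [1])


class TestInstability:
    def test_constant_trace_scores_zero(self):
        assert instability_score(_trace([2.0] * 50)) == 0.0

    def test_sawtooth_scores_its_peak_to_peak(self):
        saw = make_loss_trace_fixture("sawtooth", 40, {"amplitude": 1.0})
        assert instability_score(saw) == pytest.approx(2.0)

    def test_single_bump_then_flat(self):
        assert instability_score(_trace([0, 5, 0, 0, 0, 0])) == pytest.approx(5.0)

    @given(st.integers(0, 2 ** 31 - 1), st.integers(2, 60), st.integers(1, 60))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_matches_brute_force_oracle(self, seed, n, top_k):
        rng = np.random.default_rng(seed)
        values = rng.integers(-5, 6, size=n).astype(float)  # ties likely
        apexes = _brute_force_apexes(values)
        diffs = sorted((abs(a - b) for a, b in zip(apexes, apexes[1:])),
                       reverse=True)
        expected = float(np.mean(diffs[:top_k])) if len(diffs) else 0.0
        assert instability_score(_trace(values), top_k) == pytest.approx(expected)


class TestSpeed:
    def test_constant_trace_scores_zero(self):
        t = _trace([3.0] * 101, epochs=np.arange(101) * 20)
        assert speed_score(t, window=500) == 0.0

    def test_linear_decay_closed_form(self):
        epochs = np.arange(0, 5000, 20)
        values = 10.0 * (1 - epochs / 5000.0)
        got = speed_score(LossTrace(epochs, values), window=500)
        first = values[epochs < 500].mean()
        last = values[epochs > epochs[-1] - 500].mean()
        assert got == pytest.approx(first - last)
        assert got == pytest.approx(9.0, abs=0.1)

    def test_increasing_trace_is_negative(self):
        epochs = np.arange(0, 2000, 20)
        assert speed_score(LossTrace(epochs, epochs / 100.0), window=500) < 0

    def test_overlapping_windows_error(self):
        t = _trace([1.0, 2.0, 3.0], epochs=[0, 20, 40])
        with pytest.raises(ValueError):
            speed_score(t, window=500)


class TestSelectLr1:
    def test_smallest_loss_above_floor_wins(self):
        traces = {1e-4: _trace([10, 5, 2]), 5e-4: _trace([10, 3.2, 1]),
                  1e-3: _trace([9, 4, 2])}
        assert select_lr1(traces, floor=3.0) == 5e-4

    def test_single_candidate(self):
        assert select_lr1({1e-4: _trace([5, 4])}) == 1e-4

    def test_all_below_floor_falls_back_to_smallest_final_loss(self):
        traces = {1e-4: _trace([2, 1.5]), 5e-4: _trace([2, 0.5])}
        with pytest.warns(UserWarning, match="falling back"):
            assert select_lr1(traces, floor=3.0) == 5e-4

    def test_empty_mapping_rejected(self):
        with pytest.raises(ValueError):
            select_lr1({})


class TestSelectLr2:
    def test_arithmetic_on_fixture_scores(self):
        # candidate A: gentle oscillation (instability ~1) riding a strong
        # decline (speed ~7) -> objective well below zero; candidate B: pure
        # sawtooth (instability 3, speed 0) -> objective 9.  A must win.
        epochs = np.arange(0, 2000, 20)
        drift = 10.0 - 9.0 * epochs / epochs[-1]
        saw = 0.5 * np.where(np.arange(len(epochs)) % 2 == 0, 1.0, -1.0)
        a = LossTrace(epochs, drift + saw)
        b = make_loss_trace_fixture("sawtooth", len(epochs),
                                    {"amplitude": 1.5, "baseline": 5.0},
                                    rate_save=20)
        ia, sa = instability_score(a), speed_score(a, 500)
        ib, sb = instability_score(b), speed_score(b, 500)
        assert ia == pytest.approx(1.0, abs=0.2)
        assert ib == pytest.approx(3.0)
        assert 3 * ia - sa < 3 * ib - sb
        assert select_lr2({1e-4: a, 5e-5: b}, window=500) == 1e-4

    def test_tie_prefers_smaller_lr(self):
        t = _trace([5.0] * 100, epochs=np.arange(100) * 20)
        assert select_lr2({1e-4: t, 5e-5: t.slice(slice(None))}, window=500) == 5e-5

    def test_candidates_truncated_before_scoring(self):
        # diverging candidate is cut to a flat prefix (objective 0); the
        # noisy-but-in-bounds candidate scores worse
        div = _trace([1.0] * 30 + [20.0] * 70, epochs=np.arange(100) * 20)
        noisy = make_loss_trace_fixture("sawtooth", 100, {"amplitude": 4.0},
                                        rate_save=20)
        assert select_lr2({1e-5: noisy, 1e-4: div}, window=200) == 1e-4

    def test_all_empty_after_truncation_rejected(self):
        bad = _trace([99.0, 100.0])
        with pytest.raises(ValueError):
            select_lr2({1e-4: bad})


class TestSelectEpoch:
    def test_knee_of_noiseless_decay_matches_chord_scan(self):
        trace = make_loss_trace_fixture("decay", 250,
                                        {"a": 10, "b": 0.01, "c": 1},
                                        rate_save=20)
        # brute-force maximum chord deviation on the same (normalised) curve
        x = trace.epochs / trace.epochs.max()
        y = (trace.critic_loss - trace.critic_loss.min()) / np.ptp(trace.critic_loss)
        chord = y[0] + (y[-1] - y[0]) * x
        expected_epoch = trace.epochs[np.argmax(np.abs(y - chord))]
        assert select_epoch(trace) == expected_epoch

    def test_linear_trace_falls_back_to_minimum_loss_epoch(self):
        epochs = np.arange(0, 1000, 20)
        trace = LossTrace(epochs, 10.0 - epochs / 100.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            assert select_epoch(trace) == epochs[-1]

    def test_small_noise_barely_moves_the_knee(self):
        clean = make_loss_trace_fixture("decay", 250,
                                        {"a": 10, "b": 0.01, "c": 1},
                                        rate_save=20)
        noisy = make_loss_trace_fixture("decay", 250,
                                        {"a": 10, "b": 0.01, "c": 1,
                                         "noise_sd": 0.05},
                                        seed=3, rate_save=20)
        assert abs(select_epoch(noisy) - select_epoch(clean)) <= 20

    def test_too_short_trace_rejected(self):
        with pytest.raises(ValueError):
            select_epoch(_trace([1.0, 2.0, 3.0]))


class TestTraceFixtures:
    def test_constant(self):
        t = make_loss_trace_fixture("constant", 100, {"value": 2.0})
        assert (t.critic_loss == 2.0).all() and len(t) == 100

    def test_diverging_crossing_epoch(self):
        t = make_loss_trace_fixture("diverging", 100,
                                    {"bound": 15.0, "crossing_epoch": 40})
        assert int(np.argmax(t.critic_loss > 15.0)) == 40

    def test_decay_endpoints(self):
        t = make_loss_trace_fixture("decay", 2000, {"a": 10, "b": 0.01, "c": 1})
        assert t.critic_loss[0] == pytest.approx(11.0)
        assert t.critic_loss[-1] == pytest.approx(1.0, abs=1e-6)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            make_loss_trace_fixture("wiggle", 10)
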