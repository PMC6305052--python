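"""QC accounting, repair and smoothing, checked against independent
brute-force reference implementations."""

import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st

from ctgkit.preprocess import (
    CleanSignal,
    QCConfig,
    QCReport,
    RejectReason,
    interpolate_gaps,
    qc_filter,
    run_pipeline,
    scan_missing,
    sg_smooth,
    stabilize_spikes,
)
from ctgkit.simulate import FHRRecord


# ---------------------------------------------------------------- oracles
def oracle_interpolate(values):
    """Literal per-gap linear interpolation with edge extension."""
    v = [float(x) for x in values]
    n = len(v)
    anchors = [i for i in range(n) if v[i] != 0]
    if not anchors:
        raise ValueError("all zero")
    out = []
    for i in range(n):
        if v[i] != 0:
            out.append(v[i])
            continue
        left = max((a for a in anchors if a < i), default=None)
        right = min((a for a in anchors if a > i), default=None)
        if left is None:
            out.append(v[right])
        elif right is None:
            out.append(v[left])
        else:
            frac = (i - left) / (right - left)
            out.append(v[left] + frac * (v[right] - v[left]))
    return out


def oracle_stabilize(values, jump=25.0, window=5, diff=10.0):
    """Segment-scan spike repair, written as plain nested loops."""
    v = [float(x) for x in values]
    n = len(v)
    while True:
        changed = False
        i = 0
        while i < n - 1:
            if abs(v[i + 1] - v[i]) > jump:
                stable = None
                for cand in range(i + 1, n - window):
                    if all(
                        abs(v[t + 1] - v[t]) < diff
                        for t in range(cand, cand + window)
                    ):
                        stable = cand
                        break
                if stable is None:
                    for t in range(i + 1, n):
                        if abs(v[t] - v[i]) > 1e-12:
                            changed = True
                        v[t] = v[i]
                    i = n
                elif stable > i + 1:
                    for t in range(i + 1, stable):
                        new = v[i] + (v[stable] - v[i]) * (t - i) / (stable - i)
                        if abs(v[t] - new) > 1e-12:
                            changed = True
                        v[t] = new
                    i = stable
                else:
                    i = stable
            else:
                i += 1
        if not changed:
            return v


ALPHABET = (100.0, 140.0, 180.0, 0.0)


def _alphabet_traces(max_exhaustive=7, sampled_lengths=(8, 10, 12), n_sampled=1500):
    for length in range(1, max_exhaustive + 1):
        yield from itertools.product(ALPHABET, repeat=length)
    rng = np.random.default_rng(2024)
    for length in sampled_lengths:
        for _ in range(n_sampled // len(sampled_lengths)):
            yield tuple(rng.choice(ALPHABET, size=length))


class TestScanMissingAndQC:
    def test_clean_record_not_rejected(self):
        rec = FHRRecord("a", np.full(2400, 140.0), 0)
        rep = scan_missing(rec, QCConfig())
        assert rep.total_missing_points == 0 and not rep.rejected

    def test_thirty_second_gap_arithmetic(self):
        v = np.full(2400, 140.0)
        v[10:70] = 0  # 60 points = 30 s at 2 Hz
        rep = scan_missing(FHRRecord("a", v, 0), QCConfig())
        assert rep.longest_gap_s == 30.0
        assert rep.total_missing_s == 30.0

    def test_isolated_zeros_run_length_one(self):
        v = np.full(2400, 140.0)
        v[[3, 100, 500, 900, 1500]] = 0
        rep = scan_missing(FHRRecord("a", v, 0), QCConfig())
        assert rep.longest_gap_points == 1
        assert rep.total_missing_points == 5

    @pytest.mark.parametrize(
        "total_s,gap_s,rejected,reason",
        [
            (9.0, 5.0, False, RejectReason.NONE),
            (10.0, 10.0, False, RejectReason.NONE),  # strict ">"
            (10.5, 5.0, True, RejectReason.TOTAL_MISSING),
            (9.5, 30.5, True, RejectReason.LONG_GAP),  # scattered cfg
        ],
    )
    def test_qc_threshold_conventions(self, total_s, gap_s, rejected, reason):
        cfg = QCConfig(max_total_missing_s=10.0, max_gap_s=30.0)
        rep = QCReport("x", int(total_s * 2), total_s, int(gap_s * 2), gap_s,
                       False, RejectReason.NONE)
        got_rejected, got_reason = qc_filter(rep, cfg)
        assert got_rejected == rejected and got_reason == reason

    def test_total_missing_rule_checked_first(self):
        rep = QCReport("x", 80, 40.0, 70, 35.0, False, RejectReason.NONE)
        assert qc_filter(rep, QCConfig()) == (True, RejectReason.TOTAL_MISSING)


class TestInterpolateGaps:
    def test_interior_gap_closed_form(self):
        assert np.allclose(
            interpolate_gaps([140, 0, 0, 146]), [140, 142, 144, 146]
        )

    def test_edge_extension(self):
        assert np.allclose(
            interpolate_gaps([0, 0, 150, 150]), [150, 150, 150, 150]
        )

    def test_no_zeros_identity(self):
        v = np.array([120.0, 125.0, 130.0])
        assert np.array_equal(interpolate_gaps(v), v)

    def test_all_zero_errors(self):
        with pytest.raises(ValueError):
            interpolate_gaps(np.zeros(5))

    @given(
        st.lists(st.sampled_from([0.0, 110.0, 140.0, 170.0]), min_size=2,
                 max_size=40)
    )
    def test_output_gap_free_and_preserves_anchors(self, values):
        v = np.array(values)
        if not np.any(v != 0):
            return
        out = interpolate_gaps(v)
        assert not np.any(out == 0)
        nz = v != 0
        assert np.array_equal(out[nz], v[nz])


class TestStabilizeSpikes:
    def test_single_spike_on_flat_trace_removed(self):
        v = np.full(10, 140.0)
        v[4] = 190.0
        assert np.allclose(stabilize_spikes(v, QCConfig()), 140.0)

    def test_subthreshold_ramp_unchanged(self):
        v = 140.0 + np.concatenate([np.arange(0, 20, 2.0), np.full(20, 20.0)])
        assert np.array_equal(stabilize_spikes(v, QCConfig()), v)

    def test_idempotent(self, rng):
        v = np.full(120, 140.0)
        v[rng.integers(5, 115, size=4)] += 40.0
        cfg = QCConfig()
        once = stabilize_spikes(v, cfg)
        assert np.allclose(stabilize_spikes(once, cfg), once)

    def test_requires_gap_free_input(self):
        with pytest.raises(ValueError):
            stabilize_spikes(np.array([140.0, 0.0, 140.0]), QCConfig())


class TestOracleEquivalence:
    """Brute-force reference equivalence over short 4-letter-alphabet traces
    (exhaustive to length 7, seeded random samples at lengths 8-12)."""

    def test_interpolate_and_stabilize_match_oracles(self):
        cfg = QCConfig()
        for trace in _alphabet_traces():
            arr = np.array(trace)
            if not np.any(arr != 0):
                continue
            got = interpolate_gaps(arr)
            assert np.allclose(got, oracle_interpolate(trace)), trace
            stab = stabilize_spikes(got, cfg)
            assert np.allclose(stab, oracle_stabilize(got)), trace


class TestSmoothing:
    def test_reproduces_cubic_polynomial(self):
        x = np.linspace(0, 1, 200)
        v = 140 + 5 * x - 3 * x**2 + 2 * x**3
        out = sg_smooth(v, QCConfig())
        assert np.allclose(out, v, atol=1e-8)

    def test_constant_preserved(self):
        assert np.allclose(sg_smooth(np.full(100, 140.0), QCConfig()), 140.0)

    def test_jitter_attenuated(self, rng):
        v = np.full(200, 140.0)
        v[100] += 1.0
        out = sg_smooth(v, QCConfig())
        assert np.abs(out - 140.0).max() < 1.0

    def test_bad_window_rejected(self):
        with pytest.raises(ValueError):
            QCConfig(sg_window=14)
        with pytest.raises(ValueError):
            QCConfig(sg_window=3, sg_order=3)


class TestRunPipeline:
    def test_clean_flat_record_roundtrip(self, flat_trace):
        out = run_pipeline(FHRRecord("a", flat_trace, 0), QCConfig())
        assert isinstance(out, CleanSignal)
        assert np.allclose(out.values, 140.0, atol=1e-6)
        assert len(out.values) == 2400
        steps = [name for name, _ in out.provenance]
        assert steps == ["scan_missing", "interpolate_gaps",
                         "stabilize_spikes", "sg_smooth"]

    def test_long_gap_record_rejected(self):
        v = np.full(2400, 140.0)
        v[100:161] = 0  # 61 points = 30.5 s
        out = run_pipeline(FHRRecord("a", v, 0), QCConfig())
        assert isinstance(out, QCReport) and out.rejected

    def test_nine_second_missing_retained(self):
        v = np.full(2400, 140.0)
        v[100:118] = 0  # 18 points = 9 s
        out = run_pipeline(FHRRecord("a", v, 0), QCConfig())
        assert isinstance(out, CleanSignal)

    def test_gap_plus_spike_repaired(self):
        v = np.full(2400, 140.0)
        v[200:210] = 0
        v[1000] = 180.0
        out = run_pipeline(FHRRecord("a", v, 0), QCConfig())
        assert isinstance(out, CleanSignal)
        assert not np.any(out.values == 0)
        assert np.abs(np.diff(out.values)).max() <= 25.0
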