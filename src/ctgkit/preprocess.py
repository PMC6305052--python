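"""Four-stage FHR preprocessing.

1. Missing-value accounting: zeros (signal dropouts) are counted; records
   whose total dropout exceeds 10 s are rejected.
2. Breakpoint detection: records with a consecutive dropout run exceeding
   30 s are rejected (the gap may hide an acceleration or deceleration).
3. Linear-interpolation repair of the remaining gaps.
4. Spike stabilization: whenever neighboring samples differ by more than
   25 bpm, the unstable stretch up to the next stable point (five
   consecutive successive differences each below 10 bpm) is replaced by a
   straight line; then Savitzky–Golay smoothing removes residual
   single-sample jitter while preserving the curve trend.

Both rejection thresholds use strict comparisons ("exceeding"), so a record
with exactly 10 s total missing or exactly a 30 s gap is retained.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence, Union

import numpy as np
from scipy.signal import savgol_filter

from ctgkit.simulate import FHRRecord


class RejectReason(str, Enum):
    NONE = "none"
    TOTAL_MISSING = "total_missing"
    LONG_GAP = "long_gap"


@dataclass
class QCConfig:
    """Quality-control and repair parameters.

    ``stable_window`` successive differences each below ``stable_diff_bpm``
    define a "stable point" for spike repair; ``sg_window`` (samples, odd)
    and ``sg_order`` parametrize the Savitzky–Golay smoother.
    """

    max_total_missing_s: float = 10.0
    max_gap_s: float = 30.0
    spike_jump_bpm: float = 25.0
    stable_window: int = 5
    stable_diff_bpm: float = 10.0
    sg_window: int = 15
    sg_order: int = 3

    def __post_init__(self) -> None:
        if self.sg_window % 2 == 0 or self.sg_window <= self.sg_order:
            raise ValueError("sg_window must be odd and > sg_order")
        for name in ("max_total_missing_s", "max_gap_s", "spike_jump_bpm",
                     "stable_diff_bpm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.stable_window < 1:
            raise ValueError("stable_window must be >= 1")


@dataclass
class QCReport:
    record_id: str
    total_missing_points: int
    total_missing_s: float
    longest_gap_points: int
    longest_gap_s: float
    rejected: bool
    reject_reason: RejectReason


@dataclass
class CleanSignal:
    """Repaired, smoothed trace: no zeros, same length as the source."""

    values: np.ndarray
    provenance: list = field(default_factory=list)
    source_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values == 0):
            raise ValueError("clean signal must not contain zeros")
        if np.any((self.values <= 0) | (self.values >= 300)):
            raise ValueError("clean values must lie in (0, 300) bpm")


def _zero_runs(values: np.ndarray) -> list[tuple[int, int]]:
    runs = []
    i, n = 0, len(values)
    while i < n:
        if values[i] == 0:
            j = i
            while j < n and values[j] == 0:
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    return runs


def scan_missing(record: FHRRecord, cfg: QCConfig) -> QCReport:
    """Count zero-coded dropouts and the longest consecutive run."""
    v = np.asarray(record.values, dtype=float)
    if len(v) < 1:
        raise ValueError("empty record")
    dt = record.sample_interval
    runs = _zero_runs(v)
    total = int(sum(b - a for a, b in runs))
    longest = int(max((b - a for a, b in runs), default=0))
    report = QCReport(
        record_id=record.record_id,
        total_missing_points=total,
        total_missing_s=total * dt,
        longest_gap_points=longest,
        longest_gap_s=longest * dt,
        rejected=False,
        reject_reason=RejectReason.NONE,
    )
    report.rejected, report.reject_reason = qc_filter(report, cfg)
    return report


def qc_filter(report: QCReport, cfg: QCConfig) -> tuple[bool, RejectReason]:
    """Reject iff total missing > 10 s or longest gap > 30 s (strict).

    The total-missing rule is evaluated first; its reason wins when both
    fire.
    """
    if report.total_missing_s > cfg.max_total_missing_s:
        return True, RejectReason.TOTAL_MISSING
    if report.longest_gap_s > cfg.max_gap_s:
        return True, RejectReason.LONG_GAP
    return False, RejectReason.NONE


def interpolate_gaps(values: Sequence[float]) -> np.ndarray:
    """Replace zero runs by the straight line between the nearest nonzero
    neighbors; leading/trailing runs get constant extension."""
    v = np.asarray(values, dtype=float)
    anchors = np.flatnonzero(v != 0)
    if len(anchors) == 0:
        raise ValueError("all-zero trace: nothing to anchor interpolation")
    if len(anchors) == len(v):
        return v.copy()
    return np.interp(np.arange(len(v)), anchors, v[anchors])


def _find_stable(v: np.ndarray, start: int, window: int, diff_bpm: float):
    """First index j >= start whose next `window` successive differences are
    each < diff_bpm; None when the window no longer fits."""
    n = len(v)
    for j in range(start, n - window):
        seg = np.abs(np.diff(v[j : j + window + 1]))
        if np.all(seg < diff_bpm):
            return j
    return None


def stabilize_spikes(values: Sequence[float], cfg: QCConfig) -> np.ndarray:
    """Replace spike-contaminated stretches by linear interpolation.

    Scanning left to right, a jump of more than ``spike_jump_bpm`` between
    v[i] and v[i+1] opens an unstable segment; it closes at the first stable
    point j (``stable_window`` successive differences each below
    ``stable_diff_bpm``).  Samples strictly between i and j are replaced by
    the line from v[i] to v[j].  With no stable point before the end of the
    trace, v[i] is extended to the end.  Scanning repeats until a pass makes
    no change; a jump directly onto a stable point (j == i+1) has no
    interior samples and is kept as a genuine level shift.
    """
    v = np.asarray(values, dtype=float).copy()
    if np.any(v == 0):
        raise ValueError("stabilize_spikes requires a gap-free trace")
    n = len(v)
    for _ in range(n):  # fixpoint; each pass either changes v or stops
        changed = False
        i = 0
        while i < n - 1:
            if abs(v[i + 1] - v[i]) > cfg.spike_jump_bpm:
                j = _find_stable(v, i + 1, cfg.stable_window, cfg.stable_diff_bpm)
                if j is None:
                    if np.any(v[i + 1 :] != v[i]):
                        v[i + 1 :] = v[i]
                        changed = True
                    i = n
                elif j > i + 1:
                    repl = np.linspace(v[i], v[j], j - i + 1)[1:-1]
                    if np.any(v[i + 1 : j] != repl):
                        v[i + 1 : j] = repl
                        changed = True
                    i = j
                else:
                    i = j  # immediate stability: irreducible step
            else:
                i += 1
        if not changed:
            break
    return v


def sg_smooth(values: Sequence[float], cfg: QCConfig) -> np.ndarray:
    """Savitzky–Golay smoothing (order ``sg_order``, window ``sg_window``);
    boundaries use a polynomial fit on the truncated window."""
    v = np.asarray(values, dtype=float)
    if len(v) < cfg.sg_window:
        raise ValueError("trace shorter than the smoothing window")
    return savgol_filter(v, cfg.sg_window, cfg.sg_order, mode="interp")


def run_pipeline(
    record: FHRRecord, cfg: QCConfig | None = None
) -> Union[CleanSignal, QCReport]:
    """scan_missing -> qc_filter -> interpolate_gaps -> stabilize_spikes ->
    sg_smooth.  Rejected records return their QCReport instead."""
    cfg = cfg or QCConfig()
    report = scan_missing(record, cfg)
    if report.rejected:
        return report

    provenance = [("scan_missing", {"total_missing_s": report.total_missing_s,
                                    "longest_gap_s": report.longest_gap_s})]
    v = interpolate_gaps(record.values)
    provenance.append(("interpolate_gaps", {}))
    v = stabilize_spikes(v, cfg)
    provenance.append(("stabilize_spikes", {"spike_jump_bpm": cfg.spike_jump_bpm,
                                            "stable_window": cfg.stable_window,
                                            "stable_diff_bpm": cfg.stable_diff_bpm}))
    pre_smooth_max_step = float(np.max(np.abs(np.diff(v)))) if len(v) > 1 else 0.0
    v = sg_smooth(v, cfg)
    provenance.append(("sg_smooth", {"window": cfg.sg_window, "order": cfg.sg_order}))

    # smoothing must not create jumps beyond what stabilization left behind
    if len(v) > 1:
        post = float(np.max(np.abs(np.diff(v))))
        assert post <= max(pre_smooth_max_step, cfg.spike_jump_bpm) + 1e-6

    v = np.clip(v, 1.0, 299.0)
    return CleanSignal(values=v, provenance=provenance, source_id=record.record_id)
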