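"""Analysis-window selection from a total (gold standard) recording.

From each 240-300 s recording the pipeline analyses six windows: the total
recording itself (the gold standard), a 30 s and a 120 s window anchored at
the start, and three randomly placed, pairwise non-overlapping 10 s windows
(labelled in start-time order). The averaged 10 s measure (Avg10s) is formed
later, at the metrics stage.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import List

import numpy as np

from .series import NNSeries

LABEL_10S = ("10s_1", "10s_2", "10s_3")
LABEL_AVG10S = "Avg10s"
LABEL_30S = "30s"
LABEL_120S = "120s"
LABEL_TOTAL = "total"

#: Segment labels in analysis order (Avg10s is derived, not extracted).
SEGMENT_LABELS = (*LABEL_10S, LABEL_30S, LABEL_120S, LABEL_TOTAL)
#: Labels compared against the gold standard.
SHORT_LABELS = (*LABEL_10S, LABEL_AVG10S, LABEL_30S, LABEL_120S)
#: All labels of a complete per-subject table.
ALL_LABELS = (*LABEL_10S, LABEL_AVG10S, LABEL_30S, LABEL_120S, LABEL_TOTAL)

#: Accepted total-recording duration range in seconds (observed cohort range).
MIN_TOTAL_DURATION = 239.0
MAX_TOTAL_DURATION = 302.0


@dataclass(frozen=True)
class SegmentSpec:
    """One analysis window: label, start (s from recording start), duration (s)."""

    label: str
    start: float
    duration: float

    @property
    def end(self) -> float:
        return self.start + self.duration


def select_segments(series: NNSeries, seed: int) -> List[SegmentSpec]:
    """Select the six analysis windows for one recording.

    The total window covers the whole recording; 30 s and 120 s windows start
    at 0; three 10 s windows are drawn with continuous-uniform starts by
    rejection until pairwise non-overlapping, then labelled ``10s_1..3`` in
    start-time order. Deterministic given ``(series, seed)``.
    """
    duration = series.duration
    if not (MIN_TOTAL_DURATION <= duration <= MAX_TOTAL_DURATION):
        shortest = "total" if duration < MIN_TOTAL_DURATION else "total(max)"
        raise ValueError(
            f"subject {series.subject_id}: recording duration {duration:.1f}s "
            f"outside [{MIN_TOTAL_DURATION}, {MAX_TOTAL_DURATION}]s "
            f"(cannot satisfy segment {shortest!r})"
        )
    rng = np.random.default_rng(seed)
    starts = _draw_disjoint_starts(rng, duration, window=10.0, k=3)
    specs = [SegmentSpec(lab, s, 10.0) for lab, s in zip(LABEL_10S, sorted(starts))]
    specs.append(SegmentSpec(LABEL_30S, 0.0, 30.0))
    specs.append(SegmentSpec(LABEL_120S, 0.0, 120.0))
    specs.append(SegmentSpec(LABEL_TOTAL, 0.0, duration))
    return specs


def _draw_disjoint_starts(rng: np.random.Generator, duration: float,
                          window: float, k: int) -> List[float]:
    """Rejection-sample k window starts with pairwise gaps >= window."""
    max_start = duration - window
    while True:
        starts = rng.uniform(0.0, max_start, size=k)
        s = np.sort(starts)
        if np.all(np.diff(s) >= window):
            return [float(x) for x in starts]


def extract(series: NNSeries, spec: SegmentSpec) -> NNSeries:
    """Extract the sub-series of one window.

    An interval belongs to the window when its *terminating* beat time lies
    in the half-open window ``(start, start + duration]`` — so in a tiling of
    the recording every interval lands in exactly one window. Beat times are
    re-based to the window start (the anchor beat of the first interval may
    then sit just before 0). Windows capturing fewer than 2 intervals are
    rejected, as the SD of intervals is undefined there.
    """
    t0 = float(series.beat_times[0])
    if spec.start < 0 or spec.end > series.duration + 1e-9:
        raise ValueError(
            f"window {spec.label} [{spec.start}, {spec.end}]s outside recording "
            f"of {series.duration:.1f}s"
        )
    term = series.beat_times[1:] - t0  # terminating beat time of each interval
    mask = (term > spec.start) & (term <= spec.end + 1e-9)
    idx = np.flatnonzero(mask)
    if len(idx) < 2:
        raise ValueError(
            f"window {spec.label} captures {len(idx)} interval(s); at least 2 required"
        )
    lo, hi = int(idx[0]), int(idx[-1]) + 1
    beat_times = series.beat_times[lo:hi + 1] - t0 - spec.start
    return NNSeries(series.subject_id, beat_times,
                    series.intervals[lo:hi], series.flags[lo:hi])
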