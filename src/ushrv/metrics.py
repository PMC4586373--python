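"""Time-domain HRV statistics: SDNN, RMSSD, log transforms, Avg10s.

SDNN (standard deviation of NN intervals, divisor N-1) estimates overall
variability across all frequency components; RMSSD (root mean square of
successive differences) reflects fast, parasympathetically mediated
variability. Both are computed per analysis window; natural-log transforms
are carried alongside because HRV distributions are right-skewed and all
agreement analyses run on the ln scale.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np

from .preprocess import RULE_EXCLUDE, apply_segment_artifact_rules
from .segments import (ALL_LABELS, LABEL_10S, LABEL_AVG10S, SEGMENT_LABELS,
                       SegmentSpec, extract, select_segments)
from .series import NNSeries


def sdnn(series_or_intervals) -> float:
    """Sample standard deviation of NN intervals (ms), divisor N - 1."""
    iv = _intervals(series_or_intervals)
    if len(iv) < 2:
        raise ValueError(f"SDNN undefined on {len(iv)} interval(s); need >= 2")
    return float(np.std(iv, ddof=1))


def rmssd(series_or_intervals) -> float:
    """Root mean square of successive NN differences (ms), divisor N - 1."""
    iv = _intervals(series_or_intervals)
    if len(iv) < 2:
        raise ValueError(f"RMSSD undefined on {len(iv)} interval(s); need >= 2")
    d = np.diff(iv)
    return float(np.sqrt(np.mean(d * d)))


def _intervals(x) -> np.ndarray:
    if isinstance(x, NNSeries):
        return x.intervals
    return np.asarray(x, dtype=float)


@dataclass(frozen=True)
class HRVMeasure:
    """SDNN/RMSSD for one segment, raw (ms) and natural log, with interval count."""

    label: str
    sdnn: float
    rmssd: float
    ln_sdnn: float
    ln_rmssd: float
    n_intervals: float  # fractional only for the Avg10s aggregate

    @classmethod
    def from_series(cls, label: str, series: NNSeries) -> "HRVMeasure":
        s, r = sdnn(series), rmssd(series)
        return cls(label=label, sdnn=s, rmssd=r,
                   ln_sdnn=math.log(s) if s > 0 else float("nan"),
                   ln_rmssd=math.log(r) if r > 0 else float("nan"),
                   n_intervals=series.n_intervals)


def avg10s(m1: HRVMeasure, m2: HRVMeasure, m3: HRVMeasure) -> HRVMeasure:
    """Average the three 10 s measures.

    SDNN and RMSSD are arithmetic means of the raw millisecond values; the ln
    fields are logs of those means (not means of logs). The interval count is
    the mean of the three counts and is carried for reporting only.
    """
    s = (m1.sdnn + m2.sdnn + m3.sdnn) / 3.0
    r = (m1.rmssd + m2.rmssd + m3.rmssd) / 3.0
    n = (m1.n_intervals + m2.n_intervals + m3.n_intervals) / 3.0
    return HRVMeasure(label=LABEL_AVG10S, sdnn=s, rmssd=r,
                      ln_sdnn=math.log(s) if s > 0 else float("nan"),
                      ln_rmssd=math.log(r) if r > 0 else float("nan"),
                      n_intervals=n)


@dataclass(frozen=True)
class SubjectHRVTable:
    """Per-subject HRV measures for every segment label."""

    subject_id: str
    measures: Dict[str, HRVMeasure]

    def __post_init__(self) -> None:
        missing = set(ALL_LABELS) - set(self.measures)
        if missing:
            raise ValueError(f"subject {self.subject_id}: missing labels {sorted(missing)}")

    def __getitem__(self, label: str) -> HRVMeasure:
        return self.measures[label]


class SubjectExcluded(Exception):
    """Raised when a subject cannot contribute a complete segment table."""

    def __init__(self, subject_id: str, reason: str):
        self.subject_id = subject_id
        self.reason = reason
        super().__init__(f"subject {subject_id} excluded: {reason}")


def build_subject_table(series: NNSeries, seed: int) -> SubjectHRVTable:
    """Segment one validated recording and compute all HRV measures.

    Selects the six windows (seeded 10 s placement), applies the segment
    artifact rules to each, computes SDNN/RMSSD per surviving segment and
    forms Avg10s. A rejected required segment excludes the subject with a
    reason naming the segment and rule.
    """
    specs = select_segments(series, seed)
    measures: Dict[str, HRVMeasure] = {}
    for spec in specs:
        try:
            seg = extract(series, spec)
        except ValueError as e:
            raise SubjectExcluded(series.subject_id, f"{spec.label}: {e}") from e
        kept, rule = apply_segment_artifact_rules(seg)
        if kept is None:
            raise SubjectExcluded(
                series.subject_id,
                f"{spec.label}: segment excluded by artifact criterion (b) "
                "(interior or multiple artifacts)")
        if kept.n_intervals < 2:
            raise SubjectExcluded(series.subject_id,
                                  f"{spec.label}: fewer than 2 intervals after trim")
        measures[spec.label] = HRVMeasure.from_series(spec.label, kept)
    measures[LABEL_AVG10S] = avg10s(*(measures[lab] for lab in LABEL_10S))
    return SubjectHRVTable(subject_id=series.subject_id, measures=measures)


def tables_to_frame(tables: Iterable[SubjectHRVTable]):
    """Long-format DataFrame (one row per subject x label) of all measures."""
    import pandas as pd

    rows = []
    for t in tables:
        for lab in ALL_LABELS:
            m = t[lab]
            rows.append({"subject_id": t.subject_id, "label": lab,
                         "sdnn": m.sdnn, "rmssd": m.rmssd,
                         "ln_sdnn": m.ln_sdnn, "ln_rmssd": m.ln_rmssd,
                         "n_intervals": m.n_intervals})
    return pd.DataFrame(rows)
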