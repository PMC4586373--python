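"""Data-quality rules for NN-interval recordings.

Three rules are applied before any HRV statistic is computed:

1. artifact gaps are closed by linear interpolation between the nearest
   normal intervals (recording level);
2. a recording with more than 5% interpolated intervals is invalid and
   discarded;
3. within an extracted analysis segment, a single artifact at the first or
   last interval is trimmed; any interior artifact, or more than one
   artifact, excludes the whole segment (the successive-difference statistics
   need one continuous stretch).

The 5% budget is counted on intervals, not time; this assumption is recorded
in the pipeline metadata.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .series import FLAG_ARTIFACT, FLAG_INTERPOLATED, NNSeries

#: Recording-level validity threshold: maximum interpolated fraction.
MAX_INTERPOLATED_FRACTION = 0.05

#: Segment-rule outcomes.
RULE_NONE = "none"
RULE_TRIM = "trim"
RULE_EXCLUDE = "exclude"


@dataclass(frozen=True)
class ValidityReport:
    """Recording-level quality verdict."""

    interpolated_fraction: float
    valid: bool
    reason: str

    def __post_init__(self) -> None:
        assert self.valid == (self.interpolated_fraction <= MAX_INTERPOLATED_FRACTION)


class UnrecoverableSeriesError(ValueError):
    """Raised when an artifact run has no normal anchor on either side."""


def interpolate_artifacts(series: NNSeries) -> Tuple[NNSeries, ValidityReport]:
    """Close artifact gaps by linear interpolation and judge recording validity.

    Every maximal run of artifact-flagged intervals is replaced by intervals
    lying on the straight line between the nearest non-artifact neighbours
    (constant at the single anchor for a run touching one end of the
    recording), re-flagged ``interpolated``. The number of replacement
    intervals is chosen so their mean is close to the anchor line, and a
    constant offset makes their sum reproduce the gap duration exactly, so
    cumulative recording time is preserved. Returns the cleaned series and a
    :class:`ValidityReport` whose ``interpolated_fraction`` counts
    interpolated intervals (pre-existing plus new) over all intervals.
    """
    flags = series.flags
    artifact_idx = np.flatnonzero(flags == FLAG_ARTIFACT)
    if len(artifact_idx) == 0:
        frac = series.count_flag(FLAG_INTERPOLATED) / max(series.n_intervals, 1)
        return series, _report(frac)

    iv = list(series.intervals)
    fl = list(flags)
    # walk maximal artifact runs right-to-left so earlier indices stay valid
    runs = _maximal_runs(artifact_idx)
    for start, stop in reversed(runs):  # run covers iv[start:stop]
        left = iv[start - 1] if start > 0 else None
        right = iv[stop] if stop < len(iv) else None
        if left is None and right is None:
            raise UnrecoverableSeriesError(
                f"subject {series.subject_id}: artifact run spans the whole "
                "recording, no normal anchor to interpolate from"
            )
        gap = float(np.sum(iv[start:stop]))  # ms, true elapsed time of the run
        lo = left if left is not None else right
        hi = right if right is not None else left
        m = max(1, int(round(gap / (0.5 * (lo + hi)))))
        line = lo + (hi - lo) * (np.arange(1, m + 1) / (m + 1))
        line = line + (gap - line.sum()) / m  # exact time preservation
        line = np.maximum(line, 1.0)
        iv[start:stop] = list(line)
        fl[start:stop] = [FLAG_INTERPOLATED] * m

    cleaned = NNSeries.from_intervals(series.subject_id, iv, fl,
                                      start_time=float(series.beat_times[0]))
    frac = cleaned.count_flag(FLAG_INTERPOLATED) / cleaned.n_intervals
    return cleaned, _report(frac)


def _report(frac: float) -> ValidityReport:
    valid = frac <= MAX_INTERPOLATED_FRACTION
    reason = ("ok" if valid else
              f"interpolated fraction {frac:.3f} exceeds {MAX_INTERPOLATED_FRACTION:.0%}")
    return ValidityReport(interpolated_fraction=float(frac), valid=valid, reason=reason)


def _maximal_runs(idx: np.ndarray):
    """Group sorted indices into maximal consecutive runs [(start, stop), ...]."""
    runs = []
    start = prev = int(idx[0])
    for i in idx[1:]:
        i = int(i)
        if i != prev + 1:
            runs.append((start, prev + 1))
            start = i
        prev = i
    runs.append((start, prev + 1))
    return runs


def apply_segment_artifact_rules(
    segment: NNSeries,
) -> Tuple[Optional[NNSeries], str]:
    """Apply the ultra-short-segment artifact criteria.

    Returns ``(series, rule)`` where rule is one of ``"none"`` (no artifacts,
    unchanged), ``"trim"`` (exactly one artifact located at the first or last
    interval; that interval is dropped), or ``"exclude"`` (any interior
    artifact or more than one artifact; series is ``None``). The decision
    depends only on the flags, never on interval values.
    """
    n = segment.n_intervals
    if n == 0:
        raise ValueError("empty segment")
    artifact_idx = np.flatnonzero(segment.flags == FLAG_ARTIFACT)
    if len(artifact_idx) == 0:
        return segment, RULE_NONE
    if len(artifact_idx) == 1 and artifact_idx[0] in (0, n - 1):
        i = int(artifact_idx[0])
        if i == 0:
            trimmed = NNSeries(segment.subject_id, segment.beat_times[1:],
                               segment.intervals[1:], segment.flags[1:])
        else:
            trimmed = NNSeries(segment.subject_id, segment.beat_times[:-1],
                               segment.intervals[:-1], segment.flags[:-1])
        return trimmed, RULE_TRIM
    return None, RULE_EXCLUDE
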