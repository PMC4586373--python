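"""Bootstrap null simulation for part-whole agreement.

Because every short segment is cut from the total recording it is compared
against, some agreement between the two is guaranteed even if the remainder
of the recording carries no information about the segment. This module
quantifies that floor. For each subject the HRV of the *remainder* of the
recording is approximated by removing the short segment's contribution from
the total via the variance-decomposition identity

    HRV_rem^2 = [HRV_tot^2 (N_tot - 1) - HRV_short^2 (N_short - 1)]
                / (N_tot - N_short - 1)

(applied to SDNN and RMSSD alike, as an approximation for the latter). Under
the null hypothesis of no within-subject agreement, short values and
remainder values are then resampled *independently* with replacement across
subjects, recombined with the inverse identity (adding independent SDs)

    HRV_tot^2 = [HRV_short^2 (N_short - 1) + HRV_rem^2 (N_rem - 1)]
                / (N_short + N_rem - 1)

into simulated totals, and the agreement statistics are computed between the
drawn shorts and the simulated totals on the ln scale. Repeating this (1,000
repetitions by default) yields 95% reference ranges; an observed statistic
outside its range differs significantly (p < 0.05) from pure part-whole
agreement.

The algebra is valid on the raw millisecond scale only, so decomposition and
recombination run on raw values; ln transforms are applied afterwards, when
the agreement statistics are formed.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .agreement import AgreementResult, bland_altman, cohens_d
from .metrics import HRVMeasure, SubjectHRVTable
from .segments import LABEL_TOTAL, SHORT_LABELS

#: Default number of bootstrap repetitions.
DEFAULT_N_REPS = 1000

#: raw-scale metric names -> HRVMeasure attribute (decomposition runs raw).
RAW_METRICS = {"lnSDNN": "sdnn", "lnRMSSD": "rmssd"}


@dataclass(frozen=True)
class DecomposedPair:
    """One subject's short-segment measure and approximated remainder."""

    short_value: float
    short_n: float
    remainder_value: float
    remainder_n: float


class NegativeRadicand(ValueError):
    """Decomposition produced a negative variance; the pair must be dropped."""


def decompose_remainder(total_value: float, total_n: float,
                        short_value: float, short_n: float) -> Tuple[float, float]:
    """Approximate the remainder-segment HRV from total and short values.

    Returns ``(remainder_value, remainder_n)`` with ``remainder_n = total_n -
    short_n``. Raises :class:`NegativeRadicand` when the short segment's
    variance contribution exceeds the total's (possible for RMSSD, where the
    identity is approximate); such pairs are dropped, not clamped, to avoid
    biasing the lower tail of the null distribution.
    """
    if not total_n > short_n + 1:
        raise ValueError(
            f"need total_n > short_n + 1, got total_n={total_n}, short_n={short_n}")
    num = total_value ** 2 * (total_n - 1) - short_value ** 2 * (short_n - 1)
    den = total_n - short_n - 1
    rad = num / den
    if rad < 0:
        raise NegativeRadicand(
            f"negative radicand: total={total_value}, short={short_value}")
    return math.sqrt(rad), total_n - short_n


def recombine(short_value: float, short_n: float,
              remainder_value: float, remainder_n: float) -> Tuple[float, float]:
    """Combine independent short and remainder HRV into a simulated total.

    The algebraic inverse of :func:`decompose_remainder`:
    ``combined^2 = [s^2 (N_s - 1) + r^2 (N_r - 1)] / (N_s + N_r - 1)`` with
    combined interval count ``N_s + N_r``.
    """
    if short_value < 0 or remainder_value < 0:
        raise ValueError("HRV values must be non-negative")
    if short_n < 2 or remainder_n < 2:
        raise ValueError("both interval counts must be >= 2")
    num = short_value ** 2 * (short_n - 1) + remainder_value ** 2 * (remainder_n - 1)
    den = short_n + remainder_n - 1
    return math.sqrt(num / den), short_n + remainder_n


@dataclass(frozen=True)
class NullSimResult:
    """Simulated 95% reference ranges and verdicts for one (metric, label)."""

    metric: str
    label: str
    n_reps: int
    n_subjects: int
    n_dropped: int             # negative-radicand pairs removed up front
    n_redrawn: int             # degenerate repetitions redrawn
    ref_range_r: Tuple[float, float]
    ref_range_bias: Tuple[float, float]
    ref_range_loa_low: Tuple[float, float]
    ref_range_loa_high: Tuple[float, float]
    ref_range_d: Tuple[float, float]
    verdicts: Dict[str, str]   # statistic -> below / inside / above


def _classify(value: float, rng: Tuple[float, float]) -> str:
    lo, hi = rng
    if value < lo:
        return "below"
    if value > hi:
        return "above"
    return "inside"


def decompose_population(tables: Sequence[SubjectHRVTable], metric: str,
                         label: str) -> Tuple[List[DecomposedPair], int]:
    """Per-subject decomposed pairs for one metric/label; counts drops.

    For the Avg10s label the averaged measure enters with its mean 10 s
    interval count (an interpretive choice recorded in run metadata).
    """
    attr = RAW_METRICS[metric]
    pairs: List[DecomposedPair] = []
    dropped = 0
    for t in tables:
        short = t[label]
        total = t[LABEL_TOTAL]
        sv = getattr(short, attr)
        tv = getattr(total, attr)
        try:
            rv, rn = decompose_remainder(tv, total.n_intervals, sv, short.n_intervals)
        except NegativeRadicand:
            dropped += 1
            continue
        pairs.append(DecomposedPair(short_value=sv, short_n=short.n_intervals,
                                    remainder_value=rv, remainder_n=rn))
    return pairs, dropped


def bootstrap_null(tables: Sequence[SubjectHRVTable], metric: str, label: str,
                   n_reps: int, seed: int,
                   observed: Optional[AgreementResult] = None) -> NullSimResult:
    """Simulate the null distribution of the agreement statistics.

    Per repetition, n short values and n remainder values are drawn
    independently with replacement (each carrying its own interval count),
    recombined into simulated totals, ln-transformed, and the agreement
    statistics (r, bias, LoA bounds, Cohen's d) computed between simulated
    totals and drawn shorts. Reference ranges are the 2.5th/97.5th
    percentiles across repetitions (linear-interpolation definition). When
    ``observed`` is given, each observed statistic is classified below /
    inside / above its range. Repetitions with zero variance in either
    vector are redrawn with a logged count.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if metric not in RAW_METRICS:
        raise ValueError(f"unknown metric {metric!r}")
    pairs, dropped = decompose_population(tables, metric, label)
    n = len(pairs)
    if n < 3:
        raise ValueError(f"only {n} usable pairs for {metric}/{label}")
    sv = np.array([p.short_value for p in pairs])
    sn = np.array([p.short_n for p in pairs])
    rv = np.array([p.remainder_value for p in pairs])
    rn = np.array([p.remainder_n for p in pairs])

    rng = np.random.default_rng(seed)
    stats_rows = np.empty((n_reps, 5))
    redrawn = 0
    rep = 0
    while rep < n_reps:
        i = rng.integers(0, n, size=n)   # short draw
        j = rng.integers(0, n, size=n)   # independent remainder draw
        s, s_n = sv[i], sn[i]
        r_, r_n = rv[j], rn[j]
        comb = np.sqrt((s ** 2 * (s_n - 1) + r_ ** 2 * (r_n - 1)) / (s_n + r_n - 1))
        ok = (s > 0) & (comb > 0)
        ls = np.log(s[ok])
        lt = np.log(comb[ok])
        if len(ls) < 3 or np.std(ls) == 0 or np.std(lt) == 0:
            redrawn += 1
            continue
        r_stat = float(np.corrcoef(lt, ls)[0, 1])
        bias, _, loa_lo, loa_hi = bland_altman(lt, ls)
        d = cohens_d(bias, float(np.std(lt, ddof=1)))
        stats_rows[rep] = (r_stat, bias, loa_lo, loa_hi, d)
        rep += 1

    q = np.percentile(stats_rows, [2.5, 97.5], axis=0, method="linear")
    ranges = {name: (float(q[0, k]), float(q[1, k]))
              for k, name in enumerate(("r", "bias", "loa_low", "loa_high", "d"))}
    verdicts: Dict[str, str] = {}
    if observed is not None:
        verdicts = {
            "r": _classify(observed.r, ranges["r"]),
            "bias": _classify(observed.bias, ranges["bias"]),
            "loa_low": _classify(observed.loa_low, ranges["loa_low"]),
            "loa_high": _classify(observed.loa_high, ranges["loa_high"]),
            "d": _classify(observed.cohens_d, ranges["d"]),
        }
    return NullSimResult(
        metric=metric, label=label, n_reps=n_reps, n_subjects=n,
        n_dropped=dropped, n_redrawn=redrawn,
        ref_range_r=ranges["r"], ref_range_bias=ranges["bias"],
        ref_range_loa_low=ranges["loa_low"],
        ref_range_loa_high=ranges["loa_high"], ref_range_d=ranges["d"],
        verdicts=verdicts)


def null_simulation_table(tables: Sequence[SubjectHRVTable],
                          observed: Sequence[AgreementResult],
                          n_reps: int = DEFAULT_N_REPS,
                          seed: int = 0) -> List[NullSimResult]:
    """Run the null simulation for every (metric, short label) pair."""
    obs_map = {(o.metric, o.label): o for o in observed}
    rng = np.random.default_rng(seed)
    out: List[NullSimResult] = []
    for metric in RAW_METRICS:
        for label in SHORT_LABELS:
            out.append(bootstrap_null(
                tables, metric, label, n_reps=n_reps,
                seed=int(rng.integers(0, 2**31 - 1)),
                observed=obs_map.get((metric, label))))
    return out
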