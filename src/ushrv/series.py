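"""Beat-to-beat (NN) interval series container.

The whole package operates on :class:`NNSeries`: one subject's sequence of
normal-to-normal intervals in milliseconds, together with the cumulative beat
times (seconds from recording start) and a per-interval quality flag.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Per-interval quality flags.
FLAG_NORMAL = "normal"
FLAG_INTERPOLATED = "interpolated"
FLAG_ARTIFACT = "artifact"
VALID_FLAGS = frozenset({FLAG_NORMAL, FLAG_INTERPOLATED, FLAG_ARTIFACT})

#: Tolerance (ms) for the beat-time / interval consistency check. Beat
#: detection from pressure waveforms carries a few ms of timing error, so the
#: container does not insist on exact agreement.
TIME_CONSISTENCY_TOL_MS = 0.5


@dataclass(frozen=True)
class NNSeries:
    """One subject's NN-interval time series.

    Parameters
    ----------
    subject_id
        Opaque subject identifier.
    beat_times
        Time of each beat in seconds from recording start, strictly
        increasing; length ``len(intervals) + 1``.
    intervals
        NN intervals in milliseconds, ``intervals[i]`` spanning
        ``beat_times[i]`` to ``beat_times[i + 1]``; all positive.
    flags
        One of ``{"normal", "interpolated", "artifact"}`` per interval.
    """

    subject_id: str
    beat_times: np.ndarray
    intervals: np.ndarray
    flags: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        bt = np.asarray(self.beat_times, dtype=float)
        iv = np.asarray(self.intervals, dtype=float)
        if self.flags is None:
            fl = np.full(iv.shape, FLAG_NORMAL, dtype=object)
        else:
            fl = np.asarray(self.flags, dtype=object)
        object.__setattr__(self, "beat_times", bt)
        object.__setattr__(self, "intervals", iv)
        object.__setattr__(self, "flags", fl)
        if bt.ndim != 1 or iv.ndim != 1 or fl.ndim != 1:
            raise ValueError("beat_times, intervals and flags must be 1-D")
        if len(bt) != len(iv) + 1:
            raise ValueError(
                f"expected {len(iv) + 1} beat times for {len(iv)} intervals, got {len(bt)}"
            )
        if len(fl) != len(iv):
            raise ValueError("one flag per interval required")
        if len(iv) and not np.all(np.diff(bt) > 0):
            raise ValueError("beat_times must be strictly increasing")
        if np.any(iv <= 0):
            raise ValueError("all intervals must be positive")
        bad = set(fl) - VALID_FLAGS
        if bad:
            raise ValueError(f"unknown flags: {sorted(bad)}")
        # Artifact intervals carry aberrant values, so only check consistency
        # on intervals flagged normal/interpolated.
        ok = fl != FLAG_ARTIFACT
        implied = np.diff(bt) * 1000.0
        if np.any(np.abs(implied[ok] - iv[ok]) > TIME_CONSISTENCY_TOL_MS):
            raise ValueError(
                "intervals inconsistent with beat_times beyond "
                f"{TIME_CONSISTENCY_TOL_MS} ms tolerance"
            )

    @property
    def n_intervals(self) -> int:
        return len(self.intervals)

    @property
    def duration(self) -> float:
        """Recording span in seconds (last beat time minus first)."""
        return float(self.beat_times[-1] - self.beat_times[0])

    def count_flag(self, flag: str) -> int:
        return int(np.sum(self.flags == flag))

    @classmethod
    def from_intervals(
        cls, subject_id: str, intervals_ms, flags=None, start_time: float = 0.0
    ) -> "NNSeries":
        """Build a series from intervals alone; beat times are their cumsum."""
        iv = np.asarray(intervals_ms, dtype=float)
        bt = start_time + np.concatenate([[0.0], np.cumsum(iv) / 1000.0])
        return cls(subject_id, bt, iv, flags)
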