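"""Synthetic NN-interval recordings with realistic time-domain HRV structure.

The generator stands in for a resting-cohort recording session: ~5 minutes
supine, mean heart rate around 68 beats/min. Each subject's interval sequence
is a mean level plus

* a high-frequency (respiratory sinus arrhythmia) sinusoid — drives RMSSD,
* a low-frequency (baroreflex / Mayer-wave) sinusoid,
* a Gaussian random-walk drift — slow nonstationarity,
* white beat-to-beat noise,

evaluated at the cumulative beat times (point-process sampling). The LF and
drift components make the standard deviation of intervals (SDNN) grow with
recording length while leaving the successive-difference statistic (RMSSD)
nearly length-invariant — the structure the validity analysis must detect.
Amplitudes are log-normal across subjects, producing the right-skewed SDNN /
RMSSD distributions seen in population data.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .series import FLAG_ARTIFACT, FLAG_NORMAL, NNSeries

#: Physiologic floor (ms) applied to every generated interval.
CLAMP_FLOOR_MS = 200.0


@dataclass(frozen=True)
class GeneratorParams:
    """Parameters of one subject's NN-interval process.

    Defaults are calibrated so that a default population reproduces a resting
    adult cohort: mean heart rate ≈ 68 beats/min, median SDNN over the full
    recording ≈ 32 ms and median RMSSD ≈ 24.5 ms, with SDNN clearly
    length-dependent.
    """

    mean_nn: float = 882.0       # ms; 68 bpm
    hf_amp: float = 21.5         # ms, respiratory oscillation amplitude
    hf_freq: float = 0.25        # Hz, within the HF band (0.15-0.4)
    lf_amp: float = 30.0         # ms, slow oscillation amplitude
    lf_freq: float = 0.015       # Hz, very-low-frequency / lower LF range
    drift_sd: float = 0.5        # ms per beat, random-walk step SD
    noise_sd: float = 8.0        # ms, white beat-to-beat noise
    duration: float = 295.0      # s, recording length
    artifact_rate: float = 0.0   # probability per beat

    def validate(self) -> None:
        for name in ("mean_nn", "hf_amp", "hf_freq", "lf_amp", "lf_freq",
                     "drift_sd", "noise_sd", "duration", "artifact_rate"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"GeneratorParams.{name} must be finite, got {v!r}")
        if self.mean_nn <= 0:
            raise ValueError(f"GeneratorParams.mean_nn must be > 0, got {self.mean_nn}")
        if self.duration <= 0:
            raise ValueError(f"GeneratorParams.duration must be > 0, got {self.duration}")
        for name in ("hf_amp", "lf_amp", "drift_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"GeneratorParams.{name} must be >= 0")
        if not (0.0 <= self.artifact_rate < 1.0):
            raise ValueError(
                f"GeneratorParams.artifact_rate must be in [0, 1), got {self.artifact_rate}"
            )
        if not (self.hf_freq > self.lf_freq > 0):
            raise ValueError(
                "GeneratorParams requires hf_freq > lf_freq > 0, got "
                f"hf_freq={self.hf_freq}, lf_freq={self.lf_freq}"
            )
        nyquist = 0.5 * (1000.0 / self.mean_nn)  # half the mean beat rate, Hz
        if self.hf_freq >= nyquist:
            raise ValueError(
                f"GeneratorParams.hf_freq={self.hf_freq} Hz is not below half the "
                f"beat rate implied by mean_nn ({nyquist:.3f} Hz)"
            )


def generate_subject(params: GeneratorParams, seed: int,
                     subject_id: str = "S0") -> NNSeries:
    """Generate one subject's NN-interval recording.

    Intervals are produced beat by beat until the cumulative beat time covers
    ``params.duration``. Interval *i*, placed at cumulative time ``t_i``, is::

        mean_nn + lf_amp*sin(2*pi*lf_freq*t_i + phi_lf)
                + hf_amp*sin(2*pi*hf_freq*t_i + phi_hf)
                + drift_i + eps_i

    with ``drift`` a Gaussian random walk (step SD ``drift_sd``), ``eps``
    white Gaussian noise, and per-subject phases drawn uniformly from the
    seeded stream. Intervals are clamped at a 200 ms physiologic floor. The
    output is a pure function of ``(params, seed)``.
    """
    params.validate()
    rng = np.random.default_rng(seed)
    phi_lf = rng.uniform(0.0, 2.0 * np.pi)
    phi_hf = rng.uniform(0.0, 2.0 * np.pi)

    intervals: List[float] = []
    t = 0.0            # cumulative beat time, s
    drift = 0.0
    # subtract a small epsilon so that float accumulation (e.g. 10 x 0.8s
    # summing to 7.999...) cannot produce one beat beyond the target duration
    while t < params.duration - 1e-9:
        x = (params.mean_nn
             + params.lf_amp * math.sin(2.0 * math.pi * params.lf_freq * t + phi_lf)
             + params.hf_amp * math.sin(2.0 * math.pi * params.hf_freq * t + phi_hf)
             + drift
             + (params.noise_sd * rng.standard_normal() if params.noise_sd > 0 else 0.0))
        x = max(x, CLAMP_FLOOR_MS)
        intervals.append(x)
        t += x / 1000.0
        if params.drift_sd > 0:
            drift += params.drift_sd * rng.standard_normal()

    series = NNSeries.from_intervals(subject_id, intervals)
    if params.artifact_rate > 0:
        # dedicated sub-seed so artifact placement is reproducible on its own
        series = inject_artifacts(series, params.artifact_rate,
                                  seed=int(rng.integers(0, 2**31 - 1)))
    return series


def inject_artifacts(series: NNSeries, rate: float, seed: int) -> NNSeries:
    """Flag a seeded random subset of intervals as artifacts and corrupt them.

    Each interval is independently selected with probability ``rate``;
    selected intervals are alternately doubled and halved (emulating missed
    and spurious beat detections). Beat times are rebuilt from the corrupted
    intervals. The input series is not modified.
    """
    if not (0.0 <= rate < 1.0):
        raise ValueError(f"artifact rate must be in [0, 1), got {rate}")
    if rate == 0.0:
        return series
    rng = np.random.default_rng(seed)
    hit = rng.random(series.n_intervals) < rate
    intervals = series.intervals.copy()
    flags = series.flags.copy()
    factor_double = True
    for i in np.flatnonzero(hit):
        intervals[i] *= 2.0 if factor_double else 0.5
        factor_double = not factor_double
        flags[i] = FLAG_ARTIFACT
    return NNSeries.from_intervals(series.subject_id, intervals, flags,
                                   start_time=float(series.beat_times[0]))


# ---------------------------------------------------------------------------
# Population generation
# ---------------------------------------------------------------------------

#: distribution spec: ("fixed", value) | ("normal", mean, sd) |
#: ("lognormal", mu, sigma)  [mu/sigma on the log scale] |
#: ("uniform", low, high)
DistSpec = Tuple


@dataclass(frozen=True)
class PopulationSpec:
    """Specification of a synthetic cohort.

    ``params_distribution`` maps :class:`GeneratorParams` field names to
    distribution tuples; unmapped fields keep the GeneratorParams default.
    Amplitude-like fields default to log-normal across subjects.
    """

    n_subjects: int
    params_distribution: Dict[str, DistSpec] = field(default_factory=dict)
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ValueError(f"PopulationSpec.n_subjects must be >= 1, got {self.n_subjects}")
        for name, spec in self.params_distribution.items():
            if name not in GeneratorParams.__dataclass_fields__:
                raise ValueError(f"unknown GeneratorParams field {name!r}")
            kind = spec[0]
            if kind not in ("fixed", "normal", "lognormal", "uniform"):
                raise ValueError(f"unknown distribution kind {kind!r} for field {name!r}")
            if kind in ("normal", "lognormal") and spec[2] < 0:
                raise ValueError(f"scale parameter for field {name!r} must be >= 0")


def _draw(spec: DistSpec, rng: np.random.Generator) -> float:
    kind = spec[0]
    if kind == "fixed":
        return float(spec[1])
    if kind == "normal":
        return float(rng.normal(spec[1], spec[2]))
    if kind == "lognormal":
        return float(rng.lognormal(spec[1], spec[2]))
    if kind == "uniform":
        return float(rng.uniform(spec[1], spec[2]))
    raise ValueError(f"unknown distribution kind {kind!r}")


def default_population_spec(n_subjects: int = 500, seed: int = 0,
                            artifact_rate: float = 0.0) -> PopulationSpec:
    """Default cohort: resting adults at ~68 bpm with log-normal HRV spread.

    Location/scale values are on the log scale for the log-normal fields and
    were calibrated once so the population medians of SDNN and RMSSD over the
    total recording land near 32 ms and 24.5 ms respectively.
    """
    dist: Dict[str, DistSpec] = {
        "mean_nn": ("normal", 882.0, 115.0),
        "hf_amp": ("lognormal", math.log(21.5), 0.55),
        "lf_amp": ("lognormal", math.log(30.0), 0.55),
        "noise_sd": ("lognormal", math.log(8.0), 0.40),
        "drift_sd": ("lognormal", math.log(0.5), 0.40),
        "duration": ("uniform", 240.0, 300.0),
        "artifact_rate": ("fixed", artifact_rate),
    }
    return PopulationSpec(n_subjects=n_subjects, params_distribution=dist, seed=seed)


def draw_subject_params(spec: PopulationSpec, rng: np.random.Generator) -> GeneratorParams:
    """Draw one subject's GeneratorParams from the population distributions."""
    values = {name: _draw(d, rng) for name, d in spec.params_distribution.items()}
    # keep the physiologic envelope sane under extreme draws
    if "mean_nn" in values:
        values["mean_nn"] = float(np.clip(values["mean_nn"], 450.0, 1500.0))
    params = replace(GeneratorParams(), **values)
    params.validate()
    return params


def generate_population(spec: PopulationSpec) -> List[NNSeries]:
    """Generate ``spec.n_subjects`` independent recordings.

    Subject identifiers are ``S0001`` … and stable across runs; the whole
    population is a pure function of ``spec`` (including its seed).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    out: List[NNSeries] = []
    for k in range(spec.n_subjects):
        params = draw_subject_params(spec, rng)
        sub_seed = int(rng.integers(0, 2**31 - 1))
        out.append(generate_subject(params, sub_seed, subject_id=f"S{k + 1:04d}"))
    return out
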