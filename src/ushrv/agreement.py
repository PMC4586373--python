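"""Agreement between short-segment and gold-standard HRV on the ln scale.

For each metric (lnSDNN, lnRMSSD) and each short segment the module computes

* Pearson's r with a 95% Fisher-z confidence interval,
* Bland-Altman bias (gold minus short), its 95% CI, and 95% limits of
  agreement (bias +/- 1.96 * SD of the paired differences),
* Cohen's d = bias / SD of the gold-standard (total recording) measure
  across subjects, with a nonparametric bootstrap CI over subjects,

plus the pairwise intraclass correlations (two-way random effects, absolute
agreement, single rater — ICC(2,1)) among the three 10 s windows.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np
from scipy import stats

from .metrics import SubjectHRVTable
from .segments import LABEL_10S, LABEL_TOTAL, SHORT_LABELS

#: ln-scale metric names -> HRVMeasure attribute.
METRICS = {"lnSDNN": "ln_sdnn", "lnRMSSD": "ln_rmssd"}

#: Effect-size interpretation thresholds (|d|).
_D_BANDS = ((0.80, "large"), (0.50, "moderate"), (0.20, "small"))

#: Bootstrap resamples for the Cohen's d confidence interval.
N_BOOT_D = 2000


def effect_size_band(d: float) -> str:
    """Interpretation label for |d| (0.20/0.50/0.80 = small/moderate/large)."""
    a = abs(d)
    for thr, name in _D_BANDS:
        if a >= thr:
            return name
    return "very small"


def pearson_with_ci(x: Sequence[float], y: Sequence[float],
                    alpha: float = 0.05) -> Tuple[float, Tuple[float, float]]:
    """Pearson correlation with Fisher z-transform confidence interval."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 4:
        # the Fisher z standard error 1/sqrt(n - 3) requires n >= 4
        raise ValueError("paired vectors of length >= 4 required")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in input")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined: zero variance")
    n = len(x)
    r = float(np.corrcoef(x, y)[0, 1])
    z = np.arctanh(r)
    se = 1.0 / math.sqrt(n - 3)
    crit = stats.norm.ppf(1 - alpha / 2)
    lo, hi = np.tanh(z - crit * se), np.tanh(z + crit * se)
    return r, (float(lo), float(hi))


def bland_altman(gold: Sequence[float], short: Sequence[float]
                 ) -> Tuple[float, Tuple[float, float], float, float]:
    """Bland-Altman agreement of a short measure against the gold standard.

    Differences are ``gold - short``. Returns ``(bias, bias_ci, loa_low,
    loa_high)`` with the limits of agreement at bias +/- 1.96 * SD(d)
    (sample SD, divisor n-1) and the bias CI at bias +/- 1.96 * SD(d)/sqrt(n).
    """
    gold = np.asarray(gold, dtype=float)
    short = np.asarray(short, dtype=float)
    if len(gold) != len(short) or len(gold) < 3:
        raise ValueError("paired vectors of length >= 3 required")
    d = gold - short
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    loa_low, loa_high = bias - 1.96 * sd, bias + 1.96 * sd
    half = 1.96 * sd / math.sqrt(len(d))
    return bias, (bias - half, bias + half), loa_low, loa_high


def bland_altman_plot_data(gold, short):
    """Per-subject (gold value, difference) pairs, gold on the x-axis."""
    gold = np.asarray(gold, dtype=float)
    short = np.asarray(short, dtype=float)
    return np.column_stack([gold, gold - short])


def cohens_d(bias: float, sd_total: float) -> float:
    """Standardised bias: mean difference over the SD of the gold standard."""
    if sd_total <= 0:
        raise ValueError("Cohen's d undefined: gold-standard SD must be > 0")
    return bias / sd_total


def cohens_d_bootstrap_ci(gold: Sequence[float], short: Sequence[float],
                          seed: int, n_boot: int = N_BOOT_D,
                          alpha: float = 0.05) -> Tuple[float, float]:
    """Percentile bootstrap CI for Cohen's d, resampling subjects."""
    gold = np.asarray(gold, dtype=float)
    short = np.asarray(short, dtype=float)
    n = len(gold)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    g = gold[idx]
    s = short[idx]
    sd = g.std(axis=1, ddof=1)
    sd[sd == 0] = np.nan
    ds = (g - s).mean(axis=1) / sd
    lo, hi = np.nanpercentile(ds, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)


@dataclass(frozen=True)
class AgreementResult:
    """All agreement statistics for one (segment label, metric) pair."""

    label: str
    metric: str
    r: float
    r_ci: Tuple[float, float]
    bias: float
    bias_ci: Tuple[float, float]
    loa_low: float
    loa_high: float
    cohens_d: float
    d_ci: Tuple[float, float]
    d_band: str
    n: int


@dataclass(frozen=True)
class ICCResult:
    """Intraclass correlation for one pair of 10 s windows."""

    pair: Tuple[str, str]
    metric: str
    icc: float
    ci: Tuple[float, float]
    n: int


def icc_absolute(a: Sequence[float], b: Sequence[float],
                 alpha: float = 0.05) -> Tuple[float, Tuple[float, float]]:
    """ICC(2,1): two-way random effects, absolute agreement, single rater.

    Computed from the two-way ANOVA mean squares of the n x 2 table
    (subjects x measurements), with the standard F-based confidence interval
    (McGraw & Wong). Absolute agreement penalises systematic offsets between
    the two measurements, unlike Pearson's r.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) != len(b) or len(a) < 3:
        raise ValueError("paired vectors of length >= 3 required")
    data = np.column_stack([a, b])
    n, k = data.shape
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    msr = k * np.sum((row_means - grand) ** 2) / (n - 1)      # between subjects
    msc = n * np.sum((col_means - grand) ** 2) / (k - 1)      # between raters
    sse = np.sum((data - row_means[:, None] - col_means[None, :] + grand) ** 2)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom <= 0 or msr <= 0:
        raise ValueError("ICC undefined: no between-subject variance")
    icc = (msr - mse) / denom

    # McGraw & Wong F-based interval for ICC(A,1)
    fj = msc / mse if mse > 0 else np.inf
    if mse == 0:
        return float(icc), (float(icc), float(icc))
    vn = (k - 1) * (n - 1) * (k * icc * fj + n * (1 + (k - 1) * icc) - k * icc) ** 2
    vd = ((n - 1) * k ** 2 * icc ** 2 * fj ** 2
          + (n * (1 + (k - 1) * icc) - k * icc) ** 2)
    v = vn / vd
    f_l = stats.f.ppf(1 - alpha / 2, n - 1, v)
    f_u = stats.f.ppf(1 - alpha / 2, v, n - 1)
    lower = n * (msr - f_l * mse) / (
        f_l * (k * msc + (k * n - k - n) * mse) + n * msr)
    upper = n * (f_u * msr - mse) / (
        k * msc + (k * n - k - n) * mse + n * f_u * msr)
    return float(icc), (float(lower), float(upper))


def _metric_vectors(tables: Sequence[SubjectHRVTable], attr: str,
                    label: str) -> Tuple[np.ndarray, np.ndarray]:
    """Complete (gold, short) pairs for one metric/label, dropping NaN pairs."""
    gold = np.array([getattr(t[LABEL_TOTAL], attr) for t in tables])
    short = np.array([getattr(t[label], attr) for t in tables])
    ok = np.isfinite(gold) & np.isfinite(short)
    return gold[ok], short[ok]


def agreement_table(tables: Sequence[SubjectHRVTable], seed: int = 0
                    ) -> Tuple[List[AgreementResult], List[ICCResult]]:
    """Full agreement analysis of a cohort of subject tables.

    Returns the per-(metric, label) :class:`AgreementResult` list against the
    gold standard and the three pairwise :class:`ICCResult` entries among the
    10 s windows, for each metric, all on the natural-log scale. Subjects
    enter each comparison only with complete (finite) pairs; ``seed`` drives
    the bootstrap CIs for Cohen's d.
    """
    tables = list(tables)
    if len(tables) < 4:
        raise ValueError("at least 4 complete subjects required")
    results: List[AgreementResult] = []
    iccs: List[ICCResult] = []
    rng = np.random.default_rng(seed)
    for metric, attr in METRICS.items():
        for label in SHORT_LABELS:
            gold, short = _metric_vectors(tables, attr, label)
            r, r_ci = pearson_with_ci(gold, short)
            bias, bias_ci, lo, hi = bland_altman(gold, short)
            sd_total = float(np.std(gold, ddof=1))
            d = cohens_d(bias, sd_total)
            d_ci = cohens_d_bootstrap_ci(gold, short,
                                         seed=int(rng.integers(0, 2**31 - 1)))
            results.append(AgreementResult(
                label=label, metric=metric, r=r, r_ci=r_ci, bias=bias,
                bias_ci=bias_ci, loa_low=lo, loa_high=hi, cohens_d=d,
                d_ci=d_ci, d_band=effect_size_band(d), n=len(gold)))
        for i in range(3):
            for j in range(i + 1, 3):
                la, lb = LABEL_10S[i], LABEL_10S[j]
                va = np.array([getattr(t[la], attr) for t in tables])
                vb = np.array([getattr(t[lb], attr) for t in tables])
                ok = np.isfinite(va) & np.isfinite(vb)
                icc, ci = icc_absolute(va[ok], vb[ok])
                iccs.append(ICCResult(pair=(la, lb), metric=metric,
                                      icc=icc, ci=ci, n=int(ok.sum())))
    return results, iccs
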