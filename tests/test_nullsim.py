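import math

import numpy as np
import pytest

from ushrv.metrics import HRVMeasure, SubjectHRVTable, sdnn
from ushrv.nullsim import (NegativeRadicand, bootstrap_null,
                           decompose_population, decompose_remainder,
                           recombine)
from ushrv.segments import ALL_LABELS


class TestDecomposeRemainder:
    def test_hand_example(self):
        # total SDNN 10.954 over 6 intervals, short SDNN 14.142 over 2:
        # remainder^2 = (120*5 - 200*1)/3 = 133.33 -> 11.547
        total = math.sqrt(120.0)
        short = math.sqrt(200.0)
        value, n = decompose_remainder(total, 6, short, 2)
        assert value == pytest.approx(11.547005383792516, abs=1e-9)
        assert n == 4

    def test_homogeneous_variance_near_identity(self):
        # with equal short and total values c the df-weighted subtraction
        # gives exactly c * sqrt((N_t - N_s)/(N_t - N_s - 1)): the split
        # loses one degree of freedom, so the identity is only asymptotic
        value, n = decompose_remainder(25.0, 300, 25.0, 12)
        assert value == pytest.approx(25.0 * math.sqrt(288.0 / 287.0), rel=1e-12)
        assert value == pytest.approx(25.0, rel=2e-3)
        assert n == 288

    def test_negative_radicand_raises(self):
        with pytest.raises(NegativeRadicand):
            decompose_remainder(10.0, 6, 40.0, 4)

    def test_n_constraint_enforced(self):
        with pytest.raises(ValueError, match="total_n"):
            decompose_remainder(10.0, 5, 10.0, 4)

    def test_equal_mean_segments_match_pooled_variance_oracle(self):
        # concatenated series whose segment means equal the grand mean:
        # the decomposition returns exactly the direct SDNN of the remainder
        short_part = [790.0, 810.0]                       # mean 800
        rem_part = [780.0, 820.0, 795.0, 805.0]           # mean 800
        total = short_part + rem_part
        value, n = decompose_remainder(sdnn(total), len(total),
                                       sdnn(short_part), len(short_part))
        assert value == pytest.approx(sdnn(rem_part), abs=1e-9)
        assert n == len(rem_part)

    def test_unequal_means_discrepancy_equals_between_term(self):
        # with unequal segment means the identity is off by exactly the
        # between-segment sum of squares (brute-force variance decomposition)
        rng = np.random.default_rng(6)
        short_part = list(rng.normal(780, 15, 10))
        rem_part = list(rng.normal(830, 20, 30))
        total = short_part + rem_part
        n_s, n_r, n_t = 10, 30, 40
        ss_total = np.var(total, ddof=0) * n_t
        ss_within = (np.var(short_part, ddof=0) * n_s
                     + np.var(rem_part, ddof=0) * n_r)
        grand = np.mean(total)
        ss_between = (n_s * (np.mean(short_part) - grand) ** 2
                      + n_r * (np.mean(rem_part) - grand) ** 2)
        assert ss_total == pytest.approx(ss_within + ss_between, rel=1e-12)
        # hence Eq.-style subtraction overstates the remainder SS by ss_between
        value, _ = decompose_remainder(sdnn(total), n_t, sdnn(short_part), n_s)
        implied_ss = value ** 2 * (n_r - 1)
        direct_ss = sdnn(rem_part) ** 2 * (n_r - 1)
        assert implied_ss - direct_ss == pytest.approx(ss_between, rel=1e-9)


class TestRecombine:
    def test_round_trip_identity(self):
        rng = np.random.default_rng(17)
        for _ in range(10_000):
            total_v = rng.uniform(5.0, 80.0)
            total_n = rng.integers(40, 400)
            short_n = rng.integers(2, total_n - 2)
            # choose a short value keeping the radicand positive
            max_short = total_v * math.sqrt((total_n - 1) / (short_n - 1))
            short_v = rng.uniform(0.0, 0.999 * max_short)
            rem_v, rem_n = decompose_remainder(total_v, total_n, short_v, short_n)
            back, back_n = recombine(short_v, short_n, rem_v, rem_n)
            assert back == pytest.approx(total_v, rel=1e-9)
            assert back_n == total_n

    def test_hand_example(self):
        value, n = recombine(math.sqrt(200.0), 2, math.sqrt(400.0 / 3.0), 4)
        assert value == pytest.approx(math.sqrt(120.0), abs=1e-9)
        assert n == 6

    def test_equal_values_near_identity(self):
        # combining two equal values c gives exactly
        # c * sqrt((N_s + N_r - 2)/(N_s + N_r - 1)); the numerator carries
        # N_s + N_r - 2 degrees of freedom against the pooled N_s + N_r - 1
        value, _ = recombine(30.0, 10, 30.0, 40)
        assert value == pytest.approx(30.0 * math.sqrt(48.0 / 49.0), rel=1e-12)
        assert value == pytest.approx(30.0, rel=2e-2)
        # the near-identity tightens as the counts grow
        big, _ = recombine(30.0, 150, 30.0, 200)
        assert big == pytest.approx(30.0, rel=2e-3)

    def test_preconditions(self):
        with pytest.raises(ValueError):
            recombine(-1.0, 5, 10.0, 5)
        with pytest.raises(ValueError):
            recombine(10.0, 1, 10.0, 5)


def _toy_table(sid, sdnn_vals, rmssd_vals, ns):
    measures = {}
    for lab in ALL_LABELS:
        s, r, n = sdnn_vals[lab], rmssd_vals[lab], ns[lab]
        measures[lab] = HRVMeasure(
            label=lab, sdnn=s, rmssd=r,
            ln_sdnn=math.log(s), ln_rmssd=math.log(r), n_intervals=n)
    return SubjectHRVTable(subject_id=sid, measures=measures)


def _sampling_tables(n_subjects, n_short, n_total, sigma, seed):
    """Subjects whose segment statistics are sample SDs of a common white
    process: the regime where the part-whole correlation has the closed form
    sqrt((N_short - 1)/(N_total - 1))."""
    rng = np.random.default_rng(seed)
    tables = []
    for k in range(n_subjects):
        x = rng.normal(0.0, sigma, n_total)
        short = x[:n_short]
        vals, ns = {}, {}
        for lab in ALL_LABELS:
            if lab == "total":
                vals[lab], ns[lab] = np.std(x, ddof=1), n_total
            else:
                vals[lab], ns[lab] = np.std(short, ddof=1), n_short
        tables.append(_toy_table(f"S{k}", vals, vals, ns))
    return tables


class TestBootstrapNull:
    def test_seeded_determinism(self, default_run):
        a = bootstrap_null(default_run.tables[:100], "lnSDNN", "10s_1",
                           n_reps=50, seed=3)
        b = bootstrap_null(default_run.tables[:100], "lnSDNN", "10s_1",
                           n_reps=50, seed=3)
        assert a.ref_range_r == b.ref_range_r
        assert a.ref_range_bias == b.ref_range_bias

    def test_single_rep_matches_independent_trace(self, default_run):
        # replay the seeded draws and recompute every statistic with plain
        # numpy formulas, independently of the bootstrap implementation
        tables = default_run.tables[:20]
        res = bootstrap_null(tables, "lnSDNN", "30s", n_reps=1, seed=99)
        pairs, _ = decompose_population(tables, "lnSDNN", "30s")
        sv = np.array([p.short_value for p in pairs])
        sn = np.array([p.short_n for p in pairs])
        rv = np.array([p.remainder_value for p in pairs])
        rn = np.array([p.remainder_n for p in pairs])
        rng = np.random.default_rng(99)
        i = rng.integers(0, len(pairs), size=len(pairs))
        j = rng.integers(0, len(pairs), size=len(pairs))
        s, r = sv[i], rv[j]
        comb = np.sqrt((s**2 * (sn[i] - 1) + r**2 * (rn[j] - 1)) / (sn[i] + rn[j] - 1))
        ls, lt = np.log(s), np.log(comb)
        d = lt - ls
        exp_r = np.corrcoef(lt, ls)[0, 1]
        exp_bias = d.mean()
        exp_hi = exp_bias + 1.96 * d.std(ddof=1)
        exp_d = exp_bias / lt.std(ddof=1)
        assert res.ref_range_r == pytest.approx((exp_r, exp_r))
        assert res.ref_range_bias == pytest.approx((exp_bias, exp_bias))
        assert res.ref_range_loa_high == pytest.approx((exp_hi, exp_hi))
        assert res.ref_range_d == pytest.approx((exp_d, exp_d))

    def test_part_whole_correlation_closed_form(self):
        # homogeneous white-noise subjects: expected null correlation is
        # sqrt((N_short - 1)/(N_total - 1)) ~= 0.174 for 11/331
        tables = _sampling_tables(400, n_short=11, n_total=331, sigma=25.0,
                                  seed=8)
        res = bootstrap_null(tables, "lnSDNN", "10s_1", n_reps=1000, seed=12)
        expected = math.sqrt(10.0 / 330.0)
        lo, hi = res.ref_range_r
        assert lo < expected < hi

    def test_jitter_shrinks_with_reps(self, default_run):
        # Monte-Carlo spread of the range endpoints scales ~ 1/sqrt(n_reps)
        tables = default_run.tables[:50]
        ends = {250: [], 4000: []}
        for n_reps in ends:
            for seed in range(8):
                r = bootstrap_null(tables, "lnSDNN", "30s", n_reps=n_reps,
                                   seed=1000 + seed)
                ends[n_reps].append(r.ref_range_r[1])
        ratio = np.std(ends[250]) / np.std(ends[4000])
        assert 1.5 < ratio < 11.0   # sqrt(16) = 4 expected, wide MC band

    def test_rmssd_drops_are_counted_not_clamped(self, default_run):
        res = bootstrap_null(default_run.tables, "lnRMSSD", "120s",
                             n_reps=10, seed=5)
        assert res.n_dropped >= 0
        assert res.n_subjects + res.n_dropped == len(default_run.tables)

    def test_observed_r_above_null_everywhere(self, default_run):
        # genuine within-subject stability puts the observed correlation far
        # beyond anything part-whole overlap alone can produce
        obs = {(a.metric, a.label): a for a in default_run.agreement}
        for (metric, label), a in obs.items():
            res = bootstrap_null(default_run.tables, metric, label,
                                 n_reps=200, seed=77, observed=a)
            assert res.verdicts["r"] == "above"
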