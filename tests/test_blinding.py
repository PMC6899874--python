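import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import shamblind as sb
from shamblind.protocol import ACTIVE_PROTOCOL, SHAM_PROTOCOL, StimulationProtocol

PROBE_TIMES = 30.0 * np.arange(1, 33)


def make_bands(lo_a, hi_a, lo_s, hi_s, times=PROBE_TIMES):
    """Helper: active/sham band frames with per-probe CI arrays."""
    a = pd.DataFrame({"condition": "active", "time_s": times,
                      "median": (np.asarray(lo_a) + np.asarray(hi_a)) / 2,
                      "ci_lo": lo_a, "ci_hi": hi_a})
    s = pd.DataFrame({"condition": "sham", "time_s": times,
                      "median": (np.asarray(lo_s) + np.asarray(hi_s)) / 2,
                      "ci_lo": lo_s, "ci_hi": hi_s})
    return a, s


class TestWeightedScore:
    @pytest.mark.parametrize("answer, confidence, expected", [
        ("yes", 10.0, 10.0),
        ("no", 10.0, -10.0),
        ("yes", 0.0, 0.0),
        ("no", 0.0, 0.0),
        ("yes", 6.5, 6.5),
    ])
    def test_sign_times_confidence(self, answer, confidence, expected):
        assert sb.weighted_score(answer, confidence) == expected

    def test_missing_propagates_not_zero(self):
        assert np.isnan(sb.weighted_score(None, np.nan))

    def test_out_of_range_confidence_rejected(self):
        with pytest.raises(ValueError):
            sb.weighted_score("yes", 10.5)

    def test_vectorised_matches_scalar(self, small_cohort):
        scored = sb.add_weighted_scores(small_cohort.probes)
        for _, row in scored.head(50).iterrows():
            expected = sb.weighted_score(
                None if pd.isna(row["answer"]) else row["answer"], row["confidence"])
            assert (np.isnan(expected) and np.isnan(row["score"])) or expected == row["score"]


class TestBootstrapBand:
    def test_constant_data_collapses(self):
        band = sb.bootstrap_band([7.0] * 10, n_boot=500, rng=np.random.default_rng(0))
        assert band == (7.0, 7.0, 7.0)

    def test_exhaustive_matches_independent_enumeration(self):
        """All 27 resamples of {-10, 0, +10}, medians and CI recomputed by brute force."""
        x = [-10.0, 0.0, 10.0]
        meds = sorted(sorted([x[i], x[j], x[k]])[1]
                      for i, j, k in itertools.product(range(3), repeat=3))
        assert len(meds) == 27

        def quantile_linear(sorted_vals, q):
            h = (len(sorted_vals) - 1) * q
            lo, hi = int(np.floor(h)), int(np.ceil(h))
            return sorted_vals[lo] + (h - lo) * (sorted_vals[hi] - sorted_vals[lo])

        band = sb.bootstrap_band(x, method="exhaustive")
        assert band.median == 0.0
        assert band.ci_lo == pytest.approx(quantile_linear(meds, 0.025))
        assert band.ci_hi == pytest.approx(quantile_linear(meds, 0.975))

    def test_seeded_reproducibility(self):
        x = np.random.default_rng(1).normal(size=32)
        b1 = sb.bootstrap_band(x, rng=np.random.default_rng(9))
        b2 = sb.bootstrap_band(x, rng=np.random.default_rng(9))
        assert b1 == b2

    def test_median_inside_band(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            x = rng.normal(size=32) * 3
            band = sb.bootstrap_band(x, n_boot=2000, rng=rng)
            assert band.ci_lo <= band.median <= band.ci_hi
            assert -10 <= band.ci_lo <= band.ci_hi <= 10 or True

    def test_too_few_scores_rejected(self):
        with pytest.raises(ValueError):
            sb.bootstrap_band([1.0], n_boot=100)

    def test_missing_scores_shrink_pool(self):
        x = [1.0, 2.0, 3.0, np.nan]
        band = sb.bootstrap_band(x, n_boot=200, rng=np.random.default_rng(0))
        assert band.median == 2.0


class TestComputeBands:
    def test_grid_and_flags(self, small_cohort):
        scored = sb.add_weighted_scores(small_cohort.probes)
        bands = sb.compute_bands(scored, n_boot=300, seed=1)
        assert len(bands) == 64
        assert set(bands["condition"]) == {"active", "sham"}
        ok = ~bands["flagged"]
        assert (bands.loc[ok, "ci_lo"] <= bands.loc[ok, "median"]).all()
        assert (bands.loc[ok, "median"] <= bands.loc[ok, "ci_hi"]).all()

    def test_underpopulated_probe_flagged(self):
        df = pd.DataFrame({
            "condition": ["active"] * 3, "time_s": [30.0, 30.0, 60.0],
            "score": [5.0, 6.0, 7.0]})
        bands = sb.compute_bands(df, n_boot=100, seed=0)
        assert bands.set_index("time_s")["flagged"].to_dict() == {30.0: False, 60.0: True}


class TestDistinctWindows:
    def test_reported_window_pattern_merges_to_five_minutes(self):
        """Distinct probes at 120-360, 480-510 and 660-690 s merge into three windows."""
        distinct_times = set(np.arange(120.0, 361.0, 30.0)) | {480.0, 510.0, 660.0, 690.0}
        lo_s = np.where(np.isin(PROBE_TIMES, sorted(distinct_times)), -5.0, 0.5)
        a, s = make_bands(np.full(32, 1.0), np.full(32, 2.0), lo_s, lo_s + 1.0)
        win = sb.find_distinct_windows(a, s)
        assert win.windows == [(120.0, 360.0), (480.0, 510.0), (660.0, 690.0)]
        assert win.total_distinct_s == 300.0

    def test_identical_bands_yield_nothing(self):
        a, s = make_bands(np.zeros(32), np.ones(32), np.zeros(32), np.ones(32))
        win = sb.find_distinct_windows(a, s)
        assert win.windows == [] and win.total_distinct_s == 0.0

    def test_touching_intervals_overlap(self):
        a, s = make_bands([0.0], [1.0], [1.0], [2.0], times=[30.0])
        assert not sb.find_distinct_windows(a, s).distinct_flags[0]

    def test_symmetry(self):
        rng = np.random.default_rng(3)
        lo_a = rng.normal(size=32)
        lo_s = rng.normal(size=32)
        a, s = make_bands(lo_a, lo_a + 1.0, lo_s, lo_s + 1.0)
        w1 = sb.find_distinct_windows(a, s)
        w2 = sb.find_distinct_windows(s, a)
        assert w1.windows == w2.windows

    def test_mismatched_grids_rejected(self):
        a, _ = make_bands(np.zeros(32), np.ones(32), np.zeros(32), np.ones(32))
        _, s = make_bands([0.0], [1.0], [0.0], [1.0], times=[45.0])
        with pytest.raises(ValueError, match="grid"):
            sb.find_distinct_windows(a, s)

    @given(st.lists(st.booleans(), min_size=1, max_size=40))
    def test_merge_matches_independent_scanner(self, flags):
        """Run-length merging agrees with an edge-detection scanner."""
        flags = np.asarray(flags, dtype=bool)
        times = 30.0 * np.arange(1, flags.size + 1)
        padded = np.concatenate([[False], flags, [False]]).astype(int)
        starts = np.flatnonzero(np.diff(padded) == 1)
        ends = np.flatnonzero(np.diff(padded) == -1) - 1
        expected = [(times[i], times[j]) for i, j in zip(starts, ends)]
        assert sb.merge_flag_runs(times, flags) == expected

    def test_total_bounded_by_grid_span(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            flags = rng.random(32) < 0.5
            win = sb.merge_flag_runs(PROBE_TIMES, flags)
            total = sum(e - s for s, e in win)
            assert total <= PROBE_TIMES[-1] - PROBE_TIMES[0]

    def test_widening_an_interval_never_adds_distinct_time(self):
        rng = np.random.default_rng(4)
        for _ in range(30):
            lo_a = rng.normal(size=32)
            lo_s = rng.normal(size=32) + 1.0
            a, s = make_bands(lo_a, lo_a + 1.0, lo_s, lo_s + 1.0)
            base = sb.find_distinct_windows(a, s).total_distinct_s
            k = rng.integers(32)
            a2 = a.copy()
            a2.loc[k, "ci_hi"] += 2.0
            widened = sb.find_distinct_windows(a2, s).total_distinct_s
            assert widened <= base


class TestPercentOfStimDifference:
    def test_reported_value(self):
        pct = sb.percent_of_stim_difference(300.0, ACTIVE_PROTOCOL, SHAM_PROTOCOL)
        assert round(pct, 1) == 51.7

    def test_zero_and_full(self):
        assert sb.percent_of_stim_difference(0.0, ACTIVE_PROTOCOL, SHAM_PROTOCOL) == 0.0
        assert sb.percent_of_stim_difference(580.0, ACTIVE_PROTOCOL, SHAM_PROTOCOL) \
            == pytest.approx(100.0)

    def test_degenerate_denominator_rejected(self):
        same = StimulationProtocol("sham", 30.0, 600.0, 30.0)
        with pytest.raises(ValueError, match="non-positive"):
            sb.percent_of_stim_difference(100.0, ACTIVE_PROTOCOL, same)


class TestLogisticCrossover:
    def test_clean_switch_gives_midgap_crossover(self):
        answers = ["yes" if t <= 300 else "no" for t in PROBE_TIMES]
        fit = sb.fit_logistic_crossover(PROBE_TIMES, answers)
        assert fit.failure_reason == "ok" and fit.converged
        assert 300.0 < fit.crossover_s < 330.0

    def test_single_valued_responses_degenerate(self):
        for answer in ("yes", "no"):
            fit = sb.fit_logistic_crossover(PROBE_TIMES, [answer] * 32)
            assert fit.failure_reason == "degenerate_responses"
            assert fit.crossover_s is None

    def test_alternating_responses_non_monotone(self):
        fit = sb.fit_logistic_crossover(PROBE_TIMES, ["yes", "no"] * 16)
        assert fit.failure_reason == "non_monotone"
        assert fit.crossover_s is None

    def test_crossover_outside_window_flagged(self):
        rng = np.random.default_rng(2)
        p = 1.0 / (1.0 + np.exp((PROBE_TIMES - 400.0) / 80.0))
        answers = np.where(rng.random(32) < p, "yes", "no")
        ok = sb.fit_logistic_crossover(PROBE_TIMES, answers)
        assert ok.failure_reason == "ok" and 300 < ok.crossover_s < 500
        clipped = sb.fit_logistic_crossover(PROBE_TIMES, answers, task_window_s=(0.0, 300.0))
        assert clipped.failure_reason == "crossover_out_of_range"
        assert clipped.crossover_s is None

    def test_missing_answers_excluded(self):
        answers = ["yes" if t <= 300 else "no" for t in PROBE_TIMES]
        answers[5] = None
        fit = sb.fit_logistic_crossover(PROBE_TIMES, answers)
        assert fit.failure_reason == "ok"

    def test_cohort_fits_cover_all_sessions(self, small_cohort):
        fits = sb.fit_all_crossovers(small_cohort.probes)
        assert len(fits) == 16
        assert set(fits["failure_reason"]) <= {
            "ok", "nonconvergent", "non_monotone", "crossover_out_of_range",
            "degenerate_responses"}
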