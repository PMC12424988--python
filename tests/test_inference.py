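"""Statistical machinery: splits, cross-validation, nulls, FDR, behavior."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from eventscales import (
    SyntheticConfig,
    bh_fdr,
    brain_behavior,
    change_statistic,
    conjunction,
    filter_reliable_searchlights,
    fit_null_normal,
    paired_recall_test,
    segment_shuffle_null,
    simulate_cohort,
    split_participants,
    upper_tail_p,
    viewing_shuffle_null,
    wvb_crossval,
    wvb_similarity,
    timepoint_corr_matrix,
)
from eventscales.inference import classify_direction, count_distinct_orderings


class TestSplits:
    def test_disjoint_cover_and_sizes(self):
        rng = np.random.default_rng(0)
        (a, b), = split_participants(np.arange(4), np.zeros(4, int), 1, rng)
        assert sorted(np.concatenate([a, b])) == [0, 1, 2, 3]
        assert len(a) == len(b) == 2

    def test_stratified_within_group(self):
        rng = np.random.default_rng(1)
        groups = np.array([0, 0, 1, 1])
        for a, b in split_participants(np.arange(4), groups, 5, rng):
            assert sorted(groups[a]) == [0, 1]
            assert sorted(groups[b]) == [0, 1]

    def test_deterministic_given_seed(self):
        s1 = split_participants(np.arange(8), np.arange(8) % 2, 3, np.random.default_rng(9))
        s2 = split_participants(np.arange(8), np.arange(8) % 2, 3, np.random.default_rng(9))
        for (a1, b1), (a2, b2) in zip(s1, s2):
            np.testing.assert_array_equal(a1, a2)
            np.testing.assert_array_equal(b1, b2)

    def test_tiny_group_rejected(self):
        with pytest.raises(ValueError):
            split_participants(np.arange(3), np.array([0, 0, 1]), 1, np.random.default_rng(0))


class TestCrossval:
    def test_equals_single_matrix_wvb_without_variability(self):
        cfg = SyntheticConfig(
            n_participants=4, n_groups=1, n_clips=1, n_viewings=1,
            n_timepoints=24, n_voxels=40, true_event_counts=2,
            noise_sd=0.0, participant_sd=0.0, seed=11,
        )
        ds, truth = simulate_cohort(cfg)
        rng = np.random.default_rng(0)
        splits = split_participants(np.arange(4), ds.groups, 2, rng)
        value = wvb_crossval(ds.data[:, 0, 0], ds.groups, splits, K=2, lag=5)
        from eventscales import fit_event_hmm

        single = ds.data[0, 0, 0]
        seg = fit_event_hmm(single, 2)
        direct = wvb_similarity(timepoint_corr_matrix(single), seg.boundaries, 5).value
        assert value == pytest.approx(direct, abs=1e-10)

    def test_invariant_to_participant_relabeling(self):
        cfg = SyntheticConfig(
            n_participants=6, n_groups=1, n_clips=1, n_viewings=1,
            n_timepoints=24, n_voxels=30, true_event_counts=2,
            noise_sd=0.3, seed=12,
        )
        ds, _ = simulate_cohort(cfg)
        data = ds.data[:, 0, 0]
        splits = [(np.array([0, 1, 2]), np.array([3, 4, 5]))]
        v1 = wvb_crossval(data, ds.groups, splits, K=2, lag=5)
        perm = np.array([3, 4, 5, 0, 1, 2])
        splits_perm = [(np.array([3, 4, 5]), np.array([0, 1, 2]))]
        v2 = wvb_crossval(data[perm], ds.groups, splits_perm, K=2, lag=5)
        assert v1 == pytest.approx(v2, abs=1e-12)


class TestSegmentShuffleNull:
    @pytest.mark.parametrize(
        "lengths, expected",
        [((2, 3, 5), 5), ((3, 3, 4), 2), ((2, 3, 4, 5), 23)],
    )
    def test_null_ordering_counts(self, lengths, expected, rng):
        T = sum(lengths)
        corr = np.corrcoef(rng.standard_normal((T, T + 10)))
        values = segment_shuffle_null(lengths, corr, lag=2, max_perm=50, rng=rng)
        assert len(values) == expected

    def test_equal_lengths_yield_empty_null(self, rng):
        corr = np.corrcoef(rng.standard_normal((9, 20)))
        values = segment_shuffle_null((3, 3, 3), corr, lag=2, max_perm=50, rng=rng)
        assert len(values) == 0

    def test_sampling_branch_caps_at_max_perm(self, rng):
        lengths = (3, 4, 5, 6, 7, 8, 9, 10)  # 8! - 1 distinct null orderings
        assert count_distinct_orderings(lengths) == 40320
        T = sum(lengths)
        corr = np.corrcoef(rng.standard_normal((T, T + 5)))
        values = segment_shuffle_null(lengths, corr, lag=5, max_perm=50, rng=rng)
        assert len(values) == 50

    def test_null_values_below_real_on_planted_data(self, rng):
        from eventscales import fit_event_hmm, make_event_patterns, simulate_timecourse

        P = make_event_patterns(3, 60, rng)
        x = simulate_timecourse(P, [4, 12, 8], 0.2, rng)
        seg = fit_event_hmm(x, 3)
        corr = timepoint_corr_matrix(x)
        real = wvb_similarity(corr, seg.boundaries, 5).value
        nulls = segment_shuffle_null(seg.segment_lengths(), corr, 5, 50, rng)
        assert real > np.percentile(nulls, 95)


class TestNullNormal:
    def test_moments(self):
        null = fit_null_normal([-1.0, 0.0, 1.0])
        assert null.mu == 0.0 and null.sigma == 1.0 and null.n_values == 3

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError):
            fit_null_normal([0.5, 0.5, 0.5])
        with pytest.raises(ValueError):
            fit_null_normal([0.5])

    def test_recovers_generating_parameters(self):
        r = np.random.default_rng(3)
        vals = r.normal(0.2, 0.05, size=5000)
        null = fit_null_normal(vals)
        assert null.mu == pytest.approx(0.2, abs=3 * 0.05 / np.sqrt(5000))
        assert null.sigma == pytest.approx(0.05, rel=0.05)

    def test_upper_tail_p(self):
        null = fit_null_normal([-1.0, 0.0, 1.0])
        assert upper_tail_p(0.0, null) == pytest.approx(0.5)
        assert upper_tail_p(1.6448536, null) == pytest.approx(0.05, abs=1e-6)
        assert upper_tail_p(3.0, null) < upper_tail_p(2.0, null)


class TestFilter:
    def _table(self, p_map):
        rows = []
        for (sl, viewing), (value, p) in p_map.items():
            rows.append(
                {"searchlight_id": sl, "clip": 0, "viewing": viewing,
                 "K": 2, "value": value, "p": p}
            )
        return pd.DataFrame(rows)

    def test_requires_every_viewing_significant_somewhere(self):
        entries = {(0, v): (0.5, 0.01) for v in range(1, 7)}
        entries.update({(1, v): (0.5, 0.01) for v in range(1, 7)})
        entries[(1, 4)] = (0.5, 0.2)  # one viewing fails at every K
        retained = filter_reliable_searchlights(
            self._table(entries), alpha=0.05, n_viewings=6
        )
        assert retained[0] == [0]

    def test_positive_value_required(self):
        table = self._table({(0, v): (-0.5, 0.001) for v in range(1, 7)})
        retained = filter_reliable_searchlights(table, alpha=0.05, n_viewings=6)
        assert retained[0] == []

    def test_missing_viewing_drops_searchlight(self):
        table = self._table({(0, v): (0.5, 0.01) for v in range(1, 6)})
        retained = filter_reliable_searchlights(table, alpha=0.05, n_viewings=6)
        assert retained[0] == []


class TestChangeStatistic:
    def test_examples_and_shift_invariance(self):
        assert change_statistic([0.1, 0.2, 0.2, 0.2, 0.2, 0.2]) == pytest.approx(0.1)
        assert change_statistic([0.3] * 6) == 0.0
        v = np.array([0.1, 0.25, 0.2, 0.15, 0.3, 0.2])
        assert change_statistic(v + 5.0) == pytest.approx(change_statistic(v))

    def test_missing_viewing_gives_nan(self):
        assert np.isnan(change_statistic([0.1, np.nan, 0.2, 0.2, 0.2, 0.2]))


class TestViewingShuffle:
    def test_p_is_one_when_real_matches_null_mean(self):
        data = np.random.default_rng(0).standard_normal((3, 6, 4, 10))
        res = viewing_shuffle_null(
            data, lambda d: 0.7, n_null=20, rng=np.random.default_rng(1)
        )
        # constant statistic -> degenerate null, flagged
        assert res.degenerate.all()
        res2 = viewing_shuffle_null(
            data,
            lambda d: float(d[:, 0].mean()),
            n_null=30,
            rng=np.random.default_rng(2),
        )
        assert 0 < res2.p[0] <= 1

    def test_per_participant_permutation_preserves_content(self):
        # permuting viewing order never changes the pooled sample of values,
        # so a permutation-invariant statistic has a constant null
        rng = np.random.default_rng(5)
        data = rng.standard_normal((4, 6, 3, 8))
        stat = lambda d: float(np.sort(d.reshape(-1))[0])  # noqa: E731
        res = viewing_shuffle_null(data, stat, n_null=10, rng=np.random.default_rng(6))
        assert np.allclose(res.null_values, res.real[0])


class TestBHFDR:
    @staticmethod
    def brute_force_bh(p, q):
        p = np.asarray(p)
        m = len(p)
        order = np.argsort(p, kind="stable")
        reject = np.zeros(m, dtype=bool)
        kmax = 0
        for i, idx in enumerate(order, start=1):
            if p[idx] <= i / m * q:
                kmax = i
        reject[order[:kmax]] = True
        return reject

    def test_step_up_example(self):
        q, reject = bh_fdr([0.01, 0.02, 0.04, 0.05], q=0.05)
        assert reject.all()

    def test_all_ones_rejected_nothing(self):
        _, reject = bh_fdr([1.0, 1.0, 1.0], q=0.05)
        assert not reject.any()

    def test_matches_brute_force_on_random_vectors(self):
        r = np.random.default_rng(4)
        for _ in range(200):
            m = int(r.integers(1, 40))
            p = r.uniform(1e-6, 1.0, size=m)
            _, reject = bh_fdr(p, q=0.05)
            np.testing.assert_array_equal(reject, self.brute_force_bh(p, 0.05))

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.0, 0.5])


class TestConjunction:
    def _tables(self, signs, ps):
        tables = {}
        for c in range(3):
            tables[c] = pd.DataFrame(
                {
                    "searchlight_id": [0],
                    "delta_slow": [signs[c] * 0.2],
                    "delta_fast": [0.0],
                    "p_slow": [ps[c]],
                    "p_fast": [1.0],
                }
            )
        return tables

    def test_consistent_significant_gain_flagged(self):
        out = conjunction(self._tables([1, 1, 1], [0.01, 0.01, 0.01]))
        assert len(out) == 1
        assert out.iloc[0]["direction"] == "gain"
        assert out.iloc[0]["timescale"] == "slow"

    def test_never_flags_sign_inconsistent(self):
        # exhaustive over all non-constant sign patterns
        for pattern in [(1, 1, -1), (1, -1, 1), (-1, 1, 1),
                        (-1, -1, 1), (-1, 1, -1), (1, -1, -1)]:
            out = conjunction(self._tables(list(pattern), [0.001] * 3))
            assert len(out) == 0

    def test_not_flagged_when_one_clip_not_significant(self):
        out = conjunction(self._tables([1, 1, 1], [0.01, 0.01, 0.9]))
        assert len(out) == 0


class TestDirectionClassification:
    @pytest.mark.parametrize(
        "ds, df, ss, sf, expected",
        [
            (0.2, 0.0, True, False, "coarser"),
            (0.0, -0.2, False, True, "coarser"),
            (-0.2, 0.0, True, False, "finer"),
            (0.0, 0.2, False, True, "finer"),
            (0.2, 0.2, True, True, "mixed"),
            (0.2, 0.2, False, False, "none"),
        ],
    )
    def test_mapping(self, ds, df, ss, sf, expected):
        assert classify_direction(ds, df, ss, sf) == expected


class TestBrainBehavior:
    def test_perfect_negative_line(self):
        rng = np.random.default_rng(0)
        x = np.linspace(0, 1, 12)
        y = 30 - 10 * x
        slope, r, p = brain_behavior(x, y, n_boot=1000, rng=rng)
        assert slope == pytest.approx(-10.0)
        assert r == pytest.approx(-1.0)
        assert p <= 2 / 1000

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            brain_behavior(np.ones(10), np.arange(10.0), n_boot=1000)

    def test_small_n_and_small_boot_rejected(self):
        with pytest.raises(ValueError):
            brain_behavior(np.arange(4.0), np.arange(4.0), n_boot=1000)
        with pytest.raises(ValueError):
            brain_behavior(np.arange(10.0), np.arange(10.0), n_boot=10)

    def test_robust_option_resists_outlier(self):
        rng = np.random.default_rng(1)
        x = np.linspace(0, 1, 20)
        y = 2.0 * x + 0.01 * rng.standard_normal(20)
        y[-1] += 50
        slope_ols, _, _ = brain_behavior(x, y, n_boot=1000, rng=np.random.default_rng(2))
        slope_rob, _, _ = brain_behavior(
            x, y, n_boot=1000, rng=np.random.default_rng(2), robust=True
        )
        assert abs(slope_rob - 2.0) < abs(slope_ols - 2.0)


class TestPairedRecall:
    def test_identical_columns(self):
        res = paired_recall_test(np.arange(5.0), np.arange(5.0))
        assert res.t == 0.0 and res.p == 1.0

    def test_constant_nonzero_difference_degenerate(self):
        with pytest.raises(ValueError):
            paired_recall_test(np.arange(5.0) + 2.0, np.arange(5.0))

    def test_matches_closed_form(self):
        rng = np.random.default_rng(8)
        a = rng.normal(25, 10, 30)
        b = rng.normal(21, 10, 30)
        res = paired_recall_test(a, b)
        d = a - b
        t = d.mean() / (d.std(ddof=1) / np.sqrt(30))
        p = 2 * stats.t.sf(abs(t), df=29)
        half = stats.t.ppf(0.975, 29) * d.std(ddof=1) / np.sqrt(30)
        assert res.t == pytest.approx(t, abs=1e-10)
        assert res.p == pytest.approx(p, abs=1e-10)
        assert res.ci_low == pytest.approx(d.mean() - half, abs=1e-10)
        assert res.ci_high == pytest.approx(d.mean() + half, abs=1e-10)
        assert res.df == 29


class TestSplitCohortReliability:
    @staticmethod
    def _data(noise, seed, n_sl=4):
        from eventscales import SyntheticConfig, simulate_cohort

        out = {}
        groups = None
        for sl in range(n_sl):
            cfg = SyntheticConfig(
                n_participants=8, n_groups=1, n_clips=1, n_viewings=2,
                n_timepoints=24, n_voxels=25, true_event_counts=2 + sl % 2,
                noise_sd=noise, participant_sd=min(noise, 0.3),
                seed=seed + sl,
            )
            ds, _ = simulate_cohort(cfg)
            out[sl] = ds.data[:, 0]  # (n, n_viewings, V, T)
            groups = ds.groups
        return out, groups

    def test_perfect_halves_give_unit_correlation(self):
        from eventscales import split_cohort_reliability

        data, groups = self._data(noise=0.0, seed=50)
        r = split_cohort_reliability(
            data, groups, Ks=(2, 3), lag=5, n_splits=1,
            rng=np.random.default_rng(0),
        )
        assert np.all(r > 0.999)

    def test_reliability_decreases_with_noise(self):
        from eventscales import split_cohort_reliability

        means = []
        for noise in (0.2, 2.0):
            data, groups = self._data(noise=noise, seed=60)
            r = split_cohort_reliability(
                data, groups, Ks=(2, 3), lag=5, n_splits=2,
                rng=np.random.default_rng(1),
            )
            means.append(np.nanmean(r))
        assert means[0] > means[1]

    def test_too_few_participants_rejected(self):
        from eventscales import split_cohort_reliability

        with pytest.raises(ValueError):
            split_cohort_reliability(
                {0: np.zeros((4, 2, 10, 12))}, np.zeros(4, int), Ks=(2,),
                rng=np.random.default_rng(0),
            )
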