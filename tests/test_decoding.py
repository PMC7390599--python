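import numpy as np
import pytest

from valuedyn.decoding import (
    CTDResult,
    DecoderConfig,
    RidgeOvO,
    aggregate_pvalues,
    class_pairs,
    cross_temporal_decode,
    decode_standard,
    make_folds,
    ovo_vote,
    permutation_test,
    subsample_match,
    tune_lambda,
)


class TestOvO:
    @pytest.mark.parametrize("n_classes,n_pairs", [(2, 1), (3, 3), (4, 6)])
    def test_pair_count(self, n_classes, n_pairs):
        assert len(class_pairs(n_classes)) == n_pairs

    def test_separable_toy_problem_is_perfectly_classified(self, rng):
        # two units whose rates encode class identity linearly
        y = np.repeat([0, 1, 2, 3], 25)
        X = np.column_stack([y + rng.normal(0, 0.05, 100),
                             -y + rng.normal(0, 0.05, 100)])
        clf = RidgeOvO(lam=1e-3).fit(X, y)
        assert np.mean(clf.predict(X) == y) == 1.0

    def test_two_class_problem_uses_one_classifier(self, rng):
        y = np.repeat([0, 1], 20)
        X = y[:, None] + rng.normal(0, 0.1, (40, 1))
        clf = RidgeOvO(lam=1e-3).fit(X, y)
        assert clf.W_.shape[1] == 1

    def test_vote_tie_broken_by_summed_margins(self):
        pairs = class_pairs(3)  # (0,1), (0,2), (1,2)
        # class 0 beats 1, class 2 beats 0, class 1 beats 2: one vote each;
        # margins decide: class 2 has the largest summed signed margin
        scores = np.array([[0.1, -2.0, 0.3]])
        pred = ovo_vote(scores, pairs, 3)
        assert pred[0] == 2

    def test_full_tie_falls_back_to_lowest_class_index(self):
        pairs = class_pairs(3)
        # one vote per class and all summed margins zero: lowest index wins
        scores = np.array([[1.0, -1.0, 1.0]])
        assert ovo_vote(scores, pairs, 3)[0] == 0

    def test_missing_training_class_rejected(self, rng):
        y = np.repeat([0, 1], 10)
        X = rng.normal(size=(20, 3))
        clf = RidgeOvO(lam=1.0)
        with pytest.raises(ValueError):
            clf.fit(X, np.zeros(20, dtype=int))


class TestLambdaTuning:
    def test_grid_has_fifteen_values(self):
        assert len(DecoderConfig().lambda_grid) == 15
        assert DecoderConfig().lambda_grid[0] == pytest.approx(1e-2)
        assert DecoderConfig().lambda_grid[-1] == pytest.approx(1e5)

    def test_separable_data_ties_resolve_to_smallest_lambda(self, rng):
        # widely separated classes: accuracy is 1 for every small lambda
        y = np.repeat([1, 2, 3, 4], 16)
        cond = np.repeat(np.arange(8), 8)
        X = (10.0 * y[:, None] + rng.normal(0, 0.01, (64, 2)))[:, :, None]
        X = np.repeat(X, 3, axis=2)
        cfg = DecoderConfig(n_inner_folds=2)
        lam = tune_lambda(X, y, cond, np.arange(3), cfg, seed=0)
        grid = cfg.lambda_grid
        accs_flat_region = grid[grid <= lam]
        assert lam == grid[0] or len(accs_flat_region) <= 3  # smallest-lambda rule

    def test_tuning_deterministic(self, strong_stable_rm):
        rm = strong_stable_rm
        y = rm.values.astype(int)
        cond = rm.condition_labels()
        cfg = DecoderConfig()
        bins = np.arange(3)
        a = tune_lambda(rm.rates, y, cond, bins, cfg, seed=5)
        b = tune_lambda(rm.rates, y, cond, bins, cfg, seed=5)
        assert a == b


class TestCTD:
    def test_diagonal_equals_standard_decoding_exactly(self, strong_stable_rm, task):
        rm = strong_stable_rm
        delay = np.flatnonzero(rm.window_mask(*task.delay))
        cfg = DecoderConfig()
        full = cross_temporal_decode(rm, cfg, seed=3, train_bins=delay, test_bins=delay)
        std = decode_standard(rm, cfg, seed=3, lam=full.meta["lam"], bins=delay)
        assert np.array_equal(std.accuracy.diagonal(), full.diagonal)

    def test_stable_code_generalizes_across_the_delay(self, strong_stable_rm, task):
        rm = strong_stable_rm
        delay = np.flatnonzero(rm.window_mask(*task.delay))
        res = cross_temporal_decode(rm, DecoderConfig(), seed=4,
                                    train_bins=delay, test_bins=delay)
        diag = np.mean(res.diagonal)
        off = res.accuracy[~np.eye(len(delay), dtype=bool)].mean()
        assert diag > 0.9
        assert off > diag - 0.1  # time-invariant code: off-diagonal ~ diagonal

    def test_sequential_code_is_diagonal_concentrated(self, sequential_rm, task):
        rm = sequential_rm
        delay = np.flatnonzero(rm.window_mask(*task.delay))
        res = cross_temporal_decode(rm, DecoderConfig(), seed=5,
                                    train_bins=delay, test_bins=delay)
        tt = rm.bin_times_abs[delay]
        far = np.abs(tt[:, None] - tt[None, :]) > 0.5
        assert np.mean(res.diagonal) - res.accuracy[far].mean() > 0.2

    def test_shuffled_labels_decode_at_chance(self, strong_stable_rm, task, rng):
        rm = strong_stable_rm
        perm = rng.permutation(rm.n_trials)
        shuffled = type(rm)(
            rates=rm.rates[perm], bin_times=rm.bin_times,
            bin_times_abs=rm.bin_times_abs, epoch_ids=rm.epoch_ids,
            values=rm.values, types=rm.types, unit_ids=rm.unit_ids,
            meta=dict(rm.meta),
        )
        delay = np.flatnonzero(rm.window_mask(*task.delay))
        res = cross_temporal_decode(shuffled, DecoderConfig(), seed=6, lam=10.0,
                                    train_bins=delay, test_bins=delay)
        acc = res.accuracy.mean()
        # binomial-scale 3 SE band on the grand mean (pairs correlated; the
        # per-pair SE is an upper bound for the mean's)
        se = np.sqrt(0.25 * 0.75 / (rm.n_trials / 5 * 5))
        assert abs(acc - 0.25) < 3 * se

    def test_accuracy_bounded_and_reproducible(self, rm_coarse):
        cfg = DecoderConfig()
        bins = np.arange(0, rm_coarse.n_bins, 4)
        a = cross_temporal_decode(rm_coarse, cfg, seed=7, lam=1.0, train_bins=bins)
        b = cross_temporal_decode(rm_coarse, cfg, seed=7, lam=1.0, train_bins=bins)
        assert np.array_equal(a.accuracy, b.accuracy)
        assert np.all((a.accuracy >= 0) & (a.accuracy <= 1))


class TestPermutations:
    def test_boundary_pvalues(self, strong_stable_rm, task):
        rm = strong_stable_rm
        delay = np.flatnonzero(rm.window_mask(*task.delay))[:3]
        cfg = DecoderConfig()
        obs = cross_temporal_decode(rm, cfg, seed=8, lam=10.0,
                                    train_bins=delay, test_bins=delay)
        p = permutation_test(rm, obs, cfg, n_perm=20, seed=9)
        # strong planted signal beats every label shuffle
        assert np.all(p == 0.0)
        # an observed accuracy below every permutation gives p = 1
        fake = CTDResult(accuracy=np.full_like(obs.accuracy, -1.0),
                         train_times=obs.train_times, test_times=obs.test_times,
                         meta=obs.meta)
        p1 = permutation_test(rm, fake, cfg, n_perm=20, seed=9)
        assert np.all(p1 == 1.0)

    def test_aggregation_rule(self):
        assert aggregate_pvalues([0.002] * 5) == pytest.approx(0.004)
        assert aggregate_pvalues([1.0] * 5) == 1.0
        assert aggregate_pvalues([0, 0, 0, 0, 0.05]) == pytest.approx(0.02)

    def test_aggregation_monotone_in_each_input(self, rng):
        base = rng.uniform(0, 1, 5)
        p0 = aggregate_pvalues(base)
        for i in range(5):
            worse = base.copy()
            worse[i] = min(1.0, worse[i] + 0.1)
            assert aggregate_pvalues(worse) >= p0

    def test_aggregation_rejects_invalid_pvalues(self):
        with pytest.raises(ValueError):
            aggregate_pvalues([0.1, 1.2, 0.3, 0.4, 0.5])


class TestSubsampling:
    def test_full_size_reproduces_original_curve(self, strong_stable_rm, task):
        rm = strong_stable_rm
        bins = np.flatnonzero(rm.window_mask(*task.delay))[:4]
        cfg = DecoderConfig()
        direct = decode_standard(rm, cfg, seed=10, lam=10.0, bins=bins)
        curve = subsample_match(rm, rm.n_units, n_draws=3, seed=10, config=cfg,
                                lam=10.0, bins=bins)
        assert np.array_equal(curve, direct.diagonal)

    def test_subsamples_decode_no_better_than_full_population(
            self, strong_stable_rm, task):
        rm = strong_stable_rm
        bins = np.flatnonzero(rm.window_mask(*task.delay))[:4]
        cfg = DecoderConfig()
        full = decode_standard(rm, cfg, seed=11, lam=10.0, bins=bins).diagonal
        sub = subsample_match(rm, rm.n_units // 2, n_draws=8, seed=11, config=cfg,
                              lam=10.0, bins=bins)
        assert sub.mean() <= full.mean() + 0.02

    def test_oversized_target_rejected(self, rm_coarse):
        with pytest.raises(ValueError):
            subsample_match(rm_coarse, rm_coarse.n_units + 1)

    def test_fixed_seed_reproducible(self, rm_coarse, task):
        bins = np.flatnonzero(rm_coarse.window_mask(*task.delay))[:3]
        a = subsample_match(rm_coarse, 6, n_draws=2, seed=3, lam=1.0, bins=bins)
        b = subsample_match(rm_coarse, 6, n_draws=2, seed=3, lam=1.0, bins=bins)
        assert np.array_equal(a, b)
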