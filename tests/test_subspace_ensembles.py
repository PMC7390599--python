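import itertools

import numpy as np
import pytest

from valuedyn.decoding import DecoderConfig
from valuedyn.subspace import build_value_subspace, subspace_ctd
from valuedyn.ensembles import (
    EnsembleTrace,
    NaiveObjective,
    RawRidgeObjective,
    StableSubspaceObjective,
    ac_transform,
    accuracy_contribution,
    default_sigma_bounds,
    ensemble_overlap_test,
    fit_locality_gaussian,
    fit_locality_gaussian_grid,
    greedy_backward_ensemble,
    hypergeom_enrichment,
    locality_score,
    stability_score,
)


class TestValueSubspace:
    def test_four_values_give_three_components(self, rng):
        rates = rng.normal(5, 1, size=(80, 12, 6))
        values = np.repeat([1, 2, 3, 4], 20)
        model = build_value_subspace(rates, values)
        assert model.components.shape == (3, 12)
        # orthonormal rows
        assert np.allclose(model.components @ model.components.T, np.eye(3),
                           atol=1e-10)

    def test_identical_class_means_flagged_degenerate(self):
        rates = np.ones((40, 6, 4))
        values = np.repeat([1, 2, 3, 4], 10)
        model = build_value_subspace(rates, values)
        assert model.degenerate

    def test_hand_computed_orthogonal_geometry(self):
        # each value drives its own unit: class means = 5*I (4 units)
        values = np.repeat([1, 2, 3, 4], 2)
        rates = np.zeros((8, 4))
        for t, v in enumerate(values):
            rates[t, v - 1] = 5.0
        model = build_value_subspace(rates, values)
        Z = model.class_means @ model.components.T  # (4 classes, 3)
        d = [np.linalg.norm(Z[i] - Z[j]) for i, j in
             itertools.combinations(range(4), 2)]
        # a regular simplex: all pairwise distances equal 5*sqrt(2)
        assert np.allclose(d, 5 * np.sqrt(2), atol=1e-8)

    def test_projection_shapes(self, rng):
        rates = rng.normal(size=(30, 7, 5))
        values = np.tile([1, 2, 3], 10)
        model = build_value_subspace(rates, values, n_components=2)
        assert model.project(rates[:, :, 0]).shape == (30, 2)
        assert model.project(rates).shape == (30, 2, 5)


class TestSubspaceCTD:
    def test_chance_level_on_shuffled_labels(self, untuned_rm, task):
        rm = untuned_rm
        delay = np.flatnonzero(rm.window_mask(*task.delay))
        res, _ = subspace_ctd(rm, DecoderConfig(), seed=2, lam=10.0,
                              train_bins=delay, test_bins=delay)
        se = np.sqrt(0.25 * 0.75 / (rm.n_trials / 5 * 5))
        assert abs(res.accuracy.mean() - 0.25) < 3.5 * se

    def test_stable_population_decodes_everywhere_in_delay(
            self, strong_stable_rm, task):
        rm = strong_stable_rm
        delay = np.flatnonzero(rm.window_mask(*task.delay))
        res, p = subspace_ctd(rm, DecoderConfig(), seed=3,
                              train_bins=delay, test_bins=delay, n_perm=30)
        assert res.accuracy.min() > 0.9
        assert np.all(p == 0.0)

    def test_training_label_permutations_kill_signal(self, strong_stable_rm, task):
        rm = strong_stable_rm
        delay = np.flatnonzero(rm.window_mask(*task.delay))[:4]
        res, p = subspace_ctd(rm, DecoderConfig(), seed=4, lam=10.0,
                              train_bins=delay, test_bins=delay, n_perm=10)
        assert p.shape == res.accuracy.shape

    def test_leaking_subspace_inflates_noise_accuracy(self, task):
        # on untuned data the honest split/swap protocol stays at chance;
        # a subspace whose fit shares trials with decoder training AND
        # testing couples their class-mean noise and inflates accuracy
        from valuedyn.syndata import sample_population, generate_session
        from valuedyn.prep import bin_session
        t2 = type(task)(trials_per_condition=8)
        specs = sample_population({"untuned": 60}, seed=91, task=t2)
        rm = bin_session(generate_session(specs, t2, seed=92),
                         bin_width=0.2, step=0.2)
        delay = np.flatnonzero(rm.window_mask(*t2.delay))
        honest, _ = subspace_ctd(rm, DecoderConfig(), seed=5, lam=10.0,
                                 train_bins=delay, test_bins=delay)
        leaky, _ = subspace_ctd(rm, DecoderConfig(), seed=5, lam=10.0,
                                train_bins=delay, test_bins=delay,
                                leak_subspace_on_test=True)
        assert abs(honest.accuracy.mean() - 0.25) < 0.03
        assert leaky.accuracy.mean() > honest.accuracy.mean() + 0.05


class TestScores:
    def test_stability_score_arithmetic(self):
        acc = np.full((4, 4), 0.25)
        np.fill_diagonal(acc, 1.0)
        assert stability_score(acc) == pytest.approx((4 * 1.0 + 12 * 0.25) / 16)
        assert stability_score(np.full((3, 5), 0.25)) == pytest.approx(0.25)

    def test_stability_score_empty_window_rejected(self):
        with pytest.raises(ValueError):
            stability_score(np.ones((3, 3)), train_window=np.zeros(3, bool))

    def test_flat_chance_rows_give_zero_locality(self):
        tt = np.linspace(0, 2.4, 25)
        acc = np.full((5, 25), 0.25)
        lm = locality_score(acc, tt[::5], tt)
        assert lm == pytest.approx(0.0, abs=1e-6)

    def test_locality_grows_as_peak_narrows(self):
        tt = np.linspace(0, 2.4, 49)
        mus = tt[::8]
        lms = []
        for width in (0.6, 0.3, 0.1):
            acc = 0.25 + 0.6 * np.exp(
                -0.5 * ((tt[None, :] - mus[:, None]) / width) ** 2)
            lms.append(locality_score(acc, mus, tt))
        assert lms[0] < lms[1] < lms[2]

    def test_broad_plateau_scores_below_narrow_peak(self):
        tt = np.linspace(0, 2.4, 49)
        mu = np.array([1.2])
        peak = 0.25 + 0.55 * np.exp(-0.5 * ((tt - 1.2) / 0.08) ** 2)
        plateau = np.full_like(tt, 0.25)
        plateau[np.abs(tt - 1.2) < 0.9] = 0.8
        lm_peak = locality_score(peak[None, :], mu, tt)
        lm_plateau = locality_score(plateau[None, :], mu, tt)
        assert lm_plateau < lm_peak

    def test_profile_fit_recovers_known_gaussian(self):
        tt = np.linspace(0, 2.4, 49)
        a_true, s_true, mu = 0.5, 0.35, 1.0
        row = 0.25 + a_true * np.exp(-0.5 * ((tt - mu) / s_true) ** 2)
        fit = fit_locality_gaussian(row, tt, mu)
        assert fit["a"] == pytest.approx(a_true, rel=1e-3)
        assert fit["sigma"] == pytest.approx(s_true, rel=1e-3)

    def test_profile_fit_matches_grid_search_oracle(self, rng):
        tt = np.linspace(0, 2.4, 49)
        for trial in range(5):
            mu = float(rng.uniform(0.3, 2.1))
            a = float(rng.uniform(0.1, 0.7))
            s = float(rng.uniform(0.1, 1.0))
            row = (0.25 + a * np.exp(-0.5 * ((tt - mu) / s) ** 2)
                   + rng.normal(0, 0.02, tt.shape))
            fast = fit_locality_gaussian(row, tt, mu)
            grid = fit_locality_gaussian_grid(row, tt, mu)
            assert fast["sigma"] == pytest.approx(grid["sigma"], rel=0.02, abs=0.01)
            assert fast["a"] == pytest.approx(grid["a"], rel=0.05, abs=0.01)


class TestGreedy:
    def test_trace_length_and_selected_score(self):
        rng = np.random.default_rng(0)
        quality = rng.normal(size=10)
        obj = NaiveObjective(lambda idx: quality[idx].sum(), 10)
        trace = greedy_backward_ensemble(obj)
        assert len(trace.removal_order) == 9
        assert len(trace.scores) == 10
        assert trace.scores[trace.selected_step] >= trace.scores[0]
        # additive objective: greedy keeps exactly the positive units
        assert set(trace.selected_units) == set(np.flatnonzero(quality > 0))

    def test_greedy_matches_exhaustive_on_small_populations(self, rng):
        # non-additive random interaction objectives, 8 units
        for trial in range(3):
            q = rng.normal(size=8)
            inter = rng.normal(scale=0.3, size=(8, 8))
            inter = (inter + inter.T) / 2

            def score(idx, q=q, inter=inter):
                idx = np.asarray(idx)
                return q[idx].sum() + inter[np.ix_(idx, idx)].sum() / 2

            trace = greedy_backward_ensemble(NaiveObjective(score, 8))
            k = len(trace.selected_units)
            best_at_k = max(
                score(np.array(c)) for c in itertools.combinations(range(8), k)
            )
            got = trace.scores[trace.selected_step]
            assert got >= best_at_k - 0.05 * abs(best_at_k) - 1e-9

    def test_batched_objectives_match_naive_evaluation(self, rm_coarse, task):
        rm = rm_coarse
        win = np.flatnonzero(rm.window_mask(task.cue_on, task.reward))
        delay = np.flatnonzero(rm.window_mask(*task.delay))
        y = rm.values.astype(int)
        cond = rm.condition_labels()
        idx = np.arange(rm.n_units)
        stable = StableSubspaceObjective(rm.rates[:, :, win], y, cond,
                                         lam=10.0, seed=1)
        naive = np.array([stable.score(np.delete(idx, c)) for c in range(len(idx))])
        assert np.allclose(stable.scores_without_each(idx), naive)
        for kind in ("stability", "locality"):
            raw = RawRidgeObjective(rm.rates, y, cond, train_bins=delay[::3],
                                    test_bins=delay, bin_times=rm.bin_times_abs,
                                    kind=kind, lam=10.0, seed=2)
            nv = np.array([raw.score(np.delete(idx, c)) for c in range(len(idx))])
            assert np.allclose(raw.scores_without_each(idx), nv)

    def test_greedy_on_real_objective_tracks_exhaustive(self, task):
        # 8-unit planted population, raw stability objective, all subset sizes
        from valuedyn.syndata import sample_population, generate_session
        from valuedyn.prep import bin_session
        specs = sample_population({"stable_linear": 4, "untuned": 4}, seed=95,
                                  task=task)
        rm = bin_session(generate_session(specs, task, seed=96),
                         bin_width=0.2, step=0.2)
        win = np.flatnonzero(rm.window_mask(task.cue_on, task.reward))[::3]
        obj = RawRidgeObjective(rm.rates[:, :, win], rm.values.astype(int),
                                rm.condition_labels(),
                                train_bins=np.arange(len(win)),
                                test_bins=np.arange(len(win)),
                                bin_times=rm.bin_times_abs[win],
                                kind="stability", lam=10.0, seed=3)
        trace = greedy_backward_ensemble(obj)
        by_size = {8 - i: s for i, s in enumerate(trace.scores)}
        for k in (7, 5, 3):
            best = max(obj.score(np.array(c))
                       for c in itertools.combinations(range(8), k))
            assert by_size[k] >= 0.95 * best


class TestContributions:
    @pytest.mark.parametrize("x,expected", [(-0.04, -0.2), (0.09, 0.3), (0.0, 0.0)])
    def test_sign_sqrt_transform(self, x, expected):
        assert ac_transform(x) == pytest.approx(expected)

    def test_transform_preserves_spearman_rank_exactly(self, rng):
        from scipy.stats import spearmanr
        x = rng.normal(size=50)
        y = 0.5 * x + rng.normal(size=50)
        r0 = spearmanr(x, y).statistic
        r1 = spearmanr(ac_transform(x), y).statistic
        assert r0 == pytest.approx(r1, abs=1e-12)

    def test_leave_one_out_contribution_signs(self):
        quality = np.array([1.0, -0.5, 0.2])
        obj = NaiveObjective(lambda idx: quality[idx].sum(), 3)
        delta, ac = accuracy_contribution(obj, np.arange(3))
        assert np.allclose(delta, quality)
        assert np.allclose(ac, np.sign(quality) * np.sqrt(np.abs(quality)))

    def test_trace_contributions_discard_last_removed_and_survivor(self):
        quality = np.array([0.5, 0.1, -0.2, 0.9])
        obj = NaiveObjective(lambda idx: quality[idx].sum(), 4)
        trace = greedy_backward_ensemble(obj)
        contrib = trace.contributions()
        n_nan = np.isnan(contrib).sum()
        assert n_nan == 2  # last removed + never removed
        removed_first = trace.removal_order[0]
        assert contrib[removed_first] == pytest.approx(quality[removed_first])


class TestOverlap:
    def test_identical_ensembles_all_significant(self):
        ids = np.arange(60)
        sets = [np.arange(20) for _ in range(6)]
        res = ensemble_overlap_test(sets, sets, ids)
        assert res["n_significant"] == len(sets)

    def test_small_disjoint_ensembles_not_significant(self):
        ids = np.arange(120)
        stable = [np.arange(0, 10) for _ in range(5)]
        dynamic = [np.arange(50, 62) for _ in range(5)]
        res = ensemble_overlap_test(stable, dynamic, ids)
        assert res["n_significant"] == 0

    def test_degenerate_margins_skipped(self):
        ids = np.arange(30)
        res = ensemble_overlap_test([ids], [np.arange(10)], ids)
        assert res["n_skipped"] == 1
        assert np.isnan(res["p_values"][0])

    def test_hypergeometric_enrichment(self):
        ids = np.arange(100)
        pool = np.arange(20)
        # selecting 10 of 10 from the pool is wildly enriched
        assert hypergeom_enrichment(np.arange(10), pool, ids) < 1e-6
        # a representative selection is not
        spread = np.arange(0, 100, 10)
        assert hypergeom_enrichment(spread, pool, ids) > 0.2
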