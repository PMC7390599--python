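import numpy as np
import pytest

from valuedyn.encoding import (
    anova_pvalues_statsmodels,
    classify_nonlinear_value_units,
    coverage_distribution,
    coverage_ks_test,
    dprime,
    encode_population,
    encoding_strength,
    fit_bin_anova,
    latency_from_mask,
    pooled_sd,
    region_comparisons,
    significance_runs,
    split_half_sequence_analysis,
    stability_measure,
)
from valuedyn.syndata import TaskConfig, sample_population, generate_session
from valuedyn.prep import bin_session


class TestBinAnova:
    def test_matches_statsmodels_on_balanced_design(self, rng):
        values = np.repeat([1, 2, 3, 4], 20)
        types = np.tile(np.repeat(["juice", "bar"], 10), 4)
        rates = rng.normal(5, 1, size=80) + 0.3 * values + 0.5 * (types == "juice")
        fast = fit_bin_anova(rates[:, None], values, types)
        slow = anova_pvalues_statsmodels(rates, values, types)
        assert fast["value"][0] == pytest.approx(slow[0], rel=1e-8)
        assert fast["type"][0] == pytest.approx(slow[1], rel=1e-8)
        assert fast["interaction"][0] == pytest.approx(slow[2], rel=1e-8)

    def test_planted_stable_unit_with_strong_gain_has_tiny_delay_pvalues(self, task):
        specs = sample_population(
            {"stable_linear": 2}, seed=55, task=task,
            param_ranges={"stable_linear": {"value_gain": (2.5, 3.0)}})
        ses = generate_session(specs, task, seed=56)
        rm = bin_session(ses)
        delay = rm.window_mask(*task.delay)
        p = fit_bin_anova(rm.rates[:, 0, :], rm.values, rm.types)["value"]
        assert np.median(p[delay]) < 1e-5

    def test_untuned_units_calibrated_at_alpha(self, untuned_rm):
        ps = np.concatenate([
            fit_bin_anova(untuned_rm.rates[:, u, :], untuned_rm.values,
                          untuned_rm.types)["value"]
            for u in range(untuned_rm.n_units)
        ])
        # coarse bins are nearly independent; binomial 3-sigma band
        rate = np.mean(ps < 0.05)
        se = np.sqrt(0.05 * 0.95 / len(ps))
        assert abs(rate - 0.05) < 4 * se

    def test_shuffled_labels_destroy_significance(self, rm_encoding, rng):
        perm = rng.permutation(rm_encoding.n_trials)
        p = fit_bin_anova(rm_encoding.rates[:, 0, :], rm_encoding.values[perm],
                          rm_encoding.types[perm])["value"]
        assert np.mean(p < 0.01) < 0.15

    def test_zero_variance_bin_flagged_with_p_one(self):
        values = np.repeat([1, 2, 3, 4], 4)
        types = np.tile(np.repeat(["juice", "bar"], 2), 4)
        rates = np.zeros((16, 2))
        rates[:, 1] = np.arange(16) % 3
        out = fit_bin_anova(rates, values, types)
        assert out["zero_variance"][0] and not out["zero_variance"][1]
        assert out["value"][0] == 1.0

    def test_unbalanced_design_rejected(self):
        values = np.repeat([1, 2, 3, 4], 4).tolist() + [4]
        types = (["juice", "juice", "bar", "bar"] * 4) + ["bar"]
        with pytest.raises(ValueError, match="balanced"):
            fit_bin_anova(np.random.rand(17, 2), np.array(values), np.array(types))


class TestSignificanceRuns:
    def test_seven_consecutive_bins_qualify(self):
        p = np.ones(20)
        p[5:12] = 0.005
        mask = significance_runs(p, alpha=0.01, k=7)
        assert mask[5:12].all() and mask.sum() == 7

    def test_six_consecutive_bins_do_not(self):
        p = np.ones(20)
        p[5:11] = 0.005
        assert not significance_runs(p, alpha=0.01, k=7).any()

    def test_short_run_ignored_latency_from_long_run(self):
        p = np.ones(30)
        p[2:8] = 0.005    # 6 bins: ignored
        p[12:20] = 0.005  # 8 bins: qualifies
        mask = significance_runs(p, alpha=0.01, k=7)
        assert not mask[2:8].any() and mask[12:20].all()
        times = np.arange(30) * 0.025
        assert latency_from_mask(mask, times) == pytest.approx(12 * 0.025)

    def test_no_run_gives_nan_latency(self):
        assert np.isnan(latency_from_mask(np.zeros(5, bool), np.arange(5.0)))


class TestMeasures:
    @pytest.mark.parametrize("p,expected", [(1e-2, 2.0), (1e-3, 3.0)])
    def test_encoding_strength_constant_p(self, p, expected):
        assert encoding_strength(np.full(10, p)) == pytest.approx(expected)

    def test_encoding_strength_mixed_mean(self):
        assert encoding_strength(np.array([1e-2, 1e-4])) == pytest.approx(3.0)

    def test_pooled_sd_formula(self):
        assert pooled_sd(4.0, 16.0) == pytest.approx(np.sqrt(10.0))

    def test_stability_saturates_at_one_for_persistent_separation(self):
        # +5 Hz separation at 1 Hz pooled SD: tanh(50) ~ 1 for every pair
        n, T = 8, 10
        values = np.repeat([1, 2, 3, 4], n)
        base = np.array([0.0, 5.0, 10.0, 15.0])
        rng = np.random.default_rng(0)
        rates = base[np.repeat(np.arange(4), n)][:, None] + rng.normal(0, 1, (4 * n, T))
        assert stability_measure(rates, values) > 0.95

    def test_stability_zero_for_antisymmetric_reversal(self):
        n, T = 30, 10
        values = np.repeat([1, 2, 3, 4], n)
        sign = np.concatenate([np.ones(T // 2), -np.ones(T // 2)])
        base = np.array([0.0, 2.0, 4.0, 6.0])
        rng = np.random.default_rng(1)
        rates = (base[np.repeat(np.arange(4), n)][:, None] * sign
                 + rng.normal(0, 1, (4 * n, T)))
        assert stability_measure(rates, values) < 0.1

    def test_es_invariant_to_bin_order(self, rm_encoding, task):
        delay = rm_encoding.window_mask(*task.delay)
        p = fit_bin_anova(rm_encoding.rates[:, 6, :], rm_encoding.values,
                          rm_encoding.types)["value"][delay]
        rng = np.random.default_rng(2)
        order = rng.permutation(p.shape[0])
        assert encoding_strength(p) == pytest.approx(encoding_strength(p[order]))

    def test_stability_separates_reversal_from_matched_persistence(self):
        # same per-bin separation magnitude; only the sign history differs
        rng = np.random.default_rng(3)
        values = np.repeat([1, 2, 3, 4], 25)
        T = 20
        sign = np.concatenate([np.ones(T // 2), -np.ones(T // 2)])
        base = np.array([0.0, 2.0, 4.0, 6.0])[np.repeat(np.arange(4), 25)][:, None]
        noise = rng.normal(0, 1, (100, T))
        s_reversing = stability_measure(base * sign + noise, values)
        s_persistent = stability_measure(base + noise, values)
        assert s_reversing < 0.1 < 0.9 < s_persistent

    def test_reversing_units_score_lower_stability_than_stable(self, task):
        stable = sample_population(
            {"stable_linear": 10}, seed=51, task=task,
            param_ranges={"stable_linear": {"value_gain": (2.0, 2.0)}})
        rev = sample_population(
            {"reversing": 10}, seed=52, task=task,
            param_ranges={"reversing": {"value_gain": (2.0, 2.0)}})
        S = {}
        for name, specs in (("stable", stable), ("rev", rev)):
            ses = generate_session(specs, task, seed=53)
            rm = bin_session(ses, bin_width=0.2, step=0.2)
            delay = rm.window_mask(*task.delay)
            S[name] = [stability_measure(rm.rates[:, u, :][:, delay], rm.values)
                       for u in range(rm.n_units)]
        from scipy.stats import mannwhitneyu
        assert np.mean(S["stable"]) > np.mean(S["rev"])
        assert mannwhitneyu(S["stable"], S["rev"], alternative="greater").pvalue < 0.01

    def test_dprime_closed_form_cases(self):
        # identical distributions
        v = np.repeat([1, 2, 3, 4], 4)
        r = np.tile([1.0, 2.0, 3.0, 4.0], 4)
        assert dprime(r, v) == pytest.approx(0.0)
        # two classes, means 1 apart, sample SD exactly 1
        c = 1 / np.sqrt(2)
        r2 = np.array([0 - c, 0 + c, 1 - c, 1 + c])
        v2 = np.array([1, 1, 2, 2])
        assert dprime(r2, v2) == pytest.approx(1.0)

    def test_dprime_increases_with_planted_gain(self, task):
        dps = []
        for gain in (0.5, 1.5, 3.0):
            specs = sample_population(
                {"stable_linear": 6}, seed=61, task=task,
                param_ranges={"stable_linear": {"value_gain": (gain, gain)}})
            ses = generate_session(specs, task, seed=62)
            rm = bin_session(ses, bin_width=0.2, step=0.2)
            win = rm.window_mask(task.cue_on, task.reward)
            dps.append(np.mean([
                dprime(rm.rates[:, u, :][:, win].mean(axis=1), rm.values)
                for u in range(rm.n_units)
            ]))
        assert dps[0] < dps[1] < dps[2]


class TestSplitHalf:
    def test_sequential_population_peaks_replicate(self, task):
        specs = sample_population(
            {"sequential": 24}, seed=71, task=task,
            param_ranges={"sequential": {"bump_amp": (12.0, 18.0),
                                         "value_gain": (4.0, 6.0),
                                         "bump_sd": (0.12, 0.2)}})
        ses = generate_session(specs, task, seed=72)
        rm = bin_session(ses)
        out = split_half_sequence_analysis(rm, seed=73)
        assert out["n_kept"] >= 5
        assert out["peak_r"] > 0.7
        assert out["peak_p"] < 0.01

    def test_shuffled_labels_yield_few_kept_units(self, rm_encoding, rng):
        perm = rng.permutation(rm_encoding.n_trials)
        shuffled = type(rm_encoding)(
            rates=rm_encoding.rates, bin_times=rm_encoding.bin_times,
            bin_times_abs=rm_encoding.bin_times_abs, epoch_ids=rm_encoding.epoch_ids,
            values=rm_encoding.values[perm], types=rm_encoding.types[perm],
            unit_ids=rm_encoding.unit_ids, meta=dict(rm_encoding.meta),
        )
        out = split_half_sequence_analysis(shuffled, seed=74)
        assert out["n_kept"] <= 2


class TestCoverageAndRegions:
    def test_reverse_cumulative_step_function(self):
        grid, curve = coverage_distribution(np.full(10, 0.5))
        assert np.all(curve[grid <= 0.5] == 1.0)
        assert np.all(curve[grid > 0.5] == 0.0)

    def test_identical_samples_ks_zero(self):
        d = np.linspace(0, 1, 20)
        res = coverage_ks_test(d, d)
        assert res.statistic == 0.0

    def test_ks_detects_mixture_vs_transient(self, rng):
        mixed = np.concatenate([rng.uniform(0.6, 1.0, 40), rng.uniform(0, 0.2, 40)])
        transient = rng.uniform(0, 0.2, 80)
        assert coverage_ks_test(mixed, transient).pvalue < 0.05

    def test_equal_proportions_give_null_chi2(self):
        masks = np.zeros((100, 5), dtype=bool)
        masks[:50] = True
        lat = np.linspace(0, 1, 100)
        out = region_comparisons(masks, masks, lat, lat)
        assert out["p_overall"] == pytest.approx(1.0)
        assert out["chi2_overall"] == pytest.approx(0.0)
        assert out["kw_h"] == pytest.approx(0.0, abs=1e-9)

    def test_clear_proportion_difference_detected(self):
        a = np.zeros((100, 3), dtype=bool)
        b = np.zeros((100, 3), dtype=bool)
        a[:80] = True
        b[:40] = True
        out = region_comparisons(a, b, np.arange(80.0), np.arange(40.0))
        assert out["p_overall"] < 0.01
        assert (out["p_per_bin"] < 0.01).all()


class TestNonlinearCoders:
    def test_nonlinear_tuned_units_flagged_but_linear_and_untuned_not(self, task):
        from valuedyn.syndata import UnitSpec
        # value tuning orthogonal to a linear trend (mid-range preferring)
        specs = [
            UnitSpec(unit_id=i, coding_class="stable_nonmonotonic",
                     baseline_rate=5.0, value_rates=(0.0, 7.0, 7.0, 0.0))
            for i in range(4)
        ] + [
            UnitSpec(unit_id=4 + i, coding_class="stable_linear",
                     baseline_rate=5.0, value_gain=3.0)
            for i in range(4)
        ] + [
            UnitSpec(unit_id=8 + i, coding_class="untuned", baseline_rate=5.0)
            for i in range(4)
        ]
        ses = generate_session(specs, task, seed=82)
        rm = bin_session(ses)
        profiles, df = encode_population(rm)
        flags, prop = classify_nonlinear_value_units(profiles)
        gt = np.array([ses.ground_truth[int(u)] for u in rm.unit_ids])
        assert flags[gt == "stable_nonmonotonic"].mean() >= 0.75
        assert not flags[gt == "stable_linear"].any()
        assert not flags[gt == "untuned"].any()
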