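"""End-to-end synthetic experiments at desk scale.

These functions define the package's reference study conditions: a
120-unit mixed population (30 stable-linear, 40 sequential, 50 untuned
units) with 40 trials per condition drawn into five pseudo-population
datasets, analysis on a coarse 200 ms search grid with 100-permutation
significance tests.  They are consumed by the test suite and by
``scripts/acceptance.py``; the driver scripts under ``analysis/`` run the
same machinery with narrative output.
"""

from __future__ import annotations

import numpy as np

from .syndata import TaskConfig, sample_population, generate_session
from .prep import bin_session, build_pseudopopulation, filter_low_rate
from .encoding import fit_bin_anova, significance_runs
from .decoding import (
    DecoderConfig,
    aggregate_pvalues,
    cross_temporal_decode,
    decode_datasets,
    make_folds,
    tune_lambda,
)
from .subspace import (
    _stratified_halves,
    _subspace_fold_accuracy,
    build_value_subspace,
)
from .decoding import _zscore_params
from .ensembles import (
    RawRidgeObjective,
    StableSubspaceObjective,
    ensemble_overlap_test,
    greedy_backward_ensemble,
    hypergeom_enrichment,
)

STUDY_COMPOSITION = {"stable_linear": 30, "sequential": 40, "untuned": 50}
STUDY_TRIALS_PER_CONDITION = 40


# ---------------------------------------------------------------------------
# null calibrations
# ---------------------------------------------------------------------------

def null_calibration_encoding(
    seed: int = 0,
    n_units: int = 60,
    trials_per_condition: int = 20,
    alpha: float = 0.01,
    run_k: int = 7,
) -> dict:
    """Per-bin false-positive rate of the value F-test on untuned units.

    Units are independent replicates (bins within a unit are correlated by
    the smoothing kernel and overlapping bins), so the standard error is
    estimated across units.  Also reports the unit-level false-positive
    rate of the 7-consecutive-bin rule, which should be far below the
    per-bin rate.
    """
    task = TaskConfig(trials_per_condition=trials_per_condition)
    specs = sample_population({"untuned": n_units}, seed=seed, task=task)
    session = generate_session(specs, task, seed=seed + 1)
    rm = bin_session(session)  # encoding grid: 100 ms bins every 25 ms
    per_unit_fpr = np.empty(n_units)
    unit_hits = np.empty(n_units, dtype=bool)
    unit_any_bin = np.empty(n_units, dtype=bool)
    for u in range(rm.n_units):
        p = fit_bin_anova(rm.rates[:, u, :], rm.values, rm.types)["value"]
        per_unit_fpr[u] = np.mean(p < alpha)
        unit_hits[u] = significance_runs(p, alpha, run_k).any()
        unit_any_bin[u] = bool((p < alpha).any())
    fpr = float(per_unit_fpr.mean())
    se = float(per_unit_fpr.std(ddof=1) / np.sqrt(n_units))
    return {
        "per_bin_fpr": fpr,
        "per_bin_fpr_se": se,
        "nominal_alpha": alpha,
        "within_3se": bool(abs(fpr - alpha) <= 3 * se),
        "run_rule_unit_fpr": float(unit_hits.mean()),
        "any_bin_unit_fpr": float(unit_any_bin.mean()),
        "n_units": n_units,
        "n_bins": rm.n_bins,
    }


def null_ctd_chance(
    seed: int = 0,
    n_units: int = 24,
    trials_per_condition: int = 16,
    n_repeats: int = 4,
) -> dict:
    """Mean CTD accuracy under label shuffling (chance = 0.25 for 4 values).

    Several independent shuffles are decoded; the standard error is taken
    across repeats since time-bin pairs within one run are correlated.
    """
    task = TaskConfig(trials_per_condition=trials_per_condition)
    specs = sample_population(
        {"stable_linear": n_units // 2, "untuned": n_units - n_units // 2},
        seed=seed, task=task,
    )
    session = generate_session(specs, task, seed=seed + 1)
    rm = bin_session(session, bin_width=0.2, step=0.2)
    cfg = DecoderConfig(n_perm=0)
    delay = np.flatnonzero(rm.window_mask(*task.delay))
    rng = np.random.default_rng(np.random.SeedSequence(seed + 2))
    means = []
    for r in range(n_repeats):
        shuffled = rm.rates[rng.permutation(rm.n_trials)]
        pop = type(rm)(
            rates=shuffled, bin_times=rm.bin_times, bin_times_abs=rm.bin_times_abs,
            epoch_ids=rm.epoch_ids, values=rm.values, types=rm.types,
            unit_ids=rm.unit_ids, meta=dict(rm.meta),
        )
        res = cross_temporal_decode(pop, cfg, seed=seed + 10 + r, lam=10.0,
                                    train_bins=delay, test_bins=delay)
        means.append(res.accuracy.mean())
    means = np.asarray(means)
    mean = float(means.mean())
    se = float(means.std(ddof=1) / np.sqrt(n_repeats))
    return {
        "mean_accuracy": mean,
        "se": se,
        "chance": 0.25,
        "within_3se": bool(abs(mean - 0.25) <= 3 * max(se, 1e-6)),
        "n_repeats": n_repeats,
    }


def overlap_fdr_calibration(
    seed: int = 0,
    n_instances: int = 200,
    n_units: int = 120,
    size_range: tuple[int, int] = (15, 45),
    alpha: float = 0.01,
) -> dict:
    """False-positive rate of the ensemble-overlap test on independent
    random memberships (full null); after BH correction the fraction of
    flagged instances should not exceed the nominal level."""
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    ids = np.arange(n_units)
    stable_sets, dyn_sets = [], []
    for _ in range(n_instances):
        ks = int(rng.integers(size_range[0], size_range[1] + 1))
        kd = int(rng.integers(size_range[0], size_range[1] + 1))
        stable_sets.append(rng.choice(ids, size=ks, replace=False))
        dyn_sets.append(rng.choice(ids, size=kd, replace=False))
    res = ensemble_overlap_test(stable_sets, dyn_sets, ids, alpha=alpha)
    frac = res["n_significant"] / res["n_instances"]
    se = np.sqrt(alpha * (1 - alpha) / n_instances)
    return {
        "fraction_significant": float(frac),
        "nominal_alpha": alpha,
        "upper_bound_3se": float(alpha + 3 * se),
        "n_instances": n_instances,
    }


# ---------------------------------------------------------------------------
# regime recovery (stable vs dynamic extraction on a planted mixture)
# ---------------------------------------------------------------------------

def _study_datasets(seed: int, n_datasets: int = 5):
    """Simulate the study population and build matched coarse/medium-grid
    pseudo-population datasets (same trial draws on both grids)."""
    task = TaskConfig(trials_per_condition=50)  # session pool; draws take 40
    specs = sample_population(STUDY_COMPOSITION, seed=seed, task=task)
    session = generate_session(specs, task, seed=seed + 1)
    kept, _ = filter_low_rate(session, threshold=1.0)
    if len(kept) < len(specs):
        keep_set = set(kept)
        session.unit_specs = [s for s in session.unit_specs if s.unit_id in keep_set]
    rm_coarse = bin_session(session, kernel_sd=0.1, bin_width=0.2, step=0.2)
    rm_med = bin_session(session, kernel_sd=0.1, bin_width=0.1, step=0.1)
    pops_c = build_pseudopopulation(
        [rm_coarse], n_datasets, STUDY_TRIALS_PER_CONDITION, seed=seed + 2
    )
    pops_m = build_pseudopopulation(
        [rm_med], n_datasets, STUDY_TRIALS_PER_CONDITION, seed=seed + 2
    )
    ground_truth = session.ground_truth
    return task, pops_c, pops_m, ground_truth


def _combined_fold_eval(pop, sel_pos, lam, train_bins, test_bins, window_bins,
                        fold_seed, n_perm, perm_seed):
    """Combined subspace+ensemble CTD on one outer fold with
    training-label permutation p-values."""
    y = pop.values.astype(int)
    cond = pop.condition_labels()
    folds = make_folds(cond, 5, fold_seed)
    tr, te = folds[0]
    rng = np.random.default_rng(np.random.SeedSequence(fold_seed + 1))
    halves = _stratified_halves(cond, tr, rng)
    X = pop.rates[:, sel_pos, :]
    mu, sd = _zscore_params(X)
    X = (X - mu) / sd
    obs = _subspace_fold_accuracy(X, y, halves, te, lam, train_bins, test_bins,
                                  window_bins, y_train=y)
    prng = np.random.default_rng(np.random.SeedSequence(perm_seed))
    exceed = np.zeros_like(obs)
    for _ in range(n_perm):
        y_perm = y.copy()
        y_perm[tr] = y[tr][prng.permutation(len(tr))]
        acc = _subspace_fold_accuracy(X, y, halves, te, lam, train_bins,
                                      test_bins, window_bins, y_train=y_perm)
        exceed += acc > obs
    return obs, exceed / n_perm


def regime_recovery(
    seed: int = 0,
    n_perm: int = 100,
    n_datasets: int = 5,
    alpha_agg: float = 0.01,
) -> dict:
    """Recover planted stable and dynamic value codes from a 120-unit mixture.

    Runs, per pseudo-population dataset: raw cross-temporal decoding with
    permutation significance on the coarse delay grid; a greedy stable
    (subspace-combined) ensemble search on the first outer fold's training
    trials with held-out evaluation; a greedy dynamic (locality) ensemble
    search on the medium grid; and ensemble enrichment/overlap statistics
    against the planted pools.
    """
    task, pops_c, pops_m, ground_truth = _study_datasets(seed, n_datasets)
    pop0 = pops_c[0]
    all_ids = pop0.unit_ids
    stable_pool = np.array([u for u, c in ground_truth.items() if c == "stable_linear"])
    dynamic_pool = np.array([u for u, c in ground_truth.items() if c == "sequential"])

    delay_c = np.flatnonzero(pop0.window_mask(*task.delay))
    win_c = np.flatnonzero(pop0.window_mask(task.cue_on, task.reward))
    pop0m = pops_m[0]
    delay_m = np.flatnonzero(pop0m.window_mask(*task.delay))
    train_m = delay_m[::5]  # one in five delay bins for the dynamic search

    cfg = DecoderConfig(n_perm=n_perm)

    # --- raw population CTD with significance on the delay grid -----------
    raw = decode_datasets(pops_c, cfg, seed=seed + 11, n_perm=n_perm,
                          train_bins=delay_c, test_bins=delay_c)
    raw_sig = raw.p_agg <= alpha_agg
    n_delay_pairs = raw_sig.size

    # --- stable (combined subspace + ensemble) extraction ------------------
    stable_sets, combined_ps, combined_accs, stable_enrich = [], [], [], []
    for d, pop in enumerate(pops_c):
        y = pop.values.astype(int)
        cond = pop.condition_labels()
        fold_seed = seed + 500 + d
        folds = make_folds(cond, 5, fold_seed)
        tr, _ = folds[0]
        # tune lambda for the 3-dim projected decoder on the search trials
        rng = np.random.default_rng(np.random.SeedSequence(seed + 550 + d))
        h1, h2 = _stratified_halves(cond, tr, rng)
        Xz = pop.rates
        mu, sd = _zscore_params(Xz)
        Xz = (Xz - mu) / sd
        model0 = build_value_subspace(Xz[h1][:, :, win_c], y[h1])
        lam_s = tune_lambda(model0.project(Xz[h2]), y[h2], cond[h2],
                            np.intersect1d(win_c, delay_c), cfg, seed=seed + 560 + d)
        obj = StableSubspaceObjective(
            pop.rates[tr][:, :, win_c], y[tr], cond[tr],
            lam=lam_s, seed=seed + 600 + d,
        )
        trace = greedy_backward_ensemble(obj, unit_ids=pop.unit_ids)
        sel_ids = trace.selected_units
        sel_pos = np.flatnonzero(np.isin(pop.unit_ids, sel_ids))
        stable_sets.append(sel_ids)
        stable_enrich.append(hypergeom_enrichment(sel_ids, stable_pool, all_ids))
        obs, pmat = _combined_fold_eval(
            pop, sel_pos, lam_s, delay_c, delay_c, win_c,
            fold_seed=fold_seed, n_perm=n_perm, perm_seed=seed + 700 + d,
        )
        combined_accs.append(obs)
        combined_ps.append(pmat)
    combined_p_agg = aggregate_pvalues(np.stack(combined_ps), axis=0)
    combined_acc = np.mean(combined_accs, axis=0)
    combined_sig = combined_p_agg <= alpha_agg

    # --- dynamic (locality) extraction on the medium grid ------------------
    dynamic_sets, dyn_accs, dyn_enrich = [], [], []
    for d, pop in enumerate(pops_m):
        y = pop.values.astype(int)
        cond = pop.condition_labels()
        folds = make_folds(cond, 5, seed + 800 + d)
        tr, _ = folds[0]
        lam_d = tune_lambda(pop.rates[tr], y[tr], cond[tr], train_m, cfg,
                            seed=seed + 850 + d)
        obj = RawRidgeObjective(
            pop.rates[tr], y[tr], cond[tr],
            train_bins=train_m, test_bins=delay_m,
            bin_times=pop.bin_times_abs, kind="locality",
            lam=lam_d, seed=seed + 860 + d,
        )
        trace = greedy_backward_ensemble(obj, unit_ids=pop.unit_ids)
        sel_ids = trace.selected_units
        sel_pos = np.flatnonzero(np.isin(pop.unit_ids, sel_ids))
        dynamic_sets.append(sel_ids)
        dyn_enrich.append(hypergeom_enrichment(sel_ids, dynamic_pool, all_ids))
        res = cross_temporal_decode(
            pop.subset_units(sel_pos), cfg, seed=seed + 870 + d, lam=lam_d,
            train_bins=delay_m, test_bins=delay_m,
        )
        dyn_accs.append(res.accuracy)
    dyn_acc = np.mean(dyn_accs, axis=0)
    tt = pop0m.bin_times_abs[delay_m]
    dt_mat = np.abs(tt[:, None] - tt[None, :])
    diag_mean = float(np.mean(np.diag(dyn_acc)))
    off_mask = dt_mat > 0.5
    offdiag_mean = float(dyn_acc[off_mask].mean())

    overlap = ensemble_overlap_test(stable_sets, dynamic_sets, all_ids, alpha=0.01)

    return {
        "n_delay_pairs": int(n_delay_pairs),
        "raw_frac_sig": float(raw_sig.mean()),
        "raw_all_sig": bool(raw_sig.all()),
        "raw_diag_mean": float(np.mean(np.diag(raw.accuracy))),
        "raw_min_acc": float(raw.accuracy.min()),
        "combined_frac_sig": float(combined_sig.mean()),
        "combined_all_sig": bool(combined_sig.all()),
        "combined_min_acc": float(combined_acc.min()),
        "combined_diag_mean": float(np.mean(np.diag(combined_acc))),
        "dynamic_diag_mean": diag_mean,
        "dynamic_offdiag_mean": offdiag_mean,
        "dynamic_diag_offdiag_gap": diag_mean - offdiag_mean,
        "stable_enrichment_p": [float(p) for p in stable_enrich],
        "stable_enrichment_p_median": float(np.median(stable_enrich)),
        "dynamic_enrichment_p": [float(p) for p in dyn_enrich],
        "dynamic_enrichment_p_median": float(np.median(dyn_enrich)),
        "stable_ensemble_sizes": [int(len(s)) for s in stable_sets],
        "dynamic_ensemble_sizes": [int(len(s)) for s in dynamic_sets],
        "overlap_n_significant": overlap["n_significant"],
        "overlap_n_instances": overlap["n_instances"],
        "seed": seed,
        "n_perm": n_perm,
    }
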