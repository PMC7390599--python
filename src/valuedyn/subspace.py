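"""Value-subspace extraction and leakage-free subspace decoding.

The value subspace is found by averaging each unit's rate from cue onset
to reward delivery, averaging those values across trials sharing the same
cue value (a 4 x n_units class-mean matrix), and running a PCA on that
matrix: with four values the class means span at most three dimensions, so
three components are retained.  Population activity at any single time bin
can then be projected into this subspace, which captures value variance
while discarding temporal structure.

Decoding inside the subspace uses a split/swap nested cross-validation:
within each outer training fold the trials are split in half, one half
defines the subspace and the other trains the ridge decoder, the roles are
swapped, and the two accuracy matrices (evaluated on the untouched outer
test fold) are averaged.  The subspace therefore never sees the decoder's
test trials, which prevents trial-noise alignment from inflating accuracy.
Permutation tests in this setting shuffle only the training labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .prep import RateMatrix
from .decoding import (
    CTDResult,
    DecoderConfig,
    class_pairs,
    _fit_pair_ridge,
    _zscore_params,
    make_folds,
    ovo_vote,
    tune_lambda,
    aggregate_pvalues,
)

N_COMPONENTS = 3  # four values minus one dimension


@dataclass
class SubspaceModel:
    """PCA of the 4 x n class-mean matrix (time- and trial-averaged)."""

    class_means: np.ndarray        # (n_classes, n_units)
    col_center: np.ndarray         # (n_units,) column means removed before PCA
    components: np.ndarray         # (n_components, n_units), orthonormal rows
    singular_values: np.ndarray
    degenerate: bool = False
    meta: dict = field(default_factory=dict)

    @property
    def unit_weights(self) -> np.ndarray:
        """Unsigned per-unit contribution: L2 norm of the loadings across
        the retained components."""
        return np.linalg.norm(self.components, axis=0)

    def project(self, X: np.ndarray) -> np.ndarray:
        """Project (trials, units) or (trials, units, bins) activity."""
        Xc = X - (self.col_center[:, None] if X.ndim == 3 else self.col_center)
        if X.ndim == 2:
            return Xc @ self.components.T
        return np.einsum("nub,du->ndb", Xc, self.components)


def build_value_subspace(
    rates_window: np.ndarray,
    values: np.ndarray,
    n_components: int = N_COMPONENTS,
    tol: float = 1e-10,
) -> SubspaceModel:
    """Fit the value subspace from (trials, units, window-bins) activity.

    Rates are averaged over the supplied window bins and across trials per
    value class before the PCA.  Populations whose class means have rank
    below ``n_components`` yield fewer components and are flagged
    degenerate.
    """
    rates_window = np.asarray(rates_window, dtype=float)
    if rates_window.ndim == 3:
        avg = rates_window.mean(axis=2)
    else:
        avg = rates_window
    values = np.asarray(values)
    classes = np.unique(values)
    M = np.stack([avg[values == v].mean(axis=0) for v in classes])
    center = M.mean(axis=0)
    Mc = M - center
    U, s, Vt = np.linalg.svd(Mc, full_matrices=False)
    keep = min(n_components, int(np.sum(s > tol * max(s[0], 1.0))))
    degenerate = keep < n_components
    if keep == 0:  # identical class means: keep one (arbitrary) direction
        keep = 1
        Vt = np.eye(M.shape[1])[:1]
        s = np.zeros(1)
    return SubspaceModel(
        class_means=M,
        col_center=center,
        components=Vt[:keep],
        singular_values=s[:keep],
        degenerate=degenerate,
        meta={"classes": classes},
    )


def _stratified_halves(
    cond: np.ndarray, idx: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Split ``idx`` into two halves balanced over condition labels."""
    h1 = []
    for c in np.unique(cond[idx]):
        sub = idx[cond[idx] == c]
        pick = rng.permutation(sub)
        h1.extend(pick[: len(sub) // 2])
    h1 = np.sort(np.array(h1))
    h2 = np.setdiff1d(idx, h1)
    return h1, h2


def _subspace_fold_accuracy(
    X: np.ndarray,
    y: np.ndarray,
    halves: tuple[np.ndarray, np.ndarray],
    te: np.ndarray,
    lam: float,
    train_bins: np.ndarray,
    test_bins: np.ndarray,
    window_bins: np.ndarray,
    y_train: np.ndarray,
    leak_subspace_on_test: bool = False,
) -> np.ndarray:
    """Split/swap accuracy matrix for one outer fold.

    ``y_train`` supplies the (possibly permuted) labels used for both the
    subspace class means and the decoder targets; testing always compares
    against the true ``y``.  ``leak_subspace_on_test`` is a diagnostic mode
    that fits the subspace jointly on the decoder-training and test trials:
    the shared class-mean noise then couples the decoder's boundaries to
    the test trials, inflating accuracy even on unstructured data -- the
    failure mode the split/swap protocol exists to prevent.
    """
    classes = np.unique(y)
    pairs = class_pairs(len(classes))
    acc = np.zeros((len(train_bins), len(test_bins)))
    yte = y[te]
    for sub_half, dec_half in (halves, halves[::-1]):
        if leak_subspace_on_test:
            sub_idx = np.concatenate([dec_half, te])
            sub_labels = y[sub_idx]
        else:
            sub_idx = sub_half
            sub_labels = y_train[sub_idx]
        model = build_value_subspace(X[sub_idx][:, :, window_bins], sub_labels)
        Z_dec = model.project(X[dec_half])   # (n_dec, d, bins)
        Z_te = model.project(X[te])
        y_dec = y_train[dec_half]
        sel_pairs = [
            ((y_dec == classes[i]) | (y_dec == classes[j]), i, j) for i, j in pairs
        ]
        Z_te_t = Z_te[:, :, test_bins]
        for a_idx, t1 in enumerate(train_bins):
            Zb = Z_dec[:, :, t1]
            W = np.empty((Zb.shape[1], len(pairs)))
            b = np.empty(len(pairs))
            for p, (sel, i, j) in enumerate(sel_pairs):
                if sel.sum() == 0 or len(np.unique(y_dec[sel])) < 2:
                    raise ValueError("decoder half is missing a class")
                ys = np.where(y_dec[sel] == classes[i], 1.0, -1.0)
                W[:, p], b[p] = _fit_pair_ridge(Zb[sel], ys, lam)
            scores = np.einsum("ndb,dp->nbp", Z_te_t, W) + b
            pred = ovo_vote(scores, pairs, len(classes))
            acc[a_idx, :] += (classes[pred] == yte[:, None]).mean(axis=0)
    return acc / 2.0


def subspace_ctd(
    pop: RateMatrix,
    config: DecoderConfig | None = None,
    seed: int = 0,
    lam: float | None = None,
    train_bins: np.ndarray | None = None,
    test_bins: np.ndarray | None = None,
    n_perm: int = 0,
    perm_seed: int | None = None,
    leak_subspace_on_test: bool = False,
) -> tuple[CTDResult, np.ndarray | None]:
    """Cross-temporal decoding in the value subspace for one dataset.

    Returns the CTDResult and, when ``n_perm > 0``, the per-pair
    permutation p-values obtained by shuffling training labels only.
    """
    if config is None:
        config = DecoderConfig()
    task = pop.meta["task"]
    y = pop.values.astype(int)
    cond = pop.condition_labels()
    X = pop.rates
    all_bins = np.arange(pop.n_bins)
    train_bins = all_bins if train_bins is None else np.asarray(train_bins)
    test_bins = train_bins if test_bins is None else np.asarray(test_bins)
    window_bins = np.flatnonzero(pop.window_mask(task.cue_on, task.reward))

    # per-unit z-scoring on the full dataset: an affine per-unit map shared
    # by subspace and decoder; fold-level statistics matter little here
    # because the subspace averages over many bins
    mu, sd = _zscore_params(X)
    X = (X - mu) / sd

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    folds = make_folds(cond, config.n_outer_folds, seed)
    halves_per_fold = [_stratified_halves(cond, tr, rng) for tr, _ in folds]

    if lam is None:
        tr0, _ = folds[0]
        h1, h2 = halves_per_fold[0]
        model0 = build_value_subspace(X[h1][:, :, window_bins], y[h1])
        Z = model0.project(X[h2])
        tune_bins = np.intersect1d(
            np.flatnonzero(pop.window_mask(task.cue_on, task.reward)), train_bins
        )
        if tune_bins.size == 0:
            tune_bins = train_bins
        lam = tune_lambda(Z, y[h2], cond[h2], tune_bins, config, seed=seed + 1)

    accs = []
    for (tr, te), halves in zip(folds, halves_per_fold):
        accs.append(
            _subspace_fold_accuracy(
                X, y, halves, te, lam, train_bins, test_bins, window_bins,
                y_train=y, leak_subspace_on_test=leak_subspace_on_test,
            )
        )
    acc = np.mean(accs, axis=0)
    result = CTDResult(
        accuracy=acc,
        train_times=pop.bin_times_abs[train_bins],
        test_times=pop.bin_times_abs[test_bins],
        meta={"lam": lam, "seed": seed, "subspace": True,
              "train_bins": train_bins, "test_bins": test_bins},
    )
    if n_perm <= 0:
        return result, None

    prng = np.random.default_rng(np.random.SeedSequence(perm_seed if perm_seed is not None else seed + 7))
    exceed = np.zeros_like(acc)
    for _ in range(n_perm):
        y_perm = y.copy()
        perm_accs = []
        for (tr, te), halves in zip(folds, halves_per_fold):
            y_perm[tr] = y[tr][prng.permutation(len(tr))]
            perm_accs.append(
                _subspace_fold_accuracy(
                    X, y, halves, te, lam, train_bins, test_bins, window_bins,
                    y_train=y_perm,
                )
            )
        exceed += np.mean(perm_accs, axis=0) > acc
    return result, exceed / n_perm


def subspace_decode_datasets(
    datasets: Sequence[RateMatrix],
    config: DecoderConfig | None = None,
    seed: int = 0,
    n_perm: int = 0,
    train_bins: np.ndarray | None = None,
    test_bins: np.ndarray | None = None,
    unit_subsets: Sequence[np.ndarray] | None = None,
) -> CTDResult:
    """Subspace CTD averaged over datasets with aggregated p-values.

    ``unit_subsets`` optionally restricts each dataset to a (per-dataset)
    ensemble, as produced by the greedy stable-ensemble search.
    """
    accs, pvals = [], []
    res = None
    for d, pop in enumerate(datasets):
        sub = pop if unit_subsets is None else pop.subset_units(unit_subsets[d])
        res, p = subspace_ctd(
            sub, config, seed=seed + 131 * d, n_perm=n_perm,
            train_bins=train_bins, test_bins=test_bins,
        )
        accs.append(res.accuracy)
        if p is not None:
            pvals.append(p)
    out = CTDResult(
        accuracy=np.mean(accs, axis=0),
        train_times=res.train_times,
        test_times=res.test_times,
        per_dataset=accs,
        meta={"seed": seed, "subspace": True},
    )
    if pvals:
        out.p_agg = aggregate_pvalues(np.stack(pvals), axis=0)
    return out
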