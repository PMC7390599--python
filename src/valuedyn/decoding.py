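"""Population decoding of value (or reward type) across time.

The decoder is a ridge-regularized linear regression on +-1 targets, one
per unordered class pair (one-versus-one: 4 values -> 6 binary
classifiers), with prediction by majority vote; vote ties are broken by
the summed signed margins toward each candidate class, then by the lowest
class index.  Features (per-unit rates at one time bin) are z-scored with
training-fold statistics.  Cross-temporal decoding (CTD) trains at one
time bin and tests at every bin; the diagonal is standard decoding and is
computed by the identical code path, so it matches exactly under shared
folds.  Significance comes from label-permutation tests whose p-values
across the five pseudo-population datasets are aggregated as
min(1, 2 * mean(p)) -- valid without independence assumptions -- and
thresholded at 0.01.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .prep import RateMatrix

DEFAULT_LAMBDA_GRID = 10.0 ** np.arange(-2.0, 5.0 + 1e-9, 0.5)  # 15 values


@dataclass
class DecoderConfig:
    lambda_grid: np.ndarray = field(default_factory=lambda: DEFAULT_LAMBDA_GRID.copy())
    n_outer_folds: int = 5
    n_inner_folds: int = 4
    n_perm: int = 1000
    alpha: float = 0.01
    target: str = "value"

    def __post_init__(self) -> None:
        g = np.asarray(self.lambda_grid, dtype=float)
        if g.size == 0 or np.any(np.diff(g) <= 0):
            raise ValueError("lambda_grid must be nonempty and sorted increasing")
        self.lambda_grid = g


@dataclass
class CTDResult:
    """Train-bin x test-bin accuracy with optional aggregated p-values."""

    accuracy: np.ndarray           # (T1, T2), averaged over datasets/folds
    train_times: np.ndarray
    test_times: np.ndarray
    per_dataset: list[np.ndarray] | None = None
    p_agg: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    @property
    def diagonal(self) -> np.ndarray:
        if self.accuracy.shape[0] != self.accuracy.shape[1]:
            raise ValueError("diagonal requires matching train/test grids")
        return np.diag(self.accuracy)


def class_pairs(n_classes: int) -> list[tuple[int, int]]:
    """Unordered class-index pairs; 4 classes -> 6 pairs."""
    return [(i, j) for i in range(n_classes) for j in range(i + 1, n_classes)]


def _fit_pair_ridge(X: np.ndarray, y_sign: np.ndarray, lam: float) -> tuple[np.ndarray, float]:
    """Closed-form ridge on centered data; returns (weights, intercept)."""
    xm = X.mean(axis=0)
    ym = y_sign.mean()
    Xc = X - xm
    G = Xc.T @ Xc
    G[np.diag_indices_from(G)] += lam
    w = np.linalg.solve(G, Xc.T @ (y_sign - ym))
    b = ym - xm @ w
    return w, float(b)


def ovo_vote(scores: np.ndarray, pairs: Sequence[tuple[int, int]], n_classes: int) -> np.ndarray:
    """Predicted class from pairwise decision scores.

    ``scores[..., p]`` is the signed score of pair ``pairs[p]``; positive
    favors the first class of the pair.  Majority vote; ties resolved by
    summed signed margins, then by the lowest class index.
    """
    lead = scores.shape[:-1]
    votes = np.zeros(lead + (n_classes,))
    margins = np.zeros(lead + (n_classes,))
    for p, (i, j) in enumerate(pairs):
        s = scores[..., p]
        win_i = s > 0
        votes[..., i] += win_i
        votes[..., j] += ~win_i
        margins[..., i] += s
        margins[..., j] -= s
    best = votes.max(axis=-1, keepdims=True)
    cand = votes == best
    masked = np.where(cand, margins, -np.inf)
    return np.argmax(masked, axis=-1)  # argmax takes the lowest index on ties


class RidgeOvO:
    """One-vs-one ridge classifier over per-unit rate features."""

    def __init__(self, lam: float):
        self.lam = float(lam)

    def fit(self, X: np.ndarray, y: np.ndarray) -> "RidgeOvO":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValueError("need at least two classes in training data")
        self.pairs_ = class_pairs(len(self.classes_))
        W = np.empty((X.shape[1], len(self.pairs_)))
        b = np.empty(len(self.pairs_))
        for p, (i, j) in enumerate(self.pairs_):
            sel = (y == self.classes_[i]) | (y == self.classes_[j])
            ys = np.where(y[sel] == self.classes_[i], 1.0, -1.0)
            W[:, p], b[p] = _fit_pair_ridge(X[sel], ys, self.lam)
        self.W_, self.b_ = W, b
        return self

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.W_ + self.b_

    def predict(self, X: np.ndarray) -> np.ndarray:
        idx = ovo_vote(self.decision_scores(X), self.pairs_, len(self.classes_))
        return self.classes_[idx]


# ---------------------------------------------------------------------------
# internals shared by standard decoding, CTD and permutation tests
# ---------------------------------------------------------------------------

def _target_labels(pop: RateMatrix, target: str) -> np.ndarray:
    if target == "value":
        return pop.values.astype(int)
    if target == "type":
        _, codes = np.unique(pop.types, return_inverse=True)
        return codes
    raise ValueError(f"unknown target {target!r}")


def make_folds(cond: np.ndarray, n_folds: int, seed: int) -> list[tuple[np.ndarray, np.ndarray]]:
    """Deterministic stratified folds on (value, type) condition labels."""
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed % (2 ** 31))
    return [(tr, te) for tr, te in skf.split(np.zeros(len(cond)), cond)]


def _zscore_params(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-unit mean/SD over trials and bins; zero SD maps to 1."""
    mu = X.mean(axis=(0, 2), keepdims=True)
    sd = X.std(axis=(0, 2), keepdims=True)
    sd = np.where(sd == 0, 1.0, sd)
    return mu, sd


def _ctd_accuracy(
    X: np.ndarray,
    y: np.ndarray,
    folds: Sequence[tuple[np.ndarray, np.ndarray]],
    lam: float,
    train_bins: np.ndarray,
    test_bins: np.ndarray,
    diag_only: bool = False,
    y_train_override: np.ndarray | None = None,
) -> np.ndarray:
    """Fold-averaged CTD accuracy.

    ``y_train_override`` substitutes labels for decoder training only
    (used by training-label permutation tests); testing always uses ``y``.
    """
    classes = np.unique(y)
    n_classes = len(classes)
    pairs = class_pairs(n_classes)
    T1, T2 = len(train_bins), len(test_bins)
    acc = np.zeros((T1, T2))
    y_tr_src = y if y_train_override is None else y_train_override

    for tr, te in folds:
        mu, sd = _zscore_params(X[tr])
        Xtr = (X[tr] - mu) / sd
        Xte = (X[te] - mu) / sd
        ytr, yte = y_tr_src[tr], y[te]
        for ci, c in enumerate(classes):
            if not np.any(ytr == c):
                raise ValueError("training fold is missing a class; check stratification")
        sel_pairs = [
            ((ytr == classes[i]) | (ytr == classes[j]), i, j) for i, j in pairs
        ]
        Xte_t = Xte[:, :, test_bins]
        for a_idx, t1 in enumerate(train_bins):
            Xb = Xtr[:, :, t1]
            W = np.empty((X.shape[1], len(pairs)))
            b = np.empty(len(pairs))
            for p, (sel, i, j) in enumerate(sel_pairs):
                ys = np.where(ytr[sel] == classes[i], 1.0, -1.0)
                W[:, p], b[p] = _fit_pair_ridge(Xb[sel], ys, lam)
            if diag_only:
                scores = Xte[:, :, t1] @ W + b
                pred = ovo_vote(scores, pairs, n_classes)
                acc[a_idx, a_idx] += np.mean(classes[pred] == yte)
            else:
                scores = np.einsum("nub,up->nbp", Xte_t, W) + b
                pred = ovo_vote(scores, pairs, n_classes)  # (n_te, T2)
                acc[a_idx, :] += (classes[pred] == yte[:, None]).mean(axis=0)
    return acc / len(folds)


def tune_lambda(
    X: np.ndarray,
    y: np.ndarray,
    cond: np.ndarray,
    tune_bins: np.ndarray,
    config: DecoderConfig,
    seed: int,
) -> float:
    """Pick lambda* from the grid by inner stratified CV.

    Accuracy is evaluated training and testing at the same time point for
    every bin in ``tune_bins`` (the cue-to-reward window) and averaged over
    bins and inner folds; ties go to the smallest lambda.  The SVD of each
    training block is computed once and reused for the whole grid.
    """
    grid = config.lambda_grid
    classes = np.unique(y)
    pairs = class_pairs(len(classes))
    acc = np.zeros(len(grid))
    n_eval = 0
    for tr, te in make_folds(cond, config.n_inner_folds, seed):
        mu, sd = _zscore_params(X[tr])
        Xtr = (X[tr] - mu) / sd
        Xte = (X[te] - mu) / sd
        ytr, yte = y[tr], y[te]
        for t in tune_bins:
            scores = np.empty((len(te), len(grid), len(pairs)))
            for p, (i, j) in enumerate(pairs):
                sel = (ytr == classes[i]) | (ytr == classes[j])
                ys = np.where(ytr[sel] == classes[i], 1.0, -1.0)
                Xp = Xtr[sel][:, :, t]
                xm, ym = Xp.mean(axis=0), ys.mean()
                U, s, Vt = np.linalg.svd(Xp - xm, full_matrices=False)
                uty = U.T @ (ys - ym)
                d = s[None, :] / (s[None, :] ** 2 + grid[:, None])  # (L, r)
                Wl = (d * uty[None, :]) @ Vt                        # (L, units)
                sc = (Xte[:, :, t] - xm) @ Wl.T + (ym - Wl @ xm)
                scores[:, :, p] = sc
            pred = ovo_vote(scores, pairs, len(classes))  # (n_te, L)
            acc += (classes[pred] == yte[:, None]).mean(axis=0)
            n_eval += 1
    acc /= max(n_eval, 1)
    return float(grid[int(np.argmax(acc))])  # argmax -> smallest lambda on ties


def cross_temporal_decode(
    pop: RateMatrix,
    config: DecoderConfig | None = None,
    seed: int = 0,
    lam: float | None = None,
    train_bins: np.ndarray | None = None,
    test_bins: np.ndarray | None = None,
    diag_only: bool = False,
    folds: Sequence[tuple[np.ndarray, np.ndarray]] | None = None,
) -> CTDResult:
    """Cross-temporal decoding of one pseudo-population dataset.

    Out-of-sample throughout: testing trials are never used to fit, even on
    the diagonal.  If ``lam`` is None it is tuned by nested CV on the first
    outer fold's training trials (a single lambda* per dataset).
    """
    if config is None:
        config = DecoderConfig()
    y = _target_labels(pop, config.target)
    cond = pop.condition_labels()
    task = pop.meta["task"]
    all_bins = np.arange(pop.n_bins)
    if train_bins is None:
        train_bins = all_bins
    if test_bins is None:
        test_bins = train_bins
    train_bins = np.asarray(train_bins)
    test_bins = np.asarray(test_bins)

    if folds is None:
        folds = make_folds(cond, config.n_outer_folds, seed)
    if lam is None:
        tr0 = folds[0][0]
        tune_bins = np.flatnonzero(pop.window_mask(task.cue_on, task.reward))
        # tuning on the coarse train grid keeps the nested CV affordable
        tune_bins = np.intersect1d(tune_bins, train_bins)
        if tune_bins.size == 0:
            tune_bins = train_bins
        lam = tune_lambda(pop.rates[tr0], y[tr0], cond[tr0], tune_bins, config,
                          seed=seed + 1)

    acc = _ctd_accuracy(pop.rates, y, folds, lam, train_bins, test_bins,
                        diag_only=diag_only)
    return CTDResult(
        accuracy=acc,
        train_times=pop.bin_times_abs[train_bins],
        test_times=pop.bin_times_abs[test_bins],
        meta={"lam": lam, "seed": seed, "target": config.target,
              "train_bins": train_bins, "test_bins": test_bins,
              "n_folds": len(folds)},
    )


def decode_standard(
    pop: RateMatrix,
    config: DecoderConfig | None = None,
    seed: int = 0,
    lam: float | None = None,
    bins: np.ndarray | None = None,
) -> CTDResult:
    """Standard (train = test time) decoding; the CTD diagonal by the same
    code path and fold structure."""
    return cross_temporal_decode(pop, config, seed=seed, lam=lam,
                                 train_bins=bins, test_bins=bins, diag_only=True)


def permutation_test(
    pop: RateMatrix,
    observed: CTDResult,
    config: DecoderConfig | None = None,
    n_perm: int | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Per-(train, test)-bin permutation p-values for one dataset.

    Labels are shuffled and the full CV decoding is re-run with the same
    fold partition and lambda; p = #(permutation accuracy > observed) /
    n_perm.  A p of 0 means "below 1/n_perm".
    """
    if config is None:
        config = DecoderConfig()
    if n_perm is None:
        n_perm = config.n_perm
    y = _target_labels(pop, config.target)
    cond = pop.condition_labels()
    folds = make_folds(cond, config.n_outer_folds, observed.meta["seed"])
    lam = observed.meta["lam"]
    train_bins = observed.meta["train_bins"]
    test_bins = observed.meta["test_bins"]
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    exceed = np.zeros_like(observed.accuracy)
    for _ in range(n_perm):
        y_perm = rng.permutation(y)
        acc = _ctd_accuracy(pop.rates, y_perm, folds, lam, train_bins, test_bins)
        exceed += acc > observed.accuracy
    return exceed / n_perm


def aggregate_pvalues(ps: Sequence[float] | np.ndarray, axis: int = 0) -> np.ndarray | float:
    """Aggregate p-values over datasets: min(1, 2 * mean(p)).

    Valid for arbitrarily dependent p-values; monotone in each input.
    """
    ps = np.asarray(ps, dtype=float)
    if np.any((ps < 0) | (ps > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return np.minimum(1.0, 2.0 * ps.mean(axis=axis))


def decode_datasets(
    datasets: Sequence[RateMatrix],
    config: DecoderConfig | None = None,
    seed: int = 0,
    n_perm: int | None = None,
    train_bins: np.ndarray | None = None,
    test_bins: np.ndarray | None = None,
) -> CTDResult:
    """CTD over several pseudo-population datasets with aggregated p-values.

    Each dataset gets its own tuned lambda, CV and permutation test; the
    reported accuracy is the dataset mean and p_agg = min(1, 2 * mean p).
    """
    if config is None:
        config = DecoderConfig()
    accs, pvals = [], []
    res = None
    for d, pop in enumerate(datasets):
        res = cross_temporal_decode(pop, config, seed=seed + 101 * d,
                                    train_bins=train_bins, test_bins=test_bins)
        accs.append(res.accuracy)
        if n_perm is None or n_perm > 0:
            p = permutation_test(pop, res, config, n_perm=n_perm,
                                 seed=seed + 101 * d + 50)
            pvals.append(p)
    out = CTDResult(
        accuracy=np.mean(accs, axis=0),
        train_times=res.train_times,
        test_times=res.test_times,
        per_dataset=accs,
        meta={"seed": seed, "target": config.target},
    )
    if pvals:
        out.p_agg = aggregate_pvalues(np.stack(pvals), axis=0)
    return out


def subsample_match(
    pop: RateMatrix,
    target_size: int,
    n_draws: int = 200,
    seed: int = 0,
    config: DecoderConfig | None = None,
    lam: float | None = None,
    bins: np.ndarray | None = None,
) -> np.ndarray:
    """Mean standard-decoding accuracy curve over random unit sub-samples.

    Used to match a larger population's size to a smaller one before
    comparing decoding accuracies.  ``target_size`` equal to the population
    size reproduces the original curve (a single draw, no subsampling).
    """
    if target_size > pop.n_units:
        raise ValueError("target_size exceeds the population size")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    if target_size == pop.n_units:
        return decode_standard(pop, config, seed=seed, lam=lam, bins=bins).diagonal
    curves = []
    for _ in range(n_draws):
        units = rng.choice(pop.n_units, size=target_size, replace=False)
        sub = pop.subset_units(np.sort(units))
        curves.append(decode_standard(sub, config, seed=seed, lam=lam, bins=bins).diagonal)
    return np.mean(curves, axis=0)
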