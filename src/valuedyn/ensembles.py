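"""Greedy ensemble selection for stable and dynamic value codes.

Starting from the full population, units are removed one at a time; at
each step the unit whose removal maximizes the objective is eliminated,
down to a single unit, and the selected ensemble is the step with the
highest objective (the full population is itself a candidate, so the
selected score can never fall below the full-population score).  Two
objectives are used:

* stability: the mean cross-temporal decoding accuracy over all train/test
  time-bin pairs in the cue-to-reward window (computed in the value
  subspace for the combined stable pipeline);
* locality: how temporally local the representation is.  For each training
  bin a Gaussian ``a * exp(-(t - mu)^2 / (2 sigma^2)) + b`` is fitted to
  accuracy as a function of testing time, with the offset b fixed at
  chance (0.25) and mu fixed at the training time; the locality measure is
  the mean over training bins of (peak - 0.25) / sigma.

Exhaustively scoring every subset is infeasible, and backward elimination
does not guarantee the globally best ensemble; it does, however, preserve
unit interactions better than forward selection.  The per-candidate
evaluations are batched: dropping one unit from a ridge solution has a
closed-form block-inverse downdate, and dropping one column from the 4 x n
class-mean matrix needs only a tiny SVD, so a full elimination trace costs
a few matrix products per step rather than thousands of refits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .decoding import class_pairs, ovo_vote
from .subspace import build_value_subspace

CHANCE_4 = 0.25


def ac_transform(x: np.ndarray | float) -> np.ndarray | float:
    """Symmetric square-root display transform, ac = sign(x) sqrt(|x|).

    Strictly monotone, so rank-based statistics are unchanged.
    """
    x = np.asarray(x, dtype=float)
    out = np.sign(x) * np.sqrt(np.abs(x))
    return float(out) if out.ndim == 0 else out


def stability_score(
    accuracy: np.ndarray,
    train_window: np.ndarray | None = None,
    test_window: np.ndarray | None = None,
) -> float:
    """Mean accuracy over all (train, test) pairs inside the window."""
    acc = np.asarray(accuracy, dtype=float)
    ti = np.arange(acc.shape[0]) if train_window is None else np.flatnonzero(train_window)
    tj = np.arange(acc.shape[1]) if test_window is None else np.flatnonzero(test_window)
    if len(ti) == 0 or len(tj) == 0:
        raise ValueError("empty stability window")
    return float(acc[np.ix_(ti, tj)].mean())


# ---------------------------------------------------------------------------
# Gaussian locality fits
# ---------------------------------------------------------------------------

def _profile_gaussian(
    sigma: np.ndarray, rows: np.ndarray, tt: np.ndarray, mus: np.ndarray, b: float
) -> tuple[np.ndarray, np.ndarray]:
    """SSE and profile-optimal scale a (>= 0) for given sigma arrays.

    ``rows`` is (..., T) accuracy vs testing time, ``mus`` (...,) the fixed
    Gaussian means, ``sigma`` (...,) candidate SDs.
    """
    g = np.exp(-0.5 * ((tt - mus[..., None]) / sigma[..., None]) ** 2)
    resid0 = rows - b
    den = (g * g).sum(axis=-1)
    a = np.clip((resid0 * g).sum(axis=-1) / np.maximum(den, 1e-30), 0.0, None)
    sse = ((resid0 - a[..., None] * g) ** 2).sum(axis=-1)
    return sse, a


def default_sigma_bounds(test_times: np.ndarray) -> tuple[float, float]:
    """Half a bin width to the full span of the testing window."""
    tt = np.asarray(test_times, dtype=float)
    step = float(np.median(np.diff(np.sort(tt))))
    return (step / 2, max(float(tt.max() - tt.min()), step))


def fit_gaussian_batch(
    rows: np.ndarray,
    test_times: np.ndarray,
    mus: np.ndarray,
    b: float = CHANCE_4,
    sigma_bounds: tuple[float, float] | None = None,
    n_iter: int = 60,
) -> tuple[np.ndarray, np.ndarray]:
    """Profile least-squares Gaussian fit, vectorized over leading dims.

    For each row the scale ``a`` has a closed form given sigma, leaving a
    one-dimensional problem in sigma solved by golden-section search on
    ``sigma_bounds``.  Returns (a_hat, sigma_hat) with rows' shape.
    """
    tt = np.asarray(test_times, dtype=float)
    rows = np.asarray(rows, dtype=float)
    mus = np.broadcast_to(np.asarray(mus, dtype=float), rows.shape[:-1]).copy()
    if sigma_bounds is None:
        sigma_bounds = default_sigma_bounds(tt)
    lo = np.full(rows.shape[:-1], float(sigma_bounds[0]))
    hi = np.full(rows.shape[:-1], float(sigma_bounds[1]))
    invphi = (np.sqrt(5.0) - 1) / 2
    x1 = hi - invphi * (hi - lo)
    x2 = lo + invphi * (hi - lo)
    f1, _ = _profile_gaussian(x1, rows, tt, mus, b)
    f2, _ = _profile_gaussian(x2, rows, tt, mus, b)
    for _ in range(n_iter):
        move_right = f1 > f2  # minimum is in [x1, hi]
        lo = np.where(move_right, x1, lo)
        hi = np.where(move_right, hi, x2)
        x1n = hi - invphi * (hi - lo)
        x2n = lo + invphi * (hi - lo)
        fx1n, _ = _profile_gaussian(x1n, rows, tt, mus, b)
        fx2n, _ = _profile_gaussian(x2n, rows, tt, mus, b)
        x1, x2, f1, f2 = x1n, x2n, fx1n, fx2n
    sigma = (lo + hi) / 2
    sse, a = _profile_gaussian(sigma, rows, tt, mus, b)
    return a, sigma


def fit_locality_gaussian(
    row: np.ndarray,
    test_times: np.ndarray,
    mu: float,
    b: float = CHANCE_4,
    sigma_bounds: tuple[float, float] | None = None,
) -> dict:
    """Fit a single accuracy-vs-testing-time row; see :func:`fit_gaussian_batch`."""
    a, sigma = fit_gaussian_batch(
        np.asarray(row)[None, :], test_times, np.array([mu]), b, sigma_bounds
    )
    tt = np.asarray(test_times, dtype=float)
    curve = a[0] * np.exp(-0.5 * ((tt - mu) / sigma[0]) ** 2) + b
    return {"a": float(a[0]), "sigma": float(sigma[0]), "peak": float(curve.max()),
            "b": b, "mu": mu}


def fit_locality_gaussian_grid(
    row: np.ndarray,
    test_times: np.ndarray,
    mu: float,
    b: float = CHANCE_4,
    sigma_bounds: tuple[float, float] | None = None,
    n_sigma: int = 600,
    n_a: int = 401,
) -> dict:
    """Independent dense grid-search fitter (oracle for the profile fit)."""
    tt = np.asarray(test_times, dtype=float)
    row = np.asarray(row, dtype=float)
    if sigma_bounds is None:
        sigma_bounds = default_sigma_bounds(tt)
    sigmas = np.linspace(sigma_bounds[0], sigma_bounds[1], n_sigma)
    a_hi = max(float(np.max(row - b)) * 1.5, 1e-3)
    a_grid = np.linspace(0.0, a_hi, n_a)
    g = np.exp(-0.5 * ((tt[None, :] - mu) / sigmas[:, None]) ** 2)  # (S, T)
    pred = a_grid[:, None, None] * g[None, :, :]                     # (A, S, T)
    sse = ((row - b - pred) ** 2).sum(axis=-1)
    ai, si = np.unravel_index(np.argmin(sse), sse.shape)
    a, sigma = float(a_grid[ai]), float(sigmas[si])
    curve = a * np.exp(-0.5 * ((tt - mu) / sigma) ** 2) + b
    return {"a": a, "sigma": sigma, "peak": float(curve.max()), "b": b, "mu": mu}


def locality_score(
    accuracy: np.ndarray,
    train_times: np.ndarray,
    test_times: np.ndarray,
    b: float = CHANCE_4,
    sigma_bounds: tuple[float, float] | None = None,
) -> float:
    """Locality measure lm = mean over training bins of (peak - b) / sigma."""
    acc = np.atleast_2d(np.asarray(accuracy, dtype=float))
    lm = _locality_terms(acc[None, ...], train_times, test_times, b, sigma_bounds)
    return float(lm[0])


def _locality_terms(
    acc: np.ndarray,
    train_times: np.ndarray,
    test_times: np.ndarray,
    b: float = CHANCE_4,
    sigma_bounds: tuple[float, float] | None = None,
) -> np.ndarray:
    """lm per leading element for acc of shape (..., T1, T2)."""
    tt = np.asarray(test_times, dtype=float)
    mus = np.broadcast_to(np.asarray(train_times, dtype=float), acc.shape[:-1])
    a, sigma = fit_gaussian_batch(acc, tt, mus, b, sigma_bounds)
    # peak of the fitted curve over the actual testing grid
    nearest = np.abs(tt[None, :] - np.asarray(train_times)[:, None]).argmin(axis=1)
    gpeak = np.exp(
        -0.5 * ((tt[nearest] - np.asarray(train_times)) / sigma) ** 2
    )
    terms = a * gpeak / sigma
    terms = np.where(np.isfinite(terms), terms, 0.0)
    return terms.mean(axis=-1)


# ---------------------------------------------------------------------------
# greedy backward elimination
# ---------------------------------------------------------------------------

@dataclass
class EnsembleTrace:
    """Record of one greedy backward elimination run."""

    objective_name: str
    unit_ids: np.ndarray            # population unit ids (search order base)
    removal_order: np.ndarray       # unit ids in order of removal (n-1 entries)
    scores: np.ndarray              # objective after i removals, i = 0..n-1
    selected_units: np.ndarray      # unit ids of the argmax ensemble
    selected_step: int
    meta: dict = field(default_factory=dict)

    def contributions(self) -> "np.ndarray":
        """Per-unit contribution from the elimination trace.

        The contribution of the unit removed at step i is the score drop
        its removal caused, scores[i-1] - scores[i] (positive when the unit
        was helping).  The last removed unit's value is discarded (NaN), as
        is the single never-removed unit.
        """
        contrib = {int(u): np.nan for u in self.unit_ids}
        for i, uid in enumerate(self.removal_order, start=1):
            if i == len(self.removal_order):
                break  # last removal discarded
            contrib[int(uid)] = self.scores[i - 1] - self.scores[i]
        return np.array([contrib[int(u)] for u in self.unit_ids])


class NaiveObjective:
    """Wrap a plain callable score(unit_positions) for greedy search.

    Used for toy problems and as the reference implementation the batched
    objectives are contract-tested against.
    """

    def __init__(self, fn: Callable[[np.ndarray], float], n_units: int, name: str = "naive"):
        self.fn = fn
        self.n_units = n_units
        self.name = name

    def score(self, idx: np.ndarray) -> float:
        return float(self.fn(np.asarray(idx)))

    def scores_without_each(self, idx: np.ndarray) -> np.ndarray:
        idx = np.asarray(idx)
        return np.array(
            [self.fn(np.delete(idx, c)) for c in range(len(idx))]
        )


def greedy_backward_ensemble(objective, unit_ids: np.ndarray | None = None) -> EnsembleTrace:
    """Backward elimination to a single unit; selection by trace argmax.

    Removal ties go to the lowest unit position; the selected step is the
    first occurrence of the maximal score, i.e. the largest such ensemble.
    """
    n = objective.n_units
    if unit_ids is None:
        unit_ids = np.arange(n)
    unit_ids = np.asarray(unit_ids)
    current = np.arange(n)
    scores = [objective.score(current)]
    removal_order = []
    ensembles = [current.copy()]
    while len(current) > 1:
        cand_scores = objective.scores_without_each(current)
        best = int(np.argmax(cand_scores))
        removal_order.append(unit_ids[current[best]])
        current = np.delete(current, best)
        scores.append(float(cand_scores[best]))
        ensembles.append(current.copy())
    scores = np.asarray(scores)
    sel = int(np.argmax(scores))
    return EnsembleTrace(
        objective_name=getattr(objective, "name", type(objective).__name__),
        unit_ids=unit_ids,
        removal_order=np.asarray(removal_order),
        scores=scores,
        selected_units=unit_ids[ensembles[sel]],
        selected_step=sel,
        meta={"n_units": n},
    )


# ---------------------------------------------------------------------------
# batched objectives
# ---------------------------------------------------------------------------

def _zscore_cols(X: np.ndarray, ref: np.ndarray) -> np.ndarray:
    mu = ref.mean(axis=(0, 2), keepdims=True)
    sd = ref.std(axis=(0, 2), keepdims=True)
    sd = np.where(sd == 0, 1.0, sd)
    return (X - mu) / sd


def _stratified_split(cond: np.ndarray, frac: float, rng: np.random.Generator):
    a = []
    for c in np.unique(cond):
        idx = np.flatnonzero(cond == c)
        pick = rng.permutation(idx)
        a.extend(pick[: max(1, int(round(frac * len(idx))))])
    a = np.sort(np.array(a))
    return a, np.setdiff1d(np.arange(len(cond)), a)


class StableSubspaceObjective:
    """Mean subspace-CTD accuracy over the cue-to-reward window.

    Data passed in should already be restricted to the coarse window bins
    (the search grid).  Internally the trials are split into two stratified
    halves; each run fits the value subspace and the ridge decoder on one
    half and measures CTD accuracy on the other, and the two runs are
    averaged.  ``scores_without_each`` evaluates all leave-one-unit-out
    candidates of the current ensemble in one batched pass.
    """

    name = "stability"

    def __init__(
        self,
        X: np.ndarray,
        y: np.ndarray,
        cond: np.ndarray,
        lam: float = 1.0,
        seed: int = 0,
        n_components: int = 3,
    ):
        X = np.asarray(X, dtype=float)
        self.X = _zscore_cols(X, X)
        self.y = np.asarray(y)
        self.classes = np.unique(self.y)
        self.pairs = class_pairs(len(self.classes))
        self.lam = float(lam)
        self.n_units = X.shape[1]
        self.n_bins = X.shape[2]
        self.d = n_components
        rng = np.random.default_rng(np.random.SeedSequence(seed))
        h1, h2 = _stratified_split(cond, 0.5, rng)
        self.runs = [(h1, h2), (h2, h1)]

    # -- single-ensemble evaluation (reference path) --
    def score(self, idx: np.ndarray) -> float:
        idx = np.asarray(idx)
        total = 0.0
        for fit_idx, test_idx in self.runs:
            Xf = self.X[fit_idx][:, idx, :]
            Xt = self.X[test_idx][:, idx, :]
            model = build_value_subspace(Xf, self.y[fit_idx], n_components=self.d)
            Zf, Zt = model.project(Xf), model.project(Xt)
            total += self._ctd_mean(Zf, self.y[fit_idx], Zt, self.y[test_idx])
        return total / len(self.runs)

    def _ctd_mean(self, Zf, yf, Zt, yt) -> float:
        B = Zf.shape[2]
        acc = 0.0
        sel_pairs = [
            ((yf == self.classes[i]) | (yf == self.classes[j]), i, j)
            for i, j in self.pairs
        ]
        for b1 in range(B):
            W = np.empty((Zf.shape[1], len(self.pairs)))
            b0 = np.empty(len(self.pairs))
            for p, (sel, i, j) in enumerate(sel_pairs):
                ys = np.where(yf[sel] == self.classes[i], 1.0, -1.0)
                Zp = Zf[sel][:, :, b1]
                xm, ym = Zp.mean(axis=0), ys.mean()
                Zc = Zp - xm
                G = Zc.T @ Zc
                G[np.diag_indices_from(G)] += self.lam
                w = np.linalg.solve(G, Zc.T @ (ys - ym))
                W[:, p], b0[p] = w, ym - xm @ w
            scores = np.einsum("ndb,dp->nbp", Zt, W) + b0
            pred = ovo_vote(scores, self.pairs, len(self.classes))
            acc += (self.classes[pred] == yt[:, None]).mean(axis=0).sum()
        return acc / (B * B)

    # -- batched leave-one-out evaluation --
    def scores_without_each(self, idx: np.ndarray) -> np.ndarray:
        idx = np.asarray(idx)
        k = len(idx)
        total = np.zeros(k)
        for fit_idx, test_idx in self.runs:
            Xf = self.X[fit_idx][:, idx, :]
            Xt = self.X[test_idx][:, idx, :]
            yf, yt = self.y[fit_idx], self.y[test_idx]
            avg = Xf.mean(axis=2)
            M = np.stack([avg[yf == v].mean(axis=0) for v in self.classes])
            center = M.mean(axis=0)
            Mc = M - center
            # candidate subspaces: drop one column, embed back with a zero row
            V_all = np.zeros((k, k, self.d))
            cols = np.arange(k)
            for c in range(k):
                sub = Mc[:, cols != c]
                _, s, Vt = np.linalg.svd(sub, full_matrices=False)
                keep = min(self.d, Vt.shape[0])
                V_all[c, cols != c, :keep] = Vt[:keep].T
            Xf_c = Xf - center[None, :, None]
            Xt_c = Xt - center[None, :, None]
            nf, _, B = Xf_c.shape
            n_te = Xt_c.shape[0]
            # batched GEMMs: (1, n*B, u) @ (k, u, d) -> (k, n*B, d)
            Xf_flat = Xf_c.transpose(0, 2, 1).reshape(nf * B, k)
            Xt_flat = Xt_c.transpose(0, 2, 1).reshape(n_te * B, k)
            Zf = np.matmul(Xf_flat[None], V_all).reshape(k, nf, B, self.d)
            Zt_flat = np.matmul(Xt_flat[None], V_all)       # (k, n_te*B, d)
            total += self._ctd_mean_batch(Zf, yf, Zt_flat, yt, n_te, B)
        return total / len(self.runs)

    def _ctd_mean_batch(self, Zf, yf, Zt_flat, yt, n_te, B) -> np.ndarray:
        k, nf, _, d = Zf.shape
        nC = len(self.classes)
        acc = np.zeros(k)
        correct_base = (self.classes[:, None] == yt[None, :])  # (C, n_te)
        votes = np.empty((k, n_te, B, nC))
        margins = np.empty((k, n_te, B, nC))
        sel_pairs = [
            ((yf == self.classes[i]) | (yf == self.classes[j]), i, j)
            for i, j in self.pairs
        ]
        trial_idx = np.arange(n_te)[None, :, None]
        for b1 in range(B):
            votes[:] = 0.0
            margins[:] = 0.0
            Zfb = Zf[:, :, b1, :]                           # (k, nf, d)
            for sel, i, j in sel_pairs:
                ys = np.where(yf[sel] == self.classes[i], 1.0, -1.0)
                Zp = Zfb[:, sel, :]                         # (k, np, d)
                xm = Zp.mean(axis=1)                        # (k, d)
                ym = ys.mean()
                Zc = Zp - xm[:, None, :]
                G = np.matmul(Zc.transpose(0, 2, 1), Zc)
                G[:, np.arange(d), np.arange(d)] += self.lam
                rhs = np.matmul(Zc.transpose(0, 2, 1), (ys - ym)[:, None])
                w = np.linalg.solve(G, rhs)                 # (k, d, 1)
                b0 = ym - (xm[:, :, None] * w).sum(axis=1)  # (k, 1)
                s = (np.matmul(Zt_flat, w) + b0[:, None]).reshape(k, n_te, B)
                win = s > 0
                votes[..., i] += win
                votes[..., j] += ~win
                margins[..., i] += s
                margins[..., j] -= s
            # lexicographic (votes, margins) argmax via a combined key
            big = 2.0 * np.abs(margins).max() + 1.0
            votes *= big
            votes += margins
            pred = np.argmax(votes, axis=-1)                # (k, n_te, B)
            acc += correct_base[pred, trial_idx].mean(axis=1).sum(axis=1)
        return acc / (B * B)


class RawRidgeObjective:
    """Raw-feature ridge CTD objective with batched unit removal.

    ``kind='stability'`` scores the mean accuracy over all train/test bin
    pairs; ``kind='locality'`` fits the locality Gaussians to each training
    bin's accuracy-vs-testing-time row and scores the locality measure.
    Candidate removals reuse the inverse Gram of the full ensemble through
    an exact block-inverse downdate, so one step costs a single matrix
    inverse per (training bin, class pair).
    """

    def __init__(
        self,
        X: np.ndarray,
        y: np.ndarray,
        cond: np.ndarray,
        train_bins: np.ndarray,
        test_bins: np.ndarray,
        bin_times: np.ndarray,
        kind: str = "locality",
        lam: float = 1.0,
        seed: int = 0,
        train_frac: float = 0.75,
        sigma_bounds: tuple[float, float] | None = None,
        b: float = CHANCE_4,
    ):
        if kind not in ("stability", "locality"):
            raise ValueError("kind must be 'stability' or 'locality'")
        self.kind = kind
        self.name = kind
        X = np.asarray(X, dtype=float)
        self.y = np.asarray(y)
        self.classes = np.unique(self.y)
        self.pairs = class_pairs(len(self.classes))
        self.lam = float(lam)
        self.n_units = X.shape[1]
        rng = np.random.default_rng(np.random.SeedSequence(seed))
        tr, te = _stratified_split(cond, train_frac, rng)
        Xz = _zscore_cols(X, X[tr])
        self.Xtr, self.Xte = Xz[tr], Xz[te]
        self.ytr, self.yte = self.y[tr], self.y[te]
        self.train_bins = np.asarray(train_bins)
        self.test_bins = np.asarray(test_bins)
        self.train_times = np.asarray(bin_times)[self.train_bins]
        self.test_times = np.asarray(bin_times)[self.test_bins]
        self.sigma_bounds = sigma_bounds or default_sigma_bounds(self.test_times)
        self.b = b
        self._sel_pairs = [
            ((self.ytr == self.classes[i]) | (self.ytr == self.classes[j]), i, j)
            for i, j in self.pairs
        ]

    def _objective_from_rows(self, acc: np.ndarray) -> np.ndarray:
        """acc is (..., T1, T2)."""
        if self.kind == "stability":
            return acc.mean(axis=(-2, -1))
        return _locality_terms(acc, self.train_times, self.test_times,
                               self.b, self.sigma_bounds)

    def score(self, idx: np.ndarray) -> float:
        acc = self._accuracy_rows(np.asarray(idx), batch=False)
        return float(self._objective_from_rows(acc))

    def scores_without_each(self, idx: np.ndarray) -> np.ndarray:
        acc = self._accuracy_rows(np.asarray(idx), batch=True)
        return self._objective_from_rows(acc)

    def _accuracy_rows(self, idx: np.ndarray, batch: bool) -> np.ndarray:
        k = len(idx)
        nC = len(self.classes)
        Xte = self.Xte[:, idx, :][:, :, self.test_bins]    # (n_te, k, T2)
        n_te, _, T2 = Xte.shape
        Xte_flat = Xte.transpose(0, 2, 1).reshape(n_te * T2, k)
        T1 = len(self.train_bins)
        lead = (k,) if batch else ()
        acc = np.zeros(lead + (T1, T2))
        correct = (self.classes[:, None] == self.yte[None, :])  # (C, n_te)
        votes = np.empty(lead + (n_te, T2, nC))
        margins = np.empty(lead + (n_te, T2, nC))
        for a_i, t1 in enumerate(self.train_bins):
            votes[:] = 0.0
            margins[:] = 0.0
            for sel, i, j in self._sel_pairs:
                ys = np.where(self.ytr[sel] == self.classes[i], 1.0, -1.0)
                Xp = self.Xtr[sel][:, idx, t1]
                xm, ym = Xp.mean(axis=0), ys.mean()
                Xc = Xp - xm
                G = Xc.T @ Xc
                G[np.diag_indices_from(G)] += self.lam
                if batch:
                    A = np.linalg.inv(G)
                    w_full = A @ (Xc.T @ (ys - ym))
                    # exact solution with unit u dropped:
                    # w_{-u} = w_full_{-u} - A[:, u] * w_full[u] / A[u, u]
                    W = w_full[None, :] - (w_full / np.diag(A))[:, None] * A
                    b0 = ym - W @ xm                       # (k,)
                    s = (Xte_flat @ W.T).T.reshape(k, n_te, T2) + b0[:, None, None]
                else:
                    w = np.linalg.solve(G, Xc.T @ (ys - ym))
                    b0 = ym - xm @ w
                    s = (Xte_flat @ w).reshape(n_te, T2) + b0
                win = s > 0
                votes[..., i] += win
                votes[..., j] += ~win
                margins[..., i] += s
                margins[..., j] -= s
            big = 2.0 * np.abs(margins).max() + 1.0
            key = votes * big + margins
            pred = np.argmax(key, axis=-1)
            if batch:
                hit = correct[pred, np.arange(n_te)[None, :, None]]  # (k, n_te, T2)
                acc[:, a_i, :] = hit.mean(axis=1)
            else:
                hit = correct[pred, np.arange(n_te)[:, None]]
                acc[a_i, :] = hit.mean(axis=0)
        return acc


def combined_stable_pipeline(
    pop,
    config=None,
    seed: int = 0,
    lam: float | None = None,
    n_perm: int = 0,
):
    """Subspace + stable-ensemble extraction for one pseudo-population.

    Runs the greedy backward search (each candidate ensemble scored by its
    subspace-projected CTD over the cue-to-reward window) on the first
    outer fold's training trials, then evaluates the selected ensemble's
    full cross-temporal decoding — including bins beyond the optimization
    window — with the split/swap subspace protocol and, optionally,
    training-label permutation p-values.

    Returns (CTDResult, EnsembleTrace).
    """
    from .decoding import DecoderConfig, make_folds, tune_lambda, _zscore_params
    from .subspace import subspace_ctd, build_value_subspace, _stratified_halves

    if config is None:
        config = DecoderConfig()
    task = pop.meta["task"]
    y = pop.values.astype(int)
    cond = pop.condition_labels()
    win = np.flatnonzero(pop.window_mask(task.cue_on, task.reward))
    folds = make_folds(cond, config.n_outer_folds, seed)
    tr, _ = folds[0]
    if lam is None:
        rng = np.random.default_rng(np.random.SeedSequence(seed + 1))
        h1, h2 = _stratified_halves(cond, tr, rng)
        Xz = pop.rates
        mu, sd = _zscore_params(Xz)
        Xz = (Xz - mu) / sd
        model0 = build_value_subspace(Xz[h1][:, :, win], y[h1])
        lam = tune_lambda(model0.project(Xz[h2]), y[h2], cond[h2], win, config,
                          seed=seed + 2)
    obj = StableSubspaceObjective(pop.rates[tr][:, :, win], y[tr], cond[tr],
                                  lam=lam, seed=seed + 3)
    trace = greedy_backward_ensemble(obj, unit_ids=pop.unit_ids)
    sel_pos = np.flatnonzero(np.isin(pop.unit_ids, trace.selected_units))
    result, p = subspace_ctd(pop.subset_units(sel_pos), config, seed=seed + 4,
                             lam=lam, n_perm=n_perm)
    result.meta["ensemble_size"] = int(len(sel_pos))
    if p is not None:
        result.meta["perm_p"] = p
    return result, trace


# ---------------------------------------------------------------------------
# contributions and overlap tests
# ---------------------------------------------------------------------------

def accuracy_contribution(objective, ensemble_idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Leave-one-out contribution of each unit of an ensemble.

    raw delta = score(E) - score(E without u); ac = sign(delta) sqrt(|delta|).
    """
    ensemble_idx = np.asarray(ensemble_idx)
    full = objective.score(ensemble_idx)
    without = objective.scores_without_each(ensemble_idx)
    delta = full - without
    return delta, ac_transform(delta)


def ensemble_overlap_test(
    stable_sets: Sequence[np.ndarray],
    dynamic_sets: Sequence[np.ndarray],
    population_ids: np.ndarray,
    alpha: float = 0.01,
) -> dict:
    """Chi-square tests of independence between ensemble memberships.

    For each paired instance (same CV fold and dataset) the 2x2 table of
    joint membership over all population units is tested; p-values are
    corrected across instances with Benjamini-Hochberg FDR at ``alpha``.
    Instances with a degenerate margin (an empty or all-inclusive ensemble)
    are skipped.
    """
    if len(stable_sets) != len(dynamic_sets):
        raise ValueError("need paired ensemble instances")
    population_ids = np.asarray(population_ids)
    pvals, chi2s, skipped = [], [], 0
    for s_set, d_set in zip(stable_sets, dynamic_sets):
        in_s = np.isin(population_ids, np.asarray(s_set))
        in_d = np.isin(population_ids, np.asarray(d_set))
        table = np.array(
            [
                [np.sum(in_s & in_d), np.sum(in_s & ~in_d)],
                [np.sum(~in_s & in_d), np.sum(~in_s & ~in_d)],
            ],
            dtype=float,
        )
        if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
            skipped += 1
            pvals.append(np.nan)
            chi2s.append(np.nan)
            continue
        chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
        pvals.append(float(p))
        chi2s.append(float(chi2))
    pvals = np.asarray(pvals)
    ok = np.isfinite(pvals)
    reject = np.zeros(len(pvals), dtype=bool)
    if ok.any():
        reject[ok] = multipletests(pvals[ok], alpha=alpha, method="fdr_bh")[0]
    return {
        "p_values": pvals,
        "chi2": np.asarray(chi2s),
        "significant": reject,
        "n_significant": int(reject.sum()),
        "n_instances": len(pvals),
        "n_skipped": skipped,
    }


def hypergeom_enrichment(
    selected: np.ndarray, pool: np.ndarray, population: np.ndarray
) -> float:
    """One-sided hypergeometric p for over-representation of ``pool`` units
    in the selected ensemble."""
    selected = np.asarray(selected)
    pool = np.asarray(pool)
    population = np.asarray(population)
    N = len(population)
    K = int(np.isin(population, pool).sum())
    n = len(selected)
    x = int(np.isin(selected, pool).sum())
    return float(stats.hypergeom.sf(x - 1, N, K, n))
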