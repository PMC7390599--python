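"""Population-dynamics analyses and encoding/decoding correlations.

Trajectory speed is the Euclidean distance between successive time-bin
vectors of the trial-averaged population activity (in the neural space
spanned by the units' firing rates); it peaks when task events inject new
activity patterns.  Elapsed time itself is decodable from population
activity: a linear regression predicts the time-bin index from the
population vector, evaluated with leave-one-trial-out cross-validation.
Finally, unit-level encoding measures (strength, duration, stability) are
related to population-level contributions (subspace weights, ensemble
accuracy contributions) with Spearman correlations, which are invariant to
the monotone display transforms applied elsewhere.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .prep import RateMatrix


def trajectory_speed(pop: RateMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Speed of the trial-averaged population trajectory.

    Returns (midpoint times, speed); steps that cross an epoch junction are
    NaN because consecutive bins there are not contiguous in time.  The
    scale grows with the number of units (no per-unit normalization).
    """
    if pop.n_bins < 2:
        raise ValueError("need at least two bins")
    m = pop.rates.mean(axis=0)  # (units, bins)
    d = np.diff(m, axis=1)
    speed = np.linalg.norm(d, axis=0)
    same_epoch = pop.epoch_ids[1:] == pop.epoch_ids[:-1]
    speed = np.where(same_epoch, speed, np.nan)
    mid = (pop.bin_times_abs[1:] + pop.bin_times_abs[:-1]) / 2
    return mid, speed


def regress_time(
    pop: RateMatrix,
    bins: np.ndarray | None = None,
    ridge_eps: float = 1e-8,
) -> dict:
    """Leave-one-trial-out linear regression of bin index on activity.

    Each (trial, bin) population vector is a row; the target is the integer
    bin index.  LOO predictions use the closed-form grouped-residual
    identity e_loo = (I - H_gg)^{-1} e_g, equivalent to refitting without
    the trial.  When there are more units than rows an ill-conditioned fit
    is stabilized with a tiny ridge penalty and flagged.
    """
    if bins is None:
        bins = np.arange(pop.n_bins)
    bins = np.asarray(bins)
    n_tr, n_units = pop.n_trials, pop.n_units
    B = len(bins)
    if n_tr < 2:
        raise ValueError("leave-one-out needs at least two trials")
    R = pop.rates[:, :, bins]                      # (trials, units, B)
    X = np.concatenate(
        [np.ones((n_tr * B, 1)), R.transpose(0, 2, 1).reshape(n_tr * B, n_units)],
        axis=1,
    )
    y = np.tile(np.arange(B, dtype=float), n_tr)
    G = X.T @ X
    flagged = n_units + 1 >= n_tr * B
    lam = ridge_eps if flagged else 0.0
    G[np.diag_indices_from(G)] += lam
    try:
        A = np.linalg.inv(G)
    except np.linalg.LinAlgError:
        flagged = True
        G[np.diag_indices_from(G)] += max(ridge_eps, 1e-8)
        A = np.linalg.inv(G)
    beta = A @ (X.T @ y)
    yhat = X @ beta
    preds = np.empty((n_tr, B))
    for g in range(n_tr):
        rows = slice(g * B, (g + 1) * B)
        Xg = X[rows]
        Hgg = Xg @ A @ Xg.T
        e = y[rows] - yhat[rows]
        try:
            e_loo = np.linalg.solve(np.eye(B) - Hgg, e)
        except np.linalg.LinAlgError as exc:
            raise ValueError("degenerate leave-one-out system "
                             "(duplicated trial?)") from exc
        preds[g] = y[rows] - e_loo
    ss_res = float(((preds - y.reshape(n_tr, B)) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    return {
        "pred_mean": preds.mean(axis=0),
        "pred_sd": preds.std(axis=0),
        "pred": preds,
        "true": np.arange(B, dtype=float),
        "loo_r2": 1.0 - ss_res / ss_tot,
        "ridge_flagged": bool(flagged),
        "bin_times": pop.bin_times_abs[bins],
    }


def correlation_battery(
    measures: pd.DataFrame,
    contributions: pd.DataFrame,
    split_by_sign: tuple[str, ...] = ("stable_contrib",),
    min_n: int = 3,
) -> pd.DataFrame:
    """Spearman correlations between encoding measures and contributions.

    Both frames are indexed by unit id.  Columns listed in
    ``split_by_sign`` (ensemble accuracy contributions, whose distribution
    is asymmetric around zero) are correlated separately within their
    positive and negative strata.  Strata with fewer than ``min_n`` units
    give NaN.
    """
    joined = measures.join(contributions, how="inner")
    rows = []
    for m in measures.columns:
        for c in contributions.columns:
            strata = (
                [("pos", joined[c] > 0), ("neg", joined[c] < 0)]
                if c in split_by_sign
                else [("all", np.ones(len(joined), dtype=bool))]
            )
            for name, sel in strata:
                sub = joined.loc[sel, [m, c]].dropna()
                if len(sub) >= min_n:
                    r, p = stats.spearmanr(sub[m], sub[c])
                    rows.append((m, c, name, float(r), float(p), len(sub)))
                else:
                    rows.append((m, c, name, np.nan, np.nan, len(sub)))
    return pd.DataFrame(
        rows, columns=["measure", "contribution", "stratum", "spearman_r", "p", "n"]
    )
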