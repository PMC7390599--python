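"""Per-unit encoding statistics.

A unit's binned firing rate is modeled with a two-factor linear model
(categorical value x reward type with interaction) and per-bin F tests.
A bin counts as encoding a variable only when it lies inside a run of at
least ``k`` consecutive bins with p below ``alpha`` (7 bins at p < 0.01,
~175 ms with 25 ms steps, by default), which suppresses isolated
false-positive bins.  Three summary measures are computed over the delay
(cue offset to reward): encoding strength (mean -log10 p), encoding
duration (fraction of significant delay bins), and a stability measure
that penalizes sign reversals of between-value rate differences:

    S = avg_{v!=w} | (1/T) sum_t tanh(10 (xbar_v(t) - xbar_w(t)) / sp_vw(t)) |

with sp_vw the pooled across-trial SD.  A sensitivity index d' (absolute
mean difference over pooled SD of window-averaged rates, averaged over
value pairs) quantifies discriminability in raw-rate units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .prep import RateMatrix

P_FLOOR = 1e-300


# ---------------------------------------------------------------------------
# per-bin two-factor ANOVA (balanced, vectorized across bins)
# ---------------------------------------------------------------------------

def fit_bin_anova(
    rates: np.ndarray, values: np.ndarray, types: np.ndarray
) -> dict[str, np.ndarray]:
    """Per-bin F-test p-values for value, type and their interaction.

    ``rates`` is (trials, bins).  The design must be balanced (equal trial
    counts in every value x type cell), which holds for pseudo-populations
    by construction; balance makes type-II and type-III sums of squares
    coincide, so the classic balanced decomposition is used.  Bins with
    zero residual variance get p = 1 and are flagged.

    Returns a dict with keys ``value``, ``type``, ``interaction``,
    ``linear_value`` (slope test from a numeric-value model, used to
    identify non-linear value coders) and ``zero_variance``.
    """
    rates = np.asarray(rates, dtype=float)
    if rates.ndim == 1:
        rates = rates[:, None]
    n, n_bins = rates.shape
    vals_u, vi = np.unique(np.asarray(values), return_inverse=True)
    typ_u, ti = np.unique(np.asarray(types), return_inverse=True)
    a, b = len(vals_u), len(typ_u)
    if a < 2 or b < 2:
        raise ValueError("need >=2 levels of value and type")
    cell = vi * b + ti
    counts = np.bincount(cell, minlength=a * b)
    if counts.min() < 2:
        raise ValueError("need >=2 trials per condition")
    if counts.max() != counts.min():
        raise ValueError("design must be balanced; draw condition-matched trials")
    n_cell = counts[0]

    g = rates.mean(axis=0)
    onehot = lambda idx, k: np.eye(k)[idx]  # noqa: E731
    A = onehot(vi, a).T @ rates / (n / a)          # (a, bins) value means
    B = onehot(ti, b).T @ rates / (n / b)          # (b, bins) type means
    C = onehot(cell, a * b).T @ rates / n_cell     # (a*b, bins) cell means

    ss_a = (n / a) * ((A - g) ** 2).sum(axis=0)
    ss_b = (n / b) * ((B - g) ** 2).sum(axis=0)
    inter = C.reshape(a, b, n_bins) - A[:, None, :] - B[None, :, :] + g
    ss_ab = n_cell * (inter ** 2).sum(axis=(0, 1))
    resid = rates - C[cell]
    ss_err = (resid ** 2).sum(axis=0)

    df_a, df_b, df_ab = a - 1, b - 1, (a - 1) * (b - 1)
    df_err = n - a * b
    zero_var = ss_err <= 1e-300

    def pval(ss, df):
        with np.errstate(divide="ignore", invalid="ignore"):
            f = (ss / df) / (ss_err / df_err)
        p = stats.f.sf(f, df, df_err)
        p = np.where(zero_var, 1.0, p)
        return np.clip(p, P_FLOOR, 1.0)

    # numeric-value linear model: rate ~ value + type + value:type
    v_num = vals_u[vi].astype(float)
    v_c = v_num - v_num.mean()
    t_c = ti.astype(float) - ti.mean()
    X = np.column_stack([np.ones(n), v_c, t_c, v_c * t_c])
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ (X.T @ rates)
    rss = ((rates - X @ beta) ** 2).sum(axis=0)
    sigma2 = rss / (n - X.shape[1])
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = beta[1] / np.sqrt(sigma2 * XtX_inv[1, 1])
    p_lin = 2 * stats.t.sf(np.abs(tstat), n - X.shape[1])
    p_lin = np.clip(np.where(sigma2 <= 1e-300, 1.0, p_lin), P_FLOOR, 1.0)

    return {
        "value": pval(ss_a, df_a),
        "type": pval(ss_b, df_b),
        "interaction": pval(ss_ab, df_ab),
        "linear_value": p_lin,
        "zero_variance": zero_var,
    }


def anova_pvalues_statsmodels(
    rates_bin: np.ndarray, values: np.ndarray, types: np.ndarray
) -> tuple[float, float, float]:
    """Reference per-bin ANOVA through statsmodels OLS (slow; used to
    cross-check the vectorized balanced decomposition)."""
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    df = pd.DataFrame({"rate": rates_bin, "value": values, "type": types})
    model = ols("rate ~ C(value) * C(type)", data=df).fit()
    tab = sm.stats.anova_lm(model, typ=2)
    return (
        float(tab.loc["C(value)", "PR(>F)"]),
        float(tab.loc["C(type)", "PR(>F)"]),
        float(tab.loc["C(value):C(type)", "PR(>F)"]),
    )


# ---------------------------------------------------------------------------
# run-length significance rule and summary measures
# ---------------------------------------------------------------------------

def significance_runs(
    p: np.ndarray, alpha: float = 0.01, k: int = 7
) -> np.ndarray:
    """Mask of bins lying inside a run of >= k consecutive bins with p < alpha."""
    below = np.asarray(p) < alpha
    mask = np.zeros_like(below)
    i = 0
    n = len(below)
    while i < n:
        if below[i]:
            j = i
            while j < n and below[j]:
                j += 1
            if j - i >= k:
                mask[i:j] = True
            i = j
        else:
            i += 1
    return mask


def latency_from_mask(mask: np.ndarray, bin_times: np.ndarray) -> float:
    """Time of the first bin of the first qualifying run (NaN if none)."""
    idx = np.flatnonzero(mask)
    return float(bin_times[idx[0]]) if len(idx) else float("nan")


def encoding_strength(p_delay: np.ndarray) -> float:
    """Mean -log10 p over the delay bins (Eq. symbol es)."""
    p = np.clip(np.asarray(p_delay, dtype=float), P_FLOOR, 1.0)
    if p.size == 0:
        raise ValueError("need at least one delay bin")
    return float(np.mean(-np.log10(p)))


def pooled_sd(var_v: np.ndarray | float, var_w: np.ndarray | float) -> np.ndarray | float:
    """sp_vw = sqrt((s_v^2 + s_w^2) / 2)."""
    return np.sqrt((np.asarray(var_v, dtype=float) + np.asarray(var_w, dtype=float)) / 2)


def stability_measure(rates_delay: np.ndarray, values: np.ndarray) -> float:
    """Stability S in [0, 1] from per-bin value-pair rate differences.

    Sign reversals of xbar_v - xbar_w across the delay cancel inside the
    time sum and drive S toward 0; a persistent, well-separated difference
    saturates tanh and drives S toward 1.  A zero pooled SD contributes
    +-1 when the mean difference is nonzero and 0 when it is zero.
    """
    rates_delay = np.asarray(rates_delay, dtype=float)
    values = np.asarray(values)
    vals_u = np.unique(values)
    means, vars_ = {}, {}
    for v in vals_u:
        r = rates_delay[values == v]
        means[v] = r.mean(axis=0)
        vars_[v] = r.var(axis=0, ddof=1)
    terms = []
    for i, v in enumerate(vals_u):
        for w in vals_u[i + 1:]:
            d = means[v] - means[w]
            sp = pooled_sd(vars_[v], vars_[w])
            with np.errstate(divide="ignore", invalid="ignore"):
                z = 10.0 * d / sp
            z = np.where(sp == 0, np.where(d == 0, 0.0, np.sign(d) * np.inf), z)
            terms.append(abs(float(np.mean(np.tanh(z)))))
    return float(np.mean(terms))


def dprime(window_rates: np.ndarray, values: np.ndarray) -> float:
    """Mean sensitivity index over value pairs.

    ``window_rates`` are per-trial rates averaged over the analysis window
    (cue onset to reward by default upstream).  Pairs with zero pooled SD
    are excluded; NaN when no pair is evaluable.
    """
    window_rates = np.asarray(window_rates, dtype=float)
    values = np.asarray(values)
    vals_u = np.unique(values)
    ds = []
    for i, v in enumerate(vals_u):
        for w in vals_u[i + 1:]:
            rv, rw = window_rates[values == v], window_rates[values == w]
            sp = float(pooled_sd(rv.var(ddof=1), rw.var(ddof=1)))
            if sp == 0:
                continue
            ds.append(abs(rv.mean() - rw.mean()) / sp)
    return float(np.mean(ds)) if ds else float("nan")


@dataclass
class EncodingProfile:
    """Per-unit encoding summary (per-bin p-values plus delay measures)."""

    unit_id: int
    pvals: dict[str, np.ndarray]
    masks: dict[str, np.ndarray]
    latency: dict[str, float]
    peak_bin_time: float
    duration: float
    es: float
    S: float
    dprime: float
    flags: dict = field(default_factory=dict)


def encode_population(
    pop: RateMatrix,
    alpha: float = 0.01,
    k: int = 7,
) -> tuple[list[EncodingProfile], pd.DataFrame]:
    """Run the per-bin ANOVA and delay summaries for every unit.

    The run-length rule is applied on the full bin grid; encoding strength,
    duration, stability and the peak bin are computed over the delay (cue
    offset to reward).  d' uses per-trial rates averaged from cue onset to
    reward.
    """
    task = pop.meta["task"]
    delay_mask = pop.window_mask(*task.delay)
    cue_rwd_mask = pop.window_mask(task.cue_on, task.reward)
    if not delay_mask.any():
        raise ValueError("no bins fall inside the delay window")

    profiles = []
    rows = []
    for u in range(pop.n_units):
        r = pop.rates[:, u, :]
        pv = fit_bin_anova(r, pop.values, pop.types)
        masks = {
            var: significance_runs(pv[var], alpha, k)
            for var in ("value", "type", "interaction", "linear_value")
        }
        lat = {
            var: latency_from_mask(masks[var], pop.bin_times_abs)
            for var in ("value", "type")
        }
        p_delay = pv["value"][delay_mask]
        peak_idx = int(np.argmin(p_delay))
        peak_time = float(pop.bin_times_abs[delay_mask][peak_idx])
        duration = float(masks["value"][delay_mask].mean())
        es = encoding_strength(p_delay)
        S = stability_measure(r[:, delay_mask], pop.values)
        dp = dprime(r[:, cue_rwd_mask].mean(axis=1), pop.values)
        prof = EncodingProfile(
            unit_id=int(pop.unit_ids[u]),
            pvals=pv,
            masks=masks,
            latency=lat,
            peak_bin_time=peak_time,
            duration=duration,
            es=es,
            S=S,
            dprime=dp,
            flags={"zero_variance_bins": int(pv["zero_variance"].sum())},
        )
        profiles.append(prof)
        rows.append(
            {
                "unit_id": prof.unit_id,
                "latency_value": lat["value"],
                "latency_type": lat["type"],
                "peak_bin_time": peak_time,
                "duration": duration,
                "es": es,
                "S": S,
                "dprime": dp,
                "sig_value": bool(masks["value"].any()),
                "sig_type": bool(masks["type"].any()),
                "sig_interaction": bool(masks["interaction"].any()),
                "sig_linear_value": bool(masks["linear_value"].any()),
            }
        )
    return profiles, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# split-half sequence / duration analysis
# ---------------------------------------------------------------------------

def split_half_sequence_analysis(
    pop: RateMatrix,
    seed: int = 0,
    alpha: float = 0.01,
    k: int = 7,
) -> dict:
    """Split trials in half and compare delay peak bins and durations.

    Trials are split stratified by condition (keeping both halves
    balanced); the per-bin value ANOVA with the run rule is applied to each
    half over the delay.  Only units significant in both halves are kept;
    their peak-encoding bins (bin of minimal p) and encoding durations are
    correlated across halves with Spearman's R.
    """
    task = pop.meta["task"]
    delay_mask = pop.window_mask(*task.delay)
    delay_times = pop.bin_times_abs[delay_mask]

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    cond = pop.condition_labels()
    half1 = np.zeros(pop.n_trials, dtype=bool)
    for c in np.unique(cond):
        idx = np.flatnonzero(cond == c)
        pick = rng.permutation(idx)[: len(idx) // 2]
        half1[pick] = True

    halves = (half1, ~half1)
    peaks = np.full((2, pop.n_units), np.nan)
    durs = np.full((2, pop.n_units), np.nan)
    sig = np.zeros((2, pop.n_units), dtype=bool)
    for h, sel in enumerate(halves):
        vals, typs = pop.values[sel], pop.types[sel]
        for u in range(pop.n_units):
            p = fit_bin_anova(pop.rates[sel, u, :][:, delay_mask], vals, typs)["value"]
            mask = significance_runs(p, alpha, k)
            sig[h, u] = mask.any()
            peaks[h, u] = delay_times[int(np.argmin(p))]
            durs[h, u] = mask.mean()

    kept = sig[0] & sig[1]
    out = {
        "kept_units": pop.unit_ids[kept],
        "n_kept": int(kept.sum()),
        "peak_train": peaks[0, kept],
        "peak_test": peaks[1, kept],
        "duration_train": durs[0, kept],
        "duration_test": durs[1, kept],
    }
    if kept.sum() >= 3:
        rp, pp = stats.spearmanr(peaks[0, kept], peaks[1, kept])
        rd, pd_ = stats.spearmanr(durs[0, kept], durs[1, kept])
        out.update(
            {"peak_r": float(rp), "peak_p": float(pp),
             "duration_r": float(rd), "duration_p": float(pd_)}
        )
    else:
        out.update({"peak_r": float("nan"), "peak_p": float("nan"),
                    "duration_r": float("nan"), "duration_p": float("nan")})
    return out


def coverage_distribution(
    durations: np.ndarray, grid: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Reverse cumulative distribution: fraction of units with duration >= x."""
    durations = np.asarray(durations, dtype=float)
    if grid is None:
        grid = np.linspace(0.0, 1.0, 101)
    curve = (durations[None, :] >= grid[:, None]).mean(axis=1)
    return grid, curve


def coverage_ks_test(durations_a: np.ndarray, durations_b: np.ndarray):
    """Two-sample KS test between regional duration distributions."""
    return stats.ks_2samp(durations_a, durations_b)


def classify_nonlinear_value_units(profiles: list[EncodingProfile]) -> tuple[np.ndarray, float]:
    """Units significant for categorical value but with no interaction and no
    linear-value significance (same run-length rule for every criterion)."""
    flags = np.array(
        [
            p.masks["value"].any()
            and not p.masks["interaction"].any()
            and not p.masks["linear_value"].any()
            for p in profiles
        ]
    )
    return flags, float(flags.mean()) if len(flags) else float("nan")


# ---------------------------------------------------------------------------
# region-level comparisons
# ---------------------------------------------------------------------------

def _chi2_2x2(sig_a: int, n_a: int, sig_b: int, n_b: int) -> tuple[float, float]:
    table = np.array([[sig_a, n_a - sig_a], [sig_b, n_b - sig_b]], dtype=float)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return 0.0, 1.0
    chi2, p, _, expected = stats.chi2_contingency(table, correction=False)
    if expected.min() < 1:
        return float("nan"), float("nan")
    return float(chi2), float(p)


def region_comparisons(
    masks_a: np.ndarray,
    masks_b: np.ndarray,
    latencies_a: np.ndarray,
    latencies_b: np.ndarray,
    alpha: float = 0.01,
) -> dict:
    """Compare encoding between two regions.

    Per-bin 2x2 chi-square of the proportion of significant units (marked
    significant at p <= alpha), an overall any-time-encoding chi-square,
    and a Kruskal-Wallis test on latencies.  Bins with an expected cell
    below 1 are skipped (NaN).
    """
    masks_a, masks_b = np.asarray(masks_a), np.asarray(masks_b)
    n_a, n_b = masks_a.shape[0], masks_b.shape[0]
    n_bins = masks_a.shape[1]
    chi2_bins = np.full(n_bins, np.nan)
    p_bins = np.full(n_bins, np.nan)
    for t in range(n_bins):
        chi2_bins[t], p_bins[t] = _chi2_2x2(
            int(masks_a[:, t].sum()), n_a, int(masks_b[:, t].sum()), n_b
        )
    chi2_all, p_all = _chi2_2x2(
        int(masks_a.any(axis=1).sum()), n_a, int(masks_b.any(axis=1).sum()), n_b
    )
    la = np.asarray(latencies_a, dtype=float)
    lb = np.asarray(latencies_b, dtype=float)
    la, lb = la[np.isfinite(la)], lb[np.isfinite(lb)]
    if len(la) and len(lb):
        try:
            kw = stats.kruskal(la, lb)
            kw_h, kw_p = float(kw.statistic), float(kw.pvalue)
        except ValueError:  # all observations identical
            kw_h, kw_p = 0.0, 1.0
    else:
        kw_h, kw_p = float("nan"), float("nan")
    return {
        "chi2_per_bin": chi2_bins,
        "p_per_bin": p_bins,
        "sig_per_bin": p_bins <= alpha,
        "chi2_overall": chi2_all,
        "p_overall": p_all,
        "kw_h": kw_h,
        "kw_p": kw_p,
    }
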