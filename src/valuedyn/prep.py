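"""Rate estimation, epoching/binning and pseudo-population assembly.

Spike trains are convolved with a Gaussian kernel (unit area per spike, so
the integral of the rate estimate recovers the spike count up to boundary
truncation), divided into three epochs centered on the reward-predicting
cue onset, the response-instruction cue and reward delivery, and averaged
in overlapping bins (100 ms wide, stepped every 25 ms for encoding and
every 50 ms for decoding analyses).  Units recorded in different sessions
are combined into pseudo-populations by drawing condition-matched trials
per unit; the draw is repeated to build several datasets and population
results are reported as the average over them.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .syndata import SyntheticSession, TaskConfig

logger = logging.getLogger(__name__)

#: (name, reference event column, start offset, end offset) for the three
#: concatenated epochs.  Chosen to abut without overlap for the default
#: task timing (cue epoch ends at +1.3 s = response epoch start at
#: 2.1 - 0.8 s; response epoch ends at +0.45 s = reward epoch start at
#: 3.0 - 0.45 s).
DEFAULT_EPOCHS: tuple[tuple[str, str, float, float], ...] = (
    ("cue", "t_cue_on", -0.5, 1.3),
    ("response", "t_resp_cue", -0.8, 0.45),
    ("reward", "t_reward", -0.45, 0.5),
)

EVENT_NOMINAL = {"t_cue_on": "cue_on", "t_cue_off": "cue_off",
                 "t_resp_cue": "response_cue", "t_reward": "reward"}


@dataclass
class RateMatrix:
    """Trials x units x time-bins firing-rate tensor with labels.

    ``bin_times`` are bin centers relative to each epoch's reference event;
    ``bin_times_abs`` place the same bins on the trial clock (cue onset at
    0) using the task's nominal event times, which is what windowing
    helpers such as :meth:`window_mask` use.
    """

    rates: np.ndarray              # (trials, units, bins)
    bin_times: np.ndarray          # (bins,) epoch-relative centers
    bin_times_abs: np.ndarray      # (bins,) trial-clock centers
    epoch_ids: np.ndarray          # (bins,) epoch name per bin
    values: np.ndarray             # (trials,)
    types: np.ndarray              # (trials,)
    unit_ids: np.ndarray           # (units,)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        t, u, b = self.rates.shape
        if not (len(self.values) == len(self.types) == t):
            raise ValueError("label length must match trial count")
        if len(self.unit_ids) != u or len(self.bin_times) != b:
            raise ValueError("axis metadata does not match tensor shape")
        for name in np.unique(self.epoch_ids):
            bt = self.bin_times[self.epoch_ids == name]
            if not np.all(np.diff(bt) > 0):
                raise ValueError("bin_times must increase within an epoch")

    @property
    def n_trials(self) -> int:
        return self.rates.shape[0]

    @property
    def n_units(self) -> int:
        return self.rates.shape[1]

    @property
    def n_bins(self) -> int:
        return self.rates.shape[2]

    def window_mask(self, t0: float, t1: float) -> np.ndarray:
        """Bins whose absolute center lies in [t0, t1]."""
        return (self.bin_times_abs >= t0 - 1e-9) & (self.bin_times_abs <= t1 + 1e-9)

    def subset_units(self, idx: Sequence[int] | np.ndarray) -> "RateMatrix":
        idx = np.asarray(idx)
        return replace(self, rates=self.rates[:, idx, :], unit_ids=self.unit_ids[idx],
                       meta=dict(self.meta))

    def subset_bins(self, mask: np.ndarray) -> "RateMatrix":
        return replace(
            self,
            rates=self.rates[:, :, mask],
            bin_times=self.bin_times[mask],
            bin_times_abs=self.bin_times_abs[mask],
            epoch_ids=self.epoch_ids[mask],
            meta=dict(self.meta),
        )

    def condition_labels(self) -> np.ndarray:
        """Integer (value, type) condition code per trial."""
        types_u, type_codes = np.unique(self.types, return_inverse=True)
        return (self.values - 1) * len(types_u) + type_codes


def smooth_rates(
    spike_times: np.ndarray,
    t_start: float,
    t_end: float,
    kernel_sd: float = 0.1,
    dt: float = 0.005,
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian-kernel rate estimate for one spike train.

    Returns sample centers and the rate in Hz: the sum over spikes of a
    unit-area Gaussian of SD ``kernel_sd`` seconds, evaluated on a grid of
    resolution ``dt``.  An empty train gives an all-zero rate.
    """
    if kernel_sd <= 0:
        raise ValueError("kernel_sd must be > 0")
    spike_times = np.sort(np.asarray(spike_times, dtype=float))
    n = int(round((t_end - t_start) / dt))
    edges = t_start + dt * np.arange(n + 1)
    counts, _ = np.histogram(spike_times, bins=edges)
    rate = gaussian_filter1d(counts.astype(float), sigma=kernel_sd / dt,
                             mode="constant") / dt
    centers = edges[:-1] + dt / 2
    return centers, rate


def _bin_grid(length: float, bin_width: float, step: float) -> np.ndarray:
    """Bin start offsets for an epoch of the given length.

    One bin per step-start inside the epoch (count = ceil(length / step)),
    so 1 s of activity yields 40 bins at a 25 ms step and 20 at 50 ms; the
    last bins may extend up to ``bin_width - step`` past the epoch end,
    which the smoothed-rate grid covers.
    """
    n = int(np.ceil(length / step - 1e-9))
    if n < 1:
        raise ValueError("epoch shorter than one step")
    return step * np.arange(n)


def epoch_and_bin(
    rates: np.ndarray,
    t_grid: np.ndarray,
    events: Mapping[str, np.ndarray],
    task: TaskConfig,
    bin_width: float = 0.1,
    step: float = 0.025,
    epochs: Sequence[tuple[str, str, float, float]] = DEFAULT_EPOCHS,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Bin smoothed rates into three concatenated event-locked epochs.

    ``rates`` is (trials, samples) on the uniform grid ``t_grid``; ``events``
    maps event columns to per-trial times.  Bins are half-open
    [start, start + bin_width) and the bin value is the mean rate inside.
    Trials with a missing (NaN) event are dropped with a warning.

    Returns (binned (kept_trials, bins), bin_times, bin_times_abs,
    epoch_ids, kept_trial_mask).
    """
    dt = float(t_grid[1] - t_grid[0])
    t0 = float(t_grid[0]) - dt / 2  # left edge of first sample
    n_trials, n_samples = rates.shape

    keep = np.ones(n_trials, dtype=bool)
    for _, ev_col, _, _ in epochs:
        ev = np.asarray(events[ev_col], dtype=float)
        bad = ~np.isfinite(ev)
        if bad.any():
            warnings.warn(f"dropping {bad.sum()} trial(s) with missing {ev_col}")
            keep &= ~bad

    cs = np.concatenate(
        [np.zeros((n_trials, 1)), np.cumsum(rates, axis=1)], axis=1
    )

    nominal = {k: getattr(task, EVENT_NOMINAL[k]) for k in EVENT_NOMINAL}
    out_blocks, bt_rel, bt_abs, ep_ids = [], [], [], []
    for name, ev_col, a, b in epochs:
        starts_rel = a + _bin_grid(b - a, bin_width, step)
        centers = starts_rel + bin_width / 2
        ev = np.asarray(events[ev_col], dtype=float)
        # dropped trials get the nominal event time so indexing stays valid
        ev = np.where(np.isfinite(ev), ev, nominal[ev_col])
        # per-trial sample index of each bin start / end
        i0 = np.rint((ev[:, None] + starts_rel[None, :] - t0) / dt).astype(int)
        nw = int(round(bin_width / dt))
        i1 = i0 + nw
        if (i0 < 0).any() or (i1 > n_samples).any():
            raise ValueError(
                f"epoch {name!r} extends beyond the smoothed rate grid"
            )
        rows = np.arange(n_trials)[:, None]
        block = (cs[rows, i1] - cs[rows, i0]) / nw
        out_blocks.append(block)
        bt_rel.append(centers)
        bt_abs.append(nominal[ev_col] + centers)
        ep_ids.append(np.full(len(centers), name, dtype=object))

    binned = np.concatenate(out_blocks, axis=1)[keep]
    return (
        binned,
        np.concatenate(bt_rel),
        np.concatenate(bt_abs),
        np.concatenate(ep_ids).astype(str),
        keep,
    )


def bin_session(
    session: SyntheticSession,
    kernel_sd: float = 0.1,
    bin_width: float = 0.1,
    step: float = 0.025,
    dt: float = 0.005,
    epochs: Sequence[tuple[str, str, float, float]] = DEFAULT_EPOCHS,
) -> RateMatrix:
    """Smooth, epoch and bin a whole synthetic session into a RateMatrix."""
    w0, w1 = session.sim_window
    n_samples = int(round((w1 - w0) / dt))
    edges = w0 + dt * np.arange(n_samples + 1)
    t_grid = edges[:-1] + dt / 2
    sigma = kernel_sd / dt

    events = {
        c: session.trial_table[c].to_numpy()
        for c in ("t_cue_on", "t_cue_off", "t_resp_cue", "t_reward")
    }

    per_unit = []
    bin_meta = None
    for spec in session.unit_specs:
        trains = session.spikes[spec.unit_id]
        counts = np.zeros((len(trains), n_samples))
        for i, train in enumerate(trains):
            if len(train):
                counts[i], _ = np.histogram(train, bins=edges)
        smoothed = gaussian_filter1d(counts, sigma=sigma, axis=1, mode="constant") / dt
        binned, bt, bta, ep, keep = epoch_and_bin(
            smoothed, t_grid, events, session.task, bin_width, step, epochs
        )
        per_unit.append(binned)
        bin_meta = (bt, bta, ep, keep)

    bt, bta, ep, keep = bin_meta
    rates = np.stack(per_unit, axis=1)  # (trials, units, bins)
    return RateMatrix(
        rates=rates,
        bin_times=bt,
        bin_times_abs=bta,
        epoch_ids=ep,
        values=session.trial_table["value"].to_numpy()[keep],
        types=session.trial_table["type"].to_numpy()[keep],
        unit_ids=np.array(session.unit_ids),
        meta={
            "kernel_sd": kernel_sd,
            "bin_width": bin_width,
            "step": step,
            "dt": dt,
            "task": session.task,
            "session_seed": session.seed,
        },
    )


def filter_low_rate(
    session: SyntheticSession, threshold: float = 1.0
) -> tuple[list[int], dict]:
    """Exclude units whose session-wide mean rate is lower than ``threshold``.

    The mean is total spikes over total simulated time.  Units at exactly
    the threshold are retained (the rule is strictly "lower than").
    """
    w0, w1 = session.sim_window
    total_t = (w1 - w0) * session.n_trials
    kept, excluded = [], []
    for uid in session.unit_ids:
        n_spk = sum(len(tr) for tr in session.spikes[uid])
        mean_rate = n_spk / total_t
        (kept if mean_rate >= threshold else excluded).append(uid)
    if not kept:
        raise ValueError("all units fall below the rate threshold")
    report = {
        "threshold_hz": threshold,
        "n_kept": len(kept),
        "n_excluded": len(excluded),
        "excluded_ids": excluded,
    }
    if excluded:
        logger.info("excluded %d unit(s) below %.2f Hz", len(excluded), threshold)
    return kept, report


def build_pseudopopulation(
    sessions: Sequence[RateMatrix],
    n_datasets: int = 5,
    trials_per_condition: int | None = None,
    seed: int = 0,
) -> list[RateMatrix]:
    """Assemble pseudo-populations by drawing condition-matched trials.

    For each of ``n_datasets`` datasets and each unit, ``trials_per_condition``
    trials are drawn without replacement per (value, type) condition and
    concatenated across units as pseudo-trials.  Every unit therefore
    contributes the same number of trials per condition.  Downstream
    population statistics are averaged over the datasets.
    """
    if not sessions:
        raise ValueError("need at least one session")
    ref = sessions[0]
    for s in sessions[1:]:
        if not np.allclose(s.bin_times_abs, ref.bin_times_abs):
            raise ValueError("sessions must share the same bin grid")

    conds = sorted(
        {(int(v), str(t)) for s in sessions for v, t in zip(s.values, s.types)}
    )
    min_count = None
    for s_i, s in enumerate(sessions):
        for v, ty in conds:
            c = int(np.sum((s.values == v) & (s.types == ty)))
            if c == 0:
                raise ValueError(f"session {s_i} has no trials for condition {(v, ty)}")
            min_count = c if min_count is None else min(min_count, c)
    if trials_per_condition is None:
        trials_per_condition = min_count
    if trials_per_condition > min_count:
        raise ValueError(
            f"requested {trials_per_condition} trials/condition but a session "
            f"has only {min_count}"
        )

    tpc = trials_per_condition
    n_units_total = sum(s.n_units for s in sessions)
    n_bins = ref.n_bins
    values = np.repeat([v for v, _ in conds], tpc)
    types = np.repeat([t for _, t in conds], tpc).astype(object).astype(str)

    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_datasets)
    datasets = []
    for d in range(n_datasets):
        rng = np.random.default_rng(children[d])
        rates = np.empty((len(conds) * tpc, n_units_total, n_bins))
        u_off = 0
        unit_ids = []
        for s in sessions:
            cond_idx = {
                (v, ty): np.flatnonzero((s.values == v) & (s.types == ty))
                for v, ty in conds
            }
            for u in range(s.n_units):
                for c, (v, ty) in enumerate(conds):
                    pick = rng.choice(cond_idx[(v, ty)], size=tpc, replace=False)
                    rates[c * tpc:(c + 1) * tpc, u_off + u, :] = s.rates[pick, u, :]
            unit_ids.extend(s.unit_ids.tolist())
            u_off += s.n_units
        meta = dict(ref.meta)
        meta.update({"dataset_index": d + 1, "draw_seed": seed})
        datasets.append(
            RateMatrix(
                rates=rates,
                bin_times=ref.bin_times.copy(),
                bin_times_abs=ref.bin_times_abs.copy(),
                epoch_ids=ref.epoch_ids.copy(),
                values=values.copy(),
                types=types.copy(),
                unit_ids=np.array(unit_ids),
                meta=meta,
            )
        )
    return datasets
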