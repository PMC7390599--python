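"""Synthetic sessions with planted value-coding regimes.

Each synthetic unit fires as an inhomogeneous Poisson process whose rate
function depends on the trial's value (1..4), reward type (juice vs bar)
and time within the trial.  The coding classes cover the regimes seen in
prefrontal delay activity: stable (persistent) linear value coding,
non-monotonic value tuning, sequential (bump) coding that tiles the delay,
coding that reverses sign mid-delay, reward-type coding, pure time ramps,
and untuned units.  Ground-truth class labels are recorded so downstream
analyses can be validated against what was planted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

REWARD_TYPES = ("juice", "bar")

CODING_CLASSES = (
    "stable_linear",
    "stable_nonmonotonic",
    "sequential",
    "reversing",
    "type_coder",
    "time_ramp",
    "untuned",
)


class ConfigurationError(ValueError):
    """Invalid task or unit configuration."""


@dataclass(frozen=True)
class TaskConfig:
    """Temporal structure of a single-cue trial.

    Times are in seconds relative to the onset of the reward-predicting
    cue.  The delay (cue offset to reward, ~2.4 s by default) is
    interrupted by a response-instruction cue that triggers a joystick
    movement; reward is delivered at ``reward``.
    """

    cue_on: float = 0.0
    cue_off: float = 0.6
    response_cue: float = 2.1
    reward: float = 3.0
    pre_window: float = 0.5
    post_window: float = 0.5
    n_values: int = 4
    n_types: int = 2
    trials_per_condition: int = 40

    def __post_init__(self) -> None:
        if not (self.cue_on < self.cue_off < self.response_cue < self.reward):
            raise ConfigurationError(
                "event order must be cue_on < cue_off < response_cue < reward"
            )
        if self.pre_window <= 0 or self.post_window <= 0:
            raise ConfigurationError("windows must be positive")
        if self.n_values < 2 or self.n_types < 1 or self.trials_per_condition < 1:
            raise ConfigurationError("need >=2 values, >=1 type, >=1 trial/condition")

    @property
    def values(self) -> np.ndarray:
        return np.arange(1, self.n_values + 1)

    @property
    def mean_value(self) -> float:
        return float(self.values.mean())

    @property
    def delay(self) -> tuple[float, float]:
        """Cue offset to reward delivery."""
        return (self.cue_off, self.reward)

    @property
    def trial_window(self) -> tuple[float, float]:
        return (self.cue_on - self.pre_window, self.reward + self.post_window)

    def event_times(self) -> dict[str, float]:
        return {
            "cue_on": self.cue_on,
            "cue_off": self.cue_off,
            "response_cue": self.response_cue,
            "reward": self.reward,
        }


@dataclass(frozen=True)
class UnitSpec:
    """Parameters of one synthetic unit.

    ``value_gain`` is in Hz per value step for linear classes; for
    ``stable_nonmonotonic`` units ``value_rates`` gives an additive rate
    per value instead.  Sequential units multiply a Gaussian bump at
    ``bump_center`` (SD ``bump_sd``) by a value-dependent amplitude
    ``bump_amp + value_gain * (value - mean value)``.  Reversing units
    flip the sign of the value slope at ``reversal_time``.
    """

    unit_id: int
    coding_class: str
    baseline_rate: float = 5.0
    value_gain: float = 0.0
    value_rates: tuple[float, float, float, float] | None = None
    bump_center: float | None = None
    bump_sd: float | None = None
    bump_amp: float = 0.0
    reversal_time: float | None = None

    def __post_init__(self) -> None:
        if self.coding_class not in CODING_CLASSES:
            raise ConfigurationError(f"unknown coding_class {self.coding_class!r}")
        if self.baseline_rate < 0:
            raise ConfigurationError("baseline_rate must be >= 0")
        if self.coding_class == "sequential":
            if self.bump_center is None or self.bump_sd is None or self.bump_sd <= 0:
                raise ConfigurationError("sequential units need bump_center and bump_sd > 0")
        if self.coding_class == "reversing" and self.reversal_time is None:
            raise ConfigurationError("reversing units need reversal_time")
        if self.coding_class == "stable_nonmonotonic" and self.value_rates is None:
            raise ConfigurationError("stable_nonmonotonic units need value_rates")


@dataclass
class SyntheticSession:
    """Spike trains, trial table and ground-truth labels for one session."""

    task: TaskConfig
    unit_specs: list[UnitSpec]
    trial_table: pd.DataFrame
    spikes: dict[int, list[np.ndarray]]  # unit_id -> per-trial spike time arrays
    ground_truth: dict[int, str]
    seed: int | None = None
    sim_window: tuple[float, float] = (0.0, 0.0)

    @property
    def n_trials(self) -> int:
        return len(self.trial_table)

    @property
    def unit_ids(self) -> list[int]:
        return [s.unit_id for s in self.unit_specs]


def build_rate_function(
    spec: UnitSpec, task: TaskConfig, value: int, rtype: str
) -> Callable[[np.ndarray], np.ndarray]:
    """Deterministic firing-rate curve (Hz) for one unit and condition.

    Tuned activity spans cue onset to reward delivery; outside that window
    units sit at baseline.  The returned callable accepts an array of trial
    times (s) and returns nonnegative rates.
    """
    if value not in set(task.values.tolist()):
        raise ConfigurationError(f"value {value} outside 1..{task.n_values}")
    if rtype not in REWARD_TYPES:
        raise ConfigurationError(f"unknown reward type {rtype!r}")

    base = spec.baseline_rate
    dv = value - task.mean_value
    lo, hi = task.cue_on, task.reward
    cls = spec.coding_class

    def in_window(t: np.ndarray) -> np.ndarray:
        return (t >= lo) & (t <= hi)

    if cls == "untuned":
        def rate(t):
            t = np.asarray(t, dtype=float)
            return np.full(t.shape, base)
    elif cls == "stable_linear":
        def rate(t):
            t = np.asarray(t, dtype=float)
            return np.clip(base + in_window(t) * spec.value_gain * dv, 0.0, None)
    elif cls == "stable_nonmonotonic":
        add = spec.value_rates[value - 1]
        def rate(t):
            t = np.asarray(t, dtype=float)
            return np.clip(base + in_window(t) * add, 0.0, None)
    elif cls == "sequential":
        amp = spec.bump_amp + spec.value_gain * dv
        c, sd = spec.bump_center, spec.bump_sd
        def rate(t):
            t = np.asarray(t, dtype=float)
            bump = amp * np.exp(-0.5 * ((t - c) / sd) ** 2)
            return np.clip(base + bump, 0.0, None)
    elif cls == "reversing":
        rt = spec.reversal_time
        def rate(t):
            t = np.asarray(t, dtype=float)
            sign = np.where(t < rt, 1.0, -1.0)
            return np.clip(base + in_window(t) * sign * spec.value_gain * dv, 0.0, None)
    elif cls == "type_coder":
        # symmetric type effect: +g/2 for juice, -g/2 for bar
        shift = spec.value_gain * (0.5 if rtype == "juice" else -0.5)
        def rate(t):
            t = np.asarray(t, dtype=float)
            return np.clip(base + in_window(t) * shift, 0.0, None)
    elif cls == "time_ramp":
        span = hi - lo
        def rate(t):
            t = np.asarray(t, dtype=float)
            frac = np.clip((t - lo) / span, 0.0, 1.0)
            return np.clip(base + spec.value_gain * frac, 0.0, None)
    else:  # pragma: no cover - guarded by UnitSpec validation
        raise ConfigurationError(f"unknown coding_class {cls!r}")

    return rate


def _sample_inhomogeneous_poisson(
    rate: Callable[[np.ndarray], np.ndarray],
    t0: float,
    t1: float,
    rng: np.random.Generator,
    rate_ceiling: float,
) -> np.ndarray:
    """Thinning sampler: homogeneous candidates at ``rate_ceiling``, kept
    with probability rate(t)/ceiling."""
    lam = rate_ceiling * (t1 - t0)
    n = rng.poisson(lam)
    if n == 0:
        return np.empty(0)
    t = rng.uniform(t0, t1, size=n)
    keep = rng.uniform(0.0, rate_ceiling, size=n) < rate(t)
    return np.sort(t[keep])


def _rate_ceiling(rate: Callable, t0: float, t1: float) -> float:
    grid = np.linspace(t0, t1, 1201)
    return float(rate(grid).max()) * 1.001 + 1e-9


def generate_session(
    specs: Sequence[UnitSpec],
    task: TaskConfig,
    seed: int,
    sim_pad: float = 0.5,
) -> SyntheticSession:
    """Draw spike trains for a balanced session of single-cue trials.

    Every (value, type) condition appears ``task.trials_per_condition``
    times in a shuffled order.  Spikes are drawn per trial over the trial
    window extended by ``sim_pad`` on both sides so kernel smoothing near
    the epoch edges sees realistic activity.
    """
    if len(specs) == 0:
        raise ConfigurationError("need at least one unit spec")
    rng = np.random.default_rng(np.random.SeedSequence(seed))

    conds = [
        (v, ty)
        for v in task.values.tolist()
        for ty in REWARD_TYPES[: task.n_types]
    ]
    cond_per_trial = np.repeat(np.arange(len(conds)), task.trials_per_condition)
    rng.shuffle(cond_per_trial)
    values = np.array([conds[c][0] for c in cond_per_trial])
    types = np.array([conds[c][1] for c in cond_per_trial])

    ev = task.event_times()
    trial_table = pd.DataFrame(
        {
            "trial_id": np.arange(len(cond_per_trial)),
            "value": values,
            "type": types,
            "t_cue_on": ev["cue_on"],
            "t_cue_off": ev["cue_off"],
            "t_resp_cue": ev["response_cue"],
            "t_reward": ev["reward"],
        }
    )

    w0 = task.trial_window[0] - sim_pad
    w1 = task.trial_window[1] + sim_pad

    spikes: dict[int, list[np.ndarray]] = {}
    for spec in specs:
        # per-condition rate functions and ceilings, reused across trials
        per_cond = {}
        for v, ty in conds:
            fn = build_rate_function(spec, task, v, ty)
            per_cond[(v, ty)] = (fn, _rate_ceiling(fn, w0, w1))
        trains = []
        for v, ty in zip(values, types):
            fn, ceil = per_cond[(v, ty)]
            trains.append(_sample_inhomogeneous_poisson(fn, w0, w1, rng, ceil))
        spikes[spec.unit_id] = trains

    return SyntheticSession(
        task=task,
        unit_specs=list(specs),
        trial_table=trial_table,
        spikes=spikes,
        ground_truth={s.unit_id: s.coding_class for s in specs},
        seed=seed,
        sim_window=(w0, w1),
    )


# Default parameter ranges for sample_population.  These are the study
# conditions of all synthetic experiments: baselines in the low cortical
# range, modest persistent value gains, and strong transient bumps whose
# amplitude is value-modulated -- a population in which the raw code is
# dominated by dynamic activity while a weaker stable code runs underneath.
DEFAULT_PARAM_RANGES: dict[str, dict[str, tuple[float, float]]] = {
    "common": {"baseline_rate": (2.0, 8.0)},
    "stable_linear": {"value_gain": (0.5, 1.0)},
    "stable_nonmonotonic": {"peak_gain": (2.0, 4.0)},
    "sequential": {
        "bump_amp": (8.0, 14.0),
        "value_gain": (3.0, 6.0),
        "bump_sd": (0.15, 0.3),
    },
    "reversing": {"value_gain": (1.5, 3.0)},
    "type_coder": {"value_gain": (2.0, 4.0)},
    "time_ramp": {"value_gain": (3.0, 8.0)},
}


def sample_population(
    composition: Mapping[str, int],
    seed: int,
    task: TaskConfig | None = None,
    param_ranges: Mapping[str, Mapping[str, tuple[float, float]]] | None = None,
) -> list[UnitSpec]:
    """Draw unit specs for a mixed population.

    Sequential units' bump centers tile cue onset to reward on an even grid
    (strictly increasing), reversal times fall inside the delay, and scalar
    parameters are drawn uniformly from ``param_ranges`` (defaults above).
    """
    if task is None:
        task = TaskConfig()
    total = sum(composition.values())
    if total <= 0:
        raise ConfigurationError("composition must request at least one unit")
    for cls, n in composition.items():
        if cls not in CODING_CLASSES:
            raise ConfigurationError(f"unknown coding_class {cls!r}")
        if n < 0:
            raise ConfigurationError("counts must be >= 0")

    ranges = {k: dict(v) for k, v in DEFAULT_PARAM_RANGES.items()}
    if param_ranges:
        for k, v in param_ranges.items():
            ranges.setdefault(k, {}).update(v)

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    specs: list[UnitSpec] = []
    uid = 0

    def u(lo_hi: tuple[float, float]) -> float:
        return float(rng.uniform(*lo_hi))

    for cls in CODING_CLASSES:  # fixed class order for determinism
        n = composition.get(cls, 0)
        if n == 0:
            continue
        if cls == "sequential":
            # tile the cue->reward interval, inset half a step at each end
            centers = np.linspace(task.cue_on, task.reward, n + 2)[1:-1]
        for i in range(n):
            base = u(ranges["common"]["baseline_rate"])
            kw: dict = {"unit_id": uid, "coding_class": cls, "baseline_rate": base}
            if cls == "stable_linear":
                kw["value_gain"] = u(ranges["stable_linear"]["value_gain"])
            elif cls == "stable_nonmonotonic":
                g = u(ranges["stable_nonmonotonic"]["peak_gain"])
                rates = [0.0] * task.n_values
                rates[int(rng.integers(task.n_values))] = g
                kw["value_rates"] = tuple(rates)
            elif cls == "sequential":
                kw["bump_center"] = float(centers[i])
                kw["bump_sd"] = u(ranges["sequential"]["bump_sd"])
                kw["bump_amp"] = u(ranges["sequential"]["bump_amp"])
                kw["value_gain"] = u(ranges["sequential"]["value_gain"])
            elif cls == "reversing":
                kw["value_gain"] = u(ranges["reversing"]["value_gain"])
                d0, d1 = task.delay
                kw["reversal_time"] = float(rng.uniform(d0 + 0.2, d1 - 0.2))
            elif cls == "type_coder":
                kw["value_gain"] = u(ranges["type_coder"]["value_gain"])
            elif cls == "time_ramp":
                kw["value_gain"] = u(ranges["time_ramp"]["value_gain"])
            specs.append(UnitSpec(**kw))
            uid += 1
    return specs


def write_session(session: SyntheticSession, outdir: str | Path) -> None:
    """Write spikes.csv, trials.csv and ground_truth.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for uid, trains in session.spikes.items():
        for trial_id, train in enumerate(trains):
            for t in train:
                rows.append((uid, trial_id, t))
    pd.DataFrame(rows, columns=["unit_id", "trial_id", "spike_time_s"]).to_csv(
        outdir / "spikes.csv", index=False
    )
    session.trial_table.to_csv(outdir / "trials.csv", index=False)
    meta = {
        "ground_truth": {str(k): v for k, v in session.ground_truth.items()},
        "task": asdict(session.task),
        "seed": session.seed,
        "sim_window": list(session.sim_window),
        "unit_specs": [asdict(s) for s in session.unit_specs],
    }
    (outdir / "ground_truth.json").write_text(json.dumps(meta, indent=1))


def read_session(indir: str | Path) -> SyntheticSession:
    """Read a session written by :func:`write_session`."""
    indir = Path(indir)
    meta = json.loads((indir / "ground_truth.json").read_text())
    task_kw = meta["task"]
    task = TaskConfig(**task_kw)
    specs = []
    for d in meta["unit_specs"]:
        if d.get("value_rates") is not None:
            d["value_rates"] = tuple(d["value_rates"])
        specs.append(UnitSpec(**d))
    trials = pd.read_csv(indir / "trials.csv")
    sp = pd.read_csv(indir / "spikes.csv")
    spikes: dict[int, list[np.ndarray]] = {}
    n_trials = len(trials)
    for spec in specs:
        sub = sp[sp.unit_id == spec.unit_id]
        by_trial = {k: np.sort(g.spike_time_s.to_numpy()) for k, g in sub.groupby("trial_id")}
        spikes[spec.unit_id] = [by_trial.get(i, np.empty(0)) for i in range(n_trials)]
    return SyntheticSession(
        task=task,
        unit_specs=specs,
        trial_table=trials,
        spikes=spikes,
        ground_truth={int(k): v for k, v in meta["ground_truth"].items()},
        seed=meta.get("seed"),
        sim_window=tuple(meta.get("sim_window", task.trial_window)),
    )
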