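"""End-to-end pipeline orchestration.

``run_pipeline`` executes the stages simulate -> prep -> encoding ->
decoding -> subspace_ensembles -> dynamics on a synthetic configuration,
writing figure-ready CSV tables, JSON run metadata (seeds, sizes, timings)
and a markdown summary to the output directory.  Stages omitted from the
configuration are skipped with an explicit notice (dependent stages are
skipped too); any stage failure halts the run with a stage-tagged error
while earlier outputs remain on disk.
"""

from __future__ import annotations

import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .syndata import TaskConfig, sample_population, generate_session, write_session
from .prep import bin_session, build_pseudopopulation, filter_low_rate
from .encoding import encode_population, split_half_sequence_analysis
from .decoding import DecoderConfig, decode_datasets, make_folds
from .subspace import build_value_subspace, subspace_decode_datasets
from .decoding import _zscore_params
from .ensembles import (
    RawRidgeObjective,
    StableSubspaceObjective,
    ensemble_overlap_test,
    greedy_backward_ensemble,
)
from .dynamics import trajectory_speed, regress_time, correlation_battery

ALL_STAGES = ("simulate", "prep", "encoding", "decoding", "subspace_ensembles", "dynamics")

DEFAULT_CONFIG = {
    "stages": list(ALL_STAGES),
    "population": {"stable_linear": 10, "sequential": 12, "untuned": 10},
    "session_trials_per_condition": 30,
    "trials_per_condition": 24,
    "n_datasets": 2,
    "n_perm": 0,
    "kernel_sd": 0.1,
    "coarse_bin": 0.2,
}


class PipelineError(RuntimeError):
    def __init__(self, stage: str, exc: Exception):
        super().__init__(f"stage {stage!r} failed: {exc}")
        self.stage = stage


def run_pipeline(config: dict | str | Path, outdir: str | Path, seed: int = 0) -> dict:
    """Run the configured stages; returns a dict of summary results."""
    if not isinstance(config, dict):
        config = yaml.safe_load(Path(config).read_text())
    cfg = {**DEFAULT_CONFIG, **(config or {})}
    stages = list(cfg["stages"])
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    notices: list[str] = []
    summary: dict = {"seed": seed, "config": {k: v for k, v in cfg.items()}}
    timings: dict[str, float] = {}
    state: dict = {}

    def stage_enabled(name: str, needs: tuple[str, ...] = ()) -> bool:
        if name not in stages:
            notices.append(f"stage {name!r} skipped (not in config)")
            return False
        missing = [n for n in needs if n not in state]
        if missing:
            notices.append(f"stage {name!r} skipped (requires {missing})")
            return False
        return True

    def run_stage(name: str, fn):
        t0 = time.time()
        try:
            fn()
        except Exception as exc:  # noqa: BLE001 - re-raised with stage tag
            _write_meta(outdir, summary, timings, notices + [f"FAILED at {name}: {exc}"])
            raise PipelineError(name, exc) from exc
        timings[name] = round(time.time() - t0, 2)

    # ------------------------------------------------------------------ simulate
    if stage_enabled("simulate"):
        def _simulate():
            task = TaskConfig(trials_per_condition=cfg["session_trials_per_condition"])
            specs = sample_population(cfg["population"], seed=seed, task=task)
            session = generate_session(specs, task, seed=seed + 1)
            kept, report = filter_low_rate(session)
            write_session(session, outdir / "session")
            state["session"], state["task"] = session, task
            summary["simulate"] = {"n_units": len(specs), "n_trials": session.n_trials,
                                   "rate_filter": report}
        run_stage("simulate", _simulate)

    # ------------------------------------------------------------------ prep
    if stage_enabled("prep", needs=("session",)):
        def _prep():
            session, task = state["session"], state["task"]
            cb = cfg["coarse_bin"]
            state["rm_enc"] = bin_session(session, kernel_sd=cfg["kernel_sd"])
            state["rm_coarse"] = bin_session(session, kernel_sd=cfg["kernel_sd"],
                                             bin_width=cb, step=cb)
            state["pops"] = build_pseudopopulation(
                [state["rm_coarse"]], cfg["n_datasets"],
                cfg["trials_per_condition"], seed=seed + 2,
            )
            summary["prep"] = {
                "encoding_bins": state["rm_enc"].n_bins,
                "coarse_bins": state["rm_coarse"].n_bins,
                "n_datasets": cfg["n_datasets"],
            }
        run_stage("prep", _prep)

    # ------------------------------------------------------------------ encoding
    if stage_enabled("encoding", needs=("rm_enc",)):
        def _encoding():
            profiles, df = encode_population(state["rm_enc"])
            df.to_csv(outdir / "encoding_profiles.csv", index=False)
            sh = split_half_sequence_analysis(state["rm_enc"], seed=seed + 3)
            state["profiles_df"] = df.set_index("unit_id")
            summary["encoding"] = {
                "frac_value_sig": float(df.sig_value.mean()),
                "split_half_peak_r": sh["peak_r"],
                "split_half_n_kept": sh["n_kept"],
            }
        run_stage("encoding", _encoding)

    # ------------------------------------------------------------------ decoding
    if stage_enabled("decoding", needs=("pops",)):
        def _decoding():
            task = state["task"]
            pops = state["pops"]
            delay = np.flatnonzero(pops[0].window_mask(*task.delay))
            dc = DecoderConfig(n_perm=cfg["n_perm"])
            res = decode_datasets(pops, dc, seed=seed + 4, n_perm=cfg["n_perm"],
                                  train_bins=delay, test_bins=delay)
            pd.DataFrame(res.accuracy, index=res.train_times,
                         columns=res.test_times).to_csv(outdir / "ctd_raw.csv")
            state["raw_ctd"], state["delay_bins"] = res, delay
            summary["decoding"] = {"diag_mean": float(np.mean(res.diagonal)),
                                   "offdiag_min": float(res.accuracy.min())}
        run_stage("decoding", _decoding)

    # ------------------------------------------------------------------ subspace + ensembles
    if stage_enabled("subspace_ensembles", needs=("pops", "delay_bins")):
        def _subspace_ensembles():
            task = state["task"]
            pops = state["pops"]
            delay = state["delay_bins"]
            win = np.flatnonzero(pops[0].window_mask(task.cue_on, task.reward))
            dc = DecoderConfig(n_perm=cfg["n_perm"])
            stable_sets, dyn_sets = [], []
            stable_contrib = {}
            weights = {}
            for d, pop in enumerate(pops):
                y = pop.values.astype(int)
                cond = pop.condition_labels()
                folds = make_folds(cond, 5, seed + 600 + d)
                tr, _ = folds[0]
                Xz = pop.rates
                mu, sd = _zscore_params(Xz)
                Xz = (Xz - mu) / sd
                model = build_value_subspace(Xz[:, :, win], y)
                for u, w in zip(pop.unit_ids, model.unit_weights):
                    weights.setdefault(int(u), []).append(float(w))
                obj = StableSubspaceObjective(pop.rates[tr][:, :, win], y[tr],
                                              cond[tr], lam=10.0, seed=seed + 650 + d)
                trace = greedy_backward_ensemble(obj, unit_ids=pop.unit_ids)
                stable_sets.append(trace.selected_units)
                for u, c in zip(trace.unit_ids, trace.contributions()):
                    stable_contrib.setdefault(int(u), []).append(c)
                objL = RawRidgeObjective(
                    pop.rates[tr], y[tr], cond[tr],
                    train_bins=delay[::3], test_bins=delay,
                    bin_times=pop.bin_times_abs, kind="locality",
                    lam=10.0, seed=seed + 700 + d,
                )
                traceL = greedy_backward_ensemble(objL, unit_ids=pop.unit_ids)
                dyn_sets.append(traceL.selected_units)
            res = subspace_decode_datasets(
                pops, dc, seed=seed + 5, n_perm=cfg["n_perm"],
                train_bins=delay, test_bins=delay,
                unit_subsets=[
                    np.flatnonzero(np.isin(pops[d].unit_ids, stable_sets[d]))
                    for d in range(len(pops))
                ],
            )
            pd.DataFrame(res.accuracy, index=res.train_times,
                         columns=res.test_times).to_csv(outdir / "ctd_stable.csv")
            overlap = ensemble_overlap_test(stable_sets, dyn_sets, pops[0].unit_ids)
            contrib_df = pd.DataFrame({
                "subspace_weight": {u: float(np.mean(v)) for u, v in weights.items()},
                "stable_contrib": {u: float(np.nanmean(v)) if np.isfinite(v).any()
                                   else np.nan for u, v in stable_contrib.items()},
            })
            contrib_df.index.name = "unit_id"
            contrib_df.to_csv(outdir / "contributions.csv")
            state["contrib_df"] = contrib_df
            summary["subspace_ensembles"] = {
                "stable_sizes": [int(len(s)) for s in stable_sets],
                "dynamic_sizes": [int(len(s)) for s in dyn_sets],
                "combined_min_acc": float(res.accuracy.min()),
                "overlap_significant": overlap["n_significant"],
            }
        run_stage("subspace_ensembles", _subspace_ensembles)

    # ------------------------------------------------------------------ dynamics
    if stage_enabled("dynamics", needs=("rm_enc",)):
        def _dynamics():
            rm50 = bin_session(state["session"], kernel_sd=0.05,
                               bin_width=0.1, step=0.05)
            mid, speed = trajectory_speed(rm50)
            pd.DataFrame({"time_s": mid, "speed": speed}).to_csv(
                outdir / "trajectory_speed.csv", index=False)
            reg = regress_time(state["pops"][0] if "pops" in state else rm50)
            pd.DataFrame({"bin": reg["true"], "pred_mean": reg["pred_mean"],
                          "pred_sd": reg["pred_sd"]}).to_csv(
                outdir / "time_regression.csv", index=False)
            summary["dynamics"] = {"time_loo_r2": reg["loo_r2"]}
            if "profiles_df" in state and "contrib_df" in state:
                corr = correlation_battery(
                    state["profiles_df"][["es", "duration", "S"]],
                    state["contrib_df"],
                )
                corr.to_csv(outdir / "correlations.csv", index=False)
                summary["dynamics"]["n_correlations"] = len(corr)
        run_stage("dynamics", _dynamics)

    _write_meta(outdir, summary, timings, notices)
    return summary


def _write_meta(outdir: Path, summary: dict, timings: dict, notices: list[str]) -> None:
    meta = {"summary": summary, "timings_s": timings, "notices": notices}
    (outdir / "run_metadata.json").write_text(json.dumps(meta, indent=1, default=str))
    lines = ["# Pipeline run summary", ""]
    for stage, vals in summary.items():
        if stage in ("seed", "config"):
            continue
        lines.append(f"## {stage}")
        lines.append("```")
        lines.append(json.dumps(vals, indent=1, default=str))
        lines.append("```")
    if notices:
        lines.append("## notices")
        lines.extend(f"- {n}" for n in notices)
    (outdir / "report.md").write_text("\n".join(lines) + "\n")
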