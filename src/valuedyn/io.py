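"""HDF5 / CSV persistence for rate tensors and decoding results."""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .prep import RateMatrix
from .syndata import TaskConfig
from .decoding import CTDResult


def save_rate_matrix(rm: RateMatrix, path: str | Path) -> None:
    """Write a RateMatrix (or pseudo-population dataset) to HDF5."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta = dict(rm.meta)
    task = meta.pop("task", None)
    meta = {k: v for k, v in meta.items()
            if isinstance(v, (int, float, str, bool, type(None)))}
    with h5py.File(path, "w") as f:
        f.create_dataset("rates", data=rm.rates, compression="gzip", compression_opts=1)
        f.create_dataset("bin_times", data=rm.bin_times)
        f.create_dataset("bin_times_abs", data=rm.bin_times_abs)
        f.create_dataset("epoch_ids", data=rm.epoch_ids.astype("S"))
        f.create_dataset("values", data=rm.values.astype(int))
        f.create_dataset("types", data=rm.types.astype("S"))
        f.create_dataset("unit_ids", data=rm.unit_ids.astype(int))
        f.attrs["meta"] = json.dumps(meta)
        if task is not None:
            f.attrs["task"] = json.dumps(asdict(task))


def load_rate_matrix(path: str | Path) -> RateMatrix:
    with h5py.File(path, "r") as f:
        meta = json.loads(f.attrs.get("meta", "{}"))
        if "task" in f.attrs:
            meta["task"] = TaskConfig(**json.loads(f.attrs["task"]))
        return RateMatrix(
            rates=f["rates"][()],
            bin_times=f["bin_times"][()],
            bin_times_abs=f["bin_times_abs"][()],
            epoch_ids=f["epoch_ids"][()].astype(str),
            values=f["values"][()],
            types=f["types"][()].astype(str),
            unit_ids=f["unit_ids"][()],
            meta=meta,
        )


def save_ctd_result(res: CTDResult, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        f.create_dataset("accuracy", data=res.accuracy)
        f.create_dataset("train_times", data=res.train_times)
        f.create_dataset("test_times", data=res.test_times)
        if res.p_agg is not None:
            f.create_dataset("p_agg", data=res.p_agg)
        if res.per_dataset is not None:
            f.create_dataset("per_dataset", data=np.stack(res.per_dataset))
        meta = {k: v for k, v in res.meta.items()
                if isinstance(v, (int, float, str, bool, type(None)))}
        f.attrs["meta"] = json.dumps(meta)


def load_ctd_result(path: str | Path) -> CTDResult:
    with h5py.File(path, "r") as f:
        return CTDResult(
            accuracy=f["accuracy"][()],
            train_times=f["train_times"][()],
            test_times=f["test_times"][()],
            p_agg=f["p_agg"][()] if "p_agg" in f else None,
            per_dataset=list(f["per_dataset"][()]) if "per_dataset" in f else None,
            meta=json.loads(f.attrs.get("meta", "{}")),
        )


def ctd_diagonal_csv(res: CTDResult, path: str | Path) -> None:
    pd.DataFrame(
        {"time_s": res.train_times, "accuracy": res.diagonal}
    ).to_csv(path, index=False)
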