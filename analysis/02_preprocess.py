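"""Smooth, bin and assemble pseudo-population datasets.

Reads the session written by 01_simulate.py, estimates rates with a 100 ms
SD Gaussian kernel, bins them on the encoding grid (100 ms bins every
25 ms), a coarse search grid (non-overlapping 200 ms bins) and a medium
grid (100 ms non-overlapping, the scaled decoding grid), and draws five
pseudo-population datasets of 40 trials per condition.  Tensors are stored
as HDF5 under results/prep/.
"""

import argparse
from pathlib import Path

from valuedyn.syndata import read_session
from valuedyn.prep import bin_session, build_pseudopopulation
from valuedyn.io import save_rate_matrix


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--session", type=Path, default=Path("results/session"))
    ap.add_argument("--out", type=Path, default=Path("results/prep"))
    ap.add_argument("--trials-per-condition", type=int, default=40)
    ap.add_argument("--n-datasets", type=int, default=5)
    args = ap.parse_args()

    session = read_session(args.session)
    grids = {
        "encoding": dict(bin_width=0.1, step=0.025),
        "coarse": dict(bin_width=0.2, step=0.2),
        "medium": dict(bin_width=0.1, step=0.1),
    }
    args.out.mkdir(parents=True, exist_ok=True)
    for name, kw in grids.items():
        rm = bin_session(session, kernel_sd=0.1, **kw)
        save_rate_matrix(rm, args.out / f"rates_{name}.h5")
        print(f"{name} grid: {rm.n_bins} bins, tensor {rm.rates.shape}")
        if name in ("coarse", "medium"):
            pops = build_pseudopopulation(
                [rm], args.n_datasets, args.trials_per_condition, seed=args.seed + 2
            )
            for d, pop in enumerate(pops):
                save_rate_matrix(pop, args.out / f"pop_{name}_d{d + 1}.h5")
            print(f"  -> {args.n_datasets} pseudo-population datasets "
                  f"({pops[0].n_trials} pseudo-trials each)")


if __name__ == "__main__":
    main()
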