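"""Per-unit encoding statistics on the encoding grid.

Runs the per-bin value/type/interaction ANOVA with the 7-consecutive-bin
significance rule, the delay summary measures (encoding strength, duration,
stability S, d'), the split-half sequence/duration reliability analysis and
the non-linear value-coder classification.  Writes encoding_profiles.csv
and split_half.json under results/encoding/.
"""

import argparse
import json
from pathlib import Path

import numpy as np

from valuedyn.io import load_rate_matrix
from valuedyn.encoding import (
    encode_population,
    split_half_sequence_analysis,
    classify_nonlinear_value_units,
    coverage_distribution,
)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--rates", type=Path, default=Path("results/prep/rates_encoding.h5"))
    ap.add_argument("--out", type=Path, default=Path("results/encoding"))
    args = ap.parse_args()

    rm = load_rate_matrix(args.rates)
    args.out.mkdir(parents=True, exist_ok=True)
    profiles, df = encode_population(rm)
    nl_flags, nl_prop = classify_nonlinear_value_units(profiles)
    df["nonlinear_value_coder"] = nl_flags
    df.to_csv(args.out / "encoding_profiles.csv", index=False)
    print(f"{df.sig_value.mean():.1%} of units encode value (run rule), "
          f"{df.sig_type.mean():.1%} encode type, "
          f"{nl_prop:.1%} are non-linear value coders")

    sh = split_half_sequence_analysis(rm, seed=args.seed + 3)
    print(f"split-half: {sh['n_kept']} units significant in both halves; "
          f"peak-bin Spearman R = {sh['peak_r']:.2f} (p = {sh['peak_p']:.2g}), "
          f"duration R = {sh['duration_r']:.2f}")
    grid, curve = coverage_distribution(df.duration.to_numpy())
    out = {k: (v.tolist() if isinstance(v, np.ndarray) else v) for k, v in sh.items()}
    out["coverage_grid"] = grid.tolist()
    out["coverage_curve"] = curve.tolist()
    (args.out / "split_half.json").write_text(json.dumps(out, indent=1))


if __name__ == "__main__":
    main()
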