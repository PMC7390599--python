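"""Simulate the study session: a 120-unit mixed population.

Generates one synthetic session with 30 stable-linear, 40 sequential and
50 untuned units (50 trials per condition at the session level, so
pseudo-population draws of 40 stay random), applies the 1 Hz exclusion,
and writes spikes.csv / trials.csv / ground_truth.json under
results/session/.
"""

import argparse
import json
from pathlib import Path

from valuedyn.syndata import TaskConfig, sample_population, generate_session, write_session
from valuedyn.prep import filter_low_rate
from valuedyn.experiments import STUDY_COMPOSITION


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results/session"))
    args = ap.parse_args()

    task = TaskConfig(trials_per_condition=50)
    specs = sample_population(STUDY_COMPOSITION, seed=args.seed, task=task)
    session = generate_session(specs, task, seed=args.seed + 1)
    kept, report = filter_low_rate(session)
    write_session(session, args.out)
    print(f"wrote session with {len(specs)} units x {session.n_trials} trials to {args.out}")
    print(f"composition: {STUDY_COMPOSITION}")
    print(f"1 Hz exclusion: kept {report['n_kept']}, excluded {report['n_excluded']}")
    (args.out / "simulate_summary.json").write_text(json.dumps(report, indent=1))


if __name__ == "__main__":
    main()
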