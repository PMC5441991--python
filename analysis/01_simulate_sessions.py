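"""Simulate the two psychoacoustic cancellation experiments.

Experiment 1: one virtual participant measures every 50 Hz between 0.25
and 8 kHz across 8 one-kHz-band sittings.  Experiment 2: three virtual
participants repeat 1-8 kHz (1 kHz steps) on 8 sittings each, with
per-sitting transducer-coupling jitter.  Trial records land in
results/ as plain CSV; the experiment-1 truth model is stored as JSON so
later stages can score recovery.

Run:  python analysis/01_simulate_sessions.py [--seed 1]
"""

import argparse
from pathlib import Path

from bccancel.config import ExperimentConfig
from bccancel.pipeline import simulate_experiment

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()
    RESULTS.mkdir(exist_ok=True)

    cfg1 = ExperimentConfig(experiment="exp1", model_seed=args.seed,
                            run_seed=args.seed)
    sim1 = simulate_experiment(cfg1)
    sim1.records.to_csv(RESULTS / "exp1_records.csv", index=False)
    sim1.model.to_json(RESULTS / "exp1_truth_model.json")
    n_grade1 = (sim1.records["grade"] == 1).sum() // 2
    print(f"experiment 1: {len(sim1.records)} records "
          f"({n_grade1} trials graded 1, to be excluded)")

    for k in range(3):
        cfg2 = ExperimentConfig(experiment="exp2", model_seed=args.seed + k,
                                run_seed=100 * args.seed + k)
        sim2 = simulate_experiment(cfg2)
        sim2.records.to_csv(RESULTS / f"exp2_participant{k + 1}_records.csv",
                            index=False)
        print(f"experiment 2, participant {k + 1}: {len(sim2.records)} records")


if __name__ == "__main__":
    main()
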