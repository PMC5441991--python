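"""Across-sitting variability of the repeated 1-8 kHz measurements.

Reads the three experiment-2 participants, computes per-frequency,
per-ear means and sample SDs of cancellation level and phase, then runs
the paired comparisons: contralateral-vs-ipsilateral phase SD (expected
larger contralaterally, growing with frequency, from placement jitter),
level SD (expected similar — coupling changes hit both ears equally) and
the grade-vs-frequency curve.

Run after 01:  python analysis/03_session_variability.py
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from bccancel.analysis import paired_sd_test
from bccancel.pipeline import analyze_exp2

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    tables, grades = [], []
    ipsi_sd, contra_sd, freqs = [], [], []
    for k in (1, 2, 3):
        rec = pd.read_csv(RESULTS / f"exp2_participant{k}_records.csv")
        summ = analyze_exp2(rec)
        tables.append(summ.table.assign(participant=k))
        grades.append(rec.groupby("freq_hz")["grade"].mean().rename(f"p{k}"))
        wide = summ.table.pivot(index="freq_hz", columns="ear",
                                values="sd_phase_deg").dropna()
        ipsi_sd += list(wide["ipsi"])
        contra_sd += list(wide["contra"])
        freqs += list(wide.index)

    pd.concat(tables).to_csv(RESULTS / "exp2_variability.csv", index=False)

    phase_test = paired_sd_test(np.asarray(ipsi_sd), np.asarray(contra_sd))
    rho = stats.spearmanr(freqs, contra_sd).statistic
    grade_curve = pd.concat(grades, axis=1).mean(axis=1)
    grade_curve.rename("mean_grade").to_csv(RESULTS / "exp2_mean_grades.csv")

    report = {
        "phase_sd_paired_t": {"t": phase_test.t, "p": phase_test.p,
                              "n": phase_test.n},
        "contra_phase_sd_vs_freq_spearman": float(rho),
        "grade_min_at_hz": float(grade_curve.idxmin()),
        "grade_max_at_hz": float(grade_curve.idxmax()),
    }
    (RESULTS / "exp2_tests.json").write_text(json.dumps(report, indent=1))
    print(f"phase SD ipsi vs contra: t={phase_test.t:.2f}, p={phase_test.p:.4f} "
          f"(n={phase_test.n} frequency-participant pairs)")
    print(f"contra phase SD vs frequency: Spearman rho={rho:.2f}")
    print(f"mean grade minimal at {grade_curve.idxmin():.0f} Hz, "
          f"maximal at {grade_curve.idxmax():.0f} Hz")


if __name__ == "__main__":
    main()
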