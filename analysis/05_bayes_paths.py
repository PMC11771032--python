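#!/usr/bin/env python
"""Bayesian characterization of every mined path.

For each unique path from the whole-population run, draw from the Beta
posteriors of the outcome rate inside and outside the antecedent and
summarize the prevalence ratio against the cohort average: posterior mean,
95% equal-tailed credible interval, and the certainty that the ratio
exceeds the 1 + p threshold of the strictest task that found the path.

Writes results/05_posteriors.tsv.
"""

import json
from pathlib import Path

import pandas as pd

from guhapaths.bayes import path_posterior
from guhapaths.quantifiers import FourFoldTable

ROOT = Path(__file__).resolve().parents[1]
SEED = 20_250_926
DRAWS = 100_000

TASK_P = {
    "single": 0.5, "task1": 0.55, "task2": 0.70, "task3": 1.00,
    "task4": 1.20, "task5": 1.40, "task6": 1.50,
}


def main() -> None:
    with open(ROOT / "results" / "03_paths.json") as fh:
        paths = json.load(fh)

    rows = []
    for i, entry in enumerate(paths):
        t = FourFoldTable(**entry["table"])
        p_task = max(TASK_P[label] for label in entry["tasks"])
        s = path_posterior(t, p_task=p_task, draws=DRAWS, seed=SEED + i,
                           path=tuple(entry["predicates"]))
        rows.append(
            {
                "predicates": ";".join(entry["predicates"]),
                "ratio_mean": round(s.ratio_mean, 4),
                "ci_low": round(s.ci_low, 4),
                "ci_high": round(s.ci_high, 4),
                "p_task": p_task,
                "prob_exceeds": round(s.prob_exceeds, 4),
            }
        )
        print(f"{rows[-1]['predicates']}: ratio {rows[-1]['ratio_mean']:.2f} "
              f"[{rows[-1]['ci_low']:.2f}, {rows[-1]['ci_high']:.2f}], "
              f"P(ratio >= {1 + p_task:.2f}) = {rows[-1]['prob_exceeds']:.3f}")

    frame = pd.DataFrame(
        rows, columns=["predicates", "ratio_mean", "ci_low", "ci_high",
                       "p_task", "prob_exceeds"],
    )
    out = ROOT / "results" / "05_posteriors.tsv"
    frame.to_csv(out, sep="\t", index=False)
    print(f"wrote {out} ({len(frame)} paths)")


if __name__ == "__main__":
    main()
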