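#!/usr/bin/env python
"""Repeat the path search separately among women and men.

Stratification halves the support available to every conjunction, so the
schedule drops to Base 100 with p = 1 plus a looser p = 0.6 companion
task, alpha = 0.001, up to five predicates.  The outcome: among men the
5-predicate plant just clears the p = 1 task (realized stratum lift 2.00,
a = 120), while among women no conjunction reaches p = 1 and the plant
only surfaces under the p = 0.6 task — the same asymmetry that forces a
looser frequency coefficient for one stratum in practice.  Within a
stratum the stratum's own sex predicate is constant-true, so every path
also appears in a redundant sex-augmented variant; both are reported
as found.

Writes results/04_stratified_counts.json and per-stratum path TSVs.
"""

import json
from pathlib import Path

from guhapaths.coding import PredicateMatrix
from guhapaths.mining import TaskConfig, paths_to_frame, stratified_run

ROOT = Path(__file__).resolve().parents[1]

TASKS = [
    TaskConfig("strat_p1", base=100, p=1.0, alpha=0.001, min_length=2, max_length=5),
    TaskConfig("strat_p06", base=100, p=0.6, alpha=0.001, min_length=2, max_length=5),
]


def main() -> None:
    matrix = PredicateMatrix.from_csv(
        ROOT / "scratch" / "matrix.csv", ROOT / "scratch" / "matrix_meta.json"
    )
    results = stratified_run(matrix, TASKS, "sex")

    counts = {}
    for stratum, res in results.items():
        paths_to_frame(res.unique_paths).to_csv(
            ROOT / "results" / f"04_paths_{stratum}.tsv", sep="\t", index=False
        )
        counts[stratum] = {
            "per_task": res.per_task_counts,
            "unique": len(res.unique_paths),
        }
        print(f"{stratum}: {counts[stratum]}")
        for p in res.unique_paths:
            print(f"  {' & '.join(p.antecedent)}  a={p.table.a} "
                  f"p={p.freq_coefficient:.3f} tasks={','.join(sorted(p.tasks))}")
    with open(ROOT / "results" / "04_stratified_counts.json", "w") as fh:
        json.dump(counts, fh, indent=2)
        fh.write("\n")


if __name__ == "__main__":
    main()
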