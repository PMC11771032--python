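"""Antecedent enumeration and multi-task mining of paths.

A *path* is a conjunction of 1-5 predicates, each from a distinct attribute,
whose four-fold table against the succedent passes both the Above Average
and the Fisher quantifier of a task.  Enumeration is depth-first in
lexicographic column order with Apriori-style support pruning: the joint
count ``a`` and the antecedent count ``a+b`` are non-increasing under
conjunction extension, so once either drops below ``Base`` no superset can
become a path.  Predicates of one attribute are mutually exclusive, so
conjunctions mixing them are never visited (their ``a`` is 0).

Columns are bit-packed (uint8) and counted with ``np.bitwise_count`` so a
single verification costs two ANDs and two popcounts regardless of width.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
import yaml

from .coding import PredicateMatrix
from .errors import ValidationError
from .quantifiers import (
    FourFoldTable,
    QuantifierConfig,
    above_average_truth,
    fisher_pvalue,
    fisher_truth,
    frequency_coefficient,
)

__all__ = [
    "TaskConfig",
    "Path",
    "TaskResult",
    "ScheduleResult",
    "enumerate_antecedents",
    "run_task",
    "run_schedule",
    "stratified_run",
    "predicate_frequency",
    "load_schedule",
    "paths_to_frame",
]

MAX_CONJUNCTION = 5


@dataclass(frozen=True)
class TaskConfig:
    """One mining task: support Base, frequency coefficient p, Fisher alpha
    and antecedent length bounds, optionally restricted to rows satisfying
    a predicate column (``row_filter``, e.g. ``"sex::female"``)."""

    label: str
    base: int
    p: float
    alpha: float = 0.001
    min_length: int = 1
    max_length: int = MAX_CONJUNCTION
    row_filter: str | None = None

    def __post_init__(self) -> None:
        QuantifierConfig(p=self.p, base=self.base, alpha=self.alpha)  # bounds check
        if not 1 <= self.min_length <= self.max_length <= MAX_CONJUNCTION:
            raise ValidationError(
                f"need 1 <= min_length <= max_length <= {MAX_CONJUNCTION}, "
                f"got [{self.min_length}, {self.max_length}]"
            )

    @property
    def quantifiers(self) -> QuantifierConfig:
        return QuantifierConfig(p=self.p, base=self.base, alpha=self.alpha)


@dataclass(frozen=True)
class Path:
    """A TRUE-labelled antecedent conjunction with its evidence."""

    antecedent: tuple[str, ...]  # predicate column names, lexicographic
    columns: tuple[int, ...]  # column indices in the mined matrix
    table: FourFoldTable
    freq_coefficient: float
    fisher_p: float
    tasks: frozenset[str] = frozenset()

    def __len__(self) -> int:
        return len(self.antecedent)


@dataclass
class TaskResult:
    task: TaskConfig
    paths: list[Path]
    verifications: int
    pruned: int


@dataclass
class ScheduleResult:
    task_results: dict[str, TaskResult]
    unique_paths: list[Path]  # each carries the set of tasks that found it

    @property
    def per_task_counts(self) -> dict[str, int]:
        return {label: len(res.paths) for label, res in self.task_results.items()}


def _pack_columns(values: np.ndarray) -> np.ndarray:
    """Bit-pack each column of a Boolean matrix: result[j] is uint8[ceil(n/8)]."""
    return np.packbits(values, axis=0).T.copy()


def _popcount(packed: np.ndarray) -> int:
    return int(np.bitwise_count(packed).sum())


def _non_succedent_columns(matrix: PredicateMatrix) -> list[int]:
    return [j for j in range(matrix.n_columns) if j != matrix.succedent_index]


def _attribute_codes(matrix: PredicateMatrix, cols: Sequence[int]) -> np.ndarray:
    attrs = [matrix.attribute_of(j) for j in cols]
    seen: dict[str, int] = {}
    return np.array([seen.setdefault(a, len(seen)) for a in attrs], dtype=np.int64)


def enumerate_antecedents(
    matrix: PredicateMatrix, cfg: TaskConfig
) -> Iterator[tuple[int, ...]]:
    """Yield candidate conjunctions (tuples of matrix column indices).

    Lexicographic depth-first order over non-succedent columns, lengths up
    to ``cfg.max_length``, never combining two predicates of one attribute.
    Support pruning: a conjunction whose antecedent count ``a+b`` falls
    below ``cfg.base`` is still yielded (it was visited) but no superset of
    it is.  Conjunctions shorter than ``min_length`` are visited for pruning
    but not yielded.
    """
    cols = _non_succedent_columns(matrix)
    if not cols:
        raise ValidationError("matrix has no predicate columns to enumerate")
    packed = _pack_columns(matrix.values[:, cols])
    attr = _attribute_codes(matrix, cols)
    P = len(cols)

    # Depth-first preorder == lexicographic order on index tuples.
    stack: list[tuple[tuple[int, ...], np.ndarray | None]] = [
        ((idx,), None) for idx in range(P - 1, -1, -1)
    ]
    while stack:
        chosen, parent_mask = stack.pop()
        idx = chosen[-1]
        mask = packed[idx] if parent_mask is None else parent_mask & packed[idx]
        if len(chosen) >= cfg.min_length:
            yield tuple(cols[j] for j in chosen)
        if len(chosen) >= cfg.max_length:
            continue
        if _popcount(mask) < cfg.base:
            continue  # support pruning: no superset is yielded
        used = {attr[j] for j in chosen}
        for nxt in range(P - 1, idx, -1):
            if attr[nxt] in used:
                continue
            stack.append((chosen + (nxt,), mask))


def run_task(
    matrix: PredicateMatrix, cfg: TaskConfig, prune: bool = True
) -> TaskResult:
    """Mine one task: every admissible conjunction passing both quantifiers.

    With ``prune=True`` (default) subtrees are cut when ``a+b < base`` or
    ``a < base``; both counts are non-increasing under extension, so pruning
    never removes a true path and the result equals the unpruned run.
    """
    if matrix.succedent_index is None:
        raise ValidationError("matrix has no succedent column; cannot mine")
    work = matrix
    if cfg.row_filter is not None:
        rows = matrix.column(cfg.row_filter)
        if not rows.any():
            raise ValidationError(
                f"row filter {cfg.row_filter!r} leaves no rows"
            )
        work = matrix.filter_rows(rows)
    if work.n_rows < 1:
        raise ValidationError("empty data matrix")

    cols = _non_succedent_columns(work)
    if not cols:
        raise ValidationError("matrix has no predicate columns to mine")
    packed = _pack_columns(work.values[:, cols])
    psi = np.packbits(work.succedent)
    attr = _attribute_codes(work, cols)
    m = work.n_rows
    k = _popcount(psi)
    qcfg = cfg.quantifiers
    names = work.column_names

    paths: list[Path] = []
    verifications = 0
    pruned = 0

    def emit(chosen: tuple[int, ...], t: FourFoldTable) -> None:
        if above_average_truth(t, qcfg) and fisher_truth(t, qcfg):
            paths.append(
                Path(
                    antecedent=tuple(names[cols[j]] for j in chosen),
                    columns=tuple(cols[j] for j in chosen),
                    table=t,
                    freq_coefficient=frequency_coefficient(t),
                    fisher_p=fisher_pvalue(t),
                    tasks=frozenset({cfg.label}),
                )
            )

    # Depth-first lexicographic walk, one batched popcount pass per node's
    # children; recursion depth is at most max_length.
    def explore(chosen: tuple[int, ...], mask: np.ndarray | None, cand: np.ndarray) -> None:
        nonlocal verifications, pruned
        sub = packed[cand] if mask is None else packed[cand] & mask
        ab = np.bitwise_count(sub).sum(axis=1, dtype=np.int64)
        a = np.bitwise_count(sub & psi).sum(axis=1, dtype=np.int64)
        verifications += len(cand)
        depth = len(chosen) + 1
        for i, idx in enumerate(cand):
            ai, abi = int(a[i]), int(ab[i])
            if depth >= cfg.min_length:
                # a >= base is necessary for both quantifiers; skip the rest
                # of the evaluation early when it fails.
                if ai >= cfg.base:
                    emit(
                        chosen + (int(idx),),
                        FourFoldTable(ai, abi - ai, k - ai, m - abi - k + ai),
                    )
            if depth < cfg.max_length:
                if prune and ai < cfg.base:  # implies ab-prune too (a <= a+b)
                    pruned += 1
                    continue
                nxt = cand[(cand > idx) & (attr[cand] != attr[idx])]
                if nxt.size:
                    explore(chosen + (int(idx),), sub[i], nxt)

    explore((), None, np.arange(len(cols), dtype=np.int64))
    return TaskResult(task=cfg, paths=paths, verifications=verifications, pruned=pruned)


def run_schedule(
    matrix: PredicateMatrix, tasks: Sequence[TaskConfig], prune: bool = True
) -> ScheduleResult:
    """Run a task schedule and deduplicate paths across tasks.

    Paths found by several tasks collapse to one entry keyed by the
    antecedent set, listing every task that found it (the cross-task union
    bookkeeping behind 'n paths in total' summaries).
    """
    labels = [t.label for t in tasks]
    if not labels:
        raise ValidationError("schedule needs at least one task")
    if len(set(labels)) != len(labels):
        raise ValidationError(f"duplicate task labels in schedule: {labels}")
    results: dict[str, TaskResult] = {}
    union: dict[tuple[str, ...], Path] = {}
    for task in tasks:
        res = run_task(matrix, task, prune=prune)
        results[task.label] = res
        for path in res.paths:
            key = path.antecedent
            if key in union:
                union[key] = replace(
                    union[key], tasks=union[key].tasks | path.tasks
                )
            else:
                union[key] = path
    unique = sorted(union.values(), key=lambda p: (len(p), p.columns))
    return ScheduleResult(task_results=results, unique_paths=unique)


def stratified_run(
    matrix: PredicateMatrix,
    tasks: Sequence[TaskConfig],
    stratum_attribute: str,
    prune: bool = True,
) -> dict[str, ScheduleResult]:
    """Run the schedule separately within each stratum of an attribute.

    Strata are the attribute's predicate columns (e.g. sex -> female, male);
    each stratum keeps only rows where its predicate holds.  A stratum with
    zero rows is a validation error.
    """
    col_indices = matrix.predicate_columns(stratum_attribute)
    if not col_indices:
        raise ValidationError(
            f"attribute {stratum_attribute!r} is not binarized in the matrix"
        )
    out: dict[str, ScheduleResult] = {}
    for j in col_indices:
        label = matrix.columns[j][1]
        rows = matrix.values[:, j]
        if not rows.any():
            raise ValidationError(
                f"stratum {stratum_attribute}::{label} has zero rows"
            )
        out[label] = run_schedule(matrix.filter_rows(rows), tasks, prune=prune)
    return out


def predicate_frequency(schedule: ScheduleResult) -> pd.DataFrame:
    """How often each predicate occurs across unique paths, overall and per
    task — the cross-path summary table layout (rows: predicates sorted by
    total occurrences; columns: one per task plus 'total')."""
    labels = list(schedule.task_results)
    counts: dict[str, dict[str, int]] = {}
    for path in schedule.unique_paths:
        for name in path.antecedent:
            row = counts.setdefault(name, {label: 0 for label in labels})
            for label in path.tasks:
                row[label] += 1
    frame = pd.DataFrame.from_dict(counts, orient="index").reindex(
        columns=labels, fill_value=0
    )
    if frame.empty:
        frame = pd.DataFrame(columns=labels + ["total"])
        frame.index.name = "predicate"
        return frame
    frame["total"] = [
        sum(1 for p in schedule.unique_paths if name in p.antecedent)
        for name in frame.index
    ]
    frame = frame.sort_values("total", ascending=False, kind="stable")
    frame.index.name = "predicate"
    return frame


def paths_to_frame(paths: Sequence[Path]) -> pd.DataFrame:
    """Tabular path report: one row per path, predicates ';'-joined."""
    rows = [
        {
            "predicates": ";".join(p.antecedent),
            "length": len(p),
            "a": p.table.a,
            "b": p.table.b,
            "c": p.table.c,
            "d": p.table.d,
            "freq_coefficient": p.freq_coefficient,
            "fisher_p": p.fisher_p,
            "tasks": ";".join(sorted(p.tasks)),
        }
        for p in paths
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "predicates", "length", "a", "b", "c", "d",
            "freq_coefficient", "fisher_p", "tasks",
        ],
    )


def load_schedule(path) -> list[TaskConfig]:
    """Read a YAML/JSON task schedule: a list of
    ``{label, base, p, alpha, min_length, max_length, row_filter}``."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, list):
        raise ValidationError("schedule config must be a list of task entries")
    tasks = []
    for entry in raw:
        tasks.append(
            TaskConfig(
                label=str(entry["label"]),
                base=int(entry["base"]),
                p=float(entry["p"]),
                alpha=float(entry.get("alpha", 0.001)),
                min_length=int(entry.get("min_length", 1)),
                max_length=int(entry.get("max_length", MAX_CONJUNCTION)),
                row_filter=entry.get("row_filter"),
            )
        )
    return tasks
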