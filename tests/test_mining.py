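"""Miner: enumeration order/pruning, task runs vs brute force, schedules."""

import numpy as np
import pytest

from _oracles import brute_force_paths, random_predicate_matrix
from guhapaths.coding import PredicateMatrix
from guhapaths.errors import ValidationError
from guhapaths.mining import (
    TaskConfig,
    enumerate_antecedents,
    predicate_frequency,
    run_schedule,
    run_task,
    stratified_run,
)
from guhapaths.quantifiers import above_average_truth, fisher_truth


def _matrix_from_columns(columns: dict[str, list[int]], psi: list[int]):
    """Build a matrix from named Boolean columns ('attr::label' keys)."""
    names = list(columns)
    values = np.array([columns[n] for n in names], dtype=bool).T
    values = np.hstack([values, np.array(psi, dtype=bool)[:, None]])
    metas = [tuple(n.split("::")) for n in names] + [("premature_death", "yes")]
    ids = [str(i) for i in range(len(psi))]
    return PredicateMatrix(values, metas, ids, values.shape[1] - 1)


@pytest.fixture
def toy_matrix():
    """3 attributes x 2 predicates on 8 rows, every column non-empty."""
    rng = np.random.default_rng(42)
    cols = {}
    for attr in "ABC":
        first = rng.random(8) < 0.5
        cols[f"{attr}::p0"] = first.astype(int).tolist()
        cols[f"{attr}::p1"] = (~first).astype(int).tolist()
    psi = (rng.random(8) < 0.5).astype(int).tolist()
    return _matrix_from_columns(cols, psi)


class TestEnumerate:
    def test_candidate_count_three_attrs_two_preds(self, toy_matrix):
        # 6 singletons + 3 attribute pairs x 4 predicate combos = 18
        cfg = TaskConfig("t", base=1, p=1, min_length=1, max_length=2)
        cands = list(enumerate_antecedents(toy_matrix, cfg))
        assert len(cands) == 18
        assert all(len(set(c)) == len(c) for c in cands)

    def test_lexicographic_order(self, toy_matrix):
        cfg = TaskConfig("t", base=1, p=1, min_length=1, max_length=2)
        cands = list(enumerate_antecedents(toy_matrix, cfg))
        assert cands == sorted(cands)  # DFS preorder == lexicographic

    def test_base_above_column_sums_visits_only_singletons(self, toy_matrix):
        cfg = TaskConfig("t", base=100, p=1, min_length=1, max_length=3)
        cands = list(enumerate_antecedents(toy_matrix, cfg))
        assert all(len(c) == 1 for c in cands)

    def test_length_one_only(self, toy_matrix):
        cfg = TaskConfig("t", base=1, p=1, min_length=1, max_length=1)
        cands = list(enumerate_antecedents(toy_matrix, cfg))
        assert cands == [(j,) for j in range(6)]

    def test_never_mixes_predicates_of_one_attribute(self, toy_matrix):
        cfg = TaskConfig("t", base=1, p=1, min_length=2, max_length=3)
        for cand in enumerate_antecedents(toy_matrix, cfg):
            attrs = [toy_matrix.attribute_of(j) for j in cand]
            assert len(set(attrs)) == len(attrs)


class TestRunTask:
    def test_equals_brute_force_on_toy_matrix(self, toy_matrix):
        cfg = TaskConfig("t", base=1, p=0.01, alpha=0.5, min_length=1, max_length=3)
        mined = {p.columns for p in run_task(toy_matrix, cfg).paths}
        assert mined == brute_force_paths(toy_matrix, cfg)

    def test_all_false_succedent_yields_no_paths(self, toy_matrix):
        matrix = _matrix_from_columns(
            {n: toy_matrix.values[:, j].astype(int).tolist()
             for j, n in enumerate(toy_matrix.column_names[:-1])},
            [0] * 8,
        )
        cfg = TaskConfig("t", base=1, p=0.01, alpha=0.5, max_length=3)
        assert run_task(matrix, cfg).paths == []

    def test_missing_succedent_rejected(self, toy_matrix):
        matrix = PredicateMatrix(
            toy_matrix.values[:, :-1], toy_matrix.columns[:-1], toy_matrix.ids, None
        )
        with pytest.raises(ValidationError):
            run_task(matrix, TaskConfig("t", base=1, p=1))

    def test_emitted_paths_reverify(self, toy_matrix):
        cfg = TaskConfig("t", base=1, p=0.1, alpha=0.5, max_length=3)
        for path in run_task(toy_matrix, cfg).paths:
            q = cfg.quantifiers
            assert above_average_truth(path.table, q)
            assert fisher_truth(path.table, q)
            assert 1 <= len(path) <= 3

    def test_determinism(self, toy_matrix):
        cfg = TaskConfig("t", base=1, p=0.05, alpha=0.5, max_length=3)
        r1, r2 = run_task(toy_matrix, cfg), run_task(toy_matrix, cfg)
        assert [p.columns for p in r1.paths] == [p.columns for p in r2.paths]
        assert r1.verifications == r2.verifications

    def test_raising_p_or_base_never_adds_paths(self):
        rng = np.random.default_rng(0)
        matrix = random_predicate_matrix(rng, 60, [2, 3, 2, 3])
        loose = TaskConfig("l", base=2, p=0.05, alpha=0.5, max_length=3)
        for tighter in (
            TaskConfig("p", base=2, p=0.5, alpha=0.5, max_length=3),
            TaskConfig("b", base=6, p=0.05, alpha=0.5, max_length=3),
        ):
            tight_set = {p.columns for p in run_task(matrix, tighter).paths}
            loose_set = {p.columns for p in run_task(matrix, loose).paths}
            assert tight_set <= loose_set

    def test_row_filter_restricts_rows(self, toy_matrix):
        cfg = TaskConfig("t", base=1, p=0.01, alpha=0.5, max_length=2,
                         row_filter="A::p0")
        res = run_task(toy_matrix, cfg)
        n_filtered = int(toy_matrix.column("A::p0").sum())
        assert all(p.table.m == n_filtered for p in res.paths)

    def test_empty_row_filter_rejected(self, toy_matrix):
        matrix = _matrix_from_columns(
            {"A::p0": [0] * 4, "A::p1": [1] * 4, "B::p0": [1, 0, 1, 0],
             "B::p1": [0, 1, 0, 1]},
            [1, 0, 1, 0],
        )
        cfg = TaskConfig("t", base=1, p=1, row_filter="A::p0")
        with pytest.raises(ValidationError):
            run_task(matrix, cfg)


class TestSchedule:
    def test_identical_tasks_are_idempotent(self, toy_matrix):
        t1 = TaskConfig("t1", base=1, p=0.05, alpha=0.5, max_length=2)
        t2 = TaskConfig("t2", base=1, p=0.05, alpha=0.5, max_length=2)
        res = run_schedule(toy_matrix, [t1, t2])
        assert res.per_task_counts["t1"] == res.per_task_counts["t2"]
        assert len(res.unique_paths) == res.per_task_counts["t1"]
        assert all(p.tasks == {"t1", "t2"} for p in res.unique_paths)

    def test_lower_base_is_weaker(self):
        rng = np.random.default_rng(3)
        matrix = random_predicate_matrix(rng, 50, [2, 2, 3])
        strict = TaskConfig("s", base=5, p=0.2, alpha=0.5, max_length=2)
        weak = TaskConfig("w", base=2, p=0.2, alpha=0.5, max_length=2)
        res = run_schedule(matrix, [strict, weak])
        s_paths = {p.columns for p in res.task_results["s"].paths}
        w_paths = {p.columns for p in res.task_results["w"].paths}
        assert s_paths <= w_paths

    def test_union_bound(self):
        rng = np.random.default_rng(9)
        matrix = random_predicate_matrix(rng, 80, [2, 3, 2, 3])
        tasks = [
            TaskConfig("a", base=3, p=0.1, alpha=0.5, max_length=3),
            TaskConfig("b", base=2, p=0.3, alpha=0.5, max_length=3),
        ]
        res = run_schedule(matrix, tasks)
        assert len(res.unique_paths) <= sum(res.per_task_counts.values())

    def test_duplicate_labels_rejected(self, toy_matrix):
        t = TaskConfig("x", base=1, p=1)
        with pytest.raises(ValidationError):
            run_schedule(toy_matrix, [t, t])


class TestPredicateFrequency:
    def test_counts_paths_containing_each_predicate(self, toy_matrix):
        cfg = TaskConfig("t", base=1, p=0.01, alpha=0.5, max_length=3)
        res = run_schedule(toy_matrix, [cfg])
        freq = predicate_frequency(res)
        for name, row in freq.iterrows():
            expected = sum(1 for p in res.unique_paths if name in p.antecedent)
            assert row["total"] == expected and row["t"] == expected
        assert list(freq["total"]) == sorted(freq["total"], reverse=True)

    def test_empty_paths_give_empty_table(self, toy_matrix):
        cfg = TaskConfig("t", base=100, p=3)
        res = run_schedule(toy_matrix, [cfg])
        assert predicate_frequency(res).empty


class TestStratified:
    def _sex_structured_matrix(self):
        """Association of X::hi & Y::hi with psi exists only among females."""
        n = 80
        female = np.arange(n) < 40
        x = np.zeros(n, bool)
        y = np.zeros(n, bool)
        psi = np.zeros(n, bool)
        # female carriers of (X hi, Y hi) all have the outcome
        x[:20] = y[:20] = psi[:16] = True
        # males: same carrier pattern, outcome uncorrelated and rare
        x[40:60] = y[40:60] = True
        psi[40:44] = True
        cols = {
            "sex::female": female.astype(int).tolist(),
            "sex::male": (~female).astype(int).tolist(),
            "X::hi": x.astype(int).tolist(),
            "X::lo": (~x).astype(int).tolist(),
            "Y::hi": y.astype(int).tolist(),
            "Y::lo": (~y).astype(int).tolist(),
        }
        return _matrix_from_columns(cols, psi.astype(int).tolist())

    def test_path_planted_in_one_stratum_only(self):
        matrix = self._sex_structured_matrix()
        task = TaskConfig("t", base=5, p=0.5, alpha=0.01, min_length=2, max_length=2)
        res = stratified_run(matrix, [task], "sex")
        target = ("X::hi", "Y::hi")
        female_paths = {p.antecedent for p in res["female"].unique_paths}
        male_paths = {p.antecedent for p in res["male"].unique_paths}
        assert target in female_paths
        assert target not in male_paths

    def test_stratum_with_zero_rows_rejected(self):
        cols = {
            "sex::female": [0, 0, 0, 0],
            "sex::male": [1, 1, 1, 1],
            "X::hi": [1, 0, 1, 0],
            "X::lo": [0, 1, 0, 1],
        }
        matrix = _matrix_from_columns(cols, [1, 0, 1, 0])
        with pytest.raises(ValidationError, match="female"):
            stratified_run(matrix, [TaskConfig("t", base=1, p=1)], "sex")

    def test_unknown_stratum_attribute_rejected(self, toy_matrix):
        with pytest.raises(ValidationError):
            stratified_run(toy_matrix, [TaskConfig("t", base=1, p=1)], "nope")

    def test_whole_population_filter_equals_plain_schedule(self, toy_matrix):
        # a filter that keeps every row reproduces the unfiltered run
        cols = {
            n: toy_matrix.values[:, j].astype(int).tolist()
            for j, n in enumerate(toy_matrix.column_names[:-1])
        }
        cols["cohort::member"] = [1] * toy_matrix.n_rows
        matrix = _matrix_from_columns(cols, toy_matrix.succedent.astype(int).tolist())
        plain = TaskConfig("t", base=1, p=0.05, alpha=0.5, max_length=2)
        filtered = TaskConfig("t", base=1, p=0.05, alpha=0.5, max_length=2,
                              row_filter="cohort::member")
        plain_paths = {p.antecedent for p in run_task(matrix, plain).paths}
        filt_paths = {p.antecedent for p in run_task(matrix, filtered).paths}
        assert plain_paths == filt_paths
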