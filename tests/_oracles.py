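"""Independent oracles the tests check the implementation against.

Deliberately naive: exact big-integer arithmetic for the Fisher tail and
exhaustive itertools enumeration for the miner.  Nothing here shares code
with the implementation under test.
"""

from fractions import Fraction
from itertools import combinations, product
from math import comb

import numpy as np

from guhapaths.coding import PredicateMatrix
from guhapaths.quantifiers import FourFoldTable


def fisher_tail_exact(t: FourFoldTable) -> Fraction:
    """P(A >= a) by exhaustive hypergeometric enumeration, exact rationals."""
    m, r, k, l = t.m, t.r, t.k, t.l
    total = comb(m, r)
    num = sum(comb(k, j) * comb(l, r - j) for j in range(t.a, min(r, k) + 1))
    return Fraction(num, total)


def brute_force_paths(matrix: PredicateMatrix, cfg) -> set[tuple[int, ...]]:
    """Every admissible conjunction passing both quantifiers, by direct
    evaluation of all attribute combinations and predicate choices."""
    from guhapaths.quantifiers import (
        above_average_truth,
        build_table,
        fisher_truth,
    )

    cols = [j for j in range(matrix.n_columns) if j != matrix.succedent_index]
    by_attr: dict[str, list[int]] = {}
    for j in cols:
        by_attr.setdefault(matrix.attribute_of(j), []).append(j)
    attrs = list(by_attr)
    psi = matrix.succedent
    qcfg = cfg.quantifiers
    found: set[tuple[int, ...]] = set()
    for length in range(cfg.min_length, cfg.max_length + 1):
        for attr_combo in combinations(attrs, length):
            for choice in product(*(by_attr[a] for a in attr_combo)):
                idxs = tuple(sorted(choice))
                t = build_table([matrix.values[:, j] for j in idxs], psi)
                if t.a >= cfg.base and above_average_truth(t, qcfg) and fisher_truth(
                    t, qcfg
                ):
                    found.add(idxs)
    return found


def random_predicate_matrix(
    rng: np.random.Generator,
    n_rows: int,
    attr_sizes: list[int],
    psi_rate: float = 0.4,
) -> PredicateMatrix:
    """Small random matrix: one-hot attributes plus a random succedent."""
    blocks = []
    columns = []
    for i, size in enumerate(attr_sizes):
        cats = rng.integers(0, size, size=n_rows)
        block = np.zeros((n_rows, size), dtype=bool)
        block[np.arange(n_rows), cats] = True
        blocks.append(block)
        columns.extend((f"attr{i}", f"v{c}") for c in range(size))
    psi = rng.random(n_rows) < psi_rate
    blocks.append(psi[:, None])
    columns.append(("premature_death", "yes"))
    values = np.hstack(blocks)
    return PredicateMatrix(
        values, columns, [str(i) for i in range(n_rows)], values.shape[1] - 1
    )
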