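"""Synthetic cohorts with planted multi-predicate paths at controlled lift.

The generator emulates the statistical shape of a mid-life occupational
cohort followed for ~29 years: ~6,257 rows, ~80 categorical attributes each
split into 2-4 categories (~290 predicates), a premature-death prevalence of
~0.247, a 55.3% female share, and one or more *planted* antecedent
conjunctions (up to 5 predicates from distinct attributes) whose carriers
experience the outcome at a target lift over the cohort average.

Outcome planting uses exact counts rather than per-row Bernoulli draws: a
planted path with carrier set C and target lift ``lambda`` receives exactly
``round(lambda * prevalence * |C|)`` outcome-positive rows, and the cohort
marginal is fixed at ``round(prevalence * n)``.  Rows outside a carrier
block are resampled away from the path's full category tuple, so the
antecedent count equals the block size exactly.  This realizes the planted
lift deterministically (up to integer rounding) while the *placement* of
carriers, categories and outcomes stays random under the seed — the point
of the generator is controlled lift, and tasks whose threshold sits exactly
at ``1 + p = lambda`` must see the boundary realized, not a coin flip
around it.

Survival data are back-constructed from the planted outcome: outcome-
positive rows die with excess (ALE minus years survived) drawn above the
9-month buffer; outcome-negative rows are either censored alive or die
within the buffer / after their ALE, so re-classifying the generated
survival at the 9-month buffer reproduces the planted outcome exactly, and
3/6/9-month buffers give properly nested premature sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path as FsPath

import json

import numpy as np
import pandas as pd

from .coding import AttributeCoding, Predicate, binarize, dump_codings
from .errors import SyntheticSpecError
from .lifetable import ALIVE, DIED, BufferSpec, LifeTable, compute_outcomes
from .mining import TaskConfig
from .quantifiers import (
    build_table,
    fisher_pvalue,
    fisher_truth,
    above_average_truth,
    frequency_coefficient,
)

__all__ = ["PlantedPath", "SyntheticSpec", "SyntheticCohort", "generate", "realized_truth"]

_BUFFER_MARGIN = 0.05  # planted excess stays this far above the buffer


@dataclass(frozen=True)
class PlantedPath:
    """A conjunction to plant: (attribute index, category index) pairs, a
    target lift over the cohort prevalence, and the carrier fraction P(phi)."""

    attributes: tuple[int, ...]
    categories: tuple[int, ...]
    target_lift: float
    carrier_fraction: float

    def __post_init__(self) -> None:
        if len(self.attributes) != len(self.categories):
            raise SyntheticSpecError("attributes and categories differ in length")
        if not 1 <= len(self.attributes) <= 5:
            raise SyntheticSpecError("planted conjunction must have 1-5 predicates")
        if len(set(self.attributes)) != len(self.attributes):
            raise SyntheticSpecError("planted conjunction attributes must be distinct")
        if not self.target_lift > 1.0:
            raise SyntheticSpecError("target_lift must exceed 1")
        if not 0 < self.carrier_fraction < 1:
            raise SyntheticSpecError("carrier_fraction must be in (0,1)")


_DEFAULT_PLANTED = (
    PlantedPath(
        attributes=(0, 1, 2, 3, 4),
        categories=(0, 0, 0, 0, 0),
        target_lift=2.0,
        carrier_fraction=0.08,
    ),
    PlantedPath(
        attributes=(5, 6, 7),
        categories=(0, 0, 0),
        target_lift=1.6,
        carrier_fraction=0.10,
    ),
)


@dataclass(frozen=True)
class SyntheticSpec:
    """Generative description of a cohort.

    Defaults mirror the emulated study conditions: n=6257 participants,
    80 attributes with a 2/3/4-category mix of (10%, 20%, 70%), premature
    prevalence 0.247 (1545/6257), 55.3% female, ages 44-58 at baseline and
    a 29-year censoring horizon.  Planted paths default to one 5-predicate
    conjunction at lift 2.0 (carrier 8%) and one 3-predicate conjunction at
    lift 1.6 (carrier 10%) — lifts in the 1.5-2.5 band the mined paths of
    such cohorts occupy.
    """

    n: int = 6257
    n_attributes: int = 80
    category_mix: tuple[float, float, float] = (0.10, 0.20, 0.70)  # shares of 2/3/4
    baseline_prevalence: float = 0.247
    planted_paths: tuple[PlantedPath, ...] = _DEFAULT_PLANTED
    sex_mix_female: float = 0.553
    age_low: int = 44
    age_high: int = 58
    censor_years: float = 29.0
    buffer_months: int = 9
    death_share_background: float = 0.138  # non-premature rows that still die
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 10:
            raise SyntheticSpecError("n must be at least 10")
        if self.n_attributes < 1:
            raise SyntheticSpecError("need at least one attribute")
        if not 0 < self.baseline_prevalence < 1:
            raise SyntheticSpecError("baseline_prevalence must be in (0,1)")
        if abs(sum(self.category_mix) - 1.0) > 1e-9:
            raise SyntheticSpecError("category_mix must sum to 1")
        used_attrs: set[int] = set()
        for path in self.planted_paths:
            if used_attrs & set(path.attributes):
                raise SyntheticSpecError(
                    "planted paths must use pairwise disjoint attribute sets"
                )
            used_attrs |= set(path.attributes)
        carriers = 0.0
        for path in self.planted_paths:
            if path.target_lift * self.baseline_prevalence > 1.0:
                raise SyntheticSpecError(
                    f"infeasible plant: lift {path.target_lift} times prevalence "
                    f"{self.baseline_prevalence} exceeds 1"
                )
            if round(path.carrier_fraction * self.n) < 1:
                raise SyntheticSpecError("carrier_fraction * n must be >= 1")
            if max(path.attributes) >= self.n_attributes:
                raise SyntheticSpecError("planted attribute index out of range")
            carriers += path.carrier_fraction
        if carriers > 0.5:
            raise SyntheticSpecError("planted carrier blocks exceed half the cohort")


@dataclass
class SyntheticCohort:
    """Generated bundle: cohort table, life table, codings, ground truth."""

    cohort: pd.DataFrame
    life_table: LifeTable
    codings: list[AttributeCoding]
    ground_truth: dict
    spec: SyntheticSpec = field(repr=False, default=None)

    def write(self, out_dir) -> dict:
        out = FsPath(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "cohort": out / "cohort.csv",
            "life_table": out / "life_table.csv",
            "codings": out / "codings.yaml",
            "ground_truth": out / "ground_truth.json",
        }
        self.cohort.to_csv(paths["cohort"], index=False)
        self.life_table.to_frame().to_csv(paths["life_table"], index=False)
        dump_codings(self.codings, paths["codings"])
        with open(paths["ground_truth"], "w") as fh:
            json.dump(self.ground_truth, fh, indent=2, sort_keys=True)
            fh.write("\n")
        return {k: str(v) for k, v in paths.items()}


def _attribute_sizes(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    A = spec.n_attributes
    k2 = round(spec.category_mix[0] * A)
    k3 = round(spec.category_mix[1] * A)
    k4 = A - k2 - k3
    if k4 < 0:
        raise SyntheticSpecError("category_mix rounds to more attributes than exist")
    sizes = np.array([2] * k2 + [3] * k3 + [4] * k4, dtype=np.int64)
    return rng.permutation(sizes)


def _synthetic_life_table(spec: SyntheticSpec) -> LifeTable:
    # Linear-in-age remaining life expectancy; levels chosen so median ALE
    # sits in the mid-20s and men trail women by ~6 years, as period tables
    # for a 1980s Nordic population show.
    entries = {}
    for age in range(spec.age_low, spec.age_high + 1):
        entries[("female", age)] = round(33.0 - 0.80 * (age - spec.age_low), 2)
        entries[("male", age)] = round(27.0 - 0.80 * (age - spec.age_low), 2)
    return LifeTable(entries)


def _attr_name(i: int) -> str:
    return f"a{i:02d}"


def _cat_name(j: int) -> str:
    return f"c{j}"


def generate(spec: SyntheticSpec) -> SyntheticCohort:
    """Generate a cohort; deterministic (byte-identical) under spec.seed."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n
    sizes = _attribute_sizes(spec, rng)
    for path in spec.planted_paths:
        for attr, cat in zip(path.attributes, path.categories):
            if cat >= sizes[attr]:
                raise SyntheticSpecError(
                    f"planted category {cat} out of range for attribute "
                    f"{_attr_name(attr)} with {sizes[attr]} categories"
                )

    # Categorical attribute matrix, uniform within each attribute.
    values = np.empty((n, spec.n_attributes), dtype=np.int64)
    for j in range(spec.n_attributes):
        values[:, j] = rng.integers(0, sizes[j], size=n)

    # Disjoint carrier blocks, then force/forbid the planted tuples.
    perm = rng.permutation(n)
    blocks: list[np.ndarray] = []
    cursor = 0
    for path in spec.planted_paths:
        size = round(path.carrier_fraction * n)
        blocks.append(perm[cursor : cursor + size])
        cursor += size
    in_any_block = np.zeros(n, dtype=bool)
    for block in blocks:
        in_any_block[block] = True
    for path, block in zip(spec.planted_paths, blocks):
        for attr, cat in zip(path.attributes, path.categories):
            values[block, attr] = cat
        # Rows outside the block must not satisfy the full conjunction:
        # resample the first attribute away from its planted category.
        outside = np.flatnonzero(~np.isin(np.arange(n), block))
        match = np.ones(outside.size, dtype=bool)
        for attr, cat in zip(path.attributes, path.categories):
            match &= values[outside, attr] == cat
        clash = outside[match]
        if clash.size:
            attr0, cat0 = path.attributes[0], path.categories[0]
            other = [c for c in range(sizes[attr0]) if c != cat0]
            values[clash, attr0] = rng.choice(other, size=clash.size)

    # Outcome planting by exact counts.
    target_total = round(spec.baseline_prevalence * n)
    psi = np.zeros(n, dtype=bool)
    planted_a = []
    for path, block in zip(spec.planted_paths, blocks):
        a_j = round(path.target_lift * spec.baseline_prevalence * block.size)
        if a_j > block.size:
            raise SyntheticSpecError(
                "planted lift times prevalence exceeds 1 within a carrier block"
            )
        chosen = rng.choice(block, size=a_j, replace=False)
        psi[chosen] = True
        planted_a.append(int(a_j))
    rest = np.flatnonzero(~in_any_block)
    remaining = target_total - int(psi.sum())
    if remaining < 0 or remaining > rest.size:
        raise SyntheticSpecError(
            "planted outcome counts are incompatible with the target prevalence"
        )
    psi[rng.choice(rest, size=remaining, replace=False)] = True

    # Demographics and life table.
    sex = np.array(["male"] * n, dtype=object)
    n_female = round(spec.sex_mix_female * n)
    sex[rng.permutation(n)[:n_female]] = "female"
    age = rng.integers(spec.age_low, spec.age_high + 1, size=n) + rng.uniform(
        0.0, 1.0, size=n
    )
    age = np.minimum(age, spec.age_high + 0.999)
    life_table = _synthetic_life_table(spec)
    ale = np.array([life_table.lookup(s, a) for s, a in zip(sex, age)])

    # Back-constructed survival consistent with the planted outcome.
    buffer_years = BufferSpec(spec.buffer_months).years
    years = np.empty(n)
    status = np.empty(n, dtype=object)
    lo_feasible = ale - spec.censor_years  # excess must exceed this to die in window
    for i in range(n):
        if psi[i]:
            lo = max(buffer_years + _BUFFER_MARGIN, lo_feasible[i] + 0.01)
            hi = 0.95 * ale[i]
            excess = rng.uniform(lo, hi)
            status[i] = DIED
            years[i] = ale[i] - excess
        else:
            feasible = lo_feasible[i] < buffer_years - _BUFFER_MARGIN
            if feasible and rng.random() < spec.death_share_background:
                lo = max(-4.0, lo_feasible[i] + 0.01)
                excess = rng.uniform(lo, buffer_years - _BUFFER_MARGIN)
                status[i] = DIED
                years[i] = ale[i] - excess
            else:
                status[i] = ALIVE
                years[i] = spec.censor_years

    cohort = pd.DataFrame(
        {
            "id": [f"P{i:06d}" for i in range(n)],
            "sex": sex,
            "age": np.round(age, 3),
            "vital_status": status,
            "years_survived": np.round(years, 3),
        }
    )
    for j in range(spec.n_attributes):
        cohort[_attr_name(j)] = [_cat_name(v) for v in values[:, j]]

    codings = _build_codings(spec, sizes)

    overall_rate = target_total / n
    truth_paths = []
    for path, block, a_j in zip(spec.planted_paths, blocks, planted_a):
        predicates = [
            f"{_attr_name(attr)}::{_cat_name(cat)}"
            for attr, cat in zip(path.attributes, path.categories)
        ]
        lift = (a_j / block.size) / overall_rate
        truth_paths.append(
            {
                "predicates": predicates,
                "target_lift": path.target_lift,
                "carrier_fraction": path.carrier_fraction,
                "carriers": int(block.size),
                "outcome_positive_carriers": a_j,
                "realized_lift": lift,
            }
        )
    ground_truth = {
        "n": n,
        "n_attributes": spec.n_attributes,
        "n_predicates": int(sizes.sum()) + 2 + 3,  # attribute + sex + age columns
        "target_prevalence": spec.baseline_prevalence,
        "realized_prevalence": overall_rate,
        "planted_paths": truth_paths,
        "seed": spec.seed,
    }
    return SyntheticCohort(cohort, life_table, codings, ground_truth, spec)


def _build_codings(spec: SyntheticSpec, sizes: np.ndarray) -> list[AttributeCoding]:
    codings = [
        AttributeCoding(
            attribute="sex",
            predicates=(
                Predicate(label="male", categories=frozenset({"male"})),
                Predicate(label="female", categories=frozenset({"female"})),
            ),
        ),
        AttributeCoding(
            attribute="age",
            predicates=(
                Predicate(label=f"{spec.age_low}-<50", interval=(None, 50.0)),
                Predicate(label="50-<55", interval=(50.0, 55.0)),
                Predicate(label="55-", interval=(55.0, None)),
            ),
        ),
    ]
    for j in range(spec.n_attributes):
        codings.append(
            AttributeCoding(
                attribute=_attr_name(j),
                predicates=tuple(
                    Predicate(label=_cat_name(c), categories=frozenset({_cat_name(c)}))
                    for c in range(sizes[j])
                ),
            )
        )
    return codings


def realized_truth(bundle: SyntheticCohort, task: TaskConfig) -> list[dict]:
    """Re-derive each planted conjunction's table from the generated files
    and check it against a task's (Base, p, alpha) thresholds — the bridge
    between the generator's ground truth and the miner's acceptance."""
    outcomes = compute_outcomes(
        bundle.cohort, bundle.life_table, BufferSpec(bundle.spec.buffer_months)
    )
    matrix = binarize(bundle.cohort, bundle.codings, outcomes)
    qcfg = task.quantifiers
    report = []
    for planted in bundle.ground_truth["planted_paths"]:
        cols = [matrix.column(name) for name in planted["predicates"]]
        t = build_table(cols, matrix.succedent)
        fc = frequency_coefficient(t)
        entry = {
            "predicates": planted["predicates"],
            "table": t.to_json(),
            "empirical_lift": 1.0 + fc,
            "freq_coefficient": fc,
            "fisher_p": fisher_pvalue(t),
            "passes_base": t.a >= task.base,
            "passes_above_average": above_average_truth(t, qcfg),
            "passes_fisher": fisher_truth(t, qcfg),
        }
        entry["passes"] = (
            entry["passes_base"]
            and entry["passes_above_average"]
            and entry["passes_fisher"]
        )
        report.append(entry)
    return report
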