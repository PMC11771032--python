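"""Binarization of cohort attributes into mutually exclusive predicates.

Each attribute is split into 2-4 predicates, either by category sets
(e.g. sex -> {male}, {female}) or by half-open numeric intervals
``[low, high)`` with open ends (e.g. BMI -> (<20), [20,25), [25,30),
[30-)).  Missing values leave all of the attribute's predicate columns
false (the Boolean matrix has no third truth value).  The outcome predicate
``premature_death::yes`` is appended as the succedent column psi.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import CodingConfigError, CodingGapError, ValidationError

__all__ = [
    "Predicate",
    "AttributeCoding",
    "PredicateMatrix",
    "load_codings",
    "dump_codings",
    "validate_coding",
    "binarize",
    "SUCCEDENT_ATTRIBUTE",
    "SUCCEDENT_LABEL",
]

SUCCEDENT_ATTRIBUTE = "premature_death"
SUCCEDENT_LABEL = "yes"
COLUMN_SEP = "::"


def _is_missing(value) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and math.isnan(value):
        return True
    return False


@dataclass(frozen=True)
class Predicate:
    """One Boolean category of an attribute: a category set or an interval.

    Intervals are half-open ``[low, high)``; ``None`` at either end leaves it
    open (covers -inf / +inf on that side).
    """

    label: str
    categories: frozenset | None = None
    interval: tuple[float | None, float | None] | None = None

    def __post_init__(self) -> None:
        if (self.categories is None) == (self.interval is None):
            raise CodingConfigError(
                f"predicate {self.label!r} must define exactly one of "
                "categories or interval"
            )
        if self.interval is not None:
            low, high = self.interval
            if low is not None and high is not None and not low < high:
                raise CodingConfigError(
                    f"predicate {self.label!r}: interval low must be < high, "
                    f"got [{low}, {high})"
                )

    def matches(self, value) -> bool:
        if _is_missing(value):
            return False
        if self.categories is not None:
            return value in self.categories
        low, high = self.interval
        try:
            v = float(value)
        except (TypeError, ValueError):
            return False
        if math.isnan(v):
            return False
        return (low is None or v >= low) and (high is None or v < high)


@dataclass(frozen=True)
class AttributeCoding:
    """Ordered predicates of one attribute (2-4, pairwise disjoint)."""

    attribute: str
    predicates: tuple[Predicate, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "predicates", tuple(self.predicates))
        labels = [p.label for p in self.predicates]
        if len(set(labels)) != len(labels):
            raise CodingConfigError(
                f"attribute {self.attribute!r}: duplicate predicate labels"
            )


def _coding_issues(coding: AttributeCoding) -> list[dict]:
    """Structural issues of one attribute coding (bound, overlap, gap)."""
    issues: list[dict] = []
    preds = coding.predicates
    if not 2 <= len(preds) <= 4:
        issues.append(
            {
                "attribute": coding.attribute,
                "kind": "bound",
                "detail": f"{len(preds)} predicates; 2-4 required",
            }
        )
    cat_preds = [p for p in preds if p.categories is not None]
    int_preds = [p for p in preds if p.interval is not None]
    for i, p in enumerate(cat_preds):
        for q in cat_preds[i + 1 :]:
            shared = p.categories & q.categories
            if shared:
                issues.append(
                    {
                        "attribute": coding.attribute,
                        "kind": "overlap",
                        "detail": f"{p.label!r} and {q.label!r} share {sorted(shared)}",
                    }
                )
    ordered = sorted(
        int_preds, key=lambda p: -math.inf if p.interval[0] is None else p.interval[0]
    )
    for p, q in zip(ordered, ordered[1:]):
        p_high = math.inf if p.interval[1] is None else p.interval[1]
        q_low = -math.inf if q.interval[0] is None else q.interval[0]
        if q_low < p_high:
            issues.append(
                {
                    "attribute": coding.attribute,
                    "kind": "overlap",
                    "detail": f"intervals of {p.label!r} and {q.label!r} overlap",
                }
            )
        elif q_low > p_high:
            issues.append(
                {
                    "attribute": coding.attribute,
                    "kind": "gap",
                    "detail": f"values in [{p_high}, {q_low}) match no predicate",
                }
            )
    return issues


def validate_coding(
    codings: Sequence[AttributeCoding],
    cohort: pd.DataFrame | None = None,
) -> list[dict]:
    """Report-only validation: bound violations, overlaps, interval gaps and
    (when a cohort is given) observed values no predicate covers."""
    issues: list[dict] = []
    seen: set[str] = set()
    for coding in codings:
        if coding.attribute in seen:
            issues.append(
                {
                    "attribute": coding.attribute,
                    "kind": "duplicate",
                    "detail": "attribute coded more than once",
                }
            )
        seen.add(coding.attribute)
        issues.extend(_coding_issues(coding))
        if cohort is not None and coding.attribute in cohort.columns:
            for value in pd.unique(cohort[coding.attribute]):
                if _is_missing(value):
                    continue
                if not any(p.matches(value) for p in coding.predicates):
                    issues.append(
                        {
                            "attribute": coding.attribute,
                            "kind": "uncovered_value",
                            "detail": f"value {value!r} matches no predicate",
                        }
                    )
    return issues


@dataclass
class PredicateMatrix:
    """Boolean participant x predicate matrix with per-column provenance.

    ``columns`` holds (attribute, label) pairs; column names join them with
    ``::``.  ``succedent_index`` locates psi (``premature_death::yes``).
    """

    values: np.ndarray
    columns: list[tuple[str, str]]
    ids: list[str]
    succedent_index: int | None = None
    _name_to_index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=bool)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.columns):
            raise ValidationError("matrix shape does not match column metadata")
        if len(self.ids) != self.values.shape[0]:
            raise ValidationError("ids do not match matrix row count")
        self._name_to_index = {name: i for i, name in enumerate(self.column_names)}

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_columns(self) -> int:
        return self.values.shape[1]

    @property
    def column_names(self) -> list[str]:
        return [f"{attr}{COLUMN_SEP}{label}" for attr, label in self.columns]

    def column_index(self, name: str) -> int:
        try:
            return self._name_to_index[name]
        except KeyError:
            raise ValidationError(f"no predicate column named {name!r}") from None

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.column_index(name)]

    @property
    def succedent(self) -> np.ndarray:
        if self.succedent_index is None:
            raise ValidationError("matrix has no succedent column")
        return self.values[:, self.succedent_index]

    def attribute_of(self, index: int) -> str:
        return self.columns[index][0]

    def predicate_columns(self, attribute: str) -> list[int]:
        return [i for i, (attr, _) in enumerate(self.columns) if attr == attribute]

    def filter_rows(self, mask: np.ndarray) -> "PredicateMatrix":
        mask = np.asarray(mask, dtype=bool)
        ids = [pid for pid, keep in zip(self.ids, mask) if keep]
        return PredicateMatrix(
            self.values[mask], list(self.columns), ids, self.succedent_index
        )

    def to_csv(self, path, meta_path=None) -> None:
        frame = pd.DataFrame(
            self.values.astype(int), columns=self.column_names, index=self.ids
        )
        frame.index.name = "id"
        frame.to_csv(path)
        if meta_path is not None:
            meta = {
                "columns": [
                    {"attribute": attr, "label": label} for attr, label in self.columns
                ],
                "succedent_index": self.succedent_index,
            }
            with open(meta_path, "w") as fh:
                json.dump(meta, fh, indent=2)
                fh.write("\n")

    @classmethod
    def from_csv(cls, path, meta_path=None) -> "PredicateMatrix":
        frame = pd.read_csv(path, index_col="id")
        columns = [tuple(name.split(COLUMN_SEP, 1)) for name in frame.columns]
        succedent = None
        if meta_path is not None:
            with open(meta_path) as fh:
                succedent = json.load(fh).get("succedent_index")
        else:
            name = f"{SUCCEDENT_ATTRIBUTE}{COLUMN_SEP}{SUCCEDENT_LABEL}"
            if name in frame.columns:
                succedent = list(frame.columns).index(name)
        return cls(
            frame.to_numpy(dtype=bool),
            columns,
            [str(i) for i in frame.index],
            succedent,
        )


def _strict_validate(codings: Sequence[AttributeCoding]) -> None:
    hard = [
        issue
        for coding in codings
        for issue in _coding_issues(coding)
        if issue["kind"] in ("bound", "overlap")
    ]
    if hard:
        raise CodingConfigError(f"invalid coding config: {hard}")


def binarize(
    cohort: pd.DataFrame,
    codings: Sequence[AttributeCoding],
    outcomes: pd.DataFrame | None = None,
) -> PredicateMatrix:
    """Build the Boolean predicate matrix from a cohort table.

    Column order is (attribute order in the config, predicate order within
    the attribute); this order fixes enumeration downstream.  When an
    outcome frame (from :func:`~guhapaths.lifetable.compute_outcomes`) is
    given, its ``premature`` column becomes the succedent, aligned by id.

    Raises :class:`CodingGapError` when a non-missing value matches no
    predicate of its attribute, and :class:`CodingConfigError` for
    overlapping predicates or a predicate count outside 2-4.
    """
    _strict_validate(codings)
    for coding in codings:
        if coding.attribute not in cohort.columns:
            raise ValidationError(
                f"coded attribute {coding.attribute!r} not in cohort table"
            )
    ids = [str(v) for v in cohort["id"]] if "id" in cohort.columns else [
        str(i) for i in range(len(cohort))
    ]
    blocks: list[np.ndarray] = []
    columns: list[tuple[str, str]] = []
    for coding in codings:
        raw = cohort[coding.attribute].tolist()
        block = np.zeros((len(raw), len(coding.predicates)), dtype=bool)
        for i, value in enumerate(raw):
            if _is_missing(value):
                continue  # missing: all predicates of this attribute false
            hits = [j for j, pred in enumerate(coding.predicates) if pred.matches(value)]
            if not hits:
                raise CodingGapError(
                    f"attribute {coding.attribute!r}: value {value!r} matches "
                    "no predicate and is not missing"
                )
            block[i, hits[0]] = True  # disjointness validated: at most one hit
        blocks.append(block)
        columns.extend((coding.attribute, pred.label) for pred in coding.predicates)
    succedent_index = None
    if outcomes is not None:
        merged = pd.Series(
            outcomes["premature"].to_numpy(), index=[str(v) for v in outcomes["id"]]
        )
        try:
            psi = merged.loc[ids].to_numpy(dtype=bool)
        except KeyError as exc:
            raise ValidationError(f"outcome ids do not cover cohort ids: {exc}") from None
        blocks.append(psi[:, None])
        columns.append((SUCCEDENT_ATTRIBUTE, SUCCEDENT_LABEL))
        succedent_index = sum(b.shape[1] for b in blocks) - 1
    values = np.hstack(blocks) if blocks else np.zeros((len(ids), 0), dtype=bool)
    return PredicateMatrix(values, columns, ids, succedent_index)


def _predicate_to_obj(entry: dict) -> Predicate:
    label = entry["label"]
    if "categories" in entry and entry["categories"] is not None:
        return Predicate(label=label, categories=frozenset(entry["categories"]))
    if "interval" in entry and entry["interval"] is not None:
        low, high = entry["interval"]
        return Predicate(label=label, interval=(low, high))
    raise CodingConfigError(f"predicate {label!r} needs categories or interval")


def load_codings(path) -> list[AttributeCoding]:
    """Read a YAML/JSON coding config: a list of
    ``{attribute, predicates: [{label, categories|interval}]}`` entries."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, list):
        raise CodingConfigError("coding config must be a list of attribute entries")
    return [
        AttributeCoding(
            attribute=entry["attribute"],
            predicates=tuple(_predicate_to_obj(p) for p in entry["predicates"]),
        )
        for entry in raw
    ]


def dump_codings(codings: Iterable[AttributeCoding], path) -> None:
    payload = []
    for coding in codings:
        preds = []
        for p in coding.predicates:
            if p.categories is not None:
                preds.append({"label": p.label, "categories": sorted(p.categories)})
            else:
                preds.append({"label": p.label, "interval": list(p.interval)})
        payload.append({"attribute": coding.attribute, "predicates": preds})
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)
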