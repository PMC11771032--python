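"""Four-fold contingency tables and the two generalized quantifiers.

The mining procedure labels an association ``phi ~ psi`` TRUE when both
quantifiers hold on the 2x2 table of the antecedent conjunction ``phi``
against the succedent ``psi``:

* **Above Average** — the succedent must be at least ``(1 + p)`` times more
  common among rows satisfying ``phi`` than in the whole data matrix, and the
  joint count ``a`` must reach the support threshold ``Base``::

      a / (a + b)  >=  (1 + p) * (a + c) / m,   with  Base <= a

  ``p`` is the *frequency coefficient*: ``p = 2`` means the outcome is three
  times more common under ``phi`` than on average.

* **Fisher** — ``a*d > b*c`` (positive association) and the one-sided Fisher
  exact tail probability ``P(A >= a)`` at fixed margins is at most ``alpha``.

The Fisher tail is evaluated in log-gamma space so tables with millions of
rows do not overflow.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, logsumexp

from .errors import DegenerateTableError, ValidationError

__all__ = [
    "FourFoldTable",
    "QuantifierConfig",
    "build_table",
    "above_average_truth",
    "frequency_coefficient",
    "fisher_pvalue",
    "fisher_truth",
    "prevalence_multiplier",
    "percent_excess",
]


@dataclass(frozen=True)
class FourFoldTable:
    """2x2 contingency table of antecedent (rows) vs succedent (columns).

    ``a`` counts rows satisfying both ``phi`` and ``psi``, ``b`` rows with
    ``phi`` but not ``psi``, ``c`` rows with ``psi`` but not ``phi`` and ``d``
    the rest.  Margins: ``r = a+b`` (phi), ``s = c+d``, ``k = a+c`` (psi),
    ``l = b+d``, ``m = a+b+c+d``.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in "abcd":
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValidationError(
                    f"cell {name} must be a nonnegative integer, got {v!r}"
                )

    @property
    def r(self) -> int:
        return self.a + self.b

    @property
    def s(self) -> int:
        return self.c + self.d

    @property
    def k(self) -> int:
        return self.a + self.c

    @property
    def l(self) -> int:
        return self.b + self.d

    @property
    def m(self) -> int:
        return self.a + self.b + self.c + self.d

    def to_json(self) -> dict:
        return {"a": self.a, "b": self.b, "c": self.c, "d": self.d}


@dataclass(frozen=True)
class QuantifierConfig:
    """Thresholds of one mining task: frequency coefficient ``p``, support
    ``base`` (minimum ``a``) and the Fisher significance level ``alpha``."""

    p: float
    base: int
    alpha: float = 0.001

    def __post_init__(self) -> None:
        if not self.p > 0:
            raise ValidationError(f"frequency coefficient p must be > 0, got {self.p}")
        if int(self.base) != self.base or self.base < 1:
            raise ValidationError(f"base must be a positive integer, got {self.base}")
        if not 0 < self.alpha <= 0.5:
            raise ValidationError(f"alpha must lie in (0, 0.5], got {self.alpha}")


def build_table(antecedent_columns, succedent_column) -> FourFoldTable:
    """Count the four-fold table of a conjunction of Boolean columns vs psi.

    Raises :class:`ValidationError` for an empty antecedent list (the
    conjunction would be undefined) or mismatched column lengths.
    """
    cols = [np.asarray(col, dtype=bool) for col in antecedent_columns]
    if not cols:
        raise ValidationError("antecedent conjunction needs at least one column")
    psi = np.asarray(succedent_column, dtype=bool)
    m = psi.shape[0]
    if m < 1:
        raise ValidationError("data matrix must have at least one row")
    phi = cols[0].copy()
    for col in cols[1:]:
        if col.shape[0] != m:
            raise ValidationError("all columns must share the same length")
        phi &= col
    if cols[0].shape[0] != m:
        raise ValidationError("all columns must share the same length")
    a = int(np.count_nonzero(phi & psi))
    b = int(np.count_nonzero(phi)) - a
    k = int(np.count_nonzero(psi))
    c = k - a
    d = m - a - b - c
    return FourFoldTable(a, b, c, d)


def above_average_truth(t: FourFoldTable, cfg: QuantifierConfig) -> bool:
    """Above Average quantifier: confidence >= (1+p) * prevalence, a >= Base.

    The boundary (exact equality) is TRUE.  Cross-multiplied to avoid
    division, so tables sitting exactly on the threshold evaluate exactly.
    """
    if t.m < 1:
        raise ValidationError("empty table")
    if t.a < cfg.base:
        return False
    if t.r == 0:
        return False
    return t.a * t.m >= (1.0 + cfg.p) * t.k * t.r


def frequency_coefficient(t: FourFoldTable) -> float:
    """Achieved frequency coefficient: lift minus one.

    ``lift = (a/(a+b)) / ((a+c)/m)``; the outcome is ``1 + p`` times more
    common under ``phi`` than on average.  This is the supremum of ``p`` at
    which :func:`above_average_truth` holds (ignoring the support threshold).
    """
    if t.r == 0 or t.k == 0:
        raise DegenerateTableError(
            f"frequency coefficient undefined: a+b={t.r}, a+c={t.k}"
        )
    return t.a * t.m / (t.r * t.k) - 1.0


def fisher_pvalue(t: FourFoldTable) -> float:
    """One-sided Fisher exact tail P(A >= a) with all margins fixed.

    Hypergeometric sum over ``j = a .. min(r, k)`` of
    ``C(k, j) C(l, r - j) / C(m, r)``, accumulated with log-gamma terms and
    logsumexp; the observed table is included in the tail.
    """
    m, r, k, l = t.m, t.r, t.k, t.l
    if m < 1:
        raise ValidationError("empty table")
    hi = min(r, k)
    j = np.arange(t.a, hi + 1, dtype=np.int64)
    if j.size == 0:  # a > min(r, k) cannot occur for a valid table
        return 1.0
    log_terms = (
        gammaln(k + 1) - gammaln(j + 1) - gammaln(k - j + 1)
        + gammaln(l + 1) - gammaln(r - j + 1) - gammaln(l - r + j + 1)
        - (gammaln(m + 1) - gammaln(r + 1) - gammaln(m - r + 1))
    )
    p = float(np.exp(logsumexp(log_terms)))
    return min(p, 1.0)


def fisher_truth(t: FourFoldTable, cfg: QuantifierConfig) -> bool:
    """Fisher quantifier: strict positive association and tail <= alpha."""
    if t.a * t.d <= t.b * t.c:
        return False
    return fisher_pvalue(t) <= cfg.alpha


def prevalence_multiplier(p: float) -> float:
    """Prevalence multiplier implied by frequency coefficient ``p``.

    An Above Average association at coefficient ``p`` means the succedent is
    at least ``1 + p`` times as common among antecedent rows as on average.
    """
    if not p > 0:
        raise ValidationError(f"frequency coefficient p must be > 0, got {p}")
    return 1.0 + p


def percent_excess(p: float) -> float:
    """The same threshold as a percentage excess over the whole-matrix rate:
    at coefficient ``p`` there are at least ``100*p`` % more succedent rows
    among antecedent rows than average."""
    if not p > 0:
        raise ValidationError(f"frequency coefficient p must be > 0, got {p}")
    return 100.0 * p
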