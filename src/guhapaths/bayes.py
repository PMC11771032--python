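"""Posterior characterization of a mined path's prevalence ratio.

For a path's four-fold table, place independent uniform Beta(1,1) priors on
the succedent rate among antecedent rows (``pi_phi``, from ``a`` successes
in ``a+b``) and among the rest (``pi_notphi``, from ``c`` in ``c+d``), and
study the ratio against the whole-matrix rate — the same denominator the
Above Average quantifier uses::

    rho = pi_phi / pi_overall,   pi_overall = (r*pi_phi + s*pi_notphi) / m

Monte-Carlo draws from the two conjugate Beta posteriors give the posterior
mean of ``rho``, an equal-tailed credible interval, and the certainty that
the path's prevalence ratio exceeds the task's ``1 + p`` threshold.  This is
a documented Beta-Binomial reconstruction of a posterior over generalized-
quantifier parameters; it makes no claim of matching any particular mining
software's internal variant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateTableError, ValidationError
from .quantifiers import FourFoldTable

__all__ = ["PosteriorSummary", "path_posterior"]

DEFAULT_DRAWS = 100_000
MIN_DRAWS = 10_000


@dataclass(frozen=True)
class PosteriorSummary:
    """Posterior of one path's prevalence ratio rho (vs the overall rate)."""

    path: tuple[str, ...] | None
    ratio_mean: float
    ci_low: float
    ci_high: float
    level: float
    prob_exceeds: float  # P(rho >= 1 + p_task)
    p_task: float
    draws: int
    seed: int | None


def path_posterior(
    t: FourFoldTable,
    p_task: float,
    level: float = 0.95,
    draws: int = DEFAULT_DRAWS,
    seed: int | None = None,
    path: tuple[str, ...] | None = None,
) -> PosteriorSummary:
    """Monte-Carlo posterior summary of the prevalence ratio for one table.

    Requires non-degenerate margins (``a+b >= 1`` and ``c+d >= 1``).  Fixed
    seed gives identical summaries; ``draws`` defaults to 100,000 and must
    be at least 10,000 so the Monte-Carlo error on the reported quantities
    is well below the reporting precision.
    """
    if t.r < 1 or t.s < 1:
        raise DegenerateTableError(
            f"posterior undefined for degenerate margins a+b={t.r}, c+d={t.s}"
        )
    if not 0 < level < 1:
        raise ValidationError(f"credible level must be in (0,1), got {level}")
    if draws < MIN_DRAWS:
        raise ValidationError(f"draws must be >= {MIN_DRAWS}, got {draws}")
    rng = np.random.default_rng(seed)
    pi_phi = rng.beta(t.a + 1, t.b + 1, size=draws)
    pi_not = rng.beta(t.c + 1, t.d + 1, size=draws)
    overall = (t.r * pi_phi + t.s * pi_not) / t.m
    rho = pi_phi / overall
    tail = (1.0 - level) / 2.0
    lo, hi = np.quantile(rho, [tail, 1.0 - tail])
    return PosteriorSummary(
        path=path,
        ratio_mean=float(rho.mean()),
        ci_low=float(lo),
        ci_high=float(hi),
        level=level,
        prob_exceeds=float((rho >= 1.0 + p_task).mean()),
        p_task=float(p_task),
        draws=draws,
        seed=seed,
    )
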