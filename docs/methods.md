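# Methods

## The outcome: individual premature death from a period life table

Each participant enters the cohort at baseline with a sex and an exact age.
Their **actuarial life expectancy** (ALE) is read from a period life table
indexed by sex and *completed* age (the floor of the exact age — the
convention period life tables are published in).  For a participant who
died, the **excess** is `ALE − years_survived`; the death is **premature**
when the excess is at least a buffer period, 9 months (= 0.75 years) by
default:

```
premature  ⇔  died  ∧  ALE − years_survived ≥ buffer
```

The buffer absorbs small discrepancies between the life-table expectation
and an individual death date that should not count as premature mortality.
Two conventions needed fixing where the rule alone does not decide them:

* **Tie at the buffer.** "A death less than the buffer before ALE is not
  premature" is a strict inequality on the *excluded* side, so a death
  exactly at the buffer **is** premature (`≥`, not `>`).
* **Alive at censoring.** Participants alive at the end of follow-up are
  classified non-premature and kept in the data matrix: the mining step
  needs the full cohort as the `¬ψ` background, not only the deceased.
  A censored participant whose ALE extends past the censoring horizon
  could still die prematurely later; with registry follow-up ended this is
  unknowable, and the non-premature classification is the conservative
  choice.
* **Buffer arithmetic.** `buffer_years = months / 12` exactly; no
  calendar-day arithmetic is attempted.

`buffer_sensitivity` re-classifies the deaths under a list of buffers
(3/6/9 months by default).  Because the classification is a threshold on a
fixed excess, the premature sets are nested and counts are monotone in the
buffer; the report gives per-buffer counts, shares among deaths and
adjacent-pair percentage-point differences.

## Binarization

Every attribute is split into 2–4 mutually exclusive predicates, by
category sets for categorical attributes and half-open intervals
`[low, high)` for numeric ones (open outer ends).  Missing values leave
all of an attribute's predicate columns false — the Boolean matrix has no
third truth value.  A value that is present but covered by no predicate is
a hard error (it would silently bias the `¬φ` side); a coding whose
intervals leave a gap is flagged by the report-only validator so the user
can close it deliberately.  The shipped BMI example closes the commonly
printed `[25, <29) / [30, −)` gap as `[25, 30) / [30, −)`.  Column order
is (attribute order in the config, predicate order within attribute); this
fixes the enumeration order downstream and makes runs reproducible.

## The quantifiers

For an antecedent conjunction `φ` and the succedent `ψ =
premature_death(yes)`, the four-fold table is

|        | ψ | ¬ψ |       |
|--------|---|----|-------|
| φ      | a | b  | r=a+b |
| ¬φ     | c | d  | s=c+d |
|        | k=a+c | l=b+d | m |

`φ ≈ ψ` is labelled TRUE when **both** hold:

* **Above Average**: `a/(a+b) ≥ (1+p)(a+c)/m` with `a ≥ Base`.  The
  frequency coefficient `p > 0` says the outcome is at least `(1+p)` times
  more common under `φ` than on average; `Base` is the minimum support.
  The boundary is inclusive and is evaluated in cross-multiplied integer/
  float form (`a·m ≥ (1+p)·k·r`) so tables sitting exactly on the
  threshold evaluate exactly.
* **Fisher**: `ad > bc` (strictly positive association) and the one-sided
  exact tail `P(A ≥ a) ≤ α` under the hypergeometric null with all margins
  fixed.  The tail *includes* the observed table, the standard exact-test
  convention.  It is computed as a log-gamma/`logsumexp` sum, stable for
  tables far beyond any cohort size (tested at m ~ 6×10⁶); an exact
  big-integer enumeration and `scipy.stats.fisher_exact` serve as
  independent oracles in the test suite.

The achieved frequency coefficient of a table is `lift − 1` where
`lift = (a/(a+b)) / ((a+c)/m)`; it is the supremum of `p` at which the
Above Average condition holds, and `1+p` is the prevalence multiplier
(`p = 2` ⇒ three times as common; `p = 4` ⇒ five times, i.e. 400 % more).

## Mining

Antecedents are conjunctions of 1–5 predicates, at most one per attribute
(within-attribute predicates are mutually exclusive, so mixed conjunctions
have `a = 0` and can never reach any `Base ≥ 1`; excluding them up front
shrinks the space).  Enumeration is depth-first in lexicographic column
order with Apriori-style support pruning: both `a` and `a+b` are
non-increasing under conjunction extension, so a subtree is cut as soon as
`a < Base` (which subsumes `a+b < Base`); pruning therefore never removes
a true path, and the suite verifies pruned output equals both the unpruned
run and an exhaustive brute-force evaluation on hundreds of random
instances.  Columns are bit-packed and counted with vectorized popcounts;
one verification costs two ANDs and two popcounts independent of logical
width.  Verification and prune counters are reported per task as
diagnostics of search effort; they are traversal-specific and not
comparable across implementations with different internals.

A **schedule** is a list of tasks `(label, Base, p, α, length bounds,
optional row filter)`.  Tasks trade support against strength: lowering
`Base` while raising `p` walks down the support ladder toward rarer but
stronger associations.  Paths found by several tasks are deduplicated by
antecedent set and carry the full set of finding tasks.  `stratified_run`
repeats a schedule inside each predicate stratum of an attribute (e.g.
sex), erroring on empty strata.  Within a stratum the stratum's own
predicate is constant-true, so paths can reappear in redundant augmented
variants; they are reported as found rather than silently collapsed.
The cross-path summary counts, per predicate, the number of (per-task and
total unique) paths containing it, sorted by total.

No multiple-testing correction is applied beyond the deliberately low
default `α = 0.001`; the procedure is exploratory and its output is a set
of hypotheses, not confirmatory effect estimates.

## Bayesian path characterization

For each path, independent uniform `Beta(1,1)` priors are placed on the
outcome rate inside the antecedent (`π_φ`, conjugate update from `a` of
`a+b`) and outside (`π_¬φ`, from `c` of `c+d`).  Monte-Carlo draws from
the two Beta posteriors induce a posterior over the prevalence ratio

```
ρ = π_φ / π_overall,    π_overall = (r·π_φ + s·π_¬φ)/m
```

— the same whole-matrix denominator the Above Average quantifier uses.
Reported: posterior mean of ρ, equal-tailed credible interval (default
95 %), and `P(ρ ≥ 1 + p_task)`, the certainty that the path's ratio
exceeds the threshold of the strictest task that found it.  Defaults:
100,000 draws (floor 10,000), explicit seed required in CLI use.  This is
a transparent Beta-Binomial reconstruction of "a posterior over quantifier
parameters"; whether one targets the frequency coefficient or the
prevalence ratio is a `−1` shift, and the ratio is what is reported.  At
10⁵ draws the Monte-Carlo error on the mean and interval endpoints is well
below the two decimals reported.  Prior-predictive simulation in the test
suite confirms nominal 95 % interval coverage within binomial error.

## Synthetic cohorts

The generator produces the only data the analysis scripts consume, shaped
to the emulated study conditions: `n = 6257`; 80 categorical attributes
with a (10 %, 20 %, 70 %) mix of 2/3/4 categories (~288 predicates, plus
sex and a 3-band age coding — note that the often-quoted "333 predicates
from 80 attributes of 2–4 categories" is arithmetically unattainable,
since 80 × 4 = 320); premature prevalence 0.247; 55.3 % female; ages
44–58; 29-year censoring horizon.  Planted paths default to a 5-predicate
conjunction at lift 2.0 with 8 % carriers and a 3-predicate conjunction at
lift 1.6 with 10 % carriers, inside the 1.5–2.5 lift band that mined paths
of such cohorts occupy.

Design choices that matter:

* **Exact-count planting.**  The outcome indicator is assigned by exact
  counts — `round(λ·π·|C|)` positives inside each carrier block `C`,
  marginal fixed at `round(π·n)` — and non-carrier rows are resampled away
  from a planted path's full category tuple, so `P(φ)` equals the carrier
  block and the realized lift equals the target up to integer rounding.
  The generator's purpose is *controlled* lift: a task whose threshold
  `1+p` coincides with a planted `λ` must meet a realized boundary, not a
  Bernoulli coin flip around it.  Placement (which rows are carriers,
  which carriers are positive, all category draws) remains random under
  the seed, and outputs are byte-identical for equal seeds.  Rounding can
  land a hair on either side of the target — the whole-population analysis
  in `analysis/03` shows a plant at realized lift 1.997 slipping under an
  inclusive 2.0 threshold, which is reported as the finding it is.
* **Back-constructed survival.**  ψ is generated first; survival times are
  then drawn so that re-classification at the 9-month buffer reproduces ψ
  exactly: positives die with excess ≥ 0.8 years, negatives either die
  with excess below 0.7 years (13.8 % of them, matching a ~0.35 overall
  death rate) or are censored alive at 29 years.  Background death excess
  is drawn down to −4 years, so 3/6/9-month buffers give strictly nested
  premature sets.  Rows whose ALE exceeds the censor horizon by more than
  the buffer cannot exhibit an observable non-premature death and are
  censored alive instead.
* **Independent non-planted attributes.**  The null structure is fully
  independent categories; no attribute correlations are emulated.
* The synthetic life table is linear in age (women ~6 years above men,
  levels placing the median ALE in the mid-20s); it exercises the lookup
  path but is not a fitted national table.
* An infeasible plant (`λ·π > 1`, overlapping attribute sets, carrier
  blocks exceeding half the cohort) is an error, never silently clipped.

What passing tests on these cohorts do **not** show: real cohorts have
correlated attributes, informative missingness, non-uniform category
margins and outcome mechanisms that are not planted conjunctions, so
recovery rates here are upper bounds on behaviour under real data — the
generator validates the machinery, not the epidemiology.

## Problem sizes used by the test suite

The suite keeps every check inside a laptop-scale budget as its own
experimental design: Fisher-tail agreement on 1,000 random tables with
`m ≤ 200` against exact enumeration (tolerance 1e-10); miner equality with
brute force on 200 random matrices (≤ 6 attributes, ≤ 15 predicates,
length ≤ 3); planted-path recovery at the full `n = 6257` with a
12-attribute cohort across 20 seeds (λ = 2.4, 5 % carriers, task
Base 75 / p 1.4 / α 0.001); null false-path control on ten 2,000-row
cohorts; posterior coverage over 300 prior-predictive tables at 10,000
draws.

## Known limitations

* Verification counts are not comparable across mining implementations.
* The Bayesian layer is per-path; no hierarchical sharing across paths and
  no model averaging.
* The miner's output is the full TRUE set — no closure/maximality
  filtering, so strong paths surface together with their passing
  refinements (see `analysis/03` for a worked example of a spurious
  refinement).
* Only the Above Average + one-sided Fisher pair is implemented; other
  generalized quantifiers (implication, equivalence, two-sided tests) are
  out of scope.
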