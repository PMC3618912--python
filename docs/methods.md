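# Methods

## Rough-set model

A decision table is `(U, C ∪ {d})` with a finite universe `U` of
objects, integer-coded condition attributes `C`, and one decision
attribute `d`. For `P ⊆ C`, the indiscernibility relation partitions `U`
into blocks of objects agreeing on every attribute of `P`. For a target
set `X ⊆ U` the P-lower approximation is the union of blocks contained
in `X`, the P-upper approximation the union of blocks meeting `X`; the
boundary is their difference and the negative region the complement of
the upper approximation. The positive region of the decision,
`POS_P(d)`, is the union of the lower approximations of the decision
classes — equivalently, the union of P-blocks that are decision-pure —
and the dependency degree is `γ_P(d) = |POS_P(d)|/|U|`.

γ is computed with integer counts and exposed as an exact `Fraction`
alongside a float. This matters at the acceptance threshold: α = 0.96
comparisons are made in exact rational arithmetic (`Fraction(alpha)`
with a bounded denominator), so a subset with γ = 24/25 = 0.96 is
accepted by `≥` without any floating-point edge behaviour. Acceptance is
`γ ≥ α`, never strict.

The empty attribute subset is legal (one block covering `U`; γ is 1
only if a single decision value is present). Object indices are 0-based
internally; user-facing reports count from 1.

## Discretization

Raw measurements map onto four-level crisp scales:

| kind | unit | bins (code 1..4) |
|---|---|---|
| max flow | ml/s | [0,10), [10,20), [20,30), [30,40] |
| avg flow | ml/s | [0,7), [7,14), [14,25), [25,40] |
| sampled flow | ml/s | same as avg flow |
| residual volume | ml | {0}, (0,50), [50,150), [150,500] |

Intervals are half-open with the final upper bound inclusive; residual
volume's first bin is exactly zero ("none"). Values outside the total
range raise an error rather than clamp — the scales state closed total
ranges and no clamping rule, and silently saturating a 600 ml residual
volume would hide a data problem.

## Reducers

Three independent routes to reducts are implemented, which cross-check
each other in the tests:

1. **Exhaustive enumeration** (`rough_core.exhaustive_reduct_search`,
   `minimal_reducts`): every subset in a size range, γ computed
   directly. Refuses more than 20 attributes (a 12-attribute table
   already means 4095 subsets; the cap forestalls runaway enumeration).
   This is the correctness oracle for both other routes.
2. **Discernibility function**: for each object pair with different
   decisions, the set of attributes distinguishing the pair becomes a
   clause; empty cells (indiscernible pairs with different decisions —
   inconsistencies) are recorded but excluded from the function. After
   absorption (dropping any clause containing another) the prime
   implicants of the CNF are exactly the decision-relative reducts.
   CNF→DNF conversion distributes clauses smallest-first with absorption
   after every step; if the intermediate DNF exceeds 200 000 terms the
   result is returned flagged incomplete rather than exhausting memory.
3. **Johnson greedy cover**: repeatedly pick the attribute with the
   largest summed weight over uncovered clauses, remove what it covers.
   Clause weights default to 1 (a pure count heuristic; a per-clause
   weight vector can be supplied). Ties break toward the lowest
   attribute index so runs are reproducible. An `abort_fraction` stops
   the loop once that fraction of total clause weight is covered,
   trading coverage for speed. The result is always a hitting set, hence
   a superset of some prime implicant — not necessarily minimal.

## Genetic search

The genome is an **ordered list of k distinct attribute indices**. The
encoding follows from the operators: linear order crossover and the
input-change mutations are permutation operators, meaningless on a
bitmask. Subset sizes are handled by an outer sweep — one GA run per k
in the configured range; crossover therefore always pairs equal-length
parents.

Per generation: the **gene pool** is the union of the last two
generations, deduplicated by gene set and sorted by fitness descending;
an intermediate generation of `population_size` is selected from it;
consecutive pairs recombine by LOX with probability `crossover_rate`
(default 0.5); each offspring mutates with probability `mutation_rate`
(default 0.5, kind swap2/swap3/mixed); fitness is γ via a memoizing
evaluator. Chromosomes reaching `γ ≥ α` are accumulated throughout; by
default the run spends its full generation budget to collect many
reducts, `stop_on_first` implements the literal stop-at-threshold rule.
Accepted sets are re-verified against a fresh γ computation and
annotated with minimality before being reported.

Selection strategies:

* **roulette** — draws proportional to fitness (uniform fallback when
  all fitness is zero);
* **classical artificial** — `round(best%·n)` top ranks, remainder from
  the bottom;
* **modified artificial** — best and worst regions as above plus a
  middle region starting at the rank just past the median of the
  descending list and proceeding toward worse ranks, skipping ranks
  already taken. Region sizes use round-half-up with the remainder
  assigned to the middle region, so they always sum to n. Both starting
  generations are drawn randomly with cross-generation duplicate
  suppression.

The middle region and the duplicate-free start are the point of the
modified strategy: they keep mid-fitness genetic material in play, which
on tables with many incomparable near-reducts prevents the pool
collapsing onto one local optimum.

Defaults: population 30, α 0.96, crossover and mutation rates 0.5,
percentages 33/34/33 (classical runs use 40/60). One seeded
`numpy.random.Generator` threads through every stochastic step; the seed
is recorded in the result.

## Neural evaluation

Reducts are judged by training a one-hidden-layer MLP on the reduct's
columns. All columns — decision included — are min-max normalized to
[0, 1]; the single sigmoid output neuron regresses the normalized class
code, and prediction maps the output to the nearest normalized class
target (ties to the lower code). Training is per-pattern stochastic
gradient descent on the squared error with momentum:
`Δw(t) = λ·δ·input + μ·Δw(t−1)`, with `δ_out = C(1−C)(target−C)` and
hidden deltas back-propagated through the output weights. Weights
initialize uniformly in ±0.5 (seeded); defaults λ = 0.5, μ = 0.8,
4 hidden units. Epochs shuffle with the same seeded generator and stop
at `max_epochs` or a target MSE. A single output neuron was chosen over
one-hot outputs because the class targets live on one normalized [0, 1]
axis; with three classes the targets are 0, ½, 1, which is adequate for
ordinal risk codes but would be a poor encoding for unordered classes.

Evaluation uses a stratified 70/30 split (every class keeps at least one
training row) with a recorded seed. Metrics dichotomize: classes 1–2
(very risky, risky) positive, class 3 (healthy) negative; accuracy,
sensitivity TP/(TP+FN), specificity TN/(TN+FP), PPV, NPV as percentages
to two decimals, with zero-denominator measures reported as undefined
rather than raising. The prose definition of specificity sometimes seen
with this material (TN over FN+TP) is a known slip; the standard
TN/(TN+FP) is used.

## Synthetic generator

`synthesize_table` emulates tables with the structure of the urological
database: four value levels, three classes, 12 attributes in the usual
configuration. In consistent mode the decision is a seeded lookup table
over the planted-reduct projection — any deterministic function
guarantees γ = 1 for the planted subset and for the full attribute set.
`ensure_minimal` resamples (bounded attempts) until every
one-attribute-smaller subset of the planted reduct has γ < 1, making it
a genuine minimal reduct. Conflict mode duplicates a fraction of rows
with a changed decision, forcing γ of the full set below 1.

What the generator does **not** emulate: correlated attributes (real
uroflowmetric measurements are strongly correlated — a high maximum flow
rarely accompanies a very low average flow), ordinal smoothness of the
decision in the codes, class imbalance, and measurement noise near bin
boundaries. Passing tests on synthetic tables therefore demonstrate
combinatorial correctness of the reducers and the search, not clinical
performance on real cohorts.

## Problem sizes and numerical choices

The bundled sample table has 15 rows × 12 attributes. Oracle-equivalence
and Johnson-validity checks run on 100 seeded consistent tables of up to
25 rows × 8 attributes — sizes where exhaustive enumeration is exact and
fast. Genetic recovery runs 20 seeds of 20-row, 12-attribute tables with
a planted size-3 minimal reduct (population 30, ≤100 generations).
Gradient correctness uses central finite differences at ε = 1e−6 with
tolerance 1e−5 on networks of up to 4×4 units. Absorption ordering,
greedy tie-breaks, and report sorting are all fixed (size, then
lexicographic) so every artifact of a run is byte-reproducible from its
seed.

## Limitations

* Prime-implicant enumeration is worst-case exponential; the term cap
  makes it fail soft (flagged incomplete), not fast.
* α is applied globally; no per-class or variable-precision thresholds.
* The MLP is deliberately plain — no minibatching, regularization, or
  alternative activations — since its role is comparative evaluation of
  reducts, not state-of-the-art classification.
* With 15 sample rows the fixture's reducts are far smaller than those
  of the full 120-patient database (single attributes already reach
  γ = 1); conclusions about the real system need the real data.
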