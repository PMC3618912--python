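# roughsel

Rough-set attribute reduction with genetic search, for discrete medical
decision tables — built around a urological risk-classification system
driven by uroflowmetry.

## The problem

A uroflowmetry exam yields twelve measurements per patient: maximum flow
rate `a1` (ml/s), average flow rate `a2` (ml/s), residual urine volume
`a3` (ml), and nine flow-rate samples `a4..a12` taken between T/4 and
3T/4 of the voiding time T. Each is coded onto a four-level linguistic
scale (e.g. maximum flow: very low / low / medium / high at 10, 20 and
30 ml/s thresholds), and a clinician assigns a risk class
`d ∈ {1 very risky, 2 risky, 3 healthy}`. The question for anyone
training a classifier on such data: which of the twelve attributes are
actually needed to determine `d`?

Rough-set theory answers it without any probabilistic model. Objects
agreeing on every attribute of a subset `P ⊆ C` are indiscernible; the
**positive region** `POS_P(D)` is the union of indiscernibility classes
whose members all share one decision, and the **dependency degree**

```
γ_P(D) = |POS_P(D)| / |U|
```

is the fraction of patients whose class is fully determined by `P`. A
**reduct** is a minimal subset with γ at or above a threshold α (α = 1
demands exact functional dependency; the default α = 0.96 tolerates a
little inconsistency and yields more reducts).

## What the package provides

* `decision_table` — the `(U, C ∪ D)` container, CSV I/O, the crisp
  linguistic discretizer for raw measurements, a bundled 15-patient
  sample table, and a seeded synthetic generator with plantable minimal
  reducts.
* `rough_core` — equivalence classes, lower/upper approximations,
  positive/boundary/negative regions, exact-rational γ, brute-force
  subset enumeration (the oracle), minimality tests.
* `discernibility` — the decision-relative discernibility matrix, its
  CNF function, all reducts as prime implicants (absorption-pruned
  clause distribution, resource-capped), and the Johnson greedy
  weighted-cover reducer.
* `ga_reduct` — the genetic reduct search: chromosomes are ordered lists
  of k distinct attribute indices, fitness is γ, recombination is linear
  order crossover (LOX), mutation swaps 2–3 genes for outside
  attributes. Selection is roulette, classical artificial (best+worst
  rank regions), or the **modified artificial** strategy: both starting
  generations random, gene pool from the last two generations, and an
  additional middle region read downward from the median rank — the
  diversity of which counters lock-in to local optima.
* `ann_classifier` — a one-hidden-layer sigmoid MLP trained by
  per-pattern backprop with momentum, for judging reducts as classifier
  inputs; min-max normalization and plain-text weight persistence.
* `metrics` — accuracy, sensitivity, specificity, PPV, NPV on the
  risky-vs-healthy dichotomy (classes 1, 2 positive; 3 negative).
* `cli` — the `roughsel` command with `fixture`, `simulate`,
  `discretize`, `reduce`, and `evaluate` subcommands; every run writes a
  replayable JSON manifest.

## Worked example

```
$ roughsel fixture sample.csv
wrote 15-row sample table to sample.csv

$ roughsel reduce sample.csv --strategy exhaustive --kmin 1 --kmax 1 --alpha 1 --out singletons.tsv
element_number  reduct  dependency
1       a1      1
1       a2      1
1       a4      1
...
```

On the 15-row sample, maximum flow rate alone already determines the
class (`γ_{a1} = 1`): every patient with `a1 ∈ {1, 2}` is very risky,
every one with `a1 ∈ {3, 4}` healthy. The genetic search at a larger
subset size:

```
$ roughsel reduce sample.csv --strategy ga-modified --kmin 5 --kmax 5 \
      --alpha 1 --generations 5 --seed 1 --out reducts.tsv
element_number  reduct  dependency
5       a1a2a3a5a10     1
5       a1a2a3a5a12     1
...
```

Each reported line is a 5-attribute subset whose dependency on the risk
class is exactly 1. Evaluating one attribute subset with the neural
classifier:

```
$ roughsel evaluate sample.csv --reduct a1 --epochs 400 --seed 3
split   accuracy%       sensitivity%    specificity%    PPV%    NPV%
train   100.00  100.00  100.00  100.00  100.00
test    100.00  100.00  100.00  100.00  100.00
```

100% on all five measures, as expected for a subset with γ = 1 on a
linearly separable coding.

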