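# Methods

## Model

The scoring card method is a linear model on the dipeptide-composition
simplex. A sequence of length N contributes N−1 overlapping windows; its
DPC vector `w` lives on the 400-simplex, and the PVP score
`S(P) = w · S` is a convex combination of card scores `S ∈ [0, 1000]^400`.
Classification is a single strict-inequality threshold on `S(P)`. The model
is therefore insensitive to sequence order beyond adjacent pairs, and two
sequences with the same dipeptide frequencies are indistinguishable —
that is the price of a card a biologist can read.

Dipeptides are indexed alphabetically (`AA`=0, `AC`=1, …, `YY`=399);
every serialized card carries the dipeptide labels, the threshold, the
provenance (`init` / `optimized`), the seed and the fitness, so a result
is reproducible from the card file alone.

### Initialization

The raw score of dipeptide d is the difference of class means of the
per-sequence DPC (each sequence weighted equally, so long proteins do not
dominate), min–max mapped onto [0, 1000]. A degenerate raw vector (both
classes identical) maps to all-500 rather than erroring, keeping
pathological synthetic inputs usable. Min–max, rather than a sign- or
variance-preserving map, is the simplest normalization consistent with a
bounded, readable card; the GA's correlation term is invariant to the
choice of affine map anyway.

### Genetic-algorithm refinement

Fitness is `0.9 · auROC + 0.1 · R` with `R = corr(candidate, init)`.
The auROC term is the separation of the candidate's weighted-sum scores on
the training set. Because a fixed candidate card involves no per-fold
estimation, pooled out-of-fold scores under any fold partition equal the
full-training-set scores, so the fitness is computed directly on all
training scores; fitness is then a pure, deterministic function of the
candidate and the elitism monotonicity invariant is exact. A constant
candidate has undefined correlation; its R term is set to 0 and flagged.

Operators are conventional real-coded choices, all exposed in `GAConfig`:

| parameter | default | notes |
|---|---|---|
| population_size | 50 | init vector + 49 Gaussian-perturbed copies |
| generations | 100 | 50 suffices on strongly biased synthetic data |
| crossover_rate | 0.5 | per-gene uniform swap probability |
| mutation_rate | 0.05 | per-gene mutation probability |
| mutation_scale | 50 | std. dev. of the additive perturbation, score units |
| elite_count | 2 | copied unchanged; best fitness never decreases |
| tournament_size | 3 | selection pressure |
| w1 / w2 | 0.9 / 0.1 | must sum to 1 |

The evolved card is clipped to [0, 1000] but **not** re-min–max-normalized:
renormalizing after the fact would retroactively change the R term the
search just optimized. All randomness flows from one integer seed;
identical inputs and seed give a bit-identical card.

### Threshold

Candidates are the midpoints between consecutive distinct training scores
plus one guard below the minimum and one above the maximum; the candidate
maximizing MCC (default; ACC optional) wins, ties broken by the secondary
criterion and then by the lower cut. MCC is the default because the real
benchmark is imbalanced (~1:2) and accuracy saturates on the majority
class. Scores exactly at the threshold are negative (the rule is strictly
"greater than"). During cross-validation each fold's trainer selects its
own threshold; the deployed threshold is selected once on the full
training set.

## Evaluation protocol

Stratified k-fold cross-validation (default k=10), seeded. The summary is
computed on pooled out-of-fold predictions rather than a mean of per-fold
metrics: with small imbalanced folds, per-fold MCC is frequently undefined,
while pooled counts always are. Per-fold metrics are retained. `k = n`
degenerates to leave-one-out (stratification is then vacuous). MCC with a
zero marginal is reported as 0 with an explicit flag. auROC follows the
Mann–Whitney convention (ties count half) and is cross-checked in the test
suite against exhaustive pair counting.

## Interpretation stage

Amino-acid propensity of residue a = mean of the 40 positional dipeptide
scores containing a (20 first-position + 20 second-position terms; the
homodipeptide aa contributes twice — the 40-term convention is kept
literally even though only 39 dipeptides are distinct). Propensities are
correlated (Pearson) against AAindex1 scales; incomplete scales (any NA)
are excluded but counted. Selection is strict `|R| > cutoff`, cutoff 0.5
by default and configurable — published analyses sometimes discuss scales
just under the cutoff (e.g. a hydrophobicity index at R = 0.484), so the
cutoff is a parameter, not a constant.

Three published reference columns ship with the package as a hand-built
AAindex1-format excerpt: KOEP990101 (alpha-helix propensity), WOLR790101
(hydrophobicity) and a side-chain size scale that has no AAindex accession
and is bundled under the synthetic accession `SIDECHAIN`. The published
20-value amino-acid propensity column and per-class composition table of
the PVP benchmark are bundled alongside as worked-example inputs for the
correlation and composition stages.

## Synthetic data

The generator emulates the *structure* of the benchmark — two classes,
variable lengths, positives enriched for specific dipeptides — not phage
biology. Negatives are i.i.d. residues from a background distribution
(uniform by default); positives are a first-order Markov chain in which
the transition completing an enriched dipeptide ab is boosted:
`P(b | a) ∝ background(b) · (1 + bias · [ab enriched])`. Markov enrichment
(rather than literal motif insertion) keeps sequences realistic strings
and genuinely exercises overlapping-window counting. The analytic
stationary dipeptide frequency `π(a)·T[a,b]` serves as a law-of-large-
numbers oracle for the generator. `bias = 0` makes the class processes
identical, giving an exact null for calibration.

Defaults mirror the real benchmark's scale: ~100 positives vs ~200
negatives, lengths uniform on 50–500 residues. The study-condition runs in
the acceptance harness use 200/200 sequences, ten enriched dipeptides and
bias 20; at that bias the classes separate perfectly, so those runs
demonstrate recovery of the planted signal and pipeline correctness, not a
realistic error rate. What passing these tests does **not** show: that the
method attains any particular accuracy on real phage data — real PVPs
carry correlated, weak, length-confounded signals the generator does not
imitate.

## Numerical choices and edge cases

- Sequences must be length ≥ 2 (no dipeptide, no score) over the canonical
  20 letters. Non-canonical residues: `strict` (default) rejects with an
  error, `drop` removes the offending letters, `mask` excludes the record
  without altering it — inputs are never silently mutated.
- Min–max rescaling clips its endpoints against floating-point overshoot;
  card constructors tolerate 1e-9 and clip.
- Thresholds chosen at guard candidates are clipped into [0, 1000] when
  stored on a card (relevant only when one class's scores are empty or
  extreme).
- Welch's two-sample t-test (per-sequence composition fractions) supplies
  the composition-table p-values; it is the conservative default for
  unequal variances, and zero-variance identical columns report p = 1.
  With fewer than 2 sequences in a class the p-values are NaN.
- Ranks of composition differences and propensities use stable descending
  sort: ties rank in amino-acid alphabetical order.

## Problem sizes

Test-suite and acceptance runs use 40–400 sequences, GA populations of
12–50 and 5–50 generations — large enough to exercise every code path and
the statistical claims (recovery ≥ 8/10 planted dipeptides, pooled CV
auROC ≥ 0.9 under signal, auROC ∈ [0.4, 0.6] under the null) at
comfortable margins.

## Known limitations

- DPC only: no g-gap dipeptides, physicochemical encodings or profile
  features; order information beyond adjacent residues is invisible.
- The GA's hyperparameters are conventional, not tuned; the fitness
  landscape is mildly multimodal and different seeds give different (all
  logged) cards, which is why multi-replicate training is built in.
- The bundled AAindex excerpt contains three scales; full-database
  correlation requires the user to supply an AAindex1 flat file.
- Class-mean composition weighting (per sequence, not per residue) is a
  modelling choice; pooled-residue weighting would shift scores for
  length-skewed data.
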