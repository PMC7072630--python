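# pvpscm

An interpretable scoring-card classifier for phage (bacteriophage) virion
proteins (PVPs) — capsid, coat and tail proteins and other structural
components of the phage particle. Distinguishing PVPs from non-virion
proteins straight from sequence matters for phage biology and for the
development of phage-derived antibacterials, but black-box classifiers
(SVMs, ensembles) make it hard to see *why* a protein looks structural.
The scoring card method (SCM) trades a little machinery for a lot of
interpretability: the entire model is 400 numbers you can read.

## The method

Every protein `P = p1 p2 ... pN` over the 20 canonical amino acids is
represented by its **dipeptide composition** (DPC): the 400-vector `w` of
overlapping two-residue window frequencies, `w_i >= 0`, `Σ w_i = 1`. The
model is a **score card** assigning each dipeptide a propensity score
`S_i ∈ [0, 1000]`; a protein's PVP score is the weighted sum

    S(P) = Σ_{i=1..400} w_i · S_i        (a convex mix, so S(P) ∈ [0, 1000])

and `P` is called a PVP when `S(P)` is strictly greater than a single
decision threshold.

Training has two stages:

1. **Statistical initialization (init-DPS).** Each dipeptide's raw score is
   the difference between its mean composition in the positive and negative
   class; the 400 raw scores are min–max normalized into [0, 1000].
2. **Genetic-algorithm refinement (opti-DPS).** A seeded, elitist,
   real-coded GA perturbs the card to maximize the composite fitness

       Fit = W1 · auROC + W2 · R,    W1 = 0.9, W2 = 0.1,

   where auROC measures class separation of the weighted-sum scores and
   `R` is the Pearson correlation between the candidate and the initial
   card — a regularizer that keeps the optimized card statistically
   grounded and readable.

Evaluation uses ACC, SN, SP, MCC and auROC under stratified 10-fold
cross-validation (pooled out-of-fold predictions) and independent testing.
For interpretation, per-amino-acid propensities (the mean of the 40
positional dipeptide scores containing each residue) are correlated against
AAindex physicochemical scales; scales with `|R| > 0.5` are flagged as
informative.

## Worked example

Generate a planted-signal benchmark (100 positives enriched for ten
dipeptides, 200 background negatives, lengths 50–500), train, and inspect:

```bash
pvpscm simulate --out demo --n-pos 100 --n-neg 200 --bias 20 --seed 7
pvpscm train demo/positive.fasta demo/negative.fasta \
       --out demo/run --seed 7 --generations 30 --population 30 --k-folds 10
```

which prints the pooled cross-validation report:

```
       ACC_pct  SN_pct  SP_pct  MCC  auROC   threshold  fitness
model
rep0     100.0   100.0   100.0  1.0    1.0  113.051914      1.0
```

At bias 20 the planted signal is strong enough to separate the classes
perfectly (auROC 1.0); the threshold 113.05 is the MCC-optimal cut between
the two score distributions on the card's [0, 1000] scale. Scoring
sequences with the frozen card:

```bash
pvpscm predict demo/positive.fasta demo/run/card_opt_rep0.tsv | head -4
```

```
id      pvp_score  label
pos_0000  197.3618  positive
pos_0001  213.7022  positive
pos_0002  210.9867  positive
```

Each score is the composition-weighted mean of the card's dipeptide scores;
anything strictly above the stored threshold is labelled positive.
`pvpscm analyze-pcp demo/run/card_opt_rep0.tsv --out demo/pcp` then writes
the 20 amino-acid propensities and their Pearson correlations against the
bundled physicochemical scales (alpha-helix propensity, hydrophobicity,
side-chain size), flagging scales with `|R| > 0.5`.

The same pipeline is available as a library through a scikit-learn
estimator:

```python
from pvpscm import ScoreCardClassifier
clf = ScoreCardClassifier(generations=50, random_state=7).fit(sequences, labels)
clf.decision_function(["MKLVAT..."])   # PVP scores on [0, 1000]
clf.card_.scores                       # the 400 dipeptide propensities
```

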