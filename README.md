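# gofunc

Protein function prediction for Gene Ontology (GO) molecular-function
terms by an ensemble of heterogeneous classifiers.

Automated function annotation cast as classification needs, per GO term,
a trustworthy positive and negative training set and a way to combine
evidence of different kinds — overall homology, conserved subsequences,
and global physicochemical character — because no single feature family
recognises every function.  `gofunc` provides, for people building or
studying sequence-based annotation pipelines:

* **DAG-aware training sets.**  Positives for a term *t* are proteins
  annotated to *t* or an `is_a` descendant with an experimental evidence
  code (IDA, IEP, IGI, IMP, IPI, RCA, TAS; electronic/ambiguous codes
  IC, IEA, ISS, NAS, ND are filtered out).  Negatives are sampled (at
  most 10 per non-target term) among proteins with no annotation in
  *t*'s descendant closure; a protein annotated to an ancestor of *t*
  but to no sibling is *susceptible* — possibly an under-annotated
  positive — and is excluded from both sets.
* **Three one-vs-rest classifiers** per term:
  * alignment-score kNN — Smith–Waterman/BLOSUM62 similarities to the
    training set; score `S = (Sp − Sn)/(Sp + Sn)` over the k nearest
    neighbours, where `Sp` (`Sn`) sums positive (negative) neighbour
    scores, so `S ∈ [−1, 1]` with `S = 1` when all k neighbours are
    positives;
  * subsequence-profile SVM — fixed-length windows of the positive set
    are clustered, each cluster summarised by a position-specific
    probability profile, and sequences mapped to best-match probability
    vectors;
  * peptide-statistics SVM — a 37-dimensional vector of classical
    protein statistics (molecular weight, pI, charge, extinction
    coefficients, Dayhoff statistics, residue-category percentages),
    scaled by the positive-training ranges.
* **Threshold relaxation.**  Raw outputs are calibrated against a
  labelled helper set: `Cp(x)` = fraction of positive helpers below x,
  `Cn(x)` = fraction of negative helpers above x, and
  `P(x) = Cp/(Cp + Cn)` (0.5 when both vanish).  This counters the
  majority-class bias of the natural threshold 0 on imbalanced
  one-vs-rest data.
* **Four combiners:** majority voting, mean probability, ROC-weighted
  mean (`w_i = ROC_i^e / Σ_j ROC_j^e`, default `e = 10`), and addition
  of raw outputs followed by calibration of the sum.
* **Evaluation harness:** stratified 5-fold cross-validation with
  leave-one-out calibration inside each test fold, F1 / sensitivity /
  specificity / precision / ROC score per (term, method), and a Wilcoxon
  signed-rank comparison between methods.
* **A synthetic-world generator** producing toy `is_a` DAGs, protein
  families with planted motif / composition / homology signals, and
  annotation records with mixed evidence codes, written as standard
  OBO / GAF / FASTA so the real parsers are exercised end to end.

## Worked example

```python
from gofunc import (KnnMethod, SpmapMethod, PepstatsMethod,
                    build_term_dataset, cross_validate, generate_world)

world = generate_world(n_terms=10, n_signal_terms=3, n_per_family=20, seed=1)
term = sorted(world.signal_registry)[0]          # a motif-signal term
ds = build_term_dataset(term, world.annotations, world.ontology, seed=1)
report = cross_validate(
    ds, world.sequences,
    {"knn": lambda: KnnMethod(), "spmap": lambda: SpmapMethod(),
     "pepstats": lambda: PepstatsMethod()},
    folds=5, seed=1,
)
print(report[["f1", "sensitivity", "specificity", "roc_score"]].round(3))
```

prints (fold-averaged, per method and combiner):

```
                     f1  sensitivity  specificity  roc_score
method
knn               0.836         0.75         0.95      0.925
knn_natural       0.921         0.90         0.95      0.988
spmap             0.814         0.75         0.90      0.869
spmap_natural     0.876         0.80         1.00      0.950
pepstats          0.836         0.75         0.95      0.925
pepstats_natural  0.949         0.95         0.95      0.988
vote              0.886         0.80         1.00      0.969
mean              0.943         0.90         1.00      0.969
wmean             0.943         0.90         1.00      0.975
add               0.857         0.75         1.00      0.969
```

Rows without the `_natural` suffix use threshold-relaxed labels, rows
with it use the raw output at its natural threshold 0; `wmean` is the
ROC-weighted mean of the three calibrated probabilities.  On this small
*balanced* toy term relaxation has nothing to buy — its value shows on
imbalanced data, where it trades a small specificity loss for a much
larger sensitivity gain (see `tests/test_acceptance.py`).

The same workflow is available from the shell:

```sh
gofunc simulate --outdir world --n-terms 10 --seed 1
gofunc build-datasets --obo world/ontology.obo --gaf world/annotations.gaf \
    --fasta world/sequences.fasta --outdir datasets --min-products 10
gofunc train --datasets datasets --outdir models
gofunc predict --models models --fasta world/sequences.fasta --out pred.tsv
```

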