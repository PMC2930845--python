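# Methods

## Problem setting

Each GO molecular-function term is treated as an independent binary
(one-vs-rest) classification problem over protein sequences.  The
molecular-function aspect is used because proteins sharing a molecular
function are the most likely to share sequence, subsequence or
physicochemical features; only `is_a` relations are honoured, since the
other GO relation types are negligible for this aspect.

## Training-set construction

The GO DAG makes "positive" and "negative" non-trivial: an annotation to
a descendant implies the ancestor, and an annotation to an ancestor may
simply be an under-specified annotation to the term itself.

* **Positives** — proteins annotated to the target or an `is_a`
  descendant, restricted to experimental/traceable evidence codes
  (IDA, IEP, IGI, IMP, IPI, RCA, TAS).  Electronic or ambiguous codes
  (IC, IEA, ISS, NAS, ND) are excluded to avoid circularity with
  computational annotation and to reduce noise.  The evidence filter is
  applied to the positive side only (a config switch can extend it to
  negatives).
* **Negatives** — to keep the negative set representative yet bounded,
  up to `per_term_cap` (default 10) proteins are sampled uniformly
  without replacement from each non-target term, subject to:
  (1) no annotation to the target or any descendant; and (2) a protein
  annotated to an ancestor of the target must also be annotated to a
  sibling (a term sharing ≥ 1 parent).  Proteins failing only (2) are
  *susceptible* — plausibly future positives — and enter neither set.
  "Ancestor" is read transitively (all `is_a` ancestors, not only
  parents); the transitive reading is the safer one against leaking
  prospective positives into the negatives.
* Sampling uses a per-source-term RNG substream keyed by
  `blake2b(seed | term_id)`, so adding or removing one term never
  perturbs another term's sample, and results are independent of
  Python's hash randomisation.
* Terms are considered trainable when ≥ `min_products` (default 100)
  distinct proteins are associated after evidence filtering; overly
  broad terms (a configurable blacklist, canonically "binding") are
  dropped regardless of size.

## The three classifiers

**Alignment kNN.**  Similarities are Smith–Waterman local alignments
with BLOSUM62, gap open 11 / extend 1 (the protein defaults of the
standard local-alignment search tools), reported in bit-score-like units
via the Karlin–Altschul constants (λ = 0.267, K = 0.041); raw scores are
a config option, and the score definition is invariant to this choice up
to the additive constant's effect on low-scoring hits.  The k (default
5) highest-scoring training neighbours vote through their scores:
`S = (Sp − Sn)/(Sp + Sn) ∈ [−1, 1]`.  Ties at the k-th rank are all
included, so the result does not depend on sort order.  A query with no
positive-scoring neighbour at all scores 0 and is flagged
`no_homology` instead of raising, so the ensemble can still use the
other two methods.

**Subsequence profiles.**  All length-`l` (default 5) windows of the
positive training sequences are clustered greedily: a window joins the
first cluster whose founding window it matches with ungapped BLOSUM62
score ≥ `threshold` (default 8), else founds a new cluster.  The greedy
pass is order-dependent; input windows are canonicalised (sorted) so the
result is reproducible.  Each cluster yields an `l × 20` probability
profile with additive pseudocounts (default 1):
`p[i][a] = (count + pc)/(n + 20·pc)`.  A sequence maps to one value per
cluster: the best window probability, computed as the geometric-mean
per-position probability `exp(mean log p)`, which stays in (0, 1] and is
comparable across `l`; the raw product is available as an option.
Unknown residues (X) take the profile row mean.  The vectors feed an
RBF-kernel SVM (scikit-learn defaults, fixed seed).

**Peptide statistics.**  A 37-dimensional vector per sequence: molecular
weight, residue count, average residue weight, isoelectric point, net
charge at pH 7, both A280 extinction coefficients, improbability of
inclusion-body expression, 20 Dayhoff statistics, and 9 residue-category
percentages.  Constant tables follow the EMBOSS dialect: average residue
masses; the EMBOSS pK set (N-term 8.6, C-term 3.6, D 3.9, E 4.1, H 6.5,
C 8.5, Y 10.1, K 10.8, R 12.5) with the pI found by bisection to
|charge| < 1e−4 (the charge-vs-pH curve is strictly decreasing, so the
zero is unique); Gill–von Hippel extinction (Trp 5500, Tyr 1490, cystine
125 M⁻¹cm⁻¹, free cysteines 0, pairs counted as ⌊C/2⌋); the
Wilkinson–Harrison solubility model
(`CV = 15.43·f(N,G,P,S) − 29.56·|f_charge − 0.03|`, discriminant
CV − 1.71, probability `0.4934 + 0.276|d| − 0.0392 d²`); Dayhoff (1978)
reference composition; and the EMBOSS residue-category table (so
non-polar and polar percentages are complementary and sum to 100).
X residues contribute the mean residue mass to the weight and are
excluded from composition denominators.  The reference pH of 7 for the
charge and the pK set are documented assumptions, not givens.  Vectors
are min–max scaled by the ranges of the *positive* training vectors,
applied identically to train and test; values outside the positive range
are not clipped, and constant features map to 0.5.

## Threshold relaxation

One-vs-rest training sets are heavily imbalanced, which biases a margin
classifier's natural threshold 0 toward the negative class.  Instead of
shifting the threshold, each raw output `x` is converted to a
probability against a labelled helper set:

    Cp(x) = |{s ∈ helpers⁺ : f(s) < x}| / |helpers⁺|
    Cn(x) = |{s ∈ helpers⁻ : f(s) > x}| / |helpers⁻|
    P(x)  = Cp / (Cp + Cn),  P = 0.5 if Cp = Cn = 0

with strict inequalities (ties count to neither side) and the label
positive iff `P > 0.5`.  The algebraic form of the combination rule and
the mirror direction of the negative count are reconstructions forced by
the documented limit behaviour (P → 1 as x overtakes the positive helper
distribution or escapes the negative one); both are monotone in x, so P
is monotone in x.  A consequence of the strict-count + degenerate-0.5
convention worth knowing: the minimum positive of a perfectly separated
helper-set configuration calibrates to exactly 0.5 and is labelled
negative; with realistic helper sizes (the intended regime is tens of
samples per fold) the effect is confined to that single boundary sample.

In evaluation, each test-fold sample is calibrated leave-one-out against
the rest of its fold (the helper set), which is also where the
per-method ROC scores behind the weighted mean come from; helper samples
are never used for training or for the reported statistics.  At
deployment time no labelled test data exists, so the `train` command
holds out a stratified slice (default 25%) of the training data as the
helper set and persists its outputs with the models.

## Combination

Voting (majority of the three post-relaxation labels), mean probability,
ROC-weighted mean `w_i = ROC_i^e / Σ ROC_j^e` (default `e = 10`; any
`e > 1` prefers the stronger method, larger `e` more sharply; all-zero
ROC scores fall back to uniform), and addition (raw outputs summed on
their native scales, the sum calibrated against summed-output helper
distributions; an optional per-method standardisation pre-step exists
but is off by default to keep the rule faithful to its definition).

## Evaluation

Confusion counts with precision, recall/sensitivity, specificity and F1
(zero denominators give 0, not NaN, so macro-averages over many terms
stay defined); ROC score as the rank statistic P(score⁺ > score⁻) with
ties ½ (scikit-learn's AUC); stratified 5-fold cross-validation
(stratification is an assumption needed for small positive classes);
Wilcoxon signed-rank (scipy, zeros dropped, midranks, normal
approximation with continuity correction; the all-zero-difference case
returns statistic 0, p = 1).

## Synthetic data

The generator emulates a GO corpus at desk scale: a random single-rooted
`is_a` DAG (each term draws 1–2 parents among earlier terms, acyclic by
construction); families with planted motif / composition / homology
signals aligned one-to-one with the three classifier families; and
annotation records with a configurable evidence-code mix plus an
optional ancestor-only fraction that produces susceptible proteins.
Defaults: uniform background residues (option: Dayhoff frequencies),
motif carried by 90% of its family, composition bias 4× on Lys/Arg,
homology identity 0.6, family size 40, lengths 80–120.  What it does
*not* model: real domain architecture, indel evolution, correlated
annotations, database noise — so green tests demonstrate the machinery
and the qualitative mechanisms (imbalance bias, complementary signals),
not real-data accuracy levels.

## Problem sizes used in the checks

The behavioural checks run at sizes chosen to make their effects
unambiguous while staying desk-scale: the imbalance check uses three
independent 10:100 (1:10) terms with a weak composition signal (2× on
Lys/Arg); the combination check uses 10 mixed-signal terms of 16
positives each inside a 24-term DAG; the end-to-end smoke uses a 6-term
world with one term per signal type and 40 positives each.  The two
exact kNN limits are computed on a 7-sequence toy world (three close
homologs of the query at identity 0.8 plus four unrelated sequences).

## Known limitations

* The paper-scale regime (hundreds of terms, 10⁴–10⁵ proteins, real GOA
  evidence-code mixtures) is out of scope; nothing here indexes
  sequences for large-scale search.
* Deployment-time calibration quality depends on the held-out helper
  slice being representative; with very small positive sets the
  empirical CDFs are coarse.
* Greedy subsequence clustering is a deliberate simplification;
  profiles are ungapped and HMM-free.
* The kNN backend is an in-process aligner; scores differ from NCBI
  BLAST bit scores in detail (no composition-based statistics, no
  E-values), which only matters if raw scores are compared across
  tools.
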