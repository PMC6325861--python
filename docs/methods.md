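# Methods

## The scoring schema

A protein's annotation evidence is summarized per feature as an
`EvidenceRecord`: an ordered list of hits (rank 1 = best), each carrying the
fields the rules inspect (organism, E-value, bit score, percent identity,
ATG-start flag, ncRNA annotation, PDB-template flag) plus exclusion flags.
Three evidence classes are discarded by every rule before scoring:
`predicted`, `synthetic`, and `end_to_end_alignment` hits. Flags may sit on
the record (applying to all its hits) or on individual hits; the effective
flag set of a hit is the union.

Rules, with defaults (`RuleConfig`):

| feature | rule | default |
|---|---|---|
| 7 pseudogene | retained *H. sapiens* hit with E < cutoff and no ATG start in any of six reading frames | E-value cutoff 1.0 |
| 8 homology modelling | PDB-template hit with identity strictly greater than threshold | 30 % |
| 9 ncRNA | any ncRNA-annotated hit among the top-k human hits; k widens 3→5 when the relative bit-score spread over the top 5 is below the fraction | k=3→5, spread 5 % |
| 1–6 legacy | generic engine per feature: E-value cutoff (Pfam 1e-3), presence (orthology, BBH, localization), or minimum confidence score (interactions 0.4, linkages 0.7) | see `RuleConfig` |

Two readings deserve a note. The pseudogene criterion is stated in the
source material as considering human hits with "E-value less than zero";
E-values are non-negative, so the cutoff is read as E < 1 (negative log10)
and left configurable. "More than 30 % similarity" is implemented as a
strict inequality on percent identity — exactly 30.0 scores 0. Missing
evidence always scores 0: absence of evidence is treated as criterion not
met, which keeps the schema monotone (adding a qualifying hit can only
raise a score).

The TRS is the row sum of the nine bits. Scoring is a pure function of
(records, config); the matrix writer emits a `#` provenance header with the
config hash so any output can be traced.

## Synthetic study data

The generator emulates the study's data shape — 106 hypothetical proteins
(positive class) and 194 functional proteins (negative class) — because the
real 300-protein feature matrix is not published. Per class, feature j is
Bernoulli(p_class[j]); the default profile is

```
feature        1     2     3     4     5     6     7     8     9
p_positive   0.90  0.90  0.15  0.10  0.80  0.80  0.85  0.80  0.90
p_negative   0.10  0.10  0.60  0.50  0.15  0.15  0.10  0.15  0.05
```

The positive class is enriched on the features reported as high-impact
(Pfam, orthology, functional linkages, pseudogene, ncRNA); the negative
class — well-studied functional proteins — is instead enriched on
documented interactions and reciprocal best hits. Nothing about these
numbers is a claim about the real data; they are the package's replication
profile, chosen once so that (a) the reported within-class correlation
structure can be injected and (b) all four classifier families, including
the bias-free linear perceptron, operate in the high-accuracy regime the
study describes. The second point is geometric: a length-9 perceptron has
no bias term, so its decision boundary passes through the origin, and a
negative row whose only set bit is a positive-leaning feature is
unclassifiable by any such rule. Giving the negative class informative
bits of its own (features 3, 4) removes that degeneracy.

Correlated pairs (1,2), (5,6), (6,8) are induced by a value-copying
mixture: with probability w (default 0.5) feature j copies feature i,
otherwise it is drawn independently. For equal marginals p_i = p_j this
preserves the marginals exactly and gives within-class Pearson r = w; the
default profile therefore uses equal p inside each correlated chain
({1,2} and {5,6,8}). Copies are applied in declaration order, so the
(6,8) pair propagates through the already-mixed column 6 and the chain
also yields r(5,8) ≈ w². Induced correlation is assessed *within* a class:
pooling classes inflates r for every informative pair through class
separation and would mask the mechanism.

Evidence generation inverts the rules: a score-1 feature receives a
qualifying hit (E-values log-uniform below the cutoff, identities uniform
above the threshold), a score-0 feature receives one of several
disqualifying modes (no hits, flagged hit, ATG present, wrong organism,
weak E-value / score) chosen at random. Rescoring the emitted records
reproduces the source matrix bit for bit, which is asserted in the tests
and in the pipeline itself. What the generator does **not** emulate:
realistic E-value/bit-score distributions, hit-count distributions,
between-feature dependence beyond the three induced pairs, or any sequence
content. Passing tests therefore demonstrate correctness of the machinery
and behaviour under the documented statistical structure — not performance
on real annotation evidence.

## Classifiers

All four families consume n×9 binary matrices and predict {0,1}; decision
ties (value 0, within 1e-9 float noise) resolve to the negative, majority
class. Fitted state serializes to JSON and round-trips to identical
predictions on all 2⁹ inputs.

**Pocket perceptron.** Online updates w ← w + η(y − ŷ)x with unit-step
activation (ŷ = 1 iff w·x > 0), initialized from a seeded standard-normal
weight vector. `n_iterations` counts single-example presentations, drawn
in seeded-shuffled epoch order; defaults η = 0.2, n = 1000. After every
weight change the training accuracy is measured and the best-so-far
weights are kept in the pocket; the pocket accuracy trace is recorded and
is non-decreasing by construction. The weight vector has length 9 — no
bias — matching the schema's formulation; `include_bias=True` appends a
constant input for data that needs an offset (e.g. all-zero positives).

**Bernoulli naive Bayes.** Conditionals (count+α)/(n_c+2α) with α = 1 by
default; class priors are unsmoothed relative frequencies. α = 0 is
permitted: zero-probability features contribute −inf log-likelihood via a
select-not-multiply evaluation, so the argmax stays well defined.

**Decision tree.** Recursive binary splits on 0/1 features by gain ratio
(information gain / split entropy; plain gain optional). A feature
constant within a node is unusable; recursion stops at pure nodes, nodes
smaller than `min_leaf` (default 2), or no usable feature. Zero-gain
splits are *not* a stopping criterion — XOR-structured data requires
passing through a zero-gain root. Equal criteria resolve to the lowest
feature index; leaves predict the majority class, ties negative. Pruning
is deliberately out of scope.

**SVM (SMO).** Soft-margin dual solved by simplified sequential minimal
optimization with an objective-driven pair sweep, seeded random second
choice, C = 1, KKT tolerance 1e-3 (default). Kernels: linear x·y,
polynomial (x·y+1)^d, RBF exp(−γ‖x−y‖²), and the normalized polynomial
K/√(K_xx K_yy). The constraints 0 ≤ α ≤ C and Σαy = 0 hold at every step
by construction. The default kernel is polynomial with d = 1.

## Evaluation

Metrics follow the standard confusion-matrix formulas; MCC uses the
square-rooted denominator √((TP+FP)(TP+FN)(TN+FP)(TN+FN)), which bounds it
in [−1,1]. An unrooted variant (numerator over the raw product) exists
behind `mcc_sqrt_denominator=False` for audit only — it is not a bounded
correlation and is never used by the pipeline. Zero denominators yield NaN
plus an entry in the report's `undefined` set, never a silent 0.

Stratified k-fold CV deals each class's shuffled rows into folds so that
per-fold class counts differ by at most one *and* fold sizes are as equal
as possible (exactly n/k when k | n); folds are disjoint and exhaustive,
and the pooled report aggregates confusion counts so each row is counted
once out of sample. The repeated-split protocol draws independent
stratified 66 % train / 34 % test splits (fraction and stratification
configurable), trains fresh each time, and reports mean/max/min held-out
accuracy with the full trace. The library default is 1000 iterations; the
analysis drivers use 200, which stabilizes the mean to well under a
percentage point while keeping a desk run short.

## Feature selection

CFS merit of a subset S is k·r̄_cf / √(k + k(k−1) r̄_ff) over mean absolute
feature–class and feature–feature Pearson correlations; best-first forward
search from the empty set, lexicographic tie-breaks, stops after 5
consecutive non-improving expansions. PCA ranking weights each original
feature by Σ_c |loading| × variance-fraction over the components of the
centered score matrix (eigenvector signs fixed by making each component's
largest-magnitude loading positive); this maps component structure back to
the original feature indices, which is one defensible reading of a
"ranker" applied to PCA — the choice is documented, not claimed unique.
The exhaustive search evaluates all 2⁹−1 subsets under the caller's plan
and breaks accuracy ties toward smaller, then lexicographically earlier
subsets. Single-feature impact uses competition ranking (ties share the
better rank; the next rank is skipped), since impact tables of this kind
conventionally show tied ranks.

## Similarity and ANOVA

Jaccard similarity of two 9-bit profiles is M11/(M11+M10+M01); two
all-zero profiles are identical and score 1 (some conventions use 0 — the
choice is flagged here because it affects sparse negatives). 1−J is a
metric, so the distance matrix obeys the triangle inequality; this is
asserted on random triples. One-way ANOVA is the classical
MS_between/MS_within F test with p from the F distribution; zero
within-group variance returns an explicit degenerate flag rather than a
decision. The default grouping feeds the nine score columns of one class
as groups, i.e. it asks whether score frequencies differ across features
within a class; any other column grouping can be supplied.

## Numerical and reproducibility notes

- All randomness flows through `numpy.random.default_rng` seeds carried in
  the spec/plan/config objects; (config, seed) determines every output
  byte, and the pipeline re-run test asserts byte identity.
- Problem sizes used by the checked analyses: 300-row datasets for CV and
  subset search, 2000 rows per class for generator parameter recovery,
  10,000 random triples for the metric property, 200 split iterations in
  the drivers. These are the package's documented working sizes.
- Known limitations: no pruning in the tree; simplified SMO can leave an
  offset-level gap (~1e-2 in decision values) on bound-heavy problems at
  default tolerance; legacy-feature defaults are package conventions, not
  published thresholds; the synthetic profile is a stand-in, so headline
  accuracies here characterize the profile, not any real HP dataset.
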