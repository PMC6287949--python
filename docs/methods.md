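# Methods

## Model

`gosimpred` treats disease-gene prediction as binary classification on a
gene functional-similarity matrix. The working assumption is that genes
contributing to the same phenotype aggregate in the same biological
processes, so their Gene Ontology (GO) annotations are close in the DAG
and their pairwise semantic similarity is high. A classifier trained on
rows of that matrix therefore learns "is similar to the known disease
genes" without any expression, interaction or sequence features.

### Information content

The ontology is a DAG of terms with child→parent edges typed `is_a` or
`part_of`; only these two relation types are traversed anywhere (they are
the ones the Wang measure defines decay weights for; `regulates`-type
edges are ignored). Annotations follow the true-path rule: a gene
annotated to a term is implicitly annotated to all of the term's
ancestors. The usage probability of term *c* is gene-based:

    p(c) = (# genes whose propagated set contains c)
         / (# genes whose propagated set contains the namespace root)

and IC(c) = −ln p(c) (natural log; any fixed base only rescales IC and
cancels in the normalized measures). The gene-based definition — rather
than counting annotation lines — matches the gene-level semantics of the
downstream matrix and is reproducible from the input files alone. The IC
corpus defaults to every gene in the annotation input (positives,
negatives and candidates together); an external background gene list can
restrict it, since which background a study intends is a genuine choice
the data do not make for you. Terms covering zero genes carry no IC and
are unusable for the IC-based measures.

### Term-level similarity

* **Resnik**: IC(MICA)/IC_max, where the MICA is the common ancestor
  (ancestor sets include the terms themselves) of maximal IC and IC_max
  is the corpus-wide maximum. Raw Resnik is unbounded; the normalization
  puts all measures on the same [0, 1] scale. MICA ties are broken by the
  lexicographically smallest term id so results are bit-reproducible.
* **Relevance** (Schlicker): 2·IC(m)/(IC(t₁)+IC(t₂)) · (1 − p(m)), with
  m the MICA; defined as 0 when both terms are the root. The (1 − p(m))
  factor discounts pairs whose only shared ancestry is common.
* **Wang**: for term A, every ancestor t receives an S-value — the best
  product of edge weights (is_a 0.8, part_of 0.6, the conventional
  values; both configurable) over paths from A up to t, with S_A(A)=1 —
  and similarity is the normalized overlap of the two S-value profiles.
  Purely topological: needs no corpus, so building Wang matrices skips
  the IC stage entirely.

### Gene-level combining

Gene term lists for combining are the **direct** (post-filter)
annotations, not the propagated closures — propagation serves only IC and
MICA. `max` takes the single best term pair; `bma` averages best matches
in both directions (no bootstrap resampling is involved). A gene with no
usable terms has a *missing* similarity, represented as a `None` sentinel
and never silently replaced by 0, because a genuine similarity of 0
exists in the data and conflating the two biases both training and
evaluation. Such genes are excluded before matrix construction and
reported by name.

### Classification and evaluation

Classifiers: random forest (500 trees, mtry = ⌊√#features⌋, bootstrap
sampling per tree, no class weighting), Gaussian naive Bayes, and
linear/radial SVM (cost 1, optimizer tolerance 0.001, radial gamma 0.02).
The SVM "epsilon" of the reference R implementation is a regression-only
parameter; for classification it is interpreted here as the termination
tolerance. Naive Bayes operates on continuous similarity features, for
which class-conditional densities are Gaussian; Laplace smoothing is a
categorical-predictor device and does not apply, so `GaussianNB` is the
faithful implementation of "NB without Laplace smoothing". Each model
exposes a real-valued score (RF/NB: posterior probability of the positive
class; SVM: signed decision value), and AUC is computed rank-based
(Mann–Whitney with mid-rank ties), making it invariant under any strictly
monotone transform of the scores.

Because instances and features are the same genes, the square matrix is
split so that test genes are removed from the feature columns of both the
training and test blocks; the feature order is the training genes' matrix
order, recorded in the fitted model so prediction vectors align
deterministically. Undersampling (all positives kept, negatives sampled
without replacement to `round(P·(100−perc)/perc)`, clamped to
availability) acts on training *instances* only; feature columns remain
the full training fold and test folds are identical across repeats. The
held-out restricted scheme trains identically but computes each fold's
AUC only on HD and negative test genes; with zero LD genes it coincides
exactly with the stratified scheme, which the tests assert.

All randomness flows from one master seed through `numpy.SeedSequence`
into separate fold / undersampling / per-fold-classifier seeds, recorded
in the result object. The mean AUC over all valid fold×repeat records is
the primary aggregate; the fold-averaged-then-repeat-averaged mean is
also reported. A fold whose evaluable test set lacks a class is recorded
as invalid, warned about, and excluded from the mean. Undersampling
defaults to off and is enabled per run; the imbalanced HD-only design is
the one that needs it, and 20 repeats is the convention when it is on.

### Candidate ranking

The final classifier is trained on the full labeled square matrix.
Candidates overlapping the training set or lacking usable annotations are
excluded with an explicit reason; the rest are scored on their similarity
vectors to the training genes and ranked (ties broken by gene id). The
binary call (0.5 on probabilities, 0 on decision values) is secondary;
the ranking is the product.

## Synthetic data

The generator emulates the one property the method needs: disease genes
concentrated in shared biological processes. It builds one root plus
`n_branches` disjoint complete subtrees (default 2 branches, depth 3,
branching 2 → a 29-term DAG — deep enough for informative IC gradients
while keeping exhaustive oracles cheap), types each edge `part_of` with
probability 0.2, and annotates positives to branch 1 and each negative to
a home branch among the others. The noise rate is the per-term
probability of drawing from a non-home branch (default 0.1, a mild
realistic annotation error rate; validation conditions that require a
clean signal set it to 0 explicitly). Default sizes are 40 positives and
120 negatives with 2–5 terms per gene. HD positives annotate at half the
noise rate and LD positives at twice (capped at 1), mirroring the
stronger and weaker evidence tiers of curated disease-gene databases.
Fractions of genes can be emitted with no annotations (exercising the
exclusion path) or with IEA evidence (exercising the filter). The
generator writes real OBO/GAF/TSV files so every end-to-end test runs the
parsers, and all outputs are byte-deterministic given the seed.

What the generator does **not** emulate: the true GO term-count
distribution (tens of thousands of terms, heavy-tailed gene annotation
counts), multiple aspects, annotation biases correlated with study
attention, or inter-branch cross-links. Passing tests therefore show the
machinery is correct and recovers a planted signal, not that any
particular AUC will be attained on real GO/SFARI snapshots, which are
annotation-version dependent.

## Numerical and design notes

* Matrix entries are computed once per unordered pair and mirrored, so
  symmetry is exact; term-pair scores are memoized per matrix build, and
  results are independent of evaluation order.
* Validation rejects cyclic ontologies (naming a cycle) and namespaces
  without a unique parentless root. Alternate ids map to primary terms at
  load; rows referencing unknown terms, other aspects, excluded evidence
  codes, or carrying NOT qualifiers are dropped with logged counts.
  Malformed rows warn and skip by default, or raise in strict mode.
* Degenerate cases: a corpus whose maximum IC is 0 scores 0 under Resnik;
  Relevance at a root pair is 0; Wang of a term with itself is exactly 1.
* Fold assignment uses stratified k-fold with shuffling; per-fold class
  counts differ from proportionality by at most one gene, and a class
  smaller than k is an error naming the class.
* Problem sizes in the test-suite and acceptance runs (≤30-term random
  DAGs with ≤40 genes for oracle checks; the 160-gene default study for
  CV) were chosen so that exhaustive brute-force oracles — explicit
  ancestor walks, all-paths Wang S-values, all-pairs combines, pairwise
  concordance AUC — remain feasible as independent cross-checks.
* Known limitations: no identifier harmonization across gene namespaces
  (inputs must already share one), no OWL parsing, no cross-aspect or
  graph-embedding similarity measures, no probability calibration, and no
  gene-weighting scheme.
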