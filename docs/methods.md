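# Methods

## Problem and model

The package addresses forensic origin assignment for plant samples from a
small number of geographic origin groups, using microsatellites (SSRs) as
markers. Input is one consensus genome per sample, all expressed in the
coordinate frame of a single shared reference, plus a gene annotation and a
sample→group label table. Because coordinates are shared, a marker is
identified across samples by the triple *(locus, motif, full-unit copy
count)*; two different copy counts at one locus are two different markers.
Each sample is then a binary vector of marker presence, and every
downstream step — selection, classification, clustering — operates on that
binary matrix.

## SSR detection

A detected SSR is a *maximal perfect run*: a substring with period equal to
the motif length that cannot be extended by one base on either side, whose
motif (the unit as it first appears) is primitive (not itself a repetition,
so an `AT` run is never reported as `ATAT`), and whose number of *full*
unit copies meets a per-unit-length threshold. Partial trailing units are
excluded from both the count and the reported span, so for perfect calls
`end − start = motif_length × count` exactly.

Default minimum copies — mono 10, di 5, tri 4, tetra 3, penta 3, hexa 3 —
are the smallest counts that occur in published coding-region panels of
this kind; all are configurable. Motifs are recorded exactly as they appear
(no canonicalization across rotations or reverse complements): marker
panels in this field distinguish e.g. `AG` from `TC` compositions, and
collapsing them would merge markers practitioners treat as distinct.

`N` bases in a consensus act as wildcards when extending a run, and any
call whose span covers an `N` is flagged; the default matrix build drops
flagged calls before between-sample comparison, mirroring the usual
practice of excluding ambiguous consensus markers. A run whose every unit
contains `N` has no defined motif and is discarded.

Two post-classification rules operate on the detected stream: same-motif
perfect runs separated by at most `interrupt_max_bp` (default 4) merge into
one *imperfect* call whose count is the sum of unit copies, and calls of
different motifs separated by at most `compound_gap_bp` (default 10) are
both marked *compound*; compound takes precedence when both rules touch a
call. The defaults follow common SSR-tool conventions and are surfaced on
the CLI.

Locus assignment gives each call the annotated gene with maximal base-pair
overlap (ties to the smaller annotation start, then lexicographic id);
calls with no overlapping gene are binned into 10-kb intergenic
pseudo-loci so they remain usable when coding-only filtering is off.

## Selection strategies

* **Group-conserved filter.** A marker is kept iff at least one group
  carries it in every sample. The score is the number of such groups;
  ordering is score-descending then key-lexicographic. No cap is applied —
  the natural output size of this biologically motivated filter defines
  the panel cap used by the other three strategies (set `cap` explicitly to
  override).
* **ANOVA-F top-k.** One-way F statistic of each binary feature against
  the group label, computed directly from the sum-of-squares definition so
  the degenerate conventions are exact: zero within-group variance with
  non-zero between-group variance scores +∞ (sorts first), a constant
  feature scores 0. Ties break lexicographically for reproducibility.
* **Hybrid.** ANOVA prefilter to `k1` (default 5000), then a random
  hyperparameter search for a random forest (150 draws, stratified 4-fold
  CV, weighted F1 — the weighting matters because group sizes are
  unbalanced), then recursive elimination of the least impurity-important
  feature one at a time. Elimination continues internally to a full
  ordering, so the surviving `k2` panel is ranked (last survivor first).
* **Lasso.** One-vs-rest L1-penalized logistic regression. The inverse
  regularization strength C is drawn log-uniformly from [1e−3, 1e3]
  (25 draws by default), each candidate scored by leave-one-out weighted
  F1; ties prefer the stronger regularization. The model refits on all data
  at the best C, and markers with any non-zero coefficient are ranked by
  max-over-classes |weight|. The reported objective is mean cross-entropy
  of the normalized one-vs-rest probabilities plus λ‖W‖₁ with λ = 1/C.

Two places were genuinely open and are package decisions: the class
probability p_ik is the sigmoid score of class k's one-vs-rest classifier
normalized across classes (rather than a softmax over decision values),
and the lasso ranking statistic is the maximum absolute per-class
coefficient. Both are stated here because alternative conventions exist.

## Benchmark protocol

Each (panel × classifier) combination — classifiers: linear-kernel SVC and
random forest with balanced class weights, plus gradient boosting — runs
the same protocol: (1) hyperparameter tuning by seeded random search over a
documented space with stratified k-fold CV and weighted F1 as criterion
(the tuner is a random search; its parameters are then frozen); (2) step-1
RFE over the panel using aggregate |coefficient| for the linear SVC and
impurity importances for the ensembles; (3) for k = 1..k_max, leave-one-out
cross-validation of the top-k panel repeated over replicate seeds
(`base_seed + r`), recording mean and SD of weighted F1, accuracy, weighted
precision and weighted recall, plus replicate-averaged confusion matrices
per k and over the whole curve; (4) the chosen panel is the smallest k
whose mean weighted F1 attains the curve maximum — equal weight to
performance and parsimony. Leave-one-out folds are unstratified by
definition (they have size one); tuning folds are stratified. A linear SVC
is deterministic, so its replicate SDs are exactly zero; forest and
boosting SDs shrink with replicates.

Per-class precision of a never-predicted class is 0 (explicit
zero-division convention); weighted averages use class supports.

## Clustering

Samples restricted to the winning panel are compared as present-marker
sets with the Jaccard distance, with the convention that two samples
carrying none of the selected markers are at distance 0 (a selected panel
can zero-out a sample, and under that panel such samples are
indistinguishable). PCoA uses classical Gower double-centering of −d²/2
and a symmetric eigendecomposition; only positive-eigenvalue axes are kept,
coordinates are eigenvectors scaled by √eigenvalue, explained proportions
are computed over positive eigenvalues, and negative eigenvalues are
reported untouched — no Lingoes/Cailliez correction is applied. UPGMA is
the classical unweighted average-linkage agglomeration with size-weighted
cluster distances, ties resolved toward the smallest (i, j) cluster-index
pair; the cophenetic distance of two leaves is the height of their lowest
common merge. Newick output writes each edge as half the height difference
between parent and child, so the leaf-to-root path equals half the root
merge height; the convention is stated in the file header the pipeline
writes alongside.

## Synthetic benchmark

The generator emulates the study design: four origin groups of 12/14/8/4
samples, six planted conserved markers in each of three groups, one
heterogeneous group with *no* group-wide conserved marker, and 200
non-informative noise features; motif lengths are drawn with weights
(0.20, 0.48, 0.17, 0.06, 0.05, 0.04) so dinucleotide repeats dominate at
~48%, followed by mono- and trinucleotide repeats.

A single parameter, `noise_presence_prob`, governs both a planted marker's
presence outside its own group and noise-feature presence everywhere;
presence is independent Bernoulli per sample (the simplest exchangeable
null against which conserved structure is detectable). Its default, 0.03,
is pinned by an observable of real panels of this kind: roughly half of a
group's conserved markers are *exclusive* to the group, i.e. absent from
all ~26–34 remaining samples, and (1−p)^n = 0.5 at those n gives
p ≈ 2–4%. At sharing rates several times higher, the heterogeneous group —
which must be recognized by carrying *no complete* group signature, a
non-linear predicate — stops being linearly identifiable, which would
contradict the perfect linear separation such panels show in practice.

Two rejection passes make planted structure exact rather than merely
likely: any column that comes out conserved across a heterogeneous group
is redrawn for that group's block, and (when p > 0) any noise column
carried by no sample at all is redrawn — extraction defines features as
the union of observed keys, so an unobserved column could never round-trip.

In genome mode each feature owns one annotated locus; the present variant
carries the repeat array in a centred slot, the absent variant a
non-repetitive filler of the same width, flanks are shared, and every
variant is *validated with the detector at generation time* (redrawn until
it yields precisely the intended call set, in a spacer context). The
assembled reference is likewise scanned and junction spacers redrawn until
repeat-free. This is what makes the detector→matrix round-trip equal the
planted truth table exactly, and the property is asserted, not assumed.

What the generator does **not** emulate — and hence what passing tests do
not establish about real data: read-level sequencing error, alignment or
consensus-calling artifacts, missing data, SSR mutation processes, linkage
between markers, or within-group substructure beyond the single
heterogeneous-group mechanism. Real cross-group sharing is also not
independent Bernoulli; markers shared between specific group pairs are
common in practice and arise here only by chance.

## Problem sizes and numerical choices

The acceptance script runs the benchmark with 3 replicates, learning
curves to 12 markers, 15 tuning draws per combination, and forests capped
at 150 trees — sizes chosen so a complete single-CPU desk run finishes in
minutes while leaving every qualitative conclusion (perfect separation
with few markers, zero SD for the deterministic SVC, heterogeneous-group
behavior) intact. Probabilities inside the cross-entropy are clamped at
1e−15; eigenvalues within 1e−10·max|λ| of zero are treated as zero in
PCoA; random-search ties keep the earliest draw, RFE importance ties drop
the lowest column index, and all orderings fall back to lexicographic
feature keys, so every result is reproducible bit-for-bit from one seed.
Per-stage seeds are derived from the global seed by hashing the stage name
(SHA-256, reduced below 2³¹).

## Known limitations

Minisatellites (unit length > 6) are out of scope, as are alignment,
consensus generation, bootstrap support for dendrograms, and statistical
tests comparing classifiers. The hyperparameter tuner is a seeded random
search; a sequential model-based optimizer could find marginally better
configurations at equal budget. With groups as small as four samples,
leave-one-out estimates are high-variance and the stratified tuning folds
are forced down to the smallest class size.
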