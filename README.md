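# ssrtrace

Inferring the biogeographic origin of plant samples from microsatellite
(SSR) presence/absence profiles mined out of per-sample consensus genomes.

The motivating forensic setting is *Cannabis sativa* seized along
trafficking routes: a few dozen samples from a handful of origin groups of
unequal size (e.g. a domestic cultivation region, two foreign source
countries, and a bag of commercial strains), each sample represented by a
consensus genome aligned to one shared reference. Because all consensus
sequences live in the same coordinate frame, a repeat array can be
identified across samples by the triple **(locus, motif, copy count)** —
`LOC115707832 (AAG)5` — and each such triple becomes one binary
present/absent feature per sample. The package mines these features,
selects small informative marker panels, benchmarks origin classifiers on
them, and clusters samples, end to end.

## What it does

1. **SSR extraction** (`ssrtrace.extract`) — detects all maximal perfect
   repeat runs of 1–6 bp primitive motifs above per-unit-length copy
   thresholds (mono 10, di 5, tri 4, tetra 3, penta 3, hexa 3 by default),
   classifies them (perfect / imperfect / compound), assigns them to
   annotated gene loci by maximal overlap, and builds the binary
   samples × (locus, motif, count) feature matrix, optionally restricted to
   coding loci and purged of calls spanning `N` bases.
2. **Feature selection** (`ssrtrace.select`) — four strategies:
   * *group-conserved filter* (`gc_ssr_select`): keep a marker iff it is
     present in **every** sample of at least one origin group; its natural
     panel size caps the other methods;
   * *ANOVA-F top-k* (`select_k_best`);
   * *hybrid*: ANOVA prefilter → tuned random forest → step-1 recursive
     feature elimination;
   * *lasso*: one-vs-rest L1 logistic regression, regularization chosen by
     leave-one-out weighted F1; the objective is
     `L = -(1/n) Σᵢ Σₖ 1(yᵢ=k) log p_ik + λ Σₖ Σⱼ |ω_kj|`.
3. **Classifier benchmark** (`ssrtrace.bench`) — for every
   (panel × classifier) pair among {linear SVC, random forest, gradient
   boosting}: seeded random-search hyperparameter tuning (weighted-F1,
   stratified CV), step-1 RFE ranking, leave-one-out learning curves over
   replicate seeds for k = 1..k_max markers, replicate-averaged confusion
   matrices, and the parsimony rule *best k = smallest k attaining the
   curve's maximum mean weighted F1*.
4. **Clustering** (`ssrtrace.cluster`) — Jaccard distances on the winning
   panel, principal coordinate analysis, and a UPGMA dendrogram with Newick
   export.
5. **Synthetic benchmark** (`ssrtrace.simulate`) — generates feature tables
   *and* full FASTA/GFF3 sample sets with planted group-conserved structure
   (including one deliberately heterogeneous group with no conserved
   marker), so the whole pipeline is testable without access data.

## Worked example

```python
from ssrtrace import (SimulationConfig, simulate_feature_table,
                      gc_ssr_select, ClassifierSpec, tune, rfe_rank,
                      learning_curve, choose_best)

cfg = SimulationConfig(seed=0)          # 38 samples, groups 12/14/8/4
matrix, labels, truth = simulate_feature_table(cfg)
panel = gc_ssr_select(matrix, labels)   # group-conserved markers
sub = matrix.restrict(panel.features)

spec = tune(ClassifierSpec("linear_svc", seed=0), sub, labels,
            iterations=15, folds=3)
ranking = rfe_rank(spec, sub, labels)
curve = learning_curve(spec, ranking, sub, labels, k_max=15, replicates=5)
best_k, best_features = choose_best(curve)
print(len(panel.features), best_k, curve.means["weighted_f1"][best_k - 1])
```

prints

```
18 3 1.0
```

meaning: the group-conserved filter keeps 18 markers (six planted per
homogeneous group), and after RFE ranking the linear SVC already separates
all 38 samples perfectly (mean weighted F1 = 1.0 under leave-one-out, zero
replicate scatter) with the **3** top-ranked markers — one fixed marker per
homogeneous group, while the heterogeneous group is recognized by carrying
none of the group signatures.

The same flow is available from the shell:

```bash
ssrtrace run-all --seed 0 --output-dir out      # simulate → … → cluster
ssrtrace print-config                            # full config schema
```

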