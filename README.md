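# salpvote

Gene selection and ensemble classification for small-n / large-p expression
data (tumour microarray or pseudo-bulk single-cell profiles: tens of samples,
thousands of genes, 3–4 imbalanced classes).

Classifying cancer subtypes from expression profiles is dominated by the
curse of dimensionality: with *n* ≈ 60–90 samples and *p* ≈ 2,000–13,000
genes, most genes are irrelevant or redundant, and single-stage filters leave
far too many features for a reliable classifier. `salpvote` implements a
three-stage pipelined selector followed by a voting ensemble:

1. **All-relevant shadow-feature filter.** Each gene *f_j* gets a shadow copy
   whose values are a row permutation of *f_j* (class association destroyed,
   marginal distribution kept). A random forest is fit on the combined matrix
   and the round threshold is *I_th* = max importance over shadows; a gene
   scores a *hit* when *I(f_j) > I_th*. Hits accumulate over re-shuffled
   rounds and a one-sided binomial test against p = 0.5 confirms or rejects
   each gene.
2. **Relevance–redundancy ranking.** Each surviving gene is scored by
   `score(i) = Mre(i) − Mrd(i)` with
   `Mre(i) = α·MI(f_i, y) + (1−α)·|r(f_i, y)|` and
   `Mrd(i) = meanⱼ[α·MI(f_i, f_j) + (1−α)·|r(f_i, f_j)|]`,
   where MI is plug-in mutual information in bits over equal-frequency bins,
   *r* is Pearson correlation, and α ∈ (0, 1] blends the two association
   measures (α = 1 recovers MI-only mRMR).
3. **Salp-swarm wrapper.** A swarm of continuous positions in [−10, 10]^d is
   decoded to gene masks (coordinate > 0 ⇒ gene included); a mask's fitness
   is the stratified 5-fold cross-validated accuracy of a wrapped classifier.
   Each iteration applies an exploration step (social, personal and
   randomized terms with step size Γ₁ = 1 and damping Γ₂ = 0.8) and a
   leader–follower exploitation step, accepting candidates per salp on strict
   improvement, so the best-fitness trace is non-decreasing.

Five base classifiers (SVM, random forest, extreme learning machine,
AdaBoost, XGBoost) are trained on the selected genes; the three with the
highest training-split cross-validated accuracy are combined by hard majority
voting (three-way ties resolved by the top-ranked member). Evaluation
reports ACC, MCR, PRE, REC, SPE, F1, F2, FNR, FPR and MCC (one-vs-rest,
macro-averaged) with exact Clopper–Pearson binomial intervals and macro
one-vs-rest AUC.

A seeded synthetic-data generator plants informative genes (class-specific
mean shifts), redundant genes (perturbed copies of informative ones) and
pure-noise genes, so every stage can be validated against a known ground
truth without external downloads.

## Worked example

```python
from salpvote import PipelineConfig, SyntheticSpec, run_pipeline

config = PipelineConfig(synthetic=SyntheticSpec(), seed=1)
report = run_pipeline(config)

print("gene counts per stage:", report.feature_counts)
print("training CV accuracy :", {k: round(v, 3) for k, v in report.learner_accuracies.items()})
print("top-3 members        :", report.top3)
ens = report.test_metrics["ensemble"]
print(f"ensemble test ACC    : {ens.ACC:.3f}  (95% CI {ens.ci['ACC'][0]:.3f}-{ens.ci['ACC'][1]:.3f})")
```

Output:

```
gene counts per stage: {'input': 2000, 'boruta': 50, 'imrmr': 50, 'ssa': 26}
training CV accuracy : {'SVM': 1.0, 'RF': 0.985, 'ELM': 1.0, 'AdaBoost': 0.941, 'XGBoost': 0.897}
top-3 members        : ['SVM', 'ELM', 'RF']
ensemble test ACC    : 1.000  (95% CI 0.735-1.000)
```

The default synthetic conditions plant 10 informative and 40 redundant genes
among 2,000; the shadow-feature filter keeps exactly those 50, the ranking
stage retains all of them (none is scored as pure redundancy against this
pool), and the wrapper then prunes the set to 26 genes that preserve perfect
cross-validated accuracy. The wide interval on the test accuracy reflects the
12-sample held-out split — exactly why the exact binomial interval is
reported alongside the point estimate.

The same pipeline runs from the command line on any delimited expression
table (genes as columns, one label column):

```bash
salpvote synth --out data.csv --seed 1          # synthetic table + ground-truth JSON
salpvote run --config config.yaml --out-dir out # report.json, metrics.csv, gene lists
salpvote ablate --config config.yaml --skip ssa # compare full vs ablated variants
```

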