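# Methods

## Problem setting and model

`salpvote` targets expression-based cancer-subtype classification in the
small-n / large-p regime (n ≈ 60–90 samples, p ≈ 2,000–13,000 genes, 3–4
imbalanced classes). The method is a pipelined feature-selection stack — an
all-relevant shadow-feature filter, an α-weighted mutual-information/Pearson
relevance–redundancy ranking, and a salp-swarm wrapper — followed by five
base classifiers whose top three (by training-split cross-validated accuracy)
vote by hard majority. Stage gene counts are non-increasing by construction;
all selection is fit on the training split only, verified by a content hash
of the held-out values taken before selection and checked before evaluation.

## Preprocessing and splitting

Labels are encoded to contiguous integers in first-appearance order. Each
gene is min-max scaled to [0, 1] using training-split statistics; a constant
training gene maps to 0 (divisor replaced by 1, keeping the transform
affine), and test values are transformed with the training statistics and not
clipped, so they may fall outside [0, 1]. Missing or non-numeric cells are
rejected at load time rather than imputed.

The split is stratified with |train| = floor(ratio·n) and per-class counts by
largest-remainder allocation of the class quotas ratio·n_c, so every class
appears in training and per-class proportions differ from the global ratio by
less than one sample. The default ratio is 0.85, which reproduces the
canonical benchmark splits 61/11 (n = 72), 52/10 (n = 62) and 70/13 (n = 83).
Classes with a single sample cannot be stratified and raise.

## Stage 1: shadow-feature filter

Each round appends to every candidate gene a shadow column that is an
independent row permutation of it, fits a random forest (default 300 trees)
on the combined matrix, and takes the round threshold I_th as the maximum
mean-decrease-in-impurity importance among the shadows. A gene scores a hit
when its importance strictly exceeds I_th. After each round, a one-sided
binomial test of the hit count against p = 0.5 at the configured significance
(default 0.05) confirms genes with significantly many hits and rejects genes
with significantly few; rejected genes and their shadows leave subsequent
forests, while confirmed genes stay in to keep the importance competition
realistic. The loop ends when no gene is tentative or after max_iterations
(default 50); leftovers are resolved by comparing each gene's median
importance across rounds with the median of the round thresholds — a rule
chosen here because the underlying description gives none. The per-column
importance is the standard impurity-based forest importance; the printed
importance formula in the source description is typographically corrupted and
its per-tree weight is read as uniform.

## Stage 2: relevance–redundancy ranking

For gene i, relevance and redundancy blend two association measures through a
weight α ∈ (0, 1]:

    Mre(i) = α·MI(f_i, y) + (1−α)·|r(f_i, y)|
    Mrd(i) = mean_{j≠i} [ α·MI(f_i, f_j) + (1−α)·|r(f_i, f_j)| ]
    score(i) = Mre(i) − Mrd(i)

MI is the plug-in estimate in bits over equal-frequency discretized values
(default 3 bins; ties broken by value order; a constant vector maps to a
single bin). Pearson correlation on a constant vector is defined as 0 with a
warning rather than failing mid-pipeline. The absolute value of r is used so
that negative association counts as informative/redundant symmetrically; a
`signed_pearson` flag restores the literal signed form.

Two selection modes are shipped because the averaging set behind the printed
redundancy formula is ambiguous: `oneshot` (default) scores every candidate
once with redundancy against all other candidates (divisor p − 1, matching
the printed divisor) and keeps positive scores in descending order up to
max_features (default 500); `greedy` is the classical incremental rule where
redundancy is averaged over the already-selected set, stopping when the best
incremental score is ≤ 0. With α = 1, `greedy` reduces exactly to MI-only
mRMR, which the tests verify against an independent brute-force
implementation. α defaults to 0.5; `sweep_alpha` scans the grid
0.1, 0.2, …, 1.0 and picks the α whose selected subset maximizes the
cross-validated accuracy of a 1-nearest-neighbour evaluator (ties go to the
larger α, favouring the MI term).

## Stage 3: salp-swarm wrapper

Positions live in [lb, ub]^d with the defaults Max_It = 100, 30 salps,
lb = −10, ub = 10, Γ₁ = 1, Γ₂ = 0.8. A position decodes to a mask by
sigmoid-at-0.5 thresholding (coordinate > 0), deterministic for
reproducibility, with a fallback to the single largest coordinate so masks
are never empty. Fitness is ACC_avg, the stratified k-fold (default 5)
cross-validated accuracy of a wrapped classifier — 1-nearest-neighbour by
default, since the wrapped model and k are otherwise unspecified — and the
internal objective is 1 − ACC_avg, minimized. Fold assignments are fixed per
run and fitness values are memoized by mask, so repeated subsets cost
nothing.

Each iteration applies, per salp i with accuracy F_i:

* exploration: S_i = F_i · mean_j(X_j − X_i) (the social sum is divided by
  num_salps − 1 to keep step magnitude bounded in swarm size; the difference
  is used as a vector, which the position update requires), P_i = F_i·(Xb_i −
  X_i), E_i = κ∘R∘(Xb_i − X_i) with κ, R fresh uniform[0,1] per component;
  candidate = X_i + Γ₁·S_i + Γ₂·(P_i + E_i);
* exploitation: the leader drifts by c₁∘((ub−lb)·c₂ + lb) per component
  (fresh uniform draws; a `canonical_leader` flag substitutes the food-source
  jump around the global best), and each follower moves to the midpoint of
  itself and its predecessor's pre-step position;
* acceptance: a candidate replaces the current position and personal best
  only on strict objective improvement, and the global best is refreshed.

Positions are clipped to the box after every phase. Consequences tested as
invariants: positions always in [lb, ub], the best-fitness trace is
non-decreasing, exploitation never expands the swarm's per-dimension spread,
and the final fitness equals the cross-validated accuracy recomputed on the
final mask. Whether the two phases run in the same iteration is not pinned
down by the source description; both-per-iteration is the default and each
phase can be toggled off.

## Base learners, ranking and voting

The five learners are RBF SVM (C = 1), random forest (300 trees), an extreme
learning machine implemented here (hidden weights and biases uniform[−1, 1]
from the seed, sigmoid hidden layer, output weights by ridge-regularized
least squares against one-hot labels; defaults 256 hidden units, ridge
1e−3), AdaBoost (200 rounds) and XGBoost (200 rounds, depth 3, learning rate
0.1). None of these hyperparameters is prescribed by the source description;
they are sensible fixed defaults, all exposed in configuration. "Accuracy
during training" is read as stratified 5-fold cross-validated accuracy on the
training split — resubstitution accuracy would trivially favour interpolators
like the forest — with a `resubstitution` flag restoring the literal reading.
Ranking is by descending CV accuracy, ties broken by macro-F1 and then by the
fixed id order (SVM, RF, ELM, AdaBoost, XGBoost). The top three vote by hard
majority; with three voters and ≥ 3 classes a full three-way tie is possible
and resolves to the top-ranked member's prediction.

## Metrics

All metrics derive from one-vs-rest confusion counts per class: ACC and MCR
are overall, PRE/REC/SPE/F1/F2/FNR/FPR/MCC are per-class and macro-averaged
over classes present in the truth (classes with an undefined per-class value
are excluded from that metric's average; the excluded sets of complementary
metrics coincide, so ACC + MCR = 1, FNR = 1 − REC and FPR = 1 − SPE hold
exactly on raw values). Fβ = (1+β²)PR/(β²P+R), reported at β = 1 and β = 2;
per-class MCC uses the standard four-count formula with a 0 convention for a
zero denominator. Clopper–Pearson intervals come from Beta quantiles with the
degenerate endpoints closed (0 at k = 0, 1 at k = n); the n used is the
actual evaluation-set size of the quantity reported. Macro one-vs-rest AUC is
rank-based with average ranks, so ties receive half credit; for the hard
voting ensemble, the per-class score is the fraction of members voting for
the class.

## Synthetic data

The generator emulates the target regime (defaults: 80 samples, 2,000 genes,
three classes in proportions 0.5/0.3/0.2 by largest-remainder rounding, so
fixture sizes are exact). Informative genes (default 10) are baseline
Gaussian noise (SD 1 on the log-like intensity scale; Gaussian keeps both
Pearson and MI behaviour analyzable) plus a class-specific mean shift of
effect_size·noise_sd — class c is shifted by c·effect_size·noise_sd, so
adjacent classes differ by one effect (default 3). Redundant genes (default
40) are randomly chosen informative genes plus zero-mean perturbation (SD
0.25, giving source correlation ≥ 0.96). Remaining genes are pure noise. The
ground truth partitions the gene set and maps each redundant gene to its
source.

What this does not emulate: platform artifacts, batch effects, missingness,
heavy-tailed intensity distributions, and correlated noise blocks. Passing
the recovery tests therefore demonstrates that the pipeline's machinery
works as specified under clean planted signal — not that real-cohort
accuracies transfer; real tumour datasets must be supplied as CSV through the
loader.

## Problem sizes and numerical choices

Tests and the acceptance script run the full pipeline at the default
conditions (80 × 2,000; seconds per run) and the unit checks at 40–300
samples and up to 300 genes — sizes chosen so the whole suite completes in a
few minutes while every stage still operates in its intended regime.
Tolerances: exact identities are asserted at 1e−12; oracle equivalences at
1e−10; seeded stochastic recoveries use the thresholds stated in the tests.
Degenerate inputs have explicit rules throughout: constant genes (normalize
to 0, Pearson 0 with warning, single discretization bin), empty masks
(fallback to the largest coordinate), empty redundancy sets (Mrd = 0), zero
MCC denominators (0), and absent classes (excluded from macro averages and
AUC with a warning).

## Known limitations

* Class imbalance is observed but not corrected (no resampling or reweighting).
* The plug-in MI estimator is biased upward at small n; with the default 3
  bins the bias is shared across features and largely cancels in the
  relevance-minus-redundancy score, but absolute scores should not be
  interpreted as calibrated information estimates.
* The wrapper's greedy acceptance cannot escape a local optimum except
  through the leader's random drift; multiple seeds are advisable on hard
  pools.
* Macro Clopper–Pearson intervals treat a macro-averaged proportion as a
  single binomial proportion at the evaluation-set size; this is a reporting
  convention, not an exact interval for the macro statistic.
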