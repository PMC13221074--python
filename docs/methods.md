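# Methods

## Scope and model

`mogt` prioritizes disease risk genes on an attributed gene graph. Nodes
are candidate genes (within ±1 Mb of a genome-wide-significant GWAS SNP)
plus all labeled genes; edges aggregate SNP–SNP epistasis scores to gene
pairs; node features are z-scored multi-omics columns. A two-layer graph
transformer with a prototype layer is trained semi-supervised with a
focal + prototype-contrastive objective, and genes are called high-risk
(HRG) or low-risk (LRG) at a Youden-index threshold. The package assumes
the epistasis list is precomputed upstream (it consumes SNP-pair p-values;
it does not estimate epistasis from genotypes) and that labels are binary
with positives far rarer than negatives.

## Coordinate and windowing conventions

Gene intervals are BED (0-based, half-open); SNP positions are 1-based.
Window distances are computed by direct coordinate subtraction,
`d = max(start − pos, pos − end, 0)`, with inclusive windows (`d ≤ w`).
This treats the printed coordinates as a common scale rather than
re-basing the SNP position, which matches how a ±1 Mb window is usually
eyeballed from summary statistics; the one-base asymmetry this introduces
upstream of a gene is irrelevant at 1 Mb and 1 kb scales but is fixed here
as the single convention used by both the implementation and the
brute-force oracles in the test suite. Distance is measured to the nearest
gene-body coordinate, not the TSS: the windows are heuristics for local
regulation, and gene-body distance is the more common convention when no
regulatory map is available.

Edge weights use −log₁₀ of the interaction p-value (the GWAS convention
for "negative logarithm"). The top-fraction filter keeps
`max(1, floor(f·|E|))` edges, breaking ties at the cutoff by canonical
(gene_a, gene_b) order so output is deterministic.

## Losses

* Prototype similarity: g = ln((D+1)/(D+ε)), D the squared Euclidean
  distance; g = ln(1/ε) at D = 0 and → 0 as D → ∞. ε defaults to 1e-4 and
  the temperature T to 0.5; both are run-config parameters (no principled
  default exists — ε sets the similarity ceiling ln(1/ε) ≈ 9.2, and T = 0.5
  sharpens the contrast moderately).
* The contrastive denominator runs over prototypes **not** of the node's
  class, as specified; `prototype_denominator="all"` switches to the
  conventional InfoNCE normalization over all prototypes. With the
  non-class denominator the loss can be negative.
* Focal loss uses the standard α_t convention (α for positives, 1−α for
  negatives), α = 0.25, γ = 2. Probabilities are clipped to
  [1e-7, 1−1e-7]; the contrastive log-sum-exp is stabilized by a detached
  row-max shift. Natural logarithms are used throughout the losses.
* The total objective is the unweighted sum of the two losses.

## Architecture decisions

The published pipeline sentence leaves the operand of "max-pooling"
ambiguous. Here each center gene's representation is the element-wise max
over the nodes of its own sampled subgraph ({self} ∪ 1-hop ∪ 2-hop),
taken after the second transformer layer's normalization; the same pooled
representation feeds both the FC head and the prototype loss. Attention is
restricted to graph edges plus one self-loop per node (bias 0); the edge
weight is added raw to the pre-softmax attention score, so strongly
epistatic neighbors dominate attention. The classification head is a
single logit + sigmoid (binary task). Prototypes are initialized from a
seeded standard normal scaled by 1/√hidden_dim and trained jointly by
gradient descent.

The network runs on a small reverse-mode autodiff engine over numpy
(`mogt.nn`) with sparse-matrix scatter-adds and `reduceat`-based segment
maxima for the graph operations; every primitive's gradient is checked
against central finite differences in the test suite. Optimization uses
Adam (lr 1e-3, L2 weight decay 5e-4 added to the gradient) — optimizer
and schedule are this package's choices, as are batch size 64 and the
500-epoch cap; dropout 0.4, patience 50 and 7 prototypes per class follow
the reference setting.

## Training protocol

Labeled genes are split 80/20 by stratified sampling, then the 80% pool
into 5 stratified folds. For every fold, feature imputation (training-row
median) and z-scoring (training-row mean/SD) are refitted on that fold's
training rows only, so no validation or test information reaches the
preprocessing; the label-flip and row-perturbation tests assert this
bitwise. Training iterates mini-batches of train-mask centers; the loss is
computed exclusively on train-mask genes while all other genes participate
as unlabeled context in the sampled subgraphs. Early stopping monitors
validation AUPRC (the headline metric under imbalance; the original
early-stopping metric is unstated) and restores the best-validation
checkpoint. The fold with the highest validation AUPRC supplies the final
model; its validation scores set the Youden threshold (candidates = the
observed scores, rule = score ≥ t, ties broken by higher sensitivity then
lower threshold), and metrics are reported on the untouched hold-out set.
AUROC is the rank statistic with tied ranks averaged; AUPRC is average
precision (step-wise, no trapezoidal interpolation); F1 is that of the
positive class at the threshold. Class imbalance is addressed only through
the focal loss — no re-sampling.

Everything is deterministic given the configuration: the one run seed is
expanded via `numpy.random.SeedSequence` into independent streams for
initialization, batch shuffling and dropout, and per-fold seeds are
derived arithmetically from the training seed.

## Specificity analytics

Entropy is base-2, so JS ∈ [0, 1] bits and TS = 1 − √JS ∈ [0, 1]; a
natural-log entropy would keep 1 − √JS positive but lose the unit-interval
interpretation, which is why bits are the default (the original base is
unstated). TS uses the square root of JS — the metric form named in the
defining sentence — although the printed score formula omits it;
`no_sqrt=True` reproduces the literal formula. Genes with zero total
expression are flagged and excluded rather than scored 0. Group contrasts
test HRG specificity scores as stochastically **greater** than LRG scores
(one-sided Wilcoxon rank-sum, exact null when both sides have < 20
untied observations, normal approximation with tie correction otherwise);
BH correction is applied per analysis family (all tissues of a dataset,
all cell types, all gene sets of one enrichment run), significance at
adjusted p < 0.05.

## Synthetic data

The generators produce the study conditions everything is tested under:

* `simulate_gene_graph` — 500 genes, 20 features, 15% positives, class
  separation 1.5 SD on a random half of the features, homophily 0.8 at
  overall edge density 0.02, 60% of nodes labeled. Homophily h means a
  same-class pair is h/(1−h) times as likely to be joined as a
  cross-class pair at fixed expected density. Edge weights are uniform on
  [2, 8], mimicking −log₁₀ p of top-filtered epistasis scores.
* `simulate_snp_inputs` — genes tiled on one synthetic chromosome
  (multi-chromosome layouts are unnecessary for windowing tests); each
  planted risk gene receives one intragenic SNP with p in (1e-10, 1e-9),
  other SNPs are uniform; interaction p-values between risk-adjacent SNP
  pairs are divided by the enrichment factor (4 by default, 1 = null).
* `simulate_expression` — log-normal baseline (log-mean N(1, 0.5²)),
  5 groups × 20 samples, 10% of genes group-specific with fold change 4
  (noise SD 0.5 on the log scale) by default.

These fixtures emulate the *statistical* structure the model exploits —
informative features, assortative edges, group-specific expression — and
deliberately not the marginal distributions, dependence structure, LD, or
missingness patterns of real omics data. Passing the recovery tests
therefore shows the machinery is correct and sensitive under controlled
signal, not that real-data performance figures transfer.

## Problem sizes and statistical design of the checks

The synthetic recovery checks train single-fold models on the 500-gene
default graphs (full 5-fold CV is exercised separately in the pipeline
tests); with patience 50 a run stops after roughly 60–140 epochs. The
hold-out set under the defaults contains ~60 labeled genes (~9 positives),
so a null-model AUROC has standard deviation ≈ 0.10; the null-calibration
check accordingly applies its [0.40, 0.60] band to the AUROC averaged over
three seeds, while the separable-signal check (AUROC ≥ 0.90) holds
per-seed. Note also that average precision of random scores is slightly
*above* the positive prevalence at small positive counts (≈ 0.036 vs
0.028 at 24/826) — a finite-sample property of the AP estimator that the
Monte-Carlo baseline test makes visible.

## Known limitations

* No LD pruning or ancestry handling; the candidate window and SNP–gene
  assignment are distance heuristics.
* Binary classification only (J = 2 heads); no attention-based
  interpretability maps; no pretrained weights.
* The numpy training core is single-threaded and intended for graphs of
  order 10³–10⁴ nodes, not genome-scale atlases.
* Negative-set curation (low-expression lists, protein-interaction
  exclusion pairs) is consumed from files; building those lists from
  primary databases is upstream of this package.
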