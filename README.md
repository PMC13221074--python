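# mogt

Prototype-augmented graph-transformer prioritization of disease risk genes.

`mogt` implements MOGT, a semi-supervised classifier that ranks candidate
disease genes by combining two signals that are usually analyzed apart:
per-gene multi-omics features (differential expression, regulatory contacts,
regional expression) and a gene–gene network distilled from SNP–SNP
epistasis. It is aimed at statistical geneticists and computational
biologists who have GWAS summary statistics, a pairwise SNP interaction
list, and per-gene feature tables, and want a ranked list of high-risk
genes (HRGs) with calibrated evaluation — plus the downstream
characterization statistics (tissue/cell-type specificity, gene-set
enrichment) used to sanity-check such predictions.

## The model

**Graph construction.** Candidate genes are those within ±1 Mb of a
genome-wide-significant SNP (p < 5×10⁻⁸). SNPs are assigned to genes within
±1 kb of the gene body; for each unordered gene pair (gᵢ, gⱼ) the edge
weight is max −log₁₀ p over SNP–SNP interactions bridging the two genes,
and only the top 1% of edges by weight is kept. Node features are the
concatenated omics columns, median-imputed and z-scored with parameters
fitted on training-mask genes only.

**Encoder.** Two graph-transformer layers (multi-head scaled dot-product
attention restricted to graph edges, with the edge weight added to the
pre-softmax attention score), each followed by layer normalization; then an
element-wise max-pool over each center gene's 2-hop sampled subgraph,
dropout (0.4), and two fully connected layers producing a sigmoid
probability. The network runs on a compact numpy reverse-mode autodiff core
(`mogt.nn`) that is gradient-checked against finite differences.

**Losses.** A prototype layer holds K = J×M learnable vectors (M = 7 per
class). With similarity g(vₙ, vₚ) = ln((D+1)/(D+ε)), D = ‖vₙ−vₚ‖², the
prototype contrastive loss is

    L_pl = −(1/N) Σᵢ log [ Σ_{m: class(m)=yᵢ} exp(g(vᵢ,vₘ)/T)
                          / Σ_{j: class(j)≠yᵢ} exp(g(vᵢ,vⱼ)/T) ]

and classification uses the focal loss FL(p_t) = −α_t (1−p_t)^γ ln p_t
(α = 0.25, γ = 2) to counter class imbalance. The training objective is
their unweighted sum.

**Training and evaluation.** Labeled genes are split 80/20 by stratified
sampling; 5-fold CV runs on the 80% with mini-batch neighbor-sampled
training and masked supervision (loss only on train-mask genes; validation
and test genes are unlabeled context). Early stopping monitors validation
AUPRC with patience 50. The best fold's model supplies the Youden-index
threshold, and AUROC / AUPRC / F1 are reported on the hold-out set; genes
at or above the threshold are HRGs, the rest LRGs.

**Specificity statistics.** A gene's expression across n tissues is
normalized to a density vector E; tissue specificity against tissue t is
TS(E|t) = 1 − √JS(E, E_t) with the Jensen–Shannon divergence in bits.
Cell-type specificity is S_{g,c} = mean_c(g) / Σⱼ meanⱼ(g). HRG-vs-LRG
contrasts use the one-sided Wilcoxon rank-sum test and gene-set enrichment
the one-sided Fisher exact test, both BH-corrected.

## Worked example

```python
from mogt import MOGT, SimGraphConfig, simulate_gene_graph

graph, truth = simulate_gene_graph(SimGraphConfig(seed=0))  # 500 genes
res = MOGT(graph).fit(seed=0)
print(res.summary())
```

```
MOGT risk-gene classification results
=====================================================
nodes: 500   edges: 2481   features: 20
folds: 5 (best fold 0)   val AUPRC 0.9457 ± 0.0445
-----------------------------------------------------
hold-out AUROC      0.8726
hold-out AUPRC      0.6886   (random baseline 0.1333)
hold-out F1         0.6250
Youden threshold    0.1869
HRGs / LRGs         61 / 439
=====================================================
```

The synthetic graph plants 15% positive genes whose features are shifted by
1.5 SD on half the dimensions and whose edges are class-assortative
(homophily 0.8). The fit recovers them well above the random baseline
(AUPRC 0.69 vs 0.13 — the baseline equals the positive prevalence of the
hold-out set); the Youden threshold then calls 61 of the 500 genes HRGs.
`res.predict()` returns the per-gene probability table and
`res.classify()` the HRG/LRG lists.

The same pipeline runs from the shell on TSV/BED inputs:

```bash
mogt simulate snp --seed 0 --out fix/          # synthetic GWAS-style inputs
mogt run --config run.yaml --out results/      # build graph → CV train → report
mogt specificity --expr expr.tsv --groups groups.tsv \
     --hrg hrg.txt --lrg lrg.txt --mode tissue --out spec/
```

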