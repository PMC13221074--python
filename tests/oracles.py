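"""Independent brute-force reference implementations used by the tests.

Everything here is written as plainly as possible — O(n²) loops, exhaustive
enumeration, literal formula transcription — and deliberately shares no
code with the package, so agreement between the two routes is meaningful.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def dist(pos: int, start: int, end: int) -> int:
    """Coordinate-subtraction distance from a SNP to a gene body."""
    if start - pos > 0:
        return start - pos
    if pos - end > 0:
        return pos - end
    return 0


def candidate_genes_bruteforce(snps, genes, p_threshold, window_bp):
    out = set()
    for g in genes:
        for s in snps:
            if s.chrom != g.chrom or s.p_value >= p_threshold:
                continue
            if dist(s.pos, g.start, g.end) <= window_bp:
                out.add(g.gene_id)
    return out


def snp_gene_map_bruteforce(snps, genes, window_bp):
    mapping = {}
    for g in genes:
        hits = set()
        for s in snps:
            if s.chrom == g.chrom and dist(s.pos, g.start, g.end) <= window_bp:
                hits.add(s.snp_id)
        if hits:
            mapping[g.gene_id] = hits
    return mapping


def gene_edges_bruteforce(interactions, snp_gene_map):
    """Max −log10 p over all SNP pairs bridging each unordered gene pair."""
    snp_to_genes = {}
    for gene, snp_ids in snp_gene_map.items():
        for sid in snp_ids:
            snp_to_genes.setdefault(sid, set()).add(gene)
    best = {}
    for it in interactions:
        for ga in snp_to_genes.get(it.snp_a, ()):  # noqa: B007
            for gb in snp_to_genes.get(it.snp_b, ()):
                if ga == gb:
                    continue
                key = tuple(sorted((ga, gb)))
                w = -math.log10(it.p_interaction)
                if key not in best or w > best[key]:
                    best[key] = w
    return best


def top_fraction_bruteforce(edges, fraction):
    """Full sort by (−weight, gene_a, gene_b), then take max(1, floor(f·n))."""
    k = max(1, math.floor(fraction * len(edges)))
    ranked = sorted(edges, key=lambda e: (-e.weight, e.gene_a, e.gene_b))
    return ranked[:k]


def youden_bruteforce(scores, labels):
    """O(n²) scan over all candidate thresholds (the unique scores)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = (labels == 1).sum()
    n_neg = (labels == 0).sum()
    best_j, best_sens, best_t = -np.inf, -np.inf, None
    for t in sorted(set(scores.tolist())):
        tp = fn = tn = fp = 0
        for s, y in zip(scores, labels):
            pred = s >= t
            if y == 1 and pred:
                tp += 1
            elif y == 1:
                fn += 1
            elif pred:
                fp += 1
            else:
                tn += 1
        sens = tp / n_pos
        spec = tn / n_neg
        j = sens + spec - 1
        if (j, sens, -t) > (best_j, best_sens, -best_t if best_t is not None else -np.inf):
            best_j, best_sens, best_t = j, sens, t
    return best_t


def wilcoxon_exact_bruteforce(x, y, alternative="greater"):
    """Exact rank-sum p-value by enumerating all C(n+m, n) rank assignments.

    Requires no ties between the pooled observations.
    """
    x = list(x)
    y = list(y)
    pooled = sorted(x + y)
    assert len(set(pooled)) == len(pooled), "exact enumeration assumes no ties"
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    u_obs = sum(ranks[v] for v in x) - len(x) * (len(x) + 1) / 2
    n = len(pooled)
    count = 0
    total = 0
    for combo in itertools.combinations(range(1, n + 1), len(x)):
        u = sum(combo) - len(x) * (len(x) + 1) / 2
        total += 1
        if alternative == "greater":
            if u >= u_obs:
                count += 1
        elif alternative == "less":
            if u <= u_obs:
                count += 1
        else:
            raise ValueError(alternative)
    return count / total


def fisher_tail_bruteforce(a, b, c, d):
    """One-sided enrichment p: hypergeometric tail Σ_{k≥a} P(k) for the
    2×2 table [[a, b], [c, d]]."""
    n = a + b + c + d
    row1 = a + b
    col1 = a + c

    def log_comb(n_, k_):
        return math.lgamma(n_ + 1) - math.lgamma(k_ + 1) - math.lgamma(n_ - k_ + 1)

    denom = log_comb(n, col1)
    p = 0.0
    for k in range(a, min(row1, col1) + 1):
        if col1 - k > n - row1:
            continue
        p += math.exp(
            log_comb(row1, k) + log_comb(n - row1, col1 - k) - denom
        )
    return p


def average_precision_bruteforce(scores, labels):
    """AP = Σ_k P(k)·ΔR(k) over the ranked list, literal definition."""
    order = np.argsort(-np.asarray(scores, dtype=float), kind="stable")
    y = np.asarray(labels, dtype=int)[order]
    n_pos = y.sum()
    tp = 0
    ap = 0.0
    for i, yi in enumerate(y, start=1):
        if yi == 1:
            tp += 1
            ap += tp / i
    return ap / n_pos
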