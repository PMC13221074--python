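"""Tissue/cell-type specificity scoring and HRG-vs-LRG comparison statistics.

Tissue specificity follows the density-vector / Jensen–Shannon construction:
a gene's expression across n tissues is normalized to a probability vector
E, its distance to the indicator distribution E_t of tissue t is the square
root of the JS divergence (base-2 entropy, so JS ∈ [0, 1] bits), and the
specificity score is TS(E|t) = 1 − sqrt(JS(E, E_t)) ∈ [0, 1]. Cell-type
specificity is the share of a gene's mean expression attributable to one
cell type. Group-level HRG-vs-LRG contrasts use the one-sided Wilcoxon
rank-sum test and gene-set enrichment uses the one-sided Fisher exact test,
both with Benjamini–Hochberg correction across each analysis family.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ExpressionMatrix",
    "GroupComparison",
    "density_normalize",
    "js_divergence",
    "tissue_specificity",
    "tissue_specificity_table",
    "cell_type_specificity",
    "cell_type_specificity_table",
    "rank_sum_test",
    "compare_specificity",
    "fisher_enrichment",
    "enrichment_table",
]


@dataclass
class ExpressionMatrix:
    """Nonnegative genes × samples matrix with a sample → group mapping."""

    values: pd.DataFrame
    sample_group: dict

    def __post_init__(self):
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression values must be nonnegative")
        unmapped = [s for s in self.values.columns if s not in self.sample_group]
        if unmapped:
            raise ValueError(f"samples without group assignment: {unmapped[:5]}")
        if len(set(self.sample_group[s] for s in self.values.columns)) < 2:
            raise ValueError("at least two groups required")

    @property
    def groups(self) -> list:
        return sorted(set(self.sample_group[s] for s in self.values.columns))

    def group_means(self) -> pd.DataFrame:
        """Mean expression of every gene in every group (genes × groups)."""
        cols = {
            g: [s for s in self.values.columns if self.sample_group[s] == g]
            for g in self.groups
        }
        return pd.DataFrame(
            {g: self.values[cs].mean(axis=1) for g, cs in cols.items()}
        )


@dataclass
class GroupComparison:
    """One group's rank-sum comparison: statistic, raw and adjusted p."""

    group: str
    statistic: float
    p_value: float
    p_adjusted: float


# ------------------------------------------------------------------- scoring
def density_normalize(v) -> np.ndarray | None:
    """Normalize a nonnegative vector to a probability (density) vector.

    Returns ``None`` for an all-zero vector — such genes are flagged and
    excluded from specificity scoring rather than scored as 0.
    """
    v = np.asarray(v, dtype=float)
    if v.size < 2:
        raise ValueError("density vector needs at least 2 entries")
    if (v < 0).any():
        raise ValueError("expression values must be nonnegative")
    total = v.sum()
    if total == 0:
        return None
    return v / total


def _entropy_bits(p: np.ndarray) -> float:
    """Shannon entropy in bits with the 0·log 0 := 0 convention."""
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def js_divergence(p1, p2) -> float:
    """Jensen–Shannon divergence in bits: H((p1+p2)/2) − (H(p1)+H(p2))/2.

    Symmetric and bounded in [0, 1] for base-2 entropy.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    if p1.shape != p2.shape:
        raise ValueError("length mismatch")
    if (p1 < 0).any() or (p2 < 0).any():
        raise ValueError("negative entries")
    for p in (p1, p2):
        if abs(p.sum() - 1.0) > 1e-6:
            raise ValueError("inputs must sum to 1")
    m = 0.5 * (p1 + p2)
    js = _entropy_bits(m) - 0.5 * (_entropy_bits(p1) + _entropy_bits(p2))
    return float(min(max(js, 0.0), 1.0))


def tissue_specificity(e, t: int, no_sqrt: bool = False) -> float:
    """TS(E|t) = 1 − sqrt(JS(E, E_t)) against tissue t's indicator.

    ``no_sqrt=True`` uses the raw JS divergence as the distance instead of
    its square root (the metric form); the default is the square-root
    distance.
    """
    e = np.asarray(e, dtype=float)
    if not (0 <= t < e.size):
        raise ValueError("tissue index out of range")
    e_t = np.zeros_like(e)
    e_t[t] = 1.0
    js = js_divergence(e, e_t)
    d = js if no_sqrt else np.sqrt(js)
    return float(1.0 - d)


def tissue_specificity_table(
    values: pd.DataFrame, no_sqrt: bool = False
) -> pd.DataFrame:
    """Per-gene, per-tissue TS scores from a genes × tissues expression table.

    Genes with zero total expression are excluded (flagged) from the result.
    """
    rows = {}
    for gene, v in values.iterrows():
        e = density_normalize(v.to_numpy())
        if e is None:
            continue
        rows[gene] = [
            tissue_specificity(e, t, no_sqrt=no_sqrt) for t in range(len(v))
        ]
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(values.columns))


def cell_type_specificity(expr: ExpressionMatrix, gene: str) -> pd.Series | None:
    """S_{g,c}: share of gene g's summed group-mean expression in group c.

    Scores sum to 1 over groups. Returns ``None`` (flagged) for genes with
    zero mean expression in every group.
    """
    means = expr.group_means().loc[gene]
    total = means.sum()
    if total == 0:
        return None
    return means / total


def cell_type_specificity_table(expr: ExpressionMatrix) -> pd.DataFrame:
    """S_{g,c} for all scorable genes (genes × groups)."""
    means = expr.group_means()
    totals = means.sum(axis=1)
    scorable = totals > 0
    return means.loc[scorable].div(totals[scorable], axis=0)


# ---------------------------------------------------------------------- tests
def rank_sum_test(x, y, alternative: str = "greater") -> tuple[float, float]:
    """Wilcoxon rank-sum (Mann–Whitney U) with tie correction.

    Uses the exact null distribution when both sides have < 20 observations
    and there are no ties; the normal approximation with tie correction
    otherwise. Returns (U statistic of ``x``, p-value).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    has_ties = len(np.unique(np.concatenate([x, y]))) < (len(x) + len(y))
    method = "exact" if (len(x) < 20 and len(y) < 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative=alternative, method=method)
    return float(res.statistic), float(res.pvalue)


def compare_specificity(
    hrg_scores: pd.DataFrame,
    lrg_scores: pd.DataFrame,
    alternative: str = "greater",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-group one-sided rank-sum comparison of HRG vs LRG scores.

    ``hrg_scores``/``lrg_scores`` are genes × groups score tables sharing
    columns. Groups with fewer than 3 observations on either side are
    skipped with a warning. BH correction is applied across the family of
    groups tested; ``significant`` marks adjusted p < ``alpha``.
    """
    rows = []
    for group in hrg_scores.columns:
        x = hrg_scores[group].dropna().to_numpy()
        y = lrg_scores[group].dropna().to_numpy()
        if len(x) < 3 or len(y) < 3:
            warnings.warn(f"group {group}: fewer than 3 observations per side; skipped")
            continue
        stat, p = rank_sum_test(x, y, alternative=alternative)
        rows.append({"group": group, "statistic": stat, "p": p})
    out = pd.DataFrame(rows)
    if len(out):
        out["p_adj"] = multipletests(out["p"], method="fdr_bh")[1]
        out["significant"] = out["p_adj"] < alpha
    return out


def fisher_enrichment(query, annotation, background) -> tuple[float, float]:
    """One-sided (enrichment) Fisher exact test of a gene set overlap.

    The 2×2 table is built from ``query`` against ``annotation ∩
    background`` within ``background``; returns (odds ratio, p).
    """
    background = set(background)
    if not background:
        raise ValueError("empty background")
    query = set(query) & background
    ann = set(annotation) & background
    a = len(query & ann)
    b = len(query - ann)
    c = len(ann - query)
    d = len(background) - a - b - c
    odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
    return float(odds), float(p)


def enrichment_table(
    query, genesets: dict, background, alpha: float = 0.05
) -> pd.DataFrame:
    """Fisher enrichment of ``query`` in each gene set, BH-corrected."""
    rows = []
    for name, genes in sorted(genesets.items()):
        odds, p = fisher_enrichment(query, genes, background)
        overlap = len(set(query) & set(genes) & set(background))
        rows.append({"gene_set": name, "overlap": overlap, "odds_ratio": odds, "p": p})
    out = pd.DataFrame(rows)
    if len(out):
        out["p_adj"] = multipletests(out["p"], method="fdr_bh")[1]
        out["significant"] = out["p_adj"] < alpha
    return out
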