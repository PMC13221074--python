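"""Graph construction: windowing, edge aggregation, filtering, preprocessing."""

import numpy as np
import pandas as pd
import pytest

from mogt import (
    GeneEdge,
    GenomicInterval,
    LabelSet,
    SnpInteraction,
    SnpRecord,
    assemble_graph,
    build_gene_edges,
    derive_negative_set,
    filter_top_fraction,
    map_snps_to_genes,
    normalize_features,
    select_candidate_genes,
)
from oracles import (
    candidate_genes_bruteforce,
    gene_edges_bruteforce,
    snp_gene_map_bruteforce,
    top_fraction_bruteforce,
)


def random_instance(rng, n_snps=60, n_genes=20):
    """A random SNP/gene/interaction instance on two chromosomes."""
    genes = []
    for i in range(n_genes):
        chrom = f"chr{1 + i % 2}"
        start = int(rng.integers(0, 5_000_000))
        genes.append(
            GenomicInterval(f"g{i}", chrom, start, start + int(rng.integers(500, 50_000)))
        )
    snps = [
        SnpRecord(
            f"rs{i}",
            f"chr{1 + int(rng.integers(1, 3)) - 1}",
            int(rng.integers(1, 5_100_000)),
            float(10 ** rng.uniform(-12, 0)),
        )
        for i in range(n_snps)
    ]
    pairs = set()
    interactions = []
    for _ in range(n_snps * 2):
        a, b = rng.integers(0, n_snps, 2)
        if a == b or (min(a, b), max(a, b)) in pairs:
            continue
        pairs.add((min(a, b), max(a, b)))
        interactions.append(
            SnpInteraction(f"rs{min(a,b)}", f"rs{max(a,b)}", float(10 ** rng.uniform(-12, 0)))
        )
    return snps, genes, interactions


class TestCandidateGenes:
    def test_gene_within_window_included(self):
        snps = [SnpRecord("rs1", "chr1", 5_000_000, 1e-9)]
        genes = [GenomicInterval("gA", "chr1", 5_500_000, 5_600_000)]
        assert select_candidate_genes(snps, genes) == {"gA"}

    def test_non_significant_snp_selects_nothing(self):
        snps = [SnpRecord("rs1", "chr1", 5_000_000, 1e-7)]
        genes = [GenomicInterval("gA", "chr1", 5_000_100, 5_100_000)]
        assert select_candidate_genes(snps, genes) == set()

    def test_window_boundary_is_inclusive(self):
        # distance exactly 1 Mb by coordinate subtraction → included
        snps = [SnpRecord("rs1", "chr1", 1_000_000, 1e-9)]
        genes = [GenomicInterval("gA", "chr1", 2_000_000, 2_010_000)]
        assert select_candidate_genes(snps, genes) == {"gA"}
        oracle = candidate_genes_bruteforce(snps, genes, 5e-8, 1_000_000)
        assert oracle == {"gA"}

    def test_chromosome_must_match(self):
        snps = [SnpRecord("rs1", "chr2", 5_000_000, 1e-9)]
        genes = [GenomicInterval("gA", "chr1", 5_000_000, 5_100_000)]
        assert select_candidate_genes(snps, genes) == set()

    def test_empty_gene_list_warns(self):
        with pytest.warns(UserWarning):
            assert select_candidate_genes([SnpRecord("rs1", "chr1", 5, 1e-9)], []) == set()

    def test_matches_bruteforce_on_random_instances(self, rng):
        for _ in range(25):
            snps, genes, _ = random_instance(rng)
            window = int(rng.choice([10_000, 300_000, 1_000_000]))
            got = select_candidate_genes(snps, genes, 5e-8, window)
            assert got == candidate_genes_bruteforce(snps, genes, 5e-8, window)


class TestSnpGeneMapping:
    def test_snp_inside_gene_body(self):
        snps = [SnpRecord("rs1", "chr1", 1_500, 0.5)]
        genes = [GenomicInterval("gA", "chr1", 1_000, 2_000)]
        assert map_snps_to_genes(snps, genes) == {"gA": {"rs1"}}

    def test_snp_outside_window_unassigned(self):
        snps = [SnpRecord("rs1", "chr1", 500, 0.5)]  # 1,500 bp upstream of gene
        genes = [GenomicInterval("gA", "chr1", 2_000, 3_000)]
        assert map_snps_to_genes(snps, genes, window_bp=1_000) == {}

    def test_snp_between_adjacent_genes_maps_to_both(self, rng):
        snps = [SnpRecord("rs1", "chr1", 10_500, 0.5)]
        genes = [
            GenomicInterval("gA", "chr1", 9_000, 10_000),
            GenomicInterval("gB", "chr1", 11_000, 12_000),
        ]
        got = map_snps_to_genes(snps, genes, window_bp=1_000)
        assert got == snp_gene_map_bruteforce(snps, genes, 1_000)
        assert got == {"gA": {"rs1"}, "gB": {"rs1"}}

    def test_matches_bruteforce_on_random_instances(self, rng):
        for _ in range(25):
            snps, genes, _ = random_instance(rng)
            window = int(rng.choice([1_000, 20_000]))
            got = map_snps_to_genes(snps, genes, window)
            assert got == snp_gene_map_bruteforce(snps, genes, window)


class TestGeneEdges:
    def test_max_over_snp_pairs(self):
        mapping = {"gA": {"s1", "s2"}, "gB": {"s3"}}
        interactions = [
            SnpInteraction("s1", "s3", 1e-6),
            SnpInteraction("s2", "s3", 1e-10),
        ]
        edges = build_gene_edges(interactions, mapping)
        assert len(edges) == 1
        assert edges[0].gene_a == "gA" and edges[0].gene_b == "gB"
        assert edges[0].weight == pytest.approx(10.0)

    def test_disjoint_snp_sets_give_no_edge(self):
        mapping = {"gA": {"s1"}, "gB": {"s2"}}
        with pytest.warns(UserWarning):
            edges = build_gene_edges([SnpInteraction("s3", "s4", 1e-5)], mapping)
        assert edges == []

    def test_no_self_edges(self):
        mapping = {"gA": {"s1", "s2"}}
        assert build_gene_edges([SnpInteraction("s1", "s2", 1e-8)], mapping) == []

    def test_matches_bruteforce_on_random_instances(self, rng):
        for _ in range(25):
            snps, genes, interactions = random_instance(rng)
            mapping = map_snps_to_genes(snps, genes, 20_000)
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                edges = build_gene_edges(interactions, mapping)
            expected = gene_edges_bruteforce(interactions, mapping)
            assert {(e.gene_a, e.gene_b): e.weight for e in edges} == pytest.approx(
                expected
            )


class TestTopFraction:
    def test_keeps_two_of_two_hundred(self, rng):
        edges = [
            GeneEdge(f"a{i}", f"b{i}", float(w))
            for i, w in enumerate(rng.permutation(200))
        ]
        kept = filter_top_fraction(edges, 0.01)
        assert sorted(e.weight for e in kept) == [198.0, 199.0]

    def test_fraction_one_is_identity(self, rng):
        edges = [GeneEdge(f"a{i}", f"b{i}", float(i)) for i in range(10)]
        assert set(filter_top_fraction(edges, 1.0)) == set(edges)

    def test_tie_break_matches_full_sort_oracle(self, rng):
        # 5 edges tied at the cutoff weight; deterministic canonical order
        edges = [GeneEdge(f"a{i:02d}", f"b{i:02d}", 5.0) for i in range(5)]
        edges += [
            GeneEdge(f"c{i:02d}", f"d{i:02d}", float(6 + i)) for i in range(95)
        ]
        got = filter_top_fraction(edges, 0.03)
        assert len(got) == 3
        assert got == top_fraction_bruteforce(edges, 0.03)

    def test_subset_and_weight_dominance(self, rng):
        for _ in range(20):
            n = int(rng.integers(5, 80))
            edges = [
                GeneEdge(f"a{i}", f"b{i}", float(rng.integers(0, 10)))
                for i in range(n)
            ]
            frac = float(rng.uniform(0.05, 1.0))
            kept = filter_top_fraction(edges, frac)
            assert set(kept) <= set(edges)
            assert kept == top_fraction_bruteforce(edges, frac)
            dropped = [e for e in edges if e not in kept]
            if dropped:
                assert min(e.weight for e in kept) >= max(
                    e.weight for e in dropped
                ) - 1e-12 or min(e.weight for e in kept) == max(
                    e.weight for e in dropped
                )

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            filter_top_fraction([GeneEdge("a", "b", 1.0)], 0.0)
        with pytest.raises(ValueError):
            filter_top_fraction([GeneEdge("a", "b", 1.0)], 1.5)


class TestNegativeSet:
    def test_interactor_with_positive_excluded(self):
        got = derive_negative_set({"g1", "g2"}, {"p1"}, {("g1", "p1")})
        assert got == {"g2"}

    def test_no_pairs_means_simple_difference(self):
        assert derive_negative_set({"g1", "p1"}, {"p1"}, set()) == {"g1"}

    def test_positive_never_negative(self):
        assert "p1" not in derive_negative_set({"p1", "g1"}, {"p1"}, set())


class TestAssembleGraph:
    def _inputs(self):
        candidates = {"g1", "g2", "g3", "g4"}
        labels = LabelSet(positives={"g1", "g5"}, negatives={"g2", "g3"})
        edges = [GeneEdge("g1", "g2", 3.0)]
        omics = [
            pd.DataFrame(
                {"f1": [1.0, 2.0, np.nan, 0.4, 10.0], "f2": [0.0, 1.0, 2.0, 3.0, 4.0]},
                index=pd.Index(["g1", "g2", "g3", "g4", "g5"], name="gene_id"),
            )
        ]
        masks = {"g1": "train", "g2": "train", "g3": "val", "g5": "test"}
        return candidates, labels, edges, omics, masks

    def test_train_columns_centered(self):
        graph = assemble_graph(*self._inputs())
        train = graph.mask_indices("train")
        assert np.allclose(graph.features[train].mean(axis=0), 0.0, atol=1e-9)

    def test_missing_imputed_with_train_median(self):
        candidates, labels, edges, omics, masks = self._inputs()
        omics[0].loc["g3", "f1"] = np.nan
        graph = assemble_graph(candidates, labels, edges, omics, masks)
        raw = graph.raw_features
        j = 0  # column f1; train rows are g1 (1.0) and g2 (2.0) → median 1.5
        i = graph.node_ids.index("g3")
        assert np.isnan(raw[i, j])
        _, params = normalize_features(raw, graph.mask_indices("train"))
        assert params["median"][j] == pytest.approx(1.5)

    def test_labeled_gene_missing_from_edges_is_isolated_node(self):
        graph = assemble_graph(*self._inputs())
        assert "g5" in graph.node_ids
        src, dst, _ = graph.edge_arrays()
        i = graph.node_ids.index("g5")
        assert i not in set(src) | set(dst)

    def test_deterministic_and_byte_identical(self):
        g1 = assemble_graph(*self._inputs())
        g2 = assemble_graph(*self._inputs())
        assert g1.node_ids == g2.node_ids
        assert g1.features.tobytes() == g2.features.tobytes()

    def test_normalization_ignores_validation_rows(self):
        """Shifting only validation-row raw values leaves parameters fixed."""
        candidates, labels, edges, omics, masks = self._inputs()
        graph = assemble_graph(candidates, labels, edges, omics, masks)
        train = graph.mask_indices("train")
        _, params = normalize_features(graph.raw_features, train)
        shifted = graph.raw_features.copy()
        val = graph.mask_indices("val")
        shifted[val] += 100.0
        _, params_shifted = normalize_features(shifted, train)
        for key in params:
            np.testing.assert_array_equal(params[key], params_shifted[key])

    def test_constant_column_warns_and_uses_unit_sd(self):
        candidates, labels, edges, omics, masks = self._inputs()
        omics[0]["f2"] = 7.0
        with pytest.warns(UserWarning, match="constant"):
            graph = assemble_graph(candidates, labels, edges, omics, masks)
        assert np.isfinite(graph.features).all()
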