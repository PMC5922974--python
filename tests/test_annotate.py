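"""Insertion annotation, density/essentiality and insertion-bias tools."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from tdnaseq.annotate import (
    PARTITION_CLASSES,
    GeneIndex,
    build_feature_partition,
    call_essential_candidates,
    classify_insertion,
    density_histogram,
    feature_insertion_rates,
    gene_insert_density,
    local_gc,
    resample_feature_null,
)
from tdnaseq.models import GeneModel, PoolEntry


def entry(pos, bc="A" * 20, scaffold="s1", status="kept"):
    return PoolEntry(bc, scaffold, pos, "+", 10, 0, status)


class TestClassifyInsertion:
    def test_upstream_of_plus_gene_is_intergenic5(self, plus_gene):
        gene_id, cls, dist = classify_insertion("s1", 50, GeneIndex([plus_gene]))
        assert (gene_id, cls, dist) == ("gA", "intergenic5", 50)

    def test_inside_cds_exon(self, plus_gene):
        _, cls, dist = classify_insertion("s1", 200, GeneIndex([plus_gene]))
        assert (cls, dist) == ("exon", 0)

    def test_downstream_of_minus_gene_is_intergenic5(self, minus_gene):
        gene_id, cls, _ = classify_insertion("s1", 450, GeneIndex([minus_gene]))
        assert (gene_id, cls) == ("gB", "intergenic5")

    def test_upstream_of_minus_gene_is_intergenic3(self, minus_gene):
        _, cls, _ = classify_insertion("s1", 50, GeneIndex([minus_gene]))
        assert cls == "intergenic3"

    def test_no_genes_on_scaffold(self, plus_gene):
        gene_id, _, dist = classify_insertion("s2", 50, GeneIndex([plus_gene]))
        assert gene_id is None and dist == -1

    def test_nearest_gene_wins(self, plus_gene):
        other = GeneModel(
            "gC", "s1", "+", 1000, 1300, 1000, 1300, exons=[(1000, 1300)]
        )
        index = GeneIndex([plus_gene, other])
        gene_id, _, _ = classify_insertion("s1", 950, index)
        assert gene_id == "gC"

    def test_agrees_with_brute_force_scan(self, small_truth):
        """Feature class matches an exhaustive interval scan on toy genes."""
        genes = small_truth.genes
        index = GeneIndex(genes)
        rng = np.random.default_rng(12)
        n = len(small_truth.genome["scaffold_1"])
        for pos in rng.integers(0, n, 300).tolist():
            _, cls, _ = classify_insertion("scaffold_1", int(pos), index)
            inside = [g for g in genes if g.tx_start <= pos < g.tx_end]
            if inside:
                assert cls == inside[0].feature_at(int(pos))
            else:
                assert cls in ("intergenic5", "intergenic3")


class TestDensityAndEssentiality:
    def _gene(self, gene_id="g1", span=1000):
        return GeneModel(
            gene_id, "s1", "+", 0, span, 0, span, exons=[(0, span)]
        )

    def test_nine_inserts_in_1kb_gene_is_nine_per_kb(self):
        gene = self._gene()
        pool = [entry(i * 100 + 50, bc=f"B{i}" + "A" * 18) for i in range(9)]
        table = gene_insert_density(pool, [gene])
        assert table.loc[0, "density"] == pytest.approx(9.0)

    def test_fractional_density(self):
        gene = self._gene(span=1500)
        pool = [entry(100, bc="B1" + "A" * 18), entry(900, bc="B2" + "A" * 18)]
        table = gene_insert_density(pool, [gene])
        assert table.loc[0, "density"] == pytest.approx(2 / 1.5)

    def test_zero_insertions(self):
        table = gene_insert_density([], [self._gene()])
        assert table.loc[0, "density"] == 0.0

    @pytest.mark.parametrize(
        "density,is_candidate", [(1.333, True), (2.0, False), (9.0, False)]
    )
    def test_threshold_is_strictly_less_than_two(self, density, is_candidate):
        table = pd.DataFrame(
            {"gene_id": ["g"], "n_inserts_cds": [0], "cds_span_kb": [1.0], "density": [density]}
        )
        out = call_essential_candidates(table)
        assert bool(out.loc[0, "essential_candidate"]) is is_candidate

    def test_histogram_bins_by_one_insert_per_kb(self):
        table = pd.DataFrame({"density": [0.5, 1.2, 1.8, 9.4]})
        hist = density_histogram(table)
        assert hist.loc[0, "n_genes"] == 1
        assert hist.loc[1, "n_genes"] == 2
        assert hist.loc[9, "n_genes"] == 1


class TestLocalGC:
    def test_all_gc_window(self):
        assert local_gc({"s": "G" * 200}, "s", 100, window=101) == 1.0

    def test_half_gc_window(self):
        assert local_gc({"s": "ATGC" * 100}, "s", 200, window=101) == pytest.approx(
            0.5, abs=0.01
        )

    def test_truncated_window_matches_brute_force(self):
        rng = np.random.default_rng(3)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 70))
        got = local_gc({"s": seq}, "s", 10, window=101)
        window = seq[0:61]  # [10-50, 10+50] clipped to [0, 61)
        expected = sum(window.count(b) for b in "GC") / len(window)
        assert got == pytest.approx(expected)

    def test_n_bases_excluded(self):
        assert local_gc({"s": "N" * 40 + "GC" + "N" * 40}, "s", 41, window=11) == 1.0

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            local_gc({"s": "ACGT"}, "s", 1, window=10)


@pytest.fixture(scope="module")
def partition(small_truth):
    lengths = {s: len(seq) for s, seq in small_truth.genome.items()}
    return build_feature_partition(small_truth.genes, lengths)


class TestFeaturePartition:
    def test_partition_covers_genome_exactly(self, small_truth, partition):
        total = sum(len(seq) for seq in small_truth.genome.values())
        rates = feature_insertion_rates([], partition)
        assert rates["n_bases"].sum() == total

    def test_gene_bodies_classified_consistently(self, small_truth, partition):
        arr = partition["scaffold_1"]
        rng = np.random.default_rng(5)
        for g in list(small_truth.genes)[:10]:
            for pos in rng.integers(g.tx_start, g.tx_end, 20).tolist():
                assert PARTITION_CLASSES[arr[pos]] == g.feature_at(int(pos))

    def test_all_insertions_in_exons_yield_exon_rate_only(self, small_truth, partition):
        g = small_truth.genes[0]
        a, b = g.cds_start, min(g.cds_end, g.exons[0][1])
        pool = [
            entry(p, bc=f"B{p}" + "A" * 14, scaffold="scaffold_1")
            for p in range(a, min(a + 10, b))
        ]
        rates = feature_insertion_rates(pool, partition).set_index("feature_class")
        assert rates.loc["exon", "n_insertions"] == len(pool)
        assert rates.drop("exon")["n_insertions"].sum() == 0

    def test_resampled_null_is_deterministic_and_in_class(self, partition):
        observed = {"exon": 50, "promoter": 20, "intergenic": 30}
        a = resample_feature_null(partition, observed, seed=9)
        b = resample_feature_null(partition, observed, seed=9)
        assert a == b
        for cls, positions in a.items():
            assert len(positions) == observed[cls]
            for scaffold, pos in positions:
                assert PARTITION_CLASSES[partition[scaffold][pos]] == cls

    def test_exhaustive_sample_returns_whole_class(self, partition):
        arr = partition["scaffold_1"]
        n_prom = int((arr == PARTITION_CLASSES.index("promoter")).sum())
        out = resample_feature_null(partition, {"promoter": n_prom}, seed=1)
        assert len(out["promoter"]) == n_prom
        with pytest.raises(ValueError):
            resample_feature_null(partition, {"promoter": n_prom + 1}, seed=1)

    def test_uniform_insertions_have_uniform_rates(self, small_truth, partition):
        """Per-class rates from uniform random positions agree within a
        generous binomial envelope."""
        rng = np.random.default_rng(8)
        n = len(small_truth.genome["scaffold_1"])
        pool = [
            entry(int(p), bc=f"B{i}A" + "A" * 14, scaffold="scaffold_1")
            for i, p in enumerate(rng.integers(0, n, 4000))
        ]
        rates = feature_insertion_rates(pool, partition)
        overall = 4000 / (n / 1000.0)
        for _, row in rates.iterrows():
            if row.n_bases < 5000:
                continue
            se = np.sqrt(4000 * row.n_bases / n) / (row.n_bases / 1000.0)
            assert abs(row.inserts_per_kb - overall) < 4 * se + 1e-9
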