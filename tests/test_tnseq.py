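"""TnSeq read parsing, mapping calls and per-barcode aggregation."""

from __future__ import annotations

from collections import Counter

import numpy as np
import pytest

from tdnaseq.align import ReferenceIndex, align_fragment
from tdnaseq.models import TDNAReadModel
from tdnaseq.simulate import (
    DEFAULT_TDNA_MODEL,
    SimConfig,
    make_genome_and_genes,
    make_true_pool,
    make_tnseq_reads,
    random_dna,
)
from tdnaseq.tnseq import (
    ReadMapping,
    aggregate_barcode_evidence,
    classify_read,
    map_tnseq_reads,
    parse_tnseq_read,
)

MODEL = DEFAULT_TDNA_MODEL


def build_read(barcode: str, fragment: str, retained_border: int = 0) -> str:
    return (
        MODEL.flank_pre
        + barcode
        + MODEL.flank_post
        + MODEL.tdna_end_required
        + MODEL.tdna_end_optional[:retained_border]
        + fragment
    )


class TestParse:
    def test_well_formed_read_parses(self, rng):
        bc = random_dna(rng, 20)
        frag = random_dna(rng, 30)
        parsed = parse_tnseq_read("r1", build_read(bc, frag), MODEL)
        assert parsed.status == "ok"
        assert parsed.barcode == bc
        assert parsed.fragment == frag

    @pytest.mark.parametrize("length,status", [(16, "bad_barcode_length"),
                                               (24, "bad_barcode_length"),
                                               (17, "ok"), (23, "ok")])
    def test_barcode_length_range_is_17_to_23(self, rng, length, status):
        bc = random_dna(rng, length)
        parsed = parse_tnseq_read("r", build_read(bc, random_dna(rng, 30)), MODEL)
        assert parsed.status == status

    def test_junction_within_ignored_border_still_ok(self, rng):
        """A junction 4 bases before the nominal T-DNA end parses fine:
        the last 10 border bases are optional."""
        bc = random_dna(rng, 20)
        frag = random_dna(rng, 30)
        read = build_read(bc, frag, retained_border=MODEL.border_trim - 4)
        parsed = parse_tnseq_read("r", read, MODEL)
        assert parsed.status == "ok"
        # any accidental continuation of the border into the fragment is
        # stripped too, so check a non-matching first base explicitly
        boundary = MODEL.border_trim - 4
        if frag[0] != MODEL.tdna_end_optional[boundary]:
            assert parsed.fragment == frag

    def test_missing_flanks_reported(self, rng):
        parsed = parse_tnseq_read("r", random_dna(rng, 120), MODEL)
        assert parsed.status == "no_barcode"

    def test_short_fragment_reported(self, rng):
        read = build_read(random_dna(rng, 20), random_dna(rng, 5))
        assert parse_tnseq_read("r", read, MODEL).status == "short_fragment"

    def test_flank_mismatch_tolerance(self, rng):
        bc = random_dna(rng, 20)
        read = build_read(bc, random_dna(rng, 30))
        mutated = "A" + ("C" if read[1] != "C" else "G") + read[2:]
        parsed = parse_tnseq_read("r", mutated, MODEL, max_mismatch=2)
        assert parsed.status == "ok" and parsed.barcode == bc


@pytest.fixture(scope="module")
def genome():
    rng = np.random.default_rng(21)
    return {"chr1": random_dna(rng, 5000)}


class TestClassify:
    def _map_fragment(self, fragment, genome):
        g_index = ReferenceIndex(genome)
        pe_index = ReferenceIndex(MODEL.pastend_references())
        parsed = parse_tnseq_read(
            "r", build_read("A" * 20, fragment), MODEL
        )
        return classify_read(parsed, align_fragment(parsed.fragment, g_index, pe_index))

    def test_unique_genomic_hit(self, genome):
        m = self._map_fragment(genome["chr1"][800:840], genome)
        assert m.call == "genomic" and (m.scaffold, m.position, m.strand) == ("chr1", 800, "+")

    def test_left_border_fragment_is_past_end(self, genome):
        m = self._map_fragment(MODEL.tdna_left_border[20:60], genome)
        assert m.call == "past_end_left_border"

    def test_vector_fragment_is_past_end(self, genome):
        m = self._map_fragment(MODEL.vector_backbone[50:90], genome)
        assert m.call == "past_end_vector"

    def test_duplicated_region_is_ambiguous(self):
        rng = np.random.default_rng(22)
        block = random_dna(rng, 100)
        genome = {"c": block + random_dna(rng, 800) + block}
        m = self._map_fragment(block[10:50], genome)
        assert m.call == "ambiguous"

    def test_unalignable_fragment_is_unmapped(self, genome):
        rng = np.random.default_rng(23)
        m = self._map_fragment(random_dna(rng, 40), genome)
        assert m.call == "unmapped"


class TestAggregate:
    def _genomic(self, bc, pos, n, scaffold="s", strand="+"):
        return [
            ReadMapping(f"r{i}", bc, "genomic", scaffold, pos, strand)
            for i in range(n)
        ]

    def test_nearby_positions_merge_to_majority_coordinate(self):
        mappings = self._genomic("b1", 1000, 9) + self._genomic("b1", 1001, 1)
        tally = aggregate_barcode_evidence(mappings, merge_tolerance=3)["b1"]
        assert len(tally.locations) == 1
        assert (tally.locations[0].position, tally.locations[0].n_reads) == (1000, 10)

    def test_distant_positions_stay_separate(self):
        mappings = self._genomic("b1", 1000, 8) + self._genomic("b1", 1100, 2)
        tally = aggregate_barcode_evidence(mappings)["b1"]
        assert len(tally.locations) == 2
        assert tally.mode_location.position == 1000

    def test_pastend_only_barcode(self):
        mappings = [
            ReadMapping(f"r{i}", "b2", "past_end_vector") for i in range(5)
        ]
        tally = aggregate_barcode_evidence(mappings)["b2"]
        assert tally.n_genomic == 0 and tally.n_pastend == 5

    def test_reads_conserved_across_tally_cells(self):
        mappings = (
            self._genomic("b1", 10, 4)
            + [ReadMapping("a", "b1", "ambiguous")]
            + [ReadMapping("p", "b2", "past_end_left_border")]
            + [ReadMapping("u", "b2", "unmapped")]
        )
        tallies = aggregate_barcode_evidence(mappings)
        assert sum(t.total_reads for t in tallies.values()) == len(mappings)


class TestSimulatedReads:
    def test_zero_error_reads_all_map_to_true_location(self):
        cfg = SimConfig(
            seed=3,
            n_insertions=150,
            n_genes=20,
            genome_length=80_000,
            substitution_rate=0.0,
            off_by_one_rate=0.0,
            past_end_rate_head_to_tail=0.0,
            past_end_rate_head_to_head=0.0,
            past_end_rate_run_on=0.0,
            multilocus_rate=0.0,
            off_by_two_rate=0.0,
            ambiguous_rate=0.0,
            boundary_cases=False,
        )
        truth = make_genome_and_genes(cfg)
        pool_df = make_true_pool(cfg, truth)
        tn = make_tnseq_reads(pool_df, truth, cfg)
        mappings, stats = map_tnseq_reads(tn.reads, MODEL, truth.genome)
        assert stats["ok"] == len(tn.reads)
        expected = pool_df.set_index("barcode")
        by_barcode = Counter()
        correct = Counter()
        for m in mappings:
            assert m.call == "genomic"
            row = expected.loc[m.barcode]
            by_barcode[m.barcode] += 1
            # junction ambiguity: when the genome coincidentally continues
            # the T-DNA border sequence, the recorded junction shifts by up
            # to border_trim bases -- unresolvable for any mapper, so the
            # "true location" is a window of that width
            if (
                abs(m.position - row.position) <= MODEL.border_trim
                and m.strand == row.strand
            ):
                correct[m.barcode] += 1
        assert sum(correct.values()) == sum(by_barcode.values())

    def test_low_error_reads_mostly_map_to_true_location(self, small_cfg, small_truth, small_pool_df, small_tnseq):
        """With 0.5%/base substitutions, >= 95% of parseable reads map to
        the true insertion site."""
        expected = small_tnseq.truth.set_index("barcode")
        clean = expected[expected["artifact"] == ""]
        mappings, _ = map_tnseq_reads(small_tnseq.reads, MODEL, small_truth.genome)
        n_clean = n_correct = 0
        for m in mappings:
            if m.barcode not in clean.index:
                continue
            n_clean += 1
            row = clean.loc[m.barcode]
            if (
                m.call == "genomic"
                and m.scaffold == row.scaffold
                and abs(m.position - row.position) <= 3
            ):
                n_correct += 1
        assert n_correct / n_clean >= 0.95
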