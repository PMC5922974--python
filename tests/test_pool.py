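"""Filter-cascade rules at their printed thresholds, plus cascade
composition and idempotence properties."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tdnaseq.pool import (
    build_pool,
    classify_past_end,
    filter_ambiguous,
    filter_multilocus,
    filter_off_by_one,
    filter_off_by_two,
    levenshtein,
    levenshtein_dp,
)
from tdnaseq.tnseq import BarcodeTally, Location


def tally(
    bc,
    locations=(),
    pe_left=0,
    pe_right=0,
    pe_vector=0,
    ambiguous=0,
    unmapped=0,
):
    locs = [Location("s1", pos, "+", n) for pos, n in locations]
    locs.sort(key=lambda l: (-l.n_reads, l.scaffold, l.position))
    return BarcodeTally(
        barcode=bc,
        locations=locs,
        n_pastend_left=pe_left,
        n_pastend_right=pe_right,
        n_pastend_vector=pe_vector,
        n_ambiguous=ambiguous,
        n_unmapped=unmapped,
    )


def as_dict(*tallies):
    return {t.barcode: t for t in tallies}


def dp_oracle(a: str, b: str) -> int:
    """Independent full-matrix edit distance for cross-checking."""
    m = [[0] * (len(b) + 1) for _ in range(len(a) + 1)]
    for i in range(len(a) + 1):
        m[i][0] = i
    for j in range(len(b) + 1):
        m[0][j] = j
    for i in range(1, len(a) + 1):
        for j in range(1, len(b) + 1):
            m[i][j] = min(
                m[i - 1][j] + 1,
                m[i][j - 1] + 1,
                m[i - 1][j - 1] + (a[i - 1] != b[j - 1]),
            )
    return m[len(a)][len(b)]


class TestLevenshtein:
    @pytest.mark.parametrize(
        "a,b,d",
        [("ACGT", "ACGT", 0), ("ACGT", "ACG", 1), ("kitten", "sitting", 3)],
    )
    def test_known_distances(self, a, b, d):
        assert levenshtein(a, b) == d
        assert levenshtein_dp(a, b) == d

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        a=st.text(alphabet="ACGT", min_size=0, max_size=24),
        b=st.text(alphabet="ACGT", min_size=0, max_size=24),
    )
    def test_matches_full_matrix_oracle(self, a, b):
        assert levenshtein(a, b) == dp_oracle(a, b)
        assert levenshtein_dp(a, b) == dp_oracle(a, b)


class TestOffByOne:
    def test_removed_at_100x_with_single_substitution(self):
        t = as_dict(
            tally("AAAAACCCCCGGGGGTTTTT", [(100, 150)]),
            tally("AAAAACCCCCGGGGTTTTTT", [(100, 1)]),  # 1 substitution
        )
        assert filter_off_by_one(t) == {"AAAAACCCCCGGGGTTTTTT"}

    def test_ratio_below_100_keeps_both(self):
        t = as_dict(
            tally("AAAAACCCCCGGGGGTTTTT", [(100, 150)]),
            tally("AAAAACCCCCGGGGTTTTTT", [(100, 2)]),  # 75x < 100x
        )
        assert filter_off_by_one(t) == set()

    def test_ratio_exactly_100_removes(self):
        t = as_dict(
            tally("AAAAACCCCCGGGGGTTTTT", [(100, 200)]),
            tally("AAAAACCCCCGGGGTTTTTT", [(100, 2)]),
        )
        assert filter_off_by_one(t) == {"AAAAACCCCCGGGGTTTTTT"}

    def test_single_indel_counts_as_distance_one(self):
        t = as_dict(
            tally("AAAAACCCCCGGGGGTTTTT", [(100, 300)]),
            tally("AAAACCCCCGGGGGTTTTT", [(100, 1)]),  # one deletion
        )
        assert filter_off_by_one(t) == {"AAAACCCCCGGGGGTTTTT"}

    def test_no_close_neighbour_keeps(self):
        t = as_dict(
            tally("AAAAACCCCCGGGGGTTTTT", [(100, 300)]),
            tally("TTTTTGGGGGCCCCCAAAAA", [(500, 1)]),
        )
        assert filter_off_by_one(t) == set()


class TestPastEnd:
    def test_more_than_seven_fold_flags(self):
        t = as_dict(tally("b", [(100, 1)], pe_left=8))
        assert classify_past_end(t) == {"b": "past_end_head_to_tail"}

    def test_exactly_seven_fold_does_not_flag(self):
        t = as_dict(tally("b", [(100, 1)], pe_left=7))
        assert classify_past_end(t) == {}

    @pytest.mark.parametrize(
        "pe,expected",
        [
            (dict(pe_left=6, pe_right=1, pe_vector=1), "past_end_head_to_tail"),
            (dict(pe_left=1, pe_right=6, pe_vector=1), "past_end_head_to_head"),
            (dict(pe_left=1, pe_right=1, pe_vector=6), "past_end_run_on"),
        ],
    )
    def test_subtype_follows_majority_evidence(self, pe, expected):
        t = as_dict(tally("b", [], **pe))
        assert classify_past_end(t)["b"] == expected


class TestAmbiguous:
    @pytest.mark.parametrize("n_amb,removed", [(6, True), (5, False), (0, False)])
    def test_strict_majority_rule(self, n_amb, removed):
        t = as_dict(tally("b", [(100, 10 - n_amb)], ambiguous=n_amb))
        assert (filter_ambiguous(t) == {"b"}) is removed


class TestMultilocus:
    def test_twenty_percent_off_mode_removes(self):
        t = as_dict(tally("b", [(100, 8), (900, 2)]))
        assert filter_multilocus(t) == {"b"}

    def test_ten_percent_off_mode_keeps(self):
        t = as_dict(tally("b", [(100, 9), (900, 1)]))
        assert filter_multilocus(t) == set()

    def test_single_location_keeps(self):
        t = as_dict(tally("b", [(100, 10)]))
        assert filter_multilocus(t) == set()

    def test_no_genomic_reads_not_evaluated(self):
        t = as_dict(tally("b", [], pe_left=10))
        assert filter_multilocus(t) == set()


class TestOffByTwo:
    A = "AAAAACCCCCGGGGGTTTTT"
    B = "AAAAACCCCCGGGGGAAAAT"  # distance 3 from A

    def test_nearby_similar_less_abundant_removed(self):
        t = as_dict(tally(self.A, [(1000, 100)]), tally(self.B, [(1005, 5)]))
        assert filter_off_by_two(t) == {self.B}

    def test_edit_distance_five_keeps(self):
        far = "AAAAACCCCCGGGGGCCCCC"  # five substitutions from A
        assert dp_oracle(self.A, far) == 5
        t = as_dict(tally(self.A, [(1000, 100)]), tally(far, [(1005, 5)]))
        assert filter_off_by_two(t) == set()

    def test_position_delta_over_ten_keeps(self):
        t = as_dict(tally(self.A, [(1000, 100)]), tally(self.B, [(1012, 5)]))
        assert filter_off_by_two(t) == set()

    def test_position_delta_exactly_ten_removes(self):
        t = as_dict(tally(self.A, [(1000, 100)]), tally(self.B, [(1010, 5)]))
        assert filter_off_by_two(t) == {self.B}

    def test_equal_abundance_keeps_both(self):
        t = as_dict(tally(self.A, [(1000, 5)]), tally(self.B, [(1005, 5)]))
        assert filter_off_by_two(t) == set()


class TestBuildPool:
    def test_clean_tallies_all_kept(self, rng):
        from tdnaseq.simulate import make_barcodes

        barcodes = make_barcodes(rng, 50)
        t = as_dict(
            *(
                tally(bc, [(int(i * 1000), 10)])
                for i, bc in enumerate(barcodes)
            )
        )
        entries, report = build_pool(t)
        assert len(entries) == 50
        assert set(report.counts) == {"kept"}

    def test_one_artifact_of_each_class_removed_with_correct_label(self):
        clean = tally("AAAAACCCCCGGGGGTTTTT", [(1000, 200)])
        ob1 = tally("AAAAACCCCCGGGGTTTTTT", [(1000, 2)])
        pe = tally("CCCCCAAAAATTTTTGGGGG", [(5000, 1)], pe_left=10)
        amb = tally("GGGGGTTTTTAAAAACCCCC", [(9000, 2)], ambiguous=8)
        multi = tally("TTTTTAAAAACCCCCGGGGG", [(12000, 8), (20000, 2)])
        ob2 = tally("AAAAACCCCCGGGGGAAAAT", [(1005, 50)])
        t = as_dict(clean, ob1, pe, amb, multi, ob2)
        entries, report = build_pool(t)
        assert [e.barcode for e in entries] == [clean.barcode]
        assert report.assignments == {
            clean.barcode: "kept",
            ob1.barcode: "off_by_one",
            pe.barcode: "past_end_head_to_tail",
            amb.barcode: "ambiguous",
            multi.barcode: "multilocus",
            ob2.barcode: "off_by_two",
        }

    def test_cascade_order_labels_off_by_one_before_off_by_two(self):
        parent = tally("AAAAACCCCCGGGGGTTTTT", [(1000, 500)])
        child = tally("AAAAACCCCCGGGGTTTTTT", [(1000, 3)])
        _, report = build_pool(as_dict(parent, child))
        assert report.assignments[child.barcode] == "off_by_one"

    def test_statuses_partition_barcodes(self, rng):
        t = _random_tallies(rng, n=300)
        entries, report = build_pool(t)
        assert set(report.assignments) == set(t)
        kept = {e.barcode for e in entries}
        removed = {bc for bc, s in report.assignments.items() if s != "kept"}
        assert kept | removed == set(t) and not (kept & removed)

    def test_filters_idempotent_on_kept_set(self, rng):
        t = _random_tallies(rng, n=300)
        entries, _ = build_pool(t)
        kept = {e.barcode: t[e.barcode] for e in entries}
        entries2, report2 = build_pool(kept)
        assert {e.barcode for e in entries2} == set(kept)
        assert set(report2.counts) == {"kept"}


def _random_tallies(rng, n=300):
    """Random tallies with all artifact flavours present."""
    from tdnaseq.simulate import make_barcodes

    barcodes = make_barcodes(rng, n)
    tallies = {}
    for i, bc in enumerate(barcodes):
        reads = int(rng.integers(1, 40))
        if rng.random() < 0.05:
            reads = int(rng.integers(200, 2000))
        pos = int(rng.integers(0, 200_000))
        locs = [(pos, reads)]
        if rng.random() < 0.08:
            locs.append((int(rng.integers(0, 200_000)), int(rng.integers(1, reads + 1))))
        kwargs = {}
        if rng.random() < 0.08:
            kwargs["pe_left"] = int(rng.integers(1, 10 * reads))
        if rng.random() < 0.08:
            kwargs["ambiguous"] = int(rng.integers(1, 2 * reads))
        tallies[bc] = tally(bc, locs, **kwargs)
        if rng.random() < 0.05:
            variant = bc[:-1] + ("A" if bc[-1] != "A" else "C")
            if variant not in tallies:
                tallies[variant] = tally(variant, [(pos + int(rng.integers(0, 12)), max(1, reads // int(rng.integers(50, 200))))])
    return tallies
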