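"""TnSeq read parsing, mapping and per-barcode evidence aggregation.

A TnSeq read spans the T-DNA border into flanking genomic DNA. Parsing
extracts the barcode (between its fixed flanks) and the genomic
fragment (after the T-DNA end, whose last ``border_trim`` bases are
variably retained in the insertion and are therefore treated as
optional). Mapping classifies each read as genomic, past-end
(concatemer/vector evidence) or ambiguous; aggregation tallies the
evidence per barcode for the pool-building filters.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Iterator

from .align import FragmentAlignment, ReferenceIndex, align_fragment
from .models import TDNAReadModel

logger = logging.getLogger(__name__)

PASTEND_CALLS = {
    "left_border": "past_end_left_border",
    "right_border": "past_end_right_border",
    "vector": "past_end_vector",
}

# search window for a barcode whose length falls outside the accepted
# range (such reads are reported, not silently dropped)
_LEN_SCAN_MARGIN = 7


@dataclass
class ParsedTnSeqRead:
    read_id: str
    barcode: str | None
    fragment: str | None
    status: str  # ok | no_barcode | bad_barcode_length | short_fragment


@dataclass
class ReadMapping:
    read_id: str
    barcode: str
    call: str  # genomic | past_end_* | ambiguous | unmapped
    scaffold: str | None = None
    position: int | None = None
    strand: str | None = None


def _mismatches(a: str, b: str, limit: int) -> int:
    """Mismatch count between equal-length strings, capped at limit+1."""
    n = 0
    for x, y in zip(a, b):
        if x != y:
            n += 1
            if n > limit:
                return n
    return n


def _find_approx(seq: str, pattern: str, start: int, max_mismatch: int) -> int:
    """Leftmost position >= start where pattern matches with <= max_mismatch."""
    m = len(pattern)
    for i in range(start, len(seq) - m + 1):
        if _mismatches(seq[i : i + m], pattern, max_mismatch) <= max_mismatch:
            return i
    return -1


def parse_tnseq_read(
    read_id: str,
    seq: str,
    model: TDNAReadModel,
    max_mismatch: int = 2,
    min_fragment: int = 15,
) -> ParsedTnSeqRead:
    """Extract barcode and genomic fragment from one TnSeq read.

    The barcode flanks and the required part of the T-DNA end may each
    mismatch at up to ``max_mismatch`` positions (no indels). After the
    required T-DNA anchor, bases matching the optional border
    continuation are stripped greedily, so the fragment starts at the
    first base that departs from the border sequence.
    """
    pre = model.flank_pre
    pre_at = _find_approx(seq, pre, 0, max_mismatch)
    if pre_at < 0:
        return ParsedTnSeqRead(read_id, None, None, "no_barcode")
    bc_start = pre_at + len(pre)

    post = model.flank_post
    lo, hi = model.barcode_len_min, model.barcode_len_max
    best_len, best_mm = None, max_mismatch + 1
    for length in range(max(1, lo - _LEN_SCAN_MARGIN), hi + _LEN_SCAN_MARGIN + 1):
        j = bc_start + length
        if j + len(post) > len(seq):
            break
        mm = _mismatches(seq[j : j + len(post)], post, max_mismatch)
        if mm < best_mm or (
            mm == best_mm
            and best_len is not None
            and abs(length - 20) < abs(best_len - 20)
        ):
            best_mm, best_len = mm, length
    if best_len is None or best_mm > max_mismatch:
        return ParsedTnSeqRead(read_id, None, None, "no_barcode")
    if not (lo <= best_len <= hi):
        return ParsedTnSeqRead(read_id, None, None, "bad_barcode_length")
    barcode = seq[bc_start : bc_start + best_len]

    anchor = model.tdna_end_required
    post_end = bc_start + best_len + len(post)
    anchor_at = _find_approx(seq, anchor, post_end, max_mismatch)
    if anchor_at < 0:
        return ParsedTnSeqRead(read_id, barcode, None, "short_fragment")
    frag_start = anchor_at + len(anchor)
    # greedy strip of the variably retained border end
    optional = model.tdna_end_optional
    stripped = 0
    while (
        stripped < len(optional)
        and frag_start < len(seq)
        and seq[frag_start] == optional[stripped]
    ):
        frag_start += 1
        stripped += 1
    fragment = seq[frag_start:]
    if len(fragment) < min_fragment:
        return ParsedTnSeqRead(read_id, barcode, fragment, "short_fragment")
    return ParsedTnSeqRead(read_id, barcode, fragment, "ok")


def classify_read(
    parsed: ParsedTnSeqRead, alignment: FragmentAlignment
) -> ReadMapping:
    """Turn a parsed read's alignment evidence into a single mapping call.

    Past-end evidence wins only when it strictly outscores the best
    genomic hit; tied best genomic hits are ambiguous; a unique genomic
    best yields a genomic call at the junction coordinate.
    """
    assert parsed.status == "ok" and parsed.barcode is not None
    best_gen = alignment.best_genomic
    best_pe = alignment.best_pastend
    gen_score = best_gen.score if best_gen else 0
    pe_score = best_pe.score if best_pe else 0
    if best_pe is not None and pe_score > gen_score:
        call = PASTEND_CALLS.get(best_pe.ref_name, "past_end_vector")
        return ReadMapping(parsed.read_id, parsed.barcode, call)
    if best_gen is None:
        return ReadMapping(parsed.read_id, parsed.barcode, "unmapped")
    if not alignment.genomic_unique:
        return ReadMapping(parsed.read_id, parsed.barcode, "ambiguous")
    return ReadMapping(
        parsed.read_id,
        parsed.barcode,
        "genomic",
        scaffold=best_gen.ref_name,
        position=best_gen.junction,
        strand=best_gen.strand,
    )


def map_tnseq_reads(
    reads: Iterable[tuple[str, str]],
    model: TDNAReadModel,
    genome: dict[str, str],
    max_mismatch: int = 2,
    min_fragment: int = 15,
    min_score: int = 15,
    seed_k: int = 15,
) -> tuple[list[ReadMapping], Counter]:
    """Parse and map a stream of (read_id, sequence) TnSeq reads.

    Returns the mappings for ok-status reads and a Counter of parse
    statuses (conservation: every read lands in exactly one bucket).
    """
    logger.info(
        "mapping parameters: max_mismatch=%d min_fragment=%d min_score=%d k=%d",
        max_mismatch, min_fragment, min_score, seed_k,
    )
    genome_index = ReferenceIndex(genome, k=seed_k)
    pastend_refs = model.pastend_references()
    pastend_index = ReferenceIndex(pastend_refs, k=seed_k) if pastend_refs else None
    stats: Counter = Counter()
    mappings: list[ReadMapping] = []
    for read_id, seq in reads:
        parsed = parse_tnseq_read(
            read_id, seq, model, max_mismatch=max_mismatch, min_fragment=min_fragment
        )
        stats[parsed.status] += 1
        if parsed.status != "ok":
            continue
        alignment = align_fragment(
            parsed.fragment, genome_index, pastend_index, min_score=min_score
        )
        mappings.append(classify_read(parsed, alignment))
    logger.info("parsed %d reads: %s", sum(stats.values()), dict(stats))
    return mappings, stats


# ---------------------------------------------------------------------------
# Aggregation


@dataclass
class Location:
    scaffold: str
    position: int
    strand: str
    n_reads: int


@dataclass
class BarcodeTally:
    """Per-barcode evidence: read counts by mapping outcome and location."""

    barcode: str
    locations: list[Location] = field(default_factory=list)
    n_pastend_left: int = 0
    n_pastend_right: int = 0
    n_pastend_vector: int = 0
    n_ambiguous: int = 0
    n_unmapped: int = 0

    @property
    def n_genomic(self) -> int:
        return sum(loc.n_reads for loc in self.locations)

    @property
    def n_pastend(self) -> int:
        return self.n_pastend_left + self.n_pastend_right + self.n_pastend_vector

    @property
    def total_reads(self) -> int:
        return self.n_genomic + self.n_pastend + self.n_ambiguous + self.n_unmapped

    @property
    def mode_location(self) -> Location | None:
        return self.locations[0] if self.locations else None


def _merge_positions(
    positions: Counter, merge_tolerance: int
) -> list[tuple[int, int]]:
    """Cluster nearby junction coordinates to their most frequent value.

    Positions are assigned, in decreasing order of read support, either
    to an existing cluster centre within ``merge_tolerance`` bases or as
    a new centre; the centre is the majority coordinate.
    """
    centres: list[tuple[int, int]] = []  # (centre, reads)
    for pos, n in sorted(positions.items(), key=lambda kv: (-kv[1], kv[0])):
        placed = False
        for i, (centre, total) in enumerate(centres):
            if abs(pos - centre) <= merge_tolerance:
                centres[i] = (centre, total + n)
                placed = True
                break
        if not placed:
            centres.append((pos, n))
    return centres


def aggregate_barcode_evidence(
    mappings: Iterable[ReadMapping], merge_tolerance: int = 3
) -> dict[str, BarcodeTally]:
    """Tabulate reads per barcode: genomic locations, past-end, ambiguous.

    Genomic locations on the same scaffold and strand within
    ``merge_tolerance`` bases are merged to the most frequent
    coordinate. Location lists are sorted by decreasing read support
    (ties to the smaller coordinate) so ``locations[0]`` is the mode.
    """
    per_barcode_positions: dict[str, Counter] = {}
    tallies: dict[str, BarcodeTally] = {}
    for m in mappings:
        tally = tallies.setdefault(m.barcode, BarcodeTally(m.barcode))
        if m.call == "genomic":
            per_barcode_positions.setdefault(m.barcode, Counter())[
                (m.scaffold, m.strand, m.position)
            ] += 1
        elif m.call == "past_end_left_border":
            tally.n_pastend_left += 1
        elif m.call == "past_end_right_border":
            tally.n_pastend_right += 1
        elif m.call == "past_end_vector":
            tally.n_pastend_vector += 1
        elif m.call == "ambiguous":
            tally.n_ambiguous += 1
        else:
            tally.n_unmapped += 1
    for barcode, counter in per_barcode_positions.items():
        by_scaffold_strand: dict[tuple[str, str], Counter] = {}
        for (scaffold, strand, pos), n in counter.items():
            by_scaffold_strand.setdefault((scaffold, strand), Counter())[pos] += n
        locations: list[Location] = []
        for (scaffold, strand), positions in by_scaffold_strand.items():
            for centre, total in _merge_positions(positions, merge_tolerance):
                locations.append(Location(scaffold, centre, strand, total))
        locations.sort(key=lambda l: (-l.n_reads, l.scaffold, l.position))
        tallies[barcode].locations = locations
    return tallies


def iter_parsed_ok(
    reads: Iterable[tuple[str, str]], model: TDNAReadModel, **kwargs
) -> Iterator[ParsedTnSeqRead]:
    for read_id, seq in reads:
        parsed = parse_tnseq_read(read_id, seq, model, **kwargs)
        if parsed.status == "ok":
            yield parsed
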