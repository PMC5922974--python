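"""Exact-seed, ungapped-extension alignment of short genomic fragments.

Desk-scale genomes do not need an external aligner: fragments are
located with a k-mer seed index (default k=15) and extended without
gaps, scoring +1 per match and -1 per mismatch with an X-drop cutoff.
An external aligner can be plugged in by supplying hits in the same
``Hit`` form to the classification layer.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Hit:
    """One ungapped alignment of a query fragment to a reference."""

    ref_name: str
    strand: str  # strand of the query relative to the reference
    ref_start: int
    ref_end: int
    q_start: int  # in original query orientation
    q_end: int
    score: int

    @property
    def junction(self) -> int:
        """Reference coordinate of the first aligned base in read order.

        For a fragment that starts at a T-DNA/genome junction this is
        the insertion position: the first genomic base after the border.
        """
        return self.ref_start if self.strand == "+" else self.ref_end - 1


class ReferenceIndex:
    """k-mer lookup over a set of named reference sequences."""

    def __init__(self, sequences: Mapping[str, str], k: int = 15) -> None:
        if not sequences or all(len(s) == 0 for s in sequences.values()):
            raise ValueError("reference set is empty")
        self.k = k
        self.sequences = {name: seq.upper() for name, seq in sequences.items()}
        index: dict[str, list[tuple[str, int]]] = {}
        for name, seq in self.sequences.items():
            for i in range(len(seq) - k + 1):
                kmer = seq[i : i + k]
                if "N" in kmer:
                    continue
                index.setdefault(kmer, []).append((name, i))
        self._index = index

    def lookup(self, kmer: str) -> list[tuple[str, int]]:
        return self._index.get(kmer, [])


def _extend(query: str, ref: str, q_pos: int, r_pos: int, k: int, xdrop: int = 8):
    """Extend an exact k-mer seed in both directions without gaps.

    Returns (score, q_start, q_end) of the best-scoring extension that
    contains the seed, maximising matches - mismatches.
    """
    # right extension from seed end
    score = k
    best_right, right_score = q_pos + k, score
    qi, ri = q_pos + k, r_pos + k
    s = score
    while qi < len(query) and ri < len(ref):
        s += 1 if query[qi] == ref[ri] else -1
        qi += 1
        ri += 1
        if s > right_score:
            right_score, best_right = s, qi
        if right_score - s > xdrop:
            break
    # left extension from seed start
    best_left, left_gain = q_pos, 0
    gain = 0
    qi, ri = q_pos - 1, r_pos - 1
    while qi >= 0 and ri >= 0:
        gain += 1 if query[qi] == ref[ri] else -1
        if gain > left_gain:
            left_gain, best_left = gain, qi
        if left_gain - gain > xdrop:
            break
        qi -= 1
        ri -= 1
    return right_score + left_gain, best_left, best_right


def find_hits(
    query: str, index: ReferenceIndex, min_score: int = 15, seed_step: int = 4
) -> list[Hit]:
    """All distinct ungapped hits for the query on both strands.

    Hits on the same (reference, strand, diagonal) are collapsed to the
    best-scoring extension. Coordinates are reported in the reference
    frame; q_start/q_end are in the original query orientation.
    """
    k = index.k
    hits: dict[tuple[str, str, int], Hit] = {}
    for strand in "+-":
        oriented = query if strand == "+" else revcomp(query)
        n = len(oriented)
        if n < k:
            continue
        seed_positions = list(range(0, n - k + 1, seed_step))
        if seed_positions[-1] != n - k:
            seed_positions.append(n - k)
        seen_diag: set[tuple[str, str, int]] = set()
        for q_pos in seed_positions:
            kmer = oriented[q_pos : q_pos + k]
            for ref_name, r_pos in index.lookup(kmer):
                diag = r_pos - q_pos
                key = (ref_name, strand, diag)
                if key in seen_diag:
                    continue
                seen_diag.add(key)
                ref = index.sequences[ref_name]
                score, q_a, q_b = _extend(oriented, ref, q_pos, r_pos, k)
                if score < min_score:
                    continue
                ref_start = q_a + diag
                ref_end = q_b + diag
                if strand == "+":
                    qs, qe = q_a, q_b
                else:
                    qs, qe = n - q_b, n - q_a
                hit = Hit(ref_name, strand, ref_start, ref_end, qs, qe, score)
                prev = hits.get(key)
                if prev is None or hit.score > prev.score:
                    hits[key] = hit
    out = list(hits.values())
    out.sort(key=lambda h: (-h.score, h.ref_name, h.strand, h.ref_start))
    return out


@dataclass
class FragmentAlignment:
    """Best genomic and past-end evidence for one fragment."""

    genomic_hits: list[Hit]
    pastend_hits: list[Hit]

    @property
    def best_genomic(self) -> Hit | None:
        return self.genomic_hits[0] if self.genomic_hits else None

    @property
    def best_pastend(self) -> Hit | None:
        return self.pastend_hits[0] if self.pastend_hits else None

    @property
    def genomic_unique(self) -> bool:
        """True when the best genomic score strictly beats the runner-up."""
        if not self.genomic_hits:
            return False
        if len(self.genomic_hits) == 1:
            return True
        return self.genomic_hits[0].score > self.genomic_hits[1].score


def align_fragment(
    fragment: str,
    genome_index: ReferenceIndex,
    pastend_index: ReferenceIndex | None = None,
    min_score: int = 15,
) -> FragmentAlignment:
    """Align a fragment against the genome and the T-DNA/vector references."""
    genomic = find_hits(fragment, genome_index, min_score=min_score)
    pastend = (
        find_hits(fragment, pastend_index, min_score=min_score)
        if pastend_index is not None
        else []
    )
    return FragmentAlignment(genomic_hits=genomic, pastend_hits=pastend)
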