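"""Barcode extraction and counting from BarSeq reads, plus library
diversity estimation.

BarSeq reads carry the barcode between two fixed priming sites, after
2-4 leading random bases. Counting is exact-match against the kept
pool barcodes by default (an optional distance-1 rescue exists for
recovering reads with a single sequencing error in the barcode);
extracted-but-unknown barcodes are tallied separately so reads are
conserved: pool-matched + unknown = extracted, and
extracted + unextracted = total.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .models import BarSeqReadModel, CountMatrix
from .pool import _within_distance_one


def _mismatches(a: str, b: str, limit: int) -> int:
    n = 0
    for x, y in zip(a, b):
        if x != y:
            n += 1
            if n > limit:
                return n
    return n


def extract_barcode(
    seq: str, model: BarSeqReadModel, max_mismatch: int = 1
) -> str | None:
    """Barcode from one BarSeq read, or None when the flanks are absent.

    Scans leading offsets in [offset_min, offset_max] for ``pre_seq``
    (allowing ``max_mismatch`` mismatches), then accepts the barcode
    length (within the model's range) whose following ``post_seq``
    matches best.
    """
    pre, post = model.pre_seq, model.post_seq
    for offset in range(model.offset_min, model.offset_max + 1):
        if offset + len(pre) > len(seq):
            break
        if _mismatches(seq[offset : offset + len(pre)], pre, max_mismatch) > max_mismatch:
            continue
        bc_start = offset + len(pre)
        best_len, best_mm = None, max_mismatch + 1
        for length in range(model.barcode_len_min, model.barcode_len_max + 1):
            j = bc_start + length
            if j + len(post) > len(seq):
                break
            mm = _mismatches(seq[j : j + len(post)], post, max_mismatch)
            if mm < best_mm:
                best_mm, best_len = mm, length
        if best_len is not None and best_mm <= max_mismatch:
            return seq[bc_start : bc_start + best_len]
    return None


def count_barcodes(
    reads: Iterable[tuple[str, str]],
    pool_barcodes: Iterable[str],
    model: BarSeqReadModel,
    sample_id: str,
    max_mismatch: int = 1,
    rescue_distance_one: bool = False,
) -> CountMatrix:
    """Count occurrences of pool barcodes in one BarSeq sample.

    Matching against the pool is exact by default; with
    ``rescue_distance_one`` an unknown barcode is assigned to a pool
    barcode at distance 1 when that assignment is unambiguous.
    """
    pool = list(dict.fromkeys(pool_barcodes))
    if not pool:
        raise ValueError("empty pool")
    pool_set = set(pool)
    counts: Counter = Counter()
    unknown = 0
    total = 0
    unknown_seqs: Counter = Counter()
    for _, seq in reads:
        total += 1
        bc = extract_barcode(seq, model, max_mismatch=max_mismatch)
        if bc is None:
            continue
        if bc in pool_set:
            counts[bc] += 1
        elif rescue_distance_one:
            unknown_seqs[bc] += 1
        else:
            unknown += 1
    if rescue_distance_one:
        for bc, n in unknown_seqs.items():
            matches = [p for p in pool if _within_distance_one(bc, p)]
            if len(matches) == 1:
                counts[matches[0]] += n
            else:
                unknown += n
    frame = pd.DataFrame({sample_id: [counts.get(bc, 0) for bc in pool]}, index=pool)
    return CountMatrix(
        frame,
        unknown_reads=pd.Series({sample_id: unknown}),
        total_reads=pd.Series({sample_id: total}),
    )


merge_counts = CountMatrix.merge


# ---------------------------------------------------------------------------
# Library diversity


@dataclass
class DiversityEstimate:
    """Poisson-sampling estimate of the number of distinct barcodes.

    Under Poisson sampling at mean depth lambda, the counts of barcodes
    seen once (n1) and twice (n2) satisfy n2/n1 = lambda/2, so
    lambda_hat = 2*n2/n1 and N_hat = n1 * exp(lambda_hat) / lambda_hat.
    When n2 = 0 the estimator is undefined and the observed number of
    distinct barcodes is reported as a lower bound.
    """

    n_observed: int
    n1: int
    n2: int
    lambda_hat: float | None
    n_total: float | None
    is_lower_bound: bool


def estimate_pool_diversity(counts: Iterable[int]) -> DiversityEstimate:
    """Estimate true pool size from the barcode count histogram."""
    arr = np.asarray([c for c in counts if c > 0], dtype=np.int64)
    n_observed = int(arr.size)
    n1 = int((arr == 1).sum())
    n2 = int((arr == 2).sum())
    if n1 == 0:
        raise ValueError("diversity estimator needs at least one singleton barcode")
    if n2 == 0:
        return DiversityEstimate(n_observed, n1, n2, None, None, True)
    lam = 2.0 * n2 / n1
    n_total = n1 * math.exp(lam) / lam
    return DiversityEstimate(n_observed, n1, n2, lam, n_total, False)
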