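# Methods

`tdnaseq` analyses pooled libraries of randomly barcoded T-DNA
insertion mutants (RB-TDNAseq): insertions delivered by
*Agrobacterium*-mediated transformation, each tagged by a random 17–23
bp barcode that is first mapped to its genomic junction (TnSeq-style
reads) and thereafter counted by short amplicon sequencing (BarSeq) to
track strain abundance through competitive growth or physical
fractionation experiments. This note records the models, estimators,
defaults and numerical choices the implementation commits to, and what
the synthetic-data tests do and do not establish about real data.

## Coordinates and the insertion position convention

All intervals are 0-based half-open internally; GFF3 (1-based
inclusive) is converted at the I/O boundary and the conversion is an
exact bijection. An insertion's *position* is the genomic coordinate of
the first genomic base at the T-DNA junction in the read's orientation
(for minus-strand mappings this is the highest aligned coordinate).
The T-DNA border retained in an insertion is variable in length, so the
last `border_trim` (default 10) bases of the T-DNA end are treated as
optional when parsing reads. A consequence worth stating plainly: when
the genome immediately downstream of a junction happens to continue the
border sequence (probability ~1/4 per base), the junction coordinate is
ambiguous *in principle* — no mapper can place it exactly, and recorded
positions can shift by a few bases (geometrically distributed; ~25%
shift by ≥1, ~0.4% by ≥4). Downstream steps are insensitive to shifts
of this size because nearby junction calls are merged (below), and the
pool-recovery benchmark scores a site as correct within the 3 bp merge
tolerance for the same reason.

## TnSeq read parsing and alignment

A read is expected to contain `flank_pre` + barcode + `flank_post` +
T-DNA end + genomic fragment. Flanks and the required part of the
T-DNA end may each mismatch at up to 2 positions (no indels); barcodes
of 17–23 bp are accepted, lengths outside the range are reported as
`bad_barcode_length` rather than silently dropped. After the required
T-DNA anchor, bases matching the optional border continuation are
stripped greedily so the fragment starts at the first base departing
from the border.

Fragments are aligned with an exact-seed (k = 15, seeds every 4 bases
plus the final position), ungapped-extension aligner (+1 match, −1
mismatch, X-drop 8), against the genome on both strands and against the
past-end references (left/right T-DNA border, vector backbone).
Desk-scale genomes do not need an external aligner, and the hit model —
score, uniqueness of the best genomic hit, junction coordinate — is
exactly what classification needs; an external aligner can be plugged
in by supplying hits in the same form. Classification: past-end wins
only when it strictly outscores the best genomic hit; tied best genomic
scores are ambiguous; a unique best genomic hit yields a genomic call.
Defaults `min_fragment = 15` bases and `min_score = 15` (matches minus
mismatches) are configurable and logged; they are not taken from any
published protocol.

Per barcode, genomic junction calls on the same scaffold and strand
within `merge_tolerance = 3` bases are merged onto the most frequent
coordinate, assigning positions in decreasing order of read support.

## The filter cascade

Five rules run in a fixed order, each over the survivors of the
previous rule, with literal threshold readings (all configurable):

1. **off-by-one** — removed iff a barcode with ≥ 100× more reads sits
   at edit distance 1 (substitution or single indel — barcodes vary in
   length, so indels are included; a substitution-only mode exists).
2. **past-end** — flagged iff past-end reads strictly exceed 7× the
   genomic reads (computed over *all* past-end reads; the subtype —
   head-to-tail, head-to-head, run-on — follows the majority of the
   past-end evidence, ties broken in that fixed order and logged).
3. **ambiguous** — removed iff ambiguous reads are a strict majority
   (> 50%) of the barcode's reads.
4. **multilocus** — removed iff ≥ 20% of genomic reads map away from
   the modal location (inclusive at exactly 20%); not evaluated for
   barcodes with no genomic reads.
5. **off-by-two** — removed iff a strictly more abundant barcode maps
   within 10 bases on the same scaffold at Levenshtein distance < 5.

Levenshtein distance uses `edlib` when available with a pure-Python
dynamic-programming fallback. A surviving barcode with no genomic
location cannot be placed and is excluded from the pool (reported as
`unplaced`). The cascade is, by construction, the sequential
composition of the five single-rule operations; the test suite checks
this against an independently coded plain-loop oracle on random tallies
and on fixtures placed exactly at each threshold.

## Annotation, insertion bias and essentiality

Each kept insertion is assigned to the nearest gene (distance 0 if
inside the transcript span; equidistant ties go to the smaller gene id
and are logged) and one of six classes: 5′ intergenic, 5′ UTR, exon,
intron, 3′ UTR, 3′ intergenic, with the 5′/3′ sides reflected for
minus-strand genes and CDS-overlapping exon bases classed as exon.

For bias analysis every genomic base is assigned to exactly one class:
promoter and terminator are fixed strand-aware flanks of 500 bp
(configurable; the extent of these regions is a modelling choice, not a
measured quantity), truncated at neighbouring genes, with flank-vs-
flank conflicts resolved to the gene with the nearer transcript end and
gene-body overlaps to the earlier-starting gene. The partition property
(class base counts sum to the genome length) is tested. The
count-matched null resamples, for each class, the observed number of
insertions uniformly *without replacement* from that class's bases,
reproducibly under a seed. Local GC is computed over a centred 101-base
window (odd by construction, truncated at scaffold ends, N excluded
from the denominator).

Gene insertion density is kept insertions within the CDS span (start
codon to stop codon, introns included) per kb of that span; genes with
density strictly below 2 inserts/kb are essentiality candidates. The
histogram utility bins density at 1 insert/kb.

## BarSeq counting and library diversity

BarSeq reads carry 2–4 random leading bases, a fixed priming site, the
barcode, and a second priming site. Counting against the kept pool is
exact-match by default; an optional distance-1 rescue assigns an
unknown barcode to a pool barcode one edit away when unambiguous. Reads
are conserved at every stage (matched + unknown = extracted;
extracted + unextracted = total) and the conservation is asserted in
tests.

Library diversity is estimated from the counts of barcodes seen once
(n₁) and twice (n₂) under Poisson sampling: λ̂ = 2n₂/n₁ and
N̂ = n₁·e^λ̂/λ̂. With n₂ = 0 the estimator is undefined and the
observed distinct count is reported as a lower bound. The estimator is
noisy on a single sparse library (≈45% relative standard deviation at
N = 1000, λ = 0.1, where E[n₂] ≈ 4.5), so the recovery benchmarks pool
the count histogram over replicate simulated libraries and divide the
pooled estimate by the number of libraries; single-library estimates
should be treated as order-of-magnitude.

## Fitness model

For each biological replicate, a condition sample is compared with the
Time-0 sample from the starter culture that seeded it. Strains
(barcodes) with fewer than 3 Time-0 reads in that pairing are excluded.
Strain fitness is

    f = log2(C_condition + √P) − log2(C_time0 + 1/√P)

median-normalised to zero across all included strains — including
strains from intergenic insertions, which carry no gene but are real
members of the pool and anchor the median at "no effect". The
gene-specific pseudocount P is a two-pass scheme: pass 1 computes
preliminary gene fitness with P = 1; pass 2 sets
P = 2^F_prelim × (condition total / Time-0 total), floored at 0.1.
This keeps strains of genes with genuine effects from being shrunk
toward zero while damping low-count noise; the exact scheme is a
documented choice (only the existence of a gene-specific pseudocount is
dictated by the method's description) and is swappable.

Gene fitness F is the weighted mean of strain scores, weights the
harmonic mean of the two counts capped at 20 reads (capping limits the
influence of very abundant outlier strains); a zero count gives weight
zero, and a gene whose strains all have weight zero falls back to an
unweighted mean. The variance is

    var F = max(V_poisson, V_observed + V_global)

where V_poisson propagates per-strain count noise
(1/(1+C_cond) + 1/(1+C_t0))/ln²2 through the weighted mean, V_observed
is the weighted between-strain variance of the mean, and V_global is a
genome-wide dispersion estimated from the difference between
first-half and second-half-of-gene fitness values (scaled MAD converted
to a variance; fallback 0.01 when fewer than 5 genes have strains in
both halves; when insertion positions are unavailable the halves are
alternating strains). Adding V_global wholesale — it is an estimate on
the scale of half-gene fitness values, roughly twice the variance of a
full-gene mean — makes T = F/√var F deliberately conservative: a gene
whose few strains agree by chance cannot achieve an extreme T. The
practical consequence, visible in the calibration benchmark, is a null
T standard deviation around 0.5–0.7 rather than 1, which is what makes
|T| > 3 a conservative hit threshold.

Genes are reported only if, in at least one Time-0 sample, they have
≥ 30 total reads spread over ≥ 3 strains; the union of qualifying genes
across experiments is used everywhere, so a minority of reported genes
rest on 1–2 strains in a given experiment (their barcode count is
recorded, and the samples where they qualified are listed).

Replicates combine as F = mean(F_r) and T = ΣT_r/√N, treating
per-replicate T values as z-scores. Relative fitness between two
conditions and fraction enrichment (E = F_high − F_low, e.g. high- vs
low-lipid fractions from buoyancy or FACS separation) use the same
arithmetic: T = ΔF/√(var₁+var₂) with variances recovered as (F/T)².
That recovery is singular when F ≈ 0: with |T| moderate it
underestimates (division blow-up), and with T ≈ 0 it is a 0/0 ratio
that can wildly overestimate. Recovered variances are therefore clamped
to an empirical band — floored at the 10th and capped at the 95th
percentile of the experiment's nonzero (F/T)² values — restoring the
intended semantics on both sides of the singularity.

Hit rules are named predicates with recorded provenance: auxotrophy
(F < −1 in unsupplemented medium and T < −3 for the supplemented
contrast), consistent fitness (|T| > 3), and fraction enrichment
(|E| > 1 and |T| > 3).

Set enrichment is an upper-tail hypergeometric test per annotation term
(p = 1 by convention for empty terms) with Benjamini–Hochberg
correction. Clustering of score matrices uses 1 − Pearson r as the
distance with average linkage, or K-means on row-standardised scores
under a fixed seed; rows with missing values or zero variance are
dropped with a warning rather than imputed, for reproducibility.

## The synthetic-data generator

The generator is first-class, tested code and defines the conditions
under which the pipeline is validated. It emulates: a random genome
(one scaffold by default) with non-overlapping multi-exon genes on both
strands, UTRs, and one intergenic segment duplicated verbatim elsewhere
(the substrate for ambiguous mappings); a barcoded insertion pool with
distinct 17–23 bp barcodes (mode 20), positions uniform or
feature-biased, and designated essential genes receiving zero CDS
insertions by construction; TnSeq reads with per-insertion random
border truncation (0–10 bases), 0.5%/base substitution errors, and
injected artifact classes that mirror the filters' targets, some placed
just below each threshold so boundary behaviour is exercised; and
growth-simulated BarSeq counts in which each barcode's relative
abundance is multiplied by 2^f over the experiment (f is the gene's
true fitness, accumulated over ~7 doublings), with Dirichlet-perturbed
starting abundances per replicate, small lognormal growth noise
(sd 0.05 log2 units), and multinomial sampling at a mean depth of 50
reads per strain — the depth, replicate count (3) and generation count
the fitness benchmarks use throughout. All stages are deterministic
under a seed (integer RNG streams derived as (seed, stream index)) and
each stage emits a truth table sufficient to score the corresponding
pipeline step.

In the fitness benchmarks, 200 genes carry effects {−2, −1, 0, +1} in
equal numbers (50 each) with 10 barcodes per gene, plus 2000 intergenic
strains. Two properties of that design deserve a note. First, truth
values are heavily tied, which caps the achievable Spearman correlation
below 1 even for a perfect estimator (≈0.97 for the balanced mix;
skewed mixes cap substantially lower). Second, because 75% of
gene-bearing strains carry non-zero (net negative) effects, the median
strain is *not* exactly a null strain; the intergenic strains pull the
median back toward zero but a small positive bias (~+0.03 log2 units)
remains in null-gene fitness — a genuine property of median
normalisation under asymmetric effect loads, negligible in real
experiments where most genes are null.

What the synthetic data does **not** emulate: realistic Illumina error
profiles (quality-dependent, indels), PCR duplicates and amplification
bias beyond a single multiplier, multiplexing/index hopping, scaffold
fragmentation, repetitive genome content beyond one duplicated segment,
and batch effects between sequencing runs. Passing benchmarks therefore
establish the *estimators and filters* behave as specified under their
own model assumptions — not that any particular real library meets
those assumptions.

## Benchmark problem sizes

The repository's benchmarks (test suite and `scripts/acceptance.py`)
use: 1,000 random tallies for the cascade-equivalence oracle; 5,000
insertions on a 450 kb genome with ~8 reads/barcode (≈70k reads) for
end-to-end pool recovery; a 2 Mb genome with 1,000 genes (30 essential)
at 9 CDS inserts/kb for essentiality recovery; 200 genes × 10 barcodes
× 3 replicates at 50 reads/strain for fitness and enrichment recovery;
and Poisson libraries of N ∈ {10³, 10⁴} at λ ∈ {0.1, 0.3} (60 and 12
replicate libraries respectively) for the diversity estimator. These
sizes were chosen as the smallest at which the statistical criteria are
stable across seeds.
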