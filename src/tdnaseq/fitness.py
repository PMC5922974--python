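"""Pooled fitness estimation: strain and gene fitness, T-statistics,
replicate combination, relative-fitness and fraction-enrichment scores,
and hit calling.

For each biological replicate, every barcode with at least
``min_time0_count`` mean reads at Time 0 gets a strain fitness score

    f = log2(C_condition + sqrt(P)) - log2(C_time0 + 1/sqrt(P))

with a gene-specific pseudocount P, median-normalised to zero across
included strains. Gene fitness F is the weighted mean of its strains'
scores, weighted by the harmonic mean of the two counts capped at 20
reads. The variance of F is the maximum of a Poisson-noise propagation
and the observed between-strain spread plus a global variance term
(estimated from fitness differences between the first and second half
of each gene); T = F / sqrt(var F). Replicates combine as
F = mean(F_r) and T = sum(T_r) / sqrt(N).

The pseudocount is a two-pass scheme: a preliminary gene fitness with
P = 1 sets P = 2^F_prelim * (condition total / Time-0 total), floored
at 0.1, so that strains of genes with real fitness effects are not
shrunk toward zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .models import CountMatrix, ExperimentDesign

logger = logging.getLogger(__name__)

LOG2_SQ = np.log(2.0) ** 2


# ---------------------------------------------------------------------------
# Elementary operations


def strain_weight(c_time0, c_condition, cap: float = 20.0):
    """Harmonic-mean weight of the two counts, capped; zero if either is 0."""
    c0 = np.asarray(c_time0, dtype=float)
    c1 = np.asarray(c_condition, dtype=float)
    with np.errstate(divide="ignore"):
        w = np.where((c0 > 0) & (c1 > 0), 2.0 / (1.0 / np.maximum(c0, 1e-300) + 1.0 / np.maximum(c1, 1e-300)), 0.0)
    return np.minimum(w, cap)


def raw_strain_fitness(c_condition, c_time0, pseudocount):
    """log2(C_condition + sqrt(P)) - log2(C_time0 + 1/sqrt(P))."""
    p = np.asarray(pseudocount, dtype=float)
    if np.any(p <= 0):
        raise ValueError("pseudocounts must be positive")
    sq = np.sqrt(p)
    return np.log2(np.asarray(c_condition, float) + sq) - np.log2(
        np.asarray(c_time0, float) + 1.0 / sq
    )


def median_normalize(scores):
    """Shift scores so their median is exactly zero."""
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        return scores
    return scores - np.median(scores)


def gene_fitness(scores, weights) -> float:
    """Weighted mean of strain scores (equal weights if all weights are 0)."""
    scores = np.asarray(scores, float)
    weights = np.asarray(weights, float)
    total = weights.sum()
    if total <= 0:
        return float(np.mean(scores))
    return float(np.dot(scores, weights) / total)


def poisson_strain_variance(c_condition, c_time0):
    """Per-strain count-noise variance propagated through the log2 ratio."""
    c0 = np.asarray(c_time0, float)
    c1 = np.asarray(c_condition, float)
    return (1.0 / (1.0 + c1) + 1.0 / (1.0 + c0)) / LOG2_SQ


def gene_variance_and_T(
    scores, weights, c_condition, c_time0, global_var: float
) -> tuple[float, float]:
    """Variance of gene fitness and the T-statistic.

    var F = max(V_poisson, V_observed + global_var), where V_poisson
    propagates Poisson count noise through the weighted mean,
    V_observed is the weighted between-strain spread of the mean, and
    global_var is the genome-wide dispersion of gene scores estimated
    from half-gene comparisons. Adding the global term wholesale makes
    the statistic deliberately conservative for genes whose strains
    agree by chance. T is undefined (NaN) when the variance is zero.
    """
    scores = np.asarray(scores, float)
    weights = np.asarray(weights, float)
    n = scores.size
    F = gene_fitness(scores, weights)
    w = weights if weights.sum() > 0 else np.ones(n)
    wsum = w.sum()
    v_strain = poisson_strain_variance(c_condition, c_time0)
    v_poisson = float(np.dot(w**2, v_strain) / wsum**2)
    if n > 1:
        wvar = float(np.dot(w, (scores - F) ** 2) / wsum)
        v_observed = wvar / (n - 1)
    else:
        v_observed = 0.0
    var_f = max(v_poisson, v_observed + global_var)
    if var_f <= 0:
        return 0.0, float("nan")
    return var_f, F / np.sqrt(var_f)


def estimate_global_variance(strain_table: pd.DataFrame, fallback: float = 0.01) -> float:
    """Global gene-fitness variance from first-half/second-half splits.

    For each gene with strains in both halves (by position within the
    gene when available, else by alternating strains), the difference
    of the two half-gene fitness estimates is computed; the variance of
    a single gene estimate is then (scaled MAD of differences)^2 / 2.
    """
    diffs = []
    for _, grp in strain_table.groupby("gene_id", sort=False):
        if len(grp) < 2:
            continue
        if "insertion_frac" in grp.columns and grp["insertion_frac"].notna().all():
            first = grp[grp["insertion_frac"] < 0.5]
            second = grp[grp["insertion_frac"] >= 0.5]
        else:
            first, second = grp.iloc[0::2], grp.iloc[1::2]
        if len(first) == 0 or len(second) == 0:
            continue
        f1 = gene_fitness(first["f_strain"].to_numpy(), first["weight"].to_numpy())
        f2 = gene_fitness(second["f_strain"].to_numpy(), second["weight"].to_numpy())
        diffs.append(f1 - f2)
    if len(diffs) < 5:
        return fallback
    d = np.asarray(diffs)
    mad = np.median(np.abs(d - np.median(d)))
    return float((1.4826 * mad) ** 2 / 2.0)


def gene_inclusion_filter(
    time0_counts: pd.DataFrame,
    barcode_to_gene: pd.Series,
    min_total: float = 30.0,
    min_strains: int = 3,
) -> pd.DataFrame:
    """Genes with enough Time-0 coverage in at least one experiment.

    A gene is usable if, in any Time-0 sample, its barcodes carry at
    least ``min_total`` reads spread over at least ``min_strains``
    strains. Because the qualifying experiment can differ between
    genes, the union list is used everywhere; genes that pass only via
    the union rule in a given sample are flagged there.
    """
    genes = barcode_to_gene.reindex(time0_counts.index)
    rows = []
    for gene_id, idx in genes.groupby(genes).groups.items():
        sub = time0_counts.loc[idx]
        passing_samples = []
        for sample in sub.columns:
            col = sub[sample]
            if col.sum() >= min_total and int((col > 0).sum()) >= min_strains:
                passing_samples.append(sample)
        rows.append(
            {
                "gene_id": gene_id,
                "n_barcodes": len(idx),
                "usable": bool(passing_samples),
                "passing_samples": ",".join(passing_samples),
            }
        )
    return pd.DataFrame(rows).set_index("gene_id")


def combine_replicates(f_values, t_values) -> tuple[float, float]:
    """Average F across replicates; combine T as sum(T)/sqrt(N)."""
    f = np.asarray(f_values, float)
    t = np.asarray(t_values, float)
    if f.size == 0:
        raise ValueError("no replicates to combine")
    return float(f.mean()), float(np.nansum(t) / np.sqrt(t.size))


def relative_fitness(
    f1, t1, f2, t2, var_floor: float = 1e-4, var_cap: float | None = None
) -> tuple[float, float]:
    """Fitness difference between two conditions and its T-statistic.

    T = (F1 - F2) / sqrt(var1 + var2) with var recovered as (F/T)^2.
    The recovery is a 0/0 form when both F and T are near zero, so the
    recovered variance is clamped: floored against downward blow-ups of
    T (F ~ 0 with |T| moderate) and optionally capped against upward
    ones (F ~ 0 with T ~ 0, where the ratio is meaningless).
    """
    f1, t1, f2, t2 = (np.asarray(x, float) for x in (f1, t1, f2, t2))
    with np.errstate(divide="ignore", invalid="ignore"):
        v1 = np.where(np.abs(t1) > 0, (f1 / t1) ** 2, 0.0)
        v2 = np.where(np.abs(t2) > 0, (f2 / t2) ** 2, 0.0)
    v1 = np.maximum(np.nan_to_num(v1), var_floor)
    v2 = np.maximum(np.nan_to_num(v2), var_floor)
    if var_cap is not None:
        v1 = np.minimum(v1, var_cap)
        v2 = np.minimum(v2, var_cap)
    f_diff = f1 - f2
    return f_diff, f_diff / np.sqrt(v1 + v2)


def enrichment_scores(
    f_high, t_high, f_low, t_low, var_floor: float = 1e-4, var_cap: float | None = None
):
    """Enrichment E = F_high - F_low and its T-statistic.

    Identical arithmetic to relative fitness; positive E means the
    mutant is over-represented in the high fraction.
    """
    return relative_fitness(
        f_high, t_high, f_low, t_low, var_floor=var_floor, var_cap=var_cap
    )


def default_variance_floor(f, t, quantile: float = 0.10) -> float:
    """Floor for recovered variances: a low quantile of nonzero (F/T)^2."""
    return _variance_quantile(f, t, quantile, fallback=1e-4)


def default_variance_cap(f, t, quantile: float = 0.95) -> float:
    """Cap for recovered variances: a high quantile of nonzero (F/T)^2."""
    return _variance_quantile(f, t, quantile, fallback=np.inf)


def _variance_quantile(f, t, quantile: float, fallback: float) -> float:
    f = np.asarray(f, float)
    t = np.asarray(t, float)
    with np.errstate(divide="ignore", invalid="ignore"):
        v = (f / t) ** 2
    v = v[np.isfinite(v) & (v > 0)]
    if v.size == 0:
        return fallback
    return float(np.quantile(v, quantile))


# ---------------------------------------------------------------------------
# Hit rules


def call_hits(table: pd.DataFrame, rule: "HitRule") -> pd.DataFrame:
    """Apply a named threshold rule, recording its provenance."""
    missing = [c for c in rule.columns if c not in table.columns]
    if missing:
        raise KeyError(f"hit rule {rule.name!r} needs missing columns: {missing}")
    out = table.copy()
    out["hit"] = rule.predicate(table)
    out.attrs["hit_rule"] = rule.describe()
    return out


@dataclass
class HitRule:
    name: str
    columns: tuple[str, ...]
    predicate: "callable"
    description: str = ""

    def describe(self) -> str:
        return self.description or self.name


def auxotrophy_rule(
    f_col: str = "F_condition",
    t_diff_col: str = "T_diff",
    f_max: float = -1.0,
    t_max: float = -3.0,
) -> HitRule:
    """Fitness defect without supplement and consistent rescue with it."""
    return HitRule(
        name="auxotrophy",
        columns=(f_col, t_diff_col),
        predicate=lambda df: (df[f_col] < f_max) & (df[t_diff_col] < t_max),
        description=f"{f_col} < {f_max} and {t_diff_col} < {t_max}",
    )


def consistent_fitness_rule(t_col: str = "T", threshold: float = 3.0) -> HitRule:
    """Conservative |T| threshold for reliable fitness scores."""
    return HitRule(
        name="consistent_fitness",
        columns=(t_col,),
        predicate=lambda df: df[t_col].abs() > threshold,
        description=f"|{t_col}| > {threshold}",
    )


def enrichment_rule(
    e_col: str = "E", t_col: str = "T_E", e_threshold: float = 1.0, t_threshold: float = 3.0
) -> HitRule:
    """Consistently altered fraction enrichment: |E| > 1 and |T| > 3."""
    return HitRule(
        name="enrichment",
        columns=(e_col, t_col),
        predicate=lambda df: (df[e_col].abs() > e_threshold)
        & (df[t_col].abs() > t_threshold),
        description=f"|{e_col}| > {e_threshold} and |{t_col}| > {t_threshold}",
    )


# ---------------------------------------------------------------------------
# Pipeline


@dataclass
class FitnessParams:
    min_time0_count: float = 3.0
    weight_cap: float = 20.0
    pseudocount_floor: float = 0.1
    gene_min_total: float = 30.0
    gene_min_strains: int = 3
    global_var_fallback: float = 0.01


@dataclass
class PairResult:
    """Strain and gene tables for one condition/Time-0 pairing."""

    condition_sample: str
    time0_sample: str
    replicate_id: str
    condition_label: str
    strains: pd.DataFrame
    genes: pd.DataFrame
    global_var: float


@dataclass
class FitnessResults:
    """Fitness analysis output: per-pairing and per-condition tables."""

    pairs: list[PairResult]
    gene_info: pd.DataFrame
    combined: pd.DataFrame = field(default_factory=pd.DataFrame)

    def condition_table(self, condition_label: str) -> pd.DataFrame:
        mask = self.combined["condition_label"] == condition_label
        return self.combined[mask].set_index("gene_id")


def fit_pair(
    c_condition: pd.Series,
    c_time0: pd.Series,
    strain_info: pd.DataFrame,
    params: FitnessParams = FitnessParams(),
) -> tuple[pd.DataFrame, pd.DataFrame, float]:
    """Strain and gene fitness for one condition sample vs its Time 0.

    ``strain_info`` is indexed by barcode with columns ``gene_id`` and
    optionally ``insertion_frac`` (position within the gene, used for
    the first/second-half global variance estimate).
    """
    barcodes = strain_info.index.intersection(c_condition.index).intersection(
        c_time0.index
    )
    info = strain_info.loc[barcodes]
    c1 = c_condition.loc[barcodes].astype(float)
    c0 = c_time0.loc[barcodes].astype(float)
    included = c0 >= params.min_time0_count
    if not included.any():
        logger.warning("no strains pass the Time-0 filter")
        empty = pd.DataFrame()
        return empty, empty, params.global_var_fallback

    inc = included[included].index
    c1i, c0i = c1.loc[inc], c0.loc[inc]
    genes_i = info.loc[inc, "gene_id"]
    w = pd.Series(strain_weight(c0i, c1i, cap=params.weight_cap), index=inc)

    # pass 1: preliminary gene fitness with P = 1
    f_raw = pd.Series(raw_strain_fitness(c1i, c0i, 1.0), index=inc)
    f1 = pd.Series(median_normalize(f_raw), index=inc)
    prelim = {
        g: gene_fitness(f1.loc[idx], w.loc[idx])
        for g, idx in f1.groupby(genes_i).groups.items()
    }
    # pass 2: gene-specific pseudocount (strains outside genes keep P = 1)
    depth_ratio = c1i.sum() / max(c0i.sum(), 1.0)
    p_gene = {
        g: max(params.pseudocount_floor, (2.0**fg) * depth_ratio)
        for g, fg in prelim.items()
    }
    p = genes_i.map(p_gene).astype(float).fillna(1.0)
    f_raw2 = pd.Series(raw_strain_fitness(c1i, c0i, p), index=inc)
    f_strain = pd.Series(median_normalize(f_raw2), index=inc)

    strains = pd.DataFrame(
        {
            "barcode": inc,
            "gene_id": genes_i.to_numpy(),
            "c_condition": c1i.to_numpy(),
            "c_time0": c0i.to_numpy(),
            "pseudocount": p.to_numpy(),
            "f_strain": f_strain.to_numpy(),
            "weight": w.to_numpy(),
        }
    )
    if "insertion_frac" in info.columns:
        strains["insertion_frac"] = info.loc[inc, "insertion_frac"].to_numpy()
    global_var = estimate_global_variance(
        strains, fallback=params.global_var_fallback
    )

    gene_rows = []
    for gene_id, grp in strains.groupby("gene_id", sort=True):
        scores = grp["f_strain"].to_numpy()
        weights = grp["weight"].to_numpy()
        F = gene_fitness(scores, weights)
        var_f, t = gene_variance_and_T(
            scores,
            weights,
            grp["c_condition"].to_numpy(),
            grp["c_time0"].to_numpy(),
            global_var,
        )
        gene_rows.append(
            {
                "gene_id": gene_id,
                "F": F,
                "varF": var_f,
                "T": t,
                "n_strains": len(grp),
            }
        )
    genes = pd.DataFrame(gene_rows).set_index("gene_id")
    return strains, genes, global_var


def run_fitness_pipeline(
    counts: CountMatrix,
    design: ExperimentDesign,
    strain_info: pd.DataFrame,
    params: FitnessParams = FitnessParams(),
) -> FitnessResults:
    """Full fitness analysis over all condition/Time-0 pairings.

    ``strain_info``: index barcode, columns ``gene_id`` and optional
    ``insertion_frac``. Strains with no gene assignment (intergenic
    insertions) still contribute to the median normalisation — they are
    real members of the sequenced pool — but not to any gene's score.
    Gene usability is decided by the 30-reads/3-strains Time-0 rule in
    ANY experiment (union rule); the combined table contains usable
    genes only, with F averaged and T summed / sqrt(N) across
    replicates of each condition.
    """
    genic = strain_info[strain_info["gene_id"].notna()]
    t0_samples = [s for s in design.time0_samples() if s in counts.samples]
    t0_counts = counts.counts.loc[
        counts.counts.index.intersection(genic.index), t0_samples
    ]
    gene_info = gene_inclusion_filter(
        t0_counts,
        genic["gene_id"],
        min_total=params.gene_min_total,
        min_strains=params.gene_min_strains,
    )
    usable = set(gene_info.index[gene_info["usable"]])

    pairs: list[PairResult] = []
    for cond_sample, t0_sample, replicate, label in design.pairs():
        strains, genes, gv = fit_pair(
            counts.counts[cond_sample],
            counts.counts[t0_sample],
            strain_info,
            params,
        )
        pairs.append(
            PairResult(cond_sample, t0_sample, replicate, label, strains, genes, gv)
        )

    combined_rows = []
    labels = sorted({p.condition_label for p in pairs})
    for label in labels:
        members = [p for p in pairs if p.condition_label == label]
        gene_ids = sorted(
            set().union(*(set(p.genes.index) for p in members)) & usable
        )
        for gene_id in gene_ids:
            fs, ts, ns = [], [], []
            for p in members:
                if gene_id in p.genes.index:
                    fs.append(p.genes.loc[gene_id, "F"])
                    ts.append(p.genes.loc[gene_id, "T"])
                    ns.append(p.genes.loc[gene_id, "n_strains"])
            F, T = combine_replicates(fs, ts)
            combined_rows.append(
                {
                    "gene_id": gene_id,
                    "condition_label": label,
                    "F": F,
                    "T": T,
                    "n_replicates": len(fs),
                    "n_strains_max": int(max(ns)),
                    "n_barcodes": int(gene_info.loc[gene_id, "n_barcodes"]),
                }
            )
    combined = pd.DataFrame(
        combined_rows,
        columns=[
            "gene_id",
            "condition_label",
            "F",
            "T",
            "n_replicates",
            "n_strains_max",
            "n_barcodes",
        ],
    )
    return FitnessResults(pairs=pairs, gene_info=gene_info, combined=combined)
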