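"""Set enrichment (hypergeometric + Benjamini-Hochberg) and clustering
of score matrices.

The enrichment test asks, for each annotation term, whether the term is
over-represented in a hit set relative to the gene universe:
p = P(X >= observed overlap) under the hypergeometric distribution.
Clustering uses Pearson correlation as similarity (distance 1 - r) with
average linkage, or K-means on row-standardised scores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import hypergeom
from sklearn.cluster import KMeans
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


def hypergeom_pvalue(n_universe: int, n_term: int, n_hits: int, n_overlap: int) -> float:
    """Upper-tail hypergeometric p-value P(X >= n_overlap).

    A term with no genes in the universe (or an overlap of zero with an
    empty term) has p = 1 by convention.
    """
    if n_term == 0 or n_hits == 0:
        return 1.0
    return float(hypergeom.sf(n_overlap - 1, n_universe, n_term, n_hits))


def hypergeom_enrichment(
    hit_set: Iterable[str],
    gene_universe: Iterable[str],
    term_to_genes: Mapping[str, Iterable[str]],
) -> pd.DataFrame:
    """Per-term enrichment of a hit set within a gene universe.

    Terms are restricted to universe genes; p-values are upper-tail
    hypergeometric and q-values are Benjamini-Hochberg adjusted.
    """
    universe = set(gene_universe)
    hits = set(hit_set) & universe
    if set(hit_set) - universe:
        raise ValueError("hit set contains genes outside the universe")
    if not hits:
        return pd.DataFrame(
            columns=["term", "n_term", "n_overlap", "p_value", "q_value"]
        )
    rows = []
    for term in sorted(term_to_genes):
        term_genes = set(term_to_genes[term]) & universe
        overlap = term_genes & hits
        p = hypergeom_pvalue(len(universe), len(term_genes), len(hits), len(overlap))
        rows.append(
            {
                "term": term,
                "n_term": len(term_genes),
                "n_overlap": len(overlap),
                "p_value": p,
            }
        )
    df = pd.DataFrame(rows)
    df["q_value"] = bh_adjust(df["p_value"].to_numpy())
    return df


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Clustering


@dataclass
class ClusterResult:
    """Assignment (and, for hierarchical mode, the linkage tree)."""

    labels: pd.Series
    linkage_matrix: np.ndarray | None
    dropped: list[str]


def _clean_matrix(matrix: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    complete = matrix.dropna(axis=0)
    variable = complete.loc[complete.std(axis=1) > 0]
    dropped = sorted(set(matrix.index) - set(variable.index))
    if dropped:
        logger.warning(
            "dropping %d rows with missing values or zero variance", len(dropped)
        )
    return variable, dropped


def pearson_distance_matrix(matrix: pd.DataFrame) -> np.ndarray:
    """Condensed distance 1 - Pearson r between rows."""
    r = np.corrcoef(matrix.to_numpy())
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, 2.0)
    return squareform(d, checks=False)


def cluster_scores(
    matrix: pd.DataFrame,
    mode: str = "hierarchical",
    k: int | None = None,
    seed: int = 0,
) -> ClusterResult:
    """Cluster genes (rows) by the similarity of their score profiles.

    hierarchical: average linkage on 1 - Pearson r; labels cut at k
    clusters when k is given, else all singletons-to-root tree only.
    kmeans: K-means (fixed seed) on row-standardised scores, which
    orders points by correlation similarity.
    """
    data, dropped = _clean_matrix(matrix)
    if data.shape[0] < 2:
        raise ValueError("need at least two complete, variable rows to cluster")
    if mode == "hierarchical":
        z = linkage(pearson_distance_matrix(data), method="average")
        if k is not None:
            labels = pd.Series(
                fcluster(z, t=k, criterion="maxclust"), index=data.index
            )
        else:
            labels = pd.Series(np.ones(len(data), dtype=int), index=data.index)
        return ClusterResult(labels=labels, linkage_matrix=z, dropped=dropped)
    if mode == "kmeans":
        if k is None:
            raise ValueError("kmeans mode requires k")
        values = data.to_numpy()
        standardized = (values - values.mean(axis=1, keepdims=True)) / values.std(
            axis=1, keepdims=True
        )
        km = KMeans(n_clusters=k, random_state=seed, n_init=10)
        labels = pd.Series(km.fit_predict(standardized), index=data.index)
        return ClusterResult(labels=labels, linkage_matrix=None, dropped=dropped)
    raise ValueError(f"unknown clustering mode {mode!r}")
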