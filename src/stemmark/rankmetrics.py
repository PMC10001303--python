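"""Rank-based marker statistics.

Two per-gene statistics built to be comparable across studies without batch
correction, plus the cross-cluster scores derived from marker tables:

* abundance — the percentage of a sample's cells with non-zero expression of
  a gene.
* percentage-rank — within one cell, the gene's ascending rank among the
  cell's non-zero genes, normalized by the number of non-zero genes, x100.
  Zeros are excluded before ranking so the statistic does not depend on how
  many silent genes a dataset happens to carry; a gene with zero expression
  in a cell has no percentage-rank there (an absent value, never 0).
* marker frequency — the percentage of stem-like clusters whose retained
  marker table contains the gene.
* median p-value rank — the median, over exactly the stem tables a gene
  marks, of its within-table p-value rank percentage.

Because every statistic depends on the data only through within-cell ranks,
zero patterns, or marker-table membership, all are invariant under per-cell
monotone rescaling (library-size normalization, TPM, CPM).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import rankdata
import anndata as ad

__all__ = [
    "AbundanceRecord",
    "abundance",
    "abundance_table",
    "percentage_rank",
    "percentage_rank_matrix",
    "marker_frequency",
    "median_p_rank",
    "candidate_scores",
    "fraction_pr_above",
]


@dataclass(frozen=True)
class AbundanceRecord:
    gene: str
    sample_id: str
    abundance_pct: float


def _primary_layer(adata: ad.AnnData):
    """Layer defining 'expressed': raw counts when present, else normalized.

    The zero pattern is identical across the two, so the choice only matters
    for datasets that arrive without raw counts.
    """
    return adata.X if adata.X is not None else adata.layers["normalized"]


def abundance(adata: ad.AnnData, gene: str, sample_id: str) -> AbundanceRecord:
    """Percentage of the sample's cells expressing (value > 0) the gene."""
    if gene not in adata.var_names:
        raise KeyError(f"unknown gene {gene!r}")
    mask = (adata.obs["sample_id"] == sample_id).to_numpy()
    if not mask.any():
        raise KeyError(f"unknown sample {sample_id!r}")
    col = _primary_layer(adata)[mask, adata.var_names.get_loc(gene)]
    n_expr = int((col.toarray() > 0).sum()) if sp.issparse(col) else int((col > 0).sum())
    return AbundanceRecord(gene, sample_id, 100.0 * n_expr / int(mask.sum()))


def abundance_table(adata: ad.AnnData, genes: list[str] | None = None) -> pd.DataFrame:
    """Per-gene, per-sample abundance, long format."""
    genes = list(adata.var_names) if genes is None else list(genes)
    missing = set(genes) - set(adata.var_names)
    if missing:
        raise KeyError(f"unknown genes: {sorted(missing)[:5]}")
    cols = adata.var_names.get_indexer(genes)
    X = _primary_layer(adata)[:, cols]
    expressed = (X > 0).astype(np.int64)
    rows = []
    for sample, idx in adata.obs.groupby("sample_id", observed=True, sort=True).indices.items():
        block = expressed[np.asarray(idx)]
        n_expr = np.asarray(block.sum(axis=0)).ravel()
        pct = 100.0 * n_expr / len(idx)
        rows.append(pd.DataFrame({"gene": genes, "sample_id": sample, "abundance_pct": pct}))
    return pd.concat(rows, ignore_index=True)


def percentage_rank(cell_values: np.ndarray, gene_index: int) -> float | None:
    """Percentage-rank of one gene in one cell; None when the gene is silent.

    Ascending ranks over the cell's non-zero genes with average ranks at
    ties, normalized by the number of non-zero genes, x100.
    """
    values = np.asarray(cell_values, dtype=float)
    nonzero = np.flatnonzero(values)
    if nonzero.size == 0:
        raise ValueError("cell has no non-zero gene (should not survive QC)")
    if values[gene_index] == 0:
        return None
    ranks = rankdata(values[nonzero], method="average")
    pos = int(np.searchsorted(nonzero, gene_index))
    return 100.0 * float(ranks[pos]) / nonzero.size


def percentage_rank_matrix(
    adata: ad.AnnData,
    genes: list[str],
    cell_mask: np.ndarray | None = None,
) -> pd.DataFrame:
    """Percentage-ranks of ``genes`` for each selected cell (NaN = silent).

    Ranks are computed within each cell over ALL its non-zero genes, then
    the requested columns are extracted.
    """
    cols = adata.var_names.get_indexer(genes)
    if (cols < 0).any():
        raise KeyError(f"unknown genes: {[g for g, c in zip(genes, cols) if c < 0]}")
    X = _primary_layer(adata)
    if cell_mask is not None:
        X = X[np.asarray(cell_mask)]
        index = adata.obs_names[np.asarray(cell_mask)]
    else:
        index = adata.obs_names
    if sp.issparse(X):
        X = X.toarray()
    out = np.full((X.shape[0], len(genes)), np.nan)
    for i in range(X.shape[0]):
        row = X[i]
        nonzero = np.flatnonzero(row)
        if nonzero.size == 0:
            raise ValueError(f"cell {index[i]!r} has no non-zero gene")
        ranks = rankdata(row[nonzero], method="average")
        pr = 100.0 * ranks / nonzero.size
        pos = np.searchsorted(nonzero, cols)
        hit = (pos < nonzero.size) & (nonzero[np.minimum(pos, nonzero.size - 1)] == cols)
        out[i, hit] = pr[pos[hit]]
    return pd.DataFrame(out, index=index, columns=genes)


def marker_frequency(gene: str, stem_tables: list[pd.DataFrame]) -> float:
    """Percentage of stem-like clusters whose retained markers include gene."""
    if not stem_tables:
        raise ValueError("stem_tables must be non-empty")
    n_marked = sum(gene in set(t["gene"]) for t in stem_tables)
    return 100.0 * n_marked / len(stem_tables)


def median_p_rank(gene: str, stem_tables: list[pd.DataFrame]) -> float | None:
    """Median p-rank percentage over exactly the stem tables the gene marks."""
    pcts = [
        float(t.loc[t["gene"] == gene, "p_rank_pct"].iloc[0])
        for t in stem_tables
        if (t["gene"] == gene).any()
    ]
    if not pcts:
        return None
    return float(np.median(pcts))


def candidate_scores(stem_tables: list[pd.DataFrame]) -> pd.DataFrame:
    """Cross-cluster score for every gene in the union of stem marker tables.

    Columns: gene, n_stem_clusters_marked, frequency_pct, median_p_rank_pct.
    The candidate pool is the union of the retained (post-truncation) tables.
    """
    if not stem_tables:
        raise ValueError("stem_tables must be non-empty")
    pooled = pd.concat(stem_tables, ignore_index=True)
    grouped = pooled.groupby("gene")["p_rank_pct"]
    out = pd.DataFrame(
        {
            "n_stem_clusters_marked": grouped.size(),
            "frequency_pct": 100.0 * grouped.size() / len(stem_tables),
            "median_p_rank_pct": grouped.median(),
        }
    ).reset_index()
    return out.sort_values("gene", kind="mergesort", ignore_index=True)


def fraction_pr_above(pr_values: np.ndarray | pd.Series, threshold: float = 50.0) -> float:
    """Percentage of expressing cells whose percentage-rank exceeds threshold."""
    values = np.asarray(pd.Series(pr_values).dropna(), dtype=float)
    if values.size == 0:
        raise ValueError("no expressing cells: fraction undefined")
    return 100.0 * float((values > threshold).sum()) / values.size
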