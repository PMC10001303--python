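"""Per-sample clustering, cluster-marker calling, and stem-like annotation.

Each tumor sample is clustered independently (log1p of the normalized layer
-> PCA -> shared-nearest-neighbor graph -> Leiden). Markers of a cluster are
called one-vs-rest within the same sample with a two-sided Wilcoxon rank-sum
test and a log2 fold-change of group means; genes pass at logFC > 2 and
p < 0.05, are ranked ascending by p-value, and the top 200 are kept. A
marker's ascending p-value rank, normalized by the cluster's marker count
and expressed in percent, is the within-cluster significance statistic used
downstream.

Stem-like clusters are identified either from explicit labels or by
hypergeometric over-representation of a stem signature among the cluster's
top markers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
import anndata as ad

__all__ = [
    "cluster_sample",
    "find_cluster_markers",
    "p_rank_percent",
    "round_pct",
    "rank_sum_test",
    "annotate_stem_clusters",
    "StemAnnotation",
]

logger = logging.getLogger(__name__)

LOGFC_EPS = 1e-9          # pseudo-count on group means inside log2 fold change
EXACT_TEST_MAX_CELLS = 14  # exact rank-sum null (enumeration) up to this many cells

MARKER_COLUMNS = ["cluster_id", "gene", "logfc", "p_value", "p_rank", "p_rank_pct", "n_markers"]


def cluster_sample(
    adata: ad.AnnData,
    sample_id: str,
    n_pcs: int = 20,
    n_neighbors: int = 15,
    resolution: float = 1.0,
    seed: int = 0,
) -> pd.Series:
    """Leiden-cluster one sample; labels are '<sample>_<k>' with k >= 1.

    Writes the labels into ``adata.obs['cluster']`` (creating the column if
    needed) and returns them. Deterministic for a fixed seed.
    """
    import scanpy as sc

    mask = (adata.obs["sample_id"] == sample_id).to_numpy()
    n_cells = int(mask.sum())
    if n_cells < 2:
        raise ValueError(f"sample {sample_id!r} has fewer than 2 cells")
    if "normalized" not in adata.layers:
        raise ValueError("normalized layer missing; run preprocessing first")

    sub = ad.AnnData(X=adata.layers["normalized"][mask].copy())
    sc.pp.log1p(sub)
    n_comps = min(n_pcs, n_cells - 1, sub.n_vars - 1)
    sc.pp.pca(sub, n_comps=n_comps, svd_solver="arpack", random_state=seed)
    if n_neighbors >= n_cells:
        logger.warning(
            "sample %s: n_neighbors=%d >= %d cells, reduced to %d",
            sample_id, n_neighbors, n_cells, n_cells - 1,
        )
        n_neighbors = n_cells - 1
    sc.pp.neighbors(sub, n_neighbors=n_neighbors, random_state=seed)
    sc.tl.leiden(
        sub,
        resolution=resolution,
        random_state=seed,
        flavor="igraph",
        n_iterations=2,
        directed=False,
    )
    labels = pd.Series(
        [f"{sample_id}_{int(c) + 1}" for c in sub.obs["leiden"]],
        index=adata.obs_names[mask],
        name="cluster",
    )
    if "cluster" not in adata.obs:
        adata.obs["cluster"] = pd.Series(pd.NA, index=adata.obs_names, dtype="object")
    col = adata.obs["cluster"]
    if isinstance(col.dtype, pd.CategoricalDtype):
        adata.obs["cluster"] = col.astype("object")
    adata.obs.loc[labels.index, "cluster"] = labels
    return labels


def rank_sum_test(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Groups totalling at most EXACT_TEST_MAX_CELLS cells get the exact null:
    every assignment of the pooled values into the two group sizes is
    enumerated (valid under ties, unlike the classical tie-free tables).
    Larger groups use the normal approximation with tie correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size + y.size <= EXACT_TEST_MAX_CELLS:
        method = stats.PermutationMethod(n_resamples=9999)  # >= C(14,7): exhaustive
    else:
        method = "asymptotic"
    return float(stats.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue)


def find_cluster_markers(
    adata: ad.AnnData,
    cluster_id: str,
    logfc_min: float = 2.0,
    p_max: float = 0.05,
    top_k: int = 200,
) -> pd.DataFrame:
    """One-vs-rest marker table for a cluster, within its own sample.

    Rows pass logFC > logfc_min and p < p_max (both strict), are sorted by
    ascending p-value (ties: higher logFC, then gene ID), assigned ascending
    ranks 1..n_markers and rank percentages 100*rank/n_markers computed on
    the full passing set, and finally truncated to the top ``top_k``.
    """
    if "cluster" not in adata.obs:
        raise ValueError("no 'cluster' column; run cluster_sample first")
    in_cluster = (adata.obs["cluster"] == cluster_id).to_numpy()
    if in_cluster.sum() < 2:
        raise ValueError(f"cluster {cluster_id!r} has fewer than 2 cells")
    samples = adata.obs.loc[in_cluster, "sample_id"].unique()
    if len(samples) != 1:
        raise ValueError(f"cluster {cluster_id!r} spans multiple samples: {list(samples)}")
    same_sample = (adata.obs["sample_id"] == samples[0]).to_numpy()
    out_cluster = same_sample & ~in_cluster
    if out_cluster.sum() < 2:
        raise ValueError(f"complement of cluster {cluster_id!r} has fewer than 2 cells")

    layer = adata.layers["normalized"]
    X_in = layer[in_cluster]
    X_out = layer[out_cluster]
    if sp.issparse(X_in):
        X_in, X_out = X_in.toarray(), X_out.toarray()

    mean_in = X_in.mean(axis=0)
    mean_out = X_out.mean(axis=0)
    logfc = np.log2((mean_in + LOGFC_EPS) / (mean_out + LOGFC_EPS))

    n_total = X_in.shape[0] + X_out.shape[0]
    if n_total <= EXACT_TEST_MAX_CELLS:
        pvals = np.array([rank_sum_test(X_in[:, j], X_out[:, j]) for j in range(adata.n_vars)])
    else:
        pvals = stats.mannwhitneyu(
            X_in.T, X_out.T, alternative="two-sided", method="asymptotic", axis=-1
        ).pvalue

    table = pd.DataFrame(
        {"cluster_id": cluster_id, "gene": adata.var_names, "logfc": logfc, "p_value": pvals}
    )
    table = table[(table["logfc"] > logfc_min) & (table["p_value"] < p_max)]
    table = table.sort_values(
        ["p_value", "logfc", "gene"], ascending=[True, False, True], kind="mergesort"
    ).reset_index(drop=True)
    n_markers = len(table)
    table["p_rank"] = np.arange(1, n_markers + 1)
    table["p_rank_pct"] = 100.0 * table["p_rank"] / n_markers if n_markers else np.nan
    table["n_markers"] = n_markers
    return table.head(top_k).reset_index(drop=True)[MARKER_COLUMNS]


def p_rank_percent(rank: int, n_markers: int) -> float:
    """Ascending p-value rank as a percentage of the cluster's marker count."""
    if int(rank) != rank or int(n_markers) != n_markers:
        raise ValueError("rank and n_markers must be integers")
    if rank < 1:
        raise ValueError(f"rank must be >= 1, got {rank}")
    if rank > n_markers:
        raise ValueError(f"rank ({rank}) exceeds n_markers ({n_markers})")
    return 100.0 * rank / n_markers


def round_pct(value: float, ndigits: int = 1) -> float:
    """Round-half-up to ``ndigits`` decimals, as reported in output tables."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class StemAnnotation:
    cluster_id: str
    is_stem: bool
    method: str  # "signature_overlap" | "explicit_label"
    overlap_count: int | None = None
    overlap_p: float | None = None


def annotate_stem_clusters(
    marker_tables: list[pd.DataFrame],
    signature: set[str] | None = None,
    background_size: int | None = None,
    alpha: float = 0.01,
    explicit_labels: dict[str, bool] | None = None,
) -> list[StemAnnotation]:
    """Flag stem-like clusters.

    With ``explicit_labels`` a cluster's flag is taken verbatim
    (method "explicit_label"). Otherwise the cluster's retained top markers
    are tested for over-representation of ``signature`` genes with a
    hypergeometric tail over a background of ``background_size`` genes;
    is_stem holds when p < alpha.
    """
    explicit_labels = explicit_labels or {}
    annotations: list[StemAnnotation] = []
    for table in marker_tables:
        if len(table):
            cluster_id = str(table["cluster_id"].iloc[0])
        elif "cluster_id" in table.attrs:
            cluster_id = table.attrs["cluster_id"]
        else:
            raise ValueError("empty marker table without a cluster_id attribute")
        if cluster_id in explicit_labels:
            annotations.append(
                StemAnnotation(cluster_id, bool(explicit_labels[cluster_id]), "explicit_label")
            )
            continue
        if signature is None or background_size is None:
            raise ValueError(
                f"cluster {cluster_id!r}: no explicit label and no signature given"
            )
        if not signature:
            raise ValueError("signature must be non-empty")
        if background_size < len(signature):
            raise ValueError("background_size must be >= len(signature)")
        top = set(table["gene"])
        k = len(top & signature)
        p = float(stats.hypergeom.sf(k - 1, background_size, len(signature), len(top)))
        annotations.append(
            StemAnnotation(cluster_id, p < alpha, "signature_overlap", k, p)
        )
    return annotations
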