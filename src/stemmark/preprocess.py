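"""Quality control and normalization.

Adaptive per-sample cell filtration (median ± nmads * MAD, the "isOutlier"
convention), dataset-wide gene filtration (grand total below a floor, and
mitochondrial genes by name prefix), and library-size normalization to the
median cell total. The pipeline applies them in that fixed order:
cells first (per sample), then genes (whole dataset), then normalization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import median_abs_deviation
import anndata as ad

__all__ = ["QCThresholds", "filter_cells", "filter_genes", "normalize_library_size", "preprocess"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class QCThresholds:
    nmads: float = 3.0
    min_gene_total: int = 100
    mito_prefix: str = "MT-"

    def validate(self) -> None:
        if not self.nmads > 0:
            raise ValueError(f"nmads must be > 0, got {self.nmads}")
        if self.min_gene_total < 0:
            raise ValueError(f"min_gene_total must be >= 0, got {self.min_gene_total}")


def _row_sums(X) -> np.ndarray:
    return np.asarray(X.sum(axis=1)).ravel() if sp.issparse(X) else X.sum(axis=1)


def _detected(X) -> np.ndarray:
    if sp.issparse(X):
        return np.asarray((X > 0).sum(axis=1)).ravel()
    return (X > 0).sum(axis=1)


def _low_outlier(values: np.ndarray, nmads: float) -> np.ndarray:
    """Below median - nmads * MAD; MAD = 0 flags nothing."""
    med = np.median(values)
    mad = median_abs_deviation(values, scale="normal")
    if mad == 0:
        return np.zeros(values.shape, dtype=bool)
    return values < med - nmads * mad


def _high_outlier(values: np.ndarray, nmads: float) -> np.ndarray:
    med = np.median(values)
    mad = median_abs_deviation(values, scale="normal")
    if mad == 0:
        return np.zeros(values.shape, dtype=bool)
    return values > med + nmads * mad


def filter_cells(
    adata: ad.AnnData,
    thresholds: QCThresholds = QCThresholds(),
) -> tuple[ad.AnnData, pd.DataFrame]:
    """Single-pass adaptive cell filtration, per sample.

    A cell is removed when, within its sample, its log1p library size or
    log1p detected-gene count falls more than ``nmads`` MADs below the
    sample median, or its mitochondrial read fraction rises more than
    ``nmads`` MADs above the sample median. Returns the filtered dataset
    and a QC report listing each removed cell with the violated criteria;
    samples emptied by the filter are recorded as warnings in the report.
    """
    thresholds.validate()
    if "sample_id" not in adata.obs:
        raise ValueError("annotation must provide a 'sample_id' column")
    X = adata.X
    libsize = _row_sums(X).astype(float)
    ngenes = _detected(X).astype(float)
    is_mito = adata.var_names.str.startswith(thresholds.mito_prefix)
    mito_counts = _row_sums(X[:, np.flatnonzero(is_mito)]) if is_mito.any() else np.zeros(adata.n_obs)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(libsize > 0, mito_counts / np.maximum(libsize, 1e-300), 0.0)

    remove = np.zeros(adata.n_obs, dtype=bool)
    reasons = [[] for _ in range(adata.n_obs)]
    warnings: list[str] = []
    for sample, idx in adata.obs.groupby("sample_id", observed=True, sort=False).indices.items():
        idx = np.asarray(idx)
        for name, flagged in (
            ("low_library_size", _low_outlier(np.log1p(libsize[idx]), thresholds.nmads)),
            ("low_n_genes", _low_outlier(np.log1p(ngenes[idx]), thresholds.nmads)),
            ("high_mito_fraction", _high_outlier(mito_frac[idx], thresholds.nmads)),
        ):
            for i in idx[flagged]:
                reasons[i].append(name)
            remove[idx[flagged]] = True
        if remove[idx].all():
            warnings.append(f"sample {sample} has zero cells after filtration")
            logger.warning("sample %s has zero cells after filtration", sample)

    report = pd.DataFrame(
        {
            "cell_id": adata.obs_names[remove],
            "sample_id": adata.obs["sample_id"].to_numpy()[remove],
            "library_size": libsize[remove],
            "n_genes_detected": ngenes[remove],
            "mito_fraction": mito_frac[remove],
            "violated": [";".join(reasons[i]) for i in np.flatnonzero(remove)],
        }
    )
    report.attrs["policy"] = "single-pass per-sample MAD filter (no iterative re-filtering)"
    report.attrs["warnings"] = warnings
    return adata[~remove].copy(), report


def filter_genes(adata: ad.AnnData, thresholds: QCThresholds = QCThresholds()) -> ad.AnnData:
    """Drop genes with grand total < min_gene_total and mito-prefixed genes."""
    thresholds.validate()
    totals = np.asarray(adata.X.sum(axis=0)).ravel()
    keep = (totals >= thresholds.min_gene_total) & ~adata.var_names.str.startswith(
        thresholds.mito_prefix
    )
    if not keep.any():
        raise ValueError("gene filtration removed every gene (degenerate dataset)")
    return adata[:, keep].copy()


def normalize_library_size(adata: ad.AnnData) -> ad.AnnData:
    """Scale each cell to the median raw cell total, in layers['normalized'].

    Per-cell monotone scaling: the zero pattern and each cell's within-cell
    gene ranking are unchanged, which is what makes the downstream
    percentage-rank statistic insensitive to this choice of scale factor.
    """
    totals = _row_sums(adata.X).astype(float)
    if (totals == 0).any():
        bad = adata.obs_names[int(np.flatnonzero(totals == 0)[0])]
        raise ValueError(f"cell {bad!r} has zero total counts; remove it before normalizing")
    scale = np.median(totals) / totals
    X = adata.X
    if sp.issparse(X):
        normalized = sp.diags(scale) @ X.astype(float)
        normalized = sp.csr_matrix(normalized)
    else:
        normalized = X.astype(float) * scale[:, None]
    out = adata.copy()
    out.layers["normalized"] = normalized
    return out


def preprocess(
    adata: ad.AnnData,
    thresholds: QCThresholds = QCThresholds(),
    skip_normalization: bool = False,
) -> tuple[ad.AnnData, pd.DataFrame]:
    """Full QC pass in the pipeline's fixed order: cells, genes, normalize.

    ``skip_normalization`` accepts matrices that arrive already normalized
    (e.g. TPM): cell and gene filtration still run, and the input values are
    copied into layers['normalized'] unchanged.
    """
    filtered, report = filter_cells(adata, thresholds)
    filtered = filter_genes(filtered, thresholds)
    if skip_normalization:
        out = filtered.copy()
        out.layers["normalized"] = filtered.X.astype(float).copy()
        return out, report
    return normalize_library_size(filtered), report
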