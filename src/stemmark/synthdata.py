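"""Synthetic multi-sample scRNA-seq data with planted stem-like marker structure.

Emulates the study design the rest of the package consumes: several tumor
"samples", each containing a handful of transcriptional clusters of which one
is stem-like and overexpresses a planted marker-gene set, plus a separate
pool of normal reference cells. A subset of the planted stem markers is
cancer-specific: those genes are identically zero in every normal cell, so
the cancer/normal specificity call has a known answer.

Counts are negative binomial (gamma-Poisson) with log-normal gene-level base
means, log-normal per-cell size factors, shared dispersion, and independent
Bernoulli dropout. Each tumor cluster additionally perturbs non-planted genes
with random "state" effects whose magnitude decays with expression level, so
one-vs-rest marker tables carry a realistic long tail of weak organic markers
around the planted ones.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite
import anndata as ad

__all__ = ["SyntheticSpec", "GroundTruth", "generate_dataset", "write_fixture", "read_fixture"]

# obs columns carried by every generated / fixture-loaded AnnData
OBS_COLUMNS = ("sample_id", "cell_class", "true_cluster")

MITO_BASE_MEAN_FACTOR = 20.0   # mito genes are highly expressed (~10% of reads)
MITO_OUTLIER_FACTOR = 8.0      # extra inflation for planted QC-outlier cells
STATE_EFFECT_SIGMA = 2.2       # log2-scale sd of cluster state effects at mean -> 0
STATE_EFFECT_MEAN_SCALE = 1.0  # e-folding of state-effect sd with base mean
SIZE_FACTOR_LOG_SIGMA = 0.3    # natural-log sd of per-cell size factors


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the generated study.

    Defaults are the package's reference conditions: 6 tumor samples of 300
    cells in 3 clusters, 2,000 genes, 30 stem markers planted at log2FC 2.5
    of which 10 are cancer-specific, and a 300-cell normal pool.
    """

    n_tumor_samples: int = 6
    cells_per_sample: int = 300
    n_clusters_per_sample: int = 3
    n_genes: int = 2000
    n_stem_markers: int = 30
    stem_marker_log2fc: float = 2.5
    n_cancer_specific: int = 10
    n_normal_cells: int = 300
    nb_mean_log_mu: float = 0.0
    nb_mean_log_sigma: float = 1.0
    nb_dispersion: float = 0.5
    dropout_rate: float = 0.1
    mito_fraction_outlier_cells: int = 12
    n_mito_genes: int = 10
    nonstem_markers_per_cluster: int = 10
    seed: int = 0

    def validate(self) -> None:
        """Raise ValueError naming the first violated field."""
        counts = {
            "n_tumor_samples": self.n_tumor_samples,
            "cells_per_sample": self.cells_per_sample,
            "n_genes": self.n_genes,
            "n_stem_markers": self.n_stem_markers,
            "n_cancer_specific": self.n_cancer_specific,
            "n_normal_cells": self.n_normal_cells,
            "mito_fraction_outlier_cells": self.mito_fraction_outlier_cells,
            "n_mito_genes": self.n_mito_genes,
            "nonstem_markers_per_cluster": self.nonstem_markers_per_cluster,
        }
        for name, value in counts.items():
            if int(value) != value or value < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {value!r}")
        if self.n_tumor_samples < 1:
            raise ValueError("n_tumor_samples must be >= 1")
        if self.n_clusters_per_sample < 2:
            raise ValueError("n_clusters_per_sample must be >= 2 (one stem-like, >=1 other)")
        if not (self.n_cancer_specific <= self.n_stem_markers <= self.n_genes):
            raise ValueError(
                "n_cancer_specific <= n_stem_markers <= n_genes violated: "
                f"n_cancer_specific={self.n_cancer_specific}, "
                f"n_stem_markers={self.n_stem_markers}, n_genes={self.n_genes}"
            )
        if not 0.0 <= self.dropout_rate <= 1.0:
            raise ValueError(f"dropout_rate must lie in [0, 1], got {self.dropout_rate}")
        if self.nb_dispersion <= 0:
            raise ValueError(f"nb_dispersion must be > 0, got {self.nb_dispersion}")
        if self.cells_per_sample < self.n_clusters_per_sample:
            raise ValueError("cells_per_sample must be >= n_clusters_per_sample")


@dataclass
class GroundTruth:
    """What was planted: the answer key for parameter-recovery tests."""

    stem_cluster_per_sample: dict[str, str]
    planted_stem_markers: list[str]
    planted_cancer_specific: list[str]
    cell_cluster_assignment: dict[str, str]
    nonstem_markers: dict[str, list[str]] = field(default_factory=dict)

    def validate(self) -> None:
        if not set(self.planted_cancer_specific) <= set(self.planted_stem_markers):
            raise ValueError("planted_cancer_specific must be a subset of planted_stem_markers")


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Gamma-Poisson draw: NB with var = mu + dispersion * mu^2."""
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, scale=mean * dispersion)
    return rng.poisson(lam)


def generate_dataset(spec: SyntheticSpec) -> tuple[ad.AnnData, GroundTruth]:
    """Generate the synthetic study.

    Returns an AnnData (raw integer counts in .X, per-cell annotation in
    .obs: sample_id, cell_class in {tumor, normal}, true_cluster) and the
    GroundTruth answer key. Identical spec (including seed) reproduces a
    byte-identical dataset.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    n_mito = min(spec.n_mito_genes, spec.n_genes)
    gene_ids = [f"G{i + 1:04d}" for i in range(spec.n_genes - n_mito)]
    gene_ids += [f"MT-G{i + 1:02d}" for i in range(n_mito)]
    gene_ids = np.asarray(gene_ids, dtype=object)
    is_mito = np.char.startswith(gene_ids.astype(str), "MT-")

    base_mean = rng.lognormal(spec.nb_mean_log_mu, spec.nb_mean_log_sigma, spec.n_genes)
    base_mean[is_mito] *= MITO_BASE_MEAN_FACTOR

    # Planted markers come from detectably expressed (above-median) non-mito
    # genes; sets for different clusters are disjoint.
    detectable = np.flatnonzero((base_mean >= np.median(base_mean)) & ~is_mito)
    sample_ids = [f"S{i + 1:02d}" for i in range(spec.n_tumor_samples)]
    n_nonstem_sets = spec.n_tumor_samples * (spec.n_clusters_per_sample - 1)
    n_needed = spec.n_stem_markers + n_nonstem_sets * spec.nonstem_markers_per_cluster
    if n_needed > detectable.size:
        raise ValueError(
            "n_stem_markers/nonstem_markers_per_cluster too large: "
            f"need {n_needed} detectable genes, have {detectable.size}"
        )
    planted_pool = rng.choice(detectable, size=n_needed, replace=False)
    stem_idx = np.sort(planted_pool[: spec.n_stem_markers])
    cancer_idx = np.sort(rng.choice(stem_idx, size=spec.n_cancer_specific, replace=False))
    nonstem_sets = planted_pool[spec.n_stem_markers :].reshape(n_nonstem_sets, -1)

    planted_any = np.zeros(spec.n_genes, dtype=bool)
    planted_any[planted_pool] = True

    # State-effect sd decays with expression: low-expression genes vary a lot
    # between cell states, high-expression housekeeping genes hardly at all.
    state_sd = STATE_EFFECT_SIGMA * np.exp(-base_mean / STATE_EFFECT_MEAN_SCALE)
    state_sd[planted_any | is_mito] = 0.0

    effect = 2.0 ** spec.stem_marker_log2fc

    blocks: list[np.ndarray] = []
    obs_rows: list[tuple[str, str, str, str]] = []
    stem_cluster_per_sample: dict[str, str] = {}
    nonstem_markers: dict[str, list[str]] = {}
    set_cursor = 0
    for sample in sample_ids:
        sizes = np.full(spec.n_clusters_per_sample, spec.cells_per_sample // spec.n_clusters_per_sample)
        sizes[: spec.cells_per_sample % spec.n_clusters_per_sample] += 1
        for k in range(spec.n_clusters_per_sample):
            cluster = f"{sample}_c{k + 1}"
            n_cells = int(sizes[k])
            mean_g = base_mean.copy()
            mean_g *= 2.0 ** (rng.normal(0.0, 1.0, spec.n_genes) * state_sd)
            if k == 0:
                stem_cluster_per_sample[sample] = cluster
                mean_g[stem_idx] *= effect
            else:
                idx = nonstem_sets[set_cursor]
                set_cursor += 1
                nonstem_markers[cluster] = [str(g) for g in gene_ids[np.sort(idx)]]
                mean_g[idx] *= effect
            size_factors = rng.lognormal(0.0, SIZE_FACTOR_LOG_SIGMA, n_cells)
            block = _nb_counts(rng, size_factors[:, None] * mean_g[None, :], spec.nb_dispersion)
            blocks.append(block)
            for i in range(n_cells):
                obs_rows.append((f"{cluster}_cell{i + 1:03d}", sample, "tumor", cluster))

    # normal reference pool: base means only, cancer-specific genes silent
    if spec.n_normal_cells > 0:
        mean_g = base_mean.copy()
        mean_g[cancer_idx] = 0.0
        size_factors = rng.lognormal(0.0, SIZE_FACTOR_LOG_SIGMA, spec.n_normal_cells)
        block = _nb_counts(rng, size_factors[:, None] * mean_g[None, :], spec.nb_dispersion)
        blocks.append(block)
        for i in range(spec.n_normal_cells):
            obs_rows.append((f"normal_cell{i + 1:04d}", "normal", "normal", "normal"))

    counts = np.concatenate(blocks, axis=0)
    if spec.dropout_rate > 0:
        counts = np.where(rng.random(counts.shape) < spec.dropout_rate, 0, counts)
    counts[:, cancer_idx] *= (np.asarray([r[2] for r in obs_rows]) == "tumor").astype(int)[:, None]

    # inflate mito counts for a few tumor cells to exercise the QC filter
    n_tumor = sum(1 for r in obs_rows if r[2] == "tumor")
    n_outliers = min(spec.mito_fraction_outlier_cells, n_tumor)
    if n_outliers > 0 and n_mito > 0:
        outlier_cells = rng.choice(n_tumor, size=n_outliers, replace=False)
        counts[np.ix_(outlier_cells, np.flatnonzero(is_mito))] *= int(MITO_OUTLIER_FACTOR)

    obs = pd.DataFrame(obs_rows, columns=["cell_id", *OBS_COLUMNS]).set_index("cell_id")
    obs.index.name = None
    adata = ad.AnnData(
        X=sp.csr_matrix(counts.astype(np.int64)),
        obs=obs,
        var=pd.DataFrame(index=pd.Index(gene_ids.astype(str), name=None)),
    )

    truth = GroundTruth(
        stem_cluster_per_sample=stem_cluster_per_sample,
        planted_stem_markers=[str(g) for g in gene_ids[stem_idx]],
        planted_cancer_specific=[str(g) for g in gene_ids[cancer_idx]],
        cell_cluster_assignment=dict(zip(adata.obs_names, adata.obs["true_cluster"])),
        nonstem_markers=nonstem_markers,
    )
    truth.validate()
    return adata, truth


# ---------------------------------------------------------------------------
# fixture I/O (MatrixMarket + TSV + JSON manifest)

def write_fixture(
    adata: ad.AnnData,
    truth: GroundTruth | None,
    directory: str | Path,
    spec: SyntheticSpec | None = None,
) -> Path:
    """Write the dataset as plain-text files; returns the manifest path.

    Layout: counts.mtx (genes x cells, integer), genes.tsv, cells.tsv,
    ground_truth.tsv (one row per planted marker), manifest.json.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    X = adata.X
    if not sp.issparse(X):
        X = sp.csr_matrix(X)
    mmwrite(str(directory / "counts.mtx"), X.T.astype(np.int64), field="integer")
    pd.DataFrame({"gene_id": adata.var_names}).to_csv(directory / "genes.tsv", sep="\t", index=False)
    cells = adata.obs.reset_index(names="cell_id")[["cell_id", *OBS_COLUMNS]]
    cells.to_csv(directory / "cells.tsv", sep="\t", index=False)

    files = ["counts.mtx", "genes.tsv", "cells.tsv"]
    manifest: dict = {"files": files, "n_cells": adata.n_obs, "n_genes": adata.n_vars}
    if spec is not None:
        manifest["spec"] = asdict(spec)
        manifest["seed"] = spec.seed
    if truth is not None:
        cluster_of = {}
        for cluster, genes in truth.nonstem_markers.items():
            for g in genes:
                cluster_of[g] = cluster
        rows = [
            {"gene": g, "target": "stem", "cancer_specific": g in set(truth.planted_cancer_specific)}
            for g in truth.planted_stem_markers
        ] + [
            {"gene": g, "target": c, "cancer_specific": False}
            for g, c in sorted(cluster_of.items(), key=lambda kv: (kv[1], kv[0]))
        ]
        pd.DataFrame(rows).to_csv(directory / "ground_truth.tsv", sep="\t", index=False)
        files.append("ground_truth.tsv")
        manifest["stem_cluster_per_sample"] = truth.stem_cluster_per_sample
    manifest_path = directory / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    return manifest_path


def read_fixture(directory: str | Path) -> tuple[ad.AnnData, GroundTruth | None]:
    """Inverse of write_fixture; lossless on counts and metadata."""
    directory = Path(directory)
    X = sp.csr_matrix(mmread(str(directory / "counts.mtx")).T)
    genes = pd.read_csv(directory / "genes.tsv", sep="\t")
    cells = pd.read_csv(directory / "cells.tsv", sep="\t").set_index("cell_id")
    cells.index.name = None
    cells.index = cells.index.astype(str)
    adata = ad.AnnData(X=X.astype(np.int64), obs=cells, var=pd.DataFrame(index=genes["gene_id"].astype(str)))
    adata.var_names.name = None

    truth = None
    truth_path = directory / "ground_truth.tsv"
    manifest_path = directory / "manifest.json"
    if truth_path.exists() and manifest_path.exists():
        gt = pd.read_csv(truth_path, sep="\t")
        manifest = json.loads(manifest_path.read_text())
        stem = gt[gt["target"] == "stem"]
        nonstem: dict[str, list[str]] = {}
        for _, row in gt[gt["target"] != "stem"].iterrows():
            nonstem.setdefault(row["target"], []).append(row["gene"])
        truth = GroundTruth(
            stem_cluster_per_sample=manifest.get("stem_cluster_per_sample", {}),
            planted_stem_markers=list(stem["gene"]),
            planted_cancer_specific=list(stem.loc[stem["cancer_specific"], "gene"]),
            cell_cluster_assignment=dict(zip(adata.obs_names, adata.obs["true_cluster"])),
            nonstem_markers=nonstem,
        )
    return adata, truth
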