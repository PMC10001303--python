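import json
import time
from types import SimpleNamespace

import numpy as np
import pandas as pd
import pytest
import anndata as ad

import stemmark as sm


def make_adata(counts, sample_ids=None, cell_class="tumor", clusters=None, normalize=True):
    """Small AnnData builder for hand-constructed test matrices."""
    counts = np.asarray(counts, dtype=float)
    n_cells, n_genes = counts.shape
    obs = pd.DataFrame(index=[f"cell{i}" for i in range(n_cells)])
    obs["sample_id"] = sample_ids if sample_ids is not None else "S1"
    obs["cell_class"] = cell_class
    if clusters is not None:
        obs["cluster"] = clusters
    adata = ad.AnnData(
        X=counts,
        obs=obs,
        var=pd.DataFrame(index=[f"g{j}" for j in range(n_genes)]),
    )
    if normalize:
        adata.layers["normalized"] = counts.copy()
    return adata


def marker_table(cluster_id, genes, n_markers=None, pvals=None, logfcs=None):
    """Hand-built ClusterMarkerTable in the package's column layout."""
    n = len(genes)
    n_markers = n if n_markers is None else n_markers
    t = pd.DataFrame(
        {
            "cluster_id": cluster_id,
            "gene": list(genes),
            "logfc": logfcs if logfcs is not None else [3.0] * n,
            "p_value": pvals if pvals is not None else [10.0 ** -(n - i) for i in range(n)],
            "p_rank": np.arange(1, n + 1),
            "p_rank_pct": 100.0 * np.arange(1, n + 1) / n_markers if n_markers else np.nan,
            "n_markers": n_markers,
        }
    )
    t.attrs["cluster_id"] = cluster_id
    return t


@pytest.fixture(scope="session")
def default_study(tmp_path_factory):
    """The full default synthetic pipeline run, shared across the session.

    Reference conditions: 6 tumor samples x 300 cells in 3 clusters, 2,000
    genes, 30 planted stem markers at log2FC 2.5 (10 cancer-specific), a
    300-cell normal pool; master seed 0.
    """
    outdir = tmp_path_factory.mktemp("default_run")
    config = sm.RunConfig(outdir=outdir, seed=0, simulate=sm.SyntheticSpec())
    t0 = time.monotonic()
    sm.run_pipeline(config)
    elapsed = time.monotonic() - t0

    truth = pd.read_csv(outdir / "fixture" / "ground_truth.tsv", sep="\t")
    report = pd.read_csv(outdir / "selection_report.tsv", sep="\t", comment="#")
    markers = pd.read_csv(outdir / "markers.tsv", sep="\t")
    stem_annotations = pd.read_csv(outdir / "stem_annotations.tsv", sep="\t")
    return SimpleNamespace(
        outdir=outdir,
        config=config,
        elapsed=elapsed,
        planted=set(truth.loc[truth["target"] == "stem", "gene"]),
        cancer_specific=set(truth.loc[truth["cancer_specific"], "gene"]),
        report=report,
        scores=pd.read_csv(outdir / "candidate_scores.tsv", sep="\t"),
        markers=markers,
        stem_tables=[
            markers[markers["cluster_id"] == cid].reset_index(drop=True)
            for cid in stem_annotations.loc[stem_annotations["is_stem"], "cluster_id"]
        ],
        stem_annotations=stem_annotations,
        summary=json.loads((outdir / "summary.json").read_text()),
        manifest=json.loads((outdir / "run_manifest.json").read_text()),
    )


@pytest.fixture(scope="session")
def two_cluster_sample():
    """60-cell single-sample dataset with two strongly separated clusters."""
    spec = sm.SyntheticSpec(
        n_tumor_samples=1,
        cells_per_sample=60,
        n_clusters_per_sample=2,
        n_genes=200,
        n_stem_markers=15,
        stem_marker_log2fc=6.0,
        n_cancer_specific=0,
        n_normal_cells=0,
        dropout_rate=0.0,
        mito_fraction_outlier_cells=0,
        nonstem_markers_per_cluster=15,
        seed=3,
    )
    adata, truth = sm.generate_dataset(spec)
    adata, _ = sm.preprocess(adata)
    return adata, truth
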