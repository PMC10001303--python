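import numpy as np
import pandas as pd
import pytest

import stemmark as sm
from conftest import make_adata, marker_table
from oracles import exact_rank_sum_p, hypergeom_upper_tail


# --- clustering -----------------------------------------------------------

def test_two_planted_clusters_recovered_exactly(two_cluster_sample):
    adata, truth = two_cluster_sample
    labels = sm.cluster_sample(adata, "S01", seed=0)
    assert labels.nunique() == 2
    ct = pd.crosstab(adata.obs["true_cluster"], adata.obs["cluster"])
    # perfect agreement up to label permutation: one nonzero entry per row/col
    assert (ct.to_numpy() > 0).sum() == 2
    assert set(labels.str.rsplit("_", n=1).str[0]) == {"S01"}


def test_clustering_deterministic_given_seed(two_cluster_sample):
    adata, _ = two_cluster_sample
    l1 = sm.cluster_sample(adata, "S01", seed=5)
    l2 = sm.cluster_sample(adata, "S01", seed=5)
    assert l1.equals(l2)


def test_resolution_to_zero_yields_single_cluster():
    spec = sm.SyntheticSpec(
        n_tumor_samples=1, cells_per_sample=60, n_clusters_per_sample=2,
        n_genes=200, n_stem_markers=15, stem_marker_log2fc=0.5,
        n_cancer_specific=0, n_normal_cells=0, dropout_rate=0.0,
        mito_fraction_outlier_cells=0, nonstem_markers_per_cluster=15, seed=3,
    )
    adata, _ = sm.generate_dataset(spec)
    adata, _ = sm.preprocess(adata)
    labels = sm.cluster_sample(adata, "S01", resolution=0.001, seed=0)
    assert labels.nunique() == 1


# --- marker calling -------------------------------------------------------

def _toy_two_cluster_adata(in_values, out_values, extra_genes=None):
    """One gene of interest plus optional filler genes; two clusters."""
    n_in, n_out = len(in_values), len(out_values)
    cols = [list(in_values) + list(out_values)]
    if extra_genes:
        cols.extend(list(v) for v in extra_genes)
    counts = np.array(cols, dtype=float).T
    clusters = ["S1_1"] * n_in + ["S1_2"] * n_out
    return make_adata(counts, clusters=clusters)


def test_toy_marker_p_equals_exact_enumeration():
    """3-vs-3 toy: the reported p-value is the exact enumeration value."""
    adata = _toy_two_cluster_adata([10, 11, 12], [0, 0, 1])
    table = sm.find_cluster_markers(adata, "S1_1", logfc_min=2.0, p_max=0.5)
    assert list(table["gene"]) == ["g0"]
    expected = exact_rank_sum_p([10, 11, 12], [0, 0, 1])
    assert table["p_value"].iloc[0] == pytest.approx(expected, abs=1e-12)
    assert expected == pytest.approx(0.1)


def test_identically_distributed_gene_excluded_by_logfc():
    rng = np.random.default_rng(0)
    flat = rng.poisson(5.0, 40) + 1.0
    counts = np.column_stack([flat, np.r_[rng.poisson(50.0, 20), np.zeros(20)] + 0.5])
    adata = make_adata(counts, clusters=["S1_1"] * 20 + ["S1_2"] * 20)
    table = sm.find_cluster_markers(adata, "S1_1")
    assert "g0" not in set(table["gene"])  # logFC ~ 0


def test_marker_table_invariants_on_synthetic_sample(two_cluster_sample):
    adata, truth = two_cluster_sample
    sm.cluster_sample(adata, "S01", seed=0)
    stem_label = adata.obs.loc[
        adata.obs["true_cluster"] == truth.stem_cluster_per_sample["S01"], "cluster"
    ].iloc[0]
    table = sm.find_cluster_markers(adata, stem_label)
    n = int(table["n_markers"].iloc[0])
    assert (table["logfc"] > 2.0).all() and (table["p_value"] < 0.05).all()
    assert list(table["p_rank"]) == list(range(1, len(table) + 1))
    assert np.allclose(table["p_rank_pct"], 100.0 * table["p_rank"] / n)
    assert table["p_rank_pct"].is_monotonic_increasing
    assert len(table) <= 200 and len(table) <= n
    assert table["p_value"].is_monotonic_increasing
    # planted stem markers recovered in the table (dropout 0, huge effect)
    assert set(truth.planted_stem_markers) <= set(table["gene"])
    # deterministic re-run
    assert table.equals(sm.find_cluster_markers(adata, stem_label))


def test_markers_invariant_under_global_rescaling(two_cluster_sample):
    adata, _ = two_cluster_sample
    sm.cluster_sample(adata, "S01", seed=0)
    cid = sorted(adata.obs["cluster"].unique())[0]
    t1 = sm.find_cluster_markers(adata, cid)
    scaled = adata.copy()
    scaled.layers["normalized"] = scaled.layers["normalized"] * 7.5
    t2 = sm.find_cluster_markers(scaled, cid)
    assert list(t1["gene"]) == list(t2["gene"])
    assert np.allclose(t1["p_value"], t2["p_value"])


def test_no_gene_passing_yields_empty_table():
    counts = np.tile(np.arange(1.0, 5.0), (8, 1))  # identical cells
    adata = make_adata(counts, clusters=["S1_1"] * 4 + ["S1_2"] * 4)
    table = sm.find_cluster_markers(adata, "S1_1")
    assert table.empty


def test_small_cluster_preconditions():
    counts = np.random.default_rng(1).poisson(5.0, size=(4, 6)).astype(float)
    adata = make_adata(counts, clusters=["S1_1"] * 1 + ["S1_2"] * 3)
    with pytest.raises(ValueError, match="fewer than 2"):
        sm.find_cluster_markers(adata, "S1_1")


# --- p-value rank percentage ---------------------------------------------

@pytest.mark.parametrize(
    "rank, n, expected",
    [(66, 702, 9.4), (5499, 5901, 93.2), (236, 917, 25.7), (1269, 2181, 58.2),
     (628, 764, 82.2), (152, 739, 20.6), (1524, 2943, 51.8), (1, 1, 100.0)],
)
def test_p_rank_percent_reported_values(rank, n, expected):
    assert sm.round_pct(sm.p_rank_percent(rank, n)) == expected


@pytest.mark.parametrize("rank, n", [(0, 10), (11, 10), (-1, 5)])
def test_p_rank_percent_validates_range(rank, n):
    with pytest.raises(ValueError):
        sm.p_rank_percent(rank, n)


def test_round_pct_is_half_up():
    assert sm.round_pct(9.45) == 9.5
    assert sm.round_pct(9.44) == 9.4
    assert sm.round_pct(35.35) == 35.4


# --- stem annotation ------------------------------------------------------

def test_signature_overlap_matches_exact_hypergeometric_tail():
    signature = {f"s{i}" for i in range(30)}
    genes = [f"s{i}" for i in range(25)] + [f"x{i}" for i in range(175)]
    table = marker_table("S1_1", genes)
    (ann,) = sm.annotate_stem_clusters([table], signature, background_size=2000)
    expected = hypergeom_upper_tail(25, 2000, 30, 200)
    assert ann.overlap_count == 25
    assert ann.overlap_p == pytest.approx(expected, rel=1e-9)
    assert expected < 1e-20 and ann.is_stem


def test_zero_overlap_is_not_stem():
    table = marker_table("S1_2", [f"x{i}" for i in range(50)])
    (ann,) = sm.annotate_stem_clusters([table], {"a", "b", "c"}, background_size=500)
    assert ann.overlap_p == pytest.approx(1.0)
    assert not ann.is_stem


def test_explicit_label_overrides_overlap():
    table = marker_table("S1_3", [f"x{i}" for i in range(10)])
    (ann,) = sm.annotate_stem_clusters(
        [table], {"a"}, background_size=100, explicit_labels={"S1_3": True}
    )
    assert ann.is_stem and ann.method == "explicit_label"
    assert ann.overlap_count is None and ann.overlap_p is None


def test_planted_markers_dominate_default_stem_tables(default_study):
    """Parameter recovery at the marker-table level: each stem-like cluster's
    table contains at least 90% of the planted stem markers."""
    assert len(default_study.stem_tables) == 6
    for table in default_study.stem_tables:
        present = default_study.planted & set(table["gene"])
        assert len(present) >= 0.9 * len(default_study.planted)
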