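import numpy as np
import pandas as pd
import pytest

import stemmark as sm
from conftest import marker_table


def scores_df(rows):
    return pd.DataFrame(
        rows, columns=["gene", "n_stem_clusters_marked", "frequency_pct", "median_p_rank_pct"]
    )


# --- frequency-significance filter ---------------------------------------

def test_filter_keeps_and_drops_with_strict_boundaries():
    scores = scores_df(
        [
            ("keep", 8, 28.6, 45.0),
            ("low_freq", 3, 10.0, 20.0),
            ("boundary_freq", 4, 14.0, 20.0),
            ("boundary_rank", 8, 30.0, 50.0),
            ("keep2", 9, 30.0, 10.0),
        ]
    )
    kept = sm.frequency_significance_filter(scores)
    assert list(kept["gene"]) == ["keep2", "keep"]  # sorted by freq desc, rank asc


def test_filter_empty_input():
    assert sm.frequency_significance_filter(scores_df([])).empty


def test_filter_monotone_under_tightening():
    rng = np.random.default_rng(0)
    scores = scores_df(
        [(f"g{i}", 1, rng.uniform(0, 100), rng.uniform(0, 100)) for i in range(200)]
    )
    base = set(sm.frequency_significance_filter(scores)["gene"])
    for freq_min, rank_max in [(20, 50), (14, 30), (40, 10)]:
        cfg = sm.SelectionConfig(freq_min_pct=freq_min, med_prank_max_pct=rank_max)
        tightened = set(sm.frequency_significance_filter(scores, cfg)["gene"])
        assert tightened <= base


# --- cancer vs normal -----------------------------------------------------

def _pr_frame(columns):
    n = max(len(v) for v in columns.values())
    data = {g: list(v) + [np.nan] * (n - len(v)) for g, v in columns.items()}
    return pd.DataFrame(data)


def test_cancer_normal_categories():
    rng = np.random.default_rng(1)
    stem = _pr_frame(
        {
            "red": 70 + rng.uniform(0, 20, 40),
            "orange": 70 + rng.uniform(0, 12, 40),
            "brown": 70 + rng.uniform(0, 12, 40),
            "weak": 50 + rng.uniform(0, 10, 40),
        }
    )
    normal = _pr_frame(
        {
            "red": [np.nan] * 40,
            "orange": 30 + rng.uniform(0, 8, 40),   # median ratio > 2 -> logFC > 1
            "brown": 45 + rng.uniform(0, 8, 40),    # ratio ~1.55 -> logFC ~0.64
            "weak": 48 + rng.uniform(0, 10, 40),    # overlapping -> p large
        }
    )
    abundance = pd.Series({"red": 0.0, "orange": 80.0, "brown": 90.0, "weak": 85.0})
    out = sm.cancer_normal_compare(list(stem.columns), stem, normal, abundance).set_index("gene")

    assert out.loc["red", "category"] == "red_cross"
    assert np.isnan(out.loc["red", "wilcoxon_p"]) and np.isnan(out.loc["red", "logfc_pr"])
    assert out.loc["orange", "category"] == "orange"
    assert out.loc["orange", "logfc_pr"] > 1.0 and out.loc["orange", "wilcoxon_p"] < 0.01
    assert out.loc["brown", "category"] == "brown"
    assert 0.5 < out.loc["brown", "logfc_pr"] < 1.0
    assert out.loc["weak", "category"] == "nonsignificant"
    # fold change equals log2 ratio of group medians
    assert out.loc["orange", "logfc_pr"] == pytest.approx(
        np.log2(np.median(stem["orange"]) / np.median(normal["orange"]))
    )


def test_cancer_normal_red_cross_iff_zero_normal_abundance():
    stem = _pr_frame({"a": [80.0, 90.0], "b": [70.0, 75.0]})
    normal = _pr_frame({"a": [np.nan, np.nan], "b": [60.0, 50.0]})
    abundance = pd.Series({"a": 0.0, "b": 10.0})
    out = sm.cancer_normal_compare(["a", "b"], stem, normal, abundance).set_index("gene")
    assert out.loc["a", "category"] == "red_cross"
    assert out.loc["b", "category"] != "red_cross"


def test_cancer_normal_requires_stem_expression():
    stem = _pr_frame({"a": [np.nan, np.nan]})
    normal = _pr_frame({"a": [50.0, 60.0]})
    with pytest.raises(ValueError, match="no stem-like cell"):
        sm.cancer_normal_compare(["a"], stem, normal, pd.Series({"a": 50.0}))


# --- expression level -----------------------------------------------------

def test_expression_level_medians_and_flag():
    stem = _pr_frame({"hi": [60.0, 70.0, 80.0], "lo": [10.0, 20.0, 90.0]})
    tables = [
        marker_table("c1", ["hi", "lo"], logfcs=[2.5, 1.9]),
        marker_table("c2", ["hi"], logfcs=[3.0]),
        marker_table("c3", ["hi"], logfcs=[4.1]),
    ]
    out = sm.expression_level_scores(["hi", "lo"], stem, tables).set_index("gene")
    assert out.loc["hi", "median_pr_stem_cells"] == pytest.approx(70.0)
    assert out.loc["hi", "median_logfc_stem_clusters"] == pytest.approx(3.0)
    assert bool(out.loc["hi", "pass_expression"])
    assert out.loc["lo", "median_pr_stem_cells"] == pytest.approx(20.0)
    assert not bool(out.loc["lo", "pass_expression"])


# --- location -------------------------------------------------------------

def test_location_lookup_and_unknown_default(tmp_path):
    path = tmp_path / "loc.tsv"
    path.write_text("gene\tlocation\nA\tmembrane\nB\tintracellular\n")
    out = sm.annotate_location(["A", "B", "C"], str(path))
    assert out.to_dict() == {"A": "membrane", "B": "intracellular", "C": "unknown"}


def test_location_conflicting_duplicates_error(tmp_path):
    path = tmp_path / "loc.tsv"
    path.write_text("gene\tlocation\nA\tmembrane\nA\tintracellular\n")
    with pytest.raises(ValueError, match="conflicting"):
        sm.annotate_location(["A"], str(path))


def test_location_malformed_row_reports_line(tmp_path):
    path = tmp_path / "loc.tsv"
    path.write_text("gene\tlocation\nA\tmembrane\nB\tcytoplasmic\n")
    with pytest.raises(ValueError, match="line 3"):
        sm.annotate_location(["A"], str(path))


# --- report ---------------------------------------------------------------

def _report_inputs():
    scores = scores_df(
        [("a", 5, 80.0, 10.0), ("b", 4, 60.0, 20.0), ("fail", 1, 5.0, 90.0)]
    )
    cn = pd.DataFrame(
        {
            "gene": ["a", "b"],
            "median_pr_stem": [90.0, 85.0],
            "median_pr_normal": [np.nan, 80.0],
            "logfc_pr": [np.nan, 0.09],
            "wilcoxon_p": [np.nan, 0.6],
            "normal_abundance_pct": [0.0, 70.0],
            "category": ["red_cross", "nonsignificant"],
        }
    )
    expr = pd.DataFrame(
        {
            "gene": ["a", "b"],
            "median_pr_stem_cells": [90.0, 40.0],
            "median_logfc_stem_clusters": [3.0, 2.4],
            "pass_expression": [True, False],
        }
    )
    locations = pd.Series({"a": "membrane", "b": "unknown"})
    return scores, cn, expr, locations


def test_report_flags_and_shortlists():
    scores, cn, expr, locations = _report_inputs()
    report, summary = sm.build_report(scores, cn, expr, locations)
    row = report.set_index("gene")
    assert bool(row.loc["a", "pass_freq_sig"]) and not bool(row.loc["fail", "pass_freq_sig"])
    assert summary["shortlists"]["all_criteria"] == ["a"]
    assert summary["shortlists"]["cancer_specific"] == ["a"]
    assert "b" not in summary["shortlists"]["high_expression"]
    assert summary["category_counts"]["red_cross"] == 1
    # self-consistency: every flag is recomputable from stored columns
    cfg = sm.SelectionConfig()
    recomputed_fs = (row["frequency_pct"] > cfg.freq_min_pct) & (
        row["median_p_rank_pct"] < cfg.med_prank_max_pct
    )
    assert (recomputed_fs == row["pass_freq_sig"]).all()
    assert (row["is_surface"] == (row["location"] == "membrane")).all()


def test_report_mismatched_stage_genes_error():
    scores, cn, expr, locations = _report_inputs()
    with pytest.raises(ValueError, match="different gene sets"):
        sm.build_report(scores, cn, expr.iloc[:1], locations)


def test_report_empty_candidates():
    empty = scores_df([])
    cn = pd.DataFrame(columns=["gene", "median_pr_stem", "median_pr_normal", "logfc_pr",
                               "wilcoxon_p", "normal_abundance_pct", "category"])
    expr = pd.DataFrame(columns=["gene", "median_pr_stem_cells",
                                 "median_logfc_stem_clusters", "pass_expression"])
    report, summary = sm.build_report(empty, cn, expr, pd.Series(dtype=object))
    assert report.empty
    assert summary["n_candidates"] == 0


def test_config_invariants():
    with pytest.raises(ValueError, match="brown_logfc_min"):
        sm.SelectionConfig(brown_logfc_min=1.5, orange_logfc_min=1.0).validate()
    with pytest.raises(ValueError, match="freq_min_pct"):
        sm.SelectionConfig(freq_min_pct=120.0).validate()
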