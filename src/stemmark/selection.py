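"""Marker selection cascade.

Four stages, applied to the cross-cluster candidate pool:

1. frequency–significance filter: keep genes marking stem-like clusters
   often (frequency > 14%) and significantly (median p-value rank < 50%).
2. tumor-stem vs. normal comparison: per gene, Wilcoxon rank-sum on per-cell
   percentage-ranks of stem-like tumor cells vs. normal cells, with a log2
   fold change of the group median percentage-ranks. Genes no normal cell
   expresses are maximally cancer-specific ("red cross") and skip the test;
   the rest are binned orange (logFC > 1, p < 0.01), brown
   (0.5 < logFC < 1, p < 0.01) or nonsignificant.
3. expression-level selection: median percentage-rank over expressing
   stem-like cells combined with the median marker logFC over the stem
   tables the gene marks.
4. protein location: membrane vs. intracellular from a user-supplied table.

``build_report`` merges everything into one row per candidate with a pass
flag per stage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SelectionConfig",
    "frequency_significance_filter",
    "cancer_normal_compare",
    "expression_level_scores",
    "annotate_location",
    "build_report",
]

CATEGORIES = ("red_cross", "orange", "brown", "nonsignificant")


@dataclass(frozen=True)
class SelectionConfig:
    freq_min_pct: float = 14.0
    med_prank_max_pct: float = 50.0
    cn_p_max: float = 0.01
    orange_logfc_min: float = 1.0
    brown_logfc_min: float = 0.5
    expr_logfc_min: float = 2.0
    expr_pr_min_pct: float = 50.0

    def validate(self) -> None:
        if not self.brown_logfc_min < self.orange_logfc_min:
            raise ValueError("brown_logfc_min must be < orange_logfc_min")
        for name in ("freq_min_pct", "med_prank_max_pct", "expr_pr_min_pct"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"{name} must lie in [0, 100], got {v}")
        for name, v in asdict(self).items():
            if not math.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v}")
        if not 0.0 < self.cn_p_max <= 1.0:
            raise ValueError(f"cn_p_max must lie in (0, 1], got {self.cn_p_max}")


def frequency_significance_filter(
    scores: pd.DataFrame, config: SelectionConfig = SelectionConfig()
) -> pd.DataFrame:
    """Keep genes with frequency strictly above and median p-rank strictly
    below the thresholds; order by descending frequency, then ascending
    median p-rank, then gene ID."""
    config.validate()
    kept = scores[
        (scores["frequency_pct"] > config.freq_min_pct)
        & (scores["median_p_rank_pct"] < config.med_prank_max_pct)
    ]
    return kept.sort_values(
        ["frequency_pct", "median_p_rank_pct", "gene"],
        ascending=[False, True, True],
        kind="mergesort",
        ignore_index=True,
    )


def cancer_normal_compare(
    candidates: list[str],
    stem_prs: pd.DataFrame,
    normal_prs: pd.DataFrame,
    normal_abundance: pd.Series,
    config: SelectionConfig = SelectionConfig(),
) -> pd.DataFrame:
    """Tumor-stem vs. normal specificity per candidate gene.

    ``stem_prs`` / ``normal_prs`` are cells x genes percentage-rank frames
    (NaN where a cell does not express the gene); ``normal_abundance`` maps
    gene -> percentage of normal cells expressing it (pooled over the normal
    reference). A gene with zero normal abundance is red_cross and gets no
    test; otherwise the Wilcoxon runs on expressing cells' percentage-ranks
    and the fold change compares the group medians.
    """
    config.validate()
    rows = []
    for gene in candidates:
        stem = stem_prs[gene].dropna()
        if stem.empty:
            raise ValueError(f"candidate {gene!r} expressed in no stem-like cell")
        med_stem = float(stem.median())
        if float(normal_abundance[gene]) == 0.0:
            rows.append(
                {
                    "gene": gene,
                    "median_pr_stem": med_stem,
                    "median_pr_normal": np.nan,
                    "logfc_pr": np.nan,
                    "wilcoxon_p": np.nan,
                    "normal_abundance_pct": 0.0,
                    "category": "red_cross",
                }
            )
            continue
        normal = normal_prs[gene].dropna()
        med_normal = float(normal.median())
        logfc = float(np.log2(med_stem / med_normal))
        p = float(
            stats.mannwhitneyu(stem, normal, alternative="two-sided", method="asymptotic").pvalue
        )
        if p < config.cn_p_max and logfc > config.orange_logfc_min:
            category = "orange"
        elif p < config.cn_p_max and config.brown_logfc_min < logfc < config.orange_logfc_min:
            category = "brown"
        else:
            category = "nonsignificant"
        rows.append(
            {
                "gene": gene,
                "median_pr_stem": med_stem,
                "median_pr_normal": med_normal,
                "logfc_pr": logfc,
                "wilcoxon_p": p,
                "normal_abundance_pct": float(normal_abundance[gene]),
                "category": category,
            }
        )
    return pd.DataFrame(rows)


def expression_level_scores(
    candidates: list[str],
    stem_prs: pd.DataFrame,
    stem_tables: list[pd.DataFrame],
    config: SelectionConfig = SelectionConfig(),
) -> pd.DataFrame:
    """Expression-level stage: median percentage-rank over expressing
    stem-like cells x median marker logFC over the stem tables marked."""
    config.validate()
    pooled = pd.concat(stem_tables, ignore_index=True) if stem_tables else pd.DataFrame(columns=["gene", "logfc"])
    logfc_by_gene = pooled.groupby("gene")["logfc"].median()
    rows = []
    for gene in candidates:
        med_pr = float(stem_prs[gene].dropna().median())
        med_logfc = float(logfc_by_gene.get(gene, np.nan))
        rows.append(
            {
                "gene": gene,
                "median_pr_stem_cells": med_pr,
                "median_logfc_stem_clusters": med_logfc,
                "pass_expression": bool(
                    med_pr >= config.expr_pr_min_pct and med_logfc > config.expr_logfc_min
                ),
            }
        )
    return pd.DataFrame(rows)


def annotate_location(candidates: list[str], location_table: pd.DataFrame | str) -> pd.Series:
    """Map candidates to membrane / intracellular / unknown.

    ``location_table`` is a two-column TSV (gene, location) or an equivalent
    DataFrame. Conflicting duplicate entries or malformed rows are errors.
    """
    if isinstance(location_table, (str, bytes)) or hasattr(location_table, "__fspath__"):
        raw = pd.read_csv(location_table, sep="\t", dtype=str)
        if list(raw.columns[:2]) != ["gene", "location"]:
            raise ValueError("location table must have columns: gene, location")
        for i, row in raw.iterrows():
            if pd.isna(row["gene"]) or pd.isna(row["location"]):
                raise ValueError(f"location table line {i + 2}: missing field")
            if row["location"] not in ("membrane", "intracellular"):
                raise ValueError(
                    f"location table line {i + 2}: location must be "
                    f"'membrane' or 'intracellular', got {row['location']!r}"
                )
        table = raw
    else:
        table = location_table
    conflicts = table.groupby("gene")["location"].nunique()
    if (conflicts > 1).any():
        bad = conflicts[conflicts > 1].index[0]
        raise ValueError(f"conflicting locations for gene {bad!r}")
    mapping = table.drop_duplicates("gene").set_index("gene")["location"]
    return pd.Series(
        [mapping.get(g, "unknown") for g in candidates], index=candidates, name="location"
    )


def build_report(
    scores: pd.DataFrame,
    cn_results: pd.DataFrame,
    expr_scores: pd.DataFrame,
    locations: pd.Series,
    config: SelectionConfig = SelectionConfig(),
) -> tuple[pd.DataFrame, dict]:
    """Merge all stages into one row per candidate, with pass flags.

    ``scores`` covers the full candidate pool; ``cn_results`` and
    ``expr_scores`` cover the genes that passed the frequency–significance
    filter (their gene sets must agree); ``locations`` covers at least those
    genes. Returns (report, summary) where summary carries per-category
    counts and the shortlists.
    """
    config.validate()
    passed = set(cn_results["gene"])
    if passed != set(expr_scores["gene"]):
        raise ValueError("cancer/normal and expression stages cover different gene sets")
    if not passed <= set(scores["gene"]):
        raise ValueError("stage outputs contain genes outside the candidate pool")
    if not passed <= set(locations.index):
        raise ValueError("locations missing for some passing candidates")

    report = scores.copy()
    report["pass_freq_sig"] = (
        (report["frequency_pct"] > config.freq_min_pct)
        & (report["median_p_rank_pct"] < config.med_prank_max_pct)
    )
    if set(report.loc[report["pass_freq_sig"], "gene"]) != passed:
        raise ValueError("stage outputs do not match the frequency–significance pass set")
    report = report.merge(cn_results, on="gene", how="left")
    report = report.merge(expr_scores, on="gene", how="left")
    report["location"] = report["gene"].map(locations).fillna("unknown")
    report["pass_cancer_normal"] = report["category"].isin(("red_cross", "orange", "brown"))
    report["pass_expression"] = report["pass_expression"].astype("boolean").fillna(False).astype(bool)
    report["is_surface"] = report["location"] == "membrane"
    report = report.sort_values(
        ["pass_freq_sig", "frequency_pct", "median_p_rank_pct", "gene"],
        ascending=[False, False, True, True],
        kind="mergesort",
        ignore_index=True,
    )
    report.attrs["config"] = asdict(config)

    all_criteria = report[
        report["pass_freq_sig"]
        & report["pass_cancer_normal"]
        & report["pass_expression"]
        & report["is_surface"]
    ]
    summary = {
        "config": asdict(config),
        "n_candidates": int(len(report)),
        "n_pass_freq_sig": int(report["pass_freq_sig"].sum()),
        "category_counts": {
            c: int((report["category"] == c).sum()) for c in CATEGORIES
        },
        "shortlists": {
            "cancer_specific": sorted(report.loc[report["category"] == "red_cross", "gene"]),
            "high_expression": sorted(
                report.loc[report["pass_freq_sig"] & report["pass_expression"], "gene"]
            ),
            "surface": sorted(report.loc[report["pass_freq_sig"] & report["is_surface"], "gene"]),
            "all_criteria": sorted(all_criteria["gene"]),
        },
    }
    return report, summary
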