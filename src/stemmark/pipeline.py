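"""End-to-end orchestration.

Stages (simulate) -> preprocess -> cluster -> markers -> score -> select ->
report communicate through a run directory: matrices as .h5ad, tables as
TSV, plus a manifest recording the config hash, the seed, and per-stage row
counts. Every stage reads its inputs from the run directory, so stages are
individually rerunnable, and rerunning an identical config reproduces
byte-identical outputs.

All randomness derives from the single configured seed through stage-keyed
substreams (SeedSequence on [seed, crc32(stage)]), so a stage rerun in
isolation sees the same stream as in a full run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import anndata as ad
import yaml

from .synthdata import SyntheticSpec, generate_dataset, write_fixture, read_fixture
from .preprocess import QCThresholds, preprocess
from .cluster_markers import (
    cluster_sample,
    find_cluster_markers,
    annotate_stem_clusters,
    MARKER_COLUMNS,
)
from .rankmetrics import candidate_scores, abundance_table, percentage_rank_matrix
from .selection import (
    SelectionConfig,
    frequency_significance_filter,
    cancer_normal_compare,
    expression_level_scores,
    annotate_location,
    build_report,
)

__all__ = ["RunConfig", "StageError", "ConfigError", "run_pipeline", "ALL_STAGES", "derive_seed"]

logger = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "preprocess", "cluster", "markers", "score", "select", "report")


class ConfigError(ValueError):
    """Invalid run configuration (CLI exit code 2)."""


class StageError(RuntimeError):
    """A pipeline stage failed (CLI exit code 3)."""

    def __init__(self, stage: str, code: str, message: str):
        super().__init__(f"stage {stage}: [{code}] {message}")
        self.stage = stage
        self.code = code


def derive_seed(seed: int, stage: str) -> int:
    """Stage-keyed substream seed, kept below 2**31."""
    key = zlib.crc32(stage.encode())
    return int(np.random.SeedSequence([int(seed), key]).generate_state(1)[0] % (2**31))


@dataclass
class RunConfig:
    outdir: Path = Path("stemmark_run")
    seed: int = 0
    # inputs: either a synthetic spec or a fixture directory (counts.mtx et al.)
    simulate: SyntheticSpec | None = None
    input_dir: Path | None = None
    skip_normalization: bool = False
    qc: QCThresholds = field(default_factory=QCThresholds)
    # clustering
    n_pcs: int = 20
    n_neighbors: int = 15
    resolution: float = 1.0
    # marker calling
    logfc_min: float = 2.0
    p_max: float = 0.05
    top_k: int = 200
    # stem annotation
    stem_signature: Path | None = None
    stem_labels: Path | None = None
    stem_alpha: float = 0.01
    # selection
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    location_table: Path | None = None
    log_level: str = "INFO"

    def __post_init__(self):
        self.outdir = Path(self.outdir)
        for name in ("input_dir", "stem_signature", "stem_labels", "location_table"):
            v = getattr(self, name)
            if v is not None:
                setattr(self, name, Path(v))
        try:
            self.qc.validate()
            self.selection.validate()
            if self.simulate is not None:
                self.simulate.validate()
        except ValueError as exc:
            raise ConfigError(str(exc)) from exc
        if self.simulate is None and self.input_dir is None:
            raise ConfigError("either a synthetic spec ('simulate') or 'input_dir' is required")
        if self.simulate is None and self.stem_signature is None and self.stem_labels is None:
            raise ConfigError(
                "stem-like annotation needs 'stem_signature' or 'stem_labels' "
                "(synthetic runs default to the planted marker signature)"
            )

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"config file {path} must contain a mapping")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        try:
            if isinstance(raw.get("simulate"), dict):
                sim = dict(raw["simulate"])
                if "seed" not in sim:
                    sim["seed"] = derive_seed(int(raw.get("seed", 0)), "simulate")
                raw["simulate"] = SyntheticSpec(**sim)
            elif raw.get("simulate") is True:
                raw["simulate"] = SyntheticSpec()
            if isinstance(raw.get("qc"), dict):
                raw["qc"] = QCThresholds(**raw["qc"])
            if isinstance(raw.get("selection"), dict):
                raw["selection"] = SelectionConfig(**raw["selection"])
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_jsonable(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, Path):
                d[k] = str(v)
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_jsonable(), sort_keys=True).encode()
        ).hexdigest()[:16]


# ---------------------------------------------------------------------------
# manifest helpers

def _load_manifest(outdir: Path) -> dict:
    path = outdir / "run_manifest.json"
    if path.exists():
        return json.loads(path.read_text())
    return {"stages": {}}

def _write_manifest(outdir: Path, manifest: dict) -> None:
    (outdir / "run_manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True) + "\n"
    )


# ---------------------------------------------------------------------------
# stages

def _fixture_dir(config: RunConfig) -> Path:
    return config.outdir / "fixture" if config.simulate is not None else config.input_dir


def stage_simulate(config: RunConfig) -> dict:
    # the spec's own seed is authoritative; from_dict ties it to the master
    # seed when the config file does not set one explicitly
    adata, truth = generate_dataset(config.simulate)
    write_fixture(adata, truth, config.outdir / "fixture", spec=config.simulate)
    return {"n_cells": adata.n_obs, "n_genes": adata.n_vars}


def stage_preprocess(config: RunConfig) -> dict:
    adata, _ = read_fixture(_fixture_dir(config))
    processed, qc_report = preprocess(adata, config.qc, config.skip_normalization)
    qc_report.to_csv(config.outdir / "qc_report.tsv", sep="\t", index=False)
    processed.write_h5ad(config.outdir / "preprocessed.h5ad")
    return {
        "n_cells_in": adata.n_obs,
        "n_cells_kept": processed.n_obs,
        "n_genes_kept": processed.n_vars,
        "n_cells_removed": int(len(qc_report)),
        "qc_warnings": qc_report.attrs.get("warnings", []),
    }


def _load_preprocessed(config: RunConfig) -> ad.AnnData:
    path = config.outdir / "preprocessed.h5ad"
    if not path.exists():
        raise StageError("cluster", "missing_input", f"{path} not found; run preprocess first")
    adata = ad.read_h5ad(path)
    for col in ("sample_id", "cell_class", "true_cluster", "cluster"):
        if col in adata.obs and isinstance(adata.obs[col].dtype, pd.CategoricalDtype):
            adata.obs[col] = adata.obs[col].astype("object")
    return adata


def stage_cluster(config: RunConfig) -> dict:
    adata = _load_preprocessed(config)
    seed = derive_seed(config.seed, "cluster")
    tumor_samples = sorted(
        adata.obs.loc[adata.obs["cell_class"] == "tumor", "sample_id"].unique()
    )
    if not tumor_samples:
        raise StageError("cluster", "no_tumor_cells", "no cells with cell_class == 'tumor'")
    for sample in tumor_samples:
        cluster_sample(
            adata,
            sample,
            n_pcs=config.n_pcs,
            n_neighbors=config.n_neighbors,
            resolution=config.resolution,
            seed=seed,
        )
    clusters = adata.obs.loc[adata.obs["cell_class"] == "tumor", ["cluster"]]
    clusters.reset_index(names="cell_id").to_csv(
        config.outdir / "clusters.tsv", sep="\t", index=False
    )
    return {
        "n_samples": len(tumor_samples),
        "n_clusters": int(clusters["cluster"].nunique()),
    }


def _load_clustered(config: RunConfig) -> ad.AnnData:
    adata = _load_preprocessed(config)
    path = config.outdir / "clusters.tsv"
    if not path.exists():
        raise StageError("markers", "missing_input", f"{path} not found; run cluster first")
    clusters = pd.read_csv(path, sep="\t").set_index("cell_id")["cluster"]
    adata.obs["cluster"] = clusters.reindex(adata.obs_names)
    return adata


def _marker_tables(config: RunConfig, adata: ad.AnnData) -> list[pd.DataFrame]:
    tables = []
    for cluster_id in sorted(adata.obs["cluster"].dropna().unique()):
        table = find_cluster_markers(
            adata, cluster_id, config.logfc_min, config.p_max, config.top_k
        )
        table.attrs["cluster_id"] = cluster_id
        tables.append(table)
    return tables


def _stem_inputs(config: RunConfig, adata: ad.AnnData):
    """Resolve explicit labels and/or the signature gene set."""
    explicit = None
    if config.stem_labels is not None:
        raw = pd.read_csv(config.stem_labels, sep="\t", dtype={"cluster_id": str})
        explicit = dict(zip(raw["cluster_id"], raw["is_stem"].astype(bool)))
    signature = None
    if config.stem_signature is not None:
        signature = {
            line.strip()
            for line in Path(config.stem_signature).read_text().splitlines()
            if line.strip()
        }
    elif config.simulate is not None and explicit is None:
        truth_path = _fixture_dir(config) / "ground_truth.tsv"
        gt = pd.read_csv(truth_path, sep="\t")
        signature = set(gt.loc[gt["target"] == "stem", "gene"])
    if signature is not None:
        absent = signature - set(adata.var_names)
        if absent:
            logger.info("%d signature genes absent from the dataset", len(absent))
    return explicit, signature


def stage_markers(config: RunConfig) -> dict:
    adata = _load_clustered(config)
    tables = _marker_tables(config, adata)
    pd.concat(tables, ignore_index=True)[MARKER_COLUMNS].to_csv(
        config.outdir / "markers.tsv", sep="\t", index=False
    )
    explicit, signature = _stem_inputs(config, adata)
    annotations = annotate_stem_clusters(
        tables,
        signature=signature,
        background_size=adata.n_vars if signature is not None else None,
        alpha=config.stem_alpha,
        explicit_labels=explicit,
    )
    pd.DataFrame([dataclasses.asdict(a) for a in annotations]).to_csv(
        config.outdir / "stem_annotations.tsv", sep="\t", index=False
    )
    n_stem = sum(a.is_stem for a in annotations)
    if n_stem == 0:
        logger.warning("no cluster annotated stem-like")
    return {"n_clusters": len(tables), "n_stem_clusters": int(n_stem)}


def _load_stem_tables(config: RunConfig) -> list[pd.DataFrame]:
    markers_path = config.outdir / "markers.tsv"
    stem_path = config.outdir / "stem_annotations.tsv"
    for p in (markers_path, stem_path):
        if not p.exists():
            raise StageError("score", "missing_input", f"{p} not found; run markers first")
    markers = pd.read_csv(markers_path, sep="\t")
    stem = pd.read_csv(stem_path, sep="\t")
    stem_ids = list(stem.loc[stem["is_stem"], "cluster_id"])
    if not stem_ids:
        raise StageError("score", "no_stem_clusters", "no cluster annotated stem-like")
    return [
        markers[markers["cluster_id"] == cid].reset_index(drop=True) for cid in stem_ids
    ]


def stage_score(config: RunConfig) -> dict:
    stem_tables = _load_stem_tables(config)
    scores = candidate_scores(stem_tables)
    scores.to_csv(config.outdir / "candidate_scores.tsv", sep="\t", index=False)
    adata = _load_preprocessed(config)
    abundance_table(adata, list(scores["gene"])).to_csv(
        config.outdir / "abundance.tsv", sep="\t", index=False
    )
    return {"n_candidates": len(scores), "n_stem_clusters": len(stem_tables)}


def stage_select(config: RunConfig) -> dict:
    stem_tables = _load_stem_tables(config)
    scores_path = config.outdir / "candidate_scores.tsv"
    if not scores_path.exists():
        raise StageError("select", "missing_input", f"{scores_path} not found; run score first")
    scores = pd.read_csv(scores_path, sep="\t")
    passed = frequency_significance_filter(scores, config.selection)
    candidates = list(passed["gene"])

    adata = _load_clustered(config)
    stem_annotations = pd.read_csv(config.outdir / "stem_annotations.tsv", sep="\t")
    stem_ids = set(stem_annotations.loc[stem_annotations["is_stem"], "cluster_id"])
    stem_mask = adata.obs["cluster"].isin(stem_ids).to_numpy()
    normal_mask = (adata.obs["cell_class"] == "normal").to_numpy()
    if not normal_mask.any():
        raise StageError("select", "no_normal_cells", "no normal reference cells in the dataset")

    stem_prs = percentage_rank_matrix(adata, candidates, stem_mask)
    normal_prs = percentage_rank_matrix(adata, candidates, normal_mask)
    normal_sub = adata[normal_mask]
    n_expr = np.asarray((normal_sub.X > 0).sum(axis=0)).ravel()
    normal_abundance = pd.Series(
        100.0 * n_expr / normal_sub.n_obs, index=adata.var_names
    )[candidates]

    cn = cancer_normal_compare(candidates, stem_prs, normal_prs, normal_abundance, config.selection)
    cn.to_csv(config.outdir / "cancer_normal.tsv", sep="\t", index=False)
    expr = expression_level_scores(candidates, stem_prs, stem_tables, config.selection)
    expr.to_csv(config.outdir / "expression_scores.tsv", sep="\t", index=False)
    return {
        "n_pass_freq_sig": len(candidates),
        "n_red_cross": int((cn["category"] == "red_cross").sum()),
    }


def stage_report(config: RunConfig) -> dict:
    scores = pd.read_csv(config.outdir / "candidate_scores.tsv", sep="\t")
    cn = pd.read_csv(config.outdir / "cancer_normal.tsv", sep="\t")
    expr = pd.read_csv(config.outdir / "expression_scores.tsv", sep="\t")
    genes = list(scores["gene"])
    if config.location_table is not None:
        locations = annotate_location(genes, config.location_table)
    else:
        locations = pd.Series("unknown", index=genes, name="location")
    report, summary = build_report(scores, cn, expr, locations, config.selection)

    report_path = config.outdir / "selection_report.tsv"
    with open(report_path, "w") as fh:
        for key, value in sorted(dataclasses.asdict(config.selection).items()):
            fh.write(f"# {key}={value}\n")
        report.to_csv(fh, sep="\t", index=False)
    summary["seed"] = config.seed
    (config.outdir / "summary.json").write_text(
        json.dumps(summary, indent=1, sort_keys=True) + "\n"
    )
    return {"n_rows": len(report), "n_all_criteria": len(summary["shortlists"]["all_criteria"])}


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "preprocess": stage_preprocess,
    "cluster": stage_cluster,
    "markers": stage_markers,
    "score": stage_score,
    "select": stage_select,
    "report": stage_report,
}


def run_pipeline(config: RunConfig, stages: list[str] | None = None) -> Path:
    """Run the requested stages (default: all applicable) into config.outdir."""
    if stages is None:
        stages = [s for s in ALL_STAGES if s != "simulate" or config.simulate is not None]
    unknown = set(stages) - set(ALL_STAGES)
    if unknown:
        raise ConfigError(f"unknown stages: {sorted(unknown)}")

    config.outdir.mkdir(parents=True, exist_ok=True)
    manifest = _load_manifest(config.outdir)
    manifest["config"] = config.to_jsonable()
    manifest["config_hash"] = config.config_hash()
    manifest["seed"] = config.seed

    for stage in stages:
        logger.info("running stage %s", stage)
        try:
            info = _STAGE_FUNCS[stage](config)
        except StageError as exc:
            manifest["stages"][stage] = {"status": "failed", "error": str(exc)}
            manifest["failed"] = stage
            _write_manifest(config.outdir, manifest)
            raise
        except Exception as exc:
            manifest["stages"][stage] = {"status": "failed", "error": str(exc)}
            manifest["failed"] = stage
            _write_manifest(config.outdir, manifest)
            raise StageError(stage, type(exc).__name__, str(exc)) from exc
        manifest["stages"][stage] = {"status": "complete", **info}
        manifest.pop("failed", None)
        _write_manifest(config.outdir, manifest)
    return config.outdir
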