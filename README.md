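# stemmark

Rank-based prioritization of stem-like tumor-cell markers from multi-sample
single-cell RNA-seq.

## The problem

Glioblastoma stem-like cells (GSCs) drive relapse, and targeting them needs
marker genes that are (a) consistently overexpressed by the stem-like
subpopulation across patients, (b) absent or low in normal brain cells, (c)
expressed at a level high enough for the intended assay, and (d) — for
antibody or ligand targeting — translated into a membrane protein. Raw
expression values from different studies cannot be pooled without batch
correction, so `stemmark` scores candidates with statistics that depend only
on ranks, zero patterns, and marker-table membership, which are invariant
under any per-cell monotone rescaling (library-size scaling, CPM, TPM):

- **Abundance** of gene *x* in sample *a*: the percentage of cells
  expressing the gene,
  `Abundance_x^a = 100 × #{cells in a with x > 0} / #{cells in a}`.
- **Percentage-rank** of gene *x* in cell *i*: its ascending rank among the
  cell's non-zero genes, normalized by the number of non-zero genes,
  `PR_x^i = 100 × rank(x among non-zero genes of i) / #{non-zero genes of i}`.
  Zeros are excluded before ranking; a silent gene has *no* percentage-rank
  in that cell (an absent value, never 0).
- **Marker frequency**: the percentage of stem-like clusters whose marker
  table (one-vs-rest Wilcoxon rank-sum within each sample, logFC > 2,
  p < 0.05, top 200 by p-value) contains the gene.
- **Median p-value rank**: the median, over the stem-like clusters a gene
  marks, of its ascending p-value rank normalized by that cluster's marker
  count (×100); lower means more consistently significant.

Candidates passing the joint filter *frequency > 14% and median p-value
rank < 50%* are then compared against a normal-cell reference pool
(Wilcoxon on per-cell percentage-ranks; genes expressed by zero normal
cells are flagged maximally cancer-specific), scored for expression level
(median percentage-rank × median marker logFC), and annotated with protein
location from a user-supplied table.

## Worked example

The package ships a synthetic-study generator (negative-binomial counts
with dropout, per-cluster background effects, planted stem-marker and
cancer-specific gene sets) so the whole pipeline runs without external
data:

```python
import json
import stemmark as sm

config = sm.RunConfig(outdir="run", seed=0, simulate=sm.SyntheticSpec())
sm.run_pipeline(config)

summary = json.loads((config.outdir / "summary.json").read_text())
print("candidates scored:      ", summary["n_candidates"])
print("pass frequency filter:  ", summary["n_pass_freq_sig"])
print("category counts:        ", summary["category_counts"])
print("cancer-specific markers:", summary["shortlists"]["cancer_specific"])
```

prints

```
candidates scored:       461
pass frequency filter:   206
category counts:         {'brown': 32, 'nonsignificant': 130, 'orange': 35, 'red_cross': 9}
cancer-specific markers: ['G0063', 'G0193', 'G0452', 'G0460', 'G0527', 'G0705', 'G0729', 'G1059', 'G1803']
```

461 genes appear in at least one of the six stem-like clusters' marker
tables; 206 of them mark stem-like clusters frequently and significantly
enough to pass the principal filter. Of those, 9 are expressed by zero
normal cells (`red_cross`, the maximally cancer-specific shortlist — all
are genes the generator planted as cancer-specific), 35 are strongly and 32
moderately enriched over normal cells (`orange` / `brown`:
percentage-rank logFC > 1 resp. in (0.5, 1), at p < 0.01), and the rest do
not separate from normal brain cells. The top of the candidate table:

```
 gene  n_stem_clusters_marked  frequency_pct  median_p_rank_pct
G1049                       6          100.0          11.594473
G1106                       6          100.0          15.617433
G0118                       6          100.0          18.681456
```

The same thing from a shell, stage by stage or end to end:

```sh
stemmark run --outdir run --seed 0 --config run.yaml   # all stages
stemmark simulate --config run.yaml                    # or individually:
stemmark preprocess --config run.yaml
stemmark cluster --config run.yaml
...
```

The within-cluster significance statistic is available directly: a marker
ranked 66th by p-value among a cluster's 702 selected markers sits at

```python
>>> sm.round_pct(sm.p_rank_percent(66, 702))
9.4
```

i.e. the top 9.4% of that cluster's markers.

## Layout

- `src/stemmark/synthdata.py` — synthetic multi-sample study generator and
  plain-text fixture I/O (MatrixMarket + TSV + JSON manifest).
- `src/stemmark/preprocess.py` — adaptive per-sample QC, gene filters,
  library-size normalization.
- `src/stemmark/cluster_markers.py` — per-sample Leiden clustering,
  Wilcoxon marker calling, p-rank percentages, stem-like annotation.
- `src/stemmark/rankmetrics.py` — abundance, percentage-rank, marker
  frequency, median p-value rank.
- `src/stemmark/selection.py` — the four-stage selection cascade and the
  merged report.
- `src/stemmark/pipeline.py`, `cli.py` — run-directory orchestration and
  the `stemmark` command.
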