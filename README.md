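# restcobind

Integrative analysis of **Rest-complex co-binding** in two pluripotent
cell states. The Rest (NRSF) transcriptional repressor recruits
corepressor complexes — the HDAC adaptor **Sin3A** and the H3K4
demethylase **Lsd1** — to its genomic binding sites, but not every Rest
site carries both partners, and the partner composition shifts between
mouse embryonic stem (ES) cells and epiblast stem (EpiS) cells.
`restcobind` implements the full computational workflow for this kind of
study as a tested, reusable pipeline:

- **Tag preprocessing** — duplicate filtering of 5′-tag alignments,
  ChIP-vs-input depth matching to within 10%, and a minimal
  sliding-window Poisson peak scorer for synthetic data (peak calls with
  p < 10⁻¹⁰ are retained).
- **Co-binding classification** — every Rest peak is classified by
  ≥1-base overlap with Sin3A/Lsd1 peaks into R+/S+/L+, R+/S+/L−,
  R+/S−/L+ or R+/S−/L− (Rest-alone sites are dropped before downstream
  analysis), and site sets are compared across cell states into
  unique/common categories per reference cell.
- **Gene association** — a site belongs to a gene when it overlaps the
  gene body or lies within 50 kb of the gene's 5′ end; TSS-Seq tags are
  clustered into 500-base bins, and unassociated clusters above 5 ppm
  define novel intergenic lncRNA transcription start clusters (TSCs).
- **Signal profiling** — input-normalised binding intensities, ±500-base
  profile matrices with a 25-fold display mask, per-position vertical
  sections, Wilcoxon signed-rank paired comparisons, and mean phastCons
  conservation over ±50 bases around site anchors.
- **Expression integration** — TSS-tag counts/ppm and mRNA-Seq rpkm
  (`rpkm = tags / (kb of transcript × millions of library tags)`), fold
  changes with a one-tag pseudocount, and selection of explicit Rest
  targets whose transcript level rises more than 2-fold upon Rest
  knock-down.
- **Synthetic data** — a generator that plants sites of every
  class × cell-occupancy category on a toy genome with known induction
  folds, so every pipeline stage is testable against ground truth.

## Worked example

Generate the standard synthetic study (5 Mb genome, 60 planted sites at
20× enrichment across all four co-binding classes and three occupancy
categories, 500 k tags per sample) and run the pipeline:

```
restcobind simulate --out fixture --seed 42
restcobind all --data fixture --out results --seed 1
```

or from Python:

```python
from restcobind.simulate import SyntheticConfig, generate_fixture
from restcobind.pipeline import RunConfig, run_pipeline

generate_fixture(SyntheticConfig(seed=42), "fixture")
result = run_pipeline(RunConfig(data_dir="fixture", out_dir="results", seed=1))
print(result.report.table4.head(6).to_string(index=False))
```

which prints the coding-panel knock-down target table computed from the
synthetic data:

```
 panel specificity   cobind  total  induced  percent  empty
coding      unique R+/S+/L+     27        4       15  False
coding      unique R+/S+/L-     37        6       16  False
coding      unique R+/S-/L+     31        7       23  False
coding      common R+/S+/L+     32        6       19  False
coding      common R+/S+/L-     31        8       26  False
coding      common R+/S-/L+     37        7       19  False
```

`total` is the number of genes associated with ES-reference Rest sites
of that specificity × class category, `induced` how many of them exceed
the 2-fold knock-down rule, `percent` the induced rate. On this fixture
the pipeline recovers 100% of planted sites with the correct class and
cell specificity, and all 30 planted induced targets. Summary tables
land under `results/report/`: per-factor site/gene counts (table 1),
co-binding class counts (table 2), cross-cell overlap (table 3) and
target rates (table 4), plus per-stage artifacts (narrowPeak calls, TSC
tables, profile matrices, expression tables).

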