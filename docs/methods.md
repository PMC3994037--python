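# Methods

## Coordinate conventions

All internal coordinates are 0-based, half-open `[start, end)`; an
interval of length L contains exactly L bases. BED input is taken as-is;
1-based formats are converted on read. Overlap between intervals means
≥ 1 shared base — no minimum-fraction rule is applied anywhere, because
the classification and cross-cell comparison are defined purely in terms
of "overlaps / does not overlap". Strand is carried on every record but
ignored for peak overlap (ChIP peaks are unstranded); it matters only
for TSS clustering and gene 5′-end geometry.

## Tag preprocessing

A tag is the 5′-most base of a uniquely mapped read. Duplicate filtering
keeps at most one tag per (chromosome, position, strand, sample) key and
is idempotent. It is applied to ChIP and input libraries only: in
TSS-Seq and mRNA-Seq libraries, independent transcripts legitimately
produce tags at the same base, so position duplicates are signal there
and the pipeline quantifies those libraries unfiltered. Depth matching between a ChIP library and its input
subsamples only the larger library, without replacement, down to
`floor(smaller / (1 − tolerance))` (tolerance 0.10), the largest size
that still satisfies `(larger′ − smaller) / larger′ ≤ tolerance`; the
smaller library is never touched, and the subsample is reproducible from
the seed. Matching is global, not per-chromosome. Tags are extended to
a 200-base putative fragment for coverage pileups (configurable; the
value is a typical sonicated-fragment length, not estimated from data).

## Stand-in peak scorer

Peaks from a production caller can be supplied as narrowPeak and are
consumed as-is after the strict `p < 10⁻¹⁰` filter. For synthetic data
the package provides a deliberately minimal scorer: fixed 300-base
windows every 100 bases, each scored by the Poisson upper tail of the
ChIP 5′-tag count against λ = max(input count in the window scaled to
ChIP depth, genome-wide ChIP rate × window length); significant windows
sharing ≥ 1 base are merged, and the summit is the position of maximal
ChIP tag pileup in the merged span. There is no fragment-model building,
no FDR, and no paired-end support — it exists to exercise the pipeline,
not to replace a peak caller. Enrichment is directional: exchanging the
ChIP and input labels never reproduces a planted site.

## Co-binding classification and cross-cell comparison

Each Rest peak is assigned exactly one of four classes by overlap with
Sin3A and Lsd1 peak sets (R+/S±/L±). A Rest peak overlapping several
partner peaks yields one site with all partners listed — sites are
counted, not pairs. Rest-alone (R+/S−/L−) sites are removed before all
downstream analyses; they lack a catalytic corepressor subunit and have
the weakest signals. Cross-cell commonality is judged on the Rest peak
alone, so a common site's Sin3A/Lsd1 class may differ between cells
(component switching). Counts are per reference cell: one peak may
overlap two peaks on the other side, which is why the two "common"
counts can legitimately differ.

Composition percentages (parts of the retained-class whole) are
integerised by largest-remainder rounding, which guarantees the three
percentages sum to 100; independent rates (induced/total per category)
use plain half-up rounding. Largest-remainder was chosen because it is
the only simple integerisation consistent with the published example
compositions in both cell states.

## Gene association and TSS clusters

A site is associated with every gene whose body it overlaps or whose 5′
end lies within 50 kb (symmetric — the rule names a distance from the 5′
end, not a direction). Site→gene association is deliberately
one-to-many in both directions, which is why site counts and gene counts
differ in the summary tables. TSS tags are clustered per strand into
fixed genome-anchored 500-base bins (`[k·500, (k+1)·500)`); adjacent
non-empty bins are not merged. The simplest reading of a fixed bin width
was preferred over sliding or tag-seeded windows; the cluster interval
is the tag span within the bin. A cluster is assigned to the single
gene with the nearest 5′ end within 50 kb (ties broken lexicographically
on gene id), strand-agnostically. A cluster with > 5 ppm (strict) and no
associated gene is a novel intergenic lncRNA TSC; those join the
annotated non-coding genes to form the lncRNA universe of the
non-coding table panels.

## Signal profiles and intensities

Site intensity is `(ChIP count + 1) / (scaled input count + 1)` over the
site span, with the input scaled by the library-depth ratio. Profile
matrices cover ±500 bases around each site's anchor (peak summit when
known, interval midpoint otherwise) and are normalised per position with
the same pseudocount-1 rule, so a tag-free window normalises to 1 (the
no-enrichment baseline), never to an undefined ratio. Rows are sorted by
descending Rest intensity to match the conventional heat-map layout; the
display mask marks positions strictly above 25-fold. Windows running off
a chromosome end are zero-padded and flagged. Per-position
input-normalisation (rather than a site-level input total) was chosen so
the 25-fold mask has a per-position meaning.

Paired comparisons use the two-sided Wilcoxon signed-rank test: the
exact null for ≤ 25 non-zero differences (with an explicit
sign-enumeration fallback using average ranks when tied |differences|
occur at n ≤ 14), and the normal approximation with continuity
correction otherwise. All-zero difference vectors return p = 1 with a
warning.

Conservation is consumed as a bedGraph track of per-base scores in
[0, 1]; bases absent from the track score 0 (the convention for
unalignable regions) and remain in the denominator of the ±50-base
window mean.

## Expression and knock-down targets

`rpkm = tags / ((gene length / 1000) · (library size / 10⁶))`. TSS-based
gene expression is the sum of tag counts of all clusters assigned to the
gene. Every fold change carries a one-tag pseudocount on both sides, so
0/0 is 1 and silent genes cannot produce infinite folds. A gene is an
explicit Rest target when its knock-down/control rpkm fold strictly
exceeds 2 — a plain threshold with no variance filter, matching the
selection rule the workflow models. Genes missing from either condition
are excluded with a warning. Because one gene can be associated with
sites of different classes, per-category totals can exceed the number of
distinct genes; the package reports both the per-category sums and
deduplicated gene counts.

## Synthetic data generator

The generator emulates the study's data-generating assumptions, not its
sequencing reality:

- **Genome and genes.** One 5 Mb chromosome by default; 260 coding and
  40 non-coding genes with log-uniform lengths (1–20 kb) placed without
  overlap, uniformly within the leading 80% of the chromosome. The
  gene-free tail exists so that genuinely intergenic TSS clusters
  (> 50 kb from every gene 5′ end) are possible on a small genome; on a
  real genome, gene deserts provide this space.
- **Planted sites.** 60 sites: five per co-binding class × cell
  occupancy (ES-only / EpiS-only / both), each 300 bases wide, placed
  1–5 kb upstream of a distinct host gene's 5′ end (guaranteeing
  association under the 50 kb rule) with ≥ 2 kb mutual spacing so the
  window scorer never merges two sites. Enrichment is 20-fold over
  background. The 30 sites with a retained corepressor class and ES
  occupancy are the planted knock-down targets (induction fold 4).
- **Tags.** Each sample draws exactly its configured depth (500 k by
  default) from a background-plus-sites mixture: uniform background and
  extra mass `width × (fold − 1)` at sites bound by that factor in that
  cell. Inputs are pure background. TSS tags fall within 50 bases
  downstream of gene 5′ ends in proportion to expression; ten intergenic
  promoters are planted at ~100 ppm. mRNA tags are uniform over gene
  bodies with rates proportional to expression × body length; under
  knock-down, induced genes' rates are multiplied by the induction fold
  and the library grows proportionally, so raw count ratios centre on
  the planted fold while rpkm folds carry the modest compositional
  shrinkage a real experiment would show. Host genes of planted sites
  get a low baseline expression weight (0.25; repressed targets), other
  genes draw log-normal weights (σ = 0.5).
- **Conservation.** Background 0.1 everywhere; 0.8 over ±50 bases around
  centres of cell-shared sites hosted by coding genes, leaving
  lncRNA-hosted sites at background — the planted coding-versus-lncRNA
  conservation contrast.
- **Determinism.** One master seed; each sample uses a sub-stream keyed
  by a CRC of its label, so adding a sample never changes the others.
  The same configuration and seed reproduce every output file byte for
  byte.

What the generator does **not** model: GC/mappability bias, fragment-
size variation, replicate dispersion, isoform structure, cell-state
expression differences outside the knock-down, or read-level sequences.
Passing recovery tests therefore demonstrates that the pipeline's rules
are implemented correctly and are recoverable under clean Poisson-like
noise — not that the pipeline is robust to real-data artifacts.

## Problem sizes and tolerances

Oracle-equivalence tests run on ≥ 1,000 random instances per operation.
The standard recovery study uses the 5 Mb / 60-site / 500 k-tag
configuration above, where the pipeline is expected to recover ≥ 95% of
planted sites with the correct class and specificity and all planted
induced targets; the scaled-down suite configuration (1 Mb, 12 sites,
100 k tags) keeps the same background density (0.1 tags/base) and
enrichment so per-site statistics are comparable. Exact-test agreement
is checked to floating-point precision against full sign enumeration for
n ≤ 10.

## Known limitations

- The stand-in scorer's fixed window grid can split a site whose summit
  straddles a window boundary; merging of overlapping significant
  windows makes this harmless at 20-fold enrichment but boundary effects
  may appear near the significance threshold.
- Depth matching is global; chromosome-level composition differences
  between ChIP and input are not corrected.
- TSS bin anchoring is genome-fixed; a promoter straddling a bin
  boundary yields two clusters. The association and ppm rules are
  unaffected, but cluster counts are anchor-dependent.
- The cross-cell comparison treats any ≥ 1-base Rest-peak overlap as
  commonality; no reciprocal-fraction variant is provided.
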