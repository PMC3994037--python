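"""Synthetic data generator: a toy genome with planted Rest-complex
occupancy, expression, and conservation, for exercising every pipeline
stage without any sequencing download.

The noise model is deliberately plain: uniform Poisson-like background
tags everywhere, with site-level multiplicative enrichment for the ChIP
factors that occupy a planted site in a given cell state; TSS tags
concentrated immediately downstream of gene 5' ends in proportion to
expression; mRNA tags uniform over gene bodies; the knock-down condition
multiplies induced genes' rates by their planted induction fold (and the
library grows accordingly, as it would in reality).  There is no GC or
mappability bias and no replicate dispersion — enough structure to test
every stated rule, not a read-level simulator.

All randomness flows from one integer seed; each sample draws from a
sub-stream keyed by a label hash, so adding a sample never perturbs the
others.  The same seed reproduces every output bit for bit.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from .cobinding import CobindClass
from .genes import GeneModel, read_gene_models, write_gene_models
from .intervals import (
    GenomicInterval,
    GenomeLayout,
    PathLike,
    intervals_overlap,
    read_chrom_sizes,
    write_chrom_sizes,
)
from .tags import read_tags_bed, write_tags_bed

CELLS = ("ES", "EpiS")
FACTORS = ("Rest", "Sin3A", "Lsd1")
OCCUPANCIES = ("ES-only", "EpiS-only", "both")


@dataclass(frozen=True)
class SiteSpec:
    """Blueprint of one planted binding site."""

    cobind: str  # CobindClass value, e.g. "R+/S+/L+"
    occupancy: str  # ES-only | EpiS-only | both
    enrichment: float = 20.0
    induced: bool = False
    induction_fold: float = 4.0

    def __post_init__(self) -> None:
        CobindClass(self.cobind)  # validates
        if self.occupancy not in OCCUPANCIES:
            raise ValueError(f"unknown occupancy {self.occupancy!r}")
        if self.enrichment < 1:
            raise ValueError("enrichment fold must be >= 1")
        if self.induced and self.induction_fold <= 1:
            raise ValueError("induction fold must exceed 1 for induced sites")


def default_site_spec() -> List[SiteSpec]:
    """The standard 60-site layout: 5 sites per (class x occupancy) cell.

    The 30 sites whose class retains a corepressor and whose Rest peak
    exists in ES cells (occupancy ES-only or both) are the planted
    knock-down-responsive targets (induction fold 4).
    """
    spec: List[SiteSpec] = []
    for cls in CobindClass:
        for occ in OCCUPANCIES:
            induced = cls != CobindClass.SmLm and occ != "EpiS-only"
            for _ in range(5):
                spec.append(SiteSpec(cls.value, occ, 20.0, induced, 4.0))
    return spec


@dataclass
class SyntheticConfig:
    """Study conditions for the standard synthetic fixture."""

    seed: int = 42
    genome: List[Tuple[str, int]] = field(
        default_factory=lambda: [("chr1", 5_000_000)]
    )
    n_coding_genes: int = 260
    n_noncoding_genes: int = 40
    n_intergenic_promoters: int = 10
    site_spec: List[SiteSpec] = field(default_factory=default_site_spec)
    background_rate: Optional[float] = None  # tags/base; None => depth/genome
    chip_depth: int = 500_000
    input_depth: int = 500_000
    tss_depth: int = 500_000
    mrna_depth: int = 500_000
    fragment_extension: int = 200
    site_width: int = 300
    site_min_gap: int = 2_000
    site_gene_distance: Tuple[int, int] = (1_000, 5_000)
    gene_region_fraction: float = 0.8
    gene_length_range: Tuple[int, int] = (1_000, 20_000)
    repressed_expr_weight: float = 0.25
    expr_lognorm_sigma: float = 0.5
    intergenic_ppm: float = 100.0
    conservation_background: float = 0.1
    conservation_site: float = 0.8

    def to_dict(self) -> dict:
        d = asdict(self)
        d["genome"] = [list(g) for g in self.genome]
        d["site_gene_distance"] = list(self.site_gene_distance)
        d["gene_length_range"] = list(self.gene_length_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        d = dict(d)
        d["genome"] = [tuple(g) for g in d.get("genome", [("chr1", 5_000_000)])]
        if "site_spec" in d:
            d["site_spec"] = [
                s if isinstance(s, SiteSpec) else SiteSpec(**s)
                for s in d["site_spec"]
            ]
        for key in ("site_gene_distance", "gene_length_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()

    @classmethod
    def from_yaml(cls, path: PathLike) -> "SyntheticConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: PathLike) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def _stream(seed: int, label: str) -> np.random.Generator:
    """Independent, label-keyed sub-stream of the master seed."""
    return np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(label.encode())])


@dataclass
class PlantedSite:
    site_id: str
    interval: GenomicInterval
    cobind: CobindClass
    occupancy: str
    enrichment: float
    gene_id: str
    induced: bool
    induction_fold: float

    def rest_in(self, cell: str) -> bool:
        return self.occupancy == "both" or self.occupancy == f"{cell}-only"

    def factor_in(self, factor: str, cell: str) -> bool:
        if not self.rest_in(cell):
            return False
        if factor == "Rest":
            return True
        if factor == "Sin3A":
            return self.cobind in (CobindClass.SpLp, CobindClass.SpLm)
        if factor == "Lsd1":
            return self.cobind in (CobindClass.SpLp, CobindClass.SmLp)
        raise ValueError(f"unknown factor {factor!r}")


@dataclass
class SyntheticTruth:
    layout: GenomeLayout
    genes: List[GeneModel]
    sites: List[PlantedSite]
    gene_expression: pd.DataFrame  # gene_id, baseline_expr, kd_fold
    promoters: pd.DataFrame  # chrom, pos, strand, weight


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------

def generate_annotation(
    config: SyntheticConfig,
) -> Tuple[GenomeLayout, List[GeneModel]]:
    """Place non-overlapping genes uniformly within the leading
    ``gene_region_fraction`` of each chromosome.

    Gene lengths are log-uniform over ``gene_length_range``; strands are
    random; the first ``n_coding_genes`` ids (after shuffling positions)
    are coding.  The trailing genome fraction is left gene-free so that
    genuinely intergenic TSS clusters (> 50 kb from any 5' end) can exist
    on a small toy genome.
    """
    layout = GenomeLayout(dict(config.genome))
    n_genes = config.n_coding_genes + config.n_noncoding_genes
    if n_genes == 0:
        return layout, []
    rng = _stream(config.seed, "annotation")
    lo, hi = config.gene_length_range
    lengths = np.exp(
        rng.uniform(np.log(lo), np.log(hi), size=n_genes)
    ).astype(np.int64)

    total_genome = sum(size for _, size in config.genome)
    per_chrom = {
        chrom: max(1, round(n_genes * size / total_genome))
        for chrom, size in config.genome
    }
    # adjust rounding drift on the largest chromosome
    drift = n_genes - sum(per_chrom.values())
    largest = max(config.genome, key=lambda cs: cs[1])[0]
    per_chrom[largest] += drift

    coding_flags = np.zeros(n_genes, dtype=bool)
    coding_flags[: config.n_coding_genes] = True
    rng.shuffle(coding_flags)

    genes: List[GeneModel] = []
    cursor = 0
    for chrom, size in config.genome:
        k = per_chrom[chrom]
        chrom_lengths = lengths[cursor : cursor + k]
        usable = int(size * config.gene_region_fraction)
        free = usable - int(chrom_lengths.sum())
        if free < k + 1:
            raise ValueError(
                f"cannot place {k} genes totalling {chrom_lengths.sum()} bases "
                f"in {usable} usable bases of {chrom}"
            )
        gaps = np.floor(rng.dirichlet(np.ones(k + 1)) * free).astype(np.int64)
        pos = 0
        for j in range(k):
            pos += int(gaps[j])
            start = pos
            end = start + int(chrom_lengths[j])
            strand = "+" if rng.random() < 0.5 else "-"
            idx = cursor + j
            genes.append(
                GeneModel(
                    gene_id=f"g{idx:04d}",
                    chrom=chrom,
                    strand=strand,
                    tx_start=start,
                    tx_end=end,
                    coding=bool(coding_flags[idx]),
                )
            )
            pos = end
        cursor += k
    return layout, genes


# ---------------------------------------------------------------------------
# Site planting
# ---------------------------------------------------------------------------

def plant_sites(
    config: SyntheticConfig,
    layout: GenomeLayout,
    genes: Sequence[GeneModel],
) -> SyntheticTruth:
    """Realise the configured site blueprint on the generated annotation.

    Each site is placed just upstream (1-5 kb by default) of a distinct
    host gene's 5' end, guaranteeing association under the 50 kb rule, and
    sites keep a minimum mutual gap so the window peak scorer never merges
    two planted sites.  Induced sites mark their host gene with the
    planted knock-down induction fold; host genes of any planted site get
    the low "repressed" baseline expression weight, all other genes draw
    log-normal baseline weights.
    """
    rng = _stream(config.seed, "sites")
    gene_order = list(genes)
    rng.shuffle(gene_order)
    placed: List[PlantedSite] = []
    occupied: List[GenomicInterval] = []
    gene_iter = iter(gene_order)
    width = config.site_width
    dlo, dhi = config.site_gene_distance

    for i, spec in enumerate(config.site_spec):
        site_iv = None
        host = None
        while site_iv is None:
            host = next(gene_iter, None)
            if host is None:
                raise ValueError("ran out of host genes while planting sites")
            for _ in range(20):
                d = int(rng.integers(dlo, dhi + 1))
                if host.strand == "+":
                    start = host.five_prime - d - width
                else:
                    start = host.five_prime + d + 1
                end = start + width
                if start < 0 or end > layout.chrom_sizes[host.chrom]:
                    continue
                candidate = GenomicInterval(host.chrom, start, end)
                padded = GenomicInterval(
                    host.chrom,
                    max(0, start - config.site_min_gap),
                    end + config.site_min_gap,
                )
                if any(intervals_overlap(padded, o) for o in occupied):
                    continue
                site_iv = candidate
                break
        occupied.append(site_iv)
        placed.append(
            PlantedSite(
                site_id=f"s{i:03d}",
                interval=site_iv,
                cobind=CobindClass(spec.cobind),
                occupancy=spec.occupancy,
                enrichment=spec.enrichment,
                gene_id=host.gene_id,
                induced=spec.induced,
                induction_fold=spec.induction_fold if spec.induced else 1.0,
            )
        )

    # baseline expression weights and knock-down folds
    host_ids = {s.gene_id for s in placed}
    kd_folds = {s.gene_id: s.induction_fold for s in placed}
    expr_rng = _stream(config.seed, "expression")
    rows = []
    for g in genes:
        if g.gene_id in host_ids:
            weight = config.repressed_expr_weight
        else:
            weight = float(
                np.exp(expr_rng.normal(0.0, config.expr_lognorm_sigma))
            )
        rows.append((g.gene_id, weight, kd_folds.get(g.gene_id, 1.0)))
    gene_expr = pd.DataFrame(rows, columns=["gene_id", "baseline_expr", "kd_fold"])

    promoters = _plant_intergenic_promoters(config, layout, genes, gene_expr)
    return SyntheticTruth(
        layout=GenomeLayout(dict(config.genome)),
        genes=list(genes),
        sites=placed,
        gene_expression=gene_expr,
        promoters=promoters,
    )


def _plant_intergenic_promoters(
    config: SyntheticConfig,
    layout: GenomeLayout,
    genes: Sequence[GeneModel],
    gene_expr: pd.DataFrame,
    flank: int = 50_000,
) -> pd.DataFrame:
    """Put novel promoters in the gene-free tail, > 50 kb from every gene
    5' end, with TSS-tag weights targeting ``intergenic_ppm``."""
    n = config.n_intergenic_promoters
    if n == 0:
        return pd.DataFrame(columns=["chrom", "pos", "strand", "weight"])
    rng = _stream(config.seed, "promoters")
    chrom, size = max(config.genome, key=lambda cs: cs[1])
    region_start = int(size * config.gene_region_fraction) + flank + 1_000
    region_end = size - 1_000
    if region_end - region_start < n * 1_000:
        raise ValueError("gene-free tail too small for intergenic promoters")
    step = (region_end - region_start) // n
    fps = [g.five_prime for g in genes if g.chrom == chrom]
    total_gene_weight = float(gene_expr["baseline_expr"].sum())
    share = config.intergenic_ppm * 1e-6
    weight = share * total_gene_weight / max(1e-12, 1.0 - n * share)
    rows = []
    for i in range(n):
        pos = region_start + i * step + int(rng.integers(0, max(1, step // 4)))
        if any(abs(pos - fp) <= flank for fp in fps):
            raise ValueError("intergenic promoter fell within 50 kb of a gene 5' end")
        strand = "+" if rng.random() < 0.5 else "-"
        rows.append((chrom, pos, strand, weight))
    return pd.DataFrame(rows, columns=["chrom", "pos", "strand", "weight"])


# ---------------------------------------------------------------------------
# Tag simulation
# ---------------------------------------------------------------------------

def _uniform_positions(
    rng: np.random.Generator, layout: GenomeLayout, n: int
) -> Tuple[np.ndarray, np.ndarray]:
    """n background positions spread over chromosomes by length."""
    chroms = list(layout.chrom_sizes)
    sizes = np.array([layout.chrom_sizes[c] for c in chroms], dtype=float)
    counts = rng.multinomial(n, sizes / sizes.sum())
    chrom_col = np.repeat(np.arange(len(chroms)), counts)
    pos = np.concatenate(
        [rng.integers(0, layout.chrom_sizes[c], size=k) for c, k in
         zip(chroms, counts)]
    ) if n else np.empty(0, dtype=np.int64)
    return np.array(chroms, dtype=object)[chrom_col], pos.astype(np.int64)


def _frame(chrom, pos, strand, sample_id) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": chrom,
            "pos5": np.asarray(pos, dtype=np.int64),
            "strand": strand,
            "sample_id": sample_id,
        }
    )


def _simulate_chip_sample(
    truth: SyntheticTruth,
    config: SyntheticConfig,
    factor: str,
    cell: str,
) -> pd.DataFrame:
    """Mixture draw: uniform background plus per-site extra mass
    ``width * (enrichment - 1)`` at sites bound by ``factor`` in ``cell``."""
    label = f"chip:{factor}:{cell}"
    rng = _stream(config.seed, label)
    layout = truth.layout
    bound = [s for s in truth.sites if s.factor_in(factor, cell)]
    bg_weight = (
        config.background_rate * layout.total_length
        if config.background_rate is not None
        else float(layout.total_length)
    )
    site_weights = np.array(
        [s.interval.length * (s.enrichment - 1.0) for s in bound], dtype=float
    )
    weights = np.concatenate(([bg_weight], site_weights))
    counts = rng.multinomial(config.chip_depth, weights / weights.sum())
    chrom_bg, pos_bg = _uniform_positions(rng, layout, int(counts[0]))
    parts_chrom = [chrom_bg]
    parts_pos = [pos_bg]
    for s, k in zip(bound, counts[1:]):
        parts_chrom.append(np.full(int(k), s.interval.chrom, dtype=object))
        parts_pos.append(
            rng.integers(s.interval.start, s.interval.end, size=int(k))
        )
    chrom = np.concatenate(parts_chrom)
    pos = np.concatenate(parts_pos).astype(np.int64)
    strand = np.where(rng.random(pos.size) < 0.5, "+", "-")
    return _frame(chrom, pos, strand, f"{factor}_{cell}")


def _simulate_input_sample(
    truth: SyntheticTruth, config: SyntheticConfig, cell: str
) -> pd.DataFrame:
    rng = _stream(config.seed, f"input:{cell}")
    chrom, pos = _uniform_positions(rng, truth.layout, config.input_depth)
    strand = np.where(rng.random(pos.size) < 0.5, "+", "-")
    return _frame(chrom, pos, strand, f"Input_{cell}")


def _simulate_tss_sample(
    truth: SyntheticTruth, config: SyntheticConfig, cell: str
) -> pd.DataFrame:
    """TSS tags: multinomial over genes (baseline weights) and intergenic
    promoters; positions within 50 bases downstream of each 5' end."""
    rng = _stream(config.seed, f"tss:{cell}")
    gw = truth.gene_expression.set_index("gene_id")["baseline_expr"]
    sources: List[Tuple[str, int, str]] = [
        (g.chrom, g.five_prime, g.strand) for g in truth.genes
    ]
    weights = [float(gw[g.gene_id]) for g in truth.genes]
    for r in truth.promoters.itertuples(index=False):
        sources.append((r.chrom, int(r.pos), r.strand))
        weights.append(float(r.weight))
    weights_arr = np.array(weights, dtype=float)
    counts = rng.multinomial(config.tss_depth, weights_arr / weights_arr.sum())
    parts_chrom, parts_pos, parts_strand = [], [], []
    for (chrom, fp, strand), k in zip(sources, counts):
        if k == 0:
            continue
        off = rng.integers(0, 50, size=int(k))
        pos = fp + off if strand == "+" else fp - off
        parts_chrom.append(np.full(int(k), chrom, dtype=object))
        parts_pos.append(np.maximum(pos, 0))
        parts_strand.append(np.full(int(k), strand, dtype=object))
    chrom = np.concatenate(parts_chrom) if parts_chrom else np.empty(0, object)
    pos = (
        np.concatenate(parts_pos).astype(np.int64) if parts_pos
        else np.empty(0, np.int64)
    )
    strand = np.concatenate(parts_strand) if parts_strand else np.empty(0, object)
    return _frame(chrom, pos, strand, f"TSS_{cell}")


def _simulate_mrna_sample(
    truth: SyntheticTruth, config: SyntheticConfig, condition: str
) -> pd.DataFrame:
    """mRNA tags uniform over gene bodies; rates scale with expression
    (times induction fold under knock-down), body length included so rpkm
    recovers the expression weight.  The knock-down library is larger in
    proportion to the total induced mass, as real libraries would be."""
    rng = _stream(config.seed, f"mrna:{condition}")
    expr = truth.gene_expression
    fold = expr["kd_fold"].to_numpy() if condition.endswith("restKD") else 1.0
    lengths = np.array(
        [g.length for g in truth.genes], dtype=float
    )
    weights = expr["baseline_expr"].to_numpy() * fold * (lengths / 1000.0)
    base_weights = expr["baseline_expr"].to_numpy() * (lengths / 1000.0)
    depth = int(round(config.mrna_depth * weights.sum() / base_weights.sum()))
    counts = rng.multinomial(depth, weights / weights.sum())
    parts_chrom, parts_pos = [], []
    for g, k in zip(truth.genes, counts):
        if k == 0:
            continue
        parts_chrom.append(np.full(int(k), g.chrom, dtype=object))
        parts_pos.append(rng.integers(g.tx_start, g.tx_end, size=int(k)))
    chrom = np.concatenate(parts_chrom) if parts_chrom else np.empty(0, object)
    pos = (
        np.concatenate(parts_pos).astype(np.int64) if parts_pos
        else np.empty(0, np.int64)
    )
    strand = np.where(rng.random(pos.size) < 0.5, "+", "-")
    return _frame(chrom, pos, strand, f"mRNA_{condition}")


def simulate_tags(
    truth: SyntheticTruth, config: SyntheticConfig
) -> Dict[str, pd.DataFrame]:
    """All samples of the study design, keyed by sample id.

    ChIP for the three factors in both cells, one input per cell, TSS-Seq
    per cell, and mRNA-Seq for control and Rest-knock-down ES cells.
    """
    samples: Dict[str, pd.DataFrame] = {}
    for cell in CELLS:
        for factor in FACTORS:
            samples[f"{factor}_{cell}"] = _simulate_chip_sample(
                truth, config, factor, cell
            )
        samples[f"Input_{cell}"] = _simulate_input_sample(truth, config, cell)
        samples[f"TSS_{cell}"] = _simulate_tss_sample(truth, config, cell)
    for condition in ("ES_ctrl", "ES_restKD"):
        samples[f"mRNA_{condition}"] = _simulate_mrna_sample(
            truth, config, condition
        )
    return samples


# ---------------------------------------------------------------------------
# Conservation track
# ---------------------------------------------------------------------------

def conservation_segments(
    truth: SyntheticTruth, config: SyntheticConfig, half: int = 50
) -> List[Tuple[str, int, int, float]]:
    """Non-overlapping bedGraph segments: background score everywhere,
    elevated over +/-``half`` around centres of cell-shared sites hosted by
    coding genes (lncRNA-hosted sites stay at background, giving the
    planted coding-vs-lncRNA conservation contrast)."""
    coding = {g.gene_id for g in truth.genes if g.coding}
    elevated = []
    for s in truth.sites:
        if s.occupancy == "both" and s.gene_id in coding:
            c = s.interval.midpoint
            elevated.append((s.interval.chrom, c - half, c + half + 1))
    segments: List[Tuple[str, int, int, float]] = []
    bg = config.conservation_background
    hi = config.conservation_site
    for chrom, size in config.genome:
        windows = sorted(
            (lo, e) for (c, lo, e) in elevated if c == chrom
        )
        cursor = 0
        for lo, e in windows:
            if lo > cursor:
                segments.append((chrom, cursor, lo, bg))
            segments.append((chrom, lo, e, hi))
            cursor = e
        if cursor < size:
            segments.append((chrom, cursor, size, bg))
    return segments


# ---------------------------------------------------------------------------
# Fixture I/O
# ---------------------------------------------------------------------------

SITE_COLUMNS = [
    "site_id", "chrom", "start", "end", "cobind", "occupancy",
    "enrichment", "gene_id", "induced", "induction_fold",
]


def write_fixture(
    truth: SyntheticTruth,
    samples: Dict[str, pd.DataFrame],
    out_dir: PathLike,
    config: SyntheticConfig,
) -> Path:
    """Serialise the complete fixture as plain text.

    Layout: ``tags/<sample>.bed`` (BED6), ``genes.tsv``, ``chrom.sizes``,
    ``conservation.bedgraph``, ``truth/*.tsv``, ``samples.tsv`` and a
    ``manifest.json`` carrying the seed and a config hash.
    """
    out = Path(out_dir)
    (out / "tags").mkdir(parents=True, exist_ok=True)
    (out / "truth").mkdir(exist_ok=True)

    write_chrom_sizes(truth.layout, out / "chrom.sizes")
    write_gene_models(truth.genes, out / "genes.tsv")

    sample_rows = []
    for sample_id in sorted(samples):
        frame = samples[sample_id]
        rel = f"tags/{sample_id}.bed"
        write_tags_bed(frame, out / rel)
        factor, _, rest = sample_id.partition("_")
        sample_rows.append((sample_id, factor, rest, rel, len(frame)))
    pd.DataFrame(
        sample_rows, columns=["sample_id", "kind", "cell", "path", "library_size"]
    ).to_csv(out / "samples.tsv", sep="\t", index=False)

    with open(out / "conservation.bedgraph", "w") as fh:
        for chrom, start, end, score in conservation_segments(truth, config):
            fh.write(f"{chrom}\t{start}\t{end}\t{score:.6g}\n")

    pd.DataFrame(
        [
            (
                s.site_id, s.interval.chrom, s.interval.start, s.interval.end,
                s.cobind.value, s.occupancy, f"{s.enrichment:.6g}", s.gene_id,
                int(s.induced), f"{s.induction_fold:.6g}",
            )
            for s in truth.sites
        ],
        columns=SITE_COLUMNS,
    ).to_csv(out / "truth" / "sites.tsv", sep="\t", index=False)
    truth.gene_expression.to_csv(
        out / "truth" / "gene_expression.tsv", sep="\t", index=False,
        float_format="%.6g",
    )
    truth.promoters.to_csv(
        out / "truth" / "promoters.tsv", sep="\t", index=False,
        float_format="%.6g",
    )

    manifest = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "samples": [row[0] for row in sample_rows],
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    config.to_yaml(out / "config.yaml")
    return out


def generate_fixture(
    config: Optional[SyntheticConfig] = None, out_dir: Optional[PathLike] = None
) -> Tuple[SyntheticTruth, Dict[str, pd.DataFrame]]:
    """End-to-end generation: annotation -> planted truth -> tags
    (optionally serialised to ``out_dir``)."""
    config = config or SyntheticConfig()
    layout, genes = generate_annotation(config)
    truth = plant_sites(config, layout, genes)
    samples = simulate_tags(truth, config)
    if out_dir is not None:
        write_fixture(truth, samples, out_dir, config)
    return truth, samples


def read_truth_sites(path: PathLike) -> List[PlantedSite]:
    frame = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    out = []
    for r in frame.itertuples(index=False):
        out.append(
            PlantedSite(
                site_id=r.site_id,
                interval=GenomicInterval(r.chrom, int(r.start), int(r.end)),
                cobind=CobindClass(r.cobind),
                occupancy=r.occupancy,
                enrichment=float(r.enrichment),
                gene_id=r.gene_id,
                induced=bool(r.induced),
                induction_fold=float(r.induction_fold),
            )
        )
    return out


@dataclass
class Fixture:
    """In-memory view of a serialised fixture directory."""

    root: Path
    layout: GenomeLayout
    genes: List[GeneModel]
    samples: pd.DataFrame  # sample sheet
    truth_sites: List[PlantedSite]
    gene_expression: pd.DataFrame

    def tags(self, sample_id: str) -> pd.DataFrame:
        row = self.samples.loc[self.samples["sample_id"] == sample_id]
        if row.empty:
            raise KeyError(f"no sample {sample_id!r} in fixture")
        return read_tags_bed(self.root / row.iloc[0]["path"], sample_id=sample_id)


def load_fixture(fixture_dir: PathLike) -> Fixture:
    root = Path(fixture_dir)
    return Fixture(
        root=root,
        layout=read_chrom_sizes(root / "chrom.sizes"),
        genes=read_gene_models(root / "genes.tsv"),
        samples=pd.read_csv(root / "samples.tsv", sep="\t"),
        truth_sites=read_truth_sites(root / "truth" / "sites.tsv"),
        gene_expression=pd.read_csv(
            root / "truth" / "gene_expression.tsv", sep="\t"
        ),
    )
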