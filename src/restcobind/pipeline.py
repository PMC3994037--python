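"""End-to-end orchestration: preprocess -> classify -> compare ->
associate -> profile -> express -> targets -> report.

The pipeline consumes a data directory in the fixture layout (a
``samples.tsv`` sheet naming BED6 tag files per sample, gene models,
chromosome sizes and a conservation bedGraph) and emits per-stage
artifacts plus four summary tables mirroring the standard presentation:
per-factor site/gene counts, co-binding class counts, cross-cell overlap
counts, and knock-down target rates.  Everything is deterministic given
the configuration and seed.
"""

from __future__ import annotations

import json
import warnings
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _version
from .cobinding import (
    NON_REST_ONLY,
    CellComparison,
    ClassifiedSite,
    CobindClass,
    classify_cobinding,
    compare_cells,
    drop_rest_only,
)
from .expression import (
    TargetCall,
    compute_rpkm,
    select_targets,
    target_rate_table,
    write_target_calls,
)
from .genes import (
    GeneIndex,
    GeneModel,
    TssCluster,
    associate_cluster_to_gene,
    associate_site_to_genes,
    cluster_tss_tags,
    identify_novel_lnc_tscs,
    read_gene_models,
    tsc_as_gene,
    write_clusters,
)
from .intervals import GenomeLayout, PathLike, read_chrom_sizes
from .signals import (
    ConservationTrack,
    mean_conservation,
    profile_matrix,
    site_intensity,
    threshold_mask,
    vertical_section,
    write_mask_tsv,
    write_profile_tsv,
)
from .tags import (
    PeakCall,
    filter_duplicates,
    filter_peaks_by_pvalue,
    match_depth,
    read_tags_bed,
    score_candidate_peaks,
    write_narrowpeak,
)

CELLS = ("ES", "EpiS")
FACTORS = ("Rest", "Sin3A", "Lsd1")


class ConfigError(Exception):
    """Invalid or incomplete run configuration."""


class DataError(Exception):
    """Input data missing or unusable."""


@dataclass
class RunConfig:
    """All tunable constants of a pipeline run.

    Defaults are the analysis constants of the study design: peak p-value
    cutoff 1e-10, 50 kb gene-association flank, 500-base TSS bins, 5 ppm
    novel-TSC floor, fold > 2 knock-down target rule, +/-500 b profiles
    with a 25-fold display mask, and +/-50 b conservation windows.
    """

    data_dir: str = "."
    out_dir: str = "results"
    p_threshold: float = 1e-10
    flank: int = 50_000
    tss_bin: int = 500
    ppm_cutoff: float = 5.0
    kd_fold_threshold: float = 2.0
    profile_half_width: int = 500
    mask_fold: float = 25.0
    conservation_half: int = 50
    pseudocount: float = 1.0
    extension: int = 200
    peak_window: int = 300
    peak_step: int = 100
    depth_tolerance: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        positive = {
            "flank": self.flank, "tss_bin": self.tss_bin,
            "profile_half_width": self.profile_half_width,
            "conservation_half": self.conservation_half,
            "pseudocount": self.pseudocount, "extension": self.extension,
            "peak_window": self.peak_window, "peak_step": self.peak_step,
        }
        for name, value in positive.items():
            if value <= 0:
                raise ConfigError(f"{name} must be positive, got {value}")
        if not (0 < self.p_threshold < 1):
            raise ConfigError("p_threshold must be in (0, 1)")
        if not (0 <= self.depth_tolerance < 1):
            raise ConfigError("depth_tolerance must be in [0, 1)")

    @classmethod
    def from_yaml(cls, path: PathLike) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        try:
            return cls(**payload)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc

    def to_dict(self) -> dict:
        from dataclasses import asdict

        return asdict(self)

    def config_hash(self) -> str:
        """Hash of the analysis parameters (filesystem paths excluded, so
        the same analysis run elsewhere reports the same hash)."""
        import hashlib

        payload = {
            k: v for k, v in self.to_dict().items()
            if k not in ("data_dir", "out_dir")
        }
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()


@dataclass
class SummaryReport:
    """The four summary tables plus provenance."""

    table1: pd.DataFrame  # per-factor site/gene counts
    table2: pd.DataFrame  # co-binding class counts
    table3: pd.DataFrame  # cross-cell overlap counts
    table4: pd.DataFrame  # knock-down target rates
    provenance: Dict[str, object] = field(default_factory=dict)


@dataclass
class PipelineResult:
    report: SummaryReport
    peaks: Dict[str, List[PeakCall]]  # "<factor>_<cell>" -> filtered peaks
    sites: Dict[str, List[ClassifiedSite]]  # cell -> post-drop sites
    comparison: CellComparison
    site_genes: Dict[int, Dict[str, List[str]]]  # id(site) -> panel -> genes
    novel_tscs: List[TssCluster]
    target_calls: Dict[str, List[TargetCall]]  # panel -> calls
    rpkm: Dict[str, Dict[str, float]]  # condition -> gene -> rpkm


def _require_samples(sheet: pd.DataFrame) -> None:
    required = [f"{f}_{c}" for c in CELLS for f in FACTORS]
    required += [f"Input_{c}" for c in CELLS]
    required += ["TSS_ES", "mRNA_ES_ctrl", "mRNA_ES_restKD"]
    have = set(sheet["sample_id"])
    missing = [s for s in required if s not in have]
    if missing:
        pretty = ", ".join(m.replace("_", "/", 1) for m in missing)
        raise DataError(f"missing sample(s): {pretty}")


def _stage_seed(seed: int, label: str) -> int:
    return (seed * 1_000_003 + zlib.crc32(label.encode())) & 0x7FFFFFFF


class Pipeline:
    """Stage-by-stage executor; artifacts land under ``config.out_dir``."""

    def __init__(self, config: RunConfig) -> None:
        self.config = config
        self.data = Path(config.data_dir)
        self.out = Path(config.out_dir)
        if not (self.data / "samples.tsv").exists():
            raise ConfigError(f"no samples.tsv in data_dir {self.data}")
        self.sheet = pd.read_csv(self.data / "samples.tsv", sep="\t")
        _require_samples(self.sheet)
        self.layout: GenomeLayout = read_chrom_sizes(self.data / "chrom.sizes")
        self.genes: List[GeneModel] = read_gene_models(self.data / "genes.tsv")
        self.log: List[str] = []
        # stage products
        self.tags: Dict[str, pd.DataFrame] = {}
        self.matched: Dict[str, Tuple[pd.DataFrame, pd.DataFrame]] = {}
        self.peaks: Dict[str, List[PeakCall]] = {}
        self.classified: Dict[str, List[ClassifiedSite]] = {}
        self.sites: Dict[str, List[ClassifiedSite]] = {}
        self.comparison: Optional[CellComparison] = None
        self.novel_tscs: List[TssCluster] = []
        self.coding_index: Optional[GeneIndex] = None
        self.noncoding_index: Optional[GeneIndex] = None
        self.site_genes: Dict[int, Dict[str, List[str]]] = {}
        self.rpkm: Dict[str, Dict[str, float]] = {}
        self.tss_expression: Dict[str, Dict[str, int]] = {}
        self.target_calls: Dict[str, List[TargetCall]] = {}
        self.table1 = self.table2 = self.table3 = self.table4 = None

    def _log(self, msg: str) -> None:
        self.log.append(msg)

    def _load_tags(self, sample_id: str) -> pd.DataFrame:
        if sample_id not in self.tags:
            row = self.sheet.loc[self.sheet["sample_id"] == sample_id]
            if row.empty:
                raise DataError(f"missing sample: {sample_id.replace('_', '/', 1)}")
            path = self.data / row.iloc[0]["path"]
            self.tags[sample_id] = read_tags_bed(path, sample_id=sample_id)
        return self.tags[sample_id]

    # ------------------------------------------------------------------
    # Stages
    # ------------------------------------------------------------------

    def preprocess(self) -> None:
        """Duplicate-filter, depth-match ChIP vs input, call + filter peaks."""
        cfg = self.config
        peak_dir = self.out / "peaks"
        peak_dir.mkdir(parents=True, exist_ok=True)
        for cell in CELLS:
            input_tags = filter_duplicates(self._load_tags(f"Input_{cell}"))
            for factor in FACTORS:
                sample = f"{factor}_{cell}"
                chip = filter_duplicates(self._load_tags(sample))
                chip_m, input_m = match_depth(
                    chip, input_tags, tolerance=cfg.depth_tolerance,
                    seed=_stage_seed(cfg.seed, sample),
                )
                self.matched[sample] = (chip_m, input_m)
                called = score_candidate_peaks(
                    chip_m, input_m, self.layout,
                    window_size=cfg.peak_window, step=cfg.peak_step,
                    p_threshold=cfg.p_threshold, sample_id=sample,
                )
                kept = filter_peaks_by_pvalue(called, cfg.p_threshold)
                self.peaks[sample] = kept
                write_narrowpeak(kept, peak_dir / f"{sample}.narrowPeak")
                self._log(
                    f"preprocess {sample}: {len(chip)} tags -> {len(chip_m)} "
                    f"matched, {len(kept)} peaks"
                )

    def classify(self) -> None:
        """Co-binding classification per cell; Rest-alone sites dropped."""
        for cell in CELLS:
            full = classify_cobinding(
                self.peaks[f"Rest_{cell}"],
                self.peaks[f"Sin3A_{cell}"],
                self.peaks[f"Lsd1_{cell}"],
                cell=cell,
            )
            self.classified[cell] = full
            self.sites[cell] = drop_rest_only(full)
            self._log(
                f"classify {cell}: {len(full)} Rest sites, "
                f"{len(self.sites[cell])} after dropping Rest-alone"
            )

    def compare(self) -> None:
        """Cross-cell commonality with ES as the reference cell."""
        self.comparison = compare_cells(self.sites["ES"], self.sites["EpiS"])
        c = self.comparison
        self._log(
            f"compare: ES-unique {len(c.a_unique)}, common(ES) {len(c.common_a)}, "
            f"common(EpiS) {len(c.common_b)}, EpiS-unique {len(c.b_unique)}"
        )

    def associate(self) -> None:
        """Build gene universes (incl. novel lncRNA TSCs) and attach genes."""
        cfg = self.config
        coding = [g for g in self.genes if g.coding]
        noncoding = [g for g in self.genes if not g.coding]

        # TSS tags are NOT duplicate-filtered: independent transcripts
        # legitimately start at the same base, so position duplicates are
        # signal here (dedup is a ChIP-library artifact filter)
        tss = self._load_tags("TSS_ES")
        clusters = cluster_tss_tags(tss, bin=cfg.tss_bin, library_size=len(tss))
        all_index = GeneIndex(self.genes)
        for c in clusters:
            c.associated_gene = associate_cluster_to_gene(c, all_index, cfg.flank)
        self.novel_tscs = identify_novel_lnc_tscs(
            clusters, all_index, ppm_cutoff=cfg.ppm_cutoff, flank=cfg.flank
        )
        assoc_dir = self.out / "association"
        assoc_dir.mkdir(parents=True, exist_ok=True)
        write_clusters(clusters, assoc_dir / "tss_clusters_ES.tsv")

        lnc_universe = noncoding + [tsc_as_gene(c) for c in self.novel_tscs]
        self.coding_index = GeneIndex(coding)
        self.noncoding_index = GeneIndex(lnc_universe)
        for cell in CELLS:
            for site in self.classified[cell]:
                self.site_genes[id(site)] = {
                    "coding": associate_site_to_genes(
                        site.interval, self.coding_index, cfg.flank
                    ),
                    "noncoding": associate_site_to_genes(
                        site.interval, self.noncoding_index, cfg.flank
                    ),
                }
                site.genes = self.site_genes[id(site)]["coding"]
        self._log(
            f"associate: {len(clusters)} TSCs, {len(self.novel_tscs)} novel "
            f"lncRNA TSCs, universes {len(coding)} coding / "
            f"{len(lnc_universe)} non-coding"
        )

    def profile(self) -> None:
        """Rest-anchored signal profiles, masks, vertical sections, and
        site conservation means in ES cells."""
        cfg = self.config
        prof_dir = self.out / "profiles"
        prof_dir.mkdir(parents=True, exist_ok=True)
        sites = self.sites["ES"]
        if not sites:
            warnings.warn("no ES sites to profile")
            return
        chip_r, input_r = self.matched["Rest_ES"]
        rest_int = [
            site_intensity(chip_r, input_r, s.interval, cfg.pseudocount)
            for s in sites
        ]
        profiles = []
        for factor in FACTORS:
            chip_m, input_m = self.matched[f"{factor}_ES"]
            prof = profile_matrix(
                sites, chip_m, input_m, factor=factor,
                half_width=cfg.profile_half_width, extension=cfg.extension,
                pseudocount=cfg.pseudocount, genome=self.layout,
                sort_scores=rest_int,
            )
            profiles.append(prof)
            write_profile_tsv(prof, prof_dir / f"{factor}_ES_profile.tsv")
            write_mask_tsv(
                threshold_mask(prof, cfg.mask_fold), prof,
                prof_dir / f"{factor}_ES_mask.tsv",
            )
        curves = vertical_section(profiles)
        pd.DataFrame(curves, index=profiles[0].offsets).rename_axis(
            "offset"
        ).to_csv(prof_dir / "vertical_section_ES.tsv", sep="\t",
                 float_format="%.6g")

        cons_path = self.data / "conservation.bedgraph"
        if cons_path.exists():
            track = ConservationTrack.from_bedgraph(cons_path)
            rows = []
            for s in sites:
                rows.append(
                    (
                        f"{s.interval.chrom}:{s.interval.start}-{s.interval.end}",
                        s.cobind.value,
                        s.specificity or "",
                        f"{mean_conservation(s, track, cfg.conservation_half):.6g}",
                    )
                )
            pd.DataFrame(
                rows, columns=["site", "cobind", "specificity", "mean_phastcons"]
            ).to_csv(prof_dir / "conservation_ES.tsv", sep="\t", index=False)
        self._log(f"profile: {len(sites)} ES sites profiled")

    def express(self) -> None:
        """TSS-cluster gene expression and mRNA rpkm per condition."""
        cfg = self.config
        all_index = GeneIndex(self.genes)
        for cell in CELLS:
            sample = f"TSS_{cell}"
            if sample not in set(self.sheet["sample_id"]):
                continue
            tss = self._load_tags(sample)
            clusters = cluster_tss_tags(tss, bin=cfg.tss_bin, library_size=len(tss))
            per_gene: Dict[str, int] = {}
            for c in clusters:
                gene = associate_cluster_to_gene(c, all_index, cfg.flank)
                if gene is not None:
                    per_gene[gene] = per_gene.get(gene, 0) + c.tag_count
            self.tss_expression[cell] = per_gene

        gene_bodies = {
            g.gene_id: g for g in self.genes
        }
        for condition in ("ES_ctrl", "ES_restKD"):
            # like TSS tags, mRNA tag duplicates are kept as signal
            tags = self._load_tags(f"mRNA_{condition}")
            library = len(tags)
            by_chrom = {
                chrom: np.sort(sub["pos5"].to_numpy())
                for chrom, sub in tags.groupby("chrom")
            }
            rpkm: Dict[str, float] = {}
            for g in self.genes:
                pos = by_chrom.get(g.chrom)
                count = 0
                if pos is not None:
                    count = int(
                        np.searchsorted(pos, g.tx_end)
                        - np.searchsorted(pos, g.tx_start)
                    )
                rpkm[g.gene_id] = compute_rpkm(count, g.length, library)
            self.rpkm[condition] = rpkm
            self._log(f"express {condition}: {library} tags")

        expr_dir = self.out / "expression"
        expr_dir.mkdir(parents=True, exist_ok=True)
        rows = []
        for cell, per_gene in self.tss_expression.items():
            for gene, count in sorted(per_gene.items()):
                rows.append((gene, cell, "tss_tag_count", count))
        for condition, per_gene in self.rpkm.items():
            for gene, value in sorted(per_gene.items()):
                rows.append((gene, condition, "mrna_rpkm", f"{value:.6g}"))
        pd.DataFrame(
            rows, columns=["gene_id", "condition", "measure", "value"]
        ).to_csv(expr_dir / "expression.tsv", sep="\t", index=False)

    def _category_gene_entries(
        self, panel: str
    ) -> List[Tuple[str, str, CobindClass]]:
        """(gene, specificity, cobind) entries for the ES-reference table:
        ES-unique and common(ES) sites, genes from the given universe."""
        assert self.comparison is not None
        entries = set()
        for spec_label, group in (
            ("unique", self.comparison.a_unique),
            ("common", self.comparison.common_a),
        ):
            for site in group:
                for gene in self.site_genes[id(site)][panel]:
                    entries.add((gene, spec_label, site.cobind))
        return sorted(entries, key=lambda e: (e[0], e[1], e[2].value))

    def targets(self) -> None:
        """Knock-down target selection per coding/non-coding panel."""
        cfg = self.config
        ctrl = self.rpkm["ES_ctrl"]
        kd = self.rpkm["ES_restKD"]
        tgt_dir = self.out / "targets"
        tgt_dir.mkdir(parents=True, exist_ok=True)
        for panel in ("coding", "noncoding"):
            calls = select_targets(
                self._category_gene_entries(panel), ctrl, kd,
                threshold=cfg.kd_fold_threshold, pseudocount=cfg.pseudocount,
            )
            self.target_calls[panel] = calls
            write_target_calls(calls, tgt_dir / f"target_calls_{panel}.tsv")
            n_hit = sum(t.is_target for t in calls)
            self._log(f"targets {panel}: {n_hit}/{len(calls)} above fold "
                      f"{cfg.kd_fold_threshold}")

    # ------------------------------------------------------------------
    # Reporting
    # ------------------------------------------------------------------

    def _panel_sites(self, sites: Sequence[ClassifiedSite], panel: str):
        return [s for s in sites if self.site_genes[id(s)][panel]]

    def _genes_of(self, sites: Sequence[ClassifiedSite], panel: str) -> set:
        out = set()
        for s in sites:
            out.update(self.site_genes[id(s)][panel])
        return out

    def build_report(self) -> SummaryReport:
        assert self.comparison is not None
        # Table 1: factor-level site/gene counts per panel and cell
        rows1 = []
        for panel, index in (
            ("coding", self.coding_index),
            ("noncoding", self.noncoding_index),
        ):
            for cell in CELLS:
                for factor in FACTORS:
                    peaks = self.peaks[f"{factor}_{cell}"]
                    genes = set()
                    n_sites = 0
                    for p in peaks:
                        hit = associate_site_to_genes(
                            p.interval, index, self.config.flank
                        )
                        if hit:
                            n_sites += 1
                            genes.update(hit)
                    rows1.append((panel, cell, factor, n_sites, len(genes)))
        table1 = pd.DataFrame(
            rows1, columns=["panel", "cell", "factor", "sites", "genes"]
        )

        # Table 2: class counts (all four classes) per panel and cell
        rows2 = []
        for panel in ("coding", "noncoding"):
            for cell in CELLS:
                for cls in CobindClass:
                    members = [
                        s for s in self.classified[cell] if s.cobind == cls
                    ]
                    members = self._panel_sites(members, panel)
                    rows2.append(
                        (panel, cell, cls.value, len(members),
                         len(self._genes_of(members, panel)))
                    )
        table2 = pd.DataFrame(
            rows2, columns=["panel", "cell", "cobind", "sites", "genes"]
        )

        # Table 3: cross-cell categories x class, with totals
        categories = [
            ("ES-unique", self.comparison.a_unique),
            ("common_ES", self.comparison.common_a),
            ("common_EpiS", self.comparison.common_b),
            ("EpiS-unique", self.comparison.b_unique),
        ]
        rows3 = []
        for panel in ("coding", "noncoding"):
            for label, group in categories:
                in_panel = self._panel_sites(group, panel)
                rows3.append(
                    (panel, label, "total", len(in_panel),
                     len(self._genes_of(in_panel, panel)))
                )
                for cls in NON_REST_ONLY:
                    members = [s for s in in_panel if s.cobind == cls]
                    rows3.append(
                        (panel, label, cls.value, len(members),
                         len(self._genes_of(members, panel)))
                    )
        table3 = pd.DataFrame(
            rows3, columns=["panel", "category", "cobind", "sites", "genes"]
        )

        # Table 4: knock-down target rates per panel
        frames = []
        for panel in ("coding", "noncoding"):
            tbl = target_rate_table(self.target_calls.get(panel, []))
            tbl.insert(0, "panel", panel)
            frames.append(tbl)
        table4 = pd.concat(frames, ignore_index=True)

        provenance = {
            "config_hash": self.config.config_hash(),
            "seed": self.config.seed,
            "version": _version,
        }
        report = SummaryReport(table1, table2, table3, table4, provenance)
        check_report_consistency(report, self)
        return report

    def run(self) -> PipelineResult:
        self.out.mkdir(parents=True, exist_ok=True)
        self.preprocess()
        self.classify()
        self.compare()
        self.associate()
        self.profile()
        self.express()
        self.targets()
        report = self.build_report()
        emit_tables(report, self.out / "report")
        with open(self.out / "run.log", "w") as fh:
            fh.write("\n".join(self.log) + "\n")
        return PipelineResult(
            report=report,
            peaks=self.peaks,
            sites=self.sites,
            comparison=self.comparison,
            site_genes=self.site_genes,
            novel_tscs=self.novel_tscs,
            target_calls=self.target_calls,
            rpkm=self.rpkm,
        )


def check_report_consistency(report: SummaryReport, pipe: Pipeline) -> None:
    """Cross-table assertions: class counts sum to Rest counts; comparison
    categories partition each cell's post-filter sites; target totals match
    the overlap table's gene counts."""
    t2, t3, t4 = report.table2, report.table3, report.table4
    for panel in ("coding", "noncoding"):
        for cell in CELLS:
            class_sum = t2.query(
                "panel == @panel and cell == @cell"
            )["sites"].sum()
            rest_sites = pipe._panel_sites(pipe.classified[cell], panel)
            if class_sum != len(rest_sites):
                raise AssertionError(
                    f"table2 {panel}/{cell}: class sum {class_sum} != "
                    f"{len(rest_sites)} Rest sites"
                )
    c = pipe.comparison
    if len(c.a_unique) + len(c.common_a) != len(pipe.sites["ES"]):
        raise AssertionError("comparison does not partition ES sites")
    if len(c.b_unique) + len(c.common_b) != len(pipe.sites["EpiS"]):
        raise AssertionError("comparison does not partition EpiS sites")
    for panel in ("coding", "noncoding"):
        for cat, spec in (("ES-unique", "unique"), ("common_ES", "common")):
            for cls in NON_REST_ONLY:
                t3_genes = t3.query(
                    "panel == @panel and category == @cat and "
                    "cobind == @cls.value"
                )["genes"].iloc[0]
                t4_total = t4.query(
                    "panel == @panel and specificity == @spec and "
                    "cobind == @cls.value"
                )["total"].iloc[0]
                if t3_genes != t4_total:
                    raise AssertionError(
                        f"table4 total {t4_total} != table3 gene count "
                        f"{t3_genes} for {panel}/{cat}/{cls.value}"
                    )


def emit_tables(report: SummaryReport, out_dir: PathLike) -> None:
    """One TSV per table (counts and gene counts as separate integer
    columns, percentages as integers) plus a deterministic JSON body."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.table1.to_csv(out / "table1_factor_counts.tsv", sep="\t", index=False)
    report.table2.to_csv(out / "table2_cobinding.tsv", sep="\t", index=False)
    report.table3.to_csv(out / "table3_cross_cell.tsv", sep="\t", index=False)
    t4 = report.table4.copy()
    t4["empty"] = t4["empty"].astype(int)
    t4.to_csv(out / "table4_target_rates.tsv", sep="\t", index=False)
    body = {
        "provenance": report.provenance,
        "table1": report.table1.to_dict(orient="records"),
        "table2": report.table2.to_dict(orient="records"),
        "table3": report.table3.to_dict(orient="records"),
        "table4": t4.to_dict(orient="records"),
    }
    with open(out / "report.json", "w") as fh:
        json.dump(body, fh, indent=2, sort_keys=True)
        fh.write("\n")


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the full stage order and return the report and artifacts."""
    return Pipeline(config).run()
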