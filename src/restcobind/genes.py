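"""Gene models, site-to-gene association, TSS-tag clustering and novel
lncRNA transcription-start-cluster (TSC) discovery.

Association rule: a binding site belongs to a gene when it overlaps the
gene body or lies within ``flank`` bases (default 50 kb) of the gene's
5' end.  The flank is applied symmetrically around the 5' end since no
direction is implied by the rule.  A site may map to several genes and a
gene may collect several sites, so site counts and gene counts differ.

TSS-Seq 5'-tag positions are clustered per strand into fixed,
genome-anchored 500-base bins; each non-empty bin is one TSC whose
expression is its tag count (also expressed in ppm, tags per million
library tags).  A TSC is a novel intergenic lncRNA candidate when its
level exceeds 5 ppm (strict) and no annotated gene 5' end lies within
50 kb.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, OverlapIndex, PathLike, point_distance
from .tags import tag_frame


@dataclass(frozen=True)
class GeneModel:
    """A transcript span with a coding/non-coding flag."""

    gene_id: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    coding: bool = True

    def __post_init__(self) -> None:
        if self.tx_end <= self.tx_start:
            raise ValueError(f"{self.gene_id}: tx_end must exceed tx_start")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: gene strand must be + or -")

    @property
    def five_prime(self) -> int:
        """0-based position of the annotated TSS."""
        return self.tx_start if self.strand == "+" else self.tx_end - 1

    @property
    def body(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.tx_start, self.tx_end, self.strand)

    @property
    def length(self) -> int:
        return self.tx_end - self.tx_start


@dataclass
class TssCluster:
    """One 500-base TSS-tag cluster (TSC)."""

    interval: GenomicInterval
    strand: str
    tag_count: int
    ppm: float
    associated_gene: Optional[str] = None
    novel_lnc: bool = False

    def __post_init__(self) -> None:
        if self.tag_count < 1:
            raise ValueError("a cluster must contain at least one tag")
        if self.novel_lnc and self.associated_gene is not None:
            raise ValueError("novel lncRNA TSC cannot carry a gene association")


class GeneIndex:
    """Overlap + 5'-end lookup over a gene set, chromosome-partitioned."""

    def __init__(self, genes: Sequence[GeneModel]) -> None:
        self.genes = list(genes)
        self._body_index = OverlapIndex()
        self._fp: Dict[str, Tuple[np.ndarray, List[GeneModel]]] = {}
        by_chrom: Dict[str, List[GeneModel]] = {}
        for g in self.genes:
            self._body_index.add(g.body, g)
            by_chrom.setdefault(g.chrom, []).append(g)
        for chrom, glist in by_chrom.items():
            glist.sort(key=lambda g: (g.five_prime, g.gene_id))
            self._fp[chrom] = (
                np.array([g.five_prime for g in glist], dtype=np.int64),
                glist,
            )

    def overlapping(self, iv: GenomicInterval) -> List[GeneModel]:
        return [g for _, g in self._body_index.query_with_data(iv)]

    def five_prime_within(
        self, iv: GenomicInterval, flank: int
    ) -> List[Tuple[GeneModel, int]]:
        """Genes whose 5' end is within ``flank`` of ``iv`` (with distance)."""
        entry = self._fp.get(iv.chrom)
        if entry is None:
            return []
        fps, glist = entry
        lo = int(np.searchsorted(fps, iv.start - flank, side="left"))
        hi = int(np.searchsorted(fps, iv.end - 1 + flank, side="right"))
        out = []
        for g in glist[lo:hi]:
            d = point_distance(iv, g.five_prime)
            if d <= flank:
                out.append((g, d))
        return out


def associate_site_to_genes(
    site: GenomicInterval,
    genes: Union[GeneIndex, Sequence[GeneModel]],
    flank: int = 50_000,
) -> List[str]:
    """All genes a site belongs to: body overlap OR 5' end within ``flank``.

    Returns sorted, de-duplicated gene ids (possibly empty).
    """
    index = genes if isinstance(genes, GeneIndex) else GeneIndex(list(genes))
    hits = {g.gene_id for g in index.overlapping(site)}
    hits.update(g.gene_id for g, _ in index.five_prime_within(site, flank))
    return sorted(hits)


def cluster_tss_tags(
    tss_tags, bin: int = 500, library_size: Optional[int] = None
) -> List[TssCluster]:
    """Cluster TSS 5'-tag positions into fixed per-strand 500-base bins.

    Bins are genome-anchored: ``[k*bin, (k+1)*bin)``.  The cluster interval
    is the tag span within the bin (always contained in one bin).  Tag
    totals are conserved: cluster counts sum to the number of input tags.
    """
    frame = tag_frame(tss_tags)
    if library_size is None:
        library_size = len(frame)
    if library_size <= 0:
        raise ValueError("library_size must be positive")
    if len(frame) == 0:
        return []
    work = frame.assign(bin=frame["pos5"] // bin)
    grouped = work.groupby(["chrom", "strand", "bin"], sort=True)["pos5"]
    clusters: List[TssCluster] = []
    for (chrom, strand, _k), positions in grouped:
        n = int(positions.size)
        lo, hi = int(positions.min()), int(positions.max()) + 1
        clusters.append(
            TssCluster(
                interval=GenomicInterval(chrom, lo, hi, strand),
                strand=strand,
                tag_count=n,
                ppm=1e6 * n / library_size,
            )
        )
    return clusters


def associate_cluster_to_gene(
    cluster: TssCluster,
    genes: Union[GeneIndex, Sequence[GeneModel]],
    flank: int = 50_000,
) -> Optional[str]:
    """The single gene model a TSC is assigned to, or None.

    Among genes whose 5' end lies within ``flank`` of the cluster, the
    nearest 5' end wins; ties break lexicographically on gene id.
    """
    index = genes if isinstance(genes, GeneIndex) else GeneIndex(list(genes))
    candidates = index.five_prime_within(cluster.interval, flank)
    if not candidates:
        return None
    best = min(candidates, key=lambda gd: (gd[1], gd[0].gene_id))
    return best[0].gene_id


def identify_novel_lnc_tscs(
    clusters: Iterable[TssCluster],
    genes: Union[GeneIndex, Sequence[GeneModel]],
    ppm_cutoff: float = 5.0,
    flank: int = 50_000,
) -> List[TssCluster]:
    """Flag intergenic TSCs: > ``ppm_cutoff`` ppm (strict) and no associated
    gene.  Returns new cluster objects with associations filled in and
    ``novel_lnc`` set; together with annotated non-coding genes these form
    the lncRNA universe of the downstream tables.
    """
    index = genes if isinstance(genes, GeneIndex) else GeneIndex(list(genes))
    novel: List[TssCluster] = []
    for c in clusters:
        gene = (
            c.associated_gene
            if c.associated_gene is not None
            else associate_cluster_to_gene(c, index, flank)
        )
        c.associated_gene = gene
        if gene is None and c.ppm > ppm_cutoff:
            c.novel_lnc = True
            novel.append(c)
    return novel


def tsc_as_gene(cluster: TssCluster, idx: int = 0) -> GeneModel:
    """Promote a novel TSC to a non-coding GeneModel for the lncRNA universe."""
    iv = cluster.interval
    return GeneModel(
        gene_id=f"TSC_{iv.chrom}_{iv.start}_{cluster.strand}",
        chrom=iv.chrom,
        strand=cluster.strand,
        tx_start=iv.start,
        tx_end=iv.end,
        coding=False,
    )


# ---------------------------------------------------------------------------
# I/O — refFlat-like TSV and minimal BED12; TSC tables
# ---------------------------------------------------------------------------

GENE_COLUMNS = ["gene_id", "chrom", "strand", "tx_start", "tx_end", "coding"]


def read_gene_models(path: PathLike) -> List[GeneModel]:
    """Read a refFlat-like TSV: gene_id chrom strand txStart txEnd coding."""
    frame = pd.read_csv(path, sep="\t", dtype={"chrom": str, "gene_id": str})
    missing = [c for c in GENE_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"gene table missing columns {missing}")
    return [
        GeneModel(r.gene_id, r.chrom, r.strand, int(r.tx_start), int(r.tx_end),
                  bool(r.coding))
        for r in frame.itertuples(index=False)
    ]


def write_gene_models(genes: Sequence[GeneModel], path: PathLike) -> None:
    pd.DataFrame(
        [
            (g.gene_id, g.chrom, g.strand, g.tx_start, g.tx_end, int(g.coding))
            for g in genes
        ],
        columns=GENE_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


def read_bed12_genes(path: PathLike) -> List[GeneModel]:
    """Minimal BED12 reader; coding is inferred from a non-empty CDS
    (thickEnd > thickStart)."""
    genes: List[GeneModel] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            genes.append(
                GeneModel(
                    gene_id=f[3],
                    chrom=f[0],
                    strand=f[5],
                    tx_start=int(f[1]),
                    tx_end=int(f[2]),
                    coding=int(f[7]) > int(f[6]),
                )
            )
    return genes


def write_clusters(clusters: Sequence[TssCluster], path: PathLike) -> None:
    """BED6-plus-columns table: tag_count, ppm, associated gene, novel flag."""
    rows = []
    for c in clusters:
        rows.append(
            (
                c.interval.chrom,
                c.interval.start,
                c.interval.end,
                c.associated_gene or ".",
                c.tag_count,
                c.strand,
                f"{c.ppm:.6g}",
                int(c.novel_lnc),
            )
        )
    pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "gene", "tag_count", "strand", "ppm",
                 "novel_lnc"],
    ).to_csv(path, sep="\t", index=False)


def read_clusters(path: PathLike) -> List[TssCluster]:
    frame = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    out: List[TssCluster] = []
    for r in frame.itertuples(index=False):
        out.append(
            TssCluster(
                interval=GenomicInterval(r.chrom, int(r.start), int(r.end), r.strand),
                strand=r.strand,
                tag_count=int(r.tag_count),
                ppm=float(r.ppm),
                associated_gene=None if r.gene == "." else r.gene,
                novel_lnc=bool(r.novel_lnc),
            )
        )
    return out
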