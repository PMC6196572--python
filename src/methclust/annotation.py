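"""Genomic-context annotation of CpG sites.

Each site is classified against a gene track as promoter / gene body /
intergenic (promoter = the 2 kb immediately upstream of the stranded
TSS; gene body = [tx_start, tx_end)), with promoter taking precedence
over gene body for the single reported category while all overlapping
genes are retained in ``gene_hits``.  Within a gene body a site is
exonic or intronic; relative to a CpG-island track it is island /
shore (within 2 kb of an island edge) / shelf (the next 2 kb) /
open sea, the nearest island governing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .errors import ContractError
from .io import GeneModel, GenomicSite, IntervalTrack

logger = logging.getLogger(__name__)

__all__ = [
    "RegionAssignment",
    "GeneDMSummary",
    "GeneIndex",
    "assign_region",
    "classify_intragenic",
    "classify_island_context",
    "annotate_calls",
    "summarize_genes",
    "GENE_COUNT_THRESHOLDS",
]

GENE_COUNT_THRESHOLDS = (1, 2, 5, 8, 10, 20, 50, 100)


@dataclass(frozen=True)
class RegionAssignment:
    site: GenomicSite
    category: str  # promoter | gene_body | intergenic
    gene_hits: tuple[tuple[str, str], ...]  # (gene_id, role in {promoter, gene_body})
    subregion: str  # exon | intron | none
    island_context: str  # island | shore | shelf | open_sea | unknown


@dataclass
class GeneDMSummary:
    """Per-gene DM CpG counts by region x direction."""

    gene_id: str
    promoter_hyper: int = 0
    promoter_hypo: int = 0
    gene_body_hyper: int = 0
    gene_body_hypo: int = 0

    @property
    def total(self) -> int:
        return (
            self.promoter_hyper + self.promoter_hypo
            + self.gene_body_hyper + self.gene_body_hypo
        )


class GeneIndex:
    """Interval index over promoter and gene-body regions of a gene track."""

    def __init__(self, genes: list[GeneModel], promoter_bp: int = 2000):
        self.promoter_bp = promoter_bp
        self.genes = {g.gene_id: g for g in genes}
        self._trees: dict[str, IntervalTree] = {}
        for g in genes:
            tree = self._trees.setdefault(g.chrom, IntervalTree())
            ps, pe = g.promoter(promoter_bp)
            ps = max(ps, 0)
            if ps < pe:
                tree.addi(ps, pe, (g.gene_id, "promoter"))
            tree.addi(g.tx_start, g.tx_end, (g.gene_id, "gene_body"))

    def hits(self, chrom: str, pos: int) -> list[tuple[str, str]]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        found = sorted(iv.data for iv in tree.at(pos))
        return found


def assign_region(
    site: GenomicSite,
    genes: "list[GeneModel] | GeneIndex",
    promoter_bp: int = 2000,
    islands: IntervalTrack | None = None,
    shore_bp: int = 2000,
    shelf_bp: int = 2000,
) -> RegionAssignment:
    """Classify one CpG site against a gene track (and optional island track).

    Category precedence for the single reported label is
    promoter > gene_body > intergenic; every overlapping gene is kept in
    ``gene_hits``.  ``subregion`` is exon/intron for sites hitting at
    least one gene body (exon if exonic in any such gene), else none.
    """
    index = genes if isinstance(genes, GeneIndex) else GeneIndex(genes, promoter_bp)
    hits = tuple(index.hits(site.chrom, site.pos))
    roles = {role for _, role in hits}
    if "promoter" in roles:
        category = "promoter"
    elif "gene_body" in roles:
        category = "gene_body"
    else:
        category = "intergenic"
    subregion = "none"
    if "gene_body" in roles:
        subregion = "intron"
        for gid, role in hits:
            if role == "gene_body" and classify_intragenic(site, index.genes[gid]) == "exon":
                subregion = "exon"
                break
    island_context = "unknown"
    if islands is not None:
        island_context = classify_island_context(site, islands, shore_bp, shelf_bp)
    return RegionAssignment(
        site=site, category=category, gene_hits=hits,
        subregion=subregion, island_context=island_context,
    )


def classify_intragenic(site: GenomicSite, gene: GeneModel) -> str:
    """exon/intron dichotomy for a site inside a gene body."""
    if site.chrom != gene.chrom or not gene.tx_start <= site.pos < gene.tx_end:
        raise ContractError(
            f"site {site.chrom}:{site.pos} outside body of {gene.gene_id} "
            f"[{gene.tx_start},{gene.tx_end}) on {gene.chrom}"
        )
    for s, e in gene.exons:
        if s <= site.pos < e:
            return "exon"
    return "intron"


def island_gap(site: GenomicSite, islands: IntervalTrack) -> int | None:
    """Base pairs from the site to the nearest island (0 if inside).

    For a half-open island [s, e): positions in [s, e) have gap 0, the
    position e-1+k has gap k, and s-k has gap k.  Returns None when the
    chromosome has no islands.
    """
    arr = islands.intervals.get(site.chrom)
    if arr is None or len(arr) == 0:
        return None
    starts, ends = arr[:, 0], arr[:, 1]
    inside = (starts <= site.pos) & (site.pos < ends)
    if inside.any():
        return 0
    left = np.where(site.pos >= ends, site.pos - (ends - 1), np.iinfo(np.int64).max)
    right = np.where(site.pos < starts, starts - site.pos, np.iinfo(np.int64).max)
    return int(np.minimum(left, right).min())


def classify_island_context(
    site: GenomicSite,
    islands: IntervalTrack,
    shore_bp: int = 2000,
    shelf_bp: int = 2000,
) -> str:
    """island / shore / shelf / open_sea by distance to the nearest island."""
    gap = island_gap(site, islands)
    if gap is None:
        return "open_sea"
    if gap == 0:
        return "island"
    if gap <= shore_bp:
        return "shore"
    if gap <= shore_bp + shelf_bp:
        return "shelf"
    return "open_sea"


def annotate_calls(
    calls_frame: pd.DataFrame,
    genes: "list[GeneModel] | GeneIndex",
    islands: IntervalTrack | None = None,
    promoter_bp: int = 2000,
    shore_bp: int = 2000,
    shelf_bp: int = 2000,
) -> pd.DataFrame:
    """Append ``category gene_hits subregion island_context`` columns.

    ``gene_hits`` is serialized as ``gene:role`` items joined by ``;``
    (empty string for intergenic sites).
    """
    index = genes if isinstance(genes, GeneIndex) else GeneIndex(genes, promoter_bp)
    cats, hit_strs, subs, isls = [], [], [], []
    n_offtrack = 0
    for chrom, pos in zip(calls_frame["chrom"], calls_frame["pos"]):
        a = assign_region(
            GenomicSite(str(chrom), int(pos)), index,
            islands=islands, shore_bp=shore_bp, shelf_bp=shelf_bp,
        )
        if a.category == "intergenic" and str(chrom) not in index._trees:
            n_offtrack += 1
        cats.append(a.category)
        hit_strs.append(";".join(f"{g}:{r}" for g, r in a.gene_hits))
        subs.append(a.subregion)
        isls.append(a.island_context)
    if n_offtrack:
        logger.warning("%d sites on chromosomes absent from the gene track", n_offtrack)
    out = calls_frame.copy()
    out["category"] = cats
    out["gene_hits"] = hit_strs
    out["subregion"] = subs
    out["island_context"] = isls
    return out


def summarize_genes(
    annotated: pd.DataFrame,
    thresholds: tuple[int, ...] = GENE_COUNT_THRESHOLDS,
) -> tuple[list[GeneDMSummary], pd.DataFrame]:
    """Per-gene DM counts by region x direction, plus a gene-count histogram.

    A CpG contributes to every gene it hits, in the role it hits.  The
    histogram reports, for each threshold t, the number of genes with at
    least t affected CpGs (promoter and body combined).
    """
    per_gene: dict[str, GeneDMSummary] = {}
    for hits, direction in zip(annotated["gene_hits"], annotated["direction"]):
        if not hits:
            continue
        for item in str(hits).split(";"):
            gid, role = item.rsplit(":", 1)
            g = per_gene.setdefault(gid, GeneDMSummary(gene_id=gid))
            attr = ("promoter_" if role == "promoter" else "gene_body_") + direction
            setattr(g, attr, getattr(g, attr) + 1)
    summaries = [per_gene[k] for k in sorted(per_gene)]
    totals = np.array([g.total for g in summaries], dtype=int)
    hist = pd.DataFrame(
        {
            "min_cpgs": list(thresholds),
            "n_genes": [int(np.sum(totals >= t)) for t in thresholds],
        }
    )
    return summaries, hist


def gene_summaries_to_frame(summaries: list[GeneDMSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_id": g.gene_id,
                "promoter_hyper": g.promoter_hyper,
                "promoter_hypo": g.promoter_hypo,
                "gene_body_hyper": g.gene_body_hyper,
                "gene_body_hypo": g.gene_body_hypo,
                "total": g.total,
            }
            for g in summaries
        ],
        columns=[
            "gene_id", "promoter_hyper", "promoter_hypo",
            "gene_body_hyper", "gene_body_hypo", "total",
        ],
    )
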