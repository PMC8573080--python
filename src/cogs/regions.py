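"""Assembly of per-gene genomic regions over which variant posteriors are
aggregated.

A gene's region set has three categories:

``coding``
    The gene's (merged) exon intervals.
``promoter``
    The baited restriction fragment containing the promoter plus its
    immediate flanking fragments. Promoters that were never baited in the
    capture design receive a *virtual bait* on their TSS fragment so their
    promoter-proximal variants still count; virtual baits carry no
    interactions.
``interacting``
    Every other-end fragment (or 5-kb bin) that interacts with one of the
    gene's baits with a CHiCAGO score above the threshold in at least one
    cell type.

All interval logic is half-open; a bait shared by two promoters propagates
its regions to both genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import (
    BaitMap,
    FragmentMap,
    GeneModelSet,
    InteractionTable,
    InvalidConfigError,
    merge_intervals,
)

logger = logging.getLogger(__name__)

CATEGORIES = ("coding", "promoter", "interacting")


@dataclass(frozen=True)
class RegionConfig:
    """Thresholds and switches for region assembly.

    chicago_min: interactions are kept when the score exceeds this in at
    least one cell type (strict >; 5 is the conventional CHiCAGO cut-off).
    flank_count: promoter-proximal fragments per side of the bait.
    bin_bp: bin width for binned (DpnII-style) designs.
    cds_only: restrict the coding category to CDS intervals when available.
    """

    chicago_min: float = 5.0
    pooling: str = "max"
    flank_count: int = 1
    bin_bp: int = 5000
    use_virtual_baits: bool = True
    cds_only: bool = False

    def __post_init__(self) -> None:
        if self.chicago_min < 0:
            raise InvalidConfigError("chicago_min must be >= 0")
        if self.flank_count < 0:
            raise InvalidConfigError("flank_count must be >= 0")
        if self.bin_bp <= 0:
            raise InvalidConfigError("bin_bp must be > 0")


@dataclass
class GeneRegionSets:
    """Long-format region table: gene_id, chrom, start, end, category,
    provenance. ``merged(gene_id[, category])`` returns the disjoint union."""

    frame: pd.DataFrame

    def merged(self, gene_id: str, category: str | None = None) -> pd.DataFrame:
        sub = self.frame[self.frame["gene_id"] == gene_id]
        if category is not None:
            sub = sub[sub["category"] == category]
        return merge_intervals(sub[["chrom", "start", "end"]])

    def genes(self) -> list[str]:
        return sorted(self.frame["gene_id"].unique())

    def __len__(self) -> int:
        return len(self.frame)


def map_to_fragments(chroms, positions, fmap: FragmentMap) -> np.ndarray:
    """Fragment id per 0-based position (-1 where beyond the map)."""
    ids = fmap.locate(chroms, positions)
    n_unmapped = int((ids < 0).sum())
    if n_unmapped:
        logger.info("map_to_fragments: %d positions outside the fragment map", n_unmapped)
    return ids


def promoter_proximal(bait_id: int, fmap: FragmentMap, flank_count: int = 1) -> pd.DataFrame:
    """Bait fragment plus up to ``flank_count`` adjacent fragments per side."""
    rows = []
    for fid in fmap.neighbours(bait_id, flank_count):
        iv = fmap.interval_of(fid)
        rows.append((iv.chrom, iv.start, iv.end, fid))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "frag_id"])


def build_virtual_baits(genes: GeneModelSet, fmap: FragmentMap, baits: BaitMap) -> BaitMap:
    """Add a virtual bait on every promoter fragment missing from the baitmap.

    Genes whose TSS fragment is already baited are linked to that bait if the
    annotation missed them; the operation is idempotent.
    """
    frame = baits.frame.copy()
    links = {fid: set(gs) for fid, gs in zip(frame["frag_id"], frame["genes"])}
    virtual: dict[int, set[str]] = {}
    tss_frag = fmap.locate(genes.tss["chrom"], genes.tss["pos"])
    for gid, fid in zip(genes.tss["gene_id"], tss_frag):
        if fid < 0:
            logger.warning("build_virtual_baits: TSS of %s outside fragment map", gid)
            continue
        fid = int(fid)
        if fid in links:
            links[fid].add(gid)
        else:
            virtual.setdefault(fid, set()).add(gid)
    frame["genes"] = [tuple(sorted(links[fid])) for fid in frame["frag_id"]]
    new_rows = []
    for fid in sorted(virtual):
        iv = fmap.interval_of(fid)
        new_rows.append((fid, iv.chrom, iv.start, iv.end, tuple(sorted(virtual[fid])), True))
    if new_rows:
        frame = pd.concat(
            [frame, pd.DataFrame(new_rows, columns=["frag_id", "chrom", "start", "end", "genes", "virtual"])],
            ignore_index=True,
        )
    return BaitMap(frame)


def interacting_regions(
    interactions: InteractionTable,
    baits: BaitMap,
    cfg: RegionConfig = RegionConfig(),
) -> pd.DataFrame:
    """Other-end intervals attached to each gene via its baits.

    An other-end is kept iff its pooled (max over cell types) score exceeds
    ``cfg.chicago_min``; a bait shared by several genes propagates the region
    to all of them. Baits present in the interaction table but absent from
    the baitmap's gene links are ignored with a log message.
    """
    links = baits.gene_links()
    df = interactions.frame.copy()
    df["pooled"] = interactions.pooled_max()
    df = df[df["pooled"] > cfg.chicago_min]
    unknown = set(df["bait_id"]) - set(links["frag_id"])
    if unknown:
        logger.info("interacting_regions: %d baits have no gene link; ignored", len(unknown))
    merged = df.merge(links, left_on="bait_id", right_on="frag_id", how="inner")
    oe_id = merged["oe_id"] if "oe_id" in merged.columns else pd.Series(-1, index=merged.index)
    out = pd.DataFrame(
        {
            "gene_id": merged["gene"],
            "chrom": merged["oe_chrom"],
            "start": merged["oe_start"],
            "end": merged["oe_end"],
            "category": "interacting",
            "provenance": [
                f"oe:{o}|bait:{b}" for o, b in zip(oe_id.fillna(-1).astype(int), merged["bait_id"])
            ],
        }
    )
    return out.reset_index(drop=True)


def bin_other_ends(interactions: InteractionTable, bin_bp: int = 5000) -> InteractionTable:
    """Snap other-end coordinates to fixed-width bins; baits stay unbinned.

    The bin is the one containing the other-end start coordinate. Other-ends
    of one bait falling in the same bin are combined, keeping the per-cell-
    type maximum score.
    """
    if bin_bp <= 0:
        raise InvalidConfigError("bin_bp must be > 0")
    df = interactions.frame.copy()
    k = (df["oe_start"] // bin_bp).astype(np.int64)
    df["oe_start"] = k * bin_bp
    df["oe_end"] = (k + 1) * bin_bp
    df["oe_id"] = k
    score_cols = interactions.score_cols
    grouped = (
        df.groupby(["bait_id", "oe_chrom", "oe_start", "oe_end", "oe_id"], as_index=False)[score_cols]
        .max()
    )
    return InteractionTable(grouped)


def coding_regions(genes: GeneModelSet, cds_only: bool = False) -> pd.DataFrame:
    """Merged exon (or CDS) intervals per gene, tagged ``coding``."""
    source = genes.exons
    if cds_only:
        if genes.cds is None:
            raise InvalidConfigError("cds_only requested but gene models carry no CDS intervals")
        source = genes.cds
    rows = []
    for gid, sub in source.groupby("gene_id", sort=True):
        merged = merge_intervals(sub[["chrom", "start", "end"]])
        for iv in merged.itertuples(index=False):
            rows.append((gid, iv.chrom, iv.start, iv.end, "coding", "exons"))
    no_exons = set(genes.gene_ids) - set(source["gene_id"])
    if no_exons:
        logger.info("coding_regions: %d genes without exon models", len(no_exons))
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "category", "provenance"])


def assemble_gene_regions(
    genes: GeneModelSet,
    fmap: FragmentMap,
    baits: BaitMap,
    interactions: InteractionTable | None,
    cfg: RegionConfig = RegionConfig(),
) -> GeneRegionSets:
    """Build the full per-gene region sets (coding + promoter + interacting).

    Virtual baits (when enabled) contribute promoter-proximal regions only;
    the interacting category uses real baits alone.
    """
    all_baits = build_virtual_baits(genes, fmap, baits) if cfg.use_virtual_baits else baits

    parts = [coding_regions(genes, cfg.cds_only)]

    prom_rows = []
    for row in all_baits.frame.itertuples(index=False):
        prox = promoter_proximal(row.frag_id, fmap, cfg.flank_count)
        tag = "virtual_bait" if row.virtual else "bait"
        for gid in row.genes:
            for iv in prox.itertuples(index=False):
                prom_rows.append((gid, iv.chrom, iv.start, iv.end, "promoter", f"{tag}:{row.frag_id}|frag:{iv.frag_id}"))
    parts.append(pd.DataFrame(prom_rows, columns=["gene_id", "chrom", "start", "end", "category", "provenance"]))

    if interactions is not None and len(interactions):
        real = BaitMap(all_baits.frame[~all_baits.frame["virtual"]].copy())
        parts.append(interacting_regions(interactions, real, cfg))

    frame = pd.concat(parts, ignore_index=True)
    frame = frame.drop_duplicates().sort_values(
        ["gene_id", "category", "chrom", "start", "end"]
    ).reset_index(drop=True)
    return GeneRegionSets(frame)
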