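"""The COGS score: per-gene aggregation of fine-mapped variant posteriors.

Within one LD block, under the single-causal-variant model, the probability
that the causal variant lies in one of a gene's associated regions is the sum
of the posterior probabilities of the variants those regions cover (each
variant counted once per gene per block, however many regions it falls in).
Blocks are treated as independent, so the gene-level score is the complement
product

.. math:: G = 1 - \\prod_b (1 - s_b)

— the probability that at least one block's causal variant lands in a
gene-associated region. ``G`` is a Bayesian gene prioritisation score in
``[0, 1]``; the conventional reporting threshold is ``G > 0.3`` (strict).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .finemap import FinemapConfig, finemap_gwas
from .regions import CATEGORIES, GeneRegionSets, RegionConfig, assemble_gene_regions
from .types import BaitMap, FragmentMap, GeneModelSet, InteractionTable, LdBlockSet

logger = logging.getLogger(__name__)

#: when a variant falls in several categories of one gene it is counted once;
#: for the decomposition report it is attributed to the first matching
#: category in this order
CATEGORY_PRIORITY = ("coding", "promoter", "interacting")


@dataclass
class CogsResult:
    """Per-gene scores plus their per-block and per-category decomposition."""

    scores: pd.DataFrame       # gene_id, score, coding_share, promoter_share, interacting_share, n_blocks
    block_scores: pd.DataFrame  # gene_id, block_id, block_score
    trait: str = ""
    dataset: str = ""
    overlaps: pd.DataFrame = field(default_factory=pd.DataFrame)


def overlap_variants(region_sets: GeneRegionSets, posteriors: pd.DataFrame) -> pd.DataFrame:
    """Variants covered by each gene's regions, deduplicated per gene.

    Returns a long table (gene_id, variant_id, block_id, ppi, category); a
    variant in several regions/categories of one gene appears once, tagged
    with the highest-priority category it falls in.
    """
    chroms = posteriors["chrom"].to_numpy()
    pos = posteriors["pos0"].to_numpy()
    rows = []
    frame = region_sets.frame
    for gene_id, sub in frame.groupby("gene_id", sort=True):
        hit_cat = np.full(len(posteriors), -1, dtype=np.int8)
        for ci in reversed(range(len(CATEGORY_PRIORITY))):  # low priority first, high overwrites
            cat = CATEGORY_PRIORITY[ci]
            cat_sub = sub[sub["category"] == cat]
            if cat_sub.empty:
                continue
            for chrom, ivs in cat_sub.groupby("chrom"):
                merged = _merge_sorted(ivs["start"].to_numpy(), ivs["end"].to_numpy())
                starts, ends = merged
                mask = chroms == chrom
                if not mask.any():
                    continue
                p = pos[mask]
                idx = np.searchsorted(starts, p, side="right") - 1
                inside = (idx >= 0) & (p < ends[np.clip(idx, 0, None)])
                tgt = np.where(mask)[0][inside]
                hit_cat[tgt] = ci
        hit = hit_cat >= 0
        if not hit.any():
            continue
        sel = posteriors.loc[hit]
        rows.append(
            pd.DataFrame(
                {
                    "gene_id": gene_id,
                    "variant_id": sel["variant_id"].to_numpy(),
                    "block_id": sel["block_id"].to_numpy(),
                    "ppi": sel["ppi"].to_numpy(),
                    "category": [CATEGORY_PRIORITY[c] for c in hit_cat[hit]],
                }
            )
        )
    if not rows:
        return pd.DataFrame(columns=["gene_id", "variant_id", "block_id", "ppi", "category"])
    return pd.concat(rows, ignore_index=True)


def _merge_sorted(starts: np.ndarray, ends: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    order = np.argsort(starts, kind="mergesort")
    starts, ends = starts[order], ends[order]
    out_s, out_e = [], []
    for s, e in zip(starts, ends):
        if out_e and s <= out_e[-1]:
            out_e[-1] = max(out_e[-1], e)
        else:
            out_s.append(s)
            out_e.append(e)
    return np.asarray(out_s), np.asarray(out_e)


def block_score(ppis) -> float:
    """Probability the block's causal variant lies in the gene's regions:
    the sum of the covered variants' posteriors, clamped to 1."""
    s = float(np.sum(np.asarray(ppis, dtype=float)))
    if s > 1.0 + 1e-9:
        logger.warning("block_score: sum of posteriors %.3g > 1; clamping", s)
    return min(s, 1.0)


def gene_score(block_scores) -> float:
    """``G = 1 - prod_b (1 - s_b)`` over the gene's blocks."""
    s = np.asarray(list(block_scores), dtype=float)
    if s.size == 0:
        return 0.0
    return float(1.0 - np.prod(1.0 - s))


def score_genes(region_sets: GeneRegionSets, posteriors: pd.DataFrame, all_genes: list[str] | None = None) -> CogsResult:
    """Aggregate posteriors over region sets into per-gene COGS scores."""
    overlaps = overlap_variants(region_sets, posteriors)
    if overlaps.empty:
        blocks = pd.DataFrame(columns=["gene_id", "block_id", "block_score"])
    else:
        blocks = (
            overlaps.groupby(["gene_id", "block_id"])["ppi"]
            .apply(block_score)
            .rename("block_score")
            .reset_index()
        )
    gene_rows = []
    for gene_id, sub in blocks.groupby("gene_id", sort=True):
        g = gene_score(sub["block_score"])
        cat_mass = overlaps[overlaps["gene_id"] == gene_id].groupby("category")["ppi"].sum()
        total = float(cat_mass.sum())
        shares = {
            f"{cat}_share": (float(cat_mass.get(cat, 0.0)) / total if total > 0 else 0.0)
            for cat in CATEGORIES
        }
        gene_rows.append({"gene_id": gene_id, "score": g, "n_blocks": len(sub), **shares})
    scores = pd.DataFrame(gene_rows, columns=["gene_id", "score", "n_blocks"] + [f"{c}_share" for c in CATEGORIES])
    if all_genes is not None:
        missing = sorted(set(all_genes) - set(scores["gene_id"]))
        if missing:
            zero = pd.DataFrame({"gene_id": missing, "score": 0.0, "n_blocks": 0})
            for c in CATEGORIES:
                zero[f"{c}_share"] = 0.0
            scores = pd.concat([scores, zero], ignore_index=True)
    scores = scores.sort_values("gene_id").reset_index(drop=True)
    return CogsResult(scores=scores, block_scores=blocks, overlaps=overlaps)


def run_cogs(
    gwas: pd.DataFrame,
    fmap: FragmentMap,
    baits: BaitMap,
    interactions: InteractionTable | None,
    genes: GeneModelSet,
    blocks: LdBlockSet,
    finemap_config: FinemapConfig = FinemapConfig(),
    region_config: RegionConfig = RegionConfig(),
    trait: str = "",
    dataset: str = "",
) -> CogsResult:
    """End-to-end COGS: fine-map the GWAS, assemble regions, score genes.

    Deterministic given its inputs; every annotated gene appears in the
    output (score 0 when none of its regions capture posterior mass).
    """
    posteriors = finemap_gwas(gwas, blocks, finemap_config)
    region_sets = assemble_gene_regions(genes, fmap, baits, interactions, region_config)
    result = score_genes(region_sets, posteriors, all_genes=genes.gene_ids)
    result.trait = trait
    result.dataset = dataset
    return result


def combine_runs(results: dict[str, pd.DataFrame], threshold: float = 0.3) -> tuple[pd.DataFrame, set[str]]:
    """Join per-run score tables on gene id; report per-run scores, the max,
    and the union of genes exceeding the threshold in any run."""
    if not results:
        return pd.DataFrame(columns=["gene_id", "max_score"]), set()
    wide = None
    for name in sorted(results):
        sub = results[name][["gene_id", "score"]].rename(columns={"score": f"score_{name}"})
        wide = sub if wide is None else wide.merge(sub, on="gene_id", how="outer")
    score_cols = [c for c in wide.columns if c.startswith("score_")]
    wide[score_cols] = wide[score_cols].fillna(0.0)
    wide["max_score"] = wide[score_cols].max(axis=1)
    wide = wide.sort_values("gene_id").reset_index(drop=True)
    union = set(wide.loc[wide["max_score"] > threshold, "gene_id"])
    return wide, union


def manhattan_table(
    scores: pd.DataFrame,
    genes: GeneModelSet,
    threshold: float = 0.3,
    locus_window: int = 1_000_000,
) -> pd.DataFrame:
    """Gene-level Manhattan plotting table, ordered by genome coordinate.

    Genes with score strictly above the threshold are flagged for labelling;
    a non-coding gene's label is suppressed when a protein-coding gene within
    ``locus_window`` of it is also prioritised. Genes without model
    coordinates are dropped with a log message.
    """
    tss = genes.tss.groupby("gene_id").first().reset_index()
    meta = genes.genes[["gene_id", "name", "chrom", "biotype"]].merge(
        tss[["gene_id", "pos"]], on="gene_id", how="left"
    )
    tab = scores.merge(meta, on="gene_id", how="left")
    n_missing = int(tab["pos"].isna().sum())
    if n_missing:
        logger.info("manhattan_table: dropped %d genes without model coordinates", n_missing)
    tab = tab.dropna(subset=["pos"]).copy()
    tab["pos"] = tab["pos"].astype(np.int64)
    tab["label"] = tab["score"] > threshold

    coding = tab[(tab["biotype"] == "protein_coding") & tab["label"]]
    for i in tab.index[tab["label"] & (tab["biotype"] != "protein_coding")]:
        near = coding[
            (coding["chrom"] == tab.at[i, "chrom"])
            & ((coding["pos"] - tab.at[i, "pos"]).abs() <= locus_window)
        ]
        if len(near):
            tab.at[i, "label"] = False

    chrom_key = tab["chrom"].map(lambda c: (0, int(c)) if str(c).isdigit() else (1, str(c)))
    tab = tab.assign(_k=chrom_key).sort_values(["_k", "pos", "gene_id"]).drop(columns="_k")
    return tab.reset_index(drop=True)
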