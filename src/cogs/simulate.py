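"""Self-consistent synthetic inputs with planted ground truth.

The generator emits everything the pipeline consumes — a restriction-fragment
map, an ldetect-style LD-block partition, gene models, a baitmap with a
stated fraction of promoters left unbaited, promoter interactions with
distance-decaying CHiCAGO-like scores, and GWAS summary statistics — plus a
truth table recording which variant was planted causal for which gene and
through which placement category (coding / promoter / interacting / none).

LD is modelled at the z-score level: the planted causal variant has
``z ~ N(beta/sqrt(V), 1)`` and a non-causal variant at rank distance ``d``
within the block has ``z ~ N(ld_decay**d * beta/sqrt(V), 1)``. This is what a
summary-statistics consumer sees; no haplotypes are simulated.

All randomness flows from one seed through named sub-streams, so identical
configs give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .finemap import case_control_variance
from .types import (
    BaitMap,
    CogsError,
    FragmentMap,
    GeneModelSet,
    InteractionTable,
    InvalidConfigError,
    LdBlockSet,
)

PLACEMENTS = ("coding", "promoter", "interacting", "none")

_MIN_FRAGMENT_BP = 200


@dataclass(frozen=True)
class PlantedEffect:
    """One planted causal variant: target gene, where it sits relative to the
    gene, and its effect size (log-OR, or z-mean under ``effect_scale='z'``)."""

    gene: str
    placement: str
    beta: float

    def __post_init__(self) -> None:
        if self.placement not in PLACEMENTS:
            raise InvalidConfigError(f"unknown placement {self.placement!r}; must be one of {PLACEMENTS}")


@dataclass(frozen=True)
class SyntheticConfig:
    """Stated world for the synthetic genome.

    Defaults describe a compact genome that keeps the realistic proportions:
    HindIII-like ~4 kb fragments, LD blocks large relative to a gene's
    regulatory footprint, and GWAS variants dense relative to gene regions.
    """

    n_chromosomes: int = 2
    chrom_length_bp: int = 3_000_000
    mean_fragment_bp: int = 4_000
    bin_bp: int = 5_000
    n_genes: int = 40
    n_cell_types: int = 3
    n_variants_per_block: int = 60
    n_blocks: int = 8
    n_cases: int = 5_000
    n_controls: int = 5_000
    planted_effects: tuple[PlantedEffect, ...] = ()
    ld_decay: float = 0.5
    unbaited_fraction: float = 0.2
    effect_scale: str = "beta"  # "beta": log-OR; "z": beta is the z-mean directly
    allow_multi_causal: bool = False
    noncoding_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_chromosomes", "chrom_length_bp", "mean_fragment_bp", "bin_bp",
                     "n_genes", "n_cell_types", "n_variants_per_block", "n_blocks",
                     "n_cases", "n_controls"):
            if getattr(self, name) <= 0:
                raise InvalidConfigError(f"{name} must be > 0")
        if not (0.0 <= self.ld_decay <= 1.0):
            raise InvalidConfigError("ld_decay must lie in [0, 1]")
        if not (0.0 <= self.unbaited_fraction <= 1.0):
            raise InvalidConfigError("unbaited_fraction must lie in [0, 1]")
        if self.effect_scale not in ("beta", "z"):
            raise InvalidConfigError("effect_scale must be 'beta' or 'z'")
        if self.n_blocks < self.n_chromosomes:
            raise InvalidConfigError("need at least one LD block per chromosome")
        object.__setattr__(self, "planted_effects", tuple(self.planted_effects))


@dataclass
class TruthSet:
    """Planted causal variants: variant_id, block_id, gene_id, placement, beta."""

    entries: pd.DataFrame

    def target_genes(self) -> set[str]:
        return set(self.entries.loc[self.entries["placement"] != "none", "gene_id"])


@dataclass
class Reference:
    fmap: FragmentMap
    blocks: LdBlockSet
    genes: GeneModelSet
    baits: BaitMap
    chrom_lengths: dict[str, int] = field(default_factory=dict)


def gene_id(i: int) -> str:
    return f"G{i + 1:04d}"


def _streams(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def simulate_reference(config: SyntheticConfig) -> Reference:
    """Fragment map, LD blocks, gene models and baitmap for one genome.

    Fragments partition each chromosome (exponential-ish lengths with a
    floor); LD blocks partition each chromosome into equal parts; each gene
    gets a TSS, 2-4 exons and a strand; ``unbaited_fraction`` of promoters is
    left out of the baitmap (to be rescued by virtual baits downstream).
    """
    rng_frag, rng_gene, rng_bait = _streams(config.seed, 5)[:3]
    L = config.chrom_length_bp
    chroms = [str(i + 1) for i in range(config.n_chromosomes)]

    frag_rows = []
    fid = 0
    for chrom in chroms:
        pos = 0
        while pos < L:
            length = max(_MIN_FRAGMENT_BP, int(rng_frag.exponential(config.mean_fragment_bp)))
            end = min(pos + length, L)
            frag_rows.append((chrom, pos, end, fid))
            fid += 1
            pos = end
    fmap = FragmentMap(pd.DataFrame(frag_rows, columns=["chrom", "start", "end", "frag_id"]))

    per_chrom = [config.n_blocks // config.n_chromosomes] * config.n_chromosomes
    for i in range(config.n_blocks % config.n_chromosomes):
        per_chrom[i] += 1
    block_rows = []
    bid = 0
    for chrom, nb in zip(chroms, per_chrom):
        bounds = np.linspace(0, L, nb + 1).astype(np.int64)
        for s, e in zip(bounds[:-1], bounds[1:]):
            block_rows.append((chrom, int(s), int(e), bid))
            bid += 1
    blocks = LdBlockSet(pd.DataFrame(block_rows, columns=["chrom", "start", "end", "block_id"]))

    gene_rows, tss_rows, exon_rows = [], [], []
    per_chrom_genes = [config.n_genes // config.n_chromosomes] * config.n_chromosomes
    for i in range(config.n_genes % config.n_chromosomes):
        per_chrom_genes[i] += 1
    gi = 0
    for chrom, ng in zip(chroms, per_chrom_genes):
        anchors = np.linspace(0, L, ng + 2)[1:-1]
        for a in anchors:
            gid = gene_id(gi)
            strand = "+" if rng_gene.random() < 0.5 else "-"
            tss = int(np.clip(a + rng_gene.integers(-5_000, 5_000), 20_000, L - 40_000))
            n_exons = int(rng_gene.integers(2, 5))
            biotype = "lincRNA" if rng_gene.random() < config.noncoding_fraction else "protein_coding"
            gene_rows.append({"gene_id": gid, "name": gid, "chrom": chrom, "strand": strand, "biotype": biotype})
            tss_rows.append((gid, chrom, tss))
            pos = tss
            step = 1 if strand == "+" else -1
            for _ in range(n_exons):
                size = int(rng_gene.integers(150, 500))
                s, e = (pos, pos + size) if strand == "+" else (pos - size, pos)
                exon_rows.append((gid, chrom, max(0, s), min(L, e)))
                pos += step * (size + int(rng_gene.integers(1_000, 4_000)))
            gi += 1
    genes = GeneModelSet(
        pd.DataFrame(gene_rows),
        pd.DataFrame(tss_rows, columns=["gene_id", "chrom", "pos"]),
        pd.DataFrame(exon_rows, columns=["gene_id", "chrom", "start", "end"]),
    )

    interacting_targets = {e.gene for e in config.planted_effects if e.placement == "interacting"}
    candidates = sorted(set(genes.gene_ids) - interacting_targets)
    n_unbaited = int(round(config.unbaited_fraction * config.n_genes))
    unbaited = set(rng_bait.choice(candidates, size=min(n_unbaited, len(candidates)), replace=False))

    tss_frag = fmap.locate(genes.tss["chrom"], genes.tss["pos"])
    bait_links: dict[int, set[str]] = {}
    for gid, f in zip(genes.tss["gene_id"], tss_frag):
        if gid in unbaited or f < 0:
            continue
        bait_links.setdefault(int(f), set()).add(gid)
    bait_rows = []
    for f in sorted(bait_links):
        iv = fmap.interval_of(f)
        bait_rows.append((f, iv.chrom, iv.start, iv.end, tuple(sorted(bait_links[f])), False))
    baits = BaitMap(pd.DataFrame(bait_rows, columns=["frag_id", "chrom", "start", "end", "genes", "virtual"]))

    return Reference(fmap, blocks, genes, baits, {c: L for c in chroms})


def _score_scale(dist_bp: float) -> float:
    """Expected interaction score as a function of bait-other-end distance."""
    return 1.0 + 10.0 * np.exp(-abs(dist_bp) / 150_000.0)


def simulate_pchic(config: SyntheticConfig, reference: Reference) -> InteractionTable:
    """Promoter interactions with distance-decaying per-cell-type scores.

    Each bait receives a Poisson number of other-end fragments at
    exponentially distributed distances; scores are Gamma-distributed with a
    mean that decays with distance. Every planted ``interacting`` target gene
    is guaranteed one other-end interaction with a score above 5 in at least
    one cell type (this is the fragment its causal variant will be planted
    in).
    """
    rng = _streams(config.seed, 5)[3]
    fmap, baits = reference.fmap, reference.baits
    gene_to_bait = {g: int(f) for f, gs in zip(baits.frame["frag_id"], baits.frame["genes"]) for g in gs}

    for eff in config.planted_effects:
        if eff.placement == "interacting" and eff.gene not in gene_to_bait:
            raise CogsError(
                f"planted interacting target {eff.gene} has no baited promoter; "
                "it cannot receive promoter interactions"
            )

    rows: list[dict] = []

    def add_row(bait_id: int, oe_fid: int, scores: np.ndarray) -> None:
        iv = fmap.interval_of(oe_fid)
        row = {
            "bait_id": bait_id,
            "oe_chrom": iv.chrom,
            "oe_start": iv.start,
            "oe_end": iv.end,
            "oe_id": oe_fid,
        }
        for k in range(config.n_cell_types):
            row[f"score_CT{k + 1}"] = float(scores[k])
        rows.append(row)

    for bait in baits.frame.itertuples(index=False):
        mid = (bait.start + bait.end) // 2
        n_int = 1 + int(rng.poisson(4))
        for _ in range(n_int):
            dist = rng.exponential(150_000.0) * (1 if rng.random() < 0.5 else -1)
            target = int(mid + dist)
            if not (0 <= target < reference.chrom_lengths[bait.chrom]):
                continue
            oe = fmap.locate([bait.chrom], [target])[0]
            if oe < 0 or oe == bait.frag_id:
                continue
            scale = _score_scale(dist)
            scores = rng.gamma(2.0, scale / 2.0, size=config.n_cell_types)
            add_row(int(bait.frag_id), int(oe), scores)

    # guaranteed interactions for planted interacting targets
    for eff in config.planted_effects:
        if eff.placement != "interacting":
            continue
        bait_id = gene_to_bait[eff.gene]
        biv = fmap.interval_of(bait_id)
        mid = (biv.start + biv.end) // 2
        for attempt in range(100):
            dist = float(rng.uniform(50_000, 250_000)) * (1 if rng.random() < 0.5 else -1)
            target = int(mid + dist)
            if not (0 <= target < reference.chrom_lengths[biv.chrom]):
                continue
            oe = int(fmap.locate([biv.chrom], [target])[0])
            if oe >= 0 and oe != bait_id:
                break
        else:
            raise CogsError(f"could not place a guaranteed interaction for {eff.gene}")
        scores = rng.gamma(2.0, _score_scale(dist) / 2.0, size=config.n_cell_types)
        scores[int(rng.integers(config.n_cell_types))] = float(rng.uniform(6.0, 15.0))
        add_row(bait_id, oe, scores)

    df = pd.DataFrame(rows)
    score_cols = [f"score_CT{k + 1}" for k in range(config.n_cell_types)]
    df = df.groupby(["bait_id", "oe_chrom", "oe_start", "oe_end", "oe_id"], as_index=False)[score_cols].max()
    return InteractionTable(df)


def _placement_position(
    eff: PlantedEffect,
    reference: Reference,
    interactions: InteractionTable | None,
    rng: np.random.Generator,
) -> tuple[str, int]:
    """Pick the genomic position for a planted causal variant."""
    genes = reference.genes
    if eff.gene not in set(genes.gene_ids):
        raise InvalidConfigError(f"planted effect names unknown gene {eff.gene}")
    if eff.placement == "coding":
        ex = genes.exons[genes.exons["gene_id"] == eff.gene]
        row = ex.iloc[int(rng.integers(len(ex)))]
        return row["chrom"], int(rng.integers(row["start"], row["end"]))
    if eff.placement == "promoter":
        tss = genes.tss[genes.tss["gene_id"] == eff.gene].iloc[0]
        fid = int(reference.fmap.locate([tss["chrom"]], [tss["pos"]])[0])
        iv = reference.fmap.interval_of(fid)
        return iv.chrom, int(rng.integers(iv.start, iv.end))
    if eff.placement == "interacting":
        if interactions is None:
            raise CogsError("interacting placement requires the interaction table")
        bait_ids = {
            int(f) for f, gs in zip(reference.baits.frame["frag_id"], reference.baits.frame["genes"])
            if eff.gene in gs
        }
        if not bait_ids:
            raise CogsError(f"planted interacting target {eff.gene} has no baited promoter")
        cand = interactions.frame[
            interactions.frame["bait_id"].isin(bait_ids)
            & (interactions.pooled_max() > 5.0)
        ]
        if cand.empty:
            raise CogsError(f"no qualifying interaction for planted target {eff.gene}")
        row = cand.iloc[int(rng.integers(len(cand)))]
        return row["oe_chrom"], int(rng.integers(row["oe_start"], row["oe_end"]))
    # placement "none": anywhere on the genome
    chrom = str(int(rng.integers(len(reference.chrom_lengths))) + 1)
    return chrom, int(rng.integers(0, reference.chrom_lengths[chrom]))


_BASES = np.array(list("ACGT"))


def simulate_gwas(
    config: SyntheticConfig,
    reference: Reference,
    interactions: InteractionTable | None = None,
) -> tuple[pd.DataFrame, TruthSet]:
    """GWAS summary statistics with the configured planted causal variants.

    Returns the variant table in the pipeline's internal layout (write it
    with :func:`cogs.io.write_gwas` for the HGI-dialect file) and the truth
    set. Per block at most one causal variant is planted unless
    ``allow_multi_causal`` is set.
    """
    rng = _streams(config.seed, 5)[4]
    blocks = reference.blocks.frame

    planted: dict[int, list[tuple[PlantedEffect, int]]] = {}
    for eff in config.planted_effects:
        chrom, ppos = _placement_position(eff, reference, interactions, rng)
        bid = int(reference.blocks.locate([chrom], [ppos])[0])
        if bid in planted and not config.allow_multi_causal:
            raise InvalidConfigError(
                f"two planted effects fall in LD block {bid}; set allow_multi_causal to permit this"
            )
        planted.setdefault(bid, []).append((eff, ppos))

    var_rows = []
    truth_rows = []
    prop_cases = config.n_cases / (config.n_cases + config.n_controls)
    n_total = config.n_cases + config.n_controls

    for block in blocks.itertuples(index=False):
        n = config.n_variants_per_block
        planted_here = planted.get(block.block_id, [])
        planted_pos = [ppos for _, ppos in planted_here]
        n_background = n - len(planted_here)
        background = rng.choice(np.arange(block.start, block.end), size=n, replace=False)
        background = np.setdiff1d(background, np.asarray(planted_pos, dtype=np.int64))[:n_background]
        pos0 = np.sort(np.concatenate([background, np.asarray(planted_pos, dtype=np.int64)]).astype(np.int64))
        causal_ranks = [
            (int(np.searchsorted(pos0, ppos)), eff) for eff, ppos in planted_here
        ]

        maf = rng.uniform(0.05, 0.5, size=n)
        V = case_control_variance(maf, n_total, prop_cases)
        z_mean = np.zeros(n)
        for rank, eff in causal_ranks:
            if config.effect_scale == "z":
                nc = abs(eff.beta)
            else:
                nc = abs(eff.beta) / np.sqrt(V[rank])
            decay = config.ld_decay ** np.abs(np.arange(n) - rank)
            z_mean = z_mean + decay * nc
        z = rng.normal(z_mean, 1.0)
        sign = rng.choice([-1.0, 1.0], size=n)
        z_signed = z * sign
        p = 2.0 * stats.norm.sf(np.abs(z))
        se = np.sqrt(V)
        beta_hat = z_signed * se
        af = np.where(rng.random(n) < 0.5, maf, 1.0 - maf)
        ref = _BASES[rng.integers(0, 4, size=n)]
        alt_off = rng.integers(1, 4, size=n)
        alt = _BASES[(np.searchsorted(_BASES, ref) + alt_off) % 4]

        for i in range(n):
            vid = f"rs{block.chrom}_{pos0[i] + 1}"
            var_rows.append(
                {
                    "variant_id": vid,
                    "chrom": block.chrom,
                    "pos": int(pos0[i]) + 1,
                    "pos0": int(pos0[i]),
                    "ref": ref[i],
                    "alt": alt[i],
                    "p": float(p[i]),
                    "beta": float(beta_hat[i]),
                    "se": float(se[i]),
                    "af": float(af[i]),
                    "maf": float(maf[i]),
                    "n_cases": config.n_cases,
                    "n_controls": config.n_controls,
                    "sex_chrom": False,
                }
            )
        for rank, eff in causal_ranks:
            truth_rows.append(
                {
                    "variant_id": f"rs{block.chrom}_{pos0[rank] + 1}",
                    "block_id": int(block.block_id),
                    "gene_id": eff.gene,
                    "placement": eff.placement,
                    "beta": eff.beta,
                }
            )

    gwas = pd.DataFrame(var_rows)
    truth = TruthSet(pd.DataFrame(truth_rows, columns=["variant_id", "block_id", "gene_id", "placement", "beta"]))
    return gwas, truth


def simulate_expression(
    gene_ids: Sequence[str],
    n_samples: int = 12,
    n_clusters: int = 3,
    seed: int = 0,
    separation: float = 4.0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Gene x sample expression matrix (TPM-like) with planted clusters.

    Each cluster is high in its own subset of samples; values are log-normal
    around the cluster profile. Returns the matrix and the planted labels.
    """
    rng = np.random.default_rng(seed)
    n_genes = len(gene_ids)
    labels = np.arange(n_genes) % n_clusters
    sample_groups = np.arange(n_samples) % n_clusters
    base = np.ones((n_genes, n_samples))
    for c in range(n_clusters):
        base[np.ix_(labels == c, sample_groups == c)] = separation
    noise = rng.lognormal(mean=0.0, sigma=0.25, size=base.shape)
    mat = pd.DataFrame(base * noise * 10.0, index=list(gene_ids),
                       columns=[f"S{j + 1}" for j in range(n_samples)])
    return mat, labels


def simulate_gene_sets(
    gene_ids: Sequence[str],
    target_genes: Sequence[str],
    n_random_sets: int = 10,
    set_size: int = 10,
    seed: int = 0,
) -> dict[str, set[str]]:
    """GMT-style gene sets: one set of planted targets plus random sets."""
    rng = np.random.default_rng(seed)
    sets = {"planted_targets": set(target_genes)}
    pool = list(gene_ids)
    for i in range(n_random_sets):
        size = min(set_size, len(pool))
        sets[f"random_{i + 1:02d}"] = set(rng.choice(pool, size=size, replace=False))
    return sets


def simulate_all(config: SyntheticConfig):
    """Reference, interactions, GWAS and truth in one deterministic call."""
    reference = simulate_reference(config)
    interactions = simulate_pchic(config, reference)
    gwas, truth = simulate_gwas(config, reference, interactions)
    return reference, interactions, gwas, truth


def with_effects(config: SyntheticConfig, effects: Sequence[PlantedEffect]) -> SyntheticConfig:
    return replace(config, planted_effects=tuple(effects))
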