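"""Core genomic containers used across the pipeline.

All intervals are 0-based half-open ``[start, end)``. GWAS positions arrive
1-based (as in summary-statistics files) and are converted on load; a variant
at 1-based position ``p`` sits at 0-based coordinate ``p - 1`` and belongs to
the unique half-open interval containing that coordinate.

Containers wrap validated :class:`pandas.DataFrame` objects rather than
per-row records: every downstream operation is vectorised over them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd


class CogsError(Exception):
    """Base class for all pipeline errors."""


class FormatError(CogsError):
    """A file does not conform to its declared dialect."""


class ConsistencyError(CogsError):
    """Two inputs that must share an id/coordinate space disagree."""


class InvalidConfigError(CogsError):
    """A configuration value violates its stated domain."""


class GenomicInterval(NamedTuple):
    chrom: str
    start: int
    end: int

    def __len__(self) -> int:  # interval width, not tuple arity
        return self.end - self.start


_CANONICAL_AUTOSOMES = {str(i) for i in range(1, 23)}
_SEX_CHROMS = {"X", "Y"}


def normalize_chrom(name: str) -> str:
    """Normalise chromosome names to the bare dialect (``chr1`` -> ``1``)."""
    name = str(name).strip()
    if name.lower().startswith("chr"):
        name = name[3:]
    if name == "23":
        name = "X"
    return name


def is_sex_chrom(name: str) -> bool:
    return normalize_chrom(name) in _SEX_CHROMS


def _check_interval_frame(df: pd.DataFrame, what: str, allow_overlap: bool = False) -> pd.DataFrame:
    if (df["start"] < 0).any():
        raise ConsistencyError(f"{what}: negative start coordinate")
    if (df["end"] <= df["start"]).any():
        raise ConsistencyError(f"{what}: empty or inverted interval")
    df = df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)
    if not allow_overlap:
        for chrom, sub in df.groupby("chrom", sort=False):
            if (sub["start"].to_numpy()[1:] < sub["end"].to_numpy()[:-1]).any():
                raise ConsistencyError(f"{what}: overlapping intervals on {chrom}")
    return df


@dataclass
class FragmentMap:
    """Restriction fragments (or 5-kb bins) with stable integer ids.

    Per chromosome the fragments are sorted and non-overlapping; ids are
    unique but need not be consecutive (loaded rmaps keep their original ids).
    """

    frame: pd.DataFrame  # columns: chrom, start, end, frag_id
    _index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        df = self.frame[["chrom", "start", "end", "frag_id"]].copy()
        df["chrom"] = df["chrom"].map(normalize_chrom)
        if df["frag_id"].duplicated().any():
            raise ConsistencyError("fragment map: duplicate fragment ids")
        df = _check_interval_frame(df, "fragment map")
        self.frame = df
        self._index = {
            chrom: (sub["start"].to_numpy(), sub["end"].to_numpy(), sub["frag_id"].to_numpy())
            for chrom, sub in df.groupby("chrom", sort=False)
        }
        self._by_id = df.set_index("frag_id")

    def __len__(self) -> int:
        return len(self.frame)

    def locate(self, chroms: Iterable[str], pos: Iterable[int]) -> np.ndarray:
        """Map 0-based positions to fragment ids; -1 where unmapped."""
        chroms = np.asarray([normalize_chrom(c) for c in chroms])
        pos = np.asarray(pos, dtype=np.int64)
        out = np.full(len(pos), -1, dtype=np.int64)
        for chrom in np.unique(chroms):
            if chrom not in self._index:
                continue
            starts, ends, ids = self._index[chrom]
            mask = chroms == chrom
            p = pos[mask]
            idx = np.searchsorted(starts, p, side="right") - 1
            ok = (idx >= 0) & (p < ends[np.clip(idx, 0, None)])
            res = np.where(ok, ids[np.clip(idx, 0, None)], -1)
            out[mask] = res
        return out

    def interval_of(self, frag_id: int) -> GenomicInterval:
        row = self._by_id.loc[frag_id]
        return GenomicInterval(row["chrom"], int(row["start"]), int(row["end"]))

    def neighbours(self, frag_id: int, flank_count: int) -> list[int]:
        """Ids of the fragment plus up to ``flank_count`` adjacent fragments
        per side on the same chromosome, truncated at chromosome ends."""
        chrom = self._by_id.loc[frag_id, "chrom"]
        _, _, ids = self._index[chrom]
        i = int(np.nonzero(ids == frag_id)[0][0])
        lo = max(0, i - flank_count)
        hi = min(len(ids), i + flank_count + 1)
        return [int(x) for x in ids[lo:hi]]


@dataclass
class LdBlockSet:
    """Approximately independent LD blocks (ldetect-style genome partition)."""

    frame: pd.DataFrame  # columns: chrom, start, end, block_id

    def __post_init__(self) -> None:
        df = self.frame[["chrom", "start", "end", "block_id"]].copy()
        df["chrom"] = df["chrom"].map(normalize_chrom)
        if df["block_id"].duplicated().any():
            raise ConsistencyError("LD blocks: duplicate block ids")
        self.frame = _check_interval_frame(df, "LD blocks")
        self._index = {
            chrom: (sub["start"].to_numpy(), sub["end"].to_numpy(), sub["block_id"].to_numpy())
            for chrom, sub in self.frame.groupby("chrom", sort=False)
        }

    def __len__(self) -> int:
        return len(self.frame)

    def locate(self, chroms: Iterable[str], pos: Iterable[int]) -> np.ndarray:
        """Block id per 0-based position; -1 where no block covers it."""
        chroms = np.asarray([normalize_chrom(c) for c in chroms])
        pos = np.asarray(pos, dtype=np.int64)
        out = np.full(len(pos), -1, dtype=np.int64)
        for chrom in np.unique(chroms):
            if chrom not in self._index:
                continue
            starts, ends, ids = self._index[chrom]
            mask = chroms == chrom
            p = pos[mask]
            idx = np.searchsorted(starts, p, side="right") - 1
            ok = (idx >= 0) & (p < ends[np.clip(idx, 0, None)])
            out[mask] = np.where(ok, ids[np.clip(idx, 0, None)], -1)
        return out


@dataclass
class GeneModelSet:
    """Gene models keyed by a stable gene id.

    ``genes``: gene_id, name, chrom, strand, biotype
    ``tss``:   gene_id, chrom, pos (0-based; one row per promoter)
    ``exons``: gene_id, chrom, start, end
    """

    genes: pd.DataFrame
    tss: pd.DataFrame
    exons: pd.DataFrame
    cds: pd.DataFrame | None = None  # optional CDS intervals (same layout as exons)

    def __post_init__(self) -> None:
        if self.genes["gene_id"].duplicated().any():
            raise ConsistencyError("gene models: duplicate gene ids")
        for df in (self.genes, self.tss, self.exons):
            df["chrom"] = df["chrom"].map(normalize_chrom)
        bad = (self.exons["end"] <= self.exons["start"])
        if bad.any():
            raise ConsistencyError("gene models: empty exon interval")
        self.genes = self.genes.reset_index(drop=True)
        self.tss = self.tss.reset_index(drop=True)
        self.exons = self.exons.sort_values(["chrom", "start", "end"]).reset_index(drop=True)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.genes["gene_id"])

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class BaitMap:
    """Baited promoter fragments with their gene links.

    ``frame``: frag_id, chrom, start, end, genes (tuple of gene names/ids),
    virtual (True for virtual baits created for unbaited promoters — these
    carry no interactions, only promoter-proximal regions).
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame.copy()
        if "virtual" not in df.columns:
            df["virtual"] = False
        df["chrom"] = df["chrom"].map(normalize_chrom)
        if df["frag_id"].duplicated().any():
            raise ConsistencyError("baitmap: duplicate bait fragment ids")
        self.frame = df.sort_values(["chrom", "start"]).reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    def gene_links(self) -> pd.DataFrame:
        """Long-format (frag_id, gene) table, one row per bait-gene link."""
        rows = [
            (fid, g)
            for fid, genes in zip(self.frame["frag_id"], self.frame["genes"])
            for g in genes
        ]
        return pd.DataFrame(rows, columns=["frag_id", "gene"])


@dataclass
class InteractionTable:
    """Promoter interactions: bait fragment vs other-end interval, with one
    CHiCAGO-style score column per cell type (``score_*``)."""

    frame: pd.DataFrame  # bait_id, oe_chrom, oe_start, oe_end, [oe_id], score_*

    def __post_init__(self) -> None:
        df = self.frame.copy()
        df["oe_chrom"] = df["oe_chrom"].map(normalize_chrom)
        score_cols = self.score_columns(df)
        if not score_cols:
            raise ConsistencyError("interaction table: no score_* columns")
        if (df[score_cols] < 0).any().any():
            raise ConsistencyError("interaction table: negative score")
        self.frame = df.reset_index(drop=True)

    @staticmethod
    def score_columns(df: pd.DataFrame) -> list[str]:
        return [c for c in df.columns if c.startswith("score_")]

    @property
    def score_cols(self) -> list[str]:
        return self.score_columns(self.frame)

    def pooled_max(self) -> pd.Series:
        """Per-row maximum score across cell types (the pooling rule)."""
        return self.frame[self.score_cols].max(axis=1)

    def __len__(self) -> int:
        return len(self.frame)


def merge_intervals(df: pd.DataFrame) -> pd.DataFrame:
    """Merge overlapping or bookended intervals per chromosome.

    Half-open semantics: [0,5) and [5,9) merge to [0,9); which variants are
    covered is unchanged by merging, only the bookkeeping is.
    """
    if df.empty:
        return df.reset_index(drop=True)[["chrom", "start", "end"]]
    df = df.sort_values(["chrom", "start", "end"]).reset_index(drop=True)
    out = []
    cur = None
    for row in df.itertuples(index=False):
        if cur is None or row.chrom != cur[0] or row.start > cur[2]:
            if cur is not None:
                out.append(cur)
            cur = [row.chrom, row.start, row.end]
        else:
            cur[2] = max(cur[2], row.end)
    out.append(cur)
    return pd.DataFrame(out, columns=["chrom", "start", "end"])
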