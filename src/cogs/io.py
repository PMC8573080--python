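"""Readers and writers for the standard files the pipeline touches.

Dialects
--------
GWAS summary statistics arrive in many column layouts; a *dialect* is a
mapping from the internal field names to the file's column headers. The
built-in ``hgi_r5`` dialect mirrors the COVID-19 Host Genetics Initiative
release-5 meta-analysis layout. Additional dialects can be supplied through a
YAML config file.

Coordinate conventions: GWAS positions are 1-based in files and converted to
0-based on load (column ``pos0``); BED/rmap/baitmap inputs are already
0-based half-open. Chromosome names are unified to the bare dialect at load.
"""

from __future__ import annotations

import gzip
import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .types import (
    BaitMap,
    ConsistencyError,
    FormatError,
    FragmentMap,
    GeneModelSet,
    InteractionTable,
    LdBlockSet,
    is_sex_chrom,
    normalize_chrom,
)

logger = logging.getLogger(__name__)

#: internal field -> column header in the HGI release-5 files
GWAS_DIALECTS: dict[str, dict[str, str]] = {
    "hgi_r5": {
        "chrom": "#CHR",
        "pos": "POS",
        "ref": "REF",
        "alt": "ALT",
        "id": "SNP",
        "p": "all_inv_var_meta_p",
        "beta": "all_inv_var_meta_beta",
        "se": "all_inv_var_meta_sebeta",
        "af": "all_meta_AF",
        "n_cases": "all_inv_var_meta_cases",
        "n_controls": "all_inv_var_meta_controls",
    },
    "plain": {
        "chrom": "chrom",
        "pos": "pos",
        "ref": "ref",
        "alt": "alt",
        "id": "id",
        "p": "p",
        "beta": "beta",
        "se": "se",
        "af": "af",
        "n_cases": "n_cases",
        "n_controls": "n_controls",
    },
}

_MANDATORY = ("chrom", "pos", "ref", "alt", "af", "n_cases", "n_controls")


def _open_text(path: str | Path, mode: str = "rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def load_config(path: str | Path) -> dict:
    """Load a YAML run config (dialect mappings + thresholds)."""
    with _open_text(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    for name, mapping in cfg.get("gwas_dialects", {}).items():
        GWAS_DIALECTS[name] = dict(mapping)
    return cfg


def read_gwas(path: str | Path, dialect: str | dict = "hgi_r5") -> pd.DataFrame:
    """Read GWAS summary statistics into the internal variant table.

    Rows violating the invariants (p outside (0,1], missing MAF or sample
    sizes, neither p nor beta+se present) are dropped with a logged count;
    allele frequencies above 0.5 are folded to MAF. Duplicate positions keep
    the row with the smallest p. Sex-chromosome variants are loaded but
    flagged; downstream block assignment excludes them.
    """
    mapping = GWAS_DIALECTS[dialect] if isinstance(dialect, str) else dict(dialect)
    df = pd.read_csv(path, sep="\t", dtype={mapping["chrom"]: str})
    missing = [mapping[k] for k in _MANDATORY if mapping[k] not in df.columns]
    if missing:
        raise FormatError(f"GWAS file {path} lacks mandatory column(s): {', '.join(missing)}")

    out = pd.DataFrame()
    out["chrom"] = df[mapping["chrom"]].map(normalize_chrom)
    out["pos"] = pd.to_numeric(df[mapping["pos"]], errors="coerce")
    out["ref"] = df[mapping["ref"]].astype(str)
    out["alt"] = df[mapping["alt"]].astype(str)
    idcol = mapping.get("id")
    if idcol and idcol in df.columns:
        out["variant_id"] = df[idcol].astype(str)
    else:
        out["variant_id"] = (
            out["chrom"] + ":" + out["pos"].astype("Int64").astype(str) + ":" + out["ref"] + ":" + out["alt"]
        )
    for field in ("p", "beta", "se"):
        col = mapping.get(field)
        out[field] = pd.to_numeric(df[col], errors="coerce") if col and col in df.columns else np.nan
    out["af"] = pd.to_numeric(df[mapping["af"]], errors="coerce")
    out["n_cases"] = pd.to_numeric(df[mapping["n_cases"]], errors="coerce")
    out["n_controls"] = pd.to_numeric(df[mapping["n_controls"]], errors="coerce")

    n0 = len(out)
    has_p = (out["p"] > 0) & (out["p"] <= 1)
    has_beta = out["beta"].notna() & out["se"].notna() & (out["se"] > 0)
    keep = (
        out["pos"].notna()
        & (out["pos"] >= 1)
        & (has_p | has_beta)
        & out["af"].notna()
        & (out["af"] > 0)
        & (out["af"] < 1)
        & (out["n_cases"] > 0)
        & (out["n_controls"] > 0)
    )
    dropped = int(n0 - keep.sum())
    if dropped:
        logger.info("read_gwas: dropped %d/%d rows failing invariants", dropped, n0)
    out = out[keep].copy()
    out.loc[~((out["p"] > 0) & (out["p"] <= 1)), "p"] = np.nan
    out["maf"] = np.minimum(out["af"], 1.0 - out["af"])
    out["pos"] = out["pos"].astype(np.int64)
    out["pos0"] = out["pos"] - 1
    out["sex_chrom"] = out["chrom"].map(is_sex_chrom)

    before = len(out)
    out = (
        out.sort_values(["chrom", "pos", "p"], na_position="last")
        .drop_duplicates(subset=["chrom", "pos"], keep="first")
        .reset_index(drop=True)
    )
    if len(out) < before:
        logger.info("read_gwas: removed %d duplicate positions (kept smallest p)", before - len(out))
    return out


def write_gwas(df: pd.DataFrame, path: str | Path, dialect: str | dict = "hgi_r5") -> None:
    """Write the internal variant table back out in the given dialect."""
    mapping = GWAS_DIALECTS[dialect] if isinstance(dialect, str) else dict(dialect)
    out = pd.DataFrame()
    out[mapping["chrom"]] = df["chrom"]
    out[mapping["pos"]] = df["pos"]
    out[mapping["ref"]] = df["ref"]
    out[mapping["alt"]] = df["alt"]
    if mapping.get("id"):
        out[mapping["id"]] = df["variant_id"]
    for field in ("beta", "se", "p"):
        if mapping.get(field):
            out[mapping[field]] = df[field]
    out[mapping["af"]] = df["af"] if "af" in df.columns else df["maf"]
    out[mapping["n_cases"]] = df["n_cases"]
    out[mapping["n_controls"]] = df["n_controls"]
    out.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_rmap_baitmap(rmap_path: str | Path, baitmap_path: str | Path) -> tuple[FragmentMap, BaitMap]:
    """Read CHiCAGO rmap/baitmap files (chrom, start, end, id[, annotation]).

    The baitmap annotation column holds ``;``-separated gene names; a bait
    shared by several promoters therefore links to several genes. Bait ids
    must be a subset of the rmap ids.
    """
    rmap = pd.read_csv(
        rmap_path, sep="\t", header=None, names=["chrom", "start", "end", "frag_id"],
        dtype={0: str},
    )
    fmap = FragmentMap(rmap)
    bait = pd.read_csv(
        baitmap_path, sep="\t", header=None,
        names=["chrom", "start", "end", "frag_id", "annotation"],
        dtype={0: str},
    )
    unknown = set(bait["frag_id"]) - set(rmap["frag_id"])
    if unknown:
        raise ConsistencyError(f"baitmap ids absent from rmap: {sorted(unknown)[:5]}")
    bait["genes"] = bait["annotation"].astype(str).map(lambda s: tuple(g for g in s.split(";") if g))
    bait = bait.drop(columns=["annotation"])
    bait["virtual"] = False
    return fmap, BaitMap(bait)


def write_rmap_baitmap(fmap: FragmentMap, baits: BaitMap, rmap_path: str | Path, baitmap_path: str | Path) -> None:
    fmap.frame[["chrom", "start", "end", "frag_id"]].to_csv(rmap_path, sep="\t", header=False, index=False)
    out = baits.frame[~baits.frame["virtual"]].copy()
    out["annotation"] = out["genes"].map(";".join)
    out[["chrom", "start", "end", "frag_id", "annotation"]].to_csv(baitmap_path, sep="\t", header=False, index=False)


_PEAK_MATRIX_RENAMES = {
    "baitID": "bait_id",
    "oeChr": "oe_chrom",
    "oeStart": "oe_start",
    "oeEnd": "oe_end",
    "oeID": "oe_id",
}


def read_interactions(path: str | Path, score_columns: Sequence[str] | None = None) -> InteractionTable:
    """Read a peak-matrix-like interaction TSV.

    Expects columns ``bait_id, oe_chrom, oe_start, oe_end[, oe_id]`` (CHiCAGO
    peak-matrix headers ``baitID/oeChr/...`` are accepted) plus one score
    column per cell type. Score columns are either named explicitly or taken
    as every ``score_*`` column / every column not otherwise recognised.
    """
    df = pd.read_csv(path, sep="\t", dtype={"oe_chrom": str, "oeChr": str})
    df = df.rename(columns=_PEAK_MATRIX_RENAMES)
    needed = {"bait_id", "oe_chrom", "oe_start", "oe_end"}
    missing = needed - set(df.columns)
    if missing:
        raise FormatError(f"interaction table {path} lacks column(s): {', '.join(sorted(missing))}")
    if score_columns is None:
        score_columns = [c for c in df.columns if c.startswith("score_")]
        if not score_columns:
            score_columns = [c for c in df.columns if c not in needed | {"oe_id", "bait_chrom", "bait_start", "bait_end", "dist"}]
    df = df.rename(columns={c: c if c.startswith("score_") else f"score_{c}" for c in score_columns})
    return InteractionTable(df)


def write_interactions(tab: InteractionTable, path: str | Path) -> None:
    tab.frame.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_bed_blocks(path: str | Path) -> LdBlockSet:
    """Read LD blocks from BED3 (optional 4th column as block id)."""
    rows = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: BED line has {len(parts)} fields, need >= 3")
            try:
                rows.append((parts[0], int(parts[1]), int(parts[2]), parts[3] if len(parts) > 3 else None))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "block_id"])
    if df["block_id"].isna().any():
        df["block_id"] = np.arange(len(df))
    else:
        as_num = pd.to_numeric(df["block_id"], errors="coerce")
        if as_num.notna().all():
            df["block_id"] = as_num.astype(np.int64)
    return LdBlockSet(df)


def write_bed_blocks(blocks: LdBlockSet, path: str | Path) -> None:
    blocks.frame[["chrom", "start", "end", "block_id"]].to_csv(path, sep="\t", header=False, index=False)


def read_gene_models(path: str | Path) -> GeneModelSet:
    """Read gene models from GTF (``gene_id`` attribute is the key) or BED12."""
    path = Path(path)
    name = path.name.removesuffix(".gz")
    if name.endswith((".gtf", ".gff")):
        return _read_gtf(path)
    if name.endswith(".bed") or name.endswith(".bed12"):
        return read_bed12_genes(path)
    raise FormatError(f"unrecognised gene-model format: {path}")


def _parse_gtf_attributes(attr: str) -> dict[str, str]:
    out = {}
    for field in attr.strip().split(";"):
        field = field.strip()
        if not field:
            continue
        key, _, value = field.partition(" ")
        out[key] = value.strip().strip('"')
    return out


def _read_gtf(path: Path) -> GeneModelSet:
    genes: dict[str, dict] = {}
    tss_rows = []
    exon_rows = []
    cds_rows = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9:
                raise FormatError(f"{path}:{lineno}: GTF line has {len(parts)} fields")
            chrom, _, feature, start, end, _, strand, _, attrs = parts[:9]
            try:
                start_i, end_i = int(start) - 1, int(end)  # GTF is 1-based inclusive
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            a = _parse_gtf_attributes(attrs)
            gid = a.get("gene_id")
            if gid is None:
                raise FormatError(f"{path}:{lineno}: missing gene_id attribute")
            if gid not in genes:
                genes[gid] = {
                    "gene_id": gid,
                    "name": a.get("gene_name", gid),
                    "chrom": chrom,
                    "strand": strand,
                    "biotype": a.get("gene_biotype", a.get("gene_type", "protein_coding")),
                }
            if feature == "transcript":
                tss_rows.append((gid, chrom, start_i if strand == "+" else end_i - 1))
            elif feature == "gene":
                pass
            elif feature == "exon":
                exon_rows.append((gid, chrom, start_i, end_i))
            elif feature == "CDS":
                cds_rows.append((gid, chrom, start_i, end_i))
    gene_df = pd.DataFrame(genes.values())
    tss = pd.DataFrame(tss_rows, columns=["gene_id", "chrom", "pos"]).drop_duplicates()
    if tss.empty:  # gene-and-exon-only GTFs: TSS from the gene span
        tss = _tss_from_spans(gene_df, pd.DataFrame(exon_rows, columns=["gene_id", "chrom", "start", "end"]))
    exons = pd.DataFrame(exon_rows, columns=["gene_id", "chrom", "start", "end"])
    cds = pd.DataFrame(cds_rows, columns=["gene_id", "chrom", "start", "end"]) if cds_rows else None
    return GeneModelSet(gene_df, tss, exons, cds)


def _tss_from_spans(genes: pd.DataFrame, exons: pd.DataFrame) -> pd.DataFrame:
    spans = exons.groupby("gene_id").agg(start=("start", "min"), end=("end", "max"))
    merged = genes.set_index("gene_id").join(spans)
    pos = np.where(merged["strand"] == "+", merged["start"], merged["end"] - 1)
    return pd.DataFrame({"gene_id": merged.index, "chrom": merged["chrom"].values, "pos": pos})


def read_bed12_genes(path: str | Path) -> GeneModelSet:
    """BED12: one row per gene/transcript; blocks become exon intervals."""
    gene_rows, tss_rows, exon_rows = [], [], []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) < 12:
                raise FormatError(f"{path}:{lineno}: BED12 line has {len(parts)} fields")
            chrom, start, end, gid, _, strand = parts[0], int(parts[1]), int(parts[2]), parts[3], parts[4], parts[5]
            n_blocks = int(parts[9])
            sizes = [int(x) for x in parts[10].rstrip(",").split(",")]
            offsets = [int(x) for x in parts[11].rstrip(",").split(",")]
            if len(sizes) != n_blocks or len(offsets) != n_blocks:
                raise FormatError(f"{path}:{lineno}: blockCount disagrees with block lists")
            gene_rows.append({"gene_id": gid, "name": gid, "chrom": chrom, "strand": strand, "biotype": "protein_coding"})
            tss_rows.append((gid, chrom, start if strand == "+" else end - 1))
            for size, off in zip(sizes, offsets):
                exon_rows.append((gid, chrom, start + off, start + off + size))
    genes = pd.DataFrame(gene_rows).drop_duplicates(subset="gene_id")
    tss = pd.DataFrame(tss_rows, columns=["gene_id", "chrom", "pos"]).drop_duplicates()
    exons = pd.DataFrame(exon_rows, columns=["gene_id", "chrom", "start", "end"])
    return GeneModelSet(genes, tss, exons)


def write_bed12_genes(genes: GeneModelSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for row in genes.genes.itertuples(index=False):
            ex = genes.exons[genes.exons["gene_id"] == row.gene_id].sort_values("start")
            if ex.empty:
                continue
            start, end = int(ex["start"].min()), int(ex["end"].max())
            sizes = ",".join(str(e - s) for s, e in zip(ex["start"], ex["end"]))
            offsets = ",".join(str(s - start) for s in ex["start"])
            fh.write(
                f"{row.chrom}\t{start}\t{end}\t{row.gene_id}\t0\t{row.strand}\t"
                f"{start}\t{end}\t0\t{len(ex)}\t{sizes},\t{offsets},\n"
            )


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read GMT gene sets: name <tab> description <tab> gene1 <tab> ..."""
    sets: dict[str, set[str]] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line needs name, description and >= 1 gene")
            sets[parts[0]] = {g for g in parts[2:] if g}
    return sets


def write_gmt(sets: dict[str, set[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in sorted(sets):
            genes = "\t".join(sorted(sets[name]))
            fh.write(f"{name}\tna\t{genes}\n")


def read_expression(path: str | Path) -> pd.DataFrame:
    """Gene x sample expression matrix (TPM/FPKM TSV, genes as index)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if (df.values < 0).any():
        raise FormatError(f"expression matrix {path} contains negative values")
    return df


def write_results(table: pd.DataFrame, path: str | Path, float_digits: int = 6) -> None:
    """Write a tidy results table (TSV, fixed float precision for determinism)."""
    table.to_csv(path, sep="\t", index=False, float_format=f"%.{float_digits}g")
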