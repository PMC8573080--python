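"""Comparison and characterisation analyses over COGS results.

Includes the naive nearest-exon baseline, set comparisons, precision-recall
threshold sweeps, preranked gene-set enrichment (weighted Kolmogorov-Smirnov
running sum with gene-label permutation NES/FDR), hypergeometric
over-representation with Benjamini-Hochberg correction, and k-means
clustering of expression matrices with silhouette-based selection of k.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score
from statsmodels.stats.multitest import multipletests

from .types import CogsError, GeneModelSet, InvalidConfigError

logger = logging.getLogger(__name__)


def prioritise(results: pd.DataFrame, threshold: float = 0.3) -> set[str]:
    """Genes with COGS score strictly above the threshold."""
    return set(results.loc[results["score"] > threshold, "gene_id"])


def nearest_exon_assign(
    gwas: pd.DataFrame,
    genes: GeneModelSet,
    p_threshold: float = 1e-8,
) -> tuple[set[str], pd.DataFrame]:
    """Naive baseline: assign genome-wide-significant variants (p below the
    threshold) to the gene(s) owning the nearest exon.

    Distance is to the exon boundary (0 inside an exon); equidistant ties
    report every tied gene and are flagged. Returns the union gene set and a
    per-variant assignment table.
    """
    hits = gwas[gwas["p"] < p_threshold]
    assigned = set()
    rows = []
    exons_by_chrom = {c: sub for c, sub in genes.exons.groupby("chrom")}
    for v in hits.itertuples(index=False):
        sub = exons_by_chrom.get(v.chrom)
        if sub is None or sub.empty:
            logger.info("nearest_exon_assign: no exons on chromosome %s for %s", v.chrom, v.variant_id)
            continue
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        pos = v.pos0
        # distance 0 inside [start, end); otherwise gap to the nearest boundary
        dist = np.where(pos < starts, starts - pos, np.where(pos >= ends, pos - ends + 1, 0))
        dmin = dist.min()
        tied = sorted(set(sub["gene_id"].to_numpy()[dist == dmin]))
        assigned.update(tied)
        rows.append(
            {
                "variant_id": v.variant_id,
                "p": v.p,
                "distance": int(dmin),
                "genes": ";".join(tied),
                "tie": len(tied) > 1,
            }
        )
    table = pd.DataFrame(rows, columns=["variant_id", "p", "distance", "genes", "tie"])
    return assigned, table


def compare_sets(set_a: set[str], set_b: set[str], universe: set[str] | None = None) -> dict:
    """Overlap summary between two gene sets: sizes, intersection, Jaccard."""
    inter = set_a & set_b
    union = set_a | set_b
    return {
        "n_a": len(set_a),
        "n_b": len(set_b),
        "n_intersection": len(inter),
        "jaccard": len(inter) / len(union) if union else 0.0,
        "n_universe": len(universe) if universe is not None else None,
    }


def precision_recall(
    results: pd.DataFrame,
    reference: set[str],
    thresholds: np.ndarray | None = None,
    restrict_to_scored: bool = True,
) -> pd.DataFrame:
    """Precision/recall/fold-enrichment of the prioritised set against a
    reference gene set over a grid of score thresholds.

    By default the reference is restricted to genes carrying a non-zero COGS
    score, so recall measures ranking rather than assay coverage.
    Fold-enrichment is precision over the background rate ``|R| / |universe|``
    (universe = all scored genes). Precision is reported as NaN when nothing
    is prioritised.
    """
    if thresholds is None:
        thresholds = np.round(np.arange(0.0, 1.0, 0.05), 10)
    universe = set(results["gene_id"])
    if restrict_to_scored:
        scored = set(results.loc[results["score"] > 0, "gene_id"])
        reference = reference & scored
    else:
        reference = reference & universe
    background = len(reference) / len(universe) if universe else np.nan
    rows = []
    for t in thresholds:
        pset = prioritise(results, t)
        tp = len(pset & reference)
        precision = tp / len(pset) if pset else np.nan
        recall = tp / len(reference) if reference else np.nan
        rows.append(
            {
                "threshold": float(t),
                "n_prioritised": len(pset),
                "precision": precision,
                "recall": recall,
                "fold_enrichment": precision / background if pset and background else np.nan,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class EnrichmentResult:
    """Preranked GSEA output for one gene set."""

    name: str
    es: float
    nes: float
    p: float
    fdr: float
    size: int


def _es_running(scores: np.ndarray, in_set: np.ndarray, exponent: float) -> float:
    """Signed maximum deviation of the weighted KS running sum.

    ``scores`` are the ranking metric in list order (descending); hits climb
    by |score|^exponent (normalised), misses fall by 1/(N - N_hit).
    """
    weights = np.abs(scores) ** exponent
    hit_total = weights[in_set].sum()
    n_miss = len(scores) - int(in_set.sum())
    if hit_total == 0 or n_miss == 0:
        raise CogsError("degenerate gene set: empty, scoreless, or covering the whole list")
    steps = np.where(in_set, weights / hit_total, -1.0 / n_miss)
    running = np.cumsum(steps)
    return float(running[np.argmax(np.abs(running))])


def _es_batch(scores: np.ndarray, hit_matrix: np.ndarray, exponent: float) -> np.ndarray:
    """Vectorised ES over many hit indicator rows (permutations)."""
    weights = np.abs(scores) ** exponent
    hit_totals = hit_matrix @ weights
    n_miss = hit_matrix.shape[1] - hit_matrix.sum(axis=1)
    steps = np.where(hit_matrix, weights[None, :], 0.0) / hit_totals[:, None]
    steps = steps - np.where(~hit_matrix, 1.0, 0.0) / n_miss[:, None]
    running = np.cumsum(steps, axis=1)
    idx = np.argmax(np.abs(running), axis=1)
    return running[np.arange(len(running)), idx]


def gsea_preranked(
    ranked: pd.DataFrame,
    gene_sets: dict[str, set[str]],
    n_perm: int = 1000,
    exponent: float = 1.0,
    seed: int = 0,
    min_size: int = 1,
    max_size: int | None = None,
) -> pd.DataFrame:
    """Preranked gene-set enrichment analysis.

    ``ranked`` has columns ``gene_id`` and ``score``, ordered by score
    descending (it is re-sorted defensively; duplicate gene ids are an
    error). The null is gene-label permutation: each permutation redraws the
    set's positions uniformly. NES is ES divided by the mean magnitude of
    same-sign permuted ES; FDR follows the standard positive/negative pool
    convention. Deterministic given the seed.
    """
    if ranked["gene_id"].duplicated().any():
        raise CogsError("ranked list contains duplicate gene ids")
    if len(ranked) < 2:
        raise CogsError("ranked list needs at least 2 genes")
    ranked = ranked.sort_values("score", ascending=False, kind="mergesort").reset_index(drop=True)
    gene_order = ranked["gene_id"].to_numpy()
    scores = ranked["score"].to_numpy(dtype=float)
    N = len(gene_order)
    pos_of = {g: i for i, g in enumerate(gene_order)}
    rng = np.random.default_rng(seed)

    rows = []
    perm_es_by_set = {}
    for name in sorted(gene_sets):
        members = [pos_of[g] for g in gene_sets[name] if g in pos_of]
        size = len(members)
        if size < min_size or (max_size is not None and size > max_size):
            continue
        if size >= N:
            raise CogsError(f"gene set {name!r} covers the whole ranked list")
        in_set = np.zeros(N, dtype=bool)
        in_set[members] = True
        es = _es_running(scores, in_set, exponent)

        perm_hits = np.zeros((n_perm, N), dtype=bool)
        for b in range(n_perm):
            perm_hits[b, rng.choice(N, size=size, replace=False)] = True
        perm_es = _es_batch(scores, perm_hits, exponent)
        perm_es_by_set[name] = perm_es

        same_sign = perm_es[np.sign(perm_es) == np.sign(es)] if es != 0 else perm_es
        if len(same_sign) == 0:
            p = 1.0 / (n_perm + 1)
            nes = np.sign(es) * np.inf
        else:
            p = (np.sum(np.abs(same_sign) >= abs(es)) + 1) / (len(same_sign) + 1)
            nes = es / np.mean(np.abs(same_sign))
        rows.append({"set": name, "es": es, "nes": nes, "p": p, "size": size})

    out = pd.DataFrame(rows, columns=["set", "es", "nes", "p", "size"])
    if out.empty:
        return out.assign(fdr=pd.Series(dtype=float))
    out["fdr"] = _gsea_fdr(out, perm_es_by_set)
    return out


def _gsea_fdr(results: pd.DataFrame, perm_es_by_set: dict[str, np.ndarray]) -> np.ndarray:
    """FDR q-values via the normalised-ES pool convention.

    All permuted ES are normalised per set by the same-sign mean magnitude,
    pooled, and each observed NES is compared against the pooled null of its
    sign vs the observed NES of its sign.
    """
    all_nes_null = []
    for name, perm_es in perm_es_by_set.items():
        pos = perm_es[perm_es >= 0]
        neg = perm_es[perm_es < 0]
        pos_mean = pos.mean() if len(pos) else np.nan
        neg_mean = np.abs(neg).mean() if len(neg) else np.nan
        norm = np.where(perm_es >= 0, perm_es / pos_mean, perm_es / neg_mean)
        all_nes_null.append(norm)
    null = np.concatenate(all_nes_null)
    obs = results["nes"].to_numpy()
    fdr = np.empty(len(obs))
    for i, nes in enumerate(obs):
        if nes >= 0:
            tail_null = np.mean(null >= nes) if np.isfinite(nes) else 0.0
            tail_obs = np.mean(obs >= nes)
        else:
            tail_null = np.mean(null <= nes)
            tail_obs = np.mean(obs <= nes)
        fdr[i] = min(1.0, tail_null / tail_obs) if tail_obs > 0 else 1.0
    return fdr


def ora_hypergeometric(
    prioritised: set[str],
    annotation_sets: dict[str, set[str]],
    universe: set[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation test per gene set, with
    Benjamini-Hochberg adjustment across sets (significant: adjusted p <
    ``alpha``, the enrichKEGG-style convention)."""
    if not prioritised <= universe:
        raise InvalidConfigError("prioritised set must be a subset of the universe")
    M = len(universe)
    n_drawn = len(prioritised)
    rows = []
    for name in sorted(annotation_sets):
        members = annotation_sets[name] & universe
        K = len(members)
        k = len(prioritised & members)
        # P(X >= k) for X ~ Hypergeom(M, K, n_drawn)
        p = float(stats.hypergeom.sf(k - 1, M, K, n_drawn)) if K else 1.0
        rows.append({"set": name, "n_set": K, "n_overlap": k, "p": min(p, 1.0)})
    out = pd.DataFrame(rows, columns=["set", "n_set", "n_overlap", "p"])
    if out.empty:
        return out.assign(p_adj=pd.Series(dtype=float), significant=pd.Series(dtype=bool))
    out["p_adj"] = multipletests(out["p"], method="fdr_bh")[1]
    out["significant"] = out["p_adj"] < alpha
    return out


def cluster_expression(
    expr: pd.DataFrame,
    k_range: range = range(2, 9),
    seed: int = 0,
    n_init: int = 10,
) -> tuple[pd.Series, int, pd.DataFrame]:
    """K-means on per-gene z-scaled expression; k chosen by mean silhouette.

    Constant-expression genes cannot be scaled and are dropped with a log
    message. Returns (assignments, chosen k, diagnostics with silhouette and
    within-cluster sum of squares per k — the elbow curve is reported for
    inspection, silhouette arbitrates).
    """
    if expr.shape[0] < 2 or expr.shape[1] < 2:
        raise CogsError("expression matrix needs at least 2 genes and 2 samples")
    sd = expr.std(axis=1, ddof=0)
    constant = sd == 0
    if constant.any():
        logger.info("cluster_expression: dropped %d constant-expression genes", int(constant.sum()))
        expr = expr.loc[~constant]
        sd = sd.loc[~constant]
    scaled = expr.sub(expr.mean(axis=1), axis=0).div(sd, axis=0)
    X = scaled.to_numpy()

    diags = []
    models = {}
    for k in k_range:
        if not (2 <= k <= len(expr) - 1):
            continue  # silhouette undefined at k=1 or k=n
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
        labels = km.fit_predict(X)
        sil = silhouette_score(X, labels)
        diags.append({"k": k, "silhouette": sil, "wss": km.inertia_})
        models[k] = labels
    if not diags:
        raise CogsError("no admissible k in range (need 2 <= k <= n_genes - 1)")
    diag_df = pd.DataFrame(diags)
    best_k = int(diag_df.loc[diag_df["silhouette"].idxmax(), "k"])
    assignments = pd.Series(models[best_k], index=expr.index, name="cluster")
    return assignments, best_k, diag_df


def top_expression_filter(expr: pd.DataFrame, quantile: float = 0.75, summary: str = "max") -> list[str]:
    """Genes in the top ``1 - quantile`` of expression (per-gene max by
    default, mean as alternative). Ties at the cut-off are kept."""
    if expr.empty:
        raise CogsError("empty expression matrix")
    if summary == "max":
        per_gene = expr.max(axis=1)
    elif summary == "mean":
        per_gene = expr.mean(axis=1)
    else:
        raise InvalidConfigError("summary must be 'max' or 'mean'")
    cut = per_gene.quantile(quantile)
    return sorted(per_gene.index[per_gene >= cut])
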