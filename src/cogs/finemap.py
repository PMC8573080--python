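"""Wakefield fine-mapping of GWAS summary statistics within LD blocks.

For a variant with effect estimate :math:`\\hat\\beta` (log odds-ratio) and
sampling variance :math:`V`, the Wakefield approximate Bayes factor against
the null compares the marginal likelihoods
:math:`N(\\hat\\beta; 0, V + W)` and :math:`N(\\hat\\beta; 0, V)`, where
:math:`W` is the prior variance of the true effect. In closed form, with
:math:`r = W/(V+W)` and :math:`z = \\hat\\beta/\\sqrt{V}`:

.. math:: \\log \\mathrm{ABF} = \\tfrac12\\left[\\log(1 - r) + r z^2\\right]

Under a single-causal-variant model per LD block, the posterior probability
that variant *i* is the causal one is the Bayes factors normalised within the
block (optionally against an extra null term, giving "at most one" rather
than "exactly one" causal variant per block).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

from .types import CogsError, InvalidConfigError, LdBlockSet

logger = logging.getLogger(__name__)

#: cap for |z| when p underflows to 0 in the input
DEFAULT_Z_MAX = 40.0


@dataclass(frozen=True)
class FinemapConfig:
    """Priors and filters for Wakefield fine-mapping.

    W
        Prior variance of the true log odds-ratio. The default 0.04
        (prior sd 0.2) is the conventional choice for case-control traits.
    maf_min
        Variants rarer than this are excluded before fine-mapping; the
        case-control variance approximation degenerates at rare alleles.
    mode
        ``exactly_one_causal``: posteriors normalised to sum to 1 per block.
        ``null_model``: a null term with per-variant prior ``pi0_prior``
        joins the denominator, so block posteriors sum to < 1.
    """

    W: float = 0.04
    maf_min: float = 0.01
    mode: str = "exactly_one_causal"
    pi0_prior: float = 1e-4
    z_max: float = DEFAULT_Z_MAX

    def __post_init__(self) -> None:
        if self.W <= 0:
            raise InvalidConfigError("W must be > 0")
        if not (0 <= self.maf_min < 0.5):
            raise InvalidConfigError("maf_min must be in [0, 0.5)")
        if self.mode not in ("exactly_one_causal", "null_model"):
            raise InvalidConfigError(f"unknown mode {self.mode!r}")
        if self.mode == "null_model" and not (0 < self.pi0_prior < 1):
            raise InvalidConfigError("pi0_prior must be in (0, 1)")


def case_control_variance(maf, n_total, prop_cases):
    """Approximate sampling variance of a log-OR from a case-control GWAS.

    ``V = 1 / (2 N f (1 - f) s (1 - s))`` with ``f`` the allele frequency and
    ``s`` the proportion of cases; symmetric in ``f <-> 1-f`` and
    ``s <-> 1-s``.
    """
    maf = np.asarray(maf, dtype=float)
    prop_cases = np.asarray(prop_cases, dtype=float)
    n_total = np.asarray(n_total, dtype=float)
    if np.any((maf <= 0) | (maf >= 1)):
        raise InvalidConfigError("maf must lie strictly in (0, 1)")
    if np.any((prop_cases <= 0) | (prop_cases >= 1)):
        raise InvalidConfigError("prop_cases must lie strictly in (0, 1)")
    if np.any(n_total <= 0):
        raise InvalidConfigError("n_total must be > 0")
    return 1.0 / (2.0 * n_total * maf * (1.0 - maf) * prop_cases * (1.0 - prop_cases))


def z_from_p(p, z_max: float = DEFAULT_Z_MAX):
    """|z| from a two-sided p-value (upper-tail normal quantile of p/2).

    ``p = 0`` (numeric underflow in the source file) is capped at ``z_max``
    with a warning rather than rejected; such variants carry overwhelming
    evidence either way.
    """
    p = np.asarray(p, dtype=float)
    if np.any(p > 1) or np.any(p < 0):
        raise InvalidConfigError("p-values must lie in [0, 1]")
    if np.any(p == 0):
        logger.warning("z_from_p: p = 0 encountered; capping |z| at %g", z_max)
    with np.errstate(divide="ignore"):
        z = stats.norm.isf(np.where(p == 0, np.nan, p) / 2.0)
    return np.minimum(np.nan_to_num(z, nan=z_max), z_max)


def wakefield_labf(z, V, W):
    """Natural-log Wakefield approximate Bayes factor.

    ``labf = 0.5 * (log(1 - r) + r z**2)``, ``r = W / (V + W)``. Direction of
    effect is irrelevant: only ``z**2`` enters.
    """
    z = np.asarray(z, dtype=float)
    V = np.asarray(V, dtype=float)
    W = np.asarray(W, dtype=float)
    if np.any(V <= 0):
        raise InvalidConfigError("V must be > 0")
    if np.any(W < 0):
        raise InvalidConfigError("W must be >= 0")
    r = W / (V + W)
    return 0.5 * (np.log1p(-r) + r * z * z)


def finemap_block(labf, config: FinemapConfig = FinemapConfig()) -> np.ndarray:
    """Posterior probability of causality for each variant in one block.

    exactly_one_causal: softmax of the log-ABFs (log-sum-exp stabilised).
    null_model: each variant has prior ``pi0_prior`` of being the causal one
    and the null configuration takes the remaining prior mass, so the
    posteriors sum to less than 1.
    """
    labf = np.asarray(labf, dtype=float)
    if labf.size == 0:
        raise CogsError("finemap_block: empty block")
    if config.mode == "exactly_one_causal":
        return np.exp(labf - logsumexp(labf))
    n = labf.size
    pi = config.pi0_prior
    null_mass = max(1.0 - n * pi, pi)  # guard: huge blocks cannot push prior null mass below pi
    log_terms = labf + np.log(pi)
    log_denom = np.logaddexp(logsumexp(log_terms), np.log(null_mass))
    return np.exp(log_terms - log_denom)


def assign_blocks(variants: pd.DataFrame, blocks: LdBlockSet) -> pd.DataFrame:
    """Assign each variant to the unique LD block containing its position.

    Variants outside every block — including sex-chromosome variants when the
    block set covers autosomes only — are excluded with a logged count.
    """
    out = variants.copy()
    out["block_id"] = blocks.locate(out["chrom"], out["pos0"])
    n_dropped = int((out["block_id"] < 0).sum())
    if n_dropped:
        logger.info("assign_blocks: excluded %d variants outside all LD blocks", n_dropped)
    return out[out["block_id"] >= 0].reset_index(drop=True)


def finemap_gwas(
    variants: pd.DataFrame,
    blocks: LdBlockSet,
    config: FinemapConfig = FinemapConfig(),
) -> pd.DataFrame:
    """Full fine-mapping pass: filter, assign blocks, score, normalise.

    Returns a table with columns ``variant_id, chrom, pos, pos0, block_id, z,
    V, labf, ppi``. z comes from beta/se when both are present, otherwise
    from the two-sided p-value.
    """
    df = variants.copy()
    n0 = len(df)
    df = df[df["maf"] >= config.maf_min]
    if len(df) < n0:
        logger.info("finemap_gwas: removed %d variants with MAF < %g", n0 - len(df), config.maf_min)
    df = assign_blocks(df, blocks)
    if df.empty:
        raise CogsError("finemap_gwas: no variants left after filtering/assignment")

    n_total = df["n_cases"] + df["n_controls"]
    prop_cases = df["n_cases"] / n_total
    V = case_control_variance(df["maf"], n_total, prop_cases)

    has_beta = df["beta"].notna() & df["se"].notna() & (df["se"] > 0)
    z = np.where(
        has_beta,
        (df["beta"] / df["se"]).abs(),
        z_from_p(df["p"].fillna(1.0), config.z_max),
    )
    df["z"] = z
    df["V"] = np.asarray(V, dtype=float)
    df["labf"] = wakefield_labf(df["z"], df["V"], config.W)
    df["ppi"] = 0.0
    for _, idx in df.groupby("block_id").groups.items():
        df.loc[idx, "ppi"] = finemap_block(df.loc[idx, "labf"].to_numpy(), config)
    cols = ["variant_id", "chrom", "pos", "pos0", "block_id", "maf", "z", "V", "labf", "ppi"]
    return df[cols].reset_index(drop=True)
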