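import numpy as np
import pandas as pd
import pytest

from cogs.simulate import PlantedEffect, SyntheticConfig, simulate_all
from cogs.types import BaitMap, FragmentMap, GeneModelSet, InteractionTable, LdBlockSet


@pytest.fixture(scope="session")
def planted_bundle():
    """Default synthetic world with one strong planted interacting causal."""
    config = SyntheticConfig(
        seed=11,
        planted_effects=(PlantedEffect("G0005", "interacting", 8.0),),
        effect_scale="z",
    )
    reference, interactions, gwas, truth = simulate_all(config)
    return config, reference, interactions, gwas, truth


@pytest.fixture(scope="session")
def null_bundle():
    """Synthetic world with no planted effects (pure null GWAS)."""
    config = SyntheticConfig(seed=23)
    reference, interactions, gwas, truth = simulate_all(config)
    return config, reference, interactions, gwas, truth


@pytest.fixture
def toy_fmap():
    """Five contiguous 100-bp fragments on one chromosome."""
    return FragmentMap(
        pd.DataFrame(
            {
                "chrom": ["1"] * 5,
                "start": [0, 100, 200, 300, 400],
                "end": [100, 200, 300, 400, 500],
                "frag_id": [10, 11, 12, 13, 14],
            }
        )
    )


@pytest.fixture
def toy_blocks():
    return LdBlockSet(
        pd.DataFrame(
            {"chrom": ["1", "1"], "start": [0, 1000], "end": [1000, 2000], "block_id": [0, 1]}
        )
    )


@pytest.fixture
def toy_genes():
    """Two genes on chromosome 1: GA (+, 2 exons), GB (-, 1 exon)."""
    genes = pd.DataFrame(
        {
            "gene_id": ["GA", "GB"],
            "name": ["GA", "GB"],
            "chrom": ["1", "1"],
            "strand": ["+", "-"],
            "biotype": ["protein_coding", "protein_coding"],
        }
    )
    tss = pd.DataFrame({"gene_id": ["GA", "GB"], "chrom": ["1", "1"], "pos": [120, 460]})
    exons = pd.DataFrame(
        {
            "gene_id": ["GA", "GA", "GB"],
            "chrom": ["1", "1", "1"],
            "start": [120, 180, 420],
            "end": [150, 230, 461],
        }
    )
    return GeneModelSet(genes, tss, exons)


@pytest.fixture
def toy_baits(toy_fmap):
    """GA's TSS fragment (11) is baited; GB's (14) is not."""
    return BaitMap(
        pd.DataFrame(
            {
                "frag_id": [11],
                "chrom": ["1"],
                "start": [100],
                "end": [200],
                "genes": [("GA",)],
                "virtual": [False],
            }
        )
    )


@pytest.fixture
def toy_interactions():
    """One passing and one failing interaction from bait 11."""
    return InteractionTable(
        pd.DataFrame(
            {
                "bait_id": [11, 11],
                "oe_chrom": ["1", "1"],
                "oe_start": [300, 400],
                "oe_end": [400, 500],
                "oe_id": [13, 14],
                "score_CT1": [3.1, 2.0],
                "score_CT2": [5.2, 4.9],
                "score_CT3": [0.0, 1.0],
            }
        )
    )
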