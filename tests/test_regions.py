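"""Gene-associated region assembly: fragments, baits, interactions, exons."""

import numpy as np
import pandas as pd
import pytest

from cogs.regions import (
    RegionConfig,
    assemble_gene_regions,
    bin_other_ends,
    build_virtual_baits,
    coding_regions,
    interacting_regions,
    map_to_fragments,
    promoter_proximal,
)
from cogs.types import BaitMap, GeneModelSet, InteractionTable, InvalidConfigError


class TestMapToFragments:
    def test_half_open_boundaries(self, toy_fmap):
        # fragment start belongs to the fragment, fragment end to the next one
        ids = map_to_fragments(["1", "1", "1"], [100, 199, 200], toy_fmap)
        assert list(ids) == [11, 11, 12]

    def test_beyond_chromosome_end_unmapped(self, toy_fmap):
        assert map_to_fragments(["1"], [500], toy_fmap)[0] == -1

    def test_agrees_with_linear_scan_oracle(self, planted_bundle):
        _, reference, _, _, _ = planted_bundle
        fmap = reference.fmap
        rng = np.random.default_rng(42)
        pos = rng.integers(0, 3_000_000, size=1000)
        chroms = np.where(rng.random(1000) < 0.5, "1", "2")
        got = map_to_fragments(chroms, pos, fmap)
        rows = fmap.frame
        for c, p, g in zip(chroms, pos, got):
            hits = rows[(rows["chrom"] == c) & (rows["start"] <= p) & (p < rows["end"])]
            expected = int(hits["frag_id"].iloc[0]) if len(hits) else -1
            assert g == expected


class TestPromoterProximal:
    def test_interior_fragment_gets_both_flanks(self, toy_fmap):
        out = promoter_proximal(12, toy_fmap, flank_count=1)
        assert list(out["frag_id"]) == [11, 12, 13]

    def test_chromosome_start_truncates(self, toy_fmap):
        out = promoter_proximal(10, toy_fmap, flank_count=1)
        assert list(out["frag_id"]) == [10, 11]

    def test_zero_flanks_is_bait_only(self, toy_fmap):
        out = promoter_proximal(12, toy_fmap, flank_count=0)
        assert list(out["frag_id"]) == [12]


class TestVirtualBaits:
    def test_unbaited_promoter_gains_virtual_bait(self, toy_genes, toy_fmap, toy_baits):
        out = build_virtual_baits(toy_genes, toy_fmap, toy_baits)
        virt = out.frame[out.frame["virtual"]]
        assert list(virt["frag_id"]) == [14]  # GB's TSS (460) fragment
        assert virt["genes"].iloc[0] == ("GB",)

    def test_idempotent_on_already_baited_gene(self, toy_genes, toy_fmap, toy_baits):
        once = build_virtual_baits(toy_genes, toy_fmap, toy_baits)
        twice = build_virtual_baits(toy_genes, toy_fmap, once)
        pd.testing.assert_frame_equal(once.frame, twice.frame)

    def test_two_promoters_two_virtual_baits(self, toy_fmap, toy_baits):
        genes = GeneModelSet(
            pd.DataFrame(
                {"gene_id": ["GC"], "name": ["GC"], "chrom": ["1"], "strand": ["+"],
                 "biotype": ["protein_coding"]}
            ),
            pd.DataFrame({"gene_id": ["GC", "GC"], "chrom": ["1", "1"], "pos": [250, 450]}),
            pd.DataFrame({"gene_id": ["GC"], "chrom": ["1"], "start": [250], "end": [300]}),
        )
        out = build_virtual_baits(genes, toy_fmap, toy_baits)
        virt = out.frame[out.frame["virtual"]]
        assert sorted(virt["frag_id"]) == [12, 14]


class TestInteractingRegions:
    def test_above_threshold_in_one_cell_type_kept(self, toy_interactions, toy_baits):
        out = interacting_regions(toy_interactions, toy_baits, RegionConfig(chicago_min=5))
        # scores (3.1, 5.2, 0.0) pass; (2.0, 4.9, 1.0) fail
        assert len(out) == 1
        assert out["start"].iloc[0] == 300

    def test_all_below_threshold_excluded(self, toy_baits):
        tab = InteractionTable(
            pd.DataFrame(
                {"bait_id": [11], "oe_chrom": ["1"], "oe_start": [300], "oe_end": [400],
                 "score_CT1": [5.0], "score_CT2": [4.0]}
            )
        )
        # threshold is a strict inequality: exactly 5 does not pass
        assert interacting_regions(tab, toy_baits, RegionConfig(chicago_min=5)).empty

    def test_shared_bait_propagates_to_both_genes(self, toy_interactions, toy_fmap):
        shared = BaitMap(
            pd.DataFrame(
                {"frag_id": [11], "chrom": ["1"], "start": [100], "end": [200],
                 "genes": [("GA", "GB")], "virtual": [False]}
            )
        )
        out = interacting_regions(toy_interactions, shared, RegionConfig(chicago_min=5))
        assert sorted(out["gene_id"]) == ["GA", "GB"]


class TestBinOtherEnds:
    def test_snap_to_containing_bin(self):
        tab = InteractionTable(
            pd.DataFrame(
                {"bait_id": [1], "oe_chrom": ["1"], "oe_start": [12_345], "oe_end": [12_346],
                 "score_CT1": [6.0]}
            )
        )
        out = bin_other_ends(tab, 5_000)
        assert (out.frame["oe_start"].iloc[0], out.frame["oe_end"].iloc[0]) == (10_000, 15_000)

    def test_same_bin_scores_combined_by_max(self):
        tab = InteractionTable(
            pd.DataFrame(
                {"bait_id": [1, 1], "oe_chrom": ["1", "1"], "oe_start": [12_000, 13_000],
                 "oe_end": [12_500, 13_500], "score_CT1": [4.0, 6.0]}
            )
        )
        out = bin_other_ends(tab, 5_000)
        assert len(out) == 1
        assert out.frame["score_CT1"].iloc[0] == 6.0

    def test_invalid_bin_width_rejected(self, toy_interactions):
        with pytest.raises(InvalidConfigError):
            bin_other_ends(toy_interactions, 0)


class TestCodingRegions:
    def test_overlapping_exons_merge(self):
        genes = GeneModelSet(
            pd.DataFrame({"gene_id": ["G"], "name": ["G"], "chrom": ["1"], "strand": ["+"],
                          "biotype": ["protein_coding"]}),
            pd.DataFrame({"gene_id": ["G"], "chrom": ["1"], "pos": [100]}),
            pd.DataFrame({"gene_id": ["G", "G"], "chrom": ["1", "1"],
                          "start": [100, 150], "end": [200, 250]}),
        )
        out = coding_regions(genes)
        assert len(out) == 1
        assert (out["start"].iloc[0], out["end"].iloc[0]) == (100, 250)

    def test_strand_agnostic_and_disjoint_preserved(self, toy_genes):
        out = coding_regions(toy_genes)
        ga = out[out["gene_id"] == "GA"]
        gb = out[out["gene_id"] == "GB"]
        assert len(ga) == 2  # disjoint exons stay separate
        assert len(gb) == 1  # minus strand treated identically
        assert (gb["start"].iloc[0], gb["end"].iloc[0]) == (420, 461)


class TestAssembleGeneRegions:
    def test_baited_gene_without_interactions_has_promoter_and_coding(
        self, toy_genes, toy_fmap, toy_baits
    ):
        sets = assemble_gene_regions(toy_genes, toy_fmap, toy_baits, None)
        cats = set(sets.frame.loc[sets.frame["gene_id"] == "GA", "category"])
        assert cats == {"coding", "promoter"}

    def test_virtual_baited_gene_gets_no_interacting_regions(
        self, toy_genes, toy_fmap, toy_baits, toy_interactions
    ):
        sets = assemble_gene_regions(toy_genes, toy_fmap, toy_baits, toy_interactions)
        gb_cats = set(sets.frame.loc[sets.frame["gene_id"] == "GB", "category"])
        assert gb_cats == {"coding", "promoter"}
        ga_cats = set(sets.frame.loc[sets.frame["gene_id"] == "GA", "category"])
        assert ga_cats == {"coding", "promoter", "interacting"}

    def test_assembly_is_idempotent_under_duplicate_regions(
        self, toy_genes, toy_fmap, toy_baits, toy_interactions
    ):
        once = assemble_gene_regions(toy_genes, toy_fmap, toy_baits, toy_interactions)
        again = assemble_gene_regions(toy_genes, toy_fmap, toy_baits, toy_interactions)
        pd.testing.assert_frame_equal(once.frame, again.frame)

    def test_raising_chicago_threshold_never_adds_regions(self, planted_bundle):
        _, reference, interactions, _, _ = planted_bundle
        sizes = []
        for thr in (0.0, 3.0, 5.0, 8.0, 12.0):
            sets = assemble_gene_regions(
                reference.genes, reference.fmap, reference.baits, interactions,
                RegionConfig(chicago_min=thr),
            )
            inter = sets.frame[sets.frame["category"] == "interacting"]
            sizes.append(len(inter))
        assert all(a >= b for a, b in zip(sizes, sizes[1:]))

    def test_planted_interacting_interval_lands_in_target_regions(self, planted_bundle):
        _, reference, interactions, gwas, truth = planted_bundle
        sets = assemble_gene_regions(reference.genes, reference.fmap, reference.baits, interactions)
        entry = truth.entries.iloc[0]
        vpos = gwas.loc[gwas["variant_id"] == entry["variant_id"], "pos0"].iloc[0]
        vchrom = gwas.loc[gwas["variant_id"] == entry["variant_id"], "chrom"].iloc[0]
        inter = sets.frame[
            (sets.frame["gene_id"] == entry["gene_id"]) & (sets.frame["category"] == "interacting")
        ]
        covered = ((inter["chrom"] == vchrom) & (inter["start"] <= vpos) & (vpos < inter["end"])).any()
        assert covered

    def test_binned_and_unbinned_agree_on_interacting_genes(self, planted_bundle):
        # when every other-end fragment sits wholly inside one bin
        _, reference, interactions, _, _ = planted_bundle
        fits = interactions.frame[
            interactions.frame["oe_start"] // 50_000 == (interactions.frame["oe_end"] - 1) // 50_000
        ]
        sub = InteractionTable(fits.reset_index(drop=True))
        unbinned = assemble_gene_regions(reference.genes, reference.fmap, reference.baits, sub)
        binned = assemble_gene_regions(
            reference.genes, reference.fmap, reference.baits, bin_other_ends(sub, 50_000)
        )
        def inter_genes(s):
            return set(s.frame.loc[s.frame["category"] == "interacting", "gene_id"])
        assert inter_genes(unbinned) == inter_genes(binned)
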