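#!/usr/bin/env python
"""Generate the synthetic study inputs.

Builds a two-chromosome synthetic genome with four planted causal variants
(one coding, one promoter-proximal, two in promoter-interacting fragments;
z-mean 7-8, i.e. clearly genome-wide significant) and writes every input file
the pipeline consumes under results/synthetic/.
"""

from pathlib import Path

from cogs import io
from cogs.simulate import PlantedEffect, SyntheticConfig, simulate_all

OUT = Path(__file__).resolve().parent.parent / "results" / "synthetic"

EFFECTS = (
    PlantedEffect("G0003", "coding", 7.0),
    PlantedEffect("G0012", "promoter", 7.0),
    PlantedEffect("G0025", "interacting", 8.0),
    PlantedEffect("G0034", "interacting", 8.0),
)
CONFIG = SyntheticConfig(seed=42, planted_effects=EFFECTS, effect_scale="z")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    reference, interactions, gwas, truth = simulate_all(CONFIG)
    io.write_gwas(gwas, OUT / "gwas.tsv", "hgi_r5")
    io.write_rmap_baitmap(reference.fmap, reference.baits, OUT / "fragments.rmap", OUT / "fragments.baitmap")
    io.write_interactions(interactions, OUT / "interactions.tsv")
    io.write_bed_blocks(reference.blocks, OUT / "ld_blocks.bed")
    io.write_bed12_genes(reference.genes, OUT / "genes.bed12")
    io.write_results(truth.entries, OUT / "truth.tsv")
    print(f"wrote {len(gwas)} variants, {len(interactions)} interactions, "
          f"{len(reference.genes)} genes, {len(reference.blocks)} LD blocks -> {OUT}")
    print(f"planted truth:\n{truth.entries.to_string(index=False)}")


if __name__ == "__main__":
    main()
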