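# cogs — Capture Hi-C Omnibus Gene Score

A tested Python implementation of the COGS variant-to-gene prioritisation
pipeline: Bayesian fine-mapping of GWAS summary statistics within linkage
disequilibrium (LD) blocks, aggregation of variant posteriors over
promoter-capture Hi-C (PCHi-C) derived gene-associated regions, and a
per-gene probability-of-causality score, together with the downstream
comparison and enrichment analyses commonly run on such scores and a
synthetic-data generator with planted ground truth so every stage is testable
without external downloads.

## Who it is for

Statistical and regulatory geneticists who have (i) GWAS summary statistics
(e.g. in the COVID-19 Host Genetics Initiative release layout), (ii) CHiCAGO
-processed PCHi-C interaction calls (rmap/baitmap + peak matrix), (iii) an
ldetect-style LD-block partition, and (iv) gene models, and who want a
principled per-gene score linking non-coding GWAS signal to the genes whose
promoters physically contact it.

## The score

For each variant with effect estimate variance `V` (from the case-control
approximation `V = 1/(2N f(1-f) s(1-s))`) and z-score `z`, the Wakefield
approximate Bayes factor is, with `r = W/(V+W)` and prior effect variance
`W`:

    log ABF = ½ [ log(1 − r) + r z² ]

Under at most one causal variant per LD block, normalising the ABFs within a
block gives each variant a posterior probability of causality `ppi`. A gene's
associated regions are its coding exons, its baited promoter fragment plus
immediate flanking fragments (with *virtual baits* for promoters missing from
the capture design), and every PCHi-C other-end with a CHiCAGO score above 5
in at least one cell type. The block score is the summed `ppi` of the covered
variants, and the gene score is the complement product across blocks:

    G = 1 − Π_b (1 − s_b)

— the probability that at least one causal variant falls in at least one of
the gene's regions. Genes with `G > 0.3` (strict) are conventionally
reported as prioritised.

## Worked example

`analysis/` contains the numbered study scripts. `01_simulate.py` builds a
two-chromosome synthetic genome (8 LD blocks, 40 genes, 480 GWAS variants)
with four planted causal variants — one coding, one promoter-proximal, two in
promoter-interacting fragments — and `02_run_cogs.py` scores every gene:

```
$ python analysis/01_simulate.py
$ python analysis/02_run_cogs.py
fine-mapped 480 variants in 8 blocks
top COGS scores:
gene_id    score  n_blocks  coding_share  promoter_share  interacting_share
  G0025 1.000000         2      0.000000        0.009086           0.990914
  G0003 1.000000         1      1.000000        0.000000           0.000000
  G0034 0.999999         2      0.000000        0.000000           1.000000
  G0012 0.999574         2      0.000000        0.991729           0.008271
  G0008 0.317158         1      0.600554        0.346484           0.052962
...
5 genes prioritised at COGS > 0.3
```

The four planted target genes (G0003, G0012, G0025, G0034) take the four top
scores, each dominated by the region category its causal variant was planted
in (the `*_share` columns decompose each gene's captured posterior mass).
`03_compare_prioritisation.py` shows the naive nearest-exon baseline recovers
only 3/4 targets, `04_enrichment.py` runs preranked GSEA / hypergeometric
over-representation against synthetic gene sets (the planted-target set comes
out on top), and `05_threshold_calibration.py` sweeps the threshold:
fold-enrichment for the true targets rises from 1.18× at `t = 0` to 8× at
`t = 0.3` while recall stays 1.0.

The same stages are available as a CLI (`cogs simulate|finemap|regions|run|
combine|compare|pr|gsea|ora|cluster`); see `cogs --help`.

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
regenerates the synthetic study from scratch for the given seed, runs two
full COGS passes, combines them, sweeps the precision-recall curve against
the planted targets, writes the intermediate tables next to the output path,
and prints a one-line summary of the prioritisation outcome.

## Layout

- `src/cogs/` — the library: `simulate` (synthetic worlds), `io` (formats),
  `finemap` (Wakefield ABFs and block posteriors), `regions` (gene-associated
  region assembly), `scoring` (the COGS score), `downstream` (baselines,
  PR sweeps, GSEA, ORA, clustering), `cli`.
- `analysis/` — the numbered study drivers.
- `tests/` — unit, property and acceptance tests.
- `docs/methods.md` — model assumptions, parameter choices, limitations.
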