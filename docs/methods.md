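# Methods

## Model

### Fine-mapping

Each GWAS variant is summarised by a z-score (`beta/se` when both are
available, otherwise the two-sided normal quantile of its p-value; direction
is discarded) and a sampling variance from Wakefield's case-control
approximation, `V = 1/(2N f(1−f) s(1−s))`, with `f` the minor allele
frequency and `s` the case fraction. The log approximate Bayes factor against
the null is the closed form `½[log(1−r) + r z²]`, `r = W/(V+W)`; the test
suite verifies this against numerical integration of the two marginal
likelihoods to 1e-8.

Within an LD block the model allows at most one causal variant. Two
normalisations are implemented:

- `exactly_one_causal` (default): posteriors are the ABFs softmax-normalised
  within the block; they sum to 1 in every block, including blocks with no
  real signal. This makes the score a *relative* allocation of each block's
  single-causal assumption.
- `null_model`: each variant carries a per-variant prior `pi0_prior`
  (default 1e-4) of being the causal one and a null configuration absorbs the
  remaining mass, so block posteriors sum to < 1. The phrase "at most one
  causal variant" is compatible with either reading; the default is a
  documented package choice, not a claim about any other implementation.

All normalisations are log-sum-exp stabilised; ties in ABF produce exactly
equal posteriors.

### Gene-associated regions

Per gene, three region categories:

- **coding** — merged exon intervals of all transcripts (a `cds_only` switch
  restricts to CDS intervals when the gene models carry them);
- **promoter** — the baited fragment containing the TSS plus `flank_count`
  (default 1) adjacent fragments per side, truncated at chromosome ends.
  Promoters absent from the baitmap receive a *virtual bait* on their TSS
  fragment, built identically to real baits but contributing promoter
  regions only (no interactions exist for them);
- **interacting** — every other-end fragment (or 5-kb bin for DpnII-style
  designs, where other-ends are snapped to the bin containing their start
  coordinate and same-bin scores combine by max; baited fragments stay
  unbinned) whose interaction with one of the gene's baits scores strictly
  above `chicago_min` (default 5) in at least one cell type. Pooling across
  cell types is by max within a dataset; separate PCHi-C datasets are run
  separately and combined at the score level, never pooled at region level.
  A bait shared by several promoters propagates its regions to all linked
  genes; trans-chromosomal other-ends are retained.

All intervals are 0-based half-open; a variant at an interval end belongs to
the next interval. GWAS positions (1-based in files) are shifted on load.

### Scoring

A variant contributes to a gene at most once per block, however many of the
gene's regions cover it (probabilities, not evidence weights, are summed).
For the category decomposition report only, a multiply-covered variant is
attributed to one category by the fixed priority coding > promoter >
interacting, so the shares sum to 1. The block score is `s_b = Σ ppi`
(clamped at 1 with a warning on floating-point overshoot) and the gene score
`G = 1 − Π_b (1 − s_b)` under block independence. Exhaustive enumeration over
joint causal placements reproduces `G` to 1e-12 on small instances.

`combine_runs` joins score tables across traits/datasets by gene id and
reports per-run scores, the per-gene max, and the union of genes above the
threshold in any run. The Manhattan table flags genes with score strictly
above 0.3 for labelling and suppresses a non-coding gene's label when a
prioritised protein-coding gene lies within the (configurable, default 1 Mb)
locus window.

## Downstream analyses

- **Nearest-exon baseline**: variants with p < 1e-8 map to the gene(s) whose
  exon boundary is closest (distance 0 inside an exon); exact ties report
  every tied gene and are flagged — no arbitration is attempted.
- **Precision-recall**: reference genes are restricted by default to genes
  with a non-zero COGS score, so recall measures ranking rather than assay
  coverage; fold-enrichment is precision over the reference's base rate in
  the scored universe; precision is reported as missing when nothing is
  prioritised.
- **Preranked GSEA**: weighted Kolmogorov-Smirnov running sum (hit steps
  `|score|^p / Σ|score|^p`, default exponent 1; miss steps `1/(N−N_hit)`);
  the null is gene-label permutation, NES divides ES by the mean magnitude of
  same-sign permuted ES, the nominal p uses the same-sign permutation pool
  with the +1 correction, and FDR follows the pooled normalised-ES
  convention. Default 1,000 permutations; a seed is mandatory.
- **Over-representation**: upper-tail hypergeometric per annotation set with
  Benjamini–Hochberg adjustment across sets; significant at adjusted
  p < 0.05.
- **Expression clustering**: per-gene z-scaling across samples
  (constant-expression genes dropped), k-means with fixed seed and 10
  restarts; k is chosen by maximal mean silhouette, with the within-cluster
  sum-of-squares (elbow) curve emitted for inspection only. The
  top-expression filter keeps genes at or above the stated quantile (default
  0.75) of the per-gene maximum (mean as an option), keeping ties.

## The synthetic world

The generator's defaults describe a compact genome that preserves the
proportions the pipeline is sensitive to: 2 chromosomes × 3 Mb, HindIII-like
~4 kb fragments (exponential lengths, 200 bp floor), 8 equal LD blocks
(~750 kb — large relative to a gene's regulatory footprint, as real ldetect
blocks are), 40 genes with 2–4 exons, 20% of promoters unbaited (to exercise
virtual baits), 3 cell types, 60 variants per block (~12.5 kb spacing),
5,000 cases / 5,000 controls, MAF ~ U(0.05, 0.5).

LD is modelled at the z-score level: the causal variant draws
`z ~ N(β/√V, 1)` and a variant at rank distance `d` draws
`z ~ N(ld_decay^d · β/√V, 1)` with independent unit noise. The default
`ld_decay = 0.5` reflects typical adjacent-variant correlation at the
default ~12.5 kb spacing in outbred human populations. Because `V` depends on
the drawn MAF, `effect_scale="z"` lets an effect be specified directly as the
z-mean (non-centrality), which the recovery analyses use. Interaction scores
are Gamma(2, scale/2) with expected value `1 + 10·exp(−d/150 kb)` — positive,
right-skewed and distance-decaying, like CHiCAGO scores; each planted
"interacting" target is guaranteed one other-end scoring above 5. A
generation error names any planted interacting target whose promoter is not
baited. At most one causal variant is planted per block unless
`allow_multi_causal` is set (for probing model misspecification). All
randomness flows from one seed through named `SeedSequence` sub-streams, so
identical configs give byte-identical outputs.

What the generator does **not** emulate: realistic allele-frequency spectra,
haplotype-level LD (noise across variants is independent given the mean
structure), coverage/probe-design artefacts of real capture systems, and
population stratification. A green recovery test therefore establishes that
the pipeline's aggregation logic recovers planted signal under its own model
assumptions — not robustness to real-data pathologies.

## Numerical choices

- Log-sum-exp for all posterior normalisation; block sums clamp at 1 only on
  floating-point overshoot.
- Score TSVs are written with 6 significant digits; internal test
  comparisons use 1e-9 or tighter.
- Duplicate GWAS positions keep the smallest p (deterministic and
  conservative); rows with missing MAF or sample sizes are dropped with a
  logged count, since the variance formula needs both.
- p = 0 in input caps |z| at 40 with a warning rather than dropping an
  overwhelming signal.
- Variants rarer than `maf_min = 0.01` are excluded before fine-mapping;
  the case-control variance approximation degenerates at rare alleles.
- Sex-chromosome variants are loaded but excluded at block assignment
  (autosome-only block sets), with a logged count.
- Chromosome names are unified to the bare dialect ("chr1" → "1") at load.

## Open design points resolved here

- Virtual baits get flanking fragments exactly like real baits.
- In binned designs, promoter-proximal regions use bin neighbours the same
  way fragment designs use fragment neighbours.
- A variant in several categories of one gene is counted once in the score
  (deduplication before summation).
- W defaults to 0.2² = 0.04, the conventional prior on log odds-ratios for
  case-control traits; it is a config field, as is every threshold above.

## Limitations

Single-causal-per-block fine-mapping cannot represent allelic series within
a block; no LD matrix is used, so secondary signals leak posterior mass
toward the lead variant's neighbours; scores are comparable within a run but
depend on the capture design's coverage, which is why cross-dataset
combination reports per-run scores alongside the max.
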