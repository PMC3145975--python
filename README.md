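# mkcobind

Combinatorial transcription-factor co-occupancy analysis for
megakaryocyte (MK) ChIP-seq.

Lineage decisions in hematopoiesis are driven by small sets of
transcription factors acting together. Given genome-wide peak calls
for a core circuit of K factors — here GATA1, GATA2, RUNX1, FLI1 and
TAL1/SCL profiled in primary human megakaryocytes — the scientific
question is which *combinations* of factors co-occupy regulatory
regions more (or less) often than chance, and which combinations sit
next to the genes that define the lineage. `mkcobind` is a tested,
reusable pipeline for that analysis, aimed at computational biologists
who have per-factor peak BEDs, gene models, histone-mark calls and an
expression matrix.

## What it computes

1. **Occupancy patterns.** Peaks from all factors are merged into
   union regions (maximal covered intervals); each region gets the
   exact subset S ⊆ {1..K} of factors bound, a bitmask over the
   ordered factor list. For K = 5 there are 31 nonempty patterns, 26
   of which involve two or more factors. Exact counts ("bound by
   precisely S") and at-least counts ("bound by S, possibly more") are
   both reported.
2. **Enrichment Z-scores.** Under an independence null with a fixed
   universe of N bindable regions and marginal probabilities
   p_i = n_i/N, a region shows pattern S with probability
   p_S = ∏_{i∈S} p_i ∏_{j∉S} (1−p_j), so the exact count is
   Binomial(N, p_S) and Z_S = (O_S − N p_S)/√(N p_S(1−p_S)). A
   Monte-Carlo simulator of the same Bernoulli process audits the
   normal approximation.
3. **Peak-to-gene mapping.** Regions in a promoter window
   (TSS −1000/+500, strand-aware) or a gene body are allocated to that
   gene; the remainder go to the nearest gene on each side by TSS
   distance within 100 kb. This yields the 31 pattern target-gene
   lists.
4. **Promoter chromatin states.** H3K4me3⁺K27me3⁻ = active,
   K4⁺K27⁺ = bivalent, K4⁻ = inactive; the pipeline reports the
   fraction of promoters bound by the circuit and the expression
   summary per state.
5. **GSEA.** Each pattern's target list is tested against the genes
   ranked by log2(MK / mean of other cell types) with the weighted
   Kolmogorov–Smirnov running sum (ES), gene-set-permutation NES and
   FDR q.
6. **Motif enrichment.** IUPAC consensus scanning (GATA `WGATAR`,
   E-box `CANNTG`, ETS `GGAW`, RUNX `TGYGGT`, and the E-box–spacer–GATA
   composite that marks SCL:GATA docking sites) with Fisher exact
   tests of pattern subsets against the remaining regions.
7. **Network model.** The densely connected TF core circuit (config,
   including autoregulation) plus pattern nodes linking to effector
   genes; exported as SIF/GraphML/DOT with degree summaries.

A synthetic-data module generates all inputs — peak landscapes with
planted all-five "complex" regions and a suppressed GATA1+FLI1-only
pattern, gene models, state-coupled histone marks and expression, and
motif-planted sequences — with full ground truth, so the entire
pipeline runs and is validated without any downloads.

## Worked example

Run the whole pipeline on the default synthetic landscape:

```bash
mkcobind all --seed 1 --outdir out
```

or drive the library directly:

```python
from mkcobind.simulate import LandscapeConfig, generate_gene_models, generate_peak_landscape
from mkcobind.occupancy import assign_patterns, count_exact_patterns
from mkcobind.enrichment import NullModel, pattern_zscores

cfg = LandscapeConfig(seed=1)
genes = generate_gene_models(cfg)
peaksets, truth = generate_peak_landscape(cfg, genes)
regions, order = assign_patterns([peaksets[f] for f in cfg.factors])
table = count_exact_patterns(regions, order)
stats = pattern_zscores(table, NullModel.from_table(table, cfg.universe_n))
```

which prints (seed 1):

```
union regions: 1433
marginals: {'GATA1': 544, 'GATA2': 446, 'RUNX1': 807, 'FLI1': 885, 'SCL': 530}
pattern                          obs       exp         Z
GATA1+GATA2+RUNX1+FLI1+SCL        51  0.000574    2128.7
GATA1+RUNX1+FLI1+SCL              38    0.0252     239.4
GATA2+RUNX1+FLI1+SCL              27    0.0205     188.3
GATA1+FLI1                        12        22      -2.1
```

Reading this: 1433 union regions are bound by at least one factor.
The all-five pattern is observed 51 times against an independence
expectation of ~0.0006, by far the most enriched combination — the
planted multi-TF complex regions are recovered. The GATA1+FLI1-only
pattern (last row) is the most *depleted*: the generator suppresses
exactly that pattern, mimicking a pair that binds together only inside
larger complexes. Downstream, the GSEA stage ranks the all-five target
list top among the 31 (NES ≈ 2.4 at seed 1) and the composite
E-box/GATA motif is ~20-fold enriched in GATA1+SCL-only regions.

With real data, point the YAML config at your files instead:

```yaml
peak_paths: {GATA1: gata1.bed, GATA2: gata2.bed, RUNX1: runx1.bed,
             FLI1: fli1.bed, SCL: scl.bed}
gene_models: genes.gtf
mark_paths: {H3K4me3: k4.bed, H3K27me3: k27.bed}
expression: expression.tsv
universe_n: 80000
```

Stages degrade gracefully: with no expression matrix the GSEA and
network stages are skipped and everything upstream still runs.

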