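# Methods

This note records the models, conventions and numerical choices behind
`mkcobind`, and what the synthetic benchmark does and does not show.

## Coordinates and interval algebra

All coordinates are 0-based half-open (BED convention); GTF input is
converted on read. Chromosome names are matched verbatim — no `chr`
normalization — with a concordance report instead of silent renaming.
Union regions are defined as the maximal covered runs of the per-base
coverage vector over all factors' peaks, so overlapping *and*
bookended peaks fall into one region; the implementation is a sweep,
but its contract is the per-base definition and the test suite holds
it to a brute-force per-base oracle. Same-factor overlapping peaks
are merged at load: in the pattern logic a factor either binds a
region or it does not. Co-binding requires at least `min_overlap`
(default 1) bp of intersection between a factor's peaks and the union
region; published co-occupancy counts rarely state a threshold, so
1 bp is the default and the knob is exposed.

## Exact vs at-least pattern counts

Combination counts are *exact* patterns (bound by precisely S), one
count per union region regardless of how many same-factor peaks it
contains. At-least counts (any superset of S) are a separate
first-class query because published co-binding figures mix the two
conventions. With K = 5 there are 31 nonempty exact patterns; the 26
with ≥2 factors are the default report.

## Independence null and Z-scores

The null fixes a universe of N bindable regions (default 80,000, a
published lower-end genome-wide estimate; the synthetic default scales
it to 20,000 for a 10-Mb genome) and treats factor i as binding each
region independently with p_i = n_i/N. The exact-pattern count is then
Binomial(N, p_S) with p_S = ∏_{i∈S}p_i ∏_{j∉S}(1−p_j), giving
E_S = N·p_S, V_S = N·p_S(1−p_S) and a normal-approximation Z. The
source analyses of this kind typically do not publish their variance
form; every report header therefore states the model. Marginals n_i
default to realized region-level counts from the pattern table (not
raw peak counts) for internal consistency; a raw-peak option exists.
`monte_carlo_null` simulates the N×K Bernoulli indicator matrix
directly — it never reuses the closed-form p_S — so the analytic
approximation is auditable; zero-variance patterns with a discrepant
observation are reported as an infinite-Z sentinel with a warning
rather than an exception.

Known limitation: the null ignores GC content, accessibility and
peak-width heterogeneity; matched-background or segment-shuffling
nulls are out of scope.

## Peak-to-gene rule

Promoter windows are TSS −1000/+500 bp, strand-aware (configurable; a
"promoter" definition is a convention, not a measurement). Precedence
is promoter > intragenic > intergenic. Promoter- or body-overlapping
regions are allocated to every such gene; intergenic regions go to the
nearest gene by TSS distance on each side, each side only within
100 kb, measured from the region edge; TSS ties break to the
alphabetically first gene id so output is deterministic. Intragenic
allocation uses the whole gene body (TSS–TES): restricting to introns
would leave exon peaks unassigned for no stated reason. A
promoter-overlapping region is not additionally assigned to flanking
genes.

## Promoter chromatin states

K4⁺K27⁻ → active, K4⁺K27⁺ → bivalent, K4⁻ → inactive (K27 alone is
inactive). Marks arrive as called peak regions; in the default
`called` mode a mark is present when any called peak overlaps the
promoter window (signal = score × overlap fraction, threshold 0). A
`quantile` mode thresholds the window signal at the 75th percentile of
the nonzero genome-wide distribution for workflows that provide
continuous signal rather than calls. H3ac is accepted and reported but
does not enter the 3-way rule, which is driven by K4/K27.

## GSEA

Ranking metric: log2((target + 1)/(mean(others) + 1)) on linear
expression, descending, ties broken by gene id. The running sum
increments |s|^p/NR at hits (p = 1 default, NR = Σ|s|^p over hits) and
decrements 1/(N−Nh) at misses; ES is the signed extremum, with ties on
|value| going to the earlier rank. Significance uses gene-set
permutation — only one expression profile per cell type is assumed
available, so phenotype permutation is not an option — with NES
normalized by the mean same-sign null ES and the pooled-null FDR q,
forced monotone in |NES| within each sign. The permutation default is
200; the synthetic benchmark is insensitive to this between 100 and
1000.

## Motif scanning

Exact IUPAC consensus matching on both strands; composite motifs are
part1–spacer–part2 in fixed order on one strand with the spacer in a
configurable range (E-box–(2..10)–GATA by default). A match is a
(start, end) span; overlapping spans count separately and a
palindromic span matching both strands counts once. The defaults are
conventional consensus strings, deliberately replacing de novo
discovery: the point of this stage is the enrichment logic, not motif
rediscovery. Enrichment is a Fisher exact test on
sequences-with-≥1-match, with a Haldane 0.5 correction for degenerate
odds ratios.

## Network model

The TF→TF core circuit (dense cross-regulation and autoregulation
among the five factors) is configuration, not inference — it encodes
established connectivity; a peak-at-own-locus check is provided as an
audit, never as the source. Pattern nodes carry membership in-edges
matching their bitmask and deduplicated targeting edges per
(pattern, gene). Exports: SIF, GraphML (networkx), and a
self-contained DOT writer with a reader for the emitted subset.

## Synthetic landscapes

The generator is a latent-site mixture chosen as the simplest story
producing both excess co-binding and exact independence when needed:

* **Sites.** `n_background_sites` (1500) + `n_complex_regions` (40)
  positions on two 5-Mb chromosomes, pairwise ≥2 kb apart (sampled by
  the sorted-uniform-with-gaps construction, so spacing is guaranteed,
  and peaks of one site can never merge with another's).
* **Emission.** Background sites emit factor i's peak independently
  with e_i solved from the per-factor marginal targets
  (400–900 peaks/factor); complex sites emit every factor with
  probability 0.95. Peaks are 200–600 bp with ±100 bp center jitter.
  Realized marginals land within binomial error of targets.
* **Suppression.** Background sites realizing exactly GATA1+FLI1 are
  resampled with probability 0.9, creating the depleted pair-only
  pattern the analysis should flag as most underrepresented.
* **Genes.** 300 non-overlapping genes (2–20 kb) with ≥2.5 kb
  inter-gene gaps so neighboring promoter windows — and the mark peaks
  emitted in them, jitter included — never overlap; without this the
  noise-free state-recovery question is ill-posed.
* **Chromatin/expression coupling.** Promoter states are drawn
  conditionally on TF binding (bound: 70/20/10 active/bivalent/
  inactive; unbound: 25/15/60), which induces the monotone
  bound-fraction ordering; generating state-given-binding rather than
  binding-given-state yields the same joint law with far simpler
  placement. Marks follow the state rule with 5% dropout and 2%
  spurious-mark noise. Expression (8 cell types: MK plus seven other
  blood types) is lognormal with a state effect (0/0.5/2 log2) plus a
  2.5-log2 MK-specific boost for genes allocated to complex sites, and
  0.6 log2 noise.
* **Sequences.** Union-region sequences are i.i.d. uniform ACGT with
  motifs planted by pattern: the E-box/GATA composite in
  GATA1+SCL-only regions (p = 0.9) and single consensus elements in
  regions containing the corresponding factor (p = 0.5).
* **Null mode.** `null_config` removes complexes and suppression and
  sets universe N to the site count, so the independence null is true
  by construction; this is what the Z-calibration check (~5% of |Z|
  above 1.96) runs on.

Problem sizes — 10 Mb, 300 genes, ~3,200 peaks, 3,000-site null
landscapes, 5,000-rep Monte-Carlo audits — were chosen so a full test
cycle completes in about a minute on one CPU while keeping every
statistical check comfortably powered.

What passing on synthetic data does **not** show: real peak sets have
width, GC and accessibility structure the null ignores; real gene
annotations overlap; real histone signal is continuous and noisy in
ways the dropout model does not capture; and real expression
compendia have correlated cell types. The synthetic benchmark
validates the *logic and statistics* of the pipeline, not the
biological calibration of any threshold.

## Degenerate inputs and tie-breaks (summary)

Empty BED → empty PeakSet with a warning; malformed line → error with
line number. A factor with n_i = N makes every excluding pattern's
E = 0. Empty chromatin-state classes report NaN, never a fabricated 0.
GSEA rejects empty or all-encompassing gene sets. Gene-assignment TSS
ties go to the alphabetically first id; ES extremum ties to the
earlier rank. All stochastic stages take explicit seeds and are
bit-reproducible.
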