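# Methods

`chromstate` quantifies how loss of a chromatin regulator shifts the
balance of active (H3K4me3) and repressive (H3K27me3) histone marks at
gene promoters, and propagates that shift through co-occupancy,
accessibility and expression analyses. Because the package is exercised on
a synthetic epigenome with known ground truth, every statistic it computes
can be checked against the labels that generated the data. This note
documents the models, the parameters that matter, and the choices made
where the design was genuinely open.

## Coordinate and counting conventions

All intervals are 0-based half-open (`[start, end)`, BED convention), so
abutting intervals never overlap and the overlap predicate is
`a.start < b.end and b.start < a.end` (at least 1 bp shared). Chromosome
names are compared as exact strings. Promoter windows are symmetric in
genomic coordinates (`[tss - flank, tss + flank)`, clipped at 0) and are
*not* oriented by strand — a symmetric window needs no orientation.
Meta-profiles *are* oriented by strand so that upstream and downstream
are comparable across genes.

Two fragment-to-bin rules coexist, each stated where used: binned
coverage adds 1 to **every** bin a fragment overlaps (a fragment-count
convention, not a per-bp pileup), while nucleosome occupancy assigns each
fragment to the bin of its **midpoint**, since a nucleosome-sized fragment
localizes a single dyad.

## The promoter bivalency statistic

Per gene, H3K4me3 and H3K27me3 fragments overlapping the ±3 kb TSS window
are counted, CPM-normalized per mark library, and combined as

    ratio = (K4_CPM + α) / (K27_CPM + α),   α = 1 CPM

The pseudo-count α keeps the ratio finite when the K27 window is empty and
rank-stable at low counts; it also shrinks extreme ratios toward 1, so a
3-fold knockout gain in K4 appears as a relative ratio somewhat below 3
(about 2.3 under the default depth) — the separation from unaffected genes
is what matters, not the absolute value. CPM was adopted as the depth
normalization; it cancels exactly in the knockout/control relative ratio,
which makes the ranking invariant to library depth.

Promoters are classified into K4-only / K27-only / bivalent / neither by
comparing each mark's CPM against a per-mark threshold, by default the
95th percentile of CPM in random windows of promoter width placed at least
2×flank away from any annotated TSS (an empirical background null; no
published enrichment cutoff exists to adopt).

Replicate ChIP experiments are combined as the mean of per-replicate
ratios (not the ratio of pooled counts): with two replicates this matches
how replicate error bars are usually drawn, and it keeps each replicate's
library normalization self-contained.

The ratio–expression relationship is summarized by a sliding-window
Spearman correlation: genes are ordered by expression, both the ratio and
the expression series are averaged in a 100-gene window advanced 1 gene at
a time, and the two windowed-mean series are rank-correlated with
mid-ranked ties. Ordering by expression (rather than by ratio) treats
expression as the organizing axis; the windowing choice is configurable
(`window`, `step`). Note that rank correlation of windowed means is *not*
invariant to monotone transforms applied before windowing — only the
post-windowing ranks are transform-free.

## Co-occupancy statistics

Pairwise overlap reports, per side, the number of peaks with at least one
partner (≥ 1 bp, configurable) in the other set; the two sides coincide
exactly when overlaps are one-to-one. Percentages are rounded half-up to
whole percent for report parity with how such fractions are usually
printed; raw counts are always retained. Triple co-binding merges all
three sets into union loci and reports the fraction of loci contributed
to by all three factors — this denominator (the merged-union locus count)
is the reading that reproduces printed arithmetic of the
5,152 / 16,469 = 31% form.

TSS clusters map each gene's factor-membership triple within ±4 kb of the
TSS onto seven labels (A = factor1 only, B = factor2 only, C = factor3
only, D = 1+2, E = 1+3, F = 2+3, G = all three; no factor → none), a true
partition of the gene universe.

## Differential testing

A single negative-binomial test serves expression and accessibility.
Per feature (gene or consensus ATAC peak):

- replicate counts are normalized by total-count scaling to the mean
  library size (TMM was deliberately not implemented; at the synthetic
  data's symmetric differential structure total-count scaling is adequate
  and fully transparent);
- the NB dispersion φ is estimated by method of moments
  (`(var − mean)/mean²`), pooled across features as the median of positive
  per-feature estimates, floored at 0.01;
- the test statistic is the 1-df NB deviance between the common-mean fit
  and the two-group-mean fit, divided by a global quasi-likelihood scale —
  the mean across features of the within-group residual deviance per
  residual degree of freedom — and referred to χ²(1), two-sided by
  construction.

The quasi-likelihood scale is the load-bearing choice. At 3 replicates
per group, an unscaled Wald or LRT statistic referred to the normal/χ²
is anticonservative (empirical type-I ≈ 0.10 at nominal 0.05), while a
per-feature t(n₁+n₂−2) reference is calibrated but discards most power.
The global scale, estimated from thousands of features, absorbs both the
small-replicate inflation and the downward bias of the moment dispersion
at n = 3; the resulting test sits at empirical type-I 0.04–0.06 in the
null simulation (2,000 NB features, dispersion 0.1, 3 vs 3) while
recovering ~48/50 planted 4-fold changes. This is the same idea as
quasi-likelihood F-testing with a fully shrunk dispersion prior.

log2 fold changes use a 0.5 pseudo-count on normalized means. Multiple
testing is Benjamini–Hochberg (via `statsmodels`); a feature is called
significant when `q < 0.05` and `|log2FC| > 1`, and factor-dependent
accessibility peaks are the significant peaks with log2FC in the stated
direction (default: increased in knockout), the remainder being
factor-independent — an exact partition of the consensus set.

Gene-set ratio shifts are tested by a two-sided Mann–Whitney U between
the gene set and the remainder (default; a Welch t on log2 relative
ratios is available behind a flag) — the rank test is preferred because
per-gene relative ratios pooled from two replicates are far from normal.

qPCR utilities implement 2^−ΔΔCt relative expression and
percent-of-input ChIP enrichment
(`100 · 2^(ct_input − log2(1/input_fraction) − ct_ip)`).

## The synthetic epigenome

The generator emulates the *statistical structure* the analyses assume,
not sequencing reads. Default study conditions: 2 chromosomes × 5 Mb,
500 genes on a jittered grid (promoter windows never overlap), promoter
states drawn with fractions 0.30 / 0.20 / 0.30 / 0.20
(K4-only / K27-only / bivalent / neither), 50 knockout-responsive genes
drawn from the bivalent class, 3 replicates per genotype, 2×10⁵ fragments
per sample — sized so the full pipeline runs in seconds on one CPU.

Knockout effect sizes: `ko_k4_fold = 3` (H3K4me3 gain at responsive
promoters), `ko_atac_fold = 4` (accessibility gain at responsive
promoters and their enhancers), `ko_expr_log2fc = 2` (expression gain).

ChIP fragments follow a two-component inhomogeneous Poisson process:
a configurable fraction (default 0.5) of the nominal depth is distributed
over enrichment windows (promoter ±1.5 kb for the marks, ±1 kb for the
three factors, enhancer bodies for H3K4me1/H3K27ac) proportionally to
truth intensities, the rest uniformly over the genome. Fragment midpoints
are Gaussian around the window center; sizes are uniform on 200–500 bp
(a sonication-like range). Knockout multiplies the Poisson mean of
responsive K4 windows by `ko_k4_fold` *without* renormalizing the other
windows, so the expected KO/control window-count ratio equals the fold
exactly; the knockout library is therefore slightly deeper than nominal,
as a real re-sequenced library would be before depth normalization.

ATAC fragments draw sizes from a two-band mixture — sub-nucleosomal
(30–100 bp, weight 0.6) and mono-nucleosomal (180–247 bp, weight 0.4),
the conventional nucleosome-free/mono-nucleosome bands. Sub-nucleosomal
fragments center on the accessible locus (the nucleosome-free region);
mono-nucleosomal fragments center (σ = 20 bp) on truth dyads placed at
±200/±400 bp around each TSS and ±200 bp around enhancer centers.
Enhancers (one per gene) sit 10–50 kb from the TSS, poised at
bivalent/K27-only genes and active otherwise.

Expression counts are negative-binomial (dispersion 0.1) with log2 mean
`7 + 1 · true_log2(K4/K27)` (baseline ≈ 128 counts for a bivalent
promoter) plus `ko_expr_log2fc` for responsive genes in the knockout.
Because the truth ratio takes only a few discrete values per state, the
ratio–expression Spearman tops out near 0.94 even noise-free.

Every generator is bit-reproducible: a top-level seed plus fixed integer
codes for assay/genotype/replicate feed `numpy` `SeedSequence`-style
generator construction. The pipeline expands its single seed into
per-stage seeds with `SeedSequence.spawn`.

**What the generator does not model** — and hence what passing tests do
not show about real data: PCR duplicates, GC and mappability bias,
irregular gene spacing and overlapping transcription units, continuous
(rather than three-state) promoter mark gradients, trans effects of the
knockout beyond the designated gene set, and replicate-level batch
effects (replicates are i.i.d. redraws). Recovery metrics here are
therefore upper bounds on real-data performance.

## Numerical choices and degenerate inputs

- Meta-profile normalization divides by the mean of the first and last
  five bins; the identity `edge_mean == 1` holds to 1e-12 by construction,
  and an all-zero edge raises an error rather than returning infinities.
- The plumbing peak caller uses a pseudo-count ε = 1 on both tracks,
  scales control to the treatment library, merges candidate runs across
  gaps of ≤ 1 bin and drops runs shorter than `min_width`. It is monotone
  in the fold threshold.
- Replicate-reproducible peaks: union-merge all replicate peaks into
  loci, keep loci overlapped by ≥ `min_support` replicates (default 2),
  output the merged locus coordinates (union, not intersection —
  conservative region retention).
- Features with zero counts in both groups get `p = 1, log2FC = 0`
  (defined, not an error). Ranking ties break by gene id for determinism.
- Occupancy bins with no band fragments are NaN ("missing"), never 0.

## Problem sizes used in the test suite

Unit and property suites run on hundreds-of-interval fixtures; oracle
equivalence uses 100 randomized cases per operation (n ≤ 1,000);
parameter recovery runs the full default epigenome (500 genes, 2×10⁵
fragments/sample, 3+3 replicates); calibration uses 2,000-feature null
simulations. The complete suite runs in well under a minute.
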