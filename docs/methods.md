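# Methods

This note documents the models and procedures implemented in `spongemag`,
the conventions adopted where more than one was defensible, and what the
synthetic data do and do not establish.

## MAG quality gating and dereplication

A MAG's quality is `Q = completeness − 5 × contamination` (both in percent,
as estimated upstream by marker-gene tools); retention requires `Q ≥ 40`
**and** completeness ≥ 85%, both boundaries inclusive. `Q` may be negative
for heavily contaminated bins.

Dereplication consumes a precomputed symmetric ANI matrix (validated to
1e-9 symmetry with an exact 100 diagonal) and collapses MAGs by greedy
centroid clustering: within each scope cell (per host species for gene-content
comparisons; across species when a single non-redundant set is wanted), MAGs
are ranked by quality, then completeness, then identifier; the best
unassigned MAG becomes a representative and absorbs every unassigned MAG
with ANI ≥ 96.5% to it. This replaces two-stage MASH/ANIm workflows because
the operative parameter is the single ANI cutoff; equivalence with any
particular dereplication tool is not claimed, and the representative-scoring
rule is configurable. The procedure is idempotent on its representatives and
never assigns a MAG to a representative below the threshold (both are
property-tested).

"Present in at least half of the host species" uses `ceil(n/2)`; presence is
abundance > 0 by default.

## Permutational enrichment analysis

Copy numbers are normalised per MAG by its total predicted proteins, so the
unit is copies per predicted protein. Each annotation row counts once; a
protein's duplicated identical domain annotations are collapsed at read time
so proteins are not double-counted.

The prevalence filter removes a feature only when it occurs in fewer than
10% of MAGs in **both** groups (strict "less than"; exactly 10% in one group
retains).

The per-feature test statistic is the Welch *t* on normalised values; group
labels over MAGs are the exchangeable units. Group sizes and variances
differ strongly in the intended use (tens of host-associated vs ~100
free-living MAGs), which motivates Welch over pooled-variance Student
(both, and a plain mean difference, are available via
`RunConfig.test_statistic`). When the number of distinct label assignments
`C(nx+ny, nx)` is at most the iteration budget, the null distribution is
enumerated exactly and the exact tail returned; otherwise 10,000 Monte-Carlo
permutations are drawn and the add-one estimate `(1 + hits)/(1 + B)` is
returned, which cannot be zero. Degenerate variance is handled explicitly:
equal constant groups give *t* = 0 (p = 1); unequal constant groups give an
infinite statistic that ties only with other infinite statistics.

Benjamini–Hochberg runs step-up with an explicit family size `m`:
`q_(i) = min_{j≥i} min(1, m·p_(j)/j)`. By default `m` is the number of
features present in the category matrix *before* prevalence filtering — the
reading of "the total number of features within an annotation category" —
with tested-features-only available via `RunConfig.bh_family`; the choice is
logged. Calls are made at adjusted *p* < 0.01, the direction by the sign of
the mean difference.

The effect size is the signed log10 ratio of group means (magnitude =
log10(larger/smaller), sign = direction); a zero mean on exactly one side
produces a signed-infinity sentinel plus a flag rather than a number.

Per-feature RNG streams derive deterministically from
SHA-256(master seed, feature id), so results do not depend on feature
iteration order.

Taxon-stratified runs group at the phylum level, except Proteobacteria
which is split by class first; a stratum runs only when both life-history
categories contribute ≥ 10 MAGs, and skipped strata are reported with
reasons.

## Steroid gene cluster detection

Core genes are recognised through an identifier synonym map (gene symbols
and the EC numbers 1.3.1.70 / 1.14.14.154 / 5.4.99.7) with a product-text
regex fallback; KO identifiers can be appended per annotation pipeline. A
cluster requires all three cores on one contig and strand with at most
`max_intervening = 1` non-core gene and at most `max_gap_bp = 2000`
intergenic bp between consecutive cores; the defaults comfortably admit the
observed span range of real clusters (~5.3–6.1 kb for the trio) while
rejecting scattered copies. Strand consistency is required (operon
semantics); non-canonical core orders are reported and flagged, not
rejected, since flank arrangements vary in practice. Overlapping candidate
windows resolve greedily left-to-right. Flanks are judged on the single
gene immediately adjacent on each side, 5′/3′ defined relative to the core
strand; the 3′ flank (*SMT1*/*ERG6* or *FDFT1*) must lie on the opposite
strand to match, the 5′ flank (*DFR*/hypothetical) on the same strand.

`span_bp = max(end) − min(start) + 1` (1-based inclusive coordinates
throughout); the length summary uses the sample (n−1) standard deviation.
Cluster sequences are extracted on the forward strand and
reverse-complemented for minus-strand clusters.

## Selection inference

**Variant filtering.** Variants with QUAL < 20 are removed (strict), as are
variants with read depth above `2 × mean depth`, the mean taken over the
input sites. "Anomalously high depth" is not given a closed form in the
workflows this mirrors; the 2× multiplier is the common practice, is
configurable, and the realised cutoff is logged. Sites with unknown depth
pass the depth rule; if no depth is known at all the rule is skipped with a
warning.

**Variable-site proportions.** A gene's diversity is the count of distinct
variant positions within its interval divided by its length. The
genome-wide baseline merges all coding intervals (minus the three cluster
cores) before counting both the bp denominator and the variant positions,
so overlaps are not double-counted.

**Paired comparison.** Within each bacterial class (≥ 3 MAGs required), the
per-MAG difference (gene proportion − baseline proportion) enters a
sign-flip permutation test on the one-sample *t* statistic: exact 2ⁿ
enumeration when feasible, otherwise 10,000 Monte-Carlo flips with the
add-one estimate. The paired design reflects that gene and baseline are
measured within the same MAG; an unpaired two-sample variant is available
via `RunConfig.paired_variability`. BH-FDR is applied across the whole
(class × gene) family — the family definition is a convention, chosen as
the most conservative grouping — with tiers `*`, `**`, `***` at adjusted
p < 0.05, 0.01, 0.001.

**dN/dS.** ω is estimated by the Nei–Gojobori (1986) counting method:
per-codon synonymous site counts as the synonymous fraction of the nine
single-nucleotide neighbours (mutations to stops count nonsynonymous);
observed differences resolved by equal-weight averaging over the minimal
mutational pathways of multi-hit codons, excluding pathways through stop
codons; proportions corrected by Jukes–Cantor `d = −(3/4)·ln(1 − 4p/3)`;
gene-level dN and dS are means over all sequence pairs, ω = dN/dS (absent
when dS = 0). Pairs beyond the correction's domain (p ≥ 3/4) are excluded
with a warning. This is a deliberate replacement of likelihood (codon-model
ML) estimation: the package claims the qualitative inference — purifying
genes sit in the low tail of an empirical ω background — not numerical
equality with any ML estimate. Two counting-method caveats are documented
and tested: (i) equal-weight pathway averaging attributes fractional
nonsynonymous differences to some multi-hit codons even under a purely
synonymous history, so dN is near-zero rather than exactly zero when ω = 0;
(ii) with transition bias (κ > 1) the JC correction under-corrects
synonymous saturation, biasing ω slightly downward at moderate divergence
(mean recovered ω ≈ 0.84 over 20 seeds for neutral truth at divergence 0.3,
κ = 2).

The background filter keeps genes whose tree-wide mean ultrafast-bootstrap
support is ≥ 70% (inclusive); support is consumed as metadata, never
computed here, and genes lacking it pass with a flag. Empirical percentiles
give half weight to ties.

## Synthetic data

Every generator is a pure function of spec + seed and emits a truth table;
downstream tests read ground truth only from truth tables.

**Cohorts.** Default 40 focal vs 101 reference MAGs — echoing per-species
host cohorts against an ocean-province reference at realistic scale without
claiming to replicate any dataset — with 2000+ features. Copy numbers are
zero-inflated Poisson: per-feature prevalence ~ U(0.05, 0.9) and conditional
mean 1 + Exp(0.8). MAG protein totals ~ U(1500, 6000). A planted
fold-change acts on the feature's overall mean in the focal group by moving
*both* components — the fold splits geometrically between prevalence
(capped at 1) and conditional copy number — because real gene-family
enrichment manifests as more genomes carrying the family *and* more copies
per genome, not as a pure conditional-mean shift. Planted features start
from prevalence 0.5 and mean 6 copies when present (multi-copy families
such as repeat domains and transporter operons are the natural targets of
this analysis). Taxon labels are drawn from a ten-phylum composition with
Proteobacteria split into two classes.

**Genomes.** Filler genes (~0.3–2.4 kb) with short intergenic gaps over a
few contigs; a planted cluster reserves coordinate space for its flanks,
draws its span from U(5700, 6100) and splits it over the three cores at
fixed ratios; planted negatives contain all three core identifiers but
scatter them across contigs or put the middle core on the opposite strand.

**Variants.** Per-gene Poisson counts at 0.003/bp baseline, cluster cores
at 0.3×; ~5% of sites get QUAL < 20 and ~5% get a 5× depth spike, so the
variant filter has known targets.

**Codon alignments.** GY94-style simulation: uniform root over the 61 sense
codons, per-site Gillespie jumps with rates ∝ κ for transitions and × ω for
nonsynonymous changes, stops inaccessible, total rate normalised so branch
length is expected substitutions per codon site. Sequences evolve on a star
tree (each branch = divergence/2). Defaults: κ = 2, divergence 0.3.

**What passing does not show.** The generator draws MAGs independently — no
phylogenetic covariance among genomes, no compositional coupling between
features, no assembly/binning artefacts, no read-level error model — so
recovery rates here bound what the statistics can do under their own
assumptions, not performance on real metagenomes.

## Problem sizes

The shipped analysis and acceptance runs use 2000–2060 features at 40 vs
101 MAGs with 10,000 permutation iterations, 100 planted-positive plus 100
planted-negative genomes for detector validation, 20 replicate alignments
of 3000 codons per ω for recovery checks, and a 300-gene simulated ω
background — sizes chosen to give stable Monte-Carlo estimates on a single
CPU in minutes.

## Known limitations

* The enrichment test treats MAGs as exchangeable units; phylogenetic
  non-independence is out of scope (the taxon-stratified mode is the
  provided mitigation).
* The counting-method ω is biased downward under transition bias and
  cannot separate site classes; it supports rank/tail statements only.
* Cluster detection is identifier-driven; genomes annotated with schemes
  absent from the synonym map require extending it.
* The ANI matrix is consumed, never computed; garbage in, garbage out.
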