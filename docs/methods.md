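# Methods

This note documents the statistical machinery, the synthetic-data model it
is validated on, and the design choices made where the underlying
procedures admit more than one reasonable reading.

## Coordinates and inputs

All intervals are held 0-based half-open. GFF3 (1-based inclusive) is
converted on read and restored on write; BED passes through unchanged. A
gene's representative position is the average of its CDS midpoints (exon
midpoints, then the interval midpoint, as fallbacks); the ±1 bp extent
around it gives a minimal non-overlapping ordering of genes. Homolog hits
arrive as a TSV with ranked mappings per (query, species); hits are kept
only when strictly longer than 100 bp and strictly above 75% identity.
Sequence-search by-products that the pipeline consumes but does not
compute — whether a gene hit the wider bony-fish protein database
(`nr_hit`) and the coverage of a search against the
flanking-ortholog-bounded outgroup region (`region_hit_coverage`) — are
columns of the same table.

All inequality thresholds in the pipeline are strict, exactly as the
source procedures state them (>100 bp, >75%, >50%, >10%, >90%, <1 Mb,
<x bp).

## Event classification

**Chromosome homology** is computed, not assumed: a target chromosome is
homologous to a query chromosome when it receives ≥ 5% (configurable) of
that query chromosome's one-to-one rank-1 hits. One-to-one means the hit's
target locus (rank-1 hits clustered by interval overlap) is claimed by a
single query; duplicated loci carry no clean synteny vote. The 5% default
keeps minor but real homology blocks (e.g. a translocated arm) while
ignoring stray mappings.

**Micro-rearrangements**: a gene is a candidate iff *none* of its ≤ 5
outgroup hits lies on a homologous chromosome. Lineage is assigned by
3-taxon parsimony on best-hit chromosomes with the far outgroup (seabass)
as arbiter: far outgroup agreeing with the near outgroup (both showing the
gene elsewhere) ⇒ the move happened on the focal lineage; far outgroup
agreeing with the focal genome ⇒ the move happened on the near-outgroup
lineage (excluded); anything else ⇒ ambiguous, kept and flagged. The
original study defers the exact exclusion procedure to its supplement, so
this parsimony rule is this package's own stated reconstruction.
Candidates whose flanked outgroup region produced any homology hit
(`region_hit_coverage > 0`) are excluded as likely detection failures.
Consecutive candidate genes (gene-order adjacency, no base-pair gap limit)
merge into one multi-gene event.

**LSGs** require: no retained outgroup hit, at least one sister-species
hit (so the gene predates the two sticklebacks' split), and no wider
protein-database hit. The flanking-region coverage tiers the call:
zero/absent ⇒ stringent, ≤ 90% ⇒ permissive, > 90% ⇒ excluded. The
stringent set is a subset of the permissive set by construction.

**Duplications** are groups of ≥ 2 same-chromosome genes sharing one
single-copy outgroup locus, kept only if the same many-to-one pattern
holds against the second outgroup (otherwise a deletion in the first
outgroup explains the data more parsimoniously). Genes on different
chromosomes sharing a locus are not duplications; they surface as
rearrangement candidates, keeping the classes mutually exclusive.

**Collapsing for counting**: a multi-gene rearrangement is one event;
duplicate copies chain-merge while consecutive copies are < 1 Mb apart,
with the event position at the midpoint of the merged span. The operation
is idempotent and leaves no gene in two events of the same type.

**Macro-candidates** replace visual synteny inspection with a run-length
rule: the gene order of each chromosome is segmented into maximal runs of
rank-1 target chromosome; runs < 5 genes are noise; one surviving run ⇒
conserved, two runs from two targets each covering ≥ 20% of mapped genes ⇒
fusion/translocation candidate (breakpoint placed midway between the
boundary genes, i.e. within one intergenic interval of the true junction),
≥ 3 runs ⇒ complex.

## Positional null models and the permutation test

Events are redrawn genome-wide: chromosome ∝ gene count, then a position
from one of four within-chromosome densities. `flat` is uniform;
`gene_density` is a histogram of gene midpoints (500 kb bins).
`single_adj` fits a kernel density to the observed event positions of the
same type after *reflected rescaling* — each chromosome folded at its
midpoint so relative position lives on [0, 0.5], pooling both arms — using
only chromosomes without macro-rearrangements, and applies it to every
chromosome (unfolding with a fair coin per draw). `double_adj` applies the
same fitted density separately to each side of a supplied fusion
breakpoint, each segment rescaled to its own length and selected ∝ its
gene count (the source is silent on segment weighting; gene-count
weighting is consistent with the chromosome-level rule). A `double_adj`
model with no breakpoints at all is a configuration error; chromosomes
without a listed breakpoint fall back to the whole-chromosome density,
since real analyses mix the two model kinds across chromosomes.

The kernel is Epanechnikov with bandwidth 0.15 on the [0, 0.5] support and
boundary correction by reflecting kernel mass at both edges; the result is
renormalised on a 2001-point grid and sampled by inverse CDF. Equivalence
with any particular R implementation of bounded kernels is not claimed;
the contract is normalisation (integral 1 ± 1e-6) and recovery of the
uniform height 2 within 0.15 at n = 10,000. Fits on fewer than 10 events
fall back to the flat density (logged).

The empirical P for a region and half-width x is the fraction of
replicates whose window count ≥ the observed count, with the window open
on both sides (an event exactly x bp from the region edge is not within
< x bp). No +1 correction is applied; a zero-exceedance result is reported
as 0 and interpreted as P < 1/n_perm. Replicates are generated by an exact
factorization: the number of events landing on the region's chromosome is
binomial in that chromosome's weight, and only those positions are
simulated from the chromosome's positional sampler — identical in
distribution to redrawing every event, at a fraction of the cost.

Island-set exceedance at one window size counts islands with P < α
(α = 0.05) and compares against the exact 95th percentile of
Binomial(n_islands, α), using strict exceedance. BH-FDR q-values are
computed per window size across all islands tested (statsmodels'
step-up implementation behind the module's `bh_fdr` surface). Kendall τ
(tie-corrected τ-b) and exact binomial tests delegate to scipy.

## Draw probabilities

The equal-probability containment of a focal set is the closed form
C(n−f, k−f)/C(n, k) (e.g. 18/5985 ≈ 0.003 for 3 focal chromosomes in 4
draws from 21). The length-weighted version defines draws sequentially
without replacement with selection ∝ remaining weights, and samples them
in bulk via the Gumbel-perturbed-key equivalence (rank log-weights plus
i.i.d. Gumbel noise, take the top k — exactly the same distribution); the
estimate carries its binomial standard error. Reproducing a specific
published weighted value requires the actual chromosome-length vector,
which is external data; the machinery accepts any weights file.

## TE landscape and DE overlap

A TE is attributed to a 500 kb window when its interval intersects the
±50 kb neighbourhood of a collinear syntenic gene (a gene in no event)
whose midpoint is in the window; each TE counts at most once per window.
"Moving windows" are implemented as adjacent non-overlapping tiles, which
matches reported window centres spaced one window apart. Family z-scores
use the genome-wide per-window mean and population SD; families under 1
copy/window on average, or with zero variance, are dropped. Note that with
W windows, a single extreme hotspot's own leverage on the SD caps its z
near √(W−1); the hotspot property tested is therefore "genome-wide maximum
z", not a fixed z value.

DE overlap uses a one-sided exact binomial test per event type against the
background DE proportion of genes in no event; the source reports only
"binomial test", and every reported direction is an enrichment, so the
one-sided upper tail is the natural reading. Duplication groups are one
unit each, DE if any member is DE. DE-list identifiers can be translated
through an optional ID map; re-deriving such a map by sequence search is
out of scope.

## Synthetic data: what it emulates, and what it does not

The generator emits the same GFF3/BED/TSV dialects the readers consume.
Genes are placed one per equal slot with jitter (guaranteed
non-overlapping); homolog maps are one-to-one collinear except where
events are planted. Planted LSGs keep only a sister-species hit (a
configurable fraction stringent, the rest with partial region coverage);
planted rearrangements move all outgroup hits to a non-homologous
chromosome with the far outgroup either corroborating (focal-lineage) or
contradicting (near-outgroup-lineage decoys, plantable by a rate flag);
planted duplications map a gene pair onto one shared outgroup locus in
both outgroups. Event probability per gene is multiplied by a factor ≥ 1
inside island regions; an "end-elevated" density option mixes a uniform
with a triangular density peaked at both chromosome ends (mixture weight
0.6 by default), reproducing the qualitative end-of-chromosome excess of
rearrangements and LSGs without claiming its exact form. An exact-count
mode plants a fixed number of events by weighted sampling without
replacement under the same multipliers.

TE tracks draw per-window totals from a Gaussian copula against the
planted event counts (target Kendall τ mapped to the latent correlation by
ρ = sin(πτ/2)), split counts across families multinomially, and place TEs
inside gene neighbourhoods so the anchored windowed analysis recovers the
planted counts; one window can be forced to carry a fixed fold of a named
family's mean (the hotspot). DE labels are background-rate Bernoulli with
a multiplier for duplication groups (one member flagged per DE group,
matching how the test counts units).

The generator does not simulate sequences, assembly error, annotation
error beyond the planted decoys, gene-density heterogeneity correlated
with islands, or recombination; passing tests therefore demonstrate the
correctness and calibration of the statistical machinery on data whose
generative process matches the null/alternative structure, not robustness
to every artefact of real genome comparisons.

## Validation study designs

*Type-I calibration.* 4,480 independent null cells (2 chromosomes ×
50 Mb, 40 one-megabase islands × 7 window sizes × 16 replicates), each
drawing its own 3,000-event observed set from the same flat model the
permutation test resamples, n_perm = 1,000. The empirical rejection
fraction at α = 0.05 must lie in [0.04, 0.06]. The event count and island
size are chosen so expected null window counts are ≳ 35: the empirical
tail test over a discrete count statistic is inherently conservative
(rejection = P(N ≥ k*) where k* is the first count with tail < α), and its
conservatism decays with the count resolution (analytically ≈ 0.045 for
this design). At study scales of a few hundred events per type the same
test is more conservative, never anticonservative.

*Power.* 50 events planted with a five-fold in-island probability over 20
one-megabase islands laid out as two contiguous clusters (10 per
chromosome on 2 × 70 Mb), mirroring the clustering of real differentiation
islands on chromosomes implicated in local adaptation. The island-set
exceedance must fire for ≥ 5 of the 7 window sizes. Geometry was fixed by
a closed-form/simulated power pre-analysis: with isolated islands the
per-island expected count is bounded by n/m even as the factor grows,
leaving the smallest windows powerless, whereas clustered islands share
signal across neighbouring windows at every scale.

*Oracles.* The flat-model empirical P is checked against the exact
binomial upper tail within 3 Monte-Carlo SE; the exact draw probability
against exhaustive subset enumeration for all n ≤ 12; the weighted
estimator against the closed form under equal weights at 100,000 draws;
the exceedance threshold against a direct scan of the binomial CDF; BH
q-values against hand-computed step-up vectors; Kendall τ against an
O(n²) concordant/discordant pair count.

## Problem sizes and determinism

Default test and demo genomes use 2–4 chromosomes of 8–70 Mb with
120–1,000 genes per chromosome, n_perm = 200–1,000 for scans inside the
test suite and 10,000 as the analysis default. Every stochastic step takes
an explicit seed (numpy `SeedSequence` spawning per scan cell); reruns of
the pipeline with one config are byte-identical in all result tables (the
run log carries wall-clock timestamps and is excluded from that
guarantee).

## Known limitations

- Lineage assignment is a main-text-level reconstruction; truly ambiguous
  topologies are kept and flagged rather than resolved.
- The boundary kernel is not numerically identical to any specific R
  bounded-density implementation; agreement is at the level of shape and
  normalisation.
- Homology tables built from sparse maps (few one-to-one hits per
  chromosome) make the 5% support threshold coarse; the threshold is
  configurable.
- The duplication caller conditions on rank-1 hits only; dispersed
  duplicates whose best hits straddle loci are split or missed by design.
- Empirical P-values are reported on the 1/n_perm grid with no smoothing;
  q-values inherit that granularity.
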