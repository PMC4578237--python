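# Methods

This note records the models, parameter choices, and numerical decisions
behind `nambin`, and what the synthetic-data experiments do and do not
demonstrate.

## Synthetic NAM panels

The generator emulates the structure of a maize-style NAM design: `n`
families sharing one common parent, each family an F7 RIL population
derived by single seed descent (F1 followed by six generations of selfing,
one offspring kept per generation).  Meiosis draws crossover counts from a
Poisson with mean equal to the chromosome's genetic length in Morgans and
places them uniformly in genetic coordinates — the no-interference model
consistent with the Haldane map function used downstream.  The cM↔bp
relation is uniform per chromosome by default (a piecewise relation can be
substituted by configuring chromosomes accordingly); maize-like recombination
hot/cold spots are deliberately not modelled, so physical bin sizes in
simulation are more homogeneous than in real data.

Founder haplotypes draw each site's allele from a population frequency
(default 0.5), so a site is polymorphic within a family iff the diverse
parent differs from the common parent (probability 2p(1−p)).  GBS noise is
applied per call, independently: missing with probability 0.3, a surviving
homozygote flipped with probability 0.01, a surviving heterozygote reported
as a random homozygote with probability 0.5.  The undercall and error rates
are stand-ins — the real per-call GBS rates are not published — and all
three are exposed in `SimConfig`.

Truth is kept at two resolutions.  `raw_segments` is the diplotype mosaic
with heterozygous stretches explicit; `segments` collapses residual het
stretches into the homozygous mosaic (absorbed when both flanks agree,
split at the midpoint when they disagree), which is the resolution at which
an inbred line's genome is scored and at which breakpoint recovery is
evaluated.  One master seed drives named child generators
(`SimConfig.rng("meiosis", family)`, …), so any stage is reproducible in
isolation.

## Outlier screens

Site filters use strict inequalities throughout: taxa coverage > 10 %,
MAF > 0.01, site coverage > 20 % for the contamination screen; site
coverage > 66 %, MAF > 0.25 for the heterozygosity screen, whose line flag
fires at het ratio strictly above 10 %.

The contamination call is automatic rather than a by-eye reading of the
NJ trees: per chromosome, a line votes "contaminant" when some other
family's diverse parent is closer in IBS than its own family's diverse
parent by more than a margin (default 0.05), and the flag requires a strict
majority of chromosomes.  Two design points matter.  First, the shared
common parent is excluded from the comparison — it is a parent of every
family, so proximity to it carries no family signal, and including it
halves the discrimination margin.  Second, the margin exists because a RIL
whose realized mosaic is almost entirely common-parent is nearly equidistant
from all diverse parents; without the margin such lines are flagged on
noise.  A genuine cross-family copy shows an IBS separation near 0.25, so
the margin costs almost no sensitivity; lines that are nearly pure common
parent remain undetectable in principle (they carry no family-discriminating
sequence).  IBS treats het-vs-homozygote as half a mismatch.  NJ trees
(scikit-bio) are exported for manual review but do not drive the flag.

## Parental inference

Within a family the per-site assignment (which observed allele came from the
common parent) minimizes the number of implied parental-origin switches
summed over adjacent site pairs and RILs observed at both sites —
heterozygous calls are ignored, anticipating the HMM's het handling.  The
objective decomposes along the physical site order, so a two-state dynamic
program finds the exact minimum; ties prefer no change from the previous
site.  The global sign is unidentifiable from RIL data and is anchored to
known common-parent calls when supplied, else to the majority allele of the
first retained site.

Sites are screened by resampling: RILs are bootstrapped and the DP re-run on
overlapping windows of 15 sites (stride 7); q_j is the fraction of
sign-aligned windows agreeing with the full-data assignment at site j, and
sites with q_j < 0.9 are dropped (defaults: 200 resamples).  Published
Bayesian refinements of this step do not document their parameterization,
so this resampling-agreement score is the package's own, fully specified
criterion.  One screen is not enough: a junk site (for example a
family-monomorphic SNP whose apparent polymorphism is pure calling error)
contributes weak, noisy DP edges that can flip the chain's global sign for a
long stretch, corrupting the reference the screen compares against.
`infer_and_refine` therefore iterates screen → re-infer (two rounds by
default); window-level sign alignment makes q_j insensitive to which stretch
a site landed in, so the junk sites are removed regardless, and the re-run
chain is clean.

Residual-heterozygosity tracts get special treatment before decoding.  In an
F7 line a het tract is genotyped as a mixture of H calls and *random*
homozygote calls (undercalled hets); the random homozygotes form short
same-allele runs that can pass the block-mask rule and appear as false
double recombinants.  Since allele-call errors convert one homozygote into
the other and never create H calls, H density is a specific marker of true
het tracts: any run of 7 consecutive observed calls containing ≥ 2 H calls
is masked wholesale (`het_tract_mask`).  Flanking blocks then either rejoin
(no breakpoint) or meet at the tract midpoint, matching the collapsed-truth
convention.

## HMM decoding

Two states (common/diverse origin).  Transition probability between sites
separated by d Morgans is ½(1 − e^(−2ρd)) with ρ = 2.0 per Morgan — the
junction density of a selfed RIL at fixation — capped at ½.  Emission is
symmetric error ε (default 0.01); missing sites emit nothing.  Decoding is
posterior (forward–backward with per-site scaling), not Viterbi, so that a
confidence floor exists: sites with maximum posterior below p_min = 0.99 are
reported missing, which feeds the transition-region missing rule in the bin
builder.  The implementation is verified against exhaustive path-sum
enumeration to 1e−10 on instances up to 12 sites, and decoding is exactly
reversal-symmetric.

## Bin construction

Blocks are maximal same-origin runs over confidently decoded sites; a
breakpoint is placed at the midpoint between the last site of one block and
the first site of the next (the transition's location within the gap is
unidentifiable; midpoint is the minimax choice).  The mask rule is read as a
conjunction — a block is masked iff its span is under 1,500 kb *and* it has
fewer than five SNPs — with a switch to disjunctive masking available; the
conjunction is what removes single-site error blocks while sparing genuine
short double crossovers with dense support.  Flanking blocks of equal origin
re-merge across a masked gap; a masked gap between differing origins stays
missing and its genotype is imputed later.

Bins partition each chromosome at the union of all RILs' breakpoints,
extended to the chromosome ends; adjacent intervals with identical genotype
columns (missing-equal) merge.  The resulting map is lossless in the
following sense, enforced by test: expanding bins back to SNP coordinates
reproduces every RIL's post-mask decoded genotype at every site where that
genotype is defined, and is missing wherever no surviving block covered the
site.  Bins under 5 kb (strict) merge into the next bin (backward at a
chromosome end); on a genotype conflict the larger constituent wins and
disagreements become missing.  Remaining missing entries are imputed from
agreeing flanks, or by the same two-state HMM over the RIL's bin-midpoint
sequence when the flanks disagree; RILs missing an entire chromosome are
reported rather than guessed.

Breakpoint recovery is scored against the collapsed truth with the
"within one bin boundary" rule: an inferred breakpoint is a bin boundary,
and a true breakpoint inside bin j counts as recovered when some inferred
boundary of the same RIL touches bin j or an adjacent bin.

## Genetic maps

Observed discordance R between bins of selfed RILs relates to the meiotic
recombination fraction by the Haldane–Waddington equation R = 2r/(1+2r),
inverted as r = R/(2−2R) and mapped to distance by d = −50·ln(1−2r) cM.
Family maps accumulate adjacent-bin distances in physical order; adjacent
bins sharing fewer than 30 informative RILs are an error at the operation
level, and unlinked neighbours contribute a logged 50 cM cap.

The composite map does not re-estimate marker order by maximum likelihood
(the route commercial mapping software takes): marker physical positions
are known and already anchor the analysis to the reference genome, so order
is physical and likelihood is used only for distances.  Markers polymorphic in strictly more
than the configured number of families are encoded 1 (common-parent
allele) / 0 / NA across all RILs — family-monomorphic markers are missing
for that family — binned like a single family, and tested for segregation
distortion (1-df Pearson χ² against 1:1, P < 0.05, no continuity
correction).  Non-distorted markers form the framework; because markers can
be informative in disjoint family subsets, each framework marker takes its
distance from the nearest preceding marker with ≥ 30 jointly informative
RILs (lookback 50).  Distorted markers are inserted at their physical rank
with distance from their left framework neighbour and excluded when their
genetic position overshoots the flanking framework interval by more than
2 cM — the operationalization of "inconsistent physical position" as a
genetic-vs-physical order conflict.  Linkage groups are single-linkage
clusters at pairwise linkage LOD ≥ 10; a group spanning two chromosomes is
an error signalling upstream contamination.

## Phenotypes

Variance components come from method-of-moments on the line /
line-by-environment / within-cell mean squares (negative estimates truncated
at zero); environments are fixed and lines random.  Line-mean heritability
is H² = σ²g/(σ²g + σ²ge/E + σ²e/(ER)).  BLUPs shrink environment-adjusted
line means by σ²g/(σ²g + σ²ge/E_i + σ²e/n_i) with per-line effective
replication; a Henderson mixed-model-equation solver provides the general
cross-check and matches the closed form to 1e−8 on balanced data.
Unreplicated or single-environment designs return the confounded residual
with a warning rather than pretending to separate σ²ge from σ²e.

## Joint linkage

Marker genotypes are coded 0 (common-parent homozygote) / 2 (diverse), so a
family-nested slope is directly the additive allele effect (half the
difference between homozygous classes).  Missing cells are mean-imputed
within family; a family where the marker does not segregate contributes no
slope.  Family main effects are always in the model; in combined two-panel
designs the reference term distinguishing the two common parents is
constant within family and is absorbed by the family effects (it is listed
among the forced terms for bookkeeping).

The entry threshold is the empirical α-quantile (inverted-CDF order
statistic) of the per-permutation minimum P over markers, with trait values
permuted within family — within-family shuffling is chosen because it
preserves the forced family structure under the null.
Stepwise selection is forward (smallest P below the threshold) with a
backward pass at P_exit = P_enter (a single threshold governs entry and
exit) iterated to a fixed point; collinear candidates are rejected and
logged.  Each selected QTL is profiled by swapping its term for each of up
to four flanking markers per side, LOD = (n/2)·log₁₀(RSS_without/RSS_with)
with all other QTL retained as covariates.  The 2-LOD support interval
extends from the peak to, and including, the first marker below peak−2 on
each side, flagged truncated when the window edge is reached first.  Allele
effects are t-tested against the common-parent reference (the model
baseline) with uncorrected P-values.

The permutation scan is exact but fast: with only family effects forced,
the family-centered nested columns of different markers are orthogonal, so
each marker's model sum of squares is Σ_f (x_fᵀy_f)²/(x_fᵀx_f) and all
markers and permutations are scanned with a handful of matrix products.
The general (covariate-bearing) path uses QR residualization and is tested
to agree with the fast path.

## Experiment sizes

The verification experiments use: a 2-family × 200-RIL panel on one
200 cM / 200 Mb chromosome with ~5,000 polymorphic SNPs per family (missing
0.3, error 0.01) for breakpoint, assignment, losslessness and map-length
checks; 10,000 fair-coin markers at n = 200 for distortion-test calibration
(the exact null size of the Pearson test at n = 200 is 5.60 %, so observed
rates sit near 5.6 %, inside 5 % ± 0.7 %); 5 families × 200 RILs × 500 bins
(five 150 cM chromosomes) with five additive QTL of 0.25–1.0 residual SD
for joint-linkage power, 1,500 null replicates for selection calibration,
and 20 replicates of the two-panel merge (effects 0.2–0.5 SD) for the
combined-panel power/resolution contrast.  These sizes give Monte-Carlo
standard errors comfortably inside the asserted bounds; the acceptance
script uses moderately smaller replicate counts and reports every metric
with the problem size it was measured on.

## Known limitations

Uniform cM↔bp relation and no crossover interference; no selection during
SSD; no depth-explicit read sampling (noise is per-call, not per-read); the
contamination screen cannot detect lines nearly identical to the common
parent; composite-map distances chain across family-disjoint markers via
anchor lookback and inherit upward noise bias at small RIL counts; exact
REML is not implemented (method-of-moments components are used throughout).
Passing tests demonstrate correctness under the simulated design, not
robustness to real-data features such as segregation-distorted regions,
structural variation, or heterogeneous marker densities.
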