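# Methods

This note records the models and procedures the package implements, the
defaults that matter, and the choices made where the design was genuinely
open.

## Data model

The unit of analysis is an expression trace: one gene's FPKM values over
an ordered developmental time course in one tissue, with a per-timepoint
uncertainty column interpreted as a standard deviation in FPKM units
(`noise_scale="sd"`; the switch `"variance"` treats the column as a
variance instead, for pipelines whose quantifier reports one).  The
default time design is the sampled series days 22, 43, 64, 65, 67, 69, 72
after sowing, with a cold (vernalization) period between days 22 and 64;
nothing in the code depends on these particular values.

A gene is *expressed* in a tissue when its maximum FPKM over the series
is ≥ 2.0 (inclusive — a trace peaking at exactly 2.0 counts).  Filtering
precedes normalization; z-normalization uses the population (1/n)
variance so a normalized trace has mean 0 and variance 1 as a vector,
and rescales the uncertainty column by the same factor.  Constant traces
cannot be normalized and are excluded with a log record.

## Retention statistics

Best-hit assignment keeps, per query, the highest-bitscore hit with
e-value ≤ 10⁻⁵⁰, breaking ties by lower e-value then lexicographic
subject id, so results are reproducible to the byte.  The copy-number
distribution conditions on retention: its denominator is the number of
reference genes with at least one assigned copy.  Subset-vs-background
proportion comparisons use the two-sample equality-of-proportions test
with Yates continuity correction capped at |O − E| (the R `prop.test`
convention, so identical proportions give statistic 0 and p = 1); no
multiple-testing correction is applied across copy-number categories by
default, with a Bonferroni option left to the caller.  The
tissue-specificity χ² (df = 2) compares the subset's (apex-only,
leaf-only, both) split against its complement by default; `compare="all"`
compares against the whole gene set instead.  On the published 2×3
counts the two constructions give p = 2.7×10⁻⁸ and 5.7×10⁻⁸
respectively.  Reciprocal-best-hit pair calling applies best-hit
assignment in both directions and intersects.

## Pre-clustering and the variance-explained ratio

The ratio r(H) = BSS/TSS of cluster means over trace vectors drives two
decisions: the complete-linkage pre-clustering is cut at the smallest H
with r(H) ≥ 0.98 (ties resolved to the smaller H; r is non-decreasing
under refinement, so the scan from H = 1 upward terminates at the
minimal adequate cut), and the self-organizing map is sized at the
smallest node count whose trained-map node assignment reaches r ≥ 0.85.

## Co-expression network

Unsigned soft-threshold adjacency |cor|^β with β = 30, the standard
topological overlap TOM_ij = (Σ_u a_iu a_uj + a_ij)/(min(k_i,k_j) + 1 −
a_ij), average-linkage clustering of 1 − TOM with a static cut at the
0.99 quantile of merge heights, minimum module size 30, module eigengene
= first principal component of member profiles (sign-oriented to
positive mean member correlation), and iterative merging of the most
correlated eigengene pair while the correlation is ≥ 0.75.  Signedness,
cut rule and merge threshold are not pinned down by the configuration
being reproduced and are exposed as arguments.  Genes inherit the module
of their pre-cluster mean vector: the network clusters clusters.

## Ensemble SOM

Training is batch Kohonen by default: per epoch every codebook vector is
recomputed as the Gaussian-neighbourhood-weighted mean of the data, with
the radius decaying linearly from half the larger grid dimension to 1
over 30 epochs, initialization seeded by sampling data rows.  Batch mode
is deterministic given the seed and fast enough to train hundreds of
maps; classic online training (learning rate 0.05 → 0.01, 100 × n
steps) is provided for comparison.  The grid is rectangular and
non-toroidal; its rows/cols rectangle is the integer factorization of S
closest (in log ratio) to λ₁/λ₂ of the data's first two principal
components.  The upward search over S skips sizes whose only
factorizations distort that aspect ratio by more than 2× (large primes
would force degenerate 1-row maps), widens its stride for large S
(1/2/4/8 past 16/64/128), and caps at max(16, 2n/3) nodes; if the 0.85
target is unreachable the largest well-shaped size is used with a
warning.  All M ensemble maps share the one grid size chosen from the
data.

Resampling perturbs the *unnormalized* trace (Gaussian, per-timepoint
spread from the uncertainty column), re-normalizes each draw, and
assigns it to the nearest codebook vector; a draw that comes out
constant is re-drawn.  Counts over B draws give the empirical node
distribution; co-mapping and self-mapping probabilities are the
inner-product statistics Σ n₁n₂/B² and Σ n²/B².  Ensemble defaults are
B = 500 and M = 100; the shipped analyses use scaled-down B = 200,
M = 20, which the recovery experiments below show is already stable.
The SD over maps uses the n−1 denominator, and M ≥ 2 is required.

The threshold θ is the per-map Gaussian-KDE (Silverman bandwidth)
density argmax of self-mapping probabilities restricted to [0, 0.5],
averaged over maps.  The restriction matters: the self-probability
distribution is bimodal with modes near 1 (robustly mapping genes) and
near 1/S_eff (genes whose uncertainty spreads them over many nodes), and
the global maximum would pick the wrong mode.  A map contributes only
when the window holds a genuine subpopulation — at least 10 genes *and*
5% of the cohort; with low-noise data a handful of node-boundary
stragglers would otherwise fabricate a spurious mode near 0.45.  If no
map qualifies, θ falls back to a floor of 0.05, consistent with the
empirical low mode of uncertainty-dominated data.

The clustering coefficient ½(1 + erf((μ_p − θ)/(σ_p√2))) is monotone in
μ_p and approaches a step at θ as σ_p → 0; at σ_p = 0 exactly the limit
convention 1/0/0.5 (above/below/at θ) applies.  Binarization keeps
coefficients strictly above 0.5; a gene whose binary self-coefficient is
0 does not map robustly and is removed before module formation.
Regulatory modules are the maximal cliques of the binary graph,
enumerated deterministically and reported sorted by size then member
ids; a gene may sit in several cliques.  Pattern classification is
exhaustive and mutually exclusive: one module holding all robust copies
→ redundant; no overlapping modules → unique (all singletons) or
distinct (otherwise); overlapping modules → gradated when every module
overlaps some other, mixed when at least one module is disjoint from all
others.  Families with fewer than two robust copies are reported
unclassifiable.

## Synthetic data

The generator emits what the analysis assumes: families of traces built
from mean-0/SD-1 template shapes at a configurable base level (default
10 FPKM, template amplitude base/3 so traces stay non-negative) plus
i.i.d. Gaussian observation noise whose SD is also written out as the
uncertainty column.  Template construction per pattern: redundant — one
shared shape; unique — exactly decorrelated shapes (QR on centred random
vectors; at most n_timepoints − 1 copies); distinct — two decorrelated
groups; gradated — shapes on a geodesic arc with adjacent correlation
≈ 0.95 (18° angular gaps for a 4-chain, 25° for a 3-chain) and endpoint
correlation ≈ 0.59, the generator's operationalization of a gradient of
regulatory responses; mixed — such a chain plus a group on a third
decorrelated shape (needs ≥ 4 copies: an overlapping chain takes 3 and
the disjoint module at least 1; the default mixed family has 6).

What the generator does *not* emulate: read-level sampling noise,
between-sample normalization artefacts, correlated uncertainties across
timepoints, indels in sequence fixtures, and any biology of the cold
response.  Passing recovery tests therefore demonstrate that the method
identifies the intended module topologies under its own observation
model, not performance on real RNA-seq.

Copy-number tables draw per-reference copy counts from a stated
distribution; enriched-subset genes (deterministic count = round(fraction
× n)) gain a fixed copy-count shift, clipped at the maximum.  Hit tables
make every true pair the top hit in both directions below the e-value
threshold; decoys alternate between one-directional hits and reciprocal
hits above the threshold, so the reciprocal filter excludes exactly the
decoys.  Sequence pairs substitute sites independently at 1 −
identity/100, always to a different base, with no indels.

## Conservation scanning

Needleman–Wunsch global alignment with affine gaps (match +1, mismatch
−1, open 5, extend 1 — conventional scores standing in for the original
aligner, whose output is not bit-reproduced), sliding identity with
window 100 and step 1 over alignment columns, gap columns counted as
mismatches, N matching nothing.  Regions are maximal runs of windows ≥
70% identity spanning first window start to last window end; because a
region extends a window past its last qualifying start, runs separated
by a dip shorter than one window overlap in span and are merged, keeping
the output sorted and non-overlapping.  Coordinates are reported in
alignment space and projected to each sequence's own 0-based half-open
coordinates.

## Problem sizes and numerical conventions

The recovery experiments run 250 families (50 per pattern, ~1,200
traces), noise SD 0.1 FPKM, M = 20 maps, B = 200 draws — about half a
minute on one CPU; measured five-way accuracy is ≈ 94% with redundant
and unique recall 100%, and zero-noise redundant/unique recovery is
exact.  Chain-family (gradated, mixed) recovery is intrinsically
resolution-limited: their adjacent-copy co-mapping depends on the node
cell size the 0.85 variance target induces, which is why those two
patterns dominate the residual confusions.  Cohort percentages are
rounded half away from zero.  Symmetric matrices are enforced
symmetric to ≤ 1e-12 after construction; hierarchical clustering,
clique enumeration and all tie-breaks are deterministic, so repeated
runs with one configuration are byte-identical.

## Known limitations

Single trace per gene-tissue (replicate pools are assumed merged
upstream); no library-size normalization; no significance testing of
pattern calls; the static tree cut is cruder than dynamic hybrid
cutting; maximal-clique enumeration is exponential in the worst case and
intended for family-sized gene sets, not whole transcriptomes.
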