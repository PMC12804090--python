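# Methods

This note documents the models implemented in `nucleome`, the defaults
that matter, what the synthetic-data generators do and do not emulate,
and the numerical choices made where the procedures left room.

## Synthetic study design

All analyses are exercised on generated data with planted, recorded
truth. The generators are statistical emulators, not physics:

**Contact maps.** Counts are a single multinomial draw of `depth` reads
over the upper triangle, with intensity
λ(i,j) ∝ s^(−α) · c(i,j) · t(i,j) · l(i,j): a power-law distance decay
(α = 1 by default), a same-compartment multiplier (`compartment_strength`),
a within-TAD multiplier (`tad_strength`) and per-pixel loop factors.
Trans intensity is a constant, 1% of the shortest-range cis intensity by
default. The study conditions are 500 bins of 200 kb at depth 10⁶, with
compartment blocks of 25 bins, TADs of 20 bins and loop factors of 3 —
deep enough that recovery is limited by method calibration rather than
shot noise, small enough that everything runs in seconds. What this does
not emulate: reproducible assay-specific biases (the balancing step sees
only stochastic marginal variation), sub-TAD hierarchy, and
compartment–TAD coupling.

**Structure populations.** Each chromosome copy is a random walk with a
300-nm step confined to the nuclear envelope (ellipsoid semiaxes
(a,b,c); spheres as a = b = c; confinement by radial clamping at
r = 0.97). A radial bias pushes B-labelled beads outward and A-labelled
beads inward each step; bias 0 removes the A/B difference entirely,
which the tests use as a null. Diploidy is two independent copies per
chromosome with an explicit bead–allele map. Speckle and nucleolus
points are planted uniformly within r < 0.7 and r < 0.4. This
reproduces the radial/compartment statistics the structural features
consume; it does not model chain stiffness, excluded volume, or
data-driven ensemble optimization, so absolute feature magnitudes are
not comparable to real nuclei — only the planted orderings are.

**GAM sampling.** A nuclear profile is a random planar slab: orientation
uniform on the sphere, offset uniform over the envelope's extent along
that orientation, fixed thickness (1,500 nm in the study conditions —
thick relative to real cryosections because the toy genome has only two
alleles per window, so per-profile detection must be non-negligible). A
sequencing sample is the union of a configurable number of profiles.
Windows are detected when any bead falls inside the slab; there is no
sequencing noise on top, so window calling from raw coverage is
exercised on separately constructed coverage vectors rather than on the
slab output.

**SPIN observations.** Hidden state labels are planted in contiguous
runs (20 bins by default, 5 states over 3,000 25-kb bins); observations
are state-conditional Gaussians with means on a circle in the first two
track dimensions such that the closest pair of state means is
`separation_sigma` × sd apart (2σ in the study conditions). At 2σ the
per-bin Bayes accuracy is only ≈ 70%, so recovery above 90% must come
from the Markov random field exploiting the run structure — which is
the property the acceptance test checks.

**Loops with anchor states.** Each planted cluster owns a disjoint pair
of chromatin states; anchors are placed on non-overlapping 10-kb slots
so that every anchor carries exactly its planted signature. Real
ChromHMM segmentations bleed across anchors and share states between
loop classes; the clean version tests the pipeline's mechanics
(featurization → PCA → k-NN → consensus Leiden), not its robustness to
annotation noise.

**Expression tables.** Housekeeping genes are expressed in every tissue
at 4× the level of tissue-specific genes (expressed in 3 random
tissues); lognormal within-gene variation, optional additive noise.
The elevated housekeeping level keeps their ranks clear of the
expressed/silent boundary after quantile normalization, where the
mean-of-sorted-rows substitution mixes expressed and zero values.

## Normalization and statistics

**Iterative correction.** Damped fixed-point iteration
w ← w / √(m/m̄) on the marginals m, bad bins masked first (< 2%
non-zero coverage — the same rule the compartment pipeline uses before
eigendecomposition). Convergence is declared when the marginal
coefficient of variation falls below `tol` (default 10⁻⁶); on the
500-bin study maps this takes well under a second.

**NPMI.** Natural logarithms throughout (the base cancels between
numerator and normalizer). Windows detected in every sample make the
normalizer degenerate (−ln 1 = 0) and are excluded, as are
never-co-detected pairs (reported NaN).

**SCC.** Both maps are smoothed with a (2h+1)-square mean filter
(h = 1 by default), correlations are computed per distance stratum and
combined with weights N·sd·sd. Strata with zero variance in either map
are skipped. The default distance cap mirrors common practice of
restricting to ≤ 5 Mb at 50-kb bins; the study maps use 100 bins.

**Saddle and strength.** Bins are ranked by the profile and assigned to
rank-based quantile bins (equal occupancy; ties broken by bin order).
Value-based binning collapses for discrete profiles such as planted ±1
labels, which the calibration tests use. Corner strengths are
arithmetic means of the extreme 20% × 20% corners; on an all-ones
saddle the printed ratio AA/(AB+BA) is 0.5, which is therefore the null
level for an unstructured map.

**Insulation.** The diamond at bin i covers rows [i−w, i−1] × columns
[i, i+w−1] — the contacts crossing the bin's left edge — so a planted
domain boundary at bin b scores its minimum exactly at b. Diagonals
closer than `ignore_diags` (2) are excluded. Boundaries are local
minima with topographic prominence ≥ 0.1 log₂ units by default; the
strong/weak split uses the mean insulation of all supplied tracks, or
of the single track when only one is given (logged interpretation).

**Loop union.** Pairwise overlap under the printed rule, evaluating the
0.2|i−j| span term with the finer loop of each pair, then transitive
closure (union–find); each cluster is represented by its
finest-resolution member, ties broken by a deterministic sort. The
oracle tests compare against an independent connected-components
implementation.

**APA.** Windows are individually distance-normalized using the
chromosome-wide per-diagonal expected values; windows whose mean falls
outside the 1st–99th percentile of window means are discarded; loops
within half_size+1 bins of the diagonal or the matrix edge are skipped
and counted.

**Anchor featurization.** State proportions are bp-fractions within the
anchor interval. Standardization uses per-state statistics pooled over
both anchors; strictly column-wise z-scoring would make the output
depend on the input order of the two anchors, breaking the invariance
that anchor swapping must not change the post-swap matrix. Ties between
the two halves' maxima are broken lexicographically so the
representation is canonical.

**Consensus clustering.** PCA, then one k-NN graph per k in the grid,
Leiden (RBConfiguration, resolution 0.5, fixed seed) on each, and a
final Leiden run on the graph of pairs co-assigned in ≥ 50% of the
partitions, weighted by co-assignment frequency. The k-grid is
truncated below the sample count with a warning. A 2-D embedding for
plots is deliberately kept out of the label path.

**Shuffle nulls.** Control loops preserve each loop's chromosome,
anchor widths and anchor distance; control anchors preserve size and
chromosome; both avoid declared gaps by rejection sampling from a
named, seeded generator. Fold = observed / mean(controls); a zero
control mean is reported as infinite with a flag.

**IZ resampling test.** Null interval sets match the observed count,
sizes (resampled with replacement) and A/B composition (labels at the
IZ midpoints; placement uniform within the labelled mappable space,
length-weighted across segments). p = (1 + #{null ≥ observed})/(1 + N)
with N = 10⁴ by default — the production-scale resample count is
replaced by a desk-scale default with the +1 correction. Because the
observed statistic is a proportion over a finite IZ set, ties make the
p-values very slightly conservative; calibration uses 300 IZs, where
the tie mass is negligible (KS uniformity comfortably holds).

## The spatial-state HMRF

States are shared across cell types; graphs and observations are
per-cell-type, with no cross-cell-type edges. Emissions are
diagonal-covariance Gaussians pooled over cell types (variance floored
at 10⁻⁶). The pairwise factor is a transition-style compatibility:
row-normalized conditional frequencies Q(b|a) of neighbour state pairs
with Laplace smoothing (α = 0.1), entering the objective as the
symmetrized ½(log Q + log Qᵀ). A joint-pmf normalization was rejected
because its pairwise term carries an entropy cost that grows as
n_edges·log K, which systematically biases model selection toward too
few states; the conditional form is K-neutral on coherent
segmentations.

Fitting is hard-EM. The E-step first solves each chain of
consecutive-bin edges exactly by dynamic programming (long-range edges
contribute unary terms at their partners' current states; the proposal
is accepted only if the full objective does not decrease), then runs
graph-coloured ICM sweeps — colour classes share no edge, so
simultaneous updates within a class are exact coordinate ascent. The
M-step (Gaussian moments; smoothed conditional Q) exactly maximizes the
Laplace-penalized complete-data objective, which is therefore
non-decreasing at every iteration; the fit history records it and tests
assert it. Pure single-site ICM was measured to stall in locally
consistent but wrong segments (≈ 87% label accuracy on the study
conditions with oracle parameters, versus ≈ 98% for the exact chain
decode), which motivated the DP step. Initialization is seeded k-means
on the pooled observations; `n_restarts` fits with derived seeds and
keeps the best objective. Model selection reports k-means WCSS (elbow)
and AIC/BIC with p = 2Kd + K² parameters against the HMRF objective.

The partition function Z of the joint probability is never computed:
state assignment is an argmax, and the reported objective is the
complete-data pseudo-likelihood, suitable for comparing fits of the
same data, not across datasets.

## Structural features

Formulas follow the population convention: per structure, the two
alleles are averaged (the ½Σ over the allele pair), then structures.
RAD uses the ellipsoid-normalized radius r² = (x/a)² + (y/b)² + (z/c)².
Cell-to-cell variability is reported as δf = log₂(σ_I / mean-σ on the
chromosome) so that positive values mean above-chromosome variability —
the plain ratio cannot be negative, so the log form is what makes the
"δf > 0 (< 0)" reading literally true. transAB caps infinite A/B ratios
at the largest finite pooled ratio before medians and the genome-wide
min–max rescale. ICP, SpD/NuD and SAF/NAF exclude (structure, bead)
events with no contacts or no predicted body from that region's
average, and the counts of exclusions are recoverable from the inputs;
the alternative of imputing a maximal distance is not used. Bead radius
matters only for envelope placement; all feature distances use centre
coordinates. The lamina association threshold of 0.2 is in normalized
radial units (1 − r ≤ 0.2). Nuclear bodies are predicted per structure
by Markov clustering (expansion 2, inflation 2, pruning 10⁻⁵) of the
graph of body-associated beads within the interaction cutoff (defaults
mirror the association thresholds: 500 nm speckles, 1,000 nm nucleoli);
partitions of more than three regions become bodies at their geometric
centres, and on disconnected graphs MCL provably reduces to connected
components, which the tests assert.

## Problem sizes

The study conditions used throughout tests and the acceptance script:
500-bin maps at depth 10⁶ for compartments/boundaries/APA; 75-bin
diploid populations of 60–80 structures for GAM and structural
features; 2,000 loops in 4 clusters for consensus clustering; 3,000
bins × 2 cell types for the HMRF; 10³ shuffle controls; 2,000 resamples
× 200–500 repetitions for the IZ calibration. These sizes make every
stage's calibration measurable with comfortable margins while the whole
suite runs in a few minutes on one CPU.

## Known limitations

- The generators plant exactly the structure the analyses look for;
  passing tests demonstrate correct implementation and calibration, not
  robustness to the confounders of real data (copy-number variation,
  mappability structure, assay-specific ligation biases, annotation
  noise).
- Balancing assumes a single genome-wide weight vector; no per-chromosome
  or trans-specific balancing.
- The HMRF's trans edges are off by default; the significance procedure
  for trans contacts is dataset-specific and out of scope.
- `expression_breadth` quantile normalization interpolates mean sorted
  values at tied average ranks, which differs at ties from
  implementations that assign tie groups the mean of their occupied rank
  positions' values; both reduce to the same thing on tie-free data.
- Dense matrices throughout: the intended scale is 10²–10⁴ bins.
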