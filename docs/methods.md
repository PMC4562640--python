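# Methods

`phycosignal` implements a comparative-phylogenetics pipeline for
competitive traits of freshwater green algae: estimating the traits from
plate-reader growth experiments, then asking whether the traits carry
phylogenetic signal and which model of continuous trait evolution explains
them best. This note records the models, the numerical choices, and what
the synthetic-data tests do and do not demonstrate.

## Growth kinetics and R*

Each well's fluorescence series F(t) is treated as exponential growth,
F(t) = F₀·e^{rt}, and r is estimated by ordinary least squares of ln RFU on
day. Cultures often become density-limited late in a 14-day experiment, so
readings are eliminated from the end of the series, one at a time, until
the R² of the exponential fit stops improving (never below `min_points`,
default 4). Stopping at the first non-improvement removes the plateau while
refusing to chase short windows that happen to align with noise; a global
search for the maximal R² over all truncations is markedly noisier for
slow-growing wells (log-scale rate sd inflated several-fold in simulation)
because R² rewards any short segment with accidentally collinear noise.
Series whose final fit gives r ≤ 0 are excluded from downstream fits, as a
culture that never grew carries no information about the growth–resource
relationship beyond its failure.

R² is computed on the log scale (the scale of the fit), and replicate
wells contribute separate (R, r) points to the response fit rather than
being averaged.

The growth–resource relationship is the Monod form

μ(R) = μ_max·R / (R + μ_max/α) − D,

parameterised by the initial slope α (growth per resource unit at R → 0)
and the maximal net rate μ_max (day⁻¹); D is the dilution rate imposed by
media exchange, fixed at 0.05 day⁻¹. For light, a three-parameter
hump-shaped alternative with an optimum R_opt is also fitted (growth
declines above the optimum — photoinhibition), and AIC decides between the
two forms; the Gaussian-SSE AIC is n·ln(SSE/n) + 2(k+1), counting the error
variance as a parameter, with exact ties resolved toward the simpler Monod
form. Nonlinear least squares uses multi-start initialisation (μ_max⁰ =
max r + D; α⁰ = slope between the two lowest nonzero-R points; both scaled
by {0.5, 1, 2}), a cheap screen of every start followed by a tight polish
of the best, and an upper bound of 100× the largest treatment on R_opt —
an optimum beyond the observed range is not identifiable and the bounded
fit degrades gracefully toward the Monod shape.

The minimum resource requirement R* solves μ(R) = 0: in closed form
R* = D·μ_max / (α·(μ_max − D)) for the Monod branch, by bracketed Brent
root-finding on (0, R_opt] for the optimum branch. When μ_max ≤ D the
species cannot break even at any resource level and R* is reported
unattainable; D = 0 gives R* = 0 exactly.

## Tree machinery

Trees are rooted phylograms with branch lengths; nothing assumes
ultrametricity. Newick I/O is delegated to dendropy. The Brownian-motion
covariance C has C[i,i] = root-to-tip depth and C[i,j] = depth of the most
recent common ancestor, and the patristic distance matrix follows from the
identity d[i,j] = C[i,i] + C[j,j] − 2·C[i,j]. Pruning to the species with
data for a trait suppresses degree-2 nodes with branch lengths summed, so
pairwise distances are preserved exactly.

Three covariance transforms define the shape models:

* λ multiplies the off-diagonal (shared-history) entries; λ = 0 is a star
  phylogeny, λ = 1 Brownian motion.
* δ raises shared path lengths to a power after normalising by the tree
  height T = max C[i,i] and rescales by T, so the transform is well defined
  on non-ultrametric trees and preserves height. δ > 1 concentrates trait
  change near the tips, δ < 1 near the root.
* The Ornstein-Uhlenbeck transform uses the fixed-root, non-ultrametric-safe
  form c′[i,j] = (1/2α)·e^{−α·d[i,j]}·(1 − e^{−2α·c[i,j]}), with the BM
  limit c′ = c as α → 0. The stationary OU covariance is deliberately not
  used: it presumes all tips are at equal depth.

## Signal statistics

* **Blomberg's K** uses the phylogenetically corrected mean
  â = (1ᵀC⁻¹1)⁻¹1ᵀC⁻¹x and the ratio of the observed to the
  phylogenetically expected mean squared error, normalised so K = 1 under
  BM. Significance comes from 999 tip-shuffling randomisations, one-tailed
  for signal, with the add-one rule p = (1 + #{K* ≥ K}) / (n_rand + 1).
* **Pagel's λ** is estimated by profile maximum likelihood over λ ∈ [0, 1]
  (mean and rate profiled analytically by GLS; 51-point grid scan plus
  bounded refinement), and tested by a likelihood-ratio test against λ = 0
  on the upper χ²₁ tail, p = 1 when λ̂ = 0.
* **Moran's I** uses proximity weights w[i,j] = 1/PD[i,j] — the package
  names only a library, so the weighting is an explicit design choice here,
  recorded in run metadata and pluggable — with the same one-tailed
  randomisation test. Its randomisation expectation is −1/(n − 1).
* **Mantel tests** compare patristic distances to single-trait Euclidean
  distances with the raw cross-product statistic z = Σ_{i<j} m1·m2 and
  simultaneous row/column permutations of one matrix, one-tailed, 999
  permutations by default. Size-like traits (biovolume analogues) are
  log10-transformed first; the transform map is per-trait configuration.

All three statistics are invariant to positive affine transforms of the
trait, which the suite verifies by property test.

## Trait-evolution model fits and selection

Five Gaussian models are fitted per trait: BM (k = 2: σ², root state z0),
WN (k = 2: iid normal, no tree), and the three shape models (k = 3), each
with σ² and z0 profiled analytically at every shape value so the fit is a
one-dimensional search. The search is deterministic — a 50-point grid
(linear for λ, geometric for δ, 0 plus a geometric sweep for OU α) followed
by bounded scalar refinement between the best point's grid neighbours — so
fits are bit-reproducible without seeds. Bounds: α ∈ [0, 1000],
δ ∈ (0, 10], λ ∈ [0, 1]; δ's range deliberately extends far above 1 because
tip-concentrated evolution on real phylograms produces estimates well
above 3.

Two numerical conventions matter:

* **Plateau rule.** The shape likelihood can be flat to numerical
  resolution near a bound (an OU pull strong enough to erase all
  phylogenetic structure makes every large α equivalent). When the
  likelihood at a bound is within 10⁻⁴ of the interior maximum, the bound
  is reported and flagged `at_bound`; otherwise a deterministic optimiser
  would return an arbitrary point on the plateau. θ for OU is tied to the
  profiled root state (single-optimum model).
* **OU nests WN.** At the α bound the OU covariance is proportional to the
  identity, so OU can always reach the WN likelihood with one extra
  parameter. On white-noise data, ML overfit therefore hands OU the best
  AIC in roughly the χ²₁ tail fraction P(2Δℓ > 2) ≈ 8–16% of replicates.
  This is a structural property of the model set, not an estimation error,
  and it caps how often white-noise data can be labelled "WN or a
  stem-erasing δ/λ fit": in our simulations that fraction is ≈ 84–87%,
  with essentially all remaining replicates going to OU fits whose pull is
  itself strong enough to imply no usable phylogenetic structure.

Model comparison uses Akaike weights w_i ∝ exp(−Δᵢ/2) (plain AIC, not
AICc), declaring the argmax the best model only when its weight reaches
0.5 (inclusive; exact ties resolved toward fewer parameters) and "no
choice" otherwise. Because the three shape models each contain BM in their
interior (λ = 1, δ = 1, α = 0), data generated under BM spreads weight
across four near-equivalent fits, and "no choice" with a dominant BM
weight is the expected outcome on moderate-sized trees — the weights row,
not just the label, carries the information.

## Parametric bootstrap under BM

The null distribution of the shape estimates is built by simulating random
walks (σ² = 1, root 0 — the estimates are scale-free) on the tree,
refitting δ, λ and OU to each walk, and taking quantile intervals with the
tails matched to each parameter's alternative: α one-tailed upper
[0, q95], δ two-tailed [q2.5, q97.5], λ one-tailed lower [q5, 1]. An
observed estimate outside its interval departs significantly from the BM
expectation. The pipeline computes this null once on the full tree and
reuses it across traits (per-trait pruned-tree nulls are available through
the API); 1,000 simulations by default, 200 in the test suite. The three
intervals are marginal 95% intervals: joint coverage of all three on
held-out BM data is necessarily below 95% (≈ 85% in our measurements),
while each marginal coverage sits at ≈ 93–96%.

## Synthetic data: what it emulates and what it does not

`generate_tree` draws Yule trees (pure birth, exponential waiting times),
extends every tip edge by the waiting time to the next speciation so no
branch has zero length, and can multiply each branch by a lognormal factor
to mimic the rate heterogeneity of a phylogram. `simulate_traits` evolves
traits by recursive Gaussian transitions (exact OU transition along each
branch) or, for the transform models, by a single multivariate-normal draw
from the transformed covariance. `generate_plate_experiment` builds daily
RFU series over the experimental treatment grids — nitrate
(0, 0.2, 2, 20, 100, 200 μmol L⁻¹), phosphate (0, 1, 2, 4, 8, 16
μmol L⁻¹) and a 14-level light gradient (0–311.5 μE m⁻² s⁻¹) — from a
known growth truth, an inoculation-scale F₀ of 600, an optional hard
logistic cap, and multiplicative lognormal noise (default sd 0.05 on the
log scale, the scale on which fluorescence noise is roughly
signal-proportional). In the reference recovery scenario the cap is set so
density dependence begins to bite after day 7 and the plateau is reached
near the end of the two weeks; media exchange is folded into the constant
dilution D = 0.05 rather than simulated as discrete 10% events.

What passing recovery tests show: the estimation chain is consistent —
with realistic noise and a late plateau, R* comes back within 10% for
≈ 99/100 species, BM traits give mean K ≈ 1 and median λ̂ = 1, δ = 3 truths
give median δ̂ ≈ 3.6. What they do not show: robustness to features of real
plate data that the generator omits — lag phases, non-lognormal outliers,
evaporation edge effects, treatment-level cross-contamination — nor
robustness of the comparative statistics to tree misspecification, since
the synthetic tree is the truth by construction.

## Degenerate inputs and edge conventions

Constant traits, singular covariances, and traits observed for fewer than
4 species raise errors (the pipeline skips such traits with a logged
reason). Zero patristic distance between distinct tips is an error for
Moran's I (infinite weight). p-values never return 0 by the add-one rule.
σ̂² = 0 in the GLS profile is clamped to the smallest positive float so the
log-likelihood stays finite on degenerate-but-valid inputs. All
randomisation uses numpy Generator seeding; every pipeline run derives its
component seeds from one master seed, making reports bit-identical on
rerun.
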