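# Methods

`archroot` analyses binary genome-signature matrices — taxa × protein-domain
(SCOP superfamily) presence/absence characters — to place the root of deep
phylogenies. This note records the models, the numerical choices, what the
synthetic-data generator does and does not emulate, and the known
limitations.

## The two-state Mk model

Characters evolve independently along a rooted tree under a continuous-time
Markov chain on {absent, present} with stationary presence frequency π₁.
The rate matrix is normalised so one unit of branch length is one expected
state change per character at stationarity, which fixes the overall rate at
μ = 1/(2π₀π₁) and gives closed-form transition probabilities

    P(0→1; t) = π₁(1 − e^{−μrt}),   P(1→0; t) = π₀(1 − e^{−μrt}),

with r the per-character rate multiplier. Two variants:

- **Reversible** (stationary): the root state frequency equals π₁. By the
  pulley principle the likelihood is invariant to root placement, so the
  root cannot be inferred.
- **Directional** (non-stationary): the root frequency ρ₁ is a free
  parameter. Characters start from (1−ρ₁, ρ₁) and decay toward the
  stationary frequencies, so the likelihood depends on where the root is.
  With ρ₁ > π₁ the process is loss-dominated — the regime expected for
  domain cohorts descending from a domain-rich ancestor. For two states,
  directionality is carried entirely by the root frequency: a 2×2 rate
  matrix with free off-diagonal rates is always reversible with respect to
  its own stationary distribution, so making the rate matrix "non-reversible"
  would add nothing identifiable.

Likelihoods are computed by Felsenstein pruning, vectorised over unique
site patterns and gamma categories, with lazy per-pattern rescaling
(triggered when partials fall below 1e−150) so matrices with hundreds of
taxa do not underflow. Unknown cells (`?`, `-`, `N`) contribute partial
likelihoods of 1 for both states; no distinction is made between a missing
taxon and an ambiguous domain call.

**Rate heterogeneity across characters (CSRH)** uses the discrete-gamma
construction: K equal-probability categories, each represented by its
conditional mean, computed in closed form from regularised incomplete gamma
functions; multipliers are renormalised to mean exactly 1. Category means
(not medians) are used.

**Ascertainment.** Domain matrices cannot contain never-observed domains,
so the default conditioning is `no-all-absent`: each character's likelihood
is divided by 1 − P(all tips absent). `variable-only` additionally removes
the all-present pattern; `none` disables the correction. The test suite
demonstrates that maximum-likelihood π₁ estimates from data simulated
without all-absent characters are unbiased under the correction and
upward-biased without it.

**Clocks.** `none` treats stored branch lengths as expected changes;
`strict` multiplies an ultrametric tree's times by a global rate; `igr`
(independent gamma rates) additionally gives every branch an independent
gamma multiplier with mean 1 and variance v — a simple relaxed clock
capturing lineage-specific rate heterogeneity (heterotachy). Clocked
analyses condition on the start tree's node times; divergence times
themselves are not resampled.

## Bayesian machinery

Metropolis-coupled MCMC in the MrBayes style: per run, `chains_per_run`
chains at temperatures 1/(1+λi) (λ = 0.1 by default), one proposal per
chain per generation, one random swap attempt per generation, cold chain
sampled every `sample_interval` generations; ≥2 independent runs; the
first half of samples discarded as burn-in.

State and priors: π₁, ρ₁ ~ Uniform(0,1); α ~ Exponential(1); unrooted
branch lengths ~ iid Exponential(10) (the two root-adjacent half-edges are
one unrooted edge); root position uniform over edges and positions; clock
rate ~ Exponential(1); IGR variance ~ Exponential(10); IGR multipliers ~
Gamma(1/v, v). Moves: multiplier (scale) proposals on branch lengths, the
whole tree, α, clock rate, IGR terms; reflected sliding windows on π₁ and
ρ₁; root relocation to a uniformly chosen edge and position (the unrooted
topology and edge lengths are untouched, so the proposal is symmetric);
rooted NNI when the topology is free, with constraint clades enforced by
rejection. Proposal widths are fixed (window 0.1, multiplier log-range
0.7); no auto-tuning by default.

Diagnostics follow the field's conventions: ASDSF (mean over splits
reaching 10% in ≥1 run of the n−1-denominator standard deviation of
per-run split frequencies; < 0.01 is the usual convergence bar, 0.01–0.05
a relaxed bar for hard runs) and the Gelman–Rubin PSRF for scalars
(undefined, not an error, at zero within-run variance).

Model comparison uses the harmonic-mean estimator of the marginal
likelihood, computed stably in log space, because that is the estimator
the analysis protocol this package reproduces relied on. Its pathologies
are real and documented: the estimate is driven by the smallest sampled
log likelihood, it has infinite variance for most problems, and
differences of a few log units between models of similar dimension are
routinely within estimator noise at desk-scale sample sizes. A warning is
emitted for traces under 1000 samples. Log Bayes factors are differences
of marginal log likelihoods; |LBF| 3–5 is labelled "strong", >5 "very
strong". `llr_rank` applies the same difference-from-best convention to
maximised log likelihoods.

## Neighbor-net

Exploratory data display uses neighbor-net: an agglomerative scheme
(neighbor-joining-style selection over clusters of one or two active
nodes, three-node paths reduced with the standard 2/3–1/3 distance blend)
produces a circular taxon ordering; weights for all n(n−1)/2 splits
compatible with the ordering are then fitted by non-negative least squares
(scipy's active-set NNLS) and splits below 1e−6 are dropped. Agglomeration
ties break toward the lowest taxon index, making the ordering
deterministic. On an additive (tree) metric the output is exactly the
tree's splits with weights equal to branch lengths (verified to 1e−6 in
the tests); on a circular metric the generating weights are recovered.
The dense pair×split NNLS system grows as O(n⁴); the implementation is
comfortable to ~60 taxa, which covers exploratory use, and exports
SplitsTree-compatible NEXUS for drawing — equal-angle layout itself is out
of scope. Distances are p-distances (alignments) or Hamming distances
(binary matrices) with pairwise deletion by default; complete deletion is
available.

## Synthetic data

`simulate_tree` builds one Yule subtree per named clade (all scaled to the
deepest `clade_height_frac` of the total height) on a fixed backbone whose
root separates the first clade from the rest — so the true root is the
first clade's stem. `simulate_matrix` draws a gamma category per
character, a root state from (1−ρ₁, ρ₁) (a `core_fraction` of characters
is forced present at the root), and evolves states edge by edge; per-edge
heterotachy multipliers scale both rates while clade loss-bias factors
scale only the loss rate (genome reduction changes equilibrium presence,
not just speed). Characters that violate the model's ascertainment mode
are redrawn and counted, so corrected inference can be validated exactly.

The `scop-like` preset (three clades of 8, 1700 characters, π₁ = 0.3,
ρ₁ = 0.9, α = 0.7, K = 4, core fraction 0.5, heterotachy multipliers
uniform on 0.5–2 — a calibration choice, as no quantitative heterotachy
magnitude is established for these data — and a 1.5× archaeal loss bias)
reproduces the qualitative structure of real SCOP matrices: a large
universally distributed core and presence frequencies far below the root
frequency. With every parameter above held at its stated value the
preset yields ~60–70% of characters present in all three clades (the real
SCOP-II matrix shows ~50%); the discrepancy is dominated by processes the
generator deliberately omits — lineage-specific domain birth, horizontal
transfer, and per-taxon annotation noise, which all create clade-specific
characters. Passing recovery tests on these simulations therefore shows
the inference machinery is correct and powerful under the model's own
assumptions; it does not show the model is adequate for any particular
real matrix.

## Problem sizes used in the checks

The validation suite runs everything at desk scale, chosen so the whole
suite completes in minutes: exhaustive-enumeration likelihood checks on
4–6-taxon trees; neighbor-net consistency on 8-taxon metrics; root
recovery on 24 taxa × 1000 characters with 20 replicates of short
fixed-topology runs; model selection on 16 taxa × 1000 characters. The
full-scale analyses these mirror (hundreds of taxa, tens of millions of
generations) are supported by the same code paths but are multi-day
computations; their headline posterior results are not reproduced in the
test suite.

## Known limitations

- Harmonic-mean marginal likelihoods: see above; stepping-stone or path
  sampling are not implemented.
- Clock analyses condition on the start tree's relative node times.
- CPP and TK02 relaxed clocks are not implemented; the lineage-rate
  robustness axis is exercised with IGR only.
- Topology proposals are rooted NNI only; for matrices where topology and
  root must both mix from a poor start, constrained mode with
  user-supplied cluster constraints is the intended workflow.
- The simulator does not model horizontal transfer or lineage-specific
  domain birth (treated as minority signal for these data).
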