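# Methods

`canopycomm` analyses butterfly (or any line-transect animal) community data
along a canopy-cover gradient: raw detections → distance-sampling densities →
community metrics → ordination, permutation inference, and canopy-response
peak regressions. This note documents the models, the defaults, the
numerical choices, and what the synthetic-data generator does and does not
emulate.

## Distance sampling

Detectability decays with perpendicular distance x from the transect line.
The detection key is the half-normal, g(x) = exp(−x²/2σ²), fit by maximum
likelihood per species group. Without truncation the MLE is the closed form
σ̂ = √(Σx²/n); with a finite truncation w the truncated likelihood is
maximized numerically (bounded scalar search on log σ). The effective strip
width is ESW = ∫₀ʷ g(x)dx = σ√(π/2)·erf(w/σ√2), and density per survey is

    D = 10⁴ · n / (2 · L · ESW)   [individuals ha⁻¹]

with L the transect length (m) and n the possibly fractional count.

*Choices.* Half-normal only: it is the standard default key, has a
closed-form untruncated MLE, and suffices for simulated data generated under
the same model; hazard-rate/uniform keys and series adjustments are out of
scope. Truncation defaults to ∞. The pooling threshold defaults to 30
detections: species at or above it get their own fit; sparser species share
a fit estimated from the distances of all their congeners, else
confamilials, else all species (a sparse species borrows detectability
information from its relatives — this is why abundant species can still
appear with a shared, pooled ESW).

*Apportionment.* Records identified only to family/genus are split among
that taxon's species identified at the same site on the same day,
proportionally to identified counts; with no same-site/same-day candidate
the record is dropped and logged (season-level fallbacks would change the
phenology structure and are deliberately not attempted). Counts are
conserved: total before = total after + total dropped.

## Community metrics

* **Richness** per survey is the number of species with nonzero density.
* **Total density** is the sum of species densities per survey.
* **CVI** (conservation value index) = Σ r_s·D_s over species with reversed
  NatureServe rank r_s > 2. Rank grammar: "Gk" → k, "GjGk" → midpoint,
  "GkTm" → m (the infraspecific rank governs — it describes the population
  actually present); reversed rank = 6 − numeric, so 1 = secure and
  5 = critically imperiled.
* **ACE** richness uses the classical rare-species cutoff of 10. It is
  undefined (raises) when every rare individual is a singleton.
* **Accumulation curves**: site-based curves enumerate all site orderings
  exhaustively up to 7 sites (exact means) and randomize above that;
  individual-based curves randomize draws without replacement
  (200 randomizations by default). Habitat contrasts at a common effort use
  z = (S̄_A − S̄_B)/√(var_A + var_B) with Benjamini–Hochberg correction over
  pairs. Confidence intervals are mean ± 1.96√var.
* **Site aggregation**: site-level density and CVI are means of per-survey
  values across all rounds, with zero-detection surveys included (omitting
  them would bias means upward). Inverse-distance plot averaging uses
  exponent 1.

## Ordination

**Principal curve** (one dimension): initialize sample scores from the first
correspondence-analysis axis; iterate (i) fit each species' transformed
abundance against the scores with a cubic B-spline regression smoother of
fixed effective df (default 4, i.e. five basis functions with one interior
knot at the median score), (ii) project each sample onto the nearest point of
the fitted multivariate polyline (exact segment projection, not just the
nearest grid node, so noiseless configurations are fit exactly), (iii)
re-parameterize by arc length. Convergence when the relative change of the
residual SS is < 10⁻⁶ (max 50 iterations; non-convergence is flagged and the
partial result returned). Scores are rescaled to [0, 1]. Orientation is
arbitrary in the method; scores are flipped to correlate positively with
canopy cover when supplied, else with the initialization. Transforms: square
root for densities, ln(x + 0.5) for stem counts.

**IndVal**: specificity A_sg (share of the species' group-mean abundance in
g) × fidelity B_sg (occupancy fraction in g) × 100; abundance-based A per the
original Dufrêne–Legendre formulation. Significance of each species' maximum
IndVal by permuting the site→group assignment with sizes preserved, p =
(1 + b)/(n_perm + 1) (ties at the observed value count toward b, so even a
perfect indicator has p above the permutation floor when permutations can
reproduce the split), B-H adjusted across species; default 4999 permutations.
Tied maxima resolve to the first habitat in gradient order (open, savanna,
woodland, scrub, forest) and are logged.

**Predictive CoCA**: both matrices are reduced to row profiles, centered and
scaled chi-square-style under site weights taken from the response's row
totals; axes are extracted by weighted PLS (leading singular vector of the
weighted cross-covariance of profiles, sample scores normalized in the
weight metric, both matrices deflated). Predictive skill is the
leave-one-out cross-validated fit, 100·(1 − PRESS_k/PRESS₀), where PRESS₀
predicts every left-out profile by the training mean; an uninformative
predictor therefore gives a fit ≤ 0 in expectation (individual replicates
are noisy — null checks average over replicates). Axis significance by
permuting predictor rows and comparing singular values. Response species
absent from a training fold are necessarily skipped in that fold's error.

## Inference

PERMANOVA partitions squared dissimilarities (SS_T = Σd²/N; SS_W within
groups weighted 1/n_g) and permutes labels; with Euclidean distance on
univariate data the pseudo-F equals the classical ANOVA F exactly, which the
tests verify to 10⁻¹⁰ (and cross-check against scikit-bio on Bray–Curtis
data). "Sørensen distance on densities" is the quantitative Sørensen =
Bray–Curtis; binary Sørensen is available as `sorensen_binary`. Pairwise
contrasts rerun the two-group statistic permuting within the pair, report
t = √F, and B-H adjust. Default 9999 permutations, p = (1 + b)/(n_perm + 1).
Group-level tests of univariate metrics use tie-corrected Kruskal–Wallis
with Dunn's z on pooled midranks.

## Peak regressions and spatial eigenvectors

Each canopy response is fit with a cubic polynomial (linear LS) and a
3-parameter Gaussian peak (Levenberg–Marquardt, initialized at a = max y,
x₀ = argmax y, b = range(x)/4); the lower-AICc model wins (AICc counts the
error variance as a parameter). The reported peak is the winning curve's
argmax restricted to the observed canopy range — extrapolated cubic maxima
are refused. The composite conservation outcome averages the three
per-metric midranks (1 = worst site).

Moran spatial eigenvectors follow the PCNM construction: distances beyond
the longest minimum-spanning-tree edge are replaced by 4× the truncation,
the matrix −d²/2 is double-centered, and positive-eigenvalue eigenvectors
are returned in decreasing eigenvalue order. On a regular 25-site transect
this reproduces R `vegan::pcnm` exactly (leading eigenvalue 225641); note
the leading eigenvector of this construction is a smooth but not monotone
spatial pattern (|Spearman ρ| ≈ 0.79 with position). Which eigenvectors
enter a downstream model is left to the caller.

## Synthetic data

Each simulated species has a Gaussian canopy niche (optimum μ, breadth τ,
peak density A, all in ecological units: % canopy and individuals ha⁻¹) and
a Gaussian flight season; expected density is the product
A·exp(−(c−μ)²/2τ²)·exp(−(d−p)²/2s²). Strip abundance is Poisson(λ × strip
area), individuals are uniform in distance over [0, w_field] (w_field = 20 m,
well beyond any plausible ESW so truncation effects are negligible), detected
with half-normal probability, and downgraded to a family code with
probability 0.08 (matching the field identification rate). The default
design is 25 sites — five per habitat class with canopy drawn from
class-typical ranges (open 1–18%, savanna 22–48%, woodland 52–88%, scrub
25–65%, forest 90–99%) — surveyed 21 times across two seasons on 500-m
transects, with a fixed pool of 60 species whose niche optima are skewed
toward open habitats and whose six imperiled species (reversed rank > 2)
center near 60% canopy, mirroring the qualitative structure of the field
system. The pool is drawn once from an internal constant seed so the default
configuration is a single reproducible study system; all run-to-run
randomness flows from one user-supplied seed, and identical seeds give
byte-identical outputs.

`true_peaks` grid-searches (0.1% steps) the analytic response surfaces
averaged over the survey schedule: total expected density, expected
per-survey richness Σ(1 − exp(−λ_s·a_s)) with a_s the species' effectively
surveyed area, and expected CVI. Note the pipeline's site-level richness is
the ACE estimate of season richness, a different flavour from the analytic
per-survey richness, so peak-recovery checks target density and CVI.

**What the generator does not emulate:** overdispersed (negative-binomial)
counts, observer and weather effects, butterfly movement and double
counting, distance-measurement error, the plant community (CoCA checks use
separately generated coupled communities), and spatial autocorrelation of
site attributes. Passing recovery tests therefore show estimator correctness
under the model's own assumptions, not robustness to their violation.

## Problem sizes in tests

The test suite uses desk-scale problems chosen to keep Monte-Carlo error
well inside the asserted tolerances: 200 replicates for estimator bias,
100 null simulations at 199 permutations for type-I calibration (99%
binomial acceptance bands), 20 datasets for peak recovery, and the full
default design (525 surveys × 60 species) for end-to-end checks.
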