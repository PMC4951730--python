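# Methods

## Populations and genotype coding

The package targets experimental crosses with two genotype classes per
locus: backcross (AA/Aa) and doubled haploids (the two homozygotes).
Codes are +1/−1, so an idealized locus code has mean 0 and variance 1 and
a QTL explaining a fraction r² of the phenotypic variance has additive
effect γ = √(r²·σ²_P). Recombination follows the Haldane map function
r(d) = (1 − e^(−2d/100))/2 (no interference), consistent with the
multipoint treatment of flanking-marker probabilities; Kosambi is
available as an option for real maps whose distances were estimated under
interference.

Scan positions between markers ("pseudo markers", inserted so that no
gap exceeds d cM, default d = 1) and missing observations are represented
by the conditional expectation of the code given the nearest non-missing
observed flanking markers:

* both flanks observed — the exact two-interval conditional under the
  Markov (no-interference) model;
* one flank — code × (1 − 2r(d));
* none — 0, the prior mean.

Restricting to the nearest non-missing flanks is exact when flanking data
are observed and is the standard approximation otherwise. Markers at
identical map positions are collapsed to the first by input order.

## Stage 1: random-effect single-locus scan

Model: y = Xα + z_k γ_k + ξ + ε with γ_k ~ N(0, φ_k²), polygene
ξ ~ N(0, K φ²), residual ε ~ N(0, I σ²). K = (1/m) Σ z_j z_j′ over true
markers only (pseudo loci never enter K).

The polygenic ratio λ = φ²/σ² is estimated once by REML under the pure
polygenic model and then frozen for the whole scan (the P3D /
"population parameters previously determined" shortcut). With
K = U diag(δ) U′, rotation by U′ diagonalizes the background covariance;
the profiled restricted likelihood in λ is maximized by a 61-point
log-grid over [1e−6, 1e6] followed by bounded Brent refinement — exact
for a single unknown ratio. When the likelihood is flat (K proportional
to the identity, or zero), the fit warns and returns the lower bound:
polygenic and residual variance are then not separately identifiable and
any λ gives the same scan.

At each locus the covariance gains the rank-one term z*z*′λ_k. After
projecting out the fixed effects, the profiled restricted log-likelihood
depends on λ_k only through two scalars, θ = z*′P₀z* and κ = z*′P₀y*
(P₀ the GLS projection under the background covariance), because
Sherman–Morrison updates the projection in closed form:

    −2ℓ_R(λ_k) = ν·log(Q₀ − λ_k κ²/(1 + λ_k θ)) + log(1 + λ_k θ) + const,

ν = n − p, Q₀ = y*′P₀y*. Newton iteration with analytic first and second
derivatives runs on this scalar function (start λ_k = 1, step-halving
when the criterion worsens, projection to 0 when the gradient at zero is
nonnegative, convergence |Δλ_k| < 1e−8(1+λ_k), max 100 iterations; a
bounded Brent search on [1e−8, 1e6] is the fallback). Each locus costs
O(n) after one matrix rotation shared by all loci.

From the REML estimate follow the BLUP γ̂_k = λ̂_k κ/(1+λ̂_k θ), its
conditional (prediction-error) variance var(γ_k|y) = λ̂_k σ̂²/(1+λ̂_k θ),
and the Wald statistic γ̂_k²/var(γ_k|y) referred to a 1-df chi-square
(no boundary mixture: the LOD 2.5 ↔ p 0.000691 conversion implies the
plain 1-df convention). At λ̂_k = 0 the statistic is 0 and p = 1.
A fixed-effect GLS alternative (classical Wald) is available for
comparison. Monomorphic or collinear loci record p = 1 with a warning.

Kinship modes: `whole` uses all true markers and one background fit;
`part` removes, for every scan position in marker interval
[t_i, t_{i+1}), exactly those two flanking markers from K (a position at
a true marker belongs to its right-hand interval, so the tested marker
itself is excluded). Part mode refits the polygenic model per interval;
eigen-decompositions are cached by flanking pair and reused across the
correction rescan and across analyses of the same genotypes, since they
do not depend on the phenotype.

## Peak selection

All local maxima of the −log₁₀ p curve are candidates: index i is a peak
when the curve strictly rises into i and does not rise after it
(plateaus contribute their leftmost point; chromosome ends are compared
one-sided). Deliberately no p-value threshold — small and linked effects
must survive into stage 2, which is where stringency lives.

## Stage 2: empirical-Bayes multi-locus model

All K candidates enter y = Xα + Σ z_k γ_k + ε with γ_k ~ N(0, σ_k²) and
a scaled inverse chi-square hyperprior on each σ_k² with
(τ, ω) = (0, 0) — both exposed as arguments since this corner of the
source literature is partly ambiguous. No polygenic term: all potential
QTL are in the model. Estimation is EM:

* init: α by OLS, σ_k² = 1, σ² from OLS residuals;
* E-step: γ̂_k = σ_k² z_k′V⁻¹(y − Xα) and its posterior variance, with
  V = Σ z_k z_k′σ_k² + Iσ² handled through the Woodbury identity on the
  active components;
* M-step: σ_k² ← (γ̂_k² + postvar + ω)/(τ + 3), then α by GLS and σ²
  from the expected residual sum of squares;
* convergence when parameter changes fall below 1e−8 relative, cap 1000
  iterations (non-convergence returns the final iterate with a warning).

Components whose prior variance falls below 1e−10·var(y) are frozen at
zero — the EM's own selective shrinkage; with (τ,ω) = (0,0) the
penalized objective is unbounded as σ_k² → 0, so collapse is the correct
limiting behavior, and the monotonicity of the penalized marginal
log-likelihood is tracked between iterations that share an active set.
The candidate count is capped at 2n (error beyond), since the model is
not estimable with many more effects than observations.

Screening and declaration: effects with γ̂_k²/postvar above the
F(1, n − rank X) quantile for α = 0.01 (strict inequality; collapsed
components are dropped) proceed to a drop-one likelihood-ratio test, and
LOD = LRT/(2 ln 10) ≥ 2.5 declares a QTL. The LRT keeps the effects at
their empirical-Bayes (shrunken) estimates and profiles only the
intercept/covariates and residual variance ("plugin" form). This choice
is deliberate: the declared effect sizes are the EB estimates, so the
declaration tests exactly the quantity reported, and the shrinkage
carries through to the test — a marginal chance capture (the best of
thousands of correlated scan positions on pure noise) is shrunk enough
to stay below LOD 2.5, while a real QTL's effect is essentially
unshrunk. A classical refit LRT (both models re-estimated by least
squares) is available as `method="refit"`; it is noticeably more liberal
on null data because selection bias inflates the unshrunk estimate of
the best chance capture. Reported r² = γ̂²·var(z)/var(y)·100.

The full pipeline subtracts the declared effects from the phenotype and
repeats scan → peaks → EB → screen → LRT once on the corrected trait
("analyzed again" — a single correction round). The union of both
rounds' declarations, deduplicated within 1 cM keeping the higher-LOD
record, is the final report. An empty first round leaves the phenotype
unchanged, so the second round is skipped as exactly redundant.

## Simulator

Genotypes: the first marker is a fair ±1 coin per individual, then a
Markov chain along the chromosome with flip probability r(Δd) between
adjacent loci. The marker-grid chain is drawn first; off-grid QTL
positions are sampled afterwards from their exact conditional law given
the flanking markers, so marker data are identical across experiments
that share a seed and differ only in genetic architecture. Genotype,
polygene and residual randomness come from three independent streams
spawned from the seed.

Phenotypes: y = mean + Σ γ_k Z_k + Σ γ_AB Z_A Z_B + ξ + ε. Effects are
back-calculated from target r² fractions via
σ²_P = σ²_resid/(1 − Σr² − h²_pg − Σr²_epi) and γ = √(r²σ²_P);
epistatic pairs act on product codes only (no marginal additive term),
and the polygene is multivariate normal with covariance φ² times the
kinship of the simulated markers. Note that linked same-sign QTL are
positively correlated (code correlation 1 − 2r(d)), so the realized
phenotypic variance exceeds the naive budget; the exact value is
γ′Cγ + φ² + Σγ²_epi + σ² with C the code-correlation matrix, and the
tests verify that identity rather than the independence approximation.

Experiment presets on one 2400 cM chromosome with 481 markers at 5 cM
and n = 400, mean 100, residual variance 10:

* **I** — 20 additive QTL with r² from 0.5% to 20%. The exact positions
  and effects of the original study's table are not published in the
  available text, so the default configuration is a documented stand-in
  satisfying every stated structural constraint: QTL 9, 14, 19 and 20
  are small (r² < 1%), QTL pairs/triples {5,6}, {7,8}, {10–12} and
  {16–18} are linked at ≤ 20 cM spacing, the largest QTL (first) has
  r² = 0.20 and the smallest (last) 0.005; total r² = 0.681. No analysis
  here digit-matches per-QTL rows — all checks are structural or
  order-of-magnitude.
* **II** — experiment I plus a polygenic background, default
  h²_pg = 0.1 (configurable; the original magnitude is not recoverable
  from the available text).
* **III** — experiment I plus three epistatic pairs (default r² = 0.05
  each) placed inside the stated windows 800–1800, 1210–1860 and
  275–740 cM; a background-misspecification stress test, since the
  mapping model fits no epistasis.
* **IV** — no genetic effects; y = 100 + N(0, 10). Null calibration.

## Evaluation metrics

A detection within 5 cM of a simulated QTL counts for that QTL; the
assignment is greedy nearest-distance with each detection consumed at
most once (equidistant ties go to the earlier truth). Power per QTL is
matched replicates over total; MAD and MSE average the declared-effect
errors over matched replicates only (a never-detected QTL reports NaN,
not zero). FPR divides unmatched detections by replicates × zero-effect
positions, where zero-effect positions are scan-grid loci farther than
5 cM from every truth.

## Problem sizes and runtime choices

The full evaluation design uses 200 replicates. The package's own test
suite runs scaled-down versions chosen to keep a complete run in minutes:
40 null replicates for the false-declaration check, 12 paired replicates
for the whole- vs part-kinship contrast (with a correspondingly widened
Monte Carlo band), 25 replicates for single-QTL recovery, and reduced
replicate counts in module-level simulation tests. The acceptance script
runs the null study at the full 200 replicates and the kinship contrast
at 40 paired replicates. Part-kinship analyses factor one 400×400
eigen-decomposition per marker interval (~480 per replicate), cached and
reused wherever the genotypes are unchanged.

## Known limitations

* Two-genotype populations only (BC, DH, RILs treated as DH); F₂ and
  outbred designs need different conditional probabilities and are out of
  scope, as are genotyping-error HMMs and sex-specific maps.
* The scan's random-effect test is conservative under the null (observed
  per-locus rejection at nominal 0.05 is ≈ 0.02); stage 2, not stage 1,
  sets the effective stringency.
* Stage-2 shrinkage estimates are biased toward zero for very small
  effects; the reported r² inherits that bias.
* With part-marker kinship the per-interval refits make the scan
  ~50× slower than whole-marker mode at typical linkage-map densities
  (hundreds of marker intervals).
* The simulator emulates a single large chromosome with evenly spaced
  markers and no interference, missing data, segregation distortion or
  genotyping error; passing simulations therefore validate the
  estimation machinery, not robustness to those real-data artifacts
  (missing data and multi-chromosome maps are supported in the mapping
  code itself).
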