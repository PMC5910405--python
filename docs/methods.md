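# Methods

This note documents the models, numerical choices and synthetic-data design
behind `monolignol`. It is written for a reader who wants to know exactly
what the package computes and what its tests do and do not demonstrate.

## The integrative model

The package chains three quantitative layers that together map monolignol
gene transcript abundances to 25 lignin and wood properties of *Populus
trichocarpa* stem-differentiating xylem:

1. **Transcript → protein.** One simple linear regression per gene,
   constrained through the origin (zero transcript implies zero protein):
   `P_i = β_i · T_i`, with `β_i = Σ(T·P)/Σ(T²)`. The goodness of fit is the
   *uncentered* coefficient of determination `R² = 1 − Σ(P−P̂)²/ΣP²`; the
   centered convention is meaningless without an intercept and is not used.
   Abundances are first normalized per batch against the mean of that
   batch's wildtype replicates, so seasonal/batch structure divides out.
   A configuration option can pool gene pairs into one shared regression.

2. **Protein → fluxes and metabolites.** The monolignol pathway grid:
   24 metabolites, 37 enzymatic reactions over 10 enzyme families
   (21 genes). Every active reaction is irreversible Michaelis–Menten,
   summed over catalysing isoforms and scaled by enzyme abundance:

   `v_r = Σ_g kcat_{r,g}·E_g·S / (Km_{r,g}·α_c + S·α_u) / α_n`

   where `α_c`, `α_u`, `α_n` are 1 + Σ(I/K_i) over the declared competitive,
   uncompetitive and noncompetitive inhibitors of reaction *r*. Mechanism
   tags are data (default competitive), not code. Reactions 16, 20, 21 and
   26 are held at exactly zero flux (no kinetic constants exist for them).
   Reactions 7–8 (CoA ligation) route through the Ptr4CL3/Ptr4CL5
   heterotetramer: complex concentration `min(E_4CL3/3, E_4CL5)` with its
   own kcat/Km; leftover monomers stay catalytically active with monomer
   kinetics (configurable off). Phenylalanine (metabolite 1) is a clamped
   boundary species; the three monolignols (20, 22, 24) are sinks that
   accumulate and are excluded from the steady-state criterion. The S/G
   ratio is the flux ratio V35/V34 (sinapyl- over coniferyl-alcohol
   formation).

   The mass-balance ODE system is integrated with a stiff solver (LSODA,
   rtol 1e-8, atol 1e-9 µM) from 0 to 10,000 s. The endpoint is then
   polished by a damped Newton solve over the internal metabolites, accepted
   only if it stays non-negative and within 5% of the integrated endpoint —
   this removes the residual final-approach error without allowing jumps to
   a different basin. Convergence criterion: max over internal metabolites
   of |dC/dt| / max(C, 1e-6 µM) < 1e-6. Non-convergence is reported as a
   flag plus the residual, never as an exception: a metabolite pool whose
   inflow exceeds its maximum consumption capacity genuinely has no steady
   state, and downstream layers must see that.

   The wildtype phenylalanine input is calibrated so the wildtype S/G ratio
   matches its measured value (2.16 in the reference system): a log-spaced
   scan over 0.01–100 µM locates a sign change that Brent's method refines
   (xtol 1e-8 µM — tight enough that re-fits reproduce the same
   phenylalanine bit-for-bit on noise-free data). If the target sits at a
   tangency of the S/G curve, the scan refines around the closest approach
   and accepts within 0.1% in S/G space.

   Robustness of a steady state to initial conditions is measured with
   Latin hypercube sampling of initial internal-metabolite concentrations
   (default bounds 0–100 µM per metabolite): a sample counts as "same
   steady state" when every internal metabolite and every active flux
   agrees with the reference within 1% relative (absolute floor 1e-6).

3. **Features → traits.** Per line, the 37 steady-state fluxes and 24
   metabolite concentrations — rounded to five decimal places so that
   numerically tiny features cannot be rescued by enormous coefficients —
   feed 25 multiple linear regressions, one per trait. Features with
   pairwise |Pearson r| > 0.95 are pruned greedily in canonical
   flux-then-metabolite order (keep-first). For each trait an exhaustive
   all-subsets search up to `max_terms` predictors (default 5; the cap is
   recorded in every model) minimises the corrected Akaike information
   criterion, `AICc = n·ln(RSS/n) + 2k + 2k(k+1)/(n−k−1)` with `k` counting
   the intercept. Ties break toward the smaller subset, then lexicographic
   column order. Predictions are clamped to ≥ 0, and percentage-valued
   traits (18 of 25) additionally to ≤ 100; coefficients themselves are
   unconstrained.

   Implementation note: subset fits reuse a precomputed Gram matrix with
   batched linear solves. Because Gram-based RSS carries cancellation error
   of order eps·Σy²·cond, any subset whose RSS falls below 1e-7·Σy² is
   recomputed from explicit residuals; exact fits then tie at a tiny floor
   and the smaller-subset tie-break acts. Without this, noise-free data
   would select spurious supersets.

**Validation.** k-fold cross-validation (default 5 folds) randomly
partitions lines into near-equal groups (sizes differ by at most one) and
re-estimates *everything free* — all β_i and all trait regressions — on each
training split; kinetic constants are fixed throughout, as they come from
enzyme assays, not from this data. Phenylalanine is calibrated once on the
full data by default (a config switch enables per-fold recalibration; a fold
without wildtype lines falls back with a warning). Out-of-sample adjusted R²
is computed against the validation-set mean using the training model's
parameter count; bias is mean(predicted/measured) over lines with positive
measurements.

**Perturbation screen.** Each of the 10 gene families is set to 5%, 100% or
1000% of wildtype transcript abundance (multipliers applied uniformly to all
member genes), with at most three families modified at once; including the
all-wildtype baseline this enumerates 1161 configurations. Multipliers above
wildtype trigger an extrapolation warning — they project outside the
measured expression range. Each configuration runs the full forward chain;
configurations whose pathway state cannot settle (e.g. a 10× producer feeding
a 20×-reduced consumer — a genuine mass imbalance) are flagged and excluded
from ranking. Outcomes are ranked per trait (either direction) or by the
proportional score Σ(predicted − desired)², ascending; ties break toward
fewer modified families, then config id.

## The synthetic population generator

The generator emulates the statistical structure of a transgenic knockdown
study so that the analysis layers can be tested with known ground truth.
Defaults are the study conditions: 239 lines in 6 batches, each batch with
3 wildtype replicate lines (18 wildtype, 221 transgenic); per-line targeted
suppression of a whole family (50%), a gene pair (25%) or a single gene
(25%), with residual expression uniform in 5–95% of wildtype; cross-family
indirect effects as family-level lognormal multipliers (sd 0.2); batch
effects lognormal sd 0.1 per batch × gene; replicate noise lognormal
sd 0.05; per-gene translation coefficients lognormal around a median of
1.5×10⁴ protein molecules per transcript (sd 0.6 in log space); protein
measurement noise CV 0.2; trait noise sd equal to 10% of each trait's
realized population spread. Wildtype protein abundances are log-uniform in
0.5–10 µM.

Traits follow a sparse linear rule (1–3 predictors) on the line's *true*
steady-state features, rounded to the same five decimals the fitting layer
uses, so the regression layer's assumptions hold exactly and noise-free
recovery is a well-posed test. Ground-truth predictors are drawn only from
features that (a) survive the collinearity filter, (b) vary substantially
across the population (sd above max(5% of mean, 1e-3) — a near-constant
"predictor" would be physically meaningless and numerically fragile), and
(c) correlate at most 0.85 with every other retained feature, so that a
subsample re-fit (a cross-validation fold) cannot evict a true predictor
through correlation fluctuations across the 0.95 threshold. Effects are
scaled per predictor to 20% of the trait's wildtype baseline and shrunk, if
necessary, so the noise-free rule stays strictly inside the clamp bounds.
Trait noise is defined relative to the realized trait spread
(noise-to-signal) rather than the baseline: bounded percentage traits near
100% would otherwise have their admissible effects shrunk below any fixed
noise floor, leaving nothing recoverable by any method.

The generated dataset's "measured" wildtype S/G target is whatever the
realized wildtype anchor produces at the 1.4 µM reference phenylalanine
(batch noise shifts it a few percent from 2.16); the fitting layer is then
given that dataset-specific target, exactly as a real analysis would use its
own wildtype measurement.

Like the source study — which selected ~10% of its transgenic lines as
viable — the generator redraws a line (fresh knockdown and noise draws, up
to 20 attempts) when its pathway state cannot settle within the integration
horizon. Strong single-family knockdowns of a sole-consumer enzyme are
therefore slightly underrepresented relative to a uniform design.

Synthetic kinetic registries are log-uniform draws over kcat 0.1–100 1/s,
Km 1–1000 µM, Ki 1–1000 µM, accepted when the wildtype steady state
converges, is robust to random initial conditions (LHS fraction 1.0 at
n = 50), and — when a target S/G is requested — the V24 (coniferaldehyde
5-hydroxylation) kcat can be tuned by bisection so wildtype S/G hits the
target at the reference phenylalanine, with the S/G-vs-phenylalanine curve
crossing the target with at least 10% margin inside the calibration bracket
(otherwise calibration would be ill-posed under small anchor shifts).
Roughly 1–10% of draws are accepted; the sampler retries up to 400 times.

### The packaged default registry

`data/kinetics.json` is a synthetic registry constructed for the packaged
grid (see `scripts/make_default_kinetics.py`). It is drawn in
*drain-constant* space: per (reaction, enzyme) pair, Km log-uniform in
200–1000 µM and a first-order drain kcat·E_wt/Km log-uniform in 0.05–0.5 1/s,
from which kcat follows. This puts the wildtype system in the sub-saturated
operating regime of real enzymes (concentrations well below Km), which is
what gives the grid dynamic headroom for the 5%–1000% perturbation screen
and settling times far inside the 10,000 s horizon; the S/G–phenylalanine
nonlinearity then comes from the inhibition network (Ki 10–200 µM). The
draw is accepted under the same convergence/tunability/margin/LHS conditions
plus viability of every single-family 5% and 1000% perturbation. The
registry is tuned so wildtype S/G = 2.16 at 1.4 µM phenylalanine. Of the
1161 screen configurations, ~50 producer-up/consumer-down combinations have
no steady state and are flagged. The registry's values are *not* the
published enzyme constants; analyses of real data must load the measured
registry through the same JSON interface.

## What passing tests show — and what they do not

Noise-free closed-loop tests show the implementation is self-consistent: the
fitting layers recover the exact generating parameters (β_i and trait
coefficients to 1e-6 relative) and cross-validation shows train ≈ validation
adjusted R² ≈ 1 with bias exactly 1. Noisy tests (20% protein CV, 10% trait
noise-to-signal, n = 239) show β_i recovered within 5% and the true
predictors *detected* — contained in the selected set — for ≥ 80% of traits.

Exact support equality under noise is not an attainable bar for AICc-based
exhaustive selection and is not asserted: with ~30 candidate predictors, the
best spurious candidate reduces RSS by roughly max-of-m χ²₁/n, which exceeds
the AICc improvement threshold (≈ 2/n) with high probability at any n — AIC-
family criteria are deliberately liberal. The meaningful recovery notion
under noise is therefore detection (no misses), and that is what the tests
assert.

The generator reproduces the *statistical shape* of a transgenic study, not
its biology: indirect effects are family-level multiplicative draws rather
than a regulatory network; traits truly are sparse linear functions of
features, so model misspecification is absent by construction; kinetic
constants are synthetic. Real-data headline numbers (mean R² across traits,
lignin–carbohydrate slopes, density–stiffness relations) depend on the
experimental dataset and are replication targets, not test assertions.

## Problem sizes and runtime choices

Test and acceptance runs use: populations of 239 lines (the study size) for
recovery and cross-validation, 40 lines for unit-level closed-loop checks;
all-subsets search with max_terms 5 for single fits and 3 inside
cross-validation (the generator's true supports have at most 3 predictors,
so the noise-free identities are preserved); LHS robustness at 200 samples
in the acceptance script and 10–50 in unit tests (the estimate is a simple
binomial fraction; the packaged registry's uniqueness of attractor makes it
1.0 at any n); the full 1161-configuration screen. A steady-state solve
takes ~30–60 ms; a full 239-line fit ~30 s; the 5-fold CV a few minutes.

## Known limitations

- The packaged grid topology is a faithful reconstruction of the published
  wiring (the figure itself is not machine-readable): metabolite and flux
  numbering, inactive fluxes, the 4CL complex block, the source/sink roles
  and the S/G-defining fluxes are pinned; individual inhibition edges are a
  representative set, not the full measured network.
- Irreversible rate laws only; no thermodynamic back-pressure. HCT
  reversibility is modelled as paired antagonistic irreversible reactions.
- A single well-mixed compartment: wood formation averages over fiber,
  vessel and ray cell types, and so does this model.
- The Newton polish assumes the integrated endpoint is in the attractor's
  basin; the LHS robustness check is the guard for multistability.
- Percentage clamping applies only to traits declared as percentages;
  bounded-but-not-percentage traits (e.g. stiffness) are clamped at zero
  only.
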