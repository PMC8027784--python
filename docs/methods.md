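# Methods

## The problem

A point source (a large urban fire involving hundreds of tonnes of roofing
lead) deposits metal-bearing particles over the surrounding neighbourhood,
preferentially downwind. Months later, the only durable record of that
fallout is the very surface of unconsolidated soil — tree pits, parks,
sidewalk cracks — sampled at ~1 cm depth and measured by field XRF.
`plumefall` reconstructs the spatial concentration surface from such a
survey, quantifies how much higher concentrations are inside the downwind
sector than outside it, and integrates that excess into a deposited-mass
inventory with uncertainty.

## Model

Let `y_i` be the Pb concentration (mg/kg) of sample `i` at source-centered
polar coordinates `(r_i, θ_i)` (km; compass degrees, North = 0, East = 90),
with soil type `k[i]` among five categories. Field concentration data have
a heavy right tail; the quarter-power transform `y → y^(1/4)` stabilises it
more gently than a log, keeping additive errors comparable across the
range. On the transformed scale:

    y_i^(1/4) = μ_{k[i]} + f(r_i, θ_i) + ε_i,     ε_i ~ N(0, σ²)

* `μ_k`: soil-type offsets with prior N(0, 1) under the sum-to-zero
  constraint Σ_k μ_k = 0, enforced by construction (4 free parameters).
  Without the constraint a constant could shuttle between `μ` and `f`.
* `f`: zero-mean Gaussian process with product kernel
  `α · exp(−(r−r′)²/ρ_r²) · exp(−2 sin²(π|θ−θ′|/360)/ρ_θ²)` — squared
  exponential in distance, periodic (period 360°) in bearing so the surface
  is continuous across the north seam. The GP has no explicit intercept;
  the overall concentration level is absorbed into `f` (which is why the
  posterior of `α` sits well above the *fluctuation* variance of the
  field).
* Scales: half-normal priors `ρ_r ~ N⁺(0, 1.5²)` km, `ρ_θ ~ N⁺(0, 1)`,
  `α, σ ~ N⁺(0, 6²)` in transformed units — weakly informative given that
  distances (km) and transformed concentrations are roughly unit scale.
  The positive-truncated reading of the normal priors is the conventional
  one for scale parameters.

## Inference

Both `f` and `μ` are Gaussian given the four scales, so they are
marginalised analytically:

    y | α, ρ_r, ρ_θ, σ  ~  N(0,  αK + σ²I + X C Xᵀ)

where `X` is the soil-type design in the free (sum-to-zero) coordinates
and `C` the implied prior covariance of the free offsets. MCMC runs over
only `(log α, log ρ_r, log ρ_θ, log σ)` — the log scale with the exp
Jacobian makes the target near-Gaussian — using an affine-invariant
ensemble sampler (emcee; 32 walkers; differential-evolution and snooker
moves, which handle the correlated `α`–`ρ` ridge). For each retained draw,
`μ` and then `f` at the data locations are drawn *exactly* from their
conditional Gaussians, so every retained draw is an exact joint posterior
draw of `(μ, α, ρ_r, ρ_θ, σ, f)` and every draw satisfies Σμ_k = 0 to
machine precision.

Sampler accounting: `ModelConfig(chains=4, iterations=3000)` retains
`chains × iterations/2 = 6000` draws, evenly subsampled from the
post-warmup walker pool (first 50% of sweeps discarded). One ensemble
sweep mixes less than one iteration of a gradient-based sampler, so the
`steps` setting can raise the internal sweep count without changing the
retained-draw budget; reduced-budget runs in the test suite use
`iterations=1200, steps=2400` (= 4 × 600 retained). Convergence is gated:
`fit` computes rank-normalised split R-hat and bulk ESS over the walker
array (arviz) for the four sampled scales and raises a `ConvergenceError`
carrying the diagnostics if max R-hat > 1.05 or any ESS < 100.

The collapsed likelihood is cross-checked in the tests against
`scipy.stats.multivariate_normal` densities, and the GP conditioning
against brute-force conditioning of the dense joint covariance (1e-8).
During development the ensemble posterior was also compared with a long
adaptive random-walk Metropolis run; quantiles agreed to ~2%.

## Prediction and back-transformation

The field is reconstructed on a uniform 30×30 *polar* grid over
0.1 km ≤ r ≤ 1.5 km (polar uniformity makes ring and sector averages
direct; area weighting is handled explicitly in all integrals). The disc
r < 100 m is excluded: it contains no data, and reconstruction there would
be pure extrapolation. For each retained draw, `f̃` at the grid is drawn
from the exact GP conditional given that draw's scales and latent `f`;
observation-level predictions add independent `N(0, σ_draw)` noise,
representing a typical soil type (μ = 0) so that sector comparisons are
pure spatial effects.

Summaries are back-transformed to mg/kg via the fourth power. `f̃` has no
sign constraint; the literal `f̃⁴` (an even function) is the default,
folding the rare negative tail onto small positive concentrations, and a
sign-preserving `max(f̃, 0)⁴` alternative is available behind a flag.
Quantiles (10/25/75/90%) are computed on transformed draws and mapped
through the monotone fourth power.

## Excess and inventory

*Plume excess* at radius r: the angular mean of the back-transformed field
inside the fixed downwind sector (260°–310°, open boundaries, set from
meteorology rather than fitted) minus the mean outside it, on the same
grid ring — ring-wise differencing subtracts any radially-symmetric
background at the same distance. *Inventory*: the excess concentration is
converted to areal loading (× depth × bulk density) and integrated over
the sector by polar quadrature, per posterior draw:

    M(R) = depth · ρ_bulk · ∫∫_sector [f̃⁴(r,θ) − outside-mean(r)] r dr dθ

Quadrature uses exact cell measures — radial cells contribute
`(b²−a²)/2` over their clipped extent and angular cells the exact fraction
of the cell overlapping the sector — so a constant field integrates
exactly at any resolution. The integral runs from r = 0 with the innermost
ring's excess carried over the small unsampled central disc (the inventory
is stated "within a circle of radius R"); `inner_exclusion=True` starts at
the 0.1 km reconstruction boundary instead. Sector *averages* are reported
over 0.1 < r < R at either the mean-response (f) or observation (y) level;
the mass integral always uses the f level, since independent noise
integrates to zero over an area.

Unit conventions: mg/kg and ppm are synonyms here. Defaults
depth = 0.01 m and bulk density = 2,000 kg/m³ — the density value is the
one consistent with both standard worked conversions
(200 mg/kg ↔ 4,000,000 µg/m² at 1 cm; 1,000,000 µg/m² over 5 cm ↔
10 mg/kg); both are parameters.

## Synthetic surveys and what they do (not) show

The generator emulates the survey design: 58 samples on rings of 400 m
(24) and 1,000 m (34) with small angular jitter, 42 samples uniform in the
downwind wedge (r ∈ [0.15, 1.2] km), soil-type frequencies fixed at
55/23/7/13/2 (tree pit / park / garden / sidewalk crack / plant pot). The
truth field on the quarter scale is

    baseline + GP(α=0.6, ρ_r=0.6, ρ_θ=0.6) + bump(r, θ)

plus soil offsets (sidewalk cracks highest at +1.2, parks lowest at −0.9,
sum zero) and N(0, 0.35²) noise. Choices made here: baseline 3.44
(back-transforms to ≈140 mg/kg, a realistic urban median); the plume bump
is *deterministic* — amplitude 1.2 at bearing 285°, Gaussian in angle
(sd 20°) and in radius (scale 0.5 km) — so each replicate has a known
ground truth; a 5 mg/kg reporting floor stands in for an XRF detection
limit on rare deep-negative draws. The bump alone carries ≈815 kg of
excess Pb within 1 km at default depth/density.

Each replicate's *true* inventory is computed by the same sector
integral applied to its noise-free truth field on a fine grid. Because the
GP itself moves mass between sectors, realized true inventories vary
widely around the bump-only value (roughly ±700 kg across seeds); the
estimator targets the realized field, so coverage of the credible interval
is the meaningful check, not proximity to the bump-only number. All
randomness descends from one seed through `SeedSequence` spawning;
regeneration is bit-identical.

What passing these calibrations does **not** show: fidelity to any real
city's soil (no streets, no legacy-contamination geography, no spatially
clustered soil types), correctness of the 1 cm depth / 2,000 kg/m³
conversion for a particular site, or robustness to XRF measurement bias —
the generator shares the fitted model's additive quarter-scale structure
by construction, which is exactly what makes it a *calibration* tool.

## Calibration conventions and known limitations

* Hyperparameter recovery is checked on surveys simulated from the model
  itself (no bump — the deterministic bump is not a GP draw and would bias
  the scale posteriors) directly on the transformed scale. Coverage uses
  90% *highest-density* intervals: the `α` posterior is strongly
  right-skewed along the `α`–`ρ` smoothness ridge, where equal-tailed
  intervals are a poor summary (HDI is the arviz default for the same
  reason). Inventory coverage uses central 95% intervals.
* Frequentist coverage at a fixed truth is not exactly the Bayesian
  nominal level; with n = 100 and weak priors the measured HDI coverage of
  the scales is in the 80–95% band, and simulation-based calibration with
  prior-drawn truths is consistent with nominal.
* Numerical details: diagonal jitter `1e-9·α` on covariance factorisations
  (10× that on conditional covariances); kernel formulas take r in km and
  θ in degrees exactly as written (the 360 in the periodic kernel assumes
  degrees); angles are stored in [0, 360) and compared by minimal angular
  difference; sector boundaries are open, so boundary bearings count as
  outside, and cells straddling a boundary contribute fractionally to both
  sides in all integrals.
* Problem sizes used by the test suite: 20 replicates for scale-parameter
  coverage and 10 for inventory coverage at 4 × 600 retained draws, 300
  field draws on the 30×30 grid, truth quadrature on a 30–60 node polar
  grid. These are the package's reduced standard budgets; the full-budget
  defaults (4 × 1500 draws) behave the same, only slower.
* The fitted `α` is not interpretable as fallout signal strength: it also
  absorbs the overall concentration level (the GP has mean zero).
* Predictions inside r < 100 m, geodesy beyond a few km, deposition
  physics, and health-exposure modelling are out of scope.
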