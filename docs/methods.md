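# Methods

`beechroma` implements the quantitative machinery of a comparative bee
colour-psychophysics experiment: a trichromatic colour-hexagon model
that turns reflectance spectra into perceptual stimulus metrics, and a
random-effects multinomial choice model that turns bee choice records
into log-odds tables and species contrasts.  A synthetic-data layer
generates pigment-mixture stimuli and choice datasets so the whole
pipeline runs, and can be validated, without any external data.

## Colour-hexagon model

All spectral quantities live on a common 1 nm grid over 300–700 nm
(linear interpolation, no extrapolation).  Illuminants are held in
photon (quantal) units; energy-unit input such as the packaged CIE D65
table is converted once at load (photon flux ∝ energy × λ).

For a stimulus with reflectance I_S(λ) viewed against background
I_B(λ) under illuminant D(λ), each receptor i ∈ {UV, B, G} with
sensitivity S_i(λ) has quantum catch

    P_i = R_i ∫ I_S(λ) D(λ) S_i(λ) dλ,     R_i = 1 / ∫ I_B(λ) D(λ) S_i(λ) dλ.

The von Kries factor R_i adapts each channel to the background, so the
background itself always has P = 1 and excitation E = P/(P+1) = 0.5 in
every channel.  Integration is by the trapezoid rule; at 1 nm over
smooth integrands the quadrature error is negligible relative to every
tolerance used here.

Hexagon coordinates follow the standard trichromat construction

    x = (√3/2)(E_G − E_UV),    y = E_B − (E_UV + E_G)/2,

placing the adapted background exactly at the origin.  Colour contrast
between two loci is their Euclidean distance; because the background
and the hexagon centre coincide under von Kries adaptation, "distance
to the background" and "distance to the centre" are the same quantity
and are implemented as distance from the origin.

Derived metrics per stimulus:

- **intensity** I = (E_UV + E_B + E_G)/3;
- **green contrast** GC = E_G − 0.5 (the achromatic channel bees use
  for detection and motion);
- **spectral purity** SP = d(stimulus, origin) / d(spectral locus at
  λ_d, origin), where λ_d is the dominant wavelength.

### Spectral locus and dominant wavelength

The spectral locus is tabulated at 1 nm over 300–650 nm.  A
monochromatic light needs a flux convention; the default
`max_distance` mode chooses, per wavelength, the flux that maximises
the locus distance from the origin, by bounded scalar search over the
**normalised peak catch** in [10⁻³, 10] (log scale).  Two properties
motivated this domain:

- expressing the bound in catch relative to the adapting background
  (catch 1) rather than in absolute flux makes the locus — and hence
  SP — exactly invariant under rescaling the illuminant, as von Kries
  adaptation requires;
- an effectively unbounded search is degenerate: visual-pigment
  templates have long shallow tails, so at extreme flux two receptors
  saturate while the third is still rising and the locus of *every*
  mid-spectrum wavelength creeps toward a hexagon corner.  Capping the
  peak catch one order of magnitude above the background's keeps the
  search inside the physiologically meaningful response range.

A `fixed_flux` mode is available for sensitivity analysis; the mode is
recorded in the table.

λ_d is found by intersecting the ray from the origin through the
stimulus locus with the locus polyline (exact segment intersection,
linearly interpolating λ within the bracketing segment).  Stimuli
closer to the origin than 10⁻³ hexagon units are flagged *achromatic*
(SP = 0); rays exiting between the locus endpoints (the bee-purple
sector) are flagged *non-spectral* and SP raises unless the caller
opts into the endpoint-line ("purple line") denominator.  If a ray
intersects the polyline more than once (possible near the UV curl of
the horseshoe), the outermost intersection is used — the inner branch
would assign a purity above 1 to points outside it.

Note one consequence of the max-distance convention: bright
monochromatic lights in the 420–460 nm band recruit the green
receptor's flank and shift blue-green-ward, so broadband blue stimuli
align with a locus ray near 405–410 nm rather than with their
reflectance peak.  λ_d values are therefore convention-dependent and
only comparisons *within* one convention are meaningful.

### Receptor sensitivities

Measured sensitivity curves for the study species are not bundled;
receptors default to the Govardovskii et al. (2000) A1 visual-pigment
nomogram (alpha plus beta band, max-normalised), parameterised only by
λmax: (344, 436, 544) nm for *Apis mellifera* and (356, 428, 519) nm
for the *Trigona spinipes* proxy used for stingless bees.  Users can
substitute measured curves.  The composite UV template peaks up to
~2 nm short of its nominal λmax because the beta band rides on the
short-wavelength flank; this is a property of the nomogram, not an
implementation artefact.

## Choice model

Each experimental condition (tested parameter × trained level) yields,
after filtering to each bee's first training round and first five
unrewarded test choices, 20 bees × 5 choices per species.  Choices over
the four stimulus levels are modelled with a baseline-category logit:
with level 1 as baseline, the log odds of choosing level k ∈ {2,3,4} is

    η_k = β0_k + β1_k · species + u,      u ~ N(0, σ²),

where `species` indicates the second species and u is a per-bee random
intercept shared across the three category logits.  This is the
simplest random-term structure that imposes a correlation on all
choices made by one individual; a per-category intercept would triple
the integral dimension for data that cannot identify it (100 choices
per species).  Conditional on u, a bee's choices are independent
draws — no within-bout sequence or arena-position effects are
modelled.

The marginal likelihood integrates u out by Gauss–Hermite quadrature
with a fixed node count (default 21; configurable).  With a single
scalar random effect and σ below ~1, the non-adaptive rule at this
node count is accurate far beyond the reporting precision, and fixed
nodes plus fixed, documented starting values (smoothed per-species
empirical log count ratios; σ₀ = 0.3) make every fit deterministic.
σ is optimised directly on [0, 5] (L-BFGS-B, three-point
finite-difference gradients), so null-like data put σ at a clean zero
boundary.  The full (species) model is additionally warm-started from
the reduced fit with species terms at zero and the better optimum
kept, which guarantees a non-negative likelihood-ratio statistic.  A
line-search abort at a point whose projected gradient is below 10⁻³
is still accepted as converged: this occurs under separation, where
the profile is flat in the diverging direction.

Standard errors come from the pseudo-inverse of a central-difference
Hessian of the negative marginal log-likelihood; per-species log odds
for the second species combine β0 and β1 by the delta method.
Intervals are Wald (estimate ± 1.96 SE) with two-sided significance
stars at 0.05 / 0.01 / 0.001.  The species effect is tested by the
likelihood-ratio test with df = 3 (the three category-by-species
terms).  Predicted choice proportions are the softmax of the
fixed-effect utilities at u = 0 (population level).

**Separation.**  If a species never chooses some level, the
corresponding log odds diverge.  No continuity correction is applied:
the fit carries an explicit separation warning, the reported estimate
is large with a commensurately enormous Wald SE, and downstream
summaries use robust statistics (below).  Fabricating finite values
here would misstate the evidence.

No multiple-testing adjustment is applied across the four condition
models; raw p-values are reported with a note, matching the analysis
design the package implements.

## Synthetic data

The generator emulates the study's stimulus manufacture and test
design; it is a modelling stand-in, not a physical pigment model.

**Pigments.**  Two synthetic blue artist pigments (broadband Gaussian
reflectances peaking at 430 and 470 nm over a 0.05 pedestal) plus
spectrally flat white (0.90) and black (0.05).  Default mixing is the
convex combination of reflectances; a single-constant Kubelka–Munk
mode (linear mixing of K/S = (1−R)²/2R) is available to probe
sensitivity to the mixing law.  Real powder mixing is nonlinear, but
the downstream analyses need stimuli with *controlled metrics*, not
physically exact optics.

**Series design.**  A 4-level series varies one parameter (SP or I)
strictly monotonically while holding the other and the hue fixed.
Two facts shape the search: intensity is monotone in the white share
of the achromatic admixture, and purity is monotone in the blue
weight at held intensity, so both targets are met by nested 1-D root
refinement (Brent) after a coarse feasibility scan.  Hue, however,
cannot simply be inherited: diluting one blue blend with white/black
rotates the chromatic direction by ~15 nm across a series (the
excitation transform bends mixing lines), so the balance of the two
blue pigments is steered per level until every stimulus shares the
dominant wavelength of a mid-series reference.  Designed series come
out with hue spread < 0.1 nm and the held parameter exact to solver
tolerance.  Defaults — hold I = 0.45 for the purity series, hold
SP = 0.25 for the intensity series — were chosen once from a
feasibility scan of this pigment gamut (purity ceiling ≈ 0.43 at
I = 0.45, falling with I).  Validation tolerances default to 5 nm on
hue and 0.02 on the held parameter.  A seed jitters the four level
targets inside the feasible band; the search itself is deterministic
given the seed.  Infeasible requests (e.g. a held purity above the
gamut ceiling) raise an error naming the binding constraint.

**Choice simulation.**  Mirrors the fitted model exactly: per bee a
shared intercept shift u ~ N(0, σ²) on the non-baseline logits, then
independent softmax draws; defaults 20 bees × 5 choices per species
per condition.  Because generator and fitter share the random-effect
structure, recovery studies are well-posed.

**Arena.**  Stimulus positions are sampled uniformly without
replacement from the 6 × 6 grid over the inscribed square of the
50 cm circular arena (row-major from top-left, coordinates at cell
centres), re-randomising until all pairwise distances meet the 3 cm
minimum.

What the generator does **not** emulate: learning dynamics across
foraging bouts, position or sequence effects within a test, measured
pigment spectra or the measured arena background, and real
(nonlinear) powder optics.  Passing tests therefore demonstrate the
correctness and calibration of the *analysis machinery* under the
study's design, not properties of the original biological data.

## Monte-Carlo validation

Two simulation studies validate the inference chain end to end; both
are seeded and deterministic.

- **Null calibration**: 20+20 bees × 5 choices, both species at
  chance, σ = 0.5; across 500 replicates the species-LRT rejection
  rate at α = 0.05 should sit in [0.03, 0.07].
- **Recovery under a strong species effect**: Apis log odds
  (2.0, 3.4, 4.0) vs Tetragonula (0.2, 0.7, 0.9), σ = 0.5, 200
  replicates.  Reported are pooled Wald 95 % CI coverage (target
  [0.90, 0.98]) and the **median absolute bias**, defined as the
  median across the six log-odds parameters of |median(estimate) −
  truth|.  The median-bias form is deliberate: the Apis baseline level
  has choice probability ≈ 0.011, so roughly a quarter of replicates
  never observe it and the MLE diverges; means over replicates are
  then meaningless, while the robust median bias (~0.11) and coverage
  (separated replicates have near-infinite CIs that always cover)
  remain informative.  The same scenario's LRT rejection rate (> 0.5,
  empirically ≈ 1) against the ~5 % null rate is the power-asymmetry
  check.

The test suite runs these at 500 and 200 replicates; the acceptance
script reports the same quantities at 300 and 150 replicates, sizes
chosen to keep a full from-scratch rerun compact while leaving the
binomial noise well inside the target bands.

## Known limitations

- Receptor curves are nomogram stand-ins; absolute SP/I/GC values will
  shift with measured sensitivities (rank orders are robust in the
  blue region).
- λ_d and SP depend on the spectral-locus flux convention (see above);
  the package records the convention in its outputs.
- The fitter supports exactly two species and four levels, the study's
  design; the quadrature is one-dimensional by construction.
- Log-odds estimates under separation are reported as large finite
  numbers with huge SEs rather than ±∞; treat them as "diverged", as
  the attached warning says.
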