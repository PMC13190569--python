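# Methods

This note documents the model, its parameters, the synthetic-data
conditions, and the numerical and design choices behind `edfm`.

## The daily loop and its assumptions

The simulator advances a single representative plant of a uniform stand
through one day per step. The step order is fixed: fusion → water
stress → assimilate supply → allocation → thermal time → organ
expansion → morphology rebuild and light capture → Vcmax feedback.
Supply uses the *previous* day's light capture and photosynthetic
capacity. This one-day lag is a deliberate serialization: light capture
depends on morphology, morphology on carbon, and carbon on light
capture, so a same-day coupling would require a fixed-point iteration
with no observable benefit at daily resolution.

Assumptions worth keeping in mind:

- **Carbon is the only currency.** No nitrogen or other nutrients; no
  respiration or reserve pool — assimilate allocated beyond an organ's
  potential increment that day is simply not converted to structure.
- **The stand is uniform.** One plant geometry is replicated on a 3×3
  periodic grid and rays are cast over the centre ground cell, so
  leaves reaching past the plant's own cell are compensated by
  neighbours' leaves reaching in. Without this, interception collapses
  for any plant whose leaves are longer than the cell side.
- **Leaves are opaque single-scattering absorbers**; no transmittance,
  reflectance, or spectral detail. The overhead-sun vertical-beam mode
  is the default because it admits the Beer–Lambert closed form as an
  independent oracle; a hemispheric mode is intentionally out of scope.
- **Fusion is logged, not load-bearing.** The mechanistic loop runs on
  the physiological equations; `h_fusion` and the attention weights are
  computed (from the simulator's own synthetic scene in pure-simulation
  mode) and exported for interpretation or for an optional ridge
  readout, but no coupling equation from fused features into the
  physiology is assumed, because none is defined. This is flagged
  prominently: the architecture supplies the *mechanism* of adaptive
  weighting, not trained weight values.

## Physiology

- **Thermal time.** ΔPDT = max(0, T̄ − T_base)/pdt_norm with
  T_base = 8 °C and pdt_norm = 17 °C·day, so one physiological day
  elapses per calendar day at 25 °C. PDT is nondecreasing by
  construction and drives all developmental schedules.
- **Water stress.** WSF = ((θ − θ_wp)/(θ_fc − θ_wp))^γ · (1 + ψ_root)
  with θ clamped into [θ_wp, θ_fc] first (the response above field
  capacity is undefined otherwise; clamping keeps WSF ≤ 1 + ψ_root and
  monotone). ψ_root is quoted in MPa (−0.3 by default) but enters as
  the dimensionless modifier (1 + ψ_root); this unit tension is
  inherited from the source formulation and implemented as printed. A
  consequence: with ψ_root = −0.3 the stress factor never exceeds 0.7,
  so even irrigated plants realize at most ~70 % of daily potential
  growth. γ has no published value; default 1.0. WSF multiplies both
  assimilation and organ expansion — one of several defensible readings
  of "inhibits growth", chosen and held fixed.
- **Assimilate supply.** A full leaf-level biochemical model is not
  specifiable from available parameters, so supply is
  E = ε·I·min(1, Vcmax/Vcmax_ref)·WSF with ε = 1.0 g CH₂O per mol
  photons (≈3.3 g DM MJ⁻¹ PAR, a standard maize radiation-use
  efficiency) and Vcmax_ref = 60 µmol m⁻² s⁻¹. The function is isolated
  behind `daily_assimilation` so a mechanistic biochemistry module can
  drop in.
- **Sink strength.** R_organ is the organ's potential carbon-demand
  rate: the logistic slope k·L·(1 − L/L_max) divided by the
  carbon-to-size conversion (specific leaf area 180 cm² g⁻¹ for leaves,
  15 cm g⁻¹ for internode elongation). Dividing by the conversion puts
  leaves (cm²) and internodes (cm) on a common carbon scale. Allocation
  assigns the floating-point residual to the last organ with positive
  sink so ΣQ = E to one ulp; the season audit asserts 1e-9 relative.
- **Vcmax feedback.** Vcmax = Vcmax_ref·clamp(ratio, 0.2, 1.5)^β with
  β = 0.3 and ratio = intercepted/(PAR·ground area·0.7). The clamp
  prevents a seedling (tiny capture) from being driven into a
  starvation spiral; β < 1 keeps the feedback gentle.

## Morphology

- **NURBS machinery.** Clamped knot vectors on [0,1], Cox–de Boor basis
  and derivative recursions, rational evaluation by the quotient rule.
  No external NURBS library is used; the evaluation path is
  cross-checked in tests against an independent textbook recursive
  basis summation, and circular arcs are exact rational quadratics
  (quarter-cylinder area matches π to 1e-4 at quadrature order 16).
- **Area quadrature** is composite Gauss–Legendre per knot span —
  splines are only piecewise smooth, and quadrature across breakpoints
  stalls at ~1e-3 relative error while the composite rule is exact to
  machine precision on polynomial spans.
- **Leaf template.** Midrib a quadratic arc set by an inclination angle
  and a droop ("arch") term, half-width a sine bump along the midrib —
  simple, differentiable, NURBS-representable. Default control grid
  6×4, degrees 3×2.
- **Fitting.** Least-squares control points on the tensor-product basis
  with unit weights. The default parameterization projects points onto
  the cloud's two principal axes (exact only for planar laminae); a
  known per-point (u,v) parameterization can be supplied, under which
  refitting reproduces control points to 1e-6.
- **Rescaling.** Leaves scale uniformly about the attachment row
  (area is homogeneous of degree 2, so the closed-form factor √(target/
  current) is already the root; a bracketed root-find tightens it
  against quadrature round-off). Internodes scale the z axis exactly.
- **In the engine**, each leaf rank's unit template is tessellated once
  and thereafter only affinely transformed, so the daily scene rebuild
  is pure array work and the mesh area equals the organ's tracked size
  exactly. Leaf azimuths follow a 137.5° spiral and inclination varies
  from ~35° (lower ranks) to ~65° (upper), approximating how
  neighbouring plants' canopies interleave; without this dispersion a
  strictly distichous single plant self-shades unrealistically.
- **Ray tracing.** Vertical rays on a jittered grid; first hit (highest
  z) absorbs the ray's PAR share; triangles are bounding-box culled
  against the ray window and barycentric tests run as chunked matrix
  products. The Monte-Carlo standard error of the intercepted fraction
  is reported. The Beer–Lambert cross-check canopy places square
  horizontal leaves with centres uniform over the plot and insets the
  ray window by half a leaf, so every ray sees the same coverage
  probability and the expected fraction is 1 − (1 − a/A)^n ≈ 1 −
  e^(−LAI) with no edge bias.

## Plant architecture defaults

14 leaves and 10 internodes are instantiated at the seedling stage with
rank-staggered logistic midpoints (first leaf midpoint 10 PDT,
phyllochron 3 PDT; internodes from 16 PDT), a sine asymptote profile
over rank (mid-canopy organs largest; peak leaf 550 cm², peak internode
25 cm), k = 0.15 per physiological day everywhere, stand density
6 plants m⁻². The initial state shows three leaves at 5 % of their
asymptote and one internode; later-rank organs begin on their logistic
curves, which is what makes the "unlimited carbon ⇒ growth tracks the
potential exactly" invariant hold organ-by-organ. Organs that miss
their expansion window under stress do not catch up — the potential
increment is the curve difference, not the gap to the curve — which is
the standard determinate-growth reading and is what makes early drought
costly in the simulated seasons.

## Synthetic data: what it emulates, what it does not

- **Weather** is daily: a seasonal cosine for mean temperature with a
  symmetric diurnal range, optional Gaussian day-to-day noise, and a
  clear-sky PAR integral (half-sine diurnal course, default midday peak
  1800 µmol m⁻² s⁻¹ over 12 h ≈ 50 mol m⁻² d⁻¹) with optional
  multiplicative cloud noise. Noise defaults are zero so degenerate
  flat scenarios are exactly flat; the packaged drought/irrigated
  scenarios switch them on (T noise sd 1.2 °C, PAR cv 0.12).
- **Soil** is a three-layer bucket (0.3 m layers): temperature-driven
  ET extraction weighted by root fraction and relative availability,
  rain refilling the top layer with saturation excess cascading down,
  everything clipped to [θ_wp, θ_sat] = [0.10, 0.45] with field
  capacity 0.32. No lateral flow, no capillary rise.
- **Point clouds** sample the same lamina/cylinder parametric forms
  with Gaussian coordinate noise (emulating ±2 mm depth-camera error)
  and uniform-box outliers for the SOR filter to remove; ground truth
  is returned alongside, so measurement round-trips are testable.
- **Canopy images** are flat-shaded orthographic rasters (plant green
  on soil brown) — sufficient for the hand-crafted cover/texture
  descriptors, with no radiative-transfer realism.
- A single global seed fans out to per-generator child streams via
  `SeedSequence(seed, spawn_key=(stream,))` with frozen stream ids, so
  adding a generator never shifts existing streams.

Passing tests on these data demonstrate the *mechanisms* — conservation,
monotonicity, feedback topology, oracle agreement — not field accuracy.
Published field-scale error levels were obtained with trained deep
encoders on a season of real sensor data that is not distributed; the
hand-crafted descriptors here implement the same interfaces
deterministically and a registry hook lets trained encoders plug in.
For the same reason the packaged benchmark comparison table ships as a
transcribed fixture: the package recomputes the percent-reduction
arithmetic over it, it does not re-derive the underlying RMSEs.

## Evaluation choices

- NRMSE normalizes by the observation mean (the magnitudes of published
  organ-trait NRMSE values are consistent with mean normalization);
  range normalization is available by flag.
- The benchmark table's plant-height RMSE is kept in mm as tabulated;
  one prose source says "cm" once — the discrepancy is recorded, not
  resolved.
- `fit_logistic_growth` initializes L_max at 1.05·max(L), PDT_m at the
  half-max crossing, and k from the slope of the log-linearized logit,
  then runs Levenberg–Marquardt; standard errors come from the fit
  covariance, and data that never reach half the fitted asymptote set
  an explicit identifiability flag rather than failing silently. A
  100-seed Monte-Carlo at the test conditions (n = 60, 2 % noise)
  bounded the k recovery error at 7.3 % max; the test tolerance is
  frozen at 10 %.
- Sensitivity analysis reports both one-sided ±20 % coefficients and
  their mean, since S is direction-dependent for nonlinear responses.
  "Silking" is operationalized as the first day PDT ≥ 70 (the metric is
  read from the season's last day if never crossed). Under the packaged
  water-limited scenario |S(ψ_root)| ≈ 1.3 for LAI at silking and
  |S(T_base)| ≈ 0.06; the k coefficient is larger than ψ_root's here
  because a faster potential schedule compresses the expansion window
  exactly when drought makes carbon scarce — a scenario-conditioned
  result, the robust qualitative claim being water-response dominance
  over the phenological base temperature.

## Problem sizes

Default test and acceptance runs use 120-day seasons, 800 rays per
daily interception call (20,000 for the Beer–Lambert cross-check,
where the Monte-Carlo standard error must be small), 48×48 internal
canopy rasters upsampled to the 224×224 descriptor input, and ~1,200
sampled points per self-observed cloud. These sizes keep a full season
at a few seconds on one CPU while leaving all Monte-Carlo checks
comfortably inside three standard errors.

## Known limitations

- No nutrient dynamics, respiration, senescence, or reproductive sink;
  LAI never declines.
- The distinct "7-day growth prediction" mode is just the engine run
  ahead on supplied forecast weather — no separate algorithm.
- Smoothing-vs-normalization order for environmental series is
  smooth-then-normalize (the alternative is a config flip away).
- The concatenated attention scoring (an alternative formulation kept
  for completeness) shares no parameters with the canonical
  per-modality tanh scoring; the two coincide only in the documented
  block-sparse, tanh-bypassed case that the tests exercise.
- `eval_surface` and the tessellator are pure-Python loops over
  parameter samples: fine at the engine's cached-template usage, slow
  if called per-point on large grids.
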