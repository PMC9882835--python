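# Methods

`hyphoshell` implements three connected pieces of quantitative machinery for
fungal tip growth: subresolution cell-wall (CW) thickness mapping from
two-channel mid-slice images, thin-shell estimates of wall elasticity and
turgor, and a feedback ODE model coupling exocytic-vesicle (EV) delivery,
wall thickness and plastic expansion.  A synthetic-data module generates all
inputs with known ground truth, so every estimator is scored against the
quantity it claims to measure.

## Thickness mapping

The wall (50–250 nm) is far below the resolution of a ~200 nm-sigma PSF, but
its two faces are labeled in *different* channels: a membrane marker on the
inner face and a lectin on the outer face.  Each channel therefore contains a
single diffraction-limited peak across the wall, and the distance between the
two fitted peak *centers* — which localize far below the PSF width — is the
local thickness `h`.

Pipeline per image:

1. **Segmentation.** The membrane channel is smoothed (sigma 1.5 px), Otsu
   thresholding locates the cell, and the longest closed iso-contour is
   refined onto the intensity ridge by parabolic fits along local normals
   (two passes, with light along-contour smoothing).  Normals come from
   centered tangents over ±3 contour points.  A contour is rejected when the
   foreground does not stand at least three background standard deviations
   above the background mean (flat or pure-noise images).
2. **Profiles.** At every contour point, both channels are sampled by
   bilinear interpolation along the outward normal (step = half a pixel,
   half-length ≈ 3 PSF sigma + 400 nm).  Negative positions are inside the
   cell.
3. **Peak model.** Each profile is fitted with a Gaussian plus an
   error-function background step whose edge is tied to the Gaussian center.
   This is the physical form of the inside/outside intensity asymmetry: the
   cytoplasmic (or medium) background is a step at the labeled face,
   convolved with the same PSF as the line source.  A plain Gaussian on this
   profile is biased by >10 nm toward the bright side; the step model removes
   the bias (tests cross-check against a grid-search oracle).  Fits are
   gated: quality (an R²-style score) ≥ 0.8 and width within [0.5, 3]× the
   nominal PSF sigma, both configurable.
4. **Chromatic correction.** `h = (outer center − inner center) − s·n̂`,
   where `s` is the calibrated channel-2 shift vector and `n̂` the outward
   normal.  Non-positive corrected distances are flagged invalid.
5. **Smoothing.** Accepted values are smoothed along the arclength with a
   Gaussian kernel of 500 nm (the along-surface resolution of the method);
   flagged points carry no weight.  Tip/side summaries use windows
   |s′| ≤ 1 µm and 5 µm ≤ |s′| ≤ 10 µm, with s′ the arclength distance from
   the tip apex.

For *absolute* geometry (radii for strain measurements, not thickness), the
fitted membrane position carries a first-order inward bias of
`sigma² / (2 R_curv)` — the peak of a convolved curved line shifts toward the
center of curvature.  `measure_capsule_fitted` adds this term back; it
cancels between the two channels in the thickness difference, which is why
thickness needs no such correction.

The tip of a closed contour is the extreme point along the principal axis.
A symmetric capsule has two such candidates; an optional tip hint (known for
phantoms, and in practice from the growth direction in a time lapse)
disambiguates.

**Accuracy.** On noise-free phantoms the estimator bias is < 3 nm across
h ∈ [50, 250] nm.  Under the default imaging conditions (below), per-point
scatter is ~8–10 nm and the smoothed mean absolute error is ~2 nm; error
grows monotonically as the photon budget shrinks.

## Synthetic phantoms and the imaging model

The phantom is a capsule (tube of radius 1–1.5 µm with hemispherical caps)
whose midline may be bent; polyline corners are rounded (Gaussian smoothing,
sigma 0.15 µm) so normal offsets at the cell radius stay well defined.  The
two wall faces are infinitely thin curves: the inner contour, and the outer
contour displaced along the outward normal by the thickness profile h(s′).
The geometric offset agrees with an independent nearest-distance oracle to
better than 0.01 nm.

Rendering, per channel: the face curve is deposited as an anti-aliased line
source directly on the native pixel grid (bilinear deposition preserves the
line centroid exactly), backgrounds are added from anti-aliased polygon
coverage (4× supersampled) — cytoplasmic counts inside the cell for the
membrane channel, medium counts outside for the lectin channel — and the
whole frame is convolved with that channel's Gaussian PSF.  Channel 2 is
translated by the chromatic shift (applied to the geometry, so no
interpolation error), then Poisson shot noise and Gaussian read noise are
added from a single seeded generator.  Defaults: 65 nm pixels, PSF sigma
200 nm in both channels, peak signal ≈ 200 counts, chromatic shift
(30, −20) nm, backgrounds 50/2 counts (membrane in/out) and 2/15 counts
(lectin in/out), read noise 3 counts.  These make the 10–20 nm precision
target non-trivial but attainable.  Background levels are specified in
counts and do not scale with `photon_scale`; the linearity property of the
renderer therefore refers to the line signal (tested with backgrounds set
to zero).

Not emulated: the third dimension and focus loss, photobleaching,
fixed-pattern noise, multi-cell scenes, and any finite thickness of the
label layers (peak distance is treated as `h`, as in the measurement
convention the package implements).  Passing tests on phantoms therefore
validate the estimator under the stated optical model, not those real-data
nuisances.

Deflation pairs scale the radius by 1/(1+strain_radial) and the pole-to-pole
length by 1/(1+strain_longitudinal); because the caps scale with the radius,
the midline is rescaled so the *total* length shrinks by exactly the
requested strain.  Both frames share one raster, so they are registered.

## Wall mechanics and turgor

Elastic strains are (turgid − deflated)/deflated per axis.  Force balance in
a pressurized thin shell gives

    Y_side / P = R1 / (h_side · strain_radial)        (cylinder)
    Y_tip  / P = Rt1 / (2 · h_tip · strain_tip)       (hemisphere)

— the factor 2 is the sphere/cylinder hoop-stress ratio, and the isotropic
prediction for radial:longitudinal strain is exactly 2.  The surface modulus
is `sigma = h·Y` (1 nm·MPa = 10⁻³ N/m).

Turgor comes from an osmotic chain: (i) the external molarity `c̃₀` at which
osmotic shrinkage equals ablation shrinkage is found by piecewise-linear
interpolation of the shock series (no extrapolation — the curve crossing
must be bracketed); (ii) `c̄₀ = c̃₀ + c_media` is the internal osmolyte
concentration at zero turgor; (iii) a Boyle–van 't Hoff correction with
inaccessible volume fraction β maps it to the turgid state,
`c̄₁ = c̄₀·(V₀/V₁ − β)/(1 − β)`; (iv) `P = (c̄₁ − c_media)·R·T`.  With the
reference inputs (c̃₀ = 0.808 M, c_media = 0.112 M, V₀/V₁ = 0.70, β = 0.22,
T = 298 K) this chain gives c̄₁ = 0.566 M and P = 1.1 MPa, and 1.3 MPa with
β = 0.  The van 't Hoff temperature defaults to 298 K (growth at 25–28 °C;
the ~1% spread is below the result's rounding).

## The tip-growth model

State: tip wall thickness `h` (nm), apical EV concentration `EV` (arbitrary
units; the scale is a gauge absorbed by γ and ϕ), remodeler concentration
`c`, plastic strain rate `G` (min⁻¹).

    dh/dt     = γ·EV − G·h                      mass balance
    G         = μ·c·(PR/(Yh) − ε), clamped ≥ 0  elastoplastic flow
    dEV/dt    = ϕ·G − α·EV                      strain-rate feedback
    d(hc)/dt  = β·EV − G·h·c                    remodeler balance

`PR/(Yh)` is the dimensionless elastic strain (P, Y in MPa, R in µm, h in
nm).  G is clamped at zero below the yield strain ε — plastic flow is
irreversible — which makes the algebraic-G formulation the reference.  The
equivalent closed system in (h, EV, G), with η = βμPR/Y and θ = εY/(PR),

    dG/dt = η·EV·(1−θh)/h² − γ·(2−θh)/((1−θh)h)·G·EV + G²/(1−θh)

is kept for fidelity and is valid only while θh < 1; integrations of the two
formulations agree to 10⁻⁶ relative (tested).  Integrator: LSODA, rtol 1e−8,
atol 1e−10, max step 1 min.

**Fixed point.**  h* = γϕ/α, c* = β/γ, G* = ηϕ(1−θh*)/(α h*²),
EV* = ϕG*/α, existing iff θh* < 1.  h* depends only on (γ, ϕ, α): thickness
homeostasis is structural, independent of turgor and stiffness.  A scan of
the reduced equilibrium residual confirms the growing fixed point is unique.

**Stability.**  After scaling out the gauge freedoms, linear stability at
the fixed point depends on exactly two dimensionless groups:
`g = G*/α` (wall renewal rate over vesicle turnover) and `x = θh*`
(yield-to-stress ratio).  The strain-rate feedback stabilizes the point when
turnover is fast relative to wall renewal — roughly g ≲ 0.3 for x ≈ 0.55,
with the stable region shrinking as x → 1.  Replacing the feedback with a
constant EV source leaves the (h, hc) subsystem a saddle (its Jacobian
determinant is negative for *all* positive parameters — instability is exact,
not sampled), and a source proportional to the elastic strain PR/(Yh) is
unstable whenever x > 1/2.  The calibration below pins
x = 1 − ΔP_stop/P ≈ 0.55 > 1/2: the observation that growth stops under a
pressure drop smaller than half of turgor places the cell precisely in the
regime where only strain-rate feedback yields stable growth.  Random
parameter draws for the stability tests sample this physiological regime
(g ∈ [0.1, 0.25], x ∈ [0.52, 0.65]); uniqueness of the fixed point is tested
over unrestricted positive draws.

**Calibration.**  `calibrate` inverts the closed forms so the fixed point
reproduces chosen observables exactly.  The canonical wild-type set uses
tip thickness h* = 65 nm, turgor P = 1.1 MPa, tip modulus Y = 64 MPa, tip
radius R = 1.2 µm, and a yield strain set by the smallest growth-arresting
osmotic dose (0.2 M sorbitol, ΔP = 0.496 MPa at 298 K):
ε = (P − ΔP)·R/(Y·h*) = 0.174.  The remaining two timescales are the
package's own choice: G* = 0.3 min⁻¹ and α = 1.5 min⁻¹, selected inside the
stable regime so that de novo growth settles in 10–20 min, the observed
branching timescale (faster turnover converges too quickly, slower or
stronger growth leaves the stable region).  EV* is normalized to 1 and
c* to 0.5.  The slower closed-form example (γ=1, α=0.05, ϕ=3, β=0.5, μ=1,
ε=0.2) is retained in the tests for exact arithmetic — its fixed point
(h*=60 nm, G*=0.071875) is convenient — but note it sits at g ≈ 1.4, outside
the stable region, so it is not used for dynamics.

**Scenarios.**  All schedules are C¹ smooth-steps or exponentials:

* *branching* — de novo growth from 10% of (EV*, c*, G*) at h = h*:
  delivery and turnover start balanced, so EV and G rise monotonically and
  settle (within 2%) between 10 and 20 min, with h within ±10% of h*.
* *osmotic shock* — stepwise turgor drop at t = 5 min (default amplitude:
  the osmotic pressure of 0.2 M sorbitol) with exponential adaptation,
  τ = 6 min, chosen so growth restarts within 10–15 min.  Growth arrests
  immediately (strain falls below yield); EV decays more slowly (rate α) so
  deposition transiently exceeds expansion and the wall thickens ~20%
  before relaxing back to h* as turgor adapts.
* *secretion block* — the EV source ϕ is ramped to 7.5% and the sink α to
  5% over 3 min.  Both must drop, but not equally: scaling ϕ and α by the
  same factor leaves the fixed point (including EV*) exactly invariant and
  produces no perturbation at all, while cutting only the source drives a
  thin-wall runaway (growth continues on stored remodelers with no
  deposition).  With the source/sink ratio raised above 1 the system leaves
  the growing branch: EV collapses (half-life ~20 min), G reaches zero, and
  the wall thickens monotonically past the yield thickness 1/θ ≈ 118 nm
  toward several hundred nm over an hour — the thickening-and-ballooning
  phenotype of trafficking blocks.
* *obstacle* — turgor ramped down by 20% over 5 min, held 10 min, ramped
  back.  The drop is partial (strain stays above yield): EV and G dip to
  ~45% and recover fully, while the thickness excursion stays below 10% —
  thickness homeostasis in action.  Larger drops (≥ 40%) arrest growth
  outright and thicken the wall like a shock; the default models firm but
  survivable contact.

Kinematics: G is the surface growth rate divided by R², so a hemispherical
cap advancing at v creates surface at 2πRv and G = 2πv/R.

## Time-series statistics

* `relative_std`: sample (n−1) standard deviation over the mean.
* `cross_correlation`: mean over the overlap of centered products divided by
  the *full-series* (population) standard deviations, so the zero-lag
  autocorrelation is exactly 1; lags are capped at n/3.  Under this
  normalization the peak value for a delayed copy is near, but not exactly,
  1 (full-series means/SDs differ slightly from the overlap's); the lag
  itself is recovered exactly.  The white-noise envelope ±2/√n is a per-lag
  two-sigma band: at each lag, ≥93–95% of independent noise pairs fall
  inside it.
* `bleach_correct`: division by a fixed-cell reference normalized to its
  initial value; optionally a log-linear exponential fit of the reference is
  used instead of the raw trace, keeping reference shot noise out of the
  corrected signal.
* `fiducial_drift`: a local thickness extremum is localized per frame by
  parabolic subpixel refinement, converted to the lab frame as
  tip_position − s_mark, and the drift is the least-squares slope of that
  position versus time; the mark must persist ≥ 5 frames and stand above
  frame noise.  Zero drift means no advective backward wall flow — the mass
  balance above carries no advection term, consistently.

## Problem sizes and runtimes

Tests and the acceptance script use 50 phantoms of ~9 × 4.5 µm at 65 nm
pixels (~260 contour points each, two fits per point), 25–100 random
parameter draws for the stability/uniqueness properties, and 60–120-minute
model integrations on grids of 200–1200 points.  The full test suite runs in
about two minutes on one core; the acceptance script in about one.

## Known limitations

* The imaging model is 2-D and noise-stationary; real mid-slice data add
  focus drift, bleaching and label-layer offsets that the phantoms do not
  probe.
* The mechanical model is one-dimensional (a single tip compartment); it
  predicts no tip shape, and wall advection is neglected by construction.
* The secretion-block schedule fixes a source/sink ratio of 1.5; the
  terminal thickness tracks γ·EV₀/α_eff and is sensitive to that choice,
  so only its qualitative signature (EV collapse, monotone thickening) is
  asserted.
* `Y/P` estimates inherit the curvature correction `sigma²/2R`, which is
  first-order; radii measured this way are accurate to ~1–2% at R ≈ 1 µm,
  and strain ratios to ~10%.
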