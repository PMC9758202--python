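# Methods

## Models

All three scenarios solve the diffusion (or reaction–diffusion) equation
for the concentration of *bleached* molecules in two dimensions, with the
half-disk initial condition, and report integrated signals

* `S_B(t)`, `S_NB(t)` — double-normalised signal in the bleached and
  non-bleached half (0 and 1 at the bleach),
* `S_full(t)` — recovery after bleaching the whole circle.

**LLPS (semi-permeable circle).**  Domain of radius `R`, apparent
diffusion coefficient `D_app`, Robin boundary `−D ∂c/∂r = D h c` at
`r = R`, zero concentration of bleached molecules outside (they dilute
into a large, faster medium).  `h` (1/µm) controls the flux; `P = h·D` is
the permeability and `h⁻¹` the effective boundary thickness.  Radial
eigenvalues are the roots of `α J'_n(αR) + h J_n(αR) = 0`.

**Free diffusion.**  Permeable bleach circle `R_C` inside a reflecting
domain `R_L` (`J'_n(αR_L) = 0`; the conserved α = 0 mode gives the exact
plateaus `1 − R_C²/(2R_L²)` (half) and `1 − R_C²/R_L²` (full)).

**ICBS (reaction–diffusion).**  Free-diffusion geometry plus
pseudo-first-order exchange between a diffusing free pool and an immobile
bound pool (`k*_on`, `k_off`; equilibrium free fraction
`F_eq = k_off/(k*_on + k_off)`).  Each eigenvalue relaxes through a fast
and a slow branch with rates `w ± v`,
`w = (Dα² + k*_on + k_off)/2`, `v² = w² − k_off·Dα²`.

### Series assembly

For the half-disk initial condition only the azimuthally symmetric mode
and odd azimuthal orders contribute; odd orders enter the two halves with
opposite signs.  The curves are therefore assembled as
`S_B = M − X`, `S_NB = M + X`, with `M` the n = 0 (boundary-exchange)
series and `X` the odd-order (half-exchange) series with a factor 2 for
the ±n pairing.  The eigen-expansion identities `M(0) = 1/2` (LLPS; `1 −
R_C²/(2R_L²) − M(0) = …` in the reflecting geometry) and `X(0) = 1/2`,
required by the initial condition, are used as built-in convergence
diagnostics and hold to <1e-6 at the default truncation.

The hypergeometric factor of the half-disk projection,
`₁F₂(1+n/2; 1+n, 2+n/2; −x²/4)`, is evaluated through the identity with
`∫₀ˣ t J_n(t) dt`, which reduces to Bessel functions
(`x J_{n+1}(x) + n[∫₀ˣJ₀ − 2(J₁+J₃+…+J_n)]`) — stable at all argument
sizes.  The standalone `pfq` routine additionally keeps a Taylor branch
for small `x` and an arbitrary-precision (mpmath) branch for the
cancellation-prone window `20 < x < n + 10`; the model curves never enter
that window because radial eigenvalues of order `n` exceed `n`.

### Truncation and numerical choices

* Azimuthal orders up to `n_max = 41` (odd), with early stop once an
  order contributes less than `term_tol = 1e-9` relatively; the dropped
  tail is extrapolated (orders decay ~1/n²) and evaluation is refused if
  it exceeds 5·10⁻³ — the guard that keeps curves inside the 0.01
  envelope used for solver cross-validation.
* Radial eigenvalues per order are chosen adaptively so that
  `exp(−rate·t_min) < 1e-10` at the smallest evaluated time (minimum
  `roots_per_order = 60`).  For the reaction–diffusion model the slow
  branch of truncated high eigenvalues — bleached *bound* molecules that
  decay at `k_off` — is closed analytically with a
  `(1 − F_eq)·exp(−k_off t)` tail carrying the exactly known missing
  initial weight.
* Times below `t_min_frac·τ_D = 1e-4·τ_D` bypass the series and return
  the exact initial values; `τ_D = R²/(4D)`.
* Robin eigenvalues are bracketed by the interlacing of Bessel-function
  zeros and polished with Brent's method to |residual| < 1e-10 of local
  scale.  `h = 0` (zero eigenvalue) is not evaluated; the impermeable
  limit is exposed as `h = 1e-4/R`, where the dip saturates at 0.5.
* Dip depth of a model curve: minimum of `S_NB` on a log-spaced grid
  (default 320 points over 10⁻³–10²·τ_D) with parabolic refinement in
  log-time.  Time-rescaling symmetry (`D → cD`) is exact by construction
  for LLPS/free diffusion.
* Units are fixed: µm, s, µm²/s.  No unit inference anywhere.

### Finite-difference cross-check

`mochafrap.oracle` integrates the same problems with an explicit scheme
on a Cartesian grid with a masked disk (≥128 cells across the bleach
diameter, `D Δt/Δx² ≤ 0.25`).  The Robin condition is applied as a
boundary sink `D·h·c` weighted by the exact arc length of the interface
circle inside each boundary cell (arc segments whose nominal cell falls
outside the disk mask are shifted radially inward, and the concentration
is extrapolated from cell centre to the boundary face by `1/(1 + h d)`);
this avoids the staircase-perimeter bias of a naive ghost-node stencil
and was the design change that brought solver and series into <10⁻³
agreement.  Mass is conserved to machine precision in closed systems and
decreases monotonically with a Robin sink.  Optional Richardson
refinement (second run at half resolution) removes the leading O(Δx)
boundary error.  The series and the solver share no code beyond
elementary arithmetic, so their agreement (<0.01 required, typically
<10⁻³ at default resolution) validates both.

## Processing chain

Implements the standard half-FRAP normalisation ladder on per-frame ROI
means (bleached half, non-bleached half, background, unbleached
reference): reference/background division (cancels any per-frame decay
shared by all ROIs, e.g. acquisition photobleaching); an additive
constant restoring the non-bleached half to its pre-bleach level
(corrects bleach leakage); pixel-count weighting (particle numbers);
double normalisation by the bleached-molecule number; the +1 offset for
the non-bleached half; and rescaling by `1/(1 − X_immobile)`.

Choices the procedure leaves open, resolved here:

* `X_immobile` is the mean offset between the two halves over the
  trailing 10 % of frames, with a plateau check
  (|slope| < 10⁻³/frame on both curves; a warning flag otherwise).
  The same `1/(1 − X)` rescaling is applied to both halves.
  Offsets below −0.05 are warned about and clamped to zero.
* Replicates are averaged after dividing each time axis by the structure
  radius squared, linear interpolation onto the union grid clipped to
  common support, and multiplying the averaged axis by the squared mean
  radius.  Linear interpolation is inaccurate only across the first
  coarse frame step at the √t-like onset; the dip region is unaffected.
* Dip depth: Savitzky–Golay smoothing (order 2, window 21) of the
  stage-V non-bleached curve, minimum searched over the post-bleach
  interior excluding half a window at each end; shorter traces require an
  explicit smaller window.
* The point estimate comes from the averaged smoothed curve; the
  significance test consumes per-experiment dips (each smoothed
  individually).  The test is a one-sided two-sample Student's t-test
  with pooled variance computed from summary statistics, so a (mean, SD,
  n) summary and the full sample give identical p-values; a Welch variant
  is available.  Degenerate zero-variance/equal-mean input returns
  p = 0.5 by convention.
* Classification at level α = 0.05 against a reference dip summary
  (packaged default 10 ± 3 %, n = 7 — a *measured* free-diffusion
  reference, user-replaceable): `LLPS` if the dip exceeds the reference
  mean and p < α; `ICBS-consistent` if the dip is within one standard
  error of the reference mean and p ≥ α; `inconclusive` otherwise.

## Synthetic data generator

`mochafrap.synthetic` renders ground-truth model curves into raw ROI
traces with the artifacts the chain corrects: per-frame exponential
acquisition bleaching applied to every fluorescent ROI including the
reference (so the reference division cancels it exactly); a bleach pulse
of depth ~0.5; a constant fractional depression of the non-bleached ROI
as the bleach-leak model (matching the additive form of the correction —
a leak whose bleached molecules redistribute would instead bias the dip
by ≈ leak/depth · S_B, which no additive correction can remove); an
immobile fraction bleached in place; and multiplicative Gaussian noise
(shot-noise proxy, default 2 % — the instrument's true noise model is not
part of the emulation).  Acquisition defaults follow a typical confocal
protocol: 300 frames, 0.8 s interval, 5 pre-bleach frames.  With all
artifact knobs at zero the pipeline reproduces the ground-truth curve to
<10⁻⁶ (the immobile-fraction estimate needs the plateau actually reached
within the trace, ~420 frames for the canonical dip-0.30 parameters).

What passing these round trips does *not* show about real data: motion
of the structure, bleaching during the finite bleach pulse, detector
nonlinearity and axial (3D) diffusion are not emulated.  The last point
matters quantitatively: the measured free-diffusion reference dip
(10 ± 3 %) is smaller than the ideal 2D model value (17.6 %) because
fast-diffusing free molecules mix within the frame interval, so
measured dips should be compared against a reference *measured under the
same acquisition conditions* — which is exactly how the workflow uses it.

Coalescence events are exact exponential eccentricity relaxations
`e(t) = e_post + (e_pre − e_post)e^{−t/τ_e}` with `τ_e = (η/γ)·R_final`;
FCS curves follow the anomalous-diffusion autocorrelation with a triplet
term.  All generators are bitwise reproducible under a fixed seed.

## Calibration chain

* Inverse capillary velocity: through-origin regression of `τ_e` on
  `R_final` (the relation has no intercept), standard error from
  residuals; ≥3 distinct radii required.
* Viscosity: through-origin fit of diffusion time versus known viscosity
  (Stokes–Einstein linearity); extrapolation beyond twice the calibration
  range is flagged.  Diffusion times come from FCS fits (structural
  parameter κ held fixed) or from the half-minus-full FRAP difference
  `F_diff = F_half − F_full` fitted with the circular-spot recovery
  `A e^{−2τ/t}[I₀ + I₁](2τ/t)` (evaluated via exponentially scaled
  Bessel functions).  The fit window should cover the recovery phase
  (≲2 τ_D): the spot model plateaus at `A` while `F_diff` eventually
  decays through boundary exchange, so over-long windows bias τ low.
  Within that window the fitted τ agrees with `R²/(4D)` to <10 % for
  strong-boundary condensates and is exactly proportional to it across
  diffusion coefficients.
* `γ = η/(η/γ)` (numerically, Pa·s divided by s/µm is already µN/m =
  µJ/m²) and `ΔG = γ·2πR_h²`, reported in J and in kT
  (k_B = 1.380649·10⁻²³ J/K; default T = 298.15 K for in vitro work,
  override to 310.15 K for live-cell numbers).
* Master curve: the relation between dip and ΔG is known to be
  sigmoidal; its exact form is not prescribed, so a monotone
  four-parameter log-logistic
  `dip(E) = d₀ + (d_∞ − d₀)/(1 + (E₅₀/E)ˢ)` is fitted with bounds
  `d₀ ∈ [0, 0.15]`, `d_∞ ≤ 0.5`, anchored by a zero-energy baseline
  point; clearly non-monotone point sets are rejected.  Uncertainty by
  bootstrap (pair resampling, or parametric when point errors are
  given; 200 samples).  Inversion is closed-form on the fitted curve;
  dips within one SEM of the baseline return a `no-barrier`
  (ICBS-range) status and dips at the plateau `above-range`, rather
  than numbers.  The packaged example table is synthetic, generated
  from a representative curve, and only demonstrates the workflow.

## Known limitations

* All geometry is 2D and circular; ellipsoidal or 3D condensates, moving
  boundaries and concentration-dependent diffusion are out of scope, as
  is fitting `D_app` or `h` to measured curves — the assay is
  deliberately model-free on data.
* The LLPS model assumes negligible bleached concentration outside the
  condensate; its transparent-boundary limit (an absorbing interface,
  dip ≈ 0.123) therefore sits *below* the free-diffusion reference model
  (dip ≈ 0.176), in which bleached molecules can return from the finite
  surrounding domain.  Mechanism classification uses a measured
  reference, not either model constant.
* For strong slow binding the interior dip of the ICBS model falls below
  the finite-domain plateau depression `R_C²/(2R_L²)`; resolving it
  requires a large domain ratio (the binding-strength table defaults to
  `R_L/R_C = 10`).
* Problem sizes in the test suite (domain ratios 2–3 for
  solver-versus-series comparisons, horizons ≤1.5 τ_D, 16–20 time
  points; 1000 replicates for the test-calibration study) were chosen as
  desk-scale defaults that already determine every checked property.
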