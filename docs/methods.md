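# Methods

This note records the modelling assumptions, numerical choices and known
limitations of `sticklesim`, in the spirit of a model-description appendix.

## Generative movement model

A fish is a point with position **c** (mm) and unit heading **v**, updated
at fixed intervals τ = 0.1 s (the sampling rate of the tracking data the
model is designed around, and roughly the response latency of small fish).

**Step lengths.** The marginal is Gamma(shape a, rate b mm⁻¹). Serial
dependence is imposed by a Gaussian copula: a latent stationary AR(1)
chain z with coefficient ρ feeds s = F⁻¹(Φ(z)), where F is the gamma CDF.
Because rank correlation is invariant under the monotone transforms, the
lag-1 Spearman correlation of the steps equals that of the latent pair,
and for a bivariate normal the two are linked exactly by
ρ = 2·sin(ρ_s·π/6). The generator therefore hits a requested ρ_s without
calibration, and the marginal is exactly gamma at any ρ_s — this is the
reason the update operates on the *normal score* of the previous step
rather than the raw step value (transforming the raw step would destroy
the gamma marginal).

**Turns.** Given a drawn step length s, the new heading is a draw from a
Kent (FB5) distribution with κ(s) = k_κ·s^{d_κ}, β(s) = k_β·s^{d_β}
(β clipped to κ/2 where the fitted laws would violate the constraint
2β ≤ κ). The mean axis is the previous heading; the major axis is the
lateral (horizontal) direction heading × up; the minor axis completes the
right-handed triad. With positive exponents, κ(0) = 0: a resting fish
reorients uniformly — accepted model behaviour implied by the power law.
Because roll is undefined for a point fish, the lateral axis of the frame
is carried through near-vertical headings (re-orthogonalised against the
new heading) to keep frames continuous; standalone frame construction
falls back to a fixed horizontal reference.

**Tank and boundary.** The tank is a frustum: radius linear in depth
(defaults 150 mm at the surface, 137.5 mm at the 80 mm floor). Initial
position is uniform in the inscribed cylinder (guaranteed inside), initial
heading uniform on the sphere. A proposed move is accepted only if the
position three timesteps ahead at the same heading and step length is
inside the tank; otherwise step *and* direction are redrawn, the latent
copula chain advancing on every redraw. A cap of 10,000 redraws per
timestep guards against livelock with pathological parameters. Because
the frustum is convex, the accepted one-step position is automatically
inside whenever the three-step look-ahead is.

**Unnatural variant.** For stilted control stimuli, step lengths come from
a two-point distribution on {0, 20} mm with P(20) = mean/20, so the mean
matches the gamma mean a/b (feasible only for a/b ≤ 20 mm); turns are
drawn as in the main model.

## Default parameter regimes

`fixtures.REGIME_PARAMS` defines three per-fish parameter sets spanning
the slow/typical/fast range observed in small-fish tracking (population
median steps of roughly 1–6 mm per 0.1 s, strong step autocorrelation):

| regime | gamma (a, b) | mean step | ρ_s  | κ law (k, d) | β law (k, d) |
|--------|--------------|-----------|------|--------------|--------------|
| slow   | 1.5, 1.0     | 1.5 mm    | 0.75 | 2.5, 0.9     | 0.8, 1.0     |
| medium | 2.0, 0.5     | 4.0 mm    | 0.81 | 2.0, 1.0     | 0.7, 1.1     |
| fast   | 2.5, 0.4     | 6.25 mm   | 0.85 | 3.0, 0.8     | 1.0, 0.9     |

The medium regime sits at the population-mean step scale and
autocorrelation; the κ/β laws give turn concentrations of order 2–20 over
the realised step range, with ellipticity growing with speed (wider
lateral than dorsoventral spread). These are the package's fixture
conditions, not estimates of any particular animal.

## Inverse pipeline

`fit_movement_params` chains:

1. **Imputation** — cubic splines through observed frames per coordinate;
   leading/trailing gaps take the nearest observed value; more than 20%
   missing in a coordinate is a quality error (tracking losses in practice
   are a few percent).
2. **Smoothing** — zero-phase (forward–backward) third-order Butterworth
   low-pass, default cutoff 2 Hz. The cutoff is a free parameter: it
   should be the lowest value that leaves the real signal untouched.
   Smoothing exists to remove *measurement* noise; for noise-free
   (simulated) input it should be disabled, since the movement process
   itself has spectral content up to the Nyquist frequency and any cutoff
   distorts it.
3. **Steps and turns** — steps are Euclidean distances between consecutive
   positions; each turn is the current displacement direction expressed in
   the heading frame of the last preceding *nonzero* displacement.
   Zero-length displacements stay in the step series but emit no turn
   sample (a zero step has no direction), and the reference frame is
   carried across them.
4. **Marginal fits** — gamma MLE (values below 10⁻⁶ mm floored, since the
   gamma has no mass at zero but recorded series may contain exact zeros),
   plus an AIC table over gamma/normal/Cauchy/Weibull/logistic/log-normal;
   failures of a competitor are recorded as missing, not raised.
5. **Autocorrelation** — lag-1 Spearman with a randomisation test
   (default 999 permutations; p = (1 + #{|ρ*| ≥ |ρ̂|})/(n_perm + 1)).
6. **Turning laws** — Kent fits per 1 mm step bin (bins with ≥ 1000
   samples; moment estimators for the axes, then exact likelihood
   maximisation for κ and β — the moment estimators alone are
   large-concentration approximations and report κ̂ ≈ 1 even for uniform
   data), then nonlinear least-squares power laws through the bin
   midpoints with percentile-bootstrap 95% CIs (default 1000 resamples of
   bins).

Fish whose median step is below 0.05 mm are flagged near-immobile in the
report (an outlier flag, not an automatic exclusion).

**Population comparison.** Step-length distributions are compared on a
shared 1 mm binning up to the pooled 99.9th percentile (overflow folded
into the last bin); turn distributions on a 36 × 18 azimuth × elevation
grid of the flattened sphere. Dissimilarity is the Hellinger distance
√(1 − Σ√(pᵢqᵢ)). Embeddings use classical (Torgerson) MDS — double-centre
−D²/2 and take the top eigenpairs. Association with external covariates
(e.g. body length) uses regression between vectorised lower triangles with
significance from joint row/column permutation of the response matrix
(999 permutations).

## Tag localization

The camera is an ideal pinhole above the water (lens distortion is assumed
already removed from edge coordinates); world z is depth below the
surface. Ellipses are fitted to tag edge points by the direct
least-squares conic fit with the ellipse constraint 4AC − B² = 1 in its
numerically stable partitioned form. Rays through the fitted semimajor
endpoints are intersected with the z = 0 plane and refracted by the vector
form of Snell's law (n_air = 1, n_water = 1.333). Parameterising both
refracted rays by depth, the solver bisects for the depth z* where their
separation equals the tag diameter (7 mm), after verifying numerically
that separation grows with depth; the tag position is the midpoint of the
two ray points at z*, with tolerance 10⁻⁹ mm on the root. If a noisy
observation of a surface tag already exceeds the diameter at z = 0, the
solver clamps to the surface solution (overshoots beyond half a diameter
are treated as non-physical); the nominal bottom margin of 5 mm below the
tank floor extends adaptively because the depth solve amplifies endpoint
noise for floor-depth tags.

The synthetic scene oracle inverts this pipeline independently: it samples
the tag's circular boundary in 3D, finds each point's surface crossing by
solving Snell's law in the vertical plane through camera and point, and
projects to pixels with optional Gaussian noise. Round-trip error is
~10⁻⁷ mm for horizontal (validation-grid) tags without noise. Two
intrinsic approximations matter: the refracted image of a circle is only
approximately an ellipse, and for *tilted* tags the two endpoints lie at
different depths, so the equal-depth separation rule carries a systematic
error of order r·sin(tilt) (~0.6 mm at 0.5 rad). Depth is the
noise-amplified axis: the ray-separation derivative with depth is small
(~0.006 mm/mm for the default rig), so sub-pixel endpoint errors map to
millimetre-scale depth errors. Synthetic per-point pixel noise therefore
produces RMSEs far above what a real high-contrast tag image yields; the
monotone noise→error relationship, not the absolute RMSE, is the
meaningful synthetic check.

## Preference-test statistics

First-choice counts are tested against 0.5 with the exact binomial test,
two-sided by the minimum-likelihood convention (sum the probabilities of
all outcomes no more likely than the observed one). Latencies are compared
with the classical pooled-variance two-sample t-test (Welch's form
available by flag; pooled is the default because reported degrees of
freedom of the form n₁+n₂−2 imply it). The minimum sample size for a
one-proportion test uses the arcsine-transform normal approximation
n ≥ (z₁₋α/₂ + z_power)²/h², rounded up; Cohen's medium effect h = 0.5 with
80% power and α = 0.05 gives n = 32.

## What the synthetic data do and do not show

All tests run on data generated by the package itself (the simulator and
the camera-scene oracle). Passing them demonstrates internal consistency —
the inverse pipeline inverts the forward model, the sampler matches its
density, the geometry solver inverts the projection — but not that the
model describes any particular animal, which requires tracked fish.
Simulated trajectories are noise-free and perfectly regular in time; real
tracking adds measurement noise (hence the smoothing stage), missing
frames and occasional identity errors that the generator does not emulate.

Known limitations:

- **Boundary truncation.** In the small default tank the look-ahead
  redraw rule rejects long steps near walls, so realized step statistics
  are truncated relative to the generative gamma — about 8–15% on the mean
  and rate, and ~0.02 on ρ_s, at the typical-to-fast regimes (stronger for
  the 20 mm two-point variant). Parameters estimated *from* confined
  trajectories are therefore effective in-tank parameters. Round-trip
  estimator-consistency tests run in a geometrically similar spacious tank
  (600/550/320 mm) where the rule rarely binds; the truncation itself is
  asserted directionally in the simulate tests.
- Problem sizes in the test suite follow the published scales where those
  exist (36,000-step series, 32-trial tests, 32-location × 3-depth
  localization grids); Monte-Carlo replicate counts (e.g. 500 null
  replicates for permutation-test calibration, 150 bootstrap-coverage
  replicates) are the package's own choices sized to make the asserted
  intervals statistically comfortable.
- The model has no interaction, no hydrodynamics and no body orientation
  beyond heading; reactive/closed-loop stimuli are out of scope.
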