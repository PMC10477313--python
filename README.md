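# sticklesim

Simulation and characterisation of individual 3D fish movement at fine
temporal scale (0.1 s, millimetre resolution), with a refraction-aware
single-camera tag-localization pipeline and the statistics used in
two-choice behavioural preference tests.

Small fish such as three-spined sticklebacks move in a saltatory way:
bursts of forward motion separated by pauses and abrupt reorientations.
Experiments with animated or robotic stimulus fish, and individual-based
movement models, need paths that are statistically indistinguishable from
this behaviour. `sticklesim` provides the forward model, the inverse
pipeline that estimates its parameters from tracked trajectories, and the
supporting geometry and test statistics.

## The model

At each timestep `t` (interval τ = 0.1 s) a fish at position **c** with
heading **v** draws:

1. **Step length** `s(t)` from a Gamma(a, b) marginal with lag-1 Spearman
   autocorrelation ρ_s, generated by a Gaussian copula: a latent
   standard-normal AR(1) chain with coefficient ρ = 2·sin(ρ_s·π/6) is
   mapped through Φ and the gamma quantile function, so the marginal is
   exactly gamma at every lag.
2. **Direction** `v(t)` from a Kent (FB5) distribution on the sphere,

       f(x) ∝ exp{ κ γ₁ᵀx + β[(γ₂ᵀx)² − (γ₃ᵀx)²] },   0 ≤ 2β ≤ κ,

   whose mean axis γ₁ is the previous heading, major axis γ₂ the fish's
   lateral (horizontal) axis and minor axis γ₃ its dorsoventral axis.
   Concentration and ellipticity are power laws of step length,
   κ = k_κ·s^{d_κ} and β = k_β·s^{d_β}: fast fish go straight, slow fish
   reorient freely.
3. **Position update** `c(t) = c(t−τ) + v(t)·s(t)`, inside a tapered
   circular tank (default 300 mm top / 275 mm base diameter, 80 mm water).
   If the position three timesteps ahead (same heading and step) would
   leave the tank, step and direction are redrawn.

The inverse pipeline (`fit_movement_params`) runs cubic-spline gap
imputation, zero-phase third-order Butterworth smoothing, step/turn
extraction, gamma fitting with an AIC comparison against normal, Cauchy,
Weibull, logistic and log-normal competitors, a lag-1 Spearman
randomisation test, per-1-mm-bin Kent fits (bins with ≥ 1000 samples) and
nonlinear power-law fits with bootstrap confidence intervals. Population
comparison uses Hellinger dissimilarity matrices, classical MDS and
distance-matrix regression with a permutation test.

The `tagloc` module localizes a 7 mm circular dorsal tag in 3D from a
single overhead camera: an ellipse is fitted to the tag's image by direct
least squares, rays through the semimajor-axis endpoints are refracted at
the water surface by Snell's law (n₁ sin θ₁ = n₂ sin θ₂, n_water = 1.333),
and the tag depth is the point where the refracted rays are exactly one
tag diameter apart.

## Worked example

```python
import numpy as np
from sticklesim import simulate_path, fit_movement_params, CharacterizeConfig
from sticklesim.fixtures import REGIME_PARAMS

p = REGIME_PARAMS["medium"]          # gamma(2.0, 0.5), rho_s = 0.81
traj = simulate_path(p, n_steps=36_000, rng=np.random.default_rng(42))
cfg = CharacterizeConfig(smoothing_cutoff_hz=None)   # input is noise-free
est, report = fit_movement_params(traj, cfg, np.random.default_rng(0))
```

prints (via the report fields):

```
frames: 36000
fitted gamma: shape=1.973 rate=0.552 (true 2.0, 0.5)
rho_s: 0.792 (true 0.81), p=0.001
kappa law: k=1.834 d=1.060 (true 2.0, 1.0)
beta law:  k=0.609 d=1.213 (true 0.7, 1.1)
AIC best: gamma  delta to 2nd: 661.4
```

A 60-minute path is 36,000 samples at 0.1 s. The fitted gamma shape and
the power-law exponents recover the generative values to a few percent;
the rate and ρ_s are slightly biased low relative to the generative inputs
because wall-avoidance redraws truncate long steps in the small tank (see
`docs/methods.md`). The AIC margin of several hundred to the second-best
family reflects how strongly gamma-distributed the step lengths are.

The command line mirrors the library:

```sh
sticklesim simulate --params params.json --steps 1200 --seed 1 --out traj.csv
sticklesim fit --in traj.csv --out fitted.json --report report.json
sticklesim localize --rig rig.json --ellipses obs.csv --out positions.csv
sticklesim prefstats --k 25 --n 32 --effect-h 0.5
```

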