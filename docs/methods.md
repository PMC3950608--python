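# Methods

## Model

The package implements a one-population neural field on the ring of
motion directions `v ∈ [−π, π)`:

```
τ_p  ∂p/∂t = −p + S( λ [ J∗p − k_α α + k_X X + k_I I(v) − T ] )
τ_α  ∂α/∂t = −α + p
```

`p` is activity as a fraction of a maximal rate (the logistic `S` keeps
the attractor inside (0, 1)); `α` is linear spike-frequency adaptation;
`X(v,t)` is an Ornstein–Uhlenbeck field with stationary mean 0 and unit
variance per node, independent across nodes, relaxing on τ_X = τ_α.  The
kernel `J(v) = J₀ + 2J₁cos v + 2J₂cos 2v` is a three-mode Mexican hat
(local excitation, lateral inhibition) that produces winner-take-all
tuned responses; with no input the equations are O(2)-equivariant
(rotations and reflections of the ring), which is exercised as a test
invariant.

**Convolution normalisation.**  We define
`(J∗p)(v) = (1/2π)∫J(v−u)p(u)du`, i.e. cosine mode `n` is multiplied by
exactly `J_n`.  This convention places the flat-state pitchfork for
k_α = 0.01 at λ ≈ 21.04, inside the λ∈[12, 26] window where the tuning
transition must fall for the operating line (weakly tuned at λ = 13,
tuned at λ = 25) to make sense; the unnormalised integral would put it
near λ ≈ 3, and a `1/π` normalisation near λ ≈ 10.5.

**Closed-form flat-state conditions.**  At the homogeneous state
`p̄ = S(λ[(J₀−k_α)p̄ − T])` with gain `g = λS′(x̄)`, mode n destabilises
statically when `g(J_n − k_α) = 1` (the pitchfork to the ring of tuned
states for n = 1) and oscillatorily when `g·J_n = 1 + τ_p/τ_α` (the
trace-zero Hopf of the (p, α) pair).  The Hopf precedes the pitchfork
whenever `k_α > J₁·(τ_p/τ_α)/(1 + τ_p/τ_α)` (≈ 0.005 at τ_α = 100 ms),
the Bogdanov–Takens level; below it the attractor past threshold is a
stationary bump, above it a travelling wave.  Both closed forms serve as
oracles for the numerical continuation (matched to < 1e−6 relative).

## Discretisation and integration

A 200-point uniform grid discretises the ring; periodic trapezoid
quadrature reduces to the plain mean, so the convolution is a circulant
matrix product whose mode multipliers are exact to rounding.  Noise-free
trajectories use an adaptive stiff-capable solver (LSODA) at relative
tolerance 1e−6.  Noisy runs use fixed-step Euler–Maruyama at
dt = 0.5 ms for (p, α), while the OU field is advanced with its exact
transition density `X⁺ = X e^(−dt/τ) + √(1−e^(−2dt/τ)) ξ`; the exact
update removes one discretisation bias from the switching statistics.
Initial conditions are `p(v,0) = 0.1` plus a per-node uniform
perturbation of amplitude 1e−3 (seeded), `α = X = 0`.  The perturbation
amplitude is exposed as a parameter; measured escape times from the
diagonal-tuned state vary only logarithmically with it.  Ensembles are
vectorised (replicates × nodes) under a single seeded generator; a run
is bit-reproducible given its seed, and only the average-direction trace
and the activity maximum are recorded per snapshot (full fields for
single runs).

## Mode reduction and continuation

Because `J` carries only modes 0–2, `J∗p` depends on five projections of
`p`.  Truncating `(p, α)` to {1, cos v, sin v, cos 2v, sin 2v} gives a
10-ODE Galerkin system: reconstruct the fields, apply `S` pointwise on
the grid (with the full input profile, not its truncation), and project
back.  The truncation is **exact when k_α = 0**: the sigmoid generates
higher harmonics, but the kernel annihilates them and nothing else feeds
them back.  With adaptation the pointwise term `−k_α α(v)` re-injects
the high-harmonic content of `α = p` (up to ≈ 0.04 in amplitude at
strongly tuned states), and the reduced equilibria deviate from the
projected full equilibria by ~1e−5 near the pitchfork up to ~2e−3 at
λ = 26.  The reduction is therefore used for what it is good at —
locating equilibria and their bifurcations — while trajectories and
switching statistics always come from the full grid model.

Equilibrium branches are tracked by pseudo-arclength continuation
(secant predictor, Newton corrector to residual < 1e−11, balanced
parameter/state metric).  Eigenvalues of the 10×10 Jacobian
(central differences) are stored at every accepted point; bifurcations
are located by integer bisection on the unstable-eigenvalue count,
polished by root-finding the crossing eigenvalue's real part onto the
axis (|Re| < 1e−8 at reported Hopf points), and classified: complex pair
→ Hopf; real crossing with a symmetry-breaking null vector (modes ≥ 1)
→ pitchfork (only with zero input — with input the pitchfork unfolds
into a smooth branch plus folds, and real crossings are tagged fold).
Periodic orbits are not continued; oscillation periods are measured from
converged simulations.

Regimes are classified from post-transient deterministic trajectories
(first half discarded): flat and steady → homogeneous; tuned
(peak − mean > 0.05) and static → tuned steady; peak advancing
monotonically beyond 360° → travelling wave; amplitude oscillation with
static peak → standing wave / breather; peak rocking about a fixed
direction → pinned oscillation (slosher).  Thresholds are configurable;
mixed trajectories return an explicit "unclassified".  Near a pitchfork
the bump amplitude grows like √(λ−λ_c), so a finite tuned-threshold
biases simulated regime boundaries slightly past the true bifurcation —
boundary tracing is for maps, not for precision bifurcation location.

## Contrast calibration

On the operating line (k_α = 0.01, k_I = 0.01, simple unimodal input)
the peak steady response above baseline, `R(λ) = max p̄ − M` with
`M = max p̄` at λ = 13, rises steeply around the smoothed pitchfork
(λ ≈ 19–21) and saturates towards λ = 25.  Contrast is introduced by
requiring `R(λ(c))` to follow a Naka–Rushton function with exponent
n = 3 (the typical MT value).  The half-saturation constant c50 is not
treated as free: it is **anchored at calibration time** by requiring
that the operating point at the perceptual contrast threshold
c_thr = 0.03 — the smallest contrast at which observers reliably report
a direction — sits exactly at the travelling-wave Hopf of the D-tuned
state for the complex input (slope λ_H computed by bisection of the
reduced Jacobian's leading eigenvalue).  With the default grid this
gives c50 ≈ 0.0207, placing c = 0.04 on the steep part and c = 0.08 on
the saturated part of the contrast-response curve, and λ(c) ≈ 25 for
c > 0.2.  The resulting map is monotone, clamped to [13, 25], and
serialisable to JSON so stochastic experiments reproduce exactly from a
stored calibration.  Tuning width δ (width at half height above the
profile's own minimum) is reported for tuned states; δ at the top of the
operating line is a few tens of degrees, consistent with MT tuning.

## Switching statistics

The percept is read out as the population-vector angle
`v̄(t) = arg Σ_j p(v_j,t) e^{i v_j}` (on the uniform grid a constant
background contributes nothing to the sum, so this equals the circular
mean of `p` minus its spatial minimum).  A hysteresis automaton with
perceptual threshold ±PT detects switches: the first crossing of either
threshold is the first switch away from D; thereafter only the opposite
threshold emits one.  The automaton is armed only once the response is
direction-tuned — the first time `max_v p` exceeds `M + R_max/2`, the
same criterion used for response latency — because the near-flat initial
field has no meaningful direction.  Defaults: PT = 10° for traces and
rate curves, PT = 15° for duration-distribution work.  The first switch
is counted in the per-trial rate (it crosses a threshold); the interval
from onset to first switch is *excluded* from duration fits and
summarised separately.

Durations pooled across replicates are fitted by MLE (location fixed at
zero) with gamma, log-normal and Weibull families; each fit gets a KS
test against the fitted distribution, and families are ranked by KS
statistic.  Using fitted parameters biases KS p-values upward (the
rejection rate of the true family is well below the nominal 5%, which a
test verifies); the ranking, which is what selects the best family, is
unaffected.  Raising PT can only remove threshold crossings, so
per-trace switch counts are non-increasing in PT — a property test.

A synthetic-trace generator (alternating ±45° plateaus with first-order
transitions and OU jitter, plateau durations drawn from a configurable
distribution) exercises the automaton and the fitting stage without the
simulator.  It emulates the shape of model traces, not their dynamics:
passing those tests validates the analysis stage only.

## Problem sizes

The bundled acceptance script uses 200 stochastic replicates of 15 s per
contrast condition (the full study's distributions used 1500 and its
rate curves 500 per point — the CLI's `--reps` flag restores those), a
60 s noise-free run for the oscillation measurements, 7 deterministic
15 s runs for the rate plateau, and 10⁶ OU steps of 0.5 ms for the noise
law.  OU variance is estimated as the second moment about the known zero
mean: with τ_X = 16.5 s and a 500 s trajectory, mean-subtracted variance
would be biased low by ≈ 2τ/T ≈ 6.6%.

## Known limitations

* **Galerkin truncation error.**  With adaptation the 10-ODE reduction
  is approximate (see above); mode-coordinate agreement with the full
  model is ~1e−3 at strongly tuned states, not exact.  Bifurcation
  locations inherit an error of the same order in parameter units.
* **Deterministic transient.**  With the slow-adaptation parameter set,
  the diagonal-tuned state destabilises only once adaptation reaches
  ≈ 0.4 of its equilibrium profile, so the noise-free first switch
  occurs at ≈ 13–14 s, the asymptotic inter-switch interval is ≈ 4.2 s
  at the top of the operating line (≈ 5 s at the c = 0.08 preset), the
  ∓PT threshold-to-threshold transition of v̄ takes ≈ 240 ms (the
  underlying activity handover e-folds in ≈ 55 ms, the inverse of the
  unstable eigenvalue), and the noise-free rate plateau is ≈ 2.4
  switches per 15 s.  Noise shortens the transients substantially
  (first switches ≈ 9 s and ≈ 5 s at c = 0.04 / 0.08), and the noisy
  dominance-duration means and best-fitting families are robust; the
  deterministic transient-dependent quantities are the model's least
  certain outputs and depend on the unspecified initial perturbation
  only logarithmically.
* **No periodic-orbit continuation.**  Oscillatory branches are
  characterised by simulation; codimension-two points (Bogdanov–Takens,
  double Hopf) are discussed analytically but not computed.
* **Noise model.**  "No feature correlation" is implemented literally as
  i.i.d. unit-variance OU noise per grid node; the effective noise seen
  by any single Fourier mode therefore shrinks as the grid is refined.
  All reported statistics use the standard 200-point grid.
* The synthetic stimulus is a direction-space abstraction: no spatial
  (cortical-space) extension, no eye-movement modelling, no ingestion of
  psychophysical data.
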