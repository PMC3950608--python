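# ringswitch

A neural-field **ring model of perceptual multistability in motion
integration**: a single population of direction-selective neurons on the
periodic feature space of motion direction, with Mexican-hat lateral
connectivity, slow spike-frequency adaptation and Ornstein–Uhlenbeck
noise.  The package is written for computational neuroscientists who want
to simulate the model, map its bifurcation structure, and reproduce the
perceptual-switching statistics of the multistable barberpole illusion —
a drifting grating in a square aperture whose perceived direction
alternates between the diagonal D (0°) and the aperture-edge directions
H (−45°) and V (+45°).

## Model

Mean firing rate `p(v,t)` over direction `v ∈ [−π, π)`:

```
τ_p  ∂p/∂t = −p + S( λ [ J∗p − k_α α + k_X X + k_I I(v) − T ] )
τ_α  ∂α/∂t = −α + p
```

with logistic rate function `S(x) = 1/(1+e^(−x))`, three-mode kernel
`J(v) = J₀ + 2J₁cos v + 2J₂cos 2v` (J₀=−1, J₁=1/2, J₂=1/6), linear
adaptation `α`, and an OU noise field `X` (mean 0, unit variance,
no feature correlation, timescale τ_X = τ_α).  The convolution is
normalised as `(J∗p)(v) = (1/2π)∫J(v−u)p(u)du`, so cosine modes are
multiplied by exactly `J_n`.  The stimulus enters as Gaussian bumps in
direction space: a broad 1D (contour) cue at D and two narrow 2D
(terminator) cues at H and V, with the 1D weight decreasing linearly
with contrast, `w_1D = 0.5 − 1.1c`.

Contrast drives the sigmoid slope through a calibrated monotone map
`λ(c) ∈ [13, 25]` obtained by matching the model's peak steady response
`R(λ)` to a Naka–Rushton contrast-response function
`R_max·cⁿ/(cⁿ+c50ⁿ)`; the half-saturation constant is anchored so that
the onset of oscillations (the travelling-wave Hopf bifurcation of the
D-tuned state) coincides with the perceptual contrast threshold
c = 0.03.

Dominance durations are extracted from the population-vector direction
trace with a hysteresis automaton at a perceptual threshold ±PT, and
fitted by maximum likelihood with gamma / log-normal / Weibull families
compared through Kolmogorov–Smirnov statistics.

## Worked example

Noise-free switching at the top of the operating line (λ = 25,
k_α = 0.01, τ_α = 16.5 s) with the fixed-weight barberpole input:

```python
import numpy as np
from ringswitch import (ModelParams, RingGrid, build_input,
                        integrate_deterministic, average_direction,
                        detect_switches)
from ringswitch.response_characterization import calibrate_lambda_of_contrast
from ringswitch.switching_analysis import tuned_onset_time

grid = RingGrid()
cmap = calibrate_lambda_of_contrast()
print(f"c50 = {cmap.nr_c50:.4f}, Hopf slope at threshold = {cmap.hopf_lambda_at_thr:.3f}")

params = ModelParams(lambda_=25.0, k_alpha=0.01, k_I=0.01, tau_alpha=16500.0)
inp = build_input(grid, "complex", w_1D=0.5)
res = integrate_deterministic(params, inp, grid, t_end=30000.0, seed=0)
trace = average_direction(res)
onset = tuned_onset_time(trace.times, res.p_history.max(axis=1),
                         cmap.M + cmap.R_max / 2)
train = detect_switches(trace, pt_deg=10.0, t_start=onset)
print(f"tuned response at {onset*1000:.1f} ms; first switch at {train.switch_times[0]:.2f} s")
print("percept sequence:", "-".join(train.labels))
print("inter-switch intervals (s):", np.round(train.durations, 2))
```

prints

```
c50 = 0.0207, Hopf slope at threshold = 22.201
tuned response at 15.0 ms; first switch at 13.94 s
percept sequence: H-V-H-V-H
inter-switch intervals (s): [2.39 3.96 4.21 4.31]
```

The response tunes to the diagonal within tens of milliseconds, holds it
while adaptation builds, then settles into regular alternation between
the H and V percepts every few seconds — the deterministic skeleton of
the perceptual switching that the noisy model turns into stochastic
dominance durations.

A command-line driver exposes the experiment presets:

```bash
ringswitch calibrate --out contrast_map.json
ringswitch run --preset rate_vs_contrast --reps 50 --seed 1 --out results/
ringswitch run --preset duration_distributions --contrast low --reps 200 --out results/
```

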