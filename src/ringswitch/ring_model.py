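"""Core ring model: domain types, connectivity kernel, inputs and the
deterministic vector field.

The model describes the mean firing rate ``p(v, t)`` of a population of
direction-selective neurons over the periodic feature space of motion
direction, ``v in [-pi, pi)``.  Activity is shaped by a three-mode
Mexican-hat connectivity (local excitation, lateral inhibition), slow linear
spike-frequency adaptation ``alpha(v, t)``, an Ornstein-Uhlenbeck noise
field ``X(v, t)`` and a time-independent input ``I(v)``:

    tau_p  dp/dt     = -p + S( lambda * [J*p - k_alpha*alpha
                                          + k_X*X + k_I*I - T] )
    tau_alpha dalpha/dt = -alpha + p

with the logistic firing-rate function ``S(x) = 1/(1+exp(-x))`` and the
kernel ``J(v) = J0 + 2 J1 cos v + 2 J2 cos 2v``.  The convolution is
normalised as ``(J*p)(v) = (1/2pi) \\int J(v-u) p(u) du``, so a pure cosine
mode ``cos(n v)`` is multiplied exactly by ``J_n`` (n = 0, 1, 2) and higher
modes are annihilated.

All internal angles are radians; the public API accepts and reports degrees
where a quantity is conventionally expressed that way (input widths, tuning
widths, direction traces).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import brentq

TWO_PI = 2.0 * math.pi

__all__ = [
    "ModelParams",
    "RingGrid",
    "FieldState",
    "InputProfile",
    "PRESETS",
    "sigmoid",
    "sigmoid_prime",
    "kernel_profile",
    "kernel_matrix",
    "ring_convolve",
    "wrapped_gaussian",
    "build_input",
    "deterministic_rhs",
    "flat_fixed_point",
    "flat_mode_gain",
    "flat_pitchfork_lambda",
    "flat_hopf_lambda",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelParams:
    """Scalar parameters of the ring competition model.

    Time constants are in milliseconds; every other parameter is
    dimensionless.  Defaults are the fixed values of the reference
    parameter table; regime-specific presets live in :data:`PRESETS`.
    """

    tau_p: float = 1.0          # population time constant (ms)
    tau_alpha: float = 100.0    # adaptation (and noise) time constant (ms)
    lambda_: float = 15.0       # sigmoid slope
    T: float = -0.01            # sigmoid threshold
    k_alpha: float = 0.01       # adaptation gain
    k_X: float = 0.0            # noise gain
    k_I: float = 0.0            # input gain
    J0: float = -1.0            # kernel mode-0 coefficient
    J1: float = 0.5             # kernel mode-1 coefficient
    J2: float = 1.0 / 6.0       # kernel mode-2 coefficient

    def __post_init__(self) -> None:
        if not (self.tau_p > 0 and self.tau_alpha > 0):
            raise ValueError("time constants must be positive")
        if self.lambda_ <= 0:
            raise ValueError("lambda_ must be positive")
        for name in ("k_alpha", "k_X", "k_I"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def replace(self, **kwargs) -> "ModelParams":
        return dataclasses.replace(self, **kwargs)

    # -- plain-text (key = value) serialisation -----------------------------
    def to_text(self) -> str:
        lines = [f"{f.name} = {getattr(self, f.name)!r}"
                 for f in dataclasses.fields(self)]
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "ModelParams":
        kwargs = {}
        for raw in text.splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, value = line.partition("=")
            kwargs[key.strip()] = float(value)
        return cls(**kwargs)


def _make_presets() -> dict:
    base = ModelParams()
    return {
        # no/weak input regime maps (tau_alpha = 100 ms)
        "table1_sec3": base.replace(lambda_=15.0, k_alpha=0.01, k_I=0.0,
                                    k_X=0.0, tau_alpha=100.0),
        # simple/complex input studies, k_I = 0.01 (tau_alpha = 100 ms)
        "table1_sec4": base.replace(lambda_=20.0, k_alpha=0.01, k_I=0.01,
                                    k_X=0.0, tau_alpha=100.0),
        # slow-adaptation switching regime: operating line top, noise on
        "table1_sec5": base.replace(lambda_=25.0, k_alpha=0.01, k_I=0.01,
                                    k_X=0.0025, tau_alpha=16500.0),
    }


#: Named parameter presets mirroring the three regimes of the reference
#: parameter table.  ``table1_sec5`` is the perceptual-switching preset
#: (slow adaptation tau_alpha = 16.5 s, noise k_X = 0.0025).
PRESETS = _make_presets()


@dataclass(frozen=True)
class RingGrid:
    """Uniform discretisation of the ring [-pi, pi) with periodic adjacency."""

    n_points: int = 200
    v: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.n_points < 8:
            raise ValueError("grid too coarse")
        v = -math.pi + TWO_PI * np.arange(self.n_points) / self.n_points
        object.__setattr__(self, "v", v)

    @property
    def spacing(self) -> float:
        return TWO_PI / self.n_points

    @property
    def degrees(self) -> np.ndarray:
        """Grid positions as degrees in [-180, 180)."""
        return np.rad2deg(self.v)


DEFAULT_GRID = RingGrid()


@dataclass
class FieldState:
    """Discretised state (p, alpha, X) at one time instant (t in ms)."""

    t: float
    p: np.ndarray
    alpha: np.ndarray
    X: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.p)
        if not (len(self.alpha) == n and len(self.X) == n):
            raise ValueError("p, alpha, X must share the grid length")

    def assert_activity_bounded(self, eps: float = 1e-6) -> None:
        """Raise if activity has left [0, 1] beyond numerical slack.

        The sigmoid bounds the attractor inside (0, 1) but a defective
        integrator step could overshoot; this is asserted, never clipped.
        """
        if self.p.min() < -eps or self.p.max() > 1.0 + eps:
            raise FloatingPointError(
                f"activity left [0,1]: min={self.p.min()}, max={self.p.max()}"
            )


@dataclass
class InputProfile:
    """Time-independent input I(v) with its construction metadata.

    ``peak_raw`` records the maximum of the summed profile before unit-peak
    normalisation (the profile stored in ``I`` is always rescaled so that
    max I = 1 for the simple and complex kinds).
    """

    I: np.ndarray
    kind: str                       # "none" | "simple_1D" | "complex"
    w_1D: Optional[float] = None
    c: Optional[float] = None
    sigma_1D_deg: float = 18.0
    sigma_2D_deg: float = 6.0
    peak_raw: Optional[float] = None


# ---------------------------------------------------------------------------
# nonlinearity and kernel
# ---------------------------------------------------------------------------

def sigmoid(x):
    """Logistic firing-rate function S(x) = 1/(1+e^-x), saturating in (0,1)."""
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


def sigmoid_prime(x):
    s = sigmoid(x)
    return s * (1.0 - s)


def kernel_profile(grid: RingGrid, params: ModelParams) -> np.ndarray:
    """Kernel samples J(v) = J0 + 2 J1 cos v + 2 J2 cos 2v on the grid."""
    v = grid.v
    return params.J0 + 2 * params.J1 * np.cos(v) + 2 * params.J2 * np.cos(2 * v)


def kernel_matrix(grid: RingGrid, params: ModelParams) -> np.ndarray:
    """Circulant matrix C with (C p)_i = (1/2pi) int J(v_i - u) p(u) du.

    Periodic trapezoid quadrature on a uniform grid reduces to the plain
    mean, so C[i, j] = J(v_i - v_j) / n.  Mode-n cosines are eigenvectors
    with eigenvalue J_n exactly (n = 0, 1, 2); all higher modes map to 0 up
    to rounding.
    """
    n = grid.n_points
    d = TWO_PI * np.arange(n) / n
    Jd = params.J0 + 2 * params.J1 * np.cos(d) + 2 * params.J2 * np.cos(2 * d)
    idx = (np.arange(n)[:, None] - np.arange(n)[None, :]) % n
    return Jd[idx] / n


def ring_convolve(kernel: np.ndarray, p: np.ndarray, grid: RingGrid) -> np.ndarray:
    """Periodic convolution (1/2pi) int J(v-u) p(u) du by circulant product.

    ``kernel`` holds J sampled on ``grid.v`` (as from :func:`kernel_profile`).
    """
    kernel = np.asarray(kernel, float)
    p = np.asarray(p, float)
    n = grid.n_points
    if kernel.shape[-1] != n or p.shape[-1] != n:
        raise ValueError("kernel and field must be sampled on the grid")
    # kernel is sampled at v_i = -pi + 2pi i/n; difference v_i - v_j falls at
    # index (i - j + n/2) mod n of that sampling
    idx = (np.arange(n)[:, None] - np.arange(n)[None, :] + n // 2) % n
    return (kernel[idx] / n) @ p


# ---------------------------------------------------------------------------
# inputs
# ---------------------------------------------------------------------------

def wrapped_gaussian(v: np.ndarray, sigma: float, n_images: int = 3) -> np.ndarray:
    """Unit-peak Gaussian bump wrapped onto the ring (sum over 2pi images).

    For sigma <= 18 deg the wrap correction is < 1e-8, but the contract is
    exact periodicity.
    """
    out = np.zeros_like(v, dtype=float)
    for k in range(-n_images, n_images + 1):
        out += np.exp(-((v + TWO_PI * k) ** 2) / (2.0 * sigma ** 2))
    return out / out.max()


W0_DEFAULT = 0.5   # 1D-cue weight at zero contrast
W1_DEFAULT = 1.1   # linear decrease of the 1D weight with contrast


def build_input(
    grid: RingGrid,
    kind: str,
    c: Optional[float] = None,
    w_1D: Optional[float] = None,
    sigma_1D_deg: float = 18.0,
    sigma_2D_deg: float = 6.0,
    W0: float = W0_DEFAULT,
    W1: float = W1_DEFAULT,
    normalise: bool = True,
) -> InputProfile:
    """Construct the feature-space input profile.

    kind="none"       zero input.
    kind="simple_1D"  a unit-peak Gaussian at v = 0 of width sigma_1D
                      (the ambiguous 1D/contour cue of a drifting grating).
    kind="complex"    the multistable-barberpole input: the 1D cue weighted
                      by w_1D plus two narrow 2D (terminator) cues at
                      v = +-45 deg, rescaled to unit maximum.  If ``w_1D``
                      is not given it follows the contrast rule
                      w_1D = max(0, W0 - W1*c).
    """
    v = grid.v
    if kind == "none":
        return InputProfile(I=np.zeros(grid.n_points), kind=kind)
    s1 = math.radians(sigma_1D_deg)
    if kind == "simple_1D":
        I = wrapped_gaussian(v, s1)
        return InputProfile(I=I, kind=kind, sigma_1D_deg=sigma_1D_deg,
                            peak_raw=1.0)
    if kind != "complex":
        raise ValueError(f"unknown input kind {kind!r}")
    if w_1D is None:
        if c is None:
            raise ValueError("complex input needs a contrast c or explicit w_1D")
        if not 0.0 <= c <= 1.0:
            raise ValueError("contrast must lie in [0, 1]")
        w_1D = max(0.0, W0 - W1 * c)
    s2 = math.radians(sigma_2D_deg)
    off = math.radians(45.0)
    I = (w_1D * wrapped_gaussian(v, s1)
         + wrapped_gaussian(v - off, s2)
         + wrapped_gaussian(v + off, s2))
    peak = float(I.max())
    if normalise:
        I = I / peak
    return InputProfile(I=I, kind=kind, w_1D=w_1D, c=c,
                        sigma_1D_deg=sigma_1D_deg, sigma_2D_deg=sigma_2D_deg,
                        peak_raw=peak)


# ---------------------------------------------------------------------------
# vector field
# ---------------------------------------------------------------------------

def deterministic_rhs(
    state: FieldState,
    params: ModelParams,
    inp: InputProfile,
    grid: RingGrid = DEFAULT_GRID,
    conv: Optional[np.ndarray] = None,
):
    """Time derivatives (dp/dt, dalpha/dt) of the deterministic field.

    The noise field ``state.X`` is treated as frozen within the evaluation
    (it enters the drift, its own update is the integrator's business).
    ``conv`` may carry a precomputed :func:`kernel_matrix` to avoid
    rebuilding it per call.
    """
    p, alpha, X = state.p, state.alpha, state.X
    if not (np.all(np.isfinite(p)) and np.all(np.isfinite(alpha))
            and np.all(np.isfinite(X))):
        raise FloatingPointError("non-finite state passed to deterministic_rhs")
    if conv is None:
        conv = kernel_matrix(grid, params)
    x = params.lambda_ * (conv @ p - params.k_alpha * alpha
                          + params.k_X * X + params.k_I * inp.I - params.T)
    dp = (-p + sigmoid(x)) / params.tau_p
    dalpha = (-alpha + p) / params.tau_alpha
    return dp, dalpha


# ---------------------------------------------------------------------------
# flat-state analysis (closed forms used as oracles elsewhere)
# ---------------------------------------------------------------------------

def flat_fixed_point(params: ModelParams) -> float:
    """Homogeneous fixed point p_bar = S(lambda[(J0-k_alpha) p_bar - T])."""
    lam, ka, J0, T = params.lambda_, params.k_alpha, params.J0, params.T

    def res(p):
        return p - sigmoid(lam * ((J0 - ka) * p - T))

    return brentq(res, 0.0, 1.0, xtol=1e-15)


def flat_mode_gain(params: ModelParams) -> float:
    """Linearisation gain g = lambda * S'(x_bar) at the flat state."""
    pbar = flat_fixed_point(params)
    x = params.lambda_ * ((params.J0 - params.k_alpha) * pbar - params.T)
    return params.lambda_ * float(sigmoid_prime(x))


def flat_pitchfork_lambda(params: ModelParams, mode: int = 1,
                          bracket=(1.0, 80.0)) -> float:
    """Slope lambda at which the flat state's mode-n eigenvalue crosses zero.

    Static symmetry-breaking condition g * (J_n - k_alpha) = 1 with
    g = lambda S'(x_bar); for mode 1 this is the pitchfork to the ring of
    tuned states.
    """
    Jn = (params.J0, params.J1, params.J2)[mode]

    def res(lam):
        q = params.replace(lambda_=lam)
        return flat_mode_gain(q) * (Jn - q.k_alpha) - 1.0

    return brentq(res, *bracket, xtol=1e-12)


def flat_hopf_lambda(params: ModelParams, mode: int = 1,
                     bracket=(1.0, 80.0)) -> float:
    """Slope lambda of the flat state's mode-n Hopf (trace-zero) condition.

    Oscillatory instability of the (p, alpha) pair in mode n:
    g * J_n = 1 + tau_p / tau_alpha.
    """
    Jn = (params.J0, params.J1, params.J2)[mode]
    ratio = params.tau_p / params.tau_alpha

    def res(lam):
        q = params.replace(lambda_=lam)
        return flat_mode_gain(q) * Jn - (1.0 + ratio)

    return brentq(res, *bracket, xtol=1e-12)
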