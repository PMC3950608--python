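"""Contrast response machinery: R(lambda), Naka-Rushton matching and the
monotone operating-line map lambda(c).

The model is operated on the line k_alpha = 0.01, lambda in [13, 25] with
the simple (unimodal) input at gain k_I = 0.01.  The peak steady response
R(lambda) = max(p_bar) - M (M fixed as the peak at lambda = 13) rises
steeply around the smoothed pitchfork and saturates near the top of the
line.  Contrast enters by requiring that the composed response R(lambda(c))
follow a Naka-Rushton contrast-response function

    NR(c) = R_max_NR * c^n / (c^n + c50^n),

the standard saturating form fitted to contrast responses across the
visual pathway (including area MT).  The half-saturation constant is, by
default, anchored at calibration time so that the model's oscillation
onset for the complex input (the travelling-wave Hopf of the D-tuned
branch) coincides with the perceptual contrast threshold c_thr = 0.03 —
the smallest contrast at which observers reliably report a direction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import brentq

from .ring_model import (
    DEFAULT_GRID,
    InputProfile,
    ModelParams,
    RingGrid,
    build_input,
)
from .reduction_bifurcation import (
    ModeState,
    _ReducedProblem,
    _newton,
    _sorted_eigs,
    find_equilibrium,
    reconstruct_from_modes,
)

__all__ = [
    "ResponseSummary",
    "ContrastMap",
    "naka_rushton",
    "steady_response",
    "response_curve",
    "tuning_width",
    "hopf_lambda_for_input",
    "calibrate_lambda_of_contrast",
]

OPERATING_LAMBDA_MIN = 13.0
OPERATING_LAMBDA_MAX = 25.0
OPERATING_K_ALPHA = 0.01
OPERATING_K_I = 0.01
CONTRAST_THRESHOLD = 0.03   # perceptual threshold used as calibration anchor


@dataclass
class ResponseSummary:
    """Steady-state response descriptors at one operating point."""

    lambda_: float
    peak: float                  # max of the steady profile
    R: float                     # peak above baseline M
    M: float                     # baseline (peak at lambda_min)
    delta_deg: Optional[float]   # tuning width at half height (tuned states)
    c: Optional[float] = None


def naka_rushton(c, r_max: float, c50: float, n: float):
    """Saturating contrast-response function r_max * c^n / (c^n + c50^n)."""
    if c50 <= 0 or n <= 0 or r_max <= 0:
        raise ValueError("Naka-Rushton parameters must be positive")
    c = np.asarray(c, dtype=float)
    out = r_max * c ** n / (c ** n + c50 ** n)
    return float(out) if out.ndim == 0 else out


def tuning_width(profile: np.ndarray, grid: RingGrid = DEFAULT_GRID) -> float:
    """Width at half height (degrees) of a tuned profile, by inverse
    interpolation above the profile's own minimum."""
    p = np.asarray(profile, float)
    lo, hi = p.min(), p.max()
    half = lo + 0.5 * (hi - lo)
    # walk out from the peak in both directions to the half-height crossing
    k_pk = int(np.argmax(p))
    n = len(p)
    deg = 360.0 / n

    def arm(direction: int) -> float:
        prev = p[k_pk]
        for step in range(1, n):
            k = (k_pk + direction * step) % n
            cur = p[k]
            if cur <= half:
                frac = (prev - half) / (prev - cur)
                return (step - 1 + frac) * deg
            prev = cur
        return 180.0

    return arm(+1) + arm(-1)


def _stationary_equilibrium(params: ModelParams, inp: InputProfile,
                            grid: RingGrid, guess: Optional[np.ndarray]):
    """Damped fixed-point iteration for p = S(...) with alpha = p, then a
    Newton polish through the reduced system."""
    from .ring_model import kernel_matrix, sigmoid

    conv = kernel_matrix(grid, params)
    p = guess if guess is not None else np.full(grid.n_points, 0.1)
    lam, ka, kI, T = params.lambda_, params.k_alpha, params.k_I, params.T
    for _ in range(200000):
        x = lam * (conv @ p - ka * p + kI * inp.I - T)
        pn = sigmoid(x)
        if np.max(np.abs(pn - p)) < 1e-13:
            break
        p += 0.5 * (pn - p)
    return p


def steady_response(
    lambda_: float,
    inp: InputProfile,
    k_alpha: float = OPERATING_K_ALPHA,
    k_I: float = OPERATING_K_I,
    M: Optional[float] = None,
    grid: RingGrid = DEFAULT_GRID,
    params_base: Optional[ModelParams] = None,
    guess: Optional[np.ndarray] = None,
    check_stability: bool = False,
) -> ResponseSummary:
    """Stable steady response at (lambda, k_alpha) for a given input.

    ``M`` defaults to the peak response at lambda = 13 on the same input
    (computed on the fly if not supplied).  If ``check_stability`` is set
    and the equilibrium is oscillatory unstable, a RuntimeError is raised.
    """
    base = params_base if params_base is not None else ModelParams()
    params = base.replace(lambda_=lambda_, k_alpha=k_alpha, k_I=k_I, k_X=0.0)
    p = _stationary_equilibrium(params, inp, grid, guess)
    if check_stability:
        prob = _ReducedProblem(params, inp, grid)
        from .reduction_bifurcation import project_to_modes

        y = np.concatenate([project_to_modes(p, grid)] * 2)
        y = _newton(prob, y)
        ev = _sorted_eigs(prob.jacobian(y))
        if ev[0].real > 0:
            raise RuntimeError(
                f"operating point lambda={lambda_} is not steady "
                f"(leading eigenvalue {ev[0]:.3e})"
            )
    if M is None:
        M = (steady_response(OPERATING_LAMBDA_MIN, inp, k_alpha, k_I,
                             M=0.0, grid=grid, params_base=base).peak)
    peak = float(p.max())
    R = peak - M
    tuned = (peak - p.min()) > 0.01
    delta = tuning_width(p, grid) if tuned else None
    return ResponseSummary(lambda_=lambda_, peak=peak, R=R, M=M,
                           delta_deg=delta)


def response_curve(
    lambdas: Sequence[float],
    inp: Optional[InputProfile] = None,
    k_alpha: float = OPERATING_K_ALPHA,
    k_I: float = OPERATING_K_I,
    grid: RingGrid = DEFAULT_GRID,
):
    """Peak steady response along a lambda grid (warm-started sweep).

    Returns (lambdas, peaks) arrays; R and M are derived by the caller.
    """
    if inp is None:
        inp = build_input(grid, "simple_1D")
    base = ModelParams()
    peaks = []
    guess = None
    from .ring_model import kernel_matrix, sigmoid

    for lam in lambdas:
        params = base.replace(lambda_=lam, k_alpha=k_alpha, k_I=k_I)
        conv = kernel_matrix(grid, params)
        p = guess if guess is not None else np.full(grid.n_points, 0.1)
        for _ in range(200000):
            x = lam * (conv @ p - k_alpha * p + k_I * inp.I - params.T)
            pn = sigmoid(x)
            if np.max(np.abs(pn - p)) < 1e-13:
                break
            p += 0.5 * (pn - p)
        guess = p.copy()
        peaks.append(float(p.max()))
    return np.asarray(lambdas, float), np.asarray(peaks)


def hopf_lambda_for_input(
    inp: InputProfile,
    k_alpha: float = OPERATING_K_ALPHA,
    k_I: float = OPERATING_K_I,
    tau_alpha: float = 16500.0,
    grid: RingGrid = DEFAULT_GRID,
    bracket=(15.0, 26.0),
) -> float:
    """Slope lambda at which the input-tuned equilibrium loses stability.

    The leading eigenvalue's real part of the reduced Jacobian is bisected
    in lambda; for the complex input on the operating line this is the
    travelling-wave Hopf that seeds the H<->V oscillation.
    """
    base = ModelParams(k_alpha=k_alpha, k_I=k_I, tau_alpha=tau_alpha)

    def max_re(lam: float) -> float:
        params = base.replace(lambda_=lam)
        p = _stationary_equilibrium(params, inp, grid, None)
        prob = _ReducedProblem(params, inp, grid)
        from .reduction_bifurcation import project_to_modes

        y = np.concatenate([project_to_modes(p, grid)] * 2)
        y = _newton(prob, y)
        return float(_sorted_eigs(prob.jacobian(y))[0].real)

    return brentq(max_re, *bracket, xtol=1e-6)


@dataclass
class ContrastMap:
    """Monotone map lambda(c) matching the Naka-Rushton contrast response.

    Serialisable to JSON so stochastic experiments can be reproduced from a
    stored calibration.
    """

    lam_grid: np.ndarray
    R_grid: np.ndarray            # normalised response R/R_max, monotone
    M: float
    R_max: float
    nr_r_max: float
    nr_c50: float
    nr_n: float
    lambda_min: float = OPERATING_LAMBDA_MIN
    lambda_max: float = OPERATING_LAMBDA_MAX
    c_thr: float = CONTRAST_THRESHOLD
    hopf_lambda_at_thr: Optional[float] = None

    def lambda_of(self, c) -> float:
        """Invert R against the Naka-Rushton curve: lambda(c) = R^-1(NR(c))."""
        y = naka_rushton(c, 1.0, self.nr_c50, self.nr_n)
        y = np.clip(y, 0.0, self.R_grid[-1])
        # invert on the strictly increasing part (R is flat to quadrature
        # noise at the bottom of the operating line)
        keep = np.concatenate([[True], np.diff(self.R_grid) > 0])
        lam = np.interp(y, self.R_grid[keep], self.lam_grid[keep])
        out = np.clip(lam, self.lambda_min, self.lambda_max)
        return float(out) if np.ndim(c) == 0 else out

    def to_json(self, path) -> None:
        payload = {
            "lam_grid": self.lam_grid.tolist(),
            "R_grid": self.R_grid.tolist(),
            "M": self.M, "R_max": self.R_max,
            "nr_r_max": self.nr_r_max, "nr_c50": self.nr_c50,
            "nr_n": self.nr_n,
            "lambda_min": self.lambda_min, "lambda_max": self.lambda_max,
            "c_thr": self.c_thr, "hopf_lambda_at_thr": self.hopf_lambda_at_thr,
        }
        with open(path, "w") as f:
            json.dump(payload, f, indent=1)

    @classmethod
    def from_json(cls, path) -> "ContrastMap":
        with open(path) as f:
            d = json.load(f)
        d["lam_grid"] = np.asarray(d["lam_grid"])
        d["R_grid"] = np.asarray(d["R_grid"])
        return cls(**d)


def calibrate_lambda_of_contrast(
    lam_grid: Optional[Sequence[float]] = None,
    nr_n: float = 3.0,
    nr_c50: Optional[float] = None,
    c_thr: float = CONTRAST_THRESHOLD,
    tau_alpha: float = 16500.0,
    grid: RingGrid = DEFAULT_GRID,
) -> ContrastMap:
    """Build the operating-line contrast map.

    Steps: (1) sweep the simple-input steady response over the lambda grid
    and normalise R(lambda) = (peak - M)/R_max, enforcing monotonicity
    (the raw curve is flat to ~1e-4 near lambda_min); (2) if ``nr_c50`` is
    not given, anchor it so that lambda(c_thr) equals the complex-input
    Hopf slope at c_thr — the model's oscillation onset then coincides
    with the perceptual contrast threshold; (3) return the inverse map,
    clamped to [13, 25], which saturates for c beyond ~0.2.

    Raises a calibration error if R(lambda) is not monotone beyond
    quadrature noise.
    """
    if lam_grid is None:
        lam_grid = np.linspace(OPERATING_LAMBDA_MIN, OPERATING_LAMBDA_MAX, 49)
    lam_grid = np.asarray(lam_grid, float)
    lams, peaks = response_curve(lam_grid)
    M = peaks[0]
    R_max = peaks[-1] - M
    Rn = (peaks - M) / R_max
    drops = np.diff(Rn)
    if np.any(drops < -1e-3):
        k = int(np.argmin(drops))
        raise RuntimeError(
            f"R(lambda) is non-monotone on [{lams[k]:.3f}, {lams[k+1]:.3f}]"
        )
    Rn = np.maximum.accumulate(Rn)
    hopf_lam = None
    if nr_c50 is None:
        inp_thr = build_input(grid, "complex", c=c_thr)
        hopf_lam = hopf_lambda_for_input(inp_thr, tau_alpha=tau_alpha,
                                         grid=grid)
        y_star = float(np.interp(hopf_lam, lams, Rn))
        if not 0.0 < y_star < 1.0:
            raise RuntimeError("Hopf level outside the response range; "
                               "cannot anchor c50")
        # NR(c_thr) = y_star  =>  c50 = c_thr * ((1 - y)/y)^(1/n)
        nr_c50 = c_thr * ((1.0 - y_star) / y_star) ** (1.0 / nr_n)
    return ContrastMap(lam_grid=lams, R_grid=Rn, M=float(M),
                       R_max=float(R_max), nr_r_max=float(R_max),
                       nr_c50=float(nr_c50), nr_n=float(nr_n),
                       c_thr=c_thr, hopf_lambda_at_thr=hopf_lam)
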