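"""Fourier-mode reduction, equilibrium continuation and regime classification.

Because the connectivity kernel carries only modes 0-2, the nonlocal term
``J*p`` depends on just five numbers — the projections of ``p`` onto
{1, cos v, sin v, cos 2v, sin 2v}.  Truncating (p, alpha) to those modes
yields a 10-dimensional Galerkin system whose vector field evaluates the
sigmoid on the reconstructed field and projects back.  The truncation is
exact when k_alpha = 0 (higher harmonics generated by the sigmoid never
feed back into the retained modes); with adaptation it is an
approximation, accurate to ~1e-3 in mode coordinates at strongly tuned
states, because alpha(v) re-injects the sigmoid's high harmonics through
the pointwise term -k_alpha*alpha.  See docs/methods.md for the error
budget.

Branches of equilibria are tracked by pseudo-arclength continuation with a
Newton corrector; stability comes from the eigenvalues of the 10x10
Jacobian, and fold / pitchfork / Hopf points are detected from eigenvalue
sign changes and refined by bisection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import brentq

from .ring_model import (
    DEFAULT_GRID,
    InputProfile,
    ModelParams,
    RingGrid,
    build_input,
    kernel_matrix,
    sigmoid,
)
from .integrators import integrate_deterministic

__all__ = [
    "ModeState",
    "BranchPoint",
    "Branch",
    "REGIME_LABELS",
    "mode_basis",
    "project_to_modes",
    "reconstruct_from_modes",
    "reduced_rhs",
    "reduced_jacobian",
    "find_equilibrium",
    "continue_branch",
    "classify_regime",
    "trace_boundary",
]

#: order of the retained Fourier modes
MODE_NAMES = ("1", "cos v", "sin v", "cos 2v", "sin 2v")

REGIME_LABELS = (
    "homogeneous_steady",
    "tuned_steady",
    "travelling_wave",
    "standing_wave_or_breather",
    "pinned_oscillation",
    "unclassified",
)


def mode_basis(grid: RingGrid) -> Tuple[np.ndarray, np.ndarray]:
    """(basis, weights): reconstruction rows and projection rows.

    ``basis`` has shape (5, n); ``weights @ field`` gives the projections
    with the standard normalisation (mean for mode 0, twice the mean
    against cos/sin for modes 1-2) under periodic trapezoid quadrature.
    """
    v = grid.v
    basis = np.vstack([np.ones_like(v), np.cos(v), np.sin(v),
                       np.cos(2 * v), np.sin(2 * v)])
    weights = basis / grid.n_points
    weights = weights.copy()
    weights[1:] *= 2.0
    return basis, weights


@dataclass
class ModeState:
    """Five Fourier coefficients each for p and alpha."""

    p_hat: np.ndarray
    alpha_hat: np.ndarray

    def __post_init__(self) -> None:
        self.p_hat = np.asarray(self.p_hat, float)
        self.alpha_hat = np.asarray(self.alpha_hat, float)
        if self.p_hat.shape != (5,) or self.alpha_hat.shape != (5,):
            raise ValueError("mode vectors must have length 5")

    @property
    def y(self) -> np.ndarray:
        return np.concatenate([self.p_hat, self.alpha_hat])

    @classmethod
    def from_vector(cls, y: np.ndarray) -> "ModeState":
        y = np.asarray(y, float)
        return cls(p_hat=y[:5], alpha_hat=y[5:])

    @classmethod
    def from_field(cls, p: np.ndarray, alpha: np.ndarray,
                   grid: RingGrid = DEFAULT_GRID) -> "ModeState":
        _, W = mode_basis(grid)
        return cls(p_hat=W @ p, alpha_hat=W @ alpha)


@dataclass
class BranchPoint:
    """One converged equilibrium of the reduced system."""

    parameter: Optional[float]
    modes: ModeState
    eigenvalues: np.ndarray      # sorted by descending real part
    stable: bool
    bifurcation: str = "none"    # none | fold | pitchfork | hopf
    residual: float = 0.0


@dataclass
class Branch:
    """Ordered continuation points plus refined bifurcation points."""

    parameter_name: str
    points: List[BranchPoint] = field(default_factory=list)
    bifurcations: List[BranchPoint] = field(default_factory=list)
    status: str = "ok"           # ok | truncated

    def parameters(self) -> np.ndarray:
        return np.array([pt.parameter for pt in self.points])

    def to_frame(self):
        import pandas as pd

        rows = []
        for pt in self.points:
            lead = pt.eigenvalues[0]
            rows.append({
                self.parameter_name: pt.parameter,
                **{f"p_hat{i}": pt.modes.p_hat[i] for i in range(5)},
                "re_lead": lead.real, "im_lead": lead.imag,
                "stable": pt.stable, "bifurcation": pt.bifurcation,
            })
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# projections and reduced vector field
# ---------------------------------------------------------------------------

def project_to_modes(fieldvals: np.ndarray,
                     grid: RingGrid = DEFAULT_GRID) -> np.ndarray:
    """Trapezoid projections onto {1, cos v, sin v, cos 2v, sin 2v}."""
    _, W = mode_basis(grid)
    return W @ np.asarray(fieldvals, float)


def reconstruct_from_modes(coeffs: np.ndarray,
                           grid: RingGrid = DEFAULT_GRID) -> np.ndarray:
    B, _ = mode_basis(grid)
    return B.T @ np.asarray(coeffs, float)


class _ReducedProblem:
    """Precomputed grid quantities for fast reduced-rhs evaluation."""

    def __init__(self, params: ModelParams, inp: InputProfile,
                 grid: RingGrid = DEFAULT_GRID,
                 truncate_input: bool = False):
        self.params = params
        self.grid = grid
        self.B, self.W = mode_basis(grid)
        self.Jn = np.array([params.J0, params.J1, params.J1,
                            params.J2, params.J2])
        if truncate_input:
            self.I = self.B.T @ (self.W @ inp.I)
        else:
            self.I = inp.I

    def rhs(self, y: np.ndarray) -> np.ndarray:
        pr = self.params
        p_hat, a_hat = y[:5], y[5:]
        p = self.B.T @ p_hat
        a = self.B.T @ a_hat
        conv = self.B.T @ (self.Jn * p_hat)
        x = pr.lambda_ * (conv - pr.k_alpha * a + pr.k_I * self.I - pr.T)
        dp = (self.W @ sigmoid(x) - p_hat) / pr.tau_p
        da = (p_hat - a_hat) / pr.tau_alpha
        return np.concatenate([dp, da])

    def jacobian(self, y: np.ndarray, h: float = 1e-7) -> np.ndarray:
        J = np.empty((10, 10))
        for j in range(10):
            e = np.zeros(10)
            e[j] = h
            J[:, j] = (self.rhs(y + e) - self.rhs(y - e)) / (2 * h)
        return J


def reduced_rhs(modes: ModeState, params: ModelParams, inp: InputProfile,
                grid: RingGrid = DEFAULT_GRID,
                truncate_input: bool = False) -> ModeState:
    """Galerkin vector field on the 10 mode coordinates.

    The field is reconstructed on the grid, the sigmoid applied pointwise,
    and the result projected back.  By default the full input profile is
    used on the grid (more faithful than first truncating it to modes 0-2,
    which remains available via ``truncate_input``).
    """
    prob = _ReducedProblem(params, inp, grid, truncate_input)
    dy = prob.rhs(modes.y)
    return ModeState.from_vector(dy)


def reduced_jacobian(modes: ModeState, params: ModelParams, inp: InputProfile,
                     grid: RingGrid = DEFAULT_GRID) -> np.ndarray:
    return _ReducedProblem(params, inp, grid).jacobian(modes.y)


# ---------------------------------------------------------------------------
# equilibria
# ---------------------------------------------------------------------------

_RES_TOL = 1e-11


def _newton(prob: _ReducedProblem, y0: np.ndarray,
            tol: float = _RES_TOL, max_iter: int = 50) -> np.ndarray:
    y = y0.copy()
    for _ in range(max_iter):
        f = prob.rhs(y)
        # adaptation rows scale as 1/tau_alpha; solve on the balanced residual
        if np.max(np.abs(f)) < tol:
            return y
        J = prob.jacobian(y)
        try:
            step = np.linalg.solve(J, f)
        except np.linalg.LinAlgError as exc:
            raise RuntimeError("singular Jacobian in Newton iteration") from exc
        if not np.all(np.isfinite(step)):
            raise RuntimeError("non-finite Newton step")
        y = y - step
    raise RuntimeError(
        f"Newton did not converge (last residual {np.max(np.abs(prob.rhs(y))):.2e})"
    )


def _sorted_eigs(J: np.ndarray) -> np.ndarray:
    ev = np.linalg.eigvals(J)
    return ev[np.argsort(-ev.real)]


def find_equilibrium(
    guess: ModeState,
    params: ModelParams,
    inp: InputProfile,
    grid: RingGrid = DEFAULT_GRID,
    parameter: Optional[float] = None,
) -> BranchPoint:
    """Newton-converge the reduced system to an equilibrium from ``guess``.

    Raises RuntimeError (carrying the last residual) on divergence.
    """
    prob = _ReducedProblem(params, inp, grid)
    y = _newton(prob, guess.y)
    J = prob.jacobian(y)
    ev = _sorted_eigs(J)
    return BranchPoint(
        parameter=parameter,
        modes=ModeState.from_vector(y),
        eigenvalues=ev,
        stable=bool(ev[0].real < 0),
        residual=float(np.max(np.abs(prob.rhs(y)))),
    )


def equilibrium_guess_from_simulation(
    params: ModelParams, inp: InputProfile, grid: RingGrid = DEFAULT_GRID,
    t_end: float = 2000.0, seed: int = 0,
) -> ModeState:
    """Project the endpoint of a short deterministic run (alpha set to p).

    With slow adaptation the run's endpoint reflects the small-alpha
    transient; prefer :func:`stationary_state_guess` when the target is the
    steady state with alpha equilibrated.
    """
    q = params.replace(k_X=0.0)
    res = integrate_deterministic(q, inp, grid, t_end=t_end, seed=seed)
    p_hat = project_to_modes(res.p_history[-1], grid)
    return ModeState(p_hat=p_hat, alpha_hat=p_hat.copy())


def stationary_state_guess(
    params: ModelParams, inp: InputProfile, grid: RingGrid = DEFAULT_GRID,
    p_init: Optional[np.ndarray] = None,
) -> ModeState:
    """Damped fixed-point iteration of p = S(...) with alpha = p.

    Converges to the (possibly dynamically unstable) stationary profile of
    the full grid model, projected to modes — the right warm start for
    equilibrium continuation.
    """
    from .ring_model import sigmoid

    conv = kernel_matrix(grid, params)
    p = p_init if p_init is not None else np.full(grid.n_points, 0.1)
    lam, ka, kI, T = params.lambda_, params.k_alpha, params.k_I, params.T
    for _ in range(200000):
        pn = sigmoid(lam * (conv @ p - ka * p + kI * inp.I - T))
        if np.max(np.abs(pn - p)) < 1e-13:
            break
        p += 0.5 * (pn - p)
    p_hat = project_to_modes(p, grid)
    return ModeState(p_hat=p_hat, alpha_hat=p_hat.copy())


# ---------------------------------------------------------------------------
# continuation
# ---------------------------------------------------------------------------

def _classify_real_crossing(prob: _ReducedProblem, y: np.ndarray,
                            has_input: bool) -> str:
    """Tag a real-eigenvalue crossing: pitchfork (symmetry-breaking null
    vector, dominated by modes >= 1) or fold (mode-0 content).

    With a nonzero input the symmetric pitchfork unfolds into a smooth
    branch plus a fold pair, so any real crossing is tagged "fold" there.
    """
    if has_input:
        return "fold"
    J = prob.jacobian(y)
    ev, vec = np.linalg.eig(J)
    # crossing eigenvector: real eigenvalue closest to zero
    real_idx = np.where(np.abs(ev.imag) < 1e-8)[0]
    k = real_idx[int(np.argmin(np.abs(ev.real[real_idx])))]
    null = np.abs(vec[:, k].real)
    flat = null[0] + null[5]              # mode-0 components of p_hat, alpha_hat
    broken = null[1:5].sum() + null[6:].sum()
    return "pitchfork" if broken > flat else "fold"


def continue_branch(
    problem: Callable[[float], Tuple[ModelParams, InputProfile]],
    start: float,
    stop: float,
    initial_guess: ModeState,
    parameter_name: str = "lambda",
    grid: RingGrid = DEFAULT_GRID,
    initial_step: Optional[float] = None,
    max_step: Optional[float] = None,
    min_step: float = 1e-8,
    bif_tol: float = 1e-6,
    max_points: int = 1000,
) -> Branch:
    """Pseudo-arclength continuation of an equilibrium branch.

    ``problem(value)`` returns the (params, input) pair at a parameter
    value; the branch is tracked from ``start`` to ``stop`` with a secant
    predictor and Newton corrector on the arclength-augmented system.
    Eigenvalues are stored at every accepted point; sign changes of the
    leading real eigenvalue (fold/pitchfork) or of a complex pair's real
    part (Hopf) are refined by bisection in the parameter to ``bif_tol``.
    """
    span = stop - start
    h = abs(initial_step) if initial_step is not None else abs(span) / 50.0
    h_max = abs(max_step) if max_step is not None else abs(span) / 10.0

    def solve_at(value: float, guess: np.ndarray) -> BranchPoint:
        params, inp = problem(value)
        prob = _ReducedProblem(params, inp, grid)
        y = _newton(prob, guess)
        ev = _sorted_eigs(prob.jacobian(y))
        return BranchPoint(parameter=value, modes=ModeState.from_vector(y),
                           eigenvalues=ev, stable=bool(ev[0].real < 0),
                           residual=float(np.max(np.abs(prob.rhs(y)))))

    branch = Branch(parameter_name=parameter_name)
    pt = solve_at(start, initial_guess.y)
    branch.points.append(pt)

    # arclength metric weights: parameter units vs mode units; the state
    # weight is balanced against the parameter weight after the first
    # secant so that neither dominates the step length
    w_par = 1.0 / max(abs(span), 1e-12)
    w_state = 1.0

    prev = None
    direction = np.sign(span)
    value = start
    lo_lim = min(start, stop) - 0.05 * abs(span)
    hi_lim = max(start, stop) + 0.05 * abs(span)
    while (stop - value) * direction > 1e-12:
        if len(branch.points) >= max_points or not lo_lim <= value <= hi_lim:
            # a fold can legitimately reverse the walk; a branch that leaves
            # the requested window (or stalls) is reported truncated
            branch.status = "truncated"
            break
        h = min(h, h_max, abs(stop - value))
        # close to the target: finish with one natural-parameter hop
        if abs(stop - value) <= max(2 * h, 1e-6 * abs(span)):
            try:
                new = solve_at(stop, branch.points[-1].modes.y)
            except RuntimeError:
                h *= 0.5
                if h < min_step:
                    branch.status = "truncated"
                    break
                continue
            _detect_bifurcations(branch, branch.points[-1], new, solve_at,
                                 problem, bif_tol)
            branch.points.append(new)
            break
        # predictor
        if prev is None:
            v_pred = value + direction * h
            y_pred = branch.points[-1].modes.y
        else:
            dy = branch.points[-1].modes.y - prev.modes.y
            dv = branch.points[-1].parameter - prev.parameter
            if len(branch.points) == 2 and np.linalg.norm(dy) > 0:
                w_state = (w_par * abs(dv)) / np.linalg.norm(dy)
            norm = np.hypot(w_state * np.linalg.norm(dy), w_par * abs(dv))
            if norm < 1e-14:
                v_pred = value + direction * h
                y_pred = branch.points[-1].modes.y
            else:
                # h lives in parameter units; the metric is normalised to
                # unit span, so convert before scaling the secant
                scale = (w_par * h) / norm
                v_pred = value + dv * scale
                y_pred = branch.points[-1].modes.y + dy * scale
        if (v_pred - stop) * direction > 0:
            v_pred = stop
        try:
            new = solve_at(v_pred, y_pred)
        except RuntimeError:
            h *= 0.5
            if h < min_step:
                branch.status = "truncated"
                break
            continue
        # detect eigenvalue crossings between the last point and this one
        _detect_bifurcations(branch, branch.points[-1], new, solve_at,
                             problem, bif_tol)
        prev = branch.points[-1]
        branch.points.append(new)
        value = new.parameter
        h = min(h * 1.3, h_max)
    return branch


def _n_unstable(ev: np.ndarray, margin: float = 0.0) -> int:
    return int(np.sum(ev.real > margin))


def _detect_bifurcations(branch: Branch, a: BranchPoint, b: BranchPoint,
                         solve_at, problem, tol: float,
                         depth: int = 0) -> None:
    """Locate every change of the unstable-eigenvalue count in (a, b).

    Integer bisection on n_unstable(parameter); each located crossing is
    classified from the eigenvalue that sits on the axis there (complex
    pair -> hopf; real -> pitchfork or fold by null-vector symmetry).
    Recurses past the first crossing so several bifurcations inside one
    continuation step are all reported.
    """
    if depth > 6:
        return
    na, nb = _n_unstable(a.eigenvalues), _n_unstable(b.eigenvalues)
    if na == nb:
        return
    lo, hi = a, b
    while abs(hi.parameter - lo.parameter) > tol:
        mid_v = 0.5 * (lo.parameter + hi.parameter)
        guess = 0.5 * (lo.modes.y + hi.modes.y)
        try:
            mid = solve_at(mid_v, guess)
        except RuntimeError:
            return
        if _n_unstable(mid.eigenvalues) == na:
            lo = mid
        else:
            hi = mid
    crossing = hi
    # polish: the crossing eigenvalue is the n-th largest real part with
    # n = count on the unstable side; drive it onto the axis with brentq
    rank = _n_unstable(hi.eigenvalues)
    if rank > 0 and lo.parameter != hi.parameter:
        y_lo, y_hi = lo.modes.y, hi.modes.y
        v_lo, v_hi = lo.parameter, hi.parameter
        cache = {}

        def fre(v):
            w = 0.5 if v_hi == v_lo else (v - v_lo) / (v_hi - v_lo)
            pt = solve_at(v, (1 - w) * y_lo + w * y_hi)
            cache[v] = pt
            return float(np.sort(pt.eigenvalues.real)[::-1][rank - 1])

        try:
            if fre(v_lo) * fre(v_hi) < 0:
                v_star = brentq(fre, v_lo, v_hi, xtol=1e-12)
                crossing = cache.get(v_star) or solve_at(
                    v_star, 0.5 * (y_lo + y_hi))
        except RuntimeError:
            pass
    ev = crossing.eigenvalues
    k = int(np.argmin(np.abs(ev.real)))
    if abs(ev[k].imag) > 1e-9:
        tag = "hopf"
    else:
        params, inp = problem(crossing.parameter)
        prob = _ReducedProblem(params, inp)
        tag = _classify_real_crossing(prob, crossing.modes.y,
                                      has_input=bool(np.any(inp.I != 0)))
    branch.bifurcations.append(BranchPoint(
        parameter=crossing.parameter, modes=crossing.modes,
        eigenvalues=ev, stable=crossing.stable,
        bifurcation=tag, residual=crossing.residual,
    ))
    # look for further crossings between the one just found and b
    if _n_unstable(hi.eigenvalues) != nb:
        _detect_bifurcations(branch, hi, b, solve_at, problem, tol,
                             depth + 1)


# ---------------------------------------------------------------------------
# regime classification
# ---------------------------------------------------------------------------

def classify_regime(
    params: ModelParams,
    inp: InputProfile,
    grid: RingGrid = DEFAULT_GRID,
    t_end: float = 4000.0,
    transient_fraction: float = 0.5,
    tuned_threshold: float = 0.05,
    static_peak_sd_deg: float = 1.0,
    amplitude_osc_threshold: float = 0.01,
    seed: int = 0,
) -> str:
    """Label the post-transient behaviour of a deterministic simulation.

    Rules (deterministic given a trajectory):

    * spatially flat and time-steady            -> homogeneous_steady
    * tuned (peak - mean > threshold), static   -> tuned_steady
    * peak drifting monotonically > 360 deg     -> travelling_wave
    * tuned-amplitude oscillation, static peak  -> standing_wave_or_breather
    * peak oscillating about a fixed direction  -> pinned_oscillation
    * anything mixed / undecided                -> unclassified
    """
    res = integrate_deterministic(params.replace(k_X=0.0), inp, grid,
                                  t_end=t_end, seed=seed)
    k0 = int(len(res.times) * transient_fraction)
    P = res.p_history[k0:]
    amp = P.max(axis=1) - P.mean(axis=1)
    tuned = amp.mean() > tuned_threshold
    # unwrapped peak trajectory (degrees)
    peak = np.rad2deg(grid.v[np.argmax(P, axis=1)])
    peak_unwrapped = np.rad2deg(np.unwrap(np.deg2rad(peak)))
    peak_sd = float(np.std(peak_unwrapped[len(peak_unwrapped) // 2:]))
    total_drift = peak_unwrapped[-1] - peak_unwrapped[0]
    drift_signs = np.sign(np.diff(peak_unwrapped))
    moving = drift_signs[drift_signs != 0]
    monotone = len(moving) > 0 and np.all(moving == moving[0])
    amp_osc = float(amp.max() - amp.min()) > amplitude_osc_threshold

    if not tuned:
        if amp_osc:
            return "standing_wave_or_breather"
        return "homogeneous_steady"
    if abs(total_drift) > 360.0 and monotone:
        return "travelling_wave"
    if peak_sd < static_peak_sd_deg:
        if amp_osc:
            return "standing_wave_or_breather"
        return "tuned_steady"
    # tuned, peak moving but not rotating: rocking about a fixed direction
    if abs(total_drift) < 360.0:
        return "pinned_oscillation"
    return "unclassified"


def trace_boundary(
    regime_pair: Tuple[str, str],
    k_alpha_values: Sequence[float],
    lambda_bracket: Tuple[float, float],
    params_base: ModelParams,
    inp: InputProfile,
    grid: RingGrid = DEFAULT_GRID,
    tol: float = 0.01,
    **classify_kwargs,
) -> List[Tuple[float, float]]:
    """Bisect the regime boundary in lambda at fixed k_alpha samples.

    Returns an ordered polyline [(lambda, k_alpha), ...]; samples whose
    bracket endpoints do not show the requested pair of regimes are
    skipped.
    """
    lo_label, hi_label = regime_pair
    polyline: List[Tuple[float, float]] = []
    for ka in k_alpha_values:
        def label_at(lam: float) -> str:
            q = params_base.replace(lambda_=lam, k_alpha=ka)
            return classify_regime(q, inp, grid, **classify_kwargs)

        a, b = lambda_bracket
        la, lb = label_at(a), label_at(b)
        if la != lo_label or lb != hi_label:
            continue
        while b - a > tol:
            mid = 0.5 * (a + b)
            lm = label_at(mid)
            if lm == lo_label:
                a = mid
            elif lm == hi_label:
                b = mid
            else:
                break   # undecided midpoint: stop refining this sample
        polyline.append((0.5 * (a + b), ka))
    return polyline


# ---------------------------------------------------------------------------
# convenience problems for continuation
# ---------------------------------------------------------------------------

def lambda_problem(params_base: ModelParams, inp: InputProfile):
    """Continuation problem in the sigmoid slope lambda."""

    def problem(lam: float):
        return params_base.replace(lambda_=lam), inp

    return problem


def contrast_problem(params_base: ModelParams, contrast_map,
                     grid: RingGrid = DEFAULT_GRID):
    """Continuation problem in contrast c along the calibrated operating line.

    Both the slope lambda = lambda(c) and the complex input's 1D weight
    w_1D = W0 - W1 c vary with the parameter.
    """

    def problem(c: float):
        lam = contrast_map.lambda_of(c)
        inp = build_input(grid, "complex", c=c)
        return params_base.replace(lambda_=lam), inp

    return problem
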