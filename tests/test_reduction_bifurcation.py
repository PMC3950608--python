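"""Tests of the mode reduction, equilibrium continuation, bifurcation
detection and regime classification."""

import numpy as np
import pytest

from ringswitch import (
    ModelParams,
    ModeState,
    build_input,
    classify_regime,
    find_equilibrium,
    flat_fixed_point,
    flat_hopf_lambda,
    flat_pitchfork_lambda,
    integrate_deterministic,
    project_to_modes,
    reconstruct_from_modes,
    reduced_rhs,
)
from ringswitch.reduction_bifurcation import (
    continue_branch,
    lambda_problem,
    stationary_state_guess,
    trace_boundary,
)


# ---------------------------------------------------------------------------
# projections
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("field_fn, expected", [
    (lambda v: np.full_like(v, 0.3), [0.3, 0, 0, 0, 0]),
    (lambda v: np.cos(v), [0, 1, 0, 0, 0]),
    (lambda v: 0.1 + 0.2 * np.sin(2 * v), [0.1, 0, 0, 0, 0.2]),
    (lambda v: np.sin(v) - 0.4 * np.cos(2 * v), [0, 0, 1, -0.4, 0]),
])
def test_projection_examples(grid, field_fn, expected):
    got = project_to_modes(field_fn(grid.v), grid)
    assert np.allclose(got, expected, atol=1e-12)


def test_projection_reconstruction_roundtrip(grid):
    coeffs = np.array([0.2, -0.1, 0.3, 0.05, -0.2])
    assert np.allclose(project_to_modes(reconstruct_from_modes(coeffs, grid),
                                        grid), coeffs, atol=1e-12)


# ---------------------------------------------------------------------------
# reduced vector field
# ---------------------------------------------------------------------------

def test_reduced_rhs_mode0_matches_scalar_equation(grid):
    """A mode-0-only state reproduces the scalar flat-state dynamics."""
    from ringswitch import sigmoid

    params = ModelParams(lambda_=15.0, k_alpha=0.01, tau_alpha=100.0)
    inp = build_input(grid, "none")
    m = ModeState(p_hat=np.array([0.2, 0, 0, 0, 0]),
                  alpha_hat=np.array([0.1, 0, 0, 0, 0]))
    d = reduced_rhs(m, params, inp, grid)
    x = params.lambda_ * (params.J0 * 0.2 - params.k_alpha * 0.1 - params.T)
    assert d.p_hat[0] == pytest.approx((sigmoid(x) - 0.2) / params.tau_p,
                                       abs=1e-12)
    assert np.allclose(d.p_hat[1:], 0, atol=1e-12)
    assert d.alpha_hat[0] == pytest.approx((0.2 - 0.1) / params.tau_alpha,
                                           abs=1e-15)


def test_reduced_closure_exact_without_adaptation(grid):
    """With k_alpha = 0 the truncation closes exactly: the projected full
    equilibrium is an equilibrium of the reduced system."""
    from ringswitch.ring_model import kernel_matrix, sigmoid

    params = ModelParams(lambda_=24.0, k_alpha=0.0, tau_alpha=100.0)
    inp = build_input(grid, "none")
    conv = kernel_matrix(grid, params)
    p = 0.1 + 0.4 * np.exp(-grid.v ** 2 / 0.3)
    for _ in range(100000):
        pn = sigmoid(params.lambda_ * (conv @ p - params.T))
        if np.max(np.abs(pn - p)) < 1e-14:
            break
        p += 0.5 * (pn - p)
    m = ModeState.from_field(p, p, grid)
    d = reduced_rhs(m, params, inp, grid)
    assert np.max(np.abs(d.y)) < 1e-9


def test_reduced_galerkin_error_with_adaptation(grid):
    """With adaptation the truncation is approximate: the reduced
    equilibrium stays within ~2e-3 of the projected full equilibrium in
    mode coordinates at a strongly tuned state."""
    params = ModelParams(lambda_=24.0, k_alpha=0.01, tau_alpha=100.0)
    inp = build_input(grid, "none")
    guess = stationary_state_guess(
        params, inp, grid, p_init=0.1 + 0.4 * np.exp(-grid.v ** 2 / 0.3))
    from ringswitch.ring_model import kernel_matrix, sigmoid

    conv = kernel_matrix(grid, params)
    p = 0.1 + 0.4 * np.exp(-grid.v ** 2 / 0.3)
    for _ in range(200000):
        pn = sigmoid(params.lambda_ * (conv @ p - params.k_alpha * p
                                       - params.T))
        if np.max(np.abs(pn - p)) < 1e-14:
            break
        p += 0.5 * (pn - p)
    eq = find_equilibrium(guess, params, inp, grid)
    diff = np.max(np.abs(eq.modes.p_hat - project_to_modes(p, grid)))
    assert 0 < diff < 2e-3


def test_reduced_rhs_o2_equivariance(grid):
    """Without input, rotating the mode state (theta on mode 1, 2*theta on
    mode 2) rotates the reduced vector field identically."""
    params = ModelParams(lambda_=22.0, k_alpha=0.03, tau_alpha=100.0)
    inp = build_input(grid, "none")
    rng = np.random.default_rng(5)
    y = 0.2 * rng.standard_normal(10)

    def rotate(y, th):
        out = y.copy()
        for base in (0, 5):
            c1, s1 = np.cos(th), np.sin(th)
            c2, s2 = np.cos(2 * th), np.sin(2 * th)
            a, b = y[base + 1], y[base + 2]
            out[base + 1], out[base + 2] = c1 * a - s1 * b, s1 * a + c1 * b
            a, b = y[base + 3], y[base + 4]
            out[base + 3], out[base + 4] = c2 * a - s2 * b, s2 * a + c2 * b
        return out

    th = 0.7
    d = reduced_rhs(ModeState.from_vector(y), params, inp, grid).y
    d_rot = reduced_rhs(ModeState.from_vector(rotate(y, th)), params, inp,
                        grid).y
    assert np.allclose(d_rot, rotate(d, th), atol=1e-9)


# ---------------------------------------------------------------------------
# equilibria
# ---------------------------------------------------------------------------

def test_find_equilibrium_flat_matches_scalar_oracle(grid):
    params = ModelParams(lambda_=15.0, k_alpha=0.01, tau_alpha=100.0)
    inp = build_input(grid, "none")
    pbar = flat_fixed_point(params)
    guess = ModeState(p_hat=np.array([0.2, 0, 0, 0, 0]),
                      alpha_hat=np.array([0.2, 0, 0, 0, 0]))
    eq = find_equilibrium(guess, params, inp, grid)
    assert eq.modes.p_hat[0] == pytest.approx(pbar, abs=1e-10)
    assert np.allclose(eq.modes.p_hat[1:], 0, atol=1e-10)
    assert eq.stable
    assert eq.residual < 1e-10


def test_equilibrium_symmetric_input_even(grid):
    """A reflection-symmetric input forces an even equilibrium:
    sin-components vanish."""
    params = ModelParams(lambda_=20.0, k_alpha=0.01, k_I=0.01,
                         tau_alpha=16500.0)
    inp = build_input(grid, "complex", c=0.05)
    guess = stationary_state_guess(params, inp, grid)
    eq = find_equilibrium(guess, params, inp, grid)
    assert abs(eq.modes.p_hat[2]) < 1e-10
    assert abs(eq.modes.p_hat[4]) < 1e-10


def test_tuned_equilibrium_above_flat_level(grid):
    """Simple input, top of the operating line: the tuned peak exceeds the
    weakly tuned baseline state."""
    inp = build_input(grid, "simple_1D")
    lo = ModelParams(lambda_=13.0, k_alpha=0.01, k_I=0.01, tau_alpha=16500.0)
    hi = ModelParams(lambda_=25.0, k_alpha=0.01, k_I=0.01, tau_alpha=16500.0)
    eq_lo = find_equilibrium(stationary_state_guess(lo, inp, grid), lo, inp, grid)
    eq_hi = find_equilibrium(stationary_state_guess(hi, inp, grid), hi, inp, grid)
    peak_lo = reconstruct_from_modes(eq_lo.modes.p_hat, grid).max()
    peak_hi = reconstruct_from_modes(eq_hi.modes.p_hat, grid).max()
    assert peak_hi > peak_lo + 0.2


def test_newton_divergence_reported(grid):
    params = ModelParams(lambda_=25.0, k_alpha=0.01, tau_alpha=100.0)
    inp = build_input(grid, "none")
    wild = ModeState(p_hat=np.array([np.nan, 0, 0, 0, 0]),
                     alpha_hat=np.zeros(5))
    with pytest.raises(RuntimeError):
        find_equilibrium(wild, params, inp, grid)


# ---------------------------------------------------------------------------
# continuation
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def flat_branch(grid):
    params = ModelParams(k_alpha=0.01, tau_alpha=100.0)
    pbar = flat_fixed_point(params.replace(lambda_=12.0))
    guess = ModeState(p_hat=np.array([pbar, 0, 0, 0, 0]),
                      alpha_hat=np.array([pbar, 0, 0, 0, 0]))
    inp = build_input(grid, "none")
    branch = continue_branch(lambda_problem(params, inp), 12.0, 26.0, guess,
                             parameter_name="lambda", grid=grid)
    return params, branch


def test_flat_branch_detects_pitchfork_and_hopf(flat_branch):
    params, branch = flat_branch
    tags = {b.bifurcation: b.parameter for b in branch.bifurcations}
    assert "pitchfork" in tags and "hopf" in tags
    assert tags["pitchfork"] == pytest.approx(flat_pitchfork_lambda(params),
                                              rel=1e-6)
    assert tags["hopf"] == pytest.approx(flat_hopf_lambda(params), rel=1e-6)


def test_hopf_eigenvalues_on_axis(flat_branch):
    _, branch = flat_branch
    hopf = next(b for b in branch.bifurcations if b.bifurcation == "hopf")
    ev = hopf.eigenvalues[np.argmin(np.abs(hopf.eigenvalues.real))]
    assert abs(ev.real) < 1e-8
    assert abs(ev.imag) > 0


def test_continuation_reversible(grid):
    params = ModelParams(k_alpha=0.01, k_I=0.01, tau_alpha=16500.0)
    inp = build_input(grid, "simple_1D")
    guess = stationary_state_guess(params.replace(lambda_=14.0), inp, grid)
    problem = lambda_problem(params, inp)
    fwd = continue_branch(problem, 14.0, 20.0, guess, grid=grid)
    assert fwd.status == "ok"
    back = continue_branch(problem, 20.0, 14.0, fwd.points[-1].modes,
                           grid=grid)
    assert back.status == "ok"
    assert np.max(np.abs(back.points[-1].modes.y - fwd.points[0].modes.y)) < 1e-9


def test_branch_frame_export(flat_branch):
    _, branch = flat_branch
    df = branch.to_frame()
    assert {"lambda", "p_hat0", "re_lead", "stable",
            "bifurcation"} <= set(df.columns)
    assert len(df) == len(branch.points)


# ---------------------------------------------------------------------------
# regime classification and boundaries
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("lam, ka, kind, kI, expected", [
    (15.0, 0.010, "none", 0.0, "homogeneous_steady"),
    (24.0, 0.002, "none", 0.0, "tuned_steady"),
    (24.0, 0.050, "none", 0.0, "travelling_wave"),
    (24.0, 0.050, "simple_1D", 0.01, "pinned_oscillation"),
])
def test_classify_regimes(grid, lam, ka, kind, kI, expected):
    params = ModelParams(lambda_=lam, k_alpha=ka, k_I=kI, tau_alpha=100.0)
    inp = build_input(grid, kind)
    assert classify_regime(params, inp, grid, t_end=4000.0) == expected


def test_flat_tuned_boundary_near_pitchfork(grid):
    """At adaptation levels below the Bogdanov-Takens point the simulated
    flat/tuned boundary tracks the closed-form pitchfork.  The bump
    amplitude grows like sqrt(lambda - lambda_c), so a finite tuned
    threshold biases the detected boundary slightly rightward."""
    params = ModelParams(tau_alpha=100.0)
    inp = build_input(grid, "none")
    poly = trace_boundary(("homogeneous_steady", "tuned_steady"),
                          [0.002], (19.0, 23.0), params, inp, grid,
                          tol=0.02, t_end=8000.0, tuned_threshold=0.02)
    assert len(poly) == 1
    lam_b, ka = poly[0]
    lam_pf = flat_pitchfork_lambda(params.replace(k_alpha=ka))
    assert lam_b == pytest.approx(lam_pf, abs=0.3)
    assert lam_b >= lam_pf - 0.05
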