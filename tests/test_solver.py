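"""Solver verification against closed-form benchmarks: Poiseuille
pipe WSS, steady plane channel, and the oscillatory channel against
the exact analytic series (Womersley) solution."""
import numpy as np
import pytest

from embryoflow.hemosolver import (BoundaryConditions, FluidProps,
                                   SolverError, reynolds, solve_cycle,
                                   static_channel, static_pipe)

RHO, MU = 1060.0, 4.0e-3


def womersley_channel(y, t, a, dp0, L, omega, rho, mu):
    """Exact oscillatory plane-channel profile for inlet pressure
    dp0*sin(omega t) against a zero outlet over length L.

    Solves mu*u_yy - i*omega*rho*u_hat = i*dp0/L with u_hat(+/-a) = 0;
    u(y, t) = Re[u_hat(y) exp(i omega t)].
    """
    k = np.sqrt(1j * omega * rho / mu)
    C = -dp0 / (omega * rho * L)
    u_hat = C * (1.0 - np.cosh(k * y) / np.cosh(k * a))
    return np.real(u_hat[None, :] * np.exp(1j * omega
                                           * np.asarray(t)[:, None]))


def test_poiseuille_pipe_wss():
    """Criterion: WSS within 2% of the analytic 4*mu*Q/(pi*R^3)."""
    R = 1.5e-4
    U = 0.05
    dom = static_pipe(length=2e-3, radius=R)
    bc = BoundaryConditions(outlet_scale=U)
    sol = solve_cycle(dom, bc, FluidProps(RHO, MU))
    Q = U * np.pi * R ** 2
    exact = 4 * MU * Q / (np.pi * R ** 3)
    assert sol.meta["wss"] == pytest.approx(exact, rel=0.02)
    # parabolic profile at cell centres
    r = sol.meta["r_centers"]
    u_exact = 2 * U * (1 - (r / R) ** 2)
    assert np.allclose(sol.meta["profile"], u_exact, rtol=0.02)


def test_steady_channel_parabola():
    """Constant pressure drop over a rigid channel: Poiseuille plane
    flow u = G/(2 mu) (a^2 - y^2), WSS = G a."""
    a, L, dp0 = 1.5e-4, 2e-3, 0.5
    dom = static_channel(length=L, half_width=a, nx=48)
    bc = BoundaryConditions(inlet_pressure=lambda t: dp0,
                            outlet_bc="pressure")
    sol = solve_cycle(dom, bc, FluidProps(RHO, MU), cycles_max=8,
                      ny=16, steps_per_cycle=40)
    assert sol.converged
    G = dp0 / L
    ny = sol.u.shape[2]
    y = -a + (np.arange(ny) + 0.5) / ny * 2 * a
    u_exact = G / (2 * MU) * (a ** 2 - y ** 2)
    mid = sol.u.shape[1] // 2
    u_num = sol.u[-1, mid, :]
    assert np.max(np.abs(u_num - u_exact)) < 0.02 * u_exact.max()
    wss = np.abs(sol.tau_wall[-1, mid, :])
    assert np.allclose(wss, G * a, rtol=0.02)


@pytest.fixture(scope="module")
def oscillatory():
    """Frozen oscillatory-channel benchmark configuration."""
    a, L, T, dp0 = 1.5e-4, 2e-3, 0.45, 1.0
    omega = 2 * np.pi / T
    dom = static_channel(length=L, half_width=a, nx=48, period=T)

    cache = {}

    def solve(spc):
        if spc not in cache:
            bc = BoundaryConditions(
                inlet_pressure=lambda t: dp0 * np.sin(omega * t),
                outlet_bc="pressure")
            cache[spc] = solve_cycle(dom, bc, FluidProps(RHO, MU),
                                     cycles_max=10, ny=16,
                                     steps_per_cycle=spc)
        return cache[spc]
    return a, L, T, dp0, omega, solve


def _osc_error(sol, a, L, dp0, omega):
    ny = sol.u.shape[2]
    y = -a + (np.arange(ny) + 0.5) / ny * 2 * a
    mid = sol.u.shape[1] // 2
    u_ex = womersley_channel(y, sol.times, a, dp0, L, omega, RHO, MU)
    u_num = sol.u[:, mid, :]
    return float(np.max(np.abs(u_num - u_ex)) / np.max(np.abs(u_ex)))


def test_oscillatory_channel_vs_analytic(oscillatory):
    """Criterion: quasi-steady (alpha = 0.289) oscillatory profile
    within 3% of the analytic series solution."""
    a, L, T, dp0, omega, solve = oscillatory
    alpha = a * np.sqrt(omega * RHO / MU)
    assert alpha < 1.0                       # quasi-steady regime
    sol = solve(240)
    assert sol.converged
    assert _osc_error(sol, a, L, dp0, omega) < 0.03


def test_oscillatory_dt_refinement(oscillatory):
    """Halving dt must keep the solution within the documented 3%
    change and reduce the analytic-solution error."""
    a, L, T, dp0, omega, solve = oscillatory
    sol = solve(240)
    fine = solve(480)
    e_c = _osc_error(sol, a, L, dp0, omega)
    e_f = _osc_error(fine, a, L, dp0, omega)
    assert e_f < e_c                          # converging toward exact
    mid = sol.u.shape[1] // 2
    diff = np.max(np.abs(fine.u[1::2, mid, :] - sol.u[:, mid, :]))
    assert diff / np.max(np.abs(fine.u)) < 0.03


def test_oscillatory_mass_conservation(oscillatory):
    *_, solve = oscillatory
    sol = solve(240)
    assert sol.mass_error < 1e-2
    assert np.isfinite(sol.div_max)


def test_reynolds_region_errors():
    dom = static_pipe(length=2e-3, radius=1.5e-4)
    sol = solve_cycle(dom, BoundaryConditions(outlet_scale=0.05))
    with pytest.raises(SolverError):
        reynolds(sol, "LV")
    assert reynolds(sol, "pipe") > 0
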