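"""Projection solver for incompressible flow in a moving 2D channel.

Discretization: staggered (MAC) grid in channel-fitted coordinates
(ξ = x, η = (y − y_lo)/h with h = y_up − y_lo), semi-Lagrangian
advection traced in physical space (handles the moving grid / ALE
transport in one step), implicit viscosity with the mapped 9-point
Laplacian, and a pressure projection whose Poisson operator is the
sparse composition of the mapped divergence and gradient. Boundary
treatment follows the source study: reference-pressure inlet,
prescribed-velocity extruded outlet (the tuner's handle), no-slip
moving walls. An axisymmetric finite-volume mode covers the
Poiseuille-tube benchmark.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Tuple

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .domain import BoundaryConditions, ChannelDomain, DomainError


class SolverError(RuntimeError):
    pass


@dataclass
class FluidProps:
    """Newtonian blood analogue (defaults documented, configurable)."""

    density: float = 1060.0       # kg/m^3
    viscosity: float = 4.0e-3     # Pa*s

    def __post_init__(self) -> None:
        if self.density <= 0 or self.viscosity <= 0:
            raise ValueError("density and viscosity must be positive")

    @property
    def nu(self) -> float:
        return self.viscosity / self.density


@dataclass
class FlowSolution:
    """Fields and wall samples of the final (converged) cycle."""

    times: np.ndarray                  # (S,)
    x: np.ndarray                      # (nx+1,) face stations, m
    station_region: np.ndarray
    u: np.ndarray                      # (S, nx+1, ny) m/s
    v: np.ndarray                      # (S, nx, ny+1) m/s
    p: np.ndarray                      # (S, nx, ny) Pa (relative)
    y_lo: np.ndarray                   # (S, nx+1) m
    y_up: np.ndarray                   # (S, nx+1) m
    tau_wall: np.ndarray               # (S, nx+1, 2) signed WSS, Pa
    p_wall: np.ndarray                 # (S, nx+1, 2) Pa (relative)
    vn_wall: np.ndarray                # (S, nx+1, 2) wall vel · inward n̂
    ds_wall: np.ndarray                # (S, nx+1, 2) arc length per station, m
    converged: bool
    n_cycles: int
    convergence_history: List[float]
    mass_error: float
    div_max: float
    props: FluidProps = field(default_factory=FluidProps)
    meta: Dict[str, object] = field(default_factory=dict)

    def mean_speed(self) -> np.ndarray:
        """Cross-section mean |u| per (step, face station)."""
        return np.abs(self.u).mean(axis=2)

    def flow_rate(self) -> np.ndarray:
        """Q(t, i) per unit depth (m^2/s), signed."""
        h = self.y_up - self.y_lo
        return self.u.mean(axis=2) * h


# ----------------------------------------------------------------------
# grid geometry at one time instant
# ----------------------------------------------------------------------

class _Grid:
    def __init__(self, x: np.ndarray, y_lo: np.ndarray, y_up: np.ndarray,
                 ny: int):
        self.x = x
        self.nx = len(x) - 1
        self.ny = ny
        self.dx = float(x[1] - x[0])
        self.de = 1.0 / ny
        self.eta_c = (np.arange(ny) + 0.5) * self.de
        self.eta_f = np.arange(ny + 1) * self.de
        self.y_lo_f = y_lo
        self.y_up_f = y_up
        self.h_f = y_up - y_lo                       # (nx+1,)
        if np.any(self.h_f <= 0):
            raise SolverError("non-positive channel gap")
        self.y_lo_c = 0.5 * (y_lo[:-1] + y_lo[1:])
        self.h_c = 0.5 * (self.h_f[:-1] + self.h_f[1:])
        self.xc = 0.5 * (x[:-1] + x[1:])
        # ξ-derivatives of the walls
        self.dlo_f = np.gradient(y_lo, x)
        self.dh_f = np.gradient(self.h_f, x)
        self.dlo_c = (y_lo[1:] - y_lo[:-1]) / self.dx
        self.dh_c = (self.h_f[1:] - self.h_f[:-1]) / self.dx

    # η_x = −(y_lo_ξ + η h_ξ)/h at u nodes (faces i, centers j)
    def etax_u(self) -> np.ndarray:
        return -(self.dlo_f[:, None]
                 + self.eta_c[None, :] * self.dh_f[:, None]) \
            / self.h_f[:, None]

    def etax_v(self) -> np.ndarray:
        return -(self.dlo_c[:, None]
                 + self.eta_f[None, :] * self.dh_c[:, None]) \
            / self.h_c[:, None]

    # Y_x = y_lo_ξ + η h_ξ at G faces (centers i, faces j)
    def Yx_g(self) -> np.ndarray:
        return self.dlo_c[:, None] + self.eta_f[None, :] * self.dh_c[:, None]

    def u_xy(self) -> Tuple[np.ndarray, np.ndarray]:
        X = np.broadcast_to(self.x[:, None],
                            (self.nx + 1, self.ny)).copy()
        Y = self.y_lo_f[:, None] + self.eta_c[None, :] * self.h_f[:, None]
        return X, Y

    def v_xy(self) -> Tuple[np.ndarray, np.ndarray]:
        X = np.broadcast_to(self.xc[:, None],
                            (self.nx, self.ny + 1)).copy()
        Y = self.y_lo_c[:, None] + self.eta_f[None, :] * self.h_c[:, None]
        return X, Y


# ----------------------------------------------------------------------
# sparse operator assembly helpers
# ----------------------------------------------------------------------

def _d_eta_centers(n_i: int, ny: int, de: float) -> sp.csr_matrix:
    """η-derivative on (n_i, ny) center rows, one-sided at walls."""
    rows, cols, vals = [], [], []
    for i in range(n_i):
        for j in range(ny):
            r = i * ny + j
            if 0 < j < ny - 1:
                rows += [r, r]
                cols += [i * ny + j + 1, i * ny + j - 1]
                vals += [0.5 / de, -0.5 / de]
            elif j == 0:
                rows += [r, r]
                cols += [i * ny + 1, i * ny]
                vals += [1.0 / de, -1.0 / de]
            else:
                rows += [r, r]
                cols += [i * ny + j, i * ny + j - 1]
                vals += [1.0 / de, -1.0 / de]
    return sp.csr_matrix((vals, (rows, cols)),
                         shape=(n_i * ny, n_i * ny))


def _poisson_ops(g: _Grid, p_in_dirichlet: bool, outlet_pressure: bool
                 ) -> Tuple[sp.csr_matrix, np.ndarray, sp.csr_matrix,
                            np.ndarray, sp.csr_matrix, sp.csr_matrix]:
    """(GXU, cu0, CG, cg0, DIVU, DIVG) for the projection step.

    ``cu0``/``cg0`` multiply the inlet reference pressure (Dirichlet).
    """
    nx, ny, dx, de = g.nx, g.ny, g.dx, g.de
    Np, Nu, Ng = nx * ny, (nx + 1) * ny, nx * (ny + 1)

    DETA_P = _d_eta_centers(nx, ny, de)          # p -> dp/dη at centers

    # --- GXU: p -> physical dp/dx at u faces -------------------------
    rows, cols, vals = [], [], []
    cu0 = np.zeros(Nu)
    etax = g.etax_u()
    # ξ part
    for j in range(ny):
        for i in range(1, nx):
            r = i * ny + j
            rows += [r, r]
            cols += [i * ny + j, (i - 1) * ny + j]
            vals += [1.0 / dx, -1.0 / dx]
        r0 = 0 * ny + j
        if p_in_dirichlet:
            rows.append(r0)
            cols.append(0 * ny + j)
            vals.append(2.0 / dx)
            cu0[r0] = -2.0 / dx
        if outlet_pressure:
            rN = nx * ny + j
            rows.append(rN)
            cols.append((nx - 1) * ny + j)
            vals.append(-2.0 / dx)          # (0 - p[nx-1]) / (dx/2)
    GXI = sp.csr_matrix((vals, (rows, cols)), shape=(Nu, Np))

    # average center η-derivatives onto u faces
    rows, cols, vals = [], [], []
    for j in range(ny):
        for i in range(nx + 1):
            r = i * ny + j
            nb = []
            if i > 0:
                nb.append((i - 1) * ny + j)
            if i < nx:
                nb.append(i * ny + j)
            for c in nb:
                rows.append(r)
                cols.append(c)
                vals.append(1.0 / len(nb))
    AVP_U = sp.csr_matrix((vals, (rows, cols)), shape=(Nu, Np))
    GXU = GXI + sp.diags(etax.ravel()) @ (AVP_U @ DETA_P)

    # --- CG: p -> correction of G at η faces -------------------------
    rows, cols, vals = [], [], []
    h_c = g.h_c
    for i in range(nx):
        for j in range(1, ny):
            r = i * (ny + 1) + j
            rows += [r, r]
            cols += [i * ny + j, i * ny + j - 1]
            vals += [1.0 / (de * h_c[i]), -1.0 / (de * h_c[i])]
    GYG = sp.csr_matrix((vals, (rows, cols)), shape=(Ng, Np))

    # average u-face values onto interior G faces
    rows, cols, vals = [], [], []
    for i in range(nx):
        for j in range(1, ny):
            r = i * (ny + 1) + j
            for c in (i * ny + j - 1, (i + 1) * ny + j - 1,
                      i * ny + j, (i + 1) * ny + j):
                rows.append(r)
                cols.append(c)
                vals.append(0.25)
    AVU_G = sp.csr_matrix((vals, (rows, cols)), shape=(Ng, Nu))
    Yx = g.Yx_g().ravel()
    CG = GYG - sp.diags(Yx) @ (AVU_G @ GXU)
    cg0 = -(sp.diags(Yx) @ (AVU_G @ cu0))

    # --- divergence ---------------------------------------------------
    rows, cols, vals = [], [], []
    h_f = g.h_f
    for i in range(nx):
        for j in range(ny):
            r = i * ny + j
            rows += [r, r]
            cols += [(i + 1) * ny + j, i * ny + j]
            vals += [h_f[i + 1] / (dx * h_c[i]), -h_f[i] / (dx * h_c[i])]
    DIVU = sp.csr_matrix((vals, (rows, cols)), shape=(Np, Nu))
    rows, cols, vals = [], [], []
    for i in range(nx):
        for j in range(ny):
            r = i * ny + j
            rows += [r, r]
            cols += [i * (ny + 1) + j + 1, i * (ny + 1) + j]
            vals += [1.0 / (de * h_c[i]), -1.0 / (de * h_c[i])]
    DIVG = sp.csr_matrix((vals, (rows, cols)), shape=(Np, Ng))
    return GXU, cu0, CG, np.asarray(cg0).ravel(), DIVU, DIVG


def _mapped_laplacian(g: _Grid, grid_kind: str) -> sp.csr_matrix:
    """Mapped Laplacian Δ = ∂xx + ∂yy on the u- or v-node grid.

    Δf = f_ξξ + 2η_x f_ξη + (η_x² + 1/h²) f_ηη + B f_η with
    B = (η_x)_ξ + η_x (η_x)_η and (η_x)_η = −h_ξ/h.
    Wall BCs are eliminated into the stencil: u is antisymmetric
    across the wall (u_wall = 0); v wall rows are replaced by identity
    (Dirichlet, value supplied in the RHS).
    """
    dx, de = g.dx, g.de
    if grid_kind == "u":
        n_i, n_j = g.nx + 1, g.ny
        etax = g.etax_u()
        h = np.broadcast_to(g.h_f[:, None], etax.shape)
        dh = np.broadcast_to(g.dh_f[:, None], etax.shape)
    else:
        n_i, n_j = g.nx, g.ny + 1
        etax = g.etax_v()
        h = np.broadcast_to(g.h_c[:, None], etax.shape)
        dh = np.broadcast_to(g.dh_c[:, None], etax.shape)
    detax_dxi = np.gradient(etax, dx, axis=0)
    A_xe = 2.0 * etax
    A_ee = etax ** 2 + 1.0 / h ** 2
    B = detax_dxi + etax * (-dh / h)

    N = n_i * n_j
    idx = lambda i, j: i * n_j + j
    rows: List[int] = []
    cols: List[int] = []
    vals: List[float] = []

    def add(r, i, j, w, refl_sign_wall=None):
        """Accumulate w*f(i,j); ξ out-of-range uses linear extrapolation
        (f'' = 0 closure), η out-of-range uses wall reflection for the
        u grid (handled by caller passing clamped j with sign)."""
        if i < 0:
            add(r, 0, j, 2.0 * w, refl_sign_wall)
            add(r, 1, j, -1.0 * w, refl_sign_wall)
            return
        if i > n_i - 1:
            add(r, n_i - 1, j, 2.0 * w, refl_sign_wall)
            add(r, n_i - 2, j, -1.0 * w, refl_sign_wall)
            return
        if j < 0 or j > n_j - 1:
            if grid_kind == "u":
                # quadratic ghost enforcing u = 0 at the wall itself:
                # ghost = -2*u(first) + u(second)/3 (second order)
                if j < 0:
                    add(r, i, 0, -2.0 * w)
                    add(r, i, 1, w / 3.0)
                else:
                    add(r, i, n_j - 1, -2.0 * w)
                    add(r, i, n_j - 2, w / 3.0)
            # v grid: wall rows are Dirichlet; ghosts never requested
            return
        rows.append(r)
        cols.append(idx(i, j))
        vals.append(w)

    v_wall_rows = set()
    for i in range(n_i):
        for j in range(n_j):
            r = idx(i, j)
            if grid_kind == "v" and (j == 0 or j == n_j - 1):
                rows.append(r)
                cols.append(r)
                vals.append(0.0)          # Dirichlet row built by caller
                v_wall_rows.add(r)
                continue
            # f_ξξ
            add(r, i - 1, j, 1.0 / dx ** 2)
            add(r, i, j, -2.0 / dx ** 2)
            add(r, i + 1, j, 1.0 / dx ** 2)
            # f_ηη
            aee = A_ee[i, j]
            add(r, i, j - 1, aee / de ** 2)
            add(r, i, j, -2.0 * aee / de ** 2)
            add(r, i, j + 1, aee / de ** 2)
            # f_ξη (central both; one-sided ξ at ends via extrapolation)
            axe = A_xe[i, j] / (4.0 * dx * de)
            add(r, i + 1, j + 1, axe)
            add(r, i - 1, j - 1, axe)
            add(r, i + 1, j - 1, -axe)
            add(r, i - 1, j + 1, -axe)
            # B f_η
            b = B[i, j] / (2.0 * de)
            add(r, i, j + 1, b)
            add(r, i, j - 1, -b)
    L = sp.csr_matrix((vals, (rows, cols)), shape=(N, N))
    return L


# ----------------------------------------------------------------------
# field interpolation (for semi-Lagrangian departure values)
# ----------------------------------------------------------------------

def _interp_field(field2d: np.ndarray, xi0: float, dxi: float,
                  eta0: float, deta: float, xq: np.ndarray,
                  eq: np.ndarray) -> np.ndarray:
    """Bilinear interpolation of a (n_i, n_j) mapped-grid field."""
    n_i, n_j = field2d.shape
    fi = np.clip((xq - xi0) / dxi, 0.0, n_i - 1 - 1e-12)
    fj = np.clip((eq - eta0) / deta, 0.0, n_j - 1 - 1e-12)
    i0 = fi.astype(int)
    j0 = fj.astype(int)
    wx = fi - i0
    wy = fj - j0
    f = field2d
    return ((1 - wx) * (1 - wy) * f[i0, j0]
            + wx * (1 - wy) * f[np.minimum(i0 + 1, n_i - 1), j0]
            + (1 - wx) * wy * f[i0, np.minimum(j0 + 1, n_j - 1)]
            + wx * wy * f[np.minimum(i0 + 1, n_i - 1),
                          np.minimum(j0 + 1, n_j - 1)])


class _Sampler:
    """Physical-space velocity lookup on one time level's grid."""

    def __init__(self, g: _Grid, u: np.ndarray, v: np.ndarray):
        self.g = g
        self.u = u
        self.v = v

    def _to_mapped(self, X: np.ndarray, Y: np.ndarray
                   ) -> Tuple[np.ndarray, np.ndarray]:
        g = self.g
        xq = np.clip(X, g.x[0], g.x[-1])
        fi = (xq - g.x[0]) / g.dx
        i0 = np.clip(fi.astype(int), 0, g.nx - 1)
        w = fi - i0
        ylo = (1 - w) * g.y_lo_f[i0] + w * g.y_lo_f[i0 + 1]
        h = (1 - w) * g.h_f[i0] + w * g.h_f[i0 + 1]
        eta = np.clip((Y - ylo) / h, 0.0, 1.0)
        return xq, eta

    def velocity(self, X: np.ndarray, Y: np.ndarray
                 ) -> Tuple[np.ndarray, np.ndarray]:
        g = self.g
        xq, eta = self._to_mapped(X, Y)
        uq = _interp_field(self.u, g.x[0], g.dx, 0.5 * g.de, g.de, xq, eta)
        vq = _interp_field(self.v, g.xc[0], g.dx, 0.0, g.de, xq, eta)
        return uq, vq


# ----------------------------------------------------------------------
# main solver
# ----------------------------------------------------------------------

def solve_cycle(domain: ChannelDomain, bc: BoundaryConditions,
                props: Optional[FluidProps] = None, cycles_max: int = 10,
                tol: float = 0.005, ny: int = 16,
                steps_per_cycle: int = 240) -> FlowSolution:
    """March whole cycles until the cyclic-convergence criterion
    (< ``tol`` relative change of the phase-matched spatially averaged
    WSS magnitude) is met, and return the converged cycle.
    """
    props = props or FluidProps()
    if domain.kind == "pipe-static":
        return _solve_pipe_steady(domain, bc, props)
    return _solve_channel(domain, bc, props, cycles_max, tol, ny,
                          steps_per_cycle)


def _outlet_profile(ny: int) -> np.ndarray:
    s = 2.0 * (np.arange(ny) + 0.5) / ny - 1.0
    return 1.5 * (1.0 - s ** 2)


def _solve_channel(domain: ChannelDomain, bc: BoundaryConditions,
                   props: FluidProps, cycles_max: int, tol: float,
                   ny: int, steps_per_cycle: int) -> FlowSolution:
    rho, mu, nu = props.density, props.viscosity, props.nu
    T = domain.period
    dt = T / steps_per_cycle
    nx = domain.nx
    x = domain.x
    outlet_velocity = bc.outlet_bc == "velocity"
    prof = _outlet_profile(ny)

    # pre-tabulate geometry (periodic; reused across cycles)
    geos: List[_Grid] = []
    wall_dots: List[Tuple[np.ndarray, np.ndarray]] = []
    for n in range(steps_per_cycle):
        t = (n + 1) * dt
        lo, up, dlo, dup = domain.walls_at(t)
        geos.append(_Grid(x, lo, up, ny))
        wall_dots.append((dlo, dup))

    u = np.zeros((nx + 1, ny))
    v = np.zeros((nx, ny + 1))
    p_tot = np.zeros((nx, ny))
    p_in_prev = 0.0
    lo0, up0, dlo0, dup0 = domain.walls_at(0.0)
    grid_old = _Grid(x, lo0, up0, ny)

    hist: List[float] = []
    prev_metric: Optional[np.ndarray] = None
    converged = False
    mass_err = 0.0
    div_max = 0.0
    n_cycles = 0
    store = None

    for cyc in range(cycles_max):
        n_cycles = cyc + 1
        S = steps_per_cycle
        rec = {
            "times": np.empty(S), "u": np.empty((S, nx + 1, ny)),
            "v": np.empty((S, nx, ny + 1)), "p": np.empty((S, nx, ny)),
            "y_lo": np.empty((S, nx + 1)), "y_up": np.empty((S, nx + 1)),
            "tau": np.empty((S, nx + 1, 2)), "pw": np.empty((S, nx + 1, 2)),
            "vn": np.empty((S, nx + 1, 2)), "ds": np.empty((S, nx + 1, 2)),
        }
        metric = np.empty(S)
        for n in range(S):
            t_new = cyc * T + (n + 1) * dt
            g = geos[n]
            dlo, dup = wall_dots[n]

            # -- semi-Lagrangian advection (physical space, RK2) -------
            samp = _Sampler(grid_old, u, v)
            Xu, Yu = g.u_xy()
            uq, vq = samp.velocity(Xu, Yu)
            um, vm = samp.velocity(Xu - 0.5 * dt * uq, Yu - 0.5 * dt * vq)
            u_adv = samp.velocity(Xu - dt * um, Yu - dt * vm)[0]
            Xv, Yv = g.v_xy()
            uq, vq = samp.velocity(Xv, Yv)
            um, vm = samp.velocity(Xv - 0.5 * dt * uq, Yv - 0.5 * dt * vq)
            v_adv = samp.velocity(Xv - dt * um, Yv - dt * vm)[1]

            # -- implicit viscosity (incremental form: apply the old
            #    pressure gradient so the tentative velocity honours
            #    no-slip to second order) --------------------------------
            GXU, cu0, CG, cg0, DIVU, DIVG = _poisson_ops(
                g, p_in_dirichlet=True,
                outlet_pressure=not outlet_velocity)
            p_in = float(bc.inlet_pressure(t_new % T))
            grad_u_old = (GXU @ p_tot.ravel() + cu0 * p_in_prev)
            dpe_old = np.zeros((nx, ny + 1))
            dpe_old[:, 1:ny] = (p_tot[:, 1:] - p_tot[:, :-1]) / g.de \
                / g.h_c[:, None]

            Lu = _mapped_laplacian(g, "u")
            Au = (sp.identity(Lu.shape[0], format="csr") - nu * dt * Lu)
            bu = u_adv.ravel() - (dt / rho) * grad_u_old
            if outlet_velocity:
                U_out = bc.outlet_scale * (bc.outlet_shape(t_new)
                                           if bc.outlet_shape else 1.0)
                out_rows = nx * ny + np.arange(ny)
                _set_dirichlet(Au, out_rows)
                bu[out_rows] = U_out * prof
            u_star = spla.spsolve(Au.tocsc(), bu).reshape(nx + 1, ny)

            Lv = _mapped_laplacian(g, "v")
            Av = (sp.identity(Lv.shape[0], format="csr") - nu * dt * Lv)
            bv = (v_adv - (dt / rho) * dpe_old).ravel()
            wall_lo_rows = np.arange(nx) * (ny + 1)
            wall_up_rows = wall_lo_rows + ny
            _set_dirichlet(Av, np.concatenate([wall_lo_rows, wall_up_rows]))
            dlo_c = 0.5 * (dlo[:-1] + dlo[1:])
            dup_c = 0.5 * (dup[:-1] + dup[1:])
            bv[wall_lo_rows] = dlo_c
            bv[wall_up_rows] = dup_c
            v_star = spla.spsolve(Av.tocsc(), bv).reshape(nx, ny + 1)

            # -- projection of the pressure increment ------------------
            G_star = _g_flux(g, u_star, v_star, dlo_c, dup_c)
            div_star = (DIVU @ u_star.ravel() + DIVG @ G_star.ravel())
            d_pin = p_in - p_in_prev
            Lp = (DIVU @ GXU + DIVG @ CG).tocsc()
            rhs = (rho / dt) * div_star \
                - (DIVU @ cu0 + DIVG @ cg0) * d_pin
            phi = spla.spsolve(Lp, rhs)

            u = u_star - (dt / rho) * (GXU @ phi + cu0 * d_pin
                                       ).reshape(nx + 1, ny)
            PHI = phi.reshape(nx, ny)
            dpe = np.zeros((nx, ny + 1))
            dpe[:, 1:ny] = (PHI[:, 1:] - PHI[:, :-1]) / g.de \
                / g.h_c[:, None]
            v = v_star - (dt / rho) * dpe
            v[:, 0] = dlo_c
            v[:, -1] = dup_c
            p_tot = p_tot + PHI
            p_in_prev = p_in
            P2 = p_tot

            G = _g_flux(g, u, v, dlo_c, dup_c)
            div = DIVU @ u.ravel() + DIVG @ G.ravel()
            div_max = max(div_max, float(np.max(np.abs(div))))

            # -- wall samples ------------------------------------------
            tau, pw, vn, ds = _wall_samples(g, u, v, P2, mu, dlo, dup)
            rec["times"][n] = t_new
            rec["u"][n], rec["v"][n], rec["p"][n] = u, v, P2
            rec["y_lo"][n], rec["y_up"][n] = g.y_lo_f, g.y_up_f
            rec["tau"][n], rec["pw"][n] = tau, pw
            rec["vn"][n], rec["ds"][n] = vn, ds
            metric[n] = float(np.mean(np.abs(tau)))
            grid_old = g

        # mass balance of this cycle (per unit depth)
        Q_in = rec["u"][:, 0, :].mean(axis=1) * rec["y_up"][:, 0] \
            - rec["u"][:, 0, :].mean(axis=1) * rec["y_lo"][:, 0]
        Q_out = rec["u"][:, -1, :].mean(axis=1) \
            * (rec["y_up"][:, -1] - rec["y_lo"][:, -1])
        A = np.trapezoid(rec["y_up"] - rec["y_lo"], x, axis=1)
        dAdt = np.gradient(A, dt)
        scale = max(np.max(np.abs(Q_in)), np.max(np.abs(Q_out)), 1e-30)
        mass_err = float(np.max(np.abs(Q_in - Q_out - dAdt)) / scale)

        if prev_metric is not None:
            denom = max(float(np.max(np.abs(metric))), 1e-30)
            rel = float(np.max(np.abs(metric - prev_metric)) / denom)
            hist.append(rel)
            if rel < tol:
                converged = True
        prev_metric = metric.copy()
        store = rec
        if converged:
            break

    return FlowSolution(
        times=store["times"], x=x.copy(),
        station_region=domain.station_region.copy(),
        u=store["u"], v=store["v"], p=store["p"],
        y_lo=store["y_lo"], y_up=store["y_up"],
        tau_wall=store["tau"], p_wall=store["pw"],
        vn_wall=store["vn"], ds_wall=store["ds"],
        converged=converged, n_cycles=n_cycles,
        convergence_history=hist, mass_error=mass_err,
        div_max=div_max, props=props,
        meta={"dt": dt, "ny": ny, "steps_per_cycle": steps_per_cycle,
              "kind": domain.kind})


def _set_dirichlet(A: sp.csr_matrix, rows: np.ndarray) -> None:
    """Replace the given rows of a CSR matrix by identity rows in place."""
    A.sort_indices()
    for r in rows:
        lo, hi = A.indptr[r], A.indptr[r + 1]
        A.data[lo:hi] = 0.0
        # the diagonal entry exists structurally (I - nu dt L)
        k = lo + int(np.searchsorted(A.indices[lo:hi], r))
        if k >= hi or A.indices[k] != r:
            raise SolverError("missing structural diagonal for BC row")
        A.data[k] = 1.0


def _g_flux(g: _Grid, u: np.ndarray, v: np.ndarray, dlo_c: np.ndarray,
            dup_c: np.ndarray) -> np.ndarray:
    """Contravariant η-flux G = v − Y_x·ū with exact wall values."""
    nx, ny = g.nx, g.ny
    G = np.empty((nx, ny + 1))
    Yx = g.Yx_g()
    ubar = np.zeros((nx, ny + 1))
    ubar[:, 1:ny] = 0.25 * (u[:-1, :-1] + u[1:, :-1]
                            + u[:-1, 1:] + u[1:, 1:])
    G[:, :] = v - Yx * ubar
    G[:, 0] = dlo_c
    G[:, -1] = dup_c
    return G


def _wall_samples(g: _Grid, u: np.ndarray, v: np.ndarray, P2: np.ndarray,
                  mu: float, dlo: np.ndarray, dup: np.ndarray
                  ) -> Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Signed WSS, wall pressure, inward-normal wall speed and arc
    length at every face station for both walls (0 = lower, 1 = upper).
    """
    nx, ny = g.nx, g.ny
    de, dx = g.de, g.dx
    tau = np.empty((nx + 1, 2))
    pw = np.empty((nx + 1, 2))
    vn = np.empty((nx + 1, 2))
    ds = np.empty((nx + 1, 2))
    # v interpolated to u-node columns (faces i) at the two node rows
    v_u = np.zeros((nx + 1, ny + 1))
    v_u[1:nx, :] = 0.5 * (v[:-1, :] + v[1:, :])
    v_u[0, :] = v[0, :]
    v_u[nx, :] = v[-1, :]

    for side, (ywx, wdot, sgn) in enumerate(
            (((g.dlo_f), dlo, 1.0), ((np.gradient(g.y_up_f, g.x)), dup,
                                     -1.0))):
        s = np.sqrt(1.0 + ywx ** 2)
        tx, ty = 1.0 / s, ywx / s
        if side == 0:
            j0, j1 = 0, 1
            d0 = 0.5 * de * g.h_f / s
            d1 = 1.5 * de * g.h_f / s
            vrow0 = 0.5 * (v_u[:, 0] + v_u[:, 1])
            vrow1 = 0.5 * (v_u[:, 1] + v_u[:, 2])
        else:
            j0, j1 = ny - 1, ny - 2
            d0 = 0.5 * de * g.h_f / s
            d1 = 1.5 * de * g.h_f / s
            vrow0 = 0.5 * (v_u[:, ny] + v_u[:, ny - 1])
            vrow1 = 0.5 * (v_u[:, ny - 1] + v_u[:, ny - 2])
        # tangential velocity relative to the (moving) wall
        wall_t = ty * wdot
        ut0 = u[:, j0] * tx + vrow0 * ty - wall_t
        ut1 = u[:, j1] * tx + vrow1 * ty - wall_t
        # quadratic one-sided fit through (0,0),(d0,ut0),(d1,ut1)
        grad = (ut0 * d1 ** 2 - ut1 * d0 ** 2) / (d0 * d1 * (d1 - d0))
        tau[:, side] = mu * grad
        pc = P2[:, 0] if side == 0 else P2[:, -1]
        pw[1:nx, side] = 0.5 * (pc[:-1] + pc[1:])
        pw[0, side] = pc[0]
        pw[nx, side] = pc[-1]
        # inward normal: lower wall (−ywx, 1)/s·sgn=+1; upper (ywx, −1)/s
        vn[:, side] = sgn * wdot / s
        ds[:, side] = s * dx
    return tau, pw, vn, ds


# ----------------------------------------------------------------------
# axisymmetric steady pipe benchmark
# ----------------------------------------------------------------------

def _solve_pipe_steady(domain: ChannelDomain, bc: BoundaryConditions,
                       props: FluidProps) -> FlowSolution:
    """Steady axisymmetric Poiseuille solve (finite volume in r).

    ``bc.outlet_scale`` is the prescribed mean velocity U (m/s);
    Q = U·πR². The conservative radial stencil reproduces the parabola
    at cell centres, and the one-sided quadratic wall gradient gives
    WSS = 4μQ/(πR³) to discretization accuracy.
    """
    R = float(domain.y_up[0, 0] - domain.y_lo[0, 0])
    n_r = int(domain.meta.get("n_r", 32))
    mu = props.viscosity
    dr = R / n_r
    r_c = (np.arange(n_r) + 0.5) * dr
    r_f = np.arange(n_r + 1) * dr

    # (1/r)(r u')' = G/μ, u'(0)=0, u(R)=0; solve for unit G then scale
    main = np.zeros(n_r)
    lowr = np.zeros(n_r - 1)
    uppr = np.zeros(n_r - 1)
    for i in range(n_r):
        w_e = r_f[i + 1] / dr if i < n_r - 1 else 2.0 * r_f[n_r] / dr
        w_w = r_f[i] / dr if i > 0 else 0.0
        if i < n_r - 1:
            uppr[i] = w_e
        main[i] = -(w_e + w_w)
        if i > 0:
            lowr[i - 1] = w_w
    A = sp.diags([lowr, main, uppr], [-1, 0, 1]).tocsc()
    rhs = r_c * dr / mu          # unit pressure gradient G = 1
    u1 = spla.spsolve(A, rhs)
    Q1 = float(np.sum(2.0 * np.pi * r_c * u1 * dr))
    U = bc.outlet_scale
    Q = U * np.pi * R ** 2
    scale = Q / Q1
    u_prof = u1 * scale

    # one-sided quadratic gradient at the wall through u(R)=0
    d0, d1 = dr / 2.0, 3.0 * dr / 2.0
    grad = (u_prof[-1] * d1 ** 2 - u_prof[-2] * d0 ** 2) \
        / (d0 * d1 * (d1 - d0))
    wss = mu * abs(grad)

    nxp = domain.nx
    S = 1
    shape_u = np.tile(u_prof, (nxp + 1, 1))[None, :, :]
    sol = FlowSolution(
        times=np.array([0.0]), x=domain.x.copy(),
        station_region=domain.station_region.copy(),
        u=shape_u, v=np.zeros((S, nxp, n_r + 1)),
        p=np.zeros((S, nxp, n_r)),
        y_lo=np.tile(domain.y_lo[0], (S, 1)),
        y_up=np.tile(domain.y_up[0], (S, 1)),
        tau_wall=np.full((S, nxp + 1, 2), wss),
        p_wall=np.zeros((S, nxp + 1, 2)),
        vn_wall=np.zeros((S, nxp + 1, 2)),
        ds_wall=np.full((S, nxp + 1, 2), domain.x[1] - domain.x[0]),
        converged=True, n_cycles=1, convergence_history=[],
        mass_error=0.0, div_max=0.0, props=props,
        meta={"kind": "pipe-static", "wss": wss, "radius": R, "Q": Q,
              "r_centers": r_c, "profile": u_prof})
    return sol
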