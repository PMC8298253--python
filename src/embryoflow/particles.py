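"""Passive-tracer seeding, advection and regional retention scoring.

Particles are massless and move with the fluid (4th-order Runge-Kutta
in time; velocity linear in time between solver steps and element-
linear in space). Wall contact is handled by projecting the fluid
velocity onto the wall tangent inside a ``min_wall_distance`` shell and
clamping positions to the shell, which avoids artificial sticking.

Retention convention (documented): a particle counts as retained in its
seeding region at a checkpoint only if it has resided there
continuously since seeding; re-entries are not counted. This makes
per-region retention monotone non-increasing by construction.

Positions are reported in mm (matching the mesh/geometry stages);
advection internally uses the solver's SI units.
"""
from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np

MM = 1e-3

STATUS_ALIVE = 0
STATUS_EXITED_OUTLET = 1
STATUS_EXITED_INLET = 2
STATUS_LOOKUP_FAILED = 3


class ParticleError(RuntimeError):
    pass


# ----------------------------------------------------------------------
# velocity sampling of a FlowSolution
# ----------------------------------------------------------------------

class _FlowSampler:
    """Periodic space-time interpolation of a solved cycle.

    Velocities are bilinear in the mapped (ξ, η) coordinates and linear
    in time between the solver's stored steps; walls are interpolated
    the same way, so η is consistent with the instantaneous lumen.
    """

    def __init__(self, solution):
        self.sol = solution
        self.x = solution.x
        self.S = len(solution.times)
        self.T = float(self.S * solution.meta["dt"]) \
            if "dt" in solution.meta else \
            float(solution.times[-1] - solution.times[0]
                  + np.diff(solution.times).mean())
        self.dt = self.T / self.S
        self.ny = solution.u.shape[2]

    def _step_pair(self, t: float) -> Tuple[int, int, float]:
        """Bracketing stored steps for phase t and the blend weight.

        Stored step n holds the state at phase (n+1)·dt; phase 0 is the
        final entry (periodic).
        """
        ph = t % self.T
        f = ph / self.dt - 1.0
        n0 = int(np.floor(f))
        w = f - n0
        return n0 % self.S, (n0 + 1) % self.S, w

    def walls(self, xq: np.ndarray, t: float
              ) -> Tuple[np.ndarray, np.ndarray]:
        n0, n1, w = self._step_pair(t)
        lo = (1 - w) * np.interp(xq, self.x, self.sol.y_lo[n0]) \
            + w * np.interp(xq, self.x, self.sol.y_lo[n1])
        up = (1 - w) * np.interp(xq, self.x, self.sol.y_up[n0]) \
            + w * np.interp(xq, self.x, self.sol.y_up[n1])
        return lo, up

    def _bilinear(self, F: np.ndarray, gx: np.ndarray, ge: np.ndarray,
                  xq: np.ndarray, eq: np.ndarray) -> np.ndarray:
        i = np.clip(np.searchsorted(gx, xq) - 1, 0, len(gx) - 2)
        j = np.clip(np.searchsorted(ge, eq) - 1, 0, len(ge) - 2)
        wx = np.clip((xq - gx[i]) / (gx[i + 1] - gx[i]), 0.0, 1.0)
        we = np.clip((eq - ge[j]) / (ge[j + 1] - ge[j]), 0.0, 1.0)
        return ((1 - wx) * (1 - we) * F[i, j]
                + wx * (1 - we) * F[i + 1, j]
                + (1 - wx) * we * F[i, j + 1]
                + wx * we * F[i + 1, j + 1])

    def velocity(self, pos: np.ndarray, t: float) -> np.ndarray:
        """Fluid velocity (m/s) at positions (N, 2) and time t."""
        xq, yq = pos[:, 0], pos[:, 1]
        n0, n1, w = self._step_pair(t)
        lo, up = self.walls(xq, t)
        h = up - lo
        eq = np.clip((yq - lo) / np.where(h > 0, h, 1.0), 0.0, 1.0)
        ny = self.ny
        ec = (np.arange(ny) + 0.5) / ny
        ef = np.arange(ny + 1) / ny
        xc = 0.5 * (self.x[:-1] + self.x[1:])
        out = np.empty_like(pos)
        for comp, (F0, F1, gx, ge) in enumerate((
                (self.sol.u[n0], self.sol.u[n1], self.x, ec),
                (self.sol.v[n0], self.sol.v[n1], xc, ef))):
            f0 = self._bilinear(F0, gx, ge, xq, eq)
            f1 = self._bilinear(F1, gx, ge, xq, eq)
            out[:, comp] = (1 - w) * f0 + w * f1
        return out


# ----------------------------------------------------------------------
# ensemble
# ----------------------------------------------------------------------

@dataclass
class ParticleEnsemble:
    """Trajectories of seeded tracers over the advection run.

    ``positions`` is (n_checkstep + 1, N, 2) in mm; ``region`` the
    per-step station-region label; ``status`` the per-particle final
    state; ``exit_time`` the time of leaving the domain (NaN if alive).
    """

    positions: np.ndarray                  # (K, N, 2), mm
    times: np.ndarray                      # (K,), s
    region: np.ndarray                     # (K, N) str
    status: np.ndarray                     # (N,) int codes
    exit_time: np.ndarray                  # (N,) s
    seed_region: np.ndarray                # (N,) str
    continuously_resident: np.ndarray      # (K, N) bool
    meta: Dict[str, object] = field(default_factory=dict)

    @property
    def n_particles(self) -> int:
        return self.positions.shape[1]

    def conservation_ok(self) -> bool:
        """alive + exited + flagged == seeded at every checkpoint."""
        return int(np.sum(self.status == STATUS_ALIVE)
                   + np.sum(self.status == STATUS_EXITED_OUTLET)
                   + np.sum(self.status == STATUS_EXITED_INLET)
                   + np.sum(self.status == STATUS_LOOKUP_FAILED)) \
            == self.n_particles

    def to_csv(self) -> str:
        buf = io.StringIO()
        buf.write("particle_id,t,x_mm,y_mm,region,status\n")
        for k, t in enumerate(self.times):
            for i in range(self.n_particles):
                buf.write(f"{i},{t:.6g},{self.positions[k, i, 0]:.6g},"
                          f"{self.positions[k, i, 1]:.6g},"
                          f"{self.region[k, i]},{int(self.status[i])}\n")
        return buf.getvalue()


def _region_of(solution, xq: np.ndarray) -> np.ndarray:
    idx = np.clip(np.searchsorted(solution.x, xq), 0,
                  len(solution.x) - 1)
    return solution.station_region[idx]


def seed(solution, n: int, min_wall_distance: float = 1e-6,
         seed: int = 0, x_range: Optional[Tuple[float, float]] = None
         ) -> np.ndarray:
    """Uniform random positions (m) in the t=0 lumen, ≥ the clearance
    from both walls. Deterministic per ``seed``.
    """
    if n < 1:
        raise ParticleError("n must be >= 1")
    if min_wall_distance < 0:
        raise ParticleError("min_wall_distance must be >= 0")
    samp = _FlowSampler(solution)
    x0, x1 = (solution.x[0], solution.x[-1]) if x_range is None else x_range
    probe = np.linspace(x0, x1, 512)
    lo, up = samp.walls(probe, 0.0)
    if np.max(up - lo) <= 2 * min_wall_distance:
        raise ParticleError(
            "min_wall_distance leaves no interior to seed in")
    rng = np.random.default_rng(seed)
    out = np.empty((n, 2))
    got = 0
    for _ in range(1000):
        m = max(4 * (n - got), 64)
        xs = rng.uniform(x0, x1, m)
        ys = rng.uniform(lo.min(), up.max(), m)
        l, u_ = samp.walls(xs, 0.0)
        ok = (ys >= l + min_wall_distance) & (ys <= u_ - min_wall_distance)
        take = min(n - got, int(ok.sum()))
        out[got:got + take] = np.column_stack([xs[ok], ys[ok]])[:take]
        got += take
        if got == n:
            return out
    raise ParticleError("seeding failed; clearance too restrictive")


def advect(positions: np.ndarray, solution, n_cycles: int = 5,
           min_wall_distance: float = 1e-6,
           substeps: int = 1, store_every: int = 1) -> ParticleEnsemble:
    """RK4 advection of seeded tracers over ``n_cycles`` cardiac cycles.

    Steps on the solver's time grid (``substeps`` per solver step for
    refinement studies). Exits through the outlet/inlet ends are
    recorded and positions frozen; failed velocity lookups flag the
    particle rather than dropping it.
    """
    samp = _FlowSampler(solution)
    T, S = samp.T, samp.S
    dt = samp.dt / substeps
    n_steps = n_cycles * S * substeps
    pos = np.array(positions, dtype=float)
    N = len(pos)
    alive = np.ones(N, dtype=bool)
    status = np.full(N, STATUS_ALIVE, dtype=int)
    exit_time = np.full(N, np.nan)
    x_in, x_out = solution.x[0], solution.x[-1]

    def clamp(p: np.ndarray, t: float) -> np.ndarray:
        lo, up = samp.walls(p[:, 0], t)
        p[:, 1] = np.clip(p[:, 1], lo + min_wall_distance,
                          up - min_wall_distance)
        return p

    def vel(p: np.ndarray, t: float) -> np.ndarray:
        if not np.all(np.isfinite(p)):
            raise ParticleError("velocity lookup outside domain")
        V = samp.velocity(np.clip(p, [x_in, -np.inf], [x_out, np.inf]), t)
        # tangential projection inside the wall shell
        lo, up = samp.walls(p[:, 0], t)
        dxp = (x_out - x_in) * 1e-4
        lo_r, up_r = samp.walls(p[:, 0] + dxp, t)
        lo_l, up_l = samp.walls(p[:, 0] - dxp, t)
        shell = 2 * min_wall_distance
        for wall, wall_r, wall_l, side in ((lo, lo_r, lo_l, +1),
                                           (up, up_r, up_l, -1)):
            near = side * (p[:, 1] - wall) < shell
            if np.any(near):
                slope = (wall_r - wall_l) / (2 * dxp)
                tx = 1.0 / np.sqrt(1 + slope ** 2)
                ty = slope * tx
                vt = V[:, 0] * tx + V[:, 1] * ty
                V[near, 0] = (vt * tx)[near]
                V[near, 1] = (vt * ty)[near]
        return V

    K = n_steps // store_every + 1
    rec_pos = np.empty((K, N, 2))
    rec_t = np.empty(K)
    rec_pos[0] = pos
    rec_t[0] = 0.0
    k = 1
    t = 0.0
    for step in range(n_steps):
        if np.any(alive):
            idx = np.flatnonzero(alive)
            p = pos[idx]
            k1 = vel(p, t)
            k2 = vel(clamp(p + 0.5 * dt * k1, t + 0.5 * dt), t + 0.5 * dt)
            k3 = vel(clamp(p + 0.5 * dt * k2, t + 0.5 * dt), t + 0.5 * dt)
            k4 = vel(clamp(p + dt * k3, t + dt), t + dt)
            p = p + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
            p = clamp(p, t + dt)
            pos[idx] = p
            out = p[:, 0] >= x_out
            inl = p[:, 0] <= x_in
            for mask, code in ((out, STATUS_EXITED_OUTLET),
                               (inl, STATUS_EXITED_INLET)):
                if np.any(mask):
                    gone = idx[mask]
                    status[gone] = code
                    exit_time[gone] = t + dt
                    alive[gone] = False
        t += dt
        if (step + 1) % store_every == 0:
            rec_pos[k] = pos
            rec_t[k] = t
            k += 1

    region = np.empty((K, N), dtype=object)
    for kk in range(K):
        region[kk] = _region_of(solution, rec_pos[kk, :, 0])
    exited = status != STATUS_ALIVE
    in_domain = np.ones((K, N), dtype=bool)
    for kk in range(K):
        in_domain[kk] = ~exited | (np.isnan(exit_time)
                                   | (rec_t[kk] <= exit_time))
    seed_region = region[0].astype(str)
    same = (region.astype(str) == seed_region[None, :]) & in_domain
    resident = np.logical_and.accumulate(same, axis=0)
    return ParticleEnsemble(
        positions=rec_pos / MM, times=rec_t,
        region=region.astype(str), status=status, exit_time=exit_time,
        seed_region=seed_region, continuously_resident=resident,
        meta={"n_cycles": n_cycles, "period": T, "dt": dt,
              "min_wall_distance": min_wall_distance})


def retention(ensemble: ParticleEnsemble,
              checkpoints: Sequence[int] = (0, 2, 5),
              regions: Optional[Sequence[str]] = None
              ) -> Dict[str, Dict[int, float]]:
    """Fraction of initially-resident particles still (continuously)
    resident in their seeding region at each cycle checkpoint.
    """
    T = float(ensemble.meta["period"])
    if regions is None:
        regions = sorted(set(ensemble.seed_region.tolist()))
    out: Dict[str, Dict[int, float]] = {}
    for r in regions:
        sel = ensemble.seed_region == r
        n0 = int(sel.sum())
        if n0 == 0:
            continue
        row: Dict[int, float] = {}
        for c in checkpoints:
            tq = c * T
            k = int(np.argmin(np.abs(ensemble.times - tq)))
            row[c] = float(ensemble.continuously_resident[k, sel].mean())
        out[r] = row
    return out
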