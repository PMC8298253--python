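"""Moving 2D channel domains swept from the 3D heart geometry.

The solver's primary (scaled-down) mode is a planar long-axis slice of
the lumen: the generated heart is cut on its symmetry plane z = 0 and
the upper/lower wall curves are sampled on the solver's axial
stations, for every mesh frame. The outlet is extruded by a
configurable number of outlet diameters with wall-motion amplitude
decayed to (near) zero by a sigmoid, mirroring the boundary treatment
of the source study. Static channel/pipe domains for the analytic
benchmarks are built by the ``static_*`` constructors.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Tuple, Union

import numpy as np
import trimesh

from ..meshseq import ChamberLabels, SurfaceMeshSequence

MM = 1e-3     # mm -> m


class DomainError(RuntimeError):
    pass


@dataclass
class BoundaryConditions:
    """Inlet/outlet treatment of the moving-lumen solve.

    ``inlet_pressure`` is a callable t (s) -> Pa (relative reference
    pressure; amplitude-scaled literature waveform by default).
    ``outlet_scale`` multiplies the normalized outlet velocity shape
    (m/s); it is the quantity the BC tuner iterates on.
    """

    inlet_pressure: Callable[[float], float] = lambda t: 0.0
    outlet_scale: float = 0.0
    outlet_shape: Optional[Callable[[float], float]] = None   # peak-1 shape
    outlet_bc: str = "velocity"            # "velocity" | "pressure"
    extrusion_diameters: float = 2.0
    sigmoid_mid_diameters: float = 1.0
    sigmoid_width_diameters: float = 0.2

    def decay(self, s_over_D: np.ndarray) -> np.ndarray:
        """Sigmoid wall-motion decay along the extrusion (1 → ~0)."""
        z = (self.sigmoid_mid_diameters - np.asarray(s_over_D, float)) \
            / self.sigmoid_width_diameters
        top = 1.0 / (1.0 + math.exp(-self.sigmoid_mid_diameters
                                    / self.sigmoid_width_diameters))
        return 1.0 / (1.0 + np.exp(-z)) / top


@dataclass
class ChannelDomain:
    """Sampled moving channel: walls per mesh frame on solver stations.

    All lengths are metres, times seconds. ``y_lo``/``y_up`` have shape
    (n_frames, nx + 1) sampled at the ξ faces; the waveforms are
    periodic with the final frame duplicating frame 0.
    """

    x: np.ndarray                  # (nx+1,) face stations, m
    y_lo: np.ndarray               # (F, nx+1), m
    y_up: np.ndarray               # (F, nx+1), m
    frame_times: np.ndarray        # (F,), s
    station_region: np.ndarray     # (nx+1,) region name per face
    kind: str = "planar-moving"    # | "planar-static" | "pipe-static"
    quality: Dict[str, float] = field(default_factory=dict)
    meta: Dict[str, object] = field(default_factory=dict)

    # trig-interpolation coefficients (filled lazily)
    _cf_lo: Optional[np.ndarray] = None
    _cf_up: Optional[np.ndarray] = None

    @property
    def period(self) -> float:
        return float(self.frame_times[-1] - self.frame_times[0])

    @property
    def nx(self) -> int:
        return len(self.x) - 1

    def _coeffs(self) -> None:
        nf = len(self.frame_times) - 1
        self._cf_lo = np.fft.rfft(self.y_lo[:nf], axis=0) / nf
        self._cf_up = np.fft.rfft(self.y_up[:nf], axis=0) / nf

    def walls_at(self, t: float) -> Tuple[np.ndarray, np.ndarray,
                                          np.ndarray, np.ndarray]:
        """(y_lo, y_up, dy_lo/dt, dy_up/dt) at time t (trigonometric
        interpolation of the periodic frame samples)."""
        if self.kind != "planar-moving":
            z = np.zeros_like(self.x)
            return self.y_lo[0], self.y_up[0], z, z
        if self._cf_lo is None:
            self._coeffs()
        nf = len(self.frame_times) - 1
        T = self.period
        k = np.arange(self._cf_lo.shape[0])
        ph = np.exp(2j * np.pi * k * (t % T) / T)
        def ev(cf):
            val = (cf * ph[:, None]).real
            val[1:] *= 2.0
            if nf % 2 == 0:
                # Nyquist term: keep cosine component only, once
                val[-1] = (cf[-1] * ph[-1]).real
            return val.sum(axis=0)
        dph = ph * (2j * np.pi * k / T)
        def dev(cf):
            val = (cf * dph[:, None]).real
            val[1:] *= 2.0
            if nf % 2 == 0:
                val[-1] = (cf[-1] * dph[-1]).real
            return val.sum(axis=0)
        return ev(self._cf_lo), ev(self._cf_up), dev(self._cf_lo), \
            dev(self._cf_up)


def _slice_walls(mesh: trimesh.Trimesh, x_st: np.ndarray
                 ) -> Tuple[np.ndarray, np.ndarray]:
    """Lower/upper lumen walls y(x) on the z=0 plane at given stations."""
    segs = trimesh.intersections.mesh_plane(
        mesh, plane_normal=[0.0, 0.0, 1.0], plane_origin=[0.0, 0.0, 0.0])
    if len(segs) == 0:
        raise DomainError("mesh does not intersect the z=0 plane")
    p, q = segs[:, 0, :2], segs[:, 1, :2]
    lo = np.empty(len(x_st))
    up = np.empty(len(x_st))
    for i, xs in enumerate(x_st):
        cross = (p[:, 0] > xs) != (q[:, 0] > xs)
        if not np.any(cross):
            raise DomainError(f"station x={xs:.4f} mm misses the lumen")
        pc, qc = p[cross], q[cross]
        t = (xs - pc[:, 0]) / (qc[:, 0] - pc[:, 0])
        ys = pc[:, 1] + t * (qc[:, 1] - pc[:, 1])
        lo[i], up[i] = float(ys.min()), float(ys.max())
    return lo, up


def build_domain(mesh_seq: SurfaceMeshSequence, labels: ChamberLabels,
                 bc: BoundaryConditions, nx: int = 120,
                 margin: float = 1e-3) -> ChannelDomain:
    """Sample the moving planar slice and attach the outlet extrusion.

    ``margin`` (fraction of length) keeps stations off the capped ends.
    Emits a mesh-quality report (min gap, max wall slope) and raises if
    the walls self-intersect (non-positive gap) at any frame.
    """
    if not labels.region_x:
        raise DomainError("labels must carry region_x axial intervals")
    x0 = min(a for a, _ in labels.region_x.values())
    x1 = max(b for _, b in labels.region_x.values())
    L = x1 - x0
    x_heart = np.linspace(x0 + margin * L, x1 - margin * L, nx + 1)

    nf = mesh_seq.n_frames
    lo = np.empty((nf, nx + 1))
    up = np.empty((nf, nx + 1))
    for f in range(nf):
        lo[f], up[f] = _slice_walls(mesh_seq.frame(f), x_heart)
    lo[-1], up[-1] = lo[0], up[0]

    # outlet extrusion with sigmoid-decayed wall motion
    D_out = float(np.mean(up[:, -1] - lo[:, -1]))
    L_ext = bc.extrusion_diameters * D_out
    dx = x_heart[1] - x_heart[0]
    n_ext = max(2, int(round(L_ext / dx)))
    x_ext = x_heart[-1] + dx * np.arange(1, n_ext + 1)
    g = bc.decay((x_ext - x_heart[-1]) / D_out)
    lo_end_mean = lo[:, -1].mean()
    up_end_mean = up[:, -1].mean()
    lo_ext = lo_end_mean + (lo[:, -1:] - lo_end_mean) * g[None, :]
    up_ext = up_end_mean + (up[:, -1:] - up_end_mean) * g[None, :]

    x_all = np.concatenate([x_heart, x_ext])
    lo_all = np.concatenate([lo, lo_ext], axis=1)
    up_all = np.concatenate([up, up_ext], axis=1)

    region = np.empty(len(x_all), dtype=object)
    region[:] = "extrusion"
    for name, (a, b) in labels.region_x.items():
        inside = (x_all >= a) & (x_all <= b)
        region[inside] = name

    h = up_all - lo_all
    if np.any(h <= 0):
        f_bad, i_bad = np.unravel_index(int(np.argmin(h)), h.shape)
        raise DomainError(
            f"walls self-intersect at frame {f_bad}, station {i_bad}")
    slope = np.abs(np.gradient(up_all, x_all, axis=1))
    quality = {
        "min_gap_mm": float(h.min()),
        "max_gap_mm": float(h.max()),
        "max_wall_slope": float(max(slope.max(),
                                    np.abs(np.gradient(lo_all, x_all,
                                                       axis=1)).max())),
        "n_stations": int(len(x_all)),
        "extrusion_cells": int(n_ext),
        "decay_at_end": float(g[-1]),
    }
    return ChannelDomain(
        x=x_all * MM, y_lo=lo_all * MM, y_up=up_all * MM,
        frame_times=mesh_seq.frame_times.copy(),
        station_region=region.astype(str), kind="planar-moving",
        quality=quality,
        meta={"outlet_diameter_m": D_out * MM,
              "heart_length_m": L * MM})


def static_channel(length: float, half_width: float, nx: int = 64,
                   period: float = 1.0) -> ChannelDomain:
    """Rigid plane channel of half-width ``a`` (metres in, metres out)."""
    x = np.linspace(0.0, length, nx + 1)
    lo = np.full((2, nx + 1), -half_width)
    up = np.full((2, nx + 1), half_width)
    return ChannelDomain(x=x, y_lo=lo, y_up=up,
                         frame_times=np.array([0.0, period]),
                         station_region=np.array(["channel"] * (nx + 1)),
                         kind="planar-static",
                         quality={"min_gap_mm": 2 * half_width / MM})


def static_pipe(length: float, radius: float, nx: int = 8,
                n_r: int = 32) -> ChannelDomain:
    """Rigid circular tube (axisymmetric benchmark domain)."""
    x = np.linspace(0.0, length, nx + 1)
    lo = np.zeros((2, nx + 1))
    up = np.full((2, nx + 1), radius)
    return ChannelDomain(x=x, y_lo=lo, y_up=up,
                         frame_times=np.array([0.0, 1.0]),
                         station_region=np.array(["pipe"] * (nx + 1)),
                         kind="pipe-static",
                         quality={"min_gap_mm": radius / MM},
                         meta={"n_r": n_r})
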