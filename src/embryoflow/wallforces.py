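"""Wall-force metrics: WSS summaries, oscillatory shear index and
ejection work.

Metrics operate on "wall faces": any flat collection of wall sample
sites with per-face shear τ(t), wall pressure, inward-normal wall
velocity and face area. ``build_wall_report`` adapts a FlowSolution's
wall-sample arrays (station × side) to that layout; the functions
themselves are solver-agnostic so CSV-imported samples work too.

Conventions (documented):
- OSI = ½(1 − |∫τ dt| / ∫|τ| dt); faces with ∫|τ| dt = 0 get OSI = 0.
- Systole = the window where whole-ventricle volume decreases.
- Wall pressure in the work integral is a literature reference absolute
  pressure plus the simulated relative pressure at the wall.
- The 2D solve is per unit out-of-plane depth; ``depth`` (m) converts
  wall arc lengths to areas, so work is in J for the chosen depth.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple, Union

import numpy as np


class WallForcesError(RuntimeError):
    pass


# ----------------------------------------------------------------------
# OSI
# ----------------------------------------------------------------------

def osi(tau: np.ndarray, times: np.ndarray,
        period: Optional[float] = None, rtol: float = 1e-6) -> np.ndarray:
    """Oscillatory shear index per face, Eq. OSI = ½(1 − |∫τ|/∫|τ|).

    ``tau`` is (T, F) signed scalar shear or (T, F, C) vector
    components sampled on ``times``, which must span exactly one period
    (checked against ``period`` when given). Trapezoid quadrature.
    """
    tau = np.asarray(tau, dtype=float)
    times = np.asarray(times, dtype=float)
    if tau.ndim == 2:
        tau = tau[:, :, None]
    if tau.ndim != 3 or tau.shape[0] != len(times):
        raise WallForcesError("tau must be (T, F[, C]) matching times")
    if len(times) < 2 or np.any(np.diff(times) <= 0):
        raise WallForcesError("times must be strictly increasing")
    window = times[-1] - times[0]
    if period is not None and not np.isclose(window, period,
                                             rtol=rtol, atol=0.0):
        raise WallForcesError(
            f"sampling window {window:g} s does not equal one period "
            f"{period:g} s")
    mean_vec = np.trapezoid(tau, times, axis=0)          # (F, C)
    num = np.linalg.norm(mean_vec, axis=-1)              # |∫τ dt|
    den = np.trapezoid(np.linalg.norm(tau, axis=-1), times, axis=0)
    out = np.zeros(tau.shape[1])
    nz = den > 0.0
    out[nz] = 0.5 * (1.0 - num[nz] / den[nz])
    # guard quadrature round-off at the boundaries of [0, 0.5]
    return np.clip(out, 0.0, 0.5)


# ----------------------------------------------------------------------
# ejection work
# ----------------------------------------------------------------------

def systole_window(times: np.ndarray, ventricular_volume: np.ndarray
                   ) -> np.ndarray:
    """Boolean per-sample mask of systole (ventricular volume falling)."""
    V = np.asarray(ventricular_volume, dtype=float)
    t = np.asarray(times, dtype=float)
    if len(V) != len(t):
        raise WallForcesError("volume and times must align")
    dV = np.gradient(V, t)
    return dV < 0.0


def ejection_work(p_wall: np.ndarray, vn: np.ndarray,
                  areas: np.ndarray, times: np.ndarray,
                  window: Union[np.ndarray, Tuple[float, float]],
                  reference_pressure: float = 0.0) -> float:
    """W = ∫_window Σ_faces P_wall (v·n̂) dA dt  (J).

    ``p_wall`` and ``vn`` are (T, F); ``areas`` is (F,) or (T, F) for
    moving walls; ``vn`` is the wall velocity along the inward normal,
    so inward motion (ejection) does positive work on the fluid.
    ``window`` is a per-sample boolean mask or a (t0, t1) interval no
    longer than the sampled cycle. ``reference_pressure`` (Pa) is the
    literature absolute pressure added to the simulated relative one.
    """
    p_wall = np.asarray(p_wall, dtype=float)
    vn = np.asarray(vn, dtype=float)
    t = np.asarray(times, dtype=float)
    areas = np.asarray(areas, dtype=float)
    if p_wall.shape != vn.shape or p_wall.shape[0] != len(t):
        raise WallForcesError("p_wall/vn must be (T, F) matching times")
    if areas.ndim == 1:
        areas = np.broadcast_to(areas, p_wall.shape)
    cycle = t[-1] - t[0]
    if isinstance(window, tuple):
        t0, t1 = window
        if t1 - t0 > cycle * (1 + 1e-9):
            raise WallForcesError("systole window longer than the cycle")
        mask = (t >= t0) & (t <= t1)
    else:
        mask = np.asarray(window, dtype=bool)
        if len(mask) != len(t):
            raise WallForcesError("window mask must align with times")
    power = np.sum((p_wall + reference_pressure) * vn * areas, axis=1)
    power = np.where(mask, power, 0.0)
    return float(np.trapezoid(power, t))


# ----------------------------------------------------------------------
# regional summaries
# ----------------------------------------------------------------------

def regional_summary(values: np.ndarray, areas: np.ndarray,
                     face_region: Sequence[str],
                     regions: Optional[Sequence[str]] = None
                     ) -> Dict[str, Dict[str, float]]:
    """Area-weighted regional means of a per-face metric.

    ``values`` is (F,) for a static metric or (T, F) for a
    time-resolved one; the time-resolved case also reports
    ``peak``, the max over time of the spatial (area-weighted) mean —
    the default "temporally peak, spatially averaged" reading — and
    ``peak_facewise``, the area-weighted mean of per-face temporal
    peaks, the alternative reading.
    """
    values = np.asarray(values, dtype=float)
    areas = np.asarray(areas, dtype=float)
    face_region = np.asarray(face_region)
    if regions is None:
        regions = list(dict.fromkeys(face_region.tolist()))
    if areas.ndim == 2:
        w = areas.mean(axis=0)
    else:
        w = areas
    out: Dict[str, Dict[str, float]] = {}
    for r in regions:
        sel = np.flatnonzero(face_region == r)
        if len(sel) == 0 or w[sel].sum() <= 0:
            warnings.warn(f"region {r!r} has no wall faces; omitted")
            continue
        ws = w[sel] / w[sel].sum()
        if values.ndim == 1:
            out[r] = {"mean": float(values[sel] @ ws)}
        else:
            spatial_mean = values[:, sel] @ ws            # (T,)
            out[r] = {
                "mean": float(spatial_mean.mean()),
                "peak": float(spatial_mean.max()),
                "peak_facewise": float(values[:, sel].max(axis=0) @ ws),
            }
    return out


# ----------------------------------------------------------------------
# report assembly from a FlowSolution
# ----------------------------------------------------------------------

@dataclass
class WallMetricReport:
    """Per-face and per-region wall metrics of one solved cycle."""

    face_region: np.ndarray            # (F,)
    face_area: np.ndarray              # (F,) time-mean, m^2
    tavg_mag: np.ndarray               # (F,) time-averaged |τ|, Pa
    peak_mag: np.ndarray               # (F,) per-face temporal peak, Pa
    osi: np.ndarray                    # (F,)
    region_wss: Dict[str, Dict[str, float]]
    region_osi: Dict[str, Dict[str, float]]
    region_work: Dict[str, float]      # J (at the configured depth)
    meta: Dict[str, float] = field(default_factory=dict)


def build_wall_report(solution, reference_pressure: float = 0.0,
                      depth: float = 1.0,
                      ventricle_regions: Sequence[str] = ("LV", "RV"),
                      ) -> WallMetricReport:
    """Assemble the WSS/OSI/work report from a FlowSolution's wall
    samples.

    Faces are the (station, side) wall sample sites. Systole is where
    the summed lumen cross-section area over ``ventricle_regions`` (the
    2D surrogate of ventricular volume) decreases.
    """
    t = solution.times
    S, nxp, _ = solution.tau_wall.shape
    tau = solution.tau_wall.reshape(S, -1)         # (T, F), F = 2(nx+1)
    pw = solution.p_wall.reshape(S, -1)
    vn = solution.vn_wall.reshape(S, -1)
    ds = solution.ds_wall.reshape(S, -1) * depth   # areas (T, F)
    region = np.repeat(solution.station_region[:, None], 2,
                       axis=1).reshape(-1)

    mag = np.abs(tau)
    tavg = np.trapezoid(mag, t, axis=0) / (t[-1] - t[0])
    peak = mag.max(axis=0)
    face_osi = osi(tau, t)

    # systole from the ventricular lumen area waveform
    sel_v = np.isin(solution.station_region, list(ventricle_regions))
    gap = (solution.y_up - solution.y_lo)[:, sel_v]
    vol = np.trapezoid(gap, solution.x[sel_v], axis=1)
    mask = systole_window(t, vol)

    region_work: Dict[str, float] = {}
    for r in dict.fromkeys(solution.station_region.tolist()):
        sel = region == r
        region_work[r] = ejection_work(
            pw[:, sel], vn[:, sel], ds[:, sel], t, mask,
            reference_pressure=reference_pressure)

    return WallMetricReport(
        face_region=region,
        face_area=ds.mean(axis=0),
        tavg_mag=tavg, peak_mag=peak, osi=face_osi,
        region_wss=regional_summary(mag, ds, region),
        region_osi=regional_summary(face_osi, ds.mean(axis=0), region),
        region_work=region_work,
        meta={"reference_pressure_pa": reference_pressure,
              "depth_m": depth,
              "systole_fraction": float(mask.mean())})
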