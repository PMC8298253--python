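"""Parametric construction of deforming embryonic-heart lumen meshes.

The lumen is a lofted tube-and-lobe surface: a serial duct
(sinus-venosus inlet -> RA -> LA -> atrioventricular junction -> LV ->
RV -> outflow tract) whose chamber segments carry smooth radial lobes.
Each lobe amplitude is re-solved every frame so that the *discrete*
enclosed volume of the capped chamber matches its prescribed volume
waveform to machine precision: because axial stations are fixed and
every 3x3 determinant term of the divergence-theorem volume takes one
coordinate from each vertex, the mesh volume is an exactly quadratic
function of the lobe scale.

Morphological disease controls: the left-atrial narrowing factor
scales the LA waveform (and hence its cross sections), the ventricular
apex spike sharpens with ``apex_sharpness`` (kappa of a von-Mises-like
angular profile), and the AV junction centreline shifts medially by
``av_junction_medial_offset``. At HH28 the AV cross section is pinched
into two lumen lobes, standing in for the divided AV junction.
"""
from __future__ import annotations

import math
from typing import Dict, List, Tuple

import numpy as np
from scipy.interpolate import PchipInterpolator

from .params import CHAMBERS, DUCTS, REGIONS, GeneratorParams
from .meshseq import ChamberLabels, SurfaceMeshSequence

# axial template at unit scale (mm); boundaries of the seven regions
_TEMPLATE_X = {
    "inlet": (0.00, 0.30),
    "RA": (0.30, 1.20),
    "LA": (1.20, 2.10),
    "AV": (2.10, 2.50),
    "LV": (2.50, 3.40),
    "RV": (3.40, 4.30),
    "OFT": (4.30, 4.80),
}
_ORDER = ("inlet", "RA", "LA", "AV", "LV", "RV", "OFT")
#: reference total chamber EDV (mm^3) at which the template is unit scale
_REF_EDV = 2.0

_APEX_AMP = 1.0          # radial amplitude factor of the ventricular apex spike
_ATRIAL_APPENDAGE = 0.5  # amplitude of the mild atrial appendage lobe
_AV_PINCH_HH28 = 0.5     # sin^2(theta) pinch dividing the HH28 AV lumen


class GeometryError(RuntimeError):
    """Internal generator failure (must never yield a non-watertight mesh)."""


def smoothstep(u: np.ndarray) -> np.ndarray:
    u = np.clip(u, 0.0, 1.0)
    return u * u * (3.0 - 2.0 * u)


def activation(phase: np.ndarray, rise0: float, rise_len: float,
               hold_len: float, fall_len: float) -> np.ndarray:
    """Smooth periodic trapezoid: 0 at rest, 1 at peak contraction.

    All arguments are fractions of the cycle; the waveform has genuine
    plateaus at both extremes so volume extrema land exactly on frames.
    """
    p = (np.asarray(phase, float) - rise0) % 1.0
    a = np.zeros_like(p)
    in_rise = p < rise_len
    a[in_rise] = smoothstep(p[in_rise] / rise_len)
    in_hold = (p >= rise_len) & (p < rise_len + hold_len)
    a[in_hold] = 1.0
    in_fall = (p >= rise_len + hold_len) & (p < rise_len + hold_len + fall_len)
    a[in_fall] = 1.0 - smoothstep((p[in_fall] - rise_len - hold_len) / fall_len)
    return a


def ventricular_activation(phase: np.ndarray) -> np.ndarray:
    """Systole: rise 0.05-0.40, hold to 0.50, filling 0.50-0.90."""
    return activation(phase, 0.05, 0.35, 0.10, 0.40)


def atrial_activation(phase: np.ndarray, duty: float, offset: float) -> np.ndarray:
    """Atrial emptying starts at 0.50 + offset (aiding early ventricular
    filling) and lasts ``duty`` of the cycle; refill ends at 0.40."""
    rise0 = 0.50 + offset
    hold = 0.05
    fall = (0.40 - (rise0 + duty + hold)) % 1.0
    return activation(phase, rise0, duty, hold, fall)


def chamber_waveform(params: GeneratorParams, chamber: str,
                     phase: np.ndarray) -> np.ndarray:
    edv = params.effective_edv(chamber)
    sv = params.effective_sv(chamber)
    if chamber in ("LV", "RV"):
        act = ventricular_activation(phase)
    else:
        act = atrial_activation(phase, params.atrial_duty, params.av_phase_offset)
    return edv - sv * act


# ----------------------------------------------------------------------
# static construction
# ----------------------------------------------------------------------

def _scale(params: GeneratorParams) -> float:
    total = sum(params.effective_edv(c) for c in CHAMBERS)
    return (total / _REF_EDV) ** (1.0 / 3.0)


#: chamber EDVs (mm^3) of the unit-scale template heart
_TEMPLATE_EDV = {"LA": 0.48, "RA": 0.48, "LV": 0.4954, "RV": 0.4954}


def _layout(params: GeneratorParams):
    """Scaled region intervals, base-radius interpolant and centreline.

    Duct (junction) radii scale with the adjacent chamber's own linear
    size, not only with the whole heart: a ligated left atrium narrows
    its feeding and draining junctions along with the chamber itself.
    """
    u = _scale(params)
    region_x = {r: (a * u, b * u) for r, (a, b) in _TEMPLATE_X.items()}
    x3, x4 = region_x["AV"]
    r_out = params.oft_diameter / 2.0

    w = {}
    for ch, v_ref in _TEMPLATE_EDV.items():
        w[ch] = float(np.clip(
            (params.effective_edv(ch) / (v_ref * u ** 3)) ** (1.0 / 3.0),
            0.5, 1.6))

    ctrl_x = np.array([region_x["inlet"][0], region_x["inlet"][1],
                       region_x["RA"][1], region_x["LA"][1],
                       0.5 * (x3 + x4), region_x["AV"][1],
                       region_x["LV"][1], region_x["RV"][1],
                       region_x["OFT"][1]])
    ctrl_r = np.array([
        0.15 * u * w["RA"],
        0.16 * u * w["RA"],
        0.16 * u * math.sqrt(w["RA"] * w["LA"]),
        0.13 * u * w["LA"],
        0.115 * u * math.sqrt(w["LA"] * w["LV"]),
        0.14 * u * w["LV"],
        0.18 * u * math.sqrt(w["LV"] * w["RV"]),
        r_out, r_out])
    r_base = PchipInterpolator(ctrl_x, ctrl_r)
    xm = 0.5 * (x3 + x4)
    sigma = 0.5 * (x4 - x3)
    off = params.av_junction_medial_offset

    def centreline(x):
        return off * np.exp(-0.5 * ((np.asarray(x, float) - xm) / sigma) ** 2)

    return region_x, r_base, centreline


def _stations(region_x: Dict[str, Tuple[float, float]],
              dx_target: float) -> Tuple[np.ndarray, np.ndarray]:
    """Axial stations with every region boundary exactly on-grid.

    Returns (x stations, band region index) where band k spans
    stations k..k+1.
    """
    xs: List[float] = []
    band_region: List[int] = []
    for ri, name in enumerate(_ORDER):
        a, b = region_x[name]
        n = max(4, int(round((b - a) / dx_target)))
        seg = np.linspace(a, b, n + 1)
        if xs:
            seg = seg[1:]
        else:
            xs.append(seg[0])
            seg = seg[1:]
        xs.extend(seg.tolist())
        band_region.extend([ri] * n)
    return np.asarray(xs), np.asarray(band_region, dtype=int)


def _angular_profile(region: str, theta: np.ndarray, kappa: float) -> np.ndarray:
    if region in ("LV", "RV"):
        return 1.0 + _APEX_AMP * np.exp(kappa * (np.cos(theta - np.pi) - 1.0))
    if region in ("LA", "RA"):
        return 1.0 + _ATRIAL_APPENDAGE * np.exp(2.0 * (np.cos(theta) - 1.0))
    return np.ones_like(theta)


def signed_volume(verts: np.ndarray, tris: np.ndarray) -> float:
    """Divergence-theorem volume of an (outward-oriented) triangle soup."""
    a = verts[tris[:, 0]]
    b = verts[tris[:, 1]]
    c = verts[tris[:, 2]]
    return float(np.einsum("ij,ij->i", a, np.cross(b, c)).sum() / 6.0)


def _soup_volume(tri_pts: np.ndarray) -> float:
    return float(np.einsum("ij,ij->i", tri_pts[:, 0],
                           np.cross(tri_pts[:, 1], tri_pts[:, 2])).sum() / 6.0)


class HeartBuilder:
    """Assembles the lofted tube mesh and solves lobe amplitudes."""

    def __init__(self, params: GeneratorParams, n_theta: int = 32,
                 dx_target: float = 0.055):
        self.params = params
        self.region_x, self.r_base_f, self.centreline = _layout(params)
        u = _scale(params)
        self.x, self.band_region = _stations(self.region_x, dx_target * u)
        self.n_theta = n_theta
        self.theta = 2.0 * np.pi * np.arange(n_theta) / n_theta
        self._build_static_fields()
        self._build_topology()

    # -- static radius / bump fields -----------------------------------
    def _build_static_fields(self) -> None:
        p = self.params
        x, th = self.x, self.theta
        K1 = len(x)
        rb = self.r_base_f(x)[:, None] * np.ones((1, self.n_theta))
        if p.stage == "HH28":
            xa, xb = self.region_x["AV"]
            inside = (x >= xa) & (x <= xb)
            pinch = np.zeros(K1)
            pinch[inside] = _AV_PINCH_HH28 * np.sin(
                np.pi * (x[inside] - xa) / (xb - xa)) ** 2
            rb = rb * (1.0 - pinch[:, None] * np.sin(th)[None, :] ** 2)
        self.r_fixed = rb                       # (K+1, M)
        self.cy = self.centreline(x)            # (K+1,)

        self.bump: Dict[str, np.ndarray] = {}
        for ch in CHAMBERS:
            xa, xb = self.region_x[ch]
            ax = np.zeros(K1)
            inside = (x > xa) & (x < xb)
            ax[inside] = np.sin(np.pi * (x[inside] - xa) / (xb - xa)) ** 2
            prof = _angular_profile(ch, th, p.apex_sharpness)
            self.bump[ch] = ax[:, None] * prof[None, :]

    # -- fixed topology --------------------------------------------------
    def _build_topology(self) -> None:
        K1, M = len(self.x), self.n_theta
        self.n_ring_verts = K1 * M
        self.vid_cap_in = self.n_ring_verts
        self.vid_cap_out = self.n_ring_verts + 1

        tris: List[Tuple[int, int, int]] = []
        labels: List[str] = []

        def v(k, j):
            return k * M + (j % M)

        for k in range(K1 - 1):
            name = _ORDER[self.band_region[k]]
            for j in range(M):
                tris.append((v(k, j), v(k, j + 1), v(k + 1, j + 1)))
                tris.append((v(k, j), v(k + 1, j + 1), v(k + 1, j)))
                labels.extend([name, name])
        # inlet cap (outward -x): reversed fan; outlet cap (+x): forward fan
        for j in range(M):
            tris.append((self.vid_cap_in, v(0, j + 1), v(0, j)))
            labels.append("inlet")
        for j in range(M):
            tris.append((self.vid_cap_out, v(K1 - 1, j), v(K1 - 1, j + 1)))
            labels.append("OFT")
        self.tris = np.asarray(tris, dtype=np.int64)
        self.face_label = np.asarray(labels)

        # region boundary rings (volumetry caps)
        self.caps: Dict[str, np.ndarray] = {}
        self.cap_station: Dict[str, int] = {}
        for i in range(len(_ORDER) - 1):
            kb = int(np.searchsorted(self.band_region, i + 1))
            name = f"{_ORDER[i]}|{_ORDER[i + 1]}"
            ring = np.arange(kb * M, (kb + 1) * M, dtype=np.int64)
            self.caps[name] = ring
            self.cap_station[name] = kb

        # per-region face ids and ring index ranges
        self.region_faces = {r: np.flatnonzero(self.face_label == r)
                             for r in _ORDER}
        self.region_krange: Dict[str, Tuple[int, int]] = {}
        for i, name in enumerate(_ORDER):
            ks = int(np.searchsorted(self.band_region, i))
            ke = int(np.searchsorted(self.band_region, i, side="right"))
            self.region_krange[name] = (ks, ke)  # bands ks..ke-1, rings ks..ke

    # -- vertex assembly --------------------------------------------------
    def vertices_from_radius(self, r: np.ndarray) -> np.ndarray:
        """Vertex array from a (K+1, M) radius field."""
        th = self.theta
        verts = np.empty((self.n_ring_verts + 2, 3))
        verts[:self.n_ring_verts, 0] = np.repeat(self.x, self.n_theta)
        verts[:self.n_ring_verts, 1] = (self.cy[:, None]
                                        + r * np.cos(th)[None, :]).ravel()
        verts[:self.n_ring_verts, 2] = (r * np.sin(th)[None, :]).ravel()
        verts[self.vid_cap_in] = (self.x[0], self.cy[0], 0.0)
        verts[self.vid_cap_out] = (self.x[-1], self.cy[-1], 0.0)
        return verts

    def _cap_tris(self, ring: np.ndarray, centre: np.ndarray,
                  verts: np.ndarray, outward_positive_x: bool) -> np.ndarray:
        pts = verts[ring]
        M = len(ring)
        tri_pts = np.empty((M, 3, 3))
        tri_pts[:, 0] = centre
        if outward_positive_x:
            tri_pts[:, 1] = pts
            tri_pts[:, 2] = pts[np.r_[1:M, 0]]
        else:
            tri_pts[:, 1] = pts[np.r_[1:M, 0]]
            tri_pts[:, 2] = pts
        return tri_pts

    def region_capped_volume(self, verts: np.ndarray, region: str) -> float:
        """Enclosed volume of a region closed by flat fan caps."""
        vol = signed_volume(verts, self.tris[self.region_faces[region]])
        idx = _ORDER.index(region)
        if idx > 0:
            ring = self.caps[f"{_ORDER[idx - 1]}|{region}"]
            centre = verts[ring].mean(axis=0)
            vol += _soup_volume(self._cap_tris(ring, centre, verts, False))
        if idx < len(_ORDER) - 1:
            ring = self.caps[f"{region}|{_ORDER[idx + 1]}"]
            centre = verts[ring].mean(axis=0)
            vol += _soup_volume(self._cap_tris(ring, centre, verts, True))
        return vol

    # -- per-frame amplitude solve ----------------------------------------
    def solve_amplitude(self, chamber: str, target: float) -> float:
        """Lobe scale s such that the capped chamber volume equals
        ``target`` exactly (quadratic in s, see module docstring)."""
        vols = []
        for s in (0.0, 1.0, 2.0):
            r = self.r_fixed + s * self.bump[chamber]
            verts = self.vertices_from_radius(r)
            vols.append(self.region_capped_volume(verts, chamber))
        v0, v1, v2 = vols
        c2 = 0.5 * (v0 - 2.0 * v1 + v2)
        c1 = 0.5 * (-3.0 * v0 + 4.0 * v1 - v2)
        if target < v0 - 1e-12:
            raise GeometryError(
                f"{chamber} target volume {target:.4f} mm^3 below the duct "
                f"baseline {v0:.4f} mm^3; stroke volume too large for lobe")
        disc = c1 * c1 - 4.0 * c2 * (v0 - target)
        if disc < 0 or c2 <= 0:
            raise GeometryError(f"no valid lobe amplitude for {chamber}")
        return (-c1 + math.sqrt(disc)) / (2.0 * c2)

    def frame_radius(self, targets: Dict[str, float]) -> np.ndarray:
        r = self.r_fixed.copy()
        for ch in CHAMBERS:
            s = self.solve_amplitude(ch, targets[ch])
            r = r + s * self.bump[ch]
        return r

    def apex_vertex_id(self) -> int:
        """Vertex at the bottom (-y) of the LV lobe centre: the apex tip."""
        ks, ke = self.region_krange["LV"]
        k_mid = (ks + ke) // 2
        j_bot = self.n_theta // 2          # theta = pi -> -y
        return k_mid * self.n_theta + j_bot


# ----------------------------------------------------------------------
# public generator entry point
# ----------------------------------------------------------------------

def generate_heart(params: GeneratorParams, n_theta: int = 32,
                   dx_target: float = 0.055):
    """Build one synthetic beating heart.

    Returns ``(mesh_seq, labels, waveforms)`` where ``waveforms`` maps
    every region to its ground-truth enclosed-volume waveform (mm^3,
    one value per frame; duct regions are constant).
    """
    builder = HeartBuilder(params, n_theta=n_theta, dx_target=dx_target)
    nf = params.n_frames
    phase = np.arange(nf + 1) / nf
    times = phase * params.cycle_period

    waveforms = {ch: chamber_waveform(params, ch, phase) for ch in CHAMBERS}

    frames = np.empty((nf + 1, builder.n_ring_verts + 2, 3))
    for f in range(nf):
        targets = {ch: float(waveforms[ch][f]) for ch in CHAMBERS}
        frames[f] = builder.vertices_from_radius(builder.frame_radius(targets))
    frames[nf] = frames[0]                    # exact periodicity

    for d in DUCTS:
        waveforms[d] = np.full(nf + 1,
                               builder.region_capped_volume(frames[0], d))
    waveforms["total"] = sum(waveforms[r] for r in REGIONS)

    seq = SurfaceMeshSequence(frames, builder.tris, times)
    labels = ChamberLabels(
        face_label=builder.face_label,
        caps=dict(builder.caps),
        region_x=dict(builder.region_x),
        meta={
            "n_av_junctions": 2 if params.stage == "HH28" else 1,
            "apex_vertex": builder.apex_vertex_id(),
            "group": params.group,
            "stage": params.stage,
            "oft_diameter": params.oft_diameter,
            "cap_station": dict(builder.cap_station),
            "n_theta": n_theta,
        },
    )
    _validate_closed(seq)
    return seq, labels, waveforms


def _validate_closed(seq: SurfaceMeshSequence) -> None:
    m = seq.frame(0)
    if not m.is_watertight:
        raise GeometryError("generated surface is not watertight")
    if m.volume <= 0:
        raise GeometryError("generated surface is inside-out")


# ----------------------------------------------------------------------
# differential-geometry helpers used by tests and kinematics
# ----------------------------------------------------------------------

def vertex_solid_angle(verts: np.ndarray, tris: np.ndarray, vid: int) -> float:
    """Interior solid angle of the mesh cone at vertex ``vid`` (sr).

    Orders the one-ring neighbours into a cycle and sums the spherical
    areas of the fan triangles (Van Oosterom & Strackee).
    """
    incident = tris[np.any(tris == vid, axis=1)]
    nxt = {}
    for t in incident:
        t = list(t)
        i = t.index(vid)
        a, b = t[(i + 1) % 3], t[(i + 2) % 3]
        nxt[a] = b
    start = next(iter(nxt))
    cycle = [start]
    while True:
        n = nxt[cycle[-1]]
        if n == start:
            break
        cycle.append(n)
    u = verts[np.asarray(cycle)] - verts[vid]
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    total = 0.0
    for i in range(1, len(cycle) - 1):
        a, b, c = u[0], u[i], u[i + 1]
        num = np.dot(a, np.cross(b, c))
        den = 1.0 + np.dot(a, b) + np.dot(b, c) + np.dot(c, a)
        total += 2.0 * math.atan2(num, den)
    return abs(total)
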