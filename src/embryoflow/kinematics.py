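"""Chamber volumetry and kinematic metrics on labelled mesh sequences.

Volumes are computed by the divergence theorem over each labelled
region's faces plus fan caps built from the region's *oriented
boundary edge loops*. This is deliberately independent of any
bookkeeping the generator carries: only the face labels and the mesh
connectivity are used, so the volumetry acts as a standalone oracle
for the generator's ground-truth waveforms.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import trimesh

from .meshseq import ChamberLabels, SurfaceMeshSequence
from .params import CHAMBERS

__all__ = [
    "KinematicsError", "chamber_volumes", "stroke_metrics", "through_flow",
    "area_stretch", "section_profile", "oft_lumen_area",
    "KinematicsReport", "build_report", "region_capped_surface",
]

_ATRIA = ("LA", "RA")
_VENTRICLES = ("LV", "RV")


class KinematicsError(RuntimeError):
    pass


# ----------------------------------------------------------------------
# region capping from oriented boundary loops
# ----------------------------------------------------------------------

def _boundary_loops(faces: np.ndarray, region: str) -> List[np.ndarray]:
    """Ordered boundary vertex loops of a face subset.

    Directed edges used exactly once by the subset are boundary edges;
    they must chain into closed cycles, otherwise the region cannot be
    capped watertight.
    """
    edges = {}
    for tri in faces:
        for a, b in ((tri[0], tri[1]), (tri[1], tri[2]), (tri[2], tri[0])):
            if (b, a) in edges:
                del edges[(b, a)]          # interior edge, seen both ways
            else:
                edges[(a, b)] = None
    nxt = {}
    for a, b in edges:
        if a in nxt:
            raise KinematicsError(
                f"region {region}: non-manifold boundary at vertex {a}")
        nxt[a] = b
    loops = []
    remaining = set(nxt)
    while remaining:
        start = min(remaining)
        loop = [start]
        v = nxt[start]
        remaining.discard(start)
        while v != start:
            if v not in remaining:
                raise KinematicsError(
                    f"region {region}: open boundary loop starting at vertex "
                    f"{start} (reached {v} with no continuation)")
            loop.append(v)
            remaining.discard(v)
            v = nxt[v]
        loops.append(np.asarray(loop, dtype=np.int64))
    return loops


def region_capped_surface(triangles: np.ndarray, labels: ChamberLabels,
                          region: str) -> Tuple[np.ndarray, List[np.ndarray]]:
    """Region face list plus its boundary loops (for capping).

    Returns ``(region_triangles, loops)``; cap triangles are built per
    frame because the loop centroids move with the mesh.
    """
    idx = labels.faces_of(region)
    if len(idx) == 0:
        raise KinematicsError(f"region {region!r} has no faces")
    tris = triangles[idx]
    return tris, _boundary_loops(tris, region)


def _capped_volume(verts: np.ndarray, tris: np.ndarray,
                   loops: Sequence[np.ndarray]) -> float:
    v = verts[tris]
    vol = float(np.einsum("ij,ij->i", v[:, 0],
                          np.cross(v[:, 1], v[:, 2])).sum()) / 6.0
    for loop in loops:
        pts = verts[loop]
        centre = pts.mean(axis=0)
        a = pts
        b = pts[np.r_[1:len(pts), 0]]
        # cap triangles (centre, b, a): reuse each boundary edge in the
        # opposite direction so the capped surface stays outward-oriented
        vol += float(np.einsum("ij,ij->i", np.broadcast_to(centre, a.shape),
                               np.cross(b, a)).sum()) / 6.0
    return vol


def chamber_volumes(mesh_seq: SurfaceMeshSequence,
                    labels: ChamberLabels,
                    regions: Optional[Sequence[str]] = None
                    ) -> Dict[str, np.ndarray]:
    """Per-region enclosed volume waveform V(t) in mm^3.

    Each labelled region is closed by flat fan caps on its oriented
    boundary loops and integrated by the divergence theorem.
    """
    if regions is None:
        regions = labels.regions
    out: Dict[str, np.ndarray] = {}
    for region in regions:
        tris, loops = region_capped_surface(mesh_seq.triangles, labels, region)
        out[region] = np.array([
            _capped_volume(mesh_seq.vertices[f], tris, loops)
            for f in range(mesh_seq.n_frames)])
        if np.any(out[region] <= 0):
            raise KinematicsError(f"region {region}: non-positive volume "
                                  "(inconsistent orientation?)")
    return out


# ----------------------------------------------------------------------
# stroke metrics
# ----------------------------------------------------------------------

def stroke_metrics(V: np.ndarray, period: Optional[float] = None
                   ) -> Dict[str, float]:
    """EDV, ESV, SV, EF and (if period given) CO from one volume cycle."""
    V = np.asarray(V, dtype=float)
    if len(V) < 8:
        raise KinematicsError("need at least 8 samples per cycle")
    edv = float(V.max())
    esv = float(V.min())
    sv = edv - esv
    if sv <= 1e-12 * max(edv, 1.0):
        warnings.warn("constant volume waveform: SV = 0, EF = 0")
        sv = 0.0
    ef = sv / edv if edv > 0 else 0.0
    out = {"EDV": edv, "ESV": esv, "SV": sv, "EF": ef}
    if period is not None:
        out["CO"] = sv / period
    return out


def through_flow(V_atrium: np.ndarray, V_ventricle: np.ndarray) -> float:
    """Fraction of ventricular filling occurring while the atrial
    volume is non-decreasing (atrial contraction has ceased)."""
    Va = np.asarray(V_atrium, dtype=float)
    Vv = np.asarray(V_ventricle, dtype=float)
    if Va.shape != Vv.shape:
        raise KinematicsError("waveforms must share a time base")
    dVa = np.diff(Va)
    dVv = np.diff(Vv)
    filling = dVv > 0
    total = float(dVv[filling].sum())
    if total <= 0:
        return 0.0
    tol = 1e-9 * max(float(np.max(np.abs(Va))), 1e-30)
    direct = float(dVv[filling & (dVa >= -tol)].sum())
    return min(1.0, max(0.0, direct / total))


# ----------------------------------------------------------------------
# area stretch
# ----------------------------------------------------------------------

def _face_areas(verts: np.ndarray, tris: np.ndarray) -> np.ndarray:
    v = verts[:, tris]                                   # (F, M, 3, 3)
    n = np.cross(v[..., 1, :] - v[..., 0, :], v[..., 2, :] - v[..., 0, :])
    return 0.5 * np.linalg.norm(n, axis=-1)              # (F, M)


def area_stretch(mesh_seq: SurfaceMeshSequence) -> np.ndarray:
    """Per-face max-over-cycle area divided by min-over-cycle area."""
    areas = _face_areas(mesh_seq.vertices, mesh_seq.triangles)
    amin = areas.min(axis=0)
    if np.any(amin <= 0):
        bad = int(np.argmin(amin))
        raise KinematicsError(f"face {bad} degenerates to zero area")
    return areas.max(axis=0) / amin


# ----------------------------------------------------------------------
# cross sections
# ----------------------------------------------------------------------

def _cross_section_area(mesh: trimesh.Trimesh, origin: np.ndarray,
                        normal: np.ndarray) -> float:
    sec = mesh.section(plane_origin=origin, plane_normal=normal)
    if sec is None:
        return 0.0
    planar, _ = sec.to_2D()
    return float(planar.area)


def _region_trimesh(mesh_seq: SurfaceMeshSequence, labels: ChamberLabels,
                    region: str, frame: int) -> trimesh.Trimesh:
    """Capped, closed triangulation of one region at one frame."""
    tris, loops = region_capped_surface(mesh_seq.triangles, labels, region)
    verts = mesh_seq.vertices[frame]
    all_tris = [tris]
    extra_verts = []
    nv = len(verts)
    for loop in loops:
        centre_id = nv + len(extra_verts)
        extra_verts.append(verts[loop].mean(axis=0))
        a = loop
        b = loop[np.r_[1:len(loop), 0]]
        all_tris.append(np.column_stack(
            [np.full(len(loop), centre_id), b, a]))
    v = np.vstack([verts, np.asarray(extra_verts).reshape(-1, 3)])
    faces = np.vstack(all_tris)
    used = np.unique(faces)
    remap = np.full(len(v), -1, dtype=np.int64)
    remap[used] = np.arange(len(used))
    return trimesh.Trimesh(vertices=v[used], faces=remap[faces],
                           process=False)


def section_profile(mesh_seq: SurfaceMeshSequence, axis: np.ndarray,
                    frame: int, labels: Optional[ChamberLabels] = None,
                    region: Optional[str] = None,
                    n_stations: int = 15
                    ) -> Tuple[np.ndarray, np.ndarray]:
    """Planar cross-section areas at uniform stations along ``axis``.

    Returns ``(station_mm, area_mm2)``. Stations where the plane misses
    the (region) surface record zero area. If ``region`` is given the
    capped region submesh is sliced, otherwise the whole surface.
    """
    axis = np.asarray(axis, dtype=float)
    norm = np.linalg.norm(axis)
    if norm == 0:
        raise KinematicsError("axis must be non-zero")
    axis = axis / norm
    if region is not None:
        if labels is None:
            raise KinematicsError("labels required for a region profile")
        mesh = _region_trimesh(mesh_seq, labels, region, frame)
    else:
        mesh = mesh_seq.frame(frame)
    s = mesh.vertices @ axis
    lo, hi = float(s.min()), float(s.max())
    pad = 1e-6 * (hi - lo + 1e-12)
    stations = np.linspace(lo + pad, hi - pad, n_stations)
    centre = mesh.vertices.mean(axis=0)
    areas = np.array([
        _cross_section_area(mesh, centre + (st - centre @ axis) * axis, axis)
        for st in stations])
    return stations, areas


def oft_lumen_area(mesh_seq: SurfaceMeshSequence,
                   labels: ChamberLabels) -> float:
    """Mean OFT cross-section area (mm^2) over ventricular systole.

    The mean cross-section of the tubular OFT region equals its capped
    volume divided by its axial extent; systolic frames are those where
    the whole-ventricle volume is decreasing.
    """
    if "OFT" not in labels.regions:
        raise KinematicsError("OFT label missing")
    if "OFT" not in labels.region_x:
        raise KinematicsError("OFT axial extent (region_x) missing")
    vols = chamber_volumes(mesh_seq, labels,
                           regions=["OFT", *_VENTRICLES])
    x0, x1 = labels.region_x["OFT"]
    length = float(x1 - x0)
    Vv = vols["LV"] + vols["RV"]
    dV = np.diff(Vv)
    systole = np.flatnonzero(dV < 0)
    frames = systole if len(systole) else np.arange(mesh_seq.n_frames)
    return float(np.mean(vols["OFT"][frames])) / length


# ----------------------------------------------------------------------
# report
# ----------------------------------------------------------------------

@dataclass
class KinematicsReport:
    """Everything the volumetry stage derives from one labelled heart."""

    times: np.ndarray
    volumes: Dict[str, np.ndarray]
    chamber_metrics: Dict[str, Dict[str, float]]
    atrial_sv: float
    ventricular_sv: float
    av_sv_ratio: float
    through_flow_fraction: float
    stretch_ratio: np.ndarray
    oft_systolic_area: float
    meta: Dict[str, object] = field(default_factory=dict)

    def summary(self) -> Dict[str, object]:
        return {
            "chambers": self.chamber_metrics,
            "atrial_sv_mm3": self.atrial_sv,
            "ventricular_sv_mm3": self.ventricular_sv,
            "av_sv_ratio": self.av_sv_ratio,
            "through_flow_fraction": self.through_flow_fraction,
            "stretch_ratio_area_weighted_mean": float(self.meta.get(
                "stretch_area_weighted_mean", np.nan)),
            "stretch_ratio_unweighted_mean": float(self.stretch_ratio.mean()),
            "oft_systolic_area_mm2": self.oft_systolic_area,
        }

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.summary(), fh, indent=1)

    def volumes_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"time_s": self.times})
        for name, v in self.volumes.items():
            df[f"V_{name}_mm3"] = v
        return df


def build_report(mesh_seq: SurfaceMeshSequence,
                 labels: ChamberLabels) -> KinematicsReport:
    period = mesh_seq.period
    vols = chamber_volumes(mesh_seq, labels)
    metrics = {ch: stroke_metrics(vols[ch], period)
               for ch in CHAMBERS if ch in vols}
    asv = sum(metrics[c]["SV"] for c in _ATRIA if c in metrics)
    vsv = sum(metrics[c]["SV"] for c in _VENTRICLES if c in metrics)
    Va = sum(vols[c] for c in _ATRIA if c in vols)
    Vv = sum(vols[c] for c in _VENTRICLES if c in vols)
    stretch = area_stretch(mesh_seq)
    areas0 = _face_areas(mesh_seq.vertices[:1], mesh_seq.triangles)[0]
    report = KinematicsReport(
        times=mesh_seq.frame_times.copy(),
        volumes=vols,
        chamber_metrics=metrics,
        atrial_sv=float(asv),
        ventricular_sv=float(vsv),
        av_sv_ratio=float(asv / vsv) if vsv > 0 else float("nan"),
        through_flow_fraction=through_flow(Va, Vv),
        stretch_ratio=stretch,
        oft_systolic_area=oft_lumen_area(mesh_seq, labels),
        meta={"stretch_area_weighted_mean":
              float(np.average(stretch, weights=areas0))},
    )
    return report
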