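"""Containers for deforming surface meshes and chamber labels, plus I/O.

A :class:`SurfaceMeshSequence` is a closed triangulated endocardial
surface with fixed connectivity whose vertices move over one cardiac
cycle. Meshes are written as a VTK-XML PolyData (``.vtp``) time series
with a ``.series`` index (and optionally STL per frame); face labels as
a face-indexed CSV.
"""
from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import trimesh


@dataclass
class SurfaceMeshSequence:
    """Per-frame vertex positions (mm) on a fixed triangulation.

    ``vertices`` has shape (n_frames, n_vertices, 3); the sequence is
    periodic and the final frame duplicates frame 0.
    """

    vertices: np.ndarray          # (F, N, 3), mm
    triangles: np.ndarray         # (M, 3) int
    frame_times: np.ndarray       # (F,), s

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.triangles = np.asarray(self.triangles, dtype=np.int64)
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if self.vertices.ndim != 3 or self.vertices.shape[2] != 3:
            raise ValueError("vertices must have shape (F, N, 3)")
        if len(self.frame_times) != len(self.vertices):
            raise ValueError("frame_times length must match frame count")

    @property
    def n_frames(self) -> int:
        return self.vertices.shape[0]

    @property
    def n_vertices(self) -> int:
        return self.vertices.shape[1]

    @property
    def period(self) -> float:
        return float(self.frame_times[-1] - self.frame_times[0])

    def frame(self, i: int) -> trimesh.Trimesh:
        return trimesh.Trimesh(vertices=self.vertices[i],
                               faces=self.triangles, process=False)

    def transformed(self, matrix: np.ndarray) -> "SurfaceMeshSequence":
        """Apply a rigid-body (4x4 homogeneous) transform to every frame."""
        matrix = np.asarray(matrix, dtype=float)
        verts = self.vertices @ matrix[:3, :3].T + matrix[:3, 3]
        return SurfaceMeshSequence(verts, self.triangles.copy(),
                                   self.frame_times.copy())


@dataclass
class ChamberLabels:
    """Partition of mesh faces into named cardiac regions.

    ``face_label`` holds one region name per face. ``caps`` maps a
    boundary name ``"regionA|regionB"`` to the ordered vertex ring that
    closes both adjacent regions for volumetry (flat fan cap).
    ``region_x`` gives the axial interval of each region on the
    generator's centreline, used by the slicing and particle stages.
    """

    face_label: np.ndarray                      # (M,) of str
    caps: Dict[str, np.ndarray] = field(default_factory=dict)
    region_x: Dict[str, Tuple[float, float]] = field(default_factory=dict)
    meta: Dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.face_label = np.asarray(self.face_label)

    def faces_of(self, region: str) -> np.ndarray:
        return np.flatnonzero(self.face_label == region)

    @property
    def regions(self) -> List[str]:
        return sorted(set(self.face_label.tolist()))


# ----------------------------------------------------------------------
# I/O
# ----------------------------------------------------------------------

def _vtp_polydata_xml(vertices: np.ndarray, triangles: np.ndarray,
                      face_scalars: Optional[Dict[str, np.ndarray]] = None) -> str:
    """Serialize one triangulated surface as ASCII VTK-XML PolyData."""
    n_pts = len(vertices)
    n_tri = len(triangles)
    pts = " ".join(f"{c:.9g}" for c in np.asarray(vertices, float).ravel())
    conn = " ".join(str(i) for i in np.asarray(triangles).ravel())
    offs = " ".join(str(3 * (i + 1)) for i in range(n_tri))
    cell_arrays = ""
    if face_scalars:
        parts = []
        for name, arr in face_scalars.items():
            vals = " ".join(f"{v:.9g}" for v in np.asarray(arr, float))
            parts.append(
                f'<DataArray type="Float64" Name="{name}" format="ascii">'
                f"{vals}</DataArray>")
        cell_arrays = "<CellData>" + "".join(parts) + "</CellData>"
    return (
        '<?xml version="1.0"?>\n'
        '<VTKFile type="PolyData" version="0.1" byte_order="LittleEndian">\n'
        f'<PolyData><Piece NumberOfPoints="{n_pts}" NumberOfVerts="0" '
        f'NumberOfLines="0" NumberOfStrips="0" NumberOfPolys="{n_tri}">\n'
        '<Points><DataArray type="Float64" NumberOfComponents="3" '
        f'format="ascii">{pts}</DataArray></Points>\n'
        f"{cell_arrays}"
        f'<Polys><DataArray type="Int64" Name="connectivity" format="ascii">'
        f"{conn}</DataArray>"
        f'<DataArray type="Int64" Name="offsets" format="ascii">{offs}'
        "</DataArray></Polys>\n"
        "</Piece></PolyData></VTKFile>\n")


def write_vtp_series(seq: SurfaceMeshSequence, outdir: str,
                     basename: str = "heart",
                     labels: Optional[ChamberLabels] = None,
                     stl: bool = False) -> str:
    """Write one ``.vtp`` per frame plus a ``.series`` index; returns the
    path of the index file."""
    os.makedirs(outdir, exist_ok=True)
    scalars = None
    if labels is not None:
        codes = {r: i for i, r in enumerate(labels.regions)}
        scalars = {"region_id": np.array([codes[l] for l in labels.face_label],
                                         dtype=float)}
    entries = []
    for i in range(seq.n_frames):
        name = f"{basename}_{i:04d}.vtp"
        with open(os.path.join(outdir, name), "w") as fh:
            fh.write(_vtp_polydata_xml(seq.vertices[i], seq.triangles, scalars))
        if stl:
            seq.frame(i).export(os.path.join(outdir, f"{basename}_{i:04d}.stl"))
        entries.append({"name": name, "time": float(seq.frame_times[i])})
    index = {"file-series-version": "1.0", "files": entries}
    index_path = os.path.join(outdir, f"{basename}.vtp.series")
    with open(index_path, "w") as fh:
        json.dump(index, fh, indent=1)
    return index_path


def read_vtp(path: str) -> Tuple[np.ndarray, np.ndarray]:
    """Read back an ASCII ``.vtp`` written by :func:`write_vtp_series`."""
    import xml.etree.ElementTree as ET

    root = ET.parse(path).getroot()
    piece = root.find(".//Piece")
    pts = piece.find("Points/DataArray")
    verts = np.fromstring(pts.text, sep=" ").reshape(-1, 3)
    conn = None
    for da in piece.findall("Polys/DataArray"):
        if da.get("Name") == "connectivity":
            conn = np.fromstring(da.text, sep=" ", dtype=np.int64).reshape(-1, 3)
    return verts, conn


def read_vtp_series(index_path: str) -> SurfaceMeshSequence:
    with open(index_path) as fh:
        index = json.load(fh)
    base = os.path.dirname(index_path)
    frames, times = [], []
    tris = None
    for entry in index["files"]:
        v, t = read_vtp(os.path.join(base, entry["name"]))
        frames.append(v)
        tris = t
        times.append(entry["time"])
    return SurfaceMeshSequence(np.stack(frames), tris, np.asarray(times))


def write_labels_csv(labels: ChamberLabels, path: str) -> None:
    df = pd.DataFrame({"face_id": np.arange(len(labels.face_label)),
                       "region": labels.face_label})
    if labels.region_x:
        lo = {r: a for r, (a, b) in labels.region_x.items()}
        hi = {r: b for r, (a, b) in labels.region_x.items()}
        df["region_x_lo_mm"] = df["region"].map(lo)
        df["region_x_hi_mm"] = df["region"].map(hi)
    df.to_csv(path, index=False)


def read_labels_csv(path: str) -> ChamberLabels:
    df = pd.read_csv(path)
    region_x: Dict[str, Tuple[float, float]] = {}
    if "region_x_lo_mm" in df.columns:
        for r, sub in df.dropna(subset=["region_x_lo_mm"]).groupby(
                "region"):
            region_x[str(r)] = (float(sub["region_x_lo_mm"].iloc[0]),
                                float(sub["region_x_hi_mm"].iloc[0]))
    return ChamberLabels(face_label=df["region"].to_numpy(),
                         region_x=region_x)


def write_waveforms_csv(waveforms: Dict[str, np.ndarray],
                        times: np.ndarray, path: str) -> None:
    df = pd.DataFrame({"time_s": times})
    for name, v in waveforms.items():
        df[name] = v
    df.to_csv(path, index=False)
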