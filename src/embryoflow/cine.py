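"""Rasterized cine "ultrasound" stacks of a beating heart.

Each imaging plane (slice) is rendered over several cardiac cycles
with its own random cardiac-phase offset, blood/tissue intensity
contrast, and multiplicative speckle that decorrelates cycle-to-cycle
in moving blood but stays coherent in tissue. The injected per-slice
phase offsets are returned so the imaging stage can be round-trip
tested against ground truth.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
import trimesh

from .imaging import CineStack
from .meshseq import SurfaceMeshSequence

BLOOD_LEVEL = 0.35
TISSUE_LEVEL = 0.75
BACKGROUND_LEVEL = 0.05
TISSUE_RING_PX = 2


@dataclass
class CineResult:
    stacks: List[CineStack]
    slice_z_um: np.ndarray
    phase_offsets: np.ndarray      # frames, per slice (ground truth)
    empty: np.ndarray              # per-slice flag: plane missed the heart
    frames_per_cycle: int
    extras: dict = field(default_factory=dict)


def _inside_mask(mesh: trimesh.Trimesh, z: float, xs: np.ndarray,
                 ys: np.ndarray) -> np.ndarray:
    """Even-odd scanline test of pixel centres against the z-plane
    cross-section (robust to unordered segment soup)."""
    segs = trimesh.intersections.mesh_plane(
        mesh, plane_normal=[0.0, 0.0, 1.0], plane_origin=[0.0, 0.0, z])
    mask = np.zeros((len(ys), len(xs)), dtype=bool)
    if len(segs) == 0:
        return mask
    p = segs[:, 0, :2]
    q = segs[:, 1, :2]
    for r, y in enumerate(ys):
        cross = (p[:, 1] > y) != (q[:, 1] > y)
        if not np.any(cross):
            continue
        pc, qc = p[cross], q[cross]
        t = (y - pc[:, 1]) / (qc[:, 1] - pc[:, 1])
        x_int = pc[:, 0] + t * (qc[:, 0] - pc[:, 0])
        mask[r] = (x_int[None, :] > xs[:, None]).sum(axis=1) % 2 == 1
    return mask


def _tissue_ring(inside: np.ndarray, width: int = TISSUE_RING_PX) -> np.ndarray:
    from scipy.ndimage import binary_dilation

    return binary_dilation(inside, iterations=width) & ~inside


def render_cine(mesh_seq: SurfaceMeshSequence, slice_spacing: float = 50.0,
                n_cycles: int = 3, noise_amplitude: float = 0.15,
                pixel_size: float = 0.02, seed: int = 0,
                phase_offsets: Optional[Sequence[int]] = None,
                z_range: Optional[Sequence[float]] = None) -> CineResult:
    """Render one cine stack per imaging plane.

    ``slice_spacing`` is in µm; ``pixel_size`` in mm. Planes are normal
    to z and span the mesh's z extent (or ``z_range`` in mm). Each
    slice covers ``n_cycles`` cycles of ``frames_per_cycle`` frames
    starting at its own (returned) phase offset.
    """
    if slice_spacing <= 0:
        raise ValueError("slice_spacing must be positive")
    if n_cycles < 2:
        raise ValueError("need at least 2 cycles")
    rng = np.random.default_rng(seed)
    nf = mesh_seq.n_frames - 1          # last frame duplicates frame 0
    period = mesh_seq.period
    frame_rate = nf / period if period > 0 else 1.0

    allv = mesh_seq.vertices
    if z_range is None:
        z0, z1 = float(allv[..., 2].min()), float(allv[..., 2].max())
    else:
        z0, z1 = map(float, z_range)
    dz = slice_spacing / 1000.0         # µm -> mm
    n_slices = max(1, int(np.floor((z1 - z0) / dz + 1e-9)))
    z_planes = z0 + dz * (np.arange(n_slices) + 0.5)

    pad = 3 * pixel_size
    xs = np.arange(allv[..., 0].min() - pad, allv[..., 0].max() + pad,
                   pixel_size)
    ys = np.arange(allv[..., 1].min() - pad, allv[..., 1].max() + pad,
                   pixel_size)

    if phase_offsets is None:
        offsets = rng.integers(0, nf, size=n_slices)
        offsets[0] = 0
    else:
        offsets = np.asarray(phase_offsets, dtype=int) % nf
        if len(offsets) != n_slices:
            raise ValueError(f"expected {n_slices} phase offsets")

    stacks: List[CineStack] = []
    empty = np.zeros(n_slices, dtype=bool)
    for s, z in enumerate(z_planes):
        masks = []
        rings = []
        for f in range(nf):
            m = _inside_mask(mesh_seq.frame(f), z, xs, ys)
            masks.append(m)
            rings.append(_tissue_ring(m))
        if not any(m.any() for m in masks):
            empty[s] = True
            stacks.append(CineStack(
                np.full((n_cycles * nf, len(ys), len(xs)),
                        BACKGROUND_LEVEL),
                frame_rate, slice_z=float(z * 1000.0)))
            continue
        # tissue speckle coherent across cycles: one field per phase
        tissue_speckle = rng.standard_normal((nf, len(ys), len(xs)))
        frames = np.empty((n_cycles * nf, len(ys), len(xs)))
        for f in range(n_cycles * nf):
            ph = (f + offsets[s]) % nf
            img = np.full((len(ys), len(xs)), BACKGROUND_LEVEL)
            ring, m = rings[ph], masks[ph]
            img[ring] = TISSUE_LEVEL * (
                1.0 + noise_amplitude * tissue_speckle[ph][ring])
            blood = BLOOD_LEVEL * np.ones(int(m.sum()))
            if noise_amplitude > 0:
                # fresh draw every frame: blood speckle decorrelates
                blood *= 1.0 + noise_amplitude * rng.standard_normal(len(blood))
            img[m] = blood
            frames[f] = np.clip(img, 0.0, None)
        stacks.append(CineStack(frames, frame_rate,
                                slice_z=float(z * 1000.0)))
    return CineResult(stacks=stacks, slice_z_um=z_planes * 1000.0,
                      phase_offsets=offsets, empty=empty,
                      frames_per_cycle=nf)
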