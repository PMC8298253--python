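"""Regional flow-regime analysis of a FlowSolution."""
from __future__ import annotations

from typing import Dict, Optional, Sequence

import numpy as np

from .solver import FlowSolution, SolverError


def reynolds(solution: FlowSolution, region: str,
             props=None) -> float:
    """Peak regional Reynolds number Re = ρ·U·D_h/μ.

    U is the peak (over the cycle and over the region's stations)
    cross-section mean speed; D_h is the hydraulic diameter at the
    peak's station and time. The planar slice samples a near-circular
    conduit, whose hydraulic diameter equals the local gap.
    """
    props = props or solution.props
    sel = np.flatnonzero(solution.station_region == region)
    if len(sel) == 0:
        raise SolverError(f"region {region!r} not present in solution")
    h = (solution.y_up - solution.y_lo)[:, sel]        # (S, k)
    if np.any(h <= 0):
        raise SolverError("zero-area section in region")
    umean = np.abs(solution.u[:, sel, :]).mean(axis=2)  # (S, k)
    flat = int(np.argmax(umean))
    U = float(umean.ravel()[flat])
    D = float(h.ravel()[flat])
    return props.density * U * D / props.viscosity


def reynolds_report(solution: FlowSolution,
                    regions: Optional[Sequence[str]] = None
                    ) -> Dict[str, float]:
    if regions is None:
        regions = sorted(set(solution.station_region.tolist()))
    return {r: reynolds(solution, r) for r in regions}
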