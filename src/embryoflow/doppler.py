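"""Synthetic pulsed-wave Doppler traces at the proximal outflow tract.

The envelope velocity is modelled as the profile-peak factor times the
instantaneous mean velocity Q(t)/A(t): for a parabolic (Poiseuille)
profile the peak-to-mean factor is exactly 2, which is the documented
default. Q(t) is the ventricular ejection rate derived from the
generator's ground-truth volume waveforms (outflow only; the envelope
is clipped at zero as a Doppler gate on forward flow would be).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Union

import numpy as np
import pandas as pd

from .params import GeneratorParams

PROFILE_PEAK_FACTOR = 2.0     # parabolic profile: peak / cross-section mean


@dataclass
class DopplerTrace:
    """Envelope of peak velocity (mm/s) at the proximal OFT."""

    time: np.ndarray          # s, one cycle, endpoint included
    peak_velocity: np.ndarray  # mm/s

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.peak_velocity = np.asarray(self.peak_velocity, dtype=float)
        if self.time.shape != self.peak_velocity.shape:
            raise ValueError("time and velocity must align")
        if not np.all(np.isfinite(self.peak_velocity)):
            raise ValueError("non-finite velocity in trace")

    @property
    def period(self) -> float:
        return float(self.time[-1] - self.time[0])

    @property
    def peak(self) -> float:
        return float(self.peak_velocity.max())

    def to_csv(self, path: str) -> None:
        pd.DataFrame({"time_s": self.time,
                      "peak_velocity_mm_s": self.peak_velocity}
                     ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str) -> "DopplerTrace":
        df = pd.read_csv(path)
        return cls(df["time_s"].to_numpy(),
                   df["peak_velocity_mm_s"].to_numpy())


def velocity_from_flow(Q: np.ndarray, area: np.ndarray,
                       factor: float = PROFILE_PEAK_FACTOR) -> np.ndarray:
    """Envelope velocity from flow rate (mm^3/s) and lumen area (mm^2)."""
    area = np.asarray(area, dtype=float)
    if np.any(area <= 0):
        raise ValueError("lumen area must be positive")
    return factor * np.asarray(Q, dtype=float) / area


def synth_doppler(params: GeneratorParams,
                  oft_area: Union[float, Callable[[np.ndarray], np.ndarray]],
                  n_samples: int = 400,
                  factor: float = PROFILE_PEAK_FACTOR) -> DopplerTrace:
    """Doppler envelope for one generated heart.

    ``oft_area`` is either a constant lumen area (mm^2) or a callable
    of time (s) returning areas. Ejection rate Q(t) is the rate of
    whole-ventricle volume decrease, clipped at zero.
    """
    from .geometry import chamber_waveform

    T = params.cycle_period
    t = np.linspace(0.0, T, n_samples + 1)
    phase = t / T
    Vv = (chamber_waveform(params, "LV", phase)
          + chamber_waveform(params, "RV", phase))
    Q = np.maximum(0.0, -np.gradient(Vv, t))
    area = oft_area(t) if callable(oft_area) else np.full_like(t, oft_area)
    return DopplerTrace(t, velocity_from_flow(Q, area, factor))
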