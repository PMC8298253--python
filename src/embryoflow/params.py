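"""Parameter objects for the synthetic 4D heart generator.

Units follow the imaging convention of the pipeline: lengths in mm,
volumes in mm^3, times in seconds.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Dict, Optional

GROUPS = ("control", "LAL")
STAGES = ("HH25", "HH28")

#: chambers with prescribed volume waveforms
CHAMBERS = ("LA", "RA", "LV", "RV")
#: passive duct regions with (near) static walls
DUCTS = ("inlet", "AV", "OFT")
#: every labelled wall region of the lumen
REGIONS = CHAMBERS + DUCTS


@dataclass
class GeneratorParams:
    """Full description of one synthetic embryo heart.

    ``la_narrowing_factor`` multiplies the left-atrial volume waveform
    (EDV and SV alike), mimicking the ligature: a factor of 0.27 leaves
    the LA with 27% of its unligated end-diastolic volume.
    ``apex_sharpness`` is the angular concentration (kappa) of the
    ventricular apex spike; larger values give a sharper, more
    triangular apex. ``av_junction_medial_offset`` displaces the
    atrioventricular junction centreline medially (+y), in mm.
    """

    group: str = "control"
    stage: str = "HH25"
    cycle_period: float = 0.45          # s
    n_frames: int = 40
    edv: Dict[str, float] = field(default_factory=lambda: {
        "LA": 0.48, "RA": 0.48, "LV": 0.4954, "RV": 0.4954})
    sv: Dict[str, float] = field(default_factory=lambda: {
        "LA": 0.264, "RA": 0.264, "LV": 0.322, "RV": 0.322})
    av_phase_offset: float = 0.0        # fraction of cycle
    atrial_duty: float = 0.25           # fraction of cycle spent emptying
    apex_sharpness: float = 2.5         # dimensionless kappa >= 0
    av_junction_medial_offset: float = 0.0   # mm
    la_narrowing_factor: float = 1.0    # in (0, 1]
    oft_diameter: float = 0.28          # mm
    seed: int = 42

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")
        if self.stage not in STAGES:
            raise ValueError(f"stage must be one of {STAGES}, got {self.stage!r}")
        if self.cycle_period <= 0:
            raise ValueError("cycle_period must be positive")
        if self.n_frames < 8:
            raise ValueError("need at least 8 frames per cycle")
        for ch in CHAMBERS:
            if self.edv[ch] <= 0:
                raise ValueError(f"EDV of {ch} must be positive")
            if not (0 <= self.sv[ch] < self.edv[ch]):
                raise ValueError(f"stroke volume of {ch} must lie in [0, EDV)")
        if not (0 < self.atrial_duty < 1):
            raise ValueError("atrial_duty must lie in (0, 1)")
        if not (0 < self.la_narrowing_factor <= 1):
            raise ValueError("la_narrowing_factor must lie in (0, 1]")
        if self.apex_sharpness < 0:
            raise ValueError("apex_sharpness must be >= 0")
        if self.oft_diameter <= 0:
            raise ValueError("oft_diameter must be positive")

    # -- effective (post-ligation) chamber waveform targets --------------
    def effective_edv(self, chamber: str) -> float:
        v = self.edv[chamber]
        if chamber == "LA":
            v *= self.la_narrowing_factor
        return v

    def effective_sv(self, chamber: str) -> float:
        s = self.sv[chamber]
        if chamber == "LA":
            s *= self.la_narrowing_factor
        return s

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class CohortSpec:
    """Target sample statistics (mean, sample SD with ddof=1) that a
    generated cohort must reproduce exactly through the volumetry
    pipeline.

    ``ratio`` targets apply to the per-embryo atrial/ventricular
    stroke-volume ratio; the mean of per-embryo ratios is matched (not
    the ratio of means).
    """

    n_embryos: int
    group: str
    stage: str
    atrial_sv: tuple            # (mean, sd) of LA+RA stroke volume, mm^3
    ventricular_sv: tuple       # (mean, sd) of LV+RV stroke volume, mm^3
    av_sv_ratio: tuple          # (mean, sd) dimensionless
    la_edv: tuple               # (mean, sd) mm^3
    ra_edv: tuple
    lv_edv: tuple
    rv_edv: tuple
    cycle_period: float = 0.45
    n_frames: int = 40
    apex_sharpness: float = 2.5
    av_junction_medial_offset: float = 0.0
    la_narrowing_factor: float = 1.0
    oft_diameter: float = 0.28
    atrial_duty: float = 0.25
    seed: int = 42

    def __post_init__(self) -> None:
        if self.n_embryos < 2:
            raise ValueError("cohort needs at least 2 embryos")
        for name in ("atrial_sv", "ventricular_sv", "av_sv_ratio",
                     "la_edv", "ra_edv", "lv_edv", "rv_edv"):
            m, s = getattr(self, name)
            if s < 0:
                raise ValueError(f"{name} SD must be >= 0")
            if name != "av_sv_ratio" and m <= 0:
                raise ValueError(f"{name} mean must be positive")


class InfeasibleCohortError(ValueError):
    """Raised when no positive parameter set can reproduce the targets."""
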