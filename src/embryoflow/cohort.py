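"""Cohort calibration: per-embryo generator parameters whose derived
statistics reproduce target sample means and SDs exactly.

The atrial and ventricular stroke volumes and their per-embryo ratio
are coupled (mean of per-embryo ratios, not ratio of means), so the
stroke volumes are solved jointly by constrained least squares (SLSQP,
six equality constraints on 2n unknowns). Chamber end-diastolic
volumes use exactly standardized normal-score patterns, rank-aligned
with the stroke volumes so that larger-stroke embryos are larger
hearts and every stroke volume stays below its chamber's EDV.
"""
from __future__ import annotations

import importlib.resources as resources
from typing import List, Optional

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .params import CHAMBERS, CohortSpec, GeneratorParams, InfeasibleCohortError

_SD_TOL = 1e-12


def _sample_sd(x: np.ndarray) -> float:
    return float(np.std(x, ddof=1))


def normal_scores(n: int) -> np.ndarray:
    """Exactly standardized (mean 0, sample SD 1) normal order scores."""
    z = stats.norm.ppf((np.arange(1, n + 1) - 0.375) / (n + 0.25))
    z -= z.mean()
    z /= np.std(z, ddof=1)
    return z


def _solve_sv_joint(spec: CohortSpec, rng: np.random.Generator):
    """Per-embryo (atrial SV, ventricular SV) matching the six targets."""
    n = spec.n_embryos
    ma, sa = spec.atrial_sv
    mv, sv = spec.ventricular_sv
    mr, sr = spec.av_sv_ratio

    if max(sa, sv, sr) < _SD_TOL:
        if abs(ma / mv - mr) > 1e-6:
            raise InfeasibleCohortError(
                "zero-variance spec requires ratio mean == SV mean ratio")
        return np.full(n, ma), np.full(n, mv)

    # initial guess: normal-score patterns with the correlation implied
    # by mean(a) = mean(r*v)
    z = normal_scores(n)
    rho = (ma - mr * mv) / (sr * sv) if sr * sv > 0 else 0.0
    rho = float(np.clip(rho, -0.95, 0.95))
    perp = rng.standard_normal(n)
    perp -= perp.mean()
    # orthogonalize and standardize the perpendicular component
    perp -= z * np.dot(perp, z) / np.dot(z, z)
    if np.std(perp, ddof=1) < 1e-9:
        perp = np.roll(z, 1) - z.mean()
        perp -= z * np.dot(perp, z) / np.dot(z, z)
    perp /= np.std(perp, ddof=1)
    v0 = mv + sv * z
    r0 = mr + sr * (rho * z + np.sqrt(max(0.0, 1 - rho ** 2)) * perp)
    a0 = r0 * v0
    x0 = np.concatenate([a0, v0])

    scalevec = np.array([ma, max(sa, 1e-9), mv, max(sv, 1e-9),
                         mr, max(sr, 1e-9)])

    def stats_of(x):
        a, v = x[:n], x[n:]
        r = a / v
        raw = np.array([a.mean() - ma, _sample_sd(a) - sa,
                        v.mean() - mv, _sample_sd(v) - sv,
                        r.mean() - mr, _sample_sd(r) - sr])
        return raw / scalevec

    lo = np.concatenate([np.full(n, 0.02 * ma), np.full(n, 0.02 * mv)])
    hi = np.concatenate([np.full(n, 5.0 * ma), np.full(n, 5.0 * mv)])

    def objective(x):
        return float(np.sum((x - x0) ** 2))

    best, best_err = x0, np.inf
    for attempt in range(5):
        res = optimize.minimize(
            objective, best if attempt else x0, method="SLSQP",
            constraints=[{"type": "eq", "fun": stats_of}],
            bounds=list(zip(lo, hi)),
            options={"maxiter": 800, "ftol": 1e-16})
        # polish onto the constraint manifold (under-determined root find)
        root = optimize.least_squares(stats_of, res.x, method="trf",
                                      bounds=(lo, hi), xtol=1e-15,
                                      ftol=1e-15, gtol=1e-15)
        err = float(np.max(np.abs(stats_of(root.x))))
        if err < best_err:
            best, best_err = root.x, err
        if best_err < 1e-6:
            break
        # jitter restart
        x0 = best * (1.0 + 0.05 * rng.standard_normal(2 * n))
    if best_err > 0.01:
        raise InfeasibleCohortError(
            f"stroke-volume targets not attainable: residuals {stats_of(best)}")
    return best[:n], best[n:]


def _edv_samples(mean: float, sd: float, order: np.ndarray) -> np.ndarray:
    n = len(order)
    z = normal_scores(n)
    x = np.empty(n)
    x[order] = mean + sd * z      # rank-aligned: order[i] gets i-th score
    if np.any(x <= 0):
        raise InfeasibleCohortError(
            f"EDV spec mean={mean}, sd={sd} yields non-positive volumes")
    return x


def fit_cohort_params(spec: CohortSpec) -> List[GeneratorParams]:
    """Solve for ``spec.n_embryos`` parameter sets reproducing the
    cohort targets; deterministic for a given ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    a, v = _solve_sv_joint(spec, rng)
    n = spec.n_embryos

    order_a = np.argsort(a)   # ascending order: order_a[j] gets j-th score
    order_v = np.argsort(v)

    f = spec.la_narrowing_factor
    la = _edv_samples(*spec.la_edv, order_a)    # final (ligated) LA EDV
    ra = _edv_samples(*spec.ra_edv, order_a)
    lv = _edv_samples(*spec.lv_edv, order_v)
    rv = _edv_samples(*spec.rv_edv, order_v)

    out = []
    for i in range(n):
        la_share = la[i] / (la[i] + ra[i])
        lv_share = lv[i] / (lv[i] + rv[i])
        sv_eff = {"LA": a[i] * la_share, "RA": a[i] * (1 - la_share),
                  "LV": v[i] * lv_share, "RV": v[i] * (1 - lv_share)}
        edv_eff = {"LA": la[i], "RA": ra[i], "LV": lv[i], "RV": rv[i]}
        for ch in CHAMBERS:
            if sv_eff[ch] >= edv_eff[ch]:
                raise InfeasibleCohortError(
                    f"embryo {i}: {ch} stroke volume exceeds EDV")
        p = GeneratorParams(
            group=spec.group, stage=spec.stage,
            cycle_period=spec.cycle_period, n_frames=spec.n_frames,
            # stored LA values are pre-ligation; the narrowing factor
            # restores the ligated waveform
            edv={"LA": la[i] / f, "RA": ra[i], "LV": lv[i], "RV": rv[i]},
            sv={"LA": sv_eff["LA"] / f, "RA": sv_eff["RA"],
                "LV": sv_eff["LV"], "RV": sv_eff["RV"]},
            atrial_duty=spec.atrial_duty,
            apex_sharpness=spec.apex_sharpness,
            av_junction_medial_offset=spec.av_junction_medial_offset,
            la_narrowing_factor=f,
            oft_diameter=spec.oft_diameter,
            seed=int((spec.seed * 1009 + i) % (2 ** 31)),
        )
        out.append(p)
    return out


# ----------------------------------------------------------------------
# packaged cohort tables
# ----------------------------------------------------------------------

def load_cohort_table() -> pd.DataFrame:
    with resources.files("embryoflow.data").joinpath(
            "cohort_targets.csv").open() as fh:
        return pd.read_csv(fh)


def load_cohort_spec(group: str, stage: str,
                     seed: Optional[int] = None) -> CohortSpec:
    df = load_cohort_table()
    row = df[(df.group == group) & (df.stage == stage)]
    if row.empty:
        raise KeyError(f"no packaged cohort for {group}/{stage}")
    r = row.iloc[0]
    return CohortSpec(
        n_embryos=int(r.n_embryos), group=group, stage=stage,
        atrial_sv=(r.asv_mean, r.asv_sd),
        ventricular_sv=(r.vsv_mean, r.vsv_sd),
        av_sv_ratio=(r.ratio_mean, r.ratio_sd),
        la_edv=(r.la_edv_mean, r.la_edv_sd),
        ra_edv=(r.ra_edv_mean, r.ra_edv_sd),
        lv_edv=(r.lv_edv_mean, r.lv_edv_sd),
        rv_edv=(r.rv_edv_mean, r.rv_edv_sd),
        cycle_period=float(r.cycle_period), n_frames=int(r.n_frames),
        apex_sharpness=float(r.apex_sharpness),
        av_junction_medial_offset=float(r.av_junction_medial_offset),
        la_narrowing_factor=float(r.la_narrowing_factor),
        oft_diameter=float(r.oft_diameter),
        atrial_duty=float(r.atrial_duty),
        seed=42 if seed is None else int(seed),
    )


def generate_cohort(group: str, stage: str, seed: Optional[int] = None):
    """Generate all embryos of a packaged cohort.

    Returns a list of ``(params, mesh_seq, labels, waveforms)`` tuples.
    """
    from .geometry import generate_heart

    spec = load_cohort_spec(group, stage, seed=seed)
    out = []
    for p in fit_cohort_params(spec):
        seq, labels, wf = generate_heart(p)
        out.append((p, seq, labels, wf))
    return out
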