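"""Shared fixtures: generated cohorts, their volumetry reports, and
Doppler-tuned flow solutions reused across the suite.

Heavy artefacts are session-scoped so each cohort is generated once and
each heart solved once regardless of how many tests consume it.
"""
import numpy as np
import pytest

from embryoflow import (BoundaryConditions, build_domain,
                        build_kinematics_report, generate_cohort,
                        solve_cycle, synth_doppler, tune_outlet)
from embryoflow.bc_tuner import _doppler_shape, solver_plant

# Coarse scaled-down settings for cohort-level directional runs: one
# solve per embryo must stay ~30 s so nine fit the suite budget.
NX_COARSE = 72
SOLVE_COARSE = dict(cycles_max=6, tol=0.005, ny=12, steps_per_cycle=120)

# Full scaled-down settings for the single-heart flow-regime and
# cyclic-convergence criteria.
NX_FINE = 120
SOLVE_FINE = dict(cycles_max=10, tol=0.005, ny=16, steps_per_cycle=240)


@pytest.fixture(scope="session")
def hh25_control():
    return generate_cohort("control", "HH25", seed=42)


@pytest.fixture(scope="session")
def hh25_lal():
    return generate_cohort("LAL", "HH25", seed=42)


@pytest.fixture(scope="session")
def hh28_control():
    return generate_cohort("control", "HH28", seed=42)


@pytest.fixture(scope="session")
def hh28_lal():
    return generate_cohort("LAL", "HH28", seed=42)


def _reports(cohort):
    return [build_kinematics_report(seq, labels)
            for _, seq, labels, _ in cohort]


@pytest.fixture(scope="session")
def reports_hh25_control(hh25_control):
    return _reports(hh25_control)


@pytest.fixture(scope="session")
def reports_hh25_lal(hh25_lal):
    return _reports(hh25_lal)


@pytest.fixture(scope="session")
def reports_hh28_control(hh28_control):
    return _reports(hh28_control)


@pytest.fixture(scope="session")
def reports_hh28_lal(hh28_lal):
    return _reports(hh28_lal)


def tuned_solution(params, seq, labels, nx, solve_kw):
    """Doppler-tuned velocity-outlet solve of one generated heart."""
    from dataclasses import replace

    rep = build_kinematics_report(seq, labels)
    dop = synth_doppler(params, rep.oft_systolic_area)
    bc = BoundaryConditions(inlet_pressure=lambda t: 0.0,
                            outlet_bc="velocity")
    dom = build_domain(seq, labels, bc, nx=nx)
    target = dop.peak / 1000.0                    # mm/s -> m/s
    plant = solver_plant(dom, bc, dop, **solve_kw)
    res = tune_outlet(plant, target, tol=0.05, scale0=target)
    if plant.last_scale == res.scale:
        return plant.last_solution
    bc_fin = replace(bc, outlet_scale=res.scale,
                     outlet_shape=_doppler_shape(dop),
                     outlet_bc="velocity")
    return solve_cycle(dom, bc_fin, **solve_kw)


@pytest.fixture(scope="session")
def fine_solved_control(hh25_control):
    """Embryo 0 of the HH25 control cohort at full settings."""
    p, seq, labels, _ = hh25_control[0]
    return tuned_solution(p, seq, labels, NX_FINE, SOLVE_FINE)


@pytest.fixture(scope="session")
def coarse_solutions_hh25(hh25_control, hh25_lal):
    """Every HH25 embryo solved at the coarse settings: the input of
    the cohort-level directional criteria."""
    out = {}
    for name, cohort in (("control", hh25_control), ("LAL", hh25_lal)):
        out[name] = [tuned_solution(p, seq, labels, NX_COARSE,
                                    SOLVE_COARSE)
                     for p, seq, labels, _ in cohort]
    return out
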