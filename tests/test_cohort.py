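"""Cohort calibration: fitted parameter sets must reproduce the target
sample statistics exactly, and the packaged tables must recover the
study's printed cohort means through the full volumetry pipeline."""
import numpy as np
import pytest

from embryoflow.cohort import (fit_cohort_params, load_cohort_spec,
                               load_cohort_table, normal_scores)
from embryoflow.params import CohortSpec, InfeasibleCohortError


def _sd(x):
    return float(np.std(x, ddof=1))


def test_normal_scores_standardized():
    for n in (4, 5, 9):
        z = normal_scores(n)
        assert z.mean() == pytest.approx(0.0, abs=1e-12)
        assert _sd(z) == pytest.approx(1.0, rel=1e-12)


def test_fit_reproduces_target_statistics():
    spec = CohortSpec(
        n_embryos=5, group="control", stage="HH25",
        atrial_sv=(0.528, 0.274), ventricular_sv=(0.644, 0.321),
        av_sv_ratio=(0.87, 0.36), la_edv=(0.80, 0.10),
        ra_edv=(0.80, 0.10), lv_edv=(1.02, 0.15),
        rv_edv=(1.02, 0.15), seed=42)
    ps = fit_cohort_params(spec)
    # parameter-level SVs: atrial = LA + RA (LA stored pre-ligation)
    a = np.array([p.effective_sv("LA") + p.effective_sv("RA")
                  for p in ps])
    v = np.array([p.sv["LV"] + p.sv["RV"] for p in ps])
    r = a / v
    assert a.mean() == pytest.approx(0.528, abs=1e-4)
    assert _sd(a) == pytest.approx(0.274, abs=1e-3)
    assert v.mean() == pytest.approx(0.644, abs=1e-4)
    assert _sd(v) == pytest.approx(0.321, abs=1e-3)
    assert r.mean() == pytest.approx(0.87, abs=1e-3)
    assert _sd(r) == pytest.approx(0.36, abs=2e-3)


def test_fit_deterministic_per_seed():
    spec = load_cohort_spec("LAL", "HH25")
    p1 = fit_cohort_params(spec)
    p2 = fit_cohort_params(spec)
    for a, b in zip(p1, p2):
        assert a.to_dict() == b.to_dict()


def test_infeasible_targets_raise():
    spec = CohortSpec(
        n_embryos=4, group="control", stage="HH25",
        atrial_sv=(0.5, 0.0), ventricular_sv=(0.5, 0.0),
        # zero-variance targets with an inconsistent ratio mean
        av_sv_ratio=(2.0, 0.0), la_edv=(0.8, 0.1),
        ra_edv=(0.8, 0.1), lv_edv=(1.0, 0.1), rv_edv=(1.0, 0.1))
    with pytest.raises(InfeasibleCohortError):
        fit_cohort_params(spec)


def test_packaged_table_covers_all_cohorts():
    df = load_cohort_table()
    combos = set(zip(df.group, df.stage))
    assert {("control", "HH25"), ("LAL", "HH25"),
            ("control", "HH28"), ("LAL", "HH28")} <= combos
    with pytest.raises(KeyError):
        load_cohort_spec("control", "HH99")


def test_cohort_sizes_match_study(hh25_control, hh25_lal,
                                  hh28_control, hh28_lal):
    assert len(hh25_control) == 5
    assert len(hh25_lal) == 4
    assert len(hh28_control) == 4
    assert len(hh28_lal) == 4


def test_pipeline_recovers_sds(reports_hh25_control):
    """Volumetry must recover the printed SDs, not just the means."""
    a = np.array([r.atrial_sv for r in reports_hh25_control])
    v = np.array([r.ventricular_sv for r in reports_hh25_control])
    assert _sd(a) == pytest.approx(0.274, abs=5e-3)
    assert _sd(v) == pytest.approx(0.321, abs=5e-3)
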