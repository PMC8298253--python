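"""Wall-force metrics: OSI analytic oracles and fuzzing, ejection work
against P*dV, and regional summaries."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra import numpy as hnp

from embryoflow.wallforces import (WallForcesError, ejection_work, osi,
                                   regional_summary, systole_window)

T = np.linspace(0.0, 1.0, 201)


def test_osi_unidirectional_zero():
    """Strictly one-signed shear never reverses: OSI = 0 exactly."""
    tau = (1.5 + np.sin(2 * np.pi * T))[:, None]
    assert osi(tau, T) == pytest.approx(0.0, abs=1e-12)


def test_osi_pure_oscillation_half():
    """Zero-mean sinusoid: |integral tau| = 0 so OSI = 0.5 exactly."""
    tau = np.sin(2 * np.pi * T)[:, None]
    assert osi(tau, T)[0] == pytest.approx(0.5, abs=1e-9)


def test_osi_zero_shear_convention():
    assert osi(np.zeros((len(T), 3)), T).tolist() == [0.0, 0.0, 0.0]


def test_osi_vector_components():
    tau = np.stack([np.sin(2 * np.pi * T),
                    np.cos(2 * np.pi * T)], axis=-1)[:, None, :]
    # constant magnitude, zero-mean vector: OSI = 0.5
    assert osi(tau, T)[0] == pytest.approx(0.5, abs=1e-6)


def test_osi_window_checked():
    with pytest.raises(WallForcesError):
        osi(np.ones((len(T), 1)), T, period=0.45)
    with pytest.raises(WallForcesError):
        osi(np.ones((3, 1)), np.array([0.0, 0.5, 0.2]))


@settings(deadline=None, derandomize=True, max_examples=100)
@given(hnp.arrays(float, (25, 4),
                  elements=st.floats(-10, 10, allow_nan=False)))
def test_osi_fuzz_bounded(tau):
    """Criterion 5: OSI stays in [0, 0.5] under arbitrary shear."""
    t = np.linspace(0.0, 0.45, 25)
    vals = osi(tau, t)
    assert np.all(vals >= 0.0) and np.all(vals <= 0.5)


def test_systole_window():
    t = np.linspace(0, 1, 101)
    V = 1.0 + 0.3 * np.cos(2 * np.pi * t)
    mask = systole_window(t, V)
    # volume falls over the first half-cycle
    assert mask[2] and not mask[60]


def test_ejection_work_equals_p_dv():
    """Uniform pressure P on a shrinking surface: W = P * deltaV within
    1% (criterion 5). Faces: a unit square piston moving inward."""
    t = np.linspace(0.0, 1.0, 501)
    P = 120.0
    vn = (0.2 * np.pi * np.sin(np.pi * t))[:, None]   # inward speed
    dV = np.trapezoid(vn[:, 0], t)                    # swept volume
    areas = np.array([1.0])
    W = ejection_work(np.full((len(t), 1), 0.0), vn, areas, t,
                      np.ones(len(t), dtype=bool),
                      reference_pressure=P)
    assert W == pytest.approx(P * dV, rel=0.01)


def test_ejection_work_rigid_wall_exactly_zero():
    t = np.linspace(0.0, 1.0, 51)
    W = ejection_work(np.random.default_rng(0).random((51, 5)),
                      np.zeros((51, 5)), np.ones(5), t,
                      np.ones(51, dtype=bool))
    assert W == 0.0


def test_ejection_work_window_validation():
    t = np.linspace(0.0, 1.0, 51)
    p = np.ones((51, 2))
    with pytest.raises(WallForcesError):
        ejection_work(p, p, np.ones(2), t, (0.0, 2.0))
    with pytest.raises(WallForcesError):
        ejection_work(p, p, np.ones(2), t, np.ones(7, dtype=bool))
    with pytest.raises(WallForcesError):
        ejection_work(p, np.ones((51, 3)), np.ones(3), t,
                      np.ones(51, dtype=bool))


def test_ejection_work_interval_window():
    t = np.linspace(0.0, 1.0, 501)
    vn = np.ones((501, 1))
    W = ejection_work(np.zeros((501, 1)), vn, np.ones(1), t,
                      (0.0, 0.5), reference_pressure=2.0)
    assert W == pytest.approx(1.0, rel=5e-3)   # 2 Pa * 1 m/s * 0.5 s


def test_regional_summary_static_and_dynamic():
    vals = np.array([[1.0, 2.0, 3.0], [3.0, 0.0, 1.0]])
    areas = np.array([1.0, 1.0, 2.0])
    region = ["A", "A", "B"]
    out = regional_summary(vals, areas, region)
    # faces of A: [1,3] and [2,0]; spatial means 1.5 at both steps
    assert out["A"]["mean"] == pytest.approx(1.5)
    assert out["A"]["peak"] == pytest.approx(1.5)   # max spatial mean
    assert out["A"]["peak_facewise"] == pytest.approx(2.5)
    static = regional_summary(np.array([1.0, 3.0, 5.0]), areas, region)
    assert static["B"]["mean"] == pytest.approx(5.0)


def test_regional_summary_empty_region_warns():
    with pytest.warns(UserWarning):
        out = regional_summary(np.array([1.0]), np.array([1.0]),
                               ["A"], regions=["A", "missing"])
    assert "missing" not in out
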