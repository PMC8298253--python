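"""Volumetry oracles: divergence-theorem volumes against closed-form
solids, stroke metrics, through-flow and area stretch."""
import numpy as np
import pytest
import trimesh

from embryoflow.kinematics import (KinematicsError, area_stretch,
                                   chamber_volumes, section_profile,
                                   stroke_metrics, through_flow)
from embryoflow.meshseq import ChamberLabels, SurfaceMeshSequence


def _sphere_seq(radii, subdivisions=4):
    base = trimesh.creation.icosphere(subdivisions=subdivisions,
                                      radius=1.0)
    verts = np.stack([base.vertices * r for r in radii])
    t = np.linspace(0.0, 1.0, len(radii))
    return SurfaceMeshSequence(verts, base.faces, t), base


def test_sphere_volume_oracle():
    """Enclosed volume of an icosphere against the analytic ball volume
    (discretization error of the subdivided icosahedron ~0.3%)."""
    seq, base = _sphere_seq([1.0, 1.3])
    labels = ChamberLabels(
        face_label=np.array(["LV"] * len(base.faces)))
    vols = chamber_volumes(seq, labels)["LV"]
    exact = 4.0 / 3.0 * np.pi * np.array([1.0, 1.3]) ** 3
    assert np.allclose(vols, exact, rtol=5e-3)


def test_split_sphere_volumes_add_up():
    """Two labelled halves (plus fan caps on the equator) must sum to
    the whole enclosed volume."""
    seq, base = _sphere_seq([1.0, 1.0])
    z = base.triangles_center[:, 2]
    labels = ChamberLabels(
        face_label=np.where(z >= 0, "LV", "RV"))
    vols = chamber_volumes(seq, labels)
    whole = seq.frame(0).volume
    assert vols["LV"][0] + vols["RV"][0] == pytest.approx(
        whole, rel=1e-6)
    # the face-centre split is not exactly equatorial, so only ~half
    assert vols["LV"][0] == pytest.approx(whole / 2, rel=5e-2)


def test_stroke_metrics_basic():
    t = np.linspace(0, 1, 41)
    V = 1.0 - 0.4 * 0.5 * (1 - np.cos(2 * np.pi * t))
    m = stroke_metrics(V, period=0.45)
    assert m["EDV"] == pytest.approx(1.0)
    assert m["SV"] == pytest.approx(0.4, rel=1e-3)
    assert m["EF"] == pytest.approx(0.4, rel=1e-3)
    assert m["CO"] == pytest.approx(0.4 / 0.45, rel=1e-3)


def test_stroke_metrics_constant_warns():
    with pytest.warns(UserWarning):
        m = stroke_metrics(np.ones(16), period=0.45)
    assert m["SV"] == 0.0 and m["EF"] == 0.0


def test_through_flow_analytic():
    """Ventricle fills half while the atrium empties and half after it
    has stopped: through-flow fraction is exactly 0.5."""
    Va = np.array([1.0, 0.5, 0.5, 0.5, 0.5])
    Vv = np.array([0.5, 1.0, 1.5, 1.5, 1.5])
    assert through_flow(Va, Vv) == pytest.approx(0.5)
    # all filling during atrial emptying: zero through-flow
    assert through_flow(np.array([1.0, 0.5, 0.5]),
                        np.array([0.5, 1.0, 1.0])) == 0.0
    # no filling at all
    assert through_flow(np.array([1.0, 1.0]),
                        np.array([1.0, 1.0])) == 0.0


def test_area_stretch_rigid_is_one():
    seq, _ = _sphere_seq([1.0, 1.0, 1.0])
    assert np.allclose(area_stretch(seq), 1.0)


def test_area_stretch_uniform_scaling():
    seq, _ = _sphere_seq([1.0, 1.2])
    assert np.allclose(area_stretch(seq), 1.44, rtol=1e-9)


def test_section_profile_cylinder():
    cyl = trimesh.creation.cylinder(radius=0.5, height=2.0,
                                    sections=128)
    seq = SurfaceMeshSequence(cyl.vertices[None], cyl.faces,
                              np.array([0.0]))
    st, areas = section_profile(seq, np.array([0, 0, 1.0]), frame=0,
                                n_stations=9)
    # interior stations slice the full disc
    assert np.allclose(areas[2:-2], np.pi * 0.25, rtol=5e-3)


def test_zero_axis_rejected():
    seq, _ = _sphere_seq([1.0])
    with pytest.raises(KinematicsError):
        section_profile(seq, np.zeros(3), frame=0)
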