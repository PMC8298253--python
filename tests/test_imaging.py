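"""Cine pre-processing oracles built from synthetic periodic movies
with known period, offsets and noise."""
import numpy as np
import pytest

from embryoflow.imaging import (CineStack, ImagingError, PhaseIndex,
                                ensemble_average, phase_align,
                                retrograde_metric, select_threshold,
                                sync_slices)


def _movie(period, n_cycles, offset=0, noise=0.0, seed=0, shape=(24, 24)):
    rng = np.random.default_rng(seed)
    frames = []
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    for f in range(period * n_cycles):
        ph = ((f + offset) % period) / period
        r = 6 + 3 * np.sin(2 * np.pi * ph)
        img = 1.0 * ((yy - shape[0] / 2) ** 2
                     + (xx - shape[1] / 2) ** 2 < r ** 2)
        img = img + noise * rng.random(shape)
        frames.append(img)
    return CineStack(np.array(frames), frame_rate=100.0)


def test_phase_align_recovers_period():
    for period in (8, 12, 17):
        st = _movie(period, 4, noise=0.05, seed=1)
        ph = phase_align(st)
        assert ph.period == period
        assert np.allclose(ph.phase,
                           (np.arange(st.n_frames) % period) / period)


def test_phase_align_rejects_aperiodic():
    rng = np.random.default_rng(0)
    st = CineStack(rng.random((40, 16, 16)), 100.0)
    with pytest.raises(ImagingError):
        phase_align(st)
    with pytest.raises(ImagingError):
        phase_align(CineStack(np.zeros((40, 8, 8)), 100.0))


def test_ensemble_average_reduces_noise():
    clean = _movie(10, 1).intensity
    st = _movie(10, 6, noise=0.4, seed=2)
    ph = phase_align(st)
    avg = ensemble_average(st, ph, mode="mean")
    err_raw = np.abs(st.intensity[:10] - clean).mean()
    err_avg = np.abs(avg.intensity - clean - 0.2).mean()
    assert avg.n_frames == 10
    assert err_avg < err_raw


def test_rms_boosts_decorrelated_speckle():
    """RMS equals the mean for coherent signal but exceeds it for
    fluctuating speckle: E[x^2] = mu^2 + sigma^2."""
    rng = np.random.default_rng(3)
    period, n = 8, 8
    speckle = rng.random((period * n, 16, 16))
    st = CineStack(speckle, 100.0)
    ph = PhaseIndex(phase=(np.arange(period * n) % period) / period,
                    period=period)
    rms = ensemble_average(st, ph, mode="rms")
    mean = ensemble_average(st, ph, mode="mean")
    assert rms.intensity.mean() > mean.intensity.mean()
    # coherent movie: rms == mean
    st_c = _movie(8, 4)
    ph_c = phase_align(st_c)
    r = ensemble_average(st_c, ph_c, mode="rms")
    m = ensemble_average(st_c, ph_c, mode="mean")
    assert np.allclose(r.intensity, m.intensity, atol=1e-9)


def test_sync_slices_recovers_offsets():
    true = [0, 3, 5]
    stacks = [_movie(12, 1, offset=o, noise=0.02, seed=4 + i)
              for i, o in enumerate(true)]
    off = sync_slices(stacks)
    assert off.tolist() == true


def test_sync_slices_errors():
    with pytest.raises(ImagingError):
        sync_slices([_movie(8, 1)])
    with pytest.raises(ImagingError):
        sync_slices([_movie(8, 1), _movie(10, 1)])


def test_retrograde_metric():
    V = np.array([1.0, 2.0, 1.5, 2.5])
    # drops by 0.5 once
    assert retrograde_metric(V) == pytest.approx(0.5)
    assert retrograde_metric(np.array([1.0, 2.0, 3.0])) == 0.0


def test_select_threshold_quadratic_objective():
    res = select_threshold(lambda th: (th - 0.37) ** 2, (0.0, 1.0))
    assert res.threshold == pytest.approx(0.37, abs=5e-3)
    assert not res.boundary and not res.flat


def test_select_threshold_flat_warns():
    with pytest.warns(UserWarning):
        res = select_threshold(lambda th: 1.0, (0.0, 1.0))
    assert res.flat
    assert res.threshold == pytest.approx(0.5)


def test_select_threshold_boundary_flagged():
    res = select_threshold(lambda th: th, (0.2, 1.0))
    assert res.boundary
    assert res.threshold == pytest.approx(0.2)
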