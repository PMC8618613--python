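import numpy as np
import pytest

import undulayer as u
from undulayer.errors import AnalysisError, ParameterError

from conftest import make_frame

LY = 14.7
PAPER_WAVE = (2.1, 16.6, -0.5, 8.0)


def _sine(y, wave=PAPER_WAVE):
    amp, period, phase, y0 = wave
    return y0 + amp * np.sin(2 * np.pi * y / period + phase)


def _line_points(wave=PAPER_WAVE, n=441, noise=0.0, rng=None):
    y = np.linspace(0.0, LY, n, endpoint=False)
    z = _sine(y, wave)
    if noise and rng is not None:
        z = z + rng.normal(0.0, noise, n)
    return y, z


# ---------------------------------------------------------------------------
# surface extraction and smoothing


def test_identical_frames_average_to_any_single_frame():
    spec = u.SyntheticLayerSpec(n_molecules=49, n_frames=4, frame_jitter=0.0,
                                water_slab=(0, 998.0), seed=1)
    frames, _ = u.generate_trajectory(spec)
    points = u.extract_surface_points(frames, block=4.0)
    assert len(points) == 1
    base = frames[0].xyz[frames[0].roles == "aglycone_base"]
    order = np.argsort(frames[0].mol_ids[frames[0].roles == "aglycone_base"])
    assert np.allclose(points[0].xyz, base[order])


def test_two_jittered_frames_average_to_midpoint():
    xyz1 = [[1.0, 2.0, 5.0], [1.0, 2.0, 4.0]]
    xyz2 = [[1.0, 2.0, 5.2], [1.0, 2.0, 4.2]]
    roles = ["aglycone_base", "aglycone_tip"]
    f1 = make_frame(xyz1, roles, [1, 1], time=0.0)
    f2 = make_frame(xyz2, roles, [1, 1], time=1.0)
    points = u.extract_surface_points([f1, f2], block=2.0)
    assert points[0].xyz[0] == pytest.approx([1.0, 2.0, 5.1])


def test_point_scatter_shrinks_with_frames_per_block():
    spec = u.SyntheticLayerSpec(
        n_molecules=49, wave=(0.0, 16.6, 0.0, 8.0), z_noise=0.0,
        frame_jitter=0.1, water_slab=(0, 998.0), seed=2, n_frames=65,
        frame_interval=1.0,
    )
    frames, _ = u.generate_trajectory(spec)
    few = u.extract_surface_points(frames[1:5], block=4.0)[0]
    many = u.extract_surface_points(frames[1:65], block=64.0)[0]
    sd_few = np.std(few.xyz[:, 2])
    sd_many = np.std(many.xyz[:, 2])
    assert sd_many < sd_few / 2  # ~1/sqrt(16)


def test_block_longer_than_trajectory_rejected():
    spec = u.SyntheticLayerSpec(n_molecules=25, n_frames=3,
                                water_slab=(0, 998.0), seed=3)
    frames, _ = u.generate_trajectory(spec)
    with pytest.raises(ParameterError):
        u.extract_surface_points(frames, block=100.0)


def test_smoothing_preserves_a_straight_line():
    y = np.linspace(0, 10, 200, endpoint=False)
    xyz = np.column_stack([np.ones_like(y), y, 2.0 + 0.5 * y])
    points = u.SurfacePointSet(0.0, np.arange(200), xyz, (10.0, 10.0, 10.0))
    yc, zc = u.smooth_profile(points, 20)
    assert np.allclose(zc, 2.0 + 0.5 * yc, atol=1e-9)


def test_smoothing_error_within_curvature_bound():
    n_bins = 50
    y = np.linspace(0, LY, 5000, endpoint=False)
    xyz = np.column_stack([np.ones_like(y), y, _sine(y)])
    points = u.SurfacePointSet(0.0, np.arange(len(y)), xyz, (LY, LY, 20.0))
    yc, zc = u.smooth_profile(points, n_bins)
    amp, period = PAPER_WAVE[0], PAPER_WAVE[1]
    curvature = amp * (2 * np.pi / period) ** 2
    bound = curvature * (LY / n_bins) ** 2 / 8
    assert np.max(np.abs(zc - _sine(yc))) <= bound + 1e-6


def test_degenerate_smoothing_inputs_rejected():
    xyz = np.column_stack([np.ones(20), np.full(20, 3.0), np.ones(20)])
    points = u.SurfacePointSet(0.0, np.arange(20), xyz, (10.0, 10.0, 10.0))
    with pytest.raises(AnalysisError):
        u.smooth_profile(points, 1)
    with pytest.raises(AnalysisError):
        u.smooth_profile(points, 10)  # all points in one y-bin


# ---------------------------------------------------------------------------
# sine fitting


def test_fit_recovers_reference_wave_exactly():
    y, z = _line_points()
    fit = u.fit_sine(y, z, LY)
    assert fit.A == pytest.approx(2.1, rel=1e-3)
    assert fit.B == pytest.approx(16.6, rel=1e-3)
    assert fit.C == pytest.approx(-0.5, abs=1e-3)
    assert fit.y0 == pytest.approx(8.0, rel=1e-3)
    assert not fit.period_unidentifiable


@pytest.mark.parametrize("amp", [0.4, 1.0, 2.5])
@pytest.mark.parametrize("period", [4.0, 10.0, 20.0])
def test_fit_recovery_across_parameter_grid(amp, period):
    wave = (amp, period, 1.1, 6.0)
    y, z = _line_points(wave)
    fit = u.fit_sine(y, z, LY)
    assert fit.A == pytest.approx(amp, rel=0.01)
    assert fit.B == pytest.approx(period, rel=0.01)
    assert fit.y0 == pytest.approx(6.0, rel=0.01)


def test_flat_line_reports_zero_amplitude_and_flags_period():
    y = np.linspace(0, LY, 100)
    fit = u.fit_sine(y, np.full_like(y, 8.0), LY)
    assert fit.A == pytest.approx(0.0, abs=1e-9)
    assert fit.y0 == pytest.approx(8.0)
    assert fit.period_unidentifiable


def test_canonical_form_is_idempotent():
    y, z = _line_points()
    fit1 = u.fit_sine(y, z, LY)
    fit2 = u.fit_sine(y, fit1.z(y), LY)
    assert fit2.A == pytest.approx(fit1.A, rel=1e-6)
    assert fit2.B == pytest.approx(fit1.B, rel=1e-6)
    assert fit2.C == pytest.approx(fit1.C, abs=1e-6)
    assert fit1.A >= 0
    assert -np.pi < fit1.C <= np.pi


def test_fit_requires_enough_span_and_points():
    with pytest.raises(ParameterError):
        u.fit_sine([0, 1, 2], [1, 2, 3], LY)
    y = np.linspace(0, 3.0, 50)  # spans < Ly/2
    with pytest.raises(ParameterError):
        u.fit_sine(y, np.sin(y), LY)


def test_noisy_fit_recovery_median_over_seeds():
    errs_a, errs_b = [], []
    for seed in range(20):
        rng = np.random.default_rng(seed)
        y, z = _line_points(noise=0.3, rng=rng)
        xyz = np.column_stack([np.ones_like(y), y, z])
        points = u.SurfacePointSet(0.0, np.arange(len(y)), xyz, (LY, LY, 20.0))
        yc, zc = u.smooth_profile(points, 50)
        fit = u.fit_sine(yc, zc, LY)
        errs_a.append(abs(fit.A - 2.1) / 2.1)
        errs_b.append(abs(fit.B - 16.6) / 16.6)
    assert np.median(errs_a) < 0.05
    assert np.median(errs_b) < 0.03


def test_wave_box_ratio_examples():
    fit = u.SurfaceWaveFit(A=2.1, B=16.6, C=-0.5, y0=8.0)
    assert u.wave_box_ratio(fit, 14.7) == pytest.approx(1.129, abs=0.001)
    assert u.wave_box_ratio(u.SurfaceWaveFit(A=1, B=14.7, C=0, y0=0), 14.7) == 1.0
    assert u.wave_box_ratio(
        u.SurfaceWaveFit(A=1, B=4.5, C=0, y0=0), 4.9
    ) == pytest.approx(0.918, abs=0.001)


def test_full_chain_on_generated_layer():
    spec = u.SyntheticLayerSpec(
        n_molecules=441, z_noise=0.1, tilt_to_local_normal=(0, 0),
        water_slab=(0, 998.0), seed=4,
    )
    frame, truth = u.generate_layer(spec)
    (points, fit), = u.fit_undulation([frame], block=1.0, n_bins=50)
    assert fit.A == pytest.approx(truth.wave[0], rel=0.05)
    assert fit.B == pytest.approx(truth.wave[1], rel=0.03)
    assert fit.y0 == pytest.approx(truth.wave[3], rel=0.02)
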