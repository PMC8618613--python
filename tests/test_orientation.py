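import numpy as np
import pytest
from hypothesis import given, strategies as st

import undulayer as u
from undulayer.errors import AnalysisError, GeometryError, ParameterError
from undulayer.orientation import SlopeResult, TiltRecord

from conftest import make_frame


def _axis_frame(vectors, box=(10.0, 10.0, 10.0)):
    """One surfactant per vector: base at a lattice point, tip = base + v."""
    xyz, roles, mols = [], [], []
    for k, v in enumerate(vectors):
        base = np.array([1.0 + k, 5.0, 5.0])
        xyz += [base, base + np.asarray(v, dtype=float)]
        roles += ["aglycone_base", "aglycone_tip"]
        mols += [k + 1, k + 1]
    return make_frame(xyz, roles, mols, box=box)


def _record(angles, times=None):
    angles = np.atleast_2d(np.asarray(angles, dtype=float))
    nt, nm = angles.shape
    return TiltRecord(
        times=np.arange(nt, dtype=float) if times is None else np.asarray(times),
        mol_ids=np.arange(1, nm + 1),
        angles=angles,
        base_y=np.full((nt, nm), 5.0),
    )


@pytest.mark.parametrize(
    "vector,expected",
    [((0, 0, -1), 180.0), ((0, 1, 0), 90.0), ((0, 0, 1), 0.0),
     ((0, 1, -1), 135.0)],
)
def test_tilt_angle_of_known_vectors(vector, expected):
    record = u.tilt_angles([_axis_frame([vector])])
    assert record.angles[0, 0] == pytest.approx(expected, abs=1e-9)


def test_flat_untilted_layer_has_tilt_180():
    spec = u.SyntheticLayerSpec(
        n_molecules=49, wave=(0.0, 16.6, 0.0, 8.0),
        tilt_to_local_normal=(0.0, 0.0), z_noise=0.0, water_slab=(0, 998.0),
        seed=1,
    )
    frame, _ = u.generate_layer(spec)
    record = u.tilt_angles([frame])
    assert np.allclose(record.angles, 180.0, atol=1e-6)


def test_zero_length_axis_is_geometry_error():
    with pytest.raises(GeometryError):
        u.tilt_angles([_axis_frame([(0, 0, 0)])])


def test_histogram_single_value_bin():
    fractions = u.tilt_histogram(_record([[130.0] * 5]), [90, 120, 150, 180])
    assert fractions == pytest.approx([0.0, 1.0, 0.0])


def test_histogram_uniform_samples_proportional_to_width(rng):
    angles = rng.uniform(90.0, 180.0, size=(1, 20000))
    fractions = u.tilt_histogram(_record(angles), [90, 120, 150, 180])
    se = 3 * np.sqrt(fractions * (1 - fractions) / angles.size)
    assert np.all(np.abs(fractions - np.array([1, 1, 1]) / 3) < se + 1e-3)


def test_histogram_rejects_bad_input():
    with pytest.raises(ParameterError):
        u.tilt_histogram(_record(np.zeros((0, 0))), [0, 90])
    with pytest.raises(ParameterError):
        u.tilt_histogram(_record([[100.0]]), [180, 90])


# ---------------------------------------------------------------------------
# order parameter


@pytest.mark.parametrize("alpha,expected", [(180.0, 1.0), (90.0, 0.0),
                                            (120.0, 0.5)])
def test_order_parameter_identities(alpha, expected):
    record = _record(np.full((4, 10), alpha))
    res = u.order_parameter(record, mode="per_block", block=2.0)
    assert res.blocks.means == pytest.approx(expected, abs=1e-12)
    per_mol = u.order_parameter(record, mode="per_molecule")
    assert per_mol.per_molecule == pytest.approx([expected] * 10, abs=1e-12)


@given(st.lists(st.floats(min_value=0.0, max_value=180.0), min_size=4,
                max_size=64))
def test_order_parameter_bounded(angles):
    n = len(angles) - len(angles) % 2
    if n < 4:
        return
    record = _record(np.asarray(angles[:n]).reshape(2, -1))
    res = u.order_parameter(record, mode="per_block", block=1.0)
    assert np.all(np.abs(res.blocks.means) <= 1.0 + 1e-12)


def test_block_then_average_equals_global_for_equal_blocks(rng):
    angles = rng.uniform(90, 180, size=(20, 7))
    record = _record(angles)
    res = u.order_parameter(record, mode="per_block", block=5.0)
    global_op = float(np.mean(np.cos(np.radians(180.0 - angles))))
    assert np.mean(res.blocks.means) == pytest.approx(global_op, abs=1e-12)


# ---------------------------------------------------------------------------
# slope and corrected tilt


def test_slope_of_diagonal_and_flat_point_sets():
    xyz = [[1.0, y, y] for y in np.linspace(1, 9, 30)]
    frame = make_frame(xyz, ["aglycone_base"] * 30)
    assert u.surface_slope([frame], (1.0, 9.0)).angle == pytest.approx(45.0)
    xyz2 = [[1.0, y, 3.0] for y in np.linspace(1, 9, 30)]
    frame2 = make_frame(xyz2, ["aglycone_base"] * 30)
    assert u.surface_slope([frame2], (1.0, 9.0)).angle == pytest.approx(0.0)


def test_slope_at_inflection_matches_wave_derivative():
    spec = u.SyntheticLayerSpec(
        n_molecules=441, tilt_to_local_normal=(0.0, 0.0), z_noise=0.0,
        lattice_jitter=0.02, water_slab=(0, 998.0), seed=2,
    )
    frame, truth = u.generate_layer(spec)
    amp, period, phase, _ = truth.wave
    # inflection at 2*pi*y/B + C = 0
    y_inf = -phase * period / (2 * np.pi)
    while y_inf < 1.0:
        y_inf += period / 2
    window = (y_inf - 1.0, y_inf + 1.0)
    slope = u.surface_slope([frame], window, wave=truth.wave)
    expected = np.degrees(np.arctan(2 * np.pi * amp / period))
    assert slope.angle == pytest.approx(expected, abs=2.0)


def test_window_containing_extremum_is_rejected():
    spec = u.SyntheticLayerSpec(n_molecules=441, water_slab=(0, 998.0), seed=3)
    frame, truth = u.generate_layer(spec)
    amp, period, phase, _ = truth.wave
    y_max = (np.pi / 2 - phase) * period / (2 * np.pi)
    with pytest.raises(AnalysisError):
        u.surface_slope([frame], (y_max - 1.0, y_max + 1.0), wave=truth.wave)


def test_scalar_correction_reproduces_reported_arithmetic():
    # mean lab-frame tilt 142 deg and fitted slope 37 deg give 105 deg
    record = _record(np.full((2, 20), 142.0))
    slope = SlopeResult(angle=37.0, stderr=1.0, window=(0.0, 10.0), n_points=100)
    mean, sd = u.corrected_tilt(record, slope)
    assert mean == pytest.approx(105.0)
    assert sd == pytest.approx(1.0)  # zero tilt spread, slope SE only


def test_zero_slope_correction_is_identity():
    record = _record(np.full((1, 5), 150.0))
    slope = SlopeResult(angle=0.0, stderr=0.0, window=(0.0, 10.0), n_points=50)
    assert u.corrected_tilt(record, slope)[0] == pytest.approx(150.0)


def test_local_normal_tilt_constant_across_wave_segments():
    spec = u.SyntheticLayerSpec(
        n_molecules=441, tilt_to_local_normal=(0.0, 0.0), z_noise=0.0,
        lattice_jitter=0.02, water_slab=(0, 998.0), seed=4,
    )
    frame, truth = u.generate_layer(spec)
    means = []
    for window in u.segment_windows(truth.wave, frame.box[1]):
        local = u.local_normal_tilt([frame], truth.wave, window)
        means.append(np.mean(local))
    assert len(means) >= 2
    assert np.all(np.abs(np.array(means) - 180.0) < 3.0)
    assert np.std(means) < 3.0
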