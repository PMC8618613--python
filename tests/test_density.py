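import numpy as np
import pytest
from scipy.special import erfc

import undulayer as u
from undulayer.constants import AMU_PER_NM3_TO_KG_M3
from undulayer.density import DensityProfile
from undulayer.errors import AnalysisError, ParameterError

from conftest import make_frame


def _profile(edges, water=None, surfactant=None, area=100.0):
    nb = len(edges) - 1
    water = np.zeros(nb) if water is None else np.asarray(water, dtype=float)
    surf = np.zeros(nb) if surfactant is None else np.asarray(surfactant, float)
    return DensityProfile(
        edges=np.asarray(edges, dtype=float),
        density={"water": water, "surfactant": surf, "system": water + surf},
        sd={k: np.zeros(nb) for k in ("water", "surfactant", "system")},
        area=area,
    )


def test_uniform_water_slab_is_flat_at_requested_density():
    spec = u.SyntheticLayerSpec(n_molecules=100, water_slab=(4.0, 998.0), seed=1)
    frame, _ = u.generate_layer(spec)
    water = make_frame(
        frame.xyz[frame.roles == "water_O"],
        ["water_O"] * int(np.sum(frame.roles == "water_O")),
        box=frame.box,
        masses=[18.0153] * int(np.sum(frame.roles == "water_O")),
    )
    prof = u.compute_density_profile([water], bin_width=0.2)
    rho = prof.density["system"]
    interior = rho[2:-2]  # edge bins are half-filled
    assert np.mean(interior) == pytest.approx(998.0, rel=0.01)


def test_single_point_mass_lands_in_one_bin_with_exact_integral():
    frame = make_frame([[5.0, 5.0, 5.0]], ["other"], box=(10, 10, 10),
                       masses=[100.0])
    prof = u.compute_density_profile([frame], bin_width=0.5)
    rho = prof.density["system"]
    assert np.sum(rho > 0) == 1
    assert prof.integral("system") == pytest.approx(100.0, rel=1e-9)


@pytest.mark.parametrize("bin_width", [0.02, 0.05, 0.13])
def test_mass_conservation_for_every_binning(bin_width):
    spec = u.SyntheticLayerSpec(n_molecules=100, water_slab=(2.0, 998.0), seed=2)
    frame, _ = u.generate_layer(spec)
    prof = u.compute_density_profile([frame], bin_width=bin_width)
    comp = frame.molecule_component()
    kind = np.array([comp[int(m)] for m in frame.mol_ids])
    for component, sel in [
        ("system", np.ones(frame.n_atoms, bool)),
        ("water", kind == "water"),
        ("surfactant", kind == "surfactant"),
    ]:
        assert prof.integral(component) == pytest.approx(
            float(frame.masses[sel].sum()), rel=1e-3
        )


def test_surfactant_peak_centre_near_generator_y0():
    spec = u.SyntheticLayerSpec(n_molecules=441, seed=3)
    frame, truth = u.generate_layer(spec)
    prof = u.compute_density_profile([frame], bin_width=0.1)
    rho = prof.density["surfactant"]
    peak_z = prof.centres[np.argmax(rho)]
    assert abs(peak_z - truth.wave[3]) <= truth.wave[0] + 0.5


def test_eds_of_step_profile_is_the_step_location():
    edges = np.arange(0.0, 10.0 + 1e-9, 0.05)
    centres = 0.5 * (edges[:-1] + edges[1:])
    rho = np.where(centres < 6.0, 997.0, 0.0)
    eds = u.locate_eds(_profile(edges, water=rho))
    assert eds.z == pytest.approx(6.0, abs=1e-9)
    assert eds.bulk_density == pytest.approx(997.0)


def test_eds_invariant_to_padding_both_sides():
    edges = np.arange(0.0, 10.0 + 1e-9, 0.05)
    centres = 0.5 * (edges[:-1] + edges[1:])
    rho = np.where(centres < 6.0, 997.0, 0.0)
    z1 = u.locate_eds(_profile(edges, water=rho)).z
    edges2 = np.arange(-5.0, 15.0 + 1e-9, 0.05)
    centres2 = 0.5 * (edges2[:-1] + edges2[1:])
    rho2 = np.where(centres2 < 6.0, 997.0, 0.0)
    z2 = u.locate_eds(_profile(edges2, water=rho2)).z
    assert z2 == pytest.approx(z1, abs=1e-9)


@pytest.mark.parametrize("width", [0.2, 0.5, 1.0])
def test_eds_of_erf_profile_is_its_centre(width):
    edges = np.arange(0.0, 12.0 + 1e-9, 0.05)
    centres = 0.5 * (edges[:-1] + edges[1:])
    rho = 997.0 * 0.5 * erfc((centres - 6.0) / width)
    eds = u.locate_eds(_profile(edges, water=rho))
    assert eds.z == pytest.approx(6.0, abs=0.05)


def test_eds_halving_bin_width_moves_less_than_a_bin():
    zs = []
    for dz in (0.1, 0.05):
        edges = np.arange(0.0, 12.0 + 1e-9, dz)
        centres = 0.5 * (edges[:-1] + edges[1:])
        rho = 997.0 * 0.5 * erfc((centres - 6.0) / 0.4)
        zs.append(u.locate_eds(_profile(edges, water=rho)).z)
    assert abs(zs[1] - zs[0]) < 0.1


def test_eds_without_bulk_plateau_is_analysis_error():
    edges = np.arange(0.0, 10.0 + 1e-9, 0.05)
    centres = 0.5 * (edges[:-1] + edges[1:])
    rho = 1000.0 - 90.0 * centres  # pure gradient, no plateau
    with pytest.raises(AnalysisError):
        u.locate_eds(_profile(edges, water=rho))


def test_half_width_of_gaussian_peak():
    sigma = 0.8
    edges = np.arange(0.0, 16.0 + 1e-9, 0.02)
    centres = 0.5 * (edges[:-1] + edges[1:])
    rho = 500.0 * np.exp(-((centres - 8.0) ** 2) / (2 * sigma**2))
    hw = u.peak_half_width(_profile(edges, surfactant=rho), "surfactant")
    assert hw == pytest.approx(1.1774 * sigma, rel=0.01)


def test_half_width_of_rectangular_peak():
    edges = np.arange(0.0, 10.0 + 1e-9, 0.05)
    centres = 0.5 * (edges[:-1] + edges[1:])
    rho = np.where((centres > 4.0) & (centres < 6.0), 300.0, 0.0)
    hw = u.peak_half_width(_profile(edges, surfactant=rho), "surfactant")
    assert hw == pytest.approx(1.0, abs=0.05)


def test_half_width_rejects_twin_peaks():
    edges = np.arange(0.0, 10.0 + 1e-9, 0.1)
    centres = 0.5 * (edges[:-1] + edges[1:])
    rho = np.exp(-((centres - 3.0) ** 2)) + np.exp(-((centres - 7.0) ** 2))
    with pytest.raises(AnalysisError):
        u.peak_half_width(_profile(edges, surfactant=rho), "surfactant")


def test_half_width_rejects_boundary_peak():
    edges = np.arange(0.0, 10.0 + 1e-9, 0.1)
    centres = 0.5 * (edges[:-1] + edges[1:])
    rho = np.exp(-((centres - 0.0) ** 2))
    with pytest.raises(AnalysisError):
        u.peak_half_width(_profile(edges, surfactant=rho), "surfactant")


def test_bad_bin_width_rejected():
    frame = make_frame([[1, 1, 1]], ["other"], box=(5, 5, 5))
    with pytest.raises(ParameterError):
        u.compute_density_profile([frame], bin_width=0.0)
    with pytest.raises(ParameterError):
        u.compute_density_profile([frame], bin_width=6.0)


def test_density_units_round_trip():
    # one 18-amu bead in a 1 nm^3 bin is 18 * 1.6605 kg/m^3
    frame = make_frame([[0.5, 0.5, 0.5]], ["water_O"], box=(1, 1, 2),
                       masses=[18.0])
    prof = u.compute_density_profile([frame], bin_width=1.0)
    assert prof.density["system"].max() == pytest.approx(
        18.0 * AMU_PER_NM3_TO_KG_M3, rel=1e-9
    )
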