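import numpy as np
import pytest

from dracopcm import (
    FrozenOrderCache,
    Molecule,
    build_cavity,
    compute,
    select_order,
    water_like,
)
from dracopcm.cavity import elementary_switch, switching_value
from dracopcm.chemio import ValidationError, load_parameters
from dracopcm.draco import DracoRadii, static_radii
from dracopcm.units import angstrom_to_bohr


def _single_sphere(params_small, radius=2.0):
    mol = Molecule(["O"], np.zeros((1, 3)), [0.0])
    rad = DracoRadii(
        radii=np.array([radius]), jacobian=np.zeros((1, 1, 3)), static_flag=True
    )
    return mol, build_cavity(mol, rad, params_small)


def test_point_placement_reconstruction(params_small, water):
    cav = build_cavity(water, static_radii(water, params_small), params_small)
    recon = cav.centers[cav.sphere] + cav.radii[cav.sphere][:, None] * cav.unit
    np.testing.assert_allclose(recon, cav.points, atol=1e-12)
    np.testing.assert_allclose(np.linalg.norm(cav.unit, axis=1), 1.0, atol=1e-12)


def test_per_sphere_weights_sum_to_one(params_small, water):
    cav = build_cavity(water, static_radii(water, params_small), params_small)
    for i in range(water.n_atoms):
        assert abs(cav.weights[cav.sphere == i].sum() - 1.0) < 1e-12


def test_single_sphere_fully_active(params_small):
    _, cav = _single_sphere(params_small)
    np.testing.assert_array_equal(cav.F, 1.0)
    assert cav.n_active == params_small.n_leb
    assert cav.xi.min() > 0


def test_widths_follow_born_formula(params_small):
    _, cav = _single_sphere(params_small, radius=2.5)
    expected = cav.xi_born / (2.5 * np.sqrt(cav.weights))
    np.testing.assert_allclose(cav.xi, expected, rtol=1e-14)


def test_switching_far_sphere_is_unity():
    # r_iJ far beyond R_J + 12/xi: the attenuation saturates to 1
    f = elementary_switch(2.0, 50.0, 2.0)
    assert abs(f - 1.0) < 1e-15


def test_switching_center_of_foreign_sphere():
    from scipy.special import erf

    xi, RJ = 1.7, 2.2
    f = elementary_switch(xi, 0.0, RJ)
    np.testing.assert_allclose(f, 1.0 - erf(xi * RJ), rtol=1e-14)


def test_switching_on_surface_of_foreign_sphere():
    from scipy.special import erf

    xi, RJ = 1.3, 1.9
    f = elementary_switch(xi, RJ, RJ)
    np.testing.assert_allclose(f, 1.0 - 0.5 * erf(2.0 * xi * RJ), rtol=1e-14)


def test_switching_monotone_in_distance():
    xi, RJ = 2.0, 1.5
    r = np.linspace(0.0, 6.0, 400)
    f = elementary_switch(xi, r, RJ)
    assert np.all(np.diff(f) >= 0)  # derivative vanishes exactly at r = 0
    bulk = (r > 0.3) & (r < 4.0)
    assert np.all(np.diff(f[bulk]) > 0)
    assert f[0] < 1e-3 and abs(f[-1] - 1.0) < 1e-12


def test_deeply_buried_point_fully_attenuated():
    f = elementary_switch(1e3, 0.75, 1.5)  # far inside the sphere
    assert f < 1e-12


def test_switching_value_accessor(params_small, water):
    cav = build_cavity(water, static_radii(water, params_small), params_small)
    i = int(np.flatnonzero(cav.sphere == 0)[0])
    val = switching_value(cav, i, 1)
    assert 0.0 < val <= 1.0
    with pytest.raises(ValidationError):
        switching_value(cav, i, 0)  # own sphere


def test_select_order_isogrid_fixed(params):
    assert select_order("isogrid", angstrom_to_bohr(0.5), params) == 194
    assert select_order("isogrid", angstrom_to_bohr(5.0), params) == 194


def test_select_order_isodensity_nearest():
    params = load_parameters(overrides={"scheme": "isodensity"})
    # rho = 7.5 / A^2, R = 1.5 A: target 212.1 -> nearest packaged size 194
    assert select_order("isodensity", angstrom_to_bohr(1.5), params) == 194
    # small sphere: 7.5 * 4 pi * 0.25 = 23.6 -> 26
    assert select_order("isodensity", angstrom_to_bohr(0.5), params) == 26


def test_select_order_frozen_caches_first_choice():
    params = load_parameters(overrides={"scheme": "isodensity-frozen"})
    cache = FrozenOrderCache()
    first = select_order(
        "isodensity-frozen", angstrom_to_bohr(1.5), params, sphere=0, cache=cache
    )
    second = select_order(
        "isodensity-frozen", angstrom_to_bohr(0.5), params, sphere=0, cache=cache
    )
    assert first == second == 194


def test_zero_radius_rejected(params_small, water):
    rad = DracoRadii(
        radii=np.array([0.0, 1.0, 1.0]),
        jacobian=np.zeros((3, 3, 3)),
        static_flag=True,
    )
    with pytest.raises(ValidationError):
        build_cavity(water, rad, params_small)


def test_switching_continuity_under_rigid_displacement(params_small, water):
    """Moving one sphere by 1e-6 bohr changes every switching value by
    O(step), not O(1)."""
    cav0 = build_cavity(water, static_radii(water, params_small), params_small)
    moved = water.displaced(1, np.array([1e-6, 0, 0]))
    cav1 = build_cavity(moved, static_radii(moved, params_small), params_small)
    assert np.abs(cav1.F - cav0.F).max() < 1e-5


def test_sphere_area_consistency(params_small, water):
    cav = build_cavity(water, static_radii(water, params_small), params_small)
    for i, r in enumerate(cav.radii):
        area = 4 * np.pi * r**2 * cav.weights[cav.sphere == i].sum()
        np.testing.assert_allclose(area, 4 * np.pi * r**2, rtol=1e-13)
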