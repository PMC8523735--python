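"""FEM kernel: meshing, material law, patch test, equivalent strain."""

import numpy as np
import pytest

from osteomap.fem import (
    BoundarySpec,
    SingularStiffnessError,
    boundary_edges,
    equivalent_strain,
    mesh_from_mask,
    morgan_modulus,
    solve_plane_elastic,
)

# ----------------------------------------------------------------- meshing


def test_single_pixel_mesh():
    mesh = mesh_from_mask(np.ones((1, 1), bool), pixel_spacing=0.2, refinement=1)
    assert mesh.n_elements == 2
    assert mesh.areas().sum() == pytest.approx(0.2**2, abs=1e-15)


@pytest.mark.parametrize("refinement", [1, 2, 3])
def test_square_mask_area_closed_form(refinement):
    mesh = mesh_from_mask(np.ones((10, 10), bool), 0.1, refinement)
    assert mesh.areas().sum() == pytest.approx(1.0, abs=1e-9)
    assert np.all(mesh.areas() > 0)


def test_disconnected_mask_rejected():
    mask = np.zeros((3, 3), bool)
    mask[0, 0] = mask[2, 2] = True  # diagonal contact is not 4-connectivity
    with pytest.raises(ValueError, match="4-connected"):
        mesh_from_mask(mask, 0.1)


def test_empty_mask_rejected():
    with pytest.raises(ValueError, match="nonempty"):
        mesh_from_mask(np.zeros((3, 3), bool), 0.1)


def test_element_density_sampled_from_owner_pixel():
    density = np.array([[1.0, 2.0], [3.0, 4.0]])
    mesh = mesh_from_mask(np.ones((2, 2), bool), 0.1, refinement=2, density=density)
    for owner, d in zip(mesh.element_owner, mesh.element_density):
        assert d == density[owner[0], owner[1]]


# ----------------------------------------------------------------- material law


def test_morgan_power_law_identity_and_scaling():
    a, b = 4730.0, 1.56
    assert morgan_modulus(1.0, "vertebra") == pytest.approx(a)
    e1 = morgan_modulus(0.4, "vertebra")
    e2 = morgan_modulus(0.8, "vertebra")
    assert e2 / e1 == pytest.approx(2**b, rel=1e-12)


def test_morgan_monotone_over_density_grid():
    rho = np.linspace(1e-3, 2.0, 400)
    E = morgan_modulus(rho, "femur")
    assert np.all(np.diff(E) > 0)


def test_morgan_floor_for_nonpositive_density():
    with pytest.warns(UserWarning, match="floored"):
        E = morgan_modulus(np.array([-1.0, 0.0, 1.0]), "vertebra", floor_modulus=2.5)
    assert E[0] == E[1] == 2.5 and E[2] == pytest.approx(4730.0)


# ----------------------------------------------------------------- solver


def _tension_plate(n=8, spacing=0.1, E=1000.0, nu=0.3, sigma=5.0):
    """Uniform plate, uniform tension on the top edge, rollers at the bottom."""
    mesh = mesh_from_mask(np.ones((n, n), bool), spacing)
    y = mesh.nodes[:, 1]
    ext = boundary_edges(mesh)
    top = ext[(y[ext[:, 0]] == y.max()) & (y[ext[:, 1]] == y.max())]
    bottom = np.nonzero(y == y.min())[0]
    fixed = {int(i): (False, True) for i in bottom}
    pin = int(bottom[np.argmin(mesh.nodes[bottom, 0])])
    fixed[pin] = (True, True)
    bc = BoundarySpec(
        fixed=fixed,
        edge_tractions=[((int(a), int(b)), (0.0, sigma)) for a, b in top],
    )
    return mesh, bc, E, nu, sigma


def test_uniaxial_patch_test():
    """Uniform tension reproduces the closed-form strain state to 1e-8."""
    mesh, bc, E, nu, sigma = _tension_plate()
    field = solve_plane_elastic(mesh, E, nu, bc)
    np.testing.assert_allclose(field.strain[:, 1], sigma / E, rtol=1e-8)
    np.testing.assert_allclose(field.strain[:, 0], -nu * sigma / E, rtol=1e-8)
    np.testing.assert_allclose(field.strain[:, 2], 0.0, atol=1e-12)


def test_zero_load_zero_strain():
    mesh, bc, E, nu, _ = _tension_plate(sigma=0.0)
    field = solve_plane_elastic(mesh, E, nu, bc)
    assert np.all(field.strain == 0) and np.all(field.equivalent == 0)


def test_global_force_balance():
    """Reaction forces balance the applied load to 1e-8 relative."""
    mesh, bc, E, nu, sigma = _tension_plate(n=6)
    field = solve_plane_elastic(mesh, E, nu, bc)
    applied = field.applied.sum(axis=0)
    reactions = field.reactions.sum(axis=0)
    np.testing.assert_allclose(reactions, -applied, rtol=1e-8, atol=1e-10 * abs(sigma))


def test_unconstrained_system_diagnosed():
    mesh = mesh_from_mask(np.ones((3, 3), bool), 0.1)
    with pytest.raises(SingularStiffnessError, match="no Dirichlet"):
        solve_plane_elastic(mesh, 1000.0, 0.3, BoundarySpec())


def test_rigid_rotation_left_free_diagnosed():
    """Fixing a single node leaves a rotation mode; must raise, not return junk."""
    mesh = mesh_from_mask(np.ones((3, 3), bool), 0.1)
    bc = BoundarySpec(fixed={0: (True, True)},
                      edge_tractions=[((1, 2), (0.0, 1.0))])
    with pytest.raises(SingularStiffnessError):
        solve_plane_elastic(mesh, 1000.0, 0.3, bc)


# ----------------------------------------------------------------- equivalent strain


def test_equivalent_strain_zero_iff_zero():
    assert equivalent_strain(np.zeros(3), 0.3) == 0.0
    assert equivalent_strain(np.array([1e-9, 0, 0]), 0.3) > 0.0


def test_equivalent_strain_matches_principal_value_oracle(vm_oracle):
    rng = np.random.default_rng(17)
    for _ in range(50):
        ex, ey, gxy = rng.normal(size=3) * 1e-3
        nu = rng.uniform(0.05, 0.45)
        expected = vm_oracle(ex, ey, gxy, nu)
        assert equivalent_strain(np.array([ex, ey, gxy]), nu) == pytest.approx(
            expected, rel=1e-10, abs=1e-18
        )


def test_equivalent_strain_uniaxial_closed_form(vm_oracle):
    e, nu = 2.5e-3, 0.3
    val = equivalent_strain(np.array([-nu * e, e, 0.0]), nu)
    assert val == pytest.approx(vm_oracle(-nu * e, e, 0.0, nu), rel=1e-12)


@pytest.mark.parametrize("theta_deg", [30.0, 75.0, 120.0])
def test_equivalent_strain_rotation_invariant(theta_deg):
    rng = np.random.default_rng(3)
    ex, ey, gxy = rng.normal(size=3) * 1e-3
    nu = 0.3
    t = np.deg2rad(theta_deg)
    R = np.array([[np.cos(t), -np.sin(t)], [np.sin(t), np.cos(t)]])
    T = np.array([[ex, gxy / 2], [gxy / 2, ey]])
    Tr = R @ T @ R.T
    rotated = np.array([Tr[0, 0], Tr[1, 1], 2 * Tr[0, 1]])
    assert equivalent_strain(rotated, nu) == pytest.approx(
        equivalent_strain(np.array([ex, ey, gxy]), nu), abs=1e-12
    )


def test_equivalent_strain_rejects_nonfinite():
    with pytest.raises(ValueError, match="finite"):
        equivalent_strain(np.array([np.nan, 0.0, 0.0]), 0.3)
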