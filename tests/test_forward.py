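"""FEM forward solver: stiffness assembly, electrode model, noise."""

import numpy as np
import pytest

from eitmap._errors import ValidationError
from eitmap.forward import (
    ConductivityField,
    ForwardModel,
    assemble_system,
    add_noise,
    simulate_frame,
)
from eitmap.mesh import SuperellipseOutline, TorsoMesh, build_torso_mesh
from eitmap.protocol import default_protocol

from _oracles import disk_two_point_potential


def _unit_right_triangle():
    nodes = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
    return TorsoMesh(nodes, np.array([[0, 1, 2]]), np.array([[0, 1], [1, 2], [2, 0]]))


def test_local_stiffness_matches_cotangent_formula():
    """Hand computation for a unit right triangle with sigma = 1."""
    mesh = _unit_right_triangle()
    K = assemble_system(mesh, ConductivityField(np.array([1.0]))).toarray()
    expected = 0.5 * np.array([[2.0, -1.0, -1.0], [-1.0, 1.0, 0.0], [-1.0, 0.0, 1.0]])
    assert np.allclose(K, expected, atol=1e-14)


def test_stiffness_nullspace_and_row_sums(coarse_mesh, rng):
    sigma = rng.uniform(0.1, 2.0, coarse_mesh.n_elements)
    K = assemble_system(coarse_mesh, ConductivityField(sigma))
    const = np.ones(coarse_mesh.n_nodes)
    from scipy.sparse.linalg import norm as spnorm

    assert np.max(np.abs(K @ const)) <= 1e-12 * spnorm(K)
    assert np.max(np.abs((K - K.T).toarray())) <= 1e-14 * spnorm(K)


def test_stiffness_linear_in_sigma(coarse_mesh):
    f1 = ConductivityField.homogeneous(coarse_mesh, 1.0)
    f3 = ConductivityField.homogeneous(coarse_mesh, 3.0)
    K1 = assemble_system(coarse_mesh, f1)
    K3 = assemble_system(coarse_mesh, f3)
    # exact up to the last ulp of the per-element products
    assert np.allclose((3.0 * K1).toarray(), K3.toarray(), rtol=1e-15, atol=0)


def test_nonpositive_conductivity_rejected(coarse_mesh):
    with pytest.raises(ValidationError):
        ConductivityField(np.zeros(coarse_mesh.n_elements))


def test_current_linearity_and_sigma_scaling(coarse_mesh):
    model1 = ForwardModel(coarse_mesh, ConductivityField.homogeneous(coarse_mesh, 0.2))
    u1 = model1.solve_injection(0, 4, 1e-3)
    u2 = model1.solve_injection(0, 4, 2e-3)
    assert np.allclose(u2, 2.0 * u1, rtol=0, atol=1e-15 + 1e-12 * np.abs(u1).max())
    model_c = ForwardModel(coarse_mesh, ConductivityField.homogeneous(coarse_mesh, 0.2 * 5))
    uc = model_c.solve_injection(0, 4, 1e-3)
    assert np.allclose(uc, u1 / 5.0, rtol=1e-10)


def test_discrete_reciprocity_random_fields(coarse_mesh):
    """Transfer voltage is symmetric under source/measurement exchange."""
    rng = np.random.default_rng(11)
    pairs = [((0, 4), (1, 5)), ((2, 6), (3, 7)), ((0, 2), (5, 7))]
    for trial in range(20):
        sigma = rng.uniform(0.05, 3.0, coarse_mesh.n_elements)
        model = ForwardModel(coarse_mesh, ConductivityField(sigma))
        (a, b), (c, d) = pairs[trial % len(pairs)]
        u_ab = model.solve_injection(a, b, 1e-3)
        u_cd = model.solve_injection(c, d, 1e-3)
        v1 = model.electrode_potential(u_ab, c) - model.electrode_potential(u_ab, d)
        v2 = model.electrode_potential(u_cd, a) - model.electrode_potential(u_cd, b)
        assert v1 == pytest.approx(v2, rel=1e-8)


def test_frame_invariant_under_node_permutation(coarse_mesh, rng):
    proto = default_protocol()
    field = ConductivityField.homogeneous(coarse_mesh, 0.5)
    base = simulate_frame(coarse_mesh, field, proto).values
    perm = rng.permutation(coarse_mesh.n_nodes)
    inv = np.argsort(perm)
    permuted = TorsoMesh(
        coarse_mesh.nodes[perm],
        inv[coarse_mesh.elements],
        inv[coarse_mesh.boundary_edges],
        [list(g) for g in coarse_mesh.electrodes],
    )
    other = simulate_frame(permuted, field, proto).values
    assert np.allclose(other, base, rtol=1e-9)


def test_no_contrast_equals_homogeneous(coarse_mesh):
    proto = default_protocol()
    homo = simulate_frame(coarse_mesh, ConductivityField.homogeneous(coarse_mesh, 0.2), proto)
    same = simulate_frame(
        coarse_mesh, ConductivityField(np.full(coarse_mesh.n_elements, 0.2)), proto
    )
    assert np.array_equal(homo.values, same.values)


def _disk_mesh(h):
    return build_torso_mesh(
        SuperellipseOutline(1.0, 1.0, 2.0),
        electrode_count=2,
        electrode_arc_fraction=0.02,  # point-like: single boundary edge
        target_edge_length=h,
    )


def _disk_error(h):
    """Max relative boundary-potential error vs the closed-form solution."""
    mesh = _disk_mesh(h)
    sigma, current = 1.0, 1e-3
    model = ForwardModel(mesh, ConductivityField.homogeneous(mesh, sigma))
    u = model.solve_injection(0, 1, current)
    src = mesh.nodes[mesh.electrode_edge_nodes(0)].mean(axis=(0, 1))
    sink = mesh.nodes[mesh.electrode_edge_nodes(1)].mean(axis=(0, 1))
    boundary_nodes = np.unique(mesh.boundary_edges)
    pts = mesh.nodes[boundary_nodes]
    # stay away from the injection singularities
    keep = (np.linalg.norm(pts - src, axis=1) > 0.5) & (
        np.linalg.norm(pts - sink, axis=1) > 0.5
    )
    nodes = boundary_nodes[keep]
    exact = disk_two_point_potential(mesh.nodes[nodes], src, sink, current, sigma)
    exact -= exact.mean()
    fem = u[nodes] - u[nodes].mean()
    scale = np.abs(exact).max()
    return float(np.abs(fem - exact).max() / scale)


def test_disk_closed_form_within_2pct_and_monotone():
    errs = [_disk_error(h) for h in (0.125, 0.083, 0.05)]
    assert errs[0] > errs[1] > errs[2]
    assert errs[2] < 0.02


def test_noise_disabled_sentinel(coarse_mesh):
    proto = default_protocol()
    frame = simulate_frame(coarse_mesh, ConductivityField.homogeneous(coarse_mesh, 0.2), proto)
    assert add_noise(frame, np.inf, 0) is frame


def test_noise_deterministic_and_recorded(coarse_mesh):
    proto = default_protocol()
    frame = simulate_frame(coarse_mesh, ConductivityField.homogeneous(coarse_mesh, 0.2), proto)
    n1 = add_noise(frame, 20.0, 123)
    n2 = add_noise(frame, 20.0, 123)
    assert np.array_equal(n1.values, n2.values)
    assert not np.array_equal(n1.values, frame.values)
    assert n1.noise_record["snr_db"] == 20.0


def test_noise_snr_calibration_monte_carlo(coarse_mesh):
    """10^4 noisy replicates at 20 dB give empirical SNR within 0.5 dB."""
    proto = default_protocol()
    frame = simulate_frame(coarse_mesh, ConductivityField.homogeneous(coarse_mesh, 0.2), proto)
    signal_power = np.mean(frame.values**2)
    noise_power = np.mean(
        [
            np.mean((add_noise(frame, 20.0, [5, i]).values - frame.values) ** 2)
            for i in range(10_000)
        ]
    )
    snr = 10 * np.log10(signal_power / noise_power)
    assert snr == pytest.approx(20.0, abs=0.5)
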