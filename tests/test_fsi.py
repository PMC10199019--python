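"""Forward FSI: force assembly oracles, modal integration, cycle extraction."""

import numpy as np
import pytest

from vfpinn.contact import ContactParams, contact_pressure
from vfpinn.flow import FlowParams
from vfpinn.fsi import (ForwardFSISimulator, MedialSurface, SimConfig,
                        extract_training_set)
from vfpinn.geometry import face_areas_normals
from vfpinn.solid import solve_eigenmodes


@pytest.fixture(scope="module")
def surface(coarse_mesh, coarse_basis):
    return MedialSurface(coarse_mesh, coarse_basis)


@pytest.fixture(scope="module")
def default_sim(default_mesh):
    """Self-oscillating default configuration, simulated once."""
    from vfpinn.solid import assemble_mass_stiffness
    basis = solve_eigenmodes(assemble_mass_stiffness(default_mesh), 24)
    sim = ForwardFSISimulator(default_mesh, basis,
                              config=SimConfig(duration=0.22))
    return sim, sim.run()


NO_CONTACT = ContactParams(k_c1=0.0, k_c2=0.0)


def uniform_sections(surface, p):
    y = surface.X0_grid[..., 1]
    y_sec = np.linspace(y.min(), y.max(), 100)
    return np.full(100, p), y_sec


def test_uniform_pressure_force_equals_p_times_area(surface):
    p = 750.0
    P, y_sec = uniform_sections(surface, p)
    F = surface.nodal_forces(surface.X0_grid, P, y_sec, FlowParams(), NO_CONTACT)
    total = np.asarray(F).sum(axis=0)
    areas, normals = face_areas_normals(
        surface.X0_grid.reshape(-1, 3), surface.faces_local)
    expected = -(p * areas[:, None] * normals).sum(axis=0)
    np.testing.assert_allclose(total, expected, rtol=1e-5)
    # flat medial surface: the total force is p*A along -x
    np.testing.assert_allclose(total[0], -p * areas.sum(), rtol=1e-5)


def test_zero_pressure_zero_force(surface):
    P, y_sec = uniform_sections(surface, 0.0)
    F = surface.nodal_forces(surface.X0_grid, P, y_sec, FlowParams(), NO_CONTACT)
    np.testing.assert_allclose(np.asarray(F), 0.0, atol=1e-18)


def test_random_pressure_matches_face_loop_oracle(surface, rng):
    """Nodal assembly vs a naive per-triangle one-point-quadrature loop."""
    P = rng.uniform(0.0, 1000.0, size=100)
    y = surface.X0_grid[..., 1]
    y_sec = np.linspace(y.min(), y.max(), 100)
    cp = ContactParams(k_c1=3e6, k_c2=0.0, x_mid=-1e-4)   # some faces penetrate
    F = np.asarray(surface.nodal_forces(surface.X0_grid, P, y_sec,
                                        FlowParams(), cp))
    nodes = surface.X0_grid.reshape(-1, 3)
    oracle = np.zeros_like(nodes)
    for tri in surface.faces_local:
        v = nodes[tri]
        nvec = np.cross(v[1] - v[0], v[2] - v[0])
        area = 0.5 * np.linalg.norm(nvec)
        nhat = nvec / (2 * area)
        cy = v[:, 1].mean()
        p_face = np.interp(cy, y_sec, P)
        f = -p_face * area * nhat
        dx = max(0.0, v[:, 0].mean() - cp.x_mid)
        f = f + np.array([-contact_pressure(dx, cp) * area, 0.0, 0.0])
        for nd in tri:
            oracle[nd] += f / 3.0
    np.testing.assert_allclose(F, oracle, rtol=1e-4, atol=1e-12)


def free_vibration_sim(mesh, basis, b0, duration, dt):
    """No flow (P_sub = 0), no contact: pure modal free vibration."""
    return ForwardFSISimulator(
        mesh, basis, flow_params=FlowParams(P_sub=0.0),
        contact_params=NO_CONTACT,
        config=SimConfig(duration=duration, dt=dt, stride=1, init_b=b0))


def test_single_mode_undamped_cosine(coarse_mesh, coarse_system):
    basis = solve_eigenmodes(coarse_system, 1, alpha=0.0, beta=0.0)
    w = basis.omega[0]
    b0 = np.array([1e-8])                      # small: keeps glottis open
    period = 2 * np.pi / w
    # dt fine enough that the half-step phase offset of the rest-start
    # initialization stays below the 0.5% band
    sim = free_vibration_sim(coarse_mesh, basis, b0, 5 * period, period / 2000)
    res = sim.run()
    expected = b0[0] * np.cos(w * res.times)
    err = np.max(np.abs(res.b[:, 0] - expected)) / b0[0]
    assert err < 5e-3


def test_rayleigh_damped_log_decrement(coarse_mesh, coarse_system):
    alpha, beta = 40.0, 2.0e-5
    basis = solve_eigenmodes(coarse_system, 1, alpha=alpha, beta=beta)
    w = basis.omega[0]
    zeta = (alpha / w + beta * w) / 2.0
    period = 2 * np.pi / w
    sim = free_vibration_sim(coarse_mesh, basis, np.array([1e-8]),
                             8 * period, period / 400)
    res = sim.run()
    from scipy.signal import find_peaks
    pk, _ = find_peaks(res.b[:, 0])
    ratios = res.b[pk[:-1], 0] / res.b[pk[1:], 0]
    zeta_measured = np.log(ratios.mean()) / (2 * np.pi)
    assert zeta_measured == pytest.approx(zeta / np.sqrt(1 - zeta ** 2), rel=0.02)


def test_static_limit_heavy_damping():
    """Overdamped run settles where omega^2 b equals the modal loading.

    Uses a convex-bulge geometry: its rest state carries a nonzero
    Bernoulli load, and the flow-structure system relaxes to a static
    deflection instead of oscillating.
    """
    from vfpinn.geometry import GeometryParams, build_vocal_fold_mesh
    from vfpinn.solid import assemble_mass_stiffness
    mesh = build_vocal_fold_mesh(GeometryParams(nx=4, ny=3, nz=5, bulge=0.5e-3))
    basis = solve_eigenmodes(assemble_mass_stiffness(mesh), 6,
                             alpha=2000.0, beta=0.0)
    sim = ForwardFSISimulator(mesh, basis,
                              config=SimConfig(duration=0.15, init_amplitude=0.0))
    res = sim.run()
    b_end = res.b[-1]
    f_end, *_ = sim._step_forces(b_end)
    resid = basis.omega ** 2 * b_end - f_end
    assert np.linalg.norm(resid) < 0.02 * np.linalg.norm(f_end)


def test_modal_energy_non_increasing_without_driving(coarse_mesh, coarse_system):
    basis = solve_eigenmodes(coarse_system, 6, alpha=20.0, beta=1e-5)
    sim = free_vibration_sim(coarse_mesh, basis,
                             np.full(6, 2e-9), 0.03, 1e-5)
    res = sim.run()
    E = res.modal_energy(basis.omega)
    assert np.all(np.diff(E) <= E[0] * 1e-6)


def test_unstable_configuration_reports_dt_advice(coarse_mesh, coarse_system):
    basis = solve_eigenmodes(coarse_system, 2)
    with pytest.raises(ValueError, match="dt"):
        ForwardFSISimulator(coarse_mesh, basis,
                            config=SimConfig(dt=5e-3))


def test_self_sustained_oscillation_default_config(default_sim):
    """The packaged study conditions must phonate: a steady late cycle whose
    amplitude matches the preceding cycle within 5%."""
    _, res = default_sim
    assert res.cycle is not None
    assert res.cycle["amplitude_change"] < 0.05
    assert 80.0 < res.cycle["frequency_hz"] < 400.0


def test_flow_tissue_consistency_every_step(default_sim):
    sim, res = default_sim
    coeff = np.sqrt(2 * sim.flow_params.P_sub / sim.flow_params.rho_air)
    np.testing.assert_allclose(res.Q, coeff * res.A_min, rtol=1e-12)


def test_extract_profiles_spacing_and_determinism(default_sim):
    sim, res = default_sim
    profiles, truth = extract_training_set(res, sim.surface, n_profiles=20)
    np.testing.assert_allclose(np.diff(profiles.times),
                               truth.period / 20, rtol=1e-9)
    profiles2, truth2 = extract_training_set(res, sim.surface, n_profiles=20)
    np.testing.assert_array_equal(profiles.edges, profiles2.edges)
    np.testing.assert_array_equal(truth.b, truth2.b)
    single, _ = extract_training_set(res, sim.surface, n_profiles=1)
    assert single.n_times == 1
    assert single.times[0] == pytest.approx(res.cycle["t_start"])


def test_no_steady_cycle_raises(coarse_mesh, coarse_basis):
    sim = ForwardFSISimulator(coarse_mesh, coarse_basis,
                              config=SimConfig(duration=0.01))
    res = sim.run()
    if res.cycle is None:
        with pytest.raises(RuntimeError, match="steady cycle"):
            extract_training_set(res, sim.surface)
    else:  # pragma: no cover - extremely short runs should not settle
        pytest.fail("unexpected steady cycle in a 10 ms run")


def test_contact_penalty_monotone(default_mesh):
    """Raising k_c1 tenfold must reduce the cycle-max penetration."""
    from vfpinn.solid import assemble_mass_stiffness
    basis = solve_eigenmodes(assemble_mass_stiffness(default_mesh), 16)
    def max_dx(k):
        sim = ForwardFSISimulator(default_mesh, basis,
                                  contact_params=ContactParams(k_c1=k, k_c2=0.0),
                                  config=SimConfig(duration=0.15))
        res = sim.run()
        surf = sim.surface
        X = surf.deform(res.b[-500:])
        return np.maximum(X[..., 0], 0.0).max()
    assert max_dx(5e6) > max_dx(5e7)


def test_simulation_hdf5_roundtrip(tmp_path, default_sim):
    from vfpinn.fsi import FsiResult
    _, res = default_sim
    path = tmp_path / "sim.h5"
    res.to_hdf5(path)
    back = FsiResult.from_hdf5(path)
    np.testing.assert_array_equal(back.b, res.b)
    np.testing.assert_array_equal(back.Q, res.Q)
    assert back.cycle["frequency_hz"] == pytest.approx(res.cycle["frequency_hz"])
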