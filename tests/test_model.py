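"""Inverse model: losses, differentiability, optimization, recovery."""

import numpy as np
import pytest

from vfpinn import autodiff as ad
from vfpinn.autodiff import Tensor
from vfpinn.fsi import MedialSurface
from vfpinn.model import (GlottalPinn, NetworkConfig, TrainConfig,
                          total_loss)
from vfpinn.projection import ProfileSequence, default_stations, project_top_view
from vfpinn.solid import solve_eigenmodes

TINY_NET = NetworkConfig(hidden_size=16, mlp_depth=2, mlp_width=16)


def make_model(mesh, system, n_modes=4, T=12, n_stations=16, b_true=None,
               seed=3, net=TINY_NET, period=1.0 / 150.0):
    """Model over profiles generated from a prescribed modal trajectory."""
    basis = solve_eigenmodes(system, n_modes)
    surface = MedialSurface(mesh, basis)
    times = period * np.arange(T) / T
    if b_true is None:
        rng = np.random.default_rng(seed)
        amps = 2e-7 * rng.random(n_modes) / (1 + np.arange(n_modes))
        phases = rng.uniform(0, 2 * np.pi, n_modes)
        b_true = amps * np.cos(2 * np.pi * times[:, None] / period + phases)
    X = surface.deform(b_true)
    z = surface.X0_grid[..., 2]
    stations = default_stations(z.min(), z.max(), n_stations)
    profiles = ProfileSequence(times, stations,
                               np.asarray(project_top_view(X, stations)))
    model = GlottalPinn(profiles, basis, surface, net_config=net)
    return model, basis, surface, b_true


# -- contracts ------------------------------------------------------------

def test_network_output_shape_and_determinism(coarse_mesh, coarse_system):
    model, basis, *_ = make_model(coarse_mesh, coarse_system)
    net1 = model._build_network(7)
    net2 = model._build_network(7)
    b1 = ad.asarray(model.network_forward(net1))
    b2 = ad.asarray(model.network_forward(net2))
    assert b1.shape == (12, basis.n_modes)
    np.testing.assert_array_equal(b1, b2)
    b3 = ad.asarray(model.network_forward(model._build_network(8)))
    assert not np.allclose(b1, b3)


def test_all_parameters_receive_gradient_from_total_loss(coarse_mesh,
                                                         coarse_system):
    model, *_ = make_model(coarse_mesh, coarse_system)
    net = model._build_network(0)
    b = model.network_forward(net)
    cfg = TrainConfig()
    L_f = total_loss(model.equation_loss(b, cfg.tau_gap),
                     model.data_loss(b, cfg.tau_proj), cfg)
    L_f.backward()
    for p in net.parameters():
        assert p.grad is not None and np.any(p.grad != 0.0)


def test_nonuniform_times_rejected(coarse_mesh, coarse_system):
    model, basis, surface, b_true = make_model(coarse_mesh, coarse_system)
    bad_times = model.profiles.times.copy()
    bad_times[3] += 1e-4
    bad = ProfileSequence(bad_times, model.profiles.stations,
                          model.profiles.edges)
    with pytest.raises(ValueError, match="uniform"):
        GlottalPinn(bad, basis, surface)


# -- equation loss --------------------------------------------------------

def test_equation_loss_zero_for_rest_state(coarse_mesh, coarse_system):
    """b = 0 on the parallel-channel fold: every section is at the
    separation velocity, so P = 0 everywhere, F = 0, and the residual
    vanishes identically."""
    model, basis, *_ = make_model(coarse_mesh, coarse_system)
    b0 = Tensor(np.zeros((12, basis.n_modes)))
    assert float(ad.asarray(model.equation_loss(b0))) == pytest.approx(0.0, abs=1e-25)


def test_equation_loss_static_equilibrium(coarse_mesh, coarse_system):
    """Constant b_j = f_j / omega_j^2 with constant prescribed loading has
    zero residual to round-off (periodic wrap kills the derivatives)."""
    model, basis, *_ = make_model(coarse_mesh, coarse_system)
    f = np.array([0.3, -1.2, 0.8, 0.05])
    b_static = np.tile(f / basis.omega ** 2, (12, 1))
    L_e = model.equation_loss(Tensor(b_static), loading=f)
    char = float(np.mean(f ** 2))
    assert float(ad.asarray(L_e)) < 1e-20 * char


def test_manufactured_solution_second_order_convergence(coarse_mesh,
                                                        coarse_system):
    """b(t) = a cos(wt): with the analytically derived loading, the
    equation-loss residual is pure finite-difference truncation and its RMS
    must fall one order (ratio ~4) per halving of the sampling interval."""
    basis = solve_eigenmodes(coarse_system, 1)
    surface = MedialSurface(coarse_mesh, basis)
    w_osc = basis.omega[0] * 0.7           # incommensurate with the mode
    period = 2 * np.pi / w_osc
    a = 1e-7
    damp = basis.modal_damping()[0]
    rms = []
    for T in (10, 20, 40):
        times = period * np.arange(T) / T
        b = a * np.cos(w_osc * times)[:, None]
        f = (-a * w_osc ** 2 * np.cos(w_osc * times)
             - damp * a * w_osc * np.sin(w_osc * times)
             + basis.omega[0] ** 2 * a * np.cos(w_osc * times))[:, None]
        stations = default_stations(surface.X0_grid[..., 2].min(),
                                    surface.X0_grid[..., 2].max(), 8)
        profiles = ProfileSequence(times, stations, np.zeros((T, 8)))
        model = GlottalPinn(profiles, basis, surface, net_config=TINY_NET)
        L_e = float(ad.asarray(model.equation_loss(Tensor(b), loading=f)))
        rms.append(np.sqrt(L_e))
    assert rms[0] / rms[1] == pytest.approx(4.0, rel=0.25)
    assert rms[1] / rms[2] == pytest.approx(4.0, rel=0.25)


# -- total loss -----------------------------------------------------------

def test_total_loss_weighted_sum_arithmetic():
    cfg = TrainConfig()                      # W_e = 1e4, W_d = 1e-5
    assert total_loss(0.0, 0.0, cfg) == 0.0
    assert total_loss(2.0, 3.0, cfg) == pytest.approx(20000.00003, abs=1e-9)
    from dataclasses import replace
    c = 7.5
    scaled = replace(cfg, W_e=cfg.W_e * c, W_d=cfg.W_d * c)
    assert total_loss(2.0, 3.0, scaled) == pytest.approx(
        c * total_loss(2.0, 3.0, cfg), rel=1e-14)
    with pytest.raises(ValueError):
        total_loss(-1.0, 0.0, cfg)


# -- end-to-end differentiability ----------------------------------------

def test_total_loss_gradient_matches_fd_on_network_parameter(coarse_mesh,
                                                             coarse_system):
    model, *_ = make_model(coarse_mesh, coarse_system, T=6, n_stations=8)
    cfg = TrainConfig(auto_balance=False, W_e=1.0, W_d=1e6)
    net = model._build_network(0)

    def loss():
        b = model.network_forward(net)
        return total_loss(model.equation_loss(b, cfg.tau_gap),
                          model.data_loss(b, cfg.tau_proj), cfg)

    L = loss()
    L.backward()
    rng = np.random.default_rng(0)
    params = net.parameters()
    for pi in (0, len(params) // 2, len(params) - 1):
        p = params[pi]
        flat_idx = rng.integers(p.size)
        idx = np.unravel_index(flat_idx, p.value.shape)
        g = p.grad[idx]
        eps = 1e-6
        old = p.value[idx]
        p.value[idx] = old + eps
        lp = float(ad.asarray(loss()))
        p.value[idx] = old - eps
        lm = float(ad.asarray(loss()))
        p.value[idx] = old
        fd = (lp - lm) / (2 * eps)
        assert g == pytest.approx(fd, rel=1e-3, abs=1e-10)


# -- training -------------------------------------------------------------

def test_fit_contract_and_bookkeeping(coarse_mesh, coarse_system):
    model, *_ = make_model(coarse_mesh, coarse_system, T=8, n_stations=8)
    fit = model.fit(TrainConfig(auto_balance=True, max_epochs=120, lr=1e-3,
                                seed=0))
    r = fit.report
    # loss bookkeeping invariant at every epoch
    np.testing.assert_allclose(r.L_f, r.W_e * r.L_e + r.W_d * r.L_d,
                               rtol=1e-12)
    # optimizer contract: checkpointed loss no worse than epoch 0
    assert r.L_f[r.best_epoch] <= r.L_f[0]
    # checkpointed coefficients equal a fresh forward pass (no drift)
    np.testing.assert_array_equal(
        fit.b_hat, ad.asarray(model.network_forward(fit.net)))


def test_training_without_data_weight_ignores_data_loss(coarse_mesh,
                                                        coarse_system):
    """W_d = 0 decouples the data term: training may leave L_d anywhere,
    but L_f (= W_e L_e) must still improve."""
    model, *_ = make_model(coarse_mesh, coarse_system, T=8, n_stations=8)
    fit = model.fit(TrainConfig(auto_balance=False, W_e=1.0, W_d=0.0,
                                max_epochs=150, lr=1e-3, seed=0))
    r = fit.report
    assert r.L_f[r.best_epoch] <= r.L_f[0]
    np.testing.assert_allclose(r.L_f, r.W_e * r.L_e, rtol=1e-12)


def test_reconstruction_internally_consistent(coarse_mesh, coarse_system):
    model, basis, *_ = make_model(coarse_mesh, coarse_system, T=8,
                                  n_stations=8)
    fit = model.fit(TrainConfig(auto_balance=True, max_epochs=60, seed=0,
                                lr=1e-3))
    post = fit.reconstruct_and_postprocess()
    coeff = np.sqrt(2 * model.flow_params.P_sub / model.flow_params.rho_air)
    np.testing.assert_allclose(post["Q"], coeff * post["A_min"], rtol=1e-12)
    assert post["displacement"].shape == (8, basis.n_nodes, 3)
    assert "Physics-informed" in fit.summary()
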