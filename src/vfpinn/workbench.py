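"""Evaluation metrics and the end-to-end pipeline harness.

Holds the error measures used to judge a reconstruction against the forward
simulation ground truth (normalized L2 displacement error, relative errors
of aerodynamic scalars, SPL/power deltas), the mode-count sensitivity sweep,
and :func:`run_pipeline`, which chains
geometry → modes → simulate → extract profiles → fit → evaluate
with a single configuration.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .acoustics import AcousticConfig, cycle_acoustics
from .contact import ContactParams
from .flow import FlowParams
from .fsi import (ForwardFSISimulator, GroundTruth, SimConfig,
                  extract_training_set)
from .geometry import GeometryParams, build_vocal_fold_mesh
from .model import GlottalPinn, NetworkConfig, TrainConfig
from .solid import assemble_mass_stiffness, default_materials, solve_eigenmodes

__all__ = ["EvaluationReport", "displacement_error", "scalar_error_suite",
           "evaluate_reconstruction", "mode_sweep", "run_pipeline"]


def displacement_error(U_pred: np.ndarray, U_true: np.ndarray,
                       n_eval: int | None = None):
    """Normalized L2 displacement error per time, in percent.

    e(t) = ||U_pred(t) - U_true(t)||_2 / ||U_true(t)||_2 * 100 on the
    flattened displacement vectors.  If `n_eval` is given, the inputs are
    linearly resampled to that many equispaced points across the cycle
    before the statistics (the protocol uses 16).  Returns
    (per_time, mean, sd); times with zero true norm are excluded with a
    warning.
    """
    Up = np.asarray(U_pred, float).reshape(len(U_pred), -1)
    Ut = np.asarray(U_true, float).reshape(len(U_true), -1)
    if Up.shape != Ut.shape:
        raise ValueError("prediction/truth shapes differ")
    if n_eval is not None and n_eval != len(Up):
        s_old = np.linspace(0.0, 1.0, len(Up), endpoint=False)
        s_new = np.linspace(0.0, 1.0, n_eval, endpoint=False)
        interp = lambda U: np.stack(
            [np.interp(s_new, s_old, U[:, j], period=1.0)
             for j in range(U.shape[1])], axis=1)
        Up, Ut = interp(Up), interp(Ut)
    norms = np.linalg.norm(Ut, axis=1)
    valid = norms > 0
    if not np.all(valid):
        warnings.warn(f"{np.sum(~valid)} times with zero true displacement "
                      "excluded from the error statistics")
    e = np.full(len(Up), np.nan)
    e[valid] = (np.linalg.norm((Up - Ut)[valid], axis=1)
                / norms[valid]) * 100.0
    ev = e[valid]
    return e, float(ev.mean()), float(ev.std())


def _rel_series_error(pred: np.ndarray, true: np.ndarray):
    """Per-time relative error |p - t|/|t| in percent, with mean and SD.

    Times where the true value is (numerically) zero — e.g. the mean
    intraglottal pressure during full closure, when every section sits at
    zero gage pressure — carry no relative-error information and are
    excluded from the statistics.
    """
    pred, true = np.asarray(pred, float), np.asarray(true, float)
    if pred.shape != true.shape:
        raise ValueError("series lengths differ")
    valid = np.abs(true) > 1e-9 * np.abs(true).max()
    if not np.any(valid):
        raise ValueError("reference series is identically zero")
    e = np.full(len(pred), np.nan)
    e[valid] = np.abs(pred - true)[valid] / np.abs(true)[valid] * 100.0
    ev = e[valid]
    return e, float(ev.mean()), float(ev.std())


@dataclass
class EvaluationReport:
    """Reconstruction-vs-truth error summary (percent unless noted)."""

    n_modes: int
    frequency_hz: float
    disp_err_per_time: np.ndarray
    disp_err_mean: float
    disp_err_sd: float
    flow_err_mean: float
    flow_err_sd: float
    pressure_err_mean: float
    pressure_err_sd: float
    peak_flow_err: float          # signed %
    mean_flow_err: float          # signed %
    spl_true_db: float
    spl_pred_db: float
    spl_err_db: float
    spl_err_pct: float
    power_true_w: float
    power_pred_w: float
    power_err_db: float
    power_err_pct: float

    def to_json(self, path=None):
        d = asdict(self)
        d["disp_err_per_time"] = list(map(float, self.disp_err_per_time))
        if path is None:
            return json.dumps(d, indent=2)
        with open(path, "w") as fh:
            json.dump(d, fh, indent=2)

    def summary(self) -> str:
        return (
            f"displacement error  {self.disp_err_mean:.2f} ± {self.disp_err_sd:.2f} %\n"
            f"flow-rate error     {self.flow_err_mean:.2f} ± {self.flow_err_sd:.2f} %\n"
            f"pressure error      {self.pressure_err_mean:.2f} ± {self.pressure_err_sd:.2f} %\n"
            f"peak/mean flow err  {self.peak_flow_err:+.2f} / {self.mean_flow_err:+.2f} %\n"
            f"SPL                 {self.spl_pred_db:.2f} vs {self.spl_true_db:.2f} dB "
            f"({self.spl_err_db:+.2f} dB)\n"
            f"acoustic power      {self.power_err_db:+.2f} dB ({self.power_err_pct:+.2f} %)")


def scalar_error_suite(pred: dict, truth: GroundTruth,
                       acoustic_config: AcousticConfig | None = None) -> dict:
    """Relative errors of the aerodynamic/acoustic scalars.

    `pred` is the dict from
    :meth:`~vfpinn.model.GlottalPinnResults.reconstruct_and_postprocess`.
    """
    acfg = acoustic_config or AcousticConfig()
    _, flow_mean, flow_sd = _rel_series_error(pred["Q"], truth.Q)
    pbar_p = pred["pressures"].mean(axis=1)
    pbar_t = truth.pressures.mean(axis=1)
    _, pr_mean, pr_sd = _rel_series_error(pbar_p, pbar_t)
    peak_err = (pred["Q"].max() - truth.Q.max()) / truth.Q.max() * 100.0
    mean_err = (pred["Q"].mean() - truth.Q.mean()) / truth.Q.mean() * 100.0
    ac_t = cycle_acoustics(truth.Q, truth.period, acfg)
    ac_p = cycle_acoustics(pred["Q"], truth.period, acfg)
    return {
        "flow_err_mean": flow_mean, "flow_err_sd": flow_sd,
        "pressure_err_mean": pr_mean, "pressure_err_sd": pr_sd,
        "peak_flow_err": peak_err, "mean_flow_err": mean_err,
        "spl_true_db": ac_t["spl_db"], "spl_pred_db": ac_p["spl_db"],
        "spl_err_db": ac_p["spl_db"] - ac_t["spl_db"],
        "spl_err_pct": (ac_p["spl_db"] - ac_t["spl_db"]) / abs(ac_t["spl_db"]) * 100.0,
        "power_true_w": ac_t["power_w"], "power_pred_w": ac_p["power_w"],
        "power_err_db": ac_p["power_db"] - ac_t["power_db"],
        "power_err_pct": (ac_p["power_w"] - ac_t["power_w"]) / ac_t["power_w"] * 100.0,
    }


def evaluate_reconstruction(post: dict, truth: GroundTruth, basis,
                            acoustic_config: AcousticConfig | None = None,
                            n_eval: int = 16) -> EvaluationReport:
    """Full error report for a reconstruction against the ground truth.

    Displacement statistics use `n_eval` equispaced points across the cycle
    (default 16, the study protocol).
    """
    U_full = basis.full_modes()
    Up = post["b"] @ U_full.T
    Ut = truth.b @ U_full.T
    per_time, mean, sd = displacement_error(Up, Ut, n_eval=n_eval)
    scalars = scalar_error_suite(post, truth, acoustic_config)
    return EvaluationReport(n_modes=basis.n_modes,
                            frequency_hz=truth.frequency_hz,
                            disp_err_per_time=per_time, disp_err_mean=mean,
                            disp_err_sd=sd, **scalars)


def prepare_ground_truth(geometry: GeometryParams | None = None,
                         materials: dict | None = None,
                         truth_n_modes: int = 100,
                         flow: FlowParams | None = None,
                         contact: ContactParams | None = None,
                         sim: SimConfig | None = None,
                         n_profiles: int = 20, n_stations: int = 64,
                         alpha: float = 60.0, beta: float = 6.0e-5) -> dict:
    """Forward-simulate the study conditions and extract the observables.

    The ground truth is integrated on the `truth_n_modes`-mode basis (the
    "high-fidelity" forward model); inversions then use truncations of the
    same basis, so the mode-count sweep measures genuine truncation error.
    """
    geometry = geometry or GeometryParams()
    mesh = build_vocal_fold_mesh(geometry)
    sysm = assemble_mass_stiffness(mesh, materials or default_materials())
    basis = solve_eigenmodes(sysm, truth_n_modes, alpha=alpha, beta=beta)
    simulator = ForwardFSISimulator(mesh, basis, flow, contact, sim)
    res = simulator.run()
    if res.cycle is None:
        raise RuntimeError("forward simulation reached no steady cycle; "
                           "increase the duration")
    profiles, truth = extract_training_set(res, simulator.surface,
                                           n_profiles=n_profiles,
                                           n_stations=n_stations,
                                           flow_params=simulator.flow_params)
    return {"mesh": mesh, "system": sysm, "basis": basis,
            "simulator": simulator, "simulation": res,
            "profiles": profiles, "truth": truth}


def invert_and_evaluate(state: dict, n_modes: int,
                        network: NetworkConfig | None = None,
                        train: TrainConfig | None = None,
                        acoustic_config: AcousticConfig | None = None,
                        verbose: bool = False) -> dict:
    """Fit the inverse model on `n_modes` (≤ truth fidelity) and evaluate
    against the full-fidelity ground truth."""
    from .fsi import MedialSurface
    basis_n = state["basis"].truncate(n_modes)
    simulator = state["simulator"]
    surface = MedialSurface(state["mesh"], basis_n)
    model = GlottalPinn(state["profiles"], basis_n, surface,
                        simulator.flow_params, simulator.contact_params,
                        network)
    fit = model.fit(train, verbose=verbose)
    post = fit.reconstruct_and_postprocess()
    # compare in the full-fidelity displacement space
    U_full = state["basis"].full_modes()
    Ut = state["truth"].b @ U_full.T
    Up = post["b"] @ basis_n.full_modes().T
    per_time, mean, sd = displacement_error(Up, Ut, n_eval=16)
    scalars = scalar_error_suite(post, state["truth"], acoustic_config)
    report = EvaluationReport(n_modes=n_modes,
                              frequency_hz=state["truth"].frequency_hz,
                              disp_err_per_time=per_time, disp_err_mean=mean,
                              disp_err_sd=sd, **scalars)
    return {"model": model, "fit": fit, "post": post, "report": report}


def run_pipeline(n_modes: int = 30, truth_n_modes: int | None = None,
                 network: NetworkConfig | None = None,
                 train: TrainConfig | None = None,
                 acoustic_config: AcousticConfig | None = None,
                 verbose: bool = False, **truth_kwargs) -> dict:
    """Simulate → extract profiles → fit the inverse model → evaluate.

    Returns a dict with the mesh, bases, simulator output, observed
    profiles, ground truth, fit results and the :class:`EvaluationReport`.
    `truth_n_modes` defaults to `n_modes` (self-consistent study); pass a
    larger value for the truncation-aware protocol.
    """
    state = prepare_ground_truth(truth_n_modes=truth_n_modes or n_modes,
                                 **truth_kwargs)
    out = invert_and_evaluate(state, n_modes, network, train,
                              acoustic_config, verbose)
    state.update(out)
    return state


def mode_sweep(mode_counts, state: dict | None = None,
               truth_kwargs: dict | None = None,
               network: NetworkConfig | None = None,
               train: TrainConfig | None = None,
               verbose: bool = False) -> pd.DataFrame:
    """One inversion per mode count against a shared ground truth.

    Returns a table (n_modes, disp_err_mean, disp_err_sd, flow_err_mean,
    status); failures are recorded per row and the sweep continues.
    """
    if state is None:
        kwargs = dict(truth_kwargs or {})
        kwargs.setdefault("truth_n_modes", max(int(n) for n in mode_counts))
        state = prepare_ground_truth(**kwargs)
    rows = []
    for n in mode_counts:
        try:
            out = invert_and_evaluate(state, int(n), network, train,
                                      verbose=verbose)
            r = out["report"]
            rows.append({"n_modes": int(n), "disp_err_mean": r.disp_err_mean,
                         "disp_err_sd": r.disp_err_sd,
                         "flow_err_mean": r.flow_err_mean, "status": "ok"})
        except Exception as err:  # noqa: BLE001 - sweep must continue
            rows.append({"n_modes": int(n), "disp_err_mean": np.nan,
                         "disp_err_sd": np.nan, "flow_err_mean": np.nan,
                         "status": f"failed: {err}"})
    return pd.DataFrame(rows)
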