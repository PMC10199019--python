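"""Forward flow–structure interaction: the ground-truth generator.

Integrates the decoupled modal oscillators

    b̈_j + (α + β ω_j²) ḃ_j + ω_j² b_j = U_jᵀ F(t)

with the fluid + contact loading re-evaluated from the current reconstructed
shape at every step (explicit coupling, force lagged one step), detects a
steady vibration cycle, and extracts the time-labeled 2D profile sequence
that plays the role of the imaging observable.

The force assembly lives in :class:`MedialSurface` and is written on the
package's dispatchable ops, so the training loss reuses exactly the same
code path with gradients.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np
from scipy.signal import find_peaks

from . import autodiff as ad
from .contact import ContactParams, contact_pressure, penetration_depth
from .flow import FlowParams, flow_rate, min_area, pressure_profile, section_areas
from .geometry import TetMesh
from .ops import cross3, triangular_interp
from .projection import ProfileSequence, default_stations, project_top_view
from .solid import ModalBasis

__all__ = ["SimConfig", "MedialSurface", "ForwardFSISimulator", "FsiResult",
           "assemble_nodal_forces", "integrate", "extract_training_set"]


class MedialSurface:
    """Structured medial-surface view of the mesh with everything the
    differentiable physics needs: grid node positions, local face topology,
    lumping matrix and the modal shapes restricted to the surface."""

    def __init__(self, mesh: TetMesh, basis: ModalBasis | None = None):
        if mesh.medial_grid is None:
            raise ValueError("mesh lacks a structured medial grid")
        self.grid_ids = mesh.medial_grid                   # (R, C)
        self.R, self.C = self.grid_ids.shape
        flat = self.grid_ids.ravel()
        local = {g: i for i, g in enumerate(flat)}
        faces = mesh.medial_faces
        if not np.all(np.isin(faces, flat)):
            raise ValueError("medial faces reference nodes outside the grid")
        self.faces_local = np.vectorize(local.__getitem__)(faces)   # (F, 3)
        self.X0_grid = mesh.nodes[flat].reshape(self.R, self.C, 3)
        n_local = self.R * self.C
        L = np.zeros((n_local, len(faces)))
        for f, tri in enumerate(self.faces_local):
            L[tri, f] = 1.0 / 3.0                          # one-point lumping
        self.lump = L
        if basis is not None:
            self.U_grid = basis.modes_at(flat)             # (3*R*C, n_modes)
        else:
            self.U_grid = None

    def deform(self, b):
        """Grid positions X0 + U b for coefficients b of shape (..., n_modes)."""
        disp = ad.matmul(b, self.U_grid.T)                 # (..., 3*R*C)
        shape = ad.asarray(disp).shape[:-1] + (self.R, self.C, 3)
        return self.X0_grid + disp.reshape(shape)

    def nodal_forces(self, X_grid, pressures, y_sections,
                     flow_params: FlowParams, contact_params: ContactParams,
                     tau: float = 0.0):
        """Aerodynamic + contact loading lumped to grid nodes.

        Per medial face: intraglottal pressure interpolated to the face
        centroid's section acts along the inward (-outward-normal) direction
        over the current face area; penalty contact pressure acts along -x.
        Returns (..., R*C, 3) node forces.
        """
        Xf = X_grid.reshape(ad.asarray(X_grid).shape[:-3] + (self.R * self.C, 3))
        tri = Xf[..., self.faces_local, :]                 # (..., F, 3, 3)
        v0 = tri[..., 0, :]
        e1 = tri[..., 1, :] - v0
        e2 = tri[..., 2, :] - v0
        nvec = cross3(e1, e2)                              # outward, |n| = 2A
        area2 = ad.sqrt(ad.square(nvec).sum(axis=-1))      # (..., F)
        centroid = (tri[..., 0, :] + tri[..., 1, :] + tri[..., 2, :]) / 3.0

        # pressure at the centroid's section (hat interpolation between sections)
        S = ad.asarray(y_sections).shape[-1]
        extent = y_sections[..., S - 1] - y_sections[..., 0]
        h = extent / (S - 1)
        p_face = triangular_interp(y_sections, pressures, centroid[..., 1],
                                   ad.expand_dims(h, -1))
        f_aero = ad.expand_dims(p_face * (-0.5), -1) * nvec   # -p * A * n_hat

        dx = penetration_depth(centroid[..., 0], contact_params, tau)
        p_c = contact_pressure(dx, contact_params)
        fc_x = -p_c * 0.5 * area2                          # along -x
        zeros = 0.0 * fc_x
        f_contact = ad.stack([fc_x, zeros, zeros], axis=-1)

        face_force = f_aero + f_contact                    # (..., F, 3)
        return ad.matmul(self.lump, face_force)            # (..., R*C, 3)

    def modal_forces(self, node_forces):
        """Generalized forces f_j = U_jᵀ F from grid node forces."""
        flat = node_forces.reshape(ad.asarray(node_forces).shape[:-2]
                                   + (3 * self.R * self.C,))
        return ad.matmul(flat, self.U_grid)


def assemble_nodal_forces(surface: MedialSurface, X_grid, pressures, y_sections,
                          flow_params: FlowParams, contact_params: ContactParams,
                          tau: float = 0.0):
    """Functional wrapper around :meth:`MedialSurface.nodal_forces`."""
    return surface.nodal_forces(X_grid, pressures, y_sections,
                                flow_params, contact_params, tau)


@dataclass
class SimConfig:
    """Forward-simulation controls.

    dt = 1e-5 s resolves the retained modes of a kPa-range model with margin;
    200 ms covers a few dozen cycles at ~150 Hz so a steady cycle exists.
    """

    dt: float = 1.0e-5
    duration: float = 0.200
    stride: int = 4                 # store every stride-th step
    seed: int = 0
    init_amplitude: float = 1.0e-7  # random modal perturbation scale
                                    # (modal coordinates are kg^0.5·m: 1e-7
                                    # gives ~0.1 mm surface displacement)
    init_b: object = None           # explicit initial modal coefficients
                                    # (overrides the random perturbation)

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.stride < 1:
            raise ValueError("stride must be >= 1")


@dataclass
class FsiResult:
    """Stored forward-simulation time series (at the output stride)."""

    times: np.ndarray               # (T,)
    b: np.ndarray                   # (T, n_modes)
    bdot: np.ndarray                # (T, n_modes)
    Q: np.ndarray                   # (T,)
    A_min: np.ndarray               # (T,)
    pressures: np.ndarray           # (T, S)
    y_sections: np.ndarray          # (T, S)
    config: SimConfig = None
    cycle: dict | None = None       # steady-cycle info (filled on detection)

    def modal_energy(self, omega: np.ndarray) -> np.ndarray:
        """Σ_j (ḃ_j² + ω_j² b_j²)/2 per stored step."""
        return 0.5 * ((self.bdot ** 2).sum(axis=1)
                      + (self.b ** 2 * omega ** 2).sum(axis=1))

    def plot_cycle(self, ax=None):
        """Flow rate and minimum area over the simulation (cycle shaded)."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots(figsize=(7, 3))
        ax.plot(self.times * 1e3, self.Q * 1e3, label="Q (L/s)")
        ax2 = ax.twinx()
        ax2.plot(self.times * 1e3, self.A_min * 1e6, color="tab:orange",
                 alpha=0.6, label="A_min (mm²)")
        if self.cycle is not None:
            ax.axvspan(self.cycle["t_start"] * 1e3, self.cycle["t_end"] * 1e3,
                       color="0.9")
        ax.set_xlabel("time (ms)")
        ax.set_ylabel("glottal flow rate (L/s)")
        ax2.set_ylabel("minimum glottal area (mm²)")
        return ax

    def to_hdf5(self, path):
        with h5py.File(path, "w") as fh:
            for name in ("times", "b", "bdot", "Q", "A_min", "pressures",
                         "y_sections"):
                fh[name] = getattr(self, name)
            if self.cycle is not None:
                for k, v in self.cycle.items():
                    fh.attrs[f"cycle_{k}"] = v

    @classmethod
    def from_hdf5(cls, path) -> "FsiResult":
        with h5py.File(path, "r") as fh:
            data = {name: fh[name][...] for name in
                    ("times", "b", "bdot", "Q", "A_min", "pressures",
                     "y_sections")}
            cycle = {k[len("cycle_"):]: fh.attrs[k] for k in fh.attrs
                     if k.startswith("cycle_")}
        return cls(config=None, cycle=cycle or None, **data)


class ForwardFSISimulator:
    """Explicit central-difference integration of the modal FSI system."""

    def __init__(self, mesh: TetMesh, basis: ModalBasis,
                 flow_params: FlowParams | None = None,
                 contact_params: ContactParams | None = None,
                 config: SimConfig | None = None):
        self.mesh = mesh
        self.basis = basis
        self.flow_params = flow_params or FlowParams()
        self.contact_params = contact_params or ContactParams()
        self.config = config or SimConfig()
        self.surface = MedialSurface(mesh, basis)
        w_max = basis.omega.max()
        if w_max > 0 and self.config.dt > 0.1 * 2.0 * np.pi / w_max:
            raise ValueError(
                f"dt={self.config.dt:g} too coarse for the highest retained "
                f"mode (need <= {0.1 * 2 * np.pi / w_max:.2e} s)")

    def _step_forces(self, b):
        X = self.surface.deform(b)
        y_sec, A = section_areas(X, self.flow_params)
        Am = min_area(A, self.flow_params)
        Q = flow_rate(Am, self.flow_params)
        P, _ = pressure_profile(A, Q, self.flow_params)
        Fn = self.surface.nodal_forces(X, P, y_sec, self.flow_params,
                                       self.contact_params)
        return self.surface.modal_forces(Fn), float(Q), float(Am), P, y_sec

    def run(self) -> FsiResult:
        cfg = self.config
        nm = self.basis.n_modes
        omega2 = self.basis.omega ** 2
        damp = self.basis.modal_damping()
        dt = cfg.dt
        n_steps = int(round(cfg.duration / dt))
        if cfg.init_b is not None:
            b_prev = np.asarray(cfg.init_b, float).copy()
            if b_prev.shape != (nm,):
                raise ValueError("init_b length must equal n_modes")
        else:
            rng = np.random.default_rng(cfg.seed)
            b_prev = rng.normal(scale=cfg.init_amplitude, size=nm)
        b_cur = b_prev.copy()                      # start at rest velocity

        c0 = 1.0 / dt ** 2 + damp / (2.0 * dt)
        c1 = 2.0 / dt ** 2 - omega2
        c2 = 1.0 / dt ** 2 - damp / (2.0 * dt)

        times, bs, bdots, Qs, Ams, Ps, Ys = [], [], [], [], [], [], []
        for n in range(n_steps):
            f, Q, Am, P, y_sec = self._step_forces(b_cur)
            b_next = (f + c1 * b_cur - c2 * b_prev) / c0
            if not np.all(np.isfinite(b_next)) or np.abs(b_next).max() > 1.0:
                raise RuntimeError(
                    f"integration diverged at step {n} (t={n * dt:.4f}s); "
                    "reduce dt or check material/flow parameters")
            if n % cfg.stride == 0:
                times.append(n * dt)
                bs.append(b_cur.copy())
                bdots.append((b_next - b_prev) / (2.0 * dt))
                Qs.append(Q)
                Ams.append(Am)
                Ps.append(np.asarray(P))
                Ys.append(np.asarray(y_sec))
            b_prev, b_cur = b_cur, b_next

        res = FsiResult(times=np.asarray(times), b=np.asarray(bs),
                        bdot=np.asarray(bdots), Q=np.asarray(Qs),
                        A_min=np.asarray(Ams), pressures=np.asarray(Ps),
                        y_sections=np.asarray(Ys), config=cfg)
        res.cycle = detect_steady_cycle(res)
        return res


def integrate(basis: ModalBasis, mesh: TetMesh,
              flow_params: FlowParams | None = None,
              contact_params: ContactParams | None = None,
              config: SimConfig | None = None) -> FsiResult:
    """Functional entry point mirroring :meth:`ForwardFSISimulator.run`."""
    return ForwardFSISimulator(mesh, basis, flow_params, contact_params,
                               config).run()


def detect_steady_cycle(res: FsiResult, rel_tol: float = 0.02) -> dict | None:
    """Find a late steady vibration cycle of A_min(t).

    Returns dict(t_start, t_end, period, frequency_hz, amplitude_change)
    for the last complete cycle whose peak-to-peak amplitude differs from
    the preceding cycle by less than `rel_tol`, or None.
    """
    sig = res.A_min
    if len(sig) < 16:
        return None
    prom = 0.05 * max(sig.max() - sig.min(), 1e-30)
    peaks, _ = find_peaks(sig, prominence=prom)
    if len(peaks) < 3:
        return None
    p2, p1, p0 = peaks[-3], peaks[-2], peaks[-1]
    amp_last = sig[p1:p0 + 1].max() - sig[p1:p0 + 1].min()
    amp_prev = sig[p2:p1 + 1].max() - sig[p2:p1 + 1].min()
    if amp_prev <= 0:
        return None
    change = abs(amp_last - amp_prev) / amp_prev
    if change > rel_tol:
        return None
    period = res.times[p0] - res.times[p1]
    return {"t_start": float(res.times[p1]), "t_end": float(res.times[p0]),
            "period": float(period), "frequency_hz": float(1.0 / period),
            "amplitude_change": float(change)}


@dataclass
class GroundTruth:
    """Full-field snapshots over one cycle, kept for evaluation only."""

    times: np.ndarray
    b: np.ndarray                    # (T, n_modes)
    Q: np.ndarray
    A_min: np.ndarray
    pressures: np.ndarray            # (T, S)
    y_sections: np.ndarray
    period: float
    frequency_hz: float


def extract_training_set(res: FsiResult, surface: MedialSurface,
                         n_profiles: int = 20, n_stations: int = 64,
                         flow_params: FlowParams | None = None):
    """Sample `n_profiles` equispaced time-labeled profiles over one steady
    cycle; returns (ProfileSequence, GroundTruth).

    Sample k sits at ``t_start + k * period / n_profiles`` — for 20 profiles
    of a 143 Hz cycle that is the 1/(143·20) s spacing of the study protocol.
    Modal coefficients are interpolated linearly between stored steps; flow
    quantities are re-evaluated exactly at the sample shapes so the bundle is
    self-consistent (Q = sqrt(2 P_sub / rho) A_min holds identically).
    """
    if res.cycle is None:
        raise RuntimeError("no steady cycle detected; simulate longer")
    flow_params = flow_params or FlowParams()
    t0, period = res.cycle["t_start"], res.cycle["period"]
    t_samples = t0 + period * np.arange(n_profiles) / n_profiles
    b = np.stack([np.interp(t_samples, res.times, res.b[:, j])
                  for j in range(res.b.shape[1])], axis=1)
    X = surface.deform(b)                                   # (T, R, C, 3)
    z = surface.X0_grid[..., 2]
    stations = default_stations(z.min(), z.max(), n_stations)
    edges = project_top_view(X, stations)
    profiles = ProfileSequence(t_samples, stations, np.asarray(edges))

    y_sec, A = section_areas(np.asarray(X), flow_params)
    Am = np.asarray(min_area(A, flow_params))
    Q = np.asarray(flow_rate(Am, flow_params))
    P, _ = pressure_profile(A, Q, flow_params)
    truth = GroundTruth(times=t_samples, b=b, Q=Q, A_min=Am,
                        pressures=np.asarray(P), y_sections=np.asarray(y_sec),
                        period=period, frequency_hz=res.cycle["frequency_hz"])
    return profiles, truth
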