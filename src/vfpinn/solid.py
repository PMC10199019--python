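"""Linear elasticity on tet4 meshes and its modal (eigenmode) reduction.

The tissue obeys the damped equation of motion
``M ü + C u̇ + K u = F(t)`` with Rayleigh damping ``C = α M + β K``.
Expanding the displacement in mass-orthonormal eigenmodes ``u = Σ_j b_j U_j``
decouples the system into scalar oscillators

    b̈_j + (α + β ω_j²) ḃ_j + ω_j² b_j = U_jᵀ F(t),

which is the reduced search space both the forward simulator and the inverse
network operate in.  This module assembles the consistent-mass FEM matrices
for a two-layer transversely isotropic material, eliminates the Dirichlet
(attachment) DOFs, solves the generalized eigenproblem in shift-invert mode,
and provides projection/reconstruction between nodal and modal coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass

import h5py
import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import eigsh

from .geometry import TetMesh, LAYER_COVER

__all__ = ["Material", "SystemMatrices", "ModalBasis",
           "assemble_mass_stiffness", "solve_eigenmodes",
           "modal_project_force", "reconstruct_displacement",
           "default_materials"]


@dataclass
class Material:
    """Transversely isotropic elastic solid; fiber (longitudinal) axis = z.

    Units: moduli in Pa, density in kg/m³.  The isotropic case is recovered
    with ``E_l = E_t`` and ``G_l = E_t / (2 (1 + nu_t))``.
    """

    density: float
    E_t: float           # transverse (cross-fiber) Young's modulus
    E_l: float           # longitudinal (along-fiber) Young's modulus
    nu_t: float          # in-plane Poisson ratio
    nu_lt: float         # longitudinal Poisson ratio (loading along fiber)
    G_l: float           # longitudinal shear modulus

    @classmethod
    def isotropic(cls, density, E, nu) -> "Material":
        return cls(density=density, E_t=E, E_l=E, nu_t=nu, nu_lt=nu,
                   G_l=E / (2.0 * (1.0 + nu)))

    def stiffness_voigt(self) -> np.ndarray:
        """6x6 elasticity tensor (Voigt order xx, yy, zz, yz, xz, xy)."""
        S = np.zeros((6, 6))
        S[0, 0] = S[1, 1] = 1.0 / self.E_t
        S[2, 2] = 1.0 / self.E_l
        S[0, 1] = S[1, 0] = -self.nu_t / self.E_t
        S[0, 2] = S[2, 0] = S[1, 2] = S[2, 1] = -self.nu_lt / self.E_l
        S[3, 3] = S[4, 4] = 1.0 / self.G_l
        S[5, 5] = 2.0 * (1.0 + self.nu_t) / self.E_t
        D = np.linalg.inv(S)
        if np.any(np.linalg.eigvalsh(0.5 * (D + D.T)) <= 0):
            raise ValueError("elasticity tensor is not positive definite")
        return 0.5 * (D + D.T)


def default_materials() -> dict:
    """Two-layer defaults: soft cover over a stiffer body, fibers along z.

    Moduli sit in the low-kPa range reported for vocal-fold tissue, with the
    longitudinal (anterior–posterior) stiffening typical of the fibrous
    structure; density and near-incompressible Poisson ratios are those of
    soft tissue.  Together with the default geometry these constants put the
    flow-induced oscillation near 160 Hz at 1 kPa subglottal pressure.
    """
    return {
        "cover": Material(density=1040.0, E_t=1.2e3, E_l=12.0e3,
                          nu_t=0.45, nu_lt=0.45, G_l=4.8e3),
        "body": Material(density=1040.0, E_t=2.4e3, E_l=24.0e3,
                         nu_t=0.45, nu_lt=0.45, G_l=9.6e3),
    }


@dataclass
class SystemMatrices:
    """Sparse symmetric FEM matrices, full and Dirichlet-reduced."""

    M: sp.csr_matrix            # on free DOFs
    K: sp.csr_matrix
    M_full: sp.csr_matrix       # pre-constraint (all DOFs), for diagnostics
    K_full: sp.csr_matrix
    free_dofs: np.ndarray
    n_nodes: int


def _element_bmats(nodes, tets):
    """Shape-function gradients and volumes for all tets (vectorized)."""
    p = nodes[tets]                                  # (m, 4, 3)
    Dm = (p[:, 1:] - p[:, :1]).transpose(0, 2, 1)    # columns x_i - x_0
    vol = np.linalg.det(Dm) / 6.0
    if np.any(vol <= 0):
        raise ValueError("inverted element encountered during assembly")
    DmInvT = np.linalg.inv(Dm).transpose(0, 2, 1)    # (m, 3, 3)
    grads = np.zeros((len(tets), 4, 3))
    grads[:, 1:] = DmInvT.transpose(0, 2, 1)         # ∇N_i = Dm^{-T} e_i
    grads[:, 0] = -grads[:, 1:].sum(axis=1)
    return grads, vol


def element_stiffness(nodes, tet, D) -> np.ndarray:
    """Single-element Ke = V Bᵀ D B (12x12); exposed for oracle tests."""
    grads, vol = _element_bmats(nodes, np.asarray([tet]))
    B = _b_matrix(grads[0])
    return vol[0] * B.T @ D @ B


def _b_matrix(grad) -> np.ndarray:
    """6x12 strain-displacement matrix from the 4x3 gradient table."""
    B = np.zeros((6, 12))
    for a in range(4):
        gx, gy, gz = grad[a]
        c = 3 * a
        B[0, c] = gx
        B[1, c + 1] = gy
        B[2, c + 2] = gz
        B[3, c + 1] = gz
        B[3, c + 2] = gy
        B[4, c] = gz
        B[4, c + 2] = gx
        B[5, c] = gy
        B[5, c + 1] = gx
    return B


def assemble_mass_stiffness(mesh: TetMesh, materials: dict | None = None) -> SystemMatrices:
    """Consistent-mass tet4 assembly with per-layer materials.

    `materials` maps layer names ("cover", "body") to :class:`Material`.
    Dirichlet DOFs (``mesh.fixed_nodes``) are removed by row/column
    elimination; both the reduced and the pre-constraint matrices are kept.
    """
    materials = materials or default_materials()
    D_by_layer = {LAYER_COVER: materials["cover"].stiffness_voigt()}
    D_by_layer[0] = materials["body"].stiffness_voigt()
    rho = {LAYER_COVER: materials["cover"].density, 0: materials["body"].density}

    grads, vol = _element_bmats(mesh.nodes, mesh.tets)
    m = mesh.n_tets
    Ke = np.zeros((m, 12, 12))
    Me = np.zeros((m, 12, 12))
    mass_bar = (np.ones((4, 4)) + np.eye(4)) / 20.0
    for lab in np.unique(mesh.layer):
        sel = mesh.layer == lab
        D = D_by_layer[int(lab)]
        B = np.zeros((sel.sum(), 6, 12))
        g = grads[sel]
        for a in range(4):
            c = 3 * a
            B[:, 0, c] = g[:, a, 0]
            B[:, 1, c + 1] = g[:, a, 1]
            B[:, 2, c + 2] = g[:, a, 2]
            B[:, 3, c + 1] = g[:, a, 2]
            B[:, 3, c + 2] = g[:, a, 1]
            B[:, 4, c] = g[:, a, 2]
            B[:, 4, c + 2] = g[:, a, 0]
            B[:, 5, c] = g[:, a, 1]
            B[:, 5, c + 1] = g[:, a, 0]
        Ke[sel] = vol[sel, None, None] * np.einsum("eji,jk,ekl->eil", B, D, B)
        Me[sel] = (rho[int(lab)] * vol[sel])[:, None, None] * np.kron(mass_bar, np.eye(3))

    dofs = (3 * mesh.tets[:, :, None] + np.arange(3)).reshape(m, 12)
    rows = np.repeat(dofs, 12, axis=1).ravel()
    cols = np.tile(dofs, (1, 12)).ravel()
    n_dof = 3 * mesh.n_nodes
    K_full = sp.coo_matrix((Ke.ravel(), (rows, cols)), shape=(n_dof, n_dof)).tocsr()
    M_full = sp.coo_matrix((Me.ravel(), (rows, cols)), shape=(n_dof, n_dof)).tocsr()
    K_full = 0.5 * (K_full + K_full.T)
    M_full = 0.5 * (M_full + M_full.T)

    fixed_dofs = (3 * mesh.fixed_nodes[:, None] + np.arange(3)).ravel()
    free = np.setdiff1d(np.arange(n_dof), fixed_dofs)
    K = K_full[np.ix_(free, free)].tocsr()
    M = M_full[np.ix_(free, free)].tocsr()
    return SystemMatrices(M=M, K=K, M_full=M_full, K_full=K_full,
                          free_dofs=free, n_nodes=mesh.n_nodes)


@dataclass
class ModalBasis:
    """Mass-orthonormal eigenmodes of the constrained system.

    ``modes`` lives on free DOFs (n_free, n_modes); ``omega`` are the
    eigenfrequencies in rad/s, ascending.  Rayleigh parameters give each mode
    the damping coefficient ``alpha + beta * omega_j**2``.
    """

    modes: np.ndarray
    omega: np.ndarray
    free_dofs: np.ndarray
    n_nodes: int
    alpha: float = 60.0
    beta: float = 6.0e-5

    @property
    def n_modes(self):
        return self.modes.shape[1]

    @property
    def frequencies_hz(self):
        return self.omega / (2.0 * np.pi)

    def modal_damping(self) -> np.ndarray:
        return self.alpha + self.beta * self.omega ** 2

    def truncate(self, n_modes: int) -> "ModalBasis":
        """Sub-basis of the lowest `n_modes` modes (shares storage)."""
        if not (0 < n_modes <= self.n_modes):
            raise ValueError(f"n_modes must be in (0, {self.n_modes}]")
        return ModalBasis(modes=self.modes[:, :n_modes],
                          omega=self.omega[:n_modes],
                          free_dofs=self.free_dofs, n_nodes=self.n_nodes,
                          alpha=self.alpha, beta=self.beta)

    def full_modes(self) -> np.ndarray:
        """(3*n_nodes, n_modes) nodal mode shapes, zeros on fixed DOFs."""
        out = np.zeros((3 * self.n_nodes, self.n_modes))
        out[self.free_dofs] = self.modes
        return out

    def modes_at(self, node_ids: np.ndarray) -> np.ndarray:
        """(len(node_ids)*3, n_modes) slice of the full mode shapes."""
        dofs = (3 * np.asarray(node_ids)[:, None] + np.arange(3)).ravel()
        return self.full_modes()[dofs]

    def to_hdf5(self, path):
        with h5py.File(path, "w") as fh:
            fh["modes"] = self.modes
            fh["omega"] = self.omega
            fh["free_dofs"] = self.free_dofs
            fh.attrs["n_nodes"] = self.n_nodes
            fh.attrs["alpha"] = self.alpha
            fh.attrs["beta"] = self.beta

    @classmethod
    def from_hdf5(cls, path) -> "ModalBasis":
        with h5py.File(path, "r") as fh:
            return cls(modes=fh["modes"][...], omega=fh["omega"][...],
                       free_dofs=fh["free_dofs"][...],
                       n_nodes=int(fh.attrs["n_nodes"]),
                       alpha=float(fh.attrs["alpha"]),
                       beta=float(fh.attrs["beta"]))


def solve_eigenmodes(sys: SystemMatrices, n_modes: int,
                     alpha: float = 60.0, beta: float = 6.0e-5) -> ModalBasis:
    """Lowest `n_modes` of K U = ω² M U by shift-invert Lanczos at σ = 0.

    Modes are mass-orthonormalized and sign-fixed (largest-magnitude entry
    positive) so repeated runs agree bit-for-bit.
    """
    n_free = sys.K.shape[0]
    if not (0 < n_modes < n_free):
        raise ValueError(f"n_modes must be in (0, {n_free})")
    try:
        lam, vec = eigsh(sys.K, k=n_modes, M=sys.M, sigma=0.0, which="LM")
    except Exception as err:  # pragma: no cover - solver failure path
        raise RuntimeError(f"eigenmode solver failed: {err}") from err
    order = np.argsort(lam)
    lam, vec = lam[order], vec[:, order]
    omega = np.sqrt(np.clip(lam, 0.0, None))
    # enforce exact mass-orthonormality + deterministic sign
    norms = np.sqrt(np.einsum("ij,ij->j", vec, sys.M @ vec))
    vec = vec / norms
    idx = np.argmax(np.abs(vec), axis=0)
    sign = np.sign(vec[idx, np.arange(vec.shape[1])])
    vec = vec * sign
    return ModalBasis(modes=vec, omega=omega, free_dofs=sys.free_dofs,
                      n_nodes=sys.n_nodes, alpha=alpha, beta=beta)


def modal_project_force(basis: ModalBasis, F: np.ndarray) -> np.ndarray:
    """Per-mode generalized forces f_j = U_jᵀ F, with F on free DOFs."""
    F = np.asarray(F, dtype=float)
    if F.shape[-1] != basis.modes.shape[0]:
        raise ValueError(f"force vector has {F.shape[-1]} entries, "
                         f"expected {basis.modes.shape[0]} free DOFs")
    return F @ basis.modes


def reconstruct_displacement(basis: ModalBasis, b: np.ndarray,
                             X0: np.ndarray) -> np.ndarray:
    """Deformed nodal coordinates X = X0 + Σ_j b_j U_j.

    `b` may be (n_modes,) or (T, n_modes); output matches with node layout
    (..., n_nodes, 3).
    """
    b = np.asarray(b, dtype=float)
    if b.shape[-1] != basis.n_modes:
        raise ValueError("coefficient vector length != n_modes")
    disp = b @ self_modes_T(basis)
    return np.asarray(X0).reshape(-1, 3) + disp.reshape(b.shape[:-1] + (basis.n_nodes, 3))


def self_modes_T(basis: ModalBasis) -> np.ndarray:
    return basis.full_modes().T
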