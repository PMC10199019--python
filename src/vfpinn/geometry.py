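"""Parameterized two-layer vocal-fold solid and its tetrahedral mesh.

The geometry is a generic extruded cross-section: a wedge-like block whose
medial face carries a convex bulge toward the glottal midline.  Coordinate
convention (used throughout the package):

* ``x`` — medial–lateral; the midline symmetry plane is ``x = 0`` and the
  tissue occupies ``x < 0``.  Only the left fold is modeled; the right fold
  is its mirror image.
* ``y`` — inferior → superior (the airflow direction).
* ``z`` — anterior → posterior (the longitudinal/fiber direction).

A structured hexahedral grid is mapped onto the shape and every hex is split
into six tetrahedra with a fixed template (all cells share the same main
diagonal direction, which keeps the triangulation conforming and the mesh
bit-reproducible).  Tets are labeled cover/body by their parametric distance
from the medial surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

__all__ = ["GeometryParams", "TetMesh", "build_vocal_fold_mesh",
           "mesh_quality_report", "tet_volumes", "write_vtk", "read_vtk"]

LAYER_BODY = 0
LAYER_COVER = 1

# six tets around the 0-6 diagonal of a hex with vertices
# 0:(0,0,0) 1:(1,0,0) 2:(1,1,0) 3:(0,1,0) 4:(0,0,1) 5:(1,0,1) 6:(1,1,1) 7:(0,1,1)
_HEX_TO_TETS = np.array([
    [0, 1, 2, 6],
    [0, 2, 3, 6],
    [0, 3, 7, 6],
    [0, 7, 4, 6],
    [0, 4, 5, 6],
    [0, 5, 1, 6],
])


@dataclass
class GeometryParams:
    """Dimensions of the synthetic fold (meters).

    Defaults are in the physiological size range of a mid-size mammalian
    larynx: 10 mm anterior–posterior span, 8 mm lateral depth, a vertical
    thickness tapering from 8 mm at the lateral attachment to 3 mm at the
    medial edge, and a 0.2 mm rest half-gap to the midline.  ``bulge``
    controls the convexity of the medial gap profile; the default 0 keeps
    the rest channel parallel, which lets the minimum-area section travel
    with the mucosal wave — the mechanism that sustains flow-induced
    oscillation at a 1 kPa driving pressure.
    """

    span: float = 10.0e-3              # z extent (anterior-posterior)
    depth: float = 8.0e-3              # x extent (medial-lateral)
    thickness_lateral: float = 8.0e-3  # y extent at the lateral wall
    thickness_medial: float = 3.0e-3   # y extent at the medial surface
    rest_half_gap: float = 0.2e-3      # midline clearance g0 at the bulge apex
    bulge: float = 0.0                 # extra gap at inferior/superior margins
    cover_thickness: float = 1.5e-3    # cover-layer depth from medial surface
    nx: int = 8                        # elements: lateral->medial
    ny: int = 6                        # elements: inferior->superior
    nz: int = 10                       # elements: anterior->posterior

    def validate(self):
        lengths = dict(span=self.span, depth=self.depth,
                       thickness_lateral=self.thickness_lateral,
                       thickness_medial=self.thickness_medial)
        for name, val in lengths.items():
            if val <= 0:
                raise ValueError(f"GeometryParams.{name} must be positive, got {val}")
        if self.rest_half_gap < 0:
            raise ValueError("rest_half_gap must be >= 0")
        if self.bulge < 0:
            raise ValueError("bulge must be >= 0")
        if not (0 <= self.cover_thickness < self.depth):
            raise ValueError("cover_thickness must lie in [0, depth)")
        if min(self.nx, self.ny, self.nz) < 1:
            raise ValueError("grid resolution must be >= 1 in each direction")
        if self.depth <= self.rest_half_gap + self.bulge:
            raise ValueError("depth must exceed rest_half_gap + bulge")

    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh)

    @classmethod
    def from_yaml(cls, path) -> "GeometryParams":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


@dataclass
class TetMesh:
    """Tetrahedral mesh with layer labels and tagged boundary sets."""

    nodes: np.ndarray                 # (n_nodes, 3) float
    tets: np.ndarray                  # (n_tets, 4) int
    layer: np.ndarray                 # (n_tets,) int, LAYER_BODY | LAYER_COVER
    fixed_nodes: np.ndarray           # lateral + anterior + posterior attachment
    medial_faces: np.ndarray          # (n_faces, 3) outward-oriented triangles
    inferior_nodes: np.ndarray
    superior_nodes: np.ndarray
    medial_grid: np.ndarray | None = None   # (ny+1, nz+1) node ids, row = const y
    params: GeometryParams | None = None

    @property
    def n_nodes(self):
        return len(self.nodes)

    @property
    def n_tets(self):
        return len(self.tets)

    @property
    def medial_nodes(self) -> np.ndarray:
        """Medial-surface nodes excluding fixed (attachment) nodes."""
        surf = np.unique(self.medial_faces)
        return np.setdiff1d(surf, self.fixed_nodes)

    def validate(self):
        vols = tet_volumes(self)
        if np.any(vols <= 0):
            raise ValueError(f"{int(np.sum(vols <= 0))} non-positive tet volumes")
        if np.intersect1d(self.medial_nodes, self.fixed_nodes).size:
            raise ValueError("medial node set overlaps fixed nodes")
        return self


def tet_volumes(mesh: TetMesh) -> np.ndarray:
    """Signed volumes det([b-a, c-a, d-a])/6 per tet."""
    p = mesh.nodes[mesh.tets]
    e = p[:, 1:] - p[:, :1]
    return np.linalg.det(e) / 6.0


def build_vocal_fold_mesh(params: GeometryParams | None = None) -> TetMesh:
    """Mesh the parameterized fold on a structured grid.

    The unit cube (u, v, w) maps to the solid via

    .. math::
        z = w\\,L_z,\\quad
        y = T_{lat}/2 + (v - 1/2)\\,T(u),\\quad
        x = -D + u\\,(D - g(v)),

    with linear thickness taper ``T(u)`` and convex medial gap profile
    ``g(v) = g0 + b (2v - 1)^2`` (closest approach at mid-height).
    """
    params = params or GeometryParams()
    params.validate()
    nx, ny, nz = params.nx, params.ny, params.nz

    u = np.linspace(0.0, 1.0, nx + 1)
    v = np.linspace(0.0, 1.0, ny + 1)
    w = np.linspace(0.0, 1.0, nz + 1)
    U, V, W = np.meshgrid(u, v, w, indexing="ij")

    g = params.rest_half_gap + params.bulge * (2.0 * V - 1.0) ** 2
    T = params.thickness_lateral + U * (params.thickness_medial - params.thickness_lateral)
    X = -params.depth + U * (params.depth - g)
    Y = 0.5 * params.thickness_lateral + (V - 0.5) * T
    Z = W * params.span
    nodes = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)

    def nid(i, j, k):
        return (i * (ny + 1) + j) * (nz + 1) + k

    I, J, K = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
    I, J, K = I.ravel(), J.ravel(), K.ravel()
    corners = np.stack([
        nid(I, J, K), nid(I + 1, J, K), nid(I + 1, J + 1, K), nid(I, J + 1, K),
        nid(I, J, K + 1), nid(I + 1, J, K + 1), nid(I + 1, J + 1, K + 1),
        nid(I, J + 1, K + 1),
    ], axis=1)                                     # (n_hex, 8)
    tets = corners[:, _HEX_TO_TETS].reshape(-1, 4)

    # layer labels from parametric distance to the medial surface
    uvw = np.stack([U.ravel(), V.ravel(), W.ravel()], axis=1)
    cen = uvw[tets].mean(axis=1)
    g_c = params.rest_half_gap + params.bulge * (2.0 * cen[:, 1] - 1.0) ** 2
    depth_from_medial = (1.0 - cen[:, 0]) * (params.depth - g_c)
    layer = np.where(depth_from_medial < params.cover_thickness,
                     LAYER_COVER, LAYER_BODY).astype(np.int8)

    # boundary sets from grid indices
    ii = np.arange(nx + 1)
    jj = np.arange(ny + 1)
    kk = np.arange(nz + 1)
    JJ, KK = np.meshgrid(jj, kk, indexing="ij")
    lateral = nid(0, JJ, KK).ravel()
    II, JJ2 = np.meshgrid(ii, jj, indexing="ij")
    anterior = nid(II, JJ2, 0).ravel()
    posterior = nid(II, JJ2, nz).ravel()
    fixed = np.unique(np.concatenate([lateral, anterior, posterior]))
    II3, KK3 = np.meshgrid(ii, kk, indexing="ij")
    inferior = np.unique(nid(II3, 0, KK3).ravel())
    superior = np.unique(nid(II3, ny, KK3).ravel())
    JJm, KKm = np.meshgrid(jj, kk, indexing="ij")
    medial_grid = nid(nx, JJm, KKm)                 # (ny+1, nz+1)

    medial_faces = _boundary_faces_on(nodes, tets, np.unique(medial_grid))

    mesh = TetMesh(nodes=nodes, tets=tets, layer=layer, fixed_nodes=fixed,
                   medial_faces=medial_faces, inferior_nodes=inferior,
                   superior_nodes=superior, medial_grid=medial_grid, params=params)
    vols = tet_volumes(mesh)
    if np.any(vols <= 0):
        raise ValueError("meshing produced non-positive element volumes; "
                         "check bulge/taper against grid resolution")
    return mesh


_FACE_OF_TET = np.array([[1, 2, 3], [0, 3, 2], [0, 1, 3], [0, 2, 1]])


def _boundary_faces_on(nodes, tets, surface_nodes) -> np.ndarray:
    """Outward-oriented boundary triangles whose nodes all lie in `surface_nodes`."""
    faces = tets[:, _FACE_OF_TET].reshape(-1, 3)        # outward per tet convention
    key = np.sort(faces, axis=1)
    _, inv, counts = np.unique(key, axis=0, return_inverse=True, return_counts=True)
    boundary = faces[counts[inv] == 1]
    mask = np.isin(boundary, surface_nodes).all(axis=1)
    return boundary[mask]


def face_areas_normals(nodes: np.ndarray, faces: np.ndarray):
    """Areas and unit outward normals of oriented triangles."""
    p = nodes[faces]
    n = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
    a2 = np.linalg.norm(n, axis=1)
    return 0.5 * a2, n / a2[:, None]


def mesh_quality_report(mesh: TetMesh) -> dict:
    """Deterministic quality summary; flags inverted elements."""
    if mesh.n_tets == 0:
        raise ValueError("empty mesh")
    vols = tet_volumes(mesh)
    p = mesh.nodes[mesh.tets]
    # min dihedral per tet from face normals
    normals = np.stack([
        np.cross(p[:, 2] - p[:, 1], p[:, 3] - p[:, 1]),
        np.cross(p[:, 3] - p[:, 0], p[:, 2] - p[:, 0]),
        np.cross(p[:, 1] - p[:, 0], p[:, 3] - p[:, 0]),
        np.cross(p[:, 2] - p[:, 0], p[:, 1] - p[:, 0]),
    ], axis=1)
    normals /= np.linalg.norm(normals, axis=2, keepdims=True)
    pairs = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
    dih = []
    for a, b in pairs:
        cosang = np.clip(-(normals[:, a] * normals[:, b]).sum(axis=1), -1, 1)
        dih.append(np.degrees(np.arccos(cosang)))
    dih = np.stack(dih, axis=1)
    return {
        "n_nodes": mesh.n_nodes,
        "n_tets": mesh.n_tets,
        "n_cover": int(np.sum(mesh.layer == LAYER_COVER)),
        "n_body": int(np.sum(mesh.layer == LAYER_BODY)),
        "total_volume": float(vols.sum()),
        "min_volume": float(vols.min()),
        "max_volume": float(vols.max()),
        "n_inverted": int(np.sum(vols <= 0)),
        "min_dihedral_deg": float(dih.min()),
    }


# ---------------------------------------------------------------------------
# VTK legacy-ASCII unstructured grid I/O
# ---------------------------------------------------------------------------

def write_vtk(mesh: TetMesh, path):
    """Legacy ASCII VTK unstructured grid with layer labels and boundary tags."""
    fixed_mask = np.zeros(mesh.n_nodes, dtype=int)
    fixed_mask[mesh.fixed_nodes] = 1
    medial_mask = np.zeros(mesh.n_nodes, dtype=int)
    medial_mask[np.unique(mesh.medial_faces)] = 1
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nvfpinn mesh\nASCII\n"
                 "DATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {mesh.n_nodes} double\n")
        np.savetxt(fh, mesh.nodes, fmt="%.17g")
        fh.write(f"CELLS {mesh.n_tets} {5 * mesh.n_tets}\n")
        np.savetxt(fh, np.column_stack([np.full(mesh.n_tets, 4), mesh.tets]), fmt="%d")
        fh.write(f"CELL_TYPES {mesh.n_tets}\n")
        np.savetxt(fh, np.full(mesh.n_tets, 10), fmt="%d")
        fh.write(f"CELL_DATA {mesh.n_tets}\nSCALARS layer int 1\nLOOKUP_TABLE default\n")
        np.savetxt(fh, mesh.layer, fmt="%d")
        fh.write(f"POINT_DATA {mesh.n_nodes}\nSCALARS fixed int 1\nLOOKUP_TABLE default\n")
        np.savetxt(fh, fixed_mask, fmt="%d")
        fh.write("SCALARS medial int 1\nLOOKUP_TABLE default\n")
        np.savetxt(fh, medial_mask, fmt="%d")


def read_vtk(path) -> TetMesh:
    """Read a mesh written by :func:`write_vtk` (tet cells only)."""
    with open(path) as fh:
        tokens = fh.read().split()
    def after(word):
        return tokens.index(word)
    i = after("POINTS")
    n_nodes = int(tokens[i + 1])
    nodes = np.array(tokens[i + 3:i + 3 + 3 * n_nodes], dtype=float).reshape(-1, 3)
    i = after("CELLS")
    n_cells = int(tokens[i + 1])
    raw = np.array(tokens[i + 3:i + 3 + 5 * n_cells], dtype=int).reshape(-1, 5)
    if not np.all(raw[:, 0] == 4):
        raise ValueError("only tetrahedral cells supported")
    tets = raw[:, 1:]
    i = after("CELL_DATA")
    j = tokens.index("default", i)
    layer = np.array(tokens[j + 1:j + 1 + n_cells], dtype=np.int8)
    i = after("POINT_DATA")
    j = tokens.index("default", i)
    fixed_mask = np.array(tokens[j + 1:j + 1 + n_nodes], dtype=int)
    j = tokens.index("default", j + 1 + n_nodes)
    medial_mask = np.array(tokens[j + 1:j + 1 + n_nodes], dtype=int)
    medial_nodes = np.flatnonzero(medial_mask)
    medial_faces = _boundary_faces_on(nodes, tets, medial_nodes)
    return TetMesh(nodes=nodes, tets=tets, layer=layer,
                   fixed_nodes=np.flatnonzero(fixed_mask),
                   medial_faces=medial_faces,
                   inferior_nodes=np.array([], dtype=int),
                   superior_nodes=np.array([], dtype=int))
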