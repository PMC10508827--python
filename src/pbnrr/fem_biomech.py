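"""Linear-elastic tetrahedral FEM assembly.

Builds the global stiffness matrix K of a multi-tissue mesh of 4-node
constant-strain tetrahedra with isotropic Hookean materials, and the
sparse interpolation matrix H mapping mesh-vertex displacements to
displacements at registration points via barycentric weights.

Units: vertices in mm, E in Pa.  Only the relative magnitude of K
against the match-weight term HᵀSH matters to the registration solve;
the solver exposes an explicit scale for that balance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.spatial import cKDTree

from .core_io import MaterialTable, TetMesh

__all__ = [
    "StiffnessMatrix",
    "InterpolationMatrix",
    "DegenerateElementError",
    "hooke_matrix",
    "element_stiffness",
    "assemble_stiffness",
    "build_interpolation",
]

_MIN_VOLUME = 1e-12  # mm^3


class DegenerateElementError(ValueError):
    """Tetrahedron with (near-)zero volume."""


@dataclass
class StiffnessMatrix:
    """Sparse symmetric 3N x 3N global stiffness matrix with assembly
    provenance."""

    matrix: sparse.csr_matrix
    mesh_hash: str = ""
    materials: dict = field(default_factory=dict)

    @property
    def n_dof(self) -> int:
        return self.matrix.shape[0]


@dataclass
class InterpolationMatrix:
    """Sparse 3n x 3N barycentric interpolation matrix H plus, per kept
    point, the containing tetrahedron and its barycentric weights."""

    matrix: sparse.csr_matrix
    tet_index: np.ndarray  # (n,) containing tet per kept point
    barycentric: np.ndarray  # (n, 4) weights, >= 0, sum 1


def hooke_matrix(E: float, nu: float) -> np.ndarray:
    """6x6 isotropic elasticity matrix in Voigt (engineering-shear)
    ordering (xx, yy, zz, xy, yz, zx)."""
    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E / (2 * (1 + nu))
    C = np.zeros((6, 6))
    C[:3, :3] = lam
    C[np.arange(3), np.arange(3)] = lam + 2 * mu
    C[np.arange(3, 6), np.arange(3, 6)] = mu
    return C


def _shape_gradients(coords: np.ndarray) -> tuple[np.ndarray, float]:
    """Gradients (4, 3) of the linear shape functions and the signed
    volume of a tetrahedron with vertex rows ``coords`` (4, 3)."""
    M = np.hstack([np.ones((4, 1)), coords])  # rows [1, x, y, z]
    det = np.linalg.det(M)
    vol = det / 6.0
    if abs(vol) <= _MIN_VOLUME:
        raise DegenerateElementError(
            f"degenerate tetrahedron (volume {vol:g} mm^3)"
        )
    grads = np.linalg.inv(M)[1:, :].T  # (4, 3): row i = grad N_i
    return grads, vol


def element_stiffness(coords: np.ndarray, E: float, nu: float) -> np.ndarray:
    """12x12 stiffness K_e = V * Bᵀ C B of a 4-node linear tetrahedron.

    ``coords`` is (4, 3) in mm; dof ordering is (v0x, v0y, v0z, v1x, ...).
    Symmetric PSD with the 6 rigid-body modes as null space.
    """
    coords = np.asarray(coords, dtype=float).reshape(4, 3)
    grads, vol = _shape_gradients(coords)
    if abs(vol) <= _MIN_VOLUME:
        raise DegenerateElementError(
            f"degenerate tetrahedron (volume {vol:g} mm^3)"
        )
    B = np.zeros((6, 12))
    for i in range(4):
        gx, gy, gz = grads[i]
        c = 3 * i
        B[0, c] = gx
        B[1, c + 1] = gy
        B[2, c + 2] = gz
        B[3, c] = gy
        B[3, c + 1] = gx
        B[4, c + 1] = gz
        B[4, c + 2] = gy
        B[5, c] = gz
        B[5, c + 2] = gx
    Ke = abs(vol) * (B.T @ hooke_matrix(E, nu) @ B)
    return 0.5 * (Ke + Ke.T)


def _batch_element_stiffness(
    verts: np.ndarray, tets: np.ndarray, E: np.ndarray, nu: np.ndarray
) -> np.ndarray:
    """Vectorized element stiffness for all tets: (M, 12, 12)."""
    p = verts[tets]  # (M, 4, 3)
    M4 = np.concatenate([np.ones((len(tets), 4, 1)), p], axis=2)
    det = np.linalg.det(M4)
    vol = det / 6.0
    if np.any(np.abs(vol) <= _MIN_VOLUME):
        bad = int(np.argmin(np.abs(vol)))
        raise DegenerateElementError(
            f"degenerate tetrahedron at element {bad} (volume {vol[bad]:g} mm^3)"
        )
    inv = np.linalg.inv(M4)  # (M, 4, 4)
    grads = np.transpose(inv[:, 1:, :], (0, 2, 1))  # (M, 4, 3)
    B = np.zeros((len(tets), 6, 12))
    gx, gy, gz = grads[..., 0], grads[..., 1], grads[..., 2]
    for i in range(4):
        c = 3 * i
        B[:, 0, c] = gx[:, i]
        B[:, 1, c + 1] = gy[:, i]
        B[:, 2, c + 2] = gz[:, i]
        B[:, 3, c] = gy[:, i]
        B[:, 3, c + 1] = gx[:, i]
        B[:, 4, c + 1] = gz[:, i]
        B[:, 4, c + 2] = gy[:, i]
        B[:, 5, c] = gz[:, i]
        B[:, 5, c + 2] = gx[:, i]
    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E / (2 * (1 + nu))
    C = np.zeros((len(tets), 6, 6))
    C[:, :3, :3] = lam[:, None, None]
    for a in range(3):
        C[:, a, a] = lam + 2 * mu
        C[:, 3 + a, 3 + a] = mu
    Ke = np.abs(vol)[:, None, None] * np.einsum("mji,mjk,mkl->mil", B, C, B)
    return 0.5 * (Ke + np.transpose(Ke, (0, 2, 1)))


def assemble_stiffness(mesh: TetMesh, materials: MaterialTable) -> StiffnessMatrix:
    """Scatter-add element stiffness matrices into the global sparse K.

    Every tet label must exist in ``materials`` (KeyError otherwise).
    The result is exactly symmetric and positive semidefinite; for a
    connected mesh the null space is the 6 rigid-body modes.
    """
    labels = np.unique(mesh.tet_labels)
    for lab in labels:
        materials.lookup(int(lab))  # raises on missing label
    E = np.array([materials.lookup(int(l)).E for l in mesh.tet_labels])
    nu = np.array([materials.lookup(int(l)).nu for l in mesh.tet_labels])
    Ke = _batch_element_stiffness(mesh.vertices, mesh.tets, E, nu)

    dof = (3 * mesh.tets[:, :, None] + np.arange(3)[None, None, :]).reshape(
        len(mesh.tets), 12
    )
    rows = np.repeat(dof, 12, axis=1).ravel()
    cols = np.tile(dof, (1, 12)).ravel()
    n = 3 * mesh.n_vertices
    K = sparse.coo_matrix((Ke.ravel(), (rows, cols)), shape=(n, n)).tocsr()
    K = ((K + K.T) * 0.5).tocsr()
    mesh_hash = f"{mesh.n_vertices}v{mesh.n_tets}t"
    return StiffnessMatrix(
        matrix=K,
        mesh_hash=mesh_hash,
        materials={int(l): (materials.lookup(int(l)).E, materials.lookup(int(l)).nu)
                   for l in labels},
    )


def barycentric_coordinates(
    mesh: TetMesh, points: np.ndarray, tet_idx: np.ndarray
) -> np.ndarray:
    """Barycentric coordinates (n, 4) of points w.r.t. given tets."""
    p = mesh.vertices[mesh.tets[tet_idx]]  # (n, 4, 3)
    M4 = np.concatenate([np.ones((len(tet_idx), 4, 1)), p], axis=2)
    rhs = np.concatenate([np.ones((len(points), 1)), points], axis=1)
    return np.einsum("nij,nj->ni", np.linalg.inv(np.transpose(M4, (0, 2, 1))), rhs)


def locate_points(
    mesh: TetMesh, points: np.ndarray, tol: float = 1e-9
) -> tuple[np.ndarray, np.ndarray]:
    """Containing tet (-1 if none) and barycentric weights per point.

    Candidate tets come from a k-NN search on tet centroids, widened
    until each point is resolved or all tets are exhausted.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    n = len(points)
    tet_idx = np.full(n, -1, dtype=np.int64)
    bary = np.zeros((n, 4))
    if mesh.n_tets == 0 or n == 0:
        return tet_idx, bary
    tree = cKDTree(mesh.centroids())
    unresolved = np.arange(n)
    k = min(32, mesh.n_tets)
    while len(unresolved):
        _, cand = tree.query(points[unresolved], k=k)
        cand = np.asarray(cand).reshape(len(unresolved), -1)
        for col in range(cand.shape[1]):
            ci = cand[:, col]
            lam = barycentric_coordinates(mesh, points[unresolved], ci)
            inside = np.all(lam >= -tol, axis=1)
            if np.any(inside):
                hit = unresolved[inside]
                tet_idx[hit] = ci[inside]
                w = np.clip(lam[inside], 0.0, None)
                bary[hit] = w / w.sum(axis=1, keepdims=True)
                unresolved = unresolved[~inside]
                cand = cand[~inside]
            if not len(unresolved):
                break
        if k >= mesh.n_tets:
            break
        k = min(4 * k, mesh.n_tets)
    return tet_idx, bary


def build_interpolation(
    mesh: TetMesh, points: np.ndarray, tol: float = 1e-9
) -> tuple[InterpolationMatrix, np.ndarray]:
    """Barycentric interpolation matrix H for world points inside the mesh.

    Points outside every tetrahedron (barycentric test at tolerance
    ``tol``) are dropped; the returned index array lists the points that
    were kept, in order.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    tet_idx, bary = locate_points(mesh, points, tol=tol)
    kept = np.flatnonzero(tet_idx >= 0)
    nk = len(kept)
    N = mesh.n_vertices

    if nk == 0:
        H = sparse.csr_matrix((0, 3 * N))
        return InterpolationMatrix(H, tet_idx[kept], bary[kept]), kept

    verts = mesh.tets[tet_idx[kept]]  # (nk, 4)
    w = bary[kept]  # (nk, 4)
    # each kept point contributes 3 rows; each row has 4 entries
    row = (3 * np.arange(nk)[:, None, None] + np.arange(3)[None, None, :])
    row = np.broadcast_to(row, (nk, 4, 3)).ravel()
    col = (3 * verts[:, :, None] + np.arange(3)[None, None, :]).ravel()
    val = np.broadcast_to(w[:, :, None], (nk, 4, 3)).ravel()
    H = sparse.coo_matrix((val, (row, col)), shape=(3 * nk, 3 * N)).tocsr()
    return InterpolationMatrix(H, tet_idx[kept], w), kept
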