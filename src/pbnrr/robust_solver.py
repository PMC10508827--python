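"""Robust finite-element registration solver.

Solves the regularized interpolation system

    [K + HᵀSH] U = HᵀSD (+ F)

where K is the mesh stiffness, H the barycentric interpolation matrix
at the matched blocks, S the confidence-weighted block stiffness, and D
the matched displacements.  An external force F = K·U_i, recomputed
each iteration, gradually relaxes the internal mesh stress so the
solution converges to the approximation problem

    argmin_U (HU - D)ᵀ S (HU - D)

while a scheduled fractional rejection (total fraction f_R over n_R
iterations, ranked by the per-block error ξ_k) removes outlier matches.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Sequence

import numpy as np
from scipy import ndimage, sparse
from scipy.sparse.linalg import splu, eigsh

from .core_io import DenseField, Image3D, MaterialTable, TetMesh
from .feature_matching import BlockSpec, MatchSet, block_match, select_feature_points
from .fem_biomech import (
    StiffnessMatrix,
    assemble_stiffness,
    build_interpolation,
    locate_points,
)

__all__ = [
    "SolverConfig",
    "SolveState",
    "ConditioningError",
    "EmptySystemError",
    "build_match_system",
    "solve_interpolation",
    "block_error",
    "register",
    "nodal_to_dense",
    "warp_image",
    "register_images",
    "RegistrationResult",
]


class ConditioningError(RuntimeError):
    """The system matrix is numerically singular or indefinite."""


class EmptySystemError(RuntimeError):
    """No active matches remain."""


@dataclass
class SolverConfig:
    """Parameters of the robust registration solve.

    n_R / f_R: number of rejection iterations and the *total* fraction
    of matches discarded across them.  relax_tol / relax_max_iter bound
    the final stress-relaxation loop (relative change of U).
    linear_tol is the relative-residual contract of each linear solve.
    stiffness_scale balances K against HᵀSH: "auto" picks the scale so
    trace(K)/trace(HᵀSH) equals target_trace_ratio; a float is applied
    directly as a multiplier on K.
    """

    n_R: int = 5
    f_R: float = 0.25
    relax_tol: float = 1e-3
    relax_max_iter: int = 50
    linear_tol: float = 1e-8
    stiffness_scale: float | str = "auto"
    target_trace_ratio: float = 10.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.f_R < 1.0):
            raise ValueError(f"f_R must be in [0, 1), got {self.f_R}")
        if self.n_R < 0:
            raise ValueError("n_R must be >= 0")
        if self.relax_tol <= 0 or self.linear_tol <= 0:
            raise ValueError("tolerances must be > 0")
        if self.relax_max_iter < 0:
            raise ValueError("relax_max_iter must be >= 0")


@dataclass
class SolveState:
    """Working state of the robust solve, restricted to active matches."""

    K: sparse.csr_matrix
    H: sparse.csr_matrix
    S: sparse.csr_matrix
    D: np.ndarray
    U: np.ndarray
    F: np.ndarray
    active: np.ndarray  # boolean over the original matches
    xi: np.ndarray | None = None


def _as_matrix(K) -> sparse.csr_matrix:
    if isinstance(K, StiffnessMatrix):
        return K.matrix
    return sparse.csr_matrix(K)


def build_match_system(
    mesh: TetMesh, matches: MatchSet, floating: Image3D
) -> tuple[sparse.csr_matrix, sparse.csr_matrix, np.ndarray, np.ndarray]:
    """Assemble (H, S, D, kept) from a match set on a mesh.

    Matches whose block center falls outside every tetrahedron are
    dropped; ``kept`` indexes the surviving matches.
    """
    pts = matches.world_points(floating)
    interp, kept = build_interpolation(mesh, pts)
    W = matches.weight_tensors()[kept]
    n = len(kept)
    S = _block_diag3(W)
    D = matches.displacements[kept].reshape(3 * n)
    return interp.matrix, S, D, kept


def _block_diag3(W: np.ndarray) -> sparse.csr_matrix:
    """Sparse block-diagonal matrix from (n, 3, 3) blocks."""
    n = len(W)
    if n == 0:
        return sparse.csr_matrix((0, 0))
    rows = (3 * np.arange(n)[:, None, None] + np.arange(3)[None, :, None])
    rows = np.broadcast_to(rows, (n, 3, 3)).ravel()
    cols = (3 * np.arange(n)[:, None, None] + np.arange(3)[None, None, :])
    cols = np.broadcast_to(cols, (n, 3, 3)).ravel()
    return sparse.coo_matrix((W.ravel(), (rows, cols)), shape=(3 * n, 3 * n)).tocsr()


def _smallest_eig_estimate(A: sparse.csr_matrix) -> float:
    try:
        if A.shape[0] <= 600:
            return float(np.linalg.eigvalsh(A.toarray())[0])
        return float(eigsh(A, k=1, which="SA", tol=1e-4,
                           maxiter=5000, return_eigenvectors=False)[0])
    except Exception:
        return float("nan")


class _Factorized:
    """LU factorization of A with a per-solve relative-residual check."""

    def __init__(self, A: sparse.spmatrix, linear_tol: float):
        self.A = A.tocsc()
        self.linear_tol = linear_tol
        asym = abs(A - A.T)
        if asym.nnz and asym.max() > 1e-10 * max(abs(A).max(), 1.0):
            raise ConditioningError("system matrix is not symmetric")
        try:
            self.lu = splu(self.A)
        except RuntimeError as exc:
            raise ConditioningError(
                "singular system matrix; smallest eigenvalue estimate "
                f"{_smallest_eig_estimate(self.A.tocsr()):g}"
            ) from exc

    def solve(self, b: np.ndarray) -> np.ndarray:
        x = self.lu.solve(b)
        nb = float(np.linalg.norm(b))
        res = float(np.linalg.norm(self.A @ x - b))
        if not np.all(np.isfinite(x)) or (nb > 0 and res > self.linear_tol * nb):
            raise ConditioningError(
                "linear solve failed the residual contract "
                f"(relative residual {res / max(nb, 1e-300):g}); smallest "
                f"eigenvalue estimate {_smallest_eig_estimate(self.A.tocsr()):g}"
            )
        return x


def solve_interpolation(K, H, S, D, F=None, linear_tol: float = 1e-8) -> np.ndarray:
    """Solve [K + HᵀSH] U = HᵀSD (+ F) to relative residual linear_tol."""
    K = _as_matrix(K)
    A = (K + H.T @ S @ H).tocsr()
    b = np.asarray(H.T @ (S @ np.asarray(D, dtype=float)))
    if F is not None:
        b = b + np.asarray(F, dtype=float)
    return _Factorized(A, linear_tol).solve(b)


def block_error(U: np.ndarray, H, S, D) -> np.ndarray:
    """Per-block error ξ_k = (H_k U - D_k)ᵀ S_k (H_k U - D_k)."""
    r = np.asarray(H @ U) - np.asarray(D, dtype=float)
    return (r * (S @ r)).reshape(-1, 3).sum(axis=1)


def _resolve_scale(K: sparse.csr_matrix, M: sparse.csr_matrix,
                   cfg: SolverConfig) -> float:
    if cfg.stiffness_scale != "auto":
        return float(cfg.stiffness_scale)
    tK = float(K.diagonal().sum())
    tM = float(M.diagonal().sum())
    if tK <= 0 or tM <= 0:
        return 1.0
    return cfg.target_trace_ratio * tM / tK


def register(
    K,
    H,
    S,
    D,
    cfg: SolverConfig,
    confidences: np.ndarray | None = None,
) -> tuple[np.ndarray, dict]:
    """Robust registration: scheduled outlier rejection, then stress
    relaxation.

    Runs n_R iterations of {F <- KU; solve the relaxed system; compute
    ξ; reject the scheduled number of highest-ξ blocks; restrict S, H, D
    to the active rows}, then iterates {F <- KU; solve} until the
    relative change of U drops below relax_tol or relax_max_iter is hit.

    Per-iteration rejection count is floor(f_R * n / n_R), with the
    remainder rejected in the last rejection iteration (exactly
    floor(f_R * n) total).  ξ ties break toward lower confidence, then
    lower match id.  Returns (U, log) where log records rejected ids,
    residuals and the relaxation trace.
    """
    K = _as_matrix(K)
    H = sparse.csr_matrix(H)
    S = sparse.csr_matrix(S)
    D = np.asarray(D, dtype=float).ravel()
    n = H.shape[0] // 3
    if n == 0:
        raise EmptySystemError("no matches to register")
    if confidences is None:
        confidences = np.zeros(n)
    confidences = np.asarray(confidences, dtype=float).ravel()

    total_reject = int(np.floor(cfg.f_R * n))
    if total_reject >= n:
        raise EmptySystemError("rejection schedule would discard every match")
    if cfg.n_R > 0:
        base = int(np.floor(cfg.f_R * n / cfg.n_R))
        counts = [base] * cfg.n_R
        counts[-1] = total_reject - base * (cfg.n_R - 1)
    else:
        counts = []

    active = np.ones(n, dtype=bool)
    row_mask = np.repeat(active, 3)
    ids = np.arange(n)

    def restricted():
        rm = np.repeat(active, 3)
        Ha = H[rm]
        Sa = S[rm][:, rm]
        Da = D[rm]
        return Ha, Sa, Da

    Ha, Sa, Da = restricted()
    M = (Ha.T @ Sa @ Ha).tocsr()
    scale = _resolve_scale(K, M, cfg)
    Ks = (K * scale).tocsr()

    U = np.zeros(K.shape[0])
    log: dict = {
        "stiffness_scale": scale,
        "n_matches": n,
        "rejection": [],
        "relaxation": [],
        "rejected_ids": [],
    }

    for i, count in enumerate(counts):
        A = (Ks + M).tocsr()
        fac = _Factorized(A, cfg.linear_tol)
        b = np.asarray(Ha.T @ (Sa @ Da))
        F = Ks @ U
        U = fac.solve(b + F)
        xi = block_error(U, Ha, Sa, Da)
        act_ids = ids[active]
        order = np.lexsort((act_ids, confidences[active], -xi))
        rejected = act_ids[order[:count]]
        active[rejected] = False
        if not np.any(active):
            raise EmptySystemError("all matches rejected")
        log["rejection"].append(
            {
                "iteration": i,
                "rejected_ids": [int(r) for r in rejected],
                "n_active": int(active.sum()),
                "residual": float(
                    block_error(U, Ha, Sa, Da).sum()
                ),
            }
        )
        log["rejected_ids"].extend(int(r) for r in rejected)
        Ha, Sa, Da = restricted()
        M = (Ha.T @ Sa @ Ha).tocsr()

    # Relaxation toward the approximation problem.  The iteration
    # U <- A^-1 (b + K U) is neutrally stable on the null space of
    # HᵀSH, where it would keep permanent memory of rejected outliers;
    # after any rejection the relaxation therefore restarts from the
    # interpolation solve (F = 0) of the cleaned system, which pins the
    # unsupported d.o.f. to the elastic solution.
    A = (Ks + M).tocsr()
    fac = _Factorized(A, cfg.linear_tol)
    b = np.asarray(Ha.T @ (Sa @ Da))
    if total_reject > 0 or cfg.n_R == 0:
        U = fac.solve(b + Ks @ (U if total_reject == 0 else 0 * U))
    for j in range(cfg.relax_max_iter):
        F = Ks @ U
        U_new = fac.solve(b + F)
        denom = float(np.linalg.norm(U_new))
        change = float(np.linalg.norm(U_new - U)) / max(denom, 1e-300)
        U = U_new
        res = float(block_error(U, Ha, Sa, Da).sum())
        log["relaxation"].append(
            {"iteration": j, "residual": res, "relative_change": change}
        )
        if change < cfg.relax_tol:
            break

    log["active"] = active
    return U, log


# ---------------------------------------------------------------------------
# Dense fields and warping
# ---------------------------------------------------------------------------


def nodal_to_dense(mesh: TetMesh, U: np.ndarray, ref: Image3D) -> DenseField:
    """Rasterize a nodal displacement field onto the voxel grid of
    ``ref`` by barycentric interpolation; voxels outside the mesh get
    zero displacement."""
    U = np.asarray(U, dtype=float).reshape(-1, 3)
    if len(U) != mesh.n_vertices:
        raise ValueError("U must have one 3-vector per mesh vertex")
    out = np.zeros(ref.shape + (3,))
    spacing = np.asarray(ref.spacing)
    origin = np.asarray(ref.origin)
    shape = np.asarray(ref.shape)

    verts = mesh.vertices[mesh.tets]  # (M, 4, 3)
    M4 = np.concatenate([np.ones((mesh.n_tets, 4, 1)), verts], axis=2)
    inv = np.linalg.inv(np.transpose(M4, (0, 2, 1)))  # (M, 4, 4)

    lo = np.ceil((verts.min(axis=1) - origin) / spacing - 1e-12).astype(int)
    hi = np.floor((verts.max(axis=1) - origin) / spacing + 1e-12).astype(int)
    lo = np.clip(lo, 0, shape - 1)
    hi = np.clip(hi, -1, shape - 1)
    Utet = U[mesh.tets]  # (M, 4, 3)

    for t in range(mesh.n_tets):
        if np.any(hi[t] < lo[t]):
            continue
        gi, gj, gk = np.meshgrid(
            np.arange(lo[t, 0], hi[t, 0] + 1),
            np.arange(lo[t, 1], hi[t, 1] + 1),
            np.arange(lo[t, 2], hi[t, 2] + 1),
            indexing="ij",
        )
        pts = np.stack([gi, gj, gk], axis=-1).reshape(-1, 3) * spacing + origin
        rhs = np.concatenate([np.ones((len(pts), 1)), pts], axis=1)
        lam = rhs @ inv[t].T  # (p, 4)
        inside = np.all(lam >= -1e-9, axis=1)
        if not np.any(inside):
            continue
        vals = lam[inside] @ Utet[t]
        ii = gi.ravel()[inside]
        jj = gj.ravel()[inside]
        kk = gk.ravel()[inside]
        out[ii, jj, kk] = vals
    return DenseField(data=out, spacing=ref.spacing, origin=ref.origin)


def warp_image(img: Image3D, fld: DenseField, order: int = 1) -> Image3D:
    """Backward warping out(x) = img(x - u(x)); nearest (order 0) for
    labels, trilinear (order 1) for intensities; out-of-bounds -> 0."""
    if order not in (0, 1):
        raise ValueError("order must be 0 or 1")
    if not fld.same_geometry(img):
        raise ValueError("field and image geometries differ")
    spacing = np.asarray(img.spacing)
    idx = np.meshgrid(*[np.arange(s, dtype=float) for s in img.shape], indexing="ij")
    coords = [idx[a] - fld.data[..., a] / spacing[a] for a in range(3)]
    warped = ndimage.map_coordinates(
        img.data.astype(float), coords, order=order, mode="constant",
        cval=0.0, prefilter=False,
    )
    if order == 0:
        warped = warped.astype(img.data.dtype)
    return Image3D(data=warped, spacing=img.spacing, origin=img.origin)


def compose_fields(inc: DenseField, prev: DenseField) -> DenseField:
    """u_total(x) = u_inc(x) + u_prev(x - u_inc(x)) (trilinear sampling
    of u_prev; out-of-bounds samples contribute zero)."""
    spacing = np.asarray(inc.spacing)
    idx = np.meshgrid(*[np.arange(s, dtype=float) for s in inc.shape], indexing="ij")
    coords = [idx[a] - inc.data[..., a] / spacing[a] for a in range(3)]
    prev_sampled = np.stack(
        [
            ndimage.map_coordinates(
                prev.data[..., a], coords, order=1, mode="constant",
                cval=0.0, prefilter=False,
            )
            for a in range(3)
        ],
        axis=-1,
    )
    return DenseField(
        data=inc.data + prev_sampled, spacing=inc.spacing, origin=inc.origin
    )


def sample_field(fld: DenseField, points_mm: np.ndarray) -> np.ndarray:
    """Trilinear sample of a dense field at world points (mm)."""
    pts = np.atleast_2d(np.asarray(points_mm, dtype=float))
    idx = (pts - np.asarray(fld.origin)) / np.asarray(fld.spacing)
    return np.stack(
        [
            ndimage.map_coordinates(
                fld.data[..., a], idx.T, order=1, mode="constant",
                cval=0.0, prefilter=False,
            )
            for a in range(3)
        ],
        axis=-1,
    )


# ---------------------------------------------------------------------------
# End-to-end single-pass registration
# ---------------------------------------------------------------------------


@dataclass
class RegistrationResult:
    U: np.ndarray  # (N, 3) nodal displacement, mm
    mesh: TetMesh
    matches: MatchSet
    kept: np.ndarray  # matches used in the solve
    log: dict
    field: DenseField
    warped: Image3D


def register_images(
    floating: Image3D,
    fixed: Image3D,
    mesh: TetMesh,
    materials: MaterialTable | None = None,
    block_spec: BlockSpec | None = None,
    solver_cfg: SolverConfig | None = None,
    mask=None,
    fraction: float = 0.05,
    min_spacing: float = 2.0,
    min_confidence: float = 0.5,
    matches: MatchSet | None = None,
) -> RegistrationResult:
    """Single PBNRR pass: feature selection, block matching, FEM
    assembly, robust solve, dense field, and backward warp."""
    materials = materials or MaterialTable()
    block_spec = block_spec or BlockSpec()
    solver_cfg = solver_cfg or SolverConfig()
    if matches is None:
        margin = tuple(b + w for b, w in zip(block_spec.B, block_spec.W))
        pts = select_feature_points(
            floating, block_spec, fraction=fraction, mask=mask,
            min_spacing=min_spacing, margin=margin,
        )
        matches = block_match(floating, fixed, pts, block_spec,
                              min_confidence=min_confidence)
    if len(matches) == 0:
        raise EmptySystemError("block matching produced no matches")
    K = assemble_stiffness(mesh, materials)
    H, S, D, kept = build_match_system(mesh, matches, floating)
    if len(kept) == 0:
        raise EmptySystemError("no match falls inside the mesh")
    U_flat, log = register(K, H, S, D, solver_cfg,
                           confidences=matches.confidences[kept])
    U = U_flat.reshape(-1, 3)
    fld = nodal_to_dense(mesh, U, fixed)
    warped = warp_image(floating, fld, order=1)
    return RegistrationResult(
        U=U, mesh=mesh, matches=matches, kept=kept, log=log,
        field=fld, warped=warped,
    )
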