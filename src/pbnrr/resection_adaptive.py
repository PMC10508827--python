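"""Resection handling and incremental adaptive registration.

Resection (removed tissue) leaves a cavity in the intra-operative
image.  Mesh elements that fall into that background region and form a
maximal face-connected submesh are collected iteratively and removed
from the biomechanical model.  The adaptive loop (ANRR) interleaves
re-meshing of the incrementally warped floating image with single
registration passes, composing the incremental fields so that large
deformations never produce inverted elements in any one solve.

The internal mesher tessellates a body-centered-cubic (BCC) lattice,
whose uniformly good dihedral angles keep the stiffness matrix well
conditioned.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import ndimage
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from skimage.filters import threshold_otsu

from .core_io import DenseField, Image3D, LabelImage, MaterialTable, TetMesh, tet_volumes
from .feature_matching import BlockSpec
from .robust_solver import (
    RegistrationResult,
    SolverConfig,
    compose_fields,
    register_images,
    warp_image,
)

__all__ = [
    "ResectionConfig",
    "AdaptiveConfig",
    "EmptyMeshError",
    "bcc_mesh",
    "detect_resection_elements",
    "remove_elements",
    "adaptive_register",
]


class EmptyMeshError(ValueError):
    """Meshing produced no tetrahedra."""


@dataclass
class ResectionConfig:
    """Background-element rejection parameters.

    ``bg_threshold``: intensity below which an intra-operative voxel is
    background; None selects Otsu's threshold on the image restricted
    to the mesh bounding box.  A tetrahedron is flagged when at least
    ``bg_fraction`` of its 5 samples (4 displaced vertices + displaced
    centroid) are background.
    """

    bg_threshold: float | None = None
    bg_fraction: float = 0.8
    max_outer_iter: int = 10

    def __post_init__(self) -> None:
        if not (0.0 < self.bg_fraction <= 1.0):
            raise ValueError("bg_fraction must be in (0, 1]")
        if self.max_outer_iter < 1:
            raise ValueError("max_outer_iter must be >= 1")


@dataclass
class AdaptiveConfig:
    """Incremental adaptive registration parameters."""

    N_iter: int = 5
    cell_size: float = 8.0  # mm, BCC lattice cell
    block: BlockSpec = dc_field(default_factory=BlockSpec)
    solver: SolverConfig = dc_field(default_factory=SolverConfig)
    remesh: bool = True
    fraction: float = 0.05
    min_spacing: float = 2.0
    min_confidence: float = 0.5
    # voxels of label dilation before meshing, so the tissue always lies
    # strictly inside the mesh hull; prevents the composed field's
    # zero-outside-mesh region from eroding the warped mask iteration
    # over iteration
    mesh_dilation_vox: int = 3

    def __post_init__(self) -> None:
        if self.N_iter < 1:
            raise ValueError("N_iter must be >= 1")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be > 0")


# ---------------------------------------------------------------------------
# BCC lattice meshing
# ---------------------------------------------------------------------------

_FACE_EDGES = [(0, 1), (1, 2), (2, 3), (3, 0)]


def _sample_labels(mask: LabelImage, points_mm: np.ndarray) -> np.ndarray:
    """Nearest-voxel label at world points; 0 outside the image."""
    idx = np.rint(mask.world_to_index(points_mm)).astype(np.int64)
    shape = np.asarray(mask.shape)
    inb = np.all((idx >= 0) & (idx < shape), axis=-1)
    out = np.zeros(len(points_mm), dtype=np.int64)
    ii = idx[inb]
    out[inb] = mask.data[ii[:, 0], ii[:, 1], ii[:, 2]]
    return out


def bcc_mesh(mask: LabelImage, cell_size: float) -> TetMesh:
    """Tetrahedralize the body-centered-cubic lattice over ``mask > 0``.

    Keeps tetrahedra whose centroid lies in the foreground; each kept
    tet is labeled by the majority mask label among its 4 vertex +
    centroid samples (ties to the smaller label; a background-majority
    tet takes its centroid's label).  Raises EmptyMeshError when no tet
    survives.
    """
    if cell_size <= 0:
        raise ValueError("cell_size must be > 0")
    fg = np.argwhere(mask.data > 0)
    if len(fg) == 0:
        raise EmptyMeshError("mask has no foreground voxels")
    spacing = np.asarray(mask.spacing)
    origin = np.asarray(mask.origin)
    wmin = origin + fg.min(axis=0) * spacing - cell_size
    wmax = origin + fg.max(axis=0) * spacing + cell_size
    ncell = np.maximum(np.ceil((wmax - wmin) / cell_size).astype(int), 1)
    nx, ny, nz = ncell

    n_corners = (nx + 1) * (ny + 1) * (nz + 1)

    def corner_id(i, j, k):
        return (i * (ny + 1) + j) * (nz + 1) + k

    def center_id(i, j, k):
        return n_corners + (i * ny + j) * nz + k

    # vertex coordinate table (corners then centers)
    ci, cj, ck = np.meshgrid(
        np.arange(nx + 1), np.arange(ny + 1), np.arange(nz + 1), indexing="ij"
    )
    corners = np.stack([ci, cj, ck], axis=-1).reshape(-1, 3) * cell_size + wmin
    bi, bj, bk = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
    )
    centers = (np.stack([bi, bj, bk], axis=-1).reshape(-1, 3) + 0.5) * cell_size + wmin
    verts = np.vstack([corners, centers])

    tet_list = []
    # faces between adjacent cell centers along each axis; 4 tets per face
    for axis in range(3):
        dims = [nx, ny, nz]
        dims[axis] -= 1
        if dims[axis] < 1:
            continue
        I, J, K = np.meshgrid(
            np.arange(dims[0]), np.arange(dims[1]), np.arange(dims[2]),
            indexing="ij",
        )
        I, J, K = I.ravel(), J.ravel(), K.ravel()
        step = np.zeros(3, dtype=int)
        step[axis] = 1
        c1 = center_id(I, J, K)
        c2 = center_id(I + step[0], J + step[1], K + step[2])
        # the shared square face: corners on the plane between the two cells
        a1, a2 = [a for a in range(3) if a != axis]
        cyc = [(0, 0), (1, 0), (1, 1), (0, 1)]
        base = [I + step[0], J + step[1], K + step[2]]
        fids = []
        for (da, db) in cyc:
            off = [base[0].copy(), base[1].copy(), base[2].copy()]
            off[a1] = off[a1] + da
            off[a2] = off[a2] + db
            fids.append(corner_id(off[0], off[1], off[2]))
        for (e0, e1) in _FACE_EDGES:
            tet_list.append(np.stack([c1, c2, fids[e0], fids[e1]], axis=1))
    tets = np.vstack(tet_list)

    # keep tets whose centroid samples foreground
    centroids = verts[tets].mean(axis=1)
    keep = _sample_labels(mask, centroids) > 0
    tets = tets[keep]
    if len(tets) == 0:
        raise EmptyMeshError(
            f"no tetrahedron centroid falls in the mask at cell size {cell_size}"
        )

    # positive orientation
    vols = tet_volumes(verts, tets)
    flip = vols < 0
    tets[flip, 2], tets[flip, 3] = tets[flip, 3].copy(), tets[flip, 2].copy()

    # majority label over 4 vertices + centroid
    samples = np.concatenate(
        [verts[tets].reshape(-1, 3), verts[tets].mean(axis=1)], axis=0
    )
    lab = _sample_labels(mask, samples)
    vert_lab = lab[: 4 * len(tets)].reshape(len(tets), 4)
    cen_lab = lab[4 * len(tets):]
    all_lab = np.concatenate([vert_lab, cen_lab[:, None]], axis=1)  # (M, 5)
    labels = np.zeros(len(tets), dtype=np.int64)
    uniq = np.unique(all_lab)
    counts = np.stack([(all_lab == u).sum(axis=1) for u in uniq], axis=1)
    labels = uniq[np.argmax(counts, axis=1)]
    labels = np.where(labels == 0, cen_lab, labels)

    # compact vertices
    used, inv = np.unique(tets, return_inverse=True)
    mesh = TetMesh(
        vertices=verts[used],
        tets=inv.reshape(-1, 4),
        tet_labels=labels,
    )
    mesh.validate()
    return mesh


def dilate_labels(mask: LabelImage, margin_vox: int) -> LabelImage:
    """Binary-dilate the foreground by ``margin_vox`` voxels, filling new
    voxels with the nearest foreground label."""
    if margin_vox <= 0:
        return mask
    fg = mask.data > 0
    grown = ndimage.binary_dilation(fg, iterations=margin_vox)
    _, (ix, iy, iz) = ndimage.distance_transform_edt(~fg, return_indices=True)
    out = np.where(grown, mask.data[ix, iy, iz], 0).astype(mask.data.dtype)
    return LabelImage(data=out, spacing=mask.spacing, origin=mask.origin)


# ---------------------------------------------------------------------------
# Resection-element detection and removal
# ---------------------------------------------------------------------------


def _face_adjacency(mesh: TetMesh) -> tuple[np.ndarray, np.ndarray]:
    """Pairs (t1, t2) of tets sharing a triangular face."""
    faces = mesh.tets[:, [[1, 2, 3], [0, 2, 3], [0, 1, 3], [0, 1, 2]]]
    faces = np.sort(faces.reshape(-1, 3), axis=1)
    owner = np.repeat(np.arange(mesh.n_tets), 4)
    order = np.lexsort(faces.T)
    faces_s, owner_s = faces[order], owner[order]
    same = np.all(faces_s[1:] == faces_s[:-1], axis=1)
    return owner_s[:-1][same], owner_s[1:][same]


def detect_resection_elements(
    mesh: TetMesh,
    U: np.ndarray | None,
    intraop: Image3D,
    cfg: ResectionConfig,
) -> np.ndarray:
    """Collect the resection region as a maximal face-connected submesh
    of background tetrahedra.

    A tet is flagged when >= bg_fraction of its samples (4 vertices +
    centroid, displaced by the nodal field U) fall below the background
    threshold of the intra-operative image (samples outside the image
    count as background).  The first round seeds the result with the
    largest face-connected component of flagged tets; later rounds add
    flagged tets face-adjacent to the current set, until no addition or
    ``max_outer_iter`` rounds.  Returns sorted element indices (possibly
    empty).
    """
    if U is None:
        U = np.zeros((mesh.n_vertices, 3))
    U = np.asarray(U, dtype=float).reshape(-1, 3)

    thr = cfg.bg_threshold
    if thr is None:
        lo = intraop.world_to_index(mesh.vertices.min(axis=0))
        hi = intraop.world_to_index(mesh.vertices.max(axis=0))
        lo = np.clip(np.floor(lo).astype(int), 0, np.asarray(intraop.shape) - 1)
        hi = np.clip(np.ceil(hi).astype(int) + 1, 1, np.asarray(intraop.shape))
        sub = intraop.data[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        thr = float(threshold_otsu(np.asarray(sub, dtype=float)))

    disp_verts = mesh.vertices + U
    pv = disp_verts[mesh.tets]  # (M, 4, 3)
    samples = np.concatenate([pv.reshape(-1, 3), pv.mean(axis=1)], axis=0)
    idx = np.rint(intraop.world_to_index(samples)).astype(np.int64)
    shape = np.asarray(intraop.shape)
    inb = np.all((idx >= 0) & (idx < shape), axis=-1)
    bg = np.ones(len(samples), dtype=bool)  # outside the image = background
    ii = idx[inb]
    bg[inb] = intraop.data[ii[:, 0], ii[:, 1], ii[:, 2]] < thr
    M = mesh.n_tets
    vert_bg = bg[: 4 * M].reshape(M, 4)
    cen_bg = bg[4 * M:]
    frac = (vert_bg.sum(axis=1) + cen_bg) / 5.0
    flagged = frac >= cfg.bg_fraction
    if not np.any(flagged):
        return np.zeros(0, dtype=np.int64)

    t1, t2 = _face_adjacency(mesh)
    # components of the flagged subgraph
    e_mask = flagged[t1] & flagged[t2]
    fidx = np.flatnonzero(flagged)
    remap = -np.ones(M, dtype=np.int64)
    remap[fidx] = np.arange(len(fidx))
    g = coo_matrix(
        (np.ones(e_mask.sum()), (remap[t1[e_mask]], remap[t2[e_mask]])),
        shape=(len(fidx), len(fidx)),
    )
    ncomp, comp = connected_components(g, directed=False)
    sizes = np.bincount(comp, minlength=ncomp)
    seed_comp = int(np.argmax(sizes))
    in_rem = np.zeros(M, dtype=bool)
    in_rem[fidx[comp == seed_comp]] = True

    for _ in range(cfg.max_outer_iter - 1):
        fwd = in_rem[t1] & flagged[t2] & ~in_rem[t2]
        bwd = in_rem[t2] & flagged[t1] & ~in_rem[t1]
        add = np.unique(np.concatenate([t2[fwd], t1[bwd]]))
        if len(add) == 0:
            break
        in_rem[add] = True
    return np.flatnonzero(in_rem)


def remove_elements(
    mesh: TetMesh, elements: np.ndarray
) -> tuple[TetMesh, float]:
    """Drop the given elements, compacting unreferenced vertices.

    Returns the reduced mesh and the total removed volume (mm^3).
    Warns (does not fail) if the remaining mesh is disconnected.
    """
    elements = np.asarray(elements, dtype=np.int64)
    if elements.size and (
        elements.min() < 0 or elements.max() >= mesh.n_tets
    ):
        raise IndexError("element index out of range")
    keep = np.ones(mesh.n_tets, dtype=bool)
    keep[elements] = False
    removed_volume = float(np.abs(mesh.volumes()[~keep]).sum())
    tets = mesh.tets[keep]
    labels = mesh.tet_labels[keep]
    if len(tets) == 0:
        return TetMesh(
            vertices=np.zeros((0, 3)), tets=np.zeros((0, 4), dtype=np.int64),
            tet_labels=np.zeros(0, dtype=np.int64),
        ), removed_volume
    used, inv = np.unique(tets, return_inverse=True)
    out = TetMesh(
        vertices=mesh.vertices[used],
        tets=inv.reshape(-1, 4),
        tet_labels=labels,
    )
    t1, t2 = _face_adjacency(out)
    g = coo_matrix(
        (np.ones(len(t1)), (t1, t2)), shape=(out.n_tets, out.n_tets)
    )
    ncomp, comp = connected_components(g, directed=False)
    if ncomp > 1:
        sizes = np.bincount(comp, minlength=ncomp)
        warnings.warn(
            "element removal disconnected the mesh into components of "
            f"sizes {sorted(sizes.tolist(), reverse=True)}",
            RuntimeWarning,
        )
    return out, removed_volume


# ---------------------------------------------------------------------------
# Incremental adaptive registration (ANRR)
# ---------------------------------------------------------------------------


def adaptive_register(
    floating: Image3D,
    floating_labels: LabelImage,
    fixed: Image3D,
    cfg: AdaptiveConfig,
    rcfg: ResectionConfig | None = None,
    materials: MaterialTable | None = None,
) -> tuple[DenseField, Image3D, list[dict]]:
    """Incremental adaptive registration of floating toward fixed.

    Each iteration (i = 1..N_iter): mesh the current warped label image
    on the BCC lattice (or displace the previous mesh when remesh is
    off), block-match the warped floating image against the fixed
    image, detect and remove resection elements (when ``rcfg`` is
    given), run one robust registration pass, and compose the
    incremental field into the running total
    (u_total(x) = u_inc(x) + u_prev(x - u_inc(x))).

    Returns the composed dense field, the final warped floating image,
    and a per-iteration report.
    """
    materials = materials or MaterialTable()
    total = DenseField(
        data=np.zeros(fixed.shape + (3,)), spacing=fixed.spacing,
        origin=fixed.origin,
    )
    warped = floating
    warped_labels = floating_labels
    report: list[dict] = []
    prev_mesh: TetMesh | None = None
    prev_U: np.ndarray | None = None

    for it in range(1, cfg.N_iter + 1):
        try:
            if cfg.remesh or prev_mesh is None:
                mesh = bcc_mesh(
                    dilate_labels(warped_labels, cfg.mesh_dilation_vox),
                    cfg.cell_size,
                )
            else:
                mesh = TetMesh(
                    vertices=prev_mesh.vertices + prev_U,
                    tets=prev_mesh.tets.copy(),
                    tet_labels=prev_mesh.tet_labels.copy(),
                )
            entry: dict = {"iteration": it, "n_vertices": mesh.n_vertices,
                           "n_tets": mesh.n_tets}
            removed = np.zeros(0, dtype=np.int64)
            if rcfg is not None:
                removed = detect_resection_elements(mesh, None, fixed, rcfg)
                if len(removed):
                    mesh, vol = remove_elements(mesh, removed)
                    entry["removed_volume_mm3"] = vol
            entry["n_removed_elements"] = int(len(removed))

            result = register_images(
                warped, fixed, mesh, materials=materials,
                block_spec=cfg.block, solver_cfg=cfg.solver,
                mask=warped_labels, fraction=cfg.fraction,
                min_spacing=cfg.min_spacing,
                min_confidence=cfg.min_confidence,
            )
        except Exception as exc:
            raise RuntimeError(f"adaptive iteration {it} failed: {exc}") from exc

        total = compose_fields(result.field, total)
        warped = warp_image(floating, total, order=1)
        warped_labels = LabelImage(
            data=warp_image(
                Image3D(floating_labels.data, floating_labels.spacing,
                        floating_labels.origin),
                total, order=0,
            ).data,
            spacing=floating_labels.spacing,
            origin=floating_labels.origin,
        )
        entry["n_matches"] = len(result.matches)
        entry["n_matches_in_mesh"] = int(len(result.kept))
        entry["n_rejected"] = len(result.log["rejected_ids"])
        entry["max_increment_mm"] = float(
            np.linalg.norm(result.U, axis=1).max()
        )
        report.append(entry)
        prev_mesh, prev_U = result.mesh, result.U

    return total, warped, report
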