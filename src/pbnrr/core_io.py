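"""Domain types and file I/O for images, tetrahedral meshes, and fields.

Coordinate conventions
----------------------
Voxel indexing is 0-based and axis-aligned: ``world(i, j, k) = origin +
index * spacing``.  No direction-cosine (oblique) orientations are
supported; images carrying a non-identity direction matrix are rejected.
All displacements are expressed in world units (mm).

Formats: NIfTI-1 (.nii/.nii.gz) and NRRD (.nrrd/.nhdr) for scalar and
vector volumes, VTK legacy ASCII unstructured grids (tetrahedra only,
cell type 10) for meshes, with a ``label`` cell-data array.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import SimpleITK as sitk

__all__ = [
    "Image3D",
    "LabelImage",
    "TetMesh",
    "DenseField",
    "Material",
    "MaterialTable",
    "FormatError",
    "DimensionalityError",
    "UnsupportedCellError",
    "read_image",
    "write_image",
    "read_field",
    "write_field",
    "read_mesh",
    "write_mesh",
    "tet_volumes",
]

_IMAGE_SUFFIXES = (".nii", ".nii.gz", ".nrrd", ".nhdr")


class FormatError(ValueError):
    """File is not a readable instance of a supported format."""


class DimensionalityError(ValueError):
    """Image is not a 3-D scalar volume."""


class UnsupportedCellError(ValueError):
    """Mesh file contains non-tetrahedral cells."""


def _as_triple(x, name: str) -> tuple[float, float, float]:
    arr = np.asarray(x, dtype=float).reshape(-1)
    if arr.size != 3:
        raise ValueError(f"{name} must have 3 components, got {arr.size}")
    return (float(arr[0]), float(arr[1]), float(arr[2]))


@dataclass
class Image3D:
    """A 3-D scalar voxel grid with axis-aligned world geometry.

    ``data[i, j, k]`` is the intensity at world position
    ``origin + (i, j, k) * spacing`` (mm).
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise DimensionalityError(
                f"expected a 3-D array, got {self.data.ndim}-D"
            )
        self.spacing = _as_triple(self.spacing, "spacing")
        self.origin = _as_triple(self.origin, "origin")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def index_to_world(self, idx) -> np.ndarray:
        """World coordinates (mm) of (possibly fractional) voxel indices."""
        idx = np.asarray(idx, dtype=float)
        return np.asarray(self.origin) + idx * np.asarray(self.spacing)

    def world_to_index(self, xyz) -> np.ndarray:
        """Continuous voxel indices of world coordinates (mm)."""
        xyz = np.asarray(xyz, dtype=float)
        return (xyz - np.asarray(self.origin)) / np.asarray(self.spacing)

    def same_geometry(self, other: "Image3D", tol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
        )


@dataclass
class LabelImage(Image3D):
    """Integer tissue-label volume; 0 is background."""

    def __post_init__(self) -> None:
        super().__post_init__()
        if not np.issubdtype(self.data.dtype, np.integer):
            if not np.all(self.data == np.round(self.data)):
                raise ValueError("label image must hold integer values")
            self.data = self.data.astype(np.int32)
        if self.data.min() < 0:
            raise ValueError("label values must be >= 0")


@dataclass
class DenseField:
    """Dense displacement field: one 3-vector (mm) per voxel of a
    reference grid, stored as an (nx, ny, nz, 3) array."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4 or self.data.shape[3] != 3:
            raise DimensionalityError(
                f"expected an (nx, ny, nz, 3) array, got shape {self.data.shape}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("displacement field contains non-finite values")
        self.spacing = _as_triple(self.spacing, "spacing")
        self.origin = _as_triple(self.origin, "origin")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]  # type: ignore[return-value]

    def same_geometry(self, img: Image3D, tol: float = 1e-6) -> bool:
        return (
            self.shape == img.shape
            and np.allclose(self.spacing, img.spacing, atol=tol)
            and np.allclose(self.origin, img.origin, atol=tol)
        )


def tet_volumes(vertices: np.ndarray, tets: np.ndarray) -> np.ndarray:
    """Signed volumes (mm^3) of tetrahedra under the v1-v0, v2-v0, v3-v0
    determinant convention."""
    p = vertices[tets]
    a, b, c = p[:, 1] - p[:, 0], p[:, 2] - p[:, 0], p[:, 3] - p[:, 0]
    return np.einsum("ij,ij->i", a, np.cross(b, c)) / 6.0


@dataclass
class TetMesh:
    """Tetrahedral mesh in world coordinates with per-element tissue labels."""

    vertices: np.ndarray  # (N, 3) mm
    tets: np.ndarray  # (M, 4) vertex indices
    tet_labels: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.vertices = np.atleast_2d(np.asarray(self.vertices, dtype=float))
        self.tets = np.atleast_2d(np.asarray(self.tets, dtype=np.int64))
        if self.tet_labels is None:
            self.tet_labels = np.ones(len(self.tets), dtype=np.int64)
        self.tet_labels = np.asarray(self.tet_labels, dtype=np.int64).reshape(-1)
        if self.vertices.shape[1] != 3:
            raise ValueError("vertices must be (N, 3)")
        if self.tets.size and self.tets.shape[1] != 4:
            raise ValueError("tets must be (M, 4)")
        if len(self.tet_labels) != len(self.tets):
            raise ValueError("one label per tetrahedron required")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_tets(self) -> int:
        return len(self.tets)

    def volumes(self) -> np.ndarray:
        return tet_volumes(self.vertices, self.tets)

    def centroids(self) -> np.ndarray:
        return self.vertices[self.tets].mean(axis=1)

    def validate(self, dup_tol: float = 1e-9) -> None:
        """Check mesh invariants; raise ValueError on violation."""
        if self.tets.size:
            if self.tets.min() < 0 or self.tets.max() >= self.n_vertices:
                raise ValueError("tet vertex index out of range")
            vols = self.volumes()
            if np.any(vols <= 0):
                bad = int(np.argmin(vols))
                raise ValueError(
                    f"non-positive tet volume at element {bad}: {vols[bad]:g}"
                )
        if self.n_vertices > 1:
            order = np.lexsort(self.vertices.T)
            diffs = np.diff(self.vertices[order], axis=0)
            if np.any(np.all(np.abs(diffs) <= dup_tol, axis=1)):
                raise ValueError("duplicate vertices within tolerance")


@dataclass(frozen=True)
class Material:
    """Isotropic linear-elastic material: Young's modulus E (Pa) and
    Poisson ratio nu (dimensionless, -1 < nu < 0.5)."""

    E: float
    nu: float

    def __post_init__(self) -> None:
        if self.E <= 0:
            raise ValueError(f"elastic modulus must be > 0, got {self.E}")
        if not (-1.0 < self.nu < 0.5):
            raise ValueError(f"Poisson ratio must be in (-1, 0.5), got {self.nu}")


class MaterialTable(dict):
    """Tissue label -> Material.  Default table: brain parenchyma
    (label 1) E=3000 Pa, nu=0.45; tumor (label 2) E=9000 Pa, nu=0.45.
    These are this package's defaults, configurable per run."""

    def __init__(self, mapping: Mapping[int, Material | tuple] | None = None):
        super().__init__()
        if mapping is None:
            mapping = {1: Material(3000.0, 0.45), 2: Material(9000.0, 0.45)}
        for label, mat in mapping.items():
            if not isinstance(mat, Material):
                mat = Material(*mat)
            self[int(label)] = mat

    def lookup(self, label: int) -> Material:
        try:
            return self[int(label)]
        except KeyError:
            raise KeyError(
                f"no material defined for tissue label {label}"
            ) from None


# ---------------------------------------------------------------------------
# Image I/O (SimpleITK backend)
# ---------------------------------------------------------------------------


def _check_suffix(path: Path) -> None:
    name = path.name.lower()
    if not any(name.endswith(s) for s in _IMAGE_SUFFIXES):
        raise FormatError(
            f"unsupported image format for {path} "
            f"(expected one of {_IMAGE_SUFFIXES})"
        )


def _check_direction(img: sitk.Image, path) -> None:
    d = np.asarray(img.GetDirection()).reshape(3, 3)
    if not np.allclose(d, np.eye(3), atol=1e-6):
        raise FormatError(
            f"{path}: oblique (direction-cosine) orientations are not supported"
        )


def read_image(path, labels: bool = False) -> Image3D:
    """Read a NIfTI or NRRD scalar volume.

    With ``labels=True`` the result is a :class:`LabelImage`.
    """
    path = Path(path)
    _check_suffix(path)
    try:
        img = sitk.ReadImage(str(path))
    except RuntimeError as exc:
        raise FormatError(f"cannot read image {path}: {exc}") from exc
    if img.GetDimension() != 3:
        raise DimensionalityError(
            f"{path}: expected a 3-D volume, got {img.GetDimension()}-D"
        )
    if img.GetNumberOfComponentsPerPixel() != 1:
        raise DimensionalityError(f"{path}: expected a scalar volume")
    _check_direction(img, path)
    data = np.transpose(sitk.GetArrayFromImage(img), (2, 1, 0))
    cls = LabelImage if labels else Image3D
    return cls(data=data, spacing=img.GetSpacing(), origin=img.GetOrigin())


def write_image(img: Image3D, path) -> None:
    """Write a scalar volume as NIfTI or NRRD, preserving dtype."""
    path = Path(path)
    _check_suffix(path)
    out = sitk.GetImageFromArray(np.ascontiguousarray(np.transpose(img.data, (2, 1, 0))))
    out.SetSpacing(img.spacing)
    out.SetOrigin(img.origin)
    try:
        sitk.WriteImage(out, str(path))
    except RuntimeError as exc:
        raise IOError(f"cannot write image {path}: {exc}") from exc


def read_field(path) -> DenseField:
    """Read a dense displacement field (3-component vector volume)."""
    path = Path(path)
    _check_suffix(path)
    try:
        img = sitk.ReadImage(str(path))
    except RuntimeError as exc:
        raise FormatError(f"cannot read field {path}: {exc}") from exc
    if img.GetDimension() != 3 or img.GetNumberOfComponentsPerPixel() != 3:
        raise DimensionalityError(
            f"{path}: expected a 3-D volume with 3-vector voxels"
        )
    _check_direction(img, path)
    arr = sitk.GetArrayFromImage(img)  # (z, y, x, 3)
    data = np.transpose(arr, (2, 1, 0, 3))
    return DenseField(data=data, spacing=img.GetSpacing(), origin=img.GetOrigin())


def write_field(fld: DenseField, path) -> None:
    path = Path(path)
    _check_suffix(path)
    arr = np.ascontiguousarray(np.transpose(fld.data, (2, 1, 0, 3)))
    out = sitk.GetImageFromArray(arr, isVector=True)
    out.SetSpacing(fld.spacing)
    out.SetOrigin(fld.origin)
    try:
        sitk.WriteImage(out, str(path))
    except RuntimeError as exc:
        raise IOError(f"cannot write field {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# VTK legacy ASCII unstructured-grid mesh I/O
# ---------------------------------------------------------------------------

VTK_TET = 10


def write_mesh(mesh: TetMesh, path) -> None:
    """Write a tetrahedral mesh as a VTK legacy ASCII unstructured grid
    with a ``label`` cell-data array."""
    path = Path(path)
    lines = [
        "# vtk DataFile Version 3.0",
        "tetrahedral mesh",
        "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {mesh.n_vertices} double",
    ]
    lines += [" ".join(f"{c:.17g}" for c in v) for v in mesh.vertices]
    lines.append(f"CELLS {mesh.n_tets} {5 * mesh.n_tets}")
    lines += ["4 " + " ".join(str(i) for i in t) for t in mesh.tets]
    lines.append(f"CELL_TYPES {mesh.n_tets}")
    lines += [str(VTK_TET)] * mesh.n_tets
    lines.append(f"CELL_DATA {mesh.n_tets}")
    lines.append("SCALARS label int 1")
    lines.append("LOOKUP_TABLE default")
    lines += [str(int(l)) for l in mesh.tet_labels]
    path.write_text("\n".join(lines) + "\n")


def _read_tokens(text: str) -> list[str]:
    return text.split()


def read_mesh(path) -> TetMesh:
    """Read a tetrahedra-only VTK legacy ASCII unstructured grid."""
    path = Path(path)
    try:
        text = path.read_text()
    except OSError as exc:
        raise FormatError(f"cannot read mesh {path}: {exc}") from exc
    lines = text.splitlines()
    if len(lines) < 5 or "UNSTRUCTURED_GRID" not in text:
        raise FormatError(f"{path} is not a VTK legacy unstructured grid")

    tok = _read_tokens("\n".join(lines[4:]))
    pos = 0

    def expect(keyword: str) -> None:
        nonlocal pos
        while pos < len(tok) and tok[pos].upper() != keyword:
            pos += 1
        if pos >= len(tok):
            raise FormatError(f"{path}: missing {keyword} section")
        pos += 1

    try:
        # POINTS
        expect("POINTS")
        n_pts = int(tok[pos]); pos += 2  # skip dtype
        verts = np.array(tok[pos : pos + 3 * n_pts], dtype=float).reshape(n_pts, 3)
        pos += 3 * n_pts
        # CELLS
        expect("CELLS")
        n_cells = int(tok[pos]); total = int(tok[pos + 1]); pos += 2
        cell_tok = np.array(tok[pos : pos + total], dtype=np.int64)
        pos += total
        # CELL_TYPES
        expect("CELL_TYPES")
        n_types = int(tok[pos]); pos += 1
        ctypes = np.array(tok[pos : pos + n_types], dtype=np.int64)
        pos += n_types
    except (ValueError, IndexError) as exc:
        raise FormatError(f"{path}: malformed VTK file: {exc}") from exc

    if np.any(ctypes != VTK_TET):
        bad = int(ctypes[ctypes != VTK_TET][0])
        raise UnsupportedCellError(
            f"{path}: unsupported cell type {bad}; only tetrahedra (10) allowed"
        )
    if total != 5 * n_cells or np.any(cell_tok[::5] != 4):
        raise UnsupportedCellError(f"{path}: non-tetrahedral cell connectivity")
    tets = cell_tok.reshape(n_cells, 5)[:, 1:]

    labels = None
    rest = tok[pos:]
    for i, t in enumerate(rest):
        if t.upper() == "SCALARS" and i + 1 < len(rest) and rest[i + 1] == "label":
            start = i + 6  # SCALARS label int 1 LOOKUP_TABLE default <values>
            labels = np.array(rest[start : start + n_cells], dtype=np.int64)
            break
    return TetMesh(vertices=verts, tets=tets, tet_labels=labels)
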