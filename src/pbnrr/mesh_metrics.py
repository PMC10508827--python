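"""Registration-point-driven mesh sizing metrics.

Isotropic sizing sets the local spacing at each mesh vertex to the
distance of its k-th closest registration point, so an ideally sized
mesh puts about k points in every vertex cell complex.  The anisotropic
variant replaces the sphere with the minimum-volume enclosing ellipsoid
(Khachiyan's algorithm) of the k nearest points together with their
reflections through the vertex — the symmetry of the reflected set
forces the ellipsoid center onto the vertex — and inflates all
ellipsoids by a common constant a (semi-axes scaled by a, i.e. the
metric tensor divided by a^2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "Ellipsoid",
    "MetricField",
    "sizing_isotropic",
    "mvee",
    "anisotropic_ellipsoid",
    "metric_anisotropic",
    "export_metric",
    "read_metric",
]


@dataclass
class Ellipsoid:
    """Ellipsoid {x : (x - center)ᵀ M (x - center) <= 1} with SPD M."""

    center: np.ndarray
    M: np.ndarray
    degenerate: bool = False

    @property
    def volume(self) -> float:
        return (4.0 * np.pi / 3.0) / float(np.sqrt(np.linalg.det(self.M)))


@dataclass
class MetricField:
    """Per-vertex sizing: scalar spacing (mm) or 3x3 SPD tensor."""

    values: np.ndarray  # (N,) or (N, 3, 3)

    @property
    def kind(self) -> str:
        return "tensor" if self.values.ndim == 3 else "scalar"

    def __len__(self) -> int:
        return len(self.values)


def sizing_isotropic(
    vertices: np.ndarray,
    points: np.ndarray,
    k: int = 5,
    min_spacing: float = 0.5,
) -> MetricField:
    """spacing(v) = distance from v to its k-th nearest registration
    point, clamped below by ``min_spacing``."""
    vertices = np.atleast_2d(np.asarray(vertices, dtype=float))
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if k < 1 or len(points) < k:
        raise ValueError(f"need at least k={k} registration points, "
                         f"got {len(points)}")
    d, _ = cKDTree(points).query(vertices, k=k)
    d = np.atleast_2d(d)
    return MetricField(values=np.maximum(d[:, -1], min_spacing))


def mvee(
    points: np.ndarray,
    tol: float = 1e-6,
    max_iter: int = 20_000,
    jitter: float = 1e-6,
) -> Ellipsoid:
    """Minimum-volume enclosing ellipsoid via Khachiyan's
    barycentric-coordinate-descent algorithm.

    Every input point satisfies (x - c)ᵀ M (x - c) <= 1 + tol.
    Degenerate (coplanar/collinear) inputs are regularized by adding
    ``jitter * bbox_diagonal`` isotropically to the moment matrix; the
    result is flagged ``degenerate``.
    """
    P = np.atleast_2d(np.asarray(points, dtype=float))
    n, d = P.shape
    if n < d + 1:
        raise ValueError(f"need at least {d + 1} points, got {n}")
    Q = np.vstack([P.T, np.ones(n)])  # (d+1, n)
    u = np.full(n, 1.0 / n)
    err = np.inf
    for _ in range(max_iter):
        X = Q @ np.diag(u) @ Q.T
        try:
            Xinv = np.linalg.inv(X)
        except np.linalg.LinAlgError:
            break
        m = np.einsum("ij,jk,ki->i", Q.T, Xinv, Q)
        j = int(np.argmax(m))
        mj = m[j]
        err = mj / (d + 1) - 1.0
        if err <= tol:
            break
        step = (mj - d - 1) / ((d + 1) * (mj - 1))
        u *= 1 - step
        u[j] += step

    c = P.T @ u
    cov = P.T @ np.diag(u) @ P - np.outer(c, c)
    degenerate = False
    bbox = float(np.linalg.norm(P.max(axis=0) - P.min(axis=0)))
    eigvals = np.linalg.eigvalsh(cov)
    if eigvals[0] <= 1e-12 * max(eigvals[-1], 1.0):
        cov = cov + (jitter * max(bbox, 1.0)) ** 2 * np.eye(d)
        degenerate = True
    M = np.linalg.inv(cov) / d
    M = 0.5 * (M + M.T)
    # final rounding: rescale so every input point is contained even when
    # the first-order ascent stopped at the iteration cap
    q = np.einsum("ni,ij,nj->n", P - c, M, P - c)
    qmax = float(q.max())
    if qmax > 1.0:
        M = M / qmax
    return Ellipsoid(center=c, M=M, degenerate=degenerate)


def anisotropic_ellipsoid(
    vertex: np.ndarray,
    points: np.ndarray,
    k: int = 5,
    a: float = 1.2,
    tol: float = 1e-6,
    min_spacing: float = 0.5,
) -> Ellipsoid:
    """Sizing ellipsoid at a mesh vertex, centered exactly on it.

    The k nearest registration points and their reflections 2v - p
    through the vertex feed the MVEE; the symmetry of that cloud puts
    the optimum at the vertex, so the center is set to v by
    construction and containment is enforced about v.  Inflation by
    a >= 1 scales semi-axes by a (M /= a^2).  If the k points all
    coincide with the vertex, falls back to the isotropic clamp
    ellipsoid of radius ``min_spacing``.
    """
    if a < 1.0:
        raise ValueError("inflation constant must be >= 1")
    v = np.asarray(vertex, dtype=float).reshape(3)
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if len(points) < k:
        raise ValueError(f"need at least k={k} registration points")
    _, idx = cKDTree(points).query(v, k=k)
    near = points[np.atleast_1d(idx)]
    if np.all(np.linalg.norm(near - v, axis=1) < 1e-12):
        return Ellipsoid(center=v.copy(), M=np.eye(3) / min_spacing**2,
                         degenerate=True)
    cloud = np.vstack([near, 2.0 * v - near])
    ell = mvee(cloud, tol=tol)
    M = ell.M
    q = np.einsum("ni,ij,nj->n", cloud - v, M, cloud - v)
    qmax = float(q.max())
    if qmax > 1.0:  # re-enforce containment about the exact center
        M = M / qmax
    return Ellipsoid(center=v.copy(), M=M / a**2, degenerate=ell.degenerate)


def metric_anisotropic(
    vertex: np.ndarray,
    points: np.ndarray,
    k: int = 5,
    a: float = 1.2,
    tol: float = 1e-6,
    min_spacing: float = 0.5,
) -> np.ndarray:
    """Anisotropic sizing tensor at a mesh vertex (see
    :func:`anisotropic_ellipsoid`)."""
    return anisotropic_ellipsoid(vertex, points, k=k, a=a, tol=tol,
                                 min_spacing=min_spacing).M


_TENSOR_ORDER = "xx yy zz xy yz xz"


def export_metric(field: MetricField, path) -> None:
    """Write the metric as VTK legacy point data: a scalar ``spacing``
    array or a 6-component symmetric ``metric`` array (xx yy zz xy yz
    xz ordering)."""
    if len(field) == 0:
        raise ValueError("cannot export an empty metric field")
    lines = [
        "# vtk DataFile Version 3.0",
        f"mesh sizing field ({field.kind})",
        "ASCII",
        "DATASET POLYDATA",
        f"POINT_DATA {len(field)}",
    ]
    if field.kind == "scalar":
        lines.append("SCALARS spacing double 1")
        lines.append("LOOKUP_TABLE default")
        lines += [f"{v:.17g}" for v in field.values]
    else:
        lines.append(f"FIELD metric_field 1")
        lines.append(f"metric 6 {len(field)} double")
        for T in field.values:
            comps = (T[0, 0], T[1, 1], T[2, 2], T[0, 1], T[1, 2], T[0, 2])
            lines.append(" ".join(f"{c:.17g}" for c in comps))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_metric(path) -> MetricField:
    """Read back a metric written by :func:`export_metric`."""
    tok = open(path).read().split()
    if "SCALARS" in tok:
        i = tok.index("POINT_DATA")
        n = int(tok[i + 1])
        j = tok.index("default") + 1
        return MetricField(values=np.array(tok[j:j + n], dtype=float))
    i = tok.index("FIELD")
    # layout: FIELD <name> 1 / metric 6 <n> double / values...
    n = int(tok[i + 5])
    vals = np.array(tok[i + 7:i + 7 + 6 * n], dtype=float).reshape(n, 6)
    T = np.zeros((n, 3, 3))
    T[:, 0, 0], T[:, 1, 1], T[:, 2, 2] = vals[:, 0], vals[:, 1], vals[:, 2]
    T[:, 0, 1] = T[:, 1, 0] = vals[:, 3]
    T[:, 1, 2] = T[:, 2, 1] = vals[:, 4]
    T[:, 0, 2] = T[:, 2, 0] = vals[:, 5]
    return MetricField(values=T)
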