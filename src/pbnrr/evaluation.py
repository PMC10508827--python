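"""Registration evaluation: Hausdorff distance between point sets and
Canny-edge point extraction.

The Hausdorff distance H(A, B) = max[h(A, B), h(B, A)] with directed
h(A, B) = max_a min_b ||a - b|| measures the degree of mismatch between
two point sets; the untrimmed (100%) variant is the default, with an
optional percentile for the trimmed variant used in earlier work.

Edge point sets are extracted by full-volume 3-D Canny detection
(Gaussian smoothing, gradient magnitude, non-maximum suppression along
the gradient, hysteresis thresholding).  This evaluation is a relative
comparison instrument between registration runs, not a clinical
accuracy measure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .core_io import DenseField, Image3D
from .robust_solver import sample_field

__all__ = [
    "PointSet",
    "hausdorff",
    "canny_points",
    "evaluate_registration",
    "landmark_errors",
]


@dataclass
class PointSet:
    """World-coordinate (mm) point set with extraction provenance."""

    points: np.ndarray  # (n, 3)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.size == 0:
            self.points = self.points.reshape(0, 3)
        if not np.all(np.isfinite(self.points)):
            raise ValueError("point set contains non-finite coordinates")

    def __len__(self) -> int:
        return len(self.points)


def _as_points(x) -> np.ndarray:
    if isinstance(x, PointSet):
        return x.points
    return np.atleast_2d(np.asarray(x, dtype=float))


def hausdorff(A, B, percentile: float = 100.0) -> float:
    """Hausdorff distance (mm) between two non-empty point sets.

    ``percentile`` < 100 gives the trimmed variant (e.g. 95% HD): the
    directed distances become the given percentile of the min-distance
    distributions instead of their maximum.
    """
    a = _as_points(A)
    b = _as_points(B)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("Hausdorff distance requires non-empty point sets")
    d_ab, _ = cKDTree(b).query(a)
    d_ba, _ = cKDTree(a).query(b)
    if percentile >= 100.0:
        return float(max(d_ab.max(), d_ba.max()))
    return float(max(np.percentile(d_ab, percentile),
                     np.percentile(d_ba, percentile)))


def canny_points(
    img: Image3D,
    low: float = 0.2,
    high: float = 0.4,
    sigma: float = 1.0,
) -> PointSet:
    """3-D Canny edge voxels as world-coordinate points.

    ``low``/``high`` are hysteresis thresholds as fractions of the
    maximum gradient magnitude; ``sigma`` is the Gaussian smoothing
    scale in mm.  A constant image yields an empty set.
    """
    if not (0.0 < low <= high):
        raise ValueError("thresholds must satisfy high >= low > 0")
    data = np.asarray(img.data, dtype=float)
    spacing = np.asarray(img.spacing)
    sm = ndimage.gaussian_filter(data, sigma=sigma / spacing)
    grads = np.gradient(sm, *spacing)
    mag = np.sqrt(sum(g * g for g in grads))
    mmax = float(mag.max())
    if mmax == 0.0:
        return PointSet(points=np.zeros((0, 3)),
                        provenance={"low": low, "high": high, "sigma": sigma})

    # non-maximum suppression along the gradient direction (voxel space)
    with np.errstate(invalid="ignore", divide="ignore"):
        dirs = np.stack([g / spacing[i] for i, g in enumerate(grads)], axis=0)
        norm = np.sqrt((dirs**2).sum(axis=0))
        unit = np.where(norm > 0, dirs / np.maximum(norm, 1e-30), 0.0)
    base = np.stack(
        np.meshgrid(*[np.arange(s, dtype=float) for s in img.shape],
                    indexing="ij"),
        axis=0,
    )
    fwd = ndimage.map_coordinates(mag, base + unit, order=1,
                                  mode="constant", cval=0.0, prefilter=False)
    bwd = ndimage.map_coordinates(mag, base - unit, order=1,
                                  mode="constant", cval=0.0, prefilter=False)
    nms = np.where((mag >= fwd) & (mag >= bwd), mag, 0.0)

    strong = nms >= high * mmax
    weak = nms >= low * mmax
    lab, nlab = ndimage.label(weak, structure=np.ones((3, 3, 3), dtype=int))
    keep = np.zeros(nlab + 1, dtype=bool)
    keep[np.unique(lab[strong])] = True
    keep[0] = False
    edges = keep[lab]
    pts = img.index_to_world(np.argwhere(edges))
    return PointSet(
        points=pts,
        provenance={"low": low, "high": high, "sigma": sigma,
                    "threshold_abs": (low * mmax, high * mmax)},
    )


def evaluate_registration(
    preop: Image3D,
    intraop: Image3D,
    fld: DenseField,
    low: float = 0.2,
    high: float = 0.4,
    sigma: float = 1.0,
    percentile: float = 100.0,
) -> dict:
    """Canny/Hausdorff evaluation of a registration field.

    Edge points of the pre-operative image are mapped p -> p + u(p)
    (trilinear sampling of the field) into intra-operative space and
    compared against the intra-operative edge set.  The report carries
    the HD, both directed distances, and the set sizes; it is a
    relative comparison between methods, not a clinical accuracy claim.
    """
    if not fld.same_geometry(preop):
        raise ValueError("field geometry differs from the pre-operative image")
    pre_pts = canny_points(preop, low=low, high=high, sigma=sigma)
    intra_pts = canny_points(intraop, low=low, high=high, sigma=sigma)
    if len(pre_pts) == 0:
        raise ValueError("empty edge set on the pre-operative side")
    if len(intra_pts) == 0:
        raise ValueError("empty edge set on the intra-operative side")
    moved = pre_pts.points + sample_field(fld, pre_pts.points)
    d_ab, _ = cKDTree(intra_pts.points).query(moved)
    d_ba, _ = cKDTree(moved).query(intra_pts.points)
    if percentile >= 100.0:
        h_ab, h_ba = float(d_ab.max()), float(d_ba.max())
    else:
        h_ab = float(np.percentile(d_ab, percentile))
        h_ba = float(np.percentile(d_ba, percentile))
    return {
        "hausdorff_mm": max(h_ab, h_ba),
        "directed_pre_to_intra_mm": h_ab,
        "directed_intra_to_pre_mm": h_ba,
        "n_points_pre": len(pre_pts),
        "n_points_intra": len(intra_pts),
        "percentile": percentile,
        "note": "relative comparison instrument; not for clinical use",
    }


def landmark_errors(
    landmarks_float,
    landmarks_fixed,
    fld: DenseField,
) -> dict:
    """Per-landmark registration errors (mm) and summary statistics.

    error_i = ||(p_i + u(p_i)) - q_i|| for index-corresponding landmark
    pairs (p in floating space, q in fixed space).
    """
    p = _as_points(landmarks_float)
    q = _as_points(landmarks_fixed)
    if len(p) != len(q):
        raise ValueError("landmark sets must have equal length")
    moved = p + sample_field(fld, p)
    err = np.linalg.norm(moved - q, axis=1)
    return {
        "errors_mm": err,
        "min_mm": float(err.min()),
        "max_mm": float(err.max()),
        "mean_mm": float(err.mean()),
    }
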