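"""Feature-point selection and block matching.

Sparse displacements are estimated at high-variance feature points of
the floating (pre-operative) image by exhaustively searching, for each
point, all integer-voxel displacements within a window of the fixed
(intra-operative) image and keeping the one that maximizes normalized
cross-correlation (NCC).  The per-point cost is proportional to the
block size times the search-window size; an instrumentation counter
records the number of NCC evaluations so the cost bound is testable.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import ndimage

from .core_io import Image3D, LabelImage

__all__ = [
    "BlockSpec",
    "Match",
    "MatchSet",
    "NccValue",
    "select_feature_points",
    "ncc",
    "block_match",
]


@dataclass(frozen=True)
class BlockSpec:
    """Half-extents, in voxels, of the matching block B and the
    displacement search window W (per axis)."""

    B: tuple[int, int, int] = (3, 3, 3)
    W: tuple[int, int, int] = (5, 5, 5)

    def __post_init__(self) -> None:
        for name, ext in (("B", self.B), ("W", self.W)):
            if len(ext) != 3 or any(int(e) != e or e < 0 for e in ext):
                raise ValueError(f"{name} must be 3 non-negative integers")
        if min(self.B) < 1:
            raise ValueError("block half-extent must be >= 1 on every axis")

    @property
    def block_shape(self) -> tuple[int, int, int]:
        return tuple(2 * b + 1 for b in self.B)  # type: ignore[return-value]

    @property
    def n_candidates(self) -> int:
        """Number of integer displacements searched per point."""
        return int(np.prod([2 * w + 1 for w in self.W]))


class NccValue(NamedTuple):
    """NCC result; ``defined`` is False when either block has zero
    variance (the value is then the 0 sentinel)."""

    value: float
    defined: bool


@dataclass(frozen=True)
class Match:
    point: tuple[int, int, int]  # voxel index of block center (floating)
    displacement: np.ndarray  # (3,) mm
    confidence: float  # NCC in [-1, 1]
    weight_tensor: np.ndarray  # (3, 3) SPD contribution to S


@dataclass
class MatchSet:
    """Block-matching result: points, displacements (mm), confidences,
    and provenance (spec, geometry, NCC evaluation counts)."""

    points: np.ndarray  # (n, 3) int voxel indices
    displacements: np.ndarray  # (n, 3) mm
    confidences: np.ndarray  # (n,)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=np.int64))
        self.displacements = np.atleast_2d(np.asarray(self.displacements, dtype=float))
        self.confidences = np.asarray(self.confidences, dtype=float).reshape(-1)
        if self.points.size == 0:
            self.points = self.points.reshape(0, 3)
            self.displacements = self.displacements.reshape(0, 3)

    def __len__(self) -> int:
        return len(self.confidences)

    def __getitem__(self, k: int) -> Match:
        return Match(
            point=tuple(self.points[k]),
            displacement=self.displacements[k].copy(),
            confidence=float(self.confidences[k]),
            weight_tensor=self.weight_tensors()[k],
        )

    def weight_tensors(self) -> np.ndarray:
        """(n, 3, 3) per-match SPD weights: max(c, 0)^2 * I."""
        w = np.maximum(self.confidences, 0.0) ** 2
        return w[:, None, None] * np.eye(3)[None]

    def world_points(self, img: Image3D) -> np.ndarray:
        return img.index_to_world(self.points)

    def subset(self, idx) -> "MatchSet":
        return MatchSet(
            points=self.points[idx],
            displacements=self.displacements[idx],
            confidences=self.confidences[idx],
            provenance=dict(self.provenance),
        )

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            wr = csv.writer(fh)
            wr.writerow(["i", "j", "k", "dx_mm", "dy_mm", "dz_mm", "confidence"])
            for p, d, c in zip(self.points, self.displacements, self.confidences):
                wr.writerow([*map(int, p), *map(float, d), float(c)])

    @classmethod
    def from_csv(cls, path) -> "MatchSet":
        rows = list(csv.reader(open(path)))[1:]
        arr = np.array(rows, dtype=float) if rows else np.zeros((0, 7))
        return cls(
            points=arr[:, :3].astype(np.int64),
            displacements=arr[:, 3:6],
            confidences=arr[:, 6],
        )


def _block_variance_map(data: np.ndarray, block_shape) -> np.ndarray:
    """Per-voxel sample variance of the block centered at each voxel."""
    x = data.astype(np.float64)
    n = float(np.prod(block_shape))
    mean = ndimage.uniform_filter(x, size=block_shape, mode="constant")
    mean_sq = ndimage.uniform_filter(x * x, size=block_shape, mode="constant")
    # population variance -> sample variance; clip negative rounding noise
    var = np.maximum(mean_sq - mean * mean, 0.0)
    return var * n / max(n - 1.0, 1.0)


def select_feature_points(
    img: Image3D,
    spec: BlockSpec,
    fraction: float = 0.05,
    mask: LabelImage | None = None,
    min_spacing: float = 0.0,
    margin: tuple[int, int, int] | None = None,
    min_variance: float | None = None,
) -> np.ndarray:
    """Select block centers with the highest intensity variance.

    Candidates are voxels whose block fits in the image (at least
    ``margin`` — default B — from the border), lie in ``mask > 0`` if a
    mask is given, and have block variance > 0 (or >= ``min_variance``).
    The top ``fraction`` by variance are kept, then greedily thinned so
    no two selected centers are closer than ``min_spacing`` voxels
    (higher variance wins).

    Returns an (n, 3) array of voxel indices.  Raises ValueError when no
    candidate block fits in the image.
    """
    if not (0.0 < fraction <= 1.0):
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    if margin is None:
        margin = spec.B
    shape = np.asarray(img.shape)
    lo = np.asarray(margin, dtype=int)
    hi = shape - lo
    if np.any(hi <= lo):
        raise ValueError("no candidate block fits inside the image")

    var = _block_variance_map(img.data, spec.block_shape)
    valid = np.zeros(img.shape, dtype=bool)
    valid[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = True
    if mask is not None:
        valid &= mask.data > 0
    if min_variance is not None:
        valid &= var >= min_variance
    valid &= var > 0.0

    idx = np.argwhere(valid)
    if len(idx) == 0:
        return np.zeros((0, 3), dtype=np.int64)
    v = var[valid]
    order = np.argsort(-v, kind="stable")
    n_keep = max(1, int(np.ceil(fraction * len(idx))))
    cand = idx[order[:n_keep]]

    if min_spacing <= 0:
        return cand
    kept: list[np.ndarray] = []
    # greedy thinning on a coarse spatial hash
    cell = max(min_spacing, 1.0)
    buckets: dict[tuple[int, int, int], list[np.ndarray]] = {}
    ms2 = min_spacing * min_spacing
    for p in cand:
        key = tuple((p // cell).astype(int))
        ok = True
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                for dk in (-1, 0, 1):
                    for q in buckets.get((key[0] + di, key[1] + dj, key[2] + dk), ()):
                        if float(np.sum((p - q) ** 2)) < ms2:
                            ok = False
                            break
                    if not ok:
                        break
                if not ok:
                    break
            if not ok:
                break
        if ok:
            kept.append(p)
            buckets.setdefault(key, []).append(p)
    return np.array(kept, dtype=np.int64).reshape(-1, 3)


def ncc(a: np.ndarray, b: np.ndarray) -> NccValue:
    """Normalized cross-correlation of two equally shaped blocks.

    Returns sum((a - a_mean)(b - b_mean)) / sqrt(var_a * var_b) in
    [-1, 1], or the 0 sentinel with ``defined=False`` when either block
    has zero variance.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"block shapes differ: {a.shape} vs {b.shape}")
    if a.size < 2:
        raise ValueError("blocks must have at least 2 voxels")
    da = a - a.mean()
    db = b - b.mean()
    va = float(np.sum(da * da))
    vb = float(np.sum(db * db))
    if va == 0.0 or vb == 0.0:
        return NccValue(0.0, False)
    val = float(np.sum(da * db) / np.sqrt(va * vb))
    return NccValue(min(1.0, max(-1.0, val)), True)


def block_match(
    floating: Image3D,
    fixed: Image3D,
    points: Sequence | np.ndarray,
    spec: BlockSpec,
    min_confidence: float = 0.5,
) -> MatchSet:
    """Exhaustive integer-voxel block matching with NCC.

    For each feature point, every displacement d with |d_axis| <= W_axis
    is evaluated; the argmax-NCC displacement is converted to mm.  Ties
    are broken by smaller displacement L2 norm, then lexicographically
    on (dz, dy, dx).  Matches with undefined NCC or confidence below
    ``min_confidence`` are dropped.
    """
    if not floating.same_geometry(fixed):
        raise ValueError("floating and fixed images must share geometry")
    points = np.atleast_2d(np.asarray(points, dtype=np.int64))
    B = np.asarray(spec.B, dtype=int)
    W = np.asarray(spec.W, dtype=int)
    shape = np.asarray(floating.shape)
    if points.size and (
        np.any(points - B - W < 0) or np.any(points + B + W >= shape)
    ):
        raise ValueError("a point's block or search window exceeds the image")

    spacing = np.asarray(floating.spacing)
    block_shape = spec.block_shape
    n_block = int(np.prod(block_shape))
    win_counts = 2 * W + 1

    # displacement lattice, ordered (dx slow ... dz fast); mm norms for ties
    disp = np.stack(
        np.meshgrid(
            np.arange(-W[0], W[0] + 1),
            np.arange(-W[1], W[1] + 1),
            np.arange(-W[2], W[2] + 1),
            indexing="ij",
        ),
        axis=-1,
    ).reshape(-1, 3)
    disp_mm = disp * spacing
    disp_norm2 = np.sum(disp_mm * disp_mm, axis=1)
    # lexicographic (dz, dy, dx) rank for the final tie level
    lex_rank = np.lexsort((disp[:, 0], disp[:, 1], disp[:, 2]))
    lex_key = np.empty(len(disp), dtype=np.int64)
    lex_key[lex_rank] = np.arange(len(disp))

    ffloat = floating.data.astype(np.float64)
    ffix = fixed.data.astype(np.float64)

    out_pts, out_disp, out_conf = [], [], []
    n_evals = 0
    for p in points:
        a = ffloat[
            p[0] - B[0] : p[0] + B[0] + 1,
            p[1] - B[1] : p[1] + B[1] + 1,
            p[2] - B[2] : p[2] + B[2] + 1,
        ]
        da = a - a.mean()
        va = float(np.sum(da * da))
        n_evals += spec.n_candidates
        if va == 0.0:
            continue
        region = ffix[
            p[0] - B[0] - W[0] : p[0] + B[0] + W[0] + 1,
            p[1] - B[1] - W[1] : p[1] + B[1] + W[1] + 1,
            p[2] - B[2] - W[2] : p[2] + B[2] + W[2] + 1,
        ]
        wins = sliding_window_view(region, block_shape).reshape(-1, n_block)
        assert wins.shape[0] == spec.n_candidates
        means = wins.mean(axis=1, keepdims=True)
        dw = wins - means
        vb = np.einsum("ij,ij->i", dw, dw)
        cross = dw @ da.ravel()
        with np.errstate(divide="ignore", invalid="ignore"):
            c = cross / np.sqrt(va * vb)
        c[vb == 0.0] = -np.inf  # undefined candidates excluded
        best = float(np.max(c))
        if not np.isfinite(best):
            continue  # fixed window constant everywhere: undefined NCC
        ties = np.flatnonzero(c == best)
        k = ties[np.lexsort((lex_key[ties], disp_norm2[ties]))[0]]
        conf = min(1.0, max(-1.0, best))
        if conf < min_confidence:
            continue
        out_pts.append(p)
        out_disp.append(disp_mm[k])
        out_conf.append(conf)

    return MatchSet(
        points=np.array(out_pts, dtype=np.int64).reshape(-1, 3),
        displacements=np.array(out_disp, dtype=float).reshape(-1, 3),
        confidences=np.array(out_conf, dtype=float),
        provenance={
            "block": tuple(spec.B),
            "window": tuple(spec.W),
            "min_confidence": min_confidence,
            "spacing": tuple(floating.spacing),
            "origin": tuple(floating.origin),
            "n_points": int(len(points)),
            "ncc_evaluations": int(n_evals),
            "ncc_evaluations_per_point": spec.n_candidates,
        },
    )
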