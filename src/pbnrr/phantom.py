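"""Synthetic brain-shift phantoms.

Generates a textured, ellipsoidal "brain" with an embedded spherical
"tumor", a smooth ground-truth displacement field (sum of Gaussian
radial bumps, tapered to zero outside the brain), and a simulated
intra-operative image obtained by backward-warping the pre-operative
image by the truth field, optionally with a carved (zero-intensity)
resection cavity.  The texture is band-limited correlated noise so
normalized cross-correlation has a well-conditioned landscape; no
anatomical realism is claimed.

Determinism: the same spec (including seed) always produces
bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core_io import DenseField, Image3D, LabelImage
from .feature_matching import MatchSet
from .robust_solver import warp_image

__all__ = ["PhantomSpec", "Phantom", "make_phantom", "corrupt_matches"]


@dataclass(frozen=True)
class DeformCenter:
    center: tuple[float, float, float]  # mm
    radius: float  # mm
    direction: tuple[float, float, float]


@dataclass
class PhantomSpec:
    """Study conditions of a synthetic brain-shift experiment.

    Sizes and spacing are in voxels / mm; ``deform_max`` is the peak
    displacement magnitude in mm; ``texture_scale`` is the correlation
    length of the intensity texture in mm.  ``resection`` is an
    optional (center_mm, radius_mm) sphere carved (set to intensity 0)
    from the intra-operative image.
    """

    size: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    seed: int = 0
    texture_scale: float = 3.0
    texture_amplitude: float = 15.0
    deform_max: float = 4.0
    deform_centers: list[DeformCenter] | None = None
    resection: tuple[tuple[float, float, float], float] | None = None
    noise_sd: float = 0.0
    base_intensity: dict = field(
        default_factory=lambda: {0: 0.0, 1: 100.0, 2: 150.0}
    )

    def extent_mm(self) -> np.ndarray:
        return np.asarray(self.size) * np.asarray(self.spacing)


@dataclass
class Phantom:
    preop: Image3D
    labels: LabelImage
    truth: DenseField
    intraop: Image3D
    spec: PhantomSpec


def _default_centers(spec: PhantomSpec) -> list[DeformCenter]:
    ext = spec.extent_mm()
    c = ext / 2.0 + np.array([0.0, 0.08, 0.0]) * ext
    return [
        DeformCenter(
            center=tuple(c),
            radius=0.30 * float(ext.min()),
            direction=(0.5, 1.0, 0.3),
        )
    ]


def make_phantom(spec: PhantomSpec) -> Phantom:
    """Build (preop, labels, truth, intraop) from a phantom spec."""
    rng = np.random.default_rng(spec.seed)
    size = tuple(int(s) for s in spec.size)
    spacing = np.asarray(spec.spacing, dtype=float)
    ext = spec.extent_mm()
    ctr = ext / 2.0

    idx = np.meshgrid(*[np.arange(s, dtype=float) for s in size], indexing="ij")
    xyz = np.stack([idx[a] * spacing[a] for a in range(3)], axis=-1)  # mm

    # labels: ellipsoidal brain (1) + spherical tumor (2)
    semi = 0.35 * ext
    brain = np.sum(((xyz - ctr) / semi) ** 2, axis=-1) <= 1.0
    labels = np.where(brain, 1, 0).astype(np.int32)
    tumor_center = ctr + np.array([0.12, 0.0, 0.0]) * ext
    tumor_radius = 0.125 * float(ext.min())
    tumor = np.linalg.norm(xyz - tumor_center, axis=-1) <= tumor_radius
    if not np.all(brain[tumor]):
        raise ValueError("tumor sphere extends outside the brain mask")
    labels[tumor] = 2
    label_img = LabelImage(data=labels, spacing=spec.spacing)

    # preop: per-label base intensity + correlated texture inside the brain
    base = np.zeros(size)
    for lab, inten in spec.base_intensity.items():
        base[labels == lab] = inten
    noise = rng.standard_normal(size)
    sigma_vox = spec.texture_scale / spacing
    texture = ndimage.gaussian_filter(noise, sigma=sigma_vox)
    sd = texture.std()
    if sd > 0:
        texture = texture / sd * spec.texture_amplitude
    preop_data = base + texture * (labels > 0)
    if spec.noise_sd > 0:
        preop_data = preop_data + spec.noise_sd * rng.standard_normal(size)
    preop = Image3D(data=preop_data, spacing=spec.spacing)

    # ground-truth field: Gaussian radial bumps, cosine-tapered to zero
    # outside the brain (zero beyond a 2r dilation), peak |u| = deform_max
    centers = spec.deform_centers
    if centers is None:
        centers = _default_centers(spec)
    u = np.zeros(size + (3,))
    if spec.deform_max > 0 and centers:
        for dc in centers:
            d = np.asarray(dc.direction, dtype=float)
            nd = np.linalg.norm(d)
            if nd == 0:
                raise ValueError("deform direction must be non-zero")
            d = d / nd
            r2 = np.sum((xyz - np.asarray(dc.center)) ** 2, axis=-1)
            bump = np.exp(-r2 / (2.0 * dc.radius**2))
            u += bump[..., None] * d[None, None, None, :]
        r_env = max(dc.radius for dc in centers)
        dist_out = ndimage.distance_transform_edt(labels == 0, sampling=spacing)
        env = np.where(
            dist_out < 2.0 * r_env,
            np.cos(np.pi * dist_out / (4.0 * r_env)) ** 2,
            0.0,
        )
        u *= env[..., None]
        mags = np.linalg.norm(u, axis=-1)
        peak = float(mags.max())
        if peak > 0:
            u *= spec.deform_max / peak
    truth = DenseField(data=u, spacing=spec.spacing)

    intraop = warp_image(preop, truth, order=1)
    if spec.resection is not None:
        (rc, rr) = spec.resection
        rc = np.asarray(rc, dtype=float)
        sphere = np.linalg.norm(xyz - rc, axis=-1) <= rr
        if not np.all(brain[sphere]):
            raise ValueError("resection sphere extends outside the brain mask")
        intraop.data[sphere] = 0.0

    return Phantom(preop=preop, labels=label_img, truth=truth,
                   intraop=intraop, spec=spec)


def corrupt_matches(
    matches: MatchSet, fraction: float, magnitude: float, seed: int = 0
) -> tuple[MatchSet, np.ndarray]:
    """Replace a random fraction of match displacements with uniformly
    oriented vectors of norm ``magnitude`` (confidences unchanged).

    Returns the corrupted MatchSet and the corrupted match ids.
    """
    if not (0.0 <= fraction < 1.0):
        raise ValueError(f"fraction must be in [0, 1), got {fraction}")
    rng = np.random.default_rng(seed)
    n = len(matches)
    count = int(round(fraction * n))
    ids = np.sort(rng.choice(n, size=count, replace=False)) if count else (
        np.zeros(0, dtype=np.int64))
    disp = matches.displacements.copy()
    if count:
        vec = rng.standard_normal((count, 3))
        vec /= np.linalg.norm(vec, axis=1, keepdims=True)
        disp[ids] = vec * magnitude
    out = MatchSet(
        points=matches.points.copy(),
        displacements=disp,
        confidences=matches.confidences.copy(),
        provenance=dict(matches.provenance),
    )
    return out, np.asarray(ids, dtype=np.int64)
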