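"""Synthetic deformable multi-organ phantoms.

Generates 3D phantoms — non-overlapping ellipsoidal "organs" with distinct
intensities over a darker background — together with smooth random
displacement fields, so the whole adaptive-segmentation pipeline can be
exercised without clinical data.  Intensities are emitted already
normalized to [0, 1], emulating preprocessed CBCT/sCT; organ intensities
are drawn per phantom (per patient) so that image intensity alone does not
identify a structure, as in real soft-tissue anatomy.

Warping uses the backward (pull) convention: the output at voxel ``v``
samples the input at ``v + dvf[v]``, trilinear for images and
nearest-neighbour for masks, with edge-clamped out-of-grid samples.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage

from .grids import DisplacementField, GridMismatchError, ImageVolume, StructureSet

BACKGROUND_INTENSITY = 0.15
ORGAN_INTENSITY_RANGE = (0.55, 0.80)
ORGAN_MARGIN = 2.0  # minimum voxel gap between organs


class PlacementError(RuntimeError):
    """Could not place the requested number of organs in the volume."""


@dataclasses.dataclass
class PhantomConfig:
    shape: tuple[int, int, int] = (32, 32, 32)
    n_structures: int = 3
    noise_sd: float = 0.02
    dvf_amplitude: float = 3.0
    dvf_smoothness: float = 4.0
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    seed: int = 0

    def __post_init__(self):
        self.shape = tuple(int(s) for s in self.shape)
        if self.n_structures < 1:
            raise ValueError("n_structures must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.dvf_amplitude < 0:
            raise ValueError("dvf_amplitude must be >= 0")
        if self.dvf_smoothness <= 0:
            raise ValueError("dvf_smoothness must be > 0")


def _sample_intensities(rng: np.random.Generator, n: int) -> np.ndarray:
    """Distinct organ intensities drawn from one narrow soft-tissue band.

    All organs look alike against the background (as soft-tissue OARs do on
    CBCT/sCT), and the per-patient ordering of the slightly different
    values is random — so image intensity localizes organs but does not
    reliably identify *which* structure a blob is; that is what the prior
    contours are for.
    """
    lo, hi = ORGAN_INTENSITY_RANGE
    span = (hi - lo) / n
    slots = lo + span * (np.arange(n) + 0.5)
    vals = slots + rng.uniform(-0.2 * span, 0.2 * span, size=n)
    return rng.permutation(vals)


def make_phantom(config: PhantomConfig) -> tuple[ImageVolume, StructureSet]:
    """Build one phantom: image plus one binary mask per organ.

    Organs are axis-aligned ellipsoids, pairwise separated by at least
    ``ORGAN_MARGIN`` voxels (measured between bounding spheres) so that
    connected-component analysis of the mask union is unambiguous.
    Deterministic for a fixed ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    shape = np.array(config.shape, dtype=float)
    n = config.n_structures

    min_r = max(1.5, min(shape) / 12.0)
    max_r = max(min_r + 0.3, min(shape) / 5.0)
    placed: list[tuple[np.ndarray, np.ndarray]] = []  # (center, radii)
    attempts = 0
    while len(placed) < n:
        attempts += 1
        if attempts > 5000:
            raise PlacementError(
                f"cannot place {n} organs of radius ~{min_r:.1f}-{max_r:.1f} "
                f"in volume of shape {config.shape}")
        radii = rng.uniform(min_r, max_r, size=3)
        lo = radii + 1.0
        hi = shape - radii - 2.0
        if np.any(hi <= lo):
            raise PlacementError(f"volume {config.shape} too small for organ radii {radii}")
        center = rng.uniform(lo, hi)
        r_bound = radii.max()
        ok = all(
            np.linalg.norm(center - c) >= r_bound + pr.max() + ORGAN_MARGIN
            for c, pr in placed
        )
        if ok:
            placed.append((center, radii))

    zz, yy, xx = np.meshgrid(*(np.arange(s) for s in config.shape), indexing="ij")
    coords = np.stack([zz, yy, xx], axis=-1).astype(float)

    intensities = _sample_intensities(rng, n)
    image = np.full(config.shape, BACKGROUND_INTENSITY)
    masks: dict[str, np.ndarray] = {}
    for k, (center, radii) in enumerate(placed):
        d2 = (((coords - center) / radii) ** 2).sum(axis=-1)
        mask = (d2 <= 1.0).astype(np.uint8)
        masks[f"organ_{k + 1}"] = mask
        image[mask > 0] = intensities[k]

    if config.noise_sd > 0:
        image = image + rng.normal(0.0, config.noise_sd, size=config.shape)
        image = np.clip(image, 0.0, 1.0)

    return ImageVolume(image, config.spacing), StructureSet(masks)


def make_smooth_dvf(shape, amplitude: float, smoothness: float, seed: int) -> DisplacementField:
    """Gaussian-smoothed white noise per component, rescaled so the maximum
    displacement norm equals ``amplitude`` (zero field when amplitude is 0)."""
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    if smoothness <= 0:
        raise ValueError("smoothness must be > 0")
    shape = tuple(int(s) for s in shape)
    if amplitude == 0:
        return DisplacementField(np.zeros(shape + (3,)))
    rng = np.random.default_rng(seed)
    field = rng.normal(size=shape + (3,))
    for c in range(3):
        field[..., c] = ndimage.gaussian_filter(field[..., c], sigma=smoothness)
    norms = np.sqrt((field ** 2).sum(axis=-1))
    peak = norms.max()
    if peak > 0:
        field *= amplitude / peak
    return DisplacementField(field)


def _sample_coords(shape, dvf: DisplacementField) -> np.ndarray:
    grids = np.meshgrid(*(np.arange(s, dtype=float) for s in shape), indexing="ij")
    return np.stack([g + dvf.vectors[..., i] for i, g in enumerate(grids)])


def warp_image(img: ImageVolume, dvf: DisplacementField) -> ImageVolume:
    """Backward-warp an image by a DVF (trilinear, edge clamp)."""
    if img.shape != dvf.shape:
        raise GridMismatchError(f"image shape {img.shape} != DVF shape {dvf.shape}")
    if not np.any(dvf.vectors):
        return ImageVolume(img.data.copy(), img.spacing)
    coords = _sample_coords(img.shape, dvf)
    out = ndimage.map_coordinates(img.data, coords, order=1, mode="nearest")
    return ImageVolume(out, img.spacing)


def warp_mask(mask: np.ndarray, dvf: DisplacementField) -> np.ndarray:
    """Backward-warp a binary mask (nearest-neighbour; stays binary)."""
    mask = np.asarray(mask)
    if mask.shape != dvf.shape:
        raise GridMismatchError(f"mask shape {mask.shape} != DVF shape {dvf.shape}")
    if not np.any(dvf.vectors):
        return mask.astype(np.uint8).copy()
    coords = _sample_coords(mask.shape, dvf)
    out = ndimage.map_coordinates(mask.astype(np.uint8), coords, order=0, mode="nearest")
    return out.astype(np.uint8)


def warp_structures(ss: StructureSet, dvf: DisplacementField) -> StructureSet:
    return StructureSet({name: warp_mask(m, dvf) for name, m in ss.masks.items()})
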