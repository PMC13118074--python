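"""Reflectance calibration and automated object-mask extraction.

Recovery routes from raw digital numbers to unitless reflectance:

* local -- flat-field division of one lamp's object cube by its white
  reference, ``R = I_obj / I_ref`` (the middle lamp when a full
  illumination set is supplied);
* simultaneous -- quasi-uniform illumination emulated by summing the
  per-lamp signals before dividing, ``R = sum_i I_obj,i / sum_i I_ref,i``;
* sequential -- per-lamp reflectances fed to the specular/diffuse
  decomposition (see :mod:`hsiseg.decompose`).

Object masks come from Otsu thresholding of a single high-contrast band
(750 nm by default) followed by an area filter on 8-connected components.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure

from .spectra import IlluminationSet, ReflectanceCube, SpectralCube

__all__ = [
    "median_filter_bands",
    "reflectance_local",
    "reflectance_simultaneous",
    "per_angle_reflectance",
    "otsu_threshold",
    "ObjectMask",
    "ObjectCrop",
    "build_object_masks",
    "filter_mask_areas",
    "extract_object_cubes",
]

#: native-resolution area window for one fruit, in pixels
DEFAULT_MIN_AREA = 20_000
DEFAULT_MAX_AREA = 40_000


def median_filter_bands(cube: SpectralCube) -> SpectralCube:
    """3x3 spatial median filter applied to each band independently."""
    if cube.data.shape[2] < 1:
        raise ValueError("cube must have at least one band")
    out = ndimage.median_filter(cube.data, size=(3, 3, 1), mode="nearest")
    if isinstance(cube, ReflectanceCube):
        return ReflectanceCube(out, cube.grid, mode=cube.mode,
                               invalid=cube.invalid.copy())
    return SpectralCube(out, cube.grid)


def _divide(obj: np.ndarray, ref: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pixel-wise division; non-positive reference flags the pixel invalid."""
    invalid = np.any(ref <= 0, axis=2)
    safe = np.where(ref > 0, ref, 1.0)
    out = obj / safe
    out[invalid] = 0.0
    return out, invalid


def reflectance_local(obj: SpectralCube | IlluminationSet,
                      ref: SpectralCube | None = None,
                      angle: int = 1) -> ReflectanceCube:
    """Flat-field reflectance from a single lamp.

    When ``obj`` is a full :class:`IlluminationSet` the middle lamp
    (index 1 of three) is used, matching a single 0/45-geometry source.
    """
    if isinstance(obj, IlluminationSet):
        ill = obj
        obj, ref = ill.obj[angle], ill.ref[angle]
    if ref is None:
        raise ValueError("a reference cube is required")
    if obj.shape != ref.shape:
        raise ValueError("object and reference shapes differ")
    data, invalid = _divide(np.asarray(obj.data, dtype=np.float64),
                            np.asarray(ref.data, dtype=np.float64))
    return ReflectanceCube(data, obj.grid, mode="local", invalid=invalid)


def reflectance_simultaneous(ill: IlluminationSet) -> ReflectanceCube:
    """Reflectance under emulated uniform illumination (summed signals)."""
    if ill.n_angles < 2:
        raise ValueError("simultaneous mode needs several lamp positions")
    obj_sum = np.sum([np.asarray(c.data, dtype=np.float64) for c in ill.obj], axis=0)
    ref_sum = np.sum([np.asarray(c.data, dtype=np.float64) for c in ill.ref], axis=0)
    data, invalid = _divide(obj_sum, ref_sum)
    return ReflectanceCube(data, ill.grid, mode="simultaneous", invalid=invalid)


def per_angle_reflectance(ill: IlluminationSet) -> list[ReflectanceCube]:
    """One flat-field reflectance cube per lamp (decomposition inputs)."""
    return [reflectance_local(ill.obj[i], ill.ref[i]) for i in range(ill.n_angles)]


def otsu_threshold(values: np.ndarray, nbins: int = 256) -> float:
    """Histogram threshold maximizing between-class variance.

    The histogram uses ``nbins`` uniform bins over the data range; the
    returned threshold is the center of the best split bin, with the
    convention that values strictly above the threshold form the bright
    class.

    Bin moments are integers (counts weighted by bin index), so the
    between-class variance comparison is carried out in exact integer
    arithmetic: plateaus from empty bins tie-break deterministically to
    the first maximizing split.
    """
    v = np.asarray(values, dtype=np.float64).ravel()
    v = v[np.isfinite(v)]
    if v.size < 2 or v.min() == v.max():
        raise ValueError("Otsu threshold needs at least two distinct values")
    counts, edges = np.histogram(v, bins=nbins, range=(v.min(), v.max()))
    centers = 0.5 * (edges[:-1] + edges[1:])
    # between-class variance in bin-index units is a positive rescaling of
    # the bin-center version, so the argmax is identical
    n_total = int(counts.sum())
    m_total = int((counts * np.arange(nbins)).sum())
    n0 = 0
    m0 = 0
    best_k = -1
    best_num = 0   # (m0*n1 - m1*n0)^2 over den = n0*n1, compared exactly
    best_den = 1
    for k in range(nbins - 1):
        n0 += int(counts[k])
        m0 += int(counts[k]) * k
        n1 = n_total - n0
        if n0 == 0 or n1 == 0:
            continue
        num = (m0 * n1 - (m_total - m0) * n0) ** 2
        den = n0 * n1
        if best_k < 0 or num * best_den > best_num * den:
            best_k, best_num, best_den = k, num, den
    if best_k < 0:
        raise ValueError("degenerate histogram: no valid split")
    return float(centers[best_k])


@dataclass
class ObjectMask:
    """Retained connected components after the area filter."""

    label_image: np.ndarray          # 0 background, 1..n per component
    areas: list[int]
    min_area: int
    max_area: int

    @property
    def n_objects(self) -> int:
        return len(self.areas)

    def component(self, index: int) -> np.ndarray:
        return self.label_image == index + 1

    @property
    def any_mask(self) -> np.ndarray:
        return self.label_image > 0


def build_object_masks(R: ReflectanceCube, band_nm: float = 750.0,
                       min_area: int = DEFAULT_MIN_AREA,
                       max_area: int = DEFAULT_MAX_AREA,
                       fill_holes: bool = True) -> ObjectMask:
    """Otsu-binarize one band, keep 8-connected components in an area window.

    The native window of 20,000-40,000 px corresponds to one fruit at the
    reference magnification; scale it by the square of any frame scale
    factor for smaller scenes.  Morphological hole filling closes dark
    defect patches inside an object silhouette.
    """
    if min_area >= max_area:
        raise ValueError("min_area must be below max_area")
    band = np.array(R.band(band_nm), dtype=np.float64)
    band[R.invalid] = np.nan
    thr = otsu_threshold(band[np.isfinite(band)])
    binary = np.isfinite(band) & (band > thr)
    if fill_holes:
        binary = ndimage.binary_fill_holes(binary)
    labeled = measure.label(binary, connectivity=2)
    out = np.zeros_like(labeled)
    areas: list[int] = []
    for region in measure.regionprops(labeled):
        if min_area <= region.area <= max_area:
            out[labeled == region.label] = len(areas) + 1
            areas.append(int(region.area))
    if not areas:
        warnings.warn("no connected component survived the area filter",
                      stacklevel=2)
    return ObjectMask(label_image=out, areas=areas,
                      min_area=min_area, max_area=max_area)


def filter_mask_areas(mask: ObjectMask) -> ObjectMask:
    """Re-apply the area window to an existing mask (idempotent)."""
    out = np.zeros_like(mask.label_image)
    areas: list[int] = []
    for idx, area in enumerate(mask.areas):
        if mask.min_area <= area <= mask.max_area:
            out[mask.label_image == idx + 1] = len(areas) + 1
            areas.append(area)
    return ObjectMask(out, areas, mask.min_area, mask.max_area)


@dataclass
class ObjectCrop:
    """One object's tight bounding-box crop with its frame offset."""

    cube: ReflectanceCube
    mask: np.ndarray                 # crop-local binary mask
    offset: tuple[int, int]          # (row, col) of crop origin in the frame

    @property
    def area(self) -> int:
        return int(self.mask.sum())


def extract_object_cubes(R: ReflectanceCube, masks: ObjectMask) -> list[ObjectCrop]:
    """Tight per-component crops of the reflectance cube."""
    if masks.label_image.shape != R.data.shape[:2]:
        raise ValueError("mask frame does not match the cube")
    crops: list[ObjectCrop] = []
    for idx in range(masks.n_objects):
        comp = masks.component(idx)
        rows = np.flatnonzero(comp.any(axis=1))
        cols = np.flatnonzero(comp.any(axis=0))
        r0, r1 = rows[0], rows[-1] + 1
        c0, c1 = cols[0], cols[-1] + 1
        sub = ReflectanceCube(R.data[r0:r1, c0:c1].copy(), R.grid, mode=R.mode,
                              invalid=R.invalid[r0:r1, c0:c1].copy())
        crops.append(ObjectCrop(cube=sub, mask=comp[r0:r1, c0:c1],
                                offset=(int(r0), int(c0))))
    return crops
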