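"""Fruit/background segmentation and whole-fruit ROI spectra.

Fruit and conveyor background separate cleanly at a single waveband (700 nm
by default, where fruit flesh reflects strongly and the dark belt does not),
so the mask is a simple per-pixel threshold on that band — Otsu's method when
no explicit threshold is given.  The ROI for each fruit is its entire masked
region, and one mean spectrum per fruit represents the sample.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .envi import Hypercube, band_index

__all__ = ["Mask", "Region", "build_mask", "label_fruits", "roi_mean_spectrum", "extract_fruit_spectra"]


@dataclass
class Mask:
    """Binary fruit mask: 1 = fruit, 0 = background."""

    data: np.ndarray
    band_used: float
    threshold: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError("mask must be 2-D")
        if not np.isin(self.data, (0, 1)).all():
            raise ValueError("mask must be strictly binary")
        self.data = self.data.astype(np.uint8)

    def to_png(self, path) -> None:
        from PIL import Image

        Image.fromarray(self.data * 255).save(path)


@dataclass
class Region:
    """One labeled fruit region."""

    label: int
    mask: np.ndarray
    area: int
    centroid: tuple[float, float]


def build_mask(cube: Hypercube, band: float = 700.0, threshold: float | None = None) -> Mask:
    """Threshold a single band into a fruit mask.

    ``threshold=None`` selects Otsu's method on the band histogram; pixels
    strictly above the threshold are fruit.  A degenerate (all-fruit or
    all-background) automatic mask triggers a warning, not an error.
    """
    img = cube.band(band)
    auto = threshold is None
    if auto:
        threshold = float(threshold_otsu(img))
    mask = (img > threshold).astype(np.uint8)
    if auto and (mask.all() or not mask.any()):
        warnings.warn("automatic threshold produced a degenerate (all-0 or all-1) mask", stacklevel=2)
    nm = cube.wavelengths[band_index(cube.wavelengths, band)]
    return Mask(mask, band_used=float(nm), threshold=float(threshold))


# 4-connectivity: conservative against diagonal bridges between adjacent fruits
_STRUCTURE = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])


def label_fruits(mask: Mask, min_area: int = 50) -> list[Region]:
    """Split the mask into individual fruits (4-connected components).

    Components smaller than ``min_area`` pixels are discarded as speckle.
    Surviving regions are ordered by centroid: top-to-bottom, then
    left-to-right.  Raises if nothing survives.
    """
    labeled, n = ndimage.label(mask.data, structure=_STRUCTURE)
    regions = []
    for lab in range(1, n + 1):
        m = labeled == lab
        area = int(m.sum())
        if area < min_area:
            continue
        cy, cx = ndimage.center_of_mass(m)
        regions.append(Region(label=lab, mask=m, area=area, centroid=(cy, cx)))
    if not regions:
        raise ValueError("no fruit regions found (after min_area filtering)")
    regions.sort(key=lambda r: (r.centroid[0], r.centroid[1]))
    for i, r in enumerate(regions, start=1):
        r.label = i
    return regions


def roi_mean_spectrum(cube: Hypercube, region: Region | np.ndarray) -> np.ndarray:
    """Average reflectance spectrum over all pixels of one fruit region."""
    m = region.mask if isinstance(region, Region) else np.asarray(region, dtype=bool)
    if m.shape != cube.shape[:2]:
        raise ValueError("region shape does not match cube spatial shape")
    if not m.any():
        raise ValueError("empty region")
    return cube.data[m].mean(axis=0)


def extract_fruit_spectra(
    cube: Hypercube,
    band: float = 700.0,
    threshold: float | None = None,
    min_area: int = 50,
) -> tuple[np.ndarray, Mask, list[Region]]:
    """Mask, label and extract: one mean spectrum per fruit, in region order."""
    mask = build_mask(cube, band=band, threshold=threshold)
    regions = label_fruits(mask, min_area=min_area)
    X = np.stack([roi_mean_spectrum(cube, r) for r in regions])
    return X, mask, regions
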