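"""Random-seed generation.

A seed is a starting point for the HMM tracer together with an angular
search fan: fresh random seeds search the full 360 degrees, reaction seeds
180 degrees, and every subsequent tracing step 90 degrees.

Four strategies produce initial seeds: uniform positions over the frame,
and positions sampled from the feature maps of fast deterministic
detectors — Canny edges, a morphological skeleton of the Otsu mask, and
difference-of-Gaussian blobs.  The detectors are used only as seed
sources (their maps may be broken or artifact-ridden in low-SNR images;
the tracer, not the detector, decides what is neurite).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.feature import blob_dog, canny
from skimage.filters import threshold_otsu
from skimage.morphology import skeletonize

from .errors import ParameterError
from .imaging import GrayImage, Point

#: Fraction of skeleton pixels sampled when ``n="auto"``; a few percent of
#: the skeleton is enough because every active seed also spawns a reaction
#: seed covering the rest of its branch.
AUTO_SKELETON_FRACTION = 0.05

VALID_SPANS = (360.0, 180.0, 90.0)


@dataclass(frozen=True)
class Seed:
    """A tracing start point with its angular search fan."""

    position: Point
    heading_deg: float = 0.0
    span_deg: float = 360.0
    kind: str = "random"       # random | reaction
    origin: str = "uniform"    # uniform | edge | skeleton | blob | reaction

    def __post_init__(self) -> None:
        if self.kind not in ("random", "reaction"):
            raise ParameterError(f"unknown seed kind {self.kind!r}")
        if self.span_deg not in VALID_SPANS:
            raise ParameterError(f"span_deg must be one of {VALID_SPANS}")
        if self.kind == "random" and self.span_deg != 360.0:
            raise ParameterError("random seeds search the full 360 degrees")
        if self.kind == "reaction" and self.span_deg != 180.0:
            raise ParameterError("reaction seeds search a 180 degree fan")


def _check_n(n: int) -> None:
    if n < 1:
        raise ParameterError(f"seed count must be >= 1, got {n}")


def _seeds_from_pixels(pixels: np.ndarray, n: int, rng: np.random.Generator,
                       origin: str) -> list[Seed]:
    """Uniformly sample up to n pixel positions without replacement."""
    total = len(pixels)
    if total == 0:
        return []
    take = min(n, total)
    idx = rng.choice(total, size=take, replace=False)
    return [
        Seed(Point(float(r), float(c)), origin=origin)
        for r, c in pixels[np.sort(idx)]
    ]


def uniform_seeds(shape: tuple[int, int], n: int,
                  rng: np.random.Generator) -> list[Seed]:
    """n seeds i.i.d. uniform over the image rectangle."""
    _check_n(n)
    h, w = shape
    rows = rng.uniform(0.0, h - 1, size=n)
    cols = rng.uniform(0.0, w - 1, size=n)
    return [Seed(Point(float(r), float(c)), origin="uniform")
            for r, c in zip(rows, cols)]


def edge_seeds(img: GrayImage, n: int, rng: np.random.Generator,
               sigma: float = 1.0) -> list[Seed]:
    """Seeds sampled from a Canny edge map at default parameters."""
    _check_n(n)
    edges = canny(img.pixels, sigma=sigma)
    pixels = np.argwhere(edges)
    if len(pixels) == 0:
        warnings.warn("edge map is empty; no edge seeds generated")
        return []
    return _seeds_from_pixels(pixels, n, rng, "edge")


def skeleton_seeds(img: GrayImage, n="auto", rng: np.random.Generator = None,
                   ) -> list[Seed]:
    """Seeds sampled from the morphological skeleton of the Otsu mask.

    ``n="auto"`` samples 5% of the skeleton pixels, the typical few-percent
    density needed when reaction seeds complete each traced branch.
    """
    if rng is None:
        rng = np.random.default_rng()
    ptp = img.pixels.max() - img.pixels.min()
    if ptp <= 1e-12:
        warnings.warn("constant image has no skeleton; no seeds generated")
        return []
    mask = img.pixels > threshold_otsu(img.pixels)
    skel = skeletonize(mask)
    pixels = np.argwhere(skel)
    if len(pixels) == 0:
        warnings.warn("skeleton is empty; no skeleton seeds generated")
        return []
    if n == "auto":
        n = max(1, int(round(AUTO_SKELETON_FRACTION * len(pixels))))
    _check_n(n)
    return _seeds_from_pixels(pixels, n, rng, "skeleton")


def blob_seeds(img: GrayImage, n: int, rng: np.random.Generator,
               min_sigma: float = 1.0, max_sigma: float = 5.0,
               threshold: float = 0.02) -> list[Seed]:
    """Seeds sampled from difference-of-Gaussian blob centers."""
    _check_n(n)
    blobs = blob_dog(img.pixels, min_sigma=min_sigma, max_sigma=max_sigma,
                     threshold=threshold)
    if len(blobs) == 0:
        warnings.warn("no blobs detected; no blob seeds generated")
        return []
    centers = blobs[:, :2]
    take = min(n, len(centers))
    idx = rng.choice(len(centers), size=take, replace=False)
    return [
        Seed(Point(float(r), float(c)), origin="blob")
        for r, c in centers[np.sort(idx)]
    ]


def seeds_to_csv(seeds: list[Seed], path) -> None:
    """Serialize a seed list (row, col, span_deg, origin columns)."""
    pd.DataFrame(
        {
            "row": [s.position.row for s in seeds],
            "col": [s.position.col for s in seeds],
            "span_deg": [s.span_deg for s in seeds],
            "origin": [s.origin for s in seeds],
        }
    ).to_csv(path, index=False)
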