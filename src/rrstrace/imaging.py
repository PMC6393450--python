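"""Image loading, normalization and sub-pixel intensity sampling.

Everything the tracer observes comes through this module: a normalized
2-D intensity field (:class:`GrayImage`) and bilinear probes along line
segments (:func:`sample_line`) or rectangular zones around them
(:func:`sample_zone`).

Coordinate convention: 0-based ``(row, col)``, pixel centers at integer
coordinates, continuous sub-pixel positions are legal everywhere.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

from .errors import DataError, FormatError, GeometryError, ParameterError

logger = logging.getLogger(__name__)

#: Default normalization floor; intensities live in [eps, 1] so that
#: log(intensity) is finite and non-positive everywhere.
DEFAULT_EPS = 1e-3

_CHANNEL_INDEX = {"red": 0, "green": 1, "blue": 2}


@dataclass(frozen=True)
class Point:
    """A continuous (row, col) position in image space."""

    row: float
    col: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.row) and math.isfinite(self.col)):
            raise GeometryError(f"non-finite point ({self.row}, {self.col})")

    def as_array(self) -> np.ndarray:
        return np.array([self.row, self.col], dtype=float)

    def distance_to(self, other: "Point") -> float:
        return math.hypot(self.row - other.row, self.col - other.col)


def _as_point(p) -> Point:
    if isinstance(p, Point):
        return p
    return Point(float(p[0]), float(p[1]))


@dataclass
class GrayImage:
    """Normalized 2-D intensity field, the sole observation source of the HMM.

    Parameters
    ----------
    pixels
        Float array with every value in ``[eps, 1]``.
    eps
        The normalization floor used when the image was built.
    source_channel
        Which channel of the original file the pixels came from
        (``gray``, ``red``, ``green`` or ``blue``).
    """

    pixels: np.ndarray
    eps: float = DEFAULT_EPS
    source_channel: str = "gray"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise DataError("GrayImage needs a non-empty 2-D pixel array")
        if not np.all(np.isfinite(self.pixels)):
            raise DataError("GrayImage pixels must all be finite")
        lo, hi = float(self.pixels.min()), float(self.pixels.max())
        if lo < self.eps - 1e-12 or hi > 1.0 + 1e-12:
            raise DataError(
                f"GrayImage pixels outside [{self.eps}, 1]: min={lo}, max={hi}"
            )

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def contains(self, row: float, col: float) -> bool:
        """True if (row, col) is inside the image support (pixel centers)."""
        return 0.0 <= row <= self.height - 1 and 0.0 <= col <= self.width - 1


def normalize_image(raw: np.ndarray, eps: float = DEFAULT_EPS,
                    source_channel: str = "gray") -> GrayImage:
    """Affinely map a non-negative intensity grid onto ``[eps, 1]``.

    ``out = eps + (1 - eps) * (raw - min) / (max - min)``; a constant image
    maps to ``eps`` everywhere.  The floor keeps the log-intensity path cost
    finite on perfectly dark pixels.
    """
    if not 0.0 < eps <= 0.1:
        raise ParameterError(f"eps must be in (0, 0.1], got {eps}")
    raw = np.asarray(raw, dtype=float)
    if raw.size == 0:
        raise DataError("cannot normalize an empty image")
    if not np.all(np.isfinite(raw)):
        raise DataError("raw image contains NaN or infinite pixels")
    if raw.min() < 0:
        raise DataError("raw image contains negative pixels")
    lo, hi = raw.min(), raw.max()
    if hi == lo:
        pixels = np.full_like(raw, eps)
    else:
        pixels = eps + (1.0 - eps) * (raw - lo) / (hi - lo)
    return GrayImage(pixels, eps=eps, source_channel=source_channel)


def load_image(path, channel: str = "gray", eps: float = DEFAULT_EPS) -> GrayImage:
    """Read a TIFF or PNG micrograph and normalize it onto ``[eps, 1]``.

    RGB files are reduced to the requested channel (neurite stains are
    typically imaged in one fluorescence channel, e.g. green); single-channel
    files ignore the channel selector with a logged notice.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image not found: {path}")
    if channel not in ("gray", "red", "green", "blue"):
        raise ParameterError(f"unknown channel {channel!r}")
    suffix = path.suffix.lower()
    try:
        if suffix in (".tif", ".tiff"):
            raw = tifffile.imread(path)
        elif suffix == ".png":
            raw = iio.imread(path)
        else:
            raise FormatError(f"unsupported image format: {suffix}")
    except FormatError:
        raise
    except Exception as exc:  # decoder failure
        raise FormatError(f"could not decode {path}: {exc}") from exc

    raw = np.asarray(raw)
    if raw.dtype.kind not in "uif":
        raise FormatError(f"unsupported pixel dtype {raw.dtype}")
    if raw.ndim == 3 and raw.shape[0] in (3, 4) and raw.shape[2] not in (3, 4):
        raw = np.moveaxis(raw, 0, -1)  # channel-first TIFF planes
    if raw.ndim == 3:
        if raw.shape[2] not in (3, 4):
            raise FormatError(f"unsupported sample count {raw.shape[2]}")
        if channel == "gray":
            raw = raw[..., :3].mean(axis=2)
        else:
            raw = raw[..., _CHANNEL_INDEX[channel]]
    elif raw.ndim == 2:
        if channel != "gray":
            logger.info(
                "%s is single-channel; channel=%r ignored", path, channel
            )
            channel = "gray"
    else:
        raise FormatError(f"unsupported image dimensionality {raw.ndim}")
    return normalize_image(raw.astype(float), eps=eps, source_channel=channel)


def bilinear(pixels: np.ndarray, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
    """Bilinear interpolation of ``pixels`` at continuous positions.

    Positions are assumed to lie inside the pixel-center support
    ``[0, H-1] x [0, W-1]``; callers are responsible for bounds checks.
    """
    h, w = pixels.shape
    r0 = np.clip(np.floor(rows).astype(int), 0, max(h - 2, 0))
    c0 = np.clip(np.floor(cols).astype(int), 0, max(w - 2, 0))
    fr = rows - r0
    fc = cols - c0
    r1 = np.minimum(r0 + 1, h - 1)
    c1 = np.minimum(c0 + 1, w - 1)
    return (
        pixels[r0, c0] * (1 - fr) * (1 - fc)
        + pixels[r0, c1] * (1 - fr) * fc
        + pixels[r1, c0] * fr * (1 - fc)
        + pixels[r1, c1] * fr * fc
    )


def _segment_ts(dist: float, spacing: float) -> np.ndarray:
    """Relative sample positions on a segment: endpoints inclusive,
    ``floor(dist / spacing) + 1`` equally spaced samples."""
    if spacing <= 0:
        raise ParameterError(f"spacing must be positive, got {spacing}")
    # tiny slack so float jitter in a recomputed segment length cannot
    # change the sample count of a nominally fixed-length step
    count = int(math.floor(dist / spacing + 1e-9)) + 1
    return np.linspace(0.0, 1.0, max(count, 1))


def _segment_coords(p0: np.ndarray, p1: np.ndarray, ts: np.ndarray) -> np.ndarray:
    """Sample coordinates ``p0 + t * (p1 - p0)``, shape (len(ts), 2)."""
    return p0[None, :] + ts[:, None] * (p1 - p0)[None, :]


def sample_line(img: GrayImage, p0, p1, spacing: float = 1.0) -> np.ndarray:
    """Bilinear intensities at equally spaced samples from p0 to p1 inclusive."""
    p0 = _as_point(p0)
    p1 = _as_point(p1)
    if p0.row == p1.row and p0.col == p1.col:
        raise GeometryError("degenerate segment: p0 == p1")
    for p in (p0, p1):
        if not img.contains(p.row, p.col):
            raise GeometryError(f"segment endpoint {p} outside image bounds")
    ts = _segment_ts(p0.distance_to(p1), spacing)
    coords = _segment_coords(p0.as_array(), p1.as_array(), ts)
    return bilinear(img.pixels, coords[:, 0], coords[:, 1])


@dataclass
class IntensityProfile:
    """Line and zone intensity samples around one tracing step.

    ``line_samples`` is the 1-D intensity distribution along the step
    segment; ``zone_samples`` is a rectangular lattice centered on the
    segment with perpendicular extent twice the line width.  Lattice points
    clipped away at image borders are NaN and ``truncated`` is set.
    """

    line_samples: np.ndarray
    zone_samples: np.ndarray
    spacing: float
    truncated: bool = False

    def valid_zone_samples(self) -> np.ndarray:
        flat = self.zone_samples.ravel()
        return flat[np.isfinite(flat)]


def sample_zone(img: GrayImage, p0, p1, spacing: float = 1.0,
                line_width: float = 1.0) -> IntensityProfile:
    """Sample the line p0->p1 and its surrounding zone.

    The zone lattice shares the along-segment sample positions of the line
    and extends ``line_width`` on each side perpendicular to the segment
    (total perpendicular extent ``2 * line_width``), at the same spacing.
    Zone rows falling outside the image are clipped: their samples become
    NaN and the profile is flagged truncated.
    """
    if line_width < 1.0:
        raise ParameterError(f"line_width must be >= 1, got {line_width}")
    p0 = _as_point(p0)
    p1 = _as_point(p1)
    line = sample_line(img, p0, p1, spacing)

    a0, a1 = p0.as_array(), p1.as_array()
    ts = _segment_ts(p0.distance_to(p1), spacing)
    along = _segment_coords(a0, a1, ts)
    direction = (a1 - a0) / np.linalg.norm(a1 - a0)
    perp = np.array([-direction[1], direction[0]])
    n_side = int(round(line_width / spacing))
    offsets = np.arange(-n_side, n_side + 1) * spacing
    # lattice: (n_perp, n_along, 2)
    coords = along[None, :, :] + offsets[:, None, None] * perp[None, None, :]
    rows, cols = coords[..., 0], coords[..., 1]
    valid = (
        (rows >= 0.0) & (rows <= img.height - 1)
        & (cols >= 0.0) & (cols <= img.width - 1)
    )
    zone = np.full(rows.shape, np.nan)
    if valid.any():
        zone[valid] = bilinear(img.pixels, rows[valid], cols[valid])
    truncated = not bool(valid.all())
    return IntensityProfile(line, zone, spacing, truncated=truncated)
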