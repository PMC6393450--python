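"""Neurite phantoms with ground truth, and trace-vs-truth scoring.

Real microfluidic neurite micrographs come without objective ground
truth, so every stage of the pipeline is exercised on synthetic phantoms:
tree-like bright curvilinear structures on a dark background, degraded by
the artifact inventory of low-SNR fluorescence imaging — bright halo
rings, dot-like debris, an uneven illumination gradient, per-pixel
Gaussian noise and sensor quantization.

Trees grow by bifurcation: a trunk is a smooth random walk, and each
branching event splits a free tip into two daughters.  Ground-truth
centerlines are therefore junction-delimited polylines, matching the
semantics of branch parting, and the branch count of a tree with ``k``
bifurcations is ``1 + 2k``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.draw import disk as draw_disk
from skimage.draw import line as draw_line
from scipy.spatial import cKDTree

from .errors import ParameterError
from .imaging import DEFAULT_EPS, GrayImage, Point
from .seeding import Seed


@dataclass
class PhantomSpec:
    """Study conditions of one synthetic phantom.

    Intensities are on the normalized [0, 1] scale: foreground 0.8 against
    background 0.15 with Gaussian noise sd 0.05 emulates a moderately noisy
    well-exposed epifluorescence field; 8-bit quantization matches the
    native bit depth of typical camera exports.
    """

    shape: tuple[int, int] = (512, 512)
    n_trees: int = 2
    branches_per_tree: tuple[int, int] = (3, 5)
    branch_length: tuple[float, float] = (40.0, 120.0)
    branch_width: tuple[float, float] = (1.0, 3.0)
    curvature_deg: float = 2.0       # max heading change per 1-px step
    fg_level: float = 0.8
    bg_level: float = 0.15
    noise_sd: float = 0.05
    n_halo_spots: int = 2
    n_debris: int = 20
    illum_gradient: float = 0.2      # fractional brightness falloff
    rng_seed: int = 0
    quantize_bits: int = 8
    eps: float = DEFAULT_EPS

    def __post_init__(self) -> None:
        if self.fg_level <= self.bg_level:
            raise ParameterError("fg_level must exceed bg_level")
        if self.n_trees < 0:
            raise ParameterError("n_trees must be >= 0")


@dataclass
class GroundTruth:
    """Known centerlines of a phantom, one polyline per branch."""

    centerlines: list[np.ndarray]    # each (n, 2) float (row, col)
    total_length_px: float
    branch_count: int
    widths: list[float] = field(default_factory=list)

    @staticmethod
    def from_centerlines(centerlines, widths=None) -> "GroundTruth":
        total = float(sum(_polyline_length(c) for c in centerlines))
        return GroundTruth(
            [np.asarray(c, dtype=float) for c in centerlines],
            total,
            len(centerlines),
            list(widths) if widths is not None else [],
        )


def _polyline_length(polyline: np.ndarray) -> float:
    polyline = np.asarray(polyline, dtype=float)
    if len(polyline) < 2:
        return 0.0
    steps = np.diff(polyline, axis=0)
    return float(np.sqrt((steps ** 2).sum(axis=1)).sum())


def _random_walk(start, heading_deg, length, curvature_deg, shape, rng,
                 margin=3.0):
    """Smooth unit-step random walk; stops early at the frame margin."""
    h, w = shape
    pos = np.array(start, dtype=float)
    heading = float(heading_deg)
    points = [pos.copy()]
    for _ in range(int(round(length))):
        heading += rng.uniform(-curvature_deg, curvature_deg)
        rad = math.radians(heading)
        step = np.array([-math.sin(rad), math.cos(rad)])
        nxt = pos + step
        if not (margin <= nxt[0] <= h - 1 - margin
                and margin <= nxt[1] <= w - 1 - margin):
            break
        pos = nxt
        points.append(pos.copy())
    return np.array(points), heading


def generate_phantom(spec: PhantomSpec) -> tuple[GrayImage, GroundTruth]:
    """Draw a random phantom and its ground truth, deterministically per seed."""
    rng = np.random.default_rng(spec.rng_seed)
    h, w = spec.shape
    centerlines: list[np.ndarray] = []
    widths: list[float] = []

    for _ in range(spec.n_trees):
        lo, hi = spec.branches_per_tree
        requested = int(rng.integers(lo, hi + 1))
        n_bifurcations = max(0, (requested - 1) // 2)
        # retry placements so the trunk realizes its full requested length
        # instead of stopping at the frame margin
        length = rng.uniform(*spec.branch_length)
        trunk, tip_heading = None, 0.0
        for _ in range(30):
            root = np.array([rng.uniform(0.12 * h, 0.88 * h),
                             rng.uniform(0.12 * w, 0.88 * w)])
            heading = rng.uniform(0.0, 360.0)
            cand, cand_heading = _random_walk(
                root, heading, length, spec.curvature_deg, spec.shape, rng,
            )
            if trunk is None or len(cand) > len(trunk):
                trunk, tip_heading = cand, cand_heading
            if len(cand) >= int(round(length)):
                break
        if trunk is None or len(trunk) < 2:
            continue
        centerlines.append(trunk)
        widths.append(rng.uniform(*spec.branch_width))
        tips = [(trunk[-1], tip_heading, len(centerlines) - 1)]
        for _ in range(n_bifurcations):
            if not tips:
                break
            pos, head, parent_idx = tips.pop(int(rng.integers(len(tips))))
            daughters = []
            for sign in (-1.0, 1.0):
                length = rng.uniform(*spec.branch_length)
                child, child_tip_heading = None, 0.0
                for attempt in range(10):
                    child_heading = head + sign * rng.uniform(25.0, 55.0)
                    cand, cand_heading = _random_walk(
                        pos, child_heading, length,
                        spec.curvature_deg, spec.shape, rng,
                    )
                    if child is None or len(cand) > len(child):
                        child, child_tip_heading = cand, cand_heading
                    if len(cand) >= int(round(length)):
                        break
                # a daughter stopped by the frame margin well short of its
                # requested length is dropped: branches below a few tracer
                # steps are beneath the method's resolution
                if child is None or len(child) - 1 < max(20.0, 0.4 * length):
                    continue
                daughters.append((child, child_tip_heading))
            # a bifurcation is kept only when both daughters realize their
            # length: a lone daughter would continue its parent without any
            # junction and blur the branch accounting
            if len(daughters) == 2:
                for child, child_tip_heading in daughters:
                    centerlines.append(child)
                    widths.append(rng.uniform(*spec.branch_width))
                    tips.append((child[-1], child_tip_heading,
                                 len(centerlines) - 1))

    truth = GroundTruth.from_centerlines(centerlines, widths)
    img = _render(spec, truth, rng)
    return img, truth


def _render(spec: PhantomSpec, truth: GroundTruth, rng) -> GrayImage:
    h, w = spec.shape
    ridge = np.zeros((h, w))
    for polyline, width in zip(truth.centerlines, truth.widths):
        mask = np.zeros((h, w), dtype=bool)
        pts = np.round(polyline).astype(int)
        for a, b in zip(pts, pts[1:]):
            rr, cc = draw_line(a[0], a[1], b[0], b[1])
            mask[np.clip(rr, 0, h - 1), np.clip(cc, 0, w - 1)] = True
        if not mask.any():
            continue
        dist = ndimage.distance_transform_edt(~mask)
        sigma = max(width / 2.0, 0.5)
        ridge = np.maximum(ridge, np.exp(-dist ** 2 / (2.0 * sigma ** 2)))

    img = spec.bg_level + (spec.fg_level - spec.bg_level) * ridge

    rows, cols = np.mgrid[0:h, 0:w]
    for _ in range(spec.n_halo_spots):
        cr, cc = rng.uniform(0, h - 1), rng.uniform(0, w - 1)
        radius = rng.uniform(7.5, 15.0)
        # halo rings are thick annuli (band wider than a tracer step), the
        # polygonal regime the linear-object test is immune to
        band = rng.uniform(6.0, 10.0)
        d = np.sqrt((rows - cr) ** 2 + (cols - cc) ** 2)
        ring = np.abs(d - radius) < band / 2.0
        img[ring] = np.maximum(img[ring], spec.fg_level)
    for _ in range(spec.n_debris):
        cr = int(rng.integers(0, h))
        cc = int(rng.integers(0, w))
        rr, dd = draw_disk((cr, cc), rng.uniform(1.0, 2.5), shape=(h, w))
        img[rr, dd] = np.maximum(img[rr, dd], rng.uniform(0.6, 1.0) * spec.fg_level)

    if spec.illum_gradient > 0:
        img = img * (1.0 - spec.illum_gradient * cols / max(w - 1, 1))
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
    if spec.quantize_bits:
        levels = 2 ** spec.quantize_bits - 1
        img = np.round(np.clip(img, 0.0, 1.0) * levels) / levels
    img = np.clip(img, spec.eps, 1.0)
    return GrayImage(img, eps=spec.eps)


def tip_seeds(truth: GroundTruth, join_tol: float = 1.5) -> list[Seed]:
    """One random seed per branch, at a free tip where the branch has one.

    A polyline end is *free* when no other branch starts or ends there
    (within ``join_tol`` pixels); branches whose both ends are junctions
    get their seed at the midpoint instead — the reaction seed covers the
    other half.
    """
    seeds = []
    all_ends = [c[i] for c in truth.centerlines for i in (0, -1)]
    for line in truth.centerlines:
        chosen = None
        for idx in (-1, 0):
            end = line[idx]
            near = sum(
                1 for e in all_ends
                if np.hypot(*(e - end)) <= join_tol
            )
            if near <= 1:  # only this polyline's own end is here
                chosen = end
                break
        if chosen is None:
            chosen = line[len(line) // 2]
        seeds.append(Seed(Point(float(chosen[0]), float(chosen[1]))))
    return seeds


@dataclass
class TraceMetrics:
    """Agreement between a trace result and phantom ground truth."""

    recall: float
    precision: float
    length_rel_error: float
    branch_count_error: int
    length_error_defined: bool = True


def truth_samples(truth: GroundTruth, spacing: float = 1.0) -> np.ndarray:
    """Resample all truth centerlines at roughly unit spacing."""
    out = []
    for line in truth.centerlines:
        if len(line) < 2:
            out.append(line)
            continue
        seg = np.sqrt((np.diff(line, axis=0) ** 2).sum(axis=1))
        t = np.concatenate([[0.0], np.cumsum(seg)])
        n = max(int(math.floor(t[-1] / spacing)) + 1, 2)
        ti = np.linspace(0.0, t[-1], n)
        out.append(
            np.column_stack([np.interp(ti, t, line[:, 0]),
                             np.interp(ti, t, line[:, 1])])
        )
    return np.vstack(out) if out else np.empty((0, 2))


def evaluate_trace(result, truth: GroundTruth, tol_px: float = 3.0) -> TraceMetrics:
    """Centerline recall/precision, length error and branch-count error.

    Recall is the fraction of truth centerline samples within ``tol_px``
    of a predicted set pixel; precision the fraction of predicted set
    pixels within ``tol_px`` of the truth.  An empty prediction scores
    recall 0 and precision 0.  With an empty truth the length error is
    undefined and flagged.
    """
    if tol_px <= 0:
        raise ParameterError("tol_px must be positive")
    pred_pixels = np.argwhere(result.binary_map)
    pred_length = float(sum(b.length_px for b in result.branches))
    pred_count = len(result.branches)
    return evaluate_pixels(pred_pixels, pred_length, pred_count, truth, tol_px)


def evaluate_pixels(pred_pixels: np.ndarray, pred_length: float,
                    pred_branch_count: int, truth: GroundTruth,
                    tol_px: float = 3.0) -> TraceMetrics:
    """Metric computation on raw predicted pixels (used by the CLI eval)."""
    if tol_px <= 0:
        raise ParameterError("tol_px must be positive")
    samples = truth_samples(truth)
    pred_pixels = np.asarray(pred_pixels, dtype=float).reshape(-1, 2)

    if len(pred_pixels) == 0 or len(samples) == 0:
        recall = 0.0
        precision = 0.0
    else:
        pred_tree = cKDTree(pred_pixels)
        truth_tree = cKDTree(samples)
        d_truth, _ = pred_tree.query(samples)
        recall = float(np.mean(d_truth <= tol_px))
        d_pred, _ = truth_tree.query(pred_pixels)
        precision = float(np.mean(d_pred <= tol_px))

    if truth.total_length_px > 0:
        rel = abs(pred_length - truth.total_length_px) / truth.total_length_px
        defined = True
    else:
        rel = float("nan")
        defined = False
    return TraceMetrics(
        recall=recall,
        precision=precision,
        length_rel_error=float(rel),
        branch_count_error=int(pred_branch_count - truth.branch_count),
        length_error_defined=defined,
    )


def truth_to_json(truth: GroundTruth) -> dict:
    return {
        "centerlines": [c.tolist() for c in truth.centerlines],
        "total_length_px": truth.total_length_px,
        "branch_count": truth.branch_count,
        "widths": truth.widths,
    }


def truth_from_json(obj: dict) -> GroundTruth:
    return GroundTruth(
        [np.asarray(c, dtype=float) for c in obj["centerlines"]],
        float(obj["total_length_px"]),
        int(obj["branch_count"]),
        list(obj.get("widths", [])),
    )
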