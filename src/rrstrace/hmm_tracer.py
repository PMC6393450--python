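"""HMM centerline tracing: candidate paths, Viterbi search, node classification.

The tracer treats the unknown neurite centerline as the hidden state of an
HMM whose observations are image intensities.  One search *block* links N
events: at each event every surviving position is extended by a fan of
fixed-length candidate steps (arrow-paths), each step scored by the sum of
log pixel intensities along it, and the single maximum-score path through
the whole trellis is recovered by backtracking from the final event.
Because positions are continuous the trellis is a tree, so the dynamic
program is exactly equivalent to exhaustive maximization over all
``k_initial * k_step**(N-1)`` candidate paths.

A node is then accepted as a *neurite object* when the mean intensity
along its incoming step strictly exceeds the median of the surrounding
zone — a test that fires on chain-like linear structures narrower than
the step length and stays silent inside filled polygonal objects (halo
rings, somata, debris blobs) as well as on flat background.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import GeometryError, ParameterError
from .imaging import (
    GrayImage,
    Point,
    _segment_coords,
    _segment_ts,
    bilinear,
    sample_line,
    sample_zone,
)
from .seeding import Seed

STEP_SPAN_DEG = 90.0  # fan width for every event after the first


@dataclass
class TracerConfig:
    """Tunable parameters of the tracer.

    Attributes
    ----------
    step_length_r
        Length r of every candidate arrow-path, in pixels.  Structures wider
        than r look polygonal to the node test and are ignored; keep r above
        the neurite diameter.
    n_events
        Number N of linked events per search block.
    k_initial, k_step, k_reaction
        Candidate headings for the initial 360-degree fan of a random seed,
        the 90-degree fan of every subsequent event, and the 180-degree fan
        of a reaction seed.
    line_width
        Half-width of the classification zone; the zone extends line_width
        pixels on each side of the step segment.
    spacing
        Sample spacing along segments, in pixels.
    eps
        Intensity floor of the normalized image (log stays finite).
    max_nodes
        Hard cap on nodes per chain, guaranteeing termination.
    extend_min_run
        A chain keeps extending with further blocks only while the latest
        block contains at least this many consecutive neurite-object nodes.
    extend_patience
        Number of consecutive blocks allowed to miss the ``extend_min_run``
        requirement before the trace stops.  The default of 2 lets a chain
        survive one unrecognized block — e.g. while crossing a junction,
        where the surrounding zone contains several bright arms and the
        object test goes locally blind — without letting dead chains roam.
    object_margin
        Contrast margin of the neurite-object test: a node is an object only
        when the line mean exceeds the zone median by more than this amount
        (normalized intensity units).  The margin makes the test robust to
        per-pixel noise, whose brightest streaks the Viterbi search actively
        selects; 0 recovers the bare strict comparison, which on noisy
        backgrounds accepts the selected noise path most of the time.
    """

    step_length_r: float = 5.0
    n_events: int = 8
    k_initial: int = 32
    k_step: int = 3
    k_reaction: int = 13
    line_width: float = 2.0
    spacing: float = 1.0
    eps: float = 1e-3
    max_nodes: int = 400
    extend_min_run: int = 2
    extend_patience: int = 2
    object_margin: float = 0.05

    def __post_init__(self) -> None:
        if self.step_length_r < 2:
            raise ParameterError("step_length_r must be >= 2 pixels")
        if self.n_events < 3:
            raise ParameterError("n_events must be >= 3")
        if not self.k_initial >= self.k_step >= 2:
            raise ParameterError("need k_initial >= k_step >= 2")
        if self.extend_min_run < 1:
            raise ParameterError("extend_min_run must be >= 1")


@dataclass(frozen=True)
class CandidatePath:
    """One scored arrow-path of length r between consecutive events."""

    from_pos: Point
    to_pos: Point
    index: int
    log_cost: float


@dataclass
class ChainNode:
    """One HMM node: position, arrival direction and neurite-object flag."""

    event_index: int
    position: Point
    is_object: bool = False
    incoming_heading_deg: float | None = None


@dataclass
class Chain:
    """A traced search chain; ``stored`` marks recognized neurite bodies."""

    seed: Seed
    nodes: list[ChainNode] = field(default_factory=list)
    stored: bool = False

    @property
    def object_flags(self) -> np.ndarray:
        return np.array([n.is_object for n in self.nodes], dtype=bool)

    @property
    def n_object_nodes(self) -> int:
        return int(self.object_flags.sum())

    @property
    def is_active(self) -> bool:
        """At least one node captured a real neurite object."""
        return self.n_object_nodes >= 1

    def object_nodes(self) -> list[ChainNode]:
        return [n for n in self.nodes if n.is_object]

    def longest_object_run(self) -> int:
        return _longest_run(self.object_flags)


def _longest_run(flags) -> int:
    best = run = 0
    for f in flags:
        run = run + 1 if f else 0
        best = max(best, run)
    return best


def heading_to_unit(deg: float | np.ndarray) -> np.ndarray:
    """Unit (row, col) vector for a heading in degrees.

    Heading 0 points along +col; positive headings rotate counter-clockwise
    in the conventional display (row axis pointing down).
    """
    rad = np.deg2rad(deg)
    return np.stack([-np.sin(rad), np.cos(rad)], axis=-1)


def heading_between(p_from: Point, p_to: Point) -> float:
    """Heading in degrees of the direction from p_from to p_to."""
    return float(
        np.rad2deg(math.atan2(-(p_to.row - p_from.row), p_to.col - p_from.col))
    )


def candidate_headings(center_deg: float, span_deg: float, k: int) -> np.ndarray:
    """k headings (degrees) evenly spread over an angular fan.

    A 360-degree fan ignores the center and covers the full circle at
    ``360/k`` spacing; narrower fans span ``[center - span/2,
    center + span/2]`` inclusive of both endpoints.  Candidate 0 is the
    fan's most counter-clockwise heading.
    """
    if k < 1:
        raise ParameterError("k must be >= 1")
    if span_deg <= 0 or span_deg > 360:
        raise ParameterError("span_deg must be in (0, 360]")
    if span_deg == 360.0:
        return np.arange(k) * (360.0 / k)
    if k == 1:
        return np.array([float(center_deg)])
    return center_deg - span_deg / 2 + np.arange(k) * (span_deg / (k - 1))


def path_log_cost(img: GrayImage, p0, p1, spacing: float = 1.0) -> float:
    """Sum of log pixel intensities along the segment p0 -> p1.

    Intensities are in [eps, 1], so the cost is <= 0 and monotone in
    pointwise image brightness.
    """
    return float(np.sum(np.log(sample_line(img, p0, p1, spacing))))


@dataclass
class BlockResult:
    """Best path of one N-event search block."""

    positions: np.ndarray       # (m+1, 2) float, positions[0] is the start
    headings_deg: np.ndarray    # (m,) incoming heading of each step
    score: float                # accumulated log cost of the best path

    @property
    def n_steps(self) -> int:
        return len(self.headings_deg)

    @property
    def points(self) -> list[Point]:
        return [Point(r, c) for r, c in self.positions]


def viterbi_block(
    img: GrayImage,
    seed_pos,
    initial_fan: tuple[float, float, int],
    config: TracerConfig,
) -> BlockResult:
    """Maximum-likelihood path of one N-event block from a start position.

    ``initial_fan = (center_deg, span_deg, k)`` describes the first event's
    candidate fan; every later event uses a 90-degree fan of ``k_step``
    headings centered on the path's own incoming heading.  Candidates whose
    endpoint leaves the image are dropped; if every candidate of an event is
    dropped the trellis ends early and the best shorter path is returned.
    Ties are broken toward the lowest candidate index at every event.
    """
    if isinstance(seed_pos, Point):
        start = seed_pos.as_array()
    else:
        start = np.asarray(seed_pos, dtype=float)
    if not img.contains(start[0], start[1]):
        raise GeometryError(f"seed position {start} outside image bounds")

    r = config.step_length_r
    ts = _segment_ts(r, config.spacing)
    h_max, w_max = img.height - 1.0, img.width - 1.0
    center, span, k0 = initial_fan

    # Tree levels: each level keeps every surviving partial path, in
    # generation order (parent order, then candidate order) so that argmax
    # resolves ties toward the lowest candidate index at every event.
    pos = start[None, :]
    heading = np.array([0.0])
    score = np.zeros(1)
    parents: list[np.ndarray] = []
    level_pos = [pos]
    level_heading = [heading]

    for event in range(config.n_events):
        m = len(pos)
        if event == 0:
            fans = np.broadcast_to(candidate_headings(center, span, k0), (m, k0))
            k = k0
        else:
            k = config.k_step
            offsets = candidate_headings(0.0, STEP_SPAN_DEG, k)
            fans = heading[:, None] + offsets[None, :]
        new_heading = fans.ravel()
        units = heading_to_unit(new_heading)
        new_pos = np.repeat(pos, k, axis=0) + r * units
        parent = np.repeat(np.arange(m), k)

        ok = (
            (new_pos[:, 0] >= 0.0) & (new_pos[:, 0] <= h_max)
            & (new_pos[:, 1] >= 0.0) & (new_pos[:, 1] <= w_max)
        )
        if not ok.any():
            break
        new_pos, new_heading, parent = new_pos[ok], new_heading[ok], parent[ok]

        starts = pos[parent]
        coords = starts[:, None, :] + ts[None, :, None] * (new_pos - starts)[:, None, :]
        samples = bilinear(img.pixels, coords[..., 0], coords[..., 1])
        edge_cost = np.sum(np.log(samples), axis=1)

        score = score[parent] + edge_cost
        pos, heading = new_pos, new_heading
        parents.append(parent)
        level_pos.append(pos)
        level_heading.append(heading)

    n_steps = len(parents)
    if n_steps == 0:
        return BlockResult(start[None, :], np.empty(0), 0.0)

    best = int(np.argmax(score))
    best_score = float(score[best])
    idx = best
    path_pos = [level_pos[n_steps][idx]]
    path_heading = [level_heading[n_steps][idx]]
    for lev in range(n_steps - 1, 0, -1):
        idx = int(parents[lev][idx])
        path_pos.append(level_pos[lev][idx])
        path_heading.append(level_heading[lev][idx])
    path_pos.append(start)
    path_pos.reverse()
    path_heading.reverse()
    return BlockResult(np.array(path_pos), np.array(path_heading), best_score)


def classify_node(img: GrayImage, p_prev, p_cur, config: TracerConfig) -> int:
    """Neurite-object test for the node reached through p_prev -> p_cur.

    Returns 1 iff the mean intensity along the step segment strictly
    exceeds the median of the surrounding zone intensities by more than
    ``config.object_margin``; ties and low-contrast neighborhoods (constant
    background, the inside of filled polygonal objects) classify as
    background.  A zone with no in-bounds samples returns 0.
    """
    try:
        profile = sample_zone(img, p_prev, p_cur, config.spacing,
                              config.line_width)
    except GeometryError:
        return 0
    zone = profile.valid_zone_samples()
    if zone.size == 0 or profile.line_samples.size == 0:
        return 0
    return int(
        np.median(zone) + config.object_margin < np.mean(profile.line_samples)
    )


def _initial_fan(seed: Seed, config: TracerConfig) -> tuple[float, float, int]:
    if seed.kind == "reaction":
        return (seed.heading_deg, 180.0, config.k_reaction)
    return (0.0, 360.0, config.k_initial)


def trace_from_seed(img: GrayImage, seed: Seed, config: TracerConfig,
                    avoid: list[Point] | None = None) -> Chain:
    """Trace one chain from a seed by chaining search blocks.

    The first block uses the seed's own fan; each further block starts at
    the last node with a 90-degree fan centered on the last incoming
    heading.  Extension continues while the most recent block contains a
    run of at least ``extend_min_run`` consecutive neurite-object nodes
    (the same connectivity standard storage uses), the chain is below
    ``max_nodes``, and the chain has not curled back onto itself: a node
    landing within one step length of the earlier chain body ends the
    trace, since the search otherwise U-turns at a branch tip and
    re-traces the bright ridge it came from indefinitely.  The chain is
    stored iff it contains at least three consecutive neurite-object
    nodes; chains of seeds that capture nothing come back unstored — a
    normal outcome, not an error.

    ``avoid`` lists positions the chain must keep one step length away
    from; a reaction chain passes its primary chain's body here so the
    supplementary trace stops where the primary's coverage begins instead
    of re-tracing it on a parallel track.
    """
    nodes = [ChainNode(0, Point(seed.position.row, seed.position.col))]
    fan = _initial_fan(seed, config)
    pos = seed.position

    returned = False
    misses = 0
    while True:
        block = viterbi_block(img, pos, fan, config)
        if block.n_steps == 0:
            break
        block_flags = []
        prev = pos
        for i in range(block.n_steps):
            cur = Point(float(block.positions[i + 1, 0]),
                        float(block.positions[i + 1, 1]))
            if _returns_to_chain(nodes, cur, config.step_length_r):
                returned = True
                break
            if avoid is not None and _near_any(cur, avoid,
                                               config.step_length_r):
                returned = True
                break
            flag = bool(classify_node(img, prev, cur, config))
            nodes.append(
                ChainNode(len(nodes), cur, flag,
                          float(block.headings_deg[i]))
            )
            block_flags.append(flag)
            prev = cur
            if len(nodes) >= config.max_nodes:
                break
        pos = nodes[-1].position
        if returned or len(nodes) >= config.max_nodes:
            break
        if _longest_run(block_flags) < config.extend_min_run:
            misses += 1
            if misses >= config.extend_patience:
                break
        else:
            misses = 0
        fan = (nodes[-1].incoming_heading_deg, STEP_SPAN_DEG, config.k_step)

    chain = Chain(seed, nodes)
    chain.stored = chain.longest_object_run() >= 3
    return chain


def _returns_to_chain(nodes: list[ChainNode], cur: Point, r: float) -> bool:
    """U-turn detector: the candidate node re-enters the chain's own body.

    True when ``cur`` lies within one step length of any chain node other
    than the two most recent ones (consecutive nodes are exactly r apart
    and a maximal 45-degree-per-event turn keeps the next two nodes
    farther than r, so genuine forward progress never triggers this).
    """
    if len(nodes) < 3:
        return False
    for node in nodes[:-2]:
        if cur.distance_to(node.position) < r:
            return True
    return False


def _near_any(cur: Point, points: list[Point], r: float) -> bool:
    return any(cur.distance_to(p) < r for p in points)
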