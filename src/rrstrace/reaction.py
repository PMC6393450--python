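"""Reaction seeding: complete a one-way trace into a whole-branch trace.

The HMM tracer is strictly predictive, so a random seed landing in the
middle of a branch covers only the part ahead of it.  A *reaction seed*
repairs this: whenever a primary chain is active (captured at least one
neurite object), a secondary seed is placed at the chain's first object
node, pointing in the exact opposite direction of the chain's first two
object nodes, with a 180-degree search fan.  The union of the primary and
reaction chains then covers the whole branch from a single initial seed.
"""

from __future__ import annotations

from .hmm_tracer import Chain, TracerConfig, heading_between, trace_from_seed
from .imaging import GrayImage
from .seeding import Seed


def spawn_reaction_seed(chain: Chain) -> Seed | None:
    """Derive the reaction seed of a primary chain, or None if inactive.

    The seed sits on the first neurite-object node and points opposite the
    direction from the first toward the second object node; when only one
    object node exists, opposite that node's own incoming heading.
    """
    objects = chain.object_nodes()
    if not objects:
        return None
    first = objects[0]
    if len(objects) >= 2:
        forward = heading_between(first.position, objects[1].position)
    else:
        forward = first.incoming_heading_deg or 0.0
    return Seed(
        position=first.position,
        heading_deg=(forward + 180.0) % 360.0,
        span_deg=180.0,
        kind="reaction",
        origin="reaction",
    )


def trace_branch(
    img: GrayImage, seed: Seed, config: TracerConfig
) -> tuple[Chain, Chain | None]:
    """Trace the primary chain and, if it is active, its reaction chain.

    Returns ``(primary, reaction)``; the reaction chain is None for dead
    seeds.  The union of the two chains is the branch trace.  The reaction
    chain is supplementary by construction: it terminates if it comes back
    onto the part of the branch the primary chain already covers, so a
    reaction seed born at a branch tip dies immediately instead of
    re-tracing the branch on a parallel track.
    """
    primary = trace_from_seed(img, seed, config)
    rseed = spawn_reaction_seed(primary)
    if rseed is None:
        return primary, None
    start = rseed.position
    avoid = [
        n.position for n in primary.nodes
        if start.distance_to(n.position) > 1.5 * config.step_length_r
    ]
    reaction_chain = trace_from_seed(img, rseed, config, avoid=avoid)
    return primary, reaction_chain
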