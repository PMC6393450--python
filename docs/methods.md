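# Methods

This note documents the model behind `rrstrace`, the parameters that
matter, what the synthetic phantoms do and do not emulate, and the design
choices made where the method itself leaves the design open.

## Tracing model

The centerline of a neurite is treated as the hidden state sequence of an
HMM observed through pixel intensities. All intensities are affinely
normalized to `[ε, 1]` (default ε = 10⁻³) so that the log-likelihood of a
path is finite everywhere and non-positive.

One **search block** links `N` events. At each event every surviving
position is extended by a fan of candidate headings; a candidate step is
the straight segment of length `r` in that direction, scored by the sum
of `log I` over bilinear samples at unit spacing along it (endpoints
inclusive). Because positions are continuous, trellis states never merge:
the dynamic program over the block is a tree whose leaves are all
`k_initial · k_step^(N−1)` candidate paths, and backtracking from the
best final event recovers exactly the exhaustive maximum (this exactness
is asserted against a brute-force enumerator in the tests). Candidates
whose endpoint leaves the image are dropped; ties resolve toward the
lowest candidate index, which makes dead seeds on flat backgrounds curl
into a characteristic circular pattern rather than behave randomly.

The node reached through a step is accepted as a **neurite object** when

```
Mean(I_line) > Median(I_zone) + δ
```

where `I_line` are the step's samples and `I_zone` a rectangular lattice
sharing the step's along-axis samples and extending `line_width` to each
side (perpendicular extent `2 × line_width`). The comparison is what
makes the search selective for *chain-like* structures: on a thin bright
ridge the line is bright and the zone median samples background; inside a
filled polygonal object (halo annulus, soma, debris blob) or on flat
background, line and zone agree and the node is rejected.

### Why the margin δ exists

With δ = 0 the test accepts the selected path on *any* noisy background:
the Viterbi search maximizes path brightness, which biases `Mean(I_line)`
upward by ≈ 0.6 σ relative to the zone median, independent of the noise
scale σ. Measured on pure-noise images, the strict test fires on ~84% of
nodes of the selected path, so chains never terminate. A small absolute
margin (default δ = 0.05 on the normalized scale) restores the intended
behavior: it exceeds the selection bias for realistic noise (σ ≲ 0.1)
while staying far below on-ridge contrast (≥ 0.25 at default phantom
levels). δ = 0 recovers the bare rule. The flip side is a dither effect:
when a structure's contrast sits *near* the margin, adding noise can push
borderline nodes over it and recall can transiently *increase* with
noise before tracking collapses (see Limitations).

## Chains, termination, reaction seeds

A chain begins at a seed (random seeds: 360° fan; reaction seeds: 180°)
and repeatedly appends blocks, each new block starting at the last node
with a 90° fan centered on the incoming heading. Extension stops when

1. the most recent block lacks a run of `extend_min_run` (default 2)
   consecutive object nodes for `extend_patience` (default 2) blocks in a
   row — the patience lets a chain survive one blind block, e.g. while
   crossing a junction, where the zone contains several bright arms and
   the object test goes locally silent;
2. a node lands within `r` of the chain's own earlier body — without
   this, a chain reaching a branch tip U-turns (the 90° fan plus bright
   ridge behind make the turn the maximum-likelihood continuation) and
   re-traces the branch indefinitely; or
3. the node cap (default 400) is reached.

A chain is **stored** iff it contains ≥ 3 consecutive object nodes.

An active chain spawns one **reaction seed** at its first object node,
pointing opposite the direction from the first toward the second object
node (opposite the node's own incoming heading if it is the only one),
with a 180° fan. The reaction chain additionally terminates when it
reaches the primary chain's body: it is supplementary by construction, so
a reaction seed born at a branch tip dies immediately instead of
re-tracing the branch on a parallel track.

## From chains to branches

Stored chains are rasterized by interconnecting successive object nodes
no more than 3 events apart, drawing through the intermediate node
positions (a straight chord would cut corners at junction crossings).
The union map is then fused by binary closing (disk 1) and small-hole
filling — overlapping chains draw near-parallel 1-px braids whose loops
survive topology-preserving thinning otherwise — skeletonized, endpoint
gaps up to `3r` are bridged to the nearest pixel of a *different*
component when the bridge continues the endpoint's own tangent (the
object test's junction blind spot often leaves an arm ending a few
pixels short of the rest), and terminal twigs shorter than `2r` abutting
a junction are pruned.

Branch parting walks the thinned map from its top-left-most endpoint,
removing pixels until a dead end or a junction pixel; junction status is
fixed by the input map (thinning smears one junction over a small pixel
cluster, and a junction must stop later arrivals even after part of the
cluster is claimed), and the first branch to arrive claims the junction
pixel. Leftover cluster crumbs (≤ 5 px) are folded into the adjacent
branch. The result is a strict partition of the set pixels; branch length
is the Euclidean length of the pixel polyline, and total branch length
their sum. SWC export builds one tree per connected component by
breadth-first traversal.

## Parameters

| name | default | meaning |
|------|---------|---------|
| `step_length_r` | 5 px | candidate step length; structures wider than r look polygonal and are ignored |
| `n_events` | 8 | events per search block |
| `k_initial` | 32 | headings in the 360° fan of a random seed. All later headings live on a 45° grid anchored at the chosen initial heading, so the initial granularity (11.25°) bounds the heading error of the whole chain; coarser fans cause lateral zigzag that starves the object test |
| `k_step` | 3 | headings per 90° step fan |
| `k_reaction` | 13 | headings in the 180° reaction fan |
| `line_width` | 2 px | half-width of the classification zone; must exceed the radius of the thickest neurite expected (default phantoms: width ≤ 3 px) so the zone median reaches background |
| `spacing` | 1 px | sample spacing along segments |
| `object_margin` | 0.05 | contrast margin δ of the object test |
| `extend_min_run`, `extend_patience` | 2, 2 | chain-extension rule (above) |
| `max_nodes` | 400 | hard chain-length cap |

Phantom defaults (`PhantomSpec`): 512×512 canvas (tests use smaller),
foreground 0.8 vs background 0.15, Gaussian noise σ = 0.05, bifurcating
trees with branch lengths 40–120 px and widths 1–3 px, heading drift
≤ 2°/px, 2 halo annuli (radius 7.5–15 px, band 6–10 px — *thick* rings,
the polygonal regime the tracer must ignore), 20 debris dots, a 20%
illumination gradient, and 8-bit quantization.

## What the phantoms emulate — and what they do not

The generator reproduces the artifact inventory of immunofluorescence
slides: bright halo rings, dot-like debris, uneven illumination,
per-pixel noise, quantization. Trees grow strictly by bifurcation at
tips, so ground-truth branches are junction-delimited polylines matching
the semantics of branch parting; daughters that cannot realize at least
20 px (frame margin) are dropped. The phantoms do **not** model
out-of-focus point-spread blur across focal planes, spatially correlated
(smooth) background, curvilinear debris, branch crossings in projection,
or microfluidic device geometry. Passing tests on phantoms therefore
demonstrate the mechanics of seeding, tracing, classification and
parting under controlled degradation — not performance on any particular
microscope's data.

## Numerical choices

* Bilinear interpolation everywhere; pixel centers at integer (row, col).
* Sample count per segment is `floor(dist/spacing) + 1` with a 10⁻⁹
  slack so float jitter in a nominally fixed-length step cannot change
  the count; identical arithmetic is used for single segments and the
  vectorized block search, so block scores are bitwise reproducible and
  exactly comparable to the brute-force oracle.
* Ties in the trellis resolve to the lowest candidate index (candidate 0
  is the fan's most counter-clockwise heading).
* Degenerate inputs: constant images normalize to ε everywhere; a
  constant image yields no edges/skeleton/blobs and seed generators
  return empty lists with a warning; zones clipped at borders drop the
  out-of-bounds samples and flag truncation; fully out-of-bounds zones
  classify as background.

## Known limitations

* **Junction blind spot.** Near a junction the zone contains several
  bright arms, the median rises, and nodes go unrecognized for ~r around
  the junction point. Gap bridging and endpoint linking recover most
  junctions, but on dense trees the parted branch count can still be off
  by one in either direction (measured: exact on roughly 70–80% of
  random tip-seeded phantoms; summed length within 10% on ~85%).
* **Tip overshoot.** A spurious object within 3 events past a branch tip
  extends the trace by up to ~10 px; on short (~40 px) branches this can
  exceed 10% relative length.
* **Noise dither.** Because the object test uses a fixed margin, mean
  recall is not strictly monotone in noise level: near-margin structures
  are recognized *more* often under moderate noise. Monotone degradation
  holds once noise dominates (σ ≳ 0.4) and on well-contrasted phantoms.
* **Raster length bias.** Branch length is measured on the 8-connected
  pixel polyline, which overestimates smooth curves by up to ~8%
  depending on orientation.
* Heading resolution is bounded by the initial fan; curvature sharper
  than ~45° per step (radius < ~7 px) cannot be followed.
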