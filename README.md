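# rrstrace

Random-reaction-seed (RRS) tracing of neurite elongation and branching in
low-SNR 2-D fluorescence micrographs.

Neurite outgrowth studies — especially in microfluidic chambers, where
somata are compartmentalized away from the neurites — produce large,
noisy, stitched images in which classical deterministic pipelines
(thresholding + skeletonization, Canny edges) shatter into broken
fragments and halo artifacts. `rrstrace` implements a stochastic
alternative: seeds thrown at random start hidden-Markov-model searches
that follow bright curvilinear ridges, a local intensity test decides
which search nodes actually lie on a neurite, and secondary *reaction
seeds* complete each one-way trace into a whole-branch trace. The union
of all traces is rasterized, parted into branches, measured, and exported
as SWC/CSV.

## The method

The tracer treats the unknown centerline as the hidden state of an HMM
whose observations are pixel intensities, normalized to `[ε, 1]`.

* **Block search.** From a position, a fan of candidate headings is
  expanded; each candidate step of fixed length `r` (default 5 px) is
  scored by `Σ log I` over bilinear samples along the step. A block links
  `N = 8` such events; the maximum-score path through the block is
  recovered by backtracking from the final event and equals exhaustive
  maximization over all `k_initial · k_step^(N−1)` candidate paths.
  Fresh random seeds search 360° (32 candidate headings), reaction seeds
  180° (13), and every subsequent event 90° (3).
* **Neurite-object test.** A node reached through segment *s* is a
  neurite object iff `Mean(I_line) > Median(I_zone) + δ`, where `I_line`
  are the samples along *s* and `I_zone` a surrounding lattice twice the
  line width across (default ±2 px; margin δ = 0.05). The test fires on
  chain-like objects narrower than `r` and stays silent inside filled
  polygonal structures (halo rings, somata, debris) and on background.
* **Storage rule.** Only chains containing ≥ 3 consecutive object nodes
  are stored; everything else is a dead seed — a normal outcome.
* **Reaction seeding.** An active chain spawns one secondary seed at its
  first object node, pointed opposite the direction of its first two
  object nodes, with a 180° fan. The HMM is strictly predictive (one-way),
  so the reaction chain supplies the part of the branch behind the random
  seed: one lucky seed per branch suffices.
* **Branching.** Stored chains are rasterized into a binary map
  (overlaps merge), thinned, and parted by walking pieces from endpoints
  until a junction is claimed or a dead end reached — a strict partition
  of the map's pixels into branch polylines, from which total branch
  length is measured.

Everything is testable offline: `rrstrace.synthetic` generates neurite
phantoms (bifurcating random-walk trees, Gaussian ridge cross-sections)
with the artifact inventory of real slides — halo annuli, dot debris,
illumination gradient, Gaussian noise, 8-bit quantization — plus exact
ground-truth centerlines and scoring (recall, precision, length error,
branch count).

## Worked example

```python
import numpy as np
from rrstrace import (PhantomSpec, TracerConfig, generate_phantom,
                      tip_seeds, run_rrs, evaluate_trace)

spec = PhantomSpec(shape=(256, 256), n_trees=1, branches_per_tree=(3, 5),
                   n_halo_spots=0, n_debris=0, rng_seed=12)
img, truth = generate_phantom(spec)          # phantom + known centerlines
res = run_rrs(img, seeds=tip_seeds(truth),   # one seed per branch tip
              config=TracerConfig(), rng_seed=0)
m = evaluate_trace(res, truth, tol_px=3.0)
print(f"truth branches: {truth.branch_count}, traced: {len(res.branches)}")
print(f"recall {m.recall:.3f}  precision {m.precision:.3f}  "
      f"length error {m.length_rel_error:.3f}")
```

Output:

```
truth branches: 3, traced: 3
recall 0.986  precision 0.984  length error 0.092
```

Three seeds, one per branch tip, recover all three branches of the
phantom tree; 98.6% of the true centerline lies within 3 px of the
trace, 98.4% of traced pixels lie near the truth, and the summed branch
length is within 9.2% of the true 209 px.

The same pipeline runs from the shell:

```bash
rrs synth --spec spec.json --out phantom.tif --truth truth.json
rrs trace --input phantom.tif --channel green --strategy skeleton \
          --n-seeds auto --rng-seed 3 --out results/run1
rrs eval  --pred results/run1 --truth truth.json
```

`rrs trace` writes an SWC morphology file (one tree per connected
component), a branch CSV (id, component, length, pixels), a PNG overlay
and a JSON manifest echoing the full configuration.

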