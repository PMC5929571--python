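# trajkit

Trajectory mining for large 3D+t cell-tracking data sets.

Modern light-sheet microscopy of developing embryos yields tracking
results with thousands of cell migration trajectories — typically as
Cell Tracking Challenge exports, TrackMate XML or TGMM per-frame XML.
Turning those raw lineages into biology requires a small set of
recurring operations: quantitative per-track features, isolation of
anatomically meaningful cell groups ("virtual dissection"), local
tissue-deformation measures, and repair of the fragmented tracks that
every automatic tracker produces. `trajkit` implements this toolbox as
a scriptable Python library with a thin command-line layer, aimed at
quantitative developmental biologists and image-analysis engineers who
want reproducible, replayable analyses rather than interactive one-off
sessions.

## Data model

All inputs become a **lineage forest**: tracks are runs of detections at
consecutive frames with positions in micrometres; cell divisions link a
parent track to its daughter tracks; merges are disallowed, so the
structure is a forest. Operations (temporal/spatial cropping, span
filtering, merging, splitting) are pure functions that return new
forests and log every severed division link.

## Core quantities

For a track with positions $x_0, \dots, x_{n-1}$:

- path length $L = \sum_t \lVert x_{t+1} - x_t \rVert$ and displacement
  $d = \lVert x_{n-1} - x_0 \rVert$; the **displacement ratio** $d/L \in
  [0, 1]$ is near 1 for straight tracks and near 0 for U-shaped tracks
  that return to their origin — the signature of involuting cells during
  gastrulation.
- per-frame series: speed, local density (neighbours within a 40 µm
  sphere), directional change, distance to a reference point; group
  time courses are summarised by median, mean or quantiles.

For **tissue deformation**, the velocities of all cells within a radius
of a reference cell are fitted by an affine field
$v \approx A\,(x - x_\mathrm{ref}) + b$. With $A' = A - \tfrac{1}{3}
\mathrm{tr}(A) I$ the deviatoric part, the reported invariants are

- volume change rate $P = \mathrm{tr}(A)$ (expansion > 0, compression < 0),
- rotation discriminant $D = \tfrac{27}{4} R^2 + Q^3$ with
  $Q = -\tfrac{1}{2}\mathrm{tr}(A'^2)$, $R = -\det A'$; $D > 0$ exactly
  when $A'$ has a complex eigenpair, i.e. the neighbourhood spirals,
- distortion rate $Q_d = \lVert \mathrm{sym}(A) - \tfrac{1}{3}
  \mathrm{tr}(A) I \rVert_F$, the rate of volume-preserving cell
  rearrangement.

Tracks are optionally denoised first with a zero-phase order-2
Butterworth low-pass filter (normalized cutoff 0.01).

**Virtual dissection** composes selection predicates (feature intervals,
feature-space polygons, spatial regions at a frame, deterministic
k-means clustering, set algebra) into a recorded selection tree that
serializes to JSON and replays on other data sets. Tracks too short to
classify are assigned by a per-frame majority vote of their k nearest
labelled neighbours. **Curation** scores putative joins between track
ends and later track starts (distance plus intensity difference), links
everything below a distance threshold with globally one-to-one conflict
resolution, and offers a deterministic, log-replayable review queue.

A built-in simulator generates a two-population synthetic gastrula
(spreading "epiblast", involuting "hypoblast" with U-shaped tracks),
analytic affine-flow point clouds, and a track-fragmentation corruptor —
all with known ground truth, so every pipeline is testable end to end.

## Worked example

```python
import trajkit as tk
from trajkit.selection import SelectionTree, propagate_labels

forest, truth = tk.simulate_embryo(tk.EmbryoSimConfig(seed=1))
kept, short = tk.filter_by_span(forest, 0.7)          # tracks >= 70% of movie
tree = SelectionTree(kept)
lo, hi = tree.cluster_members(tree.root, ["displacement_ratio"], 2)
labeled = {t: "hypoblast" for t in lo.members} | {t: "epiblast" for t in hi.members}
propagated, _ = propagate_labels(forest, labeled, set(short.tracks))
```

Running `python examples/03_virtual_dissection.py` prints:

```
embryo A (seed 1): developing the selection
  599 clustered + 41 propagated tracks, 0 unassigned; accuracy vs ground truth 99.53%
embryo B (seed 7): replaying the exported template
  596 clustered + 70 propagated tracks, 0 unassigned; accuracy vs ground truth 100.00%
```

i.e. clustering the long tracks on the displacement ratio and
propagating labels to the short ones recovers the generating populations
almost perfectly, and the exported selection tree reproduces the
dissection on an independently simulated embryo. The other scripts in
`examples/` demonstrate feature extraction, the deformation invariants
on analytic flows, track curation and format round trips; each prints
the numbers it computes and what they mean.

The same workflows are available from the shell:

```bash
trajkit simulate --seed 1 --out sim/
trajkit dissect --input sim/embryo.csv --format csv --out run/
trajkit curate --input sim/embryo.csv --format csv --threshold 3.0 --out cur/
```

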