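# Methods

This note documents the models and procedures implemented in `trajkit`,
the parameter choices that matter, and what the synthetic test substrate
does and does not show about real data.

## Lineage-forest model

A tracking result is a set of tracks — runs of detections at strictly
consecutive frames — connected by parent→daughter links from cell
divisions. Merges (two parents for one object) are not representable:
importers keep the earlier link and log a warning. Positions are stored
in physical micrometres; voxel sizes are applied exactly once, at
import. Frames are 0-based; developmental time is attached by a single
calibration, `hpf(t) = time_origin + t · frame_interval / 3600`, and any
operation asked to work in hpf without that calibration raises rather
than guessing.

Structural operations are pure (the input forest is never mutated) and
conservative about lineage: a temporal crop that cuts through a division
severs the link and records it (`forest.severed_links`), because
silently re-rooting daughters would corrupt lineage statistics. Source
tracks with internal frame gaps are split at the gaps on import — the
model's "no internal gaps" invariant is what makes velocity estimation
and merging unambiguous — and the curation module can re-join them
explicitly, with interpolated detections flagged as synthetic.

The span filter keeps a track iff its frame count is at least
`ceil(fraction · L)` where `L` is the forest's *current* interval length
in frames, i.e. the filter is meant to run after cropping, matching the
order of the dissection workflow. The default fraction is 0.7.

## Track features

Single features (per track): time span, path length, displacement,
displacement ratio, centroid, mean speed, mean direction change, start
and end positions. Conventions worth stating:

- the displacement ratio of a zero-length path is defined as 1 — a
  stationary cell never deviates from the straight line between its
  endpoints, and the definition keeps the feature bounded without a
  division by zero;
- direction change is the angle between successive displacement
  vectors; zero-length steps contribute angle 0 (the only convention
  that needs no arbitrary reference direction);
- quantile aggregation uses linear interpolation between order
  statistics, the numpy/pandas default.

Time-series features (per track and frame): speed, local density
(detections of other tracks within a fixed sphere, default radius
40 µm, self excluded), direction change, and distance to a caller-
supplied reference point. 40 µm is the package-wide spatial scale: it is
also the default deformation neighbourhood and label-propagation radius,
so one parameter controls "local" everywhere.

Smoothing is *explicit and never implicit*: features operate on whatever
forest they are given, so workflows that cluster on raw tracks but
compute deformation on denoised tracks are both expressible. The
smoother is a zero-phase (forward–backward) Butterworth low-pass filter,
order 2, normalized cutoff 0.01 — aggressive enough to suppress frame-
to-frame localisation noise while keeping the global track shape. Its
zero-phase application has unit DC gain (constant tracks pass bit-near-
exactly). Numerical detail: at cutoff 0.01 the filter's settling length
is roughly `3/cutoff = 300` samples, so the edge padding is extended to
`min(n − 1, 300)` samples (odd extension) instead of the library default
of 9; without this, edge transients dominate tracks shorter than a few
hundred frames. Tracks too short to filter stably (fewer than ~10
frames) fall back to a centred moving average of window 3, with a
notice in the forest log.

## Deformation invariants

For every detection, the velocities of all same-frame detections within
the neighbourhood radius are fitted by least squares with an affine
field `v ≈ A (x − x_ref) + b`. Velocities come from finite differences
per track: central at interior frames, one-sided at track ends (exact
for trajectories affine in time at interior frames). A fit is marked
invalid — NaN, never zero-filled, so group medians are not biased —
when fewer than 4 neighbours are available or the centred position
scatter matrix has condition number above 1e8 (e.g. coplanar
neighbourhoods).

From the fitted tensor `A`, with `P = tr(A)` and deviatoric part
`A' = A − (P/3) I`:

- `P` (1/frame) is the local volume change rate: positive for
  expansion, negative for compression;
- `D = (27/4) R² + Q³` with `Q = −tr(A'²)/2`, `R = −det A'` is the
  discriminant of the characteristic polynomial of `A'`; `D > 0` iff
  `A'` has a complex-conjugate eigenpair, i.e. the local flow spirals
  around the reference cell (units 1/frame⁶);
- `Q_d = ‖sym(A) − (P/3) I‖_F` (1/frame) is the deviatoric strain
  rate: cells rearranging while the enclosed volume stays constant.

These definitions are this package's reconstruction from the standard
critical-point analysis of velocity-gradient tensors; they are chosen to
satisfy the qualitative semantics above (sign of `P`, `D > 0` ⇔
rotation, `Q_d` ⇔ volume-preserving distortion) and are validated
against closed forms and an eigenvalue oracle in the test suite.
Normalisations of `D` and `Q_d` found elsewhere in the literature may
differ by constant factors; only signs and relative time courses should
be compared across implementations. Units are per frame throughout;
conversion to per-hour is a reporting concern (`frame_interval`).

## Virtual dissection

Every selection step is a node in a tree: a serializable predicate
(feature interval, feature-space polygon, spatial region at a frame,
k-means clustering, or set algebra over earlier nodes) plus the member
track ids it produced. Invariants, re-checked by `verify()`: members of
each node are a subset of its parent's members, and re-evaluating a
node's predicate on its parent's members reproduces the stored set
exactly. The JSON-serialized tree is the reusable analysis template;
`replay_tree` re-evaluates all predicates on a new forest, with optional
per-node parameter overrides for biological variability between
specimens.

Clustering is k-means with a deterministic initialisation — centre `i`
at the `(i + ½)/k` quantile of the members' projection onto the first
principal axis — so runs and replays are reproducible without a random
seed. Cluster children are ordered by ascending mean of the first
feature, giving stable, comparable labels; in the dissection workflow
the lower-displacement-ratio cluster is labelled "hypoblast-like" (the
U-shaped, involuting-like group) — the name is tied to the feature, not
to a biological claim. If all feature values coincide, the partition
falls back to an even deterministic split (any partition is equally
good; k-means is undefined there).

Label propagation assigns each unlabelled track by majority vote: at
every frame the track exists, its k (default 5) nearest labelled
detections within the radius (default 40 µm) each cast one vote; votes
pool over all frames of the track, ties break toward the smaller mean
neighbour distance, and tracks that never see a labelled neighbour are
reported unassigned rather than guessed. Pooling across frames (rather
than per-frame assignment) is the design choice: short fragments are
exactly the tracks whose single-frame neighbourhoods are least
trustworthy.

## Curation

Link candidates for a track end are parentless track starts within
`max_gap` frames and `max_radius` µm, scored by

    score = distance / max_radius + w_I · |ΔI| / I_scale

with `w_I = 1` and `I_scale` the interquartile range of all intensities
in the forest (the term vanishes when intensities are absent). The
score ranks review suggestions (top 3 by default); the *automatic*
linker deliberately thresholds on distance alone, the more conservative
and more interpretable rule. With one-to-one resolution enabled,
conflicts are resolved by an optimal assignment (maximum number of
links, then minimum total score, via the Hungarian algorithm) — a
greedy pass is near-identical in practice but is not guaranteed to
minimise total score, and the optimal assignment is what the
brute-force oracle in the tests certifies. Accepted links merge with
linear gap interpolation; interpolated detections are flagged synthetic
and countable, so detection bookkeeping stays exact.

The review queue is deterministic: breadth-first visits loose ends in
frame order; depth-first keeps following the track just extended, so one
cell's history is completed before moving on; both run in either
temporal direction, optionally restricted to a selected group. Every
decision (chosen rank, explicit alternative, or rejection) is logged as
JSON lines; replaying a log on the original forest reproduces the final
forest exactly, which makes curation auditable and shareable.

## Synthetic test substrate

The simulator is kinematic: it prescribes paths that reproduce the
geometric signatures the analyses rely on, and nothing else. Two
populations of 300 cells each move on a 150 µm spherical shell for 90
frames at 90 s/frame starting at 5 hpf (the movie therefore spans the
5–7.25 hpf gastrulation window):

- *epiblast* agents start at polar angles 0.20–0.65 rad and drift
  toward the vegetal pole at 1.5 µm/frame (≈ 1 µm/min, a typical
  gastrulation-stage migration speed) — monotone paths, displacement
  ratio near 1;
- *hypoblast* agents start just above the margin latitude (1.2 rad),
  reach it at an individual turn time drawn uniformly from 35–58% of
  the movie, step 20 µm inward over 15 frames (one cell diameter, the
  radial separation between outer and internalised layers), then walk
  back toward the animal pole — U-shaped paths, displacement ratio
  well below 0.5 at zero noise.

Isotropic Gaussian positional noise (default σ = 1 µm, a realistic
centroid-localisation error) is added per detection. Divisions occur at
5·10⁻⁴ per cell per frame — far below the biological cell-cycle rate,
deliberately: the generator emulates *tracking output*, in which most
divisions are missed or fragment the track, and a higher rate would
leave almost no track covering 70% of the movie, emptying the very
population the dissection workflow needs. Daughters appear 8 µm apart
and continue the mother's programme. Intensities are drawn per track
(mean 500 ± 50 a.u.) with per-frame jitter (σ = 10), giving the
curation score a usable intensity term.

At these defaults the inter-cell spacing (≈ 9 µm within a population) is
six times the per-frame step (1.5 µm), so the fragmentation/auto-link
experiment is run at σ = 0 where that spacing-to-step ratio actually
holds; with σ = 1 µm the *effective* step nearly doubles and the
experiment's premise (spacing ≥ 5× step) would be violated. The
dissection experiment runs at the full σ = 1 µm.

What the simulator does **not** model: biophysical mechanics, cell-cell
exclusion, realistic division geometry, intensity bleaching, missing
detections at image borders, or anisotropic localisation error (z is
usually worse in light-sheet data). Passing tests therefore demonstrate
the *algorithms* recover known structure under realistic scales of
noise and fragmentation — not that any specific biological data set
will separate as cleanly.

The affine-flow sampler (`sample_field`) is built for machine-precision
validation: positions follow the three-term recurrence
`x_{t+1} = x_{t−1} + 2 (A x_t + b)` started on its physical
characteristic branch `A + (A² + I)^{1/2}`, so the *central difference*
at every interior frame equals `A x_t + b` exactly. The velocity
estimator followed by the affine fit therefore recovers `A` to rounding
error at interior frames, and the invariant oracles can be asserted at
1e-6. Track-end frames use one-sided differences and are excluded from
those assertions.

## Problem sizes and determinism

All shipped experiments run on a laptop-scale budget: embryos of 2×300
cells × 90 frames (~55k detections) simulate in under a second; the
full dissection-recovery experiment (5 embryos + a replay) and the
curation experiment each take a few seconds; the deformation oracles use
60-point clouds over 11 frames. Every stochastic component consumes a
single integer seed through `numpy.random.default_rng`; repeated runs
are bit-identical, and the pipeline manifests echo the full
configuration so any run directory can be reproduced from its manifest.

## Known limitations

- Deformation invariants are only as good as the local affine
  approximation; in regions thinner than the neighbourhood radius the
  fit mixes layers (the invalid-fit flag does not catch this).
- `D` has units 1/frame⁶ and an arbitrary-feeling magnitude; compare
  its sign and time course, not absolute values, across data sets.
- The TrackMate reader trusts coordinates as calibrated physical units
  and ignores all spot features except position, frame and mean
  intensity; the TGMM reader supports the per-frame XML dialect with
  `id`/`parent`/`m` attributes only.
- Lineage merges are resolved by keeping the earlier link — adequate
  for diagnostics, wrong if merges encode real biology (cell fusion).
- The curation score's intensity weight (`w_I = 1`, IQR scaling) is a
  pragmatic default, not a fitted model; auto-linking ignores it by
  design.
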