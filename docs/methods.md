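# Methods

This note documents the models, parameter choices and known limitations of
the `wormobs` pipeline, stage by stage.

## Synthetic plate simulator

The simulator (`wormobs.simulate`) emulates transmitted-illumination plate
imaging: a bright uniform background (default level 200) with additive
Gaussian noise (sd 5), and worms rendered as dark thick curves (contrast 60,
i.e. 12× the noise sd — comfortably above the ≥ 5× design floor). Frames
are 8-bit; geometry defaults match the target acquisition: 1024×1024 px at
6.25 μm/px (6.4 mm field), 2 frames/s, 8-min videos.

**Posture model.** A worm's midline is generated from its 24 intersegment
angles: θ(t) = A·(a₁ cos φ(t)·m₁ + a₂ sin φ(t)·m₂), where m₁, m₂ are a
unit-norm quadrature pair of sinusoidal spatial modes (~1.5 wavelengths
along the body) and the traveling phase φ advances at 0.3 Hz — the standard
low-dimensional description of crawling. The state-dependent amplitude
scale A implements the behavioral repertoire: 0.3 for quiescent worms
(stiff, shallow "dauer-like" bends), 0.7 for dispersal, 1.0 for dwelling.
The midline is reconstructed from the angles with 25 equal chords
(length = worm_length/25), so re-deriving angles from stored ground-truth
midlines is exact to machine precision.

**Locomotion model.** Each worm carries a three-state Markov chain
(quiescent / dispersal / dwelling; default symmetric leave-rate
0.02 s⁻¹). Centroids advance at a state-dependent speed along a heading
that diffuses with per-frame sd (1 − ρ)·2/√(fps) rad, where ρ is the
state's heading persistence. Default speeds (0.002 / 0.03 / 0.015 mm/s)
and persistences (0.5 / 0.98 / 0.5) are not taken from any measurement;
they were chosen once to straddle the printed dispersal thresholds
(0.01 mm/s, 15 °/s): quiescent worms sit below the speed floor, dispersal
worms are fast and straight (~3 °/s true angular velocity), dwelling worms
are above the speed floor but reorient far above 15 °/s (~65 °/s).
Worms reflect off an arena 25% larger than the field of view, so they leave
and re-enter the image; ground truth flags frames where the whole midline
is on-screen. Optional turn events (off by default) freeze the locomotion
wave into a uniform 200–360° bend for ~2 s.

**What the simulator does not emulate:** bacterial lawn texture,
illumination gradients or vignetting, worm-worm collision dynamics,
3-D postures (nictation), and body-size variation. Tests passing on
simulated scenes therefore validate the algorithmic chain, not robustness
to every nuisance of real plates.

## Segmentation

Background = per-pixel temporal median over stride-sampled frames (≥ 3);
worms are sparse in time, so the median is a consistent background
estimator. Detection thresholds |G(frame − background)| (G = Gaussian,
σ = 1 px; smoothing the *signed* difference lets zero-mean noise cancel) at
5× a MAD-based noise scale, fills holes, labels 8-connected components, and
keeps areas in [0.5·L·W, 3·L·W] for worm length L and width W — declared,
geometry-derived defaults (no reference values exist for these bounds). Centroids are intensity-weighted
(weight = difference magnitude), which localizes worms to ~0.24 px on
default scenes versus ~0.31 px for binary centroids — this matters
downstream because angular velocity is a heading *derivative* and inherits
centroid noise amplified by 1/step-length.

## Tracking and kinematics

Greedy mutual-nearest-neighbor linking under a distance gate (default: one
body length), ties broken by distance then area difference; no gap closing —
a missed frame ends the track, consistent with the gap-free track filter
(≥ 20 frames = 10 s at 2 fps; optionally also dropping tracks whose net
displacement is below half a body length, a proxy for segmentation
artifacts). A full linear-assignment linker was considered and rejected:
downstream analysis needs gap-free segments and population averages, not
globally optimal identities.

Per 10-s bin: speed = within-bin path length ÷ bin duration (mm/s);
angular velocity = mean |Δ heading| between successive displacement vectors
× frame rate (°/s). Headings are measured on a 3-point moving-average of
the centroid path with the two boundary steps excluded (they are only
partially smoothed), and steps below a 0.5-px noise floor carry no heading;
both choices suppress localization noise, which would otherwise add
~15–20 °/s of spurious angular velocity at dispersal speeds (~2.4 px/frame)
and misclassify genuinely straight runs. On noise-free circular paths the
estimator is exact; an all-stationary bin reports angular velocity 0 with
`heading_defined=False`. The first 30 min after transfer are discarded
(worm-handling artifacts); the boundary bin at exactly 0.5 h is kept.

## Skeletons and posture vectors

Masks are thinned to 1-px skeletons; spurs ≤ 3 px ending at junctions are
pruned; a skeleton is kept only if it has exactly two endpoints, no
junction pixels, and ≥ 26 px of arc length. Self-occluded turn shapes fail
these criteria by construction and are routed to the turn classifier
instead.

Head assignment: the head is the endpoint with the larger projection onto
the smoothed (3-frame) track displacement, accepted only when the worm
moved ≥ 1 px/frame and the projection gap exceeds 25% of body length
(worms crawl head-first); otherwise the frame inherits orientation from the
nearest motion-oriented frame of the track by endpoint proximity, and
frames that cannot be resolved either way are discarded. The displacement
smoothing and the two confidence thresholds are this package's own
calibration choices.

Posture extraction: the pixel path is smoothed (moving average, window 3),
resampled to 26 points equally spaced in arc length, optionally refined to
sub-pixel precision by sliding each point along its local normal to the
intensity-weighted center of the background-subtracted profile (3
iterations, ±3.5 px, 13 samples), and the 24 signed angles between
consecutive chords are taken, followed by a quadratic Savitzky-Golay filter
(window 9) along the body — postures are smooth at the joint scale, pixel
noise is not. Sign convention: positive = counter-clockwise in image
coordinates; dorsal/ventral is deliberately not resolved. A geometric note:
26 equally spaced points on a uniformly curved arc give 25 chords each
subtending 1/25 of the total turning, so a semicircular worm has every
intersegment angle equal to 180°/25 = 7.2°.

**Accuracy limit.** On default simulated scenes (48-px worms, 5-px width,
8-bit rendering) the per-frame correlation between recovered and true
angle vectors averages ~0.91 for moving worms (≈ 0.93 for high-amplitude
dwelling postures). The floor is rendering/binarization quantization:
at ~1.9 px per chord, half-pixel boundary wobble is comparable to shallow
bends. The test suite asserts the achieved level (mean ≥ 0.85, median
≥ 0.88 on moving worms); per-frame correlations approaching 1 would require
longer worms or higher magnification than the emulated geometry provides.

## Posture syntax

Eligibility for posture/eigenworm analysis: track duration ≥ 5 s, speed
> 0.01 mm/s, angular velocity < 50 °/s (moving worms only). Eigenworms are
the eigenvectors of the mean-centered 24×24 covariance matrix of eligible
angle vectors, sorted by eigenvalue; samples smaller than 24 vectors yield
a truncated basis with a warning.

The posture library is k-means (k = 200, k-means++ with 10 restarts,
Euclidean distance on raw signed angles — angles share units, so no
scaling) fit per condition across experimental repeats. Mirrored centroid
pairs are then merged: pairs are accepted greedily by increasing mirror
distance d(−cᵢ, cⱼ) under a gate at the 75th percentile of nearest-neighbor
distances among centroids. Greedy matching, rather than strict mutual
nearest neighbors, is used because k-means tilings of a mirror-symmetric
posture cloud are not themselves exactly symmetric; the mutual-NN relation
under-pairs them (~78% paired versus ~90% for greedy at the same gate). On
negation-symmetric synthetic data the merge shrinks the library by ~44–47%,
consistent with the roughly-half reduction expected when almost every
posture's mirror is also sampled. Class assignment of new vectors uses
min(d(θ, c), d(−θ, c)) per centroid, making classification exactly
invariant under mirroring. Each merged class is represented by the
count-weighted, sign-aligned mean of its centroid pair.

Meta-postures: a second k-means (k = 3) over the pooled class
representatives of all conditions, giving three coarse groups (in practice:
a stiff/low-curvature group versus two increasingly bent groups).
Abundance matrices: per h.a.t. bin (default 1 h) the relative class
frequencies (rows sum to 1; empty bins are NaN), z-scored per class across
bins; meta-posture occurrence is additionally reported normalized by its
condition-wide mean (both raw and normalized variants are emitted so either
convention can be plotted).

## Behavioral states and turns

Dispersal per 10-s bin: speed ≥ 0.01 mm/s AND angular velocity < 15 °/s
("minimum speed" read as inclusive, "below" as strict). Quiescence is
reported descriptively as speed below the dispersal floor — no separate
quiescence threshold exists. 2-D speed/angular-velocity histograms are
normalized to unit mass.

Turns are detected from bitmasks with a seeded random forest (500 trees,
stratified 80/20 held-out split) over 17 fixed shape descriptors: area,
perimeter, area/perimeter², major/minor ellipse axes, eccentricity,
solidity, extent, skeleton endpoint count, skeleton length,
endpoint-span/skeleton-length, deepest convexity defect, circularity,
bounding-box aspect, Hu moments 1–2, and mean distance-transform value.
The specific 17 descriptors are this package's choice: standard measures
that separate elongated from self-contacting shapes. Training labels follow the annotation rule — turn
when head or tail touches the body or when head and tail point the same way
(U-shape) — realized by the simulator's shape generator (turns: 170–360°
total bend; non-turns: locomotion-wave postures). Scores are thresholded at
0.5, and per-frame flags are collapsed to at most one turn per 10-s window
so still, curled worms are not recounted.

Condition summaries per h.a.t. bin: dispersal fraction over 10-s records,
per-track mean speed (one value per track, the statistic compared between
conditions with a Mann-Whitney test), and mean turn occurrence per 10-s
window with SEM across tracks.

## Problem sizes in the test suite

Tests run the full chain on 512-px scenes with 5–6 worms over 60–120 s, the
mirror-merge check on 5,000-vector symmetric samples (k = 200, 5 seeds),
and the turn classifier on 300–1,000 shapes; `scripts/acceptance.py` uses
the full 10,000-pair (20,000-vector) sample. These sizes give stable
statistics for every assertion while keeping the suite fast; all of them
can be scaled up through the same APIs.

## Known limitations

* Overlapping or touching worms are not split; their merged blobs are
  rejected by the size filter and their tracks end.
* Dorsal/ventral turn direction is not resolved (impossible at plate
  magnification); mirror merging is the corresponding modeling choice.
* Head assignment fails for long perfectly stationary tracks (discarded by
  design) and can propagate an error along a track if the only
  motion-oriented frame is itself wrong.
* Posture-angle recovery is quantization-limited at the emulated
  magnification (see above).
* The simulator's behavioral states are Markovian with fixed per-state
  kinematics; real dauer-exit behavior drifts continuously in time.
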