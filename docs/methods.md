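# Methods

This note documents the measurement model, its tunable constants, the
numerical conventions the implementation fixes where the method leaves
them open, and what the synthetic benchmark does and does not show.

## The measurement model

The input is an ordered open polyline p₁…pₙ (typically 500 < n < 1000
points) digitized by hand along the outline of a ventral branch, plus a
pixel-to-micrometer scale. Endpoints are arbitrary; only the central
part of the stroke carries the five features of interest.

**Normalization.** Pixels are converted to micrometers, the image y axis
(which points down) is flipped so spines point toward +Y, and traversal
is auto-reversed so the contour runs left to right. Both transforms are
recorded so normalization is invertible.

**Stage 1 — contour smoothing.** Each coordinate is replaced by the mean
of the 2⌊αn⌋+1 points centered on it. The divisor is the true window
count (2⌊αn⌋+1), which keeps the filter mean-preserving; the output is
⌊αn⌋ points shorter per side.

**Stage 2 — raw curvature.** At each interior point N with neighbors M,
P, signed curvature is the inverse circumradius of triangle MNP,
k = 2 (MN×NP)/(|MN|·|NP|·|PM|), with the cross product's sign taken so
that a *clockwise* turn in math (y-up) coordinates is positive. This is
the convention under which the formula evaluated directly on image
coordinates (y down) comes out positive at spine tips — spine tips and
the ridge are curvature maxima, cavities are minima. Collinear triples
give exactly 0; coincident points are an error. The curvilinear abscissa
s accumulates Euclidean segment lengths from the first smoothed point.

**Stage 3 — refinement.** Curvature is recomputed over a symmetric
window of half-width a points: a = round(1/|k_raw|) where
|k_raw| < 0.1 µm⁻¹ and a = 10 otherwise. Flat regions are thus measured
over a span comparable to their curvature radius (averaging out
digitization noise) without blunting sharp peaks. Choices fixed here:
the threshold compares |k_raw| (a signed comparison would send every
concave point into the 1/k branch with a negative window); a is in
points and rounded half-away-from-zero; near the contour ends a is
clamped to the available margin rather than dropping points.

**Stage 4 — curvature smoothing.** A weighted moving average with
triangular weights w = ⌊βn⌋ − |offset| (zero at the window edges, n the
raw point count), trimming ⌊βn⌋ samples per side. Its input is the
refined curvature. Margins use ⌊·⌋ throughout, so the stage lengths are
exactly: |smoothed contour| = n − 2⌊αn⌋ and
|k″| = |smoothed contour| − 2 − 2⌊βn⌋ (the extra 2 from the three-point
raw stencil).

**Landmark detection.** Extrema are strict sign changes of the first
difference of k″ (a plateau reports its first index), restricted to the
central part of the profile: the first and last 20% of the normalized
abscissa are excluded because stroke start/end curvature is noise.
Assignment: L3 = maximum nearest the midline position (0.475 by default
— freehand strokes end in a long tail, shifting the symmetry axis left
of 0.5); L2 / L4 = the *lowest* minima left / right of L3; L1 / L5 = the
maxima nearest (and strictly outside) L2 / L4. If more than one maximum
lies strictly between L2 and L4, L3 is re-seated on the highest of them;
the outer landmarks are not re-derived afterwards. Closeness is measured
in normalized abscissa with ties toward the smaller index, making the
assignment total and deterministic. Any missing role excludes the
specimen with a reason naming the role.

**Spine thrust.** With X̂ the unit vector from L2 to L4 and Ŷ = X̂
rotated +90° (counterclockwise), ST = ½(Y_L1 + Y_L5) − Y_L3 in
micrometers of frame-projected height. ST is invariant under rigid
motion, scales linearly with size (it quantifies *form*, not pure
shape), and is positive exactly when the spine tips rise above the
ridge. Landmark coordinates are taken on the smoothed contour, the curve
the curvature profile actually describes.

**Tuning.** For each (α, β) cell of a grid the full pipeline runs from
scratch on every training specimen; specimens the cell fails to detect
are dropped from that cell, and the cell score is the squared Pearson
correlation between manual-reference ST and automatic ST over the
survivors (at least 3 required, otherwise the cell is undefined and
never selectable). The optimum is the maximal r²; among ties, the cell
applying the least smoothing, formalized as smallest α+β then smallest
β. Optimizing r² against manual ST (rather than landmark-position
agreement) deliberately allows the machine to disagree pointwise with a
possibly biased human. The default grid α ∈ {0.005…0.050},
β ∈ {0.005…0.100} in steps of 0.005 brackets the calibrated optimum
α = 0.025, β = 0.055, which is the package default.

## Parameters that matter

| parameter | default | units | meaning |
|---|---|---|---|
| α | 0.025 | fraction of n | contour smoothing window; calibrated |
| β | 0.055 | fraction of n | curvature smoothing window; calibrated |
| refine threshold | 0.1 | µm⁻¹ | below it, refinement window = 1/k |
| refine cap | 10 | points | refinement half-width at high curvature |
| exclusion fraction | 0.20 | — | profile ends ignored for landmarks |
| midline | 0.475 | normalized s | symmetry axis for picking L3 |

The refinement threshold is scale dependent, so the pixel→µm scale must
be supplied; a fallback of 1.0 warns. `estimate_midline` (mean abscissa
of the global k″ maximum across profiles) is provided as a clearly
flagged extension for re-calibrating the midline on a new structure; it
is only meaningful when the central ridge is the sharpest feature.

## The synthetic benchmark

The generator builds an analytic base curve — two Gaussian spine bumps
at 0.30/0.70 of a 60 µm span and a central ridge bump, with explicit
Gaussian cavity depressions at the midpoints, on a parabolic arch of
2 µm sag — and samples it uniformly in arc length (700 points by
default). Ground truth is exact: the five y-extrema of the analytic
curve are located by root finding on y′(x), and the true ST is computed
from them with the same frame code the pipeline uses. Because
neighboring Gaussians overlap, nominal bump heights are not landmark
heights; target-ST shapes are produced by solving the spine height (or,
for strongly negative targets, the ridge height — rounded branches are
ridge-dominant) so the ground-truth ST hits the target exactly.
Digitization noise is white Gaussian displacement along the local
normal, low-pass filtered along the contour (correlation length 10
samples, sd 0.5 µm at the tested level) — a freehand pen wobbles
smoothly rather than flickering per point.

The simulated population follows the study design the package targets:
two species × two rearing temperatures, 30 individuals per group, a
3.4 µm temperature shift in the rounded species only (18 °C spinier), a
~9 µm species difference, and a between-individual sd of 1.5 µm. The sd
is a free simulation parameter (chosen to give the few-µm within-group
spread typical of such data), not a measured value.

What passing tests show: the curvature stack is accurate to < 2% on
analytic arcs; landmark rules match a brute-force transcription on
scripted and randomized extremum banks; ST detection recovers exact
ground truth within 0.5 µm on noise-free shapes over ST ∈ [−2, 8] µm and
within ~0.4 µm median error under 0.5 µm jitter; the tuner surface
equals an independent per-cell recomputation exactly; simulated group
effects are recovered within sampling error. What they do not show:
performance on real micrograph outlines, whose noise is not Gaussian,
whose features vary in width and asymmetry, and whose aberrant-detection
rate (≈4% in real data) depends on dissection and mounting quality the
generator does not model.

## Numerical choices and edge cases

- Window margins use floor (⌊αn⌋, ⌊βn⌋); only the adaptive refinement
  half-width rounds half-away-from-zero. A margin of 0 (fraction too
  small for the contour) is a parameter error, as is smoothing that
  leaves fewer than 3 points or a β window longer than the profile.
- Detection-stage failures (missing roles, degenerate L2=L4 frame,
  window errors) become excluded outcomes with reasons; batch runs
  account for every manifest specimen exactly once and are
  byte-reproducible (floats are serialized with `repr`).
- The tall-spine regime shows a small negative detection bias (≈ −0.3 µm
  at ST ≈ 9): coordinate smoothing clips narrow tips. This is inherent
  to the smoothing trade-off, shared by the manual reference the method
  is calibrated against, and cancels in group comparisons.
- Tie-breaks (equal r² cells, equidistant maxima, equal-value minima)
  are all resolved deterministically as described above.

## Known limitations

- The method measures form (size × shape); no Procrustes/centroid-size
  decomposition is attempted.
- Inferential statistics (regressions, trees, forests) are out of scope;
  the measurements CSV is designed to feed any stats package.
- Contours must be open, single-stroke, and oriented roughly left-right
  after normalization; closed-outline methods (elliptic Fourier, etc.)
  are a different tool class.
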