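# spinethrust

Semi-automatic measurement of **spine thrust (ST)** — a scalar form
statistic of the male genital *ventral branches* in the *Drosophila
yakuba* species complex — from hand-digitized open 2D contours.

Ventral branches are paired cuticular structures that are spiny in
*D. yakuba* and rounded in *D. santomea*, and their form matters for
reproductive isolation between these sister species. Digitizing a full
outline with a pen stroke is fast and robust, but turning that outline
into a comparable number requires detecting five landmarks on it.
`spinethrust` automates everything after digitization:

1. **Contour smoothing** — a rectangular (moving-average) filter over the
   raw points p₁…pₙ, window fraction α of n (the smoothed contour is
   ⌊αn⌋ points shorter on each side).
2. **Curvature** — at each point, signed curvature k = 1/r from the
   circumscribed circle of the point and its neighbors,
   k = 2 (MN×NP)/(|MN|·|NP|·|PM|), positive at spine tips; then a second
   pass over an adaptive window (half-width 1/k points where |k| < 0.1 µm⁻¹,
   10 points otherwise) and a triangular-weighted moving average with
   window fraction β.
3. **Landmarks** — Bookstein type-2 landmarks from the curvature extrema
   inside the central 60% of the profile: maxima for the two spine tips
   (L1, L5) and the central ridge (L3), minima for the two cavities
   (L2, L4). Specimens missing any role are excluded, never imputed.
4. **Spine thrust** — in the frame whose X axis runs from L2 to L4
   (Y = X rotated +90°),

   ST = ½ (Y_L1 + Y_L5) − Y_L3   [µm]

   i.e. the mean height of the spine tips above the central ridge.
   Spiny forms give ST > 0, rounded forms ST ≈ 0 or negative.
5. **Calibration** — α and β are tuned by grid search maximizing the
   squared Pearson correlation r² between ST from manual landmarks and
   ST from automatic detection; the defaults α = 0.025, β = 0.055 are the
   calibrated values.

A first-class synthetic generator produces branch-like open contours
(two spine bumps flanking a central ridge, correlated digitization
jitter, group-level effects carried by geometry) with *exact* ground
truth landmarks and ST, so the whole pipeline is verifiable without any
micrographs.

## Worked example

Simulate a small two-species dataset, measure it, and summarize:

```sh
spinethrust simulate  --out demo --n-per-group 5 --seed 42
spinethrust measure   --manifest demo/manifest.csv --out demo_m
spinethrust summarize --measurements demo_m/measurements.csv --out demo_summary.csv
```

The measure step reports `measured 20/20 specimens (0 excluded [0.0%],
0 errored)` and writes one row per specimen with its ST, the three
frame-projected landmark heights, and the five landmark coordinates in
micrometers. The summary (means ± SE, median, quartiles, and the 95%
median-CI notch 1.58·IQR/√n per group) comes out as:

```
species,strain,temperature_C,n,mean,se,median,...
santomea,sim-santomea,18.0,5,3.41,0.40,3.38,...
santomea,sim-santomea,25.0,5,0.25,0.57,0.46,...
yakuba,sim-yakuba,18.0,5,8.88,0.27,9.20,...
yakuba,sim-yakuba,25.0,5,8.15,0.49,7.69,...
```

Read: the rounded species is plastic — reared at 18 °C its branches are
about 3.2 µm spinier than at 25 °C — while the spiny species sits near
8–9 µm at both temperatures. Tuning against a manual reference table
works the same way (`spinethrust tune --manifest … --manual manual.csv
--out tune_out`), writing the full (α, β, r², n) surface with the
selected lowest-smoothing optimum.

The same operations are available as library functions
(`spinethrust.measure_contour`, `grid_search`, `generate_population`,
`summarize_measurements`, …).

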