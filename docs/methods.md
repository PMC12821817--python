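# Methods

## The measurement model

A cell's optical section is an 8- or 16-bit grayscale raster with isotropic
pixel calibration (µm/px). The user supplies, per cell, a *diagonal* transect
(corner to corner, uniformly oriented across a dataset to avoid observer
bias) and a *longitudinal* transect (cell length). The tonoplast appears as a
thin bright ridge; every crossing of the diagonal produces a peak in the 1-D
intensity profile sampled along it. The TTI is the retained-peak count
divided by the physical transect length (crossings · µm⁻¹); normalizing by
length makes cells of different sizes comparable. The VMI (length × width of
the largest compartment section, µm²) is taken from manual measurements, as
is conventional; the package only multiplies, log-transforms and merges it.

Choice of optical section is deliberately manual: tonoplast structure varies
strongly along Z, and comparable focal planes (near the cell equator, above
the nucleus) must be chosen by eye. The package validates a supplied
`z_index`; it does not try to choose one.

## Stage 1 — image preprocessing and profile extraction

* Optional contrast enhancement rescales each plane linearly to the full bit
  range, clipping `saturated_fraction` (default 0.35%) of pixels at each
  tail. It preserves pixel rank order up to the ties clipping introduces and,
  by design, leaves crossing counts essentially unchanged — detection relies
  on relative, not absolute, intensities.
* Denoising applies `smooth_rounds` (default 2) passes of a 3×3 mean filter
  with reflected edges. Accumulation is in float64 across rounds with one
  half-up rounding at the end, so total intensity of interior features is
  conserved to within one count per pixel. The round count is the main knob
  to adapt to image quality.
* Profiles are sampled at ~1-pixel spacing (`round(length_px) + 1` samples,
  evenly spaced endpoint to endpoint) with bilinear interpolation. Sampling
  coordinates use an integer-weight convex combination, which makes a
  reversed transect yield the bit-identical reversed profile. The exact
  resampling rule of interactive tools on oblique lines is not standardized;
  bilinear at 1-px spacing was chosen for smoothness and testability.
  Coordinates are 0-based with pixel centers at integers.

## Stage 2 — peak calling

Candidates are strict interior local maxima of the (optionally
Gaussian-smoothed) profile; a flat plateau contributes one candidate at its
floor-midpoint, and the first/last samples are never peaks. A candidate is
retained iff it passes **all** filters:

| parameter | meaning | unit | default |
|---|---|---|---|
| `background` | absolute height floor | intensity | 0 |
| `med_ratio` | height ≥ med_ratio × median(profile) | — | 1.0 |
| `min_ratio` | height ≥ min_ratio × min(profile) | — | 1.5 |
| `distance` | minimum index separation between retained peaks | samples | 5 |
| `prominence` | height above the higher of the two interleaving minima toward the nearest higher peaks or profile ends | intensity | 10 |
| `sigma` | Gaussian pre-smoothing (truncated at 4σ, reflect) | samples | 1.0 |

The three height criteria combine as a single maximum (their sequential
application would be equivalent for filtering); the threshold and the
prominences are computed on the smoothed profile, since smoothing precedes
detection in the pipeline. Distance conflicts are resolved greedily in
decreasing height order, ties retaining the leftmost candidate — a
deterministic rule pinned against an independent brute-force enumerator in
the tests. `distance` is in samples, i.e. independent of pixel calibration
and bit depth; with `background = 0` the whole filter chain is equivariant
under intensity rescaling, so 8- and 16-bit sources behave identically.

Defaults target 8-bit profiles whose membrane peaks sit in the mid-intensity
range; like any peak-filter preset they must be revisited for data with a
different intensity scale or noise character (all six are CLI flags and
`[peaks]` TOML keys).

Misdetection against known crossing positions is scored by greedy
nearest-first matching within a tolerance (default 0.5 µm, roughly one
resolved membrane width); errors are unmatched detections plus unmatched
truths, and the fraction is errors over true crossings (flagged infinite when
something is detected where no truth exists).

## Statistics

Each two-group comparison first screens both groups with Shapiro–Wilk
(α = 0.05). Only when *both* pass (the conservative per-group reading) is the
pooled-variance two-sided Student's *t* used; otherwise the Mann–Whitney U
test (asymptotic, tie-corrected, continuity-corrected). Welch's *t* is
available behind a flag. For significant results an effect size is reported:
r = |Z|/√N for Mann–Whitney (Z recovered from the two-sided P, consistent
with the corrections) and r = √(t²/(t²+df)) for the *t* test — the standard
formulas for these tests; r ≥ 0.5 counts as strong, 0.3 < r < 0.5 as medium.
Because Mann–Whitney is a rank test, its P is invariant under any strictly
monotone transform — raw and log-transformed VMI give identical P-values,
and the choice of logarithm base is immaterial (natural log is used).

Quartile stratification bins cells by the 25/50/75% quantiles of the
*pooled* cell lengths (linear-interpolation quantile rule, configurable) with
left-closed assignment; the four per-quartile P-values of one metric form one
Benjamini–Hochberg family (per metric, not per run), and effect sizes are
re-gated on the adjusted P. Quartiles with fewer than 3 cells in either group
are reported not-evaluable, excluded from the BH family, and warned about.
Significance stars follow the convention ** for P < 0.01 and * for
0.01 ≤ P < 0.05. QQ diagnostics pair standardized order statistics with
normal quantiles at plotting positions (i − ½)/n.

## The synthetic generator

Each simulated cell is a rectangle (default ~30 × 12 µm, 0.1 µm/px — a
transition-zone rhizodermis cell at high-NA spinning-disc sampling)
containing elliptical tonoplast contours: one large compartment (the nascent
central vacuole, semi-axes ~10 × 4 µm, near-axial orientation) and 2–6 small
ones (semi-axes ~1.6 × 1.1 µm, free orientation). Contours are rendered as
Gaussian ridges of FWHM 0.25 µm (a diffraction-limited line; σ ≈ 0.106 µm)
peaking at 120/255 over a baseline of 10, overlapping ridges combining by
maximum; Gaussian read noise is added (the detection benchmark uses
SD = 10% of the membrane peak intensity), then values are clipped and
quantized. Rendering is deterministic given the recorded seed; all sampling
randomness flows through one seeded generator per population.

Ground truth is analytic: crossing positions are the roots of the per-ellipse
quadratic along the transect (tangency, |discriminant| ≤ 1e-9, counts once),
cross-checked in tests against dense sign-change root finding; ground-truth
VMI is the bounding-box side product of the largest compartment.

Placement emulates a hand-drawn validation set whose membranes are
*unambiguously countable*, which is what makes an analytic benchmark
meaningful:

* compartments keep 0.5 µm clearance from the cell wall (cortical cytoplasm
  layer) and 0.6 µm between distinct contours (vacuole sections do not
  interpenetrate, and sub-resolution contour pairs would image as a single
  membrane);
* relative to *both* diagonals, treated identically so neither orientation is
  privileged, a compartment either crosses with chord ≥ 0.8 µm, crossings
  ≥ 0.8 µm apart, incidence angle sin ≥ 0.4 and no contour stretch hugging
  the transect away from its crossings — or misses the diagonal by ≥ 0.5 µm;
* a drawn cell is accepted only if a noiseless render processed by the
  default pipeline recovers the analytic crossing count exactly on both
  diagonals (rejection sampling with a cap).

Consequently the noisy benchmark isolates what it is meant to measure —
robustness of the filter chain to noise and discretization — rather than
grazing geometries that no intensity-based detector could resolve and that a
human rater would not score as two membranes either. The generator does *not*
emulate out-of-focus light, anisotropic PSFs, uneven illumination, marker
artifacts ("bulbs"), touching neighbor cells, or genuinely ambiguous
tangential membranes; passing its benchmarks therefore bounds detector
quality under clean geometry, and real images with such confounders will do
worse until the stage-1/stage-2 parameters are re-tuned on a subset.

The two-population contrast draws population A with no small compartments
and population B with 4–8, sharing every other setting — so their
ground-truth VMI laws coincide while crossing counts differ by construction.
The fragmentation-gradient variant couples the two metrics: cells get 0–8
small compartments while the large compartment's axes shrink by 5% per small
compartment, emulating fragmentation at the central vacuole's expense and
producing the expected negative TTI-vs-log(VMI) relationship.

## Problem sizes and determinism

The validation suite uses 200-cell benchmarks for detection quality,
direction neutrality and noiseless exactness, 2 × 30 cells for the
population contrast, 120 cells for the metric correlation, 1000 random
profiles for oracle equivalence and 2000 null replicates for test
calibration — sizes at which the checked quantities are stable across seeds
while the whole suite runs in well under a minute of simulation time. CSV
outputs are written with 6-significant-digit formatting, and every command is
deterministic given its configuration and seed, so re-runs are byte-identical.

## Known limitations

* TTI, like VMI, reads a single optical section: it cannot see 3-D
  connectedness, fragmentation in depth, or vacuolar occupancy.
* Peak counting cannot distinguish tonoplast from any other bright linear
  structure crossing the transect; marker specificity is assumed.
* Cells whose membranes cross the transect more finely than the `distance`
  filter (in samples) are undercounted by construction; the filter trades
  this against double-counting single membranes.
* The statistics module implements two-group workflows only; multi-group
  designs (e.g. ANOVA across treatments) are out of scope.
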