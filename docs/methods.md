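# Methods

## Motility models

**Fractional Brownian motion (fBm).** Each coordinate of a cell is an
independent fBm with Hurst index H ∈ (0, 1); per-component increments over
one frame have standard deviation `sigma_step` (µm), so the 2-D MSD at a lag
of k frames is exactly `2 · sigma_step² · k^{2H}` and the anomalous exponent
is α = 2H at every lag. Increments are synthesized by Cholesky
factorization of the fractional-Gaussian-noise Toeplitz covariance — exact
for any H, at O(n³) cost, which is why track length is capped at 2000
frames. This model produces clean single-exponent cohorts for
sub-diffusive (H < 0.5), diffusive (H = 0.5) and super-diffusive (H > 0.5)
regimes; it does not model a crossover.

**Persistent random walk (PRW).** Velocity components follow a stationary
Ornstein–Uhlenbeck process with relaxation time P (s) and stationary s.d.
σ_v (µm/s). The joint one-frame transition of (position increment,
velocity) is sampled from its exact Gaussian law (derived from the
integrated OU process), not by Euler stepping, so the Fürth MSD

    ⟨Δr²(t)⟩ = 4 σ_v² P [ t − P (1 − e^(−t/P)) ]

holds in expectation at any frame interval. Motion is ballistic (slope 2)
for t ≪ P and diffusive (slope 1) for t ≫ P, giving a controlled
super-diffusive-to-diffusive crossover on the scale of P.

**Immobile subpopulation.** `mix_immobile_fraction` pins
`round(fraction · n_cells)` randomly chosen cells at their initial position
plus i.i.d. localization noise. This reproduces the zero-displacement
subpopulation that dominates colonies grown without NaCl.

Localization noise (`loc_noise_sd`, µm) is added i.i.d. per frame and
component after the dynamics; it mimics centroid jitter from segmentation.

Optional reflecting walls (`arena`, either `(width, height)` or an inset
box `(x0, y0, x1, y1)`) keep cells inside the rendered field of view;
reflection slightly distorts the fBm correlation structure near the walls,
so cohorts meant for exponent estimation are simulated in free space
(`arena: null`).

## Rendering

Cells are drawn as capsules (rectangle of length `cell_length − cell_width`
with semicircular caps) at `cell_intensity` on `background_level`, blurred
by a Gaussian PSF and degraded with Gaussian read noise or Poisson shot
noise, then quantized to 8 or 16 bits. Orientation follows the smoothed
velocity direction by default (rods align with their motion at a colony
edge; 3-frame smoothing window). Defaults — 0.1 µm/px, 4 × 1 µm cells,
0.5 s frame interval — are a plausible high-magnification calibration
chosen so that a ~3 s crossover is resolvable; the acquisition settings of
any particular experiment should be supplied explicitly.

What the synthetic scenes deliberately omit: cell growth and division,
cell–cell mechanical interaction, phase-contrast halos and uneven
illumination. Passing the round-trip tests therefore demonstrates that the
segmentation/tracking/MSD chain is correct on well-behaved rod images, not
that it is robust to every real-microscopy artifact.

## Segmentation

White top-hat (disc diameter just above the cell width, so rods survive
the opening while the background is removed) → Otsu threshold on a 256-bin
histogram → removal of objects below `min_area` (default 25% of the
expected single-cell footprint) → watershed on the negated Euclidean
distance transform, seeded at distance-transform maxima at least
`min_seed_separation` px apart (default 0.8 cell lengths — larger than the
ridge plateau of a single rod, so rods are not split, while end-to-end
touching cells are). The distance transform is lightly smoothed (σ = 1 px)
for peak finding only. Measurements use the equivalent-ellipse convention:
axis lengths are 4·√(eigenvalue) of the second central moment matrix with a
+1/12 px² unit-square-pixel correction per axis (this keeps one-pixel-wide
objects from reporting a zero minor axis); orientation is measured from the
+x (column) axis and folded into (−π/2, π/2]. Note the 4·√λ convention
reports ≈ 4.4 µm for a 4 × 1 µm capsule — the equivalent ellipse of a
capsule is longer than the capsule. Border-touching objects are dropped by
default (their shape and displacement are censored).

## Tracking

Greedy nearest-neighbour association: all pairs within `gate_radius`
(default half a cell length per frame) are accepted in ascending order of
distance, one-to-one, with deterministic tie-breaking. No gap closing, no
merge/split handling — at colony-edge densities and short frame intervals
the per-frame displacement is well below the cell spacing, where greedy and
globally optimal assignment coincide. Tracks shorter than
`min_track_length` are discarded and counted.

## MSD analysis

* Per-track MSD is time-averaged over all start times; lags are capped at
  `max_lag_fraction` (default 0.25) of the track duration to bound
  estimator variance.
* The ensemble curve pools squared displacements across tracks weighted by
  each track's pair count at that lag (pairs-weighted pooling; equal-track
  weighting is available by averaging per-track curves).
* **Fixed-boundary fit**: independent OLS of log₁₀ MSD on log₁₀ τ for
  τ ≤ t_c and τ > t_c (no continuity constraint, matching the two
  independent slopes reported for colony-edge data); t_c defaults to 3 s.
  Zero-MSD lags are excluded with a logged warning; each regime requires
  ≥ 3 usable lags.
* **Free-boundary fit** (`fit_crossover`): every measured lag is a
  candidate boundary; both lines are fitted by OLS weighted by the local
  log-lag spacing, so each decade of lag time carries equal weight
  regardless of the linear sampling grid (the continuum limit of fitting on
  a log-spaced subsample, without the grid-discretization jumps in the
  recovered boundary). The boundary minimizing the total weighted residual
  is reported as t_c, defined as the largest lag of the early regime —
  consistent with the τ ≤ t_c convention above. A piecewise-linear fit to
  a smooth crossover has an O(1) window-dependent constant relating the
  knee to the underlying relaxation time; with the default window (shortest
  lag to a quarter of the track duration) the knee of a Fürth curve with
  P = 3 s lands at ≈ 3.5 s, i.e. ≈ 1.2 P.
* **Displacement statistics**: per track, the maximum distance from its
  first position (cheap, and what "maximum displacement along a
  trajectory" means operationally; the all-pairs maximum would differ only
  for looping paths). `p_large` is the fraction of tracks exceeding
  `factor · body_length` (default 3.5 body lengths; `body_length` defaults
  to the cohort mean major axis when segmentation ran, else must be given).
  `zero_fraction` is the fraction never exceeding `noise_floor`, default
  8 × the localization s.d.: the max over several hundred frames of pure
  localization noise concentrates near √(4 ln n)·sd ≈ 5–7 sd, so 2 sd would
  misclassify every immobile cell while 8 sd keeps both error rates
  negligible.
* **Exponent distributions**: the fixed-boundary fit applied per track;
  tracks failing either regime are excluded and counted. Spread is
  reported as s.d. and IQR per regime. Per-track fits use the
  time-averaged MSD of that track.

## Condition presets

`control` (W_NaCl = 0%) and `nacl` (W_NaCl = 2%) encode the qualitative
population structure of the two growth conditions: 200 cells × 600 frames
at 0.5 s, localization noise 0.05 µm, with H = 0.35 / immobile fraction 0.5
(control) versus H = 0.50 / immobile fraction 0.1 (NaCl), both at
`sigma_step` = 1 µm so that typical mobile NaCl cells exceed — and typical
mobile control cells straddle — the 3.5-body-length threshold (body length
4 µm). The exponent-recovery presets (`nacl-early`, `control-early`,
`nacl-late`, `control-late`) use H = 0.70, 0.635, 0.50, 0.35 at
`sigma_step` = 0.2 µm, 200 × 600 frames; the `crossover` preset is a PRW
with σ_v = 0.2 µm/s, P = 3 s, 300 × 400 frames at 0.25 s. These sizes keep
every cohort's estimator noise well inside the ±0.1 exponent bands while
running in seconds on one core.

## Numerical and degenerate-input choices

* All randomness flows through `numpy.random.default_rng` seeded per stage
  (deterministic offsets from the run seed); identical config + seed
  reproduces every output byte for byte.
* Constant frames have no Otsu threshold (error); featureless frames after
  enhancement yield zero observations rather than an error.
* An all-immobile cohort with zero localization noise has an identically
  zero MSD: the power-law fits are reported as null (logged), while the
  displacement statistics remain defined (zero_fraction = 1).
* Bootstrap confidence intervals resample tracks (the independent sampling
  unit) and include the observed statistic in the replicate pool, so B = 1
  degenerates to a zero-width interval at the point estimate.

## Known limitations

* The fBm cohorts have a single exponent at all lags; two-regime behaviour
  in synthetic data comes either from the PRW crossover or from population
  mixtures, not from a single two-exponent process.
* Greedy linking will mis-assign when per-frame displacement approaches
  the nearest-neighbour spacing; the identity-switch guarantee in the tests
  holds for spacing ≳ 2× the 99th-percentile per-frame displacement.
* The segmentation defaults assume bright cells on a darker, roughly flat
  background at high SNR; dense colonies with many overlapping rods need
  tuned `min_seed_separation` and will still under-segment side-by-side
  contacts closer than the seed separation.
* Exact fBm synthesis is limited to 2000 frames per track by the Cholesky
  factorization.
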