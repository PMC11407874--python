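# swarmtrack

Quantifying the surface motility of rod-shaped bacteria (*Bacillus subtilis*)
at the expanding edge of a colony, from time-lapse micrographs to
anomalous-diffusion statistics.

Salt stress reshapes how *B. subtilis* moves across an agar surface: with
NaCl in the medium more cells are motile, they travel farther, and the
population behaves more uniformly. The package turns that observation into
numbers through one reproducible pipeline:

1. **segment** — each frame is contrast-enhanced (white top-hat), binarized
   (Otsu), split into cells (watershed on the negated distance transform)
   and measured (equivalent-ellipse centroid, axes, orientation);
2. **track** — per-frame observations are linked into trajectories by
   greedy nearest-neighbour ("follow neighbour") association in successive
   frames;
3. **analyze** — from the trajectories it computes time-averaged and
   ensemble mean squared displacements ⟨Δr²(t)⟩, fits two power-law regimes
   ⟨Δr²(t)⟩ ∼ t^α (early exponent α₁ for lags ≤ t_c, late exponent α₂
   beyond; t_c = 3 s by default or recovered by a free-boundary piecewise
   fit), the large-displacement probability `p_large` (fraction of cells
   whose maximum displacement exceeds 3.5 body lengths), the
   zero-displacement fraction, and per-cell exponent distributions whose
   spread measures dynamic heterogeneity.

Because raw colony-edge movies are rarely deposited, the package also ships
a first-class **synthetic-data module**: fractional Brownian motion cohorts
with tunable anomalous exponent α = 2H, persistent random walks with an
exact Ornstein–Uhlenbeck velocity process (Fürth MSD,
4σ_v²P[t − P(1 − e^(−t/P))], crossover at the relaxation time P), immobile
subpopulations, and a renderer that draws capsule-shaped cells with PSF
blur and shot/read noise into multi-page TIFF stacks. Every stage of the
analysis is therefore testable against known ground truth.

## Worked example

```bash
swarmtrack run-all --preset control --seed 21 --out runs/control
swarmtrack run-all --preset nacl    --seed 22 --out runs/nacl
swarmtrack compare runs/control runs/nacl --out runs/comparison.csv --seed 3
```

which prints (abridged):

```
  condition  n_tracks   alpha1   alpha2  p_large  zero_fraction
W_NaCl = 0%       200 0.700854 0.702734    0.375            0.5
W_NaCl = 2%       200 0.994117 0.995076    0.895            0.1
```

Reading: the no-salt cohort moves sub-diffusively (α ≈ 0.7), only 37.5% of
cells ever travel beyond 3.5 body lengths and half the population is
immobile; with 2 wt.% NaCl the mobile cells are diffusive (α ≈ 1.0), 89.5%
make large excursions and only 10% stay put. The full table adds bootstrap
confidence intervals (resampled over tracks) and the per-regime exponent
spreads, which are narrower with NaCl.

Every run directory is self-describing: `summary.json` (all statistics +
config echo), `msd.csv`, `fits.json`, `exponents.csv`,
`displacement_stats.json`, `trajectories.csv`, and — for image-based runs —
`stack.tif` with a JSON calibration sidecar. The same stages are available
as library functions (`swarmtrack.segment_stack`, `build_trajectories`,
`ensemble_msd`, `fit_two_regime`, ...) for notebook use.

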