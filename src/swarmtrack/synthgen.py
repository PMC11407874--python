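"""Ground-truth trajectory simulation and synthetic time-lapse rendering.

Two stochastic motility models cover the phenomenology seen at the edge of
an expanding *B. subtilis* colony:

* **Fractional Brownian motion (fBm)** — each coordinate is an independent
  Gaussian process with stationary increments and per-component MSD
  ``sigma_step**2 * k**(2 * hurst)`` at a lag of ``k`` frames, so the
  two-dimensional MSD follows a pure power law with anomalous exponent
  ``alpha = 2 * hurst``.  This gives direct control over sub-, super- and
  ordinary diffusion.
* **Persistent random walk (PRW)** — each velocity component follows a
  stationary Ornstein–Uhlenbeck process with relaxation time ``P`` and
  stationary standard deviation ``sigma_v``; the resulting 2-D MSD obeys the
  Fürth formula ``4 sigma_v^2 P [t - P (1 - exp(-t/P))]``, ballistic at
  ``t << P`` and diffusive at ``t >> P``, i.e. a controlled
  super-diffusive-to-diffusive crossover at a time scale set by ``P``.

A configurable fraction of cells can be replaced by an immobile
subpopulation (fixed position plus localization noise), emulating the
non-motile cells that dominate colonies grown without NaCl.

Trajectories are rendered into noisy image stacks as capsule-shaped rods
(rectangle with semicircular caps), blurred by a Gaussian point-spread
function and degraded with Gaussian or Poisson noise.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.linalg
from scipy.ndimage import gaussian_filter

from .io import FrameStack

_MODELS = ("fbm", "prw", "immobile")
_ORIENTATION_MODELS = ("fixed", "along_velocity", "random_walk_angle")

# exact Cholesky factorization of the fBm increment covariance is used up to
# this many steps; beyond it the O(n^3)/O(n^2) cost stops being desk-scale
_MAX_CHOLESKY_STEPS = 2000


@dataclass
class MotilityModelParams:
    """Knobs of the ground-truth motility models.

    Parameters
    ----------
    model:
        One of ``"fbm"``, ``"prw"`` or ``"immobile"``.
    hurst:
        Hurst index of the fBm, in (0, 1); the MSD exponent is ``2 * hurst``.
    sigma_step:
        fBm scale: per-component standard deviation (µm) of a one-frame
        increment.
    speed_sd:
        PRW stationary per-component velocity s.d. (µm/s).
    persistence_time:
        PRW velocity relaxation time (s).
    loc_noise_sd:
        Localization noise s.d. (µm), added i.i.d. per frame and component.
    arena:
        Optional reflecting box in µm: either (width, height) anchored at the
        origin or an explicit (x0, y0, x1, y1); ``None`` simulates free space
        (cells start at the origin).
    """

    model: str
    n_cells: int
    n_frames: int
    frame_interval: float
    hurst: float = 0.5
    sigma_step: float = 0.0
    speed_sd: float = 0.0
    persistence_time: float = 1.0
    loc_noise_sd: float = 0.0
    arena: tuple[float, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in _MODELS:
            raise ValueError(f"unknown model {self.model!r}; expected one of {_MODELS}")
        if self.n_frames < 2:
            raise ValueError("n_frames must be at least 2")
        if self.n_cells < 0:
            raise ValueError("n_cells must be non-negative")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if self.model == "fbm" and not (0.0 < self.hurst < 1.0):
            raise ValueError("hurst must lie strictly inside (0, 1)")
        if self.model == "prw" and self.persistence_time <= 0:
            raise ValueError("persistence_time must be positive")
        for name in ("sigma_step", "speed_sd", "loc_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.arena is not None:
            arena = tuple(float(v) for v in self.arena)
            if len(arena) == 2:
                arena = (0.0, 0.0, arena[0], arena[1])
            if len(arena) != 4 or arena[2] <= arena[0] or arena[3] <= arena[1]:
                raise ValueError("arena must be (width, height) or (x0, y0, x1, y1)")
            self.arena = arena


@dataclass
class GroundTruthTrajectorySet:
    """Dense ground-truth positions for a cohort of simulated cells."""

    positions: np.ndarray  # (n_cells, n_frames, 2) µm
    frame_interval: float  # s
    cell_ids: np.ndarray  # (n_cells,) int
    model_labels: list[str]  # per cell
    immobile: np.ndarray  # (n_cells,) bool
    condition: str | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[-1] != 2:
            raise ValueError("positions must have shape (n_cells, n_frames, 2)")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions must be finite")
        self.cell_ids = np.asarray(self.cell_ids, dtype=int)
        self.immobile = np.asarray(self.immobile, dtype=bool)

    @property
    def n_cells(self) -> int:
        return self.positions.shape[0]

    @property
    def n_frames(self) -> int:
        return self.positions.shape[1]

    def to_dataframe(self) -> pd.DataFrame:
        n_c, n_f, _ = self.positions.shape
        return pd.DataFrame(
            {
                "cell_id": np.repeat(self.cell_ids, n_f),
                "frame": np.tile(np.arange(n_f), n_c),
                "x_um": self.positions[:, :, 0].ravel(),
                "y_um": self.positions[:, :, 1].ravel(),
                "model": np.repeat(self.model_labels, n_f),
                "immobile_flag": np.repeat(self.immobile.astype(int), n_f),
            }
        )

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, frame_interval: float, condition: str | None = None
    ) -> "GroundTruthTrajectorySet":
        ids = np.unique(df["cell_id"].to_numpy())
        pos, labels, imm = [], [], []
        for cid in ids:
            sub = df[df["cell_id"] == cid].sort_values("frame")
            pos.append(sub[["x_um", "y_um"]].to_numpy())
            labels.append(str(sub["model"].iloc[0]))
            imm.append(bool(sub["immobile_flag"].iloc[0]))
        return cls(
            positions=np.stack(pos),
            frame_interval=frame_interval,
            cell_ids=ids,
            model_labels=labels,
            immobile=np.array(imm),
            condition=condition,
        )


def _start_positions(params: MotilityModelParams, rng: np.random.Generator) -> np.ndarray:
    if params.arena is None:
        return np.zeros((params.n_cells, 2))
    x0, y0, x1, y1 = params.arena
    return rng.uniform((x0, y0), (x1, y1), size=(params.n_cells, 2))


def _reflect(pos: np.ndarray, arena: tuple[float, ...] | None) -> np.ndarray:
    """Fold positions back into the arena (reflecting walls)."""
    if arena is None:
        return pos
    x0, y0, x1, y1 = arena
    out = pos.copy()
    for dim, (lo, length) in enumerate(((x0, x1 - x0), (y0, y1 - y0))):
        x = np.mod(out[..., dim] - lo, 2.0 * length)
        out[..., dim] = lo + length - np.abs(x - length)
    return out


def _fgn_cholesky(hurst: float, n_steps: int) -> np.ndarray:
    """Lower Cholesky factor of the unit fractional-Gaussian-noise covariance."""
    if n_steps > _MAX_CHOLESKY_STEPS:
        raise ValueError(
            f"n_frames - 1 = {n_steps} exceeds the exact-synthesis limit "
            f"({_MAX_CHOLESKY_STEPS}); simulate shorter tracks"
        )
    k = np.arange(n_steps, dtype=float)
    h2 = 2.0 * hurst
    gamma = 0.5 * (np.abs(k + 1) ** h2 - 2.0 * np.abs(k) ** h2 + np.abs(k - 1) ** h2)
    cov = scipy.linalg.toeplitz(gamma)
    return np.linalg.cholesky(cov)


def simulate_fbm_trajectories(params: MotilityModelParams) -> GroundTruthTrajectorySet:
    """Simulate independent-coordinate fractional Brownian motion.

    Increments are synthesized exactly by Cholesky factorization of the
    fractional-Gaussian-noise covariance, so the per-component MSD equals
    ``sigma_step**2 * k**(2 * hurst)`` at every lag of ``k`` frames in
    expectation.  Localization noise, if any, is added i.i.d. per frame.
    """
    if params.model != "fbm":
        raise ValueError("params.model must be 'fbm'")
    rng = np.random.default_rng(params.seed)
    n_steps = params.n_frames - 1
    chol = _fgn_cholesky(params.hurst, n_steps)
    z = rng.standard_normal((params.n_cells, 2, n_steps))
    increments = params.sigma_step * (z @ chol.T)  # (n_cells, 2, n_steps)
    start = _start_positions(params, rng)
    pos = np.zeros((params.n_cells, params.n_frames, 2))
    pos[:, 0, :] = start
    pos[:, 1:, :] = start[:, None, :] + np.cumsum(increments, axis=-1).transpose(0, 2, 1)
    pos = _reflect(pos, params.arena)
    if params.loc_noise_sd > 0:
        pos = pos + rng.normal(0.0, params.loc_noise_sd, size=pos.shape)
    return GroundTruthTrajectorySet(
        positions=pos,
        frame_interval=params.frame_interval,
        cell_ids=np.arange(params.n_cells),
        model_labels=["fbm"] * params.n_cells,
        immobile=np.zeros(params.n_cells, bool),
    )


def simulate_prw_trajectories(params: MotilityModelParams) -> GroundTruthTrajectorySet:
    """Simulate a persistent random walk (integrated Ornstein–Uhlenbeck velocity).

    The joint (position increment, velocity) transition over one frame is
    sampled exactly, so the Fürth MSD
    ``4 sigma_v^2 P [t - P (1 - exp(-t / P))]`` holds in expectation at any
    frame interval, not only in the small-step limit.
    """
    if params.model != "prw":
        raise ValueError("params.model must be 'prw'")
    rng = np.random.default_rng(params.seed)
    dt, P, sv = params.frame_interval, params.persistence_time, params.speed_sd
    a = np.exp(-dt / P)
    var_v = sv**2 * (1.0 - a**2)
    var_x = 2.0 * sv**2 * P * dt - 4.0 * sv**2 * P**2 * (1.0 - a) + sv**2 * P**2 * (1.0 - a**2)
    cov_xv = sv**2 * P * (1.0 - a) ** 2
    cov = np.array([[var_x, cov_xv], [cov_xv, var_v]])
    if sv > 0:
        chol = np.linalg.cholesky(cov)
    else:
        chol = np.zeros((2, 2))

    pos = np.zeros((params.n_cells, params.n_frames, 2))
    pos[:, 0, :] = _start_positions(params, rng)
    x = pos[:, 0, :].copy()
    v = rng.normal(0.0, sv, size=(params.n_cells, 2))  # stationary start
    for n in range(1, params.n_frames):
        z = rng.standard_normal((params.n_cells, 2, 2))
        eta = z @ chol.T  # [..., 0] position part, [..., 1] velocity part
        x = x + P * (1.0 - a) * v + eta[:, :, 0]
        v = a * v + eta[:, :, 1]
        pos[:, n, :] = x
    pos = _reflect(pos, params.arena)
    if params.loc_noise_sd > 0:
        pos = pos + rng.normal(0.0, params.loc_noise_sd, size=pos.shape)
    return GroundTruthTrajectorySet(
        positions=pos,
        frame_interval=params.frame_interval,
        cell_ids=np.arange(params.n_cells),
        model_labels=["prw"] * params.n_cells,
        immobile=np.zeros(params.n_cells, bool),
    )


def simulate_trajectories(params: MotilityModelParams) -> GroundTruthTrajectorySet:
    """Dispatch on ``params.model``."""
    if params.model == "fbm":
        return simulate_fbm_trajectories(params)
    if params.model == "prw":
        return simulate_prw_trajectories(params)
    # immobile: fixed positions plus localization noise
    rng = np.random.default_rng(params.seed)
    start = _start_positions(params, rng)
    pos = np.repeat(start[:, None, :], params.n_frames, axis=1)
    if params.loc_noise_sd > 0:
        pos = pos + rng.normal(0.0, params.loc_noise_sd, size=pos.shape)
    return GroundTruthTrajectorySet(
        positions=pos,
        frame_interval=params.frame_interval,
        cell_ids=np.arange(params.n_cells),
        model_labels=["immobile"] * params.n_cells,
        immobile=np.ones(params.n_cells, bool),
    )


def mix_immobile_fraction(
    tset: GroundTruthTrajectorySet,
    fraction: float,
    loc_noise_sd: float,
    seed: int,
) -> GroundTruthTrajectorySet:
    """Replace a seeded random subset of cells by an immobile subpopulation.

    ``round(fraction * n_cells)`` cells are pinned at their initial position
    (plus i.i.d. localization noise) and flagged immobile.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    out = copy.deepcopy(tset)
    out.immobile = np.zeros(out.n_cells, bool)
    n_imm = int(round(fraction * out.n_cells))
    if n_imm == 0:
        return out
    chosen = np.sort(rng.choice(out.n_cells, size=n_imm, replace=False))
    fixed = out.positions[chosen, 0:1, :]
    noise = 0.0
    if loc_noise_sd > 0:
        noise = rng.normal(0.0, loc_noise_sd, size=(n_imm, out.n_frames, 2))
    out.positions[chosen] = fixed + noise
    out.immobile[chosen] = True
    for i in chosen:
        out.model_labels[i] = "immobile"
    return out


@dataclass
class RenderParams:
    """How ground-truth positions become pixels."""

    pixel_size: float = 0.1  # µm/px
    image_shape: tuple[int, int] = (512, 512)  # (rows, cols) px
    cell_length: float = 4.0  # µm, capsule end-to-end
    cell_width: float = 1.0  # µm
    orientation_model: str = "along_velocity"
    psf_sigma: float = 0.1  # µm
    background_level: float = 20.0
    cell_intensity: float = 200.0
    noise_model: str = "gaussian"
    noise_scale: float = 5.0
    bit_depth: int = 8

    def __post_init__(self) -> None:
        if not self.cell_length >= self.cell_width > 0:
            raise ValueError("need cell_length >= cell_width > 0")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.psf_sigma < 0:
            raise ValueError("psf_sigma must be non-negative")
        if self.cell_intensity == self.background_level:
            raise ValueError("cell_intensity must differ from background_level")
        if self.orientation_model not in _ORIENTATION_MODELS:
            raise ValueError(f"orientation_model must be one of {_ORIENTATION_MODELS}")
        if self.noise_model not in ("gaussian", "poisson"):
            raise ValueError("noise_model must be 'gaussian' or 'poisson'")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")


def _orientations(
    tset: GroundTruthTrajectorySet, rp: RenderParams, rng: np.random.Generator
) -> np.ndarray:
    """Per-cell, per-frame body angle (radians from +x)."""
    n_c, n_f = tset.n_cells, tset.n_frames
    theta = np.zeros((n_c, n_f))
    if rp.orientation_model == "fixed":
        return theta
    if rp.orientation_model == "random_walk_angle":
        theta[:, 0] = rng.uniform(-np.pi, np.pi, n_c)
        steps = rng.normal(0.0, 0.2, (n_c, n_f - 1))
        theta[:, 1:] = theta[:, 0:1] + np.cumsum(steps, axis=1)
        return theta
    # along_velocity: angle of the displacement averaged over a 3-frame window
    if n_f < 2:
        return theta
    disp = np.diff(tset.positions, axis=1)  # (n_c, n_f - 1, 2)
    kernel = np.ones(3) / 3.0
    for c in range(n_c):
        sm = np.apply_along_axis(
            lambda a: np.convolve(a, kernel, mode="same"), 0, disp[c]
        )
        ang = np.arctan2(sm[:, 1], sm[:, 0])
        moving = np.hypot(sm[:, 0], sm[:, 1]) > 0
        cur = 0.0
        for f in range(n_f - 1):
            if moving[f]:
                cur = ang[f]
            theta[c, f] = cur
        theta[c, -1] = cur
    return theta


def _draw_capsule(
    canvas: np.ndarray, cx: float, cy: float, theta: float,
    half_len: float, radius: float, intensity: float,
) -> None:
    """Max-blend a capsule (all lengths in px) onto the canvas."""
    h, w = canvas.shape
    reach = half_len + radius + 1.0
    r0 = max(int(np.floor(cy - reach)), 0)
    r1 = min(int(np.ceil(cy + reach)) + 1, h)
    c0 = max(int(np.floor(cx - reach)), 0)
    c1 = min(int(np.ceil(cx + reach)) + 1, w)
    if r0 >= r1 or c0 >= c1:
        return
    rows, cols = np.mgrid[r0:r1, c0:c1]
    dx = cols - cx
    dy = rows - cy
    ux, uy = np.cos(theta), np.sin(theta)
    proj = np.clip(dx * ux + dy * uy, -half_len, half_len)
    dist = np.hypot(dx - proj * ux, dy - proj * uy)
    patch = canvas[r0:r1, c0:c1]
    np.maximum(patch, np.where(dist <= radius, intensity, patch), out=patch)


def render_frames(
    tset: GroundTruthTrajectorySet, rp: RenderParams, seed: int = 0
) -> FrameStack:
    """Render ground-truth trajectories into a noisy grayscale image stack.

    Each cell is drawn as a capsule of end-to-end length ``cell_length`` and
    width ``cell_width`` centred at its position, blurred by a Gaussian PSF
    and degraded with the configured noise model.  Raises if any cell (with a
    half-cell-length margin) leaves the field of view.
    """
    rng = np.random.default_rng(seed)
    h, w = rp.image_shape
    field_w, field_h = w * rp.pixel_size, h * rp.pixel_size
    margin = rp.cell_length / 2.0
    x = tset.positions[:, :, 0]
    y = tset.positions[:, :, 1]
    bad = (x < margin) | (x > field_w - margin) | (y < margin) | (y > field_h - margin)
    if np.any(bad):
        cells, frames = np.nonzero(bad)
        pairs = [
            (int(tset.cell_ids[c]), int(f)) for c, f in zip(cells[:20], frames[:20])
        ]
        raise ValueError(
            f"{bad.sum()} cell positions fall outside the field of view "
            f"(first offending (cell_id, frame) pairs: {pairs})"
        )

    theta = _orientations(tset, rp, rng)
    half_len = max(rp.cell_length - rp.cell_width, 0.0) / 2.0 / rp.pixel_size
    radius = rp.cell_width / 2.0 / rp.pixel_size
    max_val = 2**rp.bit_depth - 1
    frames_out = np.empty((tset.n_frames, h, w))
    for f in range(tset.n_frames):
        canvas = np.full((h, w), float(rp.background_level))
        for c in range(tset.n_cells):
            _draw_capsule(
                canvas,
                x[c, f] / rp.pixel_size,
                y[c, f] / rp.pixel_size,
                theta[c, f],
                half_len,
                radius,
                float(rp.cell_intensity),
            )
        if rp.psf_sigma > 0:
            canvas = gaussian_filter(canvas, rp.psf_sigma / rp.pixel_size)
        if rp.noise_model == "gaussian":
            if rp.noise_scale > 0:
                canvas = canvas + rng.normal(0.0, rp.noise_scale, canvas.shape)
        else:  # poisson: noise_scale is the photon gain per intensity unit
            gain = rp.noise_scale if rp.noise_scale > 0 else 1.0
            canvas = rng.poisson(np.clip(canvas, 0, None) * gain) / gain
        frames_out[f] = np.clip(canvas, 0, max_val)
    dtype = np.uint8 if rp.bit_depth == 8 else np.uint16
    return FrameStack(
        frames=np.round(frames_out).astype(dtype),
        pixel_size=rp.pixel_size,
        frame_interval=tset.frame_interval,
        bit_depth=rp.bit_depth,
        condition=tset.condition,
    )
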