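"""Mean-squared-displacement statistics and two-regime power-law fits.

The observables mirror how colony-edge motility is quantified from tracked
cells:

* time-averaged MSD per track and its pairs-weighted ensemble pool,
* independent log-log power-law fits ``<Δr²(t)> ~ t^α`` on an early
  (``τ <= t_c``) and a late (``τ > t_c``) lag regime, with ``t_c`` either
  fixed (default 3 s) or recovered by a free-boundary piecewise fit,
* the large-displacement probability ``p_large`` (fraction of tracks whose
  maximum displacement from the start exceeds ``factor`` body lengths,
  default factor 3.5) and the zero-displacement fraction,
* per-track exponent distributions whose spread quantifies dynamic
  heterogeneity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .track import Trajectory

logger = logging.getLogger(__name__)


class FitError(ValueError):
    """A regime has too few usable lags to fit."""


@dataclass
class MSDCurve:
    lags: np.ndarray  # s, strictly increasing
    msd: np.ndarray  # µm²
    n_pairs: np.ndarray  # displacement pairs per lag
    scope: str  # "per_track" | "ensemble"

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=float)
        self.msd = np.asarray(self.msd, dtype=float)
        self.n_pairs = np.asarray(self.n_pairs, dtype=int)
        if np.any(np.diff(self.lags) <= 0):
            raise ValueError("lags must be strictly increasing")
        if np.any(self.msd < 0):
            raise ValueError("msd must be non-negative")


@dataclass
class TwoRegimeFit:
    alpha1: float
    alpha2: float
    t_c: float  # s; largest lag assigned to the early regime
    prefactor1: float  # µm²/s^alpha1
    prefactor2: float  # µm²/s^alpha2
    r2_1: float
    r2_2: float
    n_lags_1: int
    n_lags_2: int


@dataclass
class DisplacementStats:
    body_length: float  # µm
    factor: float
    noise_floor: float  # µm
    p_large: float
    zero_fraction: float
    n_tracks: int


@dataclass
class ExponentDistribution:
    track_ids: list[int]
    alpha1: np.ndarray
    alpha2: np.ndarray
    sd_alpha1: float
    sd_alpha2: float
    iqr_alpha1: float
    iqr_alpha2: float
    n_tracks_fitted: int
    n_tracks_failed: int


def msd_per_track(traj: Trajectory, max_lag_fraction: float = 0.25) -> MSDCurve:
    """Time-averaged MSD of one track over all start times.

    ``msd(k·dt) = mean_t |r(t + k·dt) - r(t)|²`` for lags up to
    ``max_lag_fraction`` of the track duration (short-lag restriction keeps
    the estimator variance bounded).
    """
    n = len(traj)
    if n < 2:
        raise ValueError("track must contain at least 2 frames")
    if not 0.0 < max_lag_fraction <= 1.0:
        raise ValueError("max_lag_fraction must lie in (0, 1]")
    k_max = max(1, int(np.floor(max_lag_fraction * (n - 1))))
    lags = np.arange(1, k_max + 1) * traj.frame_interval
    msd = np.empty(k_max)
    n_pairs = np.empty(k_max, dtype=int)
    for k in range(1, k_max + 1):
        d = traj.xy[k:] - traj.xy[:-k]
        msd[k - 1] = np.mean(np.einsum("ij,ij->i", d, d))
        n_pairs[k - 1] = n - k
    return MSDCurve(lags=lags, msd=msd, n_pairs=n_pairs, scope="per_track")


def ensemble_msd(
    tracks: list[Trajectory],
    max_lag_fraction: float = 0.25,
    min_pairs: int = 1,
) -> MSDCurve:
    """Pairs-weighted pooled MSD across tracks.

    At each lag the squared displacements of all tracks are pooled, i.e. each
    track contributes in proportion to its number of valid start times.  Lags
    with fewer than ``min_pairs`` total pairs are not reported.
    """
    if not tracks:
        raise ValueError("need at least one track")
    dt = tracks[0].frame_interval
    for t in tracks:
        if t.frame_interval != dt:
            raise ValueError("all tracks must share one frame interval")
    k_maxes = [max(1, int(np.floor(max_lag_fraction * (len(t) - 1)))) for t in tracks]
    k_top = max(k_maxes)
    sums = np.zeros(k_top)
    counts = np.zeros(k_top, dtype=int)
    for t, k_max in zip(tracks, k_maxes):
        for k in range(1, min(k_max, len(t) - 1) + 1):
            d = t.xy[k:] - t.xy[:-k]
            sums[k - 1] += np.einsum("ij,ij->", d, d)
            counts[k - 1] += len(t) - k
    keep = counts >= max(1, min_pairs)
    lags = np.arange(1, k_top + 1) * dt
    return MSDCurve(
        lags=lags[keep],
        msd=sums[keep] / counts[keep],
        n_pairs=counts[keep],
        scope="ensemble",
    )


def _ols_loglog(lags: np.ndarray, msd: np.ndarray, w: np.ndarray | None = None):
    """(Weighted) OLS of log10 msd on log10 lag -> slope, intercept, r², ssr."""
    x = np.log10(lags)
    y = np.log10(msd)
    if w is None:
        w = np.ones_like(x)
    sw = np.sqrt(w)
    a = np.vstack([x * sw, sw]).T
    coef, *_ = np.linalg.lstsq(a, y * sw, rcond=None)
    slope, intercept = float(coef[0]), float(coef[1])
    resid = y - (slope * x + intercept)
    ssr = float(np.sum(w * resid**2))
    ybar = np.sum(w * y) / np.sum(w)
    sst = float(np.sum(w * (y - ybar) ** 2))
    r2 = 1.0 if sst == 0 else 1.0 - ssr / sst
    return slope, intercept, r2, ssr


def _usable(curve: MSDCurve, t_max: float | None):
    keep = curve.msd > 0
    n_zero = int(np.sum(~keep))
    if n_zero:
        logger.warning("excluding %d zero-MSD lags from the log-log fit", n_zero)
    if t_max is not None:
        keep &= curve.lags <= t_max * (1.0 + 1e-12)
    return curve.lags[keep], curve.msd[keep]


def fit_two_regime(
    curve: MSDCurve, t_c: float = 3.0, t_max: float | None = None
) -> TwoRegimeFit:
    """Independent power-law fits on the early (τ <= t_c) and late (τ > t_c) lags.

    Plain OLS of ``log10 msd`` on ``log10 τ`` per regime; no continuity is
    imposed between the two lines.  Lags with zero MSD are excluded (logged);
    each regime needs at least 3 usable lags.
    """
    lags, msd = _usable(curve, t_max)
    early = lags <= t_c * (1.0 + 1e-12)
    late = ~early
    if early.sum() < 3:
        raise FitError(f"early regime has {int(early.sum())} usable lags; need >= 3")
    if late.sum() < 3:
        raise FitError(f"late regime has {int(late.sum())} usable lags; need >= 3")
    a1, b1, r2_1, _ = _ols_loglog(lags[early], msd[early])
    a2, b2, r2_2, _ = _ols_loglog(lags[late], msd[late])
    return TwoRegimeFit(
        alpha1=a1,
        alpha2=a2,
        t_c=t_c,
        prefactor1=10.0**b1,
        prefactor2=10.0**b2,
        r2_1=r2_1,
        r2_2=r2_2,
        n_lags_1=int(early.sum()),
        n_lags_2=int(late.sum()),
    )


def fit_crossover(
    curve: MSDCurve,
    min_lags_per_regime: int = 3,
    t_max: float | None = None,
) -> TwoRegimeFit:
    """Free-boundary piecewise power-law fit.

    Every measured lag is a candidate boundary; both regime lines are fitted
    by OLS weighted by the local log-lag spacing, so each decade of lag time
    carries equal weight regardless of the (linear) sampling grid.  The
    boundary minimizing the total weighted residual is reported as ``t_c``
    (the largest lag of the early regime, matching the ``τ <= t_c``
    convention of :func:`fit_two_regime`).
    """
    lags, msd = _usable(curve, t_max)
    if len(lags) < 2 * min_lags_per_regime:
        raise FitError(
            f"{len(lags)} usable lags cannot support two regimes of "
            f">= {min_lags_per_regime} lags"
        )
    x = np.log10(lags)
    w = np.gradient(x)
    best: tuple[float, TwoRegimeFit] | None = None
    for i in range(min_lags_per_regime, len(lags) - min_lags_per_regime + 1):
        a1, b1, r2_1, ssr1 = _ols_loglog(lags[:i], msd[:i], w[:i])
        a2, b2, r2_2, ssr2 = _ols_loglog(lags[i:], msd[i:], w[i:])
        total = ssr1 + ssr2
        if best is None or total < best[0]:
            best = (
                total,
                TwoRegimeFit(
                    alpha1=a1,
                    alpha2=a2,
                    t_c=float(lags[i - 1]),
                    prefactor1=10.0**b1,
                    prefactor2=10.0**b2,
                    r2_1=r2_1,
                    r2_2=r2_2,
                    n_lags_1=i,
                    n_lags_2=len(lags) - i,
                ),
            )
    assert best is not None
    return best[1]


def max_displacements(tracks: list[Trajectory]) -> np.ndarray:
    """Per track, the maximum distance from its first position."""
    return np.array(
        [float(np.max(np.linalg.norm(t.xy - t.xy[0], axis=1))) for t in tracks]
    )


def displacement_stats(
    tracks: list[Trajectory],
    body_length: float,
    factor: float = 3.5,
    noise_floor: float = 0.0,
) -> DisplacementStats:
    """Large-displacement probability and zero-displacement fraction.

    A track counts as a large displacement when its maximum distance from the
    starting point exceeds ``factor * body_length``; as a zero displacement
    when that distance never exceeds ``noise_floor``.
    """
    if not tracks:
        raise ValueError("need at least one track")
    if body_length <= 0 or factor <= 0:
        raise ValueError("body_length and factor must be positive")
    d = max_displacements(tracks)
    return DisplacementStats(
        body_length=body_length,
        factor=factor,
        noise_floor=noise_floor,
        p_large=float(np.mean(d > factor * body_length)),
        zero_fraction=float(np.mean(d <= noise_floor)),
        n_tracks=len(tracks),
    )


def exponent_distribution(
    tracks: list[Trajectory],
    t_c: float = 3.0,
    min_lags_per_regime: int = 3,
    max_lag_fraction: float = 0.25,
    t_max: float | None = None,
) -> ExponentDistribution:
    """Per-track two-regime exponents and their spread (dynamic heterogeneity)."""
    ids, a1s, a2s = [], [], []
    n_failed = 0
    for t in tracks:
        try:
            curve = msd_per_track(t, max_lag_fraction)
            fit = fit_two_regime(curve, t_c=t_c, t_max=t_max)
        except (FitError, ValueError):
            n_failed += 1
            continue
        if fit.n_lags_1 < min_lags_per_regime or fit.n_lags_2 < min_lags_per_regime:
            n_failed += 1
            continue
        ids.append(t.track_id)
        a1s.append(fit.alpha1)
        a2s.append(fit.alpha2)
    if not ids:
        raise FitError("no track could be fitted in both regimes")
    a1 = np.array(a1s)
    a2 = np.array(a2s)

    def iqr(v: np.ndarray) -> float:
        return float(np.percentile(v, 75) - np.percentile(v, 25))

    return ExponentDistribution(
        track_ids=ids,
        alpha1=a1,
        alpha2=a2,
        sd_alpha1=float(np.std(a1, ddof=1)) if len(a1) > 1 else 0.0,
        sd_alpha2=float(np.std(a2, ddof=1)) if len(a2) > 1 else 0.0,
        iqr_alpha1=iqr(a1),
        iqr_alpha2=iqr(a2),
        n_tracks_fitted=len(ids),
        n_tracks_failed=n_failed,
    )


def furth_msd(lags: np.ndarray, speed_sd: float, persistence_time: float) -> np.ndarray:
    """Closed-form 2-D persistent-random-walk MSD (Fürth formula)."""
    t = np.asarray(lags, dtype=float)
    P = persistence_time
    return 4.0 * speed_sd**2 * P * (t - P * (1.0 - np.exp(-t / P)))
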