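"""End-to-end orchestration: simulate -> render -> segment -> track -> analyze.

A run is described by a :class:`RunConfig` (one block per stage, YAML- or
dict-backed), executes the enabled stages in order, writes every intermediate
product to the output directory, and returns a :class:`RunSummary` in which
every reported statistic is traceable to an output file.  Identical config
and seed reproduce every output byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .io import FrameStack, read_stack, read_table, write_stack, write_table
from .motility import (
    FitError,
    displacement_stats,
    ensemble_msd,
    exponent_distribution,
    fit_crossover,
    fit_two_regime,
    max_displacements,
)
from .presets import get_preset
from .segment import SegmentConfig, segment_stack
from .synthgen import (
    GroundTruthTrajectorySet,
    MotilityModelParams,
    RenderParams,
    mix_immobile_fraction,
    render_frames,
    simulate_trajectories,
)
from .track import (
    LinkConfig,
    Trajectory,
    build_trajectories,
    ground_truth_to_trajectories,
    trajectories_from_dataframe,
    trajectories_to_dataframe,
)

logger = logging.getLogger(__name__)

_STAGES = ("simulate", "render", "segment", "track", "analyze")


class ConfigError(ValueError):
    pass


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {message}")


@dataclass
class RunConfig:
    condition: str = "unlabelled"
    seed: int = 0
    stages: list[str] = field(default_factory=lambda: list(_STAGES))
    simulate: dict = field(default_factory=dict)
    render: dict = field(default_factory=dict)
    segment: dict = field(default_factory=dict)
    track: dict = field(default_factory=dict)
    analyze: dict = field(default_factory=dict)
    input_stack: str | None = None  # TIFF to start from when simulate/render are off
    input_trajectories: str | None = None  # trajectories CSV for analyze-only runs

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(_STAGES)
        if unknown:
            raise ConfigError(f"unknown stages: {sorted(unknown)}")
        self.stages = [s for s in _STAGES if s in self.stages]
        if not self.stages:
            raise ConfigError("at least one stage must be enabled")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if not isinstance(d, dict):
            raise ConfigError("config file must contain a mapping")
        return cls.from_dict(d)

    @classmethod
    def from_preset(cls, name: str, seed: int | None = None) -> "RunConfig":
        d = get_preset(name)
        if seed is not None:
            d["seed"] = seed
        return cls.from_dict(d)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class RunSummary:
    condition: str
    seed: int
    version: str
    outdir: str
    counts: dict
    fit: dict | None  # fixed-boundary ensemble two-regime fit
    crossover: dict | None  # free-boundary fit
    displacement: dict | None
    exponent_spread: dict | None
    config: dict

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_json(cls, path: str | Path) -> "RunSummary":
        return cls(**json.loads(Path(path).read_text()))


def _stage_seed(seed: int, offset: int) -> int:
    return int((seed + 7919 * offset) % (2**31 - 1))


def _simulate(cfg: RunConfig) -> GroundTruthTrajectorySet:
    sim = dict(cfg.simulate)
    immobile_fraction = float(sim.pop("immobile_fraction", 0.0))
    try:
        params = MotilityModelParams(seed=_stage_seed(cfg.seed, 0), **sim)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid simulate block: {exc}") from exc
    tset = simulate_trajectories(params)
    if immobile_fraction > 0:
        tset = mix_immobile_fraction(
            tset, immobile_fraction, params.loc_noise_sd, _stage_seed(cfg.seed, 1)
        )
    tset.condition = cfg.condition
    return tset


def run_pipeline(cfg: RunConfig, outdir: str | Path) -> RunSummary:
    """Execute the enabled stages and write all products under ``outdir``.

    Stages not enabled are fed from the previous stage's serialized output
    (``input_stack`` for segment, ``input_trajectories`` for analyze), so a
    run can be resumed or partially re-executed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    root = logging.getLogger("swarmtrack")
    root.addHandler(handler)
    try:
        return _run_pipeline(cfg, outdir)
    except (ConfigError, StageError):
        (outdir / "FAILED").write_text("see run.log\n")
        raise
    finally:
        root.removeHandler(handler)
        handler.close()


def _run_pipeline(cfg: RunConfig, outdir: Path) -> RunSummary:
    counts: dict = {}
    tset: GroundTruthTrajectorySet | None = None
    stack: FrameStack | None = None
    tracks: list[Trajectory] | None = None
    render_params: RenderParams | None = None
    frame_interval = float(cfg.simulate.get("frame_interval", 0.5))

    def stage_log(stage: str, t0: float, **info) -> None:
        msg = f"stage={stage} " + " ".join(f"{k}={v}" for k, v in info.items())
        logger.info("%s elapsed=%.2fs", msg, time.time() - t0)

    if "simulate" in cfg.stages:
        t0 = time.time()
        try:
            tset = _simulate(cfg)
        except ConfigError:
            raise
        except Exception as exc:  # pragma: no cover - defensive
            raise StageError("simulate", str(exc)) from exc
        write_table(tset.to_dataframe(), outdir / "trajectories_truth.csv")
        frame_interval = tset.frame_interval
        counts["simulate"] = {"n_cells": tset.n_cells, "n_frames": tset.n_frames}
        stage_log("simulate", t0, cells=tset.n_cells, frames=tset.n_frames)

    if "render" in cfg.stages:
        t0 = time.time()
        if tset is None:
            raise ConfigError("render requires the simulate stage (or a truth table)")
        try:
            render_params = RenderParams(**cfg.render)
            stack = render_frames(tset, render_params, seed=_stage_seed(cfg.seed, 2))
        except (TypeError, ValueError) as exc:
            raise StageError("render", str(exc)) from exc
        write_stack(stack, outdir / "stack.tif")
        counts["render"] = {"n_frames": stack.n_frames, "shape": list(stack.shape)}
        stage_log("render", t0, frames=stack.n_frames)

    observations: pd.DataFrame | None = None
    if "segment" in cfg.stages:
        t0 = time.time()
        if stack is None:
            src = cfg.input_stack
            if src is None:
                raise ConfigError("segment needs a rendered stack or input_stack")
            stack = read_stack(src)
        try:
            seg = dict(cfg.segment)
            if seg:
                seg_cfg = SegmentConfig(**seg)
            else:
                rp = render_params or RenderParams(**cfg.render)
                seg_cfg = SegmentConfig.for_geometry(
                    rp.cell_length, rp.cell_width, stack.pixel_size
                )
            observations = segment_stack(stack, seg_cfg)
        except (TypeError, ValueError) as exc:
            raise StageError("segment", str(exc)) from exc
        write_table(observations, outdir / "observations.csv")
        counts["segment"] = {"n_observations": int(len(observations))}
        stage_log("segment", t0, observations=len(observations))
        frame_interval = stack.frame_interval

    if "track" in cfg.stages:
        t0 = time.time()
        if observations is None:
            raise ConfigError("track requires the segment stage")
        try:
            trk = dict(cfg.track)
            if "gate_radius" not in trk:
                rp = render_params or RenderParams(**cfg.render)
                trk["gate_radius"] = 0.5 * rp.cell_length
            link_cfg = LinkConfig(**trk)
            tracks, link_counts = build_trajectories(observations, link_cfg, frame_interval)
        except (TypeError, ValueError) as exc:
            raise StageError("track", str(exc)) from exc
        write_table(trajectories_to_dataframe(tracks), outdir / "trajectories.csv")
        (outdir / "track_log.json").write_text(json.dumps(link_counts, indent=1))
        counts["track"] = link_counts
        stage_log("track", t0, **link_counts)

    fit_d = cross_d = disp_d = spread_d = None
    if "analyze" in cfg.stages:
        t0 = time.time()
        if tracks is None:
            if cfg.input_trajectories is not None:
                tracks = trajectories_from_dataframe(
                    read_table(cfg.input_trajectories), frame_interval
                )
            elif tset is not None:
                tracks = ground_truth_to_trajectories(tset)
            else:
                raise ConfigError("analyze needs tracks, a truth table or input_trajectories")
        if not tracks:
            raise StageError("analyze", "no tracks to analyze")
        an = {**{"t_c": 3.0, "t_max": None, "max_lag_fraction": 0.25, "factor": 3.5,
                 "body_length_um": None, "noise_floor_um": None,
                 "min_lags_per_regime": 3}, **cfg.analyze}

        body_length = an["body_length_um"]
        if body_length is None:
            majors = [t.major_um for t in tracks if t.major_um is not None]
            if majors:
                body_length = float(np.mean(np.concatenate(majors)))
            elif cfg.render:
                body_length = RenderParams(**cfg.render).cell_length
            else:
                raise ConfigError("analyze.body_length_um must be set for this run")
        noise_floor = an["noise_floor_um"]
        if noise_floor is None:
            # covers the max over hundreds of frames of pure localization noise
            noise_floor = 8.0 * float(cfg.simulate.get("loc_noise_sd", 0.0))

        curve = ensemble_msd(tracks, an["max_lag_fraction"])
        write_table(
            pd.DataFrame(
                {
                    "scope": "ensemble",
                    "lag_s": curve.lags,
                    "msd_um2": curve.msd,
                    "n_pairs": curve.n_pairs,
                }
            ),
            outdir / "msd.csv",
        )
        try:
            fit = fit_two_regime(curve, t_c=an["t_c"], t_max=an["t_max"])
            fit_d = dataclasses.asdict(fit)
        except FitError as exc:
            logger.warning("fixed-boundary fit failed: %s", exc)
        try:
            cross = fit_crossover(curve, an["min_lags_per_regime"], t_max=None)
            cross_d = dataclasses.asdict(cross)
        except FitError as exc:
            logger.warning("free-boundary fit failed: %s", exc)
        (outdir / "fits.json").write_text(
            json.dumps({"fixed": fit_d, "free_boundary": cross_d}, indent=1)
        )

        disp = displacement_stats(tracks, body_length, an["factor"], noise_floor)
        disp_d = dataclasses.asdict(disp)
        (outdir / "displacement_stats.json").write_text(json.dumps(disp_d, indent=1))

        exp_df = pd.DataFrame({"track_id": [], "alpha1": [], "alpha2": []})
        try:
            dist = exponent_distribution(
                tracks,
                t_c=an["t_c"],
                min_lags_per_regime=an["min_lags_per_regime"],
                max_lag_fraction=an["max_lag_fraction"],
                t_max=an["t_max"],
            )
            spread_d = {
                "sd_alpha1": dist.sd_alpha1,
                "sd_alpha2": dist.sd_alpha2,
                "iqr_alpha1": dist.iqr_alpha1,
                "iqr_alpha2": dist.iqr_alpha2,
                "n_tracks_fitted": dist.n_tracks_fitted,
                "n_tracks_failed": dist.n_tracks_failed,
            }
            exp_df = pd.DataFrame(
                {"track_id": dist.track_ids, "alpha1": dist.alpha1, "alpha2": dist.alpha2}
            )
        except FitError as exc:
            logger.warning("exponent distribution failed: %s", exc)
        write_table(exp_df, outdir / "exponents.csv")

        stats_df = pd.DataFrame(
            {
                "track_id": [t.track_id for t in tracks],
                "d_max_um": max_displacements(tracks),
            }
        ).merge(exp_df, on="track_id", how="left")
        write_table(stats_df, outdir / "track_stats.csv")
        counts["analyze"] = {"n_tracks": len(tracks), "body_length_um": body_length,
                             "noise_floor_um": noise_floor}
        stage_log("analyze", t0, tracks=len(tracks))

    summary = RunSummary(
        condition=cfg.condition,
        seed=cfg.seed,
        version=__version__,
        outdir=str(outdir),
        counts=counts,
        fit=fit_d,
        crossover=cross_d,
        displacement=disp_d,
        exponent_spread=spread_d,
        config=cfg.to_dict(),
    )
    (outdir / "summary.json").write_text(json.dumps(summary.to_dict(), indent=1))
    return summary


def _bootstrap_ci(
    values: np.ndarray,
    stat,
    b: int,
    rng: np.random.Generator,
) -> tuple[float, float, float]:
    """Point estimate and percentile bootstrap CI over tracks.

    The observed statistic is included in the replicate pool, so ``b = 1``
    degenerates to a zero-width interval at the point estimate.
    """
    point = float(stat(values))
    reps = [point]
    for _ in range(max(0, b - 1)):
        sample = values[rng.integers(0, len(values), len(values))]
        reps.append(float(stat(sample)))
    lo, hi = np.percentile(reps, [2.5, 97.5])
    return point, float(lo), float(hi)


def compare_conditions(
    summaries: list[RunSummary], b: int = 200, seed: int = 0
) -> pd.DataFrame:
    """Tabulate motility statistics across conditions with bootstrap CIs.

    Bootstrapping resamples tracks (the independent sampling unit) from each
    run's ``track_stats.csv``.  Differences are reported against the first
    condition.
    """
    if len(summaries) < 2:
        raise ValueError("need at least two summaries to compare")
    labels = [s.condition for s in summaries]
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate condition labels: {labels}")
    rng = np.random.default_rng(seed)
    rows = []
    for s in summaries:
        stats = read_table(Path(s.outdir) / "track_stats.csv")
        d = stats["d_max_um"].to_numpy()
        disp = s.displacement or {}
        thr = disp.get("factor", 3.5) * disp.get("body_length", 4.0)
        floor = disp.get("noise_floor", 0.0)
        p_large = _bootstrap_ci(d, lambda v: np.mean(v > thr), b, rng)
        zero = _bootstrap_ci(d, lambda v: np.mean(v <= floor), b, rng)
        a2 = stats["alpha2"].dropna().to_numpy()
        a1 = stats["alpha1"].dropna().to_numpy()

        def spread(v: np.ndarray) -> float:
            return float(np.std(v, ddof=1)) if len(v) > 1 else 0.0

        sd1 = _bootstrap_ci(a1, spread, b, rng) if len(a1) else (np.nan,) * 3
        sd2 = _bootstrap_ci(a2, spread, b, rng) if len(a2) else (np.nan,) * 3
        rows.append(
            {
                "condition": s.condition,
                "n_tracks": len(stats),
                "alpha1": (s.fit or {}).get("alpha1", np.nan),
                "alpha2": (s.fit or {}).get("alpha2", np.nan),
                "p_large": p_large[0],
                "p_large_lo": p_large[1],
                "p_large_hi": p_large[2],
                "zero_fraction": zero[0],
                "zero_fraction_lo": zero[1],
                "zero_fraction_hi": zero[2],
                "sd_alpha1": sd1[0],
                "sd_alpha1_lo": sd1[1],
                "sd_alpha1_hi": sd1[2],
                "sd_alpha2": sd2[0],
                "sd_alpha2_lo": sd2[1],
                "sd_alpha2_hi": sd2[2],
            }
        )
    table = pd.DataFrame(rows)
    ref = table.iloc[0]
    for col in ("alpha1", "alpha2", "p_large", "zero_fraction", "sd_alpha1", "sd_alpha2"):
        table[f"delta_{col}"] = table[col] - ref[col]
    return table
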