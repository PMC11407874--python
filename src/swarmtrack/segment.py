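"""Per-frame segmentation of rod-shaped cells.

The chain is: white top-hat contrast enhancement -> Otsu binarization ->
watershed splitting of touching cells on the negated Euclidean distance
transform -> equivalent-ellipse shape measurement.  All outputs are in
physical units (µm) using the pixel-centre coordinate convention of
:class:`~swarmtrack.io.FrameStack`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.morphology import disk, white_tophat
from skimage.segmentation import watershed

from .io import FrameStack


@dataclass
class CellObservation:
    """One segmented cell in one frame (equivalent-ellipse measurements)."""

    frame_index: int
    label: int
    centroid_x: float  # µm
    centroid_y: float  # µm
    area: float  # µm²
    major_axis: float  # µm
    minor_axis: float  # µm
    orientation: float  # radians from +x axis, in (-pi/2, pi/2]
    border: bool = False


@dataclass
class SegmentConfig:
    """Segmentation knobs, with defaults tied to the expected cell geometry.

    ``feature_size_px`` is the diameter of the top-hat disc (just above the
    cell width so rods survive the opening); ``min_area_px`` rejects debris
    below a quarter of a single-cell footprint; ``min_seed_separation_px``
    (about 0.8 cell lengths) keeps the distance-transform ridge of one rod
    from seeding two cells.
    """

    feature_size_px: int = 13
    min_area_px: int = 90
    min_seed_separation_px: int = 32
    drop_border: bool = True

    @classmethod
    def for_geometry(
        cls, cell_length_um: float, cell_width_um: float, pixel_size: float,
        drop_border: bool = True,
    ) -> "SegmentConfig":
        length_px = cell_length_um / pixel_size
        width_px = cell_width_um / pixel_size
        # drawn capsule footprint: rectangle plus two half-discs
        cell_px = (length_px - width_px) * width_px + np.pi * (width_px / 2.0) ** 2
        return cls(
            feature_size_px=int(np.ceil(width_px)) + 3,
            min_area_px=max(1, int(round(0.25 * cell_px))),
            min_seed_separation_px=max(2, int(round(0.8 * length_px))),
            drop_border=drop_border,
        )


def enhance_contrast(frame: np.ndarray, feature_size: int) -> np.ndarray:
    """White top-hat with a disc of the given diameter, rescaled to input range.

    Removes any additive background (output of a flat field is zero) while
    retaining bright features narrower than the structuring element.
    """
    frame = np.asarray(frame, dtype=float)
    if feature_size < 1:
        raise ValueError("feature_size must be at least 1 px")
    if feature_size > min(frame.shape):
        raise ValueError("feature_size exceeds the smallest image dimension")
    footprint = disk(max(1, feature_size // 2))
    th = white_tophat(frame, footprint=footprint)
    peak = th.max()
    if peak > 0:
        th = th * ((frame.max() - frame.min()) / peak)
    return th


def otsu_binarize(frame: np.ndarray) -> np.ndarray:
    """Threshold with Otsu's between-class-variance criterion (256 bins)."""
    frame = np.asarray(frame)
    if frame.min() == frame.max():
        raise ValueError("constant image: no Otsu threshold exists")
    threshold = threshold_otsu(frame, nbins=256)
    return frame > threshold


def watershed_split(
    mask: np.ndarray, min_area: int = 0, min_seed_separation: int = 1
) -> np.ndarray:
    """Partition foreground into cell candidates.

    Objects below ``min_area`` pixels are removed, then the remaining
    foreground is split by watershed on the negated Euclidean distance
    transform, seeded at distance-transform maxima at least
    ``min_seed_separation`` px apart.  An empty mask yields an empty label
    image.  Foreground pixels are conserved: ``labels > 0`` equals the
    cleaned mask.
    """
    mask = np.asarray(mask, dtype=bool)
    if min_area > 1:
        cc0, n0 = ndi.label(mask)
        sizes = np.bincount(cc0.ravel())
        small = np.flatnonzero(sizes < min_area)
        mask = mask & ~np.isin(cc0, small[small > 0])
    labels_out = np.zeros(mask.shape, dtype=np.int32)
    if not mask.any():
        return labels_out
    edt = ndi.distance_transform_edt(mask)
    cc, _ = ndi.label(mask)
    # light smoothing stops noise-roughened ridge plateaus from double-seeding
    peaks = peak_local_max(
        ndi.gaussian_filter(edt, 1.0),
        min_distance=max(1, int(min_seed_separation)),
        labels=cc,
        exclude_border=False,
    )
    markers = np.zeros(mask.shape, dtype=np.int32)
    for i, (r, c) in enumerate(peaks, start=1):
        markers[r, c] = i
    # a component whose peaks were all suppressed still needs one seed
    has_seed = np.unique(cc[markers > 0])
    for comp in np.unique(cc):
        if comp == 0 or comp in has_seed:
            continue
        rr, cc_idx = np.nonzero(cc == comp)
        best = np.argmax(edt[rr, cc_idx])
        markers[rr[best], cc_idx[best]] = markers.max() + 1
    return watershed(-edt, markers, mask=mask).astype(np.int32)


def _ellipse_from_coords(rows: np.ndarray, cols: np.ndarray) -> tuple[float, float, float]:
    """Equivalent-ellipse (major, minor, orientation) from pixel coordinates.

    Axis lengths are ``4 * sqrt(eigenvalue)`` of the second central moment
    matrix (px); orientation is measured from the +x (column) axis and folded
    into (-pi/2, pi/2].
    """
    x = cols - cols.mean()
    y = rows - rows.mean()
    n = x.size
    # +1/12 per axis: each pixel is a unit square, not a point mass
    mxx = np.mean(x * x) + 1.0 / 12.0
    myy = np.mean(y * y) + 1.0 / 12.0
    mxy = np.mean(x * y)
    common = np.sqrt((mxx - myy) ** 2 + 4.0 * mxy**2)
    lam_max = (mxx + myy + common) / 2.0
    lam_min = (mxx + myy - common) / 2.0
    theta = 0.5 * np.arctan2(2.0 * mxy, mxx - myy)
    if theta <= -np.pi / 2:
        theta += np.pi
    return 4.0 * np.sqrt(lam_max), 4.0 * np.sqrt(max(lam_min, 0.0)), theta


def measure_objects(
    labels: np.ndarray,
    pixel_size: float,
    frame_index: int = 0,
    drop_border: bool = False,
) -> list[CellObservation]:
    """Equivalent-ellipse measurements for every labelled object.

    Border-touching objects are flagged; they are excluded from the result
    when ``drop_border`` is true (their shape and displacement are censored
    by the field of view).
    """
    labels = np.asarray(labels)
    h, w = labels.shape
    out: list[CellObservation] = []
    for lab in np.unique(labels):
        if lab == 0:
            continue
        rows, cols = np.nonzero(labels == lab)
        touches = (
            rows.min() == 0 or cols.min() == 0 or rows.max() == h - 1 or cols.max() == w - 1
        )
        if drop_border and touches:
            continue
        major, minor, theta = _ellipse_from_coords(rows.astype(float), cols.astype(float))
        out.append(
            CellObservation(
                frame_index=frame_index,
                label=int(lab),
                centroid_x=float(cols.mean() * pixel_size),
                centroid_y=float(rows.mean() * pixel_size),
                area=float(rows.size * pixel_size**2),
                major_axis=float(major * pixel_size),
                minor_axis=float(minor * pixel_size),
                orientation=float(theta),
                border=bool(touches),
            )
        )
    return out


def observations_to_dataframe(obs: list[CellObservation]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "frame": [o.frame_index for o in obs],
            "label": [o.label for o in obs],
            "x_um": [o.centroid_x for o in obs],
            "y_um": [o.centroid_y for o in obs],
            "area_um2": [o.area for o in obs],
            "major_um": [o.major_axis for o in obs],
            "minor_um": [o.minor_axis for o in obs],
            "orientation_rad": [o.orientation for o in obs],
            "border_flag": [int(o.border) for o in obs],
        }
    )


def segment_frame(
    frame: np.ndarray,
    pixel_size: float,
    cfg: SegmentConfig,
    frame_index: int = 0,
) -> list[CellObservation]:
    """Full enhancement -> threshold -> watershed -> measurement chain."""
    enhanced = enhance_contrast(frame, cfg.feature_size_px)
    try:
        mask = otsu_binarize(enhanced)
    except ValueError:
        return []  # featureless frame
    labels = watershed_split(mask, cfg.min_area_px, cfg.min_seed_separation_px)
    return measure_objects(labels, pixel_size, frame_index, drop_border=cfg.drop_border)


def segment_stack(stack: FrameStack, cfg: SegmentConfig) -> pd.DataFrame:
    """Segment every frame of a stack into an observation table."""
    all_obs: list[CellObservation] = []
    for f in range(stack.n_frames):
        all_obs.extend(segment_frame(stack.frames[f], stack.pixel_size, cfg, f))
    return observations_to_dataframe(all_obs)
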