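"""Marker tracking: recover a planar trajectory (mm) from grayscale frames.

The experimental footage shows a single bright paint mark on the insect's
pronotum against a dark arena, filmed from above at 1,000 fps.  Tracking is a
three-step pipeline: scale calibration from a reference square of known side
length, per-frame blob detection with a subpixel intensity-weighted centroid,
and assembly of the per-frame centroids into a uniformly sampled trajectory
with bounded gap interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import binary_dilation
from skimage.measure import label, regionprops

from .errors import ConfigError, TrackingError

__all__ = [
    "Calibration",
    "Trajectory",
    "calibrate_scale",
    "measure_square_side",
    "detect_marker",
    "track_sequence",
]


@dataclass(frozen=True)
class Calibration:
    """Pixel-to-millimetre scale with provenance.

    The reference feature in the study footage is a bold square of 10 mm side
    length visible in each photograph.
    """

    mm_per_px: float
    source: str = "reference square"

    def __post_init__(self) -> None:
        if not self.mm_per_px > 0:
            raise ConfigError(f"mm_per_px must be positive, got {self.mm_per_px}")


@dataclass
class Trajectory:
    """Uniformly sampled planar marker positions in millimetres."""

    t_ms: np.ndarray
    x_mm: np.ndarray
    y_mm: np.ndarray
    calibration: Calibration
    n_interpolated: int = 0

    def __post_init__(self) -> None:
        self.t_ms = np.asarray(self.t_ms, dtype=float)
        self.x_mm = np.asarray(self.x_mm, dtype=float)
        self.y_mm = np.asarray(self.y_mm, dtype=float)
        if not (len(self.t_ms) == len(self.x_mm) == len(self.y_mm)):
            raise ConfigError("t_ms, x_mm and y_mm must have equal length")
        if len(self.t_ms) >= 2:
            dt = np.diff(self.t_ms)
            if np.any(dt <= 0):
                raise ConfigError("timestamps must be strictly increasing")
            if np.ptp(dt) > 1e-9 * dt[0]:
                raise ConfigError("timestamps must be uniformly spaced")

    def __len__(self) -> int:
        return len(self.t_ms)

    @property
    def dt_ms(self) -> float:
        return float(self.t_ms[1] - self.t_ms[0])

    @property
    def positions_mm(self) -> np.ndarray:
        return np.column_stack([self.x_mm, self.y_mm])


def calibrate_scale(side_px: float, known_side_mm: float = 10.0,
                    source: str = "reference square") -> Calibration:
    """Derive the mm/px scale from the measured side of the reference square."""
    if not side_px > 0:
        raise ConfigError(f"square side must be positive, got {side_px} px")
    if not known_side_mm > 0:
        raise ConfigError(f"known side must be positive, got {known_side_mm} mm")
    return Calibration(mm_per_px=known_side_mm / side_px, source=source)


def measure_square_side(frame: np.ndarray, threshold_frac: float = 0.25) -> float:
    """Measure the side (px) of the filled calibration square in a frame.

    Thresholds well below the marker-detection level so the dimmer square is
    segmented, then takes the largest connected component (the square dwarfs
    the marker blob) and returns sqrt(area), exact for an axis-aligned filled
    square.
    """
    frame = np.asarray(frame, dtype=float)
    background = float(np.median(frame))
    peak = float(frame.max())
    if peak <= background:
        raise TrackingError("no calibration square found (flat frame)")
    mask = frame > background + threshold_frac * (peak - background)
    labelled = label(mask, connectivity=2)
    areas = np.bincount(labelled.ravel())[1:]
    if areas.size == 0:
        raise TrackingError("no calibration square found")
    return float(np.sqrt(areas.max()))


def detect_marker(frame: np.ndarray, threshold_frac: float = 0.5,
                  min_area_px: int = 4,
                  refine_px: int = 4) -> tuple[float, float] | None:
    """Locate the marker blob; return its subpixel centroid (x=col, y=row).

    The threshold sits at ``median + threshold_frac * (max - median)``; the
    median is a robust background estimate because the blob covers a tiny
    fraction of the frame.  8-connected components above threshold smaller
    than ``min_area_px`` are discarded (isolated noise excursions).  Among the
    survivors the largest pixel area wins; ties go to the larger integrated
    (background-subtracted) intensity, then to the component whose minimum
    (row, col) pixel is smallest.

    The centroid is weighted by background-subtracted intensity over the
    chosen component's mask dilated by ``refine_px`` pixels: a hard 50%
    cut truncates the blob tail asymmetrically and biases the centroid by
    up to ~0.1 px at half-integer positions, while including the dilated
    skirt brings the systematic error well below 0.05 px.

    Returns ``None`` when no component survives — a lost frame is a value,
    not an error.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.size == 0:
        raise ConfigError("empty frame")
    background = float(np.median(frame))
    peak = float(frame.max())
    if peak <= background:
        return None
    # robust noise floor (6 x MAD-estimated sigma): a frame with no marker is
    # pure noise, and a threshold relative to its maximum alone would segment
    # noise clusters instead of reporting the marker as lost
    mad = float(np.median(np.abs(frame - background)))
    noise_floor = 6.0 * 1.4826 * mad
    threshold = background + max(threshold_frac * (peak - background), noise_floor)
    if peak <= threshold:
        return None
    mask = frame > threshold
    labelled = label(mask, connectivity=2)
    net = frame - background
    best = None
    best_key = None
    for prop in regionprops(labelled, intensity_image=net):
        if prop.area < min_area_px:
            continue
        integrated = float(prop.image_intensity.sum())
        # coords are emitted in row-major scan order, so coords[0] is the
        # lexicographically smallest (row, col) pixel of the component
        first_pixel = tuple(int(c) for c in prop.coords[0])
        key = (-int(prop.area), -integrated, first_pixel)
        if best_key is None or key < best_key:
            best_key = key
            best = prop
    if best is None:
        return None
    region = labelled == best.label
    if refine_px > 0:
        region = binary_dilation(region, iterations=refine_px)
    weights = np.where(region, np.maximum(net, 0.0), 0.0)
    total = weights.sum()
    rows, cols = np.nonzero(weights)
    row = float((weights[rows, cols] * rows).sum() / total)
    col = float((weights[rows, cols] * cols).sum() / total)
    return col, row


def track_sequence(frames, calibration: Calibration, fps: float = 1000.0,
                   threshold_frac: float = 0.5, min_area_px: int = 4,
                   gap_limit: int = 3) -> Trajectory:
    """Track the marker through a frame stack and return a Trajectory in mm.

    Runs of at most ``gap_limit`` consecutive lost frames are filled by linear
    interpolation between the bracketing detections and counted in
    ``n_interpolated``.  The marker must be found in the first and last frame
    and no lost run may exceed ``gap_limit``.
    """
    frames = np.asarray(frames)
    if frames.ndim != 3 or len(frames) < 2:
        raise ConfigError("need a stack of at least 2 frames")
    if not fps > 0:
        raise ConfigError(f"fps must be positive, got {fps}")

    centroids: list[tuple[float, float] | None] = [
        detect_marker(f, threshold_frac=threshold_frac, min_area_px=min_area_px)
        for f in frames
    ]
    if centroids[0] is None:
        raise TrackingError("marker lost at first frame (index 0)")
    if centroids[-1] is None:
        raise TrackingError(f"marker lost at last frame (index {len(frames) - 1})")

    lost = [i for i, c in enumerate(centroids) if c is None]
    if lost:
        runs = np.split(np.array(lost), np.where(np.diff(lost) != 1)[0] + 1)
        for run in runs:
            if len(run) > gap_limit:
                raise TrackingError(
                    f"marker lost for {len(run)} consecutive frames "
                    f"(frames {run[0]}-{run[-1]}), gap_limit={gap_limit}"
                )

    idx = np.arange(len(frames), dtype=float)
    found = np.array([i for i, c in enumerate(centroids) if c is not None])
    cx = np.array([centroids[i][0] for i in found])
    cy = np.array([centroids[i][1] for i in found])
    x_px = np.interp(idx, found, cx)
    y_px = np.interp(idx, found, cy)

    t_ms = idx * 1000.0 / fps
    return Trajectory(
        t_ms=t_ms,
        x_mm=x_px * calibration.mm_per_px,
        y_mm=y_px * calibration.mm_per_px,
        calibration=calibration,
        n_interpolated=len(lost),
    )
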