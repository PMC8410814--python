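"""Time-lapse contact stability and process-tip trajectory metrics.

Contact stability of a microglia-node pair over a movie is summarised by
the percentage of frames with contact and the longest run of consecutive
frames in (or out of) contact.  Tip motility is summarised on
origin-relative trajectories: per-step Euclidean distances

    d(t_n, t_{n+1}) = sqrt((x_{n+1} - x_n)^2 + (y_{n+1} - y_n)^2)

converted to µm, total path length, mean instantaneous velocity in
µm/min, and mean distance from the t0 origin.

Movies with dropped timepoints must be split into gap-free series before
scoring — run statistics are length-sensitive, so gaps are never
interpolated (:func:`split_series`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .contacts import call_contact
from .masks import NodalStructure


@dataclass
class ContactTimeSeries:
    """Boolean per-frame contact record for one microglia-node pair."""

    frames: np.ndarray
    frame_interval: float
    pair_id: tuple[str, str] = ("", "")

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=bool)
        if self.frames.ndim != 1 or len(self.frames) < 2:
            raise ValueError("a contact series needs >= 2 consecutive frames")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")

    def __len__(self) -> int:
        return len(self.frames)


@dataclass
class TrackedTip:
    """Ordered coordinates of one process tip across frames.

    ``coords`` rows are (x, y) or (x, y, z) in pixels; x and y scale by
    ``voxel_size_xy``, z by ``voxel_size_z``.
    """

    coords: np.ndarray
    voxel_size_xy: float = 1.0
    frame_interval: float = 30.0
    voxel_size_z: float | None = None
    tip_id: str = ""
    initial_contact: bool = False

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[0] < 2:
            raise ValueError("a track needs >= 2 points")
        if self.coords.shape[1] not in (2, 3):
            raise ValueError("coordinates must be (x, y) or (x, y, z)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        if self.coords.shape[1] == 3 and self.voxel_size_z is None:
            raise ValueError("3D track requires voxel_size_z")
        if self.voxel_size_xy <= 0 or self.frame_interval <= 0:
            raise ValueError("voxel_size_xy and frame_interval must be positive")

    def _scale(self) -> np.ndarray:
        if self.coords.shape[1] == 2:
            return np.array([self.voxel_size_xy, self.voxel_size_xy])
        return np.array([self.voxel_size_xy, self.voxel_size_xy, self.voxel_size_z])


# ---------------------------------------------------------------------------
# contact-series metrics


def percent_frames_with_contact(series: ContactTimeSeries) -> float:
    """Percentage of frames in which the pair is in contact."""
    return 100.0 * float(series.frames.mean())


def longest_run(series: ContactTimeSeries, state: bool = True) -> int:
    """Longest run of consecutive frames equal to ``state`` (0 if absent)."""
    x = series.frames == state
    if not x.any():
        return 0
    # run-length encode: boundaries where the value changes
    padded = np.concatenate([[False], x, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, ends = edges[::2], edges[1::2]
    return int((ends - starts).max())


def split_series(
    frame_numbers: np.ndarray,
    states: np.ndarray,
    frame_interval: float,
    pair_id: tuple[str, str] = ("", ""),
) -> list[ContactTimeSeries]:
    """Split a contact record with dropped timepoints into gap-free series.

    Segments shorter than 2 frames are discarded (a single frame carries
    no run information).
    """
    frame_numbers = np.asarray(frame_numbers, dtype=int)
    states = np.asarray(states, dtype=bool)
    order = np.argsort(frame_numbers)
    frame_numbers, states = frame_numbers[order], states[order]
    breaks = np.flatnonzero(np.diff(frame_numbers) != 1) + 1
    out = []
    for seg in np.split(states, breaks):
        if len(seg) >= 2:
            out.append(ContactTimeSeries(seg, frame_interval, pair_id=pair_id))
    return out


def contact_timecourse_from_masks(
    microglia_movie: np.ndarray,
    node,
    frame_interval: float,
    adjacency: str = "full",
    pair_id: tuple[str, str] = ("", ""),
) -> ContactTimeSeries:
    """Apply the contact rule frame by frame to a registered movie.

    ``microglia_movie`` is (t, y, x) boolean; ``node`` a static boolean
    mask or :class:`~nodeglia.masks.NodalStructure`.  Frames must already
    be registered to each other — misregistration is not detectable here
    and silently corrupts the series (documented contract).
    """
    movie = np.asarray(microglia_movie)
    if movie.ndim != 3:
        raise ValueError("expected a (t, y, x) movie")
    states = [call_contact(movie[t], node, adjacency=adjacency) for t in range(movie.shape[0])]
    return ContactTimeSeries(np.array(states), frame_interval, pair_id=pair_id)


# ---------------------------------------------------------------------------
# trajectory metrics


def relative_trajectory(tip: TrackedTip) -> np.ndarray:
    """Coordinates relative to the t0 position: first point exactly 0."""
    return tip.coords - tip.coords[0]


def step_distances(tip: TrackedTip) -> np.ndarray:
    """Euclidean distance (µm) between successive timepoints."""
    deltas = np.diff(tip.coords, axis=0) * tip._scale()
    return np.sqrt((deltas**2).sum(axis=1))


def motility_summary(tip: TrackedTip) -> dict[str, float]:
    """Total path length (µm), mean instantaneous velocity (µm/min) and
    mean distance from the origin (µm, over frames after t0)."""
    steps = step_distances(tip)
    rel = relative_trajectory(tip) * tip._scale()
    dist_from_origin = np.sqrt((rel[1:] ** 2).sum(axis=1))
    minutes_per_frame = tip.frame_interval / 60.0
    return {
        "total_path_length_um": float(steps.sum()),
        "mean_instantaneous_velocity_um_per_min": float(steps.mean() / minutes_per_frame),
        "mean_distance_from_origin_um": float(dist_from_origin.mean()),
    }


def instantaneous_velocities(tip: TrackedTip) -> np.ndarray:
    """Per-step velocities in µm/min."""
    return step_distances(tip) / (tip.frame_interval / 60.0)


def rose_plot_coordinates(tips: list[TrackedTip]) -> "np.ndarray":
    """Stack of origin-relative trajectories in µm for external plotting.

    Returns a structured record per point: (tip index, frame, coords...).
    Provided as plain float array (n_points, 2 + ndim).
    """
    rows = []
    for i, tip in enumerate(tips):
        rel = relative_trajectory(tip) * tip._scale()
        for t, point in enumerate(rel):
            rows.append([i, t, *point])
    return np.asarray(rows, dtype=float)
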