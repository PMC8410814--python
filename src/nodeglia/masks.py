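"""Binarization, nodal-structure labelling and single-cell extraction.

The original workflow binarized channels manually in ImageJ; here the
threshold is a reproducible, recorded choice — Otsu by default, or a
fixed value — so that every downstream number can be traced to an
explicit rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.draw import polygon as _draw_polygon
from skimage.filters import threshold_otsu
from skimage.measure import label as _cc_label
from skimage.morphology import remove_small_objects

from .stacks import ChannelStack

#: default minimum object size (pixels / voxels) used to suppress
#: shot-noise specks after thresholding
MIN_OBJECT_PX_2D = 4
MIN_OBJECT_PX_3D = 8


def _as_array(image) -> np.ndarray:
    return image.data if isinstance(image, ChannelStack) else np.asarray(image)


def _resolve_threshold(image: np.ndarray, method) -> float:
    """Threshold from 'otsu', 'fixed:<value>', or a number."""
    if isinstance(method, (int, float)) and not isinstance(method, bool):
        return float(method)
    if method == "otsu":
        if np.ptp(image) == 0:
            raise ValueError("Otsu threshold undefined for a constant image")
        return float(threshold_otsu(image))
    if isinstance(method, str) and method.startswith("fixed:"):
        return float(method.split(":", 1)[1])
    raise ValueError(f"unknown threshold method {method!r}")


def binarize(channel, method="otsu", min_object_px: int | None = None) -> np.ndarray:
    """Threshold one image volume (2D or 3D) into a boolean mask.

    Objects smaller than ``min_object_px`` (default 4 px in 2D, 8 voxels
    in 3D) are removed.  ``method`` is ``"otsu"``, ``"fixed:<value>"``
    or a plain number; Otsu on a constant image raises, since the
    threshold is undefined there.
    """
    image = _as_array(channel)
    if image.size == 0:
        raise ValueError("empty image")
    thr = _resolve_threshold(image, method)
    mask = image > thr
    if min_object_px is None:
        min_object_px = MIN_OBJECT_PX_2D if image.ndim == 2 else MIN_OBJECT_PX_3D
    if min_object_px > 1:
        mask = remove_small_objects(mask, max_size=min_object_px - 1, connectivity=image.ndim)
    return mask


def binarize_movie(channel, method="otsu", min_object_px: int | None = None) -> np.ndarray:
    """Binarize a (t, y, x) movie frame by frame with one shared threshold.

    A single threshold computed on the full movie keeps frames
    comparable; small-object cleanup runs per frame so that specks are
    judged in 2D.
    """
    movie = _as_array(channel)
    if movie.ndim != 3:
        raise ValueError("expected a (t, y, x) movie")
    thr = _resolve_threshold(movie, method)
    if min_object_px is None:
        min_object_px = MIN_OBJECT_PX_2D
    frames = []
    for t in range(movie.shape[0]):
        m = movie[t] > thr
        if min_object_px > 1:
            m = remove_small_objects(m, max_size=min_object_px - 1, connectivity=2)
        frames.append(m)
    return np.stack(frames)


@dataclass
class NodalStructure:
    """One connected component of the nodal-marker mask."""

    id: int
    voxels: np.ndarray  # (n, ndim) int indices
    centroid_px: tuple[float, ...]
    centroid_um: tuple[float, ...] | None = None
    shape: tuple[int, ...] = ()

    @property
    def n_voxels(self) -> int:
        return len(self.voxels)

    def to_mask(self, shape: tuple[int, ...] | None = None) -> np.ndarray:
        shape = shape or self.shape
        mask = np.zeros(shape, dtype=bool)
        mask[tuple(self.voxels.T)] = True
        return mask


@dataclass
class LabelImage:
    """Integer-labelled connected components plus per-structure records."""

    labels: np.ndarray
    structures: list[NodalStructure] = field(default_factory=list)
    connectivity: str = "full"

    @property
    def n_structures(self) -> int:
        return len(self.structures)


def _connectivity_rank(connectivity: str, ndim: int) -> int:
    if connectivity == "face":
        return 1
    if connectivity == "full":  # 8-connectivity in 2D, 26 in 3D
        return ndim
    raise ValueError("connectivity must be 'face' or 'full'")


def label_nodes(
    node_mask: np.ndarray,
    connectivity: str = "full",
    voxel_size_xy: float | None = None,
    voxel_size_z: float | None = None,
) -> LabelImage:
    """Label connected components of a binary nodal mask.

    Returns a :class:`LabelImage` whose structures carry voxel sets and
    centroids in pixels (and in µm when voxel sizes are given; axis
    order (z,)y,x with z scaled by ``voxel_size_z``).
    """
    mask = np.asarray(node_mask)
    if mask.dtype != bool:
        raise ValueError("label_nodes expects a boolean mask")
    rank = _connectivity_rank(connectivity, mask.ndim)
    labels = _cc_label(mask, connectivity=rank)
    structures = []
    for lab in range(1, labels.max() + 1):
        idx = np.argwhere(labels == lab)
        centroid = tuple(idx.mean(axis=0))
        centroid_um = None
        if voxel_size_xy is not None:
            scale = [voxel_size_xy] * mask.ndim
            if mask.ndim == 3:
                scale[0] = voxel_size_z if voxel_size_z is not None else voxel_size_xy
            centroid_um = tuple(c * s for c, s in zip(centroid, scale))
        structures.append(
            NodalStructure(
                id=lab,
                voxels=idx,
                centroid_px=centroid,
                centroid_um=centroid_um,
                shape=mask.shape,
            )
        )
    return LabelImage(labels=labels, structures=structures, connectivity=connectivity)


def roi_to_mask(roi, shape: tuple[int, int]) -> np.ndarray:
    """ROI -> boolean mask.  ROI is a half-open bbox ((y0, y1), (x0, x1))
    or a polygon given as an (n, 2) list of (y, x) vertices."""
    mask = np.zeros(shape, dtype=bool)
    roi_arr = np.asarray(roi, dtype=float)
    if roi_arr.shape == (2, 2) and np.all(roi_arr[:, 1] >= roi_arr[:, 0]):
        (y0, y1), (x0, x1) = roi_arr.astype(int)
        if y0 < 0 or x0 < 0 or y1 > shape[0] or x1 > shape[1]:
            raise ValueError("roi exceeds image bounds")
        mask[y0:y1, x0:x1] = True
        return mask
    if roi_arr.ndim != 2 or roi_arr.shape[1] != 2:
        raise ValueError("roi must be a bbox ((y0,y1),(x0,x1)) or (n,2) polygon")
    rr, cc = _draw_polygon(roi_arr[:, 0], roi_arr[:, 1], shape=shape)
    mask[rr, cc] = True
    return mask


def extract_cell_mask(microglia_mask: np.ndarray, roi) -> np.ndarray:
    """Single-cell mask: restrict to the ROI, keep the largest component.

    Mirrors the manual step of drawing a region of interest around one
    cell; if the ROI intersects no foreground, that is an error rather
    than an empty answer.
    """
    mask = np.asarray(microglia_mask)
    if mask.dtype != bool:
        raise ValueError("expected a boolean microglia mask")
    if mask.ndim != 2:
        raise ValueError("cell extraction operates on 2D (projected) masks")
    inter = mask & roi_to_mask(roi, mask.shape)
    if not inter.any():
        raise ValueError("roi does not intersect any microglial signal")
    labels = _cc_label(inter, connectivity=2)
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    return labels == sizes.argmax()


def max_projection(stack, axis: int = 0) -> np.ndarray:
    """Maximum-intensity projection along one axis (default: z of a zyx volume)."""
    return _as_array(stack).max(axis=axis)
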