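"""Micrograph preprocessing: plane selection, normalization, instance
splitting and single-cell cropping.

The pipeline mirrors standard confocal single-cell extraction: take the first
and last plane of the z-stack, normalize each plane by its global mean +/- SD,
obtain a cell mask (external segmenter output, or an Otsu fallback on the
NeuN-analog detection channel), split fused regions of interest by iterative
erosion followed by dilation back within the parent support, drop regions
smaller than 180 px^2, and crop tight bounding-box rectangles around each
surviving region from the normalized planes.

The erosion-dilation splitter only ever edits region *masks*; raw intensity
arrays are never modified.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure
from skimage.filters import threshold_otsu
from skimage.morphology import disk

#: structuring element connectivity used for all component labeling (8-connected)
_STRUCT8 = np.ones((3, 3), dtype=bool)


@dataclass
class MicrographStack:
    """A multi-channel confocal z-stack.

    ``intensities`` has shape (n_channels, n_planes, H, W) and holds raw
    nonnegative values; ``plane_stats`` (mean, SD over all H*W pixels of one
    channel/plane) are recomputed on demand rather than cached.
    """

    intensities: np.ndarray
    channel_names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=np.float64)
        if self.intensities.ndim != 4:
            raise ValueError("intensities must be (n_channels, n_planes, H, W)")
        if len(self.channel_names) != self.intensities.shape[0]:
            raise ValueError("channel_names length must match the channel axis")
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel_names must be unique")

    @property
    def n_channels(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_planes(self) -> int:
        return self.intensities.shape[1]

    def plane(self, channel: int | str, plane_index: int) -> np.ndarray:
        if isinstance(channel, str):
            channel = self.channel_names.index(channel)
        return self.intensities[channel, plane_index]

    def plane_stats(self, channel: int | str, plane_index: int) -> tuple[float, float]:
        p = self.plane(channel, plane_index)
        return float(p.mean()), float(p.std())


@dataclass
class SegmentationMask:
    """Labeled cell mask for one plane; 0 is background."""

    labels: np.ndarray
    source: str  # "external-mask" | "internal-fallback"
    plane_index: int = 0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.min() < 0:
            raise ValueError("mask labels must be nonnegative")

    @property
    def n_labels(self) -> int:
        return int(self.labels.max())


@dataclass
class Roi:
    """A connected pixel region proposed to contain one cell body.

    The pixel set is stored as a boolean patch plus its (row, col) offset;
    ``bounding_box`` is (row, col, height, width), 0-based and half-open.
    Circularity is 4*pi*area / perimeter^2 under the contour-following
    perimeter estimator of ``skimage.measure.perimeter`` (axis steps weighted
    1, diagonal steps sqrt(2)); discretization can push it slightly above 1,
    which is reported unclipped.
    """

    patch: np.ndarray
    offset: tuple[int, int]
    roi_id: int
    parent_image: str = ""
    plane_index: int = 0
    split_lineage: int | None = None

    @property
    def area(self) -> int:
        return int(self.patch.sum())

    @property
    def perimeter(self) -> float:
        return float(measure.perimeter(np.pad(self.patch, 1), neighborhood=4))

    @property
    def circularity(self) -> float:
        per = self.perimeter
        if per == 0:
            return 0.0
        return float(4.0 * np.pi * self.area / per**2)

    @property
    def bounding_box(self) -> tuple[int, int, int, int]:
        rows = np.any(self.patch, axis=1)
        cols = np.any(self.patch, axis=0)
        r0, r1 = np.where(rows)[0][[0, -1]]
        c0, c1 = np.where(cols)[0][[0, -1]]
        return (
            self.offset[0] + int(r0),
            self.offset[1] + int(c0),
            int(r1 - r0 + 1),
            int(c1 - c0 + 1),
        )

    def full_mask(self, shape: tuple[int, int]) -> np.ndarray:
        out = np.zeros(shape, dtype=bool)
        r, c = self.offset
        out[r : r + self.patch.shape[0], c : c + self.patch.shape[1]] = self.patch
        return out

    def tighten(self) -> "Roi":
        """Return an equivalent Roi whose patch is trimmed to the bounding box."""
        r, c, h, w = self.bounding_box
        r0, c0 = r - self.offset[0], c - self.offset[1]
        return Roi(
            patch=self.patch[r0 : r0 + h, c0 : c0 + w].copy(),
            offset=(r, c),
            roi_id=self.roi_id,
            parent_image=self.parent_image,
            plane_index=self.plane_index,
            split_lineage=self.split_lineage,
        )


@dataclass
class PreprocessConfig:
    min_area: int = 180  # px^2; regions strictly smaller are discarded
    planes_used: tuple[int, ...] | None = None  # None -> (first, last)
    erosion_radius: int = 1
    max_erosion_iters: int = 10
    detection_channel: str = "neun"

    def resolve_planes(self, n_planes: int) -> tuple[int, ...]:
        planes = self.planes_used if self.planes_used is not None else (0, n_planes - 1)
        seen: list[int] = []
        for p in planes:
            if not (0 <= p < n_planes):
                raise IndexError(f"plane index {p} out of range for {n_planes} planes")
            if p not in seen:
                seen.append(p)
        return tuple(seen)


def extract_planes(
    stack: MicrographStack, cfg: PreprocessConfig | None = None
) -> tuple[tuple[int, ...], np.ndarray]:
    """Select z-planes for analysis (default: first and last).

    Returns (plane_indices, subarray of shape (n_channels, n_selected, H, W)).
    Duplicate indices (e.g. a single-plane stack where first == last) collapse.
    """
    cfg = cfg or PreprocessConfig()
    idx = cfg.resolve_planes(stack.n_planes)
    return idx, stack.intensities[:, list(idx)]


def normalize_plane(plane: np.ndarray) -> np.ndarray:
    """Affine-normalize one plane: (mean - SD) -> 0 and (mean + SD) -> 1.

    The mean and SD are taken over all pixels of the plane. Values outside
    [0, 1] are preserved (no clipping); the output mean is exactly 0.5. A
    constant plane has no scale and maps to all 0.5 with a warning.
    """
    plane = np.asarray(plane, dtype=np.float64)
    if plane.size == 0:
        raise ValueError("cannot normalize an empty plane")
    mean, sd = float(plane.mean()), float(plane.std())
    if sd == 0.0:
        warnings.warn("constant plane: SD is zero, returning 0.5 everywhere", stacklevel=2)
        return np.full_like(plane, 0.5)
    return (plane - (mean - sd)) / (2.0 * sd)


def _relabel_consecutive(labels: np.ndarray) -> np.ndarray:
    values = np.unique(labels)
    values = values[values > 0]
    out = np.zeros_like(labels, dtype=np.int64)
    for new, old in enumerate(values, start=1):
        out[labels == old] = new
    return out


def segment_cells(
    plane: np.ndarray,
    external_mask: np.ndarray | None = None,
    plane_index: int = 0,
) -> SegmentationMask:
    """Produce a labeled cell mask for one plane.

    If ``external_mask`` is given (binary or labeled output of an external
    segmenter such as a pre-trained U-Net) it passes through unmodified except
    for relabeling to consecutive positive integers. Otherwise a simple
    fallback segments the detection-channel plane: Otsu threshold, hole
    filling, 8-connected component labeling.
    """
    plane = np.asarray(plane)
    if external_mask is not None:
        external_mask = np.asarray(external_mask)
        if external_mask.shape != plane.shape:
            raise ValueError(
                f"mask shape {external_mask.shape} does not match plane shape {plane.shape}"
            )
        if external_mask.dtype == bool or external_mask.max() <= 1:
            labels, _ = ndimage.label(external_mask > 0, structure=_STRUCT8)
        else:
            labels = _relabel_consecutive(external_mask.astype(np.int64))
        return SegmentationMask(labels=labels, source="external-mask", plane_index=plane_index)

    if plane.max() == plane.min():
        return SegmentationMask(
            labels=np.zeros(plane.shape, dtype=np.int64),
            source="internal-fallback",
            plane_index=plane_index,
        )
    binary = plane > threshold_otsu(plane)
    binary = ndimage.binary_fill_holes(binary)
    labels, _ = ndimage.label(binary, structure=_STRUCT8)
    return SegmentationMask(labels=labels, source="internal-fallback", plane_index=plane_index)


def _erosion_scan(support: np.ndarray, selem: np.ndarray, max_iters: int):
    """Erode iteratively until the region splits (>1 components) or vanishes.

    Returns (n_iterations, labeled eroded components) or (0, None) when the
    region never splits within the budget.
    """
    cur = support
    for k in range(1, max_iters + 1):
        cur = ndimage.binary_erosion(cur, structure=selem, border_value=0)
        if not cur.any():
            return 0, None
        comp, n = ndimage.label(cur, structure=_STRUCT8)
        if n > 1:
            return k, comp
    return 0, None


def split_rois_erosion_dilation(
    mask: SegmentationMask, cfg: PreprocessConfig | None = None
) -> list[Roi]:
    """Split fused regions by iterative erosion, then dilate children back.

    For each label: erode with a disk of ``erosion_radius`` until the region
    separates into more than one 8-connected component (or vanishes, or the
    iteration budget runs out — then the region passes through unsplit). Each
    component is dilated by the same number of iterations and intersected with
    the parent support; pixels claimed by several children go to the nearest
    child's eroded core (ties to the lower child id), keeping children
    disjoint. Only masks are edited; image pixels are untouched.
    """
    cfg = cfg or PreprocessConfig()
    selem = disk(cfg.erosion_radius)
    rois: list[Roi] = []
    next_id = 0
    for lab in range(1, int(mask.labels.max()) + 1):
        support = mask.labels == lab
        if not support.any():
            continue
        # work on a padded bounding box for speed
        rows = np.any(support, axis=1)
        cols = np.any(support, axis=0)
        r0, r1 = np.where(rows)[0][[0, -1]]
        c0, c1 = np.where(cols)[0][[0, -1]]
        pad = cfg.erosion_radius * cfg.max_erosion_iters + 2
        patch = support[r0 : r1 + 1, c0 : c1 + 1]
        patch = np.pad(patch, pad)
        off = (int(r0) - pad, int(c0) - pad)

        k, comp = _erosion_scan(patch, selem, cfg.max_erosion_iters)
        if k == 0:
            rois.append(
                Roi(
                    patch=patch,
                    offset=off,
                    roi_id=next_id,
                    plane_index=mask.plane_index,
                    split_lineage=None,
                ).tighten()
            )
            next_id += 1
            continue

        n_children = int(comp.max())
        claims = np.zeros(patch.shape, dtype=np.int64)  # 0 none, -1 contested
        dilated = []
        for child in range(1, n_children + 1):
            core = comp == child
            grown = ndimage.binary_dilation(core, structure=selem, iterations=k) & patch
            dilated.append(grown)
            contested = grown & (claims > 0)
            claims[grown & (claims == 0)] = child
            claims[contested] = -1
        if (claims == -1).any():
            # nearest eroded core wins contested pixels; ties -> lower child id
            dists = np.stack(
                [
                    ndimage.distance_transform_edt(~(comp == child))
                    for child in range(1, n_children + 1)
                ]
            )
            winner = np.argmin(dists, axis=0) + 1  # argmin takes the first (lowest id) tie
            claims[claims == -1] = winner[claims == -1]

        parent_id = lab
        for child in range(1, n_children + 1):
            child_patch = claims == child
            if not child_patch.any():
                continue
            rois.append(
                Roi(
                    patch=child_patch,
                    offset=off,
                    roi_id=next_id,
                    plane_index=mask.plane_index,
                    split_lineage=parent_id,
                ).tighten()
            )
            next_id += 1
    return rois


def filter_rois_by_area(rois: list[Roi], cfg: PreprocessConfig | None = None) -> list[Roi]:
    """Keep ROIs with area >= min_area (strictly smaller regions discarded)."""
    cfg = cfg or PreprocessConfig()
    if cfg.min_area <= 0:
        raise ValueError("min_area must be positive")
    return [r for r in rois if r.area >= cfg.min_area]


def compute_roi_stats(roi: Roi, planes: dict[str, np.ndarray]) -> dict:
    """Per-channel mean raw intensity over the ROI pixel set, plus shape stats.

    ``planes`` maps channel name to the raw (pre-normalization) 2-D plane the
    ROI was drawn on — the statistics that populate intensity/area/circularity
    histograms.
    """
    if roi.area == 0:
        raise ValueError("cannot compute statistics of an empty ROI")
    stats: dict = {"area_px2": roi.area, "perimeter_px": roi.perimeter, "circularity": roi.circularity}
    r, c = roi.offset
    h, w = roi.patch.shape
    for name, plane in planes.items():
        if r < 0 or c < 0 or r + h > plane.shape[0] or c + w > plane.shape[1]:
            raise ValueError("ROI extends beyond the plane bounds")
        window = plane[r : r + h, c : c + w]
        stats[f"mean_{name}"] = float(window[roi.patch].mean())
    return stats


def crop_cell_images(
    rois: list[Roi],
    normalized_planes: dict[str, np.ndarray],
    channels: tuple[str, ...],
    plane_index: int = 0,
    labels: dict[int, str] | None = None,
):
    """Crop the tight bounding-box rectangle of each ROI from normalized planes.

    The full rectangle is taken (no masking to the ROI support), stacked over
    ``channels`` in the given order. Returns a list of
    :class:`gadnet.dataset.CellImage`, one per ROI, carrying the ROI id as
    cell id and, when ``labels`` provides one, the class label.
    """
    from gadnet.dataset import CellImage

    if not channels:
        raise ValueError("channel subset must be nonempty")
    out = []
    for roi in rois:
        r, c, h, w = roi.bounding_box
        if h <= 0 or w <= 0:
            raise ValueError(f"degenerate bounding box for ROI {roi.roi_id}")
        values = np.stack([normalized_planes[ch][r : r + h, c : c + w] for ch in channels])
        out.append(
            CellImage(
                values=values.astype(np.float32),
                channels=tuple(channels),
                cell_id=roi.roi_id,
                label=labels.get(roi.roi_id, "unknown") if labels else "unknown",
                plane_index=plane_index,
            )
        )
    return out
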