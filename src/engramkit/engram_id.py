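"""Reporter-snapshot segmentation and engram/non-engram cell labelling.

The snapshot is down-sampled and smoothed by a factor of 2, flat-field
corrected by dividing by a low-passed (r = 20 px) version of itself,
thresholded to keep the top 8% of pixel intensities, cleaned up and
binarized, watershed-split, and filtered by particle area; cells whose
centroids fall inside a detected ROI are labelled engram.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import gaussian
from skimage.measure import label as cc_label
from skimage.measure import regionprops
from skimage.morphology import closing, disk
from skimage.feature import peak_local_max
from skimage.segmentation import watershed
from skimage.transform import downscale_local_mean

from .signals_io import CellRegistry

DEFAULT_BIN = 2
DEFAULT_LOWPASS_RADIUS = 20.0
DEFAULT_KEEP_FRACTION = 0.08
# particle-size bounds at binned scale (unspecified upstream; configurable)
DEFAULT_MIN_AREA = math.pi * 2.0**2
DEFAULT_MAX_AREA = math.pi * 15.0**2


@dataclass
class Roi:
    id: int
    mask: np.ndarray  # boolean, full (binned) image shape
    centroid: tuple  # (x, y)
    area: int


@dataclass
class RoiSet:
    rois: list
    image_shape: tuple
    notes: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.rois)

    def labelled_image(self) -> np.ndarray:
        out = np.zeros(self.image_shape, dtype=np.int32)
        for r in self.rois:
            out[r.mask] = r.id
        return out


def enhance_snapshot(
    img: np.ndarray,
    bin_factor: int = DEFAULT_BIN,
    lowpass_radius_px: float = DEFAULT_LOWPASS_RADIUS,
) -> np.ndarray:
    """Bin + smooth the snapshot, then flat-field by its low-pass version.

    Output shape is the input shape integer-divided by ``bin_factor``; a
    flat input maps to ~1 everywhere.
    """
    img = np.asarray(img, dtype=float)
    if img.ndim != 2:
        raise ValueError("snapshot must be a single-channel 2-D image")
    if np.any(img < 0) or not np.all(np.isfinite(img)):
        raise ValueError("snapshot intensities must be finite and non-negative")
    if min(img.shape) <= 2 * lowpass_radius_px:
        raise ValueError("image too small for the low-pass radius")
    h, w = (s // bin_factor for s in img.shape)
    binned = downscale_local_mean(img, (bin_factor, bin_factor))[:h, :w]
    binned = ndimage.uniform_filter(binned, size=3)  # 3x3 mean smooth
    low = gaussian(binned, sigma=lowpass_radius_px, preserve_range=True)
    low = np.where(low > 0, low, 1.0)
    return binned / low


def threshold_top_fraction(
    img: np.ndarray, keep_top_fraction: float = DEFAULT_KEEP_FRACTION
) -> np.ndarray:
    """Binary mask of exactly the ceil(frac * P) brightest pixels.

    Ties are broken by intensity then raster order, so the kept count is
    exact even on images with repeated values.
    """
    if not (0 < keep_top_fraction < 1):
        raise ValueError("keep_top_fraction must be in (0, 1)")
    flat = np.asarray(img, dtype=float).ravel()
    P = flat.size
    k = int(math.ceil(keep_top_fraction * P))
    # stable sort descending by intensity; raster order breaks ties
    order = np.argsort(-flat, kind="stable")
    mask = np.zeros(P, dtype=bool)
    mask[order[:k]] = True
    return mask.reshape(img.shape)


def _binary_cleanup(mask: np.ndarray) -> np.ndarray:
    """One pass of majority-style cleanup: a set pixel survives iff at
    least 2 of its 8 neighbours are set (single-pixel speckle removal)."""
    kernel = np.ones((3, 3), dtype=int)
    kernel[1, 1] = 0
    neighbours = ndimage.convolve(mask.astype(int), kernel, mode="constant")
    return mask & (neighbours >= 2)


def segment_rois(
    img: np.ndarray,
    keep_top_fraction: float = DEFAULT_KEEP_FRACTION,
    min_area_px: float = DEFAULT_MIN_AREA,
    max_area_px: float = DEFAULT_MAX_AREA,
    watershed_min_distance: int = 3,
) -> RoiSet:
    """Segment an enhanced snapshot into candidate cell ROIs.

    Threshold to the top intensity fraction, clean up and close the mask,
    watershed-split touching particles, and filter components by area.
    An empty result is returned (not raised) when nothing survives.
    """
    img = np.asarray(img, dtype=float)
    mask = threshold_top_fraction(img, keep_top_fraction)
    mask = _binary_cleanup(mask)
    mask = closing(mask, disk(1)).astype(bool)
    # watershed on the distance transform, markers at local maxima
    dist = ndimage.distance_transform_edt(mask)
    peaks = peak_local_max(
        dist, min_distance=watershed_min_distance, labels=mask, exclude_border=False
    )
    markers = np.zeros(mask.shape, dtype=np.int32)
    for i, (r, c) in enumerate(peaks, start=1):
        markers[r, c] = i
    if markers.max() == 0:
        labels = cc_label(mask, connectivity=1)
    else:
        labels = watershed(-dist, markers=markers, mask=mask)
    rois: list[Roi] = []
    next_id = 1
    for prop in regionprops(labels):
        if not (min_area_px <= prop.area <= max_area_px):
            continue
        m = labels == prop.label
        cy, cx = prop.centroid
        rois.append(Roi(next_id, m, (float(cx), float(cy)), int(prop.area)))
        next_id += 1
    return RoiSet(rois, img.shape, notes={"kept_pixels": int(mask.sum())})


def match_rois_to_cells(
    rois: RoiSet,
    registry: CellRegistry,
    r_match: float | None = None,
    require_inside: bool = True,
) -> tuple[CellRegistry, list]:
    """Flag cells engram iff an ROI matches them; returns (registry, unmatched ROIs).

    A cell matches an ROI when the centroid-to-centroid distance is at
    most ``r_match`` (default: mean ROI equivalent radius) and, when
    ``require_inside``, the cell centroid lies inside the ROI mask.
    Registry centroids must be in the same (binned) coordinate frame as
    the ROIs.
    """
    cents = registry.centroids()
    if rois.rois and r_match is None:
        r_match = float(
            np.mean([math.sqrt(r.area / math.pi) for r in rois.rois])
        )
    matched_cells: set[str] = set()
    matched_rois: set[int] = set()
    h, w = rois.image_shape
    for cell, (x, y) in zip(registry.cells, cents):
        for roi in rois.rois:
            dx, dy = x - roi.centroid[0], y - roi.centroid[1]
            if math.hypot(dx, dy) > r_match:
                continue
            if require_inside:
                xi, yi = int(round(x)), int(round(y))
                if not (0 <= yi < h and 0 <= xi < w) or not roi.mask[yi, xi]:
                    continue
            matched_cells.add(cell.id)
            matched_rois.add(roi.id)
            break
    unmatched = [r for r in rois.rois if r.id not in matched_rois]
    return registry.with_engram_ids(sorted(matched_cells)), unmatched


def label_cells_from_snapshot(
    snapshot: np.ndarray,
    registry: CellRegistry,
    bin_factor: int = DEFAULT_BIN,
    lowpass_radius_px: float = DEFAULT_LOWPASS_RADIUS,
    keep_top_fraction: float = DEFAULT_KEEP_FRACTION,
    min_area_px: float = DEFAULT_MIN_AREA,
    max_area_px: float = DEFAULT_MAX_AREA,
    translate: tuple = (0.0, 0.0),
    r_match: float | None = None,
) -> tuple[CellRegistry, RoiSet]:
    """Full labelling recipe: enhance, segment, match.

    Registry centroids are given in raw-snapshot coordinates; they are
    shifted by ``translate`` (user-supplied alignment) and scaled into the
    binned frame before matching.
    """
    enhanced = enhance_snapshot(snapshot, bin_factor, lowpass_radius_px)
    rois = segment_rois(enhanced, keep_top_fraction, min_area_px, max_area_px)
    from dataclasses import replace

    scaled = CellRegistry(
        [
            replace(
                c,
                x=(c.x + translate[0]) / bin_factor,
                y=(c.y + translate[1]) / bin_factor,
            )
            for c in registry.cells
        ]
    )
    labelled_scaled, _ = match_rois_to_cells(rois, scaled, r_match=r_match)
    engram_ids = [
        c.id for c in labelled_scaled.cells if c.engram
    ]
    return registry.with_engram_ids(engram_ids), rois
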