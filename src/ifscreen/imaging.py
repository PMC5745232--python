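"""Per-cell quantification of two-channel immunofluorescence fields.

Implements the multi-wavelength cell-scoring readout used in high-content
drug screens of mixed cultures: nuclei are segmented on the pan-nuclear
(Hoechst) channel, a cytoplasmic epithelial-marker (cytokeratin-8/18) mask is
segmented on the second channel, and every nucleus is classified
marker-positive (cancer) or marker-negative (stromal / feeder) by its overlap
with the marker mask. Counts are aggregated per well.

All coordinates are 0-based, pixel-center, origin at the top-left corner;
``x`` is the column index and ``y`` the row index.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.ndimage as ndi
from scipy.optimize import linear_sum_assignment
from skimage.feature import peak_local_max
from skimage.measure import regionprops_table
from skimage.morphology import disk
from skimage.segmentation import expand_labels, watershed
from skimage.transform import resize


def _drop_small(mask: np.ndarray, min_area: int) -> np.ndarray:
    """Remove connected components with fewer than ``min_area`` pixels."""
    labels, n = ndi.label(mask)
    if n == 0:
        return mask
    areas = ndi.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    keep = np.flatnonzero(areas >= min_area) + 1
    return np.isin(labels, keep)


@dataclass
class FieldImage:
    """One imaged site of one well: two co-registered grayscale channels."""

    well: str
    site: int
    channel_nuclear: np.ndarray
    channel_marker: np.ndarray
    bit_depth: int = 16

    def __post_init__(self) -> None:
        self.channel_nuclear = np.asarray(self.channel_nuclear)
        self.channel_marker = np.asarray(self.channel_marker)
        if self.channel_nuclear.shape != self.channel_marker.shape:
            raise ValueError(
                f"channel shape mismatch in well {self.well} site {self.site}: "
                f"{self.channel_nuclear.shape} vs {self.channel_marker.shape}"
            )
        if self.channel_nuclear.ndim != 2:
            raise ValueError("channels must be 2-D rasters")
        if np.any(self.channel_nuclear < 0) or np.any(self.channel_marker < 0):
            raise ValueError("intensities must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.channel_nuclear.shape


@dataclass
class SegmentationParams:
    """Tunable knobs of the scoring module.

    ``min_width``/``max_width`` gate the equivalent diameter (px) of accepted
    nuclei; ``nuclear_threshold``/``marker_threshold`` are the required signal
    intensities above local background, one per channel; the local background
    is a median over ``background_window``-pixel neighbourhoods.
    """

    min_width: float = 6.0
    max_width: float = 30.0
    nuclear_threshold: float = 200.0
    marker_threshold: float = 150.0
    background_window: int = 64
    split_touching: bool = True
    cytoplasm_radius: int = 5
    positivity_overlap: float = 0.3
    exclude_border: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.min_width < self.max_width:
            raise ValueError("need 0 < min_width < max_width")
        if self.nuclear_threshold < 0 or self.marker_threshold < 0:
            raise ValueError("intensity thresholds must be >= 0")
        if self.background_window < 2:
            raise ValueError("background_window must be >= 2 px")


@dataclass
class SegmentationResult:
    """Labelled nucleus regions plus quality-control flags."""

    labels: np.ndarray
    warnings: list[str] = field(default_factory=list)

    @property
    def n_regions(self) -> int:
        return int(self.labels.max())


@dataclass(frozen=True)
class WellCount:
    """Per-well totals of detected nuclei by marker class."""

    well: str
    n_total: int
    n_positive: int
    n_negative: int
    n_sites: int

    def __post_init__(self) -> None:
        if self.n_positive + self.n_negative != self.n_total:
            raise ValueError("n_positive + n_negative must equal n_total")
        if min(self.n_total, self.n_positive, self.n_negative, self.n_sites) < 0:
            raise ValueError("counts must be non-negative")


CELL_TABLE_COLUMNS = [
    "well",
    "site",
    "x",
    "y",
    "nucleus_area_px2",
    "nuclear_mean",
    "marker_mean",
    "marker_positive",
]


def local_background(image: np.ndarray, window: int) -> np.ndarray:
    """Local background raster: median over ``window``-px tiles, upsampled.

    Tile medians are bilinearly interpolated back to the full frame, giving a
    smooth O(n) estimate of the slowly varying background at the requested
    spatial scale.
    """
    img = np.asarray(image, dtype=np.float64)
    h, w = img.shape
    if window >= min(h, w):
        return np.full_like(img, np.median(img))
    nh = int(np.ceil(h / window))
    nw = int(np.ceil(w / window))
    pad_h = nh * window - h
    pad_w = nw * window - w
    padded = np.pad(img, ((0, pad_h), (0, pad_w)), mode="edge")
    tiles = padded.reshape(nh, window, nw, window)
    med = np.median(tiles, axis=(1, 3))
    bg = resize(med, padded.shape, order=1, mode="edge", anti_aliasing=False)
    return bg[:h, :w]


def _min_area(params: SegmentationParams) -> float:
    return np.pi * (params.min_width / 2.0) ** 2


def _max_area(params: SegmentationParams) -> float:
    return np.pi * (params.max_width / 2.0) ** 2


def segment_nuclei(
    channel_nuclear: np.ndarray, params: SegmentationParams
) -> SegmentationResult:
    """Segment nuclei on the pan-nuclear channel.

    Pixels exceeding the local background by ``nuclear_threshold`` are
    foreground; holes are filled, objects below the size gate removed and —
    when ``split_touching`` is on — touching nuclei are separated by a
    watershed seeded at local intensity maxima (nuclei are bright blobs, so
    intensity peaks mark centres more reliably than the distance transform,
    especially for elongated fibroblast nuclei). Regions are then filtered
    by equivalent
    diameter and, optionally, border contact. Saturated or blank frames yield
    zero regions with a warning flag rather than an exception.
    """
    img = np.asarray(channel_nuclear, dtype=np.float64)
    if img.size == 0:
        raise ValueError("empty raster")
    warnings: list[str] = []

    if np.ptp(img) == 0:
        warnings.append("flat frame (blank or saturated)")
        return SegmentationResult(np.zeros(img.shape, dtype=np.int32), warnings)

    resid = img - local_background(img, params.background_window)
    fg = resid > params.nuclear_threshold
    frac = fg.mean()
    if frac > 0.8:
        warnings.append("saturated: foreground fraction > 0.8")
        return SegmentationResult(np.zeros(img.shape, dtype=np.int32), warnings)
    if not fg.any():
        warnings.append("blank: no pixels above threshold")
        return SegmentationResult(np.zeros(img.shape, dtype=np.int32), warnings)

    fg = ndi.binary_fill_holes(fg)
    fg = _drop_small(fg, max(4, int(0.3 * _min_area(params))))
    if not fg.any():
        warnings.append("blank: no objects above size gate")
        return SegmentationResult(np.zeros(img.shape, dtype=np.int32), warnings)

    if params.split_touching:
        # nuclei are bright blobs: seed the watershed from intensity peaks
        smooth = ndi.gaussian_filter(resid, sigma=1.0)
        min_dist = max(2, int(round(0.5 * params.min_width)))
        coords = peak_local_max(
            smooth, min_distance=min_dist, labels=fg, exclude_border=False
        )
        markers = np.zeros(img.shape, dtype=np.int32)
        markers[tuple(coords.T)] = np.arange(1, len(coords) + 1)
        labels = watershed(-smooth, markers, mask=fg)
    else:
        labels, _ = ndi.label(fg)

    labels = _filter_regions(labels, params)
    return SegmentationResult(labels, warnings)


def _filter_regions(labels: np.ndarray, params: SegmentationParams) -> np.ndarray:
    """Drop regions outside the width gates or touching the frame border."""
    if labels.max() == 0:
        return labels.astype(np.int32)
    ids = np.arange(1, labels.max() + 1)
    areas = ndi.sum_labels(np.ones_like(labels), labels, index=ids)
    eq_diam = 2.0 * np.sqrt(areas / np.pi)
    keep = (eq_diam >= params.min_width) & (eq_diam <= params.max_width)
    if params.exclude_border:
        border = np.zeros(labels.shape, dtype=bool)
        border[0, :] = border[-1, :] = True
        border[:, 0] = border[:, -1] = True
        on_border = np.unique(labels[border])
        keep &= ~np.isin(ids, on_border[on_border > 0])
    mapping = np.zeros(labels.max() + 1, dtype=np.int32)
    mapping[ids[keep]] = np.arange(1, keep.sum() + 1)
    return mapping[labels]


def segment_marker(
    channel_marker: np.ndarray, params: SegmentationParams
) -> np.ndarray:
    """Binary mask of marker-positive cytoplasm.

    Thresholds the marker channel at local background + ``marker_threshold``
    and cleans the mask morphologically (closing, hole filling, speckle
    removal).
    """
    img = np.asarray(channel_marker, dtype=np.float64)
    if img.size == 0:
        raise ValueError("empty raster")
    resid = img - local_background(img, params.background_window)
    mask = resid > params.marker_threshold
    if not mask.any():
        return mask
    mask = ndi.binary_closing(mask, structure=disk(2))
    mask = ndi.binary_fill_holes(mask)
    mask = _drop_small(mask, max(4, int(0.3 * _min_area(params))))
    return mask


def score_cells(
    field_image: FieldImage,
    nuclei: SegmentationResult | np.ndarray,
    marker_mask: np.ndarray,
    params: SegmentationParams,
) -> pd.DataFrame:
    """Classify every segmented nucleus as marker-positive or -negative.

    The nucleus is expanded by ``cytoplasm_radius`` px (a stand-in for the
    whole-cell region; expansion is non-overlapping between neighbours) and
    called positive when the expanded region overlaps the marker mask by at
    least ``positivity_overlap``. Returns one row per nucleus with centroid,
    area, per-channel mean intensities and the positivity call.
    """
    labels = nuclei.labels if isinstance(nuclei, SegmentationResult) else nuclei
    if labels.shape != marker_mask.shape or labels.shape != field_image.shape:
        raise ValueError("nuclei, marker mask and image must share one frame")
    n = int(labels.max())
    if n == 0:
        return pd.DataFrame(columns=CELL_TABLE_COLUMNS)

    ids = np.arange(1, n + 1)
    props = regionprops_table(
        labels, properties=("label", "centroid", "area")
    )
    expanded = expand_labels(labels, distance=params.cytoplasm_radius)
    cell_sizes = np.bincount(expanded.ravel(), minlength=n + 1)[1:]
    overlap = np.bincount(
        expanded[np.asarray(marker_mask, dtype=bool)].ravel(), minlength=n + 1
    )[1:]
    with np.errstate(invalid="ignore"):
        overlap_frac = np.where(cell_sizes > 0, overlap / cell_sizes, 0.0)

    nuclear_mean = ndi.mean(
        np.asarray(field_image.channel_nuclear, dtype=np.float64), labels, index=ids
    )
    marker_mean = ndi.mean(
        np.asarray(field_image.channel_marker, dtype=np.float64), expanded, index=ids
    )

    order = np.argsort(props["label"])
    return pd.DataFrame(
        {
            "well": field_image.well,
            "site": field_image.site,
            "x": np.asarray(props["centroid-1"])[order],
            "y": np.asarray(props["centroid-0"])[order],
            "nucleus_area_px2": np.asarray(props["area"], dtype=float)[order],
            "nuclear_mean": nuclear_mean,
            "marker_mean": marker_mean,
            "marker_positive": overlap_frac >= params.positivity_overlap,
        }
    )


def quantify_field(
    field_image: FieldImage, params: SegmentationParams
) -> pd.DataFrame:
    """Segment both channels of one field and score all cells."""
    seg = segment_nuclei(field_image.channel_nuclear, params)
    mask = segment_marker(field_image.channel_marker, params)
    return score_cells(field_image, seg, mask, params)


def quantify_well(
    fields: Sequence[FieldImage], params: SegmentationParams
) -> tuple[WellCount, pd.DataFrame]:
    """Quantify all sites of one well and sum the per-class counts."""
    fields = list(fields)
    if not fields:
        raise ValueError("need at least one site per well")
    wells = {f.well for f in fields}
    if len(wells) != 1:
        raise ValueError(f"fields from different wells passed together: {wells}")
    cells = pd.concat(
        [quantify_field(f, params) for f in fields], ignore_index=True
    )
    n_pos = int(cells["marker_positive"].sum()) if len(cells) else 0
    n_tot = int(len(cells))
    count = WellCount(
        well=fields[0].well,
        n_total=n_tot,
        n_positive=n_pos,
        n_negative=n_tot - n_pos,
        n_sites=len(fields),
    )
    return count, cells


def match_centroids(
    true_xy: np.ndarray, found_xy: np.ndarray, max_dist: float
) -> int:
    """Number of one-to-one matches between true and detected centroids.

    Optimal assignment on Euclidean distance, counting pairs closer than
    ``max_dist``; used to compute detection precision/recall against
    simulator ground truth.
    """
    true_xy = np.atleast_2d(np.asarray(true_xy, dtype=float))
    found_xy = np.atleast_2d(np.asarray(found_xy, dtype=float))
    if true_xy.size == 0 or found_xy.size == 0:
        return 0
    d = np.linalg.norm(true_xy[:, None, :] - found_xy[None, :, :], axis=2)
    cost = np.where(d <= max_dist, d, 1e9)
    rows, cols = linear_sum_assignment(cost)
    return int((d[rows, cols] <= max_dist).sum())
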