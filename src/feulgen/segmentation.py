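"""Nucleus delineation on optical-density images.

Foreground is taken where OD exceeds a threshold (Otsu on the OD
histogram by default, with a floor so blank fields yield no labels);
connected components become candidate nuclei, optionally split by a
distance-transform watershed. Components that touch the image border or
fall outside the plausible nuclear-area range are flagged rather than
dropped, so QC decisions stay visible downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import apply_hysteresis_threshold, threshold_otsu
from skimage.measure import label as cc_label
from skimage.measure import regionprops
from skimage.segmentation import watershed

from .optics import ODImage

BORDER_TOUCHING = "border_touching"
UNDER_MIN_AREA = "under_min_area"
OVER_MAX_AREA = "over_max_area"
MERGED_SUSPECT = "merged_suspect"
TINY = "tiny"  # fewer than 2 pixels: SD undefined


@dataclass
class LabelMap:
    """Integer label image plus per-label QC flags.

    Label 0 is background. Flagged labels are excluded from measurement by
    default; ``unflagged_labels`` lists the labels that pass QC.
    """

    labels: np.ndarray
    flags: dict[int, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)

    @property
    def label_ids(self) -> list[int]:
        ids = np.unique(self.labels)
        return [int(i) for i in ids if i != 0]

    @property
    def unflagged_labels(self) -> list[int]:
        return [i for i in self.label_ids if not self.flags.get(i)]


def segment_nuclei(
    od_image: ODImage,
    od_threshold: float | None = None,
    min_area_um2: float = 8.0,
    max_area_um2: float = 400.0,
    split_touching: bool = False,
    min_od: float = 0.05,
    merged_solidity_max: float = 0.75,
) -> LabelMap:
    """Delineate nuclei in an OD image.

    Parameters
    ----------
    od_threshold
        Foreground OD threshold; None selects Otsu's value on the OD
        histogram, floored at ``min_od`` so pure-noise backgrounds are not
        split into spurious foreground.
    min_area_um2, max_area_um2
        Plausible single-nucleus area range; components outside it are
        flagged (debris / clumps), not deleted.
    split_touching
        Apply a distance-transform watershed to separate touching nuclei.
    merged_solidity_max
        Components less solid than this are flagged ``merged_suspect``
        (note cup/bell-shaped and chained morphologies also trip this; use
        ``include_flagged`` at measurement time to keep them).
    """
    od = od_image.od
    if od_threshold is None:
        finite = od[np.isfinite(od)]
        if finite.size == 0 or finite.max() <= min_od:
            thresh = min_od
        else:
            thresh = max(float(threshold_otsu(finite)), min_od)
        # Hysteresis: seed nuclei at the Otsu level, then grow each seed
        # down to the OD floor so weakly stained rims are not clipped or
        # fragmented (Otsu alone sits high when foreground is sparse).
        binary = apply_hysteresis_threshold(od, min_od, thresh)
    else:
        thresh = float(od_threshold)
        binary = od >= thresh
    binary = ndi.binary_fill_holes(binary)

    if not binary.any():
        warnings.warn("no foreground above the OD threshold (acellular field)")
        return LabelMap(labels=np.zeros_like(od, dtype=np.int32), flags={})

    if split_touching:
        labels = _watershed_split(binary, min_area_um2 * od_image.scale)
    else:
        labels = cc_label(binary, connectivity=2).astype(np.int32)

    min_px = min_area_um2 * od_image.scale
    max_px = max_area_um2 * od_image.scale
    flags: dict[int, frozenset[str]] = {}
    nrows, ncols = labels.shape
    for region in regionprops(labels):
        f: set[str] = set()
        if region.area < min_px:
            f.add(UNDER_MIN_AREA)
        if region.area > max_px:
            f.add(OVER_MAX_AREA)
        if region.area < 2:
            f.add(TINY)
        minr, minc, maxr, maxc = region.bbox
        if minr == 0 or minc == 0 or maxr == nrows or maxc == ncols:
            f.add(BORDER_TOUCHING)
        if region.solidity < merged_solidity_max:
            f.add(MERGED_SUSPECT)
        flags[int(region.label)] = frozenset(f)
    return LabelMap(labels=labels, flags=flags)


def _watershed_split(binary: np.ndarray, min_px: float) -> np.ndarray:
    dist = ndi.distance_transform_edt(binary)
    min_distance = max(3, int(round(np.sqrt(max(min_px, 9.0) / np.pi))))
    peaks = peak_local_max(
        dist, min_distance=min_distance, labels=binary, exclude_border=False
    )
    markers = np.zeros_like(binary, dtype=np.int32)
    markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
    markers, _ = ndi.label(markers > 0)
    if markers.max() == 0:
        return cc_label(binary, connectivity=2).astype(np.int32)
    return watershed(-dist, markers, mask=binary).astype(np.int32)
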