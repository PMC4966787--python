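"""Per-nucleus densitometric features.

Three features are measured for every segmented nucleus: the
densitometric sum (integrated optical density, IOD = Σ log10(1/Tᵢ) over
the nucleus pixels), the densitometric area (pixels, converted to μm²
via the image scale), and the densitometric standard deviation (the SD
of per-pixel OD inside the nucleus, reflecting chromatin heterogeneity —
a single-point OD would not represent the whole nucleus).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.measure import regionprops

from .optics import ODImage
from .segmentation import TINY, LabelMap


@dataclass
class NucleusMeasurement:
    """Densitometric features of one nucleus."""

    nucleus_id: int
    iod: float
    area_px: int
    area_um2: float
    od_sd: float
    centroid_row: float
    centroid_col: float
    flags: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.iod < 0 or self.od_sd < 0:
            raise ValueError("iod and od_sd must be non-negative")


def measure_nuclei(
    od_image: ODImage,
    labels: LabelMap,
    include_flagged: bool = False,
) -> list[NucleusMeasurement]:
    """Measure IOD, area and OD-SD for every retained label.

    Flagged labels are skipped unless ``include_flagged``; single-pixel
    labels get ``od_sd = 0`` with a ``tiny`` flag (the n−1 SD is
    undefined). Areas are whole-pixel counts divided by the pixels/μm²
    scale.
    """
    od = od_image.od
    lab = labels.labels
    if lab.shape != od.shape:
        raise ValueError("label map and OD image shapes differ")
    out: list[NucleusMeasurement] = []
    for region in regionprops(lab, intensity_image=od):
        lid = int(region.label)
        flags = labels.flags.get(lid, frozenset())
        if flags and not include_flagged:
            continue
        values = od[region.slice][region.image]
        iod = float(values.sum())
        if values.size >= 2:
            od_sd = float(values.std(ddof=1))
        else:
            od_sd = 0.0
            flags = flags | {TINY}
        out.append(NucleusMeasurement(
            nucleus_id=lid,
            iod=iod,
            area_px=int(values.size),
            area_um2=values.size / od_image.scale,
            od_sd=od_sd,
            centroid_row=float(region.centroid[0]),
            centroid_col=float(region.centroid[1]),
            flags=frozenset(flags),
        ))
    return out


def measurements_to_frame(
    measurements: list[NucleusMeasurement],
    sample_id: str | None = None,
) -> pd.DataFrame:
    """Tabulate measurements, one row per nucleus."""
    rows = [{
        "nucleus_id": m.nucleus_id,
        "iod": m.iod,
        "area_px": m.area_px,
        "area_um2": m.area_um2,
        "od_sd": m.od_sd,
        "centroid_row": m.centroid_row,
        "centroid_col": m.centroid_col,
        "flags": ";".join(sorted(m.flags)),
    } for m in measurements]
    frame = pd.DataFrame(rows, columns=[
        "nucleus_id", "iod", "area_px", "area_um2", "od_sd",
        "centroid_row", "centroid_col", "flags",
    ])
    if sample_id is not None:
        frame.insert(0, "sample_id", sample_id)
    return frame
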