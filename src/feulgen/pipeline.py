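"""End-to-end orchestration: images in, calibrated per-nucleus tables out.

The pipeline is generate/load → OD transform → segment → measure →
calibrate against the co-processed cRBC standard → summarise. Each stage
is the corresponding library function; this module only wires them
together and defines the file schemas, so the command-line tool stays a
thin shell around it.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from . import __version__
from .calibration import CalibrationModel, fit_standard, iod_to_pg, pg_to_fold_c
from .config import RunConfig
from .densitometry import measure_nuclei, measurements_to_frame
from .optics import TransmittedLightImage, estimate_white_reference, transmittance_to_od
from .segmentation import segment_nuclei
from .simulate import GroundTruthRecord
from .stats import (
    compare_groups,
    describe_sample,
    pool_samples,
    summaries_to_frame,
)

logger = logging.getLogger(__name__)

NUCLEUS_COLUMNS = [
    "nucleus_id", "sample_id", "iod", "area_px", "area_um2",
    "od_sd", "pg", "fold_c", "flags",
]
TRUTH_COLUMNS = [
    "nucleus_id", "true_pg", "shape_class",
    "centroid_row", "centroid_col", "true_area_um2",
]


def read_image(path: str | Path, scale: float) -> TransmittedLightImage:
    """Read a grayscale TIFF/PNG as a transmitted-light image."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        pixels = tifffile.imread(path)
    else:
        import imageio.v3 as iio

        pixels = iio.imread(path)
    if pixels.ndim == 3:
        raise ValueError(f"{path} is not grayscale")
    return TransmittedLightImage(pixels=pixels, scale=scale)


def write_image(path: str | Path, image: TransmittedLightImage) -> None:
    tifffile.imwrite(Path(path), np.asarray(image.pixels))


def truth_to_frame(records: list[GroundTruthRecord]) -> pd.DataFrame:
    return pd.DataFrame([{
        "nucleus_id": r.nucleus_id,
        "true_pg": r.true_pg,
        "shape_class": r.shape_class,
        "centroid_row": r.centroid_row,
        "centroid_col": r.centroid_col,
        "true_area_um2": r.true_area_um2,
    } for r in records], columns=TRUTH_COLUMNS)


def measure_image(
    image: TransmittedLightImage, config: RunConfig, sample_id: str
) -> pd.DataFrame:
    """OD transform + segmentation + densitometry for one image."""
    white = estimate_white_reference(image)
    od = transmittance_to_od(image, white_reference=white,
                            t_floor=config.t_floor)
    labels = segment_nuclei(
        od,
        od_threshold=config.od_threshold,
        min_area_um2=config.min_area_um2,
        max_area_um2=config.max_area_um2,
        split_touching=config.split_touching,
    )
    flagged = [i for i in labels.label_ids if labels.flags.get(i)]
    for lid in flagged:
        logger.info("sample %s: label %d flagged %s", sample_id, lid,
                    ",".join(sorted(labels.flags[lid])))
    measurements = measure_nuclei(od, labels,
                                  include_flagged=config.include_flagged)
    return measurements_to_frame(measurements, sample_id=sample_id)


def quantify(
    sample_images: dict[str, TransmittedLightImage],
    standard_images: list[TransmittedLightImage],
    config: RunConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, CalibrationModel]:
    """Full quantification of a batch sharing one staining standard.

    Returns the per-nucleus table (with pg and fold-C), the per-sample
    summary table (with a pooled Total row when there are ≥2 samples),
    and the fitted calibration.
    """
    if not standard_images:
        raise ValueError("calibration impossible: no standard images")
    standard_measurements = []
    for img in standard_images:
        white = estimate_white_reference(img)
        od = transmittance_to_od(img, white_reference=white,
                                 t_floor=config.t_floor)
        labels = segment_nuclei(
            od, od_threshold=config.od_threshold,
            min_area_um2=config.min_area_um2,
            max_area_um2=config.max_area_um2,
            split_touching=config.split_touching,
        )
        standard_measurements.extend(
            measure_nuclei(od, labels, include_flagged=config.include_flagged)
        )
    model = fit_standard(
        standard_measurements,
        standard_2c_pg=config.standard_2c_pg,
        min_nuclei=config.min_standard_nuclei,
    )
    logger.info("standard: n=%d mean IOD=%.2f CV=%.1f%%",
                model.n_standard, model.mean_iod_standard,
                model.standard_cv_percent)

    frames = []
    for sample_id, image in sample_images.items():
        frame = measure_image(image, config, sample_id)
        if frame.empty:
            logger.warning("sample %s: empty segmentation (acellular?)",
                           sample_id)
        frames.append(frame)
    nuclei = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    if not nuclei.empty:
        nuclei["pg"] = iod_to_pg(model, nuclei["iod"].to_numpy())
        nuclei["fold_c"] = pg_to_fold_c(nuclei["pg"].to_numpy(), config.c1_pg)
        nuclei = nuclei[NUCLEUS_COLUMNS]
    summary = summarize(nuclei)
    return nuclei, summary, model


def summarize(nuclei: pd.DataFrame) -> pd.DataFrame:
    """Per-sample descriptive rows (plus Total) from a per-nucleus table."""
    summaries = []
    if not nuclei.empty:
        for sample_id, grp in nuclei.groupby("sample_id", sort=True):
            summaries.append(describe_sample(
                grp["pg"].to_numpy(), grp["area_um2"].to_numpy(),
                sample_id=str(sample_id),
            ))
    if len(summaries) >= 2:
        summaries.append(pool_samples(summaries))
    return summaries_to_frame(summaries)


def compare(nuclei: pd.DataFrame, config: RunConfig) -> dict:
    """Group-comparison report (JSON-ready) on per-nucleus DNA masses."""
    groups = {
        str(sid): grp["pg"].to_numpy()
        for sid, grp in nuclei.groupby("sample_id", sort=True)
    }
    result = compare_groups(groups, alpha=config.alpha,
                            adjust=config.dunn_adjust)
    return {
        "test": "kruskal_wallis",
        "h_statistic": result.h_statistic,
        "p_value": result.p_value,
        "alpha": result.alpha,
        "significant": result.significant,
        "pairwise_adjustment": config.dunn_adjust,
        "pairwise": [{
            "group_a": p.group_a, "group_b": p.group_b,
            "z": p.z, "p_raw": p.p_raw, "p_adjusted": p.p_adjusted,
        } for p in result.pairwise],
    }


def write_manifest(path: str | Path, config: RunConfig) -> None:
    manifest = {
        "package": "feulgen",
        "version": __version__,
        "config_hash": config.content_hash(),
        "seed": config.seed,
        "config": config.to_dict(),
    }
    Path(path).write_text(json.dumps(manifest, indent=2) + "\n")
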