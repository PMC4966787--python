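"""Bundled reference measurements.

Printed descriptive statistics from a published Feulgen image-cytometry
study of spread human vascular and fetal tissues, with its chicken
red-blood-cell (cRBC) internal standard and the companion qPCR
threshold-cycle triplicates. These serve as worked-example inputs: the
per-sample rows pool into the study's Total row, and the Ct triplicates
reproduce its ΔCT values.

Only summary statistics are bundled (the per-nucleus raw data were never
released); anything needing raw nuclei uses the synthetic-slide
generator instead.
"""

from __future__ import annotations

import pandas as pd

from .stats import SampleSummary

# sample_id, origin, tissue state, n nuclei, skewness, kurtosis,
# mean DNA pg, SD pg, mean nuclear area um^2, SD area
_TISSUE_ROWS = [
    ("1", "Adult", "Hard", 137, 0.4, -0.6, 6.0, 3.1, 72.7, 36.9),
    ("2", "Adult", "Soft", 306, 1.1, 1.8, 4.3, 2.1, 57.5, 25.9),
    ("3", "Adult", "Soft", 48, 1.4, 2.8, 5.6, 2.2, 66.1, 24.7),
    ("4", "Adult", "Soft", 92, 0.6, 0.5, 7.0, 2.8, 68.4, 27.4),
    ("5", "Fetus", "Hard", 145, 1.6, 2.7, 3.1, 1.6, 46.9, 25.3),
    ("6", "Fetus", "Hard", 46, 1.5, 1.7, 1.7, 0.9, 31.4, 16.8),
    ("7", "Fetus", "Soft", 120, 1.1, 0.5, 4.8, 2.4, 63.8, 32.7),
]

# cRBC internal standard row: constant 2.5 pg DNA per nucleus
CRBC_ROW = {
    "sample_id": "cRBC",
    "n": 339,
    "skewness": -0.1,
    "kurtosis": 1.2,
    "known_pg": 2.5,
    "mean_area_um2": 25.9,
    "sd_area_um2": 5.9,
}

# qPCR threshold-cycle triplicates per micro-dissected fetal sample.
# GUSB (beta-glucuronidase) is the reference gene; OSX (osterix) marks
# osteogenic tissue, CEA (CEACAM5) fetal intestine.
QPCR_CT_TRIPLICATES = {
    "fetal_femur_bone_12w": {
        "GUSB": (37.06, 37.50, 37.45),
        "OSX": (38.42, 38.63, 38.51),
    },
    "fetal_intestine_9w": {
        "GUSB": (30.03, 30.32, 30.37),
        "CEA": (35.70, 35.15, 35.17),
    },
}


def tissue_sample_table() -> pd.DataFrame:
    """Reference per-sample descriptive rows as a DataFrame."""
    return pd.DataFrame(_TISSUE_ROWS, columns=[
        "sample_id", "origin", "state", "n", "skewness", "kurtosis",
        "mean_pg", "sd_pg", "mean_area_um2", "sd_area_um2",
    ])


def tissue_sample_summaries() -> list[SampleSummary]:
    """Reference rows as SampleSummary objects (CV/SE/CI derived)."""
    return [
        SampleSummary.from_moments(
            sample_id=sid,
            n=n,
            mean_pg=mpg,
            sd_pg=spg,
            mean_area_um2=marea,
            sd_area_um2=sarea,
            skewness=skew,
            kurtosis=kurt,
            origin=f"{origin} {state}",
        )
        for sid, origin, state, n, skew, kurt, mpg, spg, marea, sarea
        in _TISSUE_ROWS
    ]
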