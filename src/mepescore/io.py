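"""Cohort CSV input/output.

The canonical patient-level table has one row per patient (index lesion)
with columns::

    patient_id, abutment, interface_mm, irregular_margin, bulging,
    nvb_asymmetry, angle_obliteration, capsule_breach, pepe, site,
    reader, isup

Booleans are written as 0/1, interface_mm as a decimal in millimetres,
``pepe`` is the pathologic ground truth.  ``site``/``reader``/``isup`` are
optional descriptors.  Files are comma-separated UTF-8 with a header and a
decimal point.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .scoring import LesionFeatures

__all__ = [
    "REQUIRED_COLUMNS",
    "OPTIONAL_COLUMNS",
    "read_cohort",
    "write_cohort",
    "cohort_to_lesions",
    "validate_cohort",
]

REQUIRED_COLUMNS = (
    "patient_id",
    "abutment",
    "interface_mm",
    "irregular_margin",
    "bulging",
    "nvb_asymmetry",
    "angle_obliteration",
    "capsule_breach",
)
OPTIONAL_COLUMNS = ("pepe", "site", "reader", "isup")

_BOOL_COLUMNS = (
    "abutment",
    "irregular_margin",
    "bulging",
    "nvb_asymmetry",
    "angle_obliteration",
    "capsule_breach",
    "pepe",
)


def validate_cohort(df: pd.DataFrame, require_truth: bool = False) -> pd.DataFrame:
    """Check column presence and types; warn on duplicate patient ids."""
    import logging

    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if require_truth and "pepe" not in df.columns:
        missing.append("pepe")
    if missing:
        raise ValueError(f"cohort is missing required column(s): {', '.join(missing)}")
    if df["patient_id"].duplicated().any():
        logging.getLogger(__name__).warning(
            "duplicate patient_id values found; inputs should carry one index "
            "lesion per patient"
        )
    if (df["interface_mm"].astype(float) < 0).any():
        raise ValueError("interface_mm contains negative values")
    return df


def read_cohort(path, require_truth: bool = False) -> pd.DataFrame:
    """Read a patient-level cohort CSV and normalise dtypes."""
    df = pd.read_csv(path)
    validate_cohort(df, require_truth=require_truth)
    for c in _BOOL_COLUMNS:
        if c in df.columns:
            df[c] = df[c].astype(int)
    df["interface_mm"] = df["interface_mm"].astype(float)
    return df


def write_cohort(df: pd.DataFrame, path) -> None:
    """Write a cohort CSV in the canonical column order, deterministically."""
    cols = [c for c in REQUIRED_COLUMNS + OPTIONAL_COLUMNS if c in df.columns]
    extra = [c for c in df.columns if c not in cols]
    out = df[cols + extra].copy()
    out.to_csv(path, index=False, lineterminator="\n")


def cohort_to_lesions(df: pd.DataFrame) -> list[LesionFeatures]:
    """Convert cohort rows to LesionFeatures records (order preserved)."""
    return [
        LesionFeatures(
            capsular_abutment=bool(r.abutment),
            interface_length=float(r.interface_mm),
            irregular_margin=bool(r.irregular_margin),
            bulging_contour=bool(r.bulging),
            nvb_asymmetry=bool(r.nvb_asymmetry),
            angle_obliteration=bool(r.angle_obliteration),
            capsule_breach=bool(r.capsule_breach),
        )
        for r in df.itertuples(index=False)
    ]


def truth_vector(df: pd.DataFrame) -> np.ndarray:
    """Pathologic-EPE ground truth as a boolean vector."""
    if "pepe" not in df.columns:
        raise ValueError("cohort has no 'pepe' ground-truth column")
    return df["pepe"].astype(bool).to_numpy()
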