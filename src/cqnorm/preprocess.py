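"""Replicate aggregation with QC, inter-plate calibration, and per-assay Cq summaries.

Replicates of a (sample, assay) reaction are averaged; their n−1 standard
deviation is compared against a reproducibility threshold (default 0.3
cycles, strict ``>``, so an SD of exactly 0.3 passes).  Reactions with fewer
detected replicates than ``min_detected`` are marked undetected.  QC outcomes
are expressed as flags — nothing is silently dropped; downstream stages
decide what to exclude.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .cq_data import CqDataset
from .errors import CalibrationError, ValidationError

logger = logging.getLogger(__name__)

#: Columns of an aggregated Cq table.
AGGREGATED_COLUMNS = [
    "sample_id",
    "assay_id",
    "plate_id",
    "mean_cq",
    "replicate_sd",
    "n_used",
    "detected",
    "qc_flag",
]

QC_PASS = "pass"
QC_HIGH_SD = "high_replicate_sd"
QC_INSUFFICIENT = "insufficient_replicates"


def aggregate_replicates(
    dataset: CqDataset,
    sd_threshold: float = 0.3,
    min_detected: int = 2,
) -> pd.DataFrame:
    """Collapse replicate measurements to one row per (sample, assay).

    Returns a DataFrame with columns ``AGGREGATED_COLUMNS``.  ``mean_cq`` and
    ``replicate_sd`` are computed over detected replicates only; a reaction
    with fewer than ``min_detected`` detected replicates has ``detected =
    False`` and no mean.  ``replicate_sd`` is NaN when only one replicate
    contributed.
    """
    m = dataset.measurements
    # grouping includes the plate so a calibrator sample rerun on every
    # plate keeps one aggregated row per plate
    grouped = m.groupby(["sample_id", "assay_id", "plate_id"], sort=True)
    agg = grouped.agg(
        mean_cq=("cq", "mean"),
        replicate_sd=("cq", "std"),
        n_used=("cq", "count"),
    ).reset_index()

    detected = agg["n_used"] >= min_detected
    agg["detected"] = detected
    agg.loc[~detected, ["mean_cq", "replicate_sd"]] = np.nan

    flags = np.where(~detected, QC_INSUFFICIENT, QC_PASS)
    # strict ">": an SD exactly at the threshold passes (tiny tolerance so
    # float rounding cannot push a boundary value over)
    high_sd = detected & (agg["replicate_sd"] > sd_threshold + 1e-12)
    flags = np.where(high_sd, QC_HIGH_SD, flags)
    agg["qc_flag"] = flags
    return agg[AGGREGATED_COLUMNS]


def calibrate_plates(
    aggregated: pd.DataFrame,
    calibrator_sample_id: str,
) -> pd.DataFrame:
    """Align Cq values across plates using a calibrator sample run on each plate.

    For every (plate, assay), the offset (calibrator Cq on that plate − mean
    calibrator Cq across plates) is subtracted from all of that plate's Cq
    values for the assay.  Calibration is additive on the Cq scale
    (multiplicative on the linear scale) and preserves within-plate Cq
    differences exactly.  With a single plate the output equals the input.
    """
    agg = aggregated.copy()
    cal = agg[(agg["sample_id"] == calibrator_sample_id) & agg["detected"]]
    if cal.empty:
        raise CalibrationError(
            f"calibrator sample {calibrator_sample_id!r} has no detected measurements"
        )

    cal_mean = cal.groupby("assay_id")["mean_cq"].mean()
    cal_by_plate = cal.set_index(["plate_id", "assay_id"])["mean_cq"]

    needed = agg.loc[agg["detected"], ["plate_id", "assay_id"]].drop_duplicates()
    for plate, assay in needed.itertuples(index=False):
        if (plate, assay) not in cal_by_plate.index:
            raise CalibrationError(
                f"calibrator {calibrator_sample_id!r} missing for assay "
                f"{assay!r} on plate {plate!r}"
            )

    offsets = (cal_by_plate - cal_mean).rename("offset").reset_index()
    agg = agg.merge(offsets, on=["plate_id", "assay_id"], how="left")
    agg["offset"] = agg["offset"].fillna(0.0)
    agg["mean_cq"] = agg["mean_cq"] - agg["offset"]
    return agg.drop(columns="offset")


def summarize_assays(aggregated: pd.DataFrame) -> pd.DataFrame:
    """Per-assay min, max, range, mean and SD of the detected per-sample Cq means.

    Assays with no detected values are omitted with a logged warning.  The SD
    is the n−1 sample SD and is reported absent (NaN) for a single sample.
    Columns: assay_id, cq_min, cq_max, cq_range, mean_cq, sd_cq, n_samples.
    """
    det = aggregated[aggregated["detected"]]
    skipped = sorted(set(aggregated["assay_id"]) - set(det["assay_id"]))
    if skipped:
        logger.warning("summarize_assays: no detected values for %s; omitted", skipped)
    out = (
        det.groupby("assay_id")["mean_cq"]
        .agg(cq_min="min", cq_max="max", mean_cq="mean", sd_cq="std", n_samples="count")
        .reset_index()
    )
    out["cq_range"] = out["cq_max"] - out["cq_min"]
    return out[
        ["assay_id", "cq_range", "cq_min", "cq_max", "mean_cq", "sd_cq", "n_samples"]
    ]


def attach_groups(aggregated: pd.DataFrame, samples) -> pd.DataFrame:
    """Merge the sample sheet's group labels onto an aggregated table."""
    groups = samples.groups
    unknown = set(aggregated["sample_id"]) - set(groups.index)
    if unknown:
        raise ValidationError(f"aggregated rows reference unknown samples {sorted(unknown)}")
    out = aggregated.copy()
    out["group"] = out["sample_id"].map(groups)
    return out
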