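"""Efficiency-corrected relative quantification with log-scale error propagation.

Aggregated Cq values are converted to relative quantities (RQ) per assay,

    RQ(i, s) = AF_i ^ (Cq_ref(i) - Cq(i, s))

where AF_i is the assay's amplification factor (2 for E = 100%) and the
reference point Cq_ref(i) is the assay's minimum Cq over samples (so the
highest expressor gets RQ 1) or, optionally, the assay's mean Cq (so the
geometric mean RQ is 1).  The choice only rescales each assay's column and
cancels from every ratio-based statistic downstream (geNorm M and V,
NormFinder stability, group comparisons of normalized quantities).

Normalization factors (NF) are geometric means of reference-assay RQs per
sample; targets are normalized as NRQ = RQ / NF.  Standard errors are
propagated on the log2 scale assuming independence between assays:

    se_log2 RQ(i, s)  = replicate_sd / sqrt(n_used) * log2(AF_i)
    se_log2 NF(s)     = (1/m) * sqrt(sum_i se_log2 RQ(i, s)^2)
    se_log2 NRQ(t, s) = sqrt(se_log2 RQ(t, s)^2 + se_log2 NF(s)^2)
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cq_data import AssayPanel, SampleSheet
from .errors import ValidationError


@dataclass
class RQMatrix:
    """Relative quantities (linear scale) and log2-scale standard errors.

    ``values`` and ``log2_se`` are assay x sample DataFrames; undefined cells
    (undetected reactions) are NaN, never zero.
    """

    values: pd.DataFrame
    log2_se: pd.DataFrame
    reference_point: str
    amplification_factors: pd.Series

    @property
    def assays(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def log2(self) -> pd.DataFrame:
        """log2 relative quantities (NaN where undefined)."""
        return np.log2(self.values)


@dataclass
class NormalizationFactor:
    """Per-sample normalization factor from a set of reference assays.

    NF is defined only for samples in which every member assay is detected;
    other samples are NaN and listed in ``undefined_samples``.
    """

    nf: pd.Series
    log2_se: pd.Series
    member_assays: list[str]
    undefined_samples: list[str] = field(default_factory=list)


def cq_to_rq(
    aggregated: pd.DataFrame,
    panel: AssayPanel,
    reference_point: str = "min_cq",
    default_amplification_factor: float = 2.0,
    include_flagged: bool = True,
) -> RQMatrix:
    """Convert aggregated Cq values to an efficiency-corrected RQ matrix.

    Parameters
    ----------
    aggregated
        Output of :func:`cqnorm.preprocess.aggregate_replicates`.
    panel
        Assay panel supplying amplification efficiencies; assays without a
        fitted efficiency use ``default_amplification_factor``.
    reference_point
        "min_cq" (default; per-assay maximum RQ is 1) or "mean_cq"
        (per-assay geometric mean RQ is 1).
    include_flagged
        Keep reactions flagged ``high_replicate_sd`` (default).  When False
        they are treated as undefined.
    """
    if reference_point not in ("min_cq", "mean_cq"):
        raise ValidationError(f"unknown reference_point {reference_point!r}")
    rows = aggregated[aggregated["detected"]]
    if not include_flagged:
        rows = rows[rows["qc_flag"] != "high_replicate_sd"]
    all_samples = sorted(aggregated["sample_id"].unique())
    all_assays = sorted(aggregated["assay_id"].unique())
    cq = rows.pivot(index="assay_id", columns="sample_id", values="mean_cq")
    cq = cq.reindex(index=all_assays, columns=all_samples)
    rep_sd = rows.pivot(index="assay_id", columns="sample_id", values="replicate_sd")
    rep_sd = rep_sd.reindex_like(cq)
    n_used = rows.pivot(index="assay_id", columns="sample_id", values="n_used")
    n_used = n_used.reindex_like(cq)

    af = panel.amplification_factors(default=default_amplification_factor)
    af = af.reindex(cq.index)
    if af.isna().any():
        missing = af.index[af.isna()].tolist()
        raise ValidationError(f"assays absent from panel: {missing}")

    ref = cq.min(axis=1) if reference_point == "min_cq" else cq.mean(axis=1)
    log2_rq = cq.rsub(ref, axis=0).mul(np.log2(af), axis=0)
    values = np.exp2(log2_rq)
    log2_se = rep_sd.div(np.sqrt(n_used)).mul(np.log2(af), axis=0)
    return RQMatrix(
        values=values,
        log2_se=log2_se,
        reference_point=reference_point,
        amplification_factors=af,
    )


def normalization_factor(rq: RQMatrix, reference_assays: list[str]) -> NormalizationFactor:
    """Geometric-mean normalization factor over a set of reference assays."""
    if not reference_assays:
        raise ValidationError("reference_assays must be non-empty")
    missing = [a for a in reference_assays if a not in rq.values.index]
    if missing:
        raise ValidationError(f"reference assays absent from RQ matrix: {missing}")
    members = rq.values.loc[reference_assays]
    m = len(reference_assays)
    log2_nf = np.log2(members).mean(axis=0, skipna=False)  # NaN if any member undefined
    nf = np.exp2(log2_nf)
    se = np.sqrt((rq.log2_se.loc[reference_assays] ** 2).sum(axis=0, min_count=m)) / m
    undefined = nf.index[nf.isna()].tolist()
    return NormalizationFactor(
        nf=nf, log2_se=se, member_assays=list(reference_assays),
        undefined_samples=undefined,
    )


def normalize_targets(
    rq: RQMatrix,
    nf: NormalizationFactor,
    target_assays: list[str],
    samples: SampleSheet | None = None,
) -> pd.DataFrame:
    """Normalized relative quantities NRQ = RQ_target / NF, long format.

    Columns: assay_id, sample_id, nrq, log2_se (and group when a sample sheet
    is given).  Samples where the NF or the target is undefined are omitted.
    """
    missing = [a for a in target_assays if a not in rq.values.index]
    if missing:
        raise ValidationError(f"target assays absent from RQ matrix: {missing}")
    overlap = nf.nf.dropna().index.intersection(rq.values.columns)
    if len(overlap) == 0:
        raise ValidationError("no samples with both target RQ and defined NF")

    records = []
    for assay in target_assays:
        nrq = rq.values.loc[assay, overlap] / nf.nf[overlap]
        se = np.sqrt(rq.log2_se.loc[assay, overlap] ** 2 + nf.log2_se[overlap] ** 2)
        sub = pd.DataFrame(
            {"assay_id": assay, "sample_id": overlap, "nrq": nrq.values,
             "log2_se": se.values}
        ).dropna(subset=["nrq"])
        records.append(sub)
    out = pd.concat(records, ignore_index=True)
    if samples is not None:
        out["group"] = out["sample_id"].map(samples.groups)
    return out
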