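"""Global-mean expression profiles and array-stage candidate selection.

On large qPCR panels the per-sample mean Cq over all expressed assays (the
"global mean", equivalent to the geometric mean of linear quantities at
equal efficiencies) is itself a very stable normalizer.  Individual assays
whose expression profile runs parallel to the global mean across samples are
therefore good candidate reference genes.  Two qualifying rules are
supported: every detected assay, or only assays detected below a Cq cutoff
(default 35, strict ``<``).

Composite "virtual" assays (the per-sample mean Cq of a member set, i.e. the
geometric mean on the linear scale) can be built and entered into stability
algorithms alongside single genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .preprocess import QC_PASS

logger = logging.getLogger(__name__)

RULE_ALL_DETECTED = "all_detected"
RULE_BELOW_CUTOFF = "detected_below_cutoff"


@dataclass
class GlobalMeanProfile:
    """Per-sample mean Cq over qualifying assays."""

    mean_cq: pd.Series  # indexed by sample_id
    n_assays_used: pd.Series
    rule: str
    cutoff: float


@dataclass
class CandidateScores:
    """Ranked resemblance of candidate assays to the global mean profile.

    ``table`` columns: assay_id, resemblance_score, rank, n_samples_used —
    sorted by ascending score (lower = closer to the global mean), ties
    broken lexicographically by assay_id.  ``top`` holds the best ``top_k``.
    """

    table: pd.DataFrame
    top: list[str]
    excluded: list[str]


def global_mean_profile(
    aggregated: pd.DataFrame,
    rule: str = RULE_ALL_DETECTED,
    cutoff: float = 35.0,
) -> GlobalMeanProfile:
    """Per-sample arithmetic mean Cq of qualifying assays.

    ``rule`` is "all_detected" (every detected assay contributes) or
    "detected_below_cutoff" (only Cq strictly below ``cutoff``).
    """
    if rule not in (RULE_ALL_DETECTED, RULE_BELOW_CUTOFF):
        raise ValidationError(f"unknown qualifying rule {rule!r}")
    rows = aggregated[aggregated["detected"]]
    if rule == RULE_BELOW_CUTOFF:
        rows = rows[rows["mean_cq"] < cutoff]
    per_sample = rows.groupby("sample_id")["mean_cq"].agg(["mean", "count"])

    all_samples = aggregated["sample_id"].unique()
    empty = sorted(set(all_samples) - set(per_sample.index))
    if empty:
        raise ValidationError(
            f"samples with zero qualifying assays under rule {rule!r}: {empty}"
        )
    return GlobalMeanProfile(
        mean_cq=per_sample["mean"],
        n_assays_used=per_sample["count"],
        rule=rule,
        cutoff=cutoff,
    )


def make_virtual_assay(
    aggregated: pd.DataFrame,
    member_assays: list[str],
    name: str,
) -> pd.DataFrame:
    """Composite assay: per-sample mean Cq of the members (geometric mean on
    the linear scale), usable anywhere an assay is.

    Only samples in which every member is detected are included.  The
    replicate SD is propagated as sqrt(sum sd_i^2)/m (SE of the mean of
    independent members); n_used is the members' minimum.
    """
    if not member_assays:
        raise ValidationError("member_assays must be non-empty")
    missing = set(member_assays) - set(aggregated["assay_id"])
    if missing:
        raise ValidationError(f"virtual assay members not in data: {sorted(missing)}")
    rows = aggregated[
        aggregated["assay_id"].isin(member_assays) & aggregated["detected"]
    ]
    m = len(member_assays)
    per_sample = rows.groupby("sample_id").agg(
        mean_cq=("mean_cq", "mean"),
        sq_sd=("replicate_sd", lambda s: float(np.sum(np.square(s)))),
        n_used=("n_used", "min"),
        n_members=("assay_id", "count"),
        plate_id=("plate_id", "first"),
    )
    per_sample = per_sample[per_sample["n_members"] == m]
    out = pd.DataFrame(
        {
            "sample_id": per_sample.index,
            "assay_id": name,
            "plate_id": per_sample["plate_id"].values,
            "mean_cq": per_sample["mean_cq"].values,
            "replicate_sd": np.sqrt(per_sample["sq_sd"].values) / m,
            "n_used": per_sample["n_used"].values,
            "detected": True,
            "qc_flag": QC_PASS,
        }
    ).reset_index(drop=True)
    return out


def score_candidates(
    aggregated: pd.DataFrame,
    profile: GlobalMeanProfile,
    candidates: list[str] | None = None,
    top_k: int = 4,
    metric: str = "sd",
) -> CandidateScores:
    """Rank assays by resemblance to the global mean profile.

    The resemblance score of assay i is the dispersion over samples of
    Cq(i, s) − GlobalMean(s): the n−1 SD by default, or the mean absolute
    deviation from the median with ``metric="mad"``.  A perfectly parallel
    profile (constant offset from the global mean) scores 0.  Assays must be
    detected in every retained sample; others are excluded and logged.
    """
    if metric not in ("sd", "mad"):
        raise ValidationError(f"unknown resemblance metric {metric!r}")
    samples = profile.mean_cq.index
    rows = aggregated[aggregated["detected"] & aggregated["sample_id"].isin(samples)]
    cq = rows.pivot(index="assay_id", columns="sample_id", values="mean_cq")
    cq = cq.reindex(columns=samples)
    if candidates is not None:
        cq = cq.loc[cq.index.intersection(candidates)]

    complete = cq.dropna()
    excluded = sorted(set(cq.index) - set(complete.index))
    if excluded:
        logger.info("score_candidates: excluded (not detected in all samples): %s",
                    excluded)

    diffs = complete.sub(profile.mean_cq, axis=1)
    if metric == "sd":
        score = diffs.std(axis=1, ddof=1)
    else:
        score = (diffs.sub(diffs.median(axis=1), axis=0)).abs().mean(axis=1)

    table = pd.DataFrame(
        {
            "assay_id": complete.index,
            "resemblance_score": score.values,
            "n_samples_used": len(samples),
        }
    ).sort_values(["resemblance_score", "assay_id"], kind="mergesort")
    table["rank"] = np.arange(1, len(table) + 1)
    table = table.reset_index(drop=True)
    return CandidateScores(
        table=table,
        top=table["assay_id"].head(top_k).tolist(),
        excluded=excluded,
    )
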