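"""Validation statistics for candidate reference genes.

Before stability algorithms are trusted, candidates must show no evidence of
differential expression between the study groups (geNorm and NormFinder both
assume non-differential references), and their equivalence within a stated
fold-change bound should be confirmed.  This module provides:

* a two-sample (Welch) t-test pre-check per assay, by default on log10 Cq;
* Bartlett's test of variance homogeneity across genes (heterogeneous
  variance = heterogeneous stability);
* a CI-inclusion equivalence test: the groups' mean log2-expression
  difference with a symmetric t-based confidence interval, declared
  equivalent when the CI lies strictly inside ±log2(fold-change cutoff)
  (cutoff 3 → bound 1.58; cutoff 2 → bound 1.00);
* a Kolmogorov–Smirnov normality screen (advisory only).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cq_data import SampleSheet
from .errors import ValidationError
from .preprocess import attach_groups

logger = logging.getLogger(__name__)


@dataclass
class EquivalenceResult:
    assay_id: str
    mean_log2_diff: float
    ci_low: float
    ci_high: float
    bound: float
    equivalent: bool
    ci_level: float
    n_per_group: dict


def equivalence_bound(fold_change_cutoff: float) -> float:
    """log2 of the fold-change cutoff: the symmetric deviation bound."""
    if fold_change_cutoff <= 1:
        raise ValidationError("fold_change_cutoff must be > 1")
    return float(np.log2(fold_change_cutoff))


def _two_group_values(values: pd.DataFrame, value_col: str, case: str, ref: str):
    a = values.loc[values["group"] == case, value_col].dropna().to_numpy(float)
    b = values.loc[values["group"] == ref, value_col].dropna().to_numpy(float)
    return a, b


def _resolve_case_group(levels: list[str], case_group: str | None) -> tuple[str, str]:
    if case_group is not None:
        if case_group not in levels:
            raise ValidationError(f"case_group {case_group!r} not in groups {levels}")
        ref = [lv for lv in levels if lv != case_group]
        return case_group, ref[0]
    for guess in ("tumour", "tumor", "case"):
        if guess in levels:
            return guess, [lv for lv in levels if lv != guess][0]
    return levels[0], levels[1]


def differential_precheck(
    aggregated: pd.DataFrame,
    samples: SampleSheet,
    transform: str = "log10_cq",
    alpha: float = 0.05,
    case_group: str | None = None,
    equal_var: bool = False,
) -> pd.DataFrame:
    """Per-assay two-sample t-test between groups on transformed Cq values.

    ``transform`` is "log10_cq" (t-test on log10 of the Cq value) or "cq"
    (raw Cq).  The Welch unequal-variance variant is the default.  The
    returned ``nondifferential`` flag (p > alpha) gates downstream stability
    analysis.  Assays with fewer than 2 detected values in either group are
    skipped with a log message.
    """
    if transform not in ("log10_cq", "cq"):
        raise ValidationError(f"unknown transform {transform!r}")
    samples.require_two_groups()
    levels = samples.group_levels()
    if len(levels) != 2:
        raise ValidationError(f"exactly 2 groups required, found {levels}")
    case, ref = _resolve_case_group(levels, case_group)

    data = attach_groups(aggregated[aggregated["detected"]], samples)
    if transform == "log10_cq":
        data = data.assign(value=np.log10(data["mean_cq"]))
    else:
        data = data.assign(value=data["mean_cq"])

    rows = []
    for assay, sub in data.groupby("assay_id", sort=True):
        a, b = _two_group_values(sub, "value", case, ref)
        if len(a) < 2 or len(b) < 2:
            logger.info("differential_precheck: skipped %s (<2 values per group)", assay)
            continue
        t, p = stats.ttest_ind(a, b, equal_var=equal_var)
        rows.append(
            {
                "assay_id": assay,
                "statistic": float(t),
                "p_value": float(p),
                "test_name": "t" if equal_var else "welch_t",
                "transform": transform,
                "n_case": len(a),
                "n_reference": len(b),
                "nondifferential": bool(p > alpha),
            }
        )
    return pd.DataFrame(rows)


def variance_homogeneity(
    aggregated: pd.DataFrame, genes: list[str] | None = None
) -> dict:
    """Bartlett's test of equal variance across genes' per-sample Cq values.

    A small p-value indicates heterogeneous dispersion — i.e. the candidate
    genes differ in stability.  A gene with zero variance makes the
    statistic undefined and raises an error naming it.
    """
    det = aggregated[aggregated["detected"]]
    if genes is not None:
        det = det[det["assay_id"].isin(genes)]
    series = {a: sub["mean_cq"].to_numpy(float) for a, sub in det.groupby("assay_id")}
    if len(series) < 2:
        raise ValidationError("Bartlett's test needs at least 2 genes")
    for a, vals in series.items():
        if len(vals) < 2:
            raise ValidationError(f"gene {a!r} has fewer than 2 values")
        if np.var(vals, ddof=1) == 0:
            raise ValidationError(f"gene {a!r} has zero variance; statistic undefined")
    stat, p = stats.bartlett(*series.values())
    return {
        "statistic": float(stat),
        "p_value": float(p),
        "test_name": "bartlett",
        "n_genes": len(series),
    }


def equivalence_test(
    log2_expression: pd.DataFrame,
    samples: SampleSheet,
    fold_change_cutoff: float = 3.0,
    ci_level: float = 0.90,
    paired: bool = False,
    case_group: str | None = None,
) -> pd.DataFrame:
    """CI-inclusion equivalence test per assay on log2 expression values.

    Parameters
    ----------
    log2_expression
        Long table with columns assay_id, sample_id, log2_value — e.g. from
        :func:`log2_expression_from_aggregated` (−Cq, so differences are
        log2 fold changes at E = 100%) or log2 of normalized quantities.
    fold_change_cutoff
        Equivalence margin on the linear scale; the log2 bound is its log2
        (3 → 1.58, 2 → 1.00).
    ci_level
        Symmetric CI level (default 0.90, the two-one-sided-tests
        correspondence at alpha = 0.05).
    paired
        When True, samples are matched by the sample sheet's patient_id and
        a one-sample CI of the per-patient differences is used.

    Equivalence is declared when the CI lies strictly inside (−bound, bound).
    """
    bound = equivalence_bound(fold_change_cutoff)
    samples.require_two_groups()
    levels = samples.group_levels()
    if len(levels) != 2:
        raise ValidationError(f"exactly 2 groups required, found {levels}")
    case, ref = _resolve_case_group(levels, case_group)

    ann = samples.frame.set_index("sample_id")
    data = log2_expression.copy()
    data["group"] = data["sample_id"].map(ann["group"])

    rows = []
    for assay, sub in data.groupby("assay_id", sort=True):
        if paired:
            if "patient_id" not in ann.columns:
                raise ValidationError("paired mode requires patient_id in sample sheet")
            sub = sub.assign(patient_id=sub["sample_id"].map(ann["patient_id"]))
            wide = sub.pivot_table(
                index="patient_id", columns="group", values="log2_value"
            ).dropna()
            if len(wide) < 2:
                logger.info("equivalence_test: skipped %s (<2 pairs)", assay)
                continue
            diffs = (wide[case] - wide[ref]).to_numpy(float)
            mean = float(diffs.mean())
            se = float(diffs.std(ddof=1) / np.sqrt(len(diffs)))
            df = len(diffs) - 1
            n_per_group = {case: len(diffs), ref: len(diffs)}
        else:
            a, b = _two_group_values(sub, "log2_value", case, ref)
            if len(a) < 2 or len(b) < 2:
                logger.info("equivalence_test: skipped %s (<2 values per group)", assay)
                continue
            mean = float(a.mean() - b.mean())
            va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
            se = float(np.sqrt(va + vb))
            if va + vb == 0:
                df = len(a) + len(b) - 2
            else:  # Welch–Satterthwaite
                df = (va + vb) ** 2 / (
                    va**2 / (len(a) - 1) + vb**2 / (len(b) - 1)
                )
            n_per_group = {case: len(a), ref: len(b)}
        tcrit = stats.t.ppf(0.5 + ci_level / 2.0, df) if se > 0 else 0.0
        ci_low, ci_high = mean - tcrit * se, mean + tcrit * se
        rows.append(
            {
                "assay_id": assay,
                "mean_log2_diff": mean,
                "ci_low": ci_low,
                "ci_high": ci_high,
                "bound": bound,
                "equivalent": bool(ci_low > -bound and ci_high < bound),
                "ci_level": ci_level,
                "n_case": n_per_group[case],
                "n_reference": n_per_group[ref],
                "paired": paired,
            }
        )
    return pd.DataFrame(rows)


def log2_expression_from_aggregated(aggregated: pd.DataFrame) -> pd.DataFrame:
    """Log2 expression from Cq at E = 100%: −Cq (constants cancel in group
    differences)."""
    det = aggregated[aggregated["detected"]]
    return pd.DataFrame(
        {
            "assay_id": det["assay_id"].values,
            "sample_id": det["sample_id"].values,
            "log2_value": -det["mean_cq"].values,
        }
    )


def log2_expression_from_nrq(nrq_table: pd.DataFrame) -> pd.DataFrame:
    """Log2 expression from a normalized-target table (columns assay_id,
    sample_id, nrq)."""
    return pd.DataFrame(
        {
            "assay_id": nrq_table["assay_id"].values,
            "sample_id": nrq_table["sample_id"].values,
            "log2_value": np.log2(nrq_table["nrq"].to_numpy(float)),
        }
    )


def normality_check(
    aggregated: pd.DataFrame,
    samples: SampleSheet | None = None,
    min_n: int = 5,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One-sample KS test of each assay's (optionally per-group) Cq values
    against a Normal with estimated mean and SD.  Advisory only: results
    flag, never block.  Constant or too-small cells are flagged untested.
    """
    det = aggregated[aggregated["detected"]]
    if samples is not None:
        det = attach_groups(det, samples)
        keys = ["assay_id", "group"]
    else:
        keys = ["assay_id"]
    rows = []
    for key, sub in det.groupby(keys, sort=True):
        key = key if isinstance(key, tuple) else (key,)
        vals = sub["mean_cq"].to_numpy(float)
        rec = dict(zip(keys, key))
        rec["n"] = len(vals)
        if len(vals) < min_n:
            rec.update(status="skipped_too_few", statistic=np.nan, p_value=np.nan,
                       normal=None)
        elif np.std(vals, ddof=1) == 0:
            rec.update(status="degenerate_constant", statistic=np.nan, p_value=np.nan,
                       normal=None)
        else:
            stat, p = stats.kstest(vals, "norm", args=(vals.mean(), vals.std(ddof=1)))
            rec.update(status="tested", statistic=float(stat), p_value=float(p),
                       normal=bool(p > alpha))
        rows.append(rec)
    return pd.DataFrame(rows)
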