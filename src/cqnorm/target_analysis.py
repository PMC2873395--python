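"""Effect of normalizer choice on target differential expression.

For each candidate normalizer set, target assays are normalized (NRQ =
RQ / NF) and compared between groups with a Welch t-test on log10 NRQ.  The
resulting grid — targets x normalizer sets, with p-values, directions and
fold changes side by side — makes visible how an unstable or confounded
normalizer attenuates or masks true expression differences.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .cq_data import SampleSheet
from .errors import ValidationError
from .group_stats import _resolve_case_group
from .quantification import RQMatrix, normalization_factor, normalize_targets


def compare_targets(
    rq: RQMatrix,
    normalizer_sets: dict[str, list[str]] | list[list[str]],
    targets: list[str],
    samples: SampleSheet,
    alpha: float = 0.05,
    case_group: str | None = None,
) -> pd.DataFrame:
    """Group comparison of every target under every normalizer set.

    Returns one row per (target, normalizer set) with columns: target,
    normalizer_set, members, statistic, p_value, significant,
    mean_log2_diff, direction (up/down in the case group), median_fold_change,
    n_case, n_reference.

    Raises if a target appears in its own normalizer set (a target cannot
    normalize itself).
    """
    if isinstance(normalizer_sets, list):
        normalizer_sets = {"+".join(s): list(s) for s in normalizer_sets}
    for name, members in normalizer_sets.items():
        if not members:
            raise ValidationError(f"normalizer set {name!r} is empty")
        clash = set(members) & set(targets)
        if clash:
            raise ValidationError(
                f"targets {sorted(clash)} appear in normalizer set {name!r}"
            )
    samples.require_two_groups()
    levels = samples.group_levels()
    if len(levels) != 2:
        raise ValidationError(f"exactly 2 groups required, found {levels}")
    case, ref = _resolve_case_group(levels, case_group)

    rows = []
    for name, members in normalizer_sets.items():
        nf = normalization_factor(rq, members)
        nrq = normalize_targets(rq, nf, targets, samples=samples)
        for target, sub in nrq.groupby("assay_id", sort=True):
            log10_nrq = np.log10(sub["nrq"].to_numpy(float))
            grp = sub["group"].to_numpy()
            a = log10_nrq[grp == case]
            b = log10_nrq[grp == ref]
            if len(a) < 2 or len(b) < 2:
                continue
            t, p = stats.ttest_ind(a, b, equal_var=False)
            mean_log2 = float((a.mean() - b.mean()) / np.log10(2))
            med_a = float(np.median(sub.loc[grp == case, "nrq"]))
            med_b = float(np.median(sub.loc[grp == ref, "nrq"]))
            rows.append(
                {
                    "target": target,
                    "normalizer_set": name,
                    "members": ",".join(members),
                    "statistic": float(t),
                    "p_value": float(p),
                    "significant": bool(p < alpha),
                    "mean_log2_diff": mean_log2,
                    "direction": "up" if mean_log2 > 0 else "down",
                    "median_fold_change": med_a / med_b if med_b > 0 else np.nan,
                    "n_case": int(len(a)),
                    "n_reference": int(len(b)),
                }
            )
    return pd.DataFrame(rows)
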