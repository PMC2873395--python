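"""geNorm reference-gene stability: pairwise variation, M values, stepwise
exclusion and the V series for choosing how many references to use.

For genes j and k, the pairwise variation V_jk is the standard deviation
(n−1) over samples of log2(RQ_j / RQ_k); a constant expression ratio gives
V_jk = 0.  A gene's stability measure M_j is the mean of V_jk over all other
genes in the current set — the average pairwise variation.  The least stable
gene (largest M) is excluded step by step until two genes remain; those two
necessarily share a single M equal to the SD of their mutual log-ratio.

The optimal number of references is chosen from normalization factors built
from the top-n ranked genes: V(n, n+1) is the SD over samples of
log2(NF_n / NF_{n+1}).  The smallest n with V below a threshold (0.15 by
canonical guidance) suffices; when no n passes, the n minimizing V is used.

Because every statistic is built from ratios (or ratios of geometric means),
the results are invariant to per-gene rescaling of RQ, hence to the
reference-point convention used during quantification.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .quantification import RQMatrix

logger = logging.getLogger(__name__)

V_THRESHOLD_DEFAULT = 0.15


@dataclass
class GeNormResult:
    """Full geNorm output.

    Attributes
    ----------
    pairwise_variation : pd.DataFrame
        Symmetric gene x gene grid of V_jk (diagonal NaN).
    full_panel_m : pd.Series
        Every gene's M computed on the complete panel (step 0).
    m_at_exclusion : pd.Series
        Each gene's M at the step it was excluded (final pair: their shared
        final M) — the trajectory endpoint view.
    m_trajectory : pd.DataFrame
        One row per exclusion step; columns are genes, NaN once removed.
    exclusion_order : list[str]
        Genes in order of removal, least stable first.
    final_pair : tuple[str, str]
        The two genes remaining after stepwise exclusion.
    ranking : list[str]
        Most stable first: the final pair (lexicographic) then the exclusion
        order reversed.
    v_series : pd.Series | None
        V(n, n+1) indexed by n = 2 .. G−1.
    recommended_n : int | None
        Optimal number of reference genes.
    v_threshold : float
    """

    pairwise_variation: pd.DataFrame
    full_panel_m: pd.Series
    m_at_exclusion: pd.Series
    m_trajectory: pd.DataFrame
    exclusion_order: list[str]
    final_pair: tuple[str, str]
    ranking: list[str]
    v_series: pd.Series | None = None
    recommended_n: int | None = None
    v_threshold: float = V_THRESHOLD_DEFAULT


def _log2_matrix(rq: RQMatrix, genes: list[str]) -> pd.DataFrame:
    missing = [g for g in genes if g not in rq.values.index]
    if missing:
        raise ValidationError(f"genes absent from RQ matrix: {missing}")
    return np.log2(rq.values.loc[genes])


def pairwise_variation_matrix(rq: RQMatrix, genes: list[str]) -> pd.DataFrame:
    """Symmetric grid of V_jk = SD over shared samples of log2(RQ_j / RQ_k).

    Pairwise-complete samples are used per pair; a pair sharing fewer than 2
    samples is an error naming the pair.
    """
    if len(genes) < 2:
        raise ValidationError("pairwise variation needs at least 2 genes")
    y = _log2_matrix(rq, genes)
    v = pd.DataFrame(np.nan, index=genes, columns=genes, dtype=float)
    for j, k in itertools.combinations(genes, 2):
        ratio = (y.loc[j] - y.loc[k]).dropna()
        if len(ratio) < 2:
            raise ValidationError(
                f"genes ({j!r}, {k!r}) share fewer than 2 samples with defined RQ"
            )
        v.loc[j, k] = v.loc[k, j] = ratio.std(ddof=1)
    return v


def _m_values(v: pd.DataFrame) -> pd.Series:
    """M_j = mean of V_jk over the other genes in the grid."""
    return v.mean(axis=1, skipna=True)


def genorm_rank(rq: RQMatrix, genes: list[str]) -> GeNormResult:
    """Stepwise geNorm ranking: exclude the largest-M gene until two remain.

    Ties in M are broken lexicographically by assay_id (the alphabetically
    last of the tied genes is removed) so results are deterministic.
    """
    if len(genes) < 2:
        raise ValidationError("geNorm needs at least 2 genes")
    genes = list(genes)
    v_full = pairwise_variation_matrix(rq, genes)
    full_panel_m = _m_values(v_full)

    remaining = sorted(genes)
    exclusion_order: list[str] = []
    m_at_exclusion = pd.Series(np.nan, index=genes, dtype=float)
    trajectory_rows = []
    step = 0
    while True:
        m = _m_values(v_full.loc[remaining, remaining])
        trajectory_rows.append(m.reindex(genes).rename(step))
        if len(remaining) == 2:
            for g in remaining:
                m_at_exclusion[g] = m[g]
            break
        # max M; tie -> lexicographically last so the first-named gene survives
        worst_m = m.max()
        worst = max(g for g in remaining if m[g] == worst_m)
        m_at_exclusion[worst] = m[worst]
        exclusion_order.append(worst)
        remaining.remove(worst)
        step += 1

    final_pair = tuple(sorted(remaining))
    ranking = list(final_pair) + list(reversed(exclusion_order))
    return GeNormResult(
        pairwise_variation=v_full,
        full_panel_m=full_panel_m,
        m_at_exclusion=m_at_exclusion,
        m_trajectory=pd.DataFrame(trajectory_rows),
        exclusion_order=exclusion_order,
        final_pair=final_pair,
        ranking=ranking,
    )


def pairwise_variation_series(
    rq: RQMatrix,
    ranked_genes: list[str],
    v_threshold: float = V_THRESHOLD_DEFAULT,
) -> tuple[pd.Series, int]:
    """V(n, n+1) between sequential normalization factors and the optimal n.

    ``ranked_genes`` must be ordered most → least stable.  NF_n(s) is the
    geometric mean RQ of the top-n genes; V(n, n+1) the SD over samples of
    log2(NF_n / NF_{n+1}).  Samples missing any ranked gene are dropped
    (complete cases) with a logged count.  The recommended n is the smallest
    n with V(n, n+1) < ``v_threshold``; if none passes, the n minimizing V.
    """
    g = len(ranked_genes)
    if g < 3:
        raise ValidationError("the V series needs at least 3 ranked genes")
    y = _log2_matrix(rq, list(ranked_genes))
    complete = y.dropna(axis=1)
    dropped = y.shape[1] - complete.shape[1]
    if dropped:
        logger.info("pairwise_variation_series: dropped %d incomplete samples", dropped)
    if complete.shape[1] < 2:
        raise ValidationError("fewer than 2 complete-case samples for the NF series")

    log_nf = complete.cumsum(axis=0).div(
        np.arange(1, g + 1), axis=0
    )  # row n-1: log2 NF of top-n genes
    v = {}
    for n in range(2, g):
        diff = log_nf.iloc[n - 1] - log_nf.iloc[n]
        v[n] = float(diff.std(ddof=1))
    v_series = pd.Series(v, name="V")
    passing = [n for n, val in v_series.items() if val < v_threshold]
    recommended = min(passing) if passing else int(v_series.idxmin())
    return v_series, recommended


def run_genorm(
    rq: RQMatrix,
    genes: list[str],
    v_threshold: float = V_THRESHOLD_DEFAULT,
) -> GeNormResult:
    """Complete geNorm analysis: ranking plus the V series when G >= 3."""
    result = genorm_rank(rq, genes)
    result.v_threshold = v_threshold
    if len(genes) >= 3:
        result.v_series, result.recommended_n = pairwise_variation_series(
            rq, result.ranking, v_threshold=v_threshold
        )
    return result
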