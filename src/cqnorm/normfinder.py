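"""Model-based (NormFinder-style) stability estimation for a two-group design.

Log2 relative quantities are decomposed into a sample effect, a gene effect,
a gene-by-group effect and residual noise.  Centering each sample across
genes removes sample-wide variation; what remains per gene is (i) its
intra-group residual variance and (ii) its systematic expression difference
between the groups.  A stable reference gene has both components small.

Estimator chain for G genes and K = 2 groups with n_g samples in group g,
on z = log2 RQ centered per sample across genes:

1. group means z̄_ig and residual variances s²_ig (n−1, within gene x group);
2. de-biased gene variance (the per-sample centering leaks 1/G of every
   other gene's variance into s²_ig):
       σ̂²_ig = max(0, [s²_ig − Σ_{i'} s²_{i'g} / (G(G−1))] / (1 − 2/G));
3. inter-group difference d̂_ig = z̄_ig − mean_g z̄_ig;
4. between-gene variance of group differences:
       γ̂² = max(0, Σ_ig d̂²_ig / ((G−1)(K−1)) − mean_ig(σ̂²_ig / n_g));
5. shrinkage d̃_ig = d̂_ig · γ̂² / (γ̂² + σ̂²_ig / n_g)  (0 when γ̂² = 0);
6. stability ρ_i = mean_g [ |d̃_ig| + sqrt((σ̂²_ig/n_g) · γ̂²/(γ̂² + σ̂²_ig/n_g)) ].

Lower ρ means more stable.  When γ̂² clamps to 0 every d̃ — and with it every
ρ — collapses to 0, so ties in ρ are broken by the mean intra-group variance
(then lexicographically): the ranking then reduces to variance ordering.

The best pair is found by exhaustive search: each pair's composite series
c = (z_i + z_{i'})/2 is pushed through the same chain with γ̂² held at the
panel value.  The composite's variance is de-biased through the genes'
within-group covariance (the per-sample centering induces spurious negative
covariance), which makes the estimate exact for a gene paired with an
identical copy of itself — the pair then scores its single-gene ρ — and
unbiased for independent genes, so two genes with opposite group effects
score better together than either alone.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cq_data import SampleSheet
from .errors import ValidationError
from .quantification import RQMatrix


@dataclass
class NormFinderResult:
    """Per-gene variance decomposition and stability values.

    ``table`` columns: assay_id, rho (stability, lower = more stable), and
    per-group sigma2_<g>, d_hat_<g>, d_tilde_<g>.  ``gamma2`` is the
    between-gene variance of group differences.
    """

    table: pd.DataFrame
    gamma2: float
    best_gene: str
    best_pair: tuple[str, str]
    pair_stability: float
    pair_table: pd.DataFrame
    groups: list[str]


def _prepare(rq: RQMatrix, genes: list[str], samples: SampleSheet):
    if len(genes) < 3:
        raise ValidationError("NormFinder needs at least 3 genes (per-sample centering)")
    missing = [g for g in genes if g not in rq.values.index]
    if missing:
        raise ValidationError(f"genes absent from RQ matrix: {missing}")
    y = np.log2(rq.values.loc[list(genes)]).dropna(axis=1)  # complete cases
    groups = samples.groups.reindex(y.columns)
    if groups.isna().any():
        raise ValidationError(
            f"samples missing from sheet: {groups.index[groups.isna()].tolist()}"
        )
    levels = sorted(groups.unique())
    if len(levels) != 2:
        raise ValidationError(f"exactly 2 groups required, found {levels}")
    for lv in levels:
        if (groups == lv).sum() < 3:
            raise ValidationError(f"group {lv!r} has fewer than 3 samples")
    z = y.sub(y.mean(axis=0), axis=1)  # center each sample across genes
    return z, groups, levels


def _group_stats(z: pd.DataFrame, groups: pd.Series, levels: list[str]):
    """Per gene x group means and n−1 residual variances, plus group sizes."""
    zbar = {}
    s2 = {}
    n = {}
    for lv in levels:
        cols = groups.index[groups == lv]
        sub = z[cols]
        zbar[lv] = sub.mean(axis=1)
        s2[lv] = sub.var(axis=1, ddof=1)
        n[lv] = len(cols)
    return pd.DataFrame(zbar), pd.DataFrame(s2), n


def _stability_from_components(
    sigma2: pd.DataFrame, d_hat: pd.DataFrame, gamma2: float, n: dict
) -> tuple[pd.DataFrame, pd.Series]:
    """Steps 5–6 applied row-wise; returns (d_tilde, rho)."""
    levels = list(sigma2.columns)
    d_tilde = pd.DataFrame(index=sigma2.index, columns=levels, dtype=float)
    terms = pd.DataFrame(index=sigma2.index, columns=levels, dtype=float)
    for lv in levels:
        var_of_mean = sigma2[lv] / n[lv]
        if gamma2 > 0:
            w = gamma2 / (gamma2 + var_of_mean)
        else:
            w = pd.Series(0.0, index=sigma2.index)
        d_tilde[lv] = d_hat[lv] * w
        terms[lv] = d_tilde[lv].abs() + np.sqrt(var_of_mean * w)
    return d_tilde, terms.mean(axis=1)


def normfinder_rank(
    rq: RQMatrix, genes: list[str], samples: SampleSheet
) -> NormFinderResult:
    """Per-gene stability values ρ and the exhaustive best-pair search."""
    z, groups, levels = _prepare(rq, genes, samples)
    g_genes = len(genes)
    k = len(levels)
    zbar, s2, n = _group_stats(z, groups, levels)
    correction = {lv: s2[lv].sum() / (g_genes * (g_genes - 1)) for lv in levels}
    sigma2_raw = pd.DataFrame(
        {lv: (s2[lv] - correction[lv]) / (1.0 - 2.0 / g_genes) for lv in levels}
    )
    sigma2 = sigma2_raw.clip(lower=0.0)
    d_hat = zbar.sub(zbar.mean(axis=1), axis=0)

    var_of_mean = pd.DataFrame({lv: sigma2[lv] / n[lv] for lv in levels})
    gamma2 = max(
        0.0,
        float((d_hat**2).values.sum() / ((g_genes - 1) * (k - 1))
              - var_of_mean.values.mean()),
    )
    d_tilde, rho = _stability_from_components(sigma2, d_hat, gamma2, n)

    table = pd.DataFrame({"assay_id": list(z.index), "rho": rho.values})
    table["mean_sigma2"] = sigma2.mean(axis=1).values
    for lv in levels:
        table[f"sigma2_{lv}"] = sigma2[lv].values
        table[f"d_hat_{lv}"] = d_hat[lv].values
        table[f"d_tilde_{lv}"] = d_tilde[lv].values
    table = table.sort_values(
        ["rho", "mean_sigma2", "assay_id"], kind="mergesort"
    ).reset_index(drop=True)
    best_gene = table["assay_id"].iloc[0]

    # Exhaustive pair search: composite series through the same chain with
    # gamma^2 held at the panel value.  The composite variance estimate
    # (sigma_i^2 + sigma_k^2)/4 + cov_hat(y_i, y_k)/2 inverts the centering
    # leakage exactly: cov_hat = cov(z_i, z_k) + (sigma_i^2 + sigma_k^2)/G −
    # correction, which reduces to the single-gene estimate for identical
    # series and is unbiased for independent genes.
    cov_z = {
        lv: pd.DataFrame(
            np.cov(z[groups.index[groups == lv]].to_numpy(float), ddof=1),
            index=z.index, columns=z.index,
        )
        for lv in levels
    }
    pair_rows = []
    for a, b in itertools.combinations(sorted(z.index), 2):
        sig2_c = {}
        dhat_c = {}
        for lv in levels:
            sa, sb = sigma2_raw.loc[a, lv], sigma2_raw.loc[b, lv]
            cov_hat = (
                cov_z[lv].loc[a, b] + (sa + sb) / g_genes - correction[lv]
            )
            sig2_c[lv] = max(0.0, (sa + sb) / 4.0 + cov_hat / 2.0)
            dhat_c[lv] = (d_hat.loc[a, lv] + d_hat.loc[b, lv]) / 2.0
        terms = []
        for lv in levels:
            vm = sig2_c[lv] / n[lv]
            w = gamma2 / (gamma2 + vm) if gamma2 > 0 else 0.0
            terms.append(abs(dhat_c[lv] * w) + np.sqrt(vm * w))
        pair_rows.append(
            (a, b, float(np.mean(terms)), float(np.mean(list(sig2_c.values()))))
        )
    pair_table = pd.DataFrame(
        pair_rows, columns=["gene_a", "gene_b", "stability", "mean_sigma2"]
    )
    pair_table = pair_table.sort_values(
        ["stability", "mean_sigma2", "gene_a", "gene_b"], kind="mergesort"
    ).reset_index(drop=True)
    best = pair_table.iloc[0]

    return NormFinderResult(
        table=table,
        gamma2=gamma2,
        best_gene=best_gene,
        best_pair=(best["gene_a"], best["gene_b"]),
        pair_stability=float(best["stability"]),
        pair_table=pair_table,
        groups=levels,
    )


def best_pair(
    rq: RQMatrix, genes: list[str], samples: SampleSheet
) -> tuple[tuple[str, str], float]:
    """Convenience wrapper returning only the best pair and its stability."""
    res = normfinder_rank(rq, genes, samples)
    return res.best_pair, res.pair_stability
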