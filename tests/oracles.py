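"""Independent naive reference implementations used only as test oracles.

These are deliberately written with plain Python loops and the textbook
definitions, sharing no code with the package implementations they check.
"""

import itertools
import math
import statistics


def naive_pairwise_v(rq_j, rq_k):
    """SD (n-1) of log2 ratios between two genes' linear RQ series."""
    ratios = [math.log2(a / b) for a, b in zip(rq_j, rq_k)]
    return statistics.stdev(ratios)


def naive_m_values(rq_by_gene):
    """Each gene's mean pairwise variation against all other genes."""
    genes = list(rq_by_gene)
    out = {}
    for j in genes:
        vs = [naive_pairwise_v(rq_by_gene[j], rq_by_gene[k])
              for k in genes if k != j]
        out[j] = sum(vs) / len(vs)
    return out


def naive_genorm_ranking(rq_by_gene):
    """Stepwise exclusion of the largest-M gene (lexicographically last on
    ties) until two remain; returns (exclusion_order, final_pair)."""
    remaining = dict(rq_by_gene)
    order = []
    while len(remaining) > 2:
        m = naive_m_values(remaining)
        worst_val = max(m.values())
        worst = max(g for g, v in m.items() if v == worst_val)
        order.append(worst)
        del remaining[worst]
    return order, tuple(sorted(remaining))


def naive_v_series(rq_by_gene, ranked):
    """V(n, n+1) between sequential geometric-mean normalization factors."""
    n_samples = len(next(iter(rq_by_gene.values())))

    def log_nf(n):
        return [sum(math.log2(rq_by_gene[g][s]) for g in ranked[:n]) / n
                for s in range(n_samples)]

    out = {}
    for n in range(2, len(ranked)):
        diffs = [a - b for a, b in zip(log_nf(n), log_nf(n + 1))]
        out[n] = statistics.stdev(diffs)
    return out


def naive_normfinder(log2rq_by_gene, group_of_sample):
    """Stability values and exhaustive pair search per the package's declared
    estimator chain, recomputed from first principles with plain loops.

    ``log2rq_by_gene``: {gene: {sample: log2 RQ}}; returns (rho_by_gene,
    pair_stability_by_pair, gamma2).
    """
    genes = sorted(log2rq_by_gene)
    samples = sorted(next(iter(log2rq_by_gene.values())))
    levels = sorted(set(group_of_sample.values()))
    assert len(levels) == 2
    g_count = len(genes)

    # center per sample across genes
    z = {}
    for s in samples:
        mean_s = sum(log2rq_by_gene[g][s] for g in genes) / g_count
        for g in genes:
            z[(g, s)] = log2rq_by_gene[g][s] - mean_s

    members = {lv: [s for s in samples if group_of_sample[s] == lv]
               for lv in levels}
    n = {lv: len(members[lv]) for lv in levels}

    zbar = {(g, lv): statistics.mean(z[(g, s)] for s in members[lv])
            for g in genes for lv in levels}
    s2 = {(g, lv): statistics.variance([z[(g, s)] for s in members[lv]])
          for g in genes for lv in levels}
    correction = {lv: sum(s2[(g, lv)] for g in genes) / (g_count * (g_count - 1))
                  for lv in levels}
    sigma2_raw = {(g, lv): (s2[(g, lv)] - correction[lv]) / (1 - 2 / g_count)
                  for g in genes for lv in levels}
    sigma2 = {k: max(0.0, v) for k, v in sigma2_raw.items()}
    d_hat = {(g, lv): zbar[(g, lv)]
             - statistics.mean(zbar[(g, m)] for m in levels)
             for g in genes for lv in levels}

    gamma2 = max(
        0.0,
        sum(d_hat[k] ** 2 for k in d_hat) / ((g_count - 1) * (len(levels) - 1))
        - statistics.mean(sigma2[(g, lv)] / n[lv] for g in genes for lv in levels),
    )

    def stability(sig2_by_level, dhat_by_level):
        terms = []
        for lv in levels:
            vm = sig2_by_level[lv] / n[lv]
            w = gamma2 / (gamma2 + vm) if gamma2 > 0 else 0.0
            terms.append(abs(dhat_by_level[lv] * w) + math.sqrt(vm * w))
        return statistics.mean(terms)

    rho = {g: stability({lv: sigma2[(g, lv)] for lv in levels},
                        {lv: d_hat[(g, lv)] for lv in levels})
           for g in genes}

    pair_stab = {}
    for a, b in itertools.combinations(genes, 2):
        sig2_c = {}
        dhat_c = {}
        for lv in levels:
            za = [z[(a, s)] for s in members[lv]]
            zb = [z[(b, s)] for s in members[lv]]
            ma, mb = statistics.mean(za), statistics.mean(zb)
            cov_z = sum((x - ma) * (y - mb) for x, y in zip(za, zb)) / (n[lv] - 1)
            cov_hat = (cov_z + (sigma2_raw[(a, lv)] + sigma2_raw[(b, lv)]) / g_count
                       - correction[lv])
            sig2_c[lv] = max(0.0, (sigma2_raw[(a, lv)] + sigma2_raw[(b, lv)]) / 4
                             + cov_hat / 2)
            dhat_c[lv] = (d_hat[(a, lv)] + d_hat[(b, lv)]) / 2
        pair_stab[(a, b)] = (stability(sig2_c, dhat_c),
                             statistics.mean(sig2_c.values()))
    return rho, pair_stab, gamma2


def naive_best_pair(pair_stab):
    """Minimizing pair under the documented (stability, variance, name) order."""
    return min(pair_stab, key=lambda p: (pair_stab[p][0], pair_stab[p][1], p))
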