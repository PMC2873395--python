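"""NormFinder-style variance decomposition, stability values and pair search."""

import numpy as np
import pandas as pd
import pytest

from cqnorm.cq_data import SampleSheet
from cqnorm.errors import ValidationError
from cqnorm.normfinder import best_pair, normfinder_rank
from cqnorm.preprocess import aggregate_replicates
from cqnorm.quantification import cq_to_rq
from cqnorm.synthetic_data import GenePlan, StudyConfig, simulate_study

from conftest import make_rq
from oracles import naive_best_pair, naive_normfinder


def sheet(groups: dict[str, str]) -> SampleSheet:
    return SampleSheet(pd.DataFrame({"sample_id": list(groups),
                                     "group": list(groups.values())}))


def balanced_sheet(n_per_group: int) -> SampleSheet:
    labels = {}
    for i in range(n_per_group):
        labels[f"S{i + 1}"] = "tumour"
        labels[f"S{n_per_group + i + 1}"] = "normal"
    return sheet(labels)


def rq_with_samples(gene_values: dict) -> tuple:
    rq = make_rq(gene_values)
    n = rq.values.shape[1]
    assert n % 2 == 0
    return rq, balanced_sheet(n // 2)


def simulate_rq(plans, seed, n=10):
    study = simulate_study(StudyConfig(gene_plans=plans, n_tumour=n, n_normal=n,
                                       sample_shift_sd=0.5, replicate_sd=0.1,
                                       seed=seed))
    agg = aggregate_replicates(study.dataset)
    return cq_to_rq(agg, study.dataset.panel), study.dataset.samples


class TestNormfinderRank:
    def test_zero_noise_zero_shift_gives_zero_stability(self):
        plans = [GenePlan(f"g{i}", 24.0 + i, 0.0, 0.0) for i in range(4)]
        study = simulate_study(StudyConfig(gene_plans=plans, n_tumour=4,
                                           n_normal=4, sample_shift_sd=0.0,
                                           replicate_sd=0.0, seed=0))
        agg = aggregate_replicates(study.dataset)
        rq = cq_to_rq(agg, study.dataset.panel)
        res = normfinder_rank(rq, [p.assay_id for p in plans],
                              study.dataset.samples)
        assert res.gamma2 == 0.0
        assert res.table["rho"].abs().max() == pytest.approx(0.0, abs=1e-12)

    def test_gamma_zero_ranking_reduces_to_variance_ordering(self):
        # mirror each gene's values across the two groups: group means are
        # exactly equal, so gamma^2 clamps to 0, every rho collapses to 0,
        # and the ranking falls through to intra-group variance ordering
        rng = np.random.default_rng(0)
        half = 12
        values = {}
        for name, sd in (("quiet", 0.1), ("mid", 0.8), ("loud", 2.0),
                         ("extra", 0.4)):
            one_group = rng.normal(0, sd, half)
            values[name] = np.exp2(np.concatenate([one_group, one_group]))
        rq, samples = rq_with_samples(values)
        res = normfinder_rank(rq, sorted(values), samples)
        assert res.gamma2 == 0.0
        assert res.table["rho"].abs().max() == 0.0
        ranked = list(res.table["assay_id"])
        assert ranked[0] == "quiet" and ranked[-1] == "loud"

    def test_group_label_swap_leaves_stability_unchanged(self):
        plans = [GenePlan("a", 24.0, 1.0, 0.4), GenePlan("b", 26.0, 0.0, 0.3),
                 GenePlan("c", 28.0, -0.5, 0.6)]
        rq, samples = simulate_rq(plans, seed=2)
        res1 = normfinder_rank(rq, ["a", "b", "c"], samples)
        flipped = SampleSheet(samples.frame.assign(
            group=samples.frame["group"].map(
                {"tumour": "normal", "normal": "tumour"})))
        res2 = normfinder_rank(rq, ["a", "b", "c"], flipped)
        pd.testing.assert_series_equal(res1.table.set_index("assay_id")["rho"],
                                       res2.table.set_index("assay_id")["rho"])

    def test_rho_nondecreasing_in_intra_noise(self):
        means = []
        for noise in (0.2, 0.8, 1.6):
            rhos = []
            for seed in range(20):
                plans = [GenePlan("probe", 25.0, 0.0, noise),
                         GenePlan("r1", 24.0, 0.0, 0.3),
                         GenePlan("r2", 26.0, 0.0, 0.3),
                         GenePlan("r3", 27.0, 0.0, 0.3)]
                rq, samples = simulate_rq(plans, seed=seed)
                res = normfinder_rank(rq, [p.assay_id for p in plans], samples)
                rhos.append(res.table.set_index("assay_id")["rho"]["probe"])
            means.append(np.mean(rhos))
        assert means[0] < means[1] < means[2]

    def test_stability_invariant_to_per_gene_rescaling(self):
        rng = np.random.default_rng(5)
        values = {g: np.exp2(rng.normal(0, 0.5, 8)) for g in "abc"}
        rq1, samples = rq_with_samples(values)
        scaled = {g: v * (10 ** i) for i, (g, v) in enumerate(values.items())}
        rq2, _ = rq_with_samples(scaled)
        r1 = normfinder_rank(rq1, list("abc"), samples)
        r2 = normfinder_rank(rq2, list("abc"), samples)
        pd.testing.assert_series_equal(r1.table.set_index("assay_id")["rho"],
                                       r2.table.set_index("assay_id")["rho"])

    @pytest.mark.parametrize(
        "n_genes, message",
        [(2, "at least 3 genes"), (3, "fewer than 3 samples")],
    )
    def test_preconditions(self, n_genes, message):
        rng = np.random.default_rng(1)
        values = {f"g{i}": np.exp2(rng.normal(0, 0.3, 4))
                  for i in range(n_genes)}
        rq = make_rq(values)
        samples = balanced_sheet(2)
        with pytest.raises(ValidationError, match=message):
            normfinder_rank(rq, sorted(values), samples)


class TestBestPair:
    def test_duplicated_gene_pair_equals_single_gene_stability(self):
        rng = np.random.default_rng(4)
        series = np.exp2(rng.normal(0, 0.5, 10))
        values = {"a": series, "a2": series.copy(),
                  "b": np.exp2(rng.normal(0, 0.5, 10)),
                  "c": np.exp2(rng.normal(0, 1.0, 10))}
        rq, samples = rq_with_samples(values)
        res = normfinder_rank(rq, sorted(values), samples)
        rho_a = res.table.set_index("assay_id")["rho"]["a"]
        pair = res.pair_table.set_index(["gene_a", "gene_b"])
        assert pair.loc[("a", "a2"), "stability"] == pytest.approx(rho_a, abs=1e-12)

    def test_opposite_group_effects_pair_beats_either_gene(self):
        # genes with equal and opposite group shifts: composite cancels
        rng = np.random.default_rng(8)
        n = 20
        groups = np.array([1.0] * n + [0.0] * n)
        up = np.exp2(1.0 * groups + rng.normal(0, 0.3, 2 * n))
        down = np.exp2(-1.0 * groups + rng.normal(0, 0.3, 2 * n))
        flat1 = np.exp2(rng.normal(0, 0.3, 2 * n))
        flat2 = np.exp2(rng.normal(0, 0.3, 2 * n))
        rq, samples = rq_with_samples(
            {"up": up, "down": down, "flat1": flat1, "flat2": flat2})
        res = normfinder_rank(rq, ["up", "down", "flat1", "flat2"], samples)
        rho = res.table.set_index("assay_id")["rho"]
        pair = res.pair_table.set_index(["gene_a", "gene_b"])
        assert pair.loc[("down", "up"), "stability"] < min(rho["up"], rho["down"])

    @pytest.mark.parametrize("seed", range(4))
    def test_oracle_equivalence_small_panels(self, seed):
        rng = np.random.default_rng(200 + seed)
        n_genes = int(rng.integers(3, 7))
        n_per_group = int(rng.integers(3, 6))
        shifts = rng.normal(0, 0.5, n_genes)
        groups = np.array([1.0] * n_per_group + [0.0] * n_per_group)
        values = {
            f"g{i}": np.exp2(shifts[i] * groups
                             + rng.normal(0, rng.uniform(0.2, 1.0),
                                          2 * n_per_group))
            for i in range(n_genes)
        }
        rq = make_rq(values)
        samples = balanced_sheet(n_per_group)
        res = normfinder_rank(rq, sorted(values), samples)

        group_of = samples.groups.to_dict()
        log2rq = {g: {s: float(np.log2(rq.values.loc[g, s]))
                      for s in rq.values.columns} for g in values}
        rho_o, pairs_o, gamma2_o = naive_normfinder(log2rq, group_of)

        assert res.gamma2 == pytest.approx(gamma2_o, abs=1e-12)
        rho = res.table.set_index("assay_id")["rho"]
        for g, v in rho_o.items():
            assert rho[g] == pytest.approx(v, abs=1e-12)
        pair = res.pair_table.set_index(["gene_a", "gene_b"])
        for (a, b), (stab, _) in pairs_o.items():
            assert pair.loc[(a, b), "stability"] == pytest.approx(stab, abs=1e-12)
        assert res.best_pair == naive_best_pair(pairs_o)

    def test_best_pair_wrapper_matches_rank(self):
        plans = [GenePlan("a", 24.0, 0.0, 0.2), GenePlan("b", 26.0, 0.0, 0.25),
                 GenePlan("c", 28.0, 0.0, 1.5), GenePlan("d", 29.0, 1.2, 1.2)]
        rq, samples = simulate_rq(plans, seed=3)
        pair, stability = best_pair(rq, ["a", "b", "c", "d"], samples)
        res = normfinder_rank(rq, ["a", "b", "c", "d"], samples)
        assert pair == res.best_pair
        assert stability == res.pair_stability
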