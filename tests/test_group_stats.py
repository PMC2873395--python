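"""Differential pre-check, variance homogeneity, equivalence and normality tests."""

import numpy as np
import pandas as pd
import pytest

from cqnorm.errors import ValidationError
from cqnorm.group_stats import (
    differential_precheck,
    equivalence_bound,
    equivalence_test,
    log2_expression_from_aggregated,
    normality_check,
    variance_homogeneity,
)
from cqnorm.preprocess import aggregate_replicates
from cqnorm.synthetic_data import GenePlan, StudyConfig, simulate_study

from conftest import make_dataset


def agg_and_samples(cqs, **kw):
    ds = make_dataset(cqs, **kw)
    return aggregate_replicates(ds), ds.samples


def simulated(plans, seed, n_tumour=10, n_normal=10, **kw):
    study = simulate_study(StudyConfig(gene_plans=plans, n_tumour=n_tumour,
                                       n_normal=n_normal, seed=seed, **kw))
    return aggregate_replicates(study.dataset), study.dataset.samples


class TestDifferentialPrecheck:
    def test_identical_groups_give_t_zero_p_one(self):
        cqs = {}
        for i, v in enumerate([24.0, 25.0, 26.0]):
            cqs[(f"T{i}", "a")] = [v] * 2
            cqs[(f"N{i}", "a")] = [v] * 2
        agg, samples = agg_and_samples(cqs)
        out = differential_precheck(agg, samples)
        assert out["statistic"].iloc[0] == pytest.approx(0.0)
        assert out["p_value"].iloc[0] == pytest.approx(1.0)
        assert bool(out["nondifferential"].iloc[0])

    def test_planted_shift_detected_with_high_power(self):
        hits = 0
        for seed in range(25):
            agg, samples = simulated(
                [GenePlan("shifted", 25.0, 1.0, 0.5)], seed,
                n_tumour=35, n_normal=39,
                sample_shift_sd=0.0, replicate_sd=0.15)
            out = differential_precheck(agg, samples)
            hits += out["p_value"].iloc[0] < 0.05
        assert hits >= 24

    def test_small_group_skipped(self, caplog):
        cqs = {("T1", "a"): [24.0] * 2, ("N1", "a"): [25.0] * 2,
               ("N2", "a"): [25.5] * 2}
        agg, samples = agg_and_samples(cqs)
        with caplog.at_level("INFO"):
            out = differential_precheck(agg, samples)
        assert out.empty

    def test_log10_and_raw_transforms_both_available(self):
        agg, samples = simulated([GenePlan("a", 25.0, 0.5, 0.5)], seed=1)
        p_log = differential_precheck(agg, samples, transform="log10_cq")
        p_raw = differential_precheck(agg, samples, transform="cq")
        assert p_log["transform"].iloc[0] == "log10_cq"
        assert p_raw["transform"].iloc[0] == "cq"
        assert p_log["p_value"].iloc[0] != p_raw["p_value"].iloc[0]


class TestVarianceHomogeneity:
    def test_equal_variances_give_statistic_zero(self):
        cqs = {}
        for i, offset in enumerate([0.0, 1.0, 2.0]):
            for g in ("a", "b"):
                cqs[(f"S{i}", g)] = [24.0 + offset] * 2
        agg, _ = agg_and_samples(cqs)
        out = variance_homogeneity(agg)
        assert out["statistic"] == pytest.approx(0.0, abs=1e-12)
        assert out["p_value"] == pytest.approx(1.0)

    def test_textbook_three_group_instance_matches_hand_formula(self):
        # Bartlett's statistic computed from the closed form, independently
        groups = [np.array([24.1, 24.9, 25.3, 24.6]),
                  np.array([22.0, 26.0, 23.5, 27.1]),
                  np.array([25.0, 25.1, 25.05, 24.95])]
        k = len(groups)
        n_i = np.array([len(g) for g in groups])
        n = n_i.sum()
        s2_i = np.array([g.var(ddof=1) for g in groups])
        sp2 = ((n_i - 1) * s2_i).sum() / (n - k)
        stat = ((n - k) * np.log(sp2) - ((n_i - 1) * np.log(s2_i)).sum()) / (
            1 + (np.sum(1 / (n_i - 1)) - 1 / (n - k)) / (3 * (k - 1))
        )
        cqs = {}
        for gi, vals in enumerate(groups):
            for si, v in enumerate(vals):
                cqs[(f"S{si}", f"g{gi}")] = [float(v)] * 2
        agg, _ = agg_and_samples(cqs)
        out = variance_homogeneity(agg)
        assert out["statistic"] == pytest.approx(stat, rel=1e-10)

    def test_zero_variance_gene_raises(self):
        cqs = {("S1", "a"): [24.0] * 2, ("S2", "a"): [24.0] * 2,
               ("S1", "b"): [22.0] * 2, ("S2", "b"): [23.0] * 2}
        agg, _ = agg_and_samples(cqs)
        with pytest.raises(ValidationError, match="'a'"):
            variance_homogeneity(agg)

    def test_null_rejection_rate_near_alpha(self):
        # equal-variance genes: Bartlett should reject at roughly alpha
        rejections = 0
        n_seeds = 100
        for seed in range(n_seeds):
            plans = [GenePlan(f"g{i}", 24.0 + i, 0.0, 0.8) for i in range(4)]
            agg, _ = simulated(plans, seed, n_tumour=10, n_normal=10,
                               sample_shift_sd=0.0, replicate_sd=0.0)
            out = variance_homogeneity(agg)
            rejections += out["p_value"] < 0.05
        assert 0.0 <= rejections / n_seeds <= 0.12


class TestEquivalence:
    @pytest.mark.parametrize("cutoff, bound", [(2.0, 1.00), (3.0, 1.58)])
    def test_bounds_from_fold_change_cutoffs(self, cutoff, bound):
        assert round(equivalence_bound(cutoff), 2) == bound

    def test_cutoff_at_or_below_one_rejected(self):
        with pytest.raises(ValidationError):
            equivalence_bound(1.0)

    def test_ci_inside_bound_is_equivalent(self):
        rng = np.random.default_rng(0)
        cqs = {}
        for i in range(10):
            cqs[(f"T{i}", "a")] = [float(25 + rng.normal(0, 0.2))] * 2
            cqs[(f"N{i}", "a")] = [float(25 + rng.normal(0, 0.2))] * 2
        agg, samples = agg_and_samples(cqs)
        out = equivalence_test(log2_expression_from_aggregated(agg), samples)
        row = out.iloc[0]
        assert row.ci_low > -row.bound and row.ci_high < row.bound
        assert bool(row.equivalent)
        assert row.ci_low <= row.mean_log2_diff <= row.ci_high

    def test_large_shift_is_not_equivalent(self):
        cqs = {}
        rng = np.random.default_rng(1)
        for i in range(10):
            cqs[(f"T{i}", "a")] = [float(22 + rng.normal(0, 0.3))] * 2
            cqs[(f"N{i}", "a")] = [float(25 + rng.normal(0, 0.3))] * 2
        agg, samples = agg_and_samples(cqs)
        out = equivalence_test(log2_expression_from_aggregated(agg), samples)
        assert not bool(out["equivalent"].iloc[0])
        assert out["mean_log2_diff"].iloc[0] == pytest.approx(3.0, abs=0.5)

    def test_verdict_invariant_to_group_label_swap(self):
        agg, samples = simulated([GenePlan("a", 25.0, 0.4, 0.4),
                                  GenePlan("b", 27.0, 0.0, 0.3)], seed=4)
        out1 = equivalence_test(log2_expression_from_aggregated(agg), samples)
        out2 = equivalence_test(log2_expression_from_aggregated(agg), samples,
                                case_group="normal")
        assert list(out1["equivalent"]) == list(out2["equivalent"])
        assert out1["mean_log2_diff"].iloc[0] == pytest.approx(
            -out2["mean_log2_diff"].iloc[0]
        )

    def test_tighter_cutoff_or_wider_ci_only_removes_equivalence(self):
        agg, samples = simulated([GenePlan("a", 25.0, 0.3, 0.5)], seed=7,
                                 n_tumour=15, n_normal=15)
        expr = log2_expression_from_aggregated(agg)
        verdicts = {}
        for cutoff in (1.5, 2.0, 3.0):
            for level in (0.80, 0.90, 0.99):
                out = equivalence_test(expr, samples, fold_change_cutoff=cutoff,
                                       ci_level=level)
                verdicts[(cutoff, level)] = bool(out["equivalent"].iloc[0])
        for (cutoff, level), verdict in verdicts.items():
            # anything equivalent under a stricter setting stays equivalent
            # under a looser one
            if verdict:
                for c2, l2 in verdicts:
                    if c2 >= cutoff and l2 <= level:
                        assert verdicts[(c2, l2)]

    def test_paired_mode_uses_patient_matching(self):
        rows = []
        rng = np.random.default_rng(3)
        for i in range(8):
            patient_effect = rng.normal(0, 3.0)
            rows.append((f"T{i}", "tumour", f"P{i}", 25 + patient_effect))
            rows.append((f"N{i}", "normal", f"P{i}", 25.5 + patient_effect))
        from cqnorm.cq_data import SampleSheet

        samples = SampleSheet(pd.DataFrame(
            [(s, g, p) for s, g, p, _ in rows],
            columns=["sample_id", "group", "patient_id"]))
        expr = pd.DataFrame(
            [("a", s, -cq) for s, _, _, cq in rows],
            columns=["assay_id", "sample_id", "log2_value"])
        paired = equivalence_test(expr, samples, paired=True)
        unpaired = equivalence_test(expr, samples, paired=False)
        # pairing removes the large patient effect: far tighter CI
        width_paired = paired["ci_high"].iloc[0] - paired["ci_low"].iloc[0]
        width_unpaired = unpaired["ci_high"].iloc[0] - unpaired["ci_low"].iloc[0]
        assert width_paired < width_unpaired / 3
        assert paired["mean_log2_diff"].iloc[0] == pytest.approx(0.5, abs=1e-9)


class TestNormalityCheck:
    def test_normal_data_mostly_passes(self):
        passes = 0
        for seed in range(30):
            rng = np.random.default_rng(seed)
            cqs = {(f"S{i}", "a"): [float(v)] * 2
                   for i, v in enumerate(25 + rng.normal(0, 1, 40))}
            agg, _ = agg_and_samples(cqs)
            out = normality_check(agg)
            passes += bool(out["normal"].iloc[0])
        assert passes >= 27

    def test_heavy_tailed_data_flagged(self):
        flagged = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            values = 25 + rng.standard_t(df=1, size=200)
            cqs = {(f"S{i}", "a"): [float(v)] * 2
                   for i, v in enumerate(np.abs(values) + 1)}
            agg, _ = agg_and_samples(cqs)
            out = normality_check(agg)
            flagged += not bool(out["normal"].iloc[0])
        assert flagged >= 19

    def test_constant_values_flagged_not_tested(self):
        cqs = {(f"S{i}", "a"): [25.0] * 2 for i in range(6)}
        agg, _ = agg_and_samples(cqs)
        out = normality_check(agg)
        assert out["status"].iloc[0] == "degenerate_constant"
        assert np.isnan(out["p_value"].iloc[0])

    def test_too_few_values_skipped(self):
        cqs = {(f"S{i}", "a"): [25.0 + i] * 2 for i in range(3)}
        agg, _ = agg_and_samples(cqs)
        out = normality_check(agg)
        assert out["status"].iloc[0] == "skipped_too_few"
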