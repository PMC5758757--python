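"""ROC machinery, cross-validation, DE baseline and bootstrap comparison."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hridaya.core import EnsembleConfig
from hridaya.evaluation import (
    ExpressionStudy,
    bootstrap_compare,
    compare_potentials_to_set,
    cross_validate_two_stage,
    differential_expression_scores,
    per_feature_auc,
    roc_auc,
)
from hridaya.io import FeatureTable, GeneSets, make_potential_table
from hridaya.simulate import SimulationConfig, gen_expression_study, gen_feature_table


def _pair_count_auc(scores, labels):
    """Brute-force oracle: wins + half-ties over positive x negative pairs."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_ranking(self):
        assert roc_auc([3, 4, 1, 2], [1, 1, 0, 0]) == 1.0

    def test_all_ties_give_half(self):
        assert roc_auc([1, 1, 1, 1], [1, 0, 1, 0]) == 0.5

    def test_worked_pair_example(self):
        # positives {0.9, 0.4}, negatives {0.5, 0.1}: 3 of 4 pairs won
        assert roc_auc([0.9, 0.4, 0.5, 0.1], [1, 1, 0, 0]) == 0.75

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1, 2], [1, 1])

    def test_flip_symmetry_and_mwu_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(1000):
            n = int(rng.integers(4, 30))
            scores = rng.choice([0.1, 0.25, 0.5, 0.9], size=n)  # force ties
            labels = np.r_[1, 0, rng.integers(0, 2, n - 2)]
            a = roc_auc(scores, labels)
            assert a + roc_auc(scores, 1 - labels) == pytest.approx(1.0)
            assert a == pytest.approx(_pair_count_auc(scores, labels))
            u = stats.mannwhitneyu(
                scores[labels == 1], scores[labels == 0], alternative="two-sided"
            ).statistic
            assert a == pytest.approx(u / (labels.sum() * (n - labels.sum())))


class TestCrossValidation:
    @pytest.fixture(scope="class")
    def planted(self):
        cfg = SimulationConfig(
            seed=21, n_genes=400, n_features=40, n_disease_positives=50,
            n_dcm_positives=12, missing_rate=0.0,
        )
        table, sets, _ = gen_feature_table(cfg)
        return table, sets

    def test_planted_signal_recovered(self, planted, fast_config):
        table, sets = planted
        aucs = cross_validate_two_stage(table, sets, fast_config, n_repeats=3)
        assert aucs.mean() >= 0.85

    def test_determinism(self, planted, fast_config):
        table, sets = planted
        a = cross_validate_two_stage(table, sets, fast_config, n_repeats=1)
        b = cross_validate_two_stage(table, sets, fast_config, n_repeats=1)
        assert np.array_equal(a, b)

    def test_two_stage_beats_stage1_on_nested_signal(self, planted, fast_config):
        table, sets = planted
        both = cross_validate_two_stage(table, sets, fast_config, n_repeats=6)
        s1 = cross_validate_two_stage(table, sets, fast_config, n_repeats=6, stage="stage1")
        assert both.mean() > s1.mean()

    def test_pure_noise_is_calibrated(self, fast_config):
        cfg = SimulationConfig(
            seed=22, n_genes=300, n_features=20, n_disease_positives=40,
            n_dcm_positives=10, stage1_effect=0.0, stage2_effect=0.0, missing_rate=0.0,
        )
        table, sets, _ = gen_feature_table(cfg)
        aucs = cross_validate_two_stage(table, sets, fast_config, n_repeats=10)
        assert 0.4 < aucs.mean() < 0.6


class TestDifferentialExpression:
    @staticmethod
    def _study(case, ctrl, genes=("g1",)):
        case = np.atleast_2d(case).T if np.ndim(case) == 1 else case
        ctrl = np.atleast_2d(ctrl).T if np.ndim(ctrl) == 1 else ctrl
        X = np.vstack([case, ctrl])
        samples = [f"c{i}" for i in range(len(case))] + [f"n{i}" for i in range(len(ctrl))]
        expr = pd.DataFrame(X, index=samples, columns=list(genes))
        cond = pd.Series(["case"] * len(case) + ["control"] * len(ctrl), index=samples)
        return ExpressionStudy(expr, cond)

    def test_constant_gene_scores_zero(self):
        s = self._study([5.0, 5.0, 5.0], [5.0, 5.0, 5.0])
        out = differential_expression_scores(s)
        assert out.loc["g1", "score"] == 0.0
        assert out.loc["g1", "direction"] == "none"

    def test_exact_small_sample_p(self):
        # complete separation of 3 vs 3: exact two-sided rank-sum p = 0.1
        s = self._study([10.0, 11.0, 12.0], [1.0, 2.0, 3.0])
        out = differential_expression_scores(s)
        assert out.loc["g1", "p"] == pytest.approx(0.1)
        assert out.loc["g1", "score"] == pytest.approx(-np.log(0.1))
        assert out.loc["g1", "direction"] == "up"

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(0)
        case, ctrl = rng.normal(1, 1, 8), rng.normal(0, 1, 9)
        p1 = differential_expression_scores(self._study(case, ctrl)).loc["g1", "p"]
        p2 = differential_expression_scores(
            self._study(np.exp(case), np.exp(ctrl))
        ).loc["g1", "p"]
        assert p1 == pytest.approx(p2)


class TestBootstrapCompare:
    @pytest.fixture(scope="class")
    def scored_universe(self):
        rng = np.random.default_rng(6)
        genes = [f"g{i:03d}" for i in range(200)]
        positives = genes[:25]
        perfect = pd.Series(
            [1.0 if g in set(positives) else 0.0 for g in genes], index=genes
        )
        noise = pd.Series(rng.random(200), index=genes)
        return genes, positives, perfect, noise

    def test_identical_scores_share_resamples(self, scored_universe):
        genes, positives, perfect, _ = scored_universe
        res = bootstrap_compare(perfect, perfect.copy(), positives, genes, n_boot=10)
        assert np.array_equal(res["auc_a"], res["auc_b"])
        assert res["p"] == 1.0

    def test_perfect_beats_random(self, scored_universe):
        genes, positives, perfect, noise = scored_universe
        res = bootstrap_compare(perfect, noise, positives, genes, n_boot=50, seed=1)
        assert np.all(res["auc_a"] == 1.0)
        assert 0.3 < res["auc_b"].mean() < 0.7
        assert res["p"] < 0.01

    def test_ci_ordering_and_bounds(self, scored_universe):
        genes, positives, _, noise = scored_universe
        res = bootstrap_compare(noise, noise * 2, positives, genes, n_boot=30, seed=2)
        for key in ("ci_a", "ci_b"):
            lo, hi = res[key]
            assert 0 <= lo <= hi <= 1

    def test_too_few_bootstraps_rejected(self, scored_universe):
        genes, positives, perfect, noise = scored_universe
        with pytest.raises(ValueError):
            bootstrap_compare(perfect, noise, positives, genes, n_boot=1)


class TestPerFeatureAuc:
    def test_oracle_feature_scores_one_and_shape(self):
        rng = np.random.default_rng(13)
        genes = [f"g{i:03d}" for i in range(120)]
        disease, dcm = genes[:30], genes[:8]
        indicator = np.array([3.0 if g in set(dcm) else 0.0 for g in genes])
        stage1 = np.array([1.5 if g in set(disease) else 0.0 for g in genes])
        df = pd.DataFrame(
            {
                "genetic_oracle": indicator + 0.01 * rng.standard_normal(120),
                "genetic_stage1": stage1 + 0.01 * rng.standard_normal(120),
                "evolutionary_noise": rng.standard_normal(120),
            },
            index=genes,
        )
        table = FeatureTable(
            df,
            {"genetic_oracle": "genetic", "genetic_stage1": "genetic",
             "evolutionary_noise": "evolutionary"},
        )
        sets = GeneSets(frozenset(disease), frozenset(dcm), frozenset(genes))
        cfg = EnsembleConfig(n_iterations=5, base_classifier="logistic", seed=3)
        out = per_feature_auc(table, sets, cfg, n_repeats=2, inner_iterations=5)
        assert list(out.index) == list(table.feature_names)
        assert out.loc["genetic_oracle", "mean_auc"] > 0.95
        assert 0.3 < out.loc["evolutionary_noise", "mean_auc"] < 0.7


class TestComparePotentials:
    @pytest.fixture(scope="class")
    def potentials(self):
        rng = np.random.default_rng(14)
        genes = [f"g{i:03d}" for i in range(300)]
        return make_potential_table(
            pd.Series(rng.random(300), index=genes),
            pd.Series(rng.random(300), index=genes),
        )

    def test_top_genes_give_minimal_p(self, potentials):
        top = potentials.sort_values("rank").index[:20]
        assert compare_potentials_to_set(potentials, set(top)) < 1e-10

    def test_null_p_is_uniform(self, potentials):
        rng = np.random.default_rng(15)
        ps = [
            compare_potentials_to_set(
                potentials, set(rng.choice(potentials.index, 30, replace=False))
            )
            for _ in range(300)
        ]
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_excluded_genes_drop_from_both_sides(self, potentials):
        target = set(potentials.index[:20])
        excl = set(potentials.index[10:40])
        p_with = compare_potentials_to_set(potentials, target, exclude=excl)
        manual = stats.mannwhitneyu(
            potentials.loc[sorted(target - excl), "potential"],
            potentials.loc[[g for g in potentials.index if g not in target | excl],
                           "potential"],
            alternative="greater",
        ).pvalue
        assert p_with == pytest.approx(manual)

    def test_empty_target_after_exclusion_rejected(self, potentials):
        target = set(potentials.index[:5])
        with pytest.raises(ValueError):
            compare_potentials_to_set(potentials, target, exclude=target)
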