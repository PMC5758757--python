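"""eQTL scan, per-gene eSNP features, risk classification and GWAS maxima."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hridaya.esnp import (
    GenotypeMatrix,
    eqtl_scan,
    gene_esnp_features,
    max_gwas_chisq,
    risk_classify_cv,
)
from hridaya.evaluation import ExpressionStudy
from hridaya.simulate import SimulationConfig, gen_expression_study, gen_feature_table, gen_genotypes


def _toy_study(n=40, n_genes=3, seed=0):
    rng = np.random.default_rng(seed)
    samples = [f"s{i}" for i in range(n)]
    genes = [f"g{i}" for i in range(n_genes)]
    expr = pd.DataFrame(rng.standard_normal((n, n_genes)), index=samples, columns=genes)
    cond = pd.Series(["case"] * (n // 2) + ["control"] * (n - n // 2), index=samples)
    return ExpressionStudy(expr, cond)


def _toy_genotypes(n=40, n_snps=4, seed=1, chisq=None):
    rng = np.random.default_rng(seed)
    samples = [f"s{i}" for i in range(n)]
    snps = [f"rs{i}" for i in range(n_snps)]
    dos = pd.DataFrame(
        rng.binomial(2, 0.4, size=(n, n_snps)).astype(float), index=samples, columns=snps
    )
    return GenotypeMatrix(dos, chisq)


class TestEqtlScan:
    def test_exact_linear_relation(self):
        study = _toy_study()
        gm = _toy_genotypes()
        study.expression["g0"] = 2.0 * gm.dosages["rs0"]
        out = eqtl_scan(gm, study, [("rs0", "g0")])
        assert out.iloc[0]["slope"] == pytest.approx(2.0)
        assert out.iloc[0]["p"] < 1e-12

    def test_slope_matches_normal_equations(self):
        # oracle: scipy.stats.linregress on each pair
        study = _toy_study(seed=5)
        gm = _toy_genotypes(seed=6)
        pairs = [(s, g) for s in gm.snp_ids for g in study.expression.columns]
        out = eqtl_scan(gm, study, pairs).set_index(["snp", "gene"])
        for s, g in pairs:
            ref = stats.linregress(gm.dosages[s], study.expression[g])
            assert out.loc[(s, g), "slope"] == pytest.approx(ref.slope)
            assert out.loc[(s, g), "p"] == pytest.approx(ref.pvalue)

    def test_monomorphic_snp_skipped_with_warning(self):
        study = _toy_study()
        gm = _toy_genotypes()
        gm.dosages["rs1"] = 1.0
        with pytest.warns(RuntimeWarning, match="monomorphic"):
            out = eqtl_scan(gm, study, [("rs0", "g0"), ("rs1", "g1")])
        assert list(out["snp"]) == ["rs0"]

    def test_type_one_error_calibrated(self):
        # 1000 independent null pairs; rejection rate at p<0.05 near nominal
        rng = np.random.default_rng(9)
        n = 100
        samples = [f"s{i}" for i in range(n)]
        snps = [f"rs{i}" for i in range(1000)]
        dos = pd.DataFrame(
            rng.binomial(2, 0.3, (n, 1000)).astype(float), index=samples, columns=snps
        )
        expr = pd.DataFrame(
            rng.standard_normal((n, 1000)), index=samples,
            columns=[f"g{i}" for i in range(1000)],
        )
        cond = pd.Series(["case"] * 50 + ["control"] * 50, index=samples)
        study = ExpressionStudy(expr, cond)
        out = eqtl_scan(GenotypeMatrix(dos), study, [(f"rs{i}", f"g{i}") for i in range(1000)])
        rate = (out["p"] < 0.05).mean()
        assert 0.03 <= rate <= 0.07

    def test_bh_qvalues_monotone_in_p(self):
        study = _toy_study(seed=11)
        gm = _toy_genotypes(seed=12)
        pairs = [(s, g) for s in gm.snp_ids for g in study.expression.columns]
        out = eqtl_scan(gm, study, pairs).sort_values("p")
        assert (np.diff(out["q"]) >= -1e-12).all()
        assert out["q"].between(0, 1).all()


class TestGeneFeatures:
    @staticmethod
    def _eqtl_frame(entries):
        return pd.DataFrame(entries, columns=["snp", "gene", "slope", "t", "p", "q"])

    def test_single_esnp_column_equals_dosage(self):
        gm = _toy_genotypes()
        eqtl = self._eqtl_frame([("rs0", "gA", 1.0, 5.0, 1e-4, 0.01)])
        feats, dropped = gene_esnp_features(eqtl, gm, ["gA"])
        assert np.array_equal(feats["gA"].to_numpy(), gm.dosages["rs0"].to_numpy())
        assert dropped == []

    def test_mean_of_two_dosages(self):
        gm = _toy_genotypes()
        gm.dosages.iloc[0, 0] = 0.0
        gm.dosages.iloc[0, 1] = 2.0
        eqtl = self._eqtl_frame(
            [("rs0", "gA", 1, 5, 1e-4, 0.01), ("rs1", "gA", 1, 5, 1e-4, 0.02)]
        )
        feats, _ = gene_esnp_features(eqtl, gm, ["gA"])
        assert feats["gA"].iloc[0] == pytest.approx(1.0)

    def test_threshold_filter_matches_brute_force(self):
        rng = np.random.default_rng(3)
        gm = _toy_genotypes(n_snps=30, seed=4)
        qs = rng.uniform(0, 0.2, 30)
        eqtl = self._eqtl_frame(
            [(f"rs{i}", "gA", 1, 5, qs[i] / 2, qs[i]) for i in range(30)]
        )
        feats, _ = gene_esnp_features(eqtl, gm, ["gA"], fdr_threshold=0.1)
        keep = [f"rs{i}" for i in range(30) if qs[i] < 0.1]
        expected = gm.dosages[keep].mean(axis=1)
        assert np.allclose(feats["gA"], expected)
        # invariance to eSNP ordering
        feats2, _ = gene_esnp_features(eqtl.iloc[::-1], gm, ["gA"], fdr_threshold=0.1)
        assert np.allclose(feats["gA"], feats2["gA"])

    def test_gene_without_passing_esnp_dropped_and_reported(self):
        gm = _toy_genotypes()
        eqtl = self._eqtl_frame(
            [("rs0", "gA", 1, 5, 1e-4, 0.01), ("rs1", "gB", 1, 1, 0.5, 0.7)]
        )
        feats, dropped = gene_esnp_features(eqtl, gm, ["gA", "gB"])
        assert dropped == ["gB"] and list(feats.columns) == ["gA"]

    def test_no_passing_gene_errors(self):
        gm = _toy_genotypes()
        eqtl = self._eqtl_frame([("rs0", "gA", 1, 1, 0.5, 0.9)])
        with pytest.raises(ValueError):
            gene_esnp_features(eqtl, gm, ["gA"])


class TestRiskClassification:
    @pytest.fixture(scope="class")
    def mediated(self):
        cfg = SimulationConfig(
            seed=31, n_genes=200, n_features=20, n_disease_positives=30,
            n_dcm_positives=8, missing_rate=0.0, n_case=80, n_control=120,
            n_snps=120, eqtl_beta=0.8, h2=0.8,
        )
        _, sets, _ = gen_feature_table(cfg)
        study, _ = gen_expression_study(cfg, sets)
        causal = sorted(sets.dcm)
        decoy = sorted(sets.universe - sets.disease_functional)[:8]
        gm, study2, truth = gen_genotypes(cfg, study, causal, decoy)
        pairs = list(truth[["snp", "gene"]].itertuples(index=False, name=None))
        scan = eqtl_scan(gm, study2, pairs)
        return gm, study2, scan, causal, decoy

    def test_causal_features_beat_decoy_features(self, mediated):
        gm, study, scan, causal, decoy = mediated
        f_causal, _ = gene_esnp_features(scan, gm, causal)
        f_decoy, _ = gene_esnp_features(scan, gm, decoy)
        a = risk_classify_cv(f_causal, study.condition, n_repeats=20, seed=1,
                             classifier="logistic")
        b = risk_classify_cv(f_decoy, study.condition, n_repeats=20, seed=1,
                             classifier="logistic")
        p = stats.mannwhitneyu(a, b, alternative="greater").pvalue
        assert a.mean() > b.mean()
        assert p < 0.01

    def test_label_permutation_is_null(self, mediated):
        # average over many independent permutations: a single fixed
        # permutation keeps its chance feature correlations
        gm, study, scan, causal, _ = mediated
        feats, _ = gene_esnp_features(scan, gm, causal)
        rng = np.random.default_rng(2)
        means = []
        for rep in range(15):
            perm = pd.Series(
                rng.permutation(study.condition.to_numpy()), index=study.condition.index
            )
            aucs = risk_classify_cv(feats, perm, n_repeats=2, seed=rep,
                                    classifier="logistic")
            means.append(aucs.mean())
        assert 0.45 <= np.mean(means) <= 0.55

    def test_determinism(self, mediated):
        gm, study, scan, causal, _ = mediated
        feats, _ = gene_esnp_features(scan, gm, causal)
        a = risk_classify_cv(feats, study.condition, n_repeats=3, seed=5,
                             classifier="logistic")
        b = risk_classify_cv(feats, study.condition, n_repeats=3, seed=5,
                             classifier="logistic")
        assert np.array_equal(a, b)


class TestMaxGwasChisq:
    def test_group_max_and_missing(self):
        chisq = pd.Series({"rs0": 1.2, "rs1": 7.7, "rs2": 3.0})
        gm = _toy_genotypes(n_snps=3, chisq=chisq)
        eqtl = pd.DataFrame(
            {
                "snp": ["rs0", "rs1", "rs2"],
                "gene": ["gA", "gA", "gB"],
                "slope": 1.0, "t": 1.0,
                "p": [1e-4, 1e-4, 0.5],
                "q": [0.01, 0.02, 0.9],
            }
        )
        out = max_gwas_chisq(eqtl, gm)
        assert out["gA"] == pytest.approx(7.7)
        assert np.isnan(out["gB"])

    def test_matches_brute_force_on_random_instance(self):
        rng = np.random.default_rng(17)
        snps = [f"rs{i}" for i in range(40)]
        chisq = pd.Series(rng.chisquare(1, 40), index=snps)
        gm = _toy_genotypes(n_snps=40, chisq=chisq)
        eqtl = pd.DataFrame(
            {
                "snp": snps,
                "gene": [f"g{i % 6}" for i in range(40)],
                "slope": 1.0, "t": 1.0,
                "p": rng.uniform(0, 0.2, 40),
            }
        )
        eqtl["q"] = eqtl["p"] * 2
        out = max_gwas_chisq(eqtl, gm, fdr_threshold=0.1)
        for gene in eqtl["gene"].unique():
            members = eqtl[(eqtl["gene"] == gene) & (eqtl["q"] < 0.1)]["snp"]
            if len(members):
                assert out[gene] == pytest.approx(chisq[members].max())
            else:
                assert np.isnan(out[gene])
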