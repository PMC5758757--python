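"""eQTL discovery and eSNP-based case/control risk prediction.

The scan fits a simple additive model per (SNP, gene) pair — expression
regressed on dosage coded 0/1/2 — with Benjamini-Hochberg FDR control over
the whole tested family.  Per-gene genotype features (the mean dosage over a
gene's significant eSNPs) feed a cross-validated case/control classifier.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.calibration import CalibratedClassifierCV
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from statsmodels.stats.multitest import multipletests

from .evaluation import ExpressionStudy


@dataclass
class GenotypeMatrix:
    """Samples x SNPs dosage matrix with values in {0, 1, 2} (NaN = missing),
    plus an optional per-SNP GWAS chi-square vector."""

    dosages: pd.DataFrame
    chisq: pd.Series | None = None

    def __post_init__(self) -> None:
        vals = self.dosages.to_numpy(dtype=float)
        ok = np.isnan(vals) | np.isin(vals, (0.0, 1.0, 2.0))
        if not ok.all():
            raise ValueError("dosages must be 0, 1, 2 or missing")

    @property
    def sample_ids(self) -> pd.Index:
        return self.dosages.index

    @property
    def snp_ids(self) -> pd.Index:
        return self.dosages.columns

    def imputed(self) -> pd.DataFrame:
        """Dosages with missing entries mean-imputed per SNP."""
        return self.dosages.fillna(self.dosages.mean())


def eqtl_scan(
    genotypes: GenotypeMatrix, study: ExpressionStudy | pd.DataFrame, pairs
) -> pd.DataFrame:
    """Additive-model eQTL scan over a caller-supplied (snp, gene) family.

    For each pair, expression is regressed on dosage; the slope t-test
    p-value is recorded and Benjamini-Hochberg q-values are computed over
    the whole family.  Monomorphic SNPs are skipped with a warning.
    Missing dosages are mean-imputed per SNP before regression.  ``study``
    may be a full case/control study or a bare samples x genes expression
    matrix (e.g. a case-only cohort).
    """
    expression = study.expression if isinstance(study, ExpressionStudy) else study
    common = expression.index.intersection(genotypes.sample_ids)
    if len(common) < 10:
        raise ValueError("need at least 10 samples with both genotype and expression")
    expr = expression.loc[common]
    dos = genotypes.imputed().loc[common]

    rows = []
    skipped = []
    n = len(common)
    for snp, gene in pairs:
        x = dos[snp].to_numpy(dtype=float)
        if np.unique(x).size < 2:
            skipped.append(snp)
            continue
        y = expr[gene].to_numpy(dtype=float)
        xc = x - x.mean()
        yc = y - y.mean()
        sxx = float(xc @ xc)
        slope = float(xc @ yc) / sxx
        resid = yc - slope * xc
        dof = n - 2
        sigma2 = float(resid @ resid) / dof
        if sigma2 == 0:
            p = 0.0
            tstat = np.inf
        else:
            se = np.sqrt(sigma2 / sxx)
            tstat = slope / se
            p = 2.0 * stats.t.sf(abs(tstat), dof)
        rows.append({"snp": snp, "gene": gene, "slope": slope, "t": tstat, "p": p})
    if skipped:
        warnings.warn(f"skipped {len(skipped)} monomorphic SNP(s)", RuntimeWarning)
    if not rows:
        raise ValueError("no testable (snp, gene) pairs")
    out = pd.DataFrame(rows)
    out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    return out


def gene_esnp_features(
    eqtl: pd.DataFrame,
    genotypes: GenotypeMatrix,
    genes,
    fdr_threshold: float = 0.1,
) -> tuple[pd.DataFrame, list[str]]:
    """Per-gene eSNP genotype features.

    Cell (sample, gene) is the mean dosage of the sample over all eSNPs of
    the gene with q < ``fdr_threshold``.  Genes with no passing eSNP are
    reported in the second return value and dropped from the feature matrix.
    """
    genes = list(genes)
    if not genes:
        raise ValueError("gene list is empty")
    dos = genotypes.imputed()
    passing = eqtl[eqtl["q"] < fdr_threshold]
    cols = {}
    dropped = []
    for g in genes:
        snps = passing.loc[passing["gene"] == g, "snp"].tolist()
        if not snps:
            dropped.append(g)
            continue
        cols[g] = dos[snps].mean(axis=1)
    if not cols:
        raise ValueError("no gene has a passing eSNP at the given FDR threshold")
    return pd.DataFrame(cols), dropped


def risk_classify_cv(
    features: pd.DataFrame,
    labels: pd.Series,
    n_folds: int = 5,
    n_repeats: int = 100,
    seed: int = 0,
    classifier: str = "svm",
) -> np.ndarray:
    """Repeated stratified k-fold case/control classification.

    Per repeat, held-out probabilistic scores are pooled over folds and one
    AUC is computed; returns the vector of per-repeat AUCs.
    """
    y = labels.reindex(features.index)
    if y.isna().any():
        raise ValueError("labels missing for some samples")
    y = (y == "case").astype(int) if y.dtype == object else y.astype(int)
    yv = y.to_numpy()
    if yv.sum() < n_folds or (len(yv) - yv.sum()) < n_folds:
        raise ValueError("too few samples per class for the requested folds")
    X = features.to_numpy(dtype=float)

    root = np.random.SeedSequence(seed)
    aucs = np.empty(n_repeats)
    for rep, ss in enumerate(root.spawn(n_repeats)):
        fold_seed = int(ss.generate_state(1)[0] % (2**31))
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=fold_seed)
        pooled = np.empty(len(yv))
        for train_idx, test_idx in skf.split(X, yv):
            scaler = StandardScaler().fit(X[train_idx])
            Xtr = scaler.transform(X[train_idx])
            Xte = scaler.transform(X[test_idx])
            if classifier == "svm":
                clf = CalibratedClassifierCV(
                    SVC(kernel="rbf", C=1.0, gamma="scale", random_state=fold_seed),
                    method="sigmoid", cv=3, ensemble=False,
                )
            elif classifier == "logistic":
                clf = LogisticRegression(C=1.0, max_iter=2000)
            else:
                raise ValueError(f"unknown classifier {classifier!r}")
            clf.fit(Xtr, yv[train_idx])
            pooled[test_idx] = clf.predict_proba(Xte)[:, 1]
        aucs[rep] = roc_auc_score(yv, pooled)
    return aucs


def max_gwas_chisq(
    eqtl: pd.DataFrame, genotypes: GenotypeMatrix, fdr_threshold: float = 0.1
) -> pd.Series:
    """Per-gene maximum GWAS chi-square over its q < threshold eSNPs;
    genes with no passing eSNP are missing (NaN)."""
    if genotypes.chisq is None:
        raise ValueError("genotype matrix carries no per-SNP chi-square values")
    passing = eqtl[eqtl["q"] < fdr_threshold].copy()
    passing["chisq"] = genotypes.chisq.reindex(passing["snp"]).to_numpy()
    out = passing.groupby("gene")["chisq"].max()
    return out.reindex(sorted(eqtl["gene"].unique()))
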