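"""Patient stratification from molecular profiles of top-ranked genes.

Case patients are split into two subgroups by agglomerative clustering
(Ward linkage on Euclidean distances by default), phenotype differences
between the subgroups are tested (Fisher exact for binary phenotypes,
two-sided Wilcoxon rank-sum for continuous ones), and a two-component PCA
serves as a separation diagnostic.
"""

from __future__ import annotations

import string
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score
from statsmodels.stats.multitest import multipletests


@dataclass
class SubgroupResult:
    """Cluster labels, linkage record, silhouette and phenotype tests."""

    labels: pd.Series  # per-patient label "A", "B", ...
    linkage: np.ndarray
    silhouette: float
    tests: pd.DataFrame | None = None


def cluster_patients(
    matrix: pd.DataFrame,
    k: int = 2,
    linkage: str = "ward",
    metric: str = "euclidean",
    zscore: bool = False,
) -> SubgroupResult:
    """Agglomerative clustering of patients into k subgroups.

    Label "A" is the smallest cluster (ties broken by the lexicographically
    smallest patient-id set), "B" the next, and so on.  A silhouette below
    0.2 triggers a warning that the split may not reflect real structure.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(matrix):
        raise ValueError("k exceeds the number of patients")
    X = matrix.to_numpy(dtype=float)
    if zscore:
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        X = (X - X.mean(axis=0)) / sd
    Z = scipy_linkage(X, method=linkage, metric=metric)
    raw = fcluster(Z, t=k, criterion="maxclust")
    clusters = sorted(
        ({i for i, r in zip(matrix.index, raw) if r == c} for c in np.unique(raw)),
        key=lambda s: (len(s), tuple(sorted(s))),
    )
    if len(clusters) != k or any(len(c) == 0 for c in clusters):
        raise ValueError("could not form the requested number of non-empty clusters")
    labels = pd.Series(index=matrix.index, dtype=object, name="subgroup")
    for letter, members in zip(string.ascii_uppercase, clusters):
        labels.loc[sorted(members)] = letter
    sil = float(silhouette_score(X, labels.to_numpy())) if k < len(matrix) else 0.0
    if sil < 0.2:
        warnings.warn(
            f"low silhouette ({sil:.2f}): subgroups may not reflect real structure",
            RuntimeWarning,
        )
    return SubgroupResult(labels=labels, linkage=Z, silhouette=sil)


def phenotype_association(
    labels: pd.Series, phenotypes: pd.DataFrame, phenotype_types: dict[str, str]
) -> pd.DataFrame:
    """Test each phenotype for a difference between the two subgroups.

    Binary phenotypes: Fisher exact test on the 2x2 table, with per-group
    percentages.  Continuous phenotypes: two-sided Wilcoxon rank-sum, with
    per-group medians and IQRs.  Constant phenotypes are reported as skipped.
    Benjamini-Hochberg q-values over the tested family accompany the raw p.
    """
    groups = sorted(labels.unique())
    if len(groups) != 2:
        raise ValueError("phenotype association requires exactly two subgroups")
    ga = labels.index[labels == groups[0]]
    gb = labels.index[labels == groups[1]]
    if len(ga) < 2 or len(gb) < 2:
        raise ValueError("each subgroup needs at least 2 patients")

    rows = []
    for col in phenotypes.columns:
        ptype = phenotype_types.get(col)
        if ptype not in ("binary", "continuous"):
            raise ValueError(f"phenotype {col!r} has no declared type")
        va = phenotypes.loc[ga, col].dropna()
        vb = phenotypes.loc[gb, col].dropna()
        vals = pd.concat([va, vb])
        if vals.nunique() <= 1:
            rows.append(
                {"phenotype": col, "test": "skipped", "statistic": np.nan,
                 "p": np.nan, "summary_A": "", "summary_B": "",
                 "reason": "constant across patients"}
            )
            continue
        if ptype == "binary":
            table = [
                [int((va == 1).sum()), int((va == 0).sum())],
                [int((vb == 1).sum()), int((vb == 0).sum())],
            ]
            odds, p = stats.fisher_exact(table, alternative="two-sided")
            rows.append(
                {"phenotype": col, "test": "fisher", "statistic": odds, "p": p,
                 "summary_A": f"{100 * va.mean():.1f}%",
                 "summary_B": f"{100 * vb.mean():.1f}%", "reason": ""}
            )
        else:
            res = stats.mannwhitneyu(va, vb, alternative="two-sided")
            iqr = lambda v: np.subtract(*np.percentile(v, [75, 25]))
            rows.append(
                {"phenotype": col, "test": "wilcoxon", "statistic": res.statistic,
                 "p": res.pvalue,
                 "summary_A": f"{va.median():.3g} (IQR {iqr(va):.3g})",
                 "summary_B": f"{vb.median():.3g} (IQR {iqr(vb):.3g})", "reason": ""}
            )
    out = pd.DataFrame(rows).set_index("phenotype")
    tested = out["p"].notna()
    out["q"] = np.nan
    if tested.any():
        out.loc[tested, "q"] = multipletests(out.loc[tested, "p"], method="fdr_bh")[1]
    return out


def pca_projection(expr: pd.DataFrame, gene_subset) -> tuple[pd.DataFrame, np.ndarray]:
    """First two principal components of column-centered expression over a
    gene subset; returns per-patient scores and explained-variance fractions."""
    genes = [g for g in gene_subset if g in expr.columns]
    if len(genes) < 2:
        raise ValueError("gene subset must contain at least 2 genes present in the matrix")
    if len(expr) < 3:
        raise ValueError("need at least 3 patients")
    X = expr[genes].to_numpy(dtype=float)
    if np.linalg.matrix_rank(X - X.mean(axis=0)) < 1:
        raise ValueError("expression matrix has no variation to project")
    pca = PCA(n_components=2)
    scores = pca.fit_transform(X)
    out = pd.DataFrame(scores, index=expr.index, columns=["PC1", "PC2"])
    return out, pca.explained_variance_ratio_


def stratify_by_esnp(features: pd.DataFrame, k: int = 2, **kwargs) -> SubgroupResult:
    """Cluster case patients on their per-gene eSNP genotype features
    (see :func:`hridaya.esnp.gene_esnp_features`)."""
    return cluster_patients(features, k=k, **kwargs)
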