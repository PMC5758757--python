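"""Evaluation machinery: cross-validation, ROC, bootstrap method comparison,
the differential-expression baseline, and per-feature predictive power."""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .core import EnsembleConfig, train_stage_ensemble
from .io import FeatureTable, GeneSets


@dataclass
class ExpressionStudy:
    """Samples x genes expression with case/control labels and phenotypes.

    ``phenotype_types`` declares every phenotype column as ``"binary"`` or
    ``"continuous"``; ``condition`` entries are ``"case"`` or ``"control"``.
    """

    expression: pd.DataFrame  # samples x genes
    condition: pd.Series  # "case" / "control" per sample
    phenotypes: pd.DataFrame | None = None
    phenotype_types: dict[str, str] | None = None

    def __post_init__(self) -> None:
        if not self.expression.index.equals(self.condition.index):
            self.condition = self.condition.reindex(self.expression.index)
        vc = self.condition.value_counts()
        if vc.get("case", 0) < 2 or vc.get("control", 0) < 2:
            raise ValueError("need at least 2 samples per condition")
        if self.phenotypes is not None:
            undeclared = [
                c for c in self.phenotypes.columns if c not in (self.phenotype_types or {})
            ]
            if undeclared:
                raise ValueError(f"phenotypes with no declared type: {undeclared}")

    @property
    def case_samples(self) -> pd.Index:
        return self.expression.index[self.condition == "case"]

    @property
    def control_samples(self) -> pd.Index:
        return self.expression.index[self.condition == "control"]


def roc_auc(scores, labels) -> float:
    """ROC-AUC: fraction of (positive, negative) pairs ranked correctly,
    ties counted half."""
    y = np.asarray(labels).astype(int)
    s = np.asarray(scores, dtype=float)
    if y.min() == y.max():
        raise ValueError("both classes must be present to compute an AUC")
    return float(roc_auc_score(y, s))


def cross_validate_two_stage(
    table: FeatureTable,
    sets: GeneSets,
    config: EnsembleConfig,
    n_folds: int = 5,
    n_repeats: int = 50,
    inner_iterations: int = 10,
    stage: str = "both",
) -> np.ndarray:
    """Repeated stratified k-fold cross-validation of the two-stage model.

    Folds are stratified over DCM positives versus the rest of the universe.
    In each fold both stages are trained on the training genes only (with
    ``inner_iterations`` balanced iterations each) and the held-out genes are
    scored by the product of the two stage probabilities; held-out scores are
    pooled over the folds of a repeat and a single AUC per repeat is returned.

    ``stage="stage1"`` is the single-stage ablation: held-out genes are
    scored by the disease-functional probability alone.
    """
    if stage not in ("both", "stage1"):
        raise ValueError("stage must be 'both' or 'stage1'")
    universe = np.array(sorted(sets.universe))
    is_dcm = np.isin(universe, sorted(sets.dcm))
    disease = set(sets.disease_functional)
    dcm = set(sets.dcm)
    sub = FeatureTable(table.values.loc[universe], dict(table.categories))

    root = np.random.SeedSequence(config.seed)
    aucs = np.empty(n_repeats)
    for rep, rep_ss in enumerate(root.spawn(n_repeats)):
        fold_seed = int(rep_ss.generate_state(1)[0] % (2**31))
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=fold_seed)
        pooled_scores = np.empty(len(universe))
        fold_streams = rep_ss.spawn(n_folds)
        for (train_idx, test_idx), fold_ss in zip(skf.split(universe, is_dcm), fold_streams):
            train_genes = set(universe[train_idx])
            s1_pos = disease & train_genes
            s1_pool = train_genes - disease
            s2_pos = dcm & train_genes
            s2_pool = (disease - dcm) & train_genes
            if len(s2_pos) < 2:
                raise ValueError("a fold retained fewer than 2 DCM positives")
            cfg = replace(config, n_iterations=inner_iterations)
            ss1, ss2 = fold_ss.spawn(2)
            m1 = train_stage_ensemble(sub, s1_pos, s1_pool, cfg, ss1)
            if stage == "both":
                m2 = train_stage_ensemble(sub, s2_pos, s2_pool, cfg, ss2)
                score = m1.aggregated.to_numpy() * m2.aggregated.to_numpy()
            else:
                score = m1.aggregated.to_numpy()
            pooled_scores[test_idx] = score[test_idx]
        aucs[rep] = roc_auc(pooled_scores, is_dcm)
    return aucs


def differential_expression_scores(study: ExpressionStudy) -> pd.DataFrame:
    """Per-gene differential-expression baseline.

    Two-sided Wilcoxon rank-sum test of case versus control per gene;
    score = -ln(p).  Direction (up/down in cases) is the sign of the
    case-minus-control median difference; constant genes get p = 1,
    score 0 and direction "none".
    """
    case = study.expression.loc[study.case_samples].to_numpy()
    ctrl = study.expression.loc[study.control_samples].to_numpy()
    genes = study.expression.columns
    res = stats.mannwhitneyu(case, ctrl, alternative="two-sided", axis=0)
    p = np.asarray(res.pvalue, dtype=float)
    med_diff = np.median(case, axis=0) - np.median(ctrl, axis=0)
    # a gene constant across all samples carries no rank information
    constant = study.expression.nunique(axis=0).to_numpy() == 1
    p = np.where(constant | np.isnan(p), 1.0, p)
    direction = np.where(med_diff > 0, "up", np.where(med_diff < 0, "down", "none"))
    direction = np.where(constant, "none", direction)
    return pd.DataFrame(
        {"p": p, "score": -np.log(p), "direction": direction}, index=genes
    )


def bootstrap_compare(
    scores_a: pd.Series,
    scores_b: pd.Series,
    positives,
    universe,
    n_boot: int = 100,
    seed: int = 0,
) -> dict:
    """Bootstrap AUC comparison of two gene-score vectors.

    Each bootstrap draw resamples the positive set with replacement; the
    negative set is the complement of the positive set in the universe, and
    duplicated positives contribute multiplicity to the pair counts.  Both
    score vectors are evaluated on the same resample, and the two AUC vectors
    are compared by a two-sided Wilcoxon rank-sum test.  95% percentile
    confidence intervals are reported for both methods.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    positives = sorted(set(positives))
    universe = sorted(set(universe))
    if not set(positives) <= set(universe):
        raise ValueError("positives must be contained in the universe")
    negatives = [g for g in universe if g not in set(positives)]
    rng = np.random.default_rng(seed)
    auc_a = np.empty(n_boot)
    auc_b = np.empty(n_boot)
    for i in range(n_boot):
        res_pos = rng.choice(positives, size=len(positives), replace=True)
        genes = np.concatenate([res_pos, negatives])
        labels = np.r_[np.ones(len(res_pos)), np.zeros(len(negatives))]
        auc_a[i] = roc_auc(scores_a.loc[genes].to_numpy(), labels)
        auc_b[i] = roc_auc(scores_b.loc[genes].to_numpy(), labels)
    if np.array_equal(auc_a, auc_b):
        p = 1.0
    else:
        p = float(stats.mannwhitneyu(auc_a, auc_b, alternative="two-sided").pvalue)
    ci = lambda v: tuple(np.percentile(v, [2.5, 97.5]))
    return {"auc_a": auc_a, "auc_b": auc_b, "p": p, "ci_a": ci(auc_a), "ci_b": ci(auc_b)}


def per_feature_auc(
    table: FeatureTable,
    sets: GeneSets,
    config: EnsembleConfig,
    n_repeats: int = 10,
    n_folds: int = 5,
    inner_iterations: int = 10,
) -> pd.DataFrame:
    """Mean cross-validated two-stage AUC using one feature at a time."""
    rows = {}
    for feat in table.feature_names:
        single = FeatureTable(table.values[[feat]].copy(), {feat: table.categories[feat]})
        aucs = cross_validate_two_stage(
            single, sets, config, n_folds=n_folds, n_repeats=n_repeats,
            inner_iterations=inner_iterations,
        )
        rows[feat] = {"mean_auc": aucs.mean(), "sd_auc": aucs.std(ddof=1)}
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "feature"
    return out


def compare_potentials_to_set(
    potentials: pd.DataFrame, target_set, exclude=()
) -> float:
    """One-sided Wilcoxon rank-sum p-value that the potentials of
    ``target_set`` exceed those of the remaining genes, after removing
    ``exclude`` (e.g. training gold-standard genes) from both sides."""
    excl = set(exclude)
    target = [g for g in set(target_set) if g in potentials.index and g not in excl]
    rest = [g for g in potentials.index if g not in set(target_set) and g not in excl]
    if not target or not rest:
        raise ValueError("target set or complement empty after exclusion")
    t = potentials.loc[target, "potential"].to_numpy()
    r = potentials.loc[rest, "potential"].to_numpy()
    return float(stats.mannwhitneyu(t, r, alternative="greater").pvalue)
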