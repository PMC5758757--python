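"""Core data containers and tabular I/O.

All on-disk formats are plain TSV (tab-separated, UTF-8, header row).
Gene and probe identifiers are opaque strings; no symbol normalization is
attempted.  Missing feature values are encoded as an empty cell or as
``NA`` (case-insensitive) on disk and as NaN in memory.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

FEATURE_CATEGORIES = frozenset(
    {"genetic", "epigenetic", "transcriptomic", "phenotypic", "evolutionary"}
)

#: Column order of a potential table on disk.
POTENTIAL_COLUMNS = ["gene", "p_disease", "p_dcm_given_disease", "potential", "rank"]

_NA_STRINGS = ["", "na", "NA", "Na", "nA", "NaN", "nan"]


@dataclass
class FeatureTable:
    """Entities (genes or probes) x named features, real-valued, NaN = missing.

    Parameters
    ----------
    values
        DataFrame indexed by entity id with one column per feature.
    categories
        Maps every feature name to one of :data:`FEATURE_CATEGORIES`
        (genetic, epigenetic, transcriptomic, phenotypic, evolutionary).
    """

    values: pd.DataFrame
    categories: dict[str, str]

    def __post_init__(self) -> None:
        idx = self.values.index
        if idx.has_duplicates:
            dupes = idx[idx.duplicated()].unique().tolist()
            raise ValueError(f"duplicate entity ids: {dupes}")
        cols = self.values.columns
        if cols.has_duplicates:
            dupes = cols[cols.duplicated()].unique().tolist()
            raise ValueError(f"duplicate feature names: {dupes}")
        for feat in cols:
            if feat not in self.categories:
                raise ValueError(f"feature {feat!r} has no declared category")
            cat = self.categories[feat]
            if cat not in FEATURE_CATEGORIES:
                raise ValueError(f"unknown category {cat!r} for feature {feat!r}")

    @property
    def entity_ids(self) -> pd.Index:
        return self.values.index

    @property
    def feature_names(self) -> pd.Index:
        return self.values.columns

    @property
    def missingness(self) -> pd.Series:
        """Fraction of missing values per feature."""
        return self.values.isna().mean()

    @property
    def n_missing(self) -> int:
        return int(self.values.isna().to_numpy().sum())

    def select_categories(self, keep: set[str]) -> "FeatureTable":
        """Restrict to features whose category is in ``keep``."""
        cols = [c for c in self.values.columns if self.categories[c] in keep]
        if not cols:
            raise ValueError(f"no features left after restricting to {sorted(keep)}")
        return FeatureTable(self.values[cols].copy(), {c: self.categories[c] for c in cols})

    def drop_categories(self, drop: set[str]) -> "FeatureTable":
        """Remove features whose category is in ``drop`` (e.g. mask ``genetic``
        features before eSNP-based risk prediction to avoid circularity)."""
        return self.select_categories(FEATURE_CATEGORIES - set(drop))


@dataclass(frozen=True)
class GeneSets:
    """Nested gold standards: DCM genes within disease-functional genes
    within the scored universe."""

    disease_functional: frozenset[str]
    dcm: frozenset[str]
    universe: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "disease_functional", frozenset(self.disease_functional))
        object.__setattr__(self, "dcm", frozenset(self.dcm))
        object.__setattr__(self, "universe", frozenset(self.universe))
        if not self.dcm <= self.disease_functional:
            raise ValueError("dcm set must be a subset of disease_functional")
        if not self.disease_functional <= self.universe:
            raise ValueError("disease_functional must be a subset of universe")
        if len(self.dcm) < 2:
            raise ValueError("need at least 2 DCM genes")
        n_neg = len(self.universe) - len(self.disease_functional)
        if n_neg < len(self.disease_functional):
            raise ValueError(
                "universe must contain at least as many non-disease genes as "
                "disease genes (required for balanced negative sampling)"
            )


def read_gene_list(path) -> list[str]:
    """Read a plain-text gene list, one id per line, ignoring blanks."""
    with open(path, encoding="utf-8") as fh:
        return [line.strip() for line in fh if line.strip()]


def write_gene_list(genes, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for g in genes:
            fh.write(f"{g}\n")


def read_feature_table(path, schema: dict[str, str]) -> FeatureTable:
    """Read a feature TSV (first column entity id, remaining columns features).

    ``schema`` maps each feature name to its category; a feature present in
    the file but absent from the schema is a hard error.
    """
    df = pd.read_csv(
        path, sep="\t", index_col=0, na_values=_NA_STRINGS, keep_default_na=False,
        float_precision="round_trip",
    )
    df = df.astype(float)
    df.index = df.index.astype(str)
    missing_schema = [c for c in df.columns if c not in schema]
    if missing_schema:
        raise ValueError(f"features missing from schema: {missing_schema}")
    return FeatureTable(df, {c: schema[c] for c in df.columns})


def write_feature_table(table: FeatureTable, path) -> None:
    # %.17g round-trips IEEE doubles exactly
    table.values.to_csv(
        path, sep="\t", na_rep="NA", index_label="entity", float_format="%.17g"
    )


def read_probe_gene_map(path) -> dict[str, str]:
    """Two-column TSV (probe, gene); every probe maps to exactly one gene."""
    df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    if df.shape[1] != 2:
        raise ValueError("probe-gene map must have exactly two columns")
    probes = df.iloc[:, 0]
    if probes.duplicated().any():
        raise ValueError(
            f"probes mapped more than once: {probes[probes.duplicated()].tolist()}"
        )
    return dict(zip(probes, df.iloc[:, 1]))


def impute_missing(
    table: FeatureTable,
    n_components: int = 5,
    max_iter: int = 200,
    tol: float = 1e-6,
    strategy: str = "lowrank",
) -> FeatureTable:
    """Fill missing feature values by alternating low-rank completion.

    Missing cells are initialized with column means; the centered matrix is
    then alternately approximated by its rank-``n_components`` truncated SVD
    and the missing cells refilled from the approximation, until the largest
    change in a refilled cell falls below ``tol`` or ``max_iter`` is reached.
    Observed cells are never altered.

    ``strategy='median'`` is a documented fallback that fills each missing
    cell with its feature median in a single pass.
    """
    X = table.values.to_numpy(dtype=float, copy=True)
    mask = np.isnan(X)
    if not mask.any():
        return FeatureTable(table.values.copy(), dict(table.categories))
    all_missing = mask.all(axis=0)
    if all_missing.any():
        bad = table.values.columns[all_missing].tolist()
        raise ValueError(f"features with all values missing: {bad}")

    if strategy == "median":
        med = np.nanmedian(X, axis=0)
        X[mask] = np.broadcast_to(med, X.shape)[mask]
        return FeatureTable(
            pd.DataFrame(X, index=table.values.index, columns=table.values.columns),
            dict(table.categories),
        )
    if strategy != "lowrank":
        raise ValueError(f"unknown imputation strategy {strategy!r}")

    n, p = X.shape
    if not (0 < n_components < min(n, p)):
        raise ValueError("n_components must be in (0, min(n_entities, n_features))")

    col_means = np.nanmean(X, axis=0)
    X[mask] = np.broadcast_to(col_means, X.shape)[mask]
    converged = False
    for _ in range(max_iter):
        mu = X.mean(axis=0)
        Xc = X - mu
        U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
        approx = (U[:, :n_components] * s[:n_components]) @ Vt[:n_components] + mu
        delta = np.abs(approx[mask] - X[mask]).max()
        X[mask] = approx[mask]
        if delta < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"imputation did not converge within {max_iter} iterations", RuntimeWarning
        )
    return FeatureTable(
        pd.DataFrame(X, index=table.values.index, columns=table.values.columns),
        dict(table.categories),
    )


def rank_potentials(df: pd.DataFrame) -> pd.DataFrame:
    """Assign ranks 1..n by descending potential, ties broken by ascending
    gene id; returns a copy with the ``rank`` column (re)computed."""
    out = df.copy()
    # stable sort over an id-sorted frame => ties broken by ascending gene id
    order = out.loc[sorted(out.index)].sort_values(
        by="potential", ascending=False, kind="mergesort"
    )
    out.loc[order.index, "rank"] = np.arange(1, len(out) + 1)
    out["rank"] = out["rank"].astype(int)
    return out


def make_potential_table(p_disease: pd.Series, p_dcm_given_disease: pd.Series) -> pd.DataFrame:
    """Combine the two stage probabilities into a ranked potential table.

    The potential is the product of the two probabilities; ranks are by
    descending potential with ascending-gene-id tie-break.
    """
    if not p_disease.index.equals(p_dcm_given_disease.index):
        p_dcm_given_disease = p_dcm_given_disease.reindex(p_disease.index)
    for name, s in (("p_disease", p_disease), ("p_dcm_given_disease", p_dcm_given_disease)):
        arr = s.to_numpy(dtype=float)
        if np.isnan(arr).any() or (arr < 0).any() or (arr > 1).any():
            raise ValueError(f"{name} must lie in [0, 1]")
    df = pd.DataFrame(
        {
            "p_disease": p_disease.astype(float),
            "p_dcm_given_disease": p_dcm_given_disease.astype(float),
        }
    )
    df["potential"] = df["p_disease"] * df["p_dcm_given_disease"]
    df["rank"] = 0
    df.index.name = "gene"
    return rank_potentials(df)


def validate_potential_table(df: pd.DataFrame, atol: float = 1e-9) -> None:
    """Check the potential-table invariants (product identity, rank permutation)."""
    prod = df["p_disease"] * df["p_dcm_given_disease"]
    if not np.allclose(prod, df["potential"], atol=atol):
        raise ValueError("potential column is not the product of the stage probabilities")
    ranks = np.sort(df["rank"].to_numpy())
    if not np.array_equal(ranks, np.arange(1, len(df) + 1)):
        raise ValueError("rank column is not a permutation of 1..n")


def read_potential_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"gene": str}).set_index("gene")
    missing = [c for c in POTENTIAL_COLUMNS[1:] if c not in df.columns]
    if missing:
        raise ValueError(f"potential table missing columns: {missing}")
    return df[POTENTIAL_COLUMNS[1:]]


def write_potential_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index_label="gene", float_format="%.17g")


def aggregate_probes_to_genes(
    potentials: pd.DataFrame, probe_gene_map: dict[str, str]
) -> pd.DataFrame:
    """Collapse a probe-level potential table to gene level.

    For each gene the retained row is the probe with the maximum potential;
    both stage probabilities are carried over from that same probe, and ranks
    are recomputed at gene level.
    """
    unmapped = [p for p in potentials.index if p not in probe_gene_map]
    if unmapped:
        raise ValueError(f"probes missing from probe-gene map: {unmapped}")
    df = potentials.copy()
    df["_gene"] = [probe_gene_map[p] for p in df.index]
    # stable idxmax: sort by probe id first so ties resolve to the smallest probe
    df = df.loc[sorted(df.index)]
    best = df.groupby("_gene")["potential"].idxmax()
    out = df.loc[best.to_numpy(), ["p_disease", "p_dcm_given_disease", "potential"]]
    out.index = pd.Index(best.index, name="gene")
    out = out.sort_index()
    out["rank"] = 0
    return rank_potentials(out)
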