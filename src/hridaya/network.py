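"""Interaction-network proximity of differentially expressed genes to
top-ranked versus bottom-ranked genes, with a co-expression-matched null.

Edges carry a confidence weight in [0, 1]; a stringency threshold keeps
edges at or above the cutoff before any path analysis.  Shortest paths are
unweighted breadth-first distances.
"""

from __future__ import annotations

import warnings

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats


def load_edge_list(path) -> nx.Graph:
    """Read a (geneA, geneB, weight) TSV into an undirected weighted graph;
    self-loops are dropped."""
    df = pd.read_csv(path, sep="\t", header=0, dtype={0: str, 1: str})
    g = nx.Graph()
    for a, b, w in df.itertuples(index=False):
        if a == b:
            continue
        g.add_edge(str(a), str(b), weight=float(w))
    return g


def threshold_network(net: nx.Graph, stringency: float) -> nx.Graph:
    """Subgraph of edges with confidence >= stringency; isolated nodes dropped."""
    if not (0 <= stringency <= 1):
        raise ValueError("stringency must lie in [0, 1]")
    kept = [
        (u, v, d) for u, v, d in net.edges(data=True) if d.get("weight", 1.0) >= stringency
    ]
    if not kept:
        raise ValueError(f"no edges survive stringency {stringency}")
    out = nx.Graph()
    out.add_edges_from(kept)
    return out


def shortest_path_stats(net: nx.Graph, source_set, target_set) -> pd.DataFrame:
    """Per-source mean and minimum BFS distance to the target set.

    Unreachable targets are excluded from the mean and counted in the
    ``n_unreachable`` column; a source that reaches no target at all is
    excluded from the table with a warning.
    """
    targets = [t for t in set(target_set) if t in net]
    if not targets:
        raise ValueError("target set has no nodes in the network")
    sources = sorted(s for s in set(source_set) if s in net)
    rows = {}
    excluded = []
    for s in sources:
        dist = nx.single_source_shortest_path_length(net, s)
        d = np.array([dist[t] for t in targets if t in dist], dtype=float)
        if d.size == 0:
            excluded.append(s)
            continue
        rows[s] = {
            "mean_dist": d.mean(),
            "min_dist": d.min(),
            "n_unreachable": len(targets) - d.size,
        }
    if excluded:
        warnings.warn(
            f"{len(excluded)} source gene(s) reach no target and were excluded",
            RuntimeWarning,
        )
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "gene"
    return out


def matched_background_sample(
    fg_corr: pd.Series,
    pool_corr: pd.Series,
    n_sample: int = 1000,
    n_bins: int = 20,
    rng: np.random.Generator | None = None,
) -> list[str]:
    """Sample background genes whose co-expression summary matches the
    foreground distribution.

    Foreground summaries are binned into ``n_bins`` equal-width bins over
    their range; per-bin quotas proportional to the foreground counts
    (largest-remainder rounding to exactly ``n_sample``) are drawn from the
    pool without replacement.  A non-empty foreground bin whose pool bin
    cannot fill the quota is an error.
    """
    if rng is None:
        rng = np.random.default_rng()
    fg = fg_corr.to_numpy(dtype=float)
    lo, hi = fg.min(), fg.max()
    if hi == lo:
        hi = lo + 1e-12
    edges = np.linspace(lo, hi, n_bins + 1)
    fg_bin = np.clip(np.digitize(fg, edges) - 1, 0, n_bins - 1)
    counts = np.bincount(fg_bin, minlength=n_bins)

    exact = n_sample * counts / counts.sum()
    quota = np.floor(exact).astype(int)
    remainder = exact - quota
    short = n_sample - quota.sum()
    # largest-remainder rounding; ties resolved by bin order
    for b in np.argsort(-remainder, kind="stable")[:short]:
        quota[b] += 1

    pool_vals = pool_corr.to_numpy(dtype=float)
    pool_bin = np.clip(np.digitize(pool_vals, edges) - 1, 0, n_bins - 1)
    in_range = (pool_vals >= lo) & (pool_vals <= hi)
    chosen: list[str] = []
    pool_ids = np.array(pool_corr.index)
    for b in range(n_bins):
        if quota[b] == 0:
            continue
        cand = pool_ids[(pool_bin == b) & in_range]
        if len(cand) < quota[b]:
            raise ValueError(
                f"bin {b} [{edges[b]:.3f}, {edges[b+1]:.3f}] needs {quota[b]} "
                f"pool genes but only {len(cand)} available"
            )
        chosen.extend(rng.choice(np.sort(cand), size=quota[b], replace=False).tolist())
    return chosen


def correlation_summary(
    expression: pd.DataFrame, genes, functional_genes, how: str = "max"
) -> pd.Series:
    """Per-gene summary of Spearman correlation with the functional-gene set.

    ``how="max"`` (default) is the maximum absolute correlation — the
    conservative confound summary; ``how="mean"`` averages the absolute
    correlations instead.
    """
    genes = [g for g in genes if g in expression.columns]
    fn = [g for g in functional_genes if g in expression.columns]
    if not genes or not fn:
        raise ValueError("empty gene or functional-gene list after restriction")
    ranks = expression[list(dict.fromkeys(genes + fn))].rank()
    corr = np.corrcoef(ranks.to_numpy(), rowvar=False)
    frame = pd.DataFrame(corr, index=ranks.columns, columns=ranks.columns)
    sub = frame.loc[genes, fn].abs()
    out = sub.max(axis=1) if how == "max" else sub.mean(axis=1)
    return out


def proximity_test(
    net: nx.Graph, top_set, comparison_set, query_set
) -> dict:
    """Are query genes closer to the top-ranked set than to a comparison set?

    Computes per-query mean/min BFS distances to both sets and compares the
    paired columns with two-sided Wilcoxon rank-sum tests.  Returns
    ``p_mean``, ``p_min`` and both distance tables.
    """
    d_top = shortest_path_stats(net, query_set, top_set)
    d_cmp = shortest_path_stats(net, query_set, comparison_set)
    common = d_top.index.intersection(d_cmp.index)
    if len(common) == 0:
        raise ValueError("no query gene reaches both sets")
    a, b = d_top.loc[common], d_cmp.loc[common]

    def _p(col):
        x, y = a[col].to_numpy(), b[col].to_numpy()
        if np.array_equal(x, y):
            return 1.0
        return float(stats.mannwhitneyu(x, y, alternative="two-sided").pvalue)

    return {
        "p_mean": _p("mean_dist"),
        "p_min": _p("min_dist"),
        "dist_top": d_top,
        "dist_comparison": d_cmp,
    }
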