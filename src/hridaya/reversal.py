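"""Drug-reversal candidate selection from count-based triplet experiments.

Each triplet holds RNA-seq count matrices for a cardiomyocyte cell line in
three states: naive, treated with a cardiotoxic (offending) drug, and
treated with the offending plus a mitigating drug.  A gene is a reversal
hit in a triplet when the offending drug perturbs it in the same direction
as DCM and the added mitigating drug leaves it unperturbed (or perturbed in
the opposite direction).  Genes hit in at least ``min_combinations``
triplets form the selected set.

The built-in differential-expression engine is a negative-binomial Wald
test with median-of-ratios library-size normalization and moment-estimated
tagwise dispersions shrunk toward a mean-dispersion trend; any precomputed
per-gene result table with the same columns can be substituted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

_PRIOR_DF = 10.0  # weight of the trended dispersion in the shrinkage average
_PSEUDO = 0.5  # pseudo-count for fold changes on zero means


@dataclass
class TripletExperiment:
    """(naive, offending, offending+mitigating) count matrices for one
    cell-line / drug-pair combination; genes x replicates, shared gene order."""

    cell_line: str
    offending: str
    mitigating: str
    counts_naive: pd.DataFrame
    counts_offending: pd.DataFrame
    counts_both: pd.DataFrame

    def __post_init__(self) -> None:
        genes = self.counts_naive.index
        for name in ("counts_offending", "counts_both"):
            other = getattr(self, name)
            if not other.index.equals(genes):
                raise ValueError(f"{name} gene list differs from counts_naive")
        for name in ("counts_naive", "counts_offending", "counts_both"):
            m = getattr(self, name)
            if m.shape[1] < 2:
                raise ValueError(f"{name} needs at least 2 replicates")

    @property
    def genes(self) -> pd.Index:
        return self.counts_naive.index


def _check_counts(df: pd.DataFrame, name: str) -> np.ndarray:
    arr = df.to_numpy(dtype=float)
    if (arr < 0).any() or not np.allclose(arr, np.round(arr)):
        raise ValueError(f"{name} must contain non-negative integer counts")
    return arr


def size_factors(counts: np.ndarray) -> np.ndarray:
    """Median-of-ratios scaling factors (geometric-mean reference); falls back
    to total-count scaling when too few genes are positive in every sample."""
    with np.errstate(divide="ignore"):
        log_counts = np.log(counts)
    finite = np.isfinite(log_counts).all(axis=1)
    if finite.sum() >= 10:
        ref = log_counts[finite].mean(axis=1)
        sf = np.exp(np.median(log_counts[finite] - ref[:, None], axis=0))
    else:
        totals = counts.sum(axis=0)
        sf = totals / np.exp(np.mean(np.log(totals)))
    return sf


def count_de_test(
    counts_a: pd.DataFrame, counts_b: pd.DataFrame, fdr_threshold: float = 0.1
) -> pd.DataFrame:
    """Negative-binomial differential-expression test between two count groups.

    Counts are normalized by median-of-ratios size factors computed over the
    combined matrix.  Per-gene dispersions are moment-estimated from the
    pooled within-group variability and shrunk toward a 1/mean trend; the
    log-fold-change z statistic is referred to a t distribution with the
    residual degrees of freedom.  Benjamini-Hochberg q-values give the
    up/down/ns call at ``fdr_threshold``.
    """
    if not counts_a.index.equals(counts_b.index):
        raise ValueError("count matrices must share the same gene order")
    A = _check_counts(counts_a, "counts_a")
    B = _check_counts(counts_b, "counts_b")
    na, nb = A.shape[1], B.shape[1]
    if na < 2 or nb < 2:
        raise ValueError("need at least 2 replicates per group")

    sf = size_factors(np.hstack([A, B]))
    An = A / sf[:na]
    Bn = B / sf[na:]

    mu_a = An.mean(axis=1)
    mu_b = Bn.mean(axis=1)
    lfc = np.log2((mu_b + _PSEUDO) / (mu_a + _PSEUDO))

    # pooled within-group moment estimate of the NB dispersion phi:
    # Var = mu + phi mu^2  =>  phi = (s2 - mu) / mu^2
    dof = na + nb - 2
    ss = (An.var(axis=1, ddof=1) * (na - 1)) + (Bn.var(axis=1, ddof=1) * (nb - 1))
    s2 = ss / dof
    mu_bar = (mu_a * na + mu_b * nb) / (na + nb)
    with np.errstate(divide="ignore", invalid="ignore"):
        phi_raw = (s2 - mu_bar) / mu_bar**2
    phi_raw = np.where(np.isfinite(phi_raw), np.clip(phi_raw, 0.0, None), 0.0)

    # 1/mean dispersion trend fitted on expressed genes, then shrinkage
    expressed = mu_bar > 0
    if expressed.sum() >= 10:
        X = np.column_stack([np.ones(expressed.sum()), 1.0 / mu_bar[expressed]])
        coef, *_ = np.linalg.lstsq(X, phi_raw[expressed], rcond=None)
        phi_trend = np.clip(coef[0] + coef[1] / np.where(mu_bar > 0, mu_bar, 1.0), 1e-8, None)
    else:
        phi_trend = np.full_like(phi_raw, max(phi_raw.mean(), 1e-8))
    phi = (dof * phi_raw + _PRIOR_DF * phi_trend) / (dof + _PRIOR_DF)

    # delta-method variance of the log mean difference under NB sampling;
    # dispersion shrinkage adds prior information, so the reference is a
    # moderated t with residual + prior degrees of freedom
    with np.errstate(divide="ignore", invalid="ignore"):
        var_log = (1.0 / (mu_a + _PSEUDO) + phi) / na + (1.0 / (mu_b + _PSEUDO) + phi) / nb
    z = (np.log(mu_b + _PSEUDO) - np.log(mu_a + _PSEUDO)) / np.sqrt(var_log)
    p = 2.0 * stats.t.sf(np.abs(z), dof + _PRIOR_DF)

    allzero = (mu_a == 0) & (mu_b == 0)
    p = np.where(allzero, 1.0, p)
    lfc = np.where(allzero, 0.0, lfc)

    q = multipletests(p, method="fdr_bh")[1]
    call = np.where(q < fdr_threshold, np.where(lfc > 0, "up", "down"), "ns")
    call = np.where(allzero, "ns", call)
    return pd.DataFrame(
        {"lfc": lfc, "p": p, "q": q, "call": call}, index=counts_a.index
    )


_OPPOSITE = {"up": "down", "down": "up"}


def reversal_select(
    triplets: list[TripletExperiment],
    dcm_direction: pd.Series,
    min_combinations: int = 2,
    fdr_threshold: float = 0.1,
    de_results: list[tuple[pd.DataFrame, pd.DataFrame]] | None = None,
) -> tuple[pd.Series, set[str]]:
    """Count reversal hits per gene across triplets and select candidates.

    A gene scores a hit in a triplet iff its naive-vs-offending call is
    significant, equals its DCM direction, and its naive-vs-both call is
    either not significant or significant in the opposite direction.
    ``de_results`` may supply precomputed (offending, both) DE tables per
    triplet in place of the built-in engine.  Returns the per-gene occurrence
    count and the set of genes with occurrence >= ``min_combinations``.
    """
    if not triplets:
        raise ValueError("no triplets supplied")
    genes = triplets[0].genes
    for t in triplets[1:]:
        if not t.genes.equals(genes):
            raise ValueError("triplet gene lists are inconsistent")
    missing = [g for g in genes if g not in dcm_direction.index]
    if missing:
        raise ValueError(f"dcm_direction missing genes: {missing[:5]}")

    occurrence = pd.Series(0, index=genes, dtype=int, name="occurrence")
    for i, t in enumerate(triplets):
        if de_results is not None:
            de_off, de_both = de_results[i]
        else:
            de_off = count_de_test(t.counts_naive, t.counts_offending, fdr_threshold)
            de_both = count_de_test(t.counts_naive, t.counts_both, fdr_threshold)
        off_call = de_off["call"]
        both_call = de_both["call"]
        dirs = dcm_direction.loc[genes]
        concordant = (off_call != "ns") & (off_call == dirs)
        reversed_ = (both_call == "ns") | (
            both_call == off_call.map(_OPPOSITE).fillna("")
        )
        occurrence += (concordant & reversed_).astype(int)
    selected = set(occurrence.index[occurrence >= min_combinations])
    return occurrence, selected


def upregulated_candidates(
    selected: set[str],
    dcm_direction: pd.Series,
    occurrence: pd.Series,
    potentials: pd.DataFrame,
) -> pd.DataFrame:
    """Restrict the selected set to DCM-upregulated genes and rank them.

    Joined with the potential table and sorted by potential rank (ascending),
    then by occurrence (descending).
    """
    up = [g for g in sorted(selected) if dcm_direction.get(g) == "up"]
    if not up:
        return pd.DataFrame(columns=["occurrence", "potential", "rank"])
    out = pd.DataFrame(
        {
            "occurrence": occurrence.loc[up],
            "potential": potentials["potential"].reindex(up),
            "rank": potentials["rank"].reindex(up),
        }
    )
    out.index.name = "gene"
    return out.sort_values(["rank", "occurrence"], ascending=[True, False])
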