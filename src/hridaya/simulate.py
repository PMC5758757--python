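"""Synthetic data with planted ground truth for every pipeline input.

The generators emulate the statistical structure of the real study inputs —
a gene x feature table with two nested planted positive classes, a
case/control expression study with a predominantly down-regulated
differential signal, Hardy-Weinberg genotypes with cis-eQTL effects feeding
a liability-threshold case model, an interaction network in which
differentially expressed genes are planted near functional genes,
negative-binomial drug-treatment count triplets with a reversal arm, and a
genotype-driven two-subgroup patient cohort.  All generators are pure
functions of the configuration (including its seed) and return
machine-readable truth alongside the data.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .esnp import GenotypeMatrix
from .evaluation import ExpressionStudy
from .io import FeatureTable, GeneSets
from .reversal import TripletExperiment

_CATEGORY_CYCLE = ["genetic", "epigenetic", "transcriptomic", "phenotypic", "evolutionary"]


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic study, with the shipped default conditions.

    Effects are planted on standardized scales (standard-deviation units for
    feature shifts and expression fold changes on the natural-log scale), so
    the acceptance behaviour is portable across problem sizes.
    """

    seed: int = 0

    # gene x feature table with two nested positive classes
    n_genes: int = 2000
    n_features: int = 60
    n_signal_stage1: int = 10  # features separating disease genes from the rest
    n_signal_stage2: int = 10  # disjoint features separating DCM genes from disease genes
    n_disease_positives: int = 100
    n_dcm_positives: int = 25
    stage1_effect: float = 1.5  # standardized mean shift on stage-1 features
    stage2_effect: float = 1.5
    missing_rate: float = 0.02

    # case/control expression study
    n_case: int = 77
    n_control: int = 136
    de_fraction: float = 0.3
    down_fraction: float = 0.76  # fraction of DE genes down-regulated in cases
    lfc_mean: float = 1.0
    lfc_sd: float = 0.2

    # genotypes / eQTL / liability model
    n_snps: int = 600
    esnps_per_gene: int = 3
    maf_low: float = 0.05
    maf_high: float = 0.5
    eqtl_beta: float = 0.5  # per-SNP effect on expression (R^2 ~ 0.1 at typical MAF)
    h2: float = 0.5  # liability heritability

    # interaction network
    network_nodes: int = 300
    edge_density: float = 0.02
    planting_distance: int = 1

    # drug-treatment count triplets
    nb_dispersion: float = 0.1
    n_triplets: int = 4
    n_replicates: int = 3
    count_mean_log: float = 4.0  # log-normal location of baseline counts
    count_mean_sd: float = 1.0  # log-normal scale of baseline counts
    drug_lfc: float = 2.0  # log2 fold change of the offending drug on planted genes
    reversal_fidelity: float = 1.0  # fraction of planted genes restored by the mitigating arm

    # patient subgroups
    subgroup_fraction: float = 32 / 77  # size of subgroup A among cases
    n_subgroup_genes: int = 20
    subgroup_freq_a: float = 0.1  # subgroup-SNP allele frequency in subgroup A
    subgroup_freq_b: float = 0.9
    subgroup_beta: float = 1.0  # genotype-to-expression effect for subgroup genes
    phenotype_shift: float = 1.5  # standardized shift of continuous phenotypes

    def __post_init__(self) -> None:
        if not (self.n_dcm_positives <= self.n_disease_positives <= self.n_genes):
            raise ValueError("need n_dcm <= n_disease <= n_genes")
        for name in ("missing_rate", "de_fraction", "down_fraction", "h2",
                     "reversal_fidelity", "subgroup_fraction"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must lie in [0, 1]")


def _rng(cfg: SimulationConfig, label: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((cfg.seed, label)))


def _gene_ids(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(n)]


def gen_feature_table(cfg: SimulationConfig) -> tuple[FeatureTable, GeneSets, dict]:
    """Gene x feature table with two nested planted positive classes.

    Background features are standard normal; disease positives are shifted
    by ``stage1_effect`` on the declared stage-1 feature subset and DCM
    positives additionally by ``stage2_effect`` on a disjoint stage-2 subset.
    Cells go missing completely at random at ``missing_rate``.
    """
    if cfg.n_signal_stage1 + cfg.n_signal_stage2 > cfg.n_features:
        raise ValueError("signal feature subsets exceed the feature count")
    rng = _rng(cfg, 1)
    genes = _gene_ids(cfg.n_genes)
    feats = [
        f"{_CATEGORY_CYCLE[j % 5]}_{j:03d}" for j in range(cfg.n_features)
    ]
    categories = {f: f.rsplit("_", 1)[0] for f in feats}
    s1_feats = feats[: cfg.n_signal_stage1]
    s2_feats = feats[cfg.n_signal_stage1 : cfg.n_signal_stage1 + cfg.n_signal_stage2]

    disease = sorted(rng.choice(genes, size=cfg.n_disease_positives, replace=False))
    dcm = sorted(rng.choice(disease, size=cfg.n_dcm_positives, replace=False))

    X = rng.standard_normal((cfg.n_genes, cfg.n_features))
    df = pd.DataFrame(X, index=genes, columns=feats)
    df.loc[disease, s1_feats] += cfg.stage1_effect
    df.loc[dcm, s2_feats] += cfg.stage2_effect
    if cfg.missing_rate > 0:
        mask = rng.random(df.shape) < cfg.missing_rate
        # keep at least one observed value per feature
        mask[:, mask.all(axis=0)] = False
        vals = df.to_numpy()
        vals[mask] = np.nan
        df = pd.DataFrame(vals, index=genes, columns=feats)

    table = FeatureTable(df, categories)
    sets = GeneSets(frozenset(disease), frozenset(dcm), frozenset(genes))
    truth = {
        "stage1_features": s1_feats,
        "stage2_features": s2_feats,
        "disease_genes": disease,
        "dcm_genes": dcm,
    }
    return table, sets, truth


def gen_expression_study(
    cfg: SimulationConfig, sets: GeneSets
) -> tuple[ExpressionStudy, pd.DataFrame]:
    """Case/control expression with a planted differential signal.

    Expression is Gaussian on the log scale.  Differentially expressed genes
    are drawn preferentially from the planted functional genes (all DCM genes
    are differential; remaining slots favour disease genes 3:1 over
    background), with fold-change magnitudes |N(lfc_mean, lfc_sd)| and the
    down-in-case direction drawn at ``down_fraction``.  The phenotype table
    carries two latent case subgroups shifting two continuous phenotypes
    (LVEDD/LVESD-like remodeling measures) and one binary drug phenotype,
    plus one null phenotype of each type.
    """
    rng = _rng(cfg, 2)
    genes = sorted(sets.universe)
    n_genes = len(genes)
    samples = [f"CASE{i:04d}" for i in range(cfg.n_case)] + [
        f"CTRL{i:04d}" for i in range(cfg.n_control)
    ]
    condition = pd.Series(
        ["case"] * cfg.n_case + ["control"] * cfg.n_control, index=samples, name="condition"
    )

    n_de = int(round(cfg.de_fraction * n_genes))
    dcm = sorted(sets.dcm)
    weights = np.ones(n_genes)
    disease_idx = [i for i, g in enumerate(genes) if g in sets.disease_functional]
    weights[disease_idx] = 3.0
    dcm_idx = {i for i, g in enumerate(genes) if g in sets.dcm}
    de_idx = set(dcm_idx)
    remaining = [i for i in range(n_genes) if i not in de_idx]
    w = weights[remaining]
    extra = rng.choice(remaining, size=max(0, n_de - len(de_idx)), replace=False, p=w / w.sum())
    de_idx |= set(extra.tolist())
    de_idx = sorted(de_idx)

    lfc = np.zeros(n_genes)
    mags = np.abs(rng.normal(cfg.lfc_mean, cfg.lfc_sd, size=len(de_idx)))
    signs = np.where(rng.random(len(de_idx)) < cfg.down_fraction, -1.0, 1.0)
    lfc[de_idx] = mags * signs

    base = rng.normal(0.0, 1.0, size=n_genes)
    X = base + rng.standard_normal((len(samples), n_genes))
    X[: cfg.n_case] += lfc  # cases shifted by the planted log fold change
    expr = pd.DataFrame(X, index=samples, columns=genes)

    # latent case subgroups
    n_a = int(round(cfg.subgroup_fraction * cfg.n_case))
    sub = np.array(["B"] * cfg.n_case)
    sub[rng.choice(cfg.n_case, size=n_a, replace=False)] = "A"
    ph = pd.DataFrame(index=samples)
    shift = np.where(sub == "B", cfg.phenotype_shift, 0.0)
    lvedd = np.r_[rng.normal(6.0, 0.5, cfg.n_case) + 0.5 * shift, rng.normal(5.0, 0.5, cfg.n_control)]
    lvesd = np.r_[rng.normal(5.0, 0.5, cfg.n_case) + 0.5 * shift, rng.normal(3.5, 0.5, cfg.n_control)]
    ph["lvedd"] = lvedd
    ph["lvesd"] = lvesd
    p_drug = np.where(sub == "B", 0.7, 0.2)
    ph["milrinone"] = np.r_[
        (rng.random(cfg.n_case) < p_drug).astype(int), np.zeros(cfg.n_control, dtype=int)
    ]
    ph["age"] = rng.normal(55, 10, len(samples))
    ph["hypertension"] = rng.integers(0, 2, len(samples))
    types = {
        "lvedd": "continuous", "lvesd": "continuous", "milrinone": "binary",
        "age": "continuous", "hypertension": "binary",
    }
    study = ExpressionStudy(expr, condition, ph, types)

    truth = pd.DataFrame(
        {
            "lfc": lfc,
            "is_de": np.isin(np.arange(n_genes), de_idx),
            "direction": np.where(lfc > 0, "up", np.where(lfc < 0, "down", "none")),
        },
        index=genes,
    )
    truth.attrs["case_subgroup"] = pd.Series(sub, index=samples[: cfg.n_case])
    return study, truth


def gen_genotypes(
    cfg: SimulationConfig,
    study: ExpressionStudy,
    causal_genes,
    decoy_genes=(),
) -> tuple[GenotypeMatrix, ExpressionStudy, pd.DataFrame]:
    """Hardy-Weinberg genotypes with planted cis-eQTLs and a liability model.

    Each causal or decoy gene receives ``esnps_per_gene`` eSNPs whose dosage
    adds ``eqtl_beta`` per allele to the gene's expression; the remaining
    SNPs are null and are paired with random non-eQTL genes so the scan
    family has a true-negative stratum.  Case liability is the sum of
    causal-gene expression plus Gaussian noise scaled so the genetic share
    of liability variance equals ``h2``; samples above the case-fraction
    liability quantile are relabelled cases.  Per-SNP GWAS chi-squares are
    Cochran-Armitage trend statistics computed from the generated data.

    Returns the genotype matrix, a new study with the eQTL effects added and
    liability-derived labels, and the truth table of tested pairs.
    """
    rng = _rng(cfg, 3)
    samples = study.expression.index
    n = len(samples)
    causal = sorted(set(causal_genes))
    decoy = sorted(set(decoy_genes))
    egenes = causal + decoy
    n_esnps = len(egenes) * cfg.esnps_per_gene
    if n_esnps > cfg.n_snps:
        raise ValueError("n_snps too small for the requested eQTL genes")

    snps = [f"rs{i:06d}" for i in range(cfg.n_snps)]
    maf = rng.uniform(cfg.maf_low, cfg.maf_high, cfg.n_snps)
    dos = rng.binomial(2, maf, size=(n, cfg.n_snps)).astype(float)
    dosages = pd.DataFrame(dos, index=samples, columns=snps)

    expr = study.expression.copy()
    pairs = []
    k = 0
    for g in egenes:
        for _ in range(cfg.esnps_per_gene):
            snp = snps[k]
            expr[g] = expr[g] + cfg.eqtl_beta * dosages[snp]
            pairs.append({"snp": snp, "gene": g, "is_eqtl": True, "causal": g in set(causal)})
            k += 1
    non_egenes = [g for g in expr.columns if g not in set(egenes)]
    null_genes = rng.choice(non_egenes, size=cfg.n_snps - k, replace=True)
    for snp, g in zip(snps[k:], null_genes):
        pairs.append({"snp": snp, "gene": g, "is_eqtl": False, "causal": False})
    truth = pd.DataFrame(pairs)

    genetic = expr[causal].sum(axis=1).to_numpy()
    g_var = genetic.var()
    noise_sd = np.sqrt(g_var * (1 - cfg.h2) / cfg.h2) if cfg.h2 > 0 else np.inf
    liability = genetic + rng.normal(0.0, noise_sd, n)
    case_frac = (study.condition == "case").mean()
    cut = np.quantile(liability, 1 - case_frac)
    condition = pd.Series(
        np.where(liability > cut, "case", "control"), index=samples, name="condition"
    )

    y = (condition == "case").astype(float).to_numpy()
    chis = []
    for snp in snps:
        x = dosages[snp].to_numpy()
        r = np.corrcoef(x, y)[0, 1]
        chis.append(n * r * r if np.isfinite(r) else 0.0)
    chisq = pd.Series(chis, index=snps, name="chisq")

    new_study = ExpressionStudy(expr, condition, None, None)
    return GenotypeMatrix(dosages, chisq), new_study, truth


def gen_network(
    cfg: SimulationConfig,
    functional_genes,
    query_genes,
    other_genes=(),
    plant: bool = True,
) -> tuple[nx.Graph, dict]:
    """Random interaction network, optionally planting query genes within
    ``planting_distance`` hops of the functional genes.

    The background is an Erdos-Renyi graph at ``edge_density`` with edge
    confidences uniform on [0.2, 1.0); planted edges carry confidences in
    [0.85, 1.0) so they survive stringency sweeps.
    """
    rng = _rng(cfg, 4)
    functional = sorted(set(functional_genes))
    query = sorted(set(query_genes))
    nodes = sorted(set(functional) | set(query) | set(other_genes))
    n_extra = cfg.network_nodes - len(nodes)
    if n_extra > 0:
        nodes += [f"BG{i:05d}" for i in range(n_extra)]
    nodes = sorted(nodes)

    g = nx.gnp_random_graph(
        len(nodes), cfg.edge_density, seed=int(rng.integers(2**31))
    )
    net = nx.relabel_nodes(g, dict(enumerate(nodes)))
    for u, v in net.edges:
        net.edges[u, v]["weight"] = float(rng.uniform(0.2, 1.0))

    planted_edges = []
    if plant:
        background = [x for x in nodes if x not in set(functional) and x not in set(query)]
        for q in query:
            target = functional[int(rng.integers(len(functional)))]
            chain = [q]
            for _ in range(cfg.planting_distance - 1):
                chain.append(background[int(rng.integers(len(background)))])
            chain.append(target)
            for a, b in zip(chain, chain[1:]):
                net.add_edge(a, b, weight=float(rng.uniform(0.85, 1.0)))
                planted_edges.append((a, b))
    net.remove_edges_from(nx.selfloop_edges(net))
    return net, {"nodes": nodes, "planted_edges": planted_edges}


def _nb_counts(rng, mean: np.ndarray, dispersion: float, size) -> np.ndarray:
    """Negative-binomial draws parameterized by mean and dispersion phi
    (Var = mu + phi mu^2)."""
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, np.broadcast_to(p, size))


def gen_triplets(
    cfg: SimulationConfig, dcm_direction: pd.Series, planted_genes
) -> tuple[list[TripletExperiment], dict]:
    """Drug-treatment count triplets with a planted concordant-and-reversed set.

    Baseline means are log-normal.  The offending drug multiplies each
    planted gene by 2**drug_lfc in its DCM direction; in the offending +
    mitigating arm a ``reversal_fidelity`` fraction of the planted genes
    return to baseline while the rest stay perturbed.  All other genes are
    null throughout.
    """
    rng = _rng(cfg, 5)
    genes = dcm_direction.index
    planted = [g for g in planted_genes if g in genes]
    if not planted:
        raise ValueError("no planted genes present in the gene list")
    base = np.exp(rng.normal(cfg.count_mean_log, cfg.count_mean_sd, size=len(genes)))
    sign = dcm_direction.loc[planted].map({"up": 1.0, "down": -1.0}).fillna(0.0).to_numpy()
    planted_pos = [genes.get_loc(g) for g in planted]

    triplets = []
    reverted_truth = {}
    shape = (len(genes), cfg.n_replicates)
    for t in range(cfg.n_triplets):
        off_mean = base.copy()
        off_mean[planted_pos] = base[planted_pos] * 2.0 ** (cfg.drug_lfc * sign)
        n_rev = int(round(cfg.reversal_fidelity * len(planted)))
        rev_idx = rng.choice(len(planted), size=n_rev, replace=False)
        both_mean = off_mean.copy()
        reverted = [planted[i] for i in sorted(rev_idx)]
        both_mean[[planted_pos[i] for i in rev_idx]] = base[[planted_pos[i] for i in rev_idx]]
        reverted_truth[t] = reverted

        cols = [f"rep{r}" for r in range(cfg.n_replicates)]
        mk = lambda mean: pd.DataFrame(
            _nb_counts(rng, mean[:, None], cfg.nb_dispersion, shape),
            index=genes, columns=cols,
        )
        triplets.append(
            TripletExperiment(
                cell_line=f"CL{t % 4}",
                offending=f"OFF{t}",
                mitigating=f"MIT{t}",
                counts_naive=mk(base),
                counts_offending=mk(off_mean),
                counts_both=mk(both_mean),
            )
        )
    truth = {"planted": planted, "reverted_per_triplet": reverted_truth}
    return triplets, truth


@dataclass
class StratifiedCohort:
    """Case-only cohort with genotype-driven expression subgroups."""

    expression: pd.DataFrame  # patients x genes
    genotypes: GenotypeMatrix
    phenotypes: pd.DataFrame
    phenotype_types: dict[str, str]
    subgroup: pd.Series  # truth labels "A"/"B"
    pairs: list[tuple[str, str]]  # (snp, gene) family for the eQTL scan
    subgroup_genes: list[str]


def gen_stratified_cohort(cfg: SimulationConfig) -> StratifiedCohort:
    """Case cohort whose expression subgroups are driven by genotype.

    Subgroup-tagging SNPs have allele frequency ``subgroup_freq_a`` in
    subgroup A and ``subgroup_freq_b`` in subgroup B; each subgroup gene's
    expression is ``subgroup_beta`` times the summed dosage of its SNPs plus
    unit noise, so expression-based and eSNP-based stratification should
    recover the same split.  Continuous remodeling phenotypes (LVEDD/LVESD
    analogues) are shifted by ``phenotype_shift`` in subgroup B and a binary
    drug phenotype differs in frequency; null phenotypes are included.
    """
    rng = _rng(cfg, 6)
    n = cfg.n_case
    patients = [f"CASE{i:04d}" for i in range(n)]
    n_a = int(round(cfg.subgroup_fraction * n))
    sub = np.array(["B"] * n)
    sub[rng.choice(n, size=n_a, replace=False)] = "A"
    subgroup = pd.Series(sub, index=patients, name="subgroup")

    sg_genes = [f"SG{i:04d}" for i in range(cfg.n_subgroup_genes)]
    null_genes = [f"NG{i:04d}" for i in range(cfg.n_subgroup_genes * 4)]
    genes = sg_genes + null_genes

    n_sg_snps = cfg.n_subgroup_genes * cfg.esnps_per_gene
    n_null_snps = max(cfg.n_snps - n_sg_snps, n_sg_snps)
    snps = [f"rs{i:06d}" for i in range(n_sg_snps + n_null_snps)]
    freq = np.where(sub == "A", cfg.subgroup_freq_a, cfg.subgroup_freq_b)
    dos = np.empty((n, len(snps)))
    for j in range(n_sg_snps):
        dos[:, j] = rng.binomial(2, freq)
    maf = rng.uniform(cfg.maf_low, cfg.maf_high, n_null_snps)
    dos[:, n_sg_snps:] = rng.binomial(2, maf, size=(n, n_null_snps))
    dosages = pd.DataFrame(dos, index=patients, columns=snps)

    expr = pd.DataFrame(
        rng.standard_normal((n, len(genes))), index=patients, columns=genes
    )
    pairs = []
    k = 0
    for g in sg_genes:
        for _ in range(cfg.esnps_per_gene):
            expr[g] = expr[g] + cfg.subgroup_beta * dosages[snps[k]]
            pairs.append((snps[k], g))
            k += 1
    null_assign = rng.choice(null_genes, size=n_null_snps, replace=True)
    for snp, g in zip(snps[n_sg_snps:], null_assign):
        pairs.append((snp, g))

    shift = np.where(sub == "B", cfg.phenotype_shift, 0.0)
    ph = pd.DataFrame(index=patients)
    ph["lvedd"] = rng.normal(6.0, 0.5, n) + 0.5 * shift
    ph["lvesd"] = rng.normal(5.0, 0.5, n) + 0.5 * shift
    ph["milrinone"] = (rng.random(n) < np.where(sub == "B", 0.7, 0.2)).astype(int)
    ph["age"] = rng.normal(55, 10, n)
    ph["hypertension"] = rng.integers(0, 2, n)
    types = {
        "lvedd": "continuous", "lvesd": "continuous", "milrinone": "binary",
        "age": "continuous", "hypertension": "binary",
    }
    return StratifiedCohort(
        expression=expr,
        genotypes=GenotypeMatrix(dosages),
        phenotypes=ph,
        phenotype_types=types,
        subgroup=subgroup,
        pairs=pairs,
        subgroup_genes=sg_genes,
    )
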