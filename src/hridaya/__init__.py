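"""Two-stage balanced-ensemble prioritization of DCM functional genes.

The package scores every gene's potential to be a functional gene of
idiopathic dilated cardiomyopathy (DCM) as the product of two calibrated
probabilities — disease-functional given all genes, and DCM given
disease-functional — each estimated by an ensemble of classifiers trained
on balanced subsamples of a heavily imbalanced gold standard.  Downstream
modules evaluate the ranking, predict case/control status from eSNP
genotypes, test interaction-network proximity, select drug-reversal
candidate genes from count triplets, and stratify patients into molecular
subgroups.
"""

from importlib import resources

from .core import (
    EnsembleConfig,
    StageModel,
    compute_hridaya_potential,
    run_two_stage,
    sample_balanced_negatives,
    stage_training_sets,
    train_stage_ensemble,
    trimmed_mean,
)
from .io import (
    FeatureTable,
    GeneSets,
    aggregate_probes_to_genes,
    impute_missing,
    make_potential_table,
    read_feature_table,
    read_gene_list,
    read_potential_table,
    read_probe_gene_map,
    write_feature_table,
    write_gene_list,
    write_potential_table,
)

__version__ = "0.1.0"


def load_replica_gene_sets() -> GeneSets:
    """Packaged synthetic replica of the training gold standards.

    The gene identifiers are synthetic; the lists replicate the sizes of the
    curated standards (3373 disease-linked genes of which 214 are DCM-linked)
    so that training-set bookkeeping can be exercised without the original
    data.  The universe is completed programmatically to 26804 genes, giving
    a 26590-gene stage-1 negative pool.
    """
    data = resources.files("hridaya") / "data"
    disease = (data / "replica_disease_genes.txt").read_text().split()
    dcm = (data / "replica_dcm_genes.txt").read_text().split()
    # 26804 = 214 DCM positives + 26590 non-DCM genes in the assayed genome;
    # the disease genes use a distinct HD prefix, so the filler never collides
    filler = {f"G{i:05d}" for i in range(26804 - len(disease))}
    universe = set(disease) | filler
    return GeneSets(frozenset(disease), frozenset(dcm), frozenset(universe))
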