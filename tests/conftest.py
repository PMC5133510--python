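import numpy as np
import pytest

from pathstep import (CohortConfig, build_gene_sets, compute_kinship,
                      drop_genotypes, simulate_catalog, simulate_pedigrees)
from pathstep.sets import PathwayDesign, build_synthetic_pathways


@pytest.fixture(scope="session")
def small_config():
    return CohortConfig(seed=42, n_families=6, n_genes=8)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    """Pedigree, kinship, catalog, genotypes and sets for a 102-person
    cohort — shared by the slower model-level tests."""
    cfg = small_config
    ped = simulate_pedigrees(cfg)
    kin = compute_kinship(ped)
    cat = simulate_catalog(cfg)
    gm = drop_genotypes(ped, cat, seed=cfg.seed)
    gene_sets = build_gene_sets(cat)
    pathways = build_synthetic_pathways(
        gene_sets, PathwayDesign(strata=[(5, 40, 1)]), seed=7)
    return {"config": cfg, "ped": ped, "kin": kin, "catalog": cat,
            "genotypes": gm, "gene_sets": gene_sets, "pathways": pathways}


def genedrop_ibd_phi(ped, n_drops, seed):
    """Independent Monte-Carlo kinship oracle.

    Drops distinct founder allele labels down the pedigree ``n_drops``
    times; the kinship coefficient is estimated as the probability that
    one random allele from i and one from j are identical by descent
    (averaged over the four allele pairings).
    """
    rng = np.random.default_rng(seed)
    idx = {m.iid: k for k, m in enumerate(ped.members)}
    alleles = np.empty((len(ped.members), n_drops, 2), dtype=np.int32)
    label = 0
    for k, m in enumerate(ped.members):
        if m.is_founder:
            alleles[k, :, 0] = label
            alleles[k, :, 1] = label + 1
            label += 2
        else:
            fa = alleles[idx[m.father]]
            mo = alleles[idx[m.mother]]
            rows = np.arange(n_drops)
            alleles[k, :, 0] = fa[rows, rng.integers(0, 2, n_drops)]
            alleles[k, :, 1] = mo[rows, rng.integers(0, 2, n_drops)]
    n = len(ped.members)
    phi = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            eq = 0.0
            for a in range(2):
                for b in range(2):
                    eq += np.mean(alleles[i, :, a] == alleles[j, :, b])
            phi[i, j] = phi[j, i] = eq / 4.0
    return phi
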