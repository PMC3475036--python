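"""Shared fixtures: small simulated crosses reused across test modules."""

import numpy as np
import pytest

import imprintqtl as iq


@pytest.fixture(scope="session")
def default_pedigree():
    return iq.simulate_pedigree(seed=0)


@pytest.fixture(scope="session")
def small_map():
    """Two chromosomes, 10 markers each, 5 cM spacing."""
    return iq.default_map(n_markers=20, n_chromosomes=2)


@pytest.fixture(scope="session")
def small_dataset(default_pedigree, small_map):
    """Pedigree + genotypes + one imprinted-QTL trait on chromosome 1."""
    ped = default_pedigree
    geno = iq.simulate_genotypes(ped, small_map, seed=1)
    specs = [
        iq.TraitSpec(
            "trait",
            grand_mean=10.0,
            qtls=[iq.QTLEffect(1, 20.0, i=0.8)],
            family_sd=0.5,
            residual_sd=1.0,
            sex_effect=1.0,
            cross_direction_effect=0.3,
        )
    ]
    pheno = iq.simulate_phenotypes(ped, geno, small_map, specs, seed=2)
    adjusted = iq.adjust_phenotypes(pheno)
    indices = iq.EffectIndexMatrix.from_ordered(geno)
    return {
        "pedigree": ped,
        "map": small_map,
        "genotypes": geno,
        "phenotypes": pheno,
        "adjusted": adjusted,
        "indices": indices,
    }


def balanced_classes(n_per_class: int):
    """Index scores for a perfectly balanced ordered-class sample."""
    cls = np.repeat(np.arange(4), n_per_class)
    x_a = np.array([1.0, 0.0, 0.0, -1.0])[cls]
    x_d = np.array([0.0, 1.0, 1.0, 0.0])[cls]
    x_i = np.array([0.0, 1.0, -1.0, 0.0])[cls]
    return cls, x_a, x_d, x_i
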