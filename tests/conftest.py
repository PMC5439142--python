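import numpy as np
import pytest

import gconnect as g


def random_pedigree_triples(rng, n_animals, n_founders=None):
    """Random multi-generation pedigree with inbreeding loops.

    Parents are drawn from earlier animals (or unknown), so ancestor loops and
    inbred matings arise naturally; ids are shuffled so ordering is exercised.
    """
    if n_founders is None:
        n_founders = max(4, n_animals // 5)
    triples = []
    for i in range(n_animals):
        if i < n_founders:
            s = d = 0
        else:
            s = rng.integers(1, i + 1) if rng.random() < 0.9 else 0
            d = rng.integers(1, i + 1) if rng.random() < 0.9 else 0
            if s == d:
                d = 0
        triples.append((str(i + 1), str(s), str(d)))
    perm = rng.permutation(len(triples))
    return [triples[k] for k in perm]


def fit_scenario(sc, extract_pev=True, relationship="A", blend_weight=1.0):
    """Simulate a scenario, fit the MME, return the working objects."""
    ped, rec = g.simulate_pedigree_and_records(sc)
    dm = g.build_design(rec, sc.model_spec(), ped)
    y = rec["y"].to_numpy(dtype=float)
    A_inv = g.build_A_inverse(ped)
    if relationship == "H":
        A = g.build_A(ped)
        geno = g.simulate_genotypes(ped, sc)
        gidx = ped.indices_of(geno.animal_ids)
        G = g.build_G(geno)
        A22 = g.subset_A22(A, gidx)
        Gb = g.blend_G(G, A22, blend_weight)
        K_inv = g.build_H_inverse(A_inv, A22, Gb, gidx)
    else:
        K_inv = A_inv
    fit = g.fit_mme(dm, K_inv, sc.vc, y, extract_pev_block=extract_pev)
    return ped, rec, dm, fit


@pytest.fixture
def trio():
    """Two unrelated founders and their offspring, in scrambled input order."""
    return g.order_pedigree([("3", "1", "2"), ("1", "0", "0"), ("2", "0", "0")])


@pytest.fixture
def rng():
    return np.random.default_rng(20170302)


@pytest.fixture(scope="session")
def small_multi_effect():
    """Small multi-flock herd with a factor and an uncentred covariate."""
    sc = g.SimScenario(
        n_cgs=4, offspring_per_cg=15, n_generations=2, link_sire_fraction=0.4,
        fixed_effects=g.FixedEffectSpec(factor_levels=(3,), n_covariates=1),
        seed=11)
    return sc, *fit_scenario(sc)


@pytest.fixture(scope="session")
def small_cg_only():
    """Small multi-flock herd with contemporary group as the only fixed effect."""
    sc = g.SimScenario(n_cgs=4, offspring_per_cg=15, n_generations=2,
                       link_sire_fraction=0.4, seed=7)
    return sc, *fit_scenario(sc)
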