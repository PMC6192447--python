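"""Shared fixtures: small simulated cohorts reused across test modules."""

import numpy as np
import pytest

import famvar as fv


@pytest.fixture(scope="session")
def small_pedigree() -> fv.Pedigree:
    """10 founder couples with exactly 2 offspring each (N = 40)."""
    return fv.simulate_pedigree(fv.PedigreeSpec(n_families=10, offspring_dist=2, seed=1))


@pytest.fixture(scope="session")
def family_cohort():
    """A mid-sized family cohort: pedigree, genotypes and matrices.

    60 families of 2 parents + 3 offspring (N = 300), 600 SNPs.
    """
    ped = fv.simulate_pedigree(fv.PedigreeSpec(n_families=60, offspring_dist=3, seed=7))
    geno = fv.simulate_genotypes(ped, 600, maf_low=0.1, seed=8)
    G = fv.compute_grm(geno)
    mats = {
        "G": G,
        "K": fv.threshold_grm(G),
        "F": fv.build_environment_matrix(ped, "family"),
        "S": fv.build_environment_matrix(ped, "sibling"),
        "C": fv.build_environment_matrix(ped, "couple"),
    }
    return ped, geno, mats


@pytest.fixture(scope="session")
def sib_design():
    """Balanced full-sib design: 200 sibships of size 2 with S-only structure."""
    rng = np.random.default_rng(42)
    a = 200
    fam = np.repeat(np.arange(a), 2)
    y = rng.normal(0, np.sqrt(0.4), a)[fam] + rng.normal(0, np.sqrt(0.6), 2 * a)
    S = np.zeros((2 * a, 2 * a))
    for i in range(a):
        S[2 * i : 2 * i + 2, 2 * i : 2 * i + 2] = 1.0
    ids = [f"i{k}" for k in range(2 * a)]
    return y, fv.RelationshipMatrix(S, ids, "S"), fam
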