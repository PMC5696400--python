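import numpy as np
import pandas as pd
import pytest

from hybzone.genotypes import GenotypeDataset, LocusDef, validate_metadata
from hybzone.hindex import AlleleFrequencyTable, HybridIndexEstimator
from hybzone.simulate import (
    CallModel,
    LocalitySpec,
    SimConfig,
    sim_class_batch,
    sim_parental_freqs,
    sim_zone,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20170923)


@pytest.fixture(scope="session")
def diagnostic_freqs():
    """Twelve fully diagnostic 2-allele loci, unsmoothed (alpha=0).

    Species A is fixed for the smaller allele at every locus, species B
    for the larger; informative enough that the ML hybrid index has a
    binomial closed form.
    """
    L = 12
    return AlleleFrequencyTable(
        locus_names=[f"L{j + 1:02d}" for j in range(L)],
        alleles=[np.array([100, 120])] * L,
        p_a=[np.array([1.0, 0.0])] * L,
        p_b=[np.array([0.0, 1.0])] * L,
        n_a=np.full(L, 1000),
        n_b=np.full(L, 1000),
        alpha=0.0,
    )


def diagnostic_genotype(k_a_copies: int, freqs: AlleleFrequencyTable):
    """Genotype with exactly ``k`` species-A allele copies out of 2L."""
    L = freqs.n_loci
    geno = np.full((L, 2), 120)
    flat = geno.ravel()
    flat[:k_a_copies] = 100
    return flat.reshape(L, 2)


@pytest.fixture(scope="session")
def small_zone():
    """A small but complete synthetic contact zone (fast, session-shared)."""
    layout = [
        LocalitySpec("A_allo1", "A", "allopatric", x=50, y=120, n=40),
        LocalitySpec("A_allo2", "A", "allopatric", x=300, y=150, n=40),
        LocalitySpec("B_allo1", "B", "allopatric", x=80, y=-130, n=30),
        LocalitySpec("B_allo2", "B", "allopatric", x=340, y=-110, n=30),
        LocalitySpec(
            "R1_A", "A", "sympatric", x=100, y=5, n=30, region="R1",
            class_mix={"pureA": 0.3, "pureB": 0.2, "F1": 0.3, "F2": 0.1,
                       "BxA": 0.05, "BxB": 0.05},
        ),
        LocalitySpec(
            "R1_B", "B", "sympatric", x=100, y=-5, n=30, region="R1",
            class_mix={"pureA": 0.2, "pureB": 0.4, "F1": 0.2, "F2": 0.1,
                       "BxA": 0.05, "BxB": 0.05},
        ),
        LocalitySpec(
            "R2_A", "A", "sympatric", x=250, y=5, n=30, region="R2",
            class_mix={"pureA": 0.6, "pureB": 0.3, "F1": 0.05, "F2": 0.05},
        ),
        LocalitySpec(
            "R2_B", "B", "sympatric", x=250, y=-5, n=30, region="R2",
            class_mix={"pureA": 0.3, "pureB": 0.6, "F1": 0.05, "F2": 0.05},
        ),
    ]
    return sim_zone(SimConfig(localities=layout), seed=101)


@pytest.fixture(scope="session")
def fitted_estimator(small_zone):
    ds = small_zone.dataset
    from hybzone.genotypes import pool_references

    refs = pool_references(
        ds,
        {"species": "A", "sympatry": "allopatric"},
        {"species": "B", "sympatry": "allopatric"},
    )
    est = HybridIndexEstimator()
    est.fit(refs, allele_universe=[ds.allele_universe(j) for j in range(ds.n_loci)])
    return est


@pytest.fixture
def toy_meta():
    return validate_metadata(
        pd.DataFrame(
            {
                "locality": ["a1", "a2", "b1", "s1"],
                "species": ["A", "A", "B", "A"],
                "region": [None, None, None, "R1"],
                "sympatry": ["allopatric", "allopatric", "allopatric", "sympatric"],
                "lat": [0.0, 1.0, 0.0, 2.0],
                "lon": [0.0, 0.0, 1.0, 2.0],
                "coord_system": ["lonlat"] * 4,
                "group": [None] * 4,
            }
        )
    )
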