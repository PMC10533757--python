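import numpy as np
import pytest

from shuttlegp.markers import GenomicRelationship
from shuttlegp.scenarios import StudyData
from shuttlegp.simulate import SimConfig, simulate_study


def random_relationship(n: int, n_snps: int, seed: int) -> GenomicRelationship:
    """A VanRaden-style G from random biallelic dosages (ridged, PD)."""
    rng = np.random.default_rng(seed)
    p = rng.uniform(0.1, 0.9, n_snps)
    X = rng.binomial(2, p, size=(n, n_snps)).astype(float)
    Z = X - X.mean(axis=0)
    pf = X.mean(axis=0) / 2.0
    G = Z @ Z.T / (2.0 * np.sum(pf * (1 - pf)))
    G += np.eye(n) * 1e-6 * np.mean(np.diag(G))
    ids = np.array([f"I{i:03d}" for i in range(n)], dtype=object)
    return GenomicRelationship(ids, G)


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    """Reduced two-trait study: one high-signal trait and one null trait."""
    return SimConfig(
        n_individuals_A=120, n_individuals_B=100, n_checks=20,
        n_snps=500, n_chromosomes=12,
        target_h2={"HI": 0.8, "NULL": 0.0},
        gxe_share={"HI": 0.3, "NULL": 0.0},
        loc_effects={"HI": {"PAL": 50.0, "SRO": 40.0},
                     "NULL": {"PAL": 10.0, "SRO": 12.0}},
        trait_scale={"HI": 1.0, "NULL": 1.0},
        seed=7,
    )


@pytest.fixture(scope="session")
def small_bundle(small_cfg):
    return simulate_study(small_cfg)


@pytest.fixture(scope="session")
def small_study(small_bundle) -> StudyData:
    return StudyData.from_bundle(small_bundle)
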