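"""Shared fixtures: tiny hand-built pedigrees/panels and one mid-size
simulated dataset reused by several test modules."""

import numpy as np
import pandas as pd
import pytest

from sswgwas import GenotypeSet, Pedigree, SimConfig, simulate_dataset


@pytest.fixture
def trio_pedigree() -> Pedigree:
    return Pedigree((("sire", "0", "0"), ("dam", "0", "0"), ("kid", "sire", "dam")))


@pytest.fixture
def fullsib_mating_pedigree() -> Pedigree:
    """Two founders, two full sibs, and the sibs' inbred offspring."""
    return Pedigree((
        ("f1", "0", "0"), ("f2", "0", "0"),
        ("s1", "f1", "f2"), ("s2", "f1", "f2"),
        ("x", "s1", "s2"),
    ))


def random_pedigree(n: int, seed: int, n_founders: int = 10) -> Pedigree:
    """Random valid pedigree: each non-founder picks two earlier animals."""
    rng = np.random.default_rng(seed)
    records = [(f"a{i}", "0", "0") for i in range(n_founders)]
    for i in range(n_founders, n):
        s, d = rng.choice(i, size=2, replace=False)
        records.append((f"a{i}", f"a{s}", f"a{d}"))
    return Pedigree(tuple(records))


def random_genotypes(n_animals: int, n_snps: int, seed: int,
                     maf_low: float = 0.1, maf_high: float = 0.5) -> GenotypeSet:
    """HWE genotypes at random frequencies, independent across loci."""
    rng = np.random.default_rng(seed)
    p = rng.uniform(maf_low, maf_high, n_snps)
    calls = (rng.random((n_animals, n_snps)) < p).astype(np.int16)
    calls += (rng.random((n_animals, n_snps)) < p).astype(np.int16)
    markers = pd.DataFrame({
        "snp_id": [f"m{i:04d}" for i in range(n_snps)],
        "chromosome": "1",
        "position_bp": np.arange(1, n_snps + 1) * 1000,
    })
    return GenotypeSet(animal_ids=[f"an{i}" for i in range(n_animals)],
                       markers=markers, calls=calls)


@pytest.fixture(scope="session")
def qtl_dataset() -> dict:
    """Mid-size simulated dataset with one 25 %-of-variance QTL."""
    cfg = SimConfig(seed=42, n_cows=300, n_dams=120, n_snps=600, n_chromosomes=3,
                    n_genotyped=300, n_qtl=1, qtl_variance_fractions=(0.25,))
    return simulate_dataset(cfg)
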