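import numpy as np
import pytest

from germcore import GeneratorConfig, GenotypeTable, generate_collection


def make_table(calls: dict[str, list[tuple[str, str] | None]], loci=None) -> GenotypeTable:
    """Build a small genotype table from {accession: [call, ...]}."""
    ids = list(calls)
    n_loci = len(next(iter(calls.values())))
    loci = loci or [f"LOC{l + 1}" for l in range(n_loci)]
    return GenotypeTable.from_calls(ids, loci, [calls[a] for a in ids])


def random_table(rng: np.random.Generator, n: int, n_loci: int, n_alleles: int,
                 missing_rate: float = 0.0) -> GenotypeTable:
    """Random fully independent genotype table for property tests."""
    ids = [f"A{i}" for i in range(n)]
    loci = [f"L{l}" for l in range(n_loci)]
    calls = []
    for _ in range(n):
        row = []
        for _ in range(n_loci):
            if missing_rate and rng.random() < missing_rate:
                row.append(None)
            else:
                a, b = rng.integers(n_alleles, size=2)
                row.append((f"x{a}", f"x{b}"))
        calls.append(row)
    return GenotypeTable.from_calls(ids, loci, calls)


def scaled_config(seed: int, **overrides) -> GeneratorConfig:
    """Reduced-scale study conditions for statistical tests."""
    params = dict(
        n_accessions=150, n_loci=12, mean_alleles_per_locus=10, clone_pairs=8,
        singleton_carrier_pool=15, n_haplotypes=6, n_traits=12, total_trait_classes=36,
        n_reference=5, seed=seed,
    )
    params.update(overrides)
    return GeneratorConfig(**params)


@pytest.fixture(scope="session")
def small_collection():
    """Reduced-scale synthetic collection shared across tests."""
    return generate_collection(scaled_config(42))


@pytest.fixture(scope="session")
def bank_collection():
    """Bank-scale synthetic collection (default study conditions)."""
    return generate_collection(GeneratorConfig(seed=7))
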