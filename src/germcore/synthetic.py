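"""Synthetic germplasm collections with known ground truth.

The generator emulates the statistical structure of a Mediterranean-style
clonal germplasm bank: several hundred accessions genotyped at a modest
number of highly multiallelic co-dominant loci, three partially admixed
gene pools with the central pool acting as a hybrid zone, a skewed plastid
haplotype distribution dominated by one haplotype, a sizeable fraction of
alleles observed exactly once, planted near-clone pairs, and a categorical
trait table with missing data.  Defaults reproduce the bank-scale
conditions the package's pipeline is designed for (~500 accessions,
17 loci, ~280 alleles, 12 haplotypes with one at ~83%, ~19% singleton
alleles, 72 traits / 213 classes).

Every draw flows from the config seed, so collections are bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .data import CollectionDataset, GenotypeTable, HaplotypeMap, TraitTable

__all__ = ["GeneratorConfig", "GroundTruth", "generate_collection",
           "generate_equilibrium_panel", "write_collection"]

_ZONES = ("West", "Center", "East")
_COUNTRIES = {
    "West": ("Morocco", "Spain", "Portugal"),
    "Center": ("Italy", "France", "Tunisia", "Algeria", "Greece"),
    "East": ("Syria", "Egypt", "Cyprus", "Lebanon"),
}


@dataclass
class GeneratorConfig:
    """Study-condition parameters of the synthetic germplasm bank."""

    n_accessions: int = 502
    n_loci: int = 17
    mean_alleles_per_locus: float = 16.4
    n_pools: int = 3
    #: drift parameter; between-pool differentiation (approx. Fst) grows with it
    divergence: float = 0.10
    #: Dirichlet concentration scale for individual ancestry draws
    admixture_alpha: float = 0.25
    #: fraction of the allele universe forced to single carriers
    singleton_rate: float = 0.19
    #: Dirichlet concentration of the base allele spectrum (smaller = more skewed)
    allele_evenness: float = 0.35
    #: singleton alleles are injected into carriers drawn from a random pool of
    #: this many accessions, mimicking the clustering of rare alleles on a few
    #: unusual genotypes (drives the common-set size of core families)
    singleton_carrier_pool: int = 30
    n_haplotypes: int = 12
    haplotype_freqs: tuple[float, ...] | None = None  # default: one dominant at 0.832
    n_traits: int = 72
    total_trait_classes: int = 213
    trait_missing_rate: float = 0.25
    #: planted near-duplicate pairs (1-3 allele edits apart)
    clone_pairs: int = 45
    n_reference: int = 14
    #: zone shares West / Center / East
    zone_weights: tuple[float, ...] = (0.28, 0.54, 0.18)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pools < 1:
            raise ValueError("n_pools must be >= 1")
        if self.mean_alleles_per_locus < 1 or self.total_trait_classes < self.n_traits:
            raise ValueError("infeasible allele or trait-class configuration")
        for rate in (self.divergence, self.singleton_rate, self.trait_missing_rate):
            if not 0 <= rate <= 1:
                raise ValueError("rates must lie in [0, 1]")
        if self.haplotype_freqs is not None:
            if abs(sum(self.haplotype_freqs) - 1.0) > 1e-9:
                raise ValueError("haplotype_freqs must sum to 1")
        if 2 * self.clone_pairs > self.n_accessions:
            raise ValueError("too many clone pairs for the collection size")

    def resolved_haplotype_freqs(self) -> np.ndarray:
        if self.haplotype_freqs is not None:
            return np.asarray(self.haplotype_freqs, dtype=float)
        rest = 0.7 ** np.arange(1, self.n_haplotypes)
        rest = (1.0 - 0.832) * rest / rest.sum()
        return np.concatenate([[0.832], rest])


@dataclass
class GroundTruth:
    """What the generator knows: the latent variables behind the dataset."""

    ancestry: np.ndarray  # (N, K) pool ancestry fractions
    pool: np.ndarray  # (N,) originating pool index
    clone_partner: dict[str, str]  # planted copy -> source accession
    singleton_carriers: dict[str, list[str]]  # accession -> singleton allele labels
    pool_allele_freqs: list[np.ndarray]  # per locus (K, k_l)


def _allocate(total: int, parts: int) -> np.ndarray:
    """Split `total` into `parts` near-equal integers (first ones get the remainder)."""
    base, rem = divmod(total, parts)
    out = np.full(parts, base, dtype=int)
    out[:rem] += 1
    return out


def generate_collection(config: GeneratorConfig) -> tuple[CollectionDataset, GroundTruth]:
    """Draw one synthetic collection plus its ground truth (seed-deterministic)."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n, L, K = cfg.n_accessions, cfg.n_loci, cfg.n_pools

    total_target = int(round(cfg.mean_alleles_per_locus * L))
    n_singletons = int(round(cfg.singleton_rate * total_target))
    k_common = _allocate(total_target - n_singletons, L)

    # pool-specific allele frequencies: common base measure, per-pool drift
    conc = (1.0 - cfg.divergence) / max(cfg.divergence, 1e-9)
    # floor common-allele frequencies at ~3.5 expected copies so that the
    # "observed once" class stays close to the singleton_rate dial while
    # keeping a 2-4 copy class whose interchangeable carriers give core
    # families their complement panels
    floor = 3.5 / (2.0 * n)
    pool_freqs: list[np.ndarray] = []
    for l in range(L):
        base = rng.dirichlet(np.full(k_common[l], cfg.allele_evenness))
        base = np.maximum(base, floor)
        base = base / base.sum()
        if cfg.divergence > 0:
            pools = np.vstack([rng.dirichlet(np.maximum(base * conc, 1e-6)) for _ in range(K)])
            pools = np.maximum(pools, floor)
            pools = pools / pools.sum(axis=1, keepdims=True)
        else:
            pools = np.tile(base, (K, 1))
        pool_freqs.append(pools)

    # zones, pools and individual ancestry (central pool = hybrid zone)
    zw = np.asarray(cfg.zone_weights[:K], dtype=float)
    zw = zw / zw.sum()
    pool = rng.choice(K, size=n, p=zw)
    ancestry = np.zeros((n, K))
    for i in range(n):
        alpha = np.full(K, cfg.admixture_alpha)
        boost = 4.0 if (K == 3 and pool[i] == 1) else 12.0  # center pool more admixed
        alpha[pool[i]] *= boost
        ancestry[i] = rng.dirichlet(alpha) if K > 1 else np.ones(1)

    # genotypes from ancestry-mixed pool frequencies (HWE within the mixture)
    geno = np.zeros((n, L, 2), dtype=int)
    for l in range(L):
        mixed = ancestry @ pool_freqs[l]  # (N, k_l)
        cum = mixed.cumsum(axis=1)
        u = rng.random((n, 2))
        geno[:, l, :] = (u[..., None] > cum[:, None, :]).sum(axis=2)

    # planted near-clones: the last `clone_pairs` rows copy distinct sources
    n_base = n - cfg.clone_pairs
    acc_ids = [f"ACC{i + 1:04d}" for i in range(n)]
    clone_partner: dict[str, str] = {}
    if cfg.clone_pairs:
        sources = rng.choice(n_base, size=cfg.clone_pairs, replace=False)
        for k, src in enumerate(sources):
            copy = n_base + k
            geno[copy] = geno[src]
            ancestry[copy] = ancestry[src]
            pool[copy] = pool[src]
            n_edits = int(rng.integers(1, 4))
            loci_edit = rng.choice(L, size=n_edits, replace=False)
            for l in loci_edit:
                slot = int(rng.integers(2))
                old = geno[copy, l, slot]
                choices = [a for a in range(k_common[l]) if a != old]
                geno[copy, l, slot] = int(rng.choice(choices))
            clone_partner[acc_ids[copy]] = acc_ids[src]

    # singleton alleles: overwrite one allele copy each; clone-pair members are
    # excluded so planted pair distances stay at the drawn 1-3 edits
    source_idx = {int(s) for s in sources} if cfg.clone_pairs else set()
    eligible = np.array([i for i in range(n_base) if i not in source_idx], dtype=int)
    pool_size = min(cfg.singleton_carrier_pool, eligible.size)
    eligible = rng.choice(eligible, size=pool_size, replace=False)
    singleton_code = {l: k_common[l] for l in range(L)}  # next free allele index per locus
    singleton_carriers: dict[str, list[str]] = {}
    for _ in range(n_singletons):
        l = int(rng.integers(L))
        i = int(rng.choice(eligible))
        slot = int(rng.integers(2))
        code = singleton_code[l]
        singleton_code[l] += 1
        geno[i, l, slot] = code
        singleton_carriers.setdefault(acc_ids[i], []).append(f"L{l + 1:02d}.a{code + 1:02d}")

    loci = [f"SSR{l + 1:02d}" for l in range(L)]
    calls = [
        [
            (f"L{l + 1:02d}.a{geno[i, l, 0] + 1:02d}", f"L{l + 1:02d}.a{geno[i, l, 1] + 1:02d}")
            for l in range(L)
        ]
        for i in range(n)
    ]
    table = GenotypeTable.from_calls(acc_ids, loci, calls)

    # plastid haplotypes: iid from the skewed spectrum, rare ones tilted east,
    # every haplotype forced to have at least one carrier
    hf = cfg.resolved_haplotype_freqs()
    hap_labels = [f"H{h + 1}" for h in range(len(hf))]
    hap_idx = rng.choice(len(hf), size=n, p=hf)
    east = np.flatnonzero(pool == K - 1) if K > 1 else np.arange(n)
    for h in range(len(hf)):
        if not (hap_idx == h).any():
            target = rng.choice(east if east.size else np.arange(n))
            hap_idx[target] = h
    haplotypes = HaplotypeMap({acc_ids[i]: hap_labels[hap_idx[i]] for i in range(n)})

    # pool-dependent categorical traits with missingness
    classes_per_trait = _allocate(cfg.total_trait_classes, cfg.n_traits)
    trait_cols = {}
    for t in range(cfg.n_traits):
        kt = classes_per_trait[t]
        class_freqs = np.vstack([rng.dirichlet(np.full(kt, 1.5)) for _ in range(K)])
        z = np.array([rng.choice(K, p=ancestry[i]) for i in range(n)])
        picks = np.array([rng.choice(kt, p=class_freqs[z[i]]) for i in range(n)])
        col = np.array([f"T{t + 1:02d}.c{c + 1}" for c in picks], dtype=object)
        col[rng.random(n) < cfg.trait_missing_rate] = np.nan
        trait_cols[f"trait{t + 1:02d}"] = col
    traits = TraitTable(pd.DataFrame(trait_cols, index=acc_ids))
    # make sure every allocated class label is realized at least once
    for t, (name, kt) in enumerate(zip(trait_cols, classes_per_trait)):
        present = set(traits.classes[name].dropna())
        for c in range(kt):
            label = f"T{t + 1:02d}.c{c + 1}"
            if label not in present:
                traits.classes.loc[acc_ids[int(rng.integers(n))], name] = label

    zone_of_pool = {k: _ZONES[k] if K == 3 else _ZONES[k % 3] for k in range(K)}
    zones = [zone_of_pool[int(p)] for p in pool]
    countries = [str(rng.choice(_COUNTRIES[z])) for z in zones]
    is_ref = np.zeros(n, dtype=bool)
    if cfg.n_reference:
        is_ref[rng.choice(n_base, size=min(cfg.n_reference, n_base), replace=False)] = True
    metadata = pd.DataFrame(
        {"country": countries, "zone": zones, "is_reference": is_ref}, index=acc_ids
    )

    dataset = CollectionDataset(table, traits, haplotypes, metadata)
    truth = GroundTruth(ancestry, pool, clone_partner, singleton_carriers, pool_freqs)
    return dataset, truth


def generate_equilibrium_panel(
    n: int, n_loci: int, alleles_per_locus: int, seed: int = 0
) -> GenotypeTable:
    """Mutually independent loci in Hardy-Weinberg proportions (LD null model)."""
    if min(n, n_loci, alleles_per_locus) < 1:
        raise ValueError("all parameters must be positive")
    rng = np.random.default_rng(seed)
    acc_ids = [f"EQ{i + 1:04d}" for i in range(n)]
    loci = [f"SSR{l + 1:02d}" for l in range(n_loci)]
    calls = []
    draws = np.zeros((n, n_loci, 2), dtype=int)
    for l in range(n_loci):
        freqs = rng.dirichlet(np.full(alleles_per_locus, 3.0))
        draws[:, l, :] = rng.choice(alleles_per_locus, size=(n, 2), p=freqs)
    for i in range(n):
        calls.append(
            [
                (f"L{l + 1:02d}.a{draws[i, l, 0] + 1:02d}", f"L{l + 1:02d}.a{draws[i, l, 1] + 1:02d}")
                for l in range(n_loci)
            ]
        )
    return GenotypeTable.from_calls(acc_ids, loci, calls)


def write_collection(
    dataset: CollectionDataset, outdir: str | Path, truth: GroundTruth | None = None
) -> dict[str, Path]:
    """Write a collection to the delimited text formats the loader reads."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table = dataset.genotypes
    rows = {}
    for i, acc in enumerate(table.accession_ids):
        rows[acc] = {
            locus: "NA" if not table.observed[i, l]
            else "/".join(
                table.alleles[l][c] for c in table.codes[i, l]
            )
            for l, locus in enumerate(table.loci)
        }
    paths = {"genotypes": outdir / "genotypes.csv"}
    pd.DataFrame.from_dict(rows, orient="index").rename_axis("accession").to_csv(
        paths["genotypes"]
    )
    if dataset.traits is not None:
        paths["traits"] = outdir / "traits.csv"
        dataset.traits.classes.rename_axis("accession").to_csv(paths["traits"], na_rep="NA")
    if dataset.haplotypes is not None:
        paths["haplotypes"] = outdir / "haplotypes.csv"
        pd.Series(dict(dataset.haplotypes), name="haplotype").rename_axis("accession").to_csv(
            paths["haplotypes"]
        )
    if dataset.metadata is not None:
        paths["metadata"] = outdir / "metadata.csv"
        dataset.metadata.rename_axis("accession").to_csv(paths["metadata"])
    if truth is not None:
        paths["truth"] = outdir / "ground_truth.json"
        payload = {
            "pool": truth.pool.tolist(),
            "ancestry": np.round(truth.ancestry, 6).tolist(),
            "clone_partner": truth.clone_partner,
            "singleton_carriers": truth.singleton_carriers,
        }
        paths["truth"].write_text(json.dumps(payload, indent=1))
    return paths
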