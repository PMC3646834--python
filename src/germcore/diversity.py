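"""Diversity and distance measures for multiallelic marker collections.

These are the quantities optimized by the core-subset samplers and used to
certify the resulting collections: allelic coverage (Cv), Nei gene
diversity (He), the pooled Shannon-Weaver index (Sh), the Cavalli-Sforza &
Edwards chord distance (D_CE), the simple-matching dissimilarity, plus
trait-class and plastid-haplotype coverage counts.

Conventions
-----------
* All pairwise measures use pairwise deletion: loci missing in either
  accession of a pair are skipped, and the locus average runs over the
  jointly observed loci.
* ``Sh`` is the Shannon entropy (natural log) of the pooled, locus-weighted
  allele distribution ``q_la = p_la / L'`` (``L'`` = loci with data), so a
  collection of ``L`` loci each uniform over ``k`` alleles scores exactly
  ``ln(k L)``.
* ``D_CE`` is the chord distance without the ``2/pi`` scaling constant and
  with the locus average taken under the square root, giving an exact
  [0, 1] range.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .data import CollectionDataset, GenotypeTable, HaplotypeMap, TraitTable

__all__ = [
    "AlleleFrequencySpectrum",
    "DiversityReport",
    "allele_frequencies",
    "allelic_coverage",
    "nei_he",
    "he_per_locus",
    "shannon_pooled",
    "shannon_per_locus",
    "richness_per_locus",
    "dce_distance",
    "dce_matrix",
    "dce_summary",
    "simple_matching_dissimilarity",
    "simple_matching_matrix",
    "trait_class_coverage",
    "haplotype_coverage",
    "diversity_report",
]


def _indices(table: GenotypeTable, subset: Sequence[str] | None) -> np.ndarray:
    if subset is None:
        return np.arange(table.n_accessions)
    idx = table.index_of(subset)
    if idx.size == 0:
        raise ValueError("subset must be non-empty")
    return idx


def _subset_counts(table: GenotypeTable, idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Global allele count vector (A,) and gene-copy totals per locus (L,)."""
    counts = table.dosage[idx].sum(axis=0, dtype=np.float64)
    n_l = 2.0 * table.observed[idx].sum(axis=0, dtype=np.float64)
    return counts, n_l


@dataclass
class AlleleFrequencySpectrum:
    """Per-locus allele label -> frequency maps (empty map = no data)."""

    frequencies: dict[str, dict[str, float]]

    def __getitem__(self, locus: str) -> dict[str, float]:
        return self.frequencies[locus]


def allele_frequencies(
    table: GenotypeTable, subset: Sequence[str] | None = None
) -> AlleleFrequencySpectrum:
    """Allele frequencies per locus over a subset (missing calls excluded)."""
    idx = _indices(table, subset)
    counts, n_l = _subset_counts(table, idx)
    off = table.locus_offsets
    freqs: dict[str, dict[str, float]] = {}
    for l, locus in enumerate(table.loci):
        if n_l[l] == 0:
            freqs[locus] = {}
            continue
        block = counts[off[l] : off[l + 1]] / n_l[l]
        freqs[locus] = {
            a: float(f) for a, f in zip(table.alleles[l], block) if f > 0
        }
    return AlleleFrequencySpectrum(freqs)


def allelic_coverage(
    table: GenotypeTable,
    subset: Sequence[str] | None = None,
    reference_total: int | None = None,
) -> tuple[int, float]:
    """Count and fraction of the reference allele universe present in a subset.

    The reference universe defaults to the table's full allele alphabet
    (which row-subset tables preserve), so a core built from a collection
    is scored against the collection it came from.
    """
    idx = _indices(table, subset)
    count = int((table.dosage[idx].sum(axis=0) > 0).sum())
    total = reference_total if reference_total is not None else table.n_alleles_total
    return count, count / total


def he_per_locus(table: GenotypeTable, subset: Sequence[str] | None = None) -> np.ndarray:
    """Nei gene diversity ``1 - sum(p^2)`` per locus (NaN when no data)."""
    idx = _indices(table, subset)
    counts, n_l = _subset_counts(table, idx)
    loc = table.locus_of_allele
    with np.errstate(invalid="ignore", divide="ignore"):
        p = counts / n_l[loc]
    sq = np.bincount(loc, weights=np.nan_to_num(p) ** 2, minlength=table.n_loci)
    he = 1.0 - sq
    he[n_l == 0] = np.nan
    return he

def nei_he(table: GenotypeTable, subset: Sequence[str] | None = None) -> float:
    """Nei diversity index: mean of per-locus expected heterozygosity."""
    he = he_per_locus(table, subset)
    if np.isnan(he).any():
        warnings.warn("locus with no data in subset excluded from He mean")
    return float(np.nanmean(he))


def richness_per_locus(table: GenotypeTable, subset: Sequence[str] | None = None) -> np.ndarray:
    """Distinct allele count per locus (the allelic-richness vector)."""
    idx = _indices(table, subset)
    present = table.dosage[idx].sum(axis=0) > 0
    return np.bincount(table.locus_of_allele, weights=present, minlength=table.n_loci).astype(int)


def shannon_per_locus(table: GenotypeTable, subset: Sequence[str] | None = None) -> np.ndarray:
    """Per-locus Shannon entropy ``-sum(p ln p)`` (NaN when no data)."""
    idx = _indices(table, subset)
    counts, n_l = _subset_counts(table, idx)
    loc = table.locus_of_allele
    with np.errstate(invalid="ignore", divide="ignore"):
        p = counts / n_l[loc]
    terms = np.where(np.nan_to_num(p) > 0, -p * np.log(np.where(p > 0, p, 1.0)), 0.0)
    h = np.bincount(loc, weights=np.nan_to_num(terms), minlength=table.n_loci)
    h[n_l == 0] = np.nan
    return h


def shannon_pooled(table: GenotypeTable, subset: Sequence[str] | None = None) -> float:
    """Shannon-Weaver index of the pooled, locus-weighted allele distribution.

    With per-locus frequencies ``p_la`` and ``L'`` loci carrying data, the
    pooled distribution is ``q_la = p_la / L'`` and the index is
    ``-sum q ln q``.  Equals ``ln(k L)`` for ``L`` loci uniform over ``k``
    alleles; 0 for a panel of clones fixed at every locus.
    """
    idx = _indices(table, subset)
    counts, n_l = _subset_counts(table, idx)
    loc = table.locus_of_allele
    n_data = float((n_l > 0).sum())
    if n_data == 0:
        raise ValueError("subset has no genotype data")
    with np.errstate(invalid="ignore", divide="ignore"):
        q = counts / n_l[loc] / n_data
    q = np.nan_to_num(q)
    nz = q > 0
    return float(-(q[nz] * np.log(q[nz])).sum())


# ---------------------------------------------------------------------------
# pairwise distances
# ---------------------------------------------------------------------------


def dce_distance(table: GenotypeTable, id1: str, id2: str) -> float:
    """Cavalli-Sforza & Edwards chord distance between two accessions.

    Per jointly observed locus ``f_l = sum_a sqrt(x_a y_a)`` with ``x, y``
    the within-accession allele frequencies (1, 0.5 or 0); the distance is
    ``sqrt(mean_l (1 - f_l))`` over the jointly observed loci.
    """
    i, j = table.index_of([id1, id2])
    m = dce_matrix(table, [id1, id2])
    if np.isnan(m[0, 1]):
        raise ValueError(f"accessions {id1!r} and {id2!r} share no observed locus")
    return float(m[0, 1])


def dce_matrix(table: GenotypeTable, subset: Sequence[str] | None = None) -> np.ndarray:
    """Pairwise chord-distance matrix (NaN for pairs with no shared locus)."""
    idx = _indices(table, subset)
    off = table.locus_offsets
    sqrt_x = np.sqrt(table.dosage[idx].astype(np.float64) / 2.0)
    obs = table.observed[idx].astype(np.float64)
    joint = obs @ obs.T
    acc = np.zeros_like(joint)
    for l in range(table.n_loci):
        block = sqrt_x[:, off[l] : off[l + 1]]
        f = block @ block.T
        both = np.outer(obs[:, l], obs[:, l])
        acc += both * (1.0 - np.clip(f, 0.0, 1.0))
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.sqrt(acc / joint)
    np.fill_diagonal(d, 0.0)
    return d


def dce_summary(table: GenotypeTable, subset: Sequence[str] | None = None) -> tuple[float, float]:
    """Mean and sample SD of the chord distance over all unordered pairs."""
    d = dce_matrix(table, subset)
    iu = np.triu_indices(d.shape[0], k=1)
    vals = d[iu]
    if np.isnan(vals).any():
        warnings.warn("pairs with no jointly observed locus excluded from chord-distance summary")
        vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        raise ValueError("no defined accession pair in subset")
    sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
    return float(vals.mean()), sd


def simple_matching_matrix(
    table: GenotypeTable, subset: Sequence[str] | None = None
) -> np.ndarray:
    """Pairwise simple-matching dissimilarity ``1 - shared alleles / (2 L'')``."""
    from scipy.spatial.distance import pdist, squareform

    idx = _indices(table, subset)
    off = table.locus_offsets
    obs = table.observed[idx].astype(np.float64)
    joint = obs @ obs.T
    diff = np.zeros_like(joint)
    for l in range(table.n_loci):
        block = table.dosage[idx, off[l] : off[l + 1]].astype(np.float64)
        l1 = squareform(pdist(block, metric="cityblock")) if idx.size > 1 else np.zeros((1, 1))
        both = np.outer(obs[:, l], obs[:, l])
        diff += np.where(both, l1 / 2.0, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = diff / (2.0 * joint)
    np.fill_diagonal(d, 0.0)
    return d


def simple_matching_dissimilarity(table: GenotypeTable, id1: str, id2: str) -> float:
    """Simple-matching dissimilarity between two accessions, in [0, 1]."""
    m = simple_matching_matrix(table, [id1, id2])
    if np.isnan(m[0, 1]):
        raise ValueError(f"accessions {id1!r} and {id2!r} share no observed locus")
    return float(m[0, 1])


# ---------------------------------------------------------------------------
# coverage counts and the one-row report
# ---------------------------------------------------------------------------


def trait_class_coverage(traits: TraitTable, subset: Sequence[str] | None = None) -> int:
    """Distinct trait classes observed in the subset."""
    df = traits.classes if subset is None else traits.classes.loc[
        [a for a in subset if a in set(traits.accession_ids)]
    ]
    return int(sum(df[t].dropna().nunique() for t in df.columns))


def haplotype_coverage(haplotypes: HaplotypeMap, subset: Sequence[str] | None = None) -> int:
    """Distinct plastid haplotypes carried by the subset."""
    if subset is None:
        return len(set(haplotypes.values()))
    return len({haplotypes[a] for a in subset if a in haplotypes})


@dataclass
class DiversityReport:
    """One summary row for a subset: the certification surface of a core."""

    n_entries: int
    cv_count: int
    cv_fraction: float
    dce_mean: float
    dce_sd: float
    he: float
    sh: float
    trait_class_count: int | None = None
    trait_class_fraction: float | None = None
    haplotype_count: int | None = None

    def to_row(self) -> dict:
        return {
            "n": self.n_entries,
            "Cv": self.cv_count,
            "Cv_pct": round(100 * self.cv_fraction, 1),
            "Dce_mean": round(self.dce_mean, 3),
            "Dce_sd": round(self.dce_sd, 3),
            "He": round(self.he, 3),
            "Sh": round(self.sh, 3),
            "trait_classes": self.trait_class_count,
            "haplotypes": self.haplotype_count,
        }


def diversity_report(
    dataset: CollectionDataset, subset: Sequence[str] | None = None
) -> DiversityReport:
    """Compute the full diversity report of a subset against its collection."""
    table = dataset.genotypes
    idx = _indices(table, subset)
    ids = [table.accession_ids[i] for i in idx]
    cv_count, cv_frac = allelic_coverage(table, ids)
    if len(ids) > 1:
        dce_mean, dce_sd = dce_summary(table, ids)
    else:
        dce_mean, dce_sd = 0.0, 0.0
    report = DiversityReport(
        n_entries=len(ids),
        cv_count=cv_count,
        cv_fraction=cv_frac,
        dce_mean=dce_mean,
        dce_sd=dce_sd,
        he=nei_he(table, ids),
        sh=shannon_pooled(table, ids),
    )
    if dataset.traits is not None:
        report.trait_class_count = trait_class_coverage(dataset.traits, ids)
        total = dataset.traits.n_classes_total
        report.trait_class_fraction = report.trait_class_count / total if total else None
    if dataset.haplotypes is not None:
        report.haplotype_count = haplotype_coverage(dataset.haplotypes, ids)
    return report
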