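"""Data model and I/O for multilocus co-dominant marker collections.

A germplasm bank is represented by a :class:`CollectionDataset` bundling a
:class:`GenotypeTable` (diploid, multiallelic SSR-style calls), an optional
categorical :class:`TraitTable`, an optional plastid :class:`HaplotypeMap`
and per-accession metadata (country, geographic zone, reference-variety
flag).  Allele labels are opaque strings compared by equality; there is no
fragment-length arithmetic.

Missing calls are first-class: the tokens ``NA``, the empty string and
``0/0`` all parse as missing, and every pairwise measure in the package
uses pairwise deletion (loci missing in either accession are skipped).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MISSING_TOKENS",
    "GenotypeTable",
    "TraitTable",
    "HaplotypeMap",
    "CollectionDataset",
    "QMatrixInput",
    "load_dataset",
    "read_genotype_table",
    "allele_difference_count",
    "allele_difference_matrix",
    "collapse_identical",
    "filter_min_difference",
]

#: cell values interpreted as a missing genotype call / trait class
MISSING_TOKENS = frozenset({"NA", "", "0/0", "na", "NaN", "nan"})


def _is_missing(token: str) -> bool:
    return token.strip() in MISSING_TOKENS


@dataclass(eq=False)
class GenotypeTable:
    """Accessions x loci table of unordered diploid allele-label pairs.

    ``codes[i, l]`` holds the two allele indices of accession ``i`` at locus
    ``l`` into ``alleles[l]``; a missing call is ``(-1, -1)``.  Derived
    numeric views (global allele coding, dosage matrix, observation mask)
    are built lazily and cached — the table itself is treated as immutable.
    """

    accession_ids: tuple[str, ...]
    loci: tuple[str, ...]
    codes: np.ndarray  # (N, L, 2) int32, -1 == missing
    alleles: tuple[tuple[str, ...], ...]  # per-locus allele alphabet

    def __post_init__(self) -> None:
        if len(set(self.accession_ids)) != len(self.accession_ids):
            dupes = [a for a, c in pd.Series(self.accession_ids).value_counts().items() if c > 1]
            raise ValueError(f"duplicate accession ids: {dupes}")
        if len(self.loci) < 1:
            raise ValueError("at least one locus is required")
        self.codes = np.asarray(self.codes, dtype=np.int32)
        if self.codes.shape != (self.n_accessions, self.n_loci, 2):
            raise ValueError("codes array has wrong shape")
        self._cache: dict = {}

    # -- construction ---------------------------------------------------

    @classmethod
    def from_calls(
        cls,
        accession_ids: Sequence[str],
        loci: Sequence[str],
        calls: Sequence[Sequence[tuple[str, str] | None]],
    ) -> "GenotypeTable":
        """Build a table from nested ``calls[i][l]`` allele-label pairs.

        ``None`` marks a missing call.  Allele alphabets are the observed
        labels per locus, sorted for reproducibility.
        """
        n, L = len(accession_ids), len(loci)
        alphabet: list[set[str]] = [set() for _ in range(L)]
        for row in calls:
            if len(row) != L:
                raise ValueError("call row length does not match locus count")
            for l, call in enumerate(row):
                if call is not None:
                    alphabet[l].update(call)
        alleles = tuple(tuple(sorted(a)) for a in alphabet)
        index = [{a: k for k, a in enumerate(al)} for al in alleles]
        codes = np.full((n, L, 2), -1, dtype=np.int32)
        for i, row in enumerate(calls):
            for l, call in enumerate(row):
                if call is not None:
                    codes[i, l] = sorted((index[l][call[0]], index[l][call[1]]))
        return cls(tuple(accession_ids), tuple(loci), codes, alleles)

    # -- basic properties ----------------------------------------------

    @property
    def n_accessions(self) -> int:
        return len(self.accession_ids)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def allele_alphabet(self) -> tuple[tuple[str, ...], ...]:
        return self.alleles

    @property
    def n_alleles_total(self) -> int:
        return sum(len(a) for a in self.alleles)

    def index_of(self, ids: Iterable[str]) -> np.ndarray:
        lookup = self._cached("_id_lookup", lambda: {a: i for i, a in enumerate(self.accession_ids)})
        try:
            return np.array([lookup[a] for a in ids], dtype=np.intp)
        except KeyError as exc:
            raise KeyError(f"unknown accession id {exc.args[0]!r}") from None

    def call(self, accession: str, locus: str) -> tuple[str, str] | None:
        i = self.index_of([accession])[0]
        l = self.loci.index(locus)
        a, b = self.codes[i, l]
        if a < 0:
            return None
        return (self.alleles[l][a], self.alleles[l][b])

    # -- cached numeric views -------------------------------------------

    def _cached(self, key: str, make):
        if key not in self._cache:
            self._cache[key] = make()
        return self._cache[key]

    @property
    def observed(self) -> np.ndarray:
        """(N, L) boolean mask of non-missing calls."""
        return self._cached("observed", lambda: self.codes[:, :, 0] >= 0)

    @property
    def locus_offsets(self) -> np.ndarray:
        """Start column of each locus in the global allele coding."""
        return self._cached(
            "offsets",
            lambda: np.concatenate([[0], np.cumsum([len(a) for a in self.alleles])]),
        )

    @property
    def locus_of_allele(self) -> np.ndarray:
        """(A,) locus index of every global allele column."""
        return self._cached(
            "locus_of",
            lambda: np.repeat(np.arange(self.n_loci), [len(a) for a in self.alleles]),
        )

    @property
    def dosage(self) -> np.ndarray:
        """(N, A) allele copy counts (0/1/2) on the global allele coding."""

        def make() -> np.ndarray:
            A = self.n_alleles_total
            dos = np.zeros((self.n_accessions, A), dtype=np.int8)
            off = self.locus_offsets
            rows = np.arange(self.n_accessions)
            for l in range(self.n_loci):
                obs = self.observed[:, l]
                for slot in range(2):
                    cols = off[l] + self.codes[obs, l, slot]
                    np.add.at(dos, (rows[obs], cols), 1)
            return dos

        return self._cached("dosage", make)

    @property
    def presence(self) -> np.ndarray:
        """(N, A) boolean allele presence matrix."""
        return self._cached("presence", lambda: self.dosage > 0)

    def subset(self, ids: Sequence[str]) -> "GenotypeTable":
        """Row subset preserving the full allele alphabets."""
        idx = self.index_of(ids)
        return GenotypeTable(tuple(ids), self.loci, self.codes[idx].copy(), self.alleles)


@dataclass(eq=False)
class TraitTable:
    """Accessions x traits table of categorical class labels (NaN = missing)."""

    classes: pd.DataFrame  # index = accession ids, columns = trait labels

    def __post_init__(self) -> None:
        if self.classes.index.has_duplicates:
            raise ValueError("duplicate accession ids in trait table")

    @property
    def accession_ids(self) -> tuple[str, ...]:
        return tuple(self.classes.index)

    @property
    def traits(self) -> tuple[str, ...]:
        return tuple(self.classes.columns)

    @property
    def class_universe(self) -> dict[str, tuple[str, ...]]:
        return {t: tuple(sorted(self.classes[t].dropna().unique())) for t in self.classes.columns}

    @property
    def n_classes_total(self) -> int:
        return sum(len(v) for v in self.class_universe.values())

    @property
    def indicator(self) -> tuple[np.ndarray, list[str]]:
        """(N, C) boolean trait-class indicator and the class column labels."""
        dummies = pd.get_dummies(self.classes, prefix_sep="=", dtype=bool)
        return dummies.to_numpy(), list(dummies.columns)

    def subset(self, ids: Sequence[str]) -> "TraitTable":
        return TraitTable(self.classes.loc[list(ids)])


class HaplotypeMap(dict):
    """accession id -> plastid haplotype label (missing ids simply absent)."""

    @property
    def universe(self) -> tuple[str, ...]:
        return tuple(sorted(set(self.values())))

    def subset(self, ids: Sequence[str]) -> "HaplotypeMap":
        return HaplotypeMap({a: self[a] for a in ids if a in self})


@dataclass(eq=False)
class CollectionDataset:
    """One coherent germplasm bank: genotypes plus optional annotations."""

    genotypes: GenotypeTable
    traits: TraitTable | None = None
    haplotypes: HaplotypeMap | None = None
    metadata: pd.DataFrame | None = None  # columns: country, zone, is_reference

    def __post_init__(self) -> None:
        ids = set(self.genotypes.accession_ids)
        for name, members in (
            ("trait", set(self.traits.accession_ids) if self.traits is not None else set()),
            ("haplotype", set(self.haplotypes) if self.haplotypes is not None else set()),
            ("metadata", set(self.metadata.index) if self.metadata is not None else set()),
        ):
            orphans = members - ids
            if orphans:
                raise ValueError(f"{name} rows for unknown accessions: {sorted(orphans)[:5]}")

    @property
    def accession_ids(self) -> tuple[str, ...]:
        return self.genotypes.accession_ids

    @property
    def n_accessions(self) -> int:
        return self.genotypes.n_accessions

    @property
    def reference_ids(self) -> tuple[str, ...]:
        if self.metadata is None or "is_reference" not in self.metadata.columns:
            return ()
        flagged = self.metadata.index[self.metadata["is_reference"].astype(bool)]
        return tuple(a for a in self.accession_ids if a in set(flagged))

    def subset(self, ids: Sequence[str]) -> "CollectionDataset":
        ids = list(ids)
        return CollectionDataset(
            genotypes=self.genotypes.subset(ids),
            traits=self.traits.subset([a for a in ids if a in set(self.traits.accession_ids)])
            if self.traits is not None
            else None,
            haplotypes=self.haplotypes.subset(ids) if self.haplotypes is not None else None,
            metadata=self.metadata.loc[[a for a in ids if a in self.metadata.index]]
            if self.metadata is not None
            else None,
        )


@dataclass
class QMatrixInput:
    """Externally computed ancestry proportions and per-K run log-likelihoods.

    The clustering itself (admixture-model MCMC) is out of scope; this type
    only carries its output for downstream summaries (admixture report,
    Evanno second-order rate of change of L(K)).
    """

    q: pd.DataFrame  # index = accession ids, columns = 1..K ancestry fractions
    run_loglikelihoods: Mapping[int, Sequence[float]] | None = None

    def __post_init__(self) -> None:
        sums = self.q.sum(axis=1).to_numpy()
        if not np.allclose(sums, 1.0, atol=1e-6):
            bad = self.q.index[np.abs(sums - 1.0) > 1e-6][:5]
            raise ValueError(f"ancestry vectors do not sum to 1: {list(bad)}")

    def admixed_ids(self, threshold: float = 0.80) -> tuple[str, ...]:
        """Accessions assigned to no single cluster at >= `threshold` membership."""
        return tuple(self.q.index[self.q.max(axis=1) < threshold])


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------


def _read_delimited(path: str | Path) -> pd.DataFrame:
    """Read a comma- or tab-delimited text file (auto-detected), first column = accession id."""
    with open(path, "r", encoding="utf-8") as fh:
        head = fh.readline()
    sep = "\t" if head.count("\t") >= head.count(",") and "\t" in head else ","
    return pd.read_csv(path, sep=sep, dtype=str, index_col=0, keep_default_na=False)


def read_genotype_table(path: str | Path) -> GenotypeTable:
    """Parse a delimited genotype file: header = locus names, cells ``allele1/allele2``."""
    df = _read_delimited(path)
    loci = list(df.columns)
    ids = [str(a) for a in df.index]
    calls: list[list[tuple[str, str] | None]] = []
    for acc, row in zip(ids, df.itertuples(index=False)):
        parsed: list[tuple[str, str] | None] = []
        for locus, cell in zip(loci, row):
            cell = str(cell).strip()
            if _is_missing(cell):
                parsed.append(None)
                continue
            parts = cell.split("/")
            if len(parts) != 2 or not all(p.strip() for p in parts):
                raise ValueError(
                    f"malformed genotype cell {cell!r} for accession {acc!r} at locus {locus!r}: "
                    "expected exactly two '/'-joined allele labels or a missing token"
                )
            parsed.append((parts[0].strip(), parts[1].strip()))
        calls.append(parsed)
    return GenotypeTable.from_calls(ids, loci, calls)


def load_dataset(
    genotype_path: str | Path,
    trait_path: str | Path | None = None,
    haplotype_path: str | Path | None = None,
    metadata_path: str | Path | None = None,
) -> CollectionDataset:
    """Load and validate a full collection from delimited text files.

    The genotype file is required; trait, haplotype and metadata files are
    optional and must index a subset of the genotype accessions (orphan rows
    raise).  See the module docstring for the missing-token convention.
    """
    genotypes = read_genotype_table(genotype_path)
    traits = None
    if trait_path is not None:
        df = _read_delimited(trait_path)
        df = df.map(lambda v: np.nan if _is_missing(str(v)) else str(v).strip())
        traits = TraitTable(df)
    haplotypes = None
    if haplotype_path is not None:
        df = _read_delimited(haplotype_path)
        col = df.columns[0]
        haplotypes = HaplotypeMap(
            {str(a): str(v).strip() for a, v in df[col].items() if not _is_missing(str(v))}
        )
    metadata = None
    if metadata_path is not None:
        metadata = _read_delimited(metadata_path)
        if "is_reference" in metadata.columns:
            metadata["is_reference"] = metadata["is_reference"].map(
                lambda v: str(v).strip().lower() in {"1", "true", "yes"}
            )
    return CollectionDataset(genotypes, traits, haplotypes, metadata)


# ---------------------------------------------------------------------------
# dissimilarity primitives and deduplication
# ---------------------------------------------------------------------------


def allele_difference_count(table: GenotypeTable, id1: str, id2: str) -> int:
    """Number of dissimilar alleles between two accessions.

    Each locus contributes ``2 - |multiset intersection|`` of the two
    unordered allele pairs; loci missing in either accession contribute 0.
    """
    i, j = table.index_of([id1, id2])
    return int(_difference_rows(table, i, j))


def _difference_rows(table: GenotypeTable, i: int, j: int) -> int:
    both = table.observed[i] & table.observed[j]
    diff = 0
    for l in np.flatnonzero(both):
        a = list(table.codes[i, l])
        inter = 0
        for c in table.codes[j, l]:
            if c in a:
                a.remove(c)
                inter += 1
        diff += 2 - inter
    return diff


def allele_difference_matrix(table: GenotypeTable) -> np.ndarray:
    """(N, N) matrix of pairwise dissimilar-allele counts (pairwise deletion).

    Uses the identity: per jointly observed locus the multiset-intersection
    shortfall equals half the L1 distance between the two dosage vectors.
    """
    from scipy.spatial.distance import squareform, pdist

    n = table.n_accessions
    off = table.locus_offsets
    total = np.zeros((n, n))
    for l in range(table.n_loci):
        block = table.dosage[:, off[l] : off[l + 1]].astype(np.float64)
        l1 = squareform(pdist(block, metric="cityblock"))
        both = np.outer(table.observed[:, l], table.observed[:, l])
        # missing rows have an all-zero dosage block; mask them out explicitly
        total += np.where(both, l1 / 2.0, 0.0)
    return total


def _cluster_representatives(
    dataset: CollectionDataset, max_diff: int
) -> tuple[list[str], dict[str, str]]:
    """Single-linkage clusters at `difference <= max_diff`; first-listed member represents."""
    table = dataset.genotypes
    diff = allele_difference_matrix(table)
    n = table.n_accessions
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    ii, jj = np.nonzero(np.triu(diff <= max_diff, k=1))
    for i, j in zip(ii, jj):
        ri, rj = find(int(i)), find(int(j))
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)
    rep_of: dict[int, int] = {}
    mapping: dict[str, str] = {}
    keep: list[str] = []
    for i in range(n):
        r = find(i)
        if r not in rep_of:
            rep_of[r] = i
            keep.append(table.accession_ids[i])
        mapping[table.accession_ids[i]] = table.accession_ids[rep_of[r]]
    return keep, mapping


def collapse_identical(dataset: CollectionDataset) -> tuple[CollectionDataset, dict[str, str]]:
    """Merge accessions with identical marker profiles (difference count 0).

    Returns the reduced dataset plus an original -> representative mapping
    for traceability.  The first-listed member of each group is kept.
    """
    keep, mapping = _cluster_representatives(dataset, 0)
    return dataset.subset(keep), mapping


def filter_min_difference(dataset: CollectionDataset, min_diff: int) -> CollectionDataset:
    """Retain one representative per single-linkage cluster at ``difference <= min_diff``.

    ``min_diff=3`` yields the "distinguished by more than three dissimilar
    alleles" panel used before kinship and linkage-disequilibrium analysis;
    ``min_diff=0`` coincides with :func:`collapse_identical`.
    """
    if min_diff < 0:
        raise ValueError("min_diff must be >= 0")
    keep, _ = _cluster_representatives(dataset, min_diff)
    return dataset.subset(keep)
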