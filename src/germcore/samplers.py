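"""Core-subset construction methods.

Four samplers are provided, mirroring the strategies commonly compared when
building core collections from clonal germplasm banks:

* :func:`sample_random` — uniform draw without replacement (the baseline).
* :func:`sample_m_method` — the maximization (M-) method: greedy seeding on
  marginal category gain (alleles, optionally trait classes) followed by
  single-swap hill climbing, with the pooled Shannon index as secondary
  criterion and support for a compulsory "kernel" of accessions.
* :func:`sample_asls` — advanced stochastic local search: multi-replica
  simulated annealing over fixed-size subsets optimizing a weighted,
  normalized combination of allelic coverage (Cv), chord distance (D_CE),
  Shannon index (Sh) and Nei diversity (He), finished with a
  best-improvement hill climb; the best replica is reported.
* :func:`sample_mlst` — maximum-length-sub-tree pruning of a
  neighbor-joining tree built on the simple-matching dissimilarity.

All samplers are deterministic given their seed and return
:class:`CoreSubset` objects carrying provenance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .data import CollectionDataset, GenotypeTable
from .diversity import (
    dce_matrix,
    diversity_report,
    he_per_locus,
    richness_per_locus,
    shannon_per_locus,
)

__all__ = [
    "SamplerConfig",
    "CoreSubset",
    "RedundancyCurve",
    "sample_random",
    "sample_m_method",
    "sample_asls",
    "sample_mlst",
    "redundancy_minimum_size",
    "compare_methods",
]

_WEIGHT_ALIASES = {"cv": "Cv", "dce": "Dce", "d_ce": "Dce", "sh": "Sh", "he": "He"}


def normalize_weights(weights: dict[str, float]) -> dict[str, float]:
    """Canonicalize measure names and rescale non-negative weights to sum 1."""
    out: dict[str, float] = {}
    for key, w in weights.items():
        canon = _WEIGHT_ALIASES.get(key.lower().replace("-", "_"))
        if canon is None:
            raise ValueError(f"unknown objective measure {key!r}")
        if w < 0:
            raise ValueError("weights must be non-negative")
        out[canon] = out.get(canon, 0.0) + float(w)
    total = sum(out.values())
    if total <= 0:
        raise ValueError("at least one weight must be positive")
    return {k: v / total for k, v in out.items()}


@dataclass
class SamplerConfig:
    """Configuration of one sampling run (used by :func:`compare_methods`)."""

    method: str  # RANDOM | M | ASLS | MLST
    size: int | None = None
    weights: dict[str, float] | None = None
    kernel: tuple[str, ...] = ()
    replicates: int = 20
    iterations: int = 100
    steps: int = 2500
    objective_space: str = "alleles"
    seed: int = 0
    label: str | None = None

    @property
    def name(self) -> str:
        if self.label:
            return self.label
        if self.method.upper() == "ASLS" and self.weights:
            parts = "+".join(k for k, v in normalize_weights(self.weights).items() if v > 0)
            return f"ASLS/{parts}"
        return self.method.upper()


@dataclass
class CoreSubset:
    """A selected accession set with provenance and (optionally) its report."""

    ids: tuple[str, ...]
    provenance: dict = field(default_factory=dict)
    report: object | None = None

    def __len__(self) -> int:
        return len(self.ids)

    def __contains__(self, accession: str) -> bool:
        return accession in set(self.ids)


@dataclass
class RedundancyCurve:
    """Best captured-category count as a function of subset size."""

    points: tuple[tuple[int, int], ...]  # (size, best captured categories)
    minimal_size: int
    target: int


# ---------------------------------------------------------------------------
# shared numeric scaffolding
# ---------------------------------------------------------------------------


def _category_matrix(dataset: CollectionDataset, objective_space: str) -> np.ndarray:
    """(N, C) boolean matrix: allele presence, plus trait classes if requested."""
    table = dataset.genotypes
    blocks = [table.presence]
    if objective_space == "alleles+traits":
        if dataset.traits is None:
            raise ValueError("objective space includes traits but the dataset has no trait table")
        ind, _ = dataset.traits.indicator
        aligned = np.zeros((table.n_accessions, ind.shape[1]), dtype=bool)
        aligned[table.index_of(dataset.traits.accession_ids)] = ind
        blocks.append(aligned)
    elif objective_space != "alleles":
        raise ValueError(f"unknown objective space {objective_space!r}")
    return np.concatenate(blocks, axis=1)


def _entropy_rows(counts: np.ndarray, n_l: np.ndarray, loc: np.ndarray) -> np.ndarray:
    """Pooled locus-weighted Shannon entropy per row of a counts matrix."""
    counts = np.atleast_2d(counts)
    n_l = np.atleast_2d(n_l)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = counts / n_l[:, loc]
    p = np.nan_to_num(p)
    n_data = (n_l > 0).sum(axis=1).astype(float)
    q = p / n_data[:, None]
    terms = np.where(q > 0, -q * np.log(np.where(q > 0, q, 1.0)), 0.0)
    return terms.sum(axis=1)


def _he_rows(counts: np.ndarray, n_l: np.ndarray, loc: np.ndarray, n_loci: int) -> np.ndarray:
    """Mean per-locus Nei diversity per row of a counts matrix."""
    counts = np.atleast_2d(counts)
    n_l = np.atleast_2d(n_l)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = counts / n_l[:, loc]
    p = np.nan_to_num(p)
    out = np.empty(counts.shape[0])
    for r in range(counts.shape[0]):  # loci counts are small; a row loop is fine
        sq = np.bincount(loc, weights=p[r] ** 2, minlength=n_loci)
        good = n_l[r] > 0
        out[r] = (1.0 - sq[good]).mean() if good.any() else 0.0
    return out


def _dce_full(table: GenotypeTable) -> np.ndarray:
    """Cached full pairwise chord-distance matrix; undefined pairs get the mean."""

    def make() -> np.ndarray:
        d = dce_matrix(table)
        if np.isnan(d).any():
            d = np.where(np.isnan(d), np.nanmean(d), d)
        return d

    return table._cached("dce_full", make)


# ---------------------------------------------------------------------------
# random baseline
# ---------------------------------------------------------------------------


def sample_random(dataset: CollectionDataset, size: int, seed: int = 0) -> CoreSubset:
    """Uniform draw of `size` accessions without replacement."""
    n = dataset.n_accessions
    if size > n:
        raise ValueError(f"requested size {size} exceeds collection size {n}")
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(n, size=size, replace=False))
    ids = tuple(dataset.accession_ids[i] for i in idx)
    return CoreSubset(ids, provenance={"method": "RANDOM", "size": size, "seed": seed})


# ---------------------------------------------------------------------------
# M-method (kernel-constrained category maximization)
# ---------------------------------------------------------------------------


def _m_single_run(
    table: GenotypeTable,
    pres: np.ndarray,
    kernel_idx: np.ndarray,
    size: int,
    iterations: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, int, float]:
    """One greedy-seed + hill-climb replicate; returns (indices, coverage, Sh)."""
    n = pres.shape[0]
    dosage, observed = table.dosage, table.observed
    loc = table.locus_of_allele

    in_set = np.zeros(n, dtype=bool)
    in_set[kernel_idx] = True
    cover = pres[kernel_idx].sum(axis=0).astype(np.int32) if kernel_idx.size else np.zeros(
        pres.shape[1], dtype=np.int32
    )
    # greedy seeding on marginal category gain, random tie-break
    while in_set.sum() < size:
        cand = np.flatnonzero(~in_set)
        gains = pres[cand][:, cover == 0].sum(axis=1)
        best = gains.max()
        pick = rng.choice(cand[gains == best])
        in_set[pick] = True
        cover += pres[pick]

    counts = dosage[in_set].sum(axis=0, dtype=np.float64)
    n_l = 2.0 * observed[in_set].sum(axis=0, dtype=np.float64)
    covered = int((cover > 0).sum())
    sh = float(_entropy_rows(counts, n_l, loc)[0])
    kernel_mask = np.zeros(n, dtype=bool)
    kernel_mask[kernel_idx] = True

    def apply_swap(r: int, pick: int) -> None:
        nonlocal cover, counts, n_l, covered, sh
        in_set[r] = False
        in_set[pick] = True
        cover = cover - pres[r] + pres[pick]
        counts = counts - dosage[r] + dosage[pick]
        n_l = n_l - 2.0 * observed[r] + 2.0 * observed[pick]
        covered = int((cover > 0).sum())
        sh = float(_entropy_rows(counts, n_l, loc)[0])

    best_state = (covered, sh, in_set.copy())
    stall = 0
    for _ in range(iterations):
        improved = False
        members = np.flatnonzero(in_set & ~kernel_mask)
        rng.shuffle(members)
        for r in members:
            cand = np.flatnonzero(~in_set)
            if cand.size == 0:
                break
            cover_wo = cover - pres[r]
            zero_after = cover_wo == 0
            lost = int(zero_after[pres[r]].sum())
            gains = pres[cand][:, zero_after].sum(axis=1) - lost
            best = int(gains.max())
            if best <= 0:
                # category count is the primary criterion; coverage-neutral
                # shuffling happens only as a plateau kick below, so that
                # independent runs keep exploring alternative optima
                continue
            top = cand[gains == best]
            if top.size > 1:
                c2 = counts - dosage[r] + dosage[top]
                nl2 = n_l - 2.0 * observed[r] + 2.0 * observed[top]
                sh_top = _entropy_rows(c2, nl2, loc)
                top = top[sh_top == sh_top.max()]
            apply_swap(int(r), int(rng.choice(top)))
            improved = True
        if (covered, sh) > best_state[:2]:
            best_state = (covered, sh, in_set.copy())
        if improved:
            stall = 0
            continue
        # plateau: escape the swap-local optimum via one random
        # coverage-neutral swap, keeping the best subset seen so far
        stall += 1
        if stall > 15:
            break
        members = np.flatnonzero(in_set & ~kernel_mask)
        cand_all = np.flatnonzero(~in_set)
        if members.size == 0 or cand_all.size == 0:
            break
        r = int(rng.choice(members))
        zero_after = (cover - pres[r]) == 0
        lost = int(zero_after[pres[r]].sum())
        gains = pres[cand_all][:, zero_after].sum(axis=1) - lost
        neutral = cand_all[gains == 0]
        if neutral.size == 0:
            continue
        apply_swap(r, int(rng.choice(neutral)))
    covered, sh, final = best_state
    return np.flatnonzero(final), covered, sh


def sample_m_method(
    dataset: CollectionDataset,
    size: int,
    kernel: Sequence[str] = (),
    objective_space: str = "alleles",
    replicates: int = 20,
    iterations: int = 100,
    seed: int = 0,
) -> list[CoreSubset]:
    """M-method: maximize captured categories at fixed size, kernel forced in.

    Each replicate greedily seeds the subset (kernel first) and then runs up
    to `iterations` single-swap improvement sweeps; the pooled Shannon index
    breaks ties between subsets capturing the same number of categories.
    Replicates are returned ranked by (categories, Sh), best first.
    """
    table = dataset.genotypes
    if size > table.n_accessions:
        raise ValueError("size exceeds collection size")
    kernel_idx = table.index_of(kernel)
    if size < kernel_idx.size:
        raise ValueError("size smaller than kernel")
    pres = _category_matrix(dataset, objective_space)
    seeds = np.random.SeedSequence(seed).spawn(replicates)
    results = []
    for rep, ss in enumerate(seeds):
        rng = np.random.default_rng(ss)
        idx, covered, sh = _m_single_run(table, pres, kernel_idx, size, iterations, rng)
        ids = tuple(table.accession_ids[i] for i in idx)
        results.append(
            (
                covered,
                sh,
                CoreSubset(
                    ids,
                    provenance={
                        "method": "M",
                        "size": size,
                        "kernel": tuple(kernel),
                        "objective_space": objective_space,
                        "replicate": rep,
                        "seed": seed,
                        "categories_covered": covered,
                        "sh": sh,
                    },
                ),
            )
        )
    results.sort(key=lambda t: (-t[0], -t[1]))
    return [r[2] for r in results]


def redundancy_minimum_size(
    dataset: CollectionDataset,
    kernel: Sequence[str] = (),
    objective_space: str = "alleles",
    replicates: int = 5,
    iterations: int = 100,
    seed: int = 0,
) -> RedundancyCurve:
    """Smallest subset size whose best M-method run captures every category.

    A greedy cover from the kernel provides an upper bound; the minimal size
    is then located by bisection over sizes (best captured count is
    monotone in subset size), recording every evaluated point of the
    redundancy curve.
    """
    table = dataset.genotypes
    pres = _category_matrix(dataset, objective_space)
    target = int(pres.any(axis=0).sum())
    if target < pres.shape[1]:
        raise ValueError("objective includes categories absent from the collection")
    kernel_idx = table.index_of(kernel)

    # greedy upper bound (also the M-method's own seed construction)
    in_set = np.zeros(table.n_accessions, dtype=bool)
    in_set[kernel_idx] = True
    cover = pres[in_set].sum(axis=0).astype(np.int64)
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    while (cover > 0).sum() < target:
        cand = np.flatnonzero(~in_set)
        gains = pres[cand][:, cover == 0].sum(axis=1)
        pick = rng.choice(cand[gains == gains.max()])
        in_set[pick] = True
        cover += pres[pick]
    upper = max(int(in_set.sum()), max(kernel_idx.size, 1))

    points: dict[int, int] = {upper: target}
    lo, hi = max(kernel_idx.size, 1), upper
    while lo < hi:
        mid = (lo + hi) // 2
        best = sample_m_method(
            dataset, mid, kernel, objective_space, replicates, iterations, seed + mid
        )[0]
        points[mid] = best.provenance["categories_covered"]
        if points[mid] >= target:
            hi = mid
        else:
            lo = mid + 1
    return RedundancyCurve(tuple(sorted(points.items())), minimal_size=hi, target=target)


# ---------------------------------------------------------------------------
# ASLS (weighted multi-measure stochastic local search)
# ---------------------------------------------------------------------------


class _WeightedObjective:
    """Incremental evaluation of the normalized weighted diversity objective."""

    def __init__(self, table: GenotypeTable, weights: dict[str, float]):
        self.table = table
        self.w = weights
        self.loc = table.locus_of_allele
        self.dosage = table.dosage.astype(np.float64)
        self.obs2 = 2.0 * table.observed.astype(np.float64)
        self.pres = table.presence
        self.a_total = table.n_alleles_total
        self.log_a = np.log(self.a_total) if self.a_total > 1 else 1.0
        self.d = _dce_full(table) if weights.get("Dce", 0) > 0 else None

    def value(self, counts, n_l, covered, dsum, k) -> float:
        val = 0.0
        if self.w.get("Cv", 0) > 0:
            val += self.w["Cv"] * covered / self.a_total
        if self.w.get("Sh", 0) > 0:
            val += self.w["Sh"] * float(_entropy_rows(counts, n_l, self.loc)[0]) / self.log_a
        if self.w.get("He", 0) > 0:
            val += self.w["He"] * float(_he_rows(counts, n_l, self.loc, self.table.n_loci)[0])
        if self.w.get("Dce", 0) > 0 and k > 1:
            val += self.w["Dce"] * dsum / (k * (k - 1) / 2)
        return val


def _asls_replica(
    table: GenotypeTable,
    obj: _WeightedObjective,
    size: int,
    steps: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, float]:
    n = table.n_accessions
    sel = rng.choice(n, size=size, replace=False)
    in_set = np.zeros(n, dtype=bool)
    in_set[sel] = True

    counts = obj.dosage[in_set].sum(axis=0)
    n_l = obj.obs2[in_set].sum(axis=0)
    cover = obj.pres[in_set].sum(axis=0).astype(np.int32)
    covered = int((cover > 0).sum())
    if obj.d is not None:
        rowsum = obj.d[:, in_set].sum(axis=1)
        dsum = rowsum[in_set].sum() / 2.0
    else:
        rowsum, dsum = None, 0.0
    current = obj.value(counts, n_l, covered, dsum, size)

    t0, t_end = 0.01, 1e-5
    if size < n:
        for step in range(steps):
            temp = t0 * (t_end / t0) ** (step / max(steps - 1, 1))
            r = int(rng.choice(np.flatnonzero(in_set)))
            c = int(rng.choice(np.flatnonzero(~in_set)))
            c2 = counts - obj.dosage[r] + obj.dosage[c]
            nl2 = n_l - obj.obs2[r] + obj.obs2[c]
            cov2 = cover - obj.pres[r] + obj.pres[c]
            covered2 = int((cov2 > 0).sum())
            if obj.d is not None:
                dsum2 = dsum - rowsum[r] + (rowsum[c] - obj.d[c, r])
            else:
                dsum2 = 0.0
            new = obj.value(c2, nl2, covered2, dsum2, size)
            delta = new - current
            if delta > 0 or rng.random() < np.exp(delta / temp):
                in_set[r] = False
                in_set[c] = True
                counts, n_l, cover, covered, dsum, current = c2, nl2, cov2, covered2, dsum2, new
                if obj.d is not None:
                    rowsum = rowsum + obj.d[:, c] - obj.d[:, r]

        # best-improvement polish to a local optimum
        for _ in range(100):
            improved = False
            for r in np.flatnonzero(in_set):
                cand = np.flatnonzero(~in_set)
                c2 = counts - obj.dosage[r] + obj.dosage[cand]
                nl2 = n_l - obj.obs2[r] + obj.obs2[cand]
                vals = np.zeros(cand.size)
                if obj.w.get("Cv", 0) > 0:
                    zero_after = (cover - obj.pres[r]) == 0
                    lost = int(zero_after[obj.pres[r]].sum())
                    gains = obj.pres[cand][:, zero_after].sum(axis=1) - lost
                    vals += obj.w["Cv"] * (covered + gains) / obj.a_total
                if obj.w.get("Sh", 0) > 0:
                    vals += obj.w["Sh"] * _entropy_rows(c2, nl2, obj.loc) / obj.log_a
                if obj.w.get("He", 0) > 0:
                    vals += obj.w["He"] * _he_rows(c2, nl2, obj.loc, obj.table.n_loci)
                if obj.d is not None:
                    dsum2 = dsum - rowsum[r] + (rowsum[cand] - obj.d[cand, r])
                    vals += obj.w["Dce"] * dsum2 / (size * (size - 1) / 2)
                k = int(np.argmax(vals))
                if vals[k] > current + 1e-12:
                    c = int(cand[k])
                    counts = counts - obj.dosage[r] + obj.dosage[c]
                    n_l = n_l - obj.obs2[r] + obj.obs2[c]
                    cover = cover - obj.pres[r] + obj.pres[c]
                    covered = int((cover > 0).sum())
                    if obj.d is not None:
                        dsum = dsum - rowsum[r] + (rowsum[c] - obj.d[c, r])
                        rowsum = rowsum + obj.d[:, c] - obj.d[:, r]
                    in_set[r] = False
                    in_set[c] = True
                    current = float(vals[k])
                    improved = True
            if not improved:
                break
    return np.flatnonzero(in_set), current


def sample_asls(
    dataset: CollectionDataset,
    size: int,
    weights: dict[str, float],
    replicas: int = 8,
    steps: int = 2500,
    seed: int = 0,
) -> CoreSubset:
    """ASLS: simulated-annealing subset search on a weighted diversity objective.

    `weights` maps measure names (``Cv``, ``Dce``, ``Sh``, ``He``) to
    non-negative weights (rescaled to sum to 1).  Each measure is
    min-max-normalized to [0, 1] against its theoretical bounds (coverage
    and He are natively fractions, Sh is divided by ``ln`` of the total
    allele count, D_CE is already a [0, 1] distance).  The best of
    `replicas` independent annealing runs (each polished to a swap-local
    optimum) is returned.
    """
    table = dataset.genotypes
    if size > table.n_accessions:
        raise ValueError("size exceeds collection size")
    w = normalize_weights(weights)
    obj = _WeightedObjective(table, w)
    best_idx, best_val = None, -np.inf
    for ss in np.random.SeedSequence(seed).spawn(replicas):
        idx, val = _asls_replica(table, obj, size, steps, np.random.default_rng(ss))
        if val > best_val:
            best_idx, best_val = idx, val
    ids = tuple(table.accession_ids[i] for i in best_idx)
    return CoreSubset(
        ids,
        provenance={
            "method": "ASLS",
            "size": size,
            "weights": w,
            "replicas": replicas,
            "steps": steps,
            "seed": seed,
            "objective": best_val,
        },
    )


# ---------------------------------------------------------------------------
# MLST (neighbor-joining tree pruning)
# ---------------------------------------------------------------------------


def _external_edges(d: np.ndarray, ids: list[str]) -> dict[str, float]:
    """Terminal branch length per leaf of the neighbor-joining tree of `d`."""
    n = len(ids)
    if n == 2:
        return {ids[0]: d[0, 1] / 2.0, ids[1]: d[0, 1] / 2.0}
    if n == 3:
        return {
            ids[0]: (d[0, 1] + d[0, 2] - d[1, 2]) / 2.0,
            ids[1]: (d[0, 1] + d[1, 2] - d[0, 2]) / 2.0,
            ids[2]: (d[0, 2] + d[1, 2] - d[0, 1]) / 2.0,
        }
    from skbio import DistanceMatrix
    from skbio.tree import nj

    tree = nj(DistanceMatrix(d, ids))
    return {tip.name: (tip.length or 0.0) for tip in tree.tips()}


def _cherry_leaves(d: np.ndarray, ids: list[str]) -> list[str]:
    """Leaves that belong to a cherry (share their parent with another leaf)."""
    n = len(ids)
    if n <= 3:
        return list(ids)
    from skbio import DistanceMatrix
    from skbio.tree import nj

    tree = nj(DistanceMatrix(d, ids))
    out: list[str] = []
    for node in tree.non_tips(include_self=True):
        tips = [c for c in node.children if c.is_tip()]
        if len(tips) >= 2:
            out.extend(t.name for t in tips)
    return out


def sample_mlst(dataset: CollectionDataset, size: int) -> CoreSubset:
    """Maximum-length-sub-tree sampling: prune the most redundant leaves.

    A neighbor-joining tree is built from the simple-matching dissimilarity;
    at each step the cherry (leaf pair under one node) with the globally
    shortest external edge loses its shorter-edged leaf, and edge lengths
    are re-read from the tree of the remaining accessions.  Ties break on
    the lexicographically larger id so the procedure is deterministic.
    """
    from .diversity import simple_matching_matrix

    table = dataset.genotypes
    if table.n_accessions < 3:
        raise ValueError("MLST requires at least 3 accessions")
    if size > table.n_accessions:
        raise ValueError("size exceeds collection size")
    d_full = simple_matching_matrix(table)
    if np.isnan(d_full).any():
        raise ValueError("dissimilarity undefined for some accession pair (no shared locus)")
    ids = list(table.accession_ids)
    idx = {a: i for i, a in enumerate(table.accession_ids)}
    while len(ids) > size:
        sub = d_full[np.ix_([idx[a] for a in ids], [idx[a] for a in ids])]
        edges = _external_edges(sub, ids)
        cherry = _cherry_leaves(sub, ids)
        victim = min(cherry, key=lambda a: (round(edges[a], 12), a))
        ids.remove(victim)
    ids = [a for a in table.accession_ids if a in set(ids)]
    return CoreSubset(tuple(ids), provenance={"method": "MLST", "size": size})


# ---------------------------------------------------------------------------
# method comparison (the certification table)
# ---------------------------------------------------------------------------


def compare_methods(
    dataset: CollectionDataset,
    size: int,
    configs: Sequence[SamplerConfig],
    alpha: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Run each configured sampler at `size` and certify the cores.

    For every method the returned row holds the diversity report, the
    Mann-Whitney p-values comparing per-locus allelic richness and gene
    diversity of the core against the whole collection, a paired t-test on
    per-locus Shannon components, and the number of reference varieties
    present.
    """
    from .evaluation import mann_whitney_u, paired_t

    if len(configs) < 2:
        raise ValueError("need at least two configurations to compare")
    table = dataset.genotypes
    rich_whole = richness_per_locus(table)
    he_whole = he_per_locus(table)
    sh_whole = shannon_per_locus(table)
    refs = set(dataset.reference_ids)

    rows = []
    for k, cfg in enumerate(configs):
        method = cfg.method.upper()
        run_seed = cfg.seed + seed + k
        if method == "RANDOM":
            core = sample_random(dataset, size, seed=run_seed)
        elif method == "M":
            core = sample_m_method(
                dataset, size, cfg.kernel, cfg.objective_space,
                cfg.replicates, cfg.iterations, seed=run_seed,
            )[0]
        elif method == "ASLS":
            core = sample_asls(
                dataset, size, cfg.weights or {"Sh": 1.0},
                replicas=cfg.replicates, steps=cfg.steps, seed=run_seed,
            )
        elif method == "MLST":
            core = sample_mlst(dataset, size)
        else:
            raise ValueError(f"unknown method {cfg.method!r}")
        core.report = diversity_report(dataset, core.ids)
        _, p_rich = mann_whitney_u(richness_per_locus(table, core.ids), rich_whole)
        core_he = he_per_locus(table, core.ids)
        _, p_he = mann_whitney_u(core_he[~np.isnan(core_he)], he_whole[~np.isnan(he_whole)])
        core_sh = shannon_per_locus(table, core.ids)
        _, p_sh = paired_t(core_sh, sh_whole)
        row = {"method": cfg.name, **core.report.to_row()}
        row.update(
            {
                "p_richness_mw": p_rich,
                "p_he_mw": p_he,
                "p_sh_paired_t": p_sh,
                "richness_differs": p_rich < alpha,
                "n_references": len(refs & set(core.ids)),
                "ids": core.ids,
            }
        )
        rows.append(row)
    return pd.DataFrame(rows).set_index("method")
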