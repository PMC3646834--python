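"""Association-mapping suitability diagnostics for a candidate panel.

A core collection intended for association mapping should consist of
largely unrelated accessions with little hidden structure; otherwise
spurious marker-trait associations dominate.  This module provides the
classical diagnostics: the Loiselle marker-based relative kinship, pairwise
linkage disequilibrium between loci with a permutation test, principal
coordinate analysis of a dissimilarity matrix, the Evanno ΔK summary of
externally computed clustering log-likelihoods, and the two nonparametric
tests used to certify cores against their source collection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data import GenotypeTable

__all__ = [
    "KinshipMatrix",
    "LDResult",
    "PCoAResult",
    "loiselle_kinship",
    "kinship_histogram",
    "ld_pairwise",
    "ld_significance_classes",
    "pcoa",
    "evanno_delta_k",
    "mann_whitney_u",
    "paired_t",
]


@dataclass
class KinshipMatrix:
    """Symmetric relative-kinship matrix; negatives already truncated to 0."""

    ids: tuple[str, ...]
    values: np.ndarray  # (n, n)

    def pair_values(self) -> np.ndarray:
        """Off-diagonal (unordered pair) kinship values."""
        iu = np.triu_indices(len(self.ids), k=1)
        return self.values[iu]


def loiselle_kinship(table: GenotypeTable, subset: Sequence[str] | None = None) -> KinshipMatrix:
    """Loiselle et al. relative kinship from multiallelic co-dominant markers.

    For accessions i, j:

    ``F_ij = [sum_l sum_a (x_ila - p_la)(x_jla - p_la)
              + sum_l sum_a p_la (1 - p_la) / (n_l - 1)] / sum_l sum_a p_la (1 - p_la)``

    with ``x`` the within-individual allele frequency (0, 0.5, 1),
    ``p`` the allele frequency in the evaluated panel and ``n_l`` the
    number of gene copies at locus ``l``.  Sums run over loci jointly
    observed by the pair (pairwise deletion).  Values below 0 — pairs less
    related than random — are truncated to 0.  Reference frequencies are
    computed within the evaluated panel itself.
    """
    ids = tuple(subset) if subset is not None else table.accession_ids
    idx = table.index_of(ids)
    if idx.size < 3:
        raise ValueError("kinship needs at least 3 accessions")
    loc = table.locus_of_allele
    x = table.dosage[idx].astype(np.float64) / 2.0
    obs = table.observed[idx].astype(np.float64)
    n_l = 2.0 * obs.sum(axis=0)
    counts = table.dosage[idx].sum(axis=0, dtype=np.float64)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = counts / n_l[loc]
    p = np.nan_to_num(p)
    pq = p * (1.0 - p)
    den_l = np.bincount(loc, weights=pq, minlength=table.n_loci)
    if den_l.sum() <= 0:
        raise ValueError("panel is monomorphic at every locus; kinship undefined")
    with np.errstate(invalid="ignore", divide="ignore"):
        bias_l = np.where(n_l > 1, np.bincount(loc, weights=pq, minlength=table.n_loci)
                          / np.maximum(n_l - 1.0, 1.0), 0.0)
    centered = (x - p[None, :]) * obs[:, loc]  # zero out unobserved loci
    num = centered @ centered.T + (obs * bias_l) @ obs.T
    den = (obs * den_l) @ obs.T
    with np.errstate(invalid="ignore", divide="ignore"):
        f = num / den
    f = np.nan_to_num(f)
    f[f < 0] = 0.0
    return KinshipMatrix(tuple(ids), f)


def kinship_histogram(
    kinship: KinshipMatrix, bin_width: float = 0.05, cap: float = 0.45
) -> tuple[np.ndarray, np.ndarray]:
    """Bin off-diagonal kinship values; the final bin is open at `cap`.

    Returns (lower bin edges, frequencies summing to 1).
    """
    vals = kinship.pair_values()
    edges = np.arange(0.0, cap + bin_width / 2, bin_width)
    bins = np.concatenate([edges, [np.inf]])
    freq, _ = np.histogram(vals, bins=bins)
    return edges, freq / max(vals.size, 1)


# ---------------------------------------------------------------------------
# linkage disequilibrium
# ---------------------------------------------------------------------------


@dataclass
class LDResult:
    """Per-locus-pair composite r² with permutation p-values."""

    pairs: pd.DataFrame  # columns: locus1, locus2, r2, p_value, n_perm, n_used
    retained_alleles: dict[str, int]
    dropped_loci: tuple[str, ...]

    def significant_fraction(self, alpha: float = 0.05) -> float:
        return float((self.pairs["p_value"] < alpha).mean())


def _pair_r2(
    d1: np.ndarray, d2: np.ndarray, w: np.ndarray
) -> float:
    """Frequency-weighted mean of squared dosage correlations between allele pairs."""
    c1 = d1 - d1.mean(axis=0)
    c2 = d2 - d2.mean(axis=0)
    n = d1.shape[0]
    cov = c1.T @ c2 / n
    v1 = (c1**2).mean(axis=0)
    v2 = (c2**2).mean(axis=0)
    denom = np.outer(v1, v2)
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where(denom > 0, cov**2 / denom, 0.0)
    return float((w * r2).sum() / w.sum())


def ld_pairwise(
    table: GenotypeTable,
    subset: Sequence[str] | None = None,
    min_allele_freq: float = 0.05,
    n_perm: int = 1000,
    seed: int = 0,
) -> LDResult:
    """Composite linkage disequilibrium between every pair of loci.

    Alleles rarer than `min_allele_freq` in the panel are removed first;
    an accession left with no retained allele at a locus is treated as
    missing there, and loci left with fewer than two retained alleles are
    dropped from pairing.  For each locus pair the statistic is the
    allele-frequency-weighted mean over retained allele pairs of the
    squared correlation between allele dosages (the composite genotypic
    disequilibrium, requiring no phase information).  Significance comes
    from permuting accession labels at one locus: ``p = (1 + #{permuted r²
    >= observed}) / (n_perm + 1)``, so p is never 0.
    """
    ids = tuple(subset) if subset is not None else table.accession_ids
    idx = table.index_of(ids)
    off = table.locus_offsets
    rng = np.random.default_rng(seed)

    blocks: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    dropped: list[str] = []
    retained: dict[str, int] = {}
    for l, locus in enumerate(table.loci):
        d = table.dosage[idx, off[l] : off[l + 1]].astype(np.float64)
        m = table.observed[idx, l]
        n_copies = 2.0 * m.sum()
        if n_copies == 0:
            dropped.append(locus)
            continue
        freqs = d.sum(axis=0) / n_copies
        keep = freqs >= min_allele_freq
        if keep.sum() < 2:
            dropped.append(locus)
            continue
        d = d[:, keep]
        m = m & (d.sum(axis=1) > 0)  # genotypes carrying only removed alleles -> missing
        freqs = d[m].sum(axis=0) / max(2.0 * m.sum(), 1.0)
        blocks[locus] = (d, m, freqs)
        retained[locus] = int(keep.sum())
    if dropped:
        warnings.warn(f"loci dropped after allele-frequency filter: {dropped}")
    if len(blocks) < 2:
        raise ValueError("fewer than two loci retained after allele-frequency filtering")

    rows = []
    for l1, l2 in combinations(blocks, 2):
        d1, m1, f1 = blocks[l1]
        d2, m2, f2 = blocks[l2]
        use = m1 & m2
        n_used = int(use.sum())
        if n_used < 3:
            rows.append((l1, l2, np.nan, np.nan, 0, n_used))
            continue
        a, b = d1[use], d2[use]
        w = np.outer(f1, f2)
        obs_r2 = _pair_r2(a, b, w)
        # vectorized permutation null: permute rows of the second locus
        perm = np.argsort(rng.random((n_perm, n_used)), axis=1)
        c1 = a - a.mean(axis=0)
        c2 = b - b.mean(axis=0)
        v1 = (c1**2).mean(axis=0)
        v2 = (c2**2).mean(axis=0)
        denom = np.outer(v1, v2)
        cov = np.einsum("na,pnb->pab", c1, c2[perm]) / n_used
        with np.errstate(invalid="ignore", divide="ignore"):
            r2 = np.where(denom[None] > 0, cov**2 / denom[None], 0.0)
        null = (w[None] * r2).sum(axis=(1, 2)) / w.sum()
        p = (1.0 + (null >= obs_r2 - 1e-12).sum()) / (n_perm + 1.0)
        rows.append((l1, l2, obs_r2, p, n_perm, n_used))
    pairs = pd.DataFrame(
        rows, columns=["locus1", "locus2", "r2", "p_value", "n_perm", "n_used"]
    )
    return LDResult(pairs, retained, tuple(dropped))


def ld_significance_classes(result: LDResult, alpha: float = 0.05) -> pd.Series:
    """Count locus pairs by significance class (high / intermediate / low / ns)."""
    p = result.pairs["p_value"]
    return pd.Series(
        {
            "high (p<0.0001)": int((p < 1e-4).sum()),
            "intermediate (0.0001<=p<0.01)": int(((p >= 1e-4) & (p < 0.01)).sum()),
            "low (0.01<=p<alpha)": int(((p >= 0.01) & (p < alpha)).sum()),
            "ns": int((p >= alpha).sum()),
        }
    )


# ---------------------------------------------------------------------------
# ordination
# ---------------------------------------------------------------------------


@dataclass
class PCoAResult:
    """Classical-scaling coordinates and per-axis explained variance."""

    coordinates: np.ndarray  # (n, n_axes)
    explained: np.ndarray  # (n_axes,) fractions of positive-eigenvalue variance
    eigenvalues: np.ndarray  # all eigenvalues, descending


def pcoa(dissimilarity: np.ndarray, n_axes: int = 2) -> PCoAResult:
    """Principal coordinate analysis (classical metric scaling).

    Double-centers the squared dissimilarity matrix and eigendecomposes it;
    coordinates are returned for the top `n_axes` positive-eigenvalue axes
    and explained variance is each eigenvalue's share of the positive
    spectrum.
    """
    d = np.asarray(dissimilarity, dtype=np.float64)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("dissimilarity must be a square matrix")
    if not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("dissimilarity must be symmetric")
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    pos = vals > max(vals.max(), 0) * 1e-12
    n_axes = min(n_axes, int(pos.sum()))
    coords = vecs[:, :n_axes] * np.sqrt(vals[:n_axes])
    explained = vals[:n_axes] / vals[pos].sum()
    return PCoAResult(coords, explained, vals)


# ---------------------------------------------------------------------------
# clustering summaries and certification tests
# ---------------------------------------------------------------------------


def evanno_delta_k(run_loglikelihoods: Mapping[int, Sequence[float]]) -> pd.Series:
    """Second-order rate of change of L(K) across clustering runs.

    ``ΔK = |mean L(K+1) - 2 mean L(K) + mean L(K-1)| / sd(L(K))`` for each
    interior K.  K values with zero spread across runs get NaN (undefined).
    """
    ks = sorted(run_loglikelihoods)
    if len(ks) < 3 or any(b - a != 1 for a, b in zip(ks, ks[1:])):
        raise ValueError("need >= 3 consecutive K values")
    means = {k: float(np.mean(run_loglikelihoods[k])) for k in ks}
    out = {}
    for k in ks[1:-1]:
        runs = np.asarray(run_loglikelihoods[k], dtype=float)
        if runs.size < 2:
            raise ValueError(f"K={k}: need >= 2 runs for the spread")
        sd = runs.std(ddof=1)
        if sd == 0:
            warnings.warn(f"K={k}: zero spread across runs; ΔK undefined")
            out[k] = np.nan
        else:
            out[k] = abs(means[k + 1] - 2 * means[k] + means[k - 1]) / sd
    return pd.Series(out, name="delta_k")


def mann_whitney_u(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Uses the exact null distribution when the combined sample is small
    (n <= 12) and tie-free, otherwise the tie-corrected normal
    approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs at least 2 values")
    pooled = np.concatenate([x, y])
    exact = pooled.size <= 12 and np.unique(pooled).size == pooled.size
    res = stats.mannwhitneyu(x, y, alternative="two-sided",
                             method="exact" if exact else "asymptotic")
    return float(res.statistic), float(res.pvalue)


def paired_t(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided paired t-test on elementwise differences."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 2:
        raise ValueError("paired samples must have equal length >= 2")
    diffs = x - y
    if np.allclose(diffs.std(ddof=1), 0.0):
        warnings.warn("zero variance in paired differences; p set to 1")
        return 0.0, 1.0
    res = stats.ttest_rel(x, y)
    return float(res.statistic), float(res.pvalue)
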