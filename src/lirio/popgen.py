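"""Diversity and differentiation statistics from SNP matrices.

Implements the per-base-pair estimators used in resequencing studies:
nucleotide diversity π (unbiased mean pairwise difference), the Watterson
estimator θw = S / (a_n · L), Hudson's FST as a ratio of sums over sites,
allele-sharing p-distances, and neighbour joining (delegated to
scikit-bio) for grouping samples.

Allele matrices code 0 = reference and 1 = alternate for haplotypes, or
0/1/2 alternate-allele dosage for diploid genotypes; -1 marks missing
calls.  π and FST use per-site pairwise deletion; θw normalizes by the
harmonic number of the group's full allele count.  All statistics are per
callable base pair, so the callable length ``L`` is a required input — a
per-genome π cannot be derived from a SNP count alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skbio import DistanceMatrix
from skbio.tree import nj as _skbio_nj

from .trees import Tree

__all__ = ["SNPMatrix", "DiversityStats", "FstResult", "PopgenError",
           "nucleotide_diversity", "watterson_theta", "hudson_fst",
           "pairwise_distance", "neighbor_joining", "harmonic_number"]


class PopgenError(ValueError):
    pass


@dataclass
class SNPMatrix:
    """Samples x sites allele matrix with positions and callable length."""

    samples: list[str]
    positions: np.ndarray  # integer site positions
    matrix: np.ndarray     # (n_samples, n_sites), int8; -1 = missing
    ploidy: int = 1        # 1: haplotypes 0/1; 2: genotypes 0/1/2
    L: int = 0             # callable sequence length in bp

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.int8)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        if self.matrix.shape != (len(self.samples), len(self.positions)):
            raise PopgenError("matrix shape does not match samples x positions")
        if self.ploidy not in (1, 2):
            raise PopgenError("ploidy must be 1 or 2")
        if self.matrix.size and self.matrix.max(initial=0) > self.ploidy:
            raise PopgenError("allele dosages exceed ploidy")
        if self.L < len(self.positions):
            raise PopgenError("callable length L smaller than number of sites")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.positions)

    def rows(self, names: list[str] | None) -> np.ndarray:
        if names is None:
            return np.arange(self.n_samples)
        index = {s: i for i, s in enumerate(self.samples)}
        missing = [n for n in names if n not in index]
        if missing:
            raise PopgenError(f"unknown samples: {missing}")
        return np.array([index[n] for n in names])


@dataclass
class DiversityStats:
    group: str
    pi: float
    theta_w: float
    S: int
    n: int          # allele copies in the group
    a_n: float
    L: int


@dataclass
class FstResult:
    group_a: str
    group_b: str
    fst: float
    numerator: float
    denominator: float

    @property
    def fst_clamped(self) -> float:
        return min(1.0, max(0.0, self.fst))


def harmonic_number(n: int) -> float:
    """a_n = sum_{i=1}^{n-1} 1/i, the Watterson normalizer."""
    return float(np.sum(1.0 / np.arange(1, n)))


def _allele_counts(m: SNPMatrix, rows: np.ndarray):
    """Per-site alternate-allele count and called allele count."""
    sub = m.matrix[rows]
    called = (sub >= 0)
    alt = np.where(called, sub, 0).sum(axis=0).astype(float)
    n_alleles = called.sum(axis=0).astype(float) * m.ploidy
    return alt, n_alleles


def diversity_stats(m: SNPMatrix, group: list[str] | None = None,
                    label: str = "all") -> DiversityStats:
    """π, θw and S for one group in a single pass."""
    rows = m.rows(group)
    if len(rows) < 2 and m.ploidy == 1:
        raise PopgenError("need at least 2 sequences for diversity statistics")
    if m.L <= 0:
        raise PopgenError("callable length L must be positive")
    alt, n_all = _allele_counts(m, rows)
    ok = n_all >= 2
    alt, n_all = alt[ok], n_all[ok]
    p = np.divide(alt, n_all, out=np.zeros_like(alt), where=n_all > 0)
    # unbiased per-site heterozygosity: 2 p (1-p) n/(n-1)
    het = 2.0 * p * (1.0 - p) * n_all / (n_all - 1.0)
    pi = float(het.sum() / m.L)
    seg = int(np.sum((alt > 0) & (alt < n_all)))
    n_total = len(rows) * m.ploidy
    a_n = harmonic_number(n_total)
    theta = seg / (a_n * m.L) if a_n > 0 else 0.0
    return DiversityStats(label, pi, theta, seg, n_total, a_n, m.L)


def nucleotide_diversity(m: SNPMatrix, group: list[str] | None = None,
                         label: str = "all") -> DiversityStats:
    return diversity_stats(m, group, label)


def watterson_theta(m: SNPMatrix, group: list[str] | None = None,
                    label: str = "all") -> DiversityStats:
    return diversity_stats(m, group, label)


def hudson_fst(m: SNPMatrix, group_a: list[str], group_b: list[str],
               labels: tuple[str, str] = ("A", "B")) -> FstResult:
    """Hudson's FST as a ratio of sums across sites.

    Per site, with allele frequencies pA, pB and unbiased within-group
    heterozygosities hA, hB:
        between = pA (1-pB) + pB (1-pA)
        numerator += between - (hA + hB) / 2
        denominator += between
    Sites with fewer than 2 called alleles in either group are skipped.
    Small negative values are reported raw (``fst_clamped`` clamps).
    """
    ra, rb = m.rows(group_a), m.rows(group_b)
    if len(ra) * m.ploidy < 2 or len(rb) * m.ploidy < 2:
        raise PopgenError("need at least 2 allele copies per group")
    alt_a, n_a = _allele_counts(m, ra)
    alt_b, n_b = _allele_counts(m, rb)
    ok = (n_a >= 2) & (n_b >= 2)
    alt_a, n_a, alt_b, n_b = alt_a[ok], n_a[ok], alt_b[ok], n_b[ok]
    pa, pb = alt_a / n_a, alt_b / n_b
    between = pa * (1 - pb) + pb * (1 - pa)
    ha = 2 * pa * (1 - pa) * n_a / (n_a - 1)
    hb = 2 * pb * (1 - pb) * n_b / (n_b - 1)
    num = float(np.sum(between - 0.5 * (ha + hb)))
    den = float(np.sum(between))
    if den <= 0:
        raise PopgenError("no between-group diversity; FST undefined")
    return FstResult(labels[0], labels[1], num / den, num, den)


def pairwise_distance(m: SNPMatrix) -> np.ndarray:
    """Allele-sharing p-distance between all sample pairs.

    Haplotypes: fraction of co-called sites with differing alleles.
    Diploid genotypes: mean |dosage difference| / ploidy over co-called
    sites.  A pair with zero co-called sites is an error.
    """
    if m.n_samples < 2:
        raise PopgenError("need at least 2 samples")
    x = m.matrix.astype(float)
    x[m.matrix < 0] = np.nan
    n = m.n_samples
    d = np.zeros((n, n))
    for i in range(n):
        diff = np.abs(x[i + 1:] - x[i])  # NaN where either missing
        cmp = np.sum(~np.isnan(diff), axis=1)
        if np.any(cmp == 0):
            j = i + 1 + int(np.argmax(cmp == 0))
            raise PopgenError(
                f"samples {m.samples[i]!r} and {m.samples[j]!r} share no called sites")
        d[i, i + 1:] = d[i + 1:, i] = np.nansum(diff, axis=1) / (cmp * m.ploidy)
    return d


def neighbor_joining(d: np.ndarray, names: list[str]) -> Tree:
    """Neighbour joining (Saitou–Nei) on a symmetric distance matrix.

    Delegates to scikit-bio's implementation; exact on additive matrices.
    Taxa are presented in sorted order so ties resolve deterministically.
    """
    d = np.asarray(d, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1] or d.shape[0] != len(names):
        raise PopgenError("distance matrix must be square and match names")
    if not np.allclose(d, d.T, atol=1e-12):
        raise PopgenError("distance matrix must be symmetric")
    if d.shape[0] < 3:
        raise PopgenError("neighbour joining needs at least 3 taxa")
    order = np.argsort(np.asarray(names, dtype=object))
    dm = DistanceMatrix(d[np.ix_(order, order)], [names[i] for i in order])
    result = _skbio_nj(dm)
    for node in result.traverse():  # NJ can emit tiny negative lengths
        if node.length is not None and node.length < 0:
            node.length = 0.0
    return Tree.from_newick(str(result).strip())
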