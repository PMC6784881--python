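"""Ks / 4DTv estimation and whole-genome-duplication dating.

Synonymous divergence between a pair of coding sequences is estimated
with the Nei–Gojobori (NG86) counting method: synonymous site fractions
per codon averaged over the two sequences, equal-weight pathway averaging
for codons differing at more than one position, and a Jukes–Cantor
multiple-hit correction Ks = -(3/4) ln(1 - (4/3) pS).  Mutations to stop
codons count as nonsynonymous; pathways through stop codons are excluded
from the average.

A paranome Ks distribution is built with node weighting: within each gene
family the pairwise Ks values are clustered (average linkage) and each of
the m-1 internal join nodes contributes one value, so a 10-gene family
contributes total weight 9 no matter how many of its 45 raw pairs were
measured.  Peaks of the weighted kernel density estimate are converted to
absolute ages with T = Ks / (2r) for a substitution rate r.

4DTv — the transversion fraction at fourfold-degenerate third codon
positions — is reported raw (uncorrected), exactly as defined.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio.Data.CodonTable import standard_dna_table
from scipy.cluster.hierarchy import linkage
from scipy.signal import find_peaks
from scipy.stats import gaussian_kde

from .alignment import Alignment

__all__ = ["KsEstimate", "KsDistribution", "AgeEstimate", "WgdError",
           "ng86_ks", "fourdtv", "node_weighted_paranome",
           "ks_density_peaks", "ks_to_age"]

BASES = "ACGT"
PURINES = frozenset("AG")
SHORT_ALIGNMENT_CODONS = 30

_CODE: dict[str, str] = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    _CODE[_stop] = "*"


class WgdError(ValueError):
    pass


@dataclass
class KsEstimate:
    pair_id: str
    ks: float
    ka: float
    s_sites: float
    n_sites: float
    n_codons: int
    ps: float
    pn: float
    saturated: bool = False


@dataclass
class KsDistribution:
    values: np.ndarray
    weights: np.ndarray
    peaks: list[tuple[float, float]] = field(default_factory=list)
    bandwidth: float | None = None
    range_filter: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.values.shape != self.weights.shape:
            raise WgdError("values/weights shape mismatch")
        if np.any(self.weights <= 0) or np.any(self.weights > 1 + 1e-12):
            raise WgdError("weights must lie in (0, 1]")


@dataclass
class AgeEstimate:
    ks_peak: float
    rate: float  # substitutions / site / year
    years: float = field(init=False)
    formula: str = "T = Ks/(2r)"

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise WgdError("substitution rate must be positive")
        if self.ks_peak < 0:
            raise WgdError("Ks must be non-negative")
        self.years = self.ks_peak / (2.0 * self.rate)

    @property
    def ma(self) -> float:
        return self.years / 1e6


# ----------------------------------------------------------------------
# NG86
# ----------------------------------------------------------------------

def _syn_sites(codon: str) -> float:
    """Synonymous site count of one codon (stops count as nonsynonymous)."""
    aa = _CODE[codon]
    total = 0.0
    for pos in range(3):
        for alt in BASES:
            if alt == codon[pos]:
                continue
            mutant = codon[:pos] + alt + codon[pos + 1:]
            if _CODE[mutant] == aa:  # a stop never equals a sense aa
                total += 1.0 / 3.0
    return total


_SYN_SITES = {c: _syn_sites(c) for c in _CODE if _CODE[c] != "*"}


def _step_type(c1: str, c2: str) -> str:
    return "syn" if _CODE[c1] == _CODE[c2] else "nonsyn"


def _pathway_counts(c1: str, c2: str) -> tuple[float, float]:
    """Mean (synonymous, nonsynonymous) difference counts over all
    mutational pathways between two codons, stop-free pathways only
    (all pathways if every ordering passes a stop)."""
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(diff):
        cur = c1
        steps = []
        blocked = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if _CODE[nxt] == "*":
                blocked = True
            steps.append((cur, nxt))
            cur = nxt
        syn = sum(1 for a, b in steps if _CODE[a] != "*" and _CODE[b] != "*"
                  and _step_type(a, b) == "syn")
        non = len(steps) - syn
        paths.append((blocked, syn, non))
    valid = [(s, n) for blocked, s, n in paths if not blocked]
    if not valid:
        valid = [(s, n) for _, s, n in paths]
    syn = sum(s for s, _ in valid) / len(valid)
    non = sum(n for _, n in valid) / len(valid)
    return syn, non


def _codon_pairs(pair: Alignment):
    if pair.n_taxa != 2:
        raise WgdError("NG86 requires exactly 2 sequences")
    s1, s2 = pair.sequences
    if len(s1) % 3 != 0:
        raise WgdError("sequence length not divisible by 3")
    for i in range(0, len(s1), 3):
        c1, c2 = s1[i:i + 3], s2[i:i + 3]
        if any(b not in BASES for b in c1 + c2):
            continue  # gapped or ambiguous codon: skipped
        if _CODE[c1] == "*" or _CODE[c2] == "*":
            raise WgdError(f"stop codon at codon {i // 3 + 1}")
        yield c1, c2


def _jc_correct(p: float) -> tuple[float, bool]:
    if p >= 0.75:
        return float("nan"), True
    return -0.75 * np.log1p(-4.0 * p / 3.0), False


def ng86_ks(pair: Alignment, pair_id: str = "") -> KsEstimate:
    """NG86 Ks/Ka for a two-sequence codon alignment."""
    s_sum1 = s_sum2 = 0.0
    sd = nd = 0.0
    n_codons = 0
    for c1, c2 in _codon_pairs(pair):
        n_codons += 1
        s_sum1 += _SYN_SITES[c1]
        s_sum2 += _SYN_SITES[c2]
        dsyn, dnon = _pathway_counts(c1, c2)
        sd += dsyn
        nd += dnon
    if n_codons == 0:
        raise WgdError("no comparable codons")
    if n_codons < SHORT_ALIGNMENT_CODONS:
        warnings.warn(f"only {n_codons} comparable codons; Ks estimate unstable",
                      stacklevel=2)
    s_sites = (s_sum1 + s_sum2) / 2.0
    n_sites = 3.0 * n_codons - s_sites
    ps = sd / s_sites if s_sites > 0 else 0.0
    pn = nd / n_sites if n_sites > 0 else 0.0
    ks, sat_s = _jc_correct(ps)
    ka, sat_n = _jc_correct(pn)
    return KsEstimate(pair_id or "-".join(pair.names), ks, ka,
                      s_sites, n_sites, n_codons, ps, pn,
                      saturated=sat_s or sat_n)


# ----------------------------------------------------------------------
# 4DTv
# ----------------------------------------------------------------------

_FOURFOLD_PREFIXES = frozenset(
    p for p in ("".join(t) for t in itertools.product(BASES, repeat=2))
    if len({_CODE[p + b] for b in BASES}) == 1
)


def fourdtv(pair: Alignment) -> float:
    """Transversion fraction at fourfold-degenerate third codon positions.

    A position qualifies when both codons share identical first two bases
    and that prefix is fourfold degenerate.  The fraction is raw — no
    multiple-hit correction is applied.
    """
    qualifying = 0
    transversions = 0
    for c1, c2 in _codon_pairs(pair):
        if c1[:2] != c2[:2] or c1[:2] not in _FOURFOLD_PREFIXES:
            continue
        qualifying += 1
        if (c1[2] in PURINES) != (c2[2] in PURINES):
            transversions += 1
    if qualifying == 0:
        raise WgdError("no fourfold-degenerate third-codon positions")
    return transversions / qualifying


# ----------------------------------------------------------------------
# node-weighted paranome and peak dating
# ----------------------------------------------------------------------

def node_weighted_paranome(families: dict[str, list[str]],
                           ks_values: dict[frozenset, float]) -> KsDistribution:
    """One Ks value per duplication node of each family's dendrogram.

    Average-linkage clustering on the family's pairwise Ks matrix; the
    m-1 join heights are the node values (weight 1 each), so a family
    contributes total weight m-1 regardless of its m(m-1)/2 raw pairs.
    """
    values: list[float] = []
    for fam, genes in families.items():
        if len(genes) < 2:
            raise WgdError(f"family {fam!r} has fewer than 2 genes")
        missing = [(a, b) for a, b in itertools.combinations(genes, 2)
                   if frozenset((a, b)) not in ks_values]
        if missing:
            raise WgdError(f"family {fam!r} missing Ks for pairs: {missing}")
        condensed = np.array([ks_values[frozenset((a, b))]
                              for a, b in itertools.combinations(genes, 2)])
        if len(genes) == 2:
            values.append(float(condensed[0]))
            continue
        z = linkage(condensed, method="average")
        values.extend(float(h) for h in z[:, 2])
    arr = np.asarray(values)
    return KsDistribution(arr, np.ones_like(arr))


def ks_density_peaks(dist: KsDistribution, bandwidth: float | str = "silverman",
                     ks_range: tuple[float, float] = (0.01, 3.0),
                     min_prominence: float = 0.1,
                     grid_size: int = 512) -> list[tuple[float, float]]:
    """Peaks of the weighted Gaussian KDE of a Ks distribution.

    Values outside ``ks_range`` (and non-finite values, e.g. saturated
    pairs) are excluded.  Peaks are interior local maxima with prominence
    at least ``min_prominence`` of the maximum density, sorted by height.
    """
    lo, hi = ks_range
    ok = np.isfinite(dist.values) & (dist.values >= lo) & (dist.values <= hi)
    vals, w = dist.values[ok], dist.weights[ok]
    if len(vals) == 0:
        raise WgdError("no Ks values inside the range filter")
    if len(vals) < 50:
        raise WgdError(f"only {len(vals)} Ks values in range; need >= 50")
    std = float(np.sqrt(np.cov(vals, aweights=w)))
    if bandwidth == "silverman":
        n_eff = float(w.sum() ** 2 / (w ** 2).sum())
        bw_used = 1.06 * std * n_eff ** (-1 / 5)
    else:
        bw_used = float(bandwidth)
    # boundary reflection at both range edges: the density of the
    # range-truncated sample is otherwise suppressed near the edges,
    # which manufactures spurious interior modes on decaying backgrounds
    aug = np.concatenate([vals, 2 * lo - vals, 2 * hi - vals])
    w3 = np.concatenate([w, w, w])
    std_aug = float(np.sqrt(np.cov(aug, aweights=w3)))
    kde = gaussian_kde(aug, weights=w3, bw_method=bw_used / std_aug)
    grid = np.linspace(lo, hi, grid_size)
    density = 3.0 * kde(grid)
    idx, _ = find_peaks(density, prominence=min_prominence * density.max())
    peaks = sorted(((float(grid[i]), float(density[i])) for i in idx),
                   key=lambda p: -p[1])
    dist.peaks = peaks
    dist.bandwidth = bw_used
    dist.range_filter = ks_range
    return peaks


def ks_to_age(ks: float, rate: float) -> AgeEstimate:
    """Absolute age T = Ks / (2 r) for substitution rate r per site per year."""
    return AgeEstimate(ks, rate)
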