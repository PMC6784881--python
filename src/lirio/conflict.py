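"""Gene-wise topology conflict testing (ΔGLS).

The question: when eudicots, monocots and magnoliids diverged in rapid
succession, which pair is sister?  Three competing rooted arrangements of
the five clades (gymnosperm outgroup, basal angiosperm, then the three
focal clades) are scored gene by gene: orthogroups are filtered to
low-copy, phylogenetically well-behaved sets; each gene's alignment is
scored under all three topology hypotheses with branch lengths free and
topology fixed; the difference in gene-wise log-likelihood scores (ΔGLS)
assigns each gene to the hypothesis it supports; genes with outlying
ΔGLS are removed (Tukey fences); and a chi-squared goodness-of-fit test
asks whether support is spread uniformly across the three hypotheses —
the signature of ancient rapid divergence — or concentrated on one.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import chi2 as _chi2

from .alignment import Alignment
from .likelihood import MAX_BRANCH_LENGTH, optimize_branch_lengths
from .models import SubstitutionModel
from .popgen import neighbor_joining
from .trees import Tree

__all__ = ["CladeMap", "Orthogroup", "TopologyHypothesis", "GeneTopologyResult",
           "SupportCounts", "ConflictError", "CLADES", "DEFAULT_CLADE_MINIMA",
           "build_hypotheses", "filter_low_copy", "screen_by_gene_tree",
           "gene_topology_likelihoods", "delta_gls", "exclude_outliers",
           "support_counts", "chisq_uniform_test", "chisq_sf",
           "clade_specific_families", "family_bias_test"]

CLADES = ("eudicot", "monocot", "magnoliid", "basal_angiosperm", "gymnosperm")
DEFAULT_CLADE_MINIMA = {"eudicot": 4, "monocot": 4, "magnoliid": 3,
                        "basal_angiosperm": 1, "gymnosperm": 1}
UNINFORMATIVE = "uninformative"

CladeMap = dict  # species -> clade label


class ConflictError(ValueError):
    pass


@dataclass
class Orthogroup:
    id: str
    genes: dict[str, list[str]]  # species -> gene copies
    alignment: Alignment | None = None

    @property
    def species_present(self) -> list[str]:
        return [s for s, g in self.genes.items() if g]


@dataclass
class TopologyHypothesis:
    index: int  # 1..3
    tree: Tree  # species-level, gymnosperm outgroup
    description: str = ""


@dataclass
class GeneTopologyResult:
    orthogroup_id: str
    lnl: tuple[float, float, float]
    d12: float = field(init=False)
    d13: float = field(init=False)
    d23: float = field(init=False)
    supported: int | str = field(init=False)
    tie_tol: float = 1e-3
    outlier: bool = False

    def __post_init__(self) -> None:
        l1, l2, l3 = self.lnl
        self.d12 = l1 - l2
        self.d13 = l1 - l3
        self.d23 = l2 - l3
        ordered = sorted(enumerate(self.lnl, start=1), key=lambda t: -t[1])
        if ordered[0][1] - ordered[1][1] > self.tie_tol:
            self.supported = ordered[0][0]
        else:
            self.supported = UNINFORMATIVE

    @property
    def deltas(self) -> dict[str, float]:
        return {"d12": self.d12, "d13": self.d13, "d23": self.d23}


@dataclass
class SupportCounts:
    counts: tuple[int, int, int]
    total: int = field(init=False)
    percentages: tuple[float, float, float] = field(init=False)
    chi2: float = field(init=False)
    df: int = field(init=False)
    p: float = field(init=False)

    def __post_init__(self) -> None:
        self.total = sum(self.counts)
        self.percentages = tuple(round(100.0 * c / self.total, 2)
                                 for c in self.counts)
        self.chi2, self.df, self.p = chisq_uniform_test(self.counts)


# ----------------------------------------------------------------------
# hypothesis construction
# ----------------------------------------------------------------------

def _ladder(names: list[str]) -> str:
    if len(names) == 1:
        return names[0]
    return f"({names[0]},{_ladder(names[1:])})"


def build_hypotheses(clade_species: dict[str, list[str]]) -> list[TopologyHypothesis]:
    """The three species-level arrangements of the focal clades.

    1: ((monocots, (eudicots, magnoliids)), basal angiosperm) + outgroup
    2: ((eudicots, (monocots, magnoliids)), basal angiosperm) + outgroup
    3: ((magnoliids, (monocots, eudicots)), basal angiosperm) + outgroup

    Within-clade topology is one fixed guide (a ladder over the given
    species order), identical across hypotheses, so the three trees
    differ only in the arrangement of the three focal clades.
    """
    missing = [c for c in CLADES if not clade_species.get(c)]
    if missing:
        raise ConflictError(f"clades without species: {missing}")
    sub = {c: _ladder(list(clade_species[c])) for c in CLADES}
    e, m, g = sub["eudicot"], sub["monocot"], sub["magnoliid"]
    basal, gym = sub["basal_angiosperm"], sub["gymnosperm"]
    arrangements = {
        1: f"({m},({e},{g}))",
        2: f"({e},({m},{g}))",
        3: f"({g},({m},{e}))",
    }
    descriptions = {
        1: "eudicots sister to magnoliids",
        2: "monocots sister to magnoliids",
        3: "magnoliids sister to (monocots, eudicots)",
    }
    out = []
    for i, core in arrangements.items():
        newick = f"(({core},{basal}),{gym});"
        out.append(TopologyHypothesis(i, Tree.from_newick(newick), descriptions[i]))
    trees = [h.tree for h in out]
    for a, b in itertools.combinations(trees, 2):
        if a.same_topology(b):
            raise ConflictError("hypotheses are not pairwise distinct")
    return out


# ----------------------------------------------------------------------
# orthogroup filters
# ----------------------------------------------------------------------

def filter_low_copy(orthogroups: list[Orthogroup], clade_map: dict[str, str],
                    max_copies_per_species: int = 1,
                    clade_minima: dict[str, int] | None = None) -> list[Orthogroup]:
    """Keep orthogroups that are low copy and well represented per clade.

    An orthogroup passes iff no species exceeds ``max_copies_per_species``
    copies and, per clade, the number of species with at least one copy
    meets the clade minimum (default 4 eudicots / 4 monocots /
    3 magnoliids / 1 basal angiosperm / 1 gymnosperm).
    """
    minima = dict(DEFAULT_CLADE_MINIMA if clade_minima is None else clade_minima)
    kept = []
    for og in orthogroups:
        unknown = [s for s in og.genes if s not in clade_map]
        if unknown:
            raise ConflictError(
                f"species missing from clade map in {og.id!r}: {sorted(unknown)}")
        if any(len(g) > max_copies_per_species for g in og.genes.values()):
            continue
        presence: dict[str, int] = {c: 0 for c in minima}
        for sp in og.species_present:
            clade = clade_map[sp]
            if clade in presence:
                presence[clade] += 1
        if all(presence[c] >= minima[c] for c in minima):
            kept.append(og)
    return kept


def _corrected_distance(seq1: str, seq2: str, n_states: int) -> float:
    """Jukes–Cantor-type corrected pairwise distance for the screen tree."""
    pairs = [(a, b) for a, b in zip(seq1, seq2) if a != "-" and b != "-"]
    if not pairs:
        return MAX_BRANCH_LENGTH
    p = sum(a != b for a, b in pairs) / len(pairs)
    b = (n_states - 1) / n_states
    if p >= b:
        return MAX_BRANCH_LENGTH
    return min(MAX_BRANCH_LENGTH, -b * np.log1p(-p / b))


def _is_monophyletic(tree: Tree, members: set[str], outgroup: str) -> bool:
    """Monophyly of `members` when the unrooted tree is rooted at `outgroup`."""
    leaves = set(tree.leaf_names())
    if len(members) <= 1:
        return True
    if members == leaves - {outgroup}:
        return True
    target = min(frozenset(members), frozenset(leaves - members),
                 key=lambda s: (len(s), sorted(s)))
    if outgroup in members:
        return False
    return target in tree.bipartitions()


def screen_by_gene_tree(orthogroups: list[Orthogroup], clade_map: dict[str, str],
                        model: SubstitutionModel,
                        monophyly_clades: tuple[str, ...] = ("eudicot", "monocot", "magnoliid"),
                        outgroup_clade: str = "gymnosperm") -> list[Orthogroup]:
    """Screen orthogroups by gene-tree behaviour.

    A neighbour-joining gene tree is built from corrected pairwise
    distances, rooted at the gymnosperm; the orthogroup is kept iff every
    focal clade present (with >= 2 members) is monophyletic.  This drops
    genes whose history visibly contradicts any species-level arrangement
    (paralogy, contamination, strong ILS on terminal branches).
    """
    n_states = model.n_states
    kept = []
    for og in orthogroups:
        if og.alignment is None:
            raise ConflictError(f"orthogroup {og.id!r} has no alignment")
        aln = og.alignment
        outs = [s for s in aln.names if clade_map.get(s) == outgroup_clade]
        if not outs:
            continue
        n = aln.n_taxa
        d = np.zeros((n, n))
        for i, j in itertools.combinations(range(n), 2):
            d[i, j] = d[j, i] = _corrected_distance(
                aln.sequences[i], aln.sequences[j], n_states)
        gene_tree = neighbor_joining(d, aln.names)
        ok = True
        for clade in monophyly_clades:
            members = {s for s in aln.names if clade_map.get(s) == clade}
            if len(members) >= 2 and not _is_monophyletic(gene_tree, members, outs[0]):
                ok = False
                break
        if ok:
            kept.append(og)
    return kept


# ----------------------------------------------------------------------
# per-gene scoring
# ----------------------------------------------------------------------

def gene_topology_likelihoods(orthogroup: Orthogroup,
                              hypotheses: list[TopologyHypothesis],
                              model: SubstitutionModel,
                              tol: float = 1e-4) -> tuple[float, float, float]:
    """Maximized log-likelihood of the gene under each topology hypothesis.

    Each hypothesis tree is pruned to the gene's taxon set and branch
    lengths are optimized with the topology fixed.  If all hypotheses
    prune to one topology the three scores are equal by construction.
    """
    if orthogroup.alignment is None:
        raise ConflictError(f"orthogroup {orthogroup.id!r} has no alignment")
    aln = orthogroup.alignment
    taxa = set(aln.names)
    if len(taxa) < 4:
        raise ConflictError(f"orthogroup {orthogroup.id!r} has fewer than 4 taxa")
    leaf_sets = {frozenset(h.tree.leaf_names()) for h in hypotheses}
    if len(leaf_sets) != 1:
        raise ConflictError("hypotheses have mismatched leaf sets")
    if not taxa <= next(iter(leaf_sets)):
        extra = sorted(taxa - next(iter(leaf_sets)))
        raise ConflictError(f"gene taxa absent from hypotheses: {extra}")
    pruned = [h.tree.prune_to_taxa(taxa) for h in hypotheses]
    lnls: list[float] = []
    cache: list[tuple[Tree, float]] = []
    for tree in pruned:
        hit = next((lnl for seen, lnl in cache if seen.same_topology(tree)), None)
        if hit is not None:
            lnls.append(hit)
            continue
        start = tree.set_branch_lengths(internal=0.05, terminal=0.1)
        res = optimize_branch_lengths(start, aln, model, tol=tol)
        cache.append((tree, res.log_likelihood))
        lnls.append(res.log_likelihood)
    return tuple(lnls)  # type: ignore[return-value]


def delta_gls(lnls: tuple[float, float, float], tie_tol: float = 1e-3,
              orthogroup_id: str = "") -> GeneTopologyResult:
    """Pairwise ΔGLS and the supported topology (argmax beyond tie_tol)."""
    if not all(np.isfinite(lnls)):
        raise ConflictError(f"non-finite log-likelihoods: {lnls}")
    return GeneTopologyResult(orthogroup_id, tuple(float(x) for x in lnls),
                              tie_tol=tie_tol)


def exclude_outliers(results: list[GeneTopologyResult], method: str = "tukey",
                     k: float = 1.5) -> list[GeneTopologyResult]:
    """Remove genes whose ΔGLS is an outlier under Tukey fences.

    Fences [Q1 - k·IQR, Q3 + k·IQR] are computed per pairwise-ΔGLS
    distribution; a gene is removed if any of its three ΔGLS values falls
    outside its fences.  Removed genes get ``outlier=True``.
    """
    if method != "tukey":
        raise ConflictError(f"unknown outlier method: {method}")
    if len(results) < 5:
        raise ConflictError("need at least 5 results to define outlier fences")
    fences = {}
    for key in ("d12", "d13", "d23"):
        vals = np.array([getattr(r, key) for r in results])
        q1, q3 = np.percentile(vals, [25, 75])
        iqr = q3 - q1
        fences[key] = (q1 - k * iqr, q3 + k * iqr)
    survivors = []
    for r in results:
        bad = any(not (fences[key][0] <= getattr(r, key) <= fences[key][1])
                  for key in fences)
        r.outlier = bad
        if not bad:
            survivors.append(r)
    return survivors


def support_counts(results: list[GeneTopologyResult]) -> SupportCounts:
    """Counts of genes supporting each topology, with the uniformity test.

    Uninformative (tied) genes are excluded from the total.
    """
    counts = [0, 0, 0]
    for r in results:
        if r.supported != UNINFORMATIVE:
            counts[r.supported - 1] += 1
    if sum(counts) == 0:
        raise ConflictError("all genes are uninformative; no support counts")
    return SupportCounts(tuple(counts))


# ----------------------------------------------------------------------
# chi-squared tests
# ----------------------------------------------------------------------

def chisq_sf(x: float, df: int) -> float:
    """Upper-tail chi-squared probability; for df=2 this is exp(-x/2)."""
    if x < 0:
        raise ConflictError("chi-squared statistic must be >= 0")
    if df <= 0:
        raise ConflictError("degrees of freedom must be positive")
    return float(_chi2.sf(x, df))


def chisq_uniform_test(counts) -> tuple[float, int, float]:
    """Pearson goodness-of-fit test against equal expected counts.

    No continuity correction; df = k - 1; p from the chi-squared
    survival function.
    """
    obs = np.asarray(counts, dtype=float)
    if np.any(obs < 0):
        raise ConflictError("counts must be non-negative")
    total = obs.sum()
    if total <= 0:
        raise ConflictError("total count must be positive")
    expected = total / len(obs)
    stat = float(np.sum((obs - expected) ** 2 / expected))
    df = len(obs) - 1
    return stat, df, chisq_sf(stat, df)


def family_bias_test(test_counts: tuple[int, int],
                     reference_counts: tuple[int, int]) -> tuple[float, int, float]:
    """Pearson 2x2 test for lineage-specific gene-family bias.

    Rows: (eudicot-specific, monocot-specific) family counts in the test
    species and in the reference species; statistic
    N (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d)), no continuity correction.
    """
    a, b = test_counts
    c, d = reference_counts
    if min(a, b, c, d) < 0:
        raise ConflictError("counts must be non-negative")
    n = a + b + c + d
    margins = [(a + b), (c + d), (a + c), (b + d)]
    if any(mg == 0 for mg in margins):
        raise ConflictError("zero marginal; 2x2 test undefined")
    stat = n * (a * d - b * c) ** 2 / np.prod([float(mg) for mg in margins])
    return float(stat), 1, chisq_sf(float(stat), 1)


# ----------------------------------------------------------------------
# clade-specific families
# ----------------------------------------------------------------------

def clade_specific_families(presence: "np.ndarray | object", species: list[str],
                            clade_map: dict[str, str], target_clade: str,
                            min_present: float = 1.0,
                            max_other: int = 0) -> set:
    """Families present in (a fraction of) a clade and almost nowhere else.

    ``presence`` is a boolean families x species matrix (rows indexed by
    family id if a pandas DataFrame, else positions); a family qualifies
    when it is present in at least ``min_present`` of the target clade's
    species and in at most ``max_other`` species outside the clade.
    """
    if target_clade not in set(clade_map.values()):
        raise ConflictError(f"unknown clade label: {target_clade!r}")
    try:  # pandas DataFrame: preserve the family index
        matrix = presence.to_numpy()
        families = list(presence.index)
    except AttributeError:
        matrix = np.asarray(presence)
        families = list(range(matrix.shape[0]))
    matrix = matrix.astype(bool)
    in_clade = np.array([clade_map.get(s) == target_clade for s in species])
    n_target = int(in_clade.sum())
    if n_target == 0:
        raise ConflictError(f"no species in clade {target_clade!r}")
    present_target = matrix[:, in_clade].sum(axis=1)
    present_other = matrix[:, ~in_clade].sum(axis=1)
    ok = (present_target >= min_present * n_target) & (present_other <= max_other)
    return {families[i] for i in np.nonzero(ok)[0]}
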