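"""Synthetic inputs with known ground truth for every pipeline stage.

Every generator is a pure function of its parameters and a mandatory
integer seed (no global RNG state), so identical calls are bit-identical.
The generators emulate the statistical structure of the real inputs —
gene alignments evolved under a mixture of competing species topologies,
a paranome whose Ks values mix background decay with a WGD peak, a
duplicated gene order with partial duplicate retention, and coalescent
SNP matrices from structured populations — without modelling indels,
selection, recombination within loci, or sequencing error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import msprime
import numpy as np

from .alignment import Alignment
from .models import SubstitutionModel
from .popgen import SNPMatrix
from .synteny import Genome
from .trees import Tree, TreeError

__all__ = ["SimulatedGeneSet", "CoalescentSample", "Demography",
           "SyntheticParanome", "SyntheticWGDGenome", "SimulationError",
           "simulate_alignment", "simulate_gene_set", "simulate_coalescent",
           "simulate_paranome", "simulate_wgd_genome"]

# codon families whose third position is fourfold degenerate and whose
# first/second-position single mutations are all nonsynonymous and never
# produce a stop-codon ambiguity in site counting (stops count nonsyn):
# under NG86 each such codon contributes exactly one synonymous site.
FOURFOLD_PREFIXES = ("GC", "GT", "CC", "CT", "TC", "AC", "CG", "GG")
BASES = "ACGT"


class SimulationError(ValueError):
    pass


# ----------------------------------------------------------------------
# sequence evolution
# ----------------------------------------------------------------------

def simulate_alignment(tree: Tree, model: SubstitutionModel, length: int,
                       seed: int) -> Alignment:
    """Evolve one alignment along `tree` under `model`.

    Root states are drawn from the model's stationary distribution and
    propagated by the transition probabilities of each branch; with a
    gamma model, per-site rate categories are drawn once and shared along
    the whole tree.  Branch lengths are expected substitutions per site.
    """
    if length < 1:
        raise SimulationError("alignment length must be >= 1")
    for node in tree.postorder():
        if node.parent is not None and (node.length is None or node.length < 0):
            raise TreeError("tree must have non-negative branch lengths everywhere")
    rng = np.random.default_rng(seed)
    k = model.n_states
    rates, weights = model.rate_categories()
    site_cat = rng.choice(len(rates), size=length, p=weights)
    states: dict[int, np.ndarray] = {}
    states[id(tree.root)] = rng.choice(k, size=length, p=model.frequencies)
    for node in tree.preorder():
        if node.parent is None:
            continue
        parent_states = states[id(node.parent)]
        child = np.empty(length, dtype=np.int64)
        for c, rate in enumerate(rates):
            mask = site_cat == c
            if not mask.any():
                continue
            p = model.transition_matrix(node.length * rate)
            cum = np.cumsum(p, axis=1)
            u = rng.random(mask.sum())
            child[mask] = (u[:, None] > cum[parent_states[mask]]).sum(axis=1)
        states[id(node)] = child
    chars = np.frombuffer(model.states.encode("ascii"), dtype=np.uint8)
    names, seqs = [], []
    for leaf in tree.leaves():
        names.append(leaf.name)
        seqs.append(chars[states[id(leaf)]].tobytes().decode("ascii"))
    alphabet = "protein" if model.n_states == 20 else "dna"
    return Alignment(names, seqs, alphabet)


@dataclass
class SimulatedGeneSet:
    alignments: list[Alignment]
    true_topology_labels: list[int]  # 1..3
    mixture: tuple[float, float, float]
    seed: int


def simulate_gene_set(hypotheses: list, mixture, n_genes: int, length: int,
                      internal_length: float, terminal_length: float,
                      model: SubstitutionModel, seed: int) -> SimulatedGeneSet:
    """Genes evolved under a mixture of the three topology hypotheses.

    Each gene's generating topology index is a draw from `mixture`; its
    alignment is simulated on that hypothesis tree with uniform internal
    and terminal branch lengths.  Truth labels are stored alongside.
    """
    mixture = tuple(float(m) for m in mixture)
    if abs(sum(mixture) - 1.0) > 1e-9:
        raise SimulationError("mixture proportions must sum to 1")
    if n_genes < 1:
        raise SimulationError("n_genes must be >= 1")
    trees = [h.tree if hasattr(h, "tree") else h for h in hypotheses]
    leaf_sets = {frozenset(t.leaf_names()) for t in trees}
    if len(leaf_sets) != 1:
        raise SimulationError("hypotheses have mismatched leaf sets")
    rng = np.random.default_rng(seed)
    labels = rng.choice(len(trees), size=n_genes, p=mixture) + 1
    scaled = [t.set_branch_lengths(internal=internal_length,
                                   terminal=terminal_length) for t in trees]
    alignments = []
    for lab in labels:
        gene_seed = int(rng.integers(2 ** 31))
        alignments.append(simulate_alignment(scaled[lab - 1], model, length,
                                             gene_seed))
    return SimulatedGeneSet(alignments, [int(x) for x in labels], mixture, seed)


# ----------------------------------------------------------------------
# coalescent SNP matrices
# ----------------------------------------------------------------------

@dataclass
class Demography:
    """Sampled demes with optional sequential mergers and migration.

    ``deme_sizes`` are diploid population sizes.  ``split_times`` (in
    generations, increasing) merge deme i+1 into the deme-0 lineage at
    time split_times[i], backwards in time.  ``migration`` maps ordered
    deme-index pairs to per-generation migration rates.
    """

    deme_sizes: tuple[float, ...] = (10_000.0,)
    split_times: tuple[float, ...] = ()
    migration: dict[tuple[int, int], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        d = len(self.deme_sizes)
        if self.split_times and len(self.split_times) != d - 1:
            raise SimulationError("need one split time per non-focal deme")
        if list(self.split_times) != sorted(self.split_times):
            raise SimulationError("split times must be increasing")
        for (i, j) in self.migration:
            if not (0 <= i < d and 0 <= j < d and i != j):
                raise SimulationError(
                    f"migration between nonexistent demes: ({i}, {j})")

    def to_msprime(self) -> msprime.Demography:
        dem = msprime.Demography()
        for i, size in enumerate(self.deme_sizes):
            dem.add_population(name=f"d{i}", initial_size=size)
        if self.split_times:
            anc_sizes = self.deme_sizes[0]
            current = "d0"
            for i, t in enumerate(self.split_times):
                anc = f"anc{i}"
                dem.add_population(name=anc, initial_size=anc_sizes)
                dem.add_population_split(time=t, derived=[current, f"d{i + 1}"],
                                         ancestral=anc)
                current = anc
        for (i, j), rate in self.migration.items():
            dem.set_migration_rate(source=f"d{i}", dest=f"d{j}", rate=rate)
        dem.sort_events()
        return dem


@dataclass
class CoalescentSample:
    snp_matrix: SNPMatrix
    deme_assignment: dict[str, int]
    demography: Demography
    theta: float
    seed: int


def simulate_coalescent(samples_per_deme: tuple[int, ...], demography: Demography,
                        theta: float, locus_length: int, seed: int) -> CoalescentSample:
    """Haplotype SNP matrix from the structured coalescent (msprime).

    ``theta`` is the per-locus population mutation rate 4·N0·μ·L of the
    focal deme; mutations follow the infinite-sites model (every column
    polymorphic in the full sample, biallelic 0/1).  Sample counts are
    haploid sequence counts per deme.
    """
    if len(samples_per_deme) != len(demography.deme_sizes):
        raise SimulationError("one sample count per deme required")
    if sum(samples_per_deme) < 2:
        raise SimulationError("need at least 2 samples in total")
    if theta <= 0:
        raise SimulationError("theta must be positive")
    mu = theta / (4.0 * demography.deme_sizes[0] * locus_length)
    sample_sets = [msprime.SampleSet(n, population=f"d{i}", ploidy=1)
                   for i, n in enumerate(samples_per_deme) if n > 0]
    ts = msprime.sim_ancestry(
        samples=sample_sets, demography=demography.to_msprime(),
        sequence_length=locus_length, ploidy=2, recombination_rate=0.0,
        random_seed=seed % (2 ** 31 - 1) + 1)
    mts = msprime.sim_mutations(
        ts, rate=mu, random_seed=(seed * 7919) % (2 ** 31 - 1) + 1,
        model=msprime.BinaryMutationModel(), discrete_genome=False)
    geno = mts.genotype_matrix().T.astype(np.int8)  # samples x sites
    pos = np.array([s.position for s in mts.sites()])
    # drop monomorphic columns (mutations above the sample MRCA)
    poly = (geno.sum(axis=0) > 0) & (geno.sum(axis=0) < geno.shape[0])
    geno, pos = geno[:, poly], pos[poly]
    ipos = np.floor(pos).astype(np.int64)
    # enforce strictly increasing integer positions
    for i in range(1, len(ipos)):
        if ipos[i] <= ipos[i - 1]:
            ipos[i] = ipos[i - 1] + 1
    names = []
    deme_of: dict[str, int] = {}
    counter = 0
    for i, n in enumerate(samples_per_deme):
        for _ in range(n):
            name = f"s{counter:03d}"
            names.append(name)
            deme_of[name] = i
            counter += 1
    L = max(locus_length, int(ipos[-1]) + 1 if len(ipos) else locus_length)
    matrix = SNPMatrix(names, ipos, geno, ploidy=1, L=L)
    return CoalescentSample(matrix, deme_of, demography, theta, seed)


# ----------------------------------------------------------------------
# paranome
# ----------------------------------------------------------------------

@dataclass
class SyntheticParanome:
    ks_values: np.ndarray
    labels: list[str]  # "background" | "wgd"
    wgd_mean: float
    wgd_sd: float
    background_decay_rate: float
    codon_pairs: list[Alignment] | None
    seed: int


def _evolve_codon_pair(target_ks: float, n_codons: int,
                       rng: np.random.Generator) -> Alignment:
    """Two sequences of fourfold-degenerate codons whose third positions
    diverge under JC69 at branch length `target_ks`; each codon carries
    exactly one synonymous site, so the expected NG86 Ks equals the
    target."""
    prefixes = rng.choice(len(FOURFOLD_PREFIXES), size=n_codons)
    third1 = rng.choice(4, size=n_codons)
    # JC69 transition at distance t: stay with prob 1/4 + 3/4 e^{-4t/3}
    stay = 0.25 + 0.75 * np.exp(-4.0 * target_ks / 3.0)
    moves = rng.random(n_codons) > stay
    shift = rng.integers(1, 4, size=n_codons)
    third2 = np.where(moves, (third1 + shift) % 4, third1)
    seq1 = "".join(FOURFOLD_PREFIXES[p] + BASES[b]
                   for p, b in zip(prefixes, third1))
    seq2 = "".join(FOURFOLD_PREFIXES[p] + BASES[b]
                   for p, b in zip(prefixes, third2))
    return Alignment(["copy_a", "copy_b"], [seq1, seq2], "codon")


def simulate_paranome(n_background: int, n_wgd: int, wgd_mean: float = 0.7,
                      wgd_sd: float = 0.08, decay_rate: float = 1.0,
                      seed: int = 0, emit_codon_pairs: bool = False,
                      n_codons: int = 300) -> SyntheticParanome:
    """Paranome Ks values: exponential background decay plus a WGD peak.

    Background Ks ~ Exponential(decay_rate); WGD Ks ~ Normal(wgd_mean,
    wgd_sd) truncated at 0.  With ``emit_codon_pairs``, a codon alignment
    is evolved per value so the NG86 estimator recovers each target Ks in
    expectation.
    """
    if n_background < 0 or n_wgd < 0:
        raise SimulationError("counts must be >= 0")
    if n_background + n_wgd == 0:
        raise SimulationError("empty paranome: all counts are zero")
    if n_wgd > 0 and wgd_sd <= 0:
        raise SimulationError("wgd_sd must be positive when n_wgd > 0")
    rng = np.random.default_rng(seed)
    background = rng.exponential(scale=1.0 / decay_rate, size=n_background)
    wgd = rng.normal(wgd_mean, wgd_sd, size=n_wgd)
    while np.any(wgd < 0):  # truncate at 0 by redrawing
        bad = wgd < 0
        wgd[bad] = rng.normal(wgd_mean, wgd_sd, size=int(bad.sum()))
    values = np.concatenate([background, wgd])
    labels = ["background"] * n_background + ["wgd"] * n_wgd
    pairs = None
    if emit_codon_pairs:
        pairs = [_evolve_codon_pair(float(ks), n_codons, rng) for ks in values]
    return SyntheticParanome(values, labels, wgd_mean, wgd_sd, decay_rate,
                             pairs, seed)


# ----------------------------------------------------------------------
# post-WGD gene order
# ----------------------------------------------------------------------

@dataclass
class SyntheticWGDGenome:
    ancestral: Genome
    derived: Genome
    anchor_pairs: list[tuple[str, str]]  # (ancestral gene, derived gene)
    retention_rate: float
    n_copies: int
    seed: int

    def descendants(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for anc, der in self.anchor_pairs:
            out.setdefault(anc, []).append(der)
        return out


def simulate_wgd_genome(n_genes: int, retention_rate: float, n_shuffles: int = 0,
                        seed: int = 0, n_copies: int = 2,
                        max_inversion_length: int = 5) -> SyntheticWGDGenome:
    """Gene order after whole-genome multiplication with partial retention.

    The derived genome is ``n_copies`` copies of the ancestral order.
    The first copy retains every gene; in each further copy a gene
    survives independently with probability ``retention_rate`` (so
    retention 0 collapses the genome to a single copy and retention 1
    keeps every duplicate).  ``n_shuffles`` random adjacent-segment
    inversions (length <= ``max_inversion_length`` genes) perturb local
    order.  Anchor pairs link each ancestral gene to its surviving
    descendants.
    """
    if n_genes < 10:
        raise SimulationError("n_genes must be >= 10")
    if not 0.0 <= retention_rate <= 1.0:
        raise SimulationError("retention_rate must be in [0, 1]")
    if n_copies < 2:
        raise SimulationError("n_copies must be >= 2")
    rng = np.random.default_rng(seed)
    anc_genes = [f"g{i:05d}" for i in range(n_genes)]
    ancestral = Genome({"anc1": anc_genes})
    kept = rng.random((n_genes, n_copies)) < retention_rate
    kept[:, 0] = True
    derived_chroms: dict[str, list[str]] = {}
    anchors: list[tuple[str, str]] = []
    for c in range(n_copies):
        chrom = [f"{g}_{c}" for i, g in enumerate(anc_genes) if kept[i, c]]
        derived_chroms[f"d{c + 1}"] = chrom
    for _ in range(n_shuffles):
        chrom_id = f"d{int(rng.integers(0, n_copies)) + 1}"
        genes = derived_chroms[chrom_id]
        if len(genes) < 2:
            continue
        seg = int(rng.integers(2, max_inversion_length + 1))
        seg = min(seg, len(genes))
        start = int(rng.integers(0, len(genes) - seg + 1))
        genes[start:start + seg] = genes[start:start + seg][::-1]
    derived = Genome(derived_chroms)
    for c in range(n_copies):
        for i, g in enumerate(anc_genes):
            if kept[i, c]:
                anchors.append((g, f"{g}_{c}"))
    return SyntheticWGDGenome(ancestral, derived, anchors, retention_rate,
                              n_copies, seed)


def wgd_cross_anchors(sim_a: SyntheticWGDGenome,
                      sim_b: SyntheticWGDGenome) -> list[tuple[str, str]]:
    """Homology pairs between two derived genomes that descend from the
    same ancestral gene set (e.g. a triplicated vs a duplicated genome)."""
    desc_a, desc_b = sim_a.descendants(), sim_b.descendants()
    return [(x, y) for anc, xs in desc_a.items()
            for x in xs for y in desc_b.get(anc, [])]
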