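"""Generators: determinism, conservation, and distributional checks."""

import numpy as np
import pytest

from lirio.models import jc69
from lirio.synthetic import (Demography, SimulationError, simulate_alignment,
                             simulate_coalescent, simulate_gene_set,
                             simulate_paranome, simulate_wgd_genome)
from lirio.trees import TreeError, parse_newick
from lirio.wgd import ng86_ks


# -- sequence evolution ------------------------------------------------

def test_zero_branch_lengths_give_identical_sequences():
    tree = parse_newick("((A:0,B:0):0,(C:0,D:0):0);")
    aln = simulate_alignment(tree, jc69(), 200, seed=1)
    assert len(set(aln.sequences)) == 1


def test_jc69_expected_mismatch_fraction():
    """Two taxa, total path 0.1: mismatch fraction near the JC closed form
    p = (3/4)(1 - e^{-0.4/3}), within 3 binomial standard errors."""
    n = 100_000
    aln = simulate_alignment(parse_newick("(A:0.05,B:0.05);"), jc69(), n, seed=7)
    p_exp = 0.75 * (1 - np.exp(-4 * 0.1 / 3))
    p_obs = sum(a != b for a, b in zip(*aln.sequences)) / n
    se = np.sqrt(p_exp * (1 - p_exp) / n)
    assert abs(p_obs - p_exp) < 3 * se


def test_alignment_determinism_and_validation():
    tree = parse_newick("(A:0.1,B:0.2,(C:0.3,D:0.4):0.5);")
    a1 = simulate_alignment(tree, jc69(), 100, seed=42)
    a2 = simulate_alignment(tree, jc69(), 100, seed=42)
    assert a1.sequences == a2.sequences and a1.names == a2.names
    assert a1.sequences != simulate_alignment(tree, jc69(), 100, seed=43).sequences
    with pytest.raises(SimulationError):
        simulate_alignment(tree, jc69(), 0, seed=1)
    with pytest.raises(TreeError):
        simulate_alignment(parse_newick("(A,B);"), jc69(), 10, seed=1)


# -- gene sets ---------------------------------------------------------

def test_gene_set_degenerate_mixture(hypotheses_minimal, jc):
    gs = simulate_gene_set(hypotheses_minimal, (1, 0, 0), 50, 50, 0.05, 0.2,
                           jc, seed=0)
    assert gs.true_topology_labels == [1] * 50


def test_gene_set_label_conservation(hypotheses_minimal, jc):
    gs = simulate_gene_set(hypotheses_minimal, (1 / 3, 1 / 3, 1 / 3), 300, 20,
                           0.05, 0.2, jc, seed=5)
    assert len(gs.true_topology_labels) == len(gs.alignments) == 300
    assert set(gs.true_topology_labels) <= {1, 2, 3}


def test_gene_set_rejects_bad_mixture_and_leafsets(hypotheses_minimal, jc):
    with pytest.raises(SimulationError):
        simulate_gene_set(hypotheses_minimal, (0.5, 0.5, 0.5), 10, 20,
                          0.05, 0.2, jc, seed=1)
    broken = [hypotheses_minimal[0].tree,
              hypotheses_minimal[1].tree,
              parse_newick("(x:1,y:1,(z:1,w:1):1);")]
    with pytest.raises(SimulationError):
        simulate_gene_set(broken, (1 / 3, 1 / 3, 1 / 3), 10, 20, 0.05, 0.2,
                          jc, seed=1)


# -- coalescent --------------------------------------------------------

def test_watterson_expected_segregating_sites():
    """One deme, n=10, θ=5: E[S] = θ Σ 1/i ≈ 14.14 over 2,000 replicates."""
    dem = Demography((10_000.0,))
    counts = [simulate_coalescent((10,), dem, 5.0, 10_000, seed=s)
              .snp_matrix.n_sites for s in range(2_000)]
    a9 = sum(1 / i for i in range(1, 10))
    expected = 5.0 * a9
    se = np.std(counts, ddof=1) / np.sqrt(len(counts))
    assert abs(np.mean(counts) - expected) < 3 * se


def test_old_split_drives_fst_to_one():
    from lirio.popgen import hudson_fst

    dem = Demography((10_000.0, 10_000.0), split_times=(400_000.0,))
    sample = simulate_coalescent((12, 12), dem, 20.0, 50_000, seed=3)
    groups = {}
    for s, d in sample.deme_assignment.items():
        groups.setdefault(d, []).append(s)
    fst = hudson_fst(sample.snp_matrix, groups[0], groups[1])
    assert fst.fst > 0.9


def test_coalescent_determinism_and_polymorphism():
    dem = Demography((10_000.0,))
    s1 = simulate_coalescent((8,), dem, 10.0, 20_000, seed=9)
    s2 = simulate_coalescent((8,), dem, 10.0, 20_000, seed=9)
    assert np.array_equal(s1.snp_matrix.matrix, s2.snp_matrix.matrix)
    m = s1.snp_matrix.matrix
    assert ((m.sum(axis=0) > 0) & (m.sum(axis=0) < m.shape[0])).all()
    assert (np.diff(s1.snp_matrix.positions) > 0).all()


def test_coalescent_validation():
    with pytest.raises(SimulationError):
        Demography((1e4, 1e4), migration={(0, 2): 0.1})
    with pytest.raises(SimulationError):
        simulate_coalescent((1,), Demography((1e4,)), 5.0, 1000, seed=1)
    with pytest.raises(SimulationError):
        simulate_coalescent((4,), Demography((1e4,)), -1.0, 1000, seed=1)


# -- paranome ----------------------------------------------------------

def test_paranome_conservation_and_validation():
    par = simulate_paranome(120, 80, seed=2)
    assert len(par.labels) == 200 and (par.ks_values >= 0).all()
    assert par.labels.count("background") == 120
    assert par.labels.count("wgd") == 80
    with pytest.raises(SimulationError):
        simulate_paranome(0, 0)


def test_codon_pairs_recover_target_ks():
    """NG86 on generated codon pairs is unbiased: mean estimate within
    10% of the target for Ks = 0.2 over 200 pairs."""
    rng = np.random.default_rng(0)
    from lirio.synthetic import _evolve_codon_pair

    est = [ng86_ks(_evolve_codon_pair(0.2, 300, rng)).ks for _ in range(200)]
    assert abs(np.mean(est) - 0.2) / 0.2 < 0.10


# -- WGD genome --------------------------------------------------------

def test_wgd_genome_full_retention():
    sim = simulate_wgd_genome(50, 1.0, n_shuffles=0, seed=1)
    desc = sim.descendants()
    assert all(len(v) == 2 for v in desc.values())
    assert sim.derived.n_genes == 100


def test_wgd_genome_zero_retention_collapses():
    sim = simulate_wgd_genome(50, 0.0, n_shuffles=0, seed=1)
    assert all(len(v) == 1 for v in sim.descendants().values())
    assert sim.derived.n_genes == 50


def test_wgd_anchor_pairs_reference_existing_genes():
    sim = simulate_wgd_genome(100, 0.5, n_shuffles=10, seed=4)
    for anc, der in sim.anchor_pairs:
        assert anc in sim.ancestral
        assert der in sim.derived
    assert simulate_wgd_genome(100, 0.5, n_shuffles=10, seed=4).anchor_pairs \
        == sim.anchor_pairs  # determinism
    with pytest.raises(SimulationError):
        simulate_wgd_genome(5, 0.5)
    with pytest.raises(SimulationError):
        simulate_wgd_genome(100, 1.5)
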