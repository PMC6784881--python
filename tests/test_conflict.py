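"""Orthogroup filtering, ΔGLS, support counts and chi-squared tests."""

import numpy as np
import pandas as pd
import pytest

from lirio.alignment import Alignment
from lirio.conflict import (ConflictError, Orthogroup, build_hypotheses,
                            chisq_sf, chisq_uniform_test,
                            clade_specific_families, delta_gls,
                            exclude_outliers, family_bias_test,
                            filter_low_copy, gene_topology_likelihoods,
                            screen_by_gene_tree, support_counts)
from lirio.synthetic import simulate_gene_set


@pytest.fixture
def clade_map(clade_species_full):
    return {sp: clade for clade, spp in clade_species_full.items() for sp in spp}


def og_with(presence: dict[str, int], og_id="og1") -> Orthogroup:
    return Orthogroup(og_id, {sp: [f"{sp}_g{i}" for i in range(k)]
                              for sp, k in presence.items()})


# -- low-copy filter ---------------------------------------------------

def test_filter_excludes_multicopy_species(clade_map, clade_species_full):
    presence = {sp: 1 for spp in clade_species_full.values() for sp in spp}
    presence["eud0"] = 2  # two copies in one species
    assert filter_low_copy([og_with(presence)], clade_map) == []


def test_filter_keeps_boundary_presence(clade_map):
    presence = {f"eud{i}": 1 for i in range(4)}
    presence |= {f"mon{i}": 1 for i in range(4)}
    presence |= {f"mag{i}": 1 for i in range(3)}
    presence |= {"amb0": 1, "gym0": 1}
    kept = filter_low_copy([og_with(presence)], clade_map)
    assert len(kept) == 1


def test_filter_requires_every_clade(clade_map):
    presence = {f"eud{i}": 1 for i in range(4)}
    presence |= {f"mon{i}": 1 for i in range(4)}
    presence |= {f"mag{i}": 1 for i in range(3)}
    presence |= {"amb0": 1}  # gymnosperm absent
    assert filter_low_copy([og_with(presence)], clade_map) == []


def test_filter_unknown_species_is_an_error(clade_map):
    with pytest.raises(ConflictError, match="mystery"):
        filter_low_copy([og_with({"mystery": 1})], clade_map)


def test_filter_is_idempotent(clade_map, clade_species_full):
    rng = np.random.default_rng(0)
    species = [sp for spp in clade_species_full.values() for sp in spp]
    ogs = [og_with({sp: int(rng.integers(0, 3)) for sp in species}, f"og{i}")
           for i in range(50)]
    once = filter_low_copy(ogs, clade_map)
    assert filter_low_copy(once, clade_map) == once


# -- ΔGLS --------------------------------------------------------------

def test_delta_gls_arithmetic():
    r = delta_gls((-1000.0, -1002.0, -1001.0))
    assert (r.d12, r.d13, r.d23) == (2.0, 1.0, -1.0)
    assert r.supported == 1
    assert r.d13 == pytest.approx(r.d12 + r.d23, abs=1e-6)


def test_delta_gls_tie_is_uninformative():
    assert delta_gls((-500.0, -500.0, -500.0)).supported == "uninformative"
    assert delta_gls((-500.0, -500.0005, -510.0)).supported == "uninformative"
    assert delta_gls((-500.0, -500.002, -510.0)).supported == 1


@pytest.mark.parametrize("seed", range(5))
def test_delta_gls_antisymmetry(seed):
    rng = np.random.default_rng(seed)
    lnls = tuple(-rng.uniform(500, 2000, 3))
    r = delta_gls(lnls)
    back = delta_gls((lnls[1], lnls[0], lnls[2]))
    assert r.d12 == pytest.approx(-back.d12)


def test_delta_gls_rejects_nonfinite():
    with pytest.raises(ConflictError):
        delta_gls((float("nan"), -1.0, -2.0))


# -- outlier exclusion -------------------------------------------------

def _results_from_deltas(deltas):
    # construct results with lnL triples realizing the wanted d12
    return [delta_gls((-1000.0 + d, -1000.0, -1000.0 - 0.5), orthogroup_id=str(i))
            for i, d in enumerate(deltas)]


def test_outlier_gene_removed():
    rng = np.random.default_rng(1)
    deltas = list(rng.uniform(-3, 3, 100)) + [500.0]
    out = exclude_outliers(_results_from_deltas(deltas))
    assert len(out) < 101
    assert all(r.orthogroup_id != "100" for r in out)
    q1, q3 = np.percentile(deltas, [25, 75])
    hi = q3 + 1.5 * (q3 - q1)
    assert all(r.d12 <= hi for r in out)


def test_identical_deltas_keep_everything():
    out = exclude_outliers(_results_from_deltas([2.0] * 10))
    assert len(out) == 10


def test_outlier_exclusion_idempotent_and_guarded():
    rng = np.random.default_rng(2)
    res = _results_from_deltas(rng.normal(0, 1, 40))
    once = exclude_outliers(res)
    assert exclude_outliers(once) == once
    with pytest.raises(ConflictError):
        exclude_outliers(res[:4])


# -- support counts and chi-squared -----------------------------------

def test_published_support_counts_percentages_and_test():
    sc = support_counts(
        [delta_gls((-1.0, -5.0, -5.0), orthogroup_id=f"a{i}") for i in range(172)]
        + [delta_gls((-5.0, -1.0, -5.0), orthogroup_id=f"b{i}") for i in range(155)]
        + [delta_gls((-5.0, -5.0, -1.0), orthogroup_id=f"c{i}") for i in range(175)])
    assert sc.counts == (172, 155, 175)
    assert sc.percentages == (34.26, 30.88, 34.86)
    assert round(sc.chi2, 4) == 1.3904
    assert round(sc.p, 4) == 0.4990


def test_chisq_uniform_reproduces_printed_statistics():
    chi2, df, p = chisq_uniform_test((172, 155, 175))
    assert (round(chi2, 4), df, round(p, 4)) == (1.3904, 2, 0.4990)
    chi2, df, p = chisq_uniform_test((165, 159, 157))
    assert round(chi2, 4) == 0.2162
    assert round(p, 4) == 0.8975


def test_chisq_uniform_trivial_cases():
    chi2, df, p = chisq_uniform_test((10, 10, 10))
    assert chi2 == 0 and p == 1
    with pytest.raises(ConflictError):
        chisq_uniform_test((0, 0, 0))
    with pytest.raises(ConflictError):
        chisq_uniform_test((-1, 2, 3))


def test_chisq_sf_values():
    assert round(chisq_sf(1.3904, 2), 4) == 0.4990
    assert round(chisq_sf(0.2162, 2), 4) == 0.8975
    assert round(chisq_sf(0.1166, 1), 4) == 0.7328
    assert chisq_sf(0.0, 3) == 1.0
    # df=2 closed form: exp(-x/2)
    assert chisq_sf(1.7, 2) == pytest.approx(np.exp(-0.85), abs=1e-12)
    with pytest.raises(ConflictError):
        chisq_sf(1.0, 0)


def test_uniform_support_gives_zero_statistic():
    res = [delta_gls(tuple(-1000.0 + np.eye(3)[i % 3] * 5), orthogroup_id=str(i))
           for i in range(30)]
    sc = support_counts(res)
    assert sc.counts == (10, 10, 10) and sc.chi2 == 0


def test_all_uninformative_is_an_error():
    res = [delta_gls((-1.0, -1.0, -1.0)) for _ in range(5)]
    with pytest.raises(ConflictError):
        support_counts(res)


# -- 2x2 family-bias test ---------------------------------------------

def test_family_bias_trivial_and_derived():
    chi2, df, p = family_bias_test((10, 10), (10, 10))
    assert chi2 == 0 and df == 1 and p == 1
    chi2, _, _ = family_bias_test((30, 10), (10, 30))
    assert chi2 == pytest.approx(20.0)
    a = family_bias_test((7, 13), (19, 3))[0]
    b = family_bias_test((3, 19), (13, 7))[0]  # both rows and columns swapped
    assert a == pytest.approx(b)
    with pytest.raises(ConflictError):
        family_bias_test((0, 0), (1, 2))


# -- clade-specific families ------------------------------------------

def test_clade_specific_families_rules(clade_map, clade_species_full):
    species = [sp for spp in clade_species_full.values() for sp in spp]
    df = pd.DataFrame(False, index=["famA", "famB"], columns=species)
    df.loc["famA", clade_species_full["monocot"]] = True  # all monocots only
    df.loc["famB", ["eud0", "mon0"]] = True  # one eudicot + one monocot
    mono = clade_specific_families(df, species, clade_map, "monocot")
    eudi = clade_specific_families(df, species, clade_map, "eudicot")
    assert mono == {"famA"} and eudi == set()
    # loosening max_other is monotone
    looser = clade_specific_families(df, species, clade_map, "monocot",
                                     max_other=1)
    assert mono <= looser
    with pytest.raises(ConflictError):
        clade_specific_families(df, species, clade_map, "fern")


# -- gene-tree screen and per-gene scoring ----------------------------

def test_screen_excludes_contaminated_gene(hypotheses_full, clade_map, jc):
    gs = simulate_gene_set(hypotheses_full, (1, 0, 0), 6, 400, 0.08, 0.05,
                           jc, seed=3)
    ogs = []
    for i, aln in enumerate(gs.alignments):
        if i == 0:  # emulate contamination: a eudicot gets a magnoliid sequence
            seqs = dict(zip(aln.names, aln.sequences))
            seqs["eud0"] = seqs["mag0"]
            aln = Alignment(list(seqs), list(seqs.values()))
        ogs.append(Orthogroup(f"og{i}", {n: [n] for n in aln.names}, aln))
    kept = screen_by_gene_tree(ogs, clade_map, jc)
    kept_ids = {og.id for og in kept}
    assert "og0" not in kept_ids
    assert set(kept_ids) <= {og.id for og in ogs}
    assert len(kept_ids) >= 4  # clean genes with strong signal survive


def test_gene_scoring_recovers_generating_topology(hypotheses_full, jc):
    gs = simulate_gene_set(hypotheses_full, (0, 1, 0), 5, 400, 0.08, 0.1,
                           jc, seed=11)
    for aln in gs.alignments:
        og = Orthogroup("og", {n: [n] for n in aln.names}, aln)
        lnls = gene_topology_likelihoods(og, hypotheses_full, jc)
        assert all(np.isfinite(lnls)) and all(l <= 0 for l in lnls)
        assert delta_gls(lnls).supported == 2


def test_identical_pruned_topologies_tie(clade_species_full, jc):
    """A taxon set on which the hypotheses collapse to one topology must
    give three equal scores."""
    hyps = build_hypotheses(clade_species_full)
    # no monocots or magnoliids left: the three arrangements collapse
    taxa = ["eud0", "eud1", "eud2", "eud3", "amb0", "gym0"]
    from lirio.synthetic import simulate_alignment

    tree = hyps[0].tree.prune_to_taxa(taxa).set_branch_lengths(0.05, 0.2)
    aln = simulate_alignment(tree, jc, 150, seed=2)
    og = Orthogroup("og", {n: [n] for n in aln.names}, aln)
    lnls = gene_topology_likelihoods(og, hyps, jc)
    assert max(lnls) - min(lnls) < 1e-6
    assert delta_gls(lnls).supported == "uninformative"


def test_hypotheses_are_pairwise_distinct(hypotheses_full):
    trees = [h.tree for h in hypotheses_full]
    for i in range(3):
        for j in range(i + 1, 3):
            assert not trees[i].same_topology(trees[j])
        assert trees[i].leaf_names()  # gymnosperm outgroup present
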