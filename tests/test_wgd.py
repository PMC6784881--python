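"""NG86 Ks/Ka, 4DTv, node weighting, KDE peaks and age conversion."""

import itertools
import warnings

import numpy as np
import pytest

from lirio.alignment import Alignment
from lirio.wgd import (KsDistribution, WgdError, fourdtv, ks_density_peaks,
                       ks_to_age, ng86_ks, node_weighted_paranome)


def codon_pair(codons1, codons2) -> Alignment:
    return Alignment(["a", "b"], ["".join(codons1), "".join(codons2)], "codon")


# -- NG86 --------------------------------------------------------------

def test_identical_sequences_give_zero():
    est = ng86_ks(codon_pair(["GCA"] * 40, ["GCA"] * 40))
    assert est.ks == 0 and est.ka == 0 and not est.saturated


def test_jc_correction_from_known_ps():
    """10 Gly codons, 3 with a synonymous third-position change:
    each GGN codon has exactly 1 synonymous site, so pS = 0.3 and
    Ks = -(3/4) ln(1 - 0.4) ≈ 0.3831."""
    c1 = ["GGA"] * 40
    c2 = ["GGG"] * 12 + ["GGA"] * 28
    est = ng86_ks(codon_pair(c1, c2))
    assert est.ps == pytest.approx(0.3)
    assert est.ks == pytest.approx(-0.75 * np.log(0.6), abs=1e-9)


def test_site_count_conservation():
    rng = np.random.default_rng(0)
    sense = [c for c in ("".join(t) for t in itertools.product("ACGT", repeat=3))
             if c not in ("TAA", "TAG", "TGA")]
    cod = rng.choice(sense, 60)
    est = ng86_ks(codon_pair(cod, cod))
    assert est.s_sites + est.n_sites == pytest.approx(3 * est.n_codons)


def test_saturation_flag():
    # every third position transverted twice over... force pS near 1
    c1 = ["GGA", "GGC"] * 30
    c2 = ["GGT", "GGG"] * 30
    est = ng86_ks(codon_pair(c1, c2))
    assert est.saturated and np.isnan(est.ks)


def test_stop_codon_rejected_and_short_warning():
    with pytest.raises(WgdError):
        ng86_ks(codon_pair(["TGA"] * 40, ["TGG"] * 40))
    with pytest.warns(UserWarning, match="comparable codons"):
        ng86_ks(codon_pair(["GGA"] * 5, ["GGG"] * 5))


def test_gapped_codons_skipped():
    est = ng86_ks(codon_pair(["GGA"] * 30 + ["---"], ["GGA"] * 30 + ["GGC"]))
    assert est.n_codons == 30 and est.ks == 0


def test_ng86_matches_biopython_oracle():
    """Independent cross-check against Biopython's NG86 implementation
    (conventions for stop-codon neighbourhoods differ slightly)."""
    from Bio.Align import Alignment as BioAlignment
    from Bio.Align import analysis

    rng = np.random.default_rng(3)
    sense = [c for c in ("".join(t) for t in itertools.product("ACGT", repeat=3))
             if c not in ("TAA", "TAG", "TGA")]
    for _ in range(4):
        c1 = rng.choice(sense, 150)
        c2 = [c if rng.random() < 0.75 else rng.choice(sense) for c in c1]
        mine = ng86_ks(codon_pair(c1, c2))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            dn, ds = analysis.calculate_dn_ds(
                BioAlignment(["".join(c1), "".join(c2)]), method="NG86")
        assert mine.ks == pytest.approx(ds, rel=0.05, abs=0.01)
        assert mine.ka == pytest.approx(dn, rel=0.05, abs=0.01)


# -- 4DTv --------------------------------------------------------------

def test_fourdtv_trivial_and_hand_count():
    assert fourdtv(codon_pair(["GGA"] * 10, ["GGA"] * 10)) == 0
    assert fourdtv(codon_pair(["GGA"] * 10, ["GGT"] * 10)) == 1
    # 10 qualifying Gly codons, 3 transverted (A<->T), 7 unchanged
    c1 = ["GGA"] * 10
    c2 = ["GGT"] * 3 + ["GGA"] * 7
    assert fourdtv(codon_pair(c1, c2)) == pytest.approx(0.3)


def test_fourdtv_transitions_do_not_count():
    # A->G at a fourfold third position is a transition, not a transversion
    assert fourdtv(codon_pair(["GGA"] * 10, ["GGG"] * 10)) == 0


def test_fourdtv_requires_qualifying_positions():
    # AAA (Lys) has a twofold third position; first two positions differ
    with pytest.raises(WgdError):
        fourdtv(codon_pair(["AAA"] * 10, ["AAG"] * 10))


def test_fourdtv_ignores_codons_with_changed_prefix():
    # prefix changed: position does not qualify even though fourfold
    mixed1 = ["GGA"] * 5 + ["GCA"] * 5
    mixed2 = ["CGA"] * 5 + ["GCT"] * 5  # first 5 disqualify, last 5 transvert
    assert fourdtv(codon_pair(mixed1, mixed2)) == 1.0


# -- node weighting ----------------------------------------------------

def test_two_gene_family_single_value():
    dist = node_weighted_paranome({"f": ["a", "b"]},
                                  {frozenset(("a", "b")): 0.4})
    assert dist.values.tolist() == [0.4] and dist.weights.tolist() == [1.0]


def test_four_gene_family_three_nodes():
    genes = ["a", "b", "c", "d"]
    rng = np.random.default_rng(1)
    ks = {frozenset(p): float(rng.uniform(0.1, 1.0))
          for p in itertools.combinations(genes, 2)}
    dist = node_weighted_paranome({"f": genes}, ks)
    assert len(dist.values) == 3  # 6 raw pairs -> 3 internal nodes


def test_total_weight_conservation():
    families = {"f1": ["a", "b"], "f2": ["c", "d", "e"],
                "f3": [f"g{i}" for i in range(10)]}
    ks = {}
    rng = np.random.default_rng(2)
    for genes in families.values():
        for p in itertools.combinations(genes, 2):
            ks[frozenset(p)] = float(rng.uniform(0.05, 2.0))
    dist = node_weighted_paranome(families, ks)
    assert dist.weights.sum() == pytest.approx(sum(len(g) - 1
                                                   for g in families.values()))


def test_missing_pair_is_an_error():
    with pytest.raises(WgdError, match="missing"):
        node_weighted_paranome({"f": ["a", "b", "c"]},
                               {frozenset(("a", "b")): 0.1,
                                frozenset(("a", "c")): 0.2})


# -- KDE peaks ---------------------------------------------------------

def test_peak_recovery_from_normal_sample():
    rng = np.random.default_rng(4)
    vals = rng.normal(0.7, 0.08, 1000)
    dist = KsDistribution(vals, np.ones(1000))
    peaks = ks_density_peaks(dist)
    assert peaks and abs(peaks[0][0] - 0.7) < 0.05


def test_exponential_background_has_no_interior_peak():
    hits = 0
    for seed in range(100):
        rng = np.random.default_rng(seed)
        vals = rng.exponential(1.0, 800)
        dist = KsDistribution(vals, np.ones(800))
        peaks = ks_density_peaks(dist, ks_range=(0.05, 3.0))
        interior = [p for p in peaks if 0.2 < p[0] < 2.8]
        hits += not interior
    assert hits >= 95


def test_kde_deterministic_and_guarded():
    rng = np.random.default_rng(5)
    vals = rng.normal(0.5, 0.1, 200)
    d1 = KsDistribution(vals, np.ones(200))
    d2 = KsDistribution(vals.copy(), np.ones(200))
    assert ks_density_peaks(d1, bandwidth=0.05) == ks_density_peaks(d2, bandwidth=0.05)
    with pytest.raises(WgdError):
        ks_density_peaks(KsDistribution(vals[:10], np.ones(10)))


# -- age conversion ----------------------------------------------------

def test_age_conversion_published_values():
    ltr = ks_to_age(0.05, 1.51e-9)
    assert round(ltr.ma, 1) == 16.6  # the reported ~16 Ma LTR burst
    wgd = ks_to_age(0.7006, 3.02e-9)
    assert wgd.ma == pytest.approx(116.0, abs=0.5)  # the ~116 Ma WGD


def test_age_conversion_is_linear_and_guarded():
    assert ks_to_age(0.0, 1e-9).years == 0
    assert ks_to_age(0.4, 1e-9).years == pytest.approx(2 * ks_to_age(0.2, 1e-9).years)
    assert ks_to_age(0.2, 2e-9).years == pytest.approx(ks_to_age(0.2, 1e-9).years / 2)
    with pytest.raises(WgdError):
        ks_to_age(0.1, 0.0)
    with pytest.raises(WgdError):
        ks_to_age(-0.1, 1e-9)
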