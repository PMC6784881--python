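"""Shared fixtures: clade designs, hypothesis trees, likelihood oracle."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from lirio.conflict import build_hypotheses
from lirio.models import jc69


@pytest.fixture(scope="session")
def clade_species_full() -> dict[str, list[str]]:
    """The 13-species design: 4 eudicots, 4 monocots, 3 magnoliids,
    1 basal angiosperm, 1 gymnosperm."""
    return {
        "eudicot": [f"eud{i}" for i in range(4)],
        "monocot": [f"mon{i}" for i in range(4)],
        "magnoliid": [f"mag{i}" for i in range(3)],
        "basal_angiosperm": ["amb0"],
        "gymnosperm": ["gym0"],
    }


@pytest.fixture(scope="session")
def clade_species_minimal() -> dict[str, list[str]]:
    """One species per clade (fast 5-taxon hypothesis trees)."""
    return {c: [c[:3] + "0"] for c in
            ("eudicot", "monocot", "magnoliid", "basal_angiosperm", "gymnosperm")}


@pytest.fixture(scope="session")
def hypotheses_full(clade_species_full):
    return build_hypotheses(clade_species_full)


@pytest.fixture(scope="session")
def hypotheses_minimal(clade_species_minimal):
    return build_hypotheses(clade_species_minimal)


@pytest.fixture(scope="session")
def jc():
    return jc69()


def brute_force_lnl(tree, aln, model) -> float:
    """Likelihood by explicit summation over all internal-node state
    assignments — exponential-time oracle for small trees."""
    nodes = list(tree.postorder())
    internals = [n for n in nodes if not n.is_leaf]
    k = model.n_states
    codes = aln.state_indices()
    idx = {nm: i for i, nm in enumerate(aln.names)}
    rates, w = model.rate_categories()
    total = 0.0
    pmats = {}
    for site in range(aln.n_sites):
        site_l = 0.0
        for c, r in enumerate(rates):
            for n in nodes:
                if n.parent is not None:
                    pmats[(id(n), c)] = model.transition_matrix((n.length or 0.0) * r)
            s = 0.0
            for assign in itertools.product(range(k), repeat=len(internals)):
                amap = {id(n): a for n, a in zip(internals, assign)}
                pr = model.frequencies[amap[id(tree.root)]]
                for n in nodes:
                    if n.parent is None:
                        continue
                    ps = amap[id(n.parent)]
                    if n.is_leaf:
                        obs = codes[idx[n.name], site]
                        if obs >= 0:
                            pr *= pmats[(id(n), c)][ps, obs]
                    else:
                        pr *= pmats[(id(n), c)][ps, amap[id(n)]]
                s += pr
            site_l += w[c] * s
        total += float(np.log(site_l))
    return total


@pytest.fixture(scope="session")
def likelihood_oracle():
    return brute_force_lnl
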