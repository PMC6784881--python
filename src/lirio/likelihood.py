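"""Pruning-algorithm likelihood and branch-length optimization.

The likelihood of an alignment on a tree under a reversible substitution
model is computed with Felsenstein's pruning algorithm over compressed
site patterns, with per-node log-scaling to avoid underflow and a
discrete-gamma rate mixture averaged per site.  Gaps and ambiguity codes
contribute all-ones conditional likelihoods (fully missing).

Branch lengths are optimized coordinate-wise.  For one branch, with all
others fixed, the site likelihood factorizes into an "inside" partial
below the branch and an "outside" partial above it, so the 1-D profile
likelihood costs one small matrix product per evaluation.  A sweep walks
the tree depth-first, optimizing each branch with Brent's method while
updating inside/outside partials incrementally, so every 1-D step sees
partials that reflect all branch lengths already updated — a
Gauss–Seidel scheme whose total log-likelihood never decreases.  Sweeps
repeat until the gain falls below ``tol``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .alignment import Alignment
from .models import SubstitutionModel
from .trees import Node, Tree, TreeError

__all__ = ["LikelihoodResult", "log_likelihood", "optimize_branch_lengths",
           "MIN_BRANCH_LENGTH", "MAX_BRANCH_LENGTH"]

MIN_BRANCH_LENGTH = 1e-8
MAX_BRANCH_LENGTH = 10.0
DEFAULT_BRANCH_LENGTH = 0.1


@dataclass
class LikelihoodResult:
    log_likelihood: float
    per_site_lnL: np.ndarray
    tree: Tree
    converged: bool = True
    n_sweeps: int = 0


def _rescale(arr: np.ndarray, logscale: np.ndarray) -> None:
    """Divide by the per-pattern max (over categories and states) in place,
    accumulating its log; the max is shared across categories so the
    category average stays exact."""
    scale = arr.max(axis=(0, 1))
    np.maximum(scale, 1e-300, out=scale)
    arr /= scale[None, None, :]
    logscale += np.log(scale)


class _Engine:
    """Indexed tree + compressed alignment for repeated lnL evaluations."""

    def __init__(self, tree: Tree, alignment: Alignment, model: SubstitutionModel):
        self.model = model
        self.tree = tree.copy()
        self.nodes: list[Node] = list(self.tree.postorder())  # root last
        index = {id(n): i for i, n in enumerate(self.nodes)}
        self.children = [[index[id(c)] for c in n.children] for n in self.nodes]
        self.root = len(self.nodes) - 1
        self.lengths = np.empty(len(self.nodes))
        for i, n in enumerate(self.nodes):
            if n.parent is not None and n.length is not None and n.length < 0:
                raise TreeError(f"negative branch length on {n.name or 'internal node'}")
            self.lengths[i] = n.length if n.length is not None else DEFAULT_BRANCH_LENGTH

        leaf_names = self.tree.leaf_names()
        missing = set(leaf_names) - set(alignment.names)
        if missing:
            raise ValueError(f"leaves without sequences: {sorted(missing)}")
        sub = alignment.subset(leaf_names)
        codes = sub.state_indices()
        patterns, self.pattern_index, self.pattern_counts = np.unique(
            codes.T, axis=0, return_inverse=True, return_counts=True)
        self.patterns = patterns.T  # (n_leaves, n_patterns)
        self.n_patterns = self.patterns.shape[1]
        self.n_sites = alignment.n_sites
        self.counts_f = self.pattern_counts.astype(float)

        k = model.n_states
        self.k = k
        self.rates, self.rate_weights = model.rate_categories()
        self.ncat = len(self.rates)
        # tip partials (ncat, n_states, n_patterns); category-constant
        self.tip_partials: dict[int, np.ndarray] = {}
        leaf_row = {name: i for i, name in enumerate(leaf_names)}
        for i, n in enumerate(self.nodes):
            if n.is_leaf:
                col = self.patterns[leaf_row[n.name]]
                tp = np.zeros((k, self.n_patterns))
                known = col >= 0
                tp[col[known], np.nonzero(known)[0]] = 1.0
                tp[:, ~known] = 1.0
                self.tip_partials[i] = np.broadcast_to(
                    tp, (self.ncat, k, self.n_patterns)).copy()
        # workspaces filled by down/up passes
        n = len(self.nodes)
        self.D: list[np.ndarray | None] = [None] * n
        self.D_ls = np.zeros((n, self.n_patterns))
        self.M: list[np.ndarray | None] = [None] * n  # message through edge i
        self.M_ls = np.zeros((n, self.n_patterns))

    # -- transition matrices ------------------------------------------
    def _pmats(self, t: float) -> list[np.ndarray]:
        tm = self.model.transition_matrix_unchecked
        return [tm(t * r) for r in self.rates]

    def _message(self, i: int) -> None:
        """M[i] = P(t_i) @ D[i], the message node i sends to its parent."""
        ps = self._pmats(self.lengths[i])
        d = self.D[i]
        self.M[i] = np.stack([ps[c] @ d[c] for c in range(self.ncat)])
        self.M_ls[i] = self.D_ls[i]

    # -- inside (down) pass -------------------------------------------
    def _refresh_node(self, i: int) -> None:
        """Recompute D[i] from the children's messages (assumed fresh)."""
        kids = self.children[i]
        acc = self.M[kids[0]].copy()
        ls = self.M_ls[kids[0]].copy()
        for ci in kids[1:]:
            acc *= self.M[ci]
            ls += self.M_ls[ci]
        _rescale(acc, ls)
        self.D[i] = acc
        self.D_ls[i] = ls

    def down_pass(self) -> None:
        for i, node in enumerate(self.nodes):
            if node.is_leaf:
                self.D[i] = self.tip_partials[i]
                self.D_ls[i] = 0.0
            else:
                self._refresh_node(i)
            if i != self.root:
                self._message(i)

    def root_lnl(self) -> tuple[float, np.ndarray]:
        pi = self.model.frequencies
        d = self.D[self.root]
        site = np.zeros(self.n_patterns)
        for c in range(self.ncat):
            site += self.rate_weights[c] * (pi @ d[c])
        lnl_pat = np.log(site) + self.D_ls[self.root]
        return float(self.counts_f @ lnl_pat), lnl_pat[self.pattern_index]

    def lnl(self) -> float:
        self.down_pass()
        return self.root_lnl()[0]

    # -- profile likelihood along one edge ----------------------------
    def edge_lnl(self, v: int, t: float, G: np.ndarray, G_ls: np.ndarray) -> float:
        d = self.D[v]
        if self.ncat == 1:
            p = self.model.transition_matrix_unchecked(t)
            site = np.einsum("xp,xp->p", G[0], p @ d[0], optimize=False)
        else:
            ps = self._pmats(t)
            site = np.zeros(self.n_patterns)
            for c in range(self.ncat):
                site += self.rate_weights[c] * np.einsum(
                    "xp,xp->p", G[c], ps[c] @ d[c], optimize=False)
        np.maximum(site, 1e-300, out=site)
        lnl_pat = np.log(site)
        lnl_pat += self.D_ls[v]
        lnl_pat += G_ls
        return float(self.counts_f @ lnl_pat)

    def optimize_edge(self, v: int, G: np.ndarray, G_ls: np.ndarray) -> None:
        """Brent optimization of one branch on the eigenbasis projection.

        With P(t) diagonalized as S V e^{Λt} Vᵀ S⁻¹ (S = diag(π^{-1/2})),
        the per-pattern site likelihood along this edge is a linear
        combination Σ_k A_k e^{λ_k t}, so each 1-D evaluation is a single
        matrix–vector product after a one-off projection of the inside
        and outside partials.
        """
        lam, V, sqrt_pi = self.model._eigendecomposition()
        d = self.D[v]
        proj = [
            (V.T @ (G[c] / sqrt_pi[:, None])) * (V.T @ (d[c] * sqrt_pi[:, None]))
            for c in range(self.ncat)
        ]
        ls = self.D_ls[v] + G_ls
        weights, rates, counts = self.rate_weights, self.rates, self.counts_f

        def neg_lnl(t: float) -> float:
            site = weights[0] * (np.exp(lam * (rates[0] * t)) @ proj[0])
            for c in range(1, self.ncat):
                site += weights[c] * (np.exp(lam * (rates[c] * t)) @ proj[c])
            np.maximum(site, 1e-300, out=site)
            return -float(counts @ (np.log(site) + ls))

        current = neg_lnl(self.lengths[v])
        res = minimize_scalar(neg_lnl, bounds=(MIN_BRANCH_LENGTH, MAX_BRANCH_LENGTH),
                              method="bounded", options={"xatol": 1e-7, "maxiter": 60})
        if res.fun < current:  # accept only genuine improvement
            self.lengths[v] = float(res.x)

    # -- one Gauss–Seidel sweep ---------------------------------------
    def sweep(self) -> None:
        """Optimize every branch once, depth first, updating partials so
        each 1-D optimization sees the exact profile likelihood."""

        def visit(v: int, G: np.ndarray, G_ls: np.ndarray) -> None:
            self.optimize_edge(v, G, G_ls)
            kids = self.children[v]
            if kids:
                # outside partial at v, transported through the new length
                ps = self._pmats(self.lengths[v])
                O = np.stack([ps[c].T @ G[c] for c in range(self.ncat)])
                O_ls = G_ls.copy()
                _rescale(O, O_ls)
                for w in kids:
                    g = O.copy()
                    gls = O_ls.copy()
                    for u in kids:
                        if u != w:
                            g = g * self.M[u]
                            gls = gls + self.M_ls[u]
                    _rescale(g, gls)
                    visit(w, g, gls)
                    self._message(w)  # subtree below w may have changed
                self._refresh_node(v)
            self._message(v)

        pi = self.model.frequencies
        base = np.broadcast_to(pi[None, :, None],
                               (self.ncat, self.k, self.n_patterns))
        kids = self.children[self.root]
        for w in kids:
            g = base.copy()
            gls = np.zeros(self.n_patterns)
            for u in kids:
                if u != w:
                    g = g * self.M[u]
                    gls = gls + self.M_ls[u]
            _rescale(g, gls)
            visit(w, g, gls)
            self._message(w)
        self._refresh_node(self.root)

    def write_lengths(self) -> Tree:
        for i, node in enumerate(self.nodes):
            if node.parent is not None:
                node.length = float(self.lengths[i])
        return self.tree


def log_likelihood(tree: Tree, alignment: Alignment,
                   model: SubstitutionModel) -> LikelihoodResult:
    """Felsenstein pruning log-likelihood of `alignment` on `tree`."""
    eng = _Engine(tree, alignment, model)
    eng.down_pass()
    total, per_site = eng.root_lnl()
    return LikelihoodResult(total, per_site, eng.write_lengths())


def optimize_branch_lengths(tree: Tree, alignment: Alignment,
                            model: SubstitutionModel, tol: float = 1e-6,
                            max_sweeps: int = 20) -> LikelihoodResult:
    """Maximize the likelihood over branch lengths, topology fixed.

    Returns a result whose log-likelihood is never below the initial one;
    hitting the sweep cap before the per-sweep gain drops under `tol`
    sets ``converged=False`` (a warning flag, not an exception).
    """
    eng = _Engine(tree, alignment, model)
    eng.down_pass()
    lnl = eng.root_lnl()[0]
    converged = False
    sweeps = 0
    for sweeps in range(1, max_sweeps + 1):
        eng.sweep()
        new_lnl = eng.root_lnl()[0]
        gain = new_lnl - lnl
        lnl = new_lnl
        if gain < tol:
            converged = True
            break
    total, per_site = eng.root_lnl()
    return LikelihoodResult(total, per_site, eng.write_lengths(),
                            converged=converged, n_sweeps=sweeps)
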