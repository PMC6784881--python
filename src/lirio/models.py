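"""Substitution models: JC69, HKY, GTR (nucleotide) and WAG (protein).

Every model carries a reversible rate matrix Q normalized so that the mean
rate at stationarity is one substitution per site per unit branch length,
plus an optional discrete-gamma rate mixture (equal-probability categories
with category means, the standard discretization).  Transition matrices are
computed from a cached symmetric eigendecomposition, so P(t) is exact and
cheap for repeated branch-length evaluations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammainc, gammaincinv

from ._wag import WAG_EXCHANGEABILITIES, WAG_FREQUENCIES, WAG_ORDER
from .alignment import DNA_STATES, PROTEIN_STATES

__all__ = ["SubstitutionModel", "ModelError", "jc69", "hky", "gtr", "wag", "transition_matrix"]


class ModelError(ValueError):
    pass


def _build_q(exchange: np.ndarray, freqs: np.ndarray) -> np.ndarray:
    """Reversible generator from symmetric exchangeabilities and stationary
    frequencies, normalized to mean rate 1."""
    n = len(freqs)
    q = exchange * freqs[None, :]
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    mean_rate = -(freqs * np.diag(q)).sum()
    return q / mean_rate


@dataclass
class SubstitutionModel:
    name: str
    states: str
    exchangeabilities: np.ndarray  # symmetric, zero diagonal
    frequencies: np.ndarray
    gamma_shape: float | None = None
    n_rate_categories: int = 4
    _eig: tuple | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.exchangeabilities = np.asarray(self.exchangeabilities, dtype=float)
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        if not np.isclose(self.frequencies.sum(), 1.0, atol=1e-8):
            raise ModelError("stationary frequencies must sum to 1")
        if np.any(self.frequencies <= 0):
            raise ModelError("stationary frequencies must be positive")
        if self.gamma_shape is not None and self.gamma_shape <= 0:
            raise ModelError("gamma shape must be positive")
        self.q = _build_q(self.exchangeabilities, self.frequencies)

    @property
    def n_states(self) -> int:
        return len(self.frequencies)

    def rate_categories(self) -> tuple[np.ndarray, np.ndarray]:
        """(rates, weights) of the discrete-gamma mixture (mean rate 1).

        Without a gamma shape this is the single unit-rate category.
        """
        if self.gamma_shape is None or self.n_rate_categories <= 1:
            return np.array([1.0]), np.array([1.0])
        a = self.gamma_shape
        k = self.n_rate_categories
        # category boundaries of Gamma(a, scale=1/a), then category means
        edges = gammaincinv(a, np.arange(1, k) / k) / a
        edges = np.concatenate([[0.0], edges, [np.inf]])
        upper = gammainc(a + 1, edges[1:] * a)
        lower = gammainc(a + 1, edges[:-1] * a)
        means = k * (upper - lower)
        means = means / means.mean()  # guard rounding; mean must be exactly 1
        return means, np.full(k, 1.0 / k)

    def _eigendecomposition(self):
        if self._eig is None:
            pi = self.frequencies
            sqrt_pi = np.sqrt(pi)
            b = (self.q * sqrt_pi[:, None]) / sqrt_pi[None, :]
            b = (b + b.T) / 2  # symmetric for reversible Q; enforce exactly
            w, v = np.linalg.eigh(b)
            self._eig = (w, v, sqrt_pi)
        return self._eig

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) = exp(Qt); row-stochastic; P(0) = I."""
        if t < 0:
            raise ModelError(f"branch length must be >= 0, got {t}")
        w, v, sqrt_pi = self._eigendecomposition()
        inner = (v * np.exp(w * t)) @ v.T
        p = inner * (sqrt_pi[None, :] / sqrt_pi[:, None])
        np.clip(p, 0.0, None, out=p)
        return p / p.sum(axis=1, keepdims=True)

    def transition_matrix_unchecked(self, t: float) -> np.ndarray:
        """Like :meth:`transition_matrix` but without clipping and row
        renormalization (entries exact to ~1e-15); used in the likelihood
        inner loop."""
        w, v, sqrt_pi = self._eigendecomposition()
        inner = (v * np.exp(w * t)) @ v.T
        return inner * (sqrt_pi[None, :] / sqrt_pi[:, None])


def transition_matrix(model: SubstitutionModel, t: float) -> np.ndarray:
    return model.transition_matrix(t)


def jc69(gamma_shape: float | None = None, n_rate_categories: int = 4) -> SubstitutionModel:
    ex = np.ones((4, 4)) - np.eye(4)
    return SubstitutionModel("JC69", DNA_STATES, ex, np.full(4, 0.25),
                             gamma_shape, n_rate_categories)


def hky(kappa: float = 2.0, frequencies=None,
        gamma_shape: float | None = None, n_rate_categories: int = 4) -> SubstitutionModel:
    if kappa <= 0:
        raise ModelError("kappa must be positive")
    freqs = np.full(4, 0.25) if frequencies is None else np.asarray(frequencies, float)
    ex = np.ones((4, 4)) - np.eye(4)
    # transitions: A<->G (0,2), C<->T (1,3)
    ex[0, 2] = ex[2, 0] = kappa
    ex[1, 3] = ex[3, 1] = kappa
    return SubstitutionModel("HKY", DNA_STATES, ex, freqs, gamma_shape, n_rate_categories)


def gtr(rates, frequencies, gamma_shape: float | None = None,
        n_rate_categories: int = 4) -> SubstitutionModel:
    """GTR from the 6 upper-triangle exchangeabilities in order
    AC, AG, AT, CG, CT, GT."""
    r = np.asarray(rates, float)
    if r.shape != (6,) or np.any(r <= 0):
        raise ModelError("GTR needs 6 positive exchangeabilities")
    ex = np.zeros((4, 4))
    ex[0, 1] = ex[1, 0] = r[0]
    ex[0, 2] = ex[2, 0] = r[1]
    ex[0, 3] = ex[3, 0] = r[2]
    ex[1, 2] = ex[2, 1] = r[3]
    ex[1, 3] = ex[3, 1] = r[4]
    ex[2, 3] = ex[3, 2] = r[5]
    return SubstitutionModel("GTR", DNA_STATES, ex, np.asarray(frequencies, float),
                             gamma_shape, n_rate_categories)


def wag(frequencies=None, gamma_shape: float | None = None,
        n_rate_categories: int = 4) -> SubstitutionModel:
    """WAG protein model; `frequencies` may override the published
    stationary frequencies with empirical ones."""
    assert WAG_ORDER == PROTEIN_STATES
    ex = np.zeros((20, 20))
    idx = np.tril_indices(20, k=-1)
    # stored column-major lower triangle
    col_major = [(i, j) for j in range(20) for i in range(j + 1, 20)]
    for (i, j), val in zip(col_major, WAG_EXCHANGEABILITIES):
        ex[i, j] = ex[j, i] = val
    del idx
    freqs = np.asarray(WAG_FREQUENCIES if frequencies is None else frequencies, float)
    freqs = freqs / freqs.sum()
    return SubstitutionModel("WAG", PROTEIN_STATES, ex, freqs,
                             gamma_shape, n_rate_categories)


def get_model(name: str, **kwargs) -> SubstitutionModel:
    name_l = name.lower()
    if name_l == "jc69":
        return jc69(**kwargs)
    if name_l == "hky":
        return hky(**kwargs)
    if name_l == "gtr":
        return gtr(**kwargs)
    if name_l == "wag":
        return wag(**kwargs)
    raise ModelError(f"unknown substitution model: {name}")
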