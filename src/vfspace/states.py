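"""Normalized state vectors over the tuple basis.

A state |x⟩ = Σ_k c_k |tuple_k⟩ assigns a real signed coefficient to every
tuple of the basis, under the normalization Σ|c_k|² = 1: producing a word
renders its tuples inadmissible (coefficient 0) but must not change the
magnitude of the state vector, since the suppressed representations remain
part of the network.

Constructors cover the model's named families — the uniform initial state
|x⟩, its sign-flipped inseparable variant |x̄⟩ (empty-tuple coefficient
negated), and the post-production states |x_C⟩, |x_B⟩, ... in which all
tuples containing the produced words have been zeroed.  ``is_separable``
certifies whether a state's coefficient tensor factorizes into per-item
two-component factors, the dichotomy between states in which the single
informational entities exist in separation and those in which they do not.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import AbstractSet, Iterable, Sequence

import numpy as np

from .statespace import TupleBasis

__all__ = [
    "StateVector",
    "Factorization",
    "uniform_state",
    "xbar_state",
    "post_production_state",
    "is_separable",
    "norm",
]

NORM_TOL = 1e-9


@dataclass(frozen=True)
class StateVector:
    """Unit-norm real coefficient vector over a full (2**i) tuple basis."""

    basis: TupleBasis
    coefficients: np.ndarray

    def __post_init__(self):
        coeffs = np.asarray(self.coefficients, dtype=float)
        object.__setattr__(self, "coefficients", coeffs)
        if not self.basis.include_empty:
            raise ValueError(
                "state vectors live on the full 2**i basis (include_empty=True)"
            )
        if coeffs.shape != (self.basis.dimension,):
            raise ValueError(
                f"expected {self.basis.dimension} coefficients, got {coeffs.shape}"
            )
        nsq = float(coeffs @ coeffs)
        if abs(nsq - 1.0) > NORM_TOL:
            raise ValueError(f"state not normalized: sum of squares = {nsq!r}")

    @property
    def n_items(self) -> int:
        return self.basis.n_items

    def norm_squared(self) -> float:
        c = self.coefficients
        return float(c @ c)

    def coefficient(self, members: AbstractSet[str] | Iterable[str]) -> float:
        return float(self.coefficients[self.basis.tuple_to_index(members)])

    def support(self, zero_tol: float = 1e-12) -> np.ndarray:
        """Indices of tuples with nonzero coefficient."""
        return np.flatnonzero(np.abs(self.coefficients) > zero_tol)

    def as_tensor(self) -> np.ndarray:
        """Coefficients as an i-way tensor, axis b indexing item b's digit."""
        return self.coefficients.reshape((2,) * self.n_items, order="F")


@dataclass(frozen=True)
class Factorization:
    """Result of the separability test.

    When ``separable``, ``factors[b]`` is the (digit-0 weight, digit-1
    weight) pair of item ``b``, each pair of unit squared norm, and the
    outer product of the factors reproduces the coefficients.
    """

    separable: bool
    factors: tuple[tuple[float, float], ...] | None = None


def uniform_state(basis: TupleBasis) -> StateVector:
    """The initial state |x⟩: equal positive weight 1/√(2^i) on every tuple."""
    dim = _full_dimension(basis)
    return StateVector(basis, np.full(dim, 1.0 / np.sqrt(dim)))


def xbar_state(basis: TupleBasis) -> StateVector:
    """The inseparable initial state |x̄⟩: |x⟩ with the empty-tuple
    coefficient negated (magnitudes unchanged, hence still normalized)."""
    dim = _full_dimension(basis)
    coeffs = np.full(dim, 1.0 / np.sqrt(dim))
    coeffs[0] = -coeffs[0]
    return StateVector(basis, coeffs)


def post_production_state(
    basis: TupleBasis, produced: AbstractSet[str] | Sequence[str]
) -> StateVector:
    """State after the words in *produced* have been produced.

    All tuples containing a produced word are inadmissible (coefficient 0);
    the 2^(i-m) surviving tuples carry equal positive weight.  Producing
    every item leaves the pure empty-tuple ("inactive") state.
    """
    dim = _full_dimension(basis)
    mask = basis.tuple_to_index(set(produced))
    k = np.arange(dim)
    survivors = (k & mask) == 0
    coeffs = np.where(survivors, 1.0 / np.sqrt(survivors.sum()), 0.0)
    return StateVector(basis, coeffs)


def norm(state: StateVector) -> float:
    """Sum of squared coefficient magnitudes, Σ|c_k|²."""
    return state.norm_squared()


def is_separable(state: StateVector, tol: float = 1e-9) -> Factorization:
    """Test whether the coefficient tensor factorizes item by item.

    The state is separable iff its i-way coefficient tensor has rank 1 in
    every mode unfolding (second singular value below *tol*).  Factors are
    normalized so each pair has unit squared norm, the first nonzero entry
    of every factor but the last is non-negative, and the residual global
    sign is absorbed into the last factor, so the outer product reproduces
    the coefficients exactly (not merely up to sign).
    """
    tensor = state.as_tensor()
    i = state.n_items
    factors = []
    for mode in range(i):
        unfolding = np.moveaxis(tensor, mode, 0).reshape(2, -1)
        u, s, _ = np.linalg.svd(unfolding, full_matrices=False)
        if s[1] > tol:
            return Factorization(separable=False)
        factors.append(u[:, 0])

    # orient all but the last factor to a non-negative leading entry
    for b in range(i - 1):
        lead = factors[b][np.flatnonzero(np.abs(factors[b]) > tol)[0]]
        if lead < 0:
            factors[b] = -factors[b]
    # absorb the residual sign so the outer product matches the coefficients
    recon = _outer(factors)
    sign = np.sign(np.vdot(recon, tensor))
    factors[-1] = factors[-1] * (sign if sign != 0 else 1.0)
    recon = _outer(factors)
    if np.max(np.abs(recon - tensor)) > max(tol, 1e-9):
        return Factorization(separable=False)
    return Factorization(
        separable=True,
        factors=tuple((float(f[0]), float(f[1])) for f in factors),
    )


def _outer(factors: list[np.ndarray]) -> np.ndarray:
    out = factors[0]
    for f in factors[1:]:
        out = np.multiply.outer(out, f)
    return out


def _full_dimension(basis: TupleBasis) -> int:
    if not basis.include_empty:
        raise ValueError(
            "state constructors require the full basis including the empty "
            "tuple (include_empty=True); the 2**i - 1 regime has a different "
            "normalization target"
        )
    return basis.dimension
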