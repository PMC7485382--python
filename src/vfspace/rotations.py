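"""Word-production rotation operators.

Producing a word w must zero the coefficients of every tuple containing w
while preserving the norm of the state vector — a rotation, hence an
orthogonal matrix R_w.  Every R_w is built from the same 2×2 minimal matrix

    ρ = (1/√2) [[1, 1], [−1, 1]],

a 45° plane rotation (the analogue of an elementary quantum logic gate):
R_w applies ρ to each coordinate pair (tuple without w, same tuple with w)
and touches nothing else.  Equivalently R_w is the Kronecker product with ρ
at item w's tensor factor and the identity at every other factor.  All the
production operators over one basis therefore share the structure and the
eigenvalue multiset of ρ — e^{±iπ/4}, each at multiplicity 2^(i−1) — i.e.
they lie in a single similarity equivalence class, and they commute, so the
full production sequence ends in the pure empty-tuple state regardless of
word order.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property
from typing import Sequence

import numpy as np

from .statespace import TupleBasis
from .states import StateVector

__all__ = [
    "MinimalMatrix",
    "ProductionOperator",
    "minimal_matrix",
    "production_operator",
    "apply",
    "apply_sequence",
    "spectrum",
    "similar",
]

#: largest i for which a dense 2^i × 2^i matrix is materialized
DENSE_LIMIT = 12

MinimalMatrix = np.ndarray


def minimal_matrix() -> MinimalMatrix:
    """The minimal matrix ρ = (1/√2)[[1, 1], [−1, 1]].

    Orthogonal with determinant 1; sends an equal pair (a, a) to (a√2, 0),
    which is exactly the single-item production event.
    """
    return np.array([[1.0, 1.0], [-1.0, 1.0]]) / np.sqrt(2.0)


@dataclass(frozen=True)
class ProductionOperator:
    """Orthogonal rotation R_w producing item *w* over a tuple basis."""

    basis: TupleBasis
    item: str

    def __post_init__(self):
        if self.item not in self.basis.items:
            raise ValueError(
                f"item {self.item!r} not in basis items {tuple(self.basis.items)}"
            )
        if not self.basis.include_empty:
            raise ValueError("production operators act on the full 2**i basis")

    @property
    def bit(self) -> int:
        return self.basis.items.position(self.item)

    @property
    def dimension(self) -> int:
        return self.basis.dimension

    @cached_property
    def matrix(self) -> np.ndarray:
        """Dense 2^i × 2^i matrix (available up to i = DENSE_LIMIT)."""
        if self.basis.n_items > DENSE_LIMIT:
            raise ValueError(
                f"dense matrix only materialized up to i={DENSE_LIMIT}; "
                "use apply() for matrix-free application"
            )
        rho = minimal_matrix()
        eye = np.eye(2)
        # LSB is the fastest-varying index, so item 0 is the *last* Kronecker
        # factor; build from the most-significant item downwards.
        out = np.array([[1.0]])
        for b in reversed(range(self.basis.n_items)):
            out = np.kron(out, rho if b == self.bit else eye)
        return out

    def apply_to_coefficients(self, coeffs: np.ndarray) -> np.ndarray:
        """Blockwise (matrix-free) application of ρ along item w's axis."""
        coeffs = np.asarray(coeffs, dtype=float)
        if coeffs.shape != (self.dimension,):
            raise ValueError(
                f"dimension mismatch: operator is {self.dimension}-dimensional, "
                f"state has shape {coeffs.shape}"
            )
        tensor = coeffs.reshape((2,) * self.basis.n_items, order="F")
        c0 = np.take(tensor, 0, axis=self.bit)
        c1 = np.take(tensor, 1, axis=self.bit)
        new = np.stack([(c0 + c1), (c1 - c0)], axis=self.bit) / np.sqrt(2.0)
        return new.reshape(self.dimension, order="F")

    def apply(self, state: StateVector) -> StateVector:
        return StateVector(state.basis, self.apply_to_coefficients(state.coefficients))

    def spectrum(self, decimals: int = 9) -> np.ndarray:
        """Eigenvalues as a sorted array (by real part, then imaginary).

        For i ≤ DENSE_LIMIT computed numerically from the dense matrix;
        beyond that, from the tensor structure: the eigenvalues of ρ,
        e^{±iπ/4}, each at multiplicity 2^(i−1).
        """
        if self.basis.n_items <= DENSE_LIMIT:
            eig = np.linalg.eigvals(self.matrix)
        else:
            half = 1 << (self.basis.n_items - 1)
            eig = np.repeat(np.linalg.eigvals(minimal_matrix()), half)
        eig = np.round(eig, decimals)
        order = np.lexsort((eig.imag, eig.real))
        return eig[order]


def production_operator(basis: TupleBasis, item: str) -> ProductionOperator:
    """The rotation R_item over *basis* built from the minimal matrix."""
    return ProductionOperator(basis=basis, item=item)


def apply(op: ProductionOperator, state: StateVector) -> StateVector:
    """Rotate *state* by *op*; the norm is conserved to machine precision."""
    return op.apply(state)


def apply_sequence(
    basis: TupleBasis, order: Sequence[str], start: StateVector
) -> list[StateVector]:
    """Trajectory of states after producing the items of *order* in turn.

    Starting from the uniform state and producing every item drives the
    state to the pure empty-tuple ("inactive") vector with coefficient +1,
    in any order: the operators commute.
    """
    if len(set(order)) != len(order):
        raise ValueError(f"repeated item in production order {list(order)!r}")
    trajectory = []
    state = start
    for item in order:
        state = production_operator(basis, item).apply(state)
        trajectory.append(state)
    return trajectory


def spectrum(op: ProductionOperator, decimals: int = 9) -> np.ndarray:
    """Sorted eigenvalue multiset of *op* (see
    :meth:`ProductionOperator.spectrum`)."""
    return op.spectrum(decimals=decimals)


def similar(op1: ProductionOperator, op2: ProductionOperator, tol: float = 1e-9) -> bool:
    """Whether two production operators lie in the same equivalence class.

    Orthogonal matrices are normal, so equality of eigenvalue multisets
    (within *tol*) is equivalent to similarity.
    """
    if op1.dimension != op2.dimension:
        raise ValueError(
            f"dimension mismatch: {op1.dimension} vs {op2.dimension}"
        )
    return bool(np.all(np.abs(op1.spectrum() - op2.spectrum()) <= tol))
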