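"""Tuple bases over item sets and their encodings.

An item set of size ``i`` (words of a semantic category, or feature inputs to
a neural clique) generates the family of all non-ordered tuples — subsets —
of its items.  Each tuple is encoded three equivalent ways:

* **tuple notation**: the subset itself, e.g. ``{A, C}``;
* **bitstring**: one binary digit per item, ``1`` if the item is in the
  tuple, written in item-list order, e.g. ``101``;
* **decimal**: the integer whose bit ``b`` is the digit of the item at list
  position ``b`` (position 0 is the least-significant bit), e.g. ``5``.

With the empty tuple the family has ``2**i`` members; excluding it (the
neural-clique counting, where a motif over ``i`` inputs comprises
``2**i - 1`` cliques) it has ``2**i - 1``.  The tuples, enumerated in
ascending decimal order, serve as orthonormal basis vectors of the
``2**i``-dimensional state space used throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import AbstractSet, Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ItemSet",
    "TupleBasis",
    "BasisEntry",
    "build_basis",
    "tuple_to_index",
    "index_to_tuple",
    "clique_count",
    "render_barcode",
    "barcode_figure",
]

MAX_ITEMS = 20  # caps the 2**i basis at ~1M entries

EMPTY_TUPLE_LABEL = "∅"

# Fig-1 palette: activated ("permissible") vs suppressed ("impermissible")
ACTIVATED_COLOR = "tab:orange"
SUPPRESSED_COLOR = "tab:green"


@dataclass(frozen=True)
class ItemSet:
    """Ordered collection of distinct item labels.

    The order is fixed at construction and defines the bit positions of the
    encoding: the item at position 0 is the least-significant bit.
    """

    labels: tuple[str, ...]

    def __init__(self, labels: Iterable[str]):
        labels = tuple(str(w) for w in labels)
        if not labels:
            raise ValueError("ItemSet requires at least one item")
        if len(labels) > MAX_ITEMS:
            raise ValueError(
                f"ItemSet supports at most {MAX_ITEMS} items, got {len(labels)}"
            )
        if len(set(labels)) != len(labels):
            raise ValueError(f"duplicate item labels in {labels!r}")
        object.__setattr__(self, "labels", labels)

    def __len__(self) -> int:
        return len(self.labels)

    def __iter__(self) -> Iterator[str]:
        return iter(self.labels)

    def __contains__(self, label: object) -> bool:
        return label in self.labels

    def position(self, label: str) -> int:
        """Bit position of *label* (0 = least-significant)."""
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"item {label!r} not in item set {self.labels}") from None


@dataclass(frozen=True)
class BasisEntry:
    """One basis vector in its three equivalent notations."""

    members: tuple[str, ...]  # in item-list order
    bitstring: str
    decimal: int

    @property
    def tuple_label(self) -> str:
        if not self.members:
            return EMPTY_TUPLE_LABEL
        return "{" + ",".join(self.members) + "}"

    @property
    def ket(self) -> str:
        return "|" + self.bitstring + "⟩"


@dataclass(frozen=True)
class TupleBasis:
    """The ordered tuple basis over an :class:`ItemSet`.

    ``include_empty=True`` gives all ``2**i`` tuples; ``False`` drops the
    empty tuple (decimal 0), leaving ``2**i - 1``.  Enumeration order is
    ascending decimal in both regimes.
    """

    items: ItemSet
    include_empty: bool = True

    @property
    def n_items(self) -> int:
        return len(self.items)

    @property
    def size(self) -> int:
        return clique_count(self.n_items, self.include_empty)

    @property
    def dimension(self) -> int:
        """Dimension of the ambient state space (always ``2**i``)."""
        return 1 << self.n_items

    def indices(self) -> range:
        start = 0 if self.include_empty else 1
        return range(start, self.dimension)

    def __len__(self) -> int:
        return self.size

    def __iter__(self) -> Iterator[BasisEntry]:
        return (self.entry(k) for k in self.indices())

    def bitstring(self, idx: int) -> str:
        """Binary digits of *idx* in item-list order (first item first)."""
        return "".join(str((idx >> b) & 1) for b in range(self.n_items))

    def entry(self, idx: int) -> BasisEntry:
        return BasisEntry(
            members=self.index_to_tuple(idx),
            bitstring=self.bitstring(idx),
            decimal=idx,
        )

    def tuple_to_index(self, members: AbstractSet[str] | Iterable[str]) -> int:
        idx = 0
        seen = set()
        for label in members:
            if label in seen:
                raise ValueError(f"duplicate member {label!r}")
            seen.add(label)
            idx |= 1 << self.items.position(label)
        if idx == 0 and not self.include_empty:
            raise ValueError("empty tuple is excluded from this basis")
        return idx

    def index_to_tuple(self, idx: int) -> tuple[str, ...]:
        if not 0 <= idx < self.dimension:
            raise ValueError(
                f"index {idx} out of range [0, {self.dimension}) for i={self.n_items}"
            )
        if idx == 0 and not self.include_empty:
            raise ValueError("index 0 (empty tuple) is excluded from this basis")
        return tuple(w for b, w in enumerate(self.items) if (idx >> b) & 1)

    def tuple_label(self, idx: int) -> str:
        members = self.index_to_tuple(idx)
        return "{" + ",".join(members) + "}" if members else EMPTY_TUPLE_LABEL

    def to_frame(self) -> pd.DataFrame:
        """Tabulate the basis with columns tuple_label, bitstring, decimal."""
        return pd.DataFrame(
            {
                "tuple_label": [self.tuple_label(k) for k in self.indices()],
                "bitstring": [self.bitstring(k) for k in self.indices()],
                "decimal": list(self.indices()),
            }
        )


def build_basis(items: ItemSet | Sequence[str], include_empty: bool = True) -> TupleBasis:
    """Construct the tuple basis over *items* in ascending decimal order."""
    if not isinstance(items, ItemSet):
        items = ItemSet(items)
    return TupleBasis(items=items, include_empty=include_empty)


def tuple_to_index(basis: TupleBasis, members: AbstractSet[str] | Iterable[str]) -> int:
    """Decimal encoding of a tuple: sum of ``2**position`` over its members."""
    return basis.tuple_to_index(members)


def index_to_tuple(basis: TupleBasis, idx: int) -> tuple[str, ...]:
    """Members of the tuple with decimal encoding *idx* (inverse of
    :func:`tuple_to_index`), in item-list order."""
    return basis.index_to_tuple(idx)


def clique_count(i: int, include_empty: bool) -> int:
    """Number of tuples (cliques) over ``i`` items.

    ``2**i`` with the empty tuple, ``2**i - 1`` without — the two
    power-of-two counting laws this state space unifies.
    """
    if i < 1:
        raise ValueError(f"need at least one item, got i={i}")
    n = 1 << i
    return n if include_empty else n - 1


def render_barcode(basis: TupleBasis, state=None, zero_tol: float = 1e-12) -> str:
    """Plain-text barcode: one row per basis vector, one cell per item.

    ``#`` marks an activated ("permissible") item, ``.`` a suppressed one.
    When a state vector is given, each row gains a trailing marker column:
    ``+`` if the row's coefficient is nonzero, ``0`` if it vanished (the
    tuple has become inadmissible).
    """
    coeffs = _state_coeffs(basis, state)
    rows = []
    for k in basis.indices():
        cells = "".join("#" if ch == "1" else "." for ch in basis.bitstring(k))
        if coeffs is not None:
            cells += " +" if abs(coeffs[k]) > zero_tol else " 0"
        rows.append(cells)
    return "\n".join(rows)


def barcode_figure(basis: TupleBasis, state=None, zero_tol: float = 1e-12):
    """Barcode as a matplotlib figure (orange activated, green suppressed).

    Rows whose state coefficient is zero are dimmed.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    from matplotlib.patches import Rectangle

    coeffs = _state_coeffs(basis, state)
    indices = list(basis.indices())
    n_rows, n_cols = len(indices), basis.n_items
    fig, ax = plt.subplots(figsize=(max(2.0, 0.6 * n_cols + 1.5), max(2.0, 0.25 * n_rows)))
    for row, k in enumerate(indices):
        alpha = 1.0
        if coeffs is not None and abs(coeffs[k]) <= zero_tol:
            alpha = 0.25
        for b in range(n_cols):
            color = ACTIVATED_COLOR if (k >> b) & 1 else SUPPRESSED_COLOR
            ax.add_patch(
                Rectangle((b, n_rows - 1 - row), 1, 1, facecolor=color,
                          edgecolor="white", alpha=alpha)
            )
    ax.set_xlim(0, n_cols)
    ax.set_ylim(0, n_rows)
    ax.set_xticks(np.arange(n_cols) + 0.5, list(basis.items))
    ax.set_yticks(np.arange(n_rows) + 0.5, [basis.tuple_label(k) for k in reversed(indices)])
    ax.tick_params(length=0)
    for spine in ax.spines.values():
        spine.set_visible(False)
    fig.tight_layout()
    return fig


def _state_coeffs(basis: TupleBasis, state):
    if state is None:
        return None
    coeffs = np.asarray(getattr(state, "coefficients", state), dtype=float)
    if coeffs.shape != (basis.dimension,):
        raise ValueError(
            f"state dimension {coeffs.shape} does not match basis dimension "
            f"({basis.dimension},)"
        )
    return coeffs
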