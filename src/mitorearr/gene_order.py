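"""Signed circular gene orders and their comparison.

A gene order is the circular sequence of mitochondrial elements with a sign
per element (+ for the heavy strand, − for the light strand), linearized at
tRNA-Phe by convention. Two orders are equal iff their anchored
linearizations are identical.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

from .annotation import Annotation

SignedElement = tuple[str, int]  # (label, +1 | -1)


class GeneOrderError(ValueError):
    pass


@dataclass(frozen=True)
class GeneOrder:
    elements: tuple[SignedElement, ...]
    anchor: str = "trnF"
    circular: bool = True

    def __post_init__(self) -> None:
        counts = Counter(lab for lab, _ in self.elements)
        for lab, n in counts.items():
            if n > (2 if lab == "CR" else 1):
                raise GeneOrderError(f"{lab} occurs {n} times")

    def __len__(self) -> int:
        return len(self.elements)

    def rotated(self, i: int) -> tuple[SignedElement, ...]:
        i %= len(self.elements)
        return self.elements[i:] + self.elements[:i]

    def anchored(self) -> tuple[SignedElement, ...]:
        """Linearization starting at the anchor (or unrotated if absent)."""
        if not self.circular:
            return self.elements
        for i, (lab, _) in enumerate(self.elements):
            if lab == self.anchor:
                return self.rotated(i)
        return self.elements

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneOrder):
            return NotImplemented
        if self.circular != other.circular:
            return False
        if self.anchored() == other.anchored():
            return True
        if not self.circular:
            return False
        # no shared anchor: fall back to rotation equivalence
        if len(self) != len(other):
            return False
        return any(self.rotated(i) == other.elements for i in range(len(self)))

    def __hash__(self) -> int:
        return hash(self.anchored())

    def to_string(self) -> str:
        """One token per element, '-' prefix for light-strand elements."""
        return " ".join(
            ("-" if sign < 0 else "") + lab for lab, sign in self.anchored()
        )

    @classmethod
    def from_string(cls, text: str, **kwargs) -> "GeneOrder":
        elements = []
        for tok in text.split():
            sign = -1 if tok.startswith("-") else 1
            elements.append((tok.lstrip("+-"), sign))
        return cls(elements=tuple(elements), **kwargs)


def extract_gene_order(a: Annotation, include_OL: bool = False) -> GeneOrder:
    """Signed gene order of an annotation, anchored at tRNA-Phe.

    The light-strand replication origin is excluded by default: it is a
    replication signal, not a rearrangeable gene. If tRNA-Phe is missing the
    order is anchored at the feature with the smallest start (with a warning).
    """
    elements: list[SignedElement] = []
    for f in a.features:
        if f.label == "OL" and not include_OL:
            continue
        elements.append((f.label, -1 if f.strand == "L" else 1))
    labels = {lab for lab, _ in elements}
    anchor = "trnF"
    if "trnF" not in labels:
        anchor = elements[0][0]
        warnings.warn(f"trnF absent; anchoring gene order at {anchor}")
    return GeneOrder(elements=tuple(elements), anchor=anchor, circular=a.circular)


def canonical_vertebrate_order() -> GeneOrder:
    """The consensus vertebrate mitochondrial gene order (37 genes + CR)."""
    return GeneOrder.from_string(
        "trnF 12S trnV 16S trnL1 ND1 trnI -trnQ trnM ND2 trnW -trnA -trnN "
        "-trnC -trnY COI -trnS1 trnD COII trnK ATP8 ATP6 COIII trnG ND3 "
        "trnR ND4L ND4 trnH trnS2 trnL2 ND5 -ND6 -trnE Cytb trnT -trnP CR"
    )


def _adjacencies(order: GeneOrder) -> Counter:
    elems = order.anchored()
    pairs = list(zip(elems, elems[1:]))
    if order.circular and len(elems) > 1:
        pairs.append((elems[-1], elems[0]))
    return Counter(pairs)


@dataclass(frozen=True)
class OrderDiff:
    breakpoint_count: int
    conserved_blocks: tuple[tuple[SignedElement, ...], ...] = field(default=())


def order_diff(a: GeneOrder, b: GeneOrder) -> OrderDiff:
    """Breakpoints (sign-aware circular adjacencies of ``a`` absent in ``b``)
    and the maximal blocks of ``a`` whose internal adjacencies all survive."""
    ca = Counter(lab for lab, _ in a.elements)
    cb = Counter(lab for lab, _ in b.elements)
    if {k: v for k, v in ca.items() if k != "CR"} != {
        k: v for k, v in cb.items() if k != "CR"
    }:
        raise GeneOrderError("gene content differs beyond CR copy number")
    adj_a, adj_b = _adjacencies(a), _adjacencies(b)
    breakpoints = sum((adj_a - adj_b).values())

    elems = a.anchored()
    n = len(elems)
    broken = [
        (elems[i], elems[(i + 1) % n]) not in adj_b
        or (adj_a - adj_b)[(elems[i], elems[(i + 1) % n])] > 0
        for i in range(n)
    ]
    blocks: list[tuple[SignedElement, ...]] = []
    if not any(broken):
        blocks = [tuple(elems)]
    else:
        # walk the circle, cutting at broken adjacencies
        start = next(i for i in range(n) if broken[i]) + 1
        block: list[SignedElement] = []
        for k in range(n):
            i = (start + k) % n
            block.append(elems[i])
            if broken[i]:
                blocks.append(tuple(block))
                block = []
    return OrderDiff(breakpoint_count=breakpoints, conserved_blocks=tuple(blocks))


__all__ = [
    "GeneOrder",
    "GeneOrderError",
    "OrderDiff",
    "SignedElement",
    "canonical_vertebrate_order",
    "extract_gene_order",
    "order_diff",
]
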