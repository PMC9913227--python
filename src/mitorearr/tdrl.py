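"""Tandem duplication–random loss (TDRL) rearrangement inference.

Under the TDRL model a contiguous block of the circular gene order is
duplicated in tandem; redundant copies are then deleted, one per duplicated
element (control regions may survive in both copies, which is how duplicated
control regions arise). A single TDRL event therefore rewrites the block as
an interleaving of two order-preserving sub-copies and leaves the rest of the
circle untouched. TDRL cannot change the strand of a gene.

:func:`find_minimal_tdrl` enumerates every single event transforming one
order into another and keeps the minimal ones (fewest losses, then shortest
block, then leftmost block start in the tRNA-Phe-anchored linearization).
:func:`brute_force_tdrl` is the exhaustive oracle used by the test suite.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

from .gene_order import GeneOrder, GeneOrderError, SignedElement

RETENTIONS = ("first", "second", "both")


class TDRLError(ValueError):
    pass


@dataclass(frozen=True)
class TDRLEvent:
    """One tandem duplication of ``block`` plus per-copy retention.

    ``block_start`` indexes the anchored linearization of the source order.
    ``retention[k]`` says which copy of ``block[k]`` survives the loss phase:
    ``first``/``second``, or ``both`` (control regions only).
    """

    block_start: int
    block: tuple[SignedElement, ...]
    retention: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.block) != len(self.retention):
            raise TDRLError("retention vector length must equal block length")
        for (lab, _), r in zip(self.block, self.retention):
            if r not in RETENTIONS:
                raise TDRLError(f"invalid retention {r!r}")
            if r == "both" and lab != "CR":
                raise TDRLError(f"gene {lab} cannot be retained in both copies")

    @property
    def n_losses(self) -> int:
        return sum(1 for r in self.retention if r != "both")

    @property
    def block_labels(self) -> tuple[str, ...]:
        return tuple(("-" if s < 0 else "") + lab for lab, s in self.block)

    def to_dict(self) -> dict:
        return {
            "block_labels": list(self.block_labels),
            "retention": list(self.retention),
            "n_losses": self.n_losses,
        }

    def _sort_key(self) -> tuple:
        return (self.n_losses, len(self.block), self.block_start)


@dataclass(frozen=True)
class TDRLSearch:
    """Result of a single-event search.

    ``identical`` is the designated "no event needed" marker for
    source == target; ``events`` is then empty. An empty ``events`` with
    ``identical == False`` means no single TDRL event suffices.
    """

    events: tuple[TDRLEvent, ...]
    identical: bool = False

    def __iter__(self):
        return iter(self.events)

    def __len__(self) -> int:
        return len(self.events)


def apply_tdrl(order: GeneOrder, event: TDRLEvent) -> GeneOrder:
    """Apply one TDRL event; the result is re-anchored at the order's anchor."""
    elems = order.anchored()
    n = len(elems)
    bs, L = event.block_start % n, len(event.block)
    if L > n:
        raise TDRLError("block longer than the order")
    rot = elems[bs:] + elems[:bs]
    if rot[:L] != event.block:
        raise TDRLError("event block does not match the source order at block_start")
    rest = rot[L:]
    copy1 = [e for e, r in zip(event.block, event.retention) if r in ("first", "both")]
    copy2 = [e for e, r in zip(event.block, event.retention) if r in ("second", "both")]
    return GeneOrder(
        elements=tuple(copy1 + copy2 + list(rest)),
        anchor=order.anchor,
        circular=order.circular,
    )


def _check_compatible(source: GeneOrder, target: GeneOrder) -> None:
    signs_s = {lab: s for lab, s in source.elements if lab != "CR"}
    signs_t = {lab: s for lab, s in target.elements if lab != "CR"}
    if set(signs_s) != set(signs_t):
        raise GeneOrderError("gene content differs between source and target")
    bad = [lab for lab in signs_s if signs_s[lab] != signs_t[lab]]
    if bad:
        raise TDRLError(
            f"TDRL cannot invert strands: sign mismatch for {', '.join(sorted(bad))}"
        )
    cr_s = sum(1 for lab, _ in source.elements if lab == "CR")
    cr_t = sum(1 for lab, _ in target.elements if lab == "CR")
    if cr_t not in (cr_s, cr_s + 1):
        raise GeneOrderError(
            f"target has {cr_t} control regions, source {cr_s}: not one TDRL away"
        )


def _embeddings(
    sub: tuple[SignedElement, ...], block: tuple[SignedElement, ...]
) -> list[tuple[int, ...]]:
    """All order-preserving embeddings of ``sub`` into ``block`` (as index
    tuples). Labels are unique except CR, so the count stays tiny."""
    results: list[tuple[int, ...]] = []

    def rec(si: int, bi: int, acc: list[int]) -> None:
        if si == len(sub):
            results.append(tuple(acc))
            return
        for j in range(bi, len(block) - (len(sub) - si) + 1):
            if block[j] == sub[si]:
                acc.append(j)
                rec(si + 1, j + 1, acc)
                acc.pop()

    rec(0, 0, [])
    return results


def find_minimal_tdrl(source: GeneOrder, target: GeneOrder) -> TDRLSearch:
    """All minimal single TDRL events transforming ``source`` into ``target``.

    Minimality is lexicographic (fewest losses, shortest block, leftmost
    anchored block start); the returned events are ordered by block start.
    Raises :class:`TDRLError` on a strand (sign) disagreement — a TDRL event
    cannot invert genes.
    """
    _check_compatible(source, target)
    if source == target:
        return TDRLSearch(events=(), identical=True)

    S, T = source.anchored(), target.anchored()
    n, m = len(S), len(T)

    # positions of each signed element in the anchored target, for fast
    # candidate lookup of where the unchanged remainder can sit
    positions: dict[SignedElement, list[int]] = {}
    for j, e in enumerate(T):
        positions.setdefault(e, []).append(j)
    T2 = T + T  # doubled for circular slicing

    # every valid event with block length L loses exactly L - (m - n) copies,
    # so lexicographic minimality (losses, block length) = smallest L: search
    # block lengths in ascending order and stop at the first length that works
    for L in range(1, n + 1):
        found: dict[tuple, TDRLEvent] = {}
        for bs in range(n):
            rot = S[bs:] + S[:bs]
            block, rest = rot[:L], rot[L:]
            seg_len = m - len(rest)
            if seg_len < L or seg_len > L + 1:
                continue
            starts = positions.get(rest[0], []) if rest else list(range(m))
            for j in starts:
                if rest and T2[j : j + len(rest)] != rest:
                    continue
                # segment = the circular stretch of the target after the
                # unchanged remainder
                k0 = (j + len(rest)) % m
                seg = T2[k0 : k0 + seg_len]
                for split in range(seg_len + 1):
                    c1, c2 = seg[:split], seg[split:]
                    for e1 in _embeddings(c1, block):
                        s1 = set(e1)
                        for e2 in _embeddings(c2, block):
                            s2 = set(e2)
                            if s1 | s2 != set(range(L)):
                                continue
                            dup = s1 & s2
                            if any(block[i][0] != "CR" for i in dup):
                                continue
                            retention = tuple(
                                "both" if i in dup else ("first" if i in s1 else "second")
                                for i in range(L)
                            )
                            ev = TDRLEvent(block_start=bs, block=block, retention=retention)
                            found.setdefault((bs, block, retention), ev)
        sound = [ev for ev in found.values() if apply_tdrl(source, ev) == target]
        if sound:
            return TDRLSearch(events=tuple(sorted(sound, key=lambda e: e.block_start)))
    return TDRLSearch(events=())


def brute_force_tdrl(
    source: GeneOrder, target: GeneOrder, max_block: int, budget: int = 2_000_000
) -> list[TDRLEvent]:
    """Exhaustively enumerate every (block, retention) pair up to ``max_block``
    and keep those whose application yields ``target``. Test oracle only."""
    _check_compatible(source, target)
    S = source.anchored()
    n = len(S)
    total = 0
    events: list[TDRLEvent] = []
    seen: set[tuple] = set()
    for bs in range(n):
        rot = S[bs:] + S[:bs]
        for L in range(1, min(max_block, n) + 1):
            block = rot[:L]
            options = [
                RETENTIONS if lab == "CR" else RETENTIONS[:2] for lab, _ in block
            ]
            n_combos = 1
            for o in options:
                n_combos *= len(o)
            total += n_combos
            if total > budget:
                raise TDRLError("combinatorial budget exceeded")
            for retention in itertools.product(*options):
                key = (bs, block, retention)
                if key in seen:
                    continue
                seen.add(key)
                ev = TDRLEvent(block_start=bs, block=block, retention=retention)
                if apply_tdrl(source, ev) == target:
                    events.append(ev)
    return sorted(events, key=TDRLEvent._sort_key)


def minimal_subset(events: list[TDRLEvent]) -> list[TDRLEvent]:
    """The (n_losses, block length)-minimal events of a list, by block start."""
    if not events:
        return []
    best = min(ev._sort_key()[:2] for ev in events)
    return sorted(
        (ev for ev in events if ev._sort_key()[:2] == best),
        key=lambda ev: ev.block_start,
    )


def describe_events(search: TDRLSearch, source: GeneOrder) -> str:
    """Human-readable narrative of a TDRL search result."""
    if search.identical:
        return "canonical order, no event: source and target gene orders are identical."
    if not search.events:
        return "no single tandem duplication-random loss event explains the target order."
    lines = []
    for ev in search.events:
        kept_first = [l for l, r in zip(ev.block_labels, ev.retention) if r == "first"]
        kept_second = [l for l, r in zip(ev.block_labels, ev.retention) if r == "second"]
        kept_both = [l for l, r in zip(ev.block_labels, ev.retention) if r == "both"]
        lines.append(
            "tandem duplication of the block "
            + "-".join(ev.block_labels)
            + f" followed by loss of {ev.n_losses} redundant copies: "
            + f"keep first copy of {', '.join(kept_first) or 'none'}; "
            + f"keep second copy of {', '.join(kept_second) or 'none'}"
            + (f"; keep both copies of {', '.join(kept_both)}" if kept_both else "")
        )
    return "\n".join(lines)


__all__ = [
    "TDRLError",
    "TDRLEvent",
    "TDRLSearch",
    "apply_tdrl",
    "brute_force_tdrl",
    "describe_events",
    "find_minimal_tdrl",
    "minimal_subset",
]
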