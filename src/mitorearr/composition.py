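"""Base composition, AT/GC skew and codon-position composition.

Skews are the standard strand-asymmetry statistics
``AT-skew = (A - T)/(A + T)`` and ``GC-skew = (G - C)/(G + C)``.
Protein-coding genes are counted on their coding (sense) strand, so that
codon-position statistics are meaningful; tRNAs are counted on their
annotated strand.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from .annotation import Annotation, Feature

_BASES = ("A", "T", "G", "C")
_COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHV", "TGCANYRSWMKVHDB")


class CompositionError(ValueError):
    pass


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class CompositionProfile:
    """Counts of unambiguous bases plus derived percentages and skews."""

    counts: dict[str, int]
    n_ignored: int = 0

    @property
    def total(self) -> int:
        return sum(self.counts.get(b, 0) for b in _BASES)

    def percent(self, base: str) -> float:
        return 100.0 * self.counts.get(base, 0) / self.total

    @property
    def percents(self) -> dict[str, float]:
        return {b: self.percent(b) for b in _BASES}

    @property
    def at_content(self) -> float:
        return self.percent("A") + self.percent("T")

    @property
    def at_skew(self) -> float | None:
        a, t = self.counts.get("A", 0), self.counts.get("T", 0)
        return None if a + t == 0 else (a - t) / (a + t)

    @property
    def gc_skew(self) -> float | None:
        g, c = self.counts.get("G", 0), self.counts.get("C", 0)
        return None if g + c == 0 else (g - c) / (g + c)

    def merged(self, other: "CompositionProfile") -> "CompositionProfile":
        counts = {b: self.counts.get(b, 0) + other.counts.get(b, 0) for b in _BASES}
        return CompositionProfile(counts=counts, n_ignored=self.n_ignored + other.n_ignored)


def base_composition(seq: str) -> CompositionProfile:
    """Composition of a nucleotide string; IUPAC ambiguity codes are excluded
    from percentages and counted in ``n_ignored``."""
    if not seq:
        raise CompositionError("empty sequence")
    c = Counter(seq.upper())
    counts = {b: c.get(b, 0) for b in _BASES}
    n_ignored = len(seq) - sum(counts.values())
    if sum(counts.values()) == 0:
        raise CompositionError("sequence contains no unambiguous bases")
    return CompositionProfile(counts=counts, n_ignored=n_ignored)


def skew(profile: CompositionProfile) -> tuple[float | None, float | None]:
    """(AT-skew, GC-skew); ``None`` flags an undefined (zero-denominator) skew."""
    return profile.at_skew, profile.gc_skew


def skew_from_percentages(a: float, t: float, g: float, c: float) -> tuple[float, float]:
    """Skews recomputed from printed percentage columns (scale-invariant)."""
    return (a - t) / (a + t), (g - c) / (g + c)


def feature_sequence(seq: str, f: Feature, sense: bool = True) -> str:
    """Subsequence of a circular genome covered by a feature.

    Wrap-aware; if ``sense`` and the feature is light-strand annotated, the
    reverse complement (the coding strand) is returned.
    """
    n = len(seq)
    if f.start > n or f.end > n:
        raise CompositionError(f"{f.label}: feature outside sequence bounds")
    if f.end >= f.start:
        sub = seq[f.start - 1 : f.end]
    else:
        sub = seq[f.start - 1 :] + seq[: f.end]
    if sense and f.strand == "L":
        sub = reverse_complement(sub)
    return sub.upper()


def region_composition(
    seq: str, a: Annotation, grouping: str = "per_gene", strand: str = "sense"
) -> dict[str, CompositionProfile]:
    """Composition profiles grouped per gene, per category or by codon position.

    ``grouping``:
      - ``per_gene``: one profile per feature (CR copies keyed CR1/CR2),
        PCGs on the sense strand (``strand="H"`` keeps plain H-strand counts);
      - ``category``: aggregated PCGs / tRNAs / rRNAs / CRs rows;
      - ``codon_position``: positions 1/2/3 pooled across all PCG sense
        strands, complete codons only (trailing partial codons excluded);
      - ``whole``: a single whole-genome profile.
    """
    if len(seq) != a.genome_length:
        raise CompositionError(
            f"sequence length {len(seq)} != genome length {a.genome_length}"
        )
    sense = strand == "sense"
    if grouping == "whole":
        return {"whole": base_composition(seq)}
    if grouping == "per_gene":
        out: dict[str, CompositionProfile] = {}
        cr_i = 0
        for f in a.features:
            key = f.label
            if f.label == "CR":
                cr_i += 1
                key = f"CR{cr_i}"
            use_sense = sense and f.category == "PCG"
            sub = feature_sequence(seq, f, sense=use_sense or (f.category == "tRNA"))
            out[key] = base_composition(sub)
        return out
    if grouping == "category":
        groups: dict[str, CompositionProfile] = {}
        names = {"PCG": "PCGs", "tRNA": "tRNAs", "rRNA": "rRNAs", "CR": "CRs"}
        for f in a.features:
            if f.category not in names:
                continue
            use_sense = sense and f.category == "PCG"
            sub = feature_sequence(seq, f, sense=use_sense or (f.category == "tRNA"))
            prof = base_composition(sub)
            key = names[f.category]
            groups[key] = groups[key].merged(prof) if key in groups else prof
        return groups
    if grouping == "codon_position":
        pooled = {i: Counter() for i in (1, 2, 3)}
        ignored = {i: 0 for i in (1, 2, 3)}
        for f in a.by_category("PCG"):
            sub = feature_sequence(seq, f, sense=True)
            n_codons = len(sub) // 3  # trailing partial codon dropped
            for k in range(n_codons):
                for pos in (1, 2, 3):
                    b = sub[3 * k + pos - 1]
                    if b in _BASES:
                        pooled[pos][b] += 1
                    else:
                        ignored[pos] += 1
        return {
            f"pos{i}": CompositionProfile(
                counts={b: pooled[i].get(b, 0) for b in _BASES}, n_ignored=ignored[i]
            )
            for i in (1, 2, 3)
        }
    raise ValueError(f"unknown grouping {grouping!r}")


def composition_table(profiles: dict[str, CompositionProfile]):
    """Profiles as a DataFrame with the usual report columns
    (A%, T%, G%, C%, A+T%, AT-skew, GC-skew), 2/3-decimal report rounding."""
    import pandas as pd

    rows = []
    for name, p in profiles.items():
        at, gc = skew(p)
        rows.append(
            {
                "region": name,
                "A%": round(p.percent("A"), 2),
                "T%": round(p.percent("T"), 2),
                "G%": round(p.percent("G"), 2),
                "C%": round(p.percent("C"), 2),
                "A+T%": round(p.at_content, 2),
                "AT-skew": round(at, 3) if at is not None else None,
                "GC-skew": round(gc, 3) if gc is not None else None,
            }
        )
    return pd.DataFrame(rows).set_index("region")


__all__ = [
    "CompositionError",
    "CompositionProfile",
    "base_composition",
    "composition_table",
    "feature_sequence",
    "region_composition",
    "reverse_complement",
    "skew",
    "skew_from_percentages",
]
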