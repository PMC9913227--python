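"""Codon extraction, amino-acid usage and RSCU under the vertebrate
mitochondrial genetic code (NCBI translation table 2).

Mitochondrial protein genes frequently end on an incomplete terminator
(``T--`` or ``TA-``) completed to UAA by transcript polyadenylation; codon
extraction classifies these trailing remnants and keeps them out of the
amino-acid and RSCU statistics, as is conventional.
"""

from __future__ import annotations

import itertools
import warnings
from collections import Counter
from dataclasses import dataclass, field

from Bio.Data.CodonTable import unambiguous_dna_by_id

from .annotation import Annotation, Feature
from .composition import feature_sequence

VERTEBRATE_MITO_TABLE_ID = 2
_TABLE = unambiguous_dna_by_id[VERTEBRATE_MITO_TABLE_ID]
STOP_CODONS = tuple(_TABLE.stop_codons)  # TAA, TAG, AGA, AGG

ALL_CODONS = tuple("".join(p) for p in itertools.product("TCAG", repeat=3))


def translate_codon(codon: str) -> str | None:
    """One-letter amino acid, '*' for stops, None for ambiguous codons."""
    codon = codon.upper().replace("U", "T")
    if codon in STOP_CODONS:
        return "*"
    return _TABLE.forward_table.get(codon)


def synonymous_family(amino_acid: str) -> tuple[str, ...]:
    """All codons of an amino acid under the code (Leu and Ser are single
    six-codon families; stops are not a family)."""
    return tuple(c for c in ALL_CODONS if _TABLE.forward_table.get(c) == amino_acid)


FAMILIES: dict[str, tuple[str, ...]] = {
    aa: synonymous_family(aa) for aa in sorted(set(_TABLE.forward_table.values()))
}


class CodonError(ValueError):
    pass


@dataclass(frozen=True)
class CodonExtraction:
    """Codons of one protein gene read in frame from its start codon."""

    gene: str
    codons: tuple[str, ...]  # complete codons, terminal stop excluded
    start_codon: str
    stop_codon: str | None  # "TAA", "T--", "TA-", ... or None if absent
    stop_complete: bool
    internal_stops: tuple[int, ...] = field(default=())  # codon indices

    @property
    def n_partial_stop_nt(self) -> int:
        if self.stop_codon and not self.stop_complete:
            return len(self.stop_codon.rstrip("-"))
        return 0


def extract_codons(f: Feature, seq: str) -> CodonExtraction:
    """Read a PCG's codons from the genome sequence on its sense strand.

    A trailing 1-nt remnant is classified as a ``T--``-style partial stop and
    a 2-nt remnant as ``TA-``-style; a complete terminal stop codon (TAA /
    TAG / AGA / AGG) is reported separately and excluded from the codon list.
    Internal stop codons trigger a warning, not a failure (annotations, not
    this tool, decide gene boundaries).
    """
    if f.category != "PCG":
        raise CodonError(f"{f.label} is not a protein-coding gene")
    sub = feature_sequence(seq, f, sense=True)
    n_complete, remnant_len = divmod(len(sub), 3)
    codons = [sub[3 * k : 3 * k + 3] for k in range(n_complete)]
    if remnant_len:
        stop = sub[3 * n_complete :] + "-" * (3 - remnant_len)
        stop_complete = False
    elif codons and codons[-1] in STOP_CODONS:
        stop = codons.pop()
        stop_complete = True
    else:
        stop, stop_complete = None, False
    internal = tuple(i for i, c in enumerate(codons[1:], start=1) if c in STOP_CODONS)
    if internal:
        warnings.warn(
            f"{f.label}: internal stop codon(s) at codon position(s) {internal}"
        )
    return CodonExtraction(
        gene=f.label,
        codons=tuple(codons),
        start_codon=codons[0] if codons else "",
        stop_codon=stop,
        stop_complete=stop_complete,
        internal_stops=internal,
    )


@dataclass
class CodonCounts:
    """Pooled codon counts over a set of protein genes."""

    counts: Counter = field(default_factory=Counter)
    code: int = VERTEBRATE_MITO_TABLE_ID
    n_partial_stops: int = 0
    start_codons: dict[str, str] = field(default_factory=dict)
    stop_codons: dict[str, str] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def add(self, ex: CodonExtraction) -> None:
        self.counts.update(ex.codons)
        if ex.stop_codon and not ex.stop_complete:
            self.n_partial_stops += 1
        self.start_codons[ex.gene] = ex.start_codon
        if ex.stop_codon:
            self.stop_codons[ex.gene] = ex.stop_codon


def count_codons(
    a: Annotation, seq: str, genes: list[str] | None = None
) -> CodonCounts:
    """Codon counts pooled over the annotation's PCGs (or a named subset)."""
    cc = CodonCounts()
    for f in a.by_category("PCG"):
        if genes is not None and f.label not in genes:
            continue
        cc.add(extract_codons(f, seq))
    return cc


def amino_acid_usage(c: CodonCounts) -> dict[str, float]:
    """Per-amino-acid percentages of translated codons (stops excluded)."""
    aa_counts: Counter = Counter()
    for codon, n in c.counts.items():
        aa = translate_codon(codon)
        if aa is not None and aa != "*":
            aa_counts[aa] += n
    total = sum(aa_counts.values())
    if total == 0:
        raise CodonError("no translatable codons")
    return {aa: 100.0 * aa_counts.get(aa, 0) / total for aa in FAMILIES}


@dataclass(frozen=True)
class RSCUTable:
    """RSCU per codon; ``None`` flags codons of unobserved families."""

    rscu: dict[str, float | None]
    family_of: dict[str, str]

    def to_dataframe(self):
        import pandas as pd

        rows = [
            {
                "codon": codon,
                "amino_acid": self.family_of[codon],
                "rscu": None if v is None else round(v, 3),
            }
            for codon, v in sorted(self.rscu.items())
        ]
        return pd.DataFrame(rows).set_index("codon")


def rscu(c: CodonCounts) -> RSCUTable:
    """Relative synonymous codon usage: observed count divided by the mean
    count of the codon's synonymous family. Stop codons are excluded."""
    values: dict[str, float | None] = {}
    family_of: dict[str, str] = {}
    for aa, family in FAMILIES.items():
        total = sum(c.counts.get(codon, 0) for codon in family)
        for codon in family:
            family_of[codon] = aa
            if total == 0:
                values[codon] = None
            else:
                values[codon] = c.counts.get(codon, 0) / (total / len(family))
    return RSCUTable(rscu=values, family_of=family_of)


__all__ = [
    "ALL_CODONS",
    "CodonCounts",
    "CodonError",
    "CodonExtraction",
    "FAMILIES",
    "RSCUTable",
    "STOP_CODONS",
    "amino_acid_usage",
    "count_codons",
    "extract_codons",
    "rscu",
    "synonymous_family",
    "translate_codon",
]
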