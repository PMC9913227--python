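"""Controlled vocabulary for vertebrate mitochondrial genome elements.

Canonical labels follow common mitogenomics usage: ``trnX`` for tRNAs (with
L1/L2 and S1/S2 disambiguating the two leucine and serine isoacceptors),
``12S``/``16S`` for the rRNAs, gene symbols for the 13 protein-coding genes,
``CR`` for control regions and ``OL`` for the light-strand replication origin.
"""

from __future__ import annotations

import re

PCG_LABELS = (
    "ND1", "ND2", "ND3", "ND4", "ND4L", "ND5", "ND6",
    "COI", "COII", "COIII", "ATP6", "ATP8", "Cytb",
)

TRNA_LABELS = (
    "trnF", "trnV", "trnL1", "trnL2", "trnI", "trnQ", "trnM", "trnW",
    "trnA", "trnN", "trnC", "trnY", "trnS1", "trnS2", "trnD", "trnK",
    "trnG", "trnR", "trnH", "trnT", "trnP", "trnE",
)

RRNA_LABELS = ("12S", "16S")

ALL_GENE_LABELS = PCG_LABELS + TRNA_LABELS + RRNA_LABELS

CATEGORY_BY_LABEL: dict[str, str] = (
    {lab: "PCG" for lab in PCG_LABELS}
    | {lab: "tRNA" for lab in TRNA_LABELS}
    | {lab: "rRNA" for lab in RRNA_LABELS}
    | {"CR": "CR", "OL": "OL"}
)

_AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

# codon-family hints used to split the two Leu / Ser isoacceptors
_LEU_SER_HINTS = {
    "UUA": "trnL1", "UUR": "trnL1", "TTA": "trnL1",
    "CUA": "trnL2", "CUN": "trnL2", "CTA": "trnL2", "CUR": "trnL2",
    "UCA": "trnS1", "UCN": "trnS1", "TCA": "trnS1",
    "AGC": "trnS2", "AGY": "trnS2", "AGN": "trnS2",
}

_PCG_ALIASES = {
    "COX1": "COI", "COX2": "COII", "COX3": "COIII",
    "CO1": "COI", "CO2": "COII", "CO3": "COIII",
    "COB": "Cytb", "CYTB": "Cytb", "CYB": "Cytb",
    "ATPASE6": "ATP6", "ATPASE8": "ATP8",
    "NAD1": "ND1", "NAD2": "ND2", "NAD3": "ND3", "NAD4": "ND4",
    "NAD4L": "ND4L", "NAD5": "ND5", "NAD6": "ND6",
}

_RRNA_ALIASES = {
    "12SRRNA": "12S", "RRNS": "12S", "SRRNA": "12S", "12S": "12S",
    "SMALLSUBUNITRIBOSOMALRNA": "12S",
    "16SRRNA": "16S", "RRNL": "16S", "LRRNA": "16S", "16S": "16S",
    "LARGESUBUNITRIBOSOMALRNA": "16S",
}

_CR_ALIASES = {"CR", "CR1", "CR2", "DLOOP", "CONTROLREGION", "CRA", "CRB"}
_OL_ALIASES = {"OL", "O_L", "OL_", "ORIGINOFLSTRANDREPLICATION", "REPORIGIN"}


class UnknownLabelError(ValueError):
    """Raised when a feature name cannot be mapped to the vocabulary."""


def _squash(name: str) -> str:
    return re.sub(r"[\s*_\-./]", "", name).upper()


def normalize_label(raw: str) -> str:
    """Map a free-form feature name to its canonical label.

    Accepts annotation-table style names such as ``tRNA-Phe (F)``,
    ``tRNA-Leu^UUA^ (L1)``, ``12S rRNA``, ``CO I``, ``Cyt b``, ``D-loop``,
    ``O_L`` as well as already-canonical labels (``trnF``, ``COI``...).

    Raises :class:`UnknownLabelError` for unrecognized or ambiguous names
    (e.g. a Leu/Ser tRNA with no isoacceptor hint).
    """
    name = raw.strip()
    if not name:
        raise UnknownLabelError("empty feature name")

    # tRNA forms: tRNA-Xxx, trnX, with optional ^codon^ and (letter) parts
    m = re.match(r"(?i)^t\s*RNA[-\s]*([A-Za-z]{3})(.*)$", name)
    if m:
        aa3 = m.group(1).upper()
        rest = m.group(2)
        if aa3 not in _AA3_TO_1:
            raise UnknownLabelError(f"unknown tRNA amino acid in {raw!r}")
        one = _AA3_TO_1[aa3]
        if one not in ("L", "S"):
            label = f"trn{one}"
            if label in TRNA_LABELS:
                return label
            raise UnknownLabelError(f"unknown tRNA {raw!r}")
        # Leu/Ser need a disambiguator: (L1)/(S2) or a codon-family hint
        mnum = re.search(rf"(?i)\(\s*{one}?\s*([12])\s*\)", rest)
        if mnum:
            return f"trn{one}{mnum.group(1)}"
        for hint, label in _LEU_SER_HINTS.items():
            if hint in rest.upper() and label[3] == one:
                return label
        raise UnknownLabelError(
            f"ambiguous Leu/Ser tRNA {raw!r}: needs an L1/L2/S1/S2 or "
            f"codon-family disambiguator"
        )
    m = re.match(r"(?i)^trn([A-Z])([12]?)$", name)
    if m:
        label = f"trn{m.group(1).upper()}{m.group(2)}"
        if label in TRNA_LABELS:
            return label
        raise UnknownLabelError(f"unknown tRNA label {raw!r}")

    squashed = _squash(name)
    if squashed in _CR_ALIASES:
        return "CR"
    if squashed in _OL_ALIASES:
        return "OL"
    if squashed in _RRNA_ALIASES:
        return _RRNA_ALIASES[squashed]
    if squashed in _PCG_ALIASES:
        return _PCG_ALIASES[squashed]
    if squashed in (lab.upper() for lab in PCG_LABELS):
        for lab in PCG_LABELS:
            if lab.upper() == squashed:
                return lab
    raise UnknownLabelError(f"unknown feature name {raw!r}")


def category_of(label: str) -> str:
    """Return the element category (PCG/tRNA/rRNA/CR/OL) of a canonical label."""
    try:
        return CATEGORY_BY_LABEL[label]
    except KeyError:
        raise UnknownLabelError(f"not a canonical label: {label!r}") from None
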