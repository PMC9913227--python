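"""Pairwise Ka/Ks estimation (Nei–Gojobori 1986) and selection classification.

The NG86 estimator counts, per codon, the fraction of possible
single-nucleotide changes that are synonymous (synonymous "sites"), averages
site totals over the two sequences, classifies observed codon differences by
equal-weight averaging over all mutational pathways, and corrects the
resulting proportions with the Jukes–Cantor formula
``d = -(3/4) ln(1 - 4p/3)``. Changes into stop codons are counted as
nonsynonymous, so synonymous + nonsynonymous sites always sum to the
sequence length. Ka/Ks < 1 indicates purifying selection, > 1 positive
(diversifying) selection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations

from .codons import STOP_CODONS, translate_codon

_BASES = ("A", "T", "G", "C")


class KaKsError(ValueError):
    pass


@dataclass(frozen=True)
class KaKsResult:
    gene: str
    ka: float | None
    ks: float | None
    ratio: float | None
    verdict: str  # purifying | neutral | positive | undefined
    n_sites: tuple[float, float] = (0.0, 0.0)  # (synonymous, nonsynonymous)
    n_diffs: tuple[float, float] = (0.0, 0.0)

    def to_dict(self) -> dict:
        return {
            "gene": self.gene,
            "ka": self.ka,
            "ks": self.ks,
            "ratio": self.ratio,
            "verdict": self.verdict,
        }


def _codon_sites(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts of one codon; sums to 3."""
    aa = translate_codon(codon)
    syn = 0.0
    for i, nt in enumerate(codon):
        for base in _BASES:
            if base == nt:
                continue
            neighbor = codon[:i] + base + codon[i + 1 :]
            if neighbor not in STOP_CODONS and translate_codon(neighbor) == aa:
                syn += 1.0
    syn /= 3.0
    return syn, 3.0 - syn


def _codon_diffs(c1: str, c2: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences between two codons, averaged
    with equal weight over all mutational pathways; steps through stop codons
    count as nonsynonymous."""
    if c1 == c2:
        return 0.0, 0.0
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]

    def step(a: str, b: str) -> tuple[float, float]:
        aa_a, aa_b = translate_codon(a), translate_codon(b)
        if aa_a == aa_b and aa_a != "*":
            return 1.0, 0.0
        return 0.0, 1.0

    sd = nd = 0.0
    paths = list(permutations(diff_pos))
    w = 1.0 / len(paths)
    for order in paths:
        cur = c1
        for i in order:
            nxt = cur[:i] + c2[i] + cur[i + 1 :]
            s, n = step(cur, nxt)
            sd += w * s
            nd += w * n
            cur = nxt
    return sd, nd


def jukes_cantor(p: float) -> float | None:
    """JC69 distance for a proportion of differing sites; None if saturated."""
    if p < 0:
        raise KaKsError("negative proportion")
    if p == 0:
        return 0.0
    x = 1.0 - 4.0 * p / 3.0
    if x <= 0:
        return None
    return -0.75 * math.log(x)


def _verdict(ka: float | None, ks: float | None) -> tuple[float | None, str]:
    if ka is None or ks is None or ks == 0.0:
        return None, "undefined"
    ratio = ka / ks
    if abs(ratio - 1.0) <= 1e-9:
        return ratio, "neutral"
    return ratio, "positive" if ratio > 1.0 else "purifying"


def ng86_kaks(cds1: str, cds2: str, gene: str = "") -> KaKsResult:
    """NG86 Ka/Ks for two aligned, gap-free coding sequences.

    Sequences must be equal length, a multiple of 3, with partial terminal
    codons already trimmed. Codon pairs containing ambiguity codes or stop
    codons are skipped pairwise. The ratio is flagged undefined when Ks = 0
    or when either Jukes–Cantor correction saturates (p >= 3/4).
    """
    cds1, cds2 = cds1.upper().replace("U", "T"), cds2.upper().replace("U", "T")
    if len(cds1) != len(cds2):
        raise KaKsError("sequences differ in length")
    if len(cds1) % 3:
        raise KaKsError("length is not a multiple of 3")
    if not cds1:
        raise KaKsError("empty sequences")
    S = N = sd = nd = 0.0
    for k in range(len(cds1) // 3):
        c1, c2 = cds1[3 * k : 3 * k + 3], cds2[3 * k : 3 * k + 3]
        if translate_codon(c1) in (None, "*") or translate_codon(c2) in (None, "*"):
            continue
        s1, n1 = _codon_sites(c1)
        s2, n2 = _codon_sites(c2)
        S += (s1 + s2) / 2.0
        N += (n1 + n2) / 2.0
        ds_, dn_ = _codon_diffs(c1, c2)
        sd += ds_
        nd += dn_
    if S == 0 and N == 0:
        return KaKsResult(gene=gene, ka=None, ks=None, ratio=None, verdict="undefined")
    ks = jukes_cantor(sd / S) if S > 0 else None
    ka = jukes_cantor(nd / N) if N > 0 else None
    ratio, verdict = _verdict(ka, ks)
    return KaKsResult(
        gene=gene, ka=ka, ks=ks, ratio=ratio, verdict=verdict,
        n_sites=(S, N), n_diffs=(sd, nd),
    )


def classify_selection(results: list[KaKsResult]):
    """Per-gene selection report as a DataFrame (gene, ka, ks, ratio, verdict)."""
    import pandas as pd

    rows = [r.to_dict() for r in results]
    df = pd.DataFrame(rows, columns=["gene", "ka", "ks", "ratio", "verdict"])
    return df.set_index("gene")


__all__ = [
    "KaKsError",
    "KaKsResult",
    "classify_selection",
    "jukes_cantor",
    "ng86_kaks",
]
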