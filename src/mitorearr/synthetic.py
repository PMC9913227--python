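"""Seeded synthetic mitogenomes for end-to-end testing.

The generator assembles a circular ~17.8 kb vertebrate-style mitogenome
gene-by-gene: 13 protein-coding genes (with configurable codon usage, proper
start codons and complete or polyadenylation-completed partial stop codons),
22 tRNAs, 2 rRNAs, a light-strand replication origin inside the WANCY tRNA
cluster, and one or two control regions. Gene lengths default to those of a
real snake-eel mitogenome so generated fixtures are structurally realistic;
nucleotides of non-coding elements are drawn i.i.d. from per-region base
frequencies. A TDRL event can be injected into the canonical gene order and
is recorded as ground truth next to the output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .annotation import Annotation, Feature, write_feature_table
from .codons import FAMILIES, STOP_CODONS, translate_codon
from .composition import reverse_complement
from .gene_order import GeneOrder, canonical_vertebrate_order
from .tdrl import TDRLEvent, apply_tdrl

# Default element lengths (bp), mirroring a real ~17.8 kb snake-eel mitogenome.
DEFAULT_GENE_LENGTHS: dict[str, int] = {
    "trnF": 68, "12S": 959, "trnV": 71, "16S": 1703, "trnL1": 76,
    "ND1": 969, "trnI": 73, "trnQ": 71, "trnM": 69, "ND2": 1057,
    "trnW": 69, "trnA": 69, "trnN": 73, "OL": 34, "trnC": 65, "trnY": 71,
    "COI": 1641, "trnS1": 71, "trnD": 68, "COII": 691, "trnK": 75,
    "ATP8": 168, "ATP6": 683, "COIII": 786, "trnG": 72, "ND3": 349,
    "trnR": 70, "ND4L": 297, "ND4": 1381, "trnH": 69, "trnS2": 70,
    "trnL2": 73, "ND5": 1836, "Cytb": 1142, "trnT": 72, "ND6": 519,
    "trnE": 69, "trnP": 71, "CR": 966,
}

# Whole-genome base frequencies of the same reference mitogenome (A, T, G, C).
DEFAULT_BASE_FREQS: tuple[float, float, float, float] = (0.3127, 0.2632, 0.1619, 0.2622)

DEFAULT_START_CODONS: dict[str, str] = {"COI": "GTG", "ND6": "CTA"}

_BASES = ("A", "T", "G", "C")
_NONSTOP_CODONS = tuple(c for fam in FAMILIES.values() for c in fam)


class SyntheticError(ValueError):
    pass


@dataclass
class GeneratorConfig:
    """Everything that determines a generated mitogenome (same seed + config
    gives byte-identical output)."""

    seed: int = 0
    gene_lengths: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_GENE_LENGTHS))
    base_freqs: tuple[float, float, float, float] = DEFAULT_BASE_FREQS
    region_base_freqs: dict[str, tuple[float, float, float, float]] = field(default_factory=dict)
    codon_weights: dict[str, float] | None = None  # None = frequencies from base_freqs
    start_codons: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_START_CODONS))
    intergenic_gap: int = 1
    tdrl_event: TDRLEvent | None = None
    cr_similarity: float = 0.945
    species: str = "synthetic mitogenome"

    def order(self) -> GeneOrder:
        base = canonical_vertebrate_order()
        if self.tdrl_event is None:
            return base
        return apply_tdrl(base, self.tdrl_event)


@dataclass
class SyntheticMitogenome:
    sequence: str
    annotation: Annotation
    ground_truth: dict

    def write(self, outdir: str | Path, name: str = "synthetic") -> dict[str, Path]:
        """Emit FASTA, GenBank, TSV feature table and ground-truth JSON."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": outdir / f"{name}.fasta",
            "genbank": outdir / f"{name}.gb",
            "table": outdir / f"{name}_features.tsv",
            "truth": outdir / f"{name}_truth.json",
        }
        paths["fasta"].write_text(
            f">{name} {self.annotation.species} seed={self.ground_truth['seed']}\n"
            + "\n".join(
                self.sequence[i : i + 70] for i in range(0, len(self.sequence), 70)
            )
            + "\n"
        )
        paths["genbank"].write_text(self.to_genbank(name))
        paths["table"].write_text(write_feature_table(self.annotation))
        paths["truth"].write_text(json.dumps(self.ground_truth, indent=2, sort_keys=True))
        return paths

    def to_genbank(self, name: str = "synthetic") -> str:
        from io import StringIO

        from Bio import SeqIO
        from Bio.Seq import Seq
        from Bio.SeqFeature import FeatureLocation, SeqFeature
        from Bio.SeqRecord import SeqRecord

        rec = SeqRecord(
            Seq(self.sequence),
            id=name,
            name=name[:16],
            description=self.annotation.species,
            annotations={
                "molecule_type": "DNA",
                "topology": "circular",
                "organism": self.annotation.species,
            },
        )
        type_by_cat = {"PCG": "CDS", "tRNA": "tRNA", "rRNA": "rRNA",
                       "CR": "D-loop", "OL": "rep_origin"}
        for f in self.annotation.features:
            loc = FeatureLocation(f.start - 1, f.end, strand=-1 if f.strand == "L" else 1)
            rec.features.append(
                SeqFeature(loc, type=type_by_cat[f.category], qualifiers={"gene": [f.label]})
            )
        buf = StringIO()
        SeqIO.write(rec, buf, "genbank")
        return buf.getvalue()


def _draw_bases(rng: np.random.Generator, n: int, freqs) -> str:
    p = np.asarray(freqs, dtype=float)
    p = p / p.sum()
    return "".join(np.array(_BASES)[rng.choice(4, size=n, p=p)])


def random_sequence(
    n: int, freqs=DEFAULT_BASE_FREQS, seed: int = 0
) -> str:
    """An i.i.d. nucleotide string with the given base frequencies (A,T,G,C)."""
    return _draw_bases(np.random.default_rng(seed), n, freqs)


def _codon_distribution(cfg: GeneratorConfig) -> tuple[tuple[str, ...], np.ndarray]:
    if cfg.codon_weights is not None:
        codons = tuple(cfg.codon_weights)
        w = np.array([cfg.codon_weights[c] for c in codons], dtype=float)
    else:
        # independent-position codon frequencies from the genome base bias
        p = dict(zip(_BASES, np.asarray(cfg.base_freqs) / np.sum(cfg.base_freqs)))
        codons = _NONSTOP_CODONS
        w = np.array([p[c[0]] * p[c[1]] * p[c[2]] for c in codons])
    if np.any(w < 0) or w.sum() <= 0:
        raise SyntheticError("invalid codon weights")
    for c in codons:
        if c in STOP_CODONS:
            raise SyntheticError(f"stop codon {c} in codon distribution")
    return codons, w / w.sum()


def _build_pcg(
    rng: np.random.Generator, label: str, length: int, cfg: GeneratorConfig,
    codons: tuple[str, ...], weights: np.ndarray,
) -> str:
    """Sense-strand CDS of the requested annotated length: start codon,
    internal codons from the codon distribution, and a complete TAA or a
    partial T/TA terminator depending on length mod 3."""
    n_complete, remnant = divmod(length, 3)
    n_internal = n_complete - 1 - (1 if remnant == 0 else 0)
    if n_internal < 1:
        raise SyntheticError(f"{label}: length {length} too short for a coding gene")
    start = cfg.start_codons.get(label, "ATG")
    body = "".join(np.array(codons)[rng.choice(len(codons), size=n_internal, p=weights)])
    if remnant == 0:
        return start + body + "TAA"
    return start + body + "TA"[:remnant]


def _mutate_similarity(rng: np.random.Generator, seq: str, similarity: float) -> str:
    """Substitute each position with probability 1 - similarity (to a random
    different base), giving an expected pairwise identity ~= similarity."""
    rate = 1.0 - similarity
    out = []
    for b in seq:
        if b in _BASES and rng.random() < rate:
            out.append(rng.choice([x for x in _BASES if x != b]))
        else:
            out.append(b)
    return "".join(out)


def generate_mitogenome(cfg: GeneratorConfig) -> SyntheticMitogenome:
    """Assemble sequence + annotation + ground truth for one configuration."""
    if cfg.intergenic_gap < 0:
        raise SyntheticError("negative intergenic gaps are not supported by the generator")
    if not 0.0 <= cfg.cr_similarity <= 1.0:
        raise SyntheticError("cr_similarity must be in [0, 1]")
    rng = np.random.default_rng(cfg.seed)
    order = cfg.order()
    codons, weights = _codon_distribution(cfg)

    # element plan in genomic order; OL sits after trnN (WANCY cluster)
    plan: list[tuple[str, int]] = []
    for lab, sign in order.anchored():
        plan.append((lab, sign))
        if lab == "trnN":
            plan.append(("OL", 1))

    def region_freqs(label: str, category: str):
        return cfg.region_base_freqs.get(
            label, cfg.region_base_freqs.get(category, cfg.base_freqs)
        )

    pieces: list[str] = []
    features: list[Feature] = []
    pos = 1
    cr_seq: str | None = None
    from .vocab import category_of

    for lab, sign in plan:
        length = cfg.gene_lengths.get(lab)
        if length is None:
            raise SyntheticError(f"no length configured for {lab}")
        cat = category_of(lab)
        if cat == "PCG":
            sense = _build_pcg(rng, lab, length, cfg, codons, weights)
            sub = reverse_complement(sense) if sign < 0 else sense
        elif lab == "CR":
            if cr_seq is None:
                cr_seq = _draw_bases(rng, length, region_freqs(lab, cat))
                sub = cr_seq
            else:
                sub = _mutate_similarity(rng, cr_seq, cfg.cr_similarity)
                sub = (sub + _draw_bases(rng, length, region_freqs(lab, cat)))[:length]
        else:
            sub = _draw_bases(rng, length, region_freqs(lab, cat))
            if cat == "tRNA" and sign < 0:
                sub = reverse_complement(sub)
        strand = "L" if sign < 0 else "H"
        features.append(Feature(label=lab, strand=strand, start=pos, end=pos + length - 1))
        pieces.append(sub)
        pos += length
        if cfg.intergenic_gap:
            pieces.append(_draw_bases(rng, cfg.intergenic_gap, cfg.base_freqs))
            pos += cfg.intergenic_gap

    sequence = "".join(pieces)
    annotation = Annotation(
        species=cfg.species, genome_length=len(sequence), features=features
    )
    truth = {
        "seed": cfg.seed,
        "genome_length": len(sequence),
        "gene_order": order.to_string(),
        "injected_event": cfg.tdrl_event.to_dict() if cfg.tdrl_event else None,
        "base_freqs": list(cfg.base_freqs),
        "cr_similarity": cfg.cr_similarity,
        "intergenic_gap": cfg.intergenic_gap,
        "features": [
            {"label": f.label, "strand": f.strand, "start": f.start, "end": f.end}
            for f in features
        ],
    }
    return SyntheticMitogenome(sequence=sequence, annotation=annotation, ground_truth=truth)


def mutate_cds_pair(
    cds: str, syn_rate: float, nonsyn_rate: float, seed: int
) -> tuple[str, str]:
    """Two descendants of a codon sequence with independent per-codon
    synonymous / nonsynonymous substitution probabilities."""
    for r in (syn_rate, nonsyn_rate):
        if not 0.0 <= r <= 1.0:
            raise SyntheticError("per-codon rates must be in [0, 1]")
    if len(cds) % 3:
        raise SyntheticError("codon sequence length must be a multiple of 3")
    rng = np.random.default_rng(seed)

    def mutate(seq: str) -> str:
        out = []
        for k in range(len(seq) // 3):
            codon = seq[3 * k : 3 * k + 3]
            aa = translate_codon(codon)
            if aa in (None, "*"):
                out.append(codon)
                continue
            if rng.random() < syn_rate:
                alts = [c for c in FAMILIES[aa] if c != codon]
                if alts:
                    codon = alts[rng.integers(len(alts))]
            if rng.random() < nonsyn_rate:
                choices = []
                for i in range(3):
                    for b in _BASES:
                        if b == codon[i]:
                            continue
                        alt = codon[:i] + b + codon[i + 1 :]
                        alt_aa = translate_codon(alt)
                        if alt_aa not in (None, "*") and alt_aa != aa:
                            choices.append(alt)
                codon = choices[rng.integers(len(choices))]
            out.append(codon)
        return "".join(out)

    return mutate(cds), mutate(cds)


__all__ = [
    "DEFAULT_BASE_FREQS",
    "DEFAULT_GENE_LENGTHS",
    "GeneratorConfig",
    "SyntheticError",
    "SyntheticMitogenome",
    "generate_mitogenome",
    "mutate_cds_pair",
    "random_sequence",
]
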