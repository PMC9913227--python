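"""Mitogenome annotations: parsing, validation and summary arithmetic.

Coordinates are 1-based inclusive throughout, matching the convention of
published mitogenome feature tables; a feature with ``end < start`` spans the
origin of the circular molecule. Input formats are a tab-separated feature
table (columns ``gene``, ``strand``, ``start``, ``end`` and optionally
``start_codon``/``stop_codon``) or a single-record GenBank flat file.
"""

from __future__ import annotations

import io
import json
import warnings
from dataclasses import dataclass, field

from .vocab import UnknownLabelError, category_of, normalize_label


class AnnotationError(ValueError):
    """Raised for malformed or inconsistent annotation input."""


@dataclass(frozen=True)
class Feature:
    """One annotated element of a circular mitogenome.

    ``start``/``end`` are 1-based inclusive; ``end < start`` is permitted only
    for features spanning the origin. ``strand`` is ``"H"`` (heavy) or
    ``"L"`` (light). ``stop_codon`` may be a partial terminator such as
    ``"T--"`` or ``"TA-"`` that is completed by transcript polyadenylation.
    """

    label: str
    strand: str
    start: int
    end: int
    start_codon: str | None = None
    stop_codon: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("H", "L"):
            raise AnnotationError(f"{self.label}: strand must be H or L, got {self.strand!r}")
        if self.start < 1 or self.end < 1:
            raise AnnotationError(f"{self.label}: coordinates must be >= 1")

    @property
    def category(self) -> str:
        return category_of(self.label)

    def size(self, genome_length: int) -> int:
        return feature_size(self, genome_length)

    def spans_origin(self) -> bool:
        return self.end < self.start


@dataclass
class Annotation:
    """A parsed annotation: features of one circular mitogenome, start-sorted."""

    species: str
    genome_length: int
    features: list[Feature] = field(default_factory=list)
    circular: bool = True

    def __post_init__(self) -> None:
        self.features = sorted(self.features, key=lambda f: (f.start, f.end))
        for f in self.features:
            if f.start > self.genome_length or f.end > self.genome_length:
                raise AnnotationError(
                    f"{f.label}: coordinates exceed genome length {self.genome_length}"
                )
        counts: dict[str, int] = {}
        for f in self.features:
            counts[f.label] = counts.get(f.label, 0) + 1
        for label, n in counts.items():
            if label == "CR":
                if n > 2:
                    raise AnnotationError(f"control region appears {n} times (max 2)")
            elif n > 1:
                raise AnnotationError(f"duplicate gene {label}")

    def get(self, label: str) -> Feature:
        for f in self.features:
            if f.label == label:
                return f
        raise KeyError(label)

    def by_category(self, category: str) -> list[Feature]:
        return [f for f in self.features if f.category == category]

    def validate(self) -> list[str]:
        """Return human-readable warnings for incomplete annotations."""
        problems = []
        labels = {f.label for f in self.features}
        from .vocab import ALL_GENE_LABELS

        missing = [lab for lab in ALL_GENE_LABELS if lab not in labels]
        if missing:
            problems.append(f"missing genes: {', '.join(missing)}")
        if "CR" not in labels:
            problems.append("no control region annotated")
        if "OL" not in labels:
            problems.append("no light-strand replication origin annotated")
        return problems


@dataclass(frozen=True)
class AnnotationSummary:
    """Size/gap/overlap/category totals of one annotated mitogenome."""

    species: str
    genome_length: int
    gene_count: int
    sum_positive_gaps: int
    max_gap: int
    max_overlap: int
    max_overlap_pair: tuple[str, str] | None
    wrap_gap: int
    pcg_total: int
    rrna_total: int
    pcg_fraction: float
    rrna_fraction: float
    trna_count_by_strand: dict[str, int]

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["max_overlap_pair"] = list(self.max_overlap_pair) if self.max_overlap_pair else None
        return d

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, indent=2, **kwargs)


def feature_size(f: Feature, genome_length: int) -> int:
    """Length in bp of a feature on a circular genome (wrap-aware)."""
    if f.end >= f.start:
        return f.end - f.start + 1
    return genome_length - f.start + 1 + f.end


def intergenic_lengths(a: Annotation) -> list[tuple[str, str, int]]:
    """Signed gaps between consecutive features, attached to the downstream one.

    ``gap = start(next) - end(prev) - 1``; negative values are overlaps. The
    final pair wraps from the last feature back to the first on circular
    genomes.
    """
    feats = a.features
    if len(feats) < 2:
        raise AnnotationError("need at least two features for intergenic lengths")
    out = []
    for prev, nxt in zip(feats, feats[1:]):
        out.append((prev.label, nxt.label, nxt.start - prev.end - 1))
    if a.circular:
        last, first = feats[-1], feats[0]
        wrap = first.start + a.genome_length - last.end - 1
        out.append((last.label, first.label, wrap))
    return out


def summarize(a: Annotation) -> AnnotationSummary:
    """Compute genome-level totals: gaps, overlaps and category sizes.

    ``sum_positive_gaps`` counts only strictly positive internal gaps; the
    circular wrap gap is reported separately (``wrap_gap``), matching how
    published feature tables total their intergenic column. ``gene_count``
    counts PCGs, tRNAs and rRNAs (control regions and the replication origin
    are non-genic).
    """
    gaps = intergenic_lengths(a)
    internal = gaps[:-1] if a.circular else gaps
    positive = [g for *_, g in internal if g > 0]
    overlaps = [(u, d, -g) for u, d, g in internal if g < 0]
    max_overlap, pair = 0, None
    if overlaps:
        u, d, mo = max(overlaps, key=lambda t: t[2])
        max_overlap, pair = mo, (u, d)
    pcg_total = sum(f.size(a.genome_length) for f in a.by_category("PCG"))
    rrna_total = sum(f.size(a.genome_length) for f in a.by_category("rRNA"))
    trna_by_strand = {"H": 0, "L": 0}
    for f in a.by_category("tRNA"):
        trna_by_strand[f.strand] += 1
    gene_count = sum(1 for f in a.features if f.category in ("PCG", "tRNA", "rRNA"))
    return AnnotationSummary(
        species=a.species,
        genome_length=a.genome_length,
        gene_count=gene_count,
        sum_positive_gaps=sum(positive),
        max_gap=max(positive, default=0),
        max_overlap=max_overlap,
        max_overlap_pair=pair,
        wrap_gap=gaps[-1][2] if a.circular else 0,
        pcg_total=pcg_total,
        rrna_total=rrna_total,
        pcg_fraction=100.0 * pcg_total / a.genome_length,
        rrna_fraction=100.0 * rrna_total / a.genome_length,
        trna_count_by_strand=trna_by_strand,
    )


# ---------------------------------------------------------------------------
# feature-table I/O

_REQUIRED_COLUMNS = ("gene", "strand", "start", "end")


def parse_feature_table(text: str, lenient: bool = False) -> Annotation:
    """Parse a tab-separated feature table into an :class:`Annotation`.

    Leading ``#`` lines may carry ``# species: ...`` and
    ``# genome_length: ...`` metadata; otherwise the genome length defaults to
    the maximum end coordinate. Unknown gene names are a hard error unless
    ``lenient`` is set, in which case the offending rows are dropped with a
    warning.
    """
    species = ""
    genome_length: int | None = None
    lines = text.splitlines()
    body: list[str] = []
    for line in lines:
        if line.startswith("#"):
            meta = line.lstrip("#").strip()
            if meta.lower().startswith("species:"):
                species = meta.split(":", 1)[1].strip()
            elif meta.lower().startswith("genome_length:"):
                genome_length = int(meta.split(":", 1)[1].strip())
        elif line.strip():
            body.append(line)
    if not body:
        raise AnnotationError("no features: empty table")
    header = [c.strip().lower() for c in body[0].split("\t")]
    for col in _REQUIRED_COLUMNS:
        if col not in header:
            raise AnnotationError(f"missing required column {col!r}")
    idx = {c: header.index(c) for c in header}
    features = []
    for ln, line in enumerate(body[1:], start=2):
        cells = [c.strip() for c in line.split("\t")]

        def cell(col: str) -> str:
            i = idx.get(col)
            return cells[i] if i is not None and i < len(cells) else ""

        raw = cell("gene")
        try:
            label = normalize_label(raw)
        except UnknownLabelError as e:
            if lenient:
                warnings.warn(f"row {ln}: skipping unknown gene {raw!r}")
                continue
            raise AnnotationError(f"row {ln}: {e}") from e
        try:
            start, end = int(cell("start")), int(cell("end"))
        except ValueError:
            raise AnnotationError(
                f"row {ln} ({raw}): start/end must be integers"
            ) from None
        features.append(
            Feature(
                label=label,
                strand=cell("strand").upper() or "H",
                start=start,
                end=end,
                start_codon=cell("start_codon") or None,
                stop_codon=cell("stop_codon") or None,
            )
        )
    if not features:
        raise AnnotationError("no features: all rows rejected")
    if genome_length is None:
        genome_length = max(f.end for f in features)
    return Annotation(species=species, genome_length=genome_length, features=features)


def write_feature_table(a: Annotation) -> str:
    """Serialize an :class:`Annotation` to canonical TSV (parse round-trips)."""
    out = io.StringIO()
    if a.species:
        out.write(f"# species: {a.species}\n")
    out.write(f"# genome_length: {a.genome_length}\n")
    out.write("gene\tstrand\tstart\tend\tstart_codon\tstop_codon\n")
    for f in a.features:
        out.write(
            f"{f.label}\t{f.strand}\t{f.start}\t{f.end}\t"
            f"{f.start_codon or ''}\t{f.stop_codon or ''}\n"
        )
    return out.getvalue()


def read_feature_table(path, lenient: bool = False) -> Annotation:
    with open(path) as fh:
        return parse_feature_table(fh.read(), lenient=lenient)


# ---------------------------------------------------------------------------
# GenBank I/O

_GENBANK_TYPES = ("CDS", "tRNA", "rRNA", "D-loop", "rep_origin", "misc_feature")


def parse_genbank(path) -> tuple[Annotation, str]:
    """Read a single-record GenBank flat file into (Annotation, sequence)."""
    from Bio import SeqIO

    records = list(SeqIO.parse(path, "genbank"))
    if len(records) != 1:
        raise AnnotationError(f"expected a single GenBank record, found {len(records)}")
    rec = records[0]
    seq = str(rec.seq).upper()
    declared = rec.annotations.get("sequence_length") or len(seq)
    if len(seq) != declared:
        raise AnnotationError("LOCUS length does not match sequence length")
    features = []
    for feat in rec.features:
        if feat.type not in _GENBANK_TYPES:
            continue
        name = (
            feat.qualifiers.get("gene", [None])[0]
            or feat.qualifiers.get("product", [None])[0]
            or ("D-loop" if feat.type == "D-loop" else None)
            or ("O_L" if feat.type == "rep_origin" else None)
        )
        if name is None:
            continue
        try:
            label = normalize_label(name)
        except UnknownLabelError:
            continue
        if feat.type == "misc_feature" and label not in ("CR", "OL"):
            continue
        parts = feat.location.parts
        start = int(parts[0].start) + 1
        end = int(parts[-1].end)
        strand = "L" if feat.location.strand == -1 else "H"
        features.append(Feature(label=label, strand=strand, start=start, end=end))
    if not features:
        raise AnnotationError("no features in GenBank record")
    # CDS and gene features for the same element would duplicate: dedupe
    seen: dict[tuple, Feature] = {}
    for f in features:
        seen.setdefault((f.label, f.start, f.end), f)
    ann = Annotation(
        species=rec.annotations.get("organism", "") or rec.description,
        genome_length=len(seq),
        features=list(seen.values()),
    )
    return ann, seq


__all__ = [
    "Annotation",
    "AnnotationError",
    "AnnotationSummary",
    "Feature",
    "feature_size",
    "intergenic_lengths",
    "parse_feature_table",
    "parse_genbank",
    "read_feature_table",
    "summarize",
    "write_feature_table",
]
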