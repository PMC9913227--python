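"""End-to-end comparative analysis of one or more annotated mitogenomes.

Stages run in order: annotation summary → gene order → TDRL inference against
the canonical vertebrate order → (when sequence is available) composition,
codon usage/RSCU and pairwise Ka/Ks. Inputs may be GenBank flat files (which
carry sequence) or bare feature tables (annotation arithmetic and gene-order
analysis only). Failures of one stage are recorded in the bundle's error
manifest without aborting the rest.
"""

from __future__ import annotations

import json
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .annotation import (
    Annotation,
    AnnotationSummary,
    parse_genbank,
    read_feature_table,
    summarize,
)
from .codons import amino_acid_usage, count_codons, rscu
from .composition import composition_table, region_composition
from .gene_order import GeneOrder, canonical_vertebrate_order, extract_gene_order, order_diff
from .selection import classify_selection, ng86_kaks
from .tdrl import describe_events, find_minimal_tdrl
from .codons import extract_codons


@dataclass
class PipelineConfig:
    genetic_code: int = 2
    strand: str = "sense"
    precision: int = 3
    tdrl_source: str = "canonical"
    include_OL: bool = False
    lenient: bool = False

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class SpeciesReport:
    name: str
    annotation: Annotation
    sequence: str | None
    summary: AnnotationSummary
    gene_order: GeneOrder
    breakpoints: int
    tdrl_events: list[dict]
    tdrl_narrative: str
    composition: "object | None" = None  # DataFrame
    rscu: "object | None" = None  # DataFrame
    amino_acid_usage: dict | None = None


@dataclass
class ReportBundle:
    config: PipelineConfig
    species: list[SpeciesReport] = field(default_factory=list)
    kaks: "object | None" = None  # DataFrame, when >= 2 inputs carry sequence
    errors: list[str] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def write(self, outdir) -> None:
        """Emit the deterministic TSV/JSON report files."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for rep in self.species:
            tag = rep.name.replace(" ", "_") or "input"
            (outdir / f"{tag}_summary.json").write_text(
                rep.summary.to_json() + "\n"
            )
            (outdir / f"{tag}_gene_order.txt").write_text(rep.gene_order.to_string() + "\n")
            (outdir / f"{tag}_tdrl.json").write_text(
                json.dumps(
                    {"events": rep.tdrl_events, "narrative": rep.tdrl_narrative},
                    indent=2, sort_keys=True,
                )
                + "\n"
            )
            if rep.composition is not None:
                rep.composition.to_csv(outdir / f"{tag}_composition.tsv", sep="\t")
            if rep.rscu is not None:
                rep.rscu.to_csv(outdir / f"{tag}_rscu.tsv", sep="\t")
        if self.kaks is not None:
            self.kaks.to_csv(outdir / "kaks.tsv", sep="\t", float_format="%.6f")
        (outdir / "run_metadata.json").write_text(
            json.dumps(
                {
                    "config": self.config.to_dict(),
                    "errors": self.errors,
                    **self.metadata,
                },
                indent=2, sort_keys=True,
            )
            + "\n"
        )


def _log(msg: str) -> None:
    print(msg, file=sys.stderr)


def load_input(path, config: PipelineConfig) -> tuple[Annotation, str | None]:
    path = Path(path)
    if path.suffix.lower() in (".gb", ".gbk", ".genbank"):
        return parse_genbank(path)
    return read_feature_table(path, lenient=config.lenient), None


def run_pipeline(inputs: list, config: PipelineConfig | None = None) -> ReportBundle:
    """Run all analysis stages over the given annotation files."""
    config = config or PipelineConfig()
    bundle = ReportBundle(config=config, metadata={"version": __version__})
    canonical = canonical_vertebrate_order()
    parsed: list[tuple[str, Annotation, str | None]] = []
    for path in inputs:
        try:
            ann, seq = load_input(path, config)
            parsed.append((ann.species or Path(path).stem, ann, seq))
        except Exception as e:  # noqa: BLE001 - manifest, not crash
            bundle.errors.append(f"{path}: {e}")
    if not parsed:
        raise SystemExit("no parseable inputs")

    for name, ann, seq in parsed:
        t0 = time.perf_counter()
        order = extract_gene_order(ann, include_OL=config.include_OL)
        diff = order_diff(canonical, order)
        try:
            search = find_minimal_tdrl(canonical, order)
            events = [ev.to_dict() for ev in search.events]
            narrative = describe_events(search, canonical)
        except Exception as e:  # noqa: BLE001
            events, narrative = [], f"TDRL search aborted: {e}"
            bundle.errors.append(f"{name}: {e}")
        rep = SpeciesReport(
            name=name,
            annotation=ann,
            sequence=seq,
            summary=summarize(ann),
            gene_order=order,
            breakpoints=diff.breakpoint_count,
            tdrl_events=events,
            tdrl_narrative=narrative,
        )
        if seq is not None:
            profiles = {}
            for grouping in ("category", "codon_position"):
                profiles.update(region_composition(seq, ann, grouping, strand=config.strand))
            rep.composition = composition_table(profiles)
            counts = count_codons(ann, seq)
            rep.rscu = rscu(counts).to_dataframe()
            rep.amino_acid_usage = amino_acid_usage(counts)
        bundle.species.append(rep)
        _log(f"[mitorearr] {name}: analyzed in {time.perf_counter() - t0:.2f}s")

    with_seq = [(n, a, s) for n, a, s in parsed if s is not None]
    if len(with_seq) >= 2:
        results = []
        (n1, a1, s1), (n2, a2, s2) = with_seq[0], with_seq[1]
        shared = {f.label for f in a1.by_category("PCG")} & {
            f.label for f in a2.by_category("PCG")
        }
        for gene in sorted(shared):
            ex1 = extract_codons(a1.get(gene), s1)
            ex2 = extract_codons(a2.get(gene), s2)
            n = min(len(ex1.codons), len(ex2.codons))
            try:
                results.append(
                    ng86_kaks("".join(ex1.codons[:n]), "".join(ex2.codons[:n]), gene=gene)
                )
            except Exception as e:  # noqa: BLE001
                bundle.errors.append(f"kaks {gene}: {e}")
        if results:
            bundle.kaks = classify_selection(results)
    return bundle


__all__ = ["PipelineConfig", "ReportBundle", "SpeciesReport", "load_input", "run_pipeline"]
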