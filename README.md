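# mitorearr

Comparative analysis of circular mitochondrial genomes with gene
rearrangements, built around the snake-eel mitogenomes of *Ophichthus
evermanni* (GenBank OM421636, 17,759 bp) and *Ophichthus erabo*
(OP154196, 17,856 bp). Both genomes deviate from the canonical
vertebrate gene order: the cluster spanning ND6 through the control
region is rearranged and the control region is duplicated, a pattern
explained by a single tandem duplication–random loss (TDRL) event.

The package provides:

- **Annotation arithmetic** on circular genomes: feature sizes,
  intergenic spacers, overlaps and per-category totals with exact
  handling of origin-spanning features (`mitorearr.annotation`).
- **Signed gene orders** anchored at trnF, the canonical vertebrate
  order, and breakpoint distances between orders
  (`mitorearr.gene_order`).
- **TDRL mechanics**: applying a duplication–loss event to an order,
  and an exact search for all minimal single events transforming one
  order into another, with a brute-force oracle for validation
  (`mitorearr.tdrl`).
- **Nucleotide composition**: base frequencies, AT/GC skews, and
  per-gene / per-category / codon-position profiles
  (`mitorearr.composition`).
- **Codon usage** under the vertebrate mitochondrial code: codon
  extraction with incomplete stop codons, amino-acid usage and RSCU
  (`mitorearr.codons`).
- **Selection tests**: pairwise Ka/Ks by the Nei–Gojobori (NG86)
  method with Jukes–Cantor correction (`mitorearr.selection`).
- **A synthetic mitogenome generator** producing seeded, fully
  annotated genomes with known ground truth, including injected TDRL
  events and control-region duplications (`mitorearr.synthetic`).
- **A pipeline and CLI** tying the stages together
  (`mitorearr.pipeline`, the `mitorearr` command).

The curated annotation tables for both species and their published
composition statistics ship with the package
(`mitorearr.datasets`).

## Methods in brief

Coordinates are 1-based and inclusive on a circular genome of length
*n*; a feature with end < start spans the origin and has size
*n* − start + 1 + end. The spacer upstream of a feature is
start(next) − end(prev) − 1; negative values are overlaps, and the
spacer closing the circle is reported separately from the sum of
positive spacers.

Skews follow the usual conventions

    AT-skew = (A − T) / (A + T),    GC-skew = (G − C) / (G + C),

computed from counts or from printed percentages (they agree by scale
invariance). RSCU for codon *c* in the family of amino acid *aa* is

    RSCU(c) = count(c) / (count(family) / family size).

A TDRL event duplicates a contiguous block of the circular gene order
in tandem and then deletes one copy of each duplicated element
("first"/"second"; both copies may survive only for the control
region). For a single event, the number of losses is fully determined
by the block length, so the minimal-event search enumerates block
lengths in ascending order and returns every event of the first
feasible length; each candidate is verified by re-applying it. TDRL
cannot change strands, so orders differing in sign are rejected.

Ka/Ks uses NG86 site counting under the vertebrate mitochondrial code
(mutations into stop codons count as nonsynonymous, so every codon
contributes exactly 3 sites), equal-weight pathway averaging for
multi-difference codons, and the Jukes–Cantor distance
d = −(3/4) ln(1 − 4p/3), flagged as undefined when p ≥ 3/4.

See [docs/methods.md](docs/methods.md) for the full description,
parameter defaults and limitations.

## Worked example

```python
from mitorearr import datasets
from mitorearr.annotation import summarize
from mitorearr.gene_order import canonical_vertebrate_order, extract_gene_order
from mitorearr.tdrl import describe_events, find_minimal_tdrl

ann = datasets.load_evermanni()
print(summarize(ann).to_json())
```

prints

```json
{
  "gene_count": 37,
  "genome_length": 17759,
  "max_gap": 17,
  "max_overlap": 10,
  "max_overlap_pair": [
    "ATP8",
    "ATP6"
  ],
  "pcg_fraction": 64.86288642378513,
  "pcg_total": 11519,
  "rrna_fraction": 14.989582746776282,
  "rrna_total": 2662,
  "species": "Ophichthus evermanni",
  "sum_positive_gaps": 78,
  "trna_count_by_strand": {
    "H": 14,
    "L": 8
  },
  "wrap_gap": 0
}
```

The observed gene order (a `-` prefix marks light-strand genes):

```python
order = extract_gene_order(ann)
print(order.to_string())
```

```text
trnF 12S trnV 16S trnL1 ND1 trnI -trnQ trnM ND2 trnW -trnA -trnN -trnC -trnY COI -trnS1 trnD COII trnK ATP8 ATP6 COIII trnG ND3 trnR ND4L ND4 trnH trnS2 trnL2 ND5 Cytb trnT CR -ND6 -trnE -trnP CR
```

And the minimal TDRL event explaining it from the canonical order:

```python
search = find_minimal_tdrl(canonical_vertebrate_order(), order)
print(describe_events(search, canonical_vertebrate_order()))
```

```text
tandem duplication of the block -ND6--trnE-Cytb-trnT--trnP-CR followed by loss of 5 redundant copies: keep first copy of Cytb, trnT; keep second copy of -ND6, -trnE, -trnP; keep both copies of CR
```

The same analysis is available from the shell:

```bash
mitorearr annotate-summary path/to/features.tsv
mitorearr tdrl --source canonical --target path/to/features.tsv
mitorearr synth --seed 42 --out out/          # synthetic genome + truth
mitorearr run genome1.gb genome2.gb --out report/
```

## Running the tests

```bash
python -m pytest -q tests/
```

The suite covers unit oracles computed by hand, property-based checks
(seeded and derandomized), an independent NG86 implementation as a
cross-check, and end-to-end tests that reproduce the published
annotation statistics, skews and rearrangement pathway for both
snake-eel genomes.

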