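# Methods

This note describes the models, conventions and parameter choices
behind `mitorearr`. It complements the API documentation in the
docstrings; nothing here asserts empirical results beyond what the
test suite and `scripts/acceptance.py` actually compute.

## 1. Circular annotation model

A mitogenome is modelled as a circle of length *n* with 1-based,
inclusive feature coordinates. Assumptions:

- Exactly one copy of each of the 37 canonical genes (13
  protein-coding genes, 22 tRNAs, 2 rRNAs); up to two control-region
  (CR) copies; at most one light-strand replication origin (OL).
  Duplicated genes other than CR are a hard error because the
  downstream gene-order machinery assumes unique labels.
- A feature with end < start spans the coordinate origin and has size
  *n* − start + 1 + end.
- The spacer upstream of a feature is start − end(previous) − 1, so a
  spacer of 0 means abutting features and negative values are
  overlaps. The spacer closing the circle (last feature back to the
  first) is reported as `wrap_gap` and **excluded** from
  `sum_positive_gaps`; published per-genome spacer totals for these
  annotations are conventionally reported over the linearized gene
  list, and including the wrap spacer would double-count the
  junction when the genome starts inside a feature.
- Gene labels are normalized through a controlled vocabulary
  (`mitorearr.vocab`) that accepts common synonyms (COX1/CO I/COI,
  Cyt b/COB/Cytb, D-loop/CR, …). Leucine and serine tRNAs must be
  disambiguated (L1/L2, S1/S2) either explicitly or via a codon-family
  hint; an ambiguous "trnL" is rejected rather than guessed.

## 2. Gene orders and breakpoints

A gene order is a circular sequence of signed elements (sign =
strand), anchored at trnF, the conventional start of vertebrate
mitogenome annotations. If trnF is absent the order is anchored at the
first feature and a warning is emitted — a fallback rather than an
error so that partial annotations can still be compared. OL is
excluded by default (it is not a gene and its presence varies between
annotations); `include_OL=True` retains it.

The breakpoint distance between two orders with equal gene content is
the number of signed adjacencies of the first order absent from the
second, counted with multiplicity (multisets are needed because a
duplicated CR creates repeated labels). Orders with different gene
content beyond the CR copy number are not comparable and raise an
error instead of returning a misleading number.

## 3. TDRL model and minimal-event search

A tandem duplication–random loss (TDRL) event on a circular order:

1. duplicate a contiguous block of length *L* in tandem;
2. for each duplicated element keep the first copy, the second copy,
   or — only for CR — both.

The result is the order-preserving interleaving of the two retained
sub-sequences, with the rest of the order unchanged. TDRL cannot
invert strands, so a sign mismatch between source and target is
rejected immediately.

**Minimality.** For a fixed source and target, every valid single
event with block length *L* has exactly *L* − (*m* − *n*) losses,
where *m* and *n* are the target and source lengths (each "both"
retains one extra element). The number of losses is therefore a
function of *L* alone, and "fewest losses, shortest block" reduces to
"smallest *L*". The search enumerates block lengths in ascending order
and, at the first feasible length, returns **all** events of that
length (there can be several distinct retention patterns). Each
candidate is verified by re-applying it with `apply_tdrl` before being
reported — the search is sound by construction. Completeness is
checked in the test suite against `brute_force_tdrl`, an exhaustive
enumerator with an explicit combinatorial budget (default 2·10⁶
candidate events) that errors rather than silently truncating.

Identical source and target are reported as a dedicated "no event
needed" result (`TDRLSearch.identical`) rather than as a degenerate
zero-loss event, because a zero-loss event would have to retain both
copies of every element, which the model forbids for genes.

## 4. Composition and skews

Base counts ignore IUPAC ambiguity codes (counted separately as
`n_ignored`); a sequence with no unambiguous base is an error. Skews:

- AT-skew = (A − T) / (A + T), GC-skew = (G − C) / (G + C).
- A zero denominator yields `None` (undefined), never NaN or a
  silent 0.

Skews are scale-invariant, so they can be computed identically from
counts or from printed percentages; this is how published skew values
are recomputed from published base percentages.

Per-gene profiles are computed on the **sense strand**: light-strand
features are reverse-complemented first, so the reported composition
is that of the encoded gene, not of the reference strand. Category
profiles (PCGs, tRNAs, rRNAs, CRs) are exact count-wise merges of the
per-gene profiles. Codon-position profiles use only complete codons of
protein-coding genes.

## 5. Codon usage

The vertebrate mitochondrial genetic code (NCBI translation table 2)
is used throughout: stops TAA/TAG/AGA/AGG, and the Leu and Ser
families with six codons each. Codon extraction handles incomplete
stop codons: a coding length ≡ 1 (mod 3) leaves a single-base "T--"
style remnant, ≡ 2 (mod 3) a two-base "TA-" remnant; these remnants
(completed by post-transcriptional polyadenylation in vivo) are
reported as the gene's stop codon but never enter the codon counts. A
complete terminal stop codon is likewise excluded from the counts and
reported separately. Internal stop codons trigger a warning, not an
error, since annotation slippage is common in public records.

RSCU(c) = count(c) / (family total / family size), computed per
amino-acid family (minimum family size 2: under table 2 even Met
(ATG/ATA) and Trp (TGA/TGG) have two codons — see
`mitorearr.codons.FAMILIES`). Families
with zero observations yield `None` rather than 0/0.

## 6. Ka/Ks (NG86)

Pairwise Ka/Ks follows Nei & Gojobori (1986) with these conventions,
chosen to match the independent implementation in Biopython exactly
(which the tests use as a cross-check):

- Site counting: each codon position contributes (number of
  synonymous single-base alternatives)/3 synonymous sites; mutations
  into stop codons count as **nonsynonymous**, so S + N = 3 per codon
  and total sites equal the alignment length.
- Multi-difference codons: all orderings of the single-base steps are
  averaged with equal weight; a step is synonymous iff it preserves
  the amino acid and passes through a non-stop codon.
- Distance correction: Jukes–Cantor, d = −(3/4) ln(1 − 4p/3).
  When p ≥ 3/4 the correction is undefined; the value is reported as
  `None` and the gene's verdict as "undefined" instead of raising or
  returning NaN/inf.
- Verdicts: "purifying" if Ka/Ks < 1, "positive" if > 1, "neutral"
  within 10⁻⁹ of 1, "undefined" if Ks is 0 or saturated.
- Codon pairs containing a stop or an ambiguous base are skipped.

Sequences must be equal length and a multiple of 3; anything else is
an error, because silent truncation would bias the estimate.

## 7. Synthetic generator

`generate_mitogenome` produces a fully annotated genome with known
ground truth from a seeded `numpy` generator (`default_rng`). Defaults
are the study conditions of the *O. evermanni* reference:

| parameter | default | rationale |
|---|---|---|
| `gene_lengths` | the 40 observed feature lengths (e.g. CR 966 bp, OL 34 bp) | realistic size structure |
| `base_freqs` | (A, T, G, C) = (0.3127, 0.2632, 0.1619, 0.2622) | whole-genome frequencies of the reference |
| `start_codons` | ATG; COI → GTG, ND6 → CTA | observed annotation |
| `intergenic_gap` | 1 bp | minimal spacing; keeps totals controlled |
| `cr_similarity` | 0.945 | observed identity between the two CR copies |
| `tdrl_event` | none (canonical order) | inject explicitly to create a rearranged genome |

Protein-coding genes are built as a start codon, i.i.d. non-stop
codons, and a complete or incomplete stop matching the requested
length (T-- / TA- remnants arise naturally from lengths ≢ 0 mod 3). A
duplicated CR is derived from the first copy by independent per-site
mutation at rate 1 − `cr_similarity`. `mutate_cds_pair` creates
divergent coding pairs with separate synonymous (within-family codon
swap) and nonsynonymous (single-base change avoiding stops) rates.

**What the generator emulates:** feature geometry, gene order
(including injected TDRL events), base and codon frequency structure,
CR duplication with tunable identity, incomplete stop codons.

**What it does not emulate:** secondary structure of tRNAs/rRNAs,
codon autocorrelation or context effects, strand-asymmetric
mutational pressure, indels, heteroplasmy, or realistic phylogenetic
divergence models (mutation is i.i.d. per site/codon).

## 8. Pipeline

`run_pipeline` accepts GenBank files or feature tables. Stages per
input: annotation summary → gene-order extraction → breakpoint
comparison against the canonical order → minimal TDRL search. If
sequence is available: composition profiles, RSCU, amino-acid usage;
with two sequence-bearing inputs, pairwise NG86 Ka/Ks over shared
protein-coding genes (codon lists truncated to the shorter gene, a
crude alignment surrogate — see limitations). Inputs without sequence
produce **no** sequence-dependent statistics: the pipeline never
back-fills them from summary tables. Outputs are deterministic
(sorted JSON/TSV) for diffability.

## 9. Limitations

- The TDRL search finds single events only; multi-event histories are
  out of scope (the brute-force oracle shares this limit).
- Ka/Ks assumes the input pairs are codon-aligned; truncation to the
  shorter sequence is not an alignment and is only adequate for
  length-matched orthologs.
- Jukes–Cantor is the only distance correction offered; saturated
  comparisons are flagged, not rescued.
- The generator's i.i.d. sequence model is intended for testing
  estimators, not for simulating realistic evolution.
- RSCU and skew conventions follow the definitions above; other
  conventions in the literature (e.g. counting stop codons in RSCU)
  will give different numbers.
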