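"""Codon extraction, incomplete stop handling, amino-acid usage and RSCU."""

import pytest

from mitorearr.annotation import Annotation, Feature
from mitorearr.codons import (
    ALL_CODONS,
    CodonCounts,
    FAMILIES,
    STOP_CODONS,
    amino_acid_usage,
    count_codons,
    extract_codons,
    rscu,
    translate_codon,
)
from mitorearr.composition import reverse_complement


def toy_annotation(seq_len, feats):
    return Annotation(species="toy", genome_length=seq_len, features=feats)


class TestExtractCodons:
    def test_complete_stop(self):
        ann = toy_annotation(9, [Feature(label="ND1", strand="H", start=1, end=9)])
        ex = extract_codons(ann.get("ND1"), "ATGAAATAA")
        assert ex.codons == ("ATG", "AAA")
        assert ex.stop_codon == "TAA" and ex.stop_complete

    def test_one_nt_partial_stop_like_nd2(self, evermanni):
        # ND2 is 1057 bp = 3*352 + 1: 352 complete codons and a T-- remnant
        nd2 = evermanni.get("ND2")
        seq_len = nd2.end - nd2.start + 1
        assert seq_len == 1057
        body = "ATG" + "AAA" * 351 + "T"
        ann = toy_annotation(1057, [Feature(label="ND2", strand="H", start=1, end=1057)])
        ex = extract_codons(ann.get("ND2"), body)
        assert len(ex.codons) == 352
        assert ex.stop_codon == "T--" and not ex.stop_complete

    def test_two_nt_partial_stop_like_atp6(self):
        # 683 bp = 3*227 + 2: TA- class remnant
        body = "ATG" + "CTT" * 226 + "TA"
        ann = toy_annotation(683, [Feature(label="ATP6", strand="H", start=1, end=683)])
        ex = extract_codons(ann.get("ATP6"), body)
        assert ex.stop_codon == "TA-" and ex.n_partial_stop_nt == 2

    def test_reverse_strand_equals_revcomp_extraction(self):
        sense = "ATGCTAGGATTC" + "TAA"
        genome = "GGGG" + reverse_complement(sense) + "CCCC"
        f = Feature(label="ND6", strand="L", start=5, end=4 + len(sense))
        ann = toy_annotation(len(genome), [f])
        ex = extract_codons(f, genome)
        f_h = Feature(label="ND6", strand="H", start=1, end=len(sense))
        ex_h = extract_codons(f_h, sense + "A" * (len(genome) - len(sense)))
        assert ex.codons == ex_h.codons and ex.stop_codon == ex_h.stop_codon

    def test_internal_stop_warns_but_does_not_fail(self):
        body = "ATGAGAAAATAA"  # AGA is a mitochondrial stop
        ann = toy_annotation(12, [Feature(label="ND1", strand="H", start=1, end=12)])
        with pytest.warns(UserWarning, match="internal stop"):
            ex = extract_codons(ann.get("ND1"), body)
        assert ex.internal_stops == (1,)

    def test_codon_nucleotide_accounting(self, synthetic_default):
        seq, ann = synthetic_default.sequence, synthetic_default.annotation
        total_nt = 0
        counted = 0
        for f in ann.by_category("PCG"):
            ex = extract_codons(f, seq)
            total_nt += f.size(ann.genome_length)
            counted += 3 * len(ex.codons) + ex.n_partial_stop_nt
            if ex.stop_complete:
                counted += 3
        assert counted == total_nt


class TestUsage:
    def test_single_codon_usage(self):
        cc = CodonCounts()
        cc.counts.update({"ATG": 5})
        assert amino_acid_usage(cc)["M"] == 100.0

    def test_leucine_family_pooled_over_six_codons(self):
        assert set(FAMILIES["L"]) == {"TTA", "TTG", "CTT", "CTC", "CTA", "CTG"}
        assert set(FAMILIES["S"]) == {"TCT", "TCC", "TCA", "TCG", "AGT", "AGC"}

    def test_family_sizes_audit_against_code_table(self):
        # vertebrate mitochondrial code: no 1-codon family; Met and Trp have 2
        sizes = {aa: len(fam) for aa, fam in FAMILIES.items()}
        assert min(sizes.values()) == 2
        assert sizes["M"] == 2 and sizes["W"] == 2
        assert sum(sizes.values()) + len(STOP_CODONS) == 64

    def test_usage_sums_to_100(self, synthetic_default):
        counts = count_codons(synthetic_default.annotation, synthetic_default.sequence)
        usage = amino_acid_usage(counts)
        assert sum(usage.values()) == pytest.approx(100.0, abs=0.02)

    def test_synthetic_codon_distribution_recovery(self):
        from mitorearr.synthetic import GeneratorConfig, generate_mitogenome

        weights = {"TTA": 0.5, "GCC": 0.3, "ATT": 0.2}
        g = generate_mitogenome(GeneratorConfig(seed=3, codon_weights=weights))
        counts = count_codons(g.annotation, g.sequence)
        internal = sum(counts.counts[c] for c in weights)
        for codon, w in weights.items():
            assert counts.counts[codon] / internal == pytest.approx(w, abs=0.02)


class TestRSCU:
    def test_uniform_fourfold_family(self):
        cc = CodonCounts()
        cc.counts.update({c: 10 for c in FAMILIES["A"]})  # Ala: GCN
        table = rscu(cc)
        assert all(table.rscu[c] == pytest.approx(1.0) for c in FAMILIES["A"])

    def test_twofold_family_direct_formula(self):
        cc = CodonCounts()
        cc.counts.update({"AAA": 3, "AAG": 1})  # Lys
        table = rscu(cc)
        assert table.rscu["AAA"] == pytest.approx(1.5)
        assert table.rscu["AAG"] == pytest.approx(0.5)

    def test_family_sums_and_unobserved_flagging(self, synthetic_default):
        counts = count_codons(synthetic_default.annotation, synthetic_default.sequence)
        table = rscu(counts)
        for aa, fam in FAMILIES.items():
            values = [table.rscu[c] for c in fam]
            if all(v is None for v in values):
                continue
            assert sum(values) == pytest.approx(len(fam))

    def test_stop_codons_have_no_rscu(self, synthetic_default):
        counts = count_codons(synthetic_default.annotation, synthetic_default.sequence)
        table = rscu(counts)
        assert not set(STOP_CODONS) & set(table.rscu)

    def test_every_sense_codon_translates(self):
        for codon in ALL_CODONS:
            aa = translate_codon(codon)
            assert aa == "*" if codon in STOP_CODONS else aa in FAMILIES
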