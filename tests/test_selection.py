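"""NG86 Ka/Ks estimation and selection classification."""

import numpy as np
import pytest

from mitorearr.codons import FAMILIES
from mitorearr.selection import KaKsError, classify_selection, jukes_cantor, ng86_kaks
from mitorearr.synthetic import mutate_cds_pair

NONSTOP = tuple(c for fam in FAMILIES.values() for c in fam)


class TestNG86:
    def test_identical_sequences_are_undefined(self):
        r = ng86_kaks("ATGAAA", "ATGAAA")
        assert r.ka == 0.0 and r.ks == 0.0
        assert r.verdict == "undefined"

    def test_single_synonymous_change_hand_oracle(self):
        # TTA->TTG (Leu->Leu) in a 3-codon context of TTA repeats.
        # Per TTA/TTG codon 2/3 of a site is synonymous (position 1 and 3 each
        # carry one synonymous alternative of three), so S = 3 * 2/3 = 2,
        # Sd = 1: pS = 1/2 and ks = -(3/4) ln(1 - 2/3) = 0.823959.
        r = ng86_kaks("TTATTATTA", "TTGTTATTA")
        assert r.ka == 0.0
        assert r.ks == pytest.approx(-0.75 * np.log(1 / 3), abs=1e-9)
        assert r.verdict == "purifying"
        assert r.n_sites[0] == pytest.approx(2.0)

    def test_single_codon_synonymous_change_saturates_correction(self):
        # one TTA/TTG codon alone: pS = 1/(2/3) = 1.5 >= 3/4, JC undefined
        r = ng86_kaks("TTA", "TTG")
        assert r.ks is None and r.verdict == "undefined"

    def test_single_nonsynonymous_change_hand_oracle(self):
        # GCT->GTT (Ala->Val): each codon has exactly one synonymous site
        # (the fourfold third position), N = 2, Nd = 1, ks = 0 -> undefined ratio
        r = ng86_kaks("GCT", "GTT")
        assert r.ks == 0.0
        assert r.ka == pytest.approx(-0.75 * np.log(1 / 3), abs=1e-9)
        assert r.ratio is None and r.verdict == "undefined"

    def test_symmetry(self):
        a, b = "ATGCTTGGATCA", "ATGCTCGGTTCA"
        r1, r2 = ng86_kaks(a, b), ng86_kaks(b, a)
        assert r1.ka == pytest.approx(r2.ka) and r1.ks == pytest.approx(r2.ks)

    def test_site_count_conservation(self):
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(NONSTOP, 40))
        other, _ = mutate_cds_pair(seq, 0.2, 0.2, seed=1)
        r = ng86_kaks(seq, other)
        assert sum(r.n_sites) == pytest.approx(len(seq))

    def test_length_and_frame_validation(self):
        with pytest.raises(KaKsError):
            ng86_kaks("ATGAAA", "ATG")
        with pytest.raises(KaKsError):
            ng86_kaks("ATGA", "ATGA")

    def test_agreement_with_independent_ng86_implementation(self):
        # cross-check against Biopython's NG86 on mutated codon sequences
        from Bio.Align import Alignment, analysis
        from Bio.Data.CodonTable import unambiguous_dna_by_id

        rng = np.random.default_rng(7)
        for seed in (1, 2, 3):
            seq = "".join(rng.choice(NONSTOP, 60))
            other, _ = mutate_cds_pair(seq, 0.25, 0.08, seed=seed)
            mine = ng86_kaks(seq, other)
            dn, ds = analysis.calculate_dn_ds(
                Alignment([seq, other]), method="NG86",
                codon_table=unambiguous_dna_by_id[2],
            )
            assert mine.ka == pytest.approx(dn, abs=1e-9)
            assert mine.ks == pytest.approx(ds, abs=1e-9)

    def test_jukes_cantor_saturation_flag(self):
        assert jukes_cantor(0.0) == 0.0
        assert jukes_cantor(0.74) is not None
        assert jukes_cantor(0.75) is None


class TestClassification:
    def test_verdicts_from_ratios(self):
        purifying = ng86_kaks("TTATTAGGGCCC", "TTGTTAGGGCCC")
        assert purifying.verdict == "purifying"
        df = classify_selection([purifying])
        assert df.loc[purifying.gene or "", "verdict"] == "purifying"

    def test_synonymous_biased_divergence_is_purifying(self):
        rng = np.random.default_rng(5)
        hits = 0
        for rep in range(100):
            seq = "".join(rng.choice(NONSTOP, 200))
            a, b = mutate_cds_pair(seq, 0.2, 0.01, seed=1000 + rep)
            r = ng86_kaks(a, b)
            if r.verdict == "purifying":
                hits += 1
        assert hits >= 95

    def test_nonsynonymous_biased_divergence_is_positive(self):
        rng = np.random.default_rng(6)
        hits = 0
        for rep in range(100):
            seq = "".join(rng.choice(NONSTOP, 200))
            a, b = mutate_cds_pair(seq, 0.01, 0.2, seed=2000 + rep)
            r = ng86_kaks(a, b)
            if r.verdict == "positive":
                hits += 1
        assert hits >= 95

    def test_neutral_divergence_ratio_centers_near_one(self):
        # equal per-site substitution rates with no selection: mutate single
        # random nucleotides (any outcome) and expect the mean ratio near 1
        rng = np.random.default_rng(8)
        ratios = []
        for rep in range(30):
            seq = list("".join(rng.choice(NONSTOP, 300)))
            other = seq.copy()
            n_mut = 0
            while n_mut < 90:
                i = rng.integers(len(other))
                b = "ATGC"[rng.integers(4)]
                cand = other.copy()
                cand[i] = b
                codon = "".join(cand[3 * (i // 3) : 3 * (i // 3) + 3])
                from mitorearr.codons import translate_codon

                if b != other[i] and translate_codon(codon) != "*":
                    other = cand
                    n_mut += 1
            r = ng86_kaks("".join(seq), "".join(other))
            if r.ratio is not None:
                ratios.append(r.ratio)
        mean = float(np.mean(ratios))
        assert 0.7 < mean < 1.3
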