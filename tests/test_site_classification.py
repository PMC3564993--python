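"""Codon machinery: NG86 site counts, SNP effect classes, ENC, GC3.

The NG86 oracle here is fully independent of the implementation: it carries
its own hard-coded standard genetic code and enumerates mutations directly.
"""

from __future__ import annotations

import random

import pytest

from polyload.site_classification import (
    NONCODING_EFFECT,
    NONSYNONYMOUS,
    SYNONYMOUS,
    classify_variant,
    enc,
    gc3,
    ng86_site_counts,
)

# independent standard genetic code, bases in T/C/A/G order
_ORDER = "TCAG"
_AA = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
ORACLE_CODE = {
    a + b + c: _AA[16 * _ORDER.index(a) + 4 * _ORDER.index(b) + _ORDER.index(c)]
    for a in _ORDER
    for b in _ORDER
    for c in _ORDER
}
SENSE_CODONS = sorted(c for c, aa in ORACLE_CODE.items() if aa != "*")


def oracle_ng86(codon: str) -> tuple[float, float]:
    syn = 0
    for pos in range(3):
        for base in "ACGT":
            if base == codon[pos]:
                continue
            alt = codon[:pos] + base + codon[pos + 1 :]
            if ORACLE_CODE[alt] == ORACLE_CODE[codon] and ORACLE_CODE[alt] != "*":
                syn += 1
    return syn / 3.0, (9 - syn) / 3.0


class TestNg86:
    def test_known_codons(self):
        assert ng86_site_counts("TTT") == pytest.approx((1 / 3, 8 / 3))
        assert ng86_site_counts("ATG") == (0.0, 3.0)  # Met: single-codon amino acid

    @pytest.mark.parametrize("codon", SENSE_CODONS)
    def test_matches_enumeration_oracle(self, codon):
        got = ng86_site_counts(codon)
        assert got == pytest.approx(oracle_ng86(codon))
        assert got[0] >= 0 and got[1] >= 0
        assert got[0] + got[1] == pytest.approx(3.0)

    @pytest.mark.parametrize("codon", ["ANT", "A-T", "AT", "ATGT"])
    def test_ambiguous_codon_rejected(self, codon):
        with pytest.raises(ValueError, match="ambiguous codon"):
            ng86_site_counts(codon)

    def test_stop_codon_rejected(self):
        with pytest.raises(ValueError, match="stop codon"):
            ng86_site_counts("TAA")


class TestClassifyVariant:
    def test_synonymous_third_position(self):
        # GGA -> GGG, both glycine
        assert classify_variant(("G", "G", "A"), 2, ("A", "G")) == SYNONYMOUS

    def test_nonsynonymous_first_position(self):
        # AAA (Lys) -> GAA (Glu)
        assert classify_variant(("A", "A", "A"), 0, ("A", "G")) == NONSYNONYMOUS

    def test_intron_position_is_noncoding(self):
        assert classify_variant(None, None, ("A", "G")) == NONCODING_EFFECT

    def test_stop_pathway_is_nonsynonymous(self):
        # TAT (Tyr) -> TAA (stop)
        assert classify_variant(("T", "A", "T"), 2, ("T", "A")) == NONSYNONYMOUS

    def test_double_hit_codon_averages_pathways(self):
        # focal SNP at position 3 of CT{A,G} with position 1 also segregating
        # C/T: CTA->CTG synonymous (Leu) and TTA->TTG synonymous (Leu)
        assert classify_variant((("C", "T"), "T", "A"), 2, ("A", "G")) == SYNONYMOUS
        # focal A/G at position 1 of {A}T(A|G): ATA->GTA (Ile->Val) nonsyn on
        # both backgrounds
        assert classify_variant(("A", "T", ("A", "G")), 0, ("A", "G")) == NONSYNONYMOUS

    def test_mixed_pathways_resolve_nonsynonymous(self):
        # focal T/A at codon position 3; background position 1 in {C, T}:
        # CGT->CGA synonymous (Arg), TGT->TGA nonsynonymous (Cys->stop)
        assert classify_variant((("C", "T"), "G", "T"), 2, ("T", "A")) == NONSYNONYMOUS

    def test_symmetric_in_alleles(self, rng):
        for _ in range(200):
            codon = "".join(rng.choice(list("ACGT"), 3))
            pos = int(rng.integers(0, 3))
            a = codon[pos]
            b = rng.choice([x for x in "ACGT" if x != a])
            assert classify_variant(tuple(codon), pos, (a, b)) == classify_variant(
                tuple(codon), pos, (b, a)
            )

    def test_bad_position_rejected(self):
        with pytest.raises(ValueError, match="position"):
            classify_variant(("A", "A", "A"), 3, ("A", "G"))


class TestEnc:
    def test_single_codon_per_family_gives_20(self):
        # one fixed codon per amino acid, repeated: every family homozygous
        one_per_aa = {}
        for codon in SENSE_CODONS:
            one_per_aa.setdefault(ORACLE_CODE[codon], codon)
        seq = "".join(sorted(one_per_aa.values())) * 10
        assert enc(seq) == 20.0

    def test_uniform_usage_clamps_to_61(self):
        seq = "".join(c * 50 for c in SENSE_CODONS)
        assert enc(seq) == 61.0

    def test_two_fold_family_homozygosity(self):
        # counts (3, 1) in a two-fold family: F = (4*(9/16+1/16)-1)/3 = 0.5
        seq = "AAA" * 3 + "AAG"  # Lys family
        # with only one family observed, every class mean is imputed to 0.5:
        # ENC = 2 + 9/0.5 + 1/0.5 + 5/0.5 + 3/0.5 = 38
        assert enc(seq) == pytest.approx(2 + 18 / 0.5)

    def test_range_and_shuffle_invariance(self, rng):
        for _ in range(20):
            codons = [SENSE_CODONS[i] for i in rng.integers(0, len(SENSE_CODONS), 40)]
            val = enc("".join(codons))
            assert 20.0 <= val <= 61.0
            rng.shuffle(codons)
            assert enc("".join(codons)) == pytest.approx(val)

    def test_imputation_disabled_raises(self):
        with pytest.raises(ValueError, match="no usable"):
            enc("AAA" * 3 + "AAG", impute_missing=False)


class TestGc3:
    @pytest.mark.parametrize(
        "seq,expected", [("GGGGGC", 1.0), ("GGAGGT", 0.0), ("GGAGGC", 0.5)]
    )
    def test_fraction(self, seq, expected):
        assert gc3(seq) == expected

    def test_no_complete_codon_raises(self):
        with pytest.raises(ValueError):
            gc3("GG")
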