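"""Diversity estimators: Watterson, pi, Tajima's D, SFS, F_ST, pooling."""

from __future__ import annotations

from fractions import Fraction
from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from polyload.diversity import (
    MAF_CLASSES,
    analyze_locus,
    bin_sfs_by_maf,
    expected_wf_folded_sfs,
    fold,
    folded_sfs,
    fst_weir_cockerham,
    harmonic_number,
    maf_class,
    pi,
    pooled_category_theta,
    tajima_constants,
    tajimas_d,
    watterson_theta,
)
from polyload.io_model import expand_iupac, site_columns
from conftest import make_alignment, make_annotation


class TestWatterson:
    @pytest.mark.parametrize(
        "S,n,L,expected",
        [(1, 2, 100, 0.01), (3, 4, 100, 3 / (11 / 6 * 100)), (0, 7, 50, 0.0)],
    )
    def test_values(self, S, n, L, expected):
        assert watterson_theta(S, n, L) == pytest.approx(expected)

    def test_insufficient_sample(self):
        with pytest.raises(ValueError, match="insufficient sample"):
            watterson_theta(1, 1, 100)


def brute_force_pi(aln) -> float:
    """Exhaustive pairwise comparison over expanded chromosomes, restricted
    to columns without missing data (the complete-deletion rule)."""
    chroms = []
    for ind in aln.individuals:
        pairs = [expand_iupac(ch) for ch in ind.sequence]
        chroms.append([p[0] if p else None for p in pairs])
        chroms.append([p[1] if p else None for p in pairs])
    valid = [
        j for j in range(aln.length)
        if all(c[j] is not None for c in chroms)
    ]
    n = len(chroms)
    total = sum(
        sum(a[j] != b[j] for j in valid) for a, b in combinations(chroms, 2)
    )
    return total / (n * (n - 1) / 2) / aln.length


class TestPi:
    def test_monomorphic_is_zero(self):
        aln = make_alignment(["AAAA", "AAAA"])
        assert pi(site_columns(aln), 4) == 0.0

    def test_single_column_examples(self):
        # n=4 counts {A:2, G:2}: 4 of 6 chromosome pairs differ -> 2/3
        assert pi(site_columns(make_alignment(["A", "G"])), 1) == pytest.approx(2 / 3)
        # n=4 counts {A:3, G:1}: 3 of 6 pairs differ -> 1/2
        assert pi(site_columns(make_alignment(["A", "R"])), 1) == pytest.approx(1 / 2)

    @given(
        st.lists(
            st.text(alphabet="ACGTRYSWKMN", min_size=6, max_size=6),
            min_size=2,
            max_size=4,
        )
    )
    @settings(deadline=None, max_examples=60)
    def test_matches_pairwise_oracle(self, seqs):
        aln = make_alignment(seqs)
        assert pi(site_columns(aln), aln.length) == pytest.approx(brute_force_pi(aln))

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError):
            pi([], 0)


def fraction_tajima_constants(n: int) -> dict[str, Fraction]:
    """Exact-rational re-derivation of the Tajima normalization, written
    independently of the float implementation."""
    a1 = sum((Fraction(1, i) for i in range(1, n)), Fraction(0))
    a2 = sum((Fraction(1, i * i) for i in range(1, n)), Fraction(0))
    b1 = Fraction(n + 1, 3 * (n - 1))
    b2 = Fraction(2 * (n * n + n + 3), 9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - Fraction(n + 2, n) / a1 + a2 / a1**2
    return {"e1": c1 / a1, "e2": c2 / (a1**2 + a2), "a1": a1}


class TestTajimasD:
    @pytest.mark.parametrize("n", [4, 8, 16, 32])
    def test_constants_match_exact_rederivation(self, n):
        got = tajima_constants(n)
        exact = fraction_tajima_constants(n)
        for key in ("a1", "e1", "e2"):
            assert got[key] == pytest.approx(float(exact[key]), rel=1e-12)

    def test_zero_numerator_gives_zero(self):
        c = tajima_constants(10)
        assert tajimas_d(5 / c["a1"], 5, 10) == pytest.approx(0.0)

    def test_hand_derived_value(self):
        # n=4, S=1, k_bar=2/3: D = (2/3 - 6/11) / sqrt(e1) ~= 1.633
        assert tajimas_d(2 / 3, 1, 4) == pytest.approx(1.633, abs=0.001)

    def test_undefined_when_no_segregating_sites(self):
        assert tajimas_d(0.0, 0, 10) is None


class TestFoldedSfs:
    def test_counts_conserved(self):
        macs = [1, 1, 2, 5, 8, 8, 8]
        sfs = folded_sfs(macs, 16)
        assert sfs.sum() == len(macs)

    def test_all_singletons_land_in_lt01(self):
        sfs = folded_sfs([1] * 10, 32)
        assert bin_sfs_by_maf(sfs, 32) == {"lt01": 10, "01to02": 0, "gt02": 0}

    def test_fold_is_mirror_invariant(self):
        rng = np.random.default_rng(0)
        w = np.concatenate([[0], rng.random(9)])  # unfolded, n=10
        assert np.allclose(fold(w), fold(np.concatenate([[0], w[1:][::-1]])))

    def test_expected_wf_example(self):
        # n=4, S=11: folded weights 4/3 (singleton) and 1/2 (doubleton) -> 8:3
        exp = expected_wf_folded_sfs(4, 11)
        assert exp[1] == pytest.approx(8.0)
        assert exp[2] == pytest.approx(3.0)

    def test_expected_wf_n2_all_singletons(self):
        exp = expected_wf_folded_sfs(2, 7)
        assert exp[1] == pytest.approx(7.0)

    def test_expected_wf_zero_snps(self):
        assert expected_wf_folded_sfs(8, 0).sum() == 0

    @pytest.mark.parametrize(
        "maf,cls", [(0.05, "lt01"), (0.1, "01to02"), (0.2, "01to02"), (0.21, "gt02"), (0.5, "gt02")]
    )
    def test_maf_class_boundaries(self, maf, cls):
        assert maf_class(maf) == cls


class TestFst:
    def test_complete_differentiation(self):
        counts = np.array([[10, 0], [0, 10]])
        assert fst_weir_cockerham(counts) == pytest.approx(1.0)

    def test_identical_populations_nonpositive(self):
        counts = np.array([[5, 5], [5, 5]])
        assert fst_weir_cockerham(counts) <= 0

    def test_one_monomorphic_population_allowed(self):
        counts = np.array([[10, 0], [5, 5]])
        assert np.isfinite(fst_weir_cockerham(counts))

    def test_single_population_rejected(self):
        with pytest.raises(ValueError, match="two populations"):
            fst_weir_cockerham(np.array([[5, 5]]))

    def test_panmictic_mean_near_zero(self, rng):
        """Per-SNP theta-hat over many panmictic draws averages ~0."""
        vals = []
        for _ in range(2000):
            p = rng.uniform(0.1, 0.9)
            counts = rng.binomial(8, p, size=4)
            arr = np.stack([counts, 8 - counts], axis=1)
            if 0 < counts.sum() < 32:
                vals.append(fst_weir_cockerham(arr))
        mean = np.mean(vals)
        se = np.std(vals) / np.sqrt(len(vals))
        assert abs(mean) < 4 * se + 0.005


class TestPooling:
    def _summary(self, locus_id, S, sites, n=16):
        aln = make_alignment(["A" * 10] * (n // 2), locus_id=locus_id,
                             annotation=make_annotation(10, introns=((0, 10),), locus_id=locus_id))
        summ = analyze_locus(aln)
        summ.S = dict(summ.S, noncoding=S, silent=S, all=S)
        summ.sites = dict(summ.sites, noncoding=sites, silent=sites, all=sites)
        return summ

    def test_single_locus_equals_own_theta(self):
        s = self._summary("a", 3, 100.0)
        pooled, mean = pooled_category_theta([s], "noncoding")
        assert pooled == pytest.approx(s.theta_w("noncoding"))
        assert mean == pytest.approx(pooled)

    def test_two_identical_loci_invariant(self):
        s1, s2 = self._summary("a", 3, 100.0), self._summary("b", 3, 100.0)
        pooled, _ = pooled_category_theta([s1, s2], "noncoding")
        assert pooled == pytest.approx(s1.theta_w("noncoding"))

    def test_scale_invariance(self):
        base, _ = pooled_category_theta([self._summary("a", 3, 100.0)], "noncoding")
        doubled, _ = pooled_category_theta([self._summary("a", 6, 200.0)], "noncoding")
        assert doubled == pytest.approx(base)

    def test_empty_category_rejected(self):
        s = self._summary("a", 0, 0.0)
        with pytest.raises(ValueError, match="no sites"):
            pooled_category_theta([s], "noncoding")


class TestAnalyzeLocus:
    def test_snp_record_fields(self):
        # one SNP, minor G carried once (heterozygote in ind2 of pop2)
        seqs = ["AAAA", "ARAA", "AAAA", "AAAA"]
        aln = make_alignment(seqs, pops=["p1", "p1", "p2", "p2"])
        summ = analyze_locus(aln, {"p1": "Atlantic", "p2": "Mediterranean"})
        assert summ.S["noncoding"] == 1
        (snp,) = summ.snps
        assert (snp.major, snp.minor, snp.mac, snp.n) == ("A", "G", 1, 8)
        assert snp.singleton and snp.frequency_class == "01to02"  # MAF 1/8
        assert not snp.shared_between_populations
        assert not snp.shared_between_basins({"p1": "Atlantic", "p2": "Mediterranean"})

    def test_shared_snp_flags(self):
        seqs = ["AR", "AA", "AR", "AA"]  # minor G segregates in both pops
        aln = make_alignment(seqs, pops=["p1", "p1", "p2", "p2"])
        summ = analyze_locus(aln, {"p1": "Atlantic", "p2": "Mediterranean"})
        (snp,) = summ.snps
        assert snp.shared_between_populations
        assert snp.shared_between_basins({"p1": "Atlantic", "p2": "Mediterranean"})

    def test_coding_snp_classification(self):
        # codon GGA/GGG at third position: synonymous
        ann = make_annotation(3, coding=((0, 3),))
        aln = make_alignment(["GGA", "GGR"], annotation=ann)
        summ = analyze_locus(aln)
        assert summ.S["syn"] == 1 and summ.S["nonsyn"] == 0
        assert summ.sites["syn"] + summ.sites["nonsyn"] == pytest.approx(3.0)

    def test_single_individual_rejected(self):
        aln = make_alignment(["ACGT"])
        with pytest.raises(ValueError, match="fewer than two"):
            analyze_locus(aln)

    def test_triallelic_counted_but_not_recorded(self):
        aln = make_alignment(["AA", "RA", "YA", "AA"])
        summ = analyze_locus(aln)
        assert summ.S["noncoding"] == 1
        assert summ.n_triallelic == 1
        assert summ.snps == []
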