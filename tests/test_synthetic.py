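"""Synthetic-data generator: sampled spectra, genealogies, truth consistency.

The Kingman genealogy engine is cross-checked against msprime (an independent
coalescent implementation) on segregating-site and Tajima's D distributions.
"""

from __future__ import annotations

import filecmp
from pathlib import Path

import numpy as np
import pytest
from scipy import integrate, stats
from scipy.special import comb

from polyload.diversity import analyze_locus, harmonic_number
from polyload.pipeline import analyze_dataset
from polyload.synthetic import (
    SimulationConfig,
    _genealogy_branches,
    fold_weights,
    neutral_sfs_weights,
    selected_sfs_weights,
    simulate_category_sfs,
    simulate_dataset,
    simulate_psi_mode_sfs,
    write_simulated_dataset,
)


class TestSelectedSfsWeights:
    def test_neutral_limit_is_one_over_i(self):
        w = selected_sfs_weights(0.0, 10)
        assert np.allclose(w, 1.0 / np.arange(1, 10))

    def test_matches_independent_quadrature(self):
        """Adaptive scipy.integrate.quad as an independent oracle."""
        gamma, n = -5.0, 10

        def density(q):
            return (1 - np.exp(-2 * gamma * (1 - q))) / ((1 - np.exp(-2 * gamma)) * q * (1 - q))

        for i in range(1, n):
            oracle, _ = integrate.quad(
                lambda q: density(q) * comb(n, i) * q**i * (1 - q) ** (n - i), 0, 1
            )
            assert selected_sfs_weights(gamma, n)[i - 1] == pytest.approx(oracle, rel=1e-6)

    def test_singleton_mass_grows_with_selection_strength(self):
        fractions = []
        for gamma in (0.0, -1.0, -3.0, -10.0, -30.0):
            w = selected_sfs_weights(gamma, 12)
            fractions.append(w[0] / w.sum())
        assert all(b > a for a, b in zip(fractions, fractions[1:]))
        assert fractions[-1] > 0.9

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            selected_sfs_weights(float("nan"), 10)
        with pytest.raises(ValueError, match="insufficient sample"):
            selected_sfs_weights(-5.0, 1)

    def test_fold_weights_neutral(self):
        folded = fold_weights(neutral_sfs_weights(4))
        assert np.allclose(folded, [1 + 1 / 3, 1 / 2])


class TestConfigValidation:
    def test_dfe_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            SimulationConfig(dfe=(0.5, 0.5, 0.5))

    def test_psi_range(self):
        with pytest.raises(ValueError, match="psi"):
            SimulationConfig(psi=1.0)


class TestGenealogy:
    def test_branch_structure(self, rng):
        masks, lengths = _genealogy_branches(8, rng)
        assert masks.shape[1] == 8
        assert (lengths > 0).all()
        sizes = masks.sum(axis=1)
        assert sizes.min() >= 1 and sizes.max() <= 7  # the root has no branch
        assert (sizes == 1).sum() == 8  # every leaf has an external branch

    def test_total_length_expectation(self, rng):
        n = 16
        totals = [_genealogy_branches(n, rng)[1].sum() for _ in range(400)]
        expected = 2 * harmonic_number(n)
        se = np.std(totals) / np.sqrt(len(totals))
        assert abs(np.mean(totals) - expected) < 4 * se

    def test_matches_msprime_kingman(self, rng):
        """S and Tajima's D distributions agree with an independent
        coalescent simulator at matched units."""
        msprime = pytest.importorskip("msprime")
        n, theta, reps = 10, 8.0, 300
        ours_S, ours_D = [], []
        for _ in range(reps):
            masks, lengths = _genealogy_branches(n, rng)
            S = rng.poisson(theta / 2 * lengths.sum())
            ours_S.append(S)
            if S:
                sizes = masks[rng.choice(len(lengths), S, p=lengths / lengths.sum())].sum(axis=1)
                k_bar = float((sizes * (n - sizes)).sum() / (n * (n - 1) / 2))
                from polyload.diversity import tajimas_d

                d = tajimas_d(k_bar, int(S), n)
                if d is not None:
                    ours_D.append(d)
        msp_S, msp_D = [], []
        for rep in range(reps):
            ts = msprime.sim_ancestry(samples=n, ploidy=1, population_size=1, random_seed=rep + 1)
            mts = msprime.sim_mutations(ts, rate=theta / 2, random_seed=rep + 1000, discrete_genome=False)
            msp_S.append(mts.num_sites)
            d = mts.Tajimas_D()
            if mts.num_sites and np.isfinite(d):
                msp_D.append(float(d))
        se = np.sqrt(np.var(ours_S) / reps + np.var(msp_S) / reps)
        assert abs(np.mean(ours_S) - np.mean(msp_S)) < 4 * se
        assert stats.ks_2samp(ours_D, msp_D).pvalue > 0.005


class TestCategorySfs:
    def test_f2_one_gives_no_nonsyn(self):
        cfg = SimulationConfig(dfe=(0.0, 0.0, 1.0), seed=3)
        sfs, _ = simulate_category_sfs(cfg)
        assert sfs.nonsyn.sum() == 0

    def test_fully_neutral_spectra_indistinguishable(self, rng):
        """With f0 = 1 and equal site totals the nonsynonymous and silent
        3-class spectra are homogeneous (chi-square, alpha = 0.01) in >= 95%
        of batches."""
        passes = 0
        n_batches = 20
        for b in range(n_batches):
            cfg = SimulationConfig(
                dfe=(1.0, 0.0, 0.0), n_loci=60,
                nonsyn_sites_per_locus=380.0, seed=1000 + b,
            )
            sfs, _ = simulate_category_sfs(cfg)
            mac = np.arange(1, len(sfs.silent) + 1)
            maf = mac / sfs.n
            bins = [maf < 0.1, (maf >= 0.1) & (maf <= 0.2), maf > 0.2]
            table = np.array(
                [[sfs.silent[m].sum() for m in bins], [sfs.nonsyn[m].sum() for m in bins]]
            )
            if stats.chi2_contingency(table).pvalue > 0.01:
                passes += 1
        assert passes >= 0.95 * n_batches

    def test_dfe_recovery_matches_spectral_prediction(self):
        """The full ratio-ladder estimator recovers the DFE up to the exact,
        independently computed spectral leakage of the weak class into the
        common-MAF bin: E[f0_hat] = f0 + leak * f1, E[f1_hat] = f1 * (1 -
        leak), E[f2_hat] = f2."""
        f0, f1, f2 = 0.25, 0.35, 0.40
        gamma = -5.0
        n = 32  # chromosomes: 2 x 16 diploid individuals, as configured below
        w_sel = fold_weights(selected_sfs_weights(gamma, n))
        w_neu = fold_weights(neutral_sfs_weights(n))
        mac = np.arange(1, n // 2 + 1)
        common = mac / n > 0.2
        leak = (w_sel[common].sum() / w_sel.sum()) / (w_neu[common].sum() / w_neu.sum())
        est = []
        for rep in range(200):
            cfg = SimulationConfig(dfe=(f0, f1, f2), gamma_weak=gamma, n_loci=200, seed=5000 + rep)
            sfs, _ = simulate_category_sfs(cfg)
            r = sfs.estimate_ratios()
            est.append((r["gt02"], r["all"] - r["gt02"], 1 - r["all"]))
        mean = np.mean(est, axis=0)
        assert mean[0] == pytest.approx(f0 + leak * f1, abs=0.012)
        assert mean[1] == pytest.approx(f1 * (1 - leak), abs=0.012)
        assert mean[2] == pytest.approx(f2, abs=0.012)


class TestLocusLevel:
    def test_fixed_seed_byte_identical(self, tmp_path):
        cfg = SimulationConfig(n_loci=4, seed=11)
        for sub in ("a", "b"):
            ds, truth = simulate_dataset(cfg)
            write_simulated_dataset(ds, truth, tmp_path / sub)
        files = sorted(p.name for p in (tmp_path / "a").iterdir())
        match, mismatch, errors = filecmp.cmpfiles(tmp_path / "a", tmp_path / "b", files, shallow=False)
        assert mismatch == [] and errors == []

    @pytest.mark.parametrize("seed", [2, 3])
    def test_truth_reconciles_with_alignments(self, seed):
        """Recounting segregating sites from the emitted alignments matches
        the generator's truth record exactly, per category and position."""
        ds, truth = simulate_dataset(SimulationConfig(n_loci=6, seed=seed))
        for aln, tl in zip(ds.loci, truth.per_locus):
            summ = analyze_locus(aln, ds.basins)
            counts = tl["counts"]
            assert summ.S["silent"] == counts["silent"]
            assert summ.S["nonsyn"] == counts["nonsyn_neutral"] + counts["nonsyn_weak"]
            got_positions = sorted(s.position + 1 for s in summ.snps)
            assert got_positions == sorted(m["position"] for m in tl["mutations"])

    def test_watterson_expectation_on_noncoding_loci(self, rng):
        """Mean segregating-site count over replicate neutral loci sits
        within 4 SE of theta * a_n * L."""
        cfg = SimulationConfig(
            n_loci=150, coding_length_range=(0, 0), intron_probability=1.0,
            intron_length_range=(1000, 1000), utr_length_range=(0, 0),
            missing_individual_prob=0.0, dfe=(1.0, 0.0, 0.0), seed=21,
        )
        ds, truth = simulate_dataset(cfg)
        S = [tl["counts"]["silent"] for tl in truth.per_locus]
        expected = cfg.theta_silent * harmonic_number(32) * 1000
        se = np.std(S) / np.sqrt(len(S))
        assert abs(np.mean(S) - expected) < 4 * se

    def test_heterozygotes_encoded_as_iupac(self):
        ds, truth = simulate_dataset(SimulationConfig(n_loci=2, seed=5))
        ambiguous = set("RYSWKM")
        seen_het = any(
            ch in ambiguous for aln in ds.loci for ind in aln.individuals for ch in ind.sequence
        )
        assert seen_het  # polymorphic data must contain heterozygous calls


class TestPsiMode:
    def test_reproducible_with_seed(self):
        cfg = SimulationConfig(reproduction_model="psi", psi=0.3, seed=9)
        sfs1, d1 = simulate_psi_mode_sfs(cfg, n_replicates=50, n_chromosomes=16)
        sfs2, d2 = simulate_psi_mode_sfs(cfg, n_replicates=50, n_chromosomes=16)
        assert np.array_equal(sfs1, sfs2) and np.array_equal(d1, d2)

    def test_skewed_reproduction_drives_d_negative(self):
        cfg = SimulationConfig(reproduction_model="psi", psi=0.3, seed=17)
        _, d = simulate_psi_mode_sfs(cfg, n_replicates=150, n_chromosomes=20)
        assert np.mean(d) < 0

    def test_psi_zero_recovers_kingman(self):
        cfg0 = SimulationConfig(reproduction_model="psi", psi=0.0, seed=23)
        cfgk = SimulationConfig(reproduction_model="kingman", seed=29)
        _, d0 = simulate_psi_mode_sfs(cfg0, n_replicates=250, n_chromosomes=16)
        _, dk = simulate_psi_mode_sfs(cfgk, n_replicates=250, n_chromosomes=16)
        assert stats.ks_2samp(d0, dk).pvalue > 0.005
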