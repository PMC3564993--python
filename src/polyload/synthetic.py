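"""Synthetic multilocus diploid resequencing datasets with a known truth.

Two generation levels share one configuration:

* :func:`simulate_category_sfs` draws per-category folded site-frequency
  spectra directly (independent sites) — the right null for estimator and
  goodness-of-fit tests;
* :func:`simulate_dataset` builds full locus alignments: a neutral coalescent
  genealogy per locus (Kingman, or an optional psi multiple-merger mode
  emulating sweepstakes reproduction), infinite-sites mutations placed on
  branches at class-appropriate rates, chromosomes paired into diploid
  consensus sequences with IUPAC heterozygote codes, plus GFF3 annotations, a
  populations table and a manifest — exactly the input formats of the
  analysis pipeline.

Nonsynonymous mutations follow a three-class distribution of fitness effects:
a fraction ``f0`` behaves neutrally, ``f1`` is weakly selected (its sampled
frequencies follow the Poisson-random-field spectrum for a scaled selection
coefficient ``gamma_weak``, giving the low-frequency excess), and ``f2`` is
strongly deleterious and never sampled.  Silent mutations (synonymous +
noncoding) are neutral throughout.

All randomness flows from one seeded generator; draw order is fixed, so
outputs are byte-stable across runs.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.special import gammaln

from .io_model import (
    BASES,
    CodingSegment,
    Dataset,
    Individual,
    LocusAlignment,
    LocusAnnotation,
    Segment,
    encode_iupac,
    write_annotation_gff3,
    write_locus_alignment,
)
from .diversity import harmonic_number, tajimas_d
from . import site_classification as sc

log = logging.getLogger(__name__)


@dataclass
class SimulationConfig:
    """Study-shaped simulation parameters.

    Defaults emulate the survey structure the pipeline targets: 35 nuclear
    loci resequenced in 16 diploid individuals from 4 populations (two per
    basin), EST-amplicon coding lengths, introns in roughly two thirds of
    loci, silent diversity of 0.007/site, and a (0.23, 0.33, 0.44) DFE with
    weak selection gamma = -5 for the intermediate class.
    """

    n_loci: int = 35
    n_populations: int = 4
    individuals_per_population: int = 4
    missing_individual_prob: float = 0.1
    theta_silent: float = 0.007
    dfe: tuple[float, float, float] = (0.23, 0.33, 0.44)
    gamma_weak: float = -5.0
    coding_length_range: tuple[int, int] = (150, 660)  # rounded down to codons
    intron_probability: float = 23.0 / 37.0
    intron_length_range: tuple[int, int] = (92, 600)
    utr_length_range: tuple[int, int] = (0, 120)
    reproduction_model: str = "kingman"  # 'kingman' | 'psi'
    psi: float = 0.0
    psi_event_rate: float = 1.0
    n_mitochondrial_loci: int = 0
    genetic_code_id: int = 1
    # SFS-level site totals (per locus); locus-level sims derive their own
    silent_sites_per_locus: float = 380.0
    nonsyn_sites_per_locus: float = 310.0
    seed: int = 0

    def __post_init__(self) -> None:
        f0, f1, f2 = self.dfe
        if min(f0, f1, f2) < 0 or abs(f0 + f1 + f2 - 1.0) > 1e-9:
            raise ValueError(f"DFE fractions {self.dfe} must be non-negative and sum to 1")
        if self.theta_silent <= 0:
            raise ValueError("theta_silent must be positive")
        if not 0 <= self.psi < 1:
            raise ValueError(f"psi {self.psi} outside [0, 1)")
        if self.reproduction_model not in ("kingman", "psi"):
            raise ValueError(f"unknown reproduction model {self.reproduction_model!r}")

    @property
    def n_individuals(self) -> int:
        return self.n_populations * self.individuals_per_population


@dataclass
class SyntheticTruth:
    """Ground truth written alongside generated data for recovery tests."""

    dfe: tuple[float, float, float]
    theta_silent: float
    gamma_weak: float
    per_locus: list[dict] = field(default_factory=list)

    @property
    def totals(self) -> dict[str, int]:
        keys = ("silent", "nonsyn_neutral", "nonsyn_weak")
        return {k: sum(p["counts"][k] for p in self.per_locus) for k in keys}

    def to_json(self) -> str:
        return json.dumps(
            {
                "dfe": list(self.dfe),
                "theta_silent": self.theta_silent,
                "gamma_weak": self.gamma_weak,
                "totals": self.totals,
                "per_locus": self.per_locus,
            },
            indent=2,
            sort_keys=True,
        )


# ---------------------------------------------------------------------------
# Sampled frequency spectra
# ---------------------------------------------------------------------------


def neutral_sfs_weights(n: int) -> np.ndarray:
    """Unfolded neutral weights 1/i for derived counts i = 1..n-1."""
    return 1.0 / np.arange(1, n)


def _sojourn_ratio(a: float, one_minus_q: np.ndarray) -> np.ndarray:
    """expm1(a*(1-q)) / expm1(a) evaluated stably (a = -2*gamma > 0 for
    deleterious mutations; the neutral limit is handled by the caller)."""
    if a > 700.0:  # expm1 overflows; the ratio collapses to exp(-a*q)
        return np.exp(-a * (1.0 - one_minus_q))
    return np.expm1(a * one_minus_q) / np.expm1(a)


def selected_sfs_weights(gamma: float, n: int, quad_points: int = 256, _check: bool = True) -> np.ndarray:
    """Expected sampled-frequency weights under genic selection.

    For a scaled selection coefficient ``gamma`` (negative = deleterious) the
    population-frequency density of segregating mutations is proportional to
    ``(1 - exp(-2*gamma*(1-q))) / ((1 - exp(-2*gamma)) * q * (1-q))``;
    binomial sampling of n chromosomes gives weight
    ``w_i = integral_0^1 density(q) * C(n, i) * q^i * (1-q)^(n-i) dq``
    for derived counts i = 1..n-1, evaluated by Gauss-Legendre quadrature.
    ``gamma = 0`` reduces exactly to the neutral 1/i.

    The quadrature is checked by doubling the node count; disagreement beyond
    1e-8 relative raises with diagnostics.
    """
    if n < 2:
        raise ValueError(f"insufficient sample: n={n} < 2")
    if not math.isfinite(gamma):
        raise ValueError("gamma must be finite")
    if abs(gamma) < 1e-12:
        return neutral_sfs_weights(n)

    def compute(points: int) -> np.ndarray:
        nodes, wts = np.polynomial.legendre.leggauss(points)
        q = 0.5 * (nodes + 1.0)  # map [-1,1] -> [0,1]
        wts = 0.5 * wts
        a = -2.0 * gamma
        dens = _sojourn_ratio(a, 1.0 - q) / (q * (1.0 - q))
        i = np.arange(1, n)[:, None]
        log_binom = gammaln(n + 1) - gammaln(i + 1) - gammaln(n - i + 1)
        log_kernel = log_binom + i * np.log(q)[None, :] + (n - i) * np.log1p(-q)[None, :]
        return (np.exp(log_kernel) * (dens * wts)[None, :]).sum(axis=1)

    w = compute(quad_points)
    if _check:
        w2 = compute(2 * quad_points)
        rel = np.max(np.abs(w - w2) / np.maximum(np.abs(w2), 1e-300))
        if rel > 1e-8:
            raise RuntimeError(
                f"selected_sfs_weights quadrature not converged: rel. change {rel:.3e} "
                f"between {quad_points} and {2 * quad_points} nodes (gamma={gamma}, n={n})"
            )
    return w


def fold_weights(unfolded: np.ndarray) -> np.ndarray:
    """Fold unfolded weights over derived counts 1..n-1 into minor counts
    1..floor(n/2); returns an array indexed from minor count 1 at position 0."""
    n = len(unfolded) + 1
    folded = np.zeros(n // 2)
    for i in range(1, n):
        folded[min(i, n - i) - 1] += unfolded[i - 1]
    if n % 2 == 0:
        folded[n // 2 - 1] = unfolded[n // 2 - 1]
    return folded


# ---------------------------------------------------------------------------
# Genealogies
# ---------------------------------------------------------------------------


def _genealogy_branches(
    n: int,
    rng: np.random.Generator,
    model: str = "kingman",
    psi: float = 0.0,
    psi_event_rate: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate one genealogy of n chromosomes; return (masks, lengths).

    ``masks`` is a boolean (branches, n) array marking the leaves below each
    branch; ``lengths`` holds branch lengths in units of 2N generations.
    Binary mergers occur at the Kingman rate k*(k-1)/2.  In psi mode an
    additional event class occurs at rate ``psi_event_rate``; at such an
    event every active lineage independently joins the merger with
    probability ``psi`` (events engaging fewer than two lineages change
    nothing, so psi = 0 recovers the Kingman process exactly).
    """
    lineages = [np.eye(n, dtype=bool)[i] for i in range(n)]
    births = [0.0] * n
    t = 0.0
    masks: list[np.ndarray] = []
    lengths: list[float] = []
    use_psi = model == "psi" and psi > 0
    while len(lineages) > 1:
        k = len(lineages)
        rate_binary = k * (k - 1) / 2.0
        rate_psi = psi_event_rate if (model == "psi" and k >= 2) else 0.0
        t += rng.exponential(1.0 / (rate_binary + rate_psi))
        if rate_psi and rng.random() < rate_psi / (rate_binary + rate_psi):
            take = np.nonzero(rng.random(k) < psi)[0]
            if len(take) < 2:
                continue
        else:
            take = rng.choice(k, size=2, replace=False)
        take = sorted(int(i) for i in take)
        merged = np.zeros(n, dtype=bool)
        for i in take:
            masks.append(lineages[i])
            lengths.append(t - births[i])
            merged |= lineages[i]
        for i in reversed(take):
            del lineages[i]
            del births[i]
        lineages.append(merged)
        births.append(t)
    return np.array(masks), np.array(lengths)


def _drop_mutations(
    masks: np.ndarray,
    lengths: np.ndarray,
    n_mutations: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Assign mutations to branches proportional to length; returns the
    (n_mutations, n) carrier masks."""
    if n_mutations == 0:
        return np.zeros((0, masks.shape[1]), dtype=bool)
    probs = lengths / lengths.sum()
    branch = rng.choice(len(lengths), size=n_mutations, p=probs)
    return masks[branch]


# ---------------------------------------------------------------------------
# SFS-level generator
# ---------------------------------------------------------------------------


@dataclass
class CategorySfs:
    """Folded spectra per category from the independent-sites generator."""

    n: int
    silent_sites: float
    nonsyn_sites: float
    silent: np.ndarray  # folded counts, index 0 = minor count 1
    nonsyn: np.ndarray

    def estimate_ratios(self) -> dict[str, float | None]:
        """The frequency-stratified ratio ladder computed directly from the
        spectra (site denominators unrestricted, as in the pipeline)."""
        mac = np.arange(1, len(self.silent) + 1)
        maf = mac / self.n
        subsets = {
            "all": np.ones_like(maf, dtype=bool),
            "no_singleton": mac > 1,
            "gt01": maf > 0.1,
            "gt02": maf > 0.2,
        }
        out: dict[str, float | None] = {}
        for name, mask in subsets.items():
            s_si = float(self.silent[mask].sum())
            s_n = float(self.nonsyn[mask].sum())
            out[name] = (s_n / self.nonsyn_sites) / (s_si / self.silent_sites) if s_si > 0 else None
        return out


def simulate_category_sfs(config: SimulationConfig, rng: np.random.Generator | None = None) -> tuple[CategorySfs, SyntheticTruth]:
    """Draw folded per-category spectra for one dataset, sites independent.

    Silent SNP count ~ Poisson(theta * a_n * L_si) with neutral frequencies;
    nonsynonymous mutations split into the DFE classes: the f0 share is
    neutral (with the nonsynonymous site total as denominator), the f1 share
    draws frequencies from the weak-selection spectrum, and the f2 share
    contributes nothing.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = 2 * config.n_individuals
    a_n = harmonic_number(n)
    L_si = config.silent_sites_per_locus * config.n_loci
    L_n = config.nonsyn_sites_per_locus * config.n_loci
    f0, f1, f2 = config.dfe

    w_neutral = fold_weights(neutral_sfs_weights(n))
    p_neutral = w_neutral / w_neutral.sum()
    w_weak = fold_weights(selected_sfs_weights(config.gamma_weak, n))
    p_weak = w_weak / w_weak.sum()

    s_si = rng.poisson(config.theta_silent * a_n * L_si)
    s_n0 = rng.poisson(f0 * config.theta_silent * a_n * L_n)
    s_n1 = rng.poisson(f1 * config.theta_silent * a_n * L_n)

    silent = rng.multinomial(s_si, p_neutral)
    nonsyn = rng.multinomial(s_n0, p_neutral) + rng.multinomial(s_n1, p_weak)
    truth = SyntheticTruth(
        dfe=config.dfe,
        theta_silent=config.theta_silent,
        gamma_weak=config.gamma_weak,
        per_locus=[{"locus_id": "SFS", "counts": {"silent": int(s_si), "nonsyn_neutral": int(s_n0), "nonsyn_weak": int(s_n1)}}],
    )
    return CategorySfs(n=n, silent_sites=L_si, nonsyn_sites=L_n, silent=silent, nonsyn=nonsyn), truth


# ---------------------------------------------------------------------------
# Locus-level generator
# ---------------------------------------------------------------------------


def _random_coding_sequence(n_codons: int, rng: np.random.Generator, code: dict[str, str]) -> str:
    """Random sense codons (no stops)."""
    sense = sorted(c for c, aa in code.items() if aa != "*")
    idx = rng.integers(0, len(sense), size=n_codons)
    return "".join(sense[i] for i in idx)


def _locus_structure(config: SimulationConfig, rng: np.random.Generator) -> tuple[int, int, int, int]:
    """Draw (utr5, coding, intron, utr3) lengths; coding is a codon multiple."""
    lo, hi = config.coding_length_range
    coding = 3 * int(rng.integers(lo // 3, hi // 3 + 1))
    intron = 0
    if rng.random() < config.intron_probability:
        ilo, ihi = config.intron_length_range
        intron = int(rng.integers(ilo, ihi + 1))
    ulo, uhi = config.utr_length_range
    utr = int(rng.integers(ulo, uhi + 1))
    return utr // 2, coding, intron, utr - utr // 2


def _coding_change_pools(ref_codons: list[str], code: dict[str, str]) -> tuple[list, list, int]:
    """Enumerate all single-base changes of the reference coding sequence.

    Returns (synonymous, nonsynonymous, n_nonsense): lists of (codon_index,
    within_pos, alt_base) plus the count of stop-creating changes.  Each
    change carries 1/3 of a site; nonsense changes count towards the
    nonsynonymous mutation opportunity but are kept out of the placeable
    pool (a fixed-in-the-sample premature stop would invalidate its whole
    codon), so the missense changes absorb their rate.
    """
    syn, nonsyn = [], []
    n_nonsense = 0
    for k, codon in enumerate(ref_codons):
        aa = code[codon]
        for j in range(3):
            for b in BASES:
                if b == codon[j]:
                    continue
                alt = codon[:j] + b + codon[j + 1 :]
                alt_aa = code[alt]
                if alt_aa == aa:
                    syn.append((k, j, b))
                elif alt_aa == "*":
                    n_nonsense += 1
                else:
                    nonsyn.append((k, j, b))
    return syn, nonsyn, n_nonsense


def simulate_locus_alignment(
    config: SimulationConfig,
    rng: np.random.Generator,
    locus_id: str,
    individuals: Sequence[tuple[str, str]],
    mitochondrial: bool = False,
) -> tuple[LocusAlignment, dict]:
    """Simulate one locus: genealogy, mutations, diploid IUPAC consensus.

    *individuals* is the full (individual_id, population_id) panel; each is
    present with probability 1 - missing_individual_prob (at least two are
    always kept).  Chromosome-to-individual pairing is random (leaves of the
    genealogy are exchangeable and additionally shuffled).  At most one
    mutation is placed per codon, so effect labels recovered from the
    alignment match the truth exactly.
    """
    code = sc.genetic_code(config.genetic_code_id)
    utr5, coding_len, intron_len, utr3 = _locus_structure(config, rng)
    if mitochondrial:
        utr5, coding_len, intron_len, utr3 = 0, coding_len, 0, 0
    # layout: [5'UTR][CDS-a][intron][CDS-b][3'UTR], intron on a codon boundary
    n_codons = coding_len // 3
    split = 3 * int(rng.integers(1, n_codons)) if (intron_len and n_codons > 1) else coding_len
    length = utr5 + coding_len + intron_len + utr3

    ref = np.empty(length, dtype="<U1")
    noncoding_pos = (
        list(range(utr5))
        + list(range(utr5 + split, utr5 + split + intron_len))
        + list(range(length - utr3, length))
    )
    for p in noncoding_pos:
        ref[p] = BASES[rng.integers(0, 4)]
    ref_codons = [
        _random_coding_sequence(1, rng, code) for _ in range(n_codons)
    ]
    coding_pos: list[int] = list(range(utr5, utr5 + split)) + list(
        range(utr5 + split + intron_len, utr5 + split + intron_len + coding_len - split)
    )
    for k in range(n_codons):
        for j in range(3):
            ref[coding_pos[3 * k + j]] = ref_codons[k][j]

    # sampled panel
    present = [iv for iv in individuals if rng.random() >= config.missing_individual_prob]
    while len(present) < 2:
        present = [iv for iv in individuals if rng.random() >= config.missing_individual_prob]
    m = len(present)
    n = 2 * m

    masks, lengths = _genealogy_branches(
        n, rng, model=config.reproduction_model, psi=config.psi, psi_event_rate=config.psi_event_rate
    )
    total_len = lengths.sum()

    syn_pool, nonsyn_pool, n_nonsense = _coding_change_pools(ref_codons, code)
    syn_sites = len(syn_pool) / 3.0
    nonsyn_sites = (len(nonsyn_pool) + n_nonsense) / 3.0  # NG86 opportunity
    L_silent = len(noncoding_pos) + syn_sites
    f0, f1, f2 = config.dfe
    theta = config.theta_silent

    # expected counts: theta/2 per site per unit branch length
    n_silent = rng.poisson(theta / 2.0 * L_silent * total_len)
    n_n0 = rng.poisson(f0 * theta / 2.0 * nonsyn_sites * total_len)
    # weak-selection candidates are oversampled, then thinned by the ratio of
    # the selected to the neutral sampled spectrum, so accepted mutations
    # both follow the selected spectrum and keep the f1 influx rate
    w_sel = selected_sfs_weights(config.gamma_weak, n, _check=False)
    w_neu = neutral_sfs_weights(n)
    accept = (w_sel / w_neu) / np.max(w_sel / w_neu)
    mean_accept = float((w_neu * accept).sum() / w_neu.sum())
    n_n1_candidates = rng.poisson(f1 * theta / 2.0 * nonsyn_sites * total_len / mean_accept)

    used_codons: set[int] = set()
    used_noncoding: set[int] = set()
    mutations: list[dict] = []  # position, alt, carriers, category

    def place_silent() -> None:
        # a silent mutation hits a noncoding base or a synonymous coding
        # change in proportion to their site counts
        p_noncoding = len(noncoding_pos) / L_silent if L_silent > 0 else 0.0
        if rng.random() < p_noncoding:
            if len(used_noncoding) >= len(noncoding_pos):
                return
            while True:
                p = noncoding_pos[rng.integers(0, len(noncoding_pos))]
                if p not in used_noncoding:
                    break
            used_noncoding.add(p)
            alt = BASES[(BASES.index(ref[p]) + 1 + rng.integers(0, 3)) % 4]
            mutations.append({"position": int(p), "alt": alt, "category": "silent"})
        else:
            if not syn_pool:
                return
            k, j, b = syn_pool[rng.integers(0, len(syn_pool))]
            if k in used_codons:
                return  # infinite-codons: silently thinned (rare)
            used_codons.add(k)
            mutations.append({"position": int(coding_pos[3 * k + j]), "alt": b, "category": "silent"})

    def place_nonsyn(category: str) -> bool:
        if not nonsyn_pool:
            return False
        k, j, b = nonsyn_pool[rng.integers(0, len(nonsyn_pool))]
        if k in used_codons:
            return False
        used_codons.add(k)
        mutations.append({"position": int(coding_pos[3 * k + j]), "alt": b, "category": category})
        return True

    for _ in range(n_silent):
        place_silent()
    for _ in range(n_n0):
        place_nonsyn("nonsyn_neutral")

    carriers = _drop_mutations(masks, lengths, len(mutations), rng)
    for mut, carr in zip(mutations, carriers):
        mut["carriers"] = carr

    # weak-selection candidates: drop on the tree, thin on realized frequency
    cand_carriers = _drop_mutations(masks, lengths, n_n1_candidates, rng)
    for carr in cand_carriers:
        i = int(carr.sum())
        if rng.random() >= accept[i - 1]:
            continue
        if not nonsyn_pool:
            continue
        k, j, b = nonsyn_pool[rng.integers(0, len(nonsyn_pool))]
        if k in used_codons:
            continue
        used_codons.add(k)
        mutations.append(
            {"position": int(coding_pos[3 * k + j]), "alt": b, "category": "nonsyn_weak", "carriers": carr}
        )

    # build chromosomes and pair them into diploids
    chrom = np.tile(ref, (n, 1))
    for mut in mutations:
        chrom[mut["carriers"], mut["position"]] = mut["alt"]
    perm = rng.permutation(n)
    inds = []
    for j, (ind_id, pop_id) in enumerate(present):
        c1, c2 = chrom[perm[2 * j]], chrom[perm[2 * j + 1]]
        seq = "".join(encode_iupac(a, b) for a, b in zip(c1, c2))
        inds.append(Individual(ind_id, pop_id, seq))

    coding_segments = []
    if split > 0:
        coding_segments.append(CodingSegment(utr5, utr5 + split, "+", 0))
    if coding_len - split > 0:
        coding_segments.append(
            CodingSegment(utr5 + split + intron_len, utr5 + split + intron_len + coding_len - split, "+", 0)
        )
    annotation = LocusAnnotation(
        locus_id=locus_id,
        length=length,
        coding_segments=coding_segments,
        intron_segments=[Segment(utr5 + split, utr5 + split + intron_len)] if intron_len else [],
        utr_segments=(
            ([Segment(0, utr5)] if utr5 else []) + ([Segment(length - utr3, length)] if utr3 else [])
        ),
        genome="mitochondrial" if mitochondrial else "nuclear",
        genetic_code_id=config.genetic_code_id,
    )
    aln = LocusAlignment(locus_id, inds, length, annotation)

    counts = {"silent": 0, "nonsyn_neutral": 0, "nonsyn_weak": 0}
    mut_rows = []
    for mut in mutations:
        i = int(mut["carriers"].sum())
        if 0 < i < n:  # segregating in the sample (always true for tree branches)
            counts[mut["category"]] += 1
            mut_rows.append(
                {"position": int(mut["position"]) + 1, "category": mut["category"], "derived_count": i}
            )
    truth_locus = {
        "locus_id": locus_id,
        "n_individuals": m,
        "length": length,
        "silent_sites": L_silent,
        "nonsyn_sites": nonsyn_sites,
        "counts": counts,
        "mutations": sorted(mut_rows, key=lambda r: r["position"]),
    }
    return aln, truth_locus


def simulate_dataset(config: SimulationConfig) -> tuple[Dataset, SyntheticTruth]:
    """Simulate a full in-memory dataset under one seeded generator."""
    rng = np.random.default_rng(config.seed)
    pops = [f"pop{i + 1}" for i in range(config.n_populations)]
    basin_of = {p: ("Atlantic" if i < config.n_populations / 2 else "Mediterranean") for i, p in enumerate(pops)}
    panel = [
        (f"ind{p[3:]}_{j + 1}", p)
        for p in pops
        for j in range(config.individuals_per_population)
    ]
    truth = SyntheticTruth(dfe=config.dfe, theta_silent=config.theta_silent, gamma_weak=config.gamma_weak)
    loci = []
    for i in range(config.n_loci):
        aln, tl = simulate_locus_alignment(config, rng, f"locus{i + 1:03d}", panel)
        loci.append(aln)
        truth.per_locus.append(tl)
    for i in range(config.n_mitochondrial_loci):
        aln, tl = simulate_locus_alignment(config, rng, f"mt_locus{i + 1:03d}", panel, mitochondrial=True)
        loci.append(aln)
        truth.per_locus.append(tl)
    return Dataset(loci, basin_of), truth


def write_simulated_dataset(dataset: Dataset, truth: SyntheticTruth, outdir: str | Path) -> Path:
    """Write a simulated dataset in the pipeline's input formats.

    Emits one FASTA and one GFF3 per locus, ``populations.tsv``,
    ``manifest.tsv`` and ``truth.json``; returns the manifest path.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for aln in dataset.loci:
        fasta = f"{aln.locus_id}.fa"
        gff = f"{aln.locus_id}.gff3"
        write_locus_alignment(aln, outdir / fasta)
        write_annotation_gff3(aln.annotation, outdir / gff)
        rows.append((aln.locus_id, fasta, gff, aln.annotation.genome))
    with open(outdir / "manifest.tsv", "w") as fh:
        fh.write("locus_id\tfasta\tgff\tgenome\n")
        for r in rows:
            fh.write("\t".join(r) + "\n")
    seen = {}
    for aln in dataset.loci:
        for ind in aln.individuals:
            seen[ind.individual_id] = ind.population_id
    with open(outdir / "populations.tsv", "w") as fh:
        fh.write("individual_id\tpopulation_id\tbasin\n")
        for ind_id in sorted(seen):
            pop = seen[ind_id]
            fh.write(f"{ind_id}\t{pop}\t{dataset.basins.get(pop, '')}\n")
    (outdir / "truth.json").write_text(truth.to_json())
    return outdir / "manifest.tsv"


# ---------------------------------------------------------------------------
# psi-mode spectra and Tajima's D samples
# ---------------------------------------------------------------------------


def simulate_psi_mode_sfs(
    config: SimulationConfig,
    n_replicates: int = 500,
    n_chromosomes: int = 32,
    theta_locus: float = 10.0,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Neutral single-locus replicates under the configured reproduction
    model; returns (pooled folded SFS, per-replicate Tajima's D sample).

    Under sweepstakes-like multiple mergers the genealogy becomes star-like
    and Tajima's D is negative at steady state; psi = 0 recovers the Kingman
    distribution.  Replicates without segregating sites yield no D value.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = n_chromosomes
    sfs = np.zeros(n // 2 + 1, dtype=np.int64)
    ds = []
    for _ in range(n_replicates):
        masks, lengths = _genealogy_branches(
            n, rng, model=config.reproduction_model, psi=config.psi, psi_event_rate=config.psi_event_rate
        )
        S = rng.poisson(theta_locus / 2.0 * lengths.sum())
        carriers = _drop_mutations(masks, lengths, S, rng)
        sizes = carriers.sum(axis=1)
        for i in sizes:
            sfs[min(int(i), n - int(i))] += 1
        if S > 0:
            k_bar = float((sizes * (n - sizes)).sum() / (n * (n - 1) / 2))
            d = tajimas_d(k_bar, int(S), n)
            if d is not None:
                ds.append(d)
    return sfs, np.array(ds)
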