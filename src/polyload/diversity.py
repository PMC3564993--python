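"""Diversity estimators, frequency classes, SFS and per-SNP differentiation.

Per locus and per site category (synonymous, nonsynonymous, noncoding, silent
= synonymous + noncoding, all) this module computes the number of segregating
sites S, Nei's nucleotide diversity pi (unbiased per-site heterozygosity),
Watterson's theta_W = S / (a_n * L), and Tajima's D on silent sites; it builds
one record per biallelic SNP carrying the minor-allele frequency, its
frequency class, sharedness between populations and basins, and the
Weir-Cockerham F_ST estimate; and it provides the folded site-frequency
spectrum together with its neutral Wright-Fisher expectation.

All statistics are frequency-based: a diploid individual contributes two
chromosomes and no within-individual phase or Hardy-Weinberg assumption is
made anywhere.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io_model import (
    BASES,
    CODING,
    NONCODING,
    UNANNOTATED,
    Dataset,
    LocusAlignment,
    SiteColumn,
)
from . import site_classification as sc

log = logging.getLogger(__name__)

CATEGORIES = ("syn", "nonsyn", "noncoding", "silent", "all")

#: minor-allele-frequency class labels; boundaries: lt01 = MAF < 0.1,
#: 01to02 = 0.1 <= MAF <= 0.2 (closed), gt02 = MAF > 0.2.
MAF_CLASSES = ("lt01", "01to02", "gt02")


def harmonic_number(n: int) -> float:
    """a_n = sum_{i=1}^{n-1} 1/i (the Watterson denominator)."""
    return float(sum(1.0 / i for i in range(1, n)))


def watterson_theta(S: int, n: int, L: float) -> float:
    """Watterson's per-site theta, S / (a_n * L)."""
    if n < 2:
        raise ValueError(f"insufficient sample: n={n} < 2")
    if L <= 0:
        raise ValueError("L must be positive")
    if S < 0:
        raise ValueError("S must be non-negative")
    return S / (harmonic_number(n) * L)


def _ssh_from_counts(counts: np.ndarray) -> np.ndarray:
    """Unbiased per-site heterozygosity n/(n-1) * (1 - sum p^2) per column."""
    counts = np.asarray(counts, dtype=float)
    n = counts.sum(axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        h = n / (n - 1) * (1.0 - (counts**2).sum(axis=-1) / n**2)
    return np.where(n > 1, h, 0.0)


def pi(columns: Sequence[SiteColumn], L: float) -> float:
    """Nucleotide diversity per site over valid columns.

    pi = (1/L) * sum_sites n/(n-1) * (1 - sum_a p_a^2), the unbiased mean
    pairwise difference; invalid columns contribute nothing.
    """
    if L <= 0:
        raise ValueError("L must be positive")
    total = 0.0
    for col in columns:
        if col.category == "invalid":
            continue
        counts = np.zeros(4)
        for pair in col.pairs:
            if pair is None:
                continue
            for a in pair:
                counts[BASES.index(a)] += 1
        if counts.sum() >= 2:
            total += float(_ssh_from_counts(counts))
    return total / L


def tajima_constants(n: int) -> dict[str, float]:
    """Tajima (1989) normalization constants for sample size n."""
    if n < 2:
        raise ValueError(f"insufficient sample: n={n} < 2")
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def tajimas_d(k_bar: float, S: int, n: int) -> float | None:
    """Tajima's D from the mean pairwise differences k_bar (total, not per
    site), the number of segregating sites S, and the sample size n.

    Undefined (``None``) when S = 0; never silently reported as zero.
    """
    if S == 0:
        return None
    c = tajima_constants(n)
    var = c["e1"] * S + c["e2"] * S * (S - 1)
    if var <= 0:
        return None
    return (k_bar - S / c["a1"]) / math.sqrt(var)


def maf_class(maf: float) -> str:
    if not 0 < maf <= 0.5:
        raise ValueError(f"MAF {maf} outside (0, 0.5]")
    if maf < 0.1:
        return "lt01"
    if maf <= 0.2:
        return "01to02"
    return "gt02"


# ---------------------------------------------------------------------------
# SNP records
# ---------------------------------------------------------------------------


@dataclass
class SnpRecord:
    """One biallelic variant (ancestral state unknown: major/minor alleles)."""

    locus_id: str
    position: int  # 0-based; reports add 1
    major: str
    minor: str
    effect: str  # synonymous | nonsynonymous | noncoding
    n: int  # total chromosomes at this locus
    n_individuals: int
    mac: int  # minor allele count, >= 1
    pop_minor_counts: dict[str, int] = field(default_factory=dict)
    pop_chromosomes: dict[str, int] = field(default_factory=dict)
    fst: float | None = None

    @property
    def maf(self) -> float:
        return self.mac / self.n

    @property
    def frequency_class(self) -> str:
        return maf_class(self.maf)

    @property
    def singleton(self) -> bool:
        return self.mac == 1

    @property
    def shared_between_populations(self) -> bool:
        return sum(c > 0 for c in self.pop_minor_counts.values()) >= 2

    def shared_between_basins(self, basins: dict[str, str]) -> bool:
        present = {basins.get(p) for p, c in self.pop_minor_counts.items() if c > 0}
        present.discard(None)
        return len(present) >= 2


def fst_weir_cockerham(pop_counts: np.ndarray) -> float:
    """Weir & Cockerham (1984) theta-hat for one SNP from per-population
    chromosome-level allele counts (shape: populations x alleles).

    Chromosomes are the sampling unit (two per diploid individual), so there
    is no within-individual heterozygosity component.  Monomorphic
    populations are allowed; the estimate may be negative.  Raises for fewer
    than two populations with data.
    """
    counts = np.asarray(pop_counts, dtype=float)
    ni = counts.sum(axis=1)
    keep = ni > 0
    counts, ni = counts[keep], ni[keep]
    r = len(ni)
    if r < 2:
        raise ValueError("F_ST needs at least two populations with data")
    N = ni.sum()
    n_c = (N - (ni**2).sum() / N) / (r - 1)
    p = counts / ni[:, None]
    p_bar = counts.sum(axis=0) / N
    msp = (ni[:, None] * (p - p_bar) ** 2).sum(axis=0) / (r - 1)
    denom_g = (ni - 1).sum()
    if denom_g <= 0:
        return float("nan")
    msg = (ni[:, None] * p * (1 - p)).sum(axis=0) / denom_g
    num = (msp - msg).sum()
    den = (msp + (n_c - 1) * msg).sum()
    if den == 0:
        return float("nan")
    return float(num / den)


# ---------------------------------------------------------------------------
# Folded SFS
# ---------------------------------------------------------------------------


def folded_sfs(minor_counts: Iterable[int], n: int) -> np.ndarray:
    """Counts per minor-allele-count class 1..floor(n/2) (index 0 unused)."""
    sfs = np.zeros(n // 2 + 1, dtype=np.int64)
    for mac in minor_counts:
        if not 1 <= mac <= n // 2:
            raise ValueError(f"minor count {mac} outside 1..{n // 2} for n={n}")
        sfs[mac] += 1
    return sfs


def fold(unfolded: np.ndarray) -> np.ndarray:
    """Fold an unfolded spectrum indexed 1..n-1 (index 0 unused)."""
    n = len(unfolded)
    folded = np.zeros(n // 2 + 1, dtype=unfolded.dtype)
    for i in range(1, n):
        folded[min(i, n - i)] += unfolded[i]
    # a class that is its own mirror (i = n - i) was added twice
    if n % 2 == 0:
        folded[n // 2] = unfolded[n // 2]
    return folded


def expected_wf_folded_sfs(n: int, S: float) -> np.ndarray:
    """Expected folded SFS under the neutral Wright-Fisher model.

    The unfolded expectation is proportional to 1/i for derived count i;
    minor-count class i receives (1/i + 1/(n-i)) / (1 + [i == n-i]),
    normalized so the classes sum to S.  Indexed 1..floor(n/2), index 0
    unused.
    """
    if n < 2:
        raise ValueError(f"insufficient sample: n={n} < 2")
    weights = np.zeros(n // 2 + 1)
    for i in range(1, n // 2 + 1):
        weights[i] = (1.0 / i + 1.0 / (n - i)) / (2.0 if i == n - i else 1.0)
    total = weights.sum()
    return weights * (S / total) if total > 0 else weights


def bin_sfs_by_maf(sfs: np.ndarray, n: int) -> dict[str, float]:
    """Collapse a folded spectrum (indexed by minor count) into the three
    minor-allele-frequency classes."""
    out = {c: 0.0 for c in MAF_CLASSES}
    for i in range(1, len(sfs)):
        if sfs[i]:
            out[maf_class(i / n)] += float(sfs[i])
    return out


# ---------------------------------------------------------------------------
# Per-locus analysis
# ---------------------------------------------------------------------------


@dataclass
class LocusSummary:
    """Everything computed from one locus alignment."""

    locus_id: str
    genome: str
    n_individuals: int
    n: int  # chromosomes
    a_n: float
    length: int
    sites: dict[str, float]  # per CATEGORIES
    S: dict[str, int]
    pi_num: dict[str, float]  # sum of per-site heterozygosities (k_bar per category)
    enc: float | None
    gc3: float | None
    snps: list[SnpRecord]
    n_triallelic: int
    n_stop_codons: int
    n_incomplete_codons: int

    def pi_per_site(self, category: str) -> float | None:
        L = self.sites[category]
        return self.pi_num[category] / L if L > 0 else None

    def theta_w(self, category: str) -> float | None:
        L = self.sites[category]
        return self.S[category] / (self.a_n * L) if L > 0 else None

    def tajima_d_silent(self) -> float | None:
        if self.sites["silent"] <= 0:
            return None
        return tajimas_d(self.pi_num["silent"], self.S["silent"], self.n)


def _allele_counts(geno: np.ndarray) -> np.ndarray:
    L = geno.shape[0]
    flat = geno.reshape(L, -1)
    counts = np.zeros((L, 4), dtype=np.int64)
    for a in range(4):
        counts[:, a] = (flat == a).sum(axis=1)
    return counts


def _top_two_alleles(col_counts: np.ndarray) -> tuple[int, int]:
    """(major, minor) allele indices; count ties break alphabetically, the
    smaller base becoming the major allele."""
    order = sorted(range(4), key=lambda a: (-col_counts[a], a))
    return order[0], order[1]


def analyze_locus(alignment: LocusAlignment, basins: dict[str, str] | None = None) -> LocusSummary:
    """Classify and summarize one locus.

    Raises ``ValueError`` for alignments with fewer than two individuals (no
    pairwise comparisons possible).
    """
    ann = alignment.annotation
    geno = alignment.genotypes()
    L, m, _ = geno.shape
    if m < 2:
        raise ValueError(f"{alignment.locus_id}: fewer than two individuals")
    n = 2 * m
    counts = _allele_counts(geno)
    missing_any = (geno < 0).any(axis=(1, 2))
    cat = ann.category_codes()
    valid = ~missing_any & (cat != UNANNOTATED)
    view = sc.build_codon_view(alignment, valid)
    stat_valid = view.stat_valid

    syn_sites = nonsyn_sites = 0.0
    for codon in view.consensus:
        if codon is not None:
            s, ns = sc.ng86_site_counts(codon, ann.genetic_code_id)
            syn_sites += s
            nonsyn_sites += ns
    noncoding_sites = int((stat_valid & (cat == NONCODING)).sum())

    ssh = _ssh_from_counts(counts)
    n_alleles = (counts > 0).sum(axis=1)
    segregating = stat_valid & (n_alleles >= 2)

    code_id = ann.genetic_code_id
    comp = sc._COMP
    seg_positions = np.nonzero(segregating)[0]
    seg_set = set(int(p) for p in seg_positions)
    effects: dict[int, str] = {}
    for p in seg_positions:
        p = int(p)
        if cat[p] == NONCODING:
            effects[p] = sc.NONCODING_EFFECT
            continue
        k, j = view.pos_to_codon[p]
        codon = view.consensus[k]
        assert codon is not None
        a_maj, a_min = _top_two_alleles(counts[p])
        pair = (BASES[a_maj], BASES[a_min])
        if view.strand == "-":
            pair = (comp[pair[0]], comp[pair[1]])
        context: list = list(codon)
        for j2 in range(3):
            if j2 == j:
                continue
            p2 = int(view.codon_positions[k][j2])
            if p2 in seg_set:  # double-hit codon: average over pathways
                b_maj, b_min = _top_two_alleles(counts[p2])
                bases2 = (BASES[b_maj], BASES[b_min])
                if view.strand == "-":
                    bases2 = (comp[bases2[0]], comp[bases2[1]])
                context[j2] = bases2
        effects[p] = sc.classify_variant(tuple(context), j, pair, code_id)

    S = {c: 0 for c in CATEGORIES}
    pi_num = {c: 0.0 for c in CATEGORIES}
    cat_of_effect = {sc.SYNONYMOUS: "syn", sc.NONSYNONYMOUS: "nonsyn", sc.NONCODING_EFFECT: "noncoding"}
    for p, eff in effects.items():
        c = cat_of_effect[eff]
        S[c] += 1
        pi_num[c] += float(ssh[p])
    S["silent"] = S["syn"] + S["noncoding"]
    S["all"] = S["syn"] + S["nonsyn"] + S["noncoding"]
    pi_num["silent"] = pi_num["syn"] + pi_num["noncoding"]
    pi_num["all"] = pi_num["syn"] + pi_num["nonsyn"] + pi_num["noncoding"]

    sites = {
        "syn": syn_sites,
        "nonsyn": nonsyn_sites,
        "noncoding": float(noncoding_sites),
        "silent": syn_sites + noncoding_sites,
        "all": syn_sites + nonsyn_sites + noncoding_sites,
    }

    # SNP records: biallelic columns only (tri-allelic counted in S, flagged)
    pops = sorted({ind.population_id for ind in alignment.individuals})
    pop_members = {p: [j for j, ind in enumerate(alignment.individuals) if ind.population_id == p] for p in pops}
    snps: list[SnpRecord] = []
    n_tri = 0
    for p in seg_positions:
        p = int(p)
        if n_alleles[p] > 2:
            n_tri += 1
            log.warning("%s: tri-allelic column at position %d excluded from SNP records",
                        alignment.locus_id, p + 1)
            continue
        a_maj, a_min = _top_two_alleles(counts[p])
        pop_minor: dict[str, int] = {}
        pop_chrom: dict[str, int] = {}
        pop_rows = []
        for pop in pops:
            sub = geno[p, pop_members[pop], :].ravel()
            pop_chrom[pop] = int(sub.size)
            pop_minor[pop] = int((sub == a_min).sum())
            pop_rows.append([pop_minor[pop], int((sub == a_maj).sum())])
        try:
            fst = fst_weir_cockerham(np.array(pop_rows))
        except ValueError:
            fst = None
        snps.append(
            SnpRecord(
                locus_id=alignment.locus_id,
                position=p,
                major=BASES[a_maj],
                minor=BASES[a_min],
                effect=effects[p],
                n=n,
                n_individuals=m,
                mac=int(counts[p, a_min]),
                pop_minor_counts=pop_minor,
                pop_chromosomes=pop_chrom,
                fst=fst,
            )
        )

    coding_seq = sc.consensus_coding_sequence(alignment, view)
    enc_val = gc3_val = None
    if coding_seq:
        try:
            enc_val = sc.enc(coding_seq, code_id)
        except ValueError:
            enc_val = None
        gc3_val = sc.gc3(coding_seq)

    return LocusSummary(
        locus_id=alignment.locus_id,
        genome=ann.genome,
        n_individuals=m,
        n=n,
        a_n=harmonic_number(n),
        length=L,
        sites=sites,
        S=S,
        pi_num=pi_num,
        enc=enc_val,
        gc3=gc3_val,
        snps=snps,
        n_triallelic=n_tri,
        n_stop_codons=view.n_stop_codons,
        n_incomplete_codons=view.n_incomplete_codons,
    )


def build_snp_records(dataset: Dataset) -> tuple[list[SnpRecord], dict[str, float | None]]:
    """All SNP records of a dataset plus per-category SNP densities
    (sites per SNP, e.g. '1 SNP every X bp')."""
    summaries = [analyze_locus(aln, dataset.basins) for aln in dataset.loci]
    snps = [s for summ in summaries for s in summ.snps]
    densities: dict[str, float | None] = {}
    coding_sites = sum(s.sites["syn"] + s.sites["nonsyn"] for s in summaries)
    coding_S = sum(s.S["syn"] + s.S["nonsyn"] for s in summaries)
    nc_sites = sum(s.sites["noncoding"] for s in summaries)
    nc_S = sum(s.S["noncoding"] for s in summaries)
    densities["coding_bp_per_snp"] = coding_sites / coding_S if coding_S else None
    densities["noncoding_bp_per_snp"] = nc_sites / nc_S if nc_S else None
    return snps, densities


# ---------------------------------------------------------------------------
# Pooled summaries
# ---------------------------------------------------------------------------


def pooled_category_theta(summaries: Sequence[LocusSummary], category: str) -> tuple[float, float | None]:
    """(pooled, unweighted-mean) Watterson theta for a site category.

    Pooled: sum_loci S / sum_loci (a_n * sites), with the per-locus a_n (the
    headline estimate, propagated to the DFE chain).  The unweighted mean
    over loci with a defined estimate is reported for comparison.
    """
    num = sum(s.S[category] for s in summaries)
    den = sum(s.a_n * s.sites[category] for s in summaries)
    if den <= 0:
        raise ValueError(f"no sites in category {category!r}")
    per_locus = [s.theta_w(category) for s in summaries]
    per_locus = [v for v in per_locus if v is not None]
    mean = float(np.mean(per_locus)) if per_locus else None
    return num / den, mean


def pooled_category_pi(summaries: Sequence[LocusSummary], category: str) -> tuple[float, float | None]:
    """(site-weighted pooled, unweighted-mean) nucleotide diversity."""
    num = sum(s.pi_num[category] for s in summaries)
    den = sum(s.sites[category] for s in summaries)
    if den <= 0:
        raise ValueError(f"no sites in category {category!r}")
    per_locus = [s.pi_per_site(category) for s in summaries]
    per_locus = [v for v in per_locus if v is not None]
    mean = float(np.mean(per_locus)) if per_locus else None
    return num / den, mean


def diversity_table(summaries: Sequence[LocusSummary]) -> pd.DataFrame:
    """Long-format per-locus x category table plus pooled rows."""
    rows = []
    for s in summaries:
        for c in CATEGORIES:
            rows.append(
                {
                    "locus_id": s.locus_id,
                    "category": c,
                    "n": s.n,
                    "S": s.S[c],
                    "sites": s.sites[c],
                    "pi": s.pi_per_site(c),
                    "theta_w": s.theta_w(c),
                    "tajima_d": s.tajima_d_silent() if c == "silent" else None,
                }
            )
    for c in CATEGORIES:
        if sum(s.sites[c] for s in summaries) <= 0:
            continue
        theta_pooled, theta_mean = pooled_category_theta(summaries, c)
        pi_pooled, pi_mean = pooled_category_pi(summaries, c)
        rows.append(
            {
                "locus_id": "POOLED",
                "category": c,
                "n": None,
                "S": sum(s.S[c] for s in summaries),
                "sites": sum(s.sites[c] for s in summaries),
                "pi": pi_pooled,
                "theta_w": theta_pooled,
                "tajima_d": None,
                "pi_unweighted_mean": pi_mean,
                "theta_w_unweighted_mean": theta_mean,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Optional Tajima's D significance by conditional coalescent simulation
# ---------------------------------------------------------------------------


def tajima_d_pvalue(
    d_obs: float,
    n: int,
    S: int,
    n_replicates: int = 10_000,
    rng: np.random.Generator | None = None,
) -> float:
    """Two-sided p-value for Tajima's D by neutral coalescent simulation
    conditional on the sample size n and the observed S (mutations placed
    multinomially on branches of a Kingman genealogy)."""
    from .synthetic import _genealogy_branches  # local import to avoid a cycle

    if rng is None:
        rng = np.random.default_rng(0)
    hits = 0
    used = 0
    for _ in range(n_replicates):
        masks, lengths = _genealogy_branches(n, rng)
        probs = lengths / lengths.sum()
        muts = rng.multinomial(S, probs)
        sizes = masks.sum(axis=1)
        k_bar = float(sum(m * i * (n - i) for m, i in zip(muts, sizes)) / (n * (n - 1) / 2))
        d = tajimas_d(k_bar, S, n)
        if d is None:
            continue
        used += 1
        if abs(d) >= abs(d_obs):
            hits += 1
    return (hits + 1) / (used + 1) if used else 1.0
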