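"""Frequency-stratified theta ratios, the three-class DFE partition, and the
segregating-load extrapolation.

The core inference partitions amino-acid-changing mutations into three
fractions by comparing the nonsynonymous-to-silent Watterson theta ratio
R = theta_n / theta_si across SNP frequency classes:

* f0 (effectively neutral)   = R restricted to common SNPs, where slightly
  selected variants have been purged from the spectrum (the ratio converges);
* f2 (strongly deleterious)  = 1 - R over all SNPs, the nonsynonymous
  mutations missing from the sample relative to silent diversity;
* f1 (slightly selected)     = R_all - f0, the excess of low-frequency
  amino-acid variants.

The method assumes only that silent and nonsynonymous sites within a locus
share one genealogy (they are interspersed), not any particular population
model, so a skewed-offspring (multiple-merger) genealogy does not bias it.

The load chain then converts the fraction of non-neutral nonsynonymous SNPs
observed in the sample into a conservative per-individual count of
heterozygous non-neutral mutations (each non-neutral allele assumed present
exactly once in the sample) and extrapolates it to genome and genetic-map
scale.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

from .diversity import LocusSummary, SnpRecord

log = logging.getLogger(__name__)

#: the frequency-stratified ratio ladder (order matters: increasingly
#: stringent subsets, expected to decrease towards f0)
RATIO_SUBSETS = ("all", "no_singleton", "gt01", "gt02", "shared")


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass
class DfePartition:
    """(f0, f1, f2) partition of amino-acid mutations with provenance."""

    r_all: float
    r_common: float
    f0: float
    f1: float
    f2: float
    f0_source: str = "gt02"
    clamped: list[str] = field(default_factory=list)


def partition_dfe(r_all: float, r_common: float, f0_source: str = "gt02") -> DfePartition:
    """Partition amino-acid mutations from the all-SNP and common-SNP ratios.

    f0 = r_common, f1 = r_all - r_common, f2 = 1 - r_all.  Out-of-range
    values are clamped (f0 to [0, 1], f1 and f2 to >= 0) with a recorded
    warning; clamping events are reported, never silently renormalized, so
    f0 + f1 + f2 may differ from 1 after clamping.
    """
    if r_all < 0 or r_common < 0:
        raise ValueError("theta ratios must be non-negative")
    clamped = []
    f0 = r_common
    if f0 > 1:
        clamped.append(f"f0 clamped from {f0:.4f} to 1")
        f0 = 1.0
    f1 = r_all - f0
    if f1 < 0:
        clamped.append(f"f1 clamped from {f1:.4f} to 0")
        f1 = 0.0
    f2 = 1.0 - r_all
    if f2 < 0:
        clamped.append(f"f2 clamped from {f2:.4f} to 0")
        f2 = 0.0
    for msg in clamped:
        log.warning("DFE partition: %s", msg)
    return DfePartition(r_all, r_common, f0, f1, f2, f0_source, clamped)


def theta_ratio(
    snps: Sequence[SnpRecord],
    denom_nonsyn: float,
    denom_silent: float,
    predicate: Callable[[SnpRecord], bool] = lambda s: True,
) -> float:
    """Pooled theta_n / theta_si with the SNP numerators restricted by
    *predicate*.

    The site denominators (sum over loci of a_n * sites, per category) are
    never restricted: only S changes with the subset, so the ratio compares
    like-for-like theta estimates.  Raises when the subset holds no silent
    SNP (undefined ratio).
    """
    if denom_nonsyn <= 0 or denom_silent <= 0:
        raise ValueError("site denominators must be positive")
    s_n = sum(1 for s in snps if s.effect == "nonsynonymous" and predicate(s))
    s_si = sum(1 for s in snps if s.effect != "nonsynonymous" and predicate(s))
    if s_si == 0:
        raise ValueError("undefined ratio: no silent SNPs in subset")
    return (s_n / denom_nonsyn) / (s_si / denom_silent)


def ratio_denominators(summaries: Sequence[LocusSummary]) -> tuple[float, float]:
    """(sum a_n * nonsyn_sites, sum a_n * silent_sites) over retained loci."""
    denom_n = sum(s.a_n * s.sites["nonsyn"] for s in summaries)
    denom_si = sum(s.a_n * s.sites["silent"] for s in summaries)
    return denom_n, denom_si


def subset_predicate(name: str, basins: dict[str, str] | None = None) -> Callable[[SnpRecord], bool]:
    if name == "all":
        return lambda s: True
    if name == "no_singleton":
        return lambda s: not s.singleton
    if name == "gt01":
        return lambda s: s.maf > 0.1
    if name == "gt02":
        return lambda s: s.maf > 0.2
    if name == "shared":
        return lambda s: s.shared_between_populations
    if name == "shared_basins":
        b = basins or {}
        return lambda s: s.shared_between_basins(b)
    raise ValueError(f"unknown SNP subset {name!r}")


def ratio_table(
    snps: Sequence[SnpRecord],
    summaries: Sequence[LocusSummary],
    basins: dict[str, str] | None = None,
) -> dict[str, float | None]:
    """The frequency-stratified ratio ladder: R over all SNPs, without
    singletons, MAF > 0.1, MAF > 0.2 (common), and shared between
    populations.  Subsets without silent SNPs yield ``None``."""
    denom_n, denom_si = ratio_denominators(summaries)
    out: dict[str, float | None] = {}
    for name in RATIO_SUBSETS:
        try:
            out[name] = theta_ratio(snps, denom_n, denom_si, subset_predicate(name, basins))
        except ValueError:
            out[name] = None
    return out


def synonymous_only_ratio(snps: Sequence[SnpRecord], summaries: Sequence[LocusSummary]) -> float | None:
    """theta_n / theta_s with synonymous sites only (the stricter variant of
    the headline silent-based ratio; both are reported)."""
    denom_n = sum(s.a_n * s.sites["nonsyn"] for s in summaries)
    denom_s = sum(s.a_n * s.sites["syn"] for s in summaries)
    if denom_n <= 0 or denom_s <= 0:
        return None
    s_n = sum(1 for s in snps if s.effect == "nonsynonymous")
    s_s = sum(1 for s in snps if s.effect == "synonymous")
    if s_s == 0:
        return None
    return (s_n / denom_n) / (s_s / denom_s)


def expected_neutral_nonsyn(per_locus: Sequence[tuple[int, float, float]]) -> float:
    """Expected count of nonsynonymous SNPs were they all neutral.

    *per_locus* rows are (S_silent, silent_sites, nonsyn_sites); each locus
    contributes S_silent * nonsyn_sites / silent_sites.  Because silent and
    nonsynonymous sites of a locus share the same chromosomes, the a_n factor
    cancels within each locus.  Loci without silent sites are excluded with a
    warning.
    """
    total = 0.0
    for s_si, silent_sites, nonsyn_sites in per_locus:
        if silent_sites <= 0:
            log.warning("locus with zero silent sites excluded from expected-neutral count")
            continue
        total += s_si * nonsyn_sites / silent_sites
    return total


def load_in_sample(s_n_obs: int, s_n_exp: float, f0: float) -> tuple[int, int]:
    """Split observed nonsynonymous SNPs into expected-neutral and
    expected-non-neutral counts: neutral = round(f0 * S_n_exp), capped at
    the observed count."""
    if s_n_obs < 0 or s_n_exp < 0:
        raise ValueError("counts must be non-negative")
    if not 0 <= f0 <= 1:
        raise ValueError("f0 must lie in [0, 1]")
    neutral = min(_round_half_up(f0 * s_n_exp), s_n_obs)
    return neutral, s_n_obs - neutral


def per_individual_load(nonneutral_count: int, per_snp_individual_counts: Sequence[int]) -> float:
    """Conservative per-individual count of heterozygous non-neutral
    mutations.

    Assuming each non-neutral allele is present exactly once in the sample,
    a SNP observed among n_j sampled individuals is heterozygous in exactly
    one of them, so the expected per-individual load is sum_j 1/n_j.
    """
    if len(per_snp_individual_counts) != nonneutral_count:
        raise ValueError(
            f"expected {nonneutral_count} per-SNP sample sizes, got {len(per_snp_individual_counts)}"
        )
    if any(n <= 0 for n in per_snp_individual_counts):
        raise ValueError("per-SNP individual counts must be positive")
    return float(sum(1.0 / n for n in per_snp_individual_counts))


def attribute_nonneutral(snps: Sequence[SnpRecord], count: int) -> list[SnpRecord]:
    """Deterministically attribute the non-neutral count to the lowest-MAF
    nonsynonymous SNPs (ties by locus id, then position), consistent with the
    assumption that non-neutral alleles segregate at the lowest frequencies."""
    nonsyn = sorted(
        (s for s in snps if s.effect == "nonsynonymous"),
        key=lambda s: (s.maf, s.locus_id, s.position),
    )
    if count > len(nonsyn):
        raise ValueError(f"cannot attribute {count} non-neutral SNPs among {len(nonsyn)}")
    return nonsyn[:count]


@dataclass
class LoadEstimate:
    """The full segregating-load chain."""

    s_n_obs: int
    s_n_exp: float
    f0: float
    neutral_in_sample: int
    nonneutral_in_sample: int
    per_individual_het_load: float
    nonsyn_sites_survey: float
    genome_nonsyn_sites: float = 1e7
    map_length_cM: float = 575.0
    genome_load_diploid: float = 0.0
    genome_load_haploid: float = 0.0
    load_per_cM: float = 0.0


def genome_extrapolation(
    per_individual_load_value: float,
    nonsyn_sites_survey: float,
    genome_nonsyn_sites: float = 1e7,
    map_length_cM: float = 575.0,
) -> tuple[float, float, float]:
    """Scale the surveyed per-individual load to the genome and genetic map.

    Returns (diploid genome load, haploid genome load, load per cM):
    diploid = load * genome_nonsyn_sites / nonsyn_sites_survey, haploid is
    half of that, and the map density divides the haploid load by the map
    length in centimorgans.
    """
    if nonsyn_sites_survey <= 0 or genome_nonsyn_sites <= 0 or map_length_cM <= 0:
        raise ValueError("extrapolation inputs must be positive")
    if per_individual_load_value < 0:
        raise ValueError("load must be non-negative")
    diploid = per_individual_load_value * genome_nonsyn_sites / nonsyn_sites_survey
    haploid = diploid / 2.0
    return diploid, haploid, haploid / map_length_cM


def dfe_load_analysis(
    summaries: Sequence[LocusSummary],
    snps: Sequence[SnpRecord],
    basins: dict[str, str] | None = None,
    f0_source: str = "gt02",
    genome_nonsyn_sites: float = 1e7,
    map_length_cM: float = 575.0,
) -> tuple[DfePartition, LoadEstimate, dict[str, float | None]]:
    """The full inference on an analyzed dataset.

    f0 is taken from the common-SNP (MAF > 0.2) ratio by default, where the
    ratio ladder converges; ``f0_source='shared'`` uses the shared-SNP ratio
    instead.  The surveyed nonsynonymous site total comes from the
    retained-locus site counts and is reported explicitly because the genome
    extrapolation is directly sensitive to it.
    """
    ratios = ratio_table(snps, summaries, basins)
    r_all = ratios["all"]
    r_common = ratios["gt02"] if f0_source == "gt02" else ratios[f0_source]
    if r_all is None or r_common is None:
        raise ValueError("theta ratios undefined: no silent SNPs in a required subset")
    part = partition_dfe(r_all, r_common, f0_source)

    by_locus = {s.locus_id: s for s in summaries}
    per_locus_rows = [(s.S["silent"], s.sites["silent"], s.sites["nonsyn"]) for s in summaries]
    s_n_exp = expected_neutral_nonsyn(per_locus_rows)
    s_n_obs = sum(s.S["nonsyn"] for s in summaries)
    neutral, nonneutral = load_in_sample(s_n_obs, s_n_exp, part.f0)

    attributed = attribute_nonneutral(snps, min(nonneutral, sum(1 for s in snps if s.effect == "nonsynonymous")))
    load = per_individual_load(len(attributed), [s.n_individuals for s in attributed])

    survey = sum(s.sites["nonsyn"] for s in summaries)
    diploid, haploid, per_cm = genome_extrapolation(load, survey, genome_nonsyn_sites, map_length_cM)
    est = LoadEstimate(
        s_n_obs=s_n_obs,
        s_n_exp=s_n_exp,
        f0=part.f0,
        neutral_in_sample=neutral,
        nonneutral_in_sample=nonneutral,
        per_individual_het_load=load,
        nonsyn_sites_survey=survey,
        genome_nonsyn_sites=genome_nonsyn_sites,
        map_length_cM=map_length_cM,
        genome_load_diploid=diploid,
        genome_load_haploid=haploid,
        load_per_cM=per_cm,
    )
    return part, est, ratios
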