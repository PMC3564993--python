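"""Codon-aware site machinery.

Synonymous / nonsynonymous site counting follows the Nei-Gojobori (1986)
mutation-opportunity scheme: each of the nine single-base changes of a codon
contributes 1/3 of a site to the synonymous or the nonsynonymous pool
depending on whether it preserves the encoded amino acid.  Changes that create
a stop codon count as nonsynonymous.  Codon-usage bias is summarized by
Wright's (1990) effective number of codons (ENC) and by GC3, the G+C fraction
at third codon positions.

Site counting for polymorphism data uses, per codon column, the majority
(consensus) codon across sampled chromosomes, ties broken toward the
alphabetically smaller codon; the per-locus denominators of the per-category
diversity estimators come from these counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache
from itertools import product

import numpy as np
from Bio.Data import CodonTable

from .io_model import BASES, CODING, NONCODING, LocusAlignment

log = logging.getLogger(__name__)

SYNONYMOUS = "synonymous"
NONSYNONYMOUS = "nonsynonymous"
NONCODING_EFFECT = "noncoding"

EFFECT_CLASSES = (SYNONYMOUS, NONSYNONYMOUS, NONCODING_EFFECT)


@lru_cache(maxsize=None)
def genetic_code(genetic_code_id: int = 1) -> dict[str, str]:
    """Codon -> amino acid map for an NCBI translation table; stops are ``*``."""
    table = CodonTable.unambiguous_dna_by_id[genetic_code_id]
    code = dict(table.forward_table)
    for stop in table.stop_codons:
        code[stop] = "*"
    return code


def translate_codon(codon: str, genetic_code_id: int = 1) -> str:
    code = genetic_code(genetic_code_id)
    try:
        return code[codon.upper()]
    except KeyError:
        raise ValueError(f"ambiguous codon {codon!r}") from None


@lru_cache(maxsize=None)
def ng86_site_counts(codon: str, genetic_code_id: int = 1) -> tuple[float, float]:
    """Nei-Gojobori fractional (synonymous, nonsynonymous) site counts of a codon.

    Each of the nine single-base changes scores 1/3 synonymous if the amino
    acid is unchanged, else 1/3 nonsynonymous; changes to stop codons count as
    nonsynonymous.  The two fractions always sum to exactly 3.

    Raises ``ValueError`` for codons containing anything but A/C/G/T and for
    stop codons (the consensus-codon caller skips those).
    """
    codon = codon.upper()
    if len(codon) != 3 or any(b not in BASES for b in codon):
        raise ValueError(f"ambiguous codon {codon!r}")
    code = genetic_code(genetic_code_id)
    aa = code[codon]
    if aa == "*":
        raise ValueError(f"stop codon {codon!r} has no site counts")
    syn = 0
    for pos in range(3):
        for base in BASES:
            if base == codon[pos]:
                continue
            alt = codon[:pos] + base + codon[pos + 1 :]
            if code[alt] == aa:  # a change to a stop is never synonymous
                syn += 1
    return syn / 3.0, (9 - syn) / 3.0


def _is_synonymous_change(codon_a: str, codon_b: str, code: dict[str, str]) -> bool:
    """Synonymous iff both codons translate identically and neither is a stop.

    A mutational pathway through a stop codon counts as nonsynonymous.
    """
    aa, ab = code[codon_a], code[codon_b]
    return aa == ab and aa != "*"


CodonContext = tuple  # 3 entries: a base, or a tuple of candidate bases


def classify_variant(
    codon_context: CodonContext | None,
    within_codon_position: int | None,
    allele_pair: tuple[str, str],
    genetic_code_id: int = 1,
) -> str:
    """Effect class of one biallelic SNP.

    *codon_context* is the containing codon in translation orientation; each
    entry is either a single background base or, where a second site in the
    same codon also segregates, a tuple of its observed bases.  The effect is
    then averaged over the mutational pathways (all background combinations);
    pathways through stop codons count as nonsynonymous.  A mixed pathway
    average resolves to nonsynonymous (the conservative reading used
    throughout).  ``codon_context=None`` marks an intron/UTR position and
    returns ``noncoding``.

    The classification is symmetric in the two alleles.
    """
    if codon_context is None or within_codon_position is None:
        return NONCODING_EFFECT
    if within_codon_position not in (0, 1, 2):
        raise ValueError(f"bad within-codon position {within_codon_position!r}")
    code = genetic_code(genetic_code_id)
    a, b = (x.upper() for x in allele_pair)
    if a == b:
        raise ValueError("allele pair is monomorphic")
    options = []
    for j, entry in enumerate(codon_context):
        if j == within_codon_position:
            continue
        options.append(tuple(entry) if isinstance(entry, (tuple, list)) else (entry,))
    syn_votes = []
    for bg in product(*options):
        bg = list(bg)
        codon_a = "".join(bg[: within_codon_position]) + a + "".join(bg[within_codon_position:])
        codon_b = "".join(bg[: within_codon_position]) + b + "".join(bg[within_codon_position:])
        for c in (codon_a, codon_b):
            if any(x not in BASES for x in c):
                raise ValueError(f"ambiguous codon {c!r}")
        syn_votes.append(_is_synonymous_change(codon_a, codon_b, code))
    return SYNONYMOUS if all(syn_votes) else NONSYNONYMOUS


# ---------------------------------------------------------------------------
# Codon usage summaries
# ---------------------------------------------------------------------------


@lru_cache(maxsize=None)
def _codon_families(genetic_code_id: int) -> tuple[dict[str, str], dict[str, int]]:
    """aa -> codons grouping and aa -> degeneracy (family size), stops excluded."""
    code = genetic_code(genetic_code_id)
    fam: dict[str, list[str]] = {}
    for codon, aa in code.items():
        if aa != "*":
            fam.setdefault(aa, []).append(codon)
    codon2aa = {c: aa for aa, cs in fam.items() for c in cs}
    degeneracy = {aa: len(cs) for aa, cs in fam.items()}
    return codon2aa, degeneracy


def _codon_iter(coding_sequence: str):
    seq = coding_sequence.upper().replace("U", "T")
    if len(seq) < 3:
        raise ValueError("no complete codon in coding sequence")
    for i in range(0, len(seq) - len(seq) % 3, 3):
        yield seq[i : i + 3]


def enc(coding_sequence: str, genetic_code_id: int = 1, impute_missing: bool = True) -> float:
    """Wright's (1990) effective number of codons, clamped to [20, 61].

    For each amino-acid family with n >= 2 observed codons the codon
    homozygosity is estimated as ``F = (n * sum(p^2) - 1) / (n - 1)``;
    families with F <= 0 are unusable and skipped.  Per degeneracy class the
    family mean ``F_c`` enters ``ENC = n1 + sum_c k_c / F_c`` (n1 = number of
    single-codon amino acids, k_c = families in class c; for the standard code
    this is the familiar 2 + 9/F2 + 1/F3 + 5/F4 + 3/F6).  An empty 3-fold
    class is imputed as the mean of the 2- and 4-fold class values; any other
    empty class as the mean F over all usable families.
    """
    codon2aa, degeneracy = _codon_families(genetic_code_id)
    counts: dict[str, dict[str, int]] = {}
    for codon in _codon_iter(coding_sequence):
        if any(b not in BASES for b in codon):
            continue  # ambiguous codons carry no usage information
        aa = codon2aa.get(codon)
        if aa is None:
            continue  # stop codon (premature or terminal): skipped
        counts.setdefault(aa, {})
        counts[aa][codon] = counts[aa].get(codon, 0) + 1

    class_F: dict[int, list[float]] = {}
    for aa, deg in degeneracy.items():
        if deg < 2:
            continue
        cc = counts.get(aa)
        if not cc:
            continue
        n = sum(cc.values())
        if n < 2:
            continue
        p2 = sum((c / n) ** 2 for c in cc.values())
        f_hat = (n * p2 - 1) / (n - 1)
        if f_hat > 0:
            class_F.setdefault(deg, []).append(f_hat)

    class_sizes: dict[int, int] = {}
    n_single = 0
    for aa, deg in degeneracy.items():
        if deg < 2:
            n_single += 1
        else:
            class_sizes[deg] = class_sizes.get(deg, 0) + 1

    all_f = [f for fs in class_F.values() for f in fs]
    value = float(n_single)
    for deg, k in sorted(class_sizes.items()):
        fs = class_F.get(deg)
        if fs:
            f_bar = float(np.mean(fs))
        elif not impute_missing:
            raise ValueError(f"no usable {deg}-fold family and imputation disabled")
        elif deg == 3 and class_F.get(2) and class_F.get(4):
            f_bar = float((np.mean(class_F[2]) + np.mean(class_F[4])) / 2)
        elif all_f:
            f_bar = float(np.mean(all_f))
        else:
            raise ValueError("no usable codon family in any degeneracy class")
        value += k / f_bar
    return float(min(61.0, max(20.0, value)))


def gc3(coding_sequence: str) -> float:
    """G+C fraction at third codon positions of an in-frame coding sequence."""
    thirds = [codon[2] for codon in _codon_iter(coding_sequence)]
    if not thirds:
        raise ValueError("no complete codon in coding sequence")
    return sum(b in "GC" for b in thirds) / len(thirds)


# ---------------------------------------------------------------------------
# Per-locus consensus codon view and site counts
# ---------------------------------------------------------------------------


@dataclass
class SiteCounts:
    """Per-locus site denominators by category (NG86 fractional for coding)."""

    locus_id: str
    syn_sites: float
    nonsyn_sites: float
    noncoding_sites: int

    @property
    def silent_sites(self) -> float:
        return self.syn_sites + self.noncoding_sites

    @property
    def all_sites(self) -> float:
        return self.syn_sites + self.nonsyn_sites + self.noncoding_sites

    def __add__(self, other: "SiteCounts") -> "SiteCounts":
        return SiteCounts(
            self.locus_id,
            self.syn_sites + other.syn_sites,
            self.nonsyn_sites + other.nonsyn_sites,
            self.noncoding_sites + other.noncoding_sites,
        )


@dataclass
class CodonView:
    """Consensus-codon decomposition of a locus alignment.

    ``codon_positions[k]`` are the three plus-strand column indices of codon k
    in translation order; ``consensus[k]`` is its consensus codon (translation
    orientation) or ``None`` if the codon is unusable (a column is invalid, or
    the consensus codon is a stop).  Columns of unusable codons are excluded
    from all statistics so that syn + nonsyn sites remain exactly three times
    the number of usable codons.
    """

    codon_positions: np.ndarray  # (n_codons, 3)
    consensus: list[str | None]
    strand: str
    pos_to_codon: dict[int, tuple[int, int]]
    stat_valid: np.ndarray  # per-column usable-for-statistics mask
    n_stop_codons: int
    n_incomplete_codons: int


_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def build_codon_view(alignment: LocusAlignment, valid: np.ndarray) -> CodonView:
    """Resolve consensus codons over the valid columns of an alignment.

    *valid* is the per-column completeness mask (no missing calls, annotated).
    Consensus per column is the most frequent allele across chromosomes, ties
    broken toward the alphabetically smaller base.
    """
    ann = alignment.annotation
    geno = alignment.genotypes()
    counts = np.zeros((alignment.length, 4), dtype=np.int64)
    flat = geno.reshape(alignment.length, -1)
    for a in range(4):
        counts[:, a] = (flat == a).sum(axis=1)
    consensus_idx = counts.argmax(axis=1)  # first max -> alphabetical tie-break

    order = ann.coding_order()
    n_codons = len(order) // 3
    codon_positions = order[: 3 * n_codons].reshape(n_codons, 3)
    n_incomplete = 0  # codons dropped because a column is invalid
    n_stop = 0
    consensus: list[str | None] = []
    cat = ann.category_codes()
    stat_valid = valid.copy()
    code = genetic_code(ann.genetic_code_id)
    for k in range(n_codons):
        pos = codon_positions[k]
        if not valid[pos].all():
            consensus.append(None)
            n_incomplete += 1
            continue
        bases = [BASES[consensus_idx[p]] for p in pos]
        if ann.strand == "-":
            bases = [_COMP[b] for b in bases]
        codon = "".join(bases)
        if code[codon] == "*":
            consensus.append(None)
            n_stop += 1
            continue
        consensus.append(codon)
    # columns of coding codons that are unusable leave every statistic
    usable = np.zeros(alignment.length, dtype=bool)
    for k, cod in enumerate(consensus):
        if cod is not None:
            usable[codon_positions[k]] = True
    stat_valid &= np.where(cat == CODING, usable, True)
    pos_to_codon = {
        int(p): (k, j) for k in range(n_codons) for j, p in enumerate(codon_positions[k])
    }
    return CodonView(
        codon_positions=codon_positions,
        consensus=consensus,
        strand=ann.strand,
        pos_to_codon=pos_to_codon,
        stat_valid=stat_valid,
        n_stop_codons=n_stop,
        n_incomplete_codons=n_incomplete,
    )


def site_counts(alignment: LocusAlignment, valid: np.ndarray | None = None) -> SiteCounts:
    """NG86 site denominators of one locus over its usable columns."""
    if valid is None:
        geno = alignment.genotypes()
        missing = (geno < 0).any(axis=(1, 2))
        valid = ~missing & (alignment.annotation.category_codes() != -1)
    view = build_codon_view(alignment, valid)
    syn = nonsyn = 0.0
    for codon in view.consensus:
        if codon is not None:
            s, n = ng86_site_counts(codon, alignment.annotation.genetic_code_id)
            syn += s
            nonsyn += n
    cat = alignment.annotation.category_codes()
    noncoding = int((view.stat_valid & (cat == NONCODING)).sum())
    return SiteCounts(alignment.locus_id, syn, nonsyn, noncoding)


def consensus_coding_sequence(alignment: LocusAlignment, view: CodonView) -> str:
    """Concatenated usable consensus codons, translation orientation."""
    return "".join(c for c in view.consensus if c is not None)
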