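"""Input layer: aligned diploid consensus sequences, annotations, dataset filters.

Direct Sanger resequencing of diploid individuals produces one consensus
sequence per individual and locus, with heterozygous positions encoded as
IUPAC two-allele ambiguity codes (``R`` = A/G, ``Y`` = C/T, ...).  This module
parses per-locus FASTA alignments of such sequences, a light GFF3 annotation
subset (CDS / intron / UTR segments), and the individual-to-population table;
it exposes the internal genotype representation (one unordered allele pair per
individual per column) on which every statistic downstream operates, and the
dataset-level locus filters (mitochondrial exclusion, explicit exclusion
lists).

Conventions
-----------
* External coordinates are 1-based inclusive (GFF3); everything internal is
  0-based half-open.  Reported SNP positions are 1-based.
* Columns containing ``N`` or ``-`` in any retained individual are invalid and
  excluded from all statistics (complete deletion); sample size still varies
  across loci because whole individuals may be absent from an alignment.
* Minus-strand ORFs are reverse-complemented for codon work only; positions
  stay plus-strand.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger(__name__)

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

#: IUPAC codes a diploid consensus chromatogram can produce: the four bases
#: (homozygous) and the six two-allele ambiguity codes (heterozygous).
IUPAC_PAIRS: dict[str, tuple[str, str]] = {
    "A": ("A", "A"),
    "C": ("C", "C"),
    "G": ("G", "G"),
    "T": ("T", "T"),
    "R": ("A", "G"),
    "Y": ("C", "T"),
    "S": ("C", "G"),
    "W": ("A", "T"),
    "K": ("G", "T"),
    "M": ("A", "C"),
}
MISSING_SYMBOLS = frozenset("N-")
THREE_ALLELE_CODES = frozenset("BDHV")
ALPHABET = frozenset(IUPAC_PAIRS) | MISSING_SYMBOLS

_PAIR_TO_IUPAC = {frozenset(pair): sym for sym, pair in IUPAC_PAIRS.items()}

# Byte lookup tables mapping an ASCII symbol to its two allele indices
# (-1 = missing, -8 = three-allele ambiguity, -9 = unknown symbol).
_LUT1 = np.full(256, -9, dtype=np.int8)
_LUT2 = np.full(256, -9, dtype=np.int8)
for _sym, (_a, _b) in IUPAC_PAIRS.items():
    _LUT1[ord(_sym)] = BASE_INDEX[_a]
    _LUT2[ord(_sym)] = BASE_INDEX[_b]
for _sym in MISSING_SYMBOLS:
    _LUT1[ord(_sym)] = -1
    _LUT2[ord(_sym)] = -1
for _sym in THREE_ALLELE_CODES:
    _LUT1[ord(_sym)] = -8
    _LUT2[ord(_sym)] = -8


class FormatError(ValueError):
    """Malformed input file or sequence."""


def expand_iupac(symbol: str) -> tuple[str, str] | None:
    """Expand a normalized IUPAC symbol into an unordered diploid allele pair.

    Returns ``None`` for missing data (``N`` or ``-``).  Three-allele codes
    (B, D, H, V) are rejected: direct diploid sequencing cannot produce them.
    """
    symbol = symbol.upper()
    if symbol in MISSING_SYMBOLS:
        return None
    if symbol in THREE_ALLELE_CODES:
        raise FormatError(f"unsupported ambiguity code {symbol!r}")
    try:
        return IUPAC_PAIRS[symbol]
    except KeyError:
        raise FormatError(f"unknown symbol {symbol!r}") from None


def encode_iupac(a: str, b: str) -> str:
    """Inverse of :func:`expand_iupac` on supported symbols."""
    try:
        return _PAIR_TO_IUPAC[frozenset((a, b))]
    except KeyError:
        raise FormatError(f"no IUPAC code for allele pair ({a!r}, {b!r})") from None


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------

#: per-column annotation category codes
CODING, NONCODING, UNANNOTATED = 1, 0, -1


@dataclass(frozen=True)
class Segment:
    """0-based half-open interval [start, end)."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"bad segment [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class CodingSegment(Segment):
    strand: str = "+"
    frame: int = 0

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if self.frame not in (0, 1, 2):
            raise ValueError(f"bad frame {self.frame!r}")


@dataclass
class LocusAnnotation:
    """CDS / intron / UTR structure of one locus.

    Unannotated bases are allowed and excluded from every statistic.  All
    coding segments must lie on the same strand; the concatenated,
    strand-resolved coding sequence must be a whole number of codons unless a
    partial-codon flag is set at the corresponding end.
    """

    locus_id: str
    length: int
    coding_segments: list[CodingSegment] = field(default_factory=list)
    intron_segments: list[Segment] = field(default_factory=list)
    utr_segments: list[Segment] = field(default_factory=list)
    genome: str = "nuclear"
    genetic_code_id: int = 1
    partial_start: bool = False
    partial_end: bool = False

    def __post_init__(self) -> None:
        if self.genome not in ("nuclear", "mitochondrial"):
            raise ValueError(f"bad genome flag {self.genome!r}")
        segs = [*self.coding_segments, *self.intron_segments, *self.utr_segments]
        for s in segs:
            if s.end > self.length:
                raise ValueError(
                    f"{self.locus_id}: segment [{s.start}, {s.end}) exceeds length {self.length}"
                )
        for a, b in zip(sorted(segs, key=lambda s: s.start), sorted(segs, key=lambda s: s.start)[1:]):
            if b.start < a.end:
                raise ValueError(f"{self.locus_id}: overlapping segments {a} and {b}")
        strands = {s.strand for s in self.coding_segments}
        if len(strands) > 1:
            raise ValueError(f"{self.locus_id}: coding segments on both strands")
        self.strand = strands.pop() if strands else "+"
        n_cod = sum(len(s) for s in self.coding_segments)
        frame = self._initial_frame()
        if n_cod and (n_cod - frame) % 3 and not (self.partial_start or self.partial_end):
            raise ValueError(
                f"{self.locus_id}: coding length {n_cod} (frame {frame}) is not a "
                "whole number of codons and no partial-codon flag is set"
            )

    def _ordered_coding_segments(self) -> list[CodingSegment]:
        segs = sorted(self.coding_segments, key=lambda s: s.start)
        return segs if self.strand == "+" else segs[::-1]

    def _initial_frame(self) -> int:
        segs = self._ordered_coding_segments()
        return segs[0].frame if segs else 0

    def coding_order(self) -> np.ndarray:
        """Plus-strand positions of complete codons, in translation order.

        The leading ``frame`` bases and any trailing partial codon are
        dropped, so the result length is always a multiple of 3.
        """
        parts = []
        for s in self._ordered_coding_segments():
            pos = np.arange(s.start, s.end)
            parts.append(pos if self.strand == "+" else pos[::-1])
        if not parts:
            return np.empty(0, dtype=np.int64)
        order = np.concatenate(parts)[self._initial_frame():]
        return order[: 3 * (len(order) // 3)]

    def category_codes(self) -> np.ndarray:
        """Per-column category: CODING, NONCODING or UNANNOTATED."""
        cat = np.full(self.length, UNANNOTATED, dtype=np.int8)
        for s in (*self.intron_segments, *self.utr_segments):
            cat[s.start : s.end] = NONCODING
        for s in self.coding_segments:
            cat[s.start : s.end] = CODING
        return cat


_GFF_UTR_TYPES = {"five_prime_UTR", "three_prime_UTR", "UTR"}


def read_annotation_gff3(
    path: str | Path,
    locus_id: str | None = None,
    length: int | None = None,
    genome: str = "nuclear",
    genetic_code_id: int = 1,
) -> LocusAnnotation:
    """Read the GFF3 subset used here (CDS / intron / UTR features, one locus).

    The locus length is taken from a ``##sequence-region`` pragma unless given
    explicitly.  Unknown feature types are ignored with a debug message.
    """
    coding: list[CodingSegment] = []
    introns: list[Segment] = []
    utrs: list[Segment] = []
    seen_id = locus_id
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("##sequence-region"):
                parts = line.split()
                if len(parts) >= 4:
                    if seen_id is None:
                        seen_id = parts[1]
                    if length is None:
                        length = int(parts[3])
                continue
            if line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 GFF3 columns, got {len(cols)}")
            seqid, _src, ftype, start, end, _score, strand, phase, _attrs = cols
            if seen_id is None:
                seen_id = seqid
            if locus_id is not None and seqid != locus_id:
                continue
            start0, end0 = int(start) - 1, int(end)  # 1-based inclusive -> half-open
            if ftype == "CDS":
                frame = int(phase) if phase in "012" else 0
                coding.append(CodingSegment(start0, end0, strand if strand in "+-" else "+", frame))
            elif ftype == "intron":
                introns.append(Segment(start0, end0))
            elif ftype in _GFF_UTR_TYPES:
                utrs.append(Segment(start0, end0))
            else:
                log.debug("%s:%d: ignoring feature type %r", path, lineno, ftype)
    if seen_id is None or length is None:
        raise FormatError(f"{path}: locus id / length not determinable (no ##sequence-region?)")
    return LocusAnnotation(
        locus_id=seen_id,
        length=length,
        coding_segments=coding,
        intron_segments=introns,
        utr_segments=utrs,
        genome=genome,
        genetic_code_id=genetic_code_id,
    )


def write_annotation_gff3(annotation: LocusAnnotation, path: str | Path) -> None:
    lid = annotation.locus_id
    rows = []
    for s in annotation.coding_segments:
        rows.append((s.start, "CDS", s.end, s.strand, str(s.frame)))
    for s in annotation.intron_segments:
        rows.append((s.start, "intron", s.end, "+", "."))
    for s in annotation.utr_segments:
        rows.append((s.start, "UTR", s.end, "+", "."))
    rows.sort()
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {lid} 1 {annotation.length}\n")
        for start, ftype, end, strand, phase in rows:
            fh.write(f"{lid}\tpolyload\t{ftype}\t{start + 1}\t{end}\t.\t{strand}\t{phase}\t.\n")


# ---------------------------------------------------------------------------
# Alignments
# ---------------------------------------------------------------------------


@dataclass
class Individual:
    individual_id: str
    population_id: str
    sequence: str


@dataclass
class LocusAlignment:
    """One locus: aligned diploid consensus sequences plus its annotation."""

    locus_id: str
    individuals: list[Individual]
    length: int
    annotation: LocusAnnotation
    _genotypes: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        ids = [ind.individual_id for ind in self.individuals]
        if len(set(ids)) != len(ids):
            raise FormatError(f"{self.locus_id}: duplicate individual ids")
        for ind in self.individuals:
            if len(ind.sequence) != self.length:
                raise FormatError(
                    f"{self.locus_id}: length mismatch for {ind.individual_id}: "
                    f"{len(ind.sequence)} != {self.length}"
                )
        if self.annotation.length != self.length:
            raise FormatError(
                f"{self.locus_id}: annotation length {self.annotation.length} != alignment length {self.length}"
            )

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    def genotypes(self) -> np.ndarray:
        """(length, n_individuals, 2) int8 array of allele indices, -1 missing."""
        if self._genotypes is None:
            geno = np.empty((self.length, self.n_individuals, 2), dtype=np.int8)
            for j, ind in enumerate(self.individuals):
                raw = np.frombuffer(ind.sequence.encode("ascii"), dtype=np.uint8)
                a1, a2 = _LUT1[raw], _LUT2[raw]
                bad = np.nonzero(a1 == -9)[0]
                if bad.size:
                    p = int(bad[0])
                    raise FormatError(
                        f"{self.locus_id}/{ind.individual_id}: unknown symbol "
                        f"{ind.sequence[p]!r} at position {p + 1}"
                    )
                amb = np.nonzero(a1 == -8)[0]
                if amb.size:
                    p = int(amb[0])
                    raise FormatError(
                        f"{self.locus_id}/{ind.individual_id}: unsupported ambiguity "
                        f"{ind.sequence[p]!r} at position {p + 1}"
                    )
                geno[:, j, 0] = a1
                geno[:, j, 1] = a2
            self._genotypes = geno
        return self._genotypes


@dataclass
class SiteColumn:
    """One alignment column expanded into per-individual allele pairs."""

    locus_id: str
    position: int  # 0-based
    pairs: list[tuple[str, str] | None]
    n: int  # chromosomes with a non-missing call
    category: str  # 'coding' | 'noncoding' | 'unannotated' | 'invalid'


def site_columns(alignment: LocusAlignment) -> list[SiteColumn]:
    """Expand an alignment into columns.

    Any column with a missing call (``N``/``-``) in any individual is marked
    ``invalid`` (complete deletion); otherwise the annotation category is
    attached.  Empty alignments yield an empty list.
    """
    if not alignment.individuals:
        return []
    geno = alignment.genotypes()
    cat = alignment.annotation.category_codes()
    names = {CODING: "coding", NONCODING: "noncoding", UNANNOTATED: "unannotated"}
    out = []
    for pos in range(alignment.length):
        col = geno[pos]
        pairs: list[tuple[str, str] | None] = []
        for a, b in col:
            pairs.append(None if a < 0 else (BASES[a], BASES[b]))
        n = 2 * sum(p is not None for p in pairs)
        invalid = any(p is None for p in pairs)
        out.append(
            SiteColumn(
                locus_id=alignment.locus_id,
                position=pos,
                pairs=pairs,
                n=n,
                category="invalid" if invalid else names[int(cat[pos])],
            )
        )
    return out


def read_locus_alignment(
    fasta_path: str | Path,
    annotation: LocusAnnotation,
    populations: Mapping[str, str],
) -> LocusAlignment:
    """Read one per-locus FASTA alignment of diploid consensus sequences.

    The first whitespace-delimited token of each header is the individual id;
    its population is resolved through *populations*.  Sequences are
    normalized to upper case; record order is preserved.
    """
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if not records:
        raise FormatError(f"{fasta_path}: no FASTA records")
    length = len(records[0].seq)
    individuals = []
    for rec in records:
        if len(rec.seq) != length:
            raise FormatError(
                f"{fasta_path}: length mismatch: record {rec.id!r} has length "
                f"{len(rec.seq)}, expected {length}"
            )
        ind_id = rec.id
        if ind_id not in populations:
            raise FormatError(f"{fasta_path}: individual {ind_id!r} missing from population table")
        individuals.append(Individual(ind_id, populations[ind_id], str(rec.seq).upper()))
    aln = LocusAlignment(annotation.locus_id, individuals, length, annotation)
    aln.genotypes()  # force alphabet validation at read time
    return aln


def write_locus_alignment(alignment: LocusAlignment, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(ind.sequence), id=ind.individual_id, description="")
        for ind in alignment.individuals
    ]
    SeqIO.write(records, str(path), "fasta-2line")


# ---------------------------------------------------------------------------
# Dataset
# ---------------------------------------------------------------------------


@dataclass
class Dataset:
    """All retained loci plus the population/basin structure."""

    loci: list[LocusAlignment]
    basins: dict[str, str] = field(default_factory=dict)  # population_id -> basin

    @property
    def locus_ids(self) -> list[str]:
        return [a.locus_id for a in self.loci]

    def sorted(self) -> "Dataset":
        return Dataset(sorted(self.loci, key=lambda a: a.locus_id), dict(self.basins))


def read_populations(path: str | Path) -> tuple[dict[str, str], dict[str, str]]:
    """Read the populations TSV: individual_id, population_id, basin."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"individual_id", "population_id"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: needs columns {sorted(required)}")
    ind2pop = dict(zip(df["individual_id"], df["population_id"]))
    basins: dict[str, str] = {}
    if "basin" in df.columns:
        for pop, basin in zip(df["population_id"], df["basin"]):
            prev = basins.setdefault(pop, basin)
            if prev != basin:
                raise FormatError(f"{path}: population {pop!r} assigned to two basins")
    return ind2pop, basins


def load_dataset(manifest_path: str | Path, populations_path: str | Path) -> Dataset:
    """Load a dataset from a manifest TSV (locus_id, fasta, gff, genome)."""
    manifest_path = Path(manifest_path)
    ind2pop, basins = read_populations(populations_path)
    df = pd.read_csv(manifest_path, sep="\t", dtype=str)
    required = {"locus_id", "fasta", "gff", "genome"}
    if not required.issubset(df.columns):
        raise FormatError(f"{manifest_path}: needs columns {sorted(required)}")
    root = manifest_path.parent
    loci = []
    for row in df.itertuples(index=False):
        ann = read_annotation_gff3(root / row.gff, locus_id=row.locus_id, genome=row.genome)
        loci.append(read_locus_alignment(root / row.fasta, ann, ind2pop))
    return Dataset(loci, basins)


def apply_locus_filters(
    dataset: Dataset,
    exclude_mitochondrial: bool = True,
    exclude_locus_ids: Iterable[str] = (),
) -> Dataset:
    """Restrict a dataset to retained loci.

    Mitochondrial loci (uniparental, non-recombining, differently constrained)
    and explicitly named loci are dropped.  Exclusion ids not present in the
    dataset produce a warning, not an error.
    """
    exclude = set(exclude_locus_ids)
    missing = exclude - set(dataset.locus_ids)
    for lid in sorted(missing):
        log.warning("exclusion id %r not present in dataset", lid)
    kept = []
    n_mito = 0
    for aln in dataset.loci:
        if exclude_mitochondrial and aln.annotation.genome == "mitochondrial":
            n_mito += 1
            continue
        if aln.locus_id in exclude:
            continue
        kept.append(aln)
    log.info(
        "locus filters: %d -> %d loci (%d mitochondrial, %d excluded by id)",
        len(dataset.loci), len(kept), n_mito, len(exclude - missing),
    )
    return Dataset(kept, dict(dataset.basins))
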