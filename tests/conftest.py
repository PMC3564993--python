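"""Shared fixtures: programmatic construction of tiny alignments."""

from __future__ import annotations

import numpy as np
import pytest

from polyload.io_model import (
    CodingSegment,
    Individual,
    LocusAlignment,
    LocusAnnotation,
    Segment,
)


def make_annotation(
    length: int,
    coding: tuple[tuple[int, int], ...] = (),
    introns: tuple[tuple[int, int], ...] = (),
    utrs: tuple[tuple[int, int], ...] = (),
    genome: str = "nuclear",
    strand: str = "+",
    locus_id: str = "L1",
) -> LocusAnnotation:
    return LocusAnnotation(
        locus_id=locus_id,
        length=length,
        coding_segments=[CodingSegment(a, b, strand, 0) for a, b in coding],
        intron_segments=[Segment(a, b) for a, b in introns],
        utr_segments=[Segment(a, b) for a, b in utrs],
        genome=genome,
    )


def make_alignment(
    seqs: list[str],
    annotation: LocusAnnotation | None = None,
    pops: list[str] | None = None,
    locus_id: str = "L1",
) -> LocusAlignment:
    """Alignment from raw IUPAC sequences; defaults to an all-noncoding locus."""
    length = len(seqs[0])
    if annotation is None:
        annotation = make_annotation(length, introns=((0, length),), locus_id=locus_id)
    if pops is None:
        pops = [f"pop{1 + i % 2}" for i in range(len(seqs))]
    inds = [Individual(f"ind{i + 1}", pops[i], s) for i, s in enumerate(seqs)]
    return LocusAlignment(locus_id, inds, length, annotation)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
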