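"""Back-splice junction construction and circRNA read quantification.

A circRNA is a covalently closed circle whose diagnostic sequence is the
back-splice junction: the 3' end of the circle joined to its own 5' start. A
junction library stores, per circle, the last F bases followed by the first F
bases of the circle sequence (F = flank, default the read length). A read
counts as a junction read only if it matches a junction sequence exactly,
crossing the junction midpoint with at least ``min_overlap`` bases on each
side (concordant), and has no exact full-length match anywhere in the linear
genome (exclusive).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from ._util import revcomp
from .mapping import KmerIndex, map_read
from .simulate import FeatureInterval, ReadSet, Reference

DEFAULT_MIN_OVERLAP = 10


@dataclass(frozen=True)
class Junction:
    circ_id: str
    junction_seq: str
    flank: int
    chrom: str
    donor: int      # genomic coordinate of the circle 3' end (0-based, exclusive)
    acceptor: int   # genomic coordinate of the circle 5' start
    strand: str


@dataclass
class JunctionLibrary:
    junctions: list[Junction]
    flank: int
    min_overlap: int = DEFAULT_MIN_OVERLAP


@dataclass
class CircFractionReport:
    sample_id: str
    junction_reads: int
    total_reads: int
    per_circ: pd.Series

    @property
    def percentage(self) -> float:
        return 100.0 * self.junction_reads / self.total_reads


def build_junction_library(
    circles: list[FeatureInterval] | pd.DataFrame,
    reference: Reference,
    flank: int,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> JunctionLibrary:
    """Junction sequences for annotated circles: last ``flank`` bases of the
    circle followed by its first ``flank`` bases, on the annotated strand."""
    if isinstance(circles, pd.DataFrame):
        circles = [FeatureInterval(str(r.circ_id), str(r.chrom), int(r.start), int(r.end),
                                   str(r.strand), "circRNA")
                   for r in circles.itertuples(index=False)]
    junctions = []
    for c in circles:
        if flank > c.length:
            raise ValueError(f"{c.feature_id}: flank {flank} exceeds circle length {c.length}")
        seq = reference.fetch(c.chrom, c.start, c.end, c.strand)
        junctions.append(Junction(c.feature_id, seq[-flank:] + seq[:flank], flank,
                                  c.chrom, c.end, c.start, c.strand))
    return JunctionLibrary(junctions, flank, min_overlap)


def is_junction_read(
    read: str,
    junctions: JunctionLibrary,
    genome_index: KmerIndex,
    reference: Reference,
    m: int | None = None,
) -> tuple[bool, str | None]:
    """Concordant-and-exclusive junction test for one read.

    Checks the read and its reverse complement against every junction
    sequence; an occurrence must straddle the junction midpoint with >= m
    bases on each side, and the read must not match the linear genome.
    """
    m = junctions.min_overlap if m is None else m
    n = len(read)
    hit_circ = None
    for query in (read, revcomp(read)):
        for j in junctions.junctions:
            f = j.flank
            start = 0
            while True:
                q = j.junction_seq.find(query, start)
                if q < 0:
                    break
                if q <= f - m and q + n >= f + m:
                    hit_circ = j.circ_id
                    break
                start = q + 1
            if hit_circ:
                break
        if hit_circ:
            break
    if hit_circ is None:
        return False, None
    if map_read(read, genome_index, reference):
        return False, None  # maps to the linear genome -> not exclusive
    return True, hit_circ


def circ_fraction(
    readset: ReadSet,
    junctions: JunctionLibrary,
    genome_index: KmerIndex,
    reference: Reference,
    m: int | None = None,
) -> CircFractionReport:
    """Classify every read of a library; report the junction-read percentage."""
    if readset.n_reads == 0:
        raise ValueError(f"{readset.sample_id}: empty read set")
    per_circ: dict[str, int] = {j.circ_id: 0 for j in junctions.junctions}
    junction_reads = 0
    cache: dict[str, tuple[bool, str | None]] = {}
    for row in readset.reads.itertuples(index=False):
        seq, n = row.sequence, int(row.count)
        if seq not in cache:
            cache[seq] = is_junction_read(seq, junctions, genome_index, reference, m)
        ok, circ = cache[seq]
        if ok:
            junction_reads += n
            per_circ[circ] += n
    return CircFractionReport(readset.sample_id, junction_reads, readset.n_reads,
                              pd.Series(per_circ, name=readset.sample_id))
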