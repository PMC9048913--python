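"""Exact-match read mapping and origin categorization on the toy genome.

Reads are error-free genome substrings by construction, so the mapper is an
exact full-length matcher seeded by a k-mer index (default k = 10, the
shortest read the trimming bounds admit). A read with multiple hits is counted
once, under the highest-priority category among its hits; structural RNAs rank
first so multimapping cannot inflate regulatory classes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from ._util import is_dna, revcomp
from .simulate import ConfigurationError, FeatureInterval, ReadSet, Reference

log = logging.getLogger(__name__)

# multimapping tie-break: structural RNAs outrank regulatory classes
CATEGORY_PRIORITY = (
    "rRNA", "tRNA", "snRNA", "snoRNA", "miRNA", "TAS",
    "polIV", "TE", "mRNA", "circRNA", "intergenic",
)
_PRIORITY_RANK = {c: i for i, c in enumerate(CATEGORY_PRIORITY)}

MIN_READ_LEN = 10
MAX_READ_LEN = 34

UNANNOTATED = "unannotated"


@dataclass(frozen=True)
class Hit:
    chrom: str
    start: int
    end: int
    strand: str


@dataclass
class KmerIndex:
    k: int
    positions: dict[str, list[tuple[str, int]]]


def build_index(reference: Reference, k: int = 10) -> KmerIndex:
    """Index every forward-strand genomic k-mer; minus-strand hits are found by
    looking up the reverse complement of the read."""
    if k > 32:
        raise ConfigurationError("seed length k must be <= 32")
    if k < 1:
        raise ConfigurationError("seed length k must be >= 1")
    positions: dict[str, list[tuple[str, int]]] = {}
    for chrom, seq in reference.chromosomes.items():
        for i in range(len(seq) - k + 1):
            positions.setdefault(seq[i:i + k], []).append((chrom, i))
    return KmerIndex(k, positions)


def map_read(read: str, index: KmerIndex, reference: Reference) -> list[Hit]:
    """All exact full-length matches of a read on both strands.

    Reads with non-ACGT characters are skipped with a warning. Reads shorter
    than the seed cannot be anchored and raise a configuration error.
    """
    if not is_dna(read):
        log.warning("skipping read with non-ACGT characters: %r", read[:40])
        return []
    if len(read) < index.k:
        raise ConfigurationError(
            f"read of length {len(read)} is shorter than the seed k={index.k}")
    hits: list[Hit] = []
    n = len(read)
    for query, strand in ((read, "+"), (revcomp(read), "-")):
        for chrom, pos in index.positions.get(query[:index.k], ()):
            if reference.chromosomes[chrom][pos:pos + n] == query:
                hits.append(Hit(chrom, pos, pos + n, strand))
    return hits


class FeatureLookup:
    """Interval overlap queries over the annotation, per chromosome."""

    def __init__(self, features: list[FeatureInterval]):
        self.trees: dict[str, IntervalTree] = {}
        for f in features:
            self.trees.setdefault(f.chrom, IntervalTree())[f.start:f.end] = f

    def overlapping(self, hit: Hit) -> list[FeatureInterval]:
        tree = self.trees.get(hit.chrom)
        if tree is None:
            return []
        return [iv.data for iv in tree.overlap(hit.start, hit.end)]


def categorize_read(
    hits: list[Hit],
    lookup: FeatureLookup,
    priority: tuple[str, ...] = CATEGORY_PRIORITY,
) -> tuple[str, str, str]:
    """Assign one (category, subfeature, feature_id) to a mapped read.

    The category is the highest-priority one among all features any hit
    overlaps; hits overlapping nothing are intergenic. For mRNA, the
    sub-feature with the largest overlap wins, ties going to the CDS; the
    read is counted against the parent gene.
    """
    if not hits:
        raise ValueError("categorize_read requires at least one hit")
    rank = {c: i for i, c in enumerate(priority)}
    best: tuple[int, str, FeatureInterval, Hit] | None = None
    for hit in hits:
        for f in lookup.overlapping(hit):
            key = (rank.get(f.category, len(rank)), f.feature_id)
            if best is None or key < (best[0], best[1]):
                best = (key[0], key[1], f, hit)
    if best is None:
        return "intergenic", "none", UNANNOTATED
    _, _, feat, hit = best
    if feat.category != "mRNA":
        return feat.category, "none", feat.feature_id
    gene_id = feat.parent or feat.feature_id
    # sub-feature with the largest overlap; ties -> CDS
    sub_order = {"cds": 0, "five_utr": 1, "intron": 2, "three_utr": 3}
    best_sub: tuple[int, int, str] | None = None  # (overlap, -tie_rank, name)
    for f in lookup.overlapping(hit):
        if f.category != "mRNA" or f.subfeature == "none" or f.parent != gene_id:
            continue
        ov = min(f.end, hit.end) - max(f.start, hit.start)
        cand = (ov, -sub_order.get(f.subfeature, 9), f.subfeature)
        if best_sub is None or cand[:2] > best_sub[:2]:
            best_sub = cand
    return "mRNA", best_sub[2] if best_sub else "none", gene_id


@dataclass
class QuantResult:
    """Counts, per-million normalizations and length spectra for a run."""

    counts: pd.DataFrame          # feature x sample, raw assigned reads
    rpm: pd.DataFrame             # feature x sample, reads per million mapped
    spectrum: pd.DataFrame        # length (10..34) x sample, RPM
    category_rpm: pd.DataFrame    # category x sample, RPM
    subfeature_rpm: pd.DataFrame  # mRNA sub-feature x sample, RPM
    mapped_total: pd.Series
    unmapped: pd.Series
    flags: list = field(default_factory=list)


def count_and_normalize(
    readsets: list[ReadSet],
    reference: Reference,
    k: int = 10,
    min_len: int = MIN_READ_LEN,
    max_len: int = MAX_READ_LEN,
    index: KmerIndex | None = None,
) -> QuantResult:
    """Map, categorize and count every library; normalize to RPM mapped reads.

    Unmapped reads are excluded from the RPM denominator. Identical sequences
    are mapped once and their assignment cached across libraries.
    """
    if index is None:
        index = build_index(reference, k)
    lookup = FeatureLookup(reference.features)
    cache: dict[str, tuple[str, str, str] | None] = {}

    feature_ids = sorted({f.feature_id for f in reference.features if f.subfeature == "none"})
    sample_ids = [rs.sample_id for rs in readsets]
    counts = pd.DataFrame(0, index=feature_ids + [UNANNOTATED], columns=sample_ids, dtype=int)
    lengths = list(range(min_len, max_len + 1))
    spec_counts = pd.DataFrame(0, index=lengths, columns=sample_ids, dtype=int)
    cat_counts = pd.DataFrame(0, index=list(CATEGORY_PRIORITY), columns=sample_ids, dtype=int)
    subs = ["five_utr", "cds", "intron", "three_utr"]
    sub_counts = pd.DataFrame(0, index=subs, columns=sample_ids, dtype=int)
    unmapped = pd.Series(0, index=sample_ids, dtype=int)

    for rs in readsets:
        sid = rs.sample_id
        for row in rs.reads.itertuples(index=False):
            seq, n = row.sequence, int(row.count)
            if seq not in cache:
                hits = map_read(seq, index, reference)
                cache[seq] = categorize_read(hits, lookup) if hits else None
            assign = cache[seq]
            if assign is None:
                unmapped[sid] += n
                continue
            category, subfeature, feature_id = assign
            counts.loc[feature_id, sid] += n
            cat_counts.loc[category, sid] += n
            if subfeature in sub_counts.index:
                sub_counts.loc[subfeature, sid] += n
            if min_len <= len(seq) <= max_len:
                spec_counts.loc[len(seq), sid] += n

    mapped_total = counts.sum(axis=0)
    flags = [s for s in sample_ids if mapped_total[s] == 0]
    for s in flags:
        log.warning("sample %s has zero mapped reads; RPM undefined", s)
    denom = mapped_total.replace(0, np.nan)
    rpm = counts.div(denom, axis=1) * 1e6
    spectrum = spec_counts.div(denom, axis=1) * 1e6
    category_rpm = cat_counts.div(denom, axis=1) * 1e6
    subfeature_rpm = sub_counts.div(denom, axis=1) * 1e6
    return QuantResult(counts, rpm, spectrum, category_rpm, subfeature_rpm,
                       mapped_total, unmapped, flags)
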