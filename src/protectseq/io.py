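"""On-disk formats: FASTA, FASTQ, GFF3 (1-based inclusive), TSV tables.

All tables are headered, tab-separated, UTF-8 with '.' decimals. FASTA/FASTQ go
through Biopython; GFF3 is written and parsed here directly (nine tab columns,
feature metadata in the attribute field).
"""

from __future__ import annotations

from collections import Counter

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .simulate import FeatureInterval, ReadSet


class IoError(OSError):
    pass


def write_genome_fasta(chromosomes: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in chromosomes.items()]
    try:
        SeqIO.write(records, str(path), "fasta")
    except OSError as exc:
        raise IoError(f"{path}: {exc}") from exc


def read_genome_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_gff3(features: list[FeatureInterval], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            attrs = f"ID={f.feature_id};category={f.category};subfeature={f.subfeature}"
            if f.parent:
                attrs += f";Parent={f.parent}"
            fh.write("\t".join([
                f.chrom, "protectseq", f.category,
                str(f.start + 1), str(f.end),  # 1-based inclusive on disk
                ".", f.strand, ".", attrs,
            ]) + "\n")


def read_gff3(path) -> list[FeatureInterval]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            chrom, _src, _type, start, end, _score, strand, _phase, attrs = \
                line.rstrip("\n").split("\t")
            kv = dict(item.split("=", 1) for item in attrs.split(";") if "=" in item)
            out.append(FeatureInterval(
                kv["ID"], chrom, int(start) - 1, int(end), strand,
                kv.get("category", _type), kv.get("subfeature", "none"),
                kv.get("Parent"),
            ))
    return out


def write_fastq(readset: ReadSet, path) -> int:
    """Write one library as FASTQ with constant quality 'I'; returns read count."""
    n = 0
    with open(path, "w") as fh:
        for read_id, seq, _sp, _comp in readset.iter_reads():
            fh.write(f"@{read_id}\n{seq}\n+\n{'I' * len(seq)}\n")
            n += 1
    return n


def read_fastq_counts(path) -> Counter:
    """Sequence multiset of a FASTQ file (order-free, memory-light)."""
    counts: Counter = Counter()
    for rec in SeqIO.parse(str(path), "fastq"):
        counts[str(rec.seq).upper()] += 1
    return counts


def write_circles_tsv(circles: list[FeatureInterval], path) -> None:
    df = pd.DataFrame(
        [(c.feature_id, c.chrom, c.start, c.end, c.strand) for c in circles],
        columns=["circ_id", "chrom", "start", "end", "strand"],
    )
    df.to_csv(path, sep="\t", index=False)


def read_circles_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"circ_id": str, "chrom": str})


def write_table(df: pd.DataFrame, path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_table(path, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)
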