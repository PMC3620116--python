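"""Input/output helpers: genomes, gene models and the pipeline's tab-separated tables.

Genomes are handled as plain ``{contig_name: sequence}`` dictionaries of
upper-case DNA.  Gene models carry a transcription start site (TSS), a strand
and an exon structure; they round-trip through GFF3 (1-based, inclusive) and
BED12 (0-based, half-open).
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an upper-case DNA string."""
    return seq.translate(COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# genomes


def read_fasta(path: str | Path) -> dict[str, str]:
    """Load a (multi-contig) FASTA into a dict of upper-case sequences."""
    genome = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    if not genome:
        raise ValueError(f"no sequences found in {path}")
    return genome


def write_fasta(genome: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# gene models


@dataclass
class Gene:
    """A gene model on one contig.

    ``start``/``end`` are 0-based half-open genomic coordinates of the full
    transcript span; ``exons`` is a list of (start, end) pairs in the same
    convention.  The TSS is ``start`` on the plus strand and ``end - 1`` on
    the minus strand.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r} for {self.gene_id}")
        if not 0 <= self.start < self.end:
            raise ValueError(f"bad span [{self.start},{self.end}) for {self.gene_id}")
        if not self.exons:
            self.exons = [(self.start, self.end)]

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def exon_length(self) -> int:
        return sum(e - s for s, e in self.exons)


def write_gff3(genes: Iterable[Gene], path: str | Path, source: str = "mscc") -> None:
    """Write gene models as GFF3 (gene + mRNA + exon features, 1-based)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = f"ID={g.gene_id}"
            fh.write(
                f"{g.chrom}\t{source}\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            fh.write(
                f"{g.chrom}\t{source}\tmRNA\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}.1;Parent={g.gene_id}\n"
            )
            for i, (s, e) in enumerate(g.exons, 1):
                fh.write(
                    f"{g.chrom}\t{source}\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                    f"ID={g.gene_id}.1.exon{i};Parent={g.gene_id}.1\n"
                )


def _gff3_attr(attrs: str, key: str) -> str | None:
    for part in attrs.strip().split(";"):
        if "=" in part:
            k, v = part.split("=", 1)
            if k.strip() == key:
                return v.strip()
    return None


def read_gff3(path: str | Path) -> list[Gene]:
    """Read gene models from GFF3; exons are attached via Parent chains."""
    genes: dict[str, Gene] = {}
    parent_of: dict[str, str] = {}
    exon_rows: list[tuple[str, int, int]] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9:
                continue
            chrom, _, ftype, start1, end1, _, strand, _, attrs = f[:9]
            start, end = int(start1) - 1, int(end1)
            if ftype == "gene":
                gid = _gff3_attr(attrs, "ID") or f"gene{len(genes)}"
                genes[gid] = Gene(gid, chrom, start, end, strand, exons=[(start, end)])
                genes[gid].exons = []  # filled from exon features below
            elif ftype in ("mRNA", "transcript"):
                tid = _gff3_attr(attrs, "ID")
                parent = _gff3_attr(attrs, "Parent")
                if tid and parent:
                    parent_of[tid] = parent
            elif ftype == "exon":
                parent = _gff3_attr(attrs, "Parent")
                if parent:
                    exon_rows.append((parent, start, end))
    for parent, start, end in exon_rows:
        gid = parent_of.get(parent, parent)
        if gid in genes:
            genes[gid].exons.append((start, end))
    out = []
    for g in genes.values():
        if not g.exons:
            g.exons = [(g.start, g.end)]
        g.exons.sort()
        out.append(g)
    out.sort(key=lambda g: (g.chrom, g.start, g.gene_id))
    return out


def write_bed12(genes: Iterable[Gene], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            sizes = ",".join(str(e - s) for s, e in g.exons) + ","
            starts = ",".join(str(s - g.start) for s, e in g.exons) + ","
            fh.write(
                f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\t"
                f"{g.start}\t{g.end}\t0\t{len(g.exons)}\t{sizes}\t{starts}\n"
            )


def read_bed12(path: str | Path) -> list[Gene]:
    genes = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            chrom, start, end, name, _, strand = f[0], int(f[1]), int(f[2]), f[3], f[4], f[5]
            exons = [(start, end)]
            if len(f) >= 12:
                sizes = [int(x) for x in f[10].rstrip(",").split(",")]
                offsets = [int(x) for x in f[11].rstrip(",").split(",")]
                exons = [(start + o, start + o + sz) for o, sz in zip(offsets, sizes)]
            genes.append(Gene(name, chrom, start, end, strand, exons=exons))
    genes.sort(key=lambda g: (g.chrom, g.start, g.gene_id))
    return genes


def read_annotation(path: str | Path) -> list[Gene]:
    """Read gene models from GFF3 (.gff/.gff3) or BED12 (.bed)."""
    p = str(path)
    if p.endswith((".bed", ".bed12")):
        return read_bed12(path)
    return read_gff3(path)


# ---------------------------------------------------------------------------
# FASTQ and flat tables


def open_maybe_gzip(path: str | Path, mode: str = "rt"):
    p = str(path)
    return gzip.open(p, mode) if p.endswith(".gz") else open(p, mode)


def read_fastq_sequences(path: str | Path) -> list[str]:
    """Read the sequences of a FASTQ(.gz) file."""
    with open_maybe_gzip(path) as fh:
        return [str(rec.seq).upper() for rec in SeqIO.parse(fh, "fastq")]


def write_fastq(reads: Iterable[str], path: str | Path, prefix: str = "read") -> None:
    """Write raw sequences as FASTQ with constant quality."""
    with open_maybe_gzip(path, "wt") as fh:
        for i, seq in enumerate(reads):
            fh.write(f"@{prefix}:{i}\n{seq}\n+\n{'I' * len(seq)}\n")


def read_table(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)
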