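"""In-silico digestion: catalog the CG sites surveyed by a panel of
methylation-sensitive restriction enzymes (MSRE) and extract their CG tags.

The assay digests genomic DNA with four MSREs whose recognition sites all
contain a CG and whose cuts leave a 5'-CG overhang.  A type-III enzyme then
releases 27-nt fragments flanking each cut; those fragments ("CG tags")
identify the cut site when sequenced.  This module builds the site universe:
every genomic position where some panel enzyme can cut, keyed by the
forward-strand coordinate of the C of the CG, together with the pair of
27-nt tags (one per strand) that reads from that site will carry.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

import pandas as pd

from .io import revcomp, write_table, read_table

TAG_LEN_DEFAULT = 27


@dataclass(frozen=True)
class Enzyme:
    name: str
    motif: str
    cg_offset: int  # offset of the CG within the motif

    def __post_init__(self) -> None:
        if "CG" not in self.motif:
            raise ValueError(f"enzyme {self.name}: motif {self.motif} lacks a CG")
        if self.motif[self.cg_offset : self.cg_offset + 2] != "CG":
            raise ValueError(f"enzyme {self.name}: cg_offset does not point at CG")


@dataclass
class EnzymePanel:
    """The four-enzyme MSRE panel (HpaII, AciI, HpyCH4IV, HinP1I by default)."""

    enzymes: list[Enzyme] = field(
        default_factory=lambda: [
            Enzyme("HpaII", "CCGG", 1),
            Enzyme("AciI", "CCGC", 1),
            Enzyme("HpyCH4IV", "ACGT", 1),
            Enzyme("HinP1I", "GCGC", 1),
        ]
    )

    def scan_motifs(self, both_strands: bool = True) -> list[tuple[str, str, int]]:
        """(enzyme name, motif to search on the forward strand, CG offset).

        Palindromic motifs appear once; non-palindromic ones (AciI's CCGC)
        contribute their reverse complement as a second search motif so that
        cut sites on the minus strand are found by forward-strand scanning.
        """
        out = []
        for enz in self.enzymes:
            out.append((enz.name, enz.motif, enz.cg_offset))
            rc = revcomp(enz.motif)
            if both_strands and rc != enz.motif:
                # the CG of the reflected motif: CG at offset k maps to
                # offset len-2-k under reverse complement
                out.append((enz.name, rc, len(enz.motif) - 2 - enz.cg_offset))
        return out


@dataclass
class CGSite:
    chrom: str
    pos: int  # 0-based coordinate of the C of the CG, forward strand
    enzymes: frozenset[str]
    tag_fwd: str = ""
    tag_rev: str = ""
    unique: bool = True

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.pos}"


@dataclass
class CGSiteCatalog:
    """Sorted, duplicate-free collection of surveyed CG sites plus a census."""

    sites: list[CGSite]
    genome_id: str = ""
    total_cg: int = 0
    dropped_edge: int = 0

    def __len__(self) -> int:
        return len(self.sites)

    def __iter__(self) -> Iterator[CGSite]:
        return iter(self.sites)

    @property
    def surveyed_cg(self) -> int:
        return len(self.sites)

    @property
    def surveyed_fraction(self) -> float:
        return self.surveyed_cg / self.total_cg if self.total_cg else 0.0

    def site_keys(self) -> list[str]:
        return [s.key for s in self.sites]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [s.chrom for s in self.sites],
                "pos0": [s.pos for s in self.sites],
                "enzymes": [",".join(sorted(s.enzymes)) for s in self.sites],
                "tag_fwd": [s.tag_fwd for s in self.sites],
                "tag_rev": [s.tag_rev for s in self.sites],
                "unique": [s.unique for s in self.sites],
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        write_table(self.to_frame(), path)

    def to_bed(self, path: str | Path) -> None:
        """Surveyed sites as BED (0-based half-open intervals over the CG)."""
        with open(path, "w") as fh:
            for s in self.sites:
                fh.write(f"{s.chrom}\t{s.pos}\t{s.pos + 2}\t{','.join(sorted(s.enzymes))}\n")

    def to_gff3(self, path: str | Path) -> None:
        """Surveyed sites as GFF3 (1-based inclusive)."""
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for s in self.sites:
                fh.write(
                    f"{s.chrom}\tmscc\tCG_site\t{s.pos + 1}\t{s.pos + 2}\t.\t+\t.\t"
                    f"ID={s.key};enzymes={','.join(sorted(s.enzymes))}\n"
                )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CGSiteCatalog":
        df = read_table(path, dtype={"tag_fwd": str, "tag_rev": str})
        sites = [
            CGSite(
                chrom=str(r.chrom),
                pos=int(r.pos0),
                enzymes=frozenset(str(r.enzymes).split(",")),
                tag_fwd="" if pd.isna(r.tag_fwd) else str(r.tag_fwd),
                tag_rev="" if pd.isna(r.tag_rev) else str(r.tag_rev),
                unique=bool(r.unique),
            )
            for r in df.itertuples()
        ]
        return cls(sites=sites)


def _find_all(seq: str, motif: str) -> Iterator[int]:
    start = seq.find(motif)
    while start != -1:
        yield start
        start = seq.find(motif, start + 1)


def count_cg(genome: Mapping[str, str]) -> int:
    """Number of forward-strand CG dinucleotide occurrences in the genome."""
    return sum(len(list(_find_all(seq, "CG"))) for seq in genome.values())


def scan_restriction_sites(
    genome: Mapping[str, str],
    panel: EnzymePanel | None = None,
    both_strands: bool = True,
) -> CGSiteCatalog:
    """Scan a genome for MSRE recognition sites and build the CG-site catalog.

    Every occurrence of every panel motif (in both orientations for
    non-palindromic motifs) yields one site keyed by the forward-strand
    position of the C of its CG; a CG cut by several enzymes appears once
    with all enzyme names.  Motif windows containing N are skipped.
    """
    if not genome:
        raise ValueError("empty genome")
    panel = panel or EnzymePanel()
    hits: dict[tuple[str, int], set[str]] = defaultdict(set)
    for chrom, seq in genome.items():
        for name, motif, cg_off in panel.scan_motifs(both_strands=both_strands):
            for start in _find_all(seq, motif):
                hits[(chrom, start + cg_off)].add(name)
    sites = [
        CGSite(chrom=c, pos=p, enzymes=frozenset(enz))
        for (c, p), enz in sorted(hits.items())
    ]
    return CGSiteCatalog(sites=sites, total_cg=count_cg(genome))


def extract_tags(
    catalog: CGSiteCatalog,
    genome: Mapping[str, str],
    tag_len: int = TAG_LEN_DEFAULT,
) -> CGSiteCatalog:
    """Attach the per-site tag pair and drop sites too close to a contig edge.

    ``tag_fwd`` is the ``tag_len`` nt of the forward strand starting at the
    CG; ``tag_rev`` is the reverse complement of the ``tag_len`` nt ending
    just past the CG — the two sequences a read from either cut flank will
    carry.  Sites whose tag pair collides with another site's tags at
    Hamming distance <= 1 are flagged ``unique=False``.
    """
    if tag_len <= 0:
        raise ValueError("tag_len must be positive")
    kept: list[CGSite] = []
    dropped = 0
    for s in catalog:
        seq = genome[s.chrom]
        if s.pos + tag_len > len(seq) or s.pos + 2 - tag_len < 0:
            dropped += 1
            continue
        tag_fwd = seq[s.pos : s.pos + tag_len]
        tag_rev = revcomp(seq[s.pos + 2 - tag_len : s.pos + 2])
        if "N" in tag_fwd or "N" in tag_rev:
            dropped += 1
            continue
        kept.append(CGSite(s.chrom, s.pos, s.enzymes, tag_fwd, tag_rev, True))
    _flag_ambiguous(kept, tag_len)
    return CGSiteCatalog(
        sites=kept,
        genome_id=catalog.genome_id,
        total_cg=catalog.total_cg,
        dropped_edge=dropped,
    )


def _wildcard_keys(tag: str) -> Iterator[str]:
    """The tag with each single position masked; two tags at Hamming
    distance <= 1 share at least one key."""
    for i in range(len(tag)):
        yield f"{i}:{tag[:i]}{tag[i + 1:]}"


def _flag_ambiguous(sites: list[CGSite], tag_len: int) -> None:
    buckets: dict[str, list[int]] = defaultdict(list)
    for idx, s in enumerate(sites):
        for tag in (s.tag_fwd, s.tag_rev):
            for key in _wildcard_keys(tag):
                buckets[key].append(idx)
    clash = set()
    for members in buckets.values():
        if len(set(members)) > 1:
            clash.update(members)
    for idx in clash:
        sites[idx].unique = False


def census(catalog: CGSiteCatalog) -> dict[str, float]:
    """Total CGs, surveyed CGs and the surveyed fraction."""
    return {
        "total_cg": catalog.total_cg,
        "surveyed_cg": catalog.surveyed_cg,
        "surveyed_fraction": catalog.surveyed_fraction,
    }


def build_catalog(
    genome: Mapping[str, str],
    panel: EnzymePanel | None = None,
    tag_len: int = TAG_LEN_DEFAULT,
) -> CGSiteCatalog:
    """Scan + tag extraction in one call."""
    return extract_tags(scan_restriction_sites(genome, panel), genome, tag_len)
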