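"""Tag quantification: demultiplex barcoded reads, map 27-nt CG tags to
catalog sites allowing one mismatch, collapse the two strand tags of each
site into a single digestion frequency, and normalize across libraries.

Reads are 30 nt: a 27-nt CG tag followed by a 3-nt replicate barcode.
Barcode matching is exact (a 3-mer cannot safely absorb errors).  A tag maps
to a site if it equals the site's forward or reverse tag exactly, else if it
is within Hamming distance 1 of exactly one catalog tag; ties at the minimal
distance are ambiguous and dropped.  Only sites flagged ``unique`` in the
catalog participate, so one-mismatch assignment is well defined.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .digest import CGSiteCatalog, _wildcard_keys


@dataclass
class MappingReport:
    """Per-library read accounting; categories partition the input."""

    reads_in: int = 0
    demultiplexed: dict[str, int] = field(default_factory=dict)
    unassigned_barcode: int = 0
    mapped_exact: dict[str, int] = field(default_factory=dict)
    mapped_1mm: dict[str, int] = field(default_factory=dict)
    ambiguous: dict[str, int] = field(default_factory=dict)
    unmapped: dict[str, int] = field(default_factory=dict)
    malformed: dict[str, int] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        libs = sorted(self.demultiplexed)
        return pd.DataFrame(
            {
                "library": libs,
                "demultiplexed": [self.demultiplexed.get(l, 0) for l in libs],
                "mapped_exact": [self.mapped_exact.get(l, 0) for l in libs],
                "mapped_1mm": [self.mapped_1mm.get(l, 0) for l in libs],
                "ambiguous": [self.ambiguous.get(l, 0) for l in libs],
                "unmapped": [self.unmapped.get(l, 0) for l in libs],
                "malformed": [self.malformed.get(l, 0) for l in libs],
            }
        )


def demultiplex(
    reads: Iterable[str],
    barcode_map: Mapping[str, str],
    tag_len: int = 27,
    barcode_len: int = 3,
) -> tuple[dict[str, list[str]], MappingReport]:
    """Split reads by the exact barcode at positions tag_len..tag_len+3.

    ``barcode_map`` maps library name -> barcode.  Reads whose barcode
    matches no library (or that are too short) are discarded and counted.
    """
    if len(set(barcode_map.values())) != len(barcode_map):
        raise ValueError("duplicate barcodes in barcode map")
    lib_of = {bc: lib for lib, bc in barcode_map.items()}
    out: dict[str, list[str]] = {lib: [] for lib in barcode_map}
    report = MappingReport(demultiplexed={lib: 0 for lib in barcode_map})
    for read in reads:
        report.reads_in += 1
        if len(read) < tag_len + barcode_len:
            report.unassigned_barcode += 1
            continue
        lib = lib_of.get(read[tag_len : tag_len + barcode_len])
        if lib is None:
            report.unassigned_barcode += 1
        else:
            out[lib].append(read[:tag_len])
            report.demultiplexed[lib] += 1
    return out, report


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance needs equal lengths")
    return sum(x != y for x, y in zip(a, b))


class TagIndex:
    """Exact + one-mismatch lookup from 27-nt tags to catalog site keys.

    The one-mismatch index masks each tag position in turn; two tags within
    Hamming distance 1 share a masked key, so candidate sites are recovered
    by 27 dictionary probes and verified explicitly.
    """

    def __init__(self, catalog: CGSiteCatalog, tag_len: int = 27):
        self.tag_len = tag_len
        self.exact: dict[str, str] = {}
        self.tags_of_site: dict[str, tuple[str, str]] = {}
        self.buckets: dict[str, set[str]] = defaultdict(set)
        for s in catalog:
            if not s.unique or len(s.tag_fwd) != tag_len:
                continue
            self.tags_of_site[s.key] = (s.tag_fwd, s.tag_rev)
            for strand, tag in (("+", s.tag_fwd), ("-", s.tag_rev)):
                self.exact[tag] = s.key
                for key in _wildcard_keys(tag):
                    self.buckets[key].add(s.key)
        self.strand_of_tag = {}
        for site, (fwd, rev) in self.tags_of_site.items():
            self.strand_of_tag[fwd] = "+"
            self.strand_of_tag[rev] = "-"

    def lookup(self, tag: str) -> tuple[str | None, str]:
        """(site key or None, status in {exact, 1mm, ambiguous, unmapped,
        malformed}); the strand is recoverable from which site tag matched."""
        if len(tag) != self.tag_len or set(tag) - set("ACGTN"):
            return None, "malformed"
        site = self.exact.get(tag)
        if site is not None:
            return site, "exact"
        candidates: set[str] = set()
        for key in _wildcard_keys(tag):
            candidates |= self.buckets.get(key, set())
        hits = set()
        for site in candidates:
            fwd, rev = self.tags_of_site[site]
            if hamming(tag, fwd) <= 1 or hamming(tag, rev) <= 1:
                hits.add(site)
        if not hits:
            return None, "unmapped"
        if len(hits) > 1:
            return None, "ambiguous"
        return hits.pop(), "1mm"


def map_tags(
    tags: Sequence[str], catalog: CGSiteCatalog | TagIndex
) -> tuple[list[tuple[str, str]], dict[str, int]]:
    """Assign tags to sites; returns ([(site, strand)] for mapped tags,
    status counts).  Strand is '+' for a forward-tag hit, '-' for reverse;
    one-mismatch hits take the strand of the closer site tag."""
    index = catalog if isinstance(catalog, TagIndex) else TagIndex(catalog)
    assignments: list[tuple[str, str]] = []
    stats = {"exact": 0, "1mm": 0, "ambiguous": 0, "unmapped": 0, "malformed": 0}
    for tag in tags:
        site, status = index.lookup(tag)
        stats[status] += 1
        if site is not None:
            fwd, rev = index.tags_of_site[site]
            strand = "+" if hamming(tag, fwd) <= hamming(tag, rev) else "-"
            assignments.append((site, strand))
    return assignments, stats


def collapse_strands(
    assignments_by_library: Mapping[str, Sequence[tuple[str, str]]],
    site_keys: Sequence[str],
) -> pd.DataFrame:
    """Dense site x library raw count matrix; forward- and reverse-tag hits
    at one CG collapse into a single digestion frequency.  Zeros are kept —
    an unobserved site is data (methylated or shallowly covered), not a gap."""
    libs = list(assignments_by_library)
    raw = pd.DataFrame(0, index=pd.Index(site_keys, name="site"), columns=libs, dtype=int)
    for lib, assignments in assignments_by_library.items():
        counts: dict[str, int] = defaultdict(int)
        for site, _strand in assignments:
            counts[site] += 1
        if counts:
            col = pd.Series(counts)
            raw.loc[col.index, lib] += col.astype(int)
    return raw


def normalize(raw: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Scale each library by mean(total reads) / its total reads.

    After normalization every library has the same total; the scale choice
    (mean of library totals) is cosmetic — per-site test statistics are
    invariant to a common rescaling.
    """
    totals = raw.sum(axis=0).astype(float)
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(f"zero-total libraries: {', '.join(zero.index)}")
    factors = totals.mean() / totals
    return raw * factors, factors


def quantify_reads(
    reads: Iterable[str],
    catalog: CGSiteCatalog,
    barcode_map: Mapping[str, str],
    tag_len: int = 27,
) -> tuple[pd.DataFrame, pd.DataFrame, MappingReport]:
    """Demultiplex + map + collapse + normalize in one pass.

    Returns (normalized counts, raw counts, report).  The matrix is dense
    over the catalog's unique sites.
    """
    index = TagIndex(catalog, tag_len)
    by_lib, report = demultiplex(reads, barcode_map, tag_len)
    assignments = {}
    for lib, tags in by_lib.items():
        asn, stats = map_tags(tags, index)
        assignments[lib] = asn
        report.mapped_exact[lib] = stats["exact"]
        report.mapped_1mm[lib] = stats["1mm"]
        report.ambiguous[lib] = stats["ambiguous"]
        report.unmapped[lib] = stats["unmapped"]
        report.malformed[lib] = stats["malformed"]
    raw = collapse_strands(assignments, list(index.tags_of_site))
    normalized, _ = normalize(raw)
    return normalized, raw, report
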