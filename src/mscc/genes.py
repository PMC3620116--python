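"""Gene-level consequences of differential methylation: closest-TSS gene
sets, promoter-window flags, RPKM-based differential expression, the
methylation-expression odds ratio and gene-set (term) enrichment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dms import bh_fdr, _welch_arrays
from .io import Gene
from .tss import distances_to_tss


# ---------------------------------------------------------------------------
# DMS -> gene assignment


def assign_closest_gene(
    dms_table: pd.DataFrame, genes: Sequence[Gene]
) -> tuple[set[str], set[str]]:
    """Split genes by the direction of their nearest DMS.

    Each differentially methylated site contributes its nearest-TSS gene to
    the "met" set (gain of methylation) or the "unmet" set (loss); a gene
    hit by both directions appears in both sets.  ``dms_table`` is indexed
    by site key with a ``direction`` column.
    """
    if not genes:
        raise ValueError("empty annotation")
    called = dms_table[dms_table["direction"].isin(["methylated", "demethylated"])]
    dist = distances_to_tss(list(called.index), genes)
    met, unmet = set(), set()
    for key, row in called.iterrows():
        g = dist.loc[key, "nearest_gene"]
        if g is None or (isinstance(g, float) and math.isnan(g)):
            continue
        (met if row["direction"] == "methylated" else unmet).add(g)
    return met, unmet


def flag_window_dm(
    genes: Sequence[Gene],
    dms_sites: Sequence[str],
    upstream: int = 3000,
    downstream: int = 2000,
) -> pd.Series:
    """Per-gene flag: does any DMS fall in the promoter window?

    The window is the closed, strand-aware interval [-upstream, +downstream]
    around the TSS (negative = upstream of the gene).  Boundaries are
    inclusive.
    """
    flags = pd.Series(False, index=pd.Index([g.gene_id for g in genes], name="gene"))
    by_chrom: dict[str, list[tuple[int, str]]] = {}
    for key in dms_sites:
        chrom, pos = key.rsplit(":", 1)
        by_chrom.setdefault(chrom, []).append((int(pos), key))
    for g in genes:
        for pos, _key in by_chrom.get(g.chrom, []):
            signed = (pos - g.tss) if g.strand == "+" else (g.tss - pos)
            if -upstream <= signed <= downstream:
                flags[g.gene_id] = True
                break
    return flags


# ---------------------------------------------------------------------------
# expression


def rpkm(counts, exon_length_nt, library_total) -> float | np.ndarray:
    """Reads per kilobase of exon model per million mapped reads:
    counts * 1e9 / (length * total)."""
    length = np.asarray(exon_length_nt, dtype=float)
    total = np.asarray(library_total, dtype=float)
    if np.any(length <= 0):
        raise ValueError("exon length must be positive")
    if np.any(total <= 0):
        raise ValueError("library total must be positive")
    return np.asarray(counts, dtype=float) * 1e9 / (length * total)


def rpkm_matrix(counts: pd.DataFrame, exon_lengths: pd.Series) -> pd.DataFrame:
    """Gene x library RPKM from a raw count matrix (totals = column sums)."""
    lengths = exon_lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = lengths.index[lengths.isna()].tolist()[:5]
        raise ValueError(f"genes without exon length, e.g. {missing}")
    totals = counts.sum(axis=0)
    vals = rpkm(
        counts.to_numpy(dtype=float),
        lengths.to_numpy(dtype=float)[:, None],
        totals.to_numpy(dtype=float)[None, :],
    )
    return pd.DataFrame(vals, index=counts.index, columns=counts.columns)


def call_de(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    exon_lengths: pd.Series,
    fold_cut: float = 1.5,
    alpha: float = 0.05,
    mode: str = "p",
) -> pd.DataFrame:
    """Two-group differential expression on RPKM.

    Welch t test per gene on log2(RPKM + 1); a gene is DE iff its fold
    change (ratio of mean RPKM, larger over smaller) reaches ``fold_cut``
    and its p (mode "p") or BH q (mode "fdr") is below ``alpha``.
    Direction: "up" means higher in the second condition (treated).
    """
    if mode not in ("p", "fdr"):
        raise ValueError(f"unknown mode {mode!r}")
    conds = list(dict.fromkeys(design["condition"]))
    if len(conds) != 2:
        raise ValueError(f"need exactly 2 conditions, got {conds}")
    libs_c = design.loc[design["condition"] == conds[0], "library"].tolist()
    libs_t = design.loc[design["condition"] == conds[1], "library"].tolist()
    if len(libs_c) < 2 or len(libs_t) < 2:
        raise ValueError("need >= 2 replicates per condition")
    r = rpkm_matrix(counts, exon_lengths)
    mean_c = r[libs_c].mean(axis=1)
    mean_t = r[libs_t].mean(axis=1)
    log_c = np.log2(r[libs_c].to_numpy() + 1)
    log_t = np.log2(r[libs_t].to_numpy() + 1)
    tstat, df, p = _welch_arrays(log_c, log_t)
    q = bh_fdr(p)
    eps = 1e-12
    fc = (mean_t + eps) / (mean_c + eps)
    fold = np.maximum(fc, 1 / fc)
    crit = q if mode == "fdr" else p
    is_de = (fold >= fold_cut) & (crit < alpha)
    direction = np.where(~is_de, "none", np.where(mean_t > mean_c, "up", "down"))
    return pd.DataFrame(
        {
            "rpkm_control": mean_c,
            "rpkm_treated": mean_t,
            "fold": fold,
            "t": tstat,
            "df": df,
            "p": p,
            "q": q,
            "is_de": is_de,
            "direction": direction,
        },
        index=counts.index,
    )


# ---------------------------------------------------------------------------
# association and enrichment


@dataclass
class ContingencyTable:
    """2x2 gene table: a = DM and DE, b = DM only, c = DE only, d = neither."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be non-negative")

    @classmethod
    def from_flags(cls, dm: pd.Series, de: pd.Series) -> "ContingencyTable":
        common = dm.index.intersection(de.index)
        dm, de = dm.loc[common].astype(bool), de.loc[common].astype(bool)
        return cls(
            a=int((dm & de).sum()),
            b=int((dm & ~de).sum()),
            c=int((~dm & de).sum()),
            d=int((~dm & ~de).sum()),
        )


def odds_ratio(table: ContingencyTable) -> float:
    """OR = (a/c)/(b/d) = ad/bc.

    With a zero in b or c only, the ratio diverges (+inf).  A margin that is
    entirely zero leaves the ratio undefined.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    for name, m in {
        "DM": a + b, "non-DM": c + d, "DE": a + c, "non-DE": b + d,
    }.items():
        if m == 0:
            raise ValueError(f"odds ratio undefined: empty {name} margin")
    if b == 0 or c == 0:
        return math.inf
    return (a * d) / (b * c)


@dataclass
class EnrichmentInput:
    """Hypergeometric quadruple: N background genes with any term, B with
    this term, n target genes, b target genes with this term."""

    N: int
    B: int
    n: int
    b: int

    def __post_init__(self) -> None:
        if not (0 <= self.b <= min(self.B, self.n) and self.n <= self.N and self.B <= self.N):
            raise ValueError(f"inconsistent quadruple (N={self.N}, B={self.B}, n={self.n}, b={self.b})")


def enrichment_fold(inp: EnrichmentInput) -> float:
    """Fold enrichment (b/n)/(B/N): the term's frequency in the target set
    over its frequency in the background."""
    if inp.n == 0 or inp.B == 0:
        raise ValueError("fold undefined for n=0 or B=0")
    return (inp.b / inp.n) / (inp.B / inp.N)


def hypergeom_tail(inp: EnrichmentInput) -> float:
    """Upper tail P(X >= b), X ~ Hypergeom(N, B, n)."""
    return float(stats.hypergeom.sf(inp.b - 1, inp.N, inp.B, inp.n))


def enrichment_test(
    target: Sequence[str],
    term_map: Mapping[str, Sequence[str]] | pd.DataFrame,
    background: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-term hypergeometric over-representation of a target gene set.

    ``term_map`` maps term -> genes (or a frame with ``term``/``gene``
    columns).  The background defaults to all genes with at least one term;
    target genes must be a subset of the background.  Returns per term:
    (N, B, n, b), fold, upper-tail p and BH q across terms.
    """
    if isinstance(term_map, pd.DataFrame):
        grouped = term_map.groupby("term")["gene"].apply(set).to_dict()
    else:
        grouped = {t: set(gs) for t, gs in term_map.items()}
    if not grouped:
        raise ValueError("empty term map")
    annotated = set().union(*grouped.values())
    bg = set(background) if background is not None else annotated
    target_set = set(target)
    stray = target_set - bg
    if stray:
        raise ValueError(f"target genes absent from background: {sorted(stray)[:5]}")
    N = len(bg)
    n = len(target_set)
    rows = []
    for term, members in sorted(grouped.items()):
        members = members & bg
        inp = EnrichmentInput(N=N, B=len(members), n=n, b=len(members & target_set))
        rows.append(
            {
                "term": term,
                "N": inp.N,
                "B": inp.B,
                "n": inp.n,
                "b": inp.b,
                "fold": enrichment_fold(inp) if inp.B else np.nan,
                "p": hypergeom_tail(inp),
            }
        )
    out = pd.DataFrame(rows).set_index("term")
    out["q"] = bh_fdr(out["p"].to_numpy())
    return out
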