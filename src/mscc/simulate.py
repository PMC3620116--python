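"""Synthetic data with the statistical structure the assay assumes.

The generator emulates the measurement model of methyl-sensitive cut
counting: per-site digestion counts are inversely proportional to the
methylation level of the site (a cell-population average in [0, 1], not a
per-cell binary state), scaled by a site-specific multiplicative bias that
is shared across libraries — systematic and reproducible among replicates —
and overdispersed around the expectation.  Treatment perturbs a small
fraction of sites, with odds 9:1 toward gain of methylation and placement
preferentially near transcription start sites, mirroring the drought
response the pipeline was built to detect.  Gene expression counts with
planted fold changes stand in for the companion RNA-seq libraries.

One global seed drives named sub-streams (genome, methylome, reads,
expression) so each stage is independently reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .digest import CGSiteCatalog, build_catalog
from .io import Gene, write_fasta, write_gff3, write_bed12, write_fastq, write_table
from .tss import distances_to_tss

# sub-stream identifiers hashed together with the global seed
_GENOME, _METHYLOME, _READS, _EXPRESSION = 1, 2, 3, 4

#: default replicate barcodes: 4 distinct 3-mers, pairwise Hamming distance 3
DEFAULT_BARCODES = ("AAA", "CCC", "GGG", "TTT")


@dataclass
class SimConfig:
    """Study-design knobs for the synthetic dataset.

    Defaults mirror the assay's design: 2 conditions x 4 barcoded
    replicates, ~9:1 methylation:demethylation odds among perturbed sites,
    DMS placed preferentially within 500 nt of a TSS, and per-site
    multiplicative biases shared across libraries.
    """

    seed: int = 0
    n_contigs: int = 2
    contig_len: int = 50_000
    n_genes: int = 30
    gc_content: float = 0.36  # Arabidopsis-like
    n_replicates: int = 4
    library_depth: float = 30_000.0  # expected reads per library
    bias_sd: float = 0.5  # log-scale sd of the per-site bias
    dispersion: float = 0.005  # NB overdispersion: var = mu + dispersion * mu^2
    dms_fraction: float = 0.02
    dms_delta: float = 0.6  # |methylation-level change| at perturbed sites
    direction_ratio: float = 9.0  # methylation : demethylation odds
    tss_enrichment_window: int = 500
    tss_enrichment_strength: float = 5.0  # placement weight near TSS
    read_error_rate: float = 0.01  # fraction of reads with one substitution
    gene_len_min: int = 1_000
    gene_len_max: int = 3_000
    max_exons: int = 4
    de_fraction: float = 0.1
    de_fold: float = 4.0
    expression_depth: float = 200_000.0
    conditions: tuple[str, str] = ("control", "treated")
    barcodes: tuple[str, ...] = DEFAULT_BARCODES

    def __post_init__(self) -> None:
        for name in ("gc_content", "dms_fraction", "read_error_rate", "de_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.library_depth <= 0 or self.expression_depth <= 0:
            raise ValueError("depths must be positive")
        if self.direction_ratio <= 0:
            raise ValueError("direction_ratio must be positive")
        if len(set(self.barcodes)) < self.n_replicates:
            raise ValueError("need one distinct barcode per replicate")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream])

    @property
    def libraries(self) -> list[str]:
        return [
            f"{cond}_{r + 1}"
            for cond in self.conditions
            for r in range(self.n_replicates)
        ]

    def design(self) -> pd.DataFrame:
        rows = [
            {
                "library": f"{cond}_{r + 1}",
                "condition": cond,
                "replicate": r + 1,
                "barcode": self.barcodes[r],
            }
            for cond in self.conditions
            for r in range(self.n_replicates)
        ]
        return pd.DataFrame(rows)


@dataclass
class TruthTable:
    """Ground truth: per-site methylation levels/bias/DMS calls and per-gene
    expression fold changes."""

    sites: pd.DataFrame  # index site key; level_control, level_treated, bias,
    #                      is_dms, direction
    genes: pd.DataFrame  # index gene id; baseline, is_de, fold, direction


# ---------------------------------------------------------------------------
# genome + annotation


def generate_genome_and_annotation(config: SimConfig) -> tuple[dict[str, str], list[Gene]]:
    """Random genome at the configured GC content plus non-overlapping gene
    models on both strands.  Deterministic under the config seed."""
    rng = config.rng(_GENOME)
    gc = config.gc_content
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    bases = np.array(list("ACGT"))
    genome = {
        f"chr{i + 1}": "".join(rng.choice(bases, size=config.contig_len, p=probs))
        for i in range(config.n_contigs)
    }
    genes: list[Gene] = []
    if config.n_genes:
        # near-even split across contigs, then lay genes end to end with the
        # leftover space distributed randomly between them (never overlaps)
        per_contig = [
            config.n_genes // config.n_contigs
            + (1 if i < config.n_genes % config.n_contigs else 0)
            for i in range(config.n_contigs)
        ]
        margin = 100
        gid = 0
        for ci, n_here in enumerate(per_contig):
            if n_here == 0:
                continue
            chrom = f"chr{ci + 1}"
            lengths = rng.integers(config.gene_len_min, config.gene_len_max + 1, size=n_here)
            slack = config.contig_len - int(lengths.sum()) - margin * (n_here + 1)
            if slack < 0:
                raise RuntimeError(
                    f"cannot place {n_here} genes of {config.gene_len_min}-"
                    f"{config.gene_len_max} nt on a {config.contig_len}-nt contig; "
                    "reduce n_genes or gene lengths"
                )
            gaps = np.sort(rng.integers(0, slack + 1, size=n_here))
            cursor = margin
            prev_gap = 0
            for k in range(n_here):
                cursor += int(gaps[k]) - prev_gap
                prev_gap = int(gaps[k])
                start, end = cursor, cursor + int(lengths[k])
                strand = "+" if rng.random() < 0.5 else "-"
                genes.append(
                    Gene(f"g{gid + 1:04d}", chrom, start, end, strand,
                         exons=_split_exons(start, end, config.max_exons, rng))
                )
                gid += 1
                cursor = end + margin
        genes.sort(key=lambda g: (g.chrom, g.start, g.gene_id))
    return genome, genes


def _split_exons(
    start: int, end: int, max_exons: int, rng: np.random.Generator
) -> list[tuple[int, int]]:
    n = int(rng.integers(1, max_exons + 1))
    length = end - start
    if n == 1 or length < 2 * n * 100:
        return [(start, end)]
    cuts = np.sort(rng.choice(np.arange(100, length - 100), size=2 * (n - 1), replace=False))
    bounds = [start] + (start + cuts).tolist() + [end]
    return [(bounds[2 * i], bounds[2 * i + 1]) for i in range(n)]


# ---------------------------------------------------------------------------
# methylomes


def generate_methylomes(
    catalog: CGSiteCatalog, genes: Sequence[Gene], config: SimConfig
) -> TruthTable:
    """Baseline methylation per site plus treatment perturbations.

    Baseline: promoter-proximal sites (within 1 kb of a TSS) are mostly
    unmethylated, intergenic/gene-body sites mostly methylated.  A
    ``dms_fraction`` subset is perturbed in the treated condition by
    ±``dms_delta``, with odds ``direction_ratio``:1 toward gain of
    methylation and placement weight ``tss_enrichment_strength`` within
    ``tss_enrichment_window`` nt of a TSS.
    """
    if len(catalog) == 0:
        raise ValueError("empty catalog")
    rng = config.rng(_METHYLOME)
    keys = catalog.site_keys()
    n = len(keys)
    if genes:
        dist = distances_to_tss(keys, genes)["distance"].to_numpy()
    else:
        dist = np.full(n, np.nan)
    promoter = np.abs(dist) <= 1_000  # NaN compares False: intergenic
    base = np.where(promoter, rng.beta(2, 6, size=n), rng.beta(6, 2, size=n))

    level_c = base.copy()
    level_t = base.copy()
    is_dms = np.zeros(n, dtype=bool)
    direction = np.array(["none"] * n, dtype=object)
    n_dms = int(np.floor(config.dms_fraction * n))
    if config.dms_fraction > 0 and n_dms == 0:
        warnings.warn("dms_fraction too small for catalog size; zero DMS planted")
    if n_dms:
        w = np.ones(n)
        near = np.abs(dist) <= config.tss_enrichment_window
        w[near] = config.tss_enrichment_strength
        chosen = rng.choice(n, size=n_dms, replace=False, p=w / w.sum())
        gain = rng.random(n_dms) < config.direction_ratio / (1 + config.direction_ratio)
        delta = config.dms_delta
        for j, site in enumerate(chosen):
            if gain[j]:  # methylation gain under treatment: digestion falls
                c = min(base[site], 1 - delta)
                level_c[site], level_t[site] = c, c + delta
                direction[site] = "methylated"
            else:
                c = max(base[site], delta)
                level_c[site], level_t[site] = c, c - delta
                direction[site] = "demethylated"
            is_dms[site] = True

    bias = rng.lognormal(mean=0.0, sigma=config.bias_sd, size=n)
    sites = pd.DataFrame(
        {
            "level_control": level_c,
            "level_treated": level_t,
            "bias": bias,
            "is_dms": is_dms,
            "direction": direction,
            "tss_distance": dist,
        },
        index=pd.Index(keys, name="site"),
    )
    return TruthTable(sites=sites, genes=pd.DataFrame())


# ---------------------------------------------------------------------------
# counts and reads


def _nb_draw(
    mu: np.ndarray, dispersion: float, rng: np.random.Generator
) -> np.ndarray:
    """Negative-binomial-like draw: var = mu + dispersion * mu^2 (Poisson at
    dispersion 0), via gamma-Poisson mixing."""
    if dispersion <= 0:
        return rng.poisson(mu)
    lam = rng.gamma(shape=1.0 / dispersion, scale=mu * dispersion)
    return rng.poisson(lam)


def simulate_site_counts(
    truth: TruthTable, config: SimConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Raw per-site tag counts for every library.

    Expected count at site i in library j of condition c is
    ``depth * bias_i * (1 - level_ic) / Z_c`` with Z_c normalising the
    per-condition relative abundances, so library totals concentrate
    around ``library_depth``.
    """
    rng = config.rng(_READS)
    sites = truth.sites
    counts = {}
    for cond in config.conditions:
        level = sites[f"level_{cond}"].to_numpy()
        rel = sites["bias"].to_numpy() * (1.0 - level)
        z = rel.sum()
        if z <= 0:
            raise ValueError(f"condition {cond}: all sites fully methylated")
        mu = config.library_depth * rel / z
        for r in range(config.n_replicates):
            counts[f"{cond}_{r + 1}"] = _nb_draw(mu, config.dispersion, rng)
    raw = pd.DataFrame(counts, index=sites.index)
    return raw, config.design()


def simulate_tag_reads(
    truth: TruthTable,
    catalog: CGSiteCatalog,
    config: SimConfig,
    outdir: str | Path | None = None,
) -> tuple[dict[str, list[str]], pd.DataFrame, pd.DataFrame]:
    """30-nt reads (27-nt CG tag + 3-nt replicate barcode) per condition.

    The four barcoded replicates of one condition are pooled into a single
    sequenced library, as in the assay.  Each read carries the forward or
    reverse tag of its source site with equal odds; a ``read_error_rate``
    fraction of reads carries one random substitution.  Returns
    (reads per condition, barcode map, true per-site count matrix).
    """
    raw, design = simulate_site_counts(truth, config)
    rng = config.rng(_READS + 10)
    tag_of = {s.key: (s.tag_fwd, s.tag_rev) for s in catalog}
    reads_by_cond: dict[str, list[str]] = {c: [] for c in config.conditions}
    for _, lib_row in design.iterrows():
        lib, cond, bc = lib_row["library"], lib_row["condition"], lib_row["barcode"]
        col = raw[lib]
        for key, k in col[col > 0].items():
            fwd, rev = tag_of[key]
            n_fwd = int(rng.binomial(int(k), 0.5))
            reads_by_cond[cond].extend([fwd + bc] * n_fwd)
            reads_by_cond[cond].extend([rev + bc] * (int(k) - n_fwd))
    alphabet = "ACGT"
    for cond, reads in reads_by_cond.items():
        rng.shuffle(reads)
        if config.read_error_rate > 0:
            n_err = rng.binomial(len(reads), config.read_error_rate)
            for i in rng.choice(len(reads), size=n_err, replace=False):
                read = reads[i]
                p = int(rng.integers(len(read)))
                new = alphabet[int(rng.integers(4))]
                while new == read[p]:
                    new = alphabet[int(rng.integers(4))]
                reads[i] = read[:p] + new + read[p + 1 :]
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for cond, reads in reads_by_cond.items():
            write_fastq(reads, outdir / f"{cond}.fq.gz", prefix=cond)
        write_table(design, outdir / "barcodes.tsv")
    return reads_by_cond, design, raw


# ---------------------------------------------------------------------------
# expression


def generate_expression_truth(genes: Sequence[Gene], config: SimConfig) -> pd.DataFrame:
    rng = config.rng(_EXPRESSION)
    n = len(genes)
    baseline = rng.lognormal(mean=np.log(100.0), sigma=1.0, size=n)
    is_de = rng.random(n) < config.de_fraction
    up = rng.random(n) < 0.5
    fold = np.where(is_de, np.where(up, config.de_fold, 1.0 / config.de_fold), 1.0)
    return pd.DataFrame(
        {
            "baseline": baseline,
            "is_de": is_de,
            "fold": fold,
            "direction": np.where(~is_de, "none", np.where(up, "up", "down")),
            "exon_length": [g.exon_length for g in genes],
        },
        index=pd.Index([g.gene_id for g in genes], name="gene"),
    )


def simulate_expression_counts(
    genes: Sequence[Gene], config: SimConfig, truth_genes: pd.DataFrame | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Gene x library read counts with planted fold changes.

    Expected reads per gene are proportional to molar expression times exon
    length (longer transcripts yield more reads); library sizes vary ±15%
    around ``expression_depth``; counts are overdispersed like the tag
    counts.  Returns (counts, design, per-gene truth).
    """
    if truth_genes is None:
        truth_genes = generate_expression_truth(genes, config)
    rng = config.rng(_EXPRESSION + 10)
    lengths = truth_genes["exon_length"].to_numpy(dtype=float)
    base = truth_genes["baseline"].to_numpy()
    fold = truth_genes["fold"].to_numpy()
    counts = {}
    for cond in config.conditions:
        expr = base * fold if cond == config.conditions[1] else base
        w = expr * lengths
        w = w / w.sum()
        for r in range(config.n_replicates):
            lib_size = config.expression_depth * rng.uniform(0.85, 1.15)
            counts[f"{cond}_{r + 1}"] = _nb_draw(lib_size * w, config.dispersion, rng)
    mat = pd.DataFrame(counts, index=truth_genes.index)
    return mat, config.design(), truth_genes


# ---------------------------------------------------------------------------
# one-stop dataset


@dataclass
class SimulatedDataset:
    config: SimConfig
    genome: dict[str, str]
    genes: list[Gene]
    catalog: CGSiteCatalog
    truth: TruthTable
    counts: pd.DataFrame
    design: pd.DataFrame
    expression: pd.DataFrame
    expression_truth: pd.DataFrame


def simulate_dataset(config: SimConfig) -> SimulatedDataset:
    """Genome → catalog → methylomes → counts → expression, end to end."""
    genome, genes = generate_genome_and_annotation(config)
    catalog = build_catalog(genome)
    truth = generate_methylomes(catalog, genes, config)
    counts, design = simulate_site_counts(truth, config)
    expression, _, expr_truth = simulate_expression_counts(genes, config)
    truth.genes = expr_truth
    return SimulatedDataset(
        config=config,
        genome=genome,
        genes=genes,
        catalog=catalog,
        truth=truth,
        counts=counts,
        design=design,
        expression=expression,
        expression_truth=expr_truth,
    )


def write_dataset(ds: SimulatedDataset, outdir: str | Path) -> None:
    """Write FASTA/GFF3/BED12, catalog, truth tables and count matrices."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(ds.genome, outdir / "genome.fa")
    write_gff3(ds.genes, outdir / "genes.gff3")
    write_bed12(ds.genes, outdir / "genes.bed12")
    ds.catalog.to_tsv(outdir / "catalog.tsv")
    write_table(ds.truth.sites.reset_index(), outdir / "truth_sites.tsv")
    write_table(ds.expression_truth.reset_index(), outdir / "truth_genes.tsv")
    write_table(ds.counts.reset_index(), outdir / "site_counts.tsv")
    write_table(ds.expression.reset_index(), outdir / "expression_counts.tsv")
    write_table(ds.design, outdir / "design.tsv")
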