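"""mscc: methyl-sensitive cut counting analysis.

An end-to-end pipeline for MSRE-based methylome profiling: in-silico
digestion and CG-tag cataloging, barcoded tag-read quantification,
per-site differential-methylation calling (Welch t + BH-FDR), TSS-proximal
enrichment by permutation, and gene-level methylation-expression
association — plus a synthetic-data generator that emulates the assay's
measurement model for validation.
"""

from importlib.resources import files as _files

import pandas as _pd

from .digest import (
    CGSite,
    CGSiteCatalog,
    Enzyme,
    EnzymePanel,
    build_catalog,
    census,
    count_cg,
    extract_tags,
    scan_restriction_sites,
)
from .dms import (
    FilterPolicy,
    bh_fdr,
    call_dms,
    classify_direction,
    filter_sites,
    replicate_r2,
    welch_test,
    within_between_r2,
)
from .genes import (
    ContingencyTable,
    EnrichmentInput,
    assign_closest_gene,
    call_de,
    enrichment_fold,
    enrichment_test,
    flag_window_dm,
    hypergeom_tail,
    odds_ratio,
    rpkm,
    rpkm_matrix,
)
from .io import Gene, read_annotation, read_fasta, write_fasta, write_gff3
from .quant import (
    MappingReport,
    TagIndex,
    collapse_strands,
    demultiplex,
    map_tags,
    normalize,
    quantify_reads,
)
from .simulate import (
    SimConfig,
    SimulatedDataset,
    TruthTable,
    generate_genome_and_annotation,
    generate_methylomes,
    simulate_dataset,
    simulate_expression_counts,
    simulate_site_counts,
    simulate_tag_reads,
)
from .tss import (
    PermutationResult,
    TSSIndex,
    binned_profile,
    distance_to_tss,
    distances_to_tss,
    empirical_p,
    simulate_null_dms,
    tss_proximal_fraction,
)

__version__ = "0.1.0"


def go_enrichment_examples() -> _pd.DataFrame:
    """Published worked examples of the fold statistic: (N, B, n, b)
    quadruples with their two-decimal folds, used as regression fixtures."""
    path = _files("mscc").joinpath("data/go_enrichment_examples.tsv")
    with path.open() as fh:
        return _pd.read_csv(fh, sep="\t")
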