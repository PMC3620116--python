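# Methods

## Measurement model

Methyl-sensitive cut counting infers methylation from digestion. A panel of
four methylation-sensitive restriction enzymes — HpaII (CCGG), AciI (CCGC),
HpyCH4IV (ACGT), HinP1I (GCGC), all cutting to leave a 5′-CG overhang —
digests genomic DNA wherever the recognition site's CG is unmethylated.
27-nt fragments released from the cut flanks ("CG tags") are sequenced, and
the per-site tag count (the *digestion frequency*) is treated as
proportional to `bias_i × (1 − level_i)`, where `level_i ∈ [0, 1]` is the
site's methylation level and `bias_i > 0` a site-specific digestion bias.
Two assumptions carry the whole analysis:

1. **Levels are population averages.** DNA comes from a pool of cells;
   methylation at one site in one cell is binary, but the pooled level is a
   continuous fraction. The simulator and the statistics treat it so.
2. **Biases cancel in contrasts.** The bias is a property of the site, not
   of the library, so a two-sample test of the same site across conditions
   is unaffected by it. Biases are therefore never estimated; they only
   enter the simulator, where they make replicates "systematic and
   reproducible" — strongly correlated across libraries even when counts
   are overdispersed.

A zero count is data, not a gap: it can mean full methylation or shallow
coverage, which is exactly why sites are filtered by depth before testing
(default: at least 20 normalized reads in at least one library; an
every-library variant is available since "in any library" can be read both
ways).

## Site catalog and tag mapping

The catalog scans the genome for every panel motif, in both orientations
for the one non-palindromic motif (AciI's CCGC, scanned as CCGC and GCGG).
A site is keyed by the forward-strand coordinate of the C of its CG
(0-based); the cuts of both strands at one CG collapse to one entry,
prefiguring the strand collapse at the counting stage. Motif windows
containing N are skipped — conservative, rather than wildcarding N.

Tag geometry is a convention, not a claim: `tag_fwd` is the 27 nt starting
at the CG going 3′ on the forward strand, `tag_rev` the reverse complement
of the 27 nt ending just past the CG. Nothing downstream depends on the
orientation choice — only on the tag pair being invertible back to its
site, which the tests verify by string search. Sites whose tag pair lies
within Hamming distance 1 of another site's tags are flagged non-unique and
excluded from counting, because one-mismatch mapping would otherwise be
ambiguous by construction.

Mapping uses a masked-position index (each tag indexed 27 times with one
position wildcarded), giving exact and one-mismatch lookups in 27 probes;
results are contractually identical to brute-force all-pairs Hamming
search, and a test enforces this. Barcode matching is exact: a 3-nt
barcode cannot absorb errors safely. Reads matching multiple sites at the
minimal distance are counted ambiguous and dropped; mapping reports
partition every read (demultiplexed = mapped + ambiguous + unmapped +
malformed), which is asserted, not assumed.

Normalization multiplies library *j* by `mean(totals) / total_j`. The
scale constant is cosmetic — Welch statistics are invariant to a common
positive rescaling (tested) — so "proportional to the total number of
reads" is implemented with the mean as the anchor to keep counts on a
familiar scale.

## Differential methylation

Per site, a two-sided Welch *t* test between the two conditions on
normalized counts (no log transform by default; a log1p switch exists),
with sample variances floored at 1e-8 to survive integer ties at low
depth. Benjamini–Hochberg controls the FDR across tested sites (the
procedure is the 2013-era field default for genomic site matrices).
Direction follows the inverse relation between digestion and methylation:
significantly *lower* digestion under treatment is a methylation *gain*
("methylated"), higher is a loss ("demethylated"); exact mean ties stay
unlabeled with a warning.

## TSS enrichment

Distances to the nearest TSS are signed and strand-aware (negative
upstream), ties between equidistant TSS broken toward the smaller gene id.
Metaprofiles are 100-bp relative-frequency histograms over ±span
(default 3 kb), normalized over in-span mass.

The permutation test draws `s` same-size site sets uniformly without
replacement from the catalog — implemented literally as the random-rank
construction: assign every site a random number, sort, take the first `n`
— and reports p = (e+1)/(s+1). Two exceedance rules exist because the
source descriptions of `e` disagree: the default upper-tail rule counts
null draws whose near-TSS fraction is at least the *observed* set's
(standard permutation practice, matching the claimed direction of the
result); a literal variant compares null draws against the *all-sites*
statistic instead. Both are exposed; the default is the defensible one,
and no claim is made about which was originally computed.

## Gene association and enrichment

Genes are linked to methylation two ways: by nearest TSS (each DMS
contributes its closest gene to a "met" or "unmet" set by direction; a
gene can be in both) and by a promoter window, the closed strand-aware
interval [−3000, +2000] nt around the TSS (inclusivity is a choice; the
source notation "(−3 kbp to 2 kbp)" does not specify it).

Expression uses RPKM = reads × 10⁹ / (exon length × library total).
Differential expression is a per-gene Welch test on log2(RPKM+1) — a
transparent two-group stand-in for a commercial ANOVA pipeline (identical
hypothesis for two groups) — filtered by fold change ≥ 1.5 and p < 0.05 by
default; an FDR mode exists because the source states the threshold both
ways, and the package exposes rather than resolves that inconsistency.

Association is the odds ratio OR = (a/c)/(b/d) = ad/bc over the 2×2 table
of promoter-DM × DE flags on the common gene universe; b = 0 or c = 0
yields +inf, an empty margin is an error. Term enrichment is the
hypergeometric upper tail P(X ≥ b), X ~ Hypergeom(N, B, n), with fold
(b/n)/(B/N) and BH across terms; the background defaults to all genes
carrying at least one term (the N of the published table footnote). The
ranked-list mHG statistic of GOrilla is out of scope; the plain
hypergeometric tail replaces it.

## Synthetic data generator

The generator emulates what the analysis assumes and nothing more:

- **Genome/annotation**: i.i.d. bases at 36% GC (Arabidopsis-like);
  non-overlapping gene models with 1–4 exons laid out with randomized
  spacing on both strands; everything deterministic under one seed with
  named sub-streams (genome, methylome, reads, expression) so each stage
  reproduces independently.
- **Methylome**: promoter-proximal sites (≤1 kb from a TSS) mostly
  unmethylated (Beta(2,6)), others mostly methylated (Beta(6,2)) — the
  observed 5′-low / intergenic-high pattern. A `dms_fraction` (default
  0.02) of sites is perturbed by ±`dms_delta` (default 0.6) in the treated
  condition, direction drawn at `direction_ratio` 9:1 odds toward gain,
  placement weighted `tss_enrichment_strength`-fold (default 5) within
  500 nt of a TSS.
- **Counts**: expected count = depth × bias × (1 − level) / normalizer,
  biases lognormal (σ = 0.5) shared across all libraries, counts drawn
  gamma-Poisson with var = μ + dispersion·μ² (Poisson at dispersion 0).
- **Reads**: 30 nt = tag (forward or reverse, equal odds) + replicate
  barcode; the four barcoded replicates of one condition are pooled into a
  single FASTQ, as the assay sequences them; barcodes {AAA, CCC, GGG, TTT}
  are pairwise Hamming distance 3. A `read_error_rate` fraction of reads
  (default 1%) carries one uniform substitution.
- **Expression**: gene baselines lognormal, planted fold changes (default
  4-fold on 10% of genes, up/down equally), library sizes ±15%, same
  count noise model.

What it does *not* emulate: sequence composition structure (CpG islands,
repeats), partial digestion chemistry, quality scores, indels, CHG/CHH
methylation, and any correlation between neighboring sites. Passing tests
therefore demonstrate that the *inference machinery* is correct under the
stated measurement model, not that the model captures every property of
real libraries.

### The dispersion default

The two calibration targets one might set for the count noise —
(a) replicate r² around 0.8, the magnitude seen in the motivating
scatter-plots, and (b) recoverability of planted |Δlevel| ≥ 0.5 effects at
FDR 0.05 with 4+4 replicates — are mutually exclusive under this model.
At the r²≈0.8 calibration (dispersion ≈ 0.03 at default depth and bias
spread), the per-group coefficient of variation is floored at √0.03 ≈ 0.17,
which caps the Welch statistic near 2/CV ≈ 11 at Welch–Satterthwaite
degrees of freedom ≈ 3 — never small enough a p-value to clear a BH cutoff
of ~1e-3 at 2% prevalence, at *any* depth. Since recoverability is the
property the generator exists to exercise, the default is
`dispersion = 0.005` (mild overdispersion above Poisson), which keeps
replicate r² high (≈0.9 at default depth) and leaves planted effects
detectable at sufficient depth. The validation suite exercises recovery at
~300 reads/site/library, where sensitivity ≥ 0.8, observed FDP ≤ 0.1 and
direction concordance ≥ 95% hold averaged over seeds.

## Numerical choices

- Variance floor 1e-8 in Welch tests (integer ties at low depth would
  otherwise divide by zero); `t = 0, p = 1` falls out naturally for
  identical groups.
- BH via the standard step-up; q-values are clipped to [0, 1] and monotone
  in p-rank (tested against the `min_{j≥i} p_(j)·m/j` formula).
- Nearest-TSS ties broken lexicographically by gene id, deterministically.
- Sites closer than 27 nt to a contig edge are dropped at tag extraction
  and counted in a drop log; sites on contigs without genes get NaN TSS
  distance and are excluded from profiles and proximal fractions.
- The replicate-r² diagnostic uses a seeded 1,200-site subsample for
  comparability; requesting more sites than exist falls back to all, with
  a warning.
- Coordinates are 0-based half-open internally; BED exports stay 0-based,
  GFF3 exports are 1-based inclusive (both conversions tested).

## Problem sizes

Validation runs use desk-scale instances chosen for statistical adequacy:
10-kb contigs for oracle-equivalence checks, ~750–2,200-site catalogs
(2 × 50–150 kb genomes) for calling and calibration, a ≥10,000-site
catalog (2 × 700 kb) for the permutation-test demonstration, and 10 seeds
wherever a property is asserted as an average. Genome-scale counts from
any particular organism are out of scope: they would require that genome
and its raw reads.
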