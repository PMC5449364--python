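# Methods

## Overview

lectinkit reimplements a genome-wide lectin-family characterization workflow
as a set of composable, tested modules. Each module consumes standard file
formats (GFF3, FASTA, BED, JASPAR-style PWMs, TSV tables) and exposes pure
functions over in-memory objects; the CLI is a thin wrapper. A first-class
synthetic-data module generates every input with planted ground truth, so
each stage's recovery behaviour is measurable.

## Census (`lectinkit.census`)

Genes are classified from InterProScan-style domain annotations via a fixed
map of the 12 diagnostic Pfam accessions (ABA PF07367, amaranthin PF07468,
CRA PF00704, cyanovirin PF08881, EUL PF14200, GNA PF01453, hevein PF00187,
JRL PF01419, legume PF00139, LysM PF01476, nictaba PF14299, ricin-B PF00652).
Unknown accessions are ignored with a warning — they are simply non-lectin
domains, not errors. A gene with domains from two families is counted in each
family but once in the distinct-gene total; the census reports both sums and
flags such genes, since a census table is ambiguous about them. Percentages
are rounded half-up to one decimal, matching printed-table style. A family is
"represented" iff its count is ≥ 1.

## Duplication calling (`lectinkit.duplication`)

The tandem rule links two genes iff same family, same chromosome, and
intervening-gene count ≤ 10 (boundary inclusive: exactly ten intervening
genes still link). Intervening genes are counted among **all** annotated
genes, not only lectins — a deliberate interpretation, since a gene-distance
threshold in a genome context conventionally refers to the full gene order.
Blocks are transitive closures of pairwise links, so a chain a–b–c is one
block even when a and c alone exceed the gap; this matches how multi-gene
tandem arrays are reported in practice. Because the link relation is an
interval condition on ranks, connected components equal maximal runs of
consecutive linked genes; the test suite nevertheless verifies equivalence
against an explicit all-pairs union-find oracle. Segmental blocks are
consumed from a collinearity table and retained iff Ks ≤ 1.0 (strictly
greater is omitted) and at least one anchor is a lectin.

## Variation (`lectinkit.variation`)

Coding variants are mapped through the spliced CDS in transcript
orientation, complementing alleles on minus-strand genes, and translated
with the standard genetic code; a CDS whose length is not a multiple of
three is a structural error. Features are resolved in the order
exon-CDS → UTR → intron → intergenic.

Allele-frequency cells are percentages of **non-missing** haploid calls,
with denominators recorded; a cell with no calls is NA. The subpopulation
dendrogram uses the RMSD distance on allele *fractions* (0–1) rather than
percentages so that merge heights are scale-free; the scale is configurable.
Pairwise-complete loci are used when cells are missing. UPGMA is implemented
directly: average linkage with size-weighted updates, merge height = half
the merged distance, ties broken toward the lowest-index pair for
determinism. The tests cross-check topology and heights against scipy's
average-linkage on random (tie-free) matrices, and the Newick output parses
as an ultrametric tree.

## Promoter pipeline (`lectinkit.promoter`)

Promoters are the `length` (default 2000) bases strictly upstream of the
translation start, anchored on the ATG by default (the TSS is available via
`anchor="tss"`), clipped at chromosome ends with the clipping recorded.

Motif scanning is per-motif log-odds in bits, log₂(p/background), on both
strands; windows overlapping an ambiguous base score −∞ and are never
reported. This replaces an HMM-based cluster scanner deliberately: when
cluster-level filtering is disabled, the operative output is individual
motif matches, so plain log-odds scanning with a per-motif threshold
(default 6.0 bits, configurable) is the appropriate equivalent. A batch
presence scanner (`motif_presence`) computes promoter-level presence only,
with a fast path for PWMs whose columns take two values; tests pin it to
the per-match scanner.

The functional-region filter merges regions (union of overlapping or
book-ended intervals) and keeps a match iff a **single** merged region
covers ≥ `min_fraction` (default 0.5) of its length — the same semantics as
`intersectBed -f 0.5`. Two nearby regions separated by a gap do not pool
their overlap. The three analysis tracks (open chromatin, conservation,
regulon enrichment) are one pipeline with the filter optional and the
region set selectable.

Regulons are the `top_n` (default 200) genes with the highest **signed**
Pearson correlation to the focal gene — co-expression means positive
co-variation; |r| selection is not used. Ids absent from the id-mapping
table are dropped afterwards, reproducing the ~200 → ~150 shrinkage seen
when converting between annotation namespaces. Pipelines correlate
log2-transformed values (standard for expression data); the transform is a
flag.

Enrichment is presence/absence (≥ 1 retained match), not match counts: the
hypergeometric sampling frame is promoters, not matches. p = P(X ≥ k) for
X ~ Hypergeometric(N, K, n) with the background N = all genes with extracted
promoters (the universe is not otherwise stated by convention, and this is
the set actually scanned). q-values are Benjamini–Hochberg; the final report
keeps motifs with q < 0.05 that are also present in the focal promoter.

## Expression response (`lectinkit.expression`)

Fold change is (treated + ε)/(control + ε) per transcript against the
control of the same tissue and timepoint, ε = 1e−6 by default to keep
zero-expression controls finite (such rows are flagged). Replicates are
averaged before the ratio; the per-gene value is the arithmetic mean over
its transcripts. Significance stars default to a two-tier scheme —
q < 0.001 ⇒ `***`, 0.001 ≤ q < 0.05 ⇒ `**`, nothing otherwise — because the
conventional three-tier legend overlaps its own tiers; a single-star tier
can be configured. FDR values are consumed when the table provides them; for
synthetic tables `replicate_fdr` supplies a stand-in (Welch t-tests of
treated vs control replicates, BH-corrected across strata).

## Domain conservation (`lectinkit.domains`)

One EUL-domain hit ⇒ S-type; two ordered hits ⇒ D-type with the inter-domain
residues as linker; zero hits reject the protein and more than two are
flagged unsupported. Percent identity excludes dual-gap columns from the
denominator and counts single-gap columns as mismatches; percent similarity
additionally counts substitutions scoring positive under BLOSUM62 (the
notion of "similarity" is not standardized, so the matrix is configurable).
Information content is IC = log₂20 − H per column over non-gap residues;
the small-sample correction (19/(2·ln2·n)) is off by default because the
profile is used quantitatively per landmark, not as a rendered logo.
Landmarks are defined in the 151-residue domain frame (1-based): QxW at
34–36 (Q and W fixed, the middle free), D116, F/L118, W136, N143, Q144; a
column map is required when the MSA contains insertions.

## Synthetic data (`lectinkit.simulate`)

All generators draw from per-stream seeded RNGs; identical seed and
configuration give byte-identical files. Defaults are the study conditions:

- **Genome**: 7 chromosomes × 50 genes, 1–4 exons per gene, UTRs trimmed so
  every CDS length is a multiple of three; one planted 3-gene EUL tandem
  array on chr7 (members 0–2 intervening genes apart) plus scattered
  family genes kept ≥ 12 ranks from any same-family gene, so planted arrays
  are recoverable exactly. 5 % of non-family genes carry a decoy non-lectin
  domain to exercise the ignore rule.
- **SNP panels**: 20 loci in gene bodies; six subpopulations of 50
  accessions in two clusters at reference-allele fractions 0.95 vs 0.05
  (a japonica/indica-like split); haploid calls with 2 % missingness.
- **Expression**: 2000 genes × (control + drought/osmotic/ABA/JA) × 2
  tissues × 3 timepoints × 3 replicates. One planted 150-gene module with
  fold changes 4/3/2/0.5 and lognormal noise, sd 0.35 in log₂ units —
  calibrated analytically so that member–member log-scale correlation is
  ≈ 0.9 under the default profile. Background genes are flat lognormal
  noise. A quarter of ids are absent from the id-mapping table.
- **Promoters**: 2000 bp i.i.d. uniform A/C/G/T (so chance-hit rates are
  analytically checkable); the planted motif is an exact consensus
  insertion at probability 0.6 inside the module vs 0.1 outside. The PWM
  library is 10 near-consensus 8-mers (dominant probability 0.999, chosen
  so a full consensus match is required at the 6-bit threshold and chance
  presence per promoter is ≈ 6 %); 9 of them are never planted, providing
  the null. Functional regions cover exactly 30 % of each promoter and
  additionally always cover planted instances (configurable).
- **EUL proteins**: 2 S-type and 3 D-type; every domain is 151 aa with
  Q34/W36, D116, W136, N143, Q144 fixed, position 118 an F/L mixture
  (63/37), all other sites substituted with probability 0.05; N-termini
  19–117 aa and linkers 18–76 aa.

What the generator does **not** emulate: realistic genome composition,
linkage disequilibrium, read-level noise, diploid genotypes, motif
positional preferences, or correlated expression noise. Passing recovery
tests therefore demonstrates correctness of the rules and statistics under
their stated models, not performance on real rice data; the quantities that
depend on the actual rice genome and external databases (genome-wide gene
counts, database SNP tallies, database fold changes, observed cis-element
counts, observed identity/similarity maxima) are out of reach at this scale
and are covered instead by the oracle-equivalence and recovery suites, with
the census arithmetic exercised on the published per-family counts.

## Numerical choices

- Percentages: decimal half-up rounding, one decimal.
- UPGMA ties: lowest-index pair first; distances on fractions.
- BH step-up via statsmodels; p-values validated to lie in (0, 1].
- Hypergeometric upper tail via `scipy.stats.hypergeom.sf(k−1, N, K, n)`.
- PWM pseudocount applied at construction (default 0.5 for count matrices,
  0 for probability matrices); scan scores in float32 in the batch path
  (≈ 1e−3 bits precision, far below any threshold granularity).
- Degenerate inputs raise typed errors (`ConfigurationError`,
  `StructuralError`) rather than propagating NaNs.

## Study sizes

The recovery studies run at 20 seeds (tandem), 100 seeds (regulon and motif
enrichment, at 2000 background genes), 200 seeds (subpopulation
bipartition, on a compact 1-chromosome genome since genome size does not
enter the measured quantity). These sizes give binomial standard errors
≤ 2–5 percentage points on the reported rates while keeping a full
reproduction run to a few minutes.

## Known limitations

- Similarity percentages depend on the chosen substitution matrix; other
  groupings will shift values by a few points.
- The enrichment background is the scanned promoter universe; restricting
  it (e.g. to expressed genes) changes K and N and is the caller's choice.
- The UPGMA tie-break is an arbitrary determinism device; tied topologies
  are reported in one canonical form, not enumerated.
- `replicate_fdr` is a stand-in for externally supplied q-values and is
  labelled as such; with few replicates its power after BH correction
  across thousands of strata is limited.
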