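# Methods

This note documents the models, defaults and numerical choices behind
`cysvarforge`, and what the synthetic-fixture tests do and do not
demonstrate about real data.

## Consequence prediction

Gene models are the CDS features of a GTF/GFF3 file (1-based inclusive
intervals, sorted in genomic order); the spliced CDS must be divisible by 3
and translate without an internal stop under the standard nuclear genetic
code. Genomic and protein coordinates are 1-based at every interface; CDS
offsets are 0-based internally. For an SNV inside a CDS the affected codon
is substituted (the alternate base is complemented on minus-strand models)
and the reference and alternate codons are translated; the call is
classified missense, synonymous or nonsense, and positions outside all CDS
intervals are noncoding. Only SNVs are handled — indels, multi-nucleotide
and splice variants are out of scope — so protein length never changes and
variant-protein residue numbering equals reference numbering everywhere
downstream.

Design choices: a VCF REF base that disagrees with the genome raises an
error (the inputs are inconsistent); an ambiguity code (N) in the genome
skips the variant with a logged warning; calls failing caller filters are
retained and flagged (`--pass-only` drops them); consequences are computed
per supplied transcript, so redundancy control is delegated to a
non-redundant transcript list supplied by the caller. Variants with
identical protein-level change seen in both RNA and exome data merge into
one record with the union of sources. Rarity is an exact
(chromosome, position, ref, alt) membership test against a common-SNP key
set; CADD phred scores join on the same key.

## Combinatorial database construction

Per protein, variants are clustered by single linkage on sorted residue
positions with gap ≤ `window_size` (default 30 residues); combinations
never cross clusters, which bounds the blow-up while still pairing variants
close enough to co-occur on one tryptic peptide. Within a cluster every
nonempty subset is applied, except that two alternate alleles at the same
residue are never co-applied (biologically impossible on one molecule);
with gᵢ alleles at each of k sites the subset count is ∏(gᵢ+1) − 1, i.e.
2ⁿ − 1 for n distinct sites. The count is evaluated arithmetically so the
combinability guard never materializes a billion-scale enumeration;
enumeration itself is a generator. The cap (`max_combinable_variants`,
default 25 per protein) switches hyperpolymorphic proteins to Single-Each
output (one variant per sequence).

The emitted database is peptide-level: tryptic peptides with ≤ 2 missed
cleavages that cover at least one applied variant, filtered to length 7–50
and monoisotopic mass 500–5000 Da, and excluding any sequence identical to
a reference tryptic peptide of the same protein (such a peptide carries no
variant evidence). Exact-sequence deduplication keeps the first entry after
a deterministic sort by (accession, start, sequence, variants) — forging
twice yields byte-identical FASTA — and a sidecar TSV retains every
(protein, variants, sources) provenance for each peptide. `search` mode
writes accession-only headers (engine-friendly); `detailed` mode writes
accession|gene|transcript|variants|sample|sources. Decoys are per-record
sequence reversals with a `rev_` accession prefix (an involution).

## Proteolysis and masses

Trypsin cleaves after K/R; by default the K/R–P bond is not cleaved (the
common convention — the strict mode cleaves regardless, since search
engines support both). Digestion is fully tryptic; half-tryptic
identifications occur in practice but are not modeled (known limitation).
Monoisotopic residue masses come from the standard table; water
18.010565 Da, proton 1.007276 Da; masses are reported to 5 decimals.
Variable cysteine modifications carried by the workflow:
carbamidomethyl +57.02146, light biotin-azide +463.2366, heavy
biotin-azide +469.2742 (heavy − light ≈ 6 Da nominal), Met oxidation
+15.9949. Fragment ions are singly-charged b/y series with modification
shifts applied positionally; b_i + y_{n−i} equals the precursor neutral
mass plus two protons.

## Two-stage search and FDR

Stage 1 searches all spectra against the reference database (targets +
decoys); target matches with q ≤ the FDR level (default 1%, configurable)
define the excluded-scan list — scan numbers with leading zeros stripped,
deduplicated, one integer per line — and those scans are removed before
stage 2 searches the variant database. q-values for stage 2 are computed
only within stage-2 matches (class-specific FDR), so an abundant wild-type
peptide can never absorb a variant spectrum and vice versa.

The scorer is intentionally simple: candidates within the precursor
tolerance (default 20 ppm) are scored by matched b/y fragment count with a
continuous tie-break on mean ppm error (score = n_matched − 0.5·err/tol),
and the best target and best decoy per spectrum are kept. The q-value
estimator is the plain ratio FDR̂(s) = #decoys≥s / max(1, #targets≥s),
monotonized and clipped to [0,1]; a conservative (+1 numerator) variant is
available. Rescoring (PeptideProphet/Percolator-style semi-supervised
models) is deliberately not implemented — the raw score feeds the estimate
directly, which is a stated limitation of the stand-in engine, not of the
two-stage scheme. Peptide-level q uses the best PSM per peptide sequence;
protein-level q uses the best peptide per accession with alphabetical razor
assignment on ties.

## Cysteine site mapping

Peptides are located by exact substring match against the protein database
(I/L distinct; no tolerant alignment). A peptide matching more than one
protein is multi-mapped and reported separately rather than contributing an
ambiguous site — multi-mapping is a real hazard, since distinct genes can
share variant peptide sequences exactly. Site classes: *acquired* (variant
alt residue is C), *lost* (variant ref residue is C), *reference* otherwise;
a reference cysteine is annotated variant-proximal when a variant lies
within the linear window (default 10 residues, boundary inclusive — one
shared window parameter serves both the results-style "within 10 aa" and
functional-site "±10 aa" uses; users who need different windows pass them
explicitly). Labeling state (light/heavy/both) is the union over observed
rows. Site identifiers follow the accession_position_labelingstate
convention; accession_position keys support joins against external cysteine
databases, and (chrom, pos, ref, alt) keys against clinical variant tables.
Non-cysteine peptides are dropped in enrichment mode and retained in bulk
(high-pH) mode.

## Ratio aggregation and ligandability

Row rules: Met-oxidized rows excluded; both channels present →
log₂(H/L); unpaired heavy-only/light-only rows kept at ±log₂ 20 (a zero
intensity counts as absent rather than an infinite ratio); both absent is
an error. Site aggregation: median log₂ ratio over peptide rows per
replicate (midpoint convention for even counts), then mean and sample SD
(n−1) across replicate medians — the median/SD conventions are documented
choices where common practice varies, and the SD is computed on the log₂
scale, matching the magnitude of an SD ≤ 1 filter. Sites pass with ≥ 2
replicates and SD ≤ 1; the SD filter can be disabled for ratio-skew
benchmarking. Ligandable means passing filters with mean log₂ ratio
strictly > 2, under the DMSO = heavy / compound = light orientation
(`swap_channels` inverts). All emitted ratios lie in [−log₂ 20, +log₂ 20]
and aggregation is invariant to row order.

## Synthetic fixtures

The generators produce every input the pipeline reads, deterministically
under a fixed seed:

- **Genome/models/proteome**: random proteins (length 60–120, residue
  frequencies mildly favoring K/R/C/L/S so tryptic peptides and cysteines
  are plentiful), back-translated through random codon choices, placed on
  3 chromosomes with ~40% minus-strand genes and ~50% two-exon genes.
  Translating each model's spliced CDS reproduces its proteome record; the
  toy GTF writes stop-exclusive CDS intervals.
- **Variants**: SNVs at random coding positions; plus-strand C→T and G→A
  changes (the same transition read from either strand) carry weight 10
  versus 1 for other substitutions, emulating the CpG-deamination signature
  that favors gain-of-cysteine codons. ~10% of calls are flagged non-PASS
  and ~50% designated common. A truth table of expected consequences is
  computed in transcript space, independent of the genomic-coordinate
  prediction path it is tested against.
- **Quant tables**: triplicate tables per mixing design of the six-design
  benchmark (1:1, 10:10, 1:4, 4:1, 1:10, 10:1), 500 peptides per replicate,
  multiplicative lognormal noise at 10% CV (mean-one convention), plus
  planted heavy-only, light-only and Met-ox rows under separate site ids to
  exercise the caps and filters without disturbing the design medians.
- **Spectra**: b/y ladders with uniform ppm jitter (default 5 ppm) plus 20%
  noise peaks; noise spectra reuse a true precursor (so database candidates
  exist) with random peaks; occasional zero-padded scan ids exercise the
  excluded-scan normalization; a sidecar maps scans to planted identities.

What passing these tests shows — and does not. The fixtures exercise the
bookkeeping (coordinates, strands, combinatorics, FDR mechanics, capping
and filter rules) exactly, and the recovery/calibration claims hold under
the stated noise model. They do not emulate chromatography or retention
time, isotope envelopes, charge-state or intensity-dependent detectability,
co-eluting chimeric spectra, shared peptides at proteome scale, or real
score distributions from a production search engine; absolute
identification rates on real data will differ.

## Numerical and protocol choices

- Problem sizes: the end-to-end synthetic run uses 20 proteins, 40 SNVs,
  ~200 spectra; the FDR calibration uses 20 replicates of 200 planted
  scores; the ratio benchmark uses 500 peptides × 3 replicates per design.
  These sizes give stable medians and Monte-Carlo error small enough for
  the stated tolerances while keeping a full run under a minute on one CPU.
- FDR calibration is asserted as |mean FDP − 1%| ≤ max(1 pt, 3 SEM) over
  replicates; the plain d/t estimator runs slightly conservative (mean FDP
  ≈ 0.5% in the shipped configuration), which is the expected direction.
- Tolerances: design-recovery within 5%; mass identities to 5 decimals;
  exact Mann-Whitney enumeration only for tie-free samples with
  n₁+n₂ ≤ 8, tie-corrected normal approximation otherwise; KS p asymptotic.
- Degenerate inputs: empty samples are errors for distribution tests; a
  pooled proportion of exactly 0 or 1 returns z = 0, p = 1 by convention;
  a search with no decoys returns q = 0 everywhere with a warning;
  residues without Cα coordinates are skipped with a warning and a missing
  focal Cα is an error.
- p-values are reported raw (no multiple-testing correction by default); a
  Benjamini-Hochberg utility is provided.
- Every pipeline run writes a manifest (tool version, seed, config hash);
  reruns from one seed are byte-identical across all text outputs.

## Known limitations

No indel/splice/MNV consequences; no isoform-level protein inference or
spectral counting; no semi-tryptic database forging (the matcher could
score half-tryptic candidates, the forge does not emit them); no rescoring;
no MS1 feature extraction (intensities are consumed, not computed); no
structure-to-sequence alignment (the Cα analysis assumes a supplied
residue-number correspondence); standard genetic code only.
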