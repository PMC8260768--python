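# Methods

This note records the models implemented by `tallfusion`, the conventions
and numerical choices behind them, what the synthetic-data generators do
and do not emulate, and the design decisions taken where more than one
reasonable reading existed.

## Somatic variant filter

A candidate variant carries paired tumor/remission read counts; VAF =
alt/(ref+alt), undefined at zero depth (such records are rejected with
rule `no_coverage`). A record is called somatic iff all four rules hold:

1. `min_tumor_vaf` — tumor VAF ≥ 0.05 (inclusive, "at least 5 %");
2. `min_relative_diff` — (VAF_T − VAF_R)/VAF_T ≥ 0.20. The 20 % threshold
   is read as *relative to the tumor VAF*; because the wording also admits
   an absolute percentage-point reading, `FilterParams(diff_mode=
   "absolute")` switches to VAF_T − VAF_R ≥ 0.20;
3. `fisher_significance` — two-sided Fisher exact p < α on the 2×2 table
   [tumor_alt, tumor_ref; remission_alt, remission_ref]. No significance
   level is prescribed for the rule, so α defaults to the conventional
   0.05 and is configurable;
4. `max_remission_vaf` — remission VAF < 0.05 (exclusive, "<5 %").

Every record receives a decision listing the rules it failed, so filter
audits can be reconstructed from the output alone. The Fisher p-value sums
hypergeometric probabilities ≤ the observed table's probability, with the
conventional (1 + 1e-7) relative tie tolerance; degenerate margins return
p = 1. The test suite checks it against exhaustive enumeration over all
2×2 tables with total ≤ 40 and against an independent library
implementation. The filter is monotone in tumor alt count at fixed depth
(checked as a property).

## Fusion transcript and protein model

Gene models are ordered exon lists (0-based half-open genomic intervals in
transcription order; minus-strand genes therefore list decreasing
coordinates) with a protein length and named domains in 1-based inclusive
residue coordinates. A fusion breakpoint must be intronic — exonic
breakpoints raise, since only exon-level structure is modelled — and every
coordinate within the same intron yields the same fusion transcript: the
5′ gene's exons up to the breakpoint intron followed by the 3′ gene's
exons after its breakpoint intron. A breakpoint downstream of the 5′
gene's last exon retains the whole gene.

The fusion protein joins residues 1..a_end of protein A to residues
b_start..b_end of protein B; total length = a_end + (b_end − b_start + 1).
A domain is retained iff fully contained in its retained segment (a
domain straddling a_end is never reported retained); B-domain coordinates
shift by a_end − b_start + 1. The motivating chimera (A segment 1–182,
B segment 52–271) is 402 residues; removing the 55-residue N-terminal
β-catenin binding region leaves 347. The reading frame is assumed
preserved; frame checking is not modelled.

`classify_breakpoint_read` decides junction support by requiring, at
adjacent read positions, ≥ m consecutive nucleotides matching each side of
a junction-centred window (default m = 20, ≤ 2 substitutions per side).

## Long-read demultiplexing and read classification

Reads of length ≤ 250 nt are set aside (`too_short`). For longer reads
the first and last 200 nt (clipped, and possibly overlapping, for short
reads) are scanned against every whitelist barcode in forward and
reverse-complement orientation by sliding Hamming distance — substitutions
only, leftmost offset on ties, non-ACGT characters mismatching every
base. The best hit wins if it has ≤ 1 mismatch ("fewer than two"); when
two *distinct* barcodes tie at the best distance the read is `ambiguous`
rather than arbitrarily assigned — the safer convention, since the
matching strategy gives no basis for breaking such ties. Distance is
Hamming rather than edit distance: direct sequence matching implies no
indel handling, and the substitution-only error model of the simulator
matches this assumption.

Classification is marker-based: *fusion* = 5′-gene exon-4 marker AND
junction marker AND 3′-gene exon-3 marker; *canonical* = 5′-gene exon-4
AND exon-7 markers; anything else *other*, with reads matching both rule
sets flagged as conflicts. Each marker search tolerates substitutions up
to 10 % of the marker length; this marker search replaces the original
per-cell consensus-assembly/alignment route, and the 10 % tolerance is a
documented stand-in calibrated to the substitution error rates the
simulator produces. Demultiplexing conserves counts exactly
(assigned + ambiguous + unassigned + too_short = total) and per-cell FASTQ
files contain exactly the assigned reads.

## Expression and signatures

* **TPM** — per sample, rate_g = count_g / length_kb_g and TPM_g =
  rate_g / Σrate × 10⁶, so columns sum to 10⁶; all-zero samples cannot be
  normalized and stay zero with a warning.
* **Cell QC** — drop iff ribosomal fraction > 0.6 OR mitochondrial
  fraction > 0.1 OR expressed genes < 200, all strict, matching the
  stated boundary semantics (a cell at mito fraction exactly 0.1 is kept).
* **DE stand-in** — Welch t on log2(CPM+1) with BH adjustment
  (statsmodels). This is deliberately simple: it exists so the pipeline
  runs end-to-end on synthetic data, and externally fitted DE tables
  (negative-binomial GLMs etc.) can be supplied in its place. Zero-variance
  genes get p = 1.
* **Signature derivation** — up = {FC > 2 and p_adj < 0.05}, down =
  {FC < −2 and p_adj < 0.05}, both thresholds strict (FC exactly 2 is
  excluded).
* **Bulk scoring** — each signature gene z-scored *across samples*, the
  per-sample mean taken over signature genes, and the means z-scored
  across samples. The phrase "z-score scaling across signature genes" is
  ambiguous between gene-wise and sample-wise scaling; the gene-wise
  construction is the standard one and is used here. All z-scores use the
  sample (n−1) SD — pinned by a hand-computed two-sample test (values
  (1, 3) → scores ∓0.7071). Constant genes are dropped with a warning;
  gene-wise scaling makes the score invariant to affine per-gene
  transformations of the input.
* **Per-cell scoring** — on log-normalized data (counts per 10,000 then
  log1p), genes are ranked into 24 equal-occupancy bins by average
  expression; for each signature gene, 100 control genes are drawn from
  its bin (with replacement only when the bin is too small, logged); raw
  score = mean(signature) − mean(controls), then z-scored across cells.
  Seeded and deterministic.
* **Ranking statistic** — −sign(log2FC)·log10(p_adj), descending, ties
  broken by gene id; zero p_adj clipped to the smallest positive float.
* **Correlation ranking** — Pearson r of every gene against an anchor
  (e.g. the 3′ fusion partner) across cells; constant genes excluded,
  the anchor excluded from the top-k. The exact normalization layer
  behind the original correlation analysis is under-specified;
  CP10K-log1p is used.

## Pre-ranked enrichment

The weighted KS running sum increments by |s|^w / Σ_hits |s|^w at set
members and decrements by 1/(N − n_hit) at non-members; ES is the running
value of largest magnitude, taking the earliest extremum on exact ties.
The null resamples gene sets of equal size uniformly (gene-set
permutation — the module consumes pre-ranked lists only, so phenotype
permutation is not applicable); p = (1 + #{|ES⁰| ≥ |ES|})/(n_perm + 1),
and NES = ES / mean(|ES⁰| among null scores of matching sign) —
conventions differ between implementations, so this sign-matched
normalization is stated explicitly. With weight 0 the ES is invariant
under monotone transformations of the ranking scores. If every hit weight
is zero the score falls back to unweighted increments with a warning.

## Limiting dilution and co-occurrence

Single-hit model: P(response) = 1 − e^(−d·f). The log-likelihood
Σ r log(1 − e^(−df)) − (n − r) d f is maximized on log f by bounded 1-D
search over f ∈ [1e-9, 1) with xatol 1e-12, reproducing the single-dose
closed form −log(1 − r/n)/d to ~1e-10 relative. Saturated tables (every
graft responds) and all-negative tables are rejected as uninformative.
The default 95 % CI is Wald on log f with the expected Fisher information
I = Σ n (df)² e^(−df) / (1 − e^(−df)) — the standard complementary
log-log GLM standard error, cross-checked against an independent GLM fit
in the tests; a profile-likelihood CI is available for small samples.
Two conditions are compared by a likelihood-ratio statistic against
χ²(1).

Calibration and recovery are assessed by simulation at the study design
(dose ladder 2×10³–2×10⁶, 5 animals per dose). Replicates in which every
graft responds carry no information about f and are excluded from
recovery/coverage summaries (about a third of replicates at f = 1/1243,
where even the lowest dose responds with probability ≈ 0.80). The LR
test's type-I error is evaluated at a frequency bracketed by the dose
ladder (f = 1/20 000), the regime the assay is designed for and where the
χ² approximation is expected to hold; at frequencies outside the ladder
the test is conservative (empirical type-I below nominal), never
anti-conservative.

The co-occurrence odds ratio is (a·d)/(b·c) with the Haldane–Anscombe
0.5 correction applied (and flagged) only when a zero cell exists; the
p-value is always the uncorrected two-sided Fisher exact test. Because
the original per-patient 2×2 counts live in supplementary data, the test
suite uses a synthetic reconstruction of the cohort table ([[6, 6],
[24, 140]]: 12 fusion-positive patients, 6 with the RAS-pathway
mutation) chosen by integer search to be consistent with both published
summary statistics (OR 5.833, p 0.0067) and the cohort structure; it is
labelled as reconstructed wherever it appears.

## Synthetic data generators

All generators are pure functions of their parameters and seed
(numpy `default_rng`); moments are verified within 3 Monte-Carlo SE.

* **Paired variants** — somatic records draw tumor alt ~ Binomial(depth,
  VAF) with remission VAF 0; germline records use VAF 0.5 in both
  samples. Defaults: depth 100; the benchmark condition for filter
  sensitivity/specificity uses somatic VAF 0.25 at depth 100.
* **Long reads** — per-exon 40-nt random marker sequences (fixed by seed,
  on a stream decoupled from the whitelist's so the two can share a seed
  integer); fusion body = 5′ exons 1–4 + 3′ exons 3–5, canonical body =
  5′ exons 1–7; junction marker spans the last 20 nt of exon 4 and first
  20 nt of the 3′ gene's exon 3. Each read embeds its cell's 16-nt
  barcode near one end (reverse-complemented at the 3′ end), with short
  random pads, length always > 250 nt, substitution errors applied
  uniformly (default 0.5 %). Not emulated: indels, realistic nanopore
  error profiles, UMIs, doublets, chimeric artefacts — so passing
  demultiplexing tests bound performance under the substitution-only
  model, not on real nanopore data.
* **Expression** — negative-binomial counts with log-normal gene means
  (log-mean 3, log-SD 1), dispersion 0.1 by default; planted genes
  shifted ±log2_effect (default 2, i.e. 4-fold) in group A; gene lengths
  uniform 200–10 000 bp. Real RNA-seq features not emulated: library-size
  imbalance beyond sampling noise, batch effects, gene–gene correlation.
* **Limiting dilution** — responders ~ Binomial(n, 1 − e^(−d·f)) at the
  study's dose ladder, 5 animals per dose by default.

## Problem sizes used in the validation suite

Filter benchmark: 200 somatic + 200 germline records. Demultiplexing:
8 cells × 50 reads (error-free truth recovery) and 10⁴ random
Hamming-scan instances against a per-offset oracle. Limiting dilution:
500 recovery replicates and 2000 null replicates for LR calibration.
Signature pipeline: 2000 genes, 10 vs 10 samples, 50 + 50 planted genes.
Enrichment: exhaustive oracle comparison over every gene-set placement
with N ≤ 20 and |set| ≤ 5, and 1000 independent null datasets at
n_perm = 1000 for the uniformity check.

## Known limitations

* The DE stand-in is a t-test on transformed counts, not a count GLM;
  it is adequate for the planted-effect recovery it is used for, not a
  replacement for a dedicated DE package on real data.
* The demultiplexer has no indel handling by design; nanopore indel
  errors would degrade real-data assignment rates relative to the
  substitution-only simulations.
* Enrichment p-values use gene-set permutation, which treats genes as
  exchangeable; inter-gene correlation on real data makes these p-values
  anti-conservative relative to phenotype permutation.
* The Wald CI on log f is asymptotic; at the assay's design sizes
  (5 animals per dose) its empirical coverage is slightly above nominal,
  as the simulation study quantifies.
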