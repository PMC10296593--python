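# Methods

This note documents the models, parameter choices and numerical conventions
behind each stage of the pipeline, what the synthetic-data generators do and
do not emulate, and the design decisions taken where the problem was
genuinely open.

## Gene model and isoform nomenclature

A gene is an ordered list of numbered exons (1-based numbers, 0-based
half-open genomic coordinates internally; BED12 is passed through unchanged
and GFF3 is converted from 1-based closed at the boundary). Exon numbering
follows the longest annotated transcript so that every possible exon has a
stable number regardless of which isoform a read comes from. The alternative
splicing region (ASR) is a configuration input — a contiguous sub-range of
exon numbers, default 12–17 — rather than a hard-coded property, so the
pipeline generalizes to other genes with a localized splicing hotspot.

Isoforms over the ASR are named by their excluded exons in ascending order
(Δ14Δ16), with "long" for the pattern including everything. The naming is a
bijection between ASR subsets and names (tested exhaustively for the 64
subsets of a 6-exon ASR), and the parser accepts an ASCII `d` alias for Δ so
shell usage does not require Unicode input.

## Read simulation

`simulate_reads` draws each read's isoform from the configured mixture,
concatenates the included exon sequences (the two ASR-flanking anchor exons
are always present — in the real assay the PCR primers sit in them), then
applies independent per-base errors: substitution (uniform over the three
other bases), deletion, and insertion (one random base per inter-base slot).
Reads are reverse-complemented with probability 0.5 by default, since a PCR
amplicon has no strand preference, and written as FASTQ with constant Q20
qualities. Defaults are 10,000 reads at 5% substitution + 1.5% insertion +
1.5% deletion — a read-quality regime typical of current long-read amplicon
data after basecalling.

The generator is intentionally simple in three respects: no homopolymer or
sequence-context error bias, no quality-value structure, and no PCR
amplification bias between isoforms of different lengths (a bias the real
data is known to exhibit). Passing tests therefore demonstrate that the
caller is robust to uniform indel/substitution noise at realistic rates —
not that it is robust to every Nanopore-specific artifact. The synthetic
gene (30 exons of 90–180 bp, ASR exons 12–17) matches the target gene's
geometry; all generators are byte-deterministic given a seed.

## Isoform calling

Rather than spliced genome alignment followed by transcript collapse, the
caller exploits the amplicon design directly: with a known, small exon set,
per-exon presence calling is exhaustive and auditable.

* **Orientation**: both anchor exons are infix-aligned (edlib, edit-distance
  alignment of the whole exon inside the read) against the read and its
  reverse complement; the strand with the higher summed identity wins, with
  ties or identities below the floor reported as undetermined.
* **Presence**: an exon is present when matched bases / exon length ≥ 0.7
  over ≥ 0.8 of the exon's length. The 0.7 floor tolerates ~10–15% read
  error on exons ≥ 50 bp while rejecting random-sequence matches (random
  DNA reaches ~0.6 identity against a ~150 bp exon; the orientation test
  asserts ≥ 96% of random reads come back undetermined). Exons shorter than
  25 bp would be hit by chance too easily and require identity ≥ 0.9; the
  default synthetic gene has none.
* **Chaining**: called exons must appear at strictly increasing positions
  along the read, and both anchors must be present; violations leave the
  read unassigned rather than guessing.
* **Quantification**: reads collapse by inclusion pattern. An isoform is
  retained only with ≥ 100 reads *and* ≥ 1% of assigned reads (the two
  filters are evaluated together on the full count table; "or fails either"
  removes it). Percentages are computed over assigned reads — the assay
  reports fractions of sequenced cDNAs, not of raw reads — and are not
  re-normalized after pooling, so retained + others = 100 exactly.

Intron retention is deliberately out of the core path: in this gene
retention is rare (~2% of transcripts, one intron) and falls outside the
ASR, so it does not affect pattern calling over exons 12–17.

## Exon skipping and PSI

skip(e) sums the percentages of retained isoforms whose pattern excludes
exon e; PSI(e) = 100 − skip(e) on unrounded fractions, so the pair always
sums to exactly 100. Published tables rounded to integers can be internally
inconsistent by one unit (a skip of 61 printed beside a PSI of 38); all
comparisons in this package use the unrounded arithmetic and round only for
display. Isoforms pooled into "others" have lost pattern resolution and are
excluded; a warning fires when the others bucket exceeds 5% of reads since
exon-level statistics then ignore a non-trivial fraction of the sample.

Group comparison is a two-sided Mann–Whitney U per exon with
Benjamini–Hochberg adjustment across the tested exons. No distributional
claim is defensible at n = 5 vs 9 samples, so a rank test is the natural
choice; with it, the bundled bladder cohort reproduces the expected
conclusion (no exon differs significantly between normal and tumor, minimum
adjusted p ≈ 0.46), while a 40-point PSI shift at the same sample sizes is
reliably detected.

## Pulldown simulation and interactome scoring

The simulator plants proteins with a chosen log2 LFQ enrichment and a chosen
linear iBAQ level over a background of null proteins (per-protein mean
log2 intensity ~ N(25, 2), replicate noise sd 0.3, three replicates per
group). Missingness is logistic in the low-intensity tail (midpoint 21,
steepness 0.8, maximum rate 0.9) — the left-censoring mechanism that the
down-shifted-Gaussian imputation assumes, which is exactly why it is
simulated that way: it makes the imputation stage testable on data where its
model is true. Real AP-MS data adds peptide-level effects (shared peptides,
ionization differences) that are not modeled.

Preprocessing removes contaminant and reverse-decoy rows and proteins
identified in fewer than two replicates (the three filters commute), then
log2-transforms LFQ intensities. Imputation fills each replicate column's
missing cells from Normal(m − 1.8·s, (0.3·s)²) with m, s the column's
observed mean and standard deviation — the width/shift parameters are
interpreted as multiples of the per-column sd, the established convention.

The enrichment statistic is (mean_GFP − mean_ctrl)/(S0 + SE_pooled) with
S0 = 1, which damps the spuriously large t values that near-zero variance
produces at n = 3. Significance is controlled by group-label permutations:
all distinct label reassignments except the identity and its complement
(those two reproduce the observed |statistic| exactly, letting a strong true
positive inflate its own null), capped at 250. The estimated FDR at
threshold t is the smoothed expected null count ((#perm stats ≥ t) + 1) /
(#permutations + 1) divided by the observed count ≥ t; each protein's q is
the minimum estimate over thresholds that include it. The add-one smoothing
(the standard finite-permutation correction) matters: without it the
top-ranked null protein's FDR estimate collapses to exactly zero in a few
percent of datasets, and with only 18 distinct 3v3 permutations that is the
difference between a calibrated and an anti-conservative test. A
consequence worth knowing: with 18 permutations a *single* enriched protein
cannot reach q ≤ 0.01 (the floor is 1/19 per discovery) — five or more
co-discovered proteins can, which is the situation in any real pulldown of
a complex-forming protein. When fewer than 10 distinct permutations exist
the test falls back to Benjamini–Hochberg on the classical pooled-variance
t p-values.

Stoichiometry: per protein, the mean over GFP replicates of (iBAQ − mean
control iBAQ), clipped at zero after averaging (negative abundances are
subtraction artifacts), divided by the anchor protein's value (default
PAXIP1, the conventional reference subunit). Per-replicate ratios are kept
for error bars. Complex membership (MLL3/MLL4 COMPASS, PR-DUB, MiDAC) ships
as an editable TSV so the biology stays data, not code.

## Differential peaks

Spike-in normalization divides each condition's counts by its exogenous
spike-in total and rescales by the geometric mean of the totals to keep
values count-like. Fold change is the signed linear ratio of normalized
counts with a +1 pseudocount, negative when condition B is lower; linear
(not log2) because the category thresholds are quoted as ±2/±4 ratios. The
pseudocount makes fold changes finite at zero counts at the cost of exact
scale invariance: rescaling both a condition's counts and its spike-in total
together preserves categories exactly and fold changes to well under 1% at
realistic depths.

The significance test is a two-sided comparison of two Poisson rates
(scipy's E-test) on rounded normalized counts — a pragmatic choice for
single-replicate count data; no test is canonical here and the choice is
isolated in one function. Categories partition (FC, p) space exactly as
quoted: FC ≤ −4 strongly down, −4 < FC < −2 mildly down, −2 ≤ FC ≤ 2
common, 2 < FC < 4 mildly up, FC ≥ 4 strongly up, and any peak with
p ≥ 1e-4 is common regardless of FC.

The background threshold is ceil(median + 3 × 1.4826 × MAD) of coverage in
~10,000 random peak-sized regions (lengths uniform in 540 ± 100 bp, sampled
rejecting overlap with called peaks, seeded). The 1.4826 constant makes the
MAD estimate a normal sd, so median + 3·scaled-MAD covers ~99% of a
normal-like background; on integer coverages with median 1 and MAD 1 this
gives ceil(5.45) = 6. Rounding is upward: a threshold is a ceiling on
background, and rounding down would admit it. A peak is condition-specific
when its coverage is ≤ the threshold in the low condition and ≥ twice the
threshold in the high one, guaranteeing at least a two-fold change over
background. Peak calling itself, alignment, and genomic annotation are
upstream of this package.

The peak simulator draws Poisson counts (matching the test's model — by
design, so the classifier is exercised under its own assumptions) around
means whose normalized ratio equals the planted fold change, with planted
categories placed well inside their intervals; overdispersion and
copy-number structure of real coverage are not modeled.

## Problem sizes and determinism

Defaults throughout are the sizes the analyses are designed around: 10,000
reads per amplicon sample, 1,000 background proteins × 3v3 replicates per
pulldown, 200 planted peaks + 10,000 background regions per comparison, and
50 replicate simulations for null calibration. Every stochastic component
takes an explicit seed; identical seeds give byte-identical FASTQ/TSV
outputs and reports.

## Known limitations

* The error model is uniform per base; callers facing homopolymer-biased
  error or systematic strand effects may need stricter thresholds.
* Exon-presence calling assumes amplicon reads over a known model; it does
  not discover unannotated exons or handle genome-scale spliced alignment.
* The permutation FDR's granularity at 3v3 (18 permutations) is coarse;
  more replicates sharpen it.
* Single-replicate peak comparisons cannot estimate biological variance;
  the Poisson test captures only counting noise.
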