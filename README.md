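# utxsplice

Tools for quantifying alternative splicing of the *UTX*/*KDM6A* histone
H3K27 demethylase gene — and for the downstream analyses its isoforms feed
into: interaction proteomics and differential genome occupancy.

The central region of *UTX* mRNAs, exons 12–17, is an **alternative splicing
region (ASR)**: exons 13, 14 and 16 are variably included, producing isoforms
named by the exons they lack (Δ14, Δ14Δ16, …; the isoform containing every
exon is called "long"). Exon 14 encodes a nuclear localization sequence, so
the isoform mix controls where the protein acts. This package re-implements
the full quantitative pipeline on long-read amplicon data as a tested,
reusable library, with seeded synthetic-data generators standing in for raw
sequencing and mass-spectrometry data so that every stage can be validated
against known ground truth.

## What it computes

**Isoform calling** (`isoform_caller`). Each long cDNA read is an RT-PCR
amplicon spanning the ASR, so spliced alignment reduces to per-exon presence
calling: every ASR exon is locally aligned (edlib) against the oriented read
and called present when identity ≥ 0.7 over ≥ 0.8 of its length, with called
exons required to appear in transcript order. Reads collapse by inclusion
pattern; isoforms with fewer than 100 reads **or** under 1% of assigned reads
are pooled into "others".

**Exon statistics** (`splice_stats`). For exon *e* with isoform percentages
*p_i* over patterns *S_i*:

    skip(e) = Σ_{i : e ∉ S_i} p_i        PSI(e) = 100 − skip(e)

Group comparison uses a two-sided Mann–Whitney U test per exon with
Benjamini–Hochberg adjustment across exons.

**Interactome scoring** (`interactome`). GFP vs bead-control pulldown
matrices are filtered (contaminants, decoys, single-replicate IDs),
log2-transformed, and missing values imputed from a down-shifted Gaussian
(per column: mean − 1.8·sd, width 0.3·sd). Enrichment uses the S0-moderated
t statistic

    t_S0 = (mean_GFP − mean_ctrl) / (S0 + SE_pooled),   S0 = 1

with permutation-based FDR control at q = 0.01, and iBAQ stoichiometries are
control-subtracted and normalized to the PAXIP1 subunit.

**Differential peaks** (`peak_diff`). Two-condition peak counts are
normalized by exogenous spike-in totals, tested by a two-sided Poisson rate
comparison, and classified into five categories by signed fold change
(strong/mild down, common, mild/strong up at |FC| thresholds 2 and 4) with a
p < 1e-4 significance gate. Condition-specific peaks are called against a
background threshold ceil(median + 3 × 1.4826 × MAD) of coverage in ~10,000
random peak-sized (540 ± 100 bp) regions.

**Synthetic data** (`synthetic_data`). Deterministic generators for
error-bearing amplicon reads from known isoform mixtures, pulldown matrices
with planted interactors and left-censored missingness, and peak tables with
planted fold changes — each paired with a truth table.

## Worked example

```bash
utxsplice demo --seed 1 --n-reads 10000 --out demo_out
```

simulates 10,000 reads at 5% substitution + 3% indel error from a bladder
carcinoma cell-line-like mixture (Δ14 39%, Δ14Δ16 27%, long 14%, Δ16 8%,
Δ13 6%, Δ13Δ16 4%, plus 2% of sub-1% isoforms), calls and quantifies the
isoforms, and prints a recovered-vs-truth report:

| isoform | simulated % | recovered % |
|---|---|---|
| Δ14 | 38.52 | 38.50 |
| Δ14Δ16 | 27.18 | 27.14 |
| long | 14.08 | 14.11 |
| Δ16 | 7.89 | 7.92 |
| Δ13 | 5.86 | 5.86 |
| Δ13Δ16 | 4.49 | 4.49 |
| Δ13Δ14 | 1.01 | 1.01 |
| others | — | 0.97 |

Every recovered percentage sits within a few hundredths of a point of the
simulated truth at this error rate (Δ13Δ14 happened to draw just over 100
reads and 1%, so it cleared both abundance filters). The same run scores a
synthetic pulldown ("planted interactors recovered: 18/18; false positives:
0") and classifies a synthetic peak table ("planted-category agreement:
98.5%; background threshold: 6").

The same stages are available individually as `utxsplice simulate-reads`,
`call-isoforms`, `psi`, `interactome` and `peak-diff`; see `--help` on each.

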