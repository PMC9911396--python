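# ervkit

Retroelement-centric regulatory genomics toolkit: nanoCAGE TSS/promoter
processing, repeat-subfamily differential-expression statistics, ChIP-peak
repeat-class enrichment, HERVH–lncRNA overlap/correlation, and paired-LTR
Kimura 2-parameter divergence dating.

## The problem

Human endogenous retrovirus H (HERVH) and its long terminal repeat LTR7 are
highly expressed in pluripotent stem cells, where they act as promoters and
enhancers and give rise to pluripotency-associated lncRNAs (LINC-ROR, ESRG).
Studying how transcription factors fine-tune HERVH requires a chain of
computations that recur across such studies:

- **TSS mapping** from 5′-capture (nanoCAGE) reads: demultiplex by a 6-nt
  sample barcode (Hamming distance ≤ 2, ties unassigned), trim the 11-nt
  non-genomic prefix, cluster read 5′ ends into peaks, keep peaks supported
  by ≥ 30 unique reads, classify them against gene models (< 1 kb from an
  annotated TSS ⇒ TSS peak; else 3′UTR > exonic > intronic > intergenic),
  and extract 300-bp proximal promoters (250 bp upstream / 50 bp downstream)
  for known-motif enrichment (Fisher exact, BH-corrected; significant at
  p < 0.01 and q < 0.01).
- **Repeat-subfamily expression shifts**: per-locus counts → CPM, per-locus
  log2 fold change between knockdown and control, and a two-sample
  Kolmogorov–Smirnov test of each retrotransposon subtype (LINE, SINE, LTR,
  ERV1, LTR7/HERVH, MERs, other-ERV1) against a reference distribution;
  Pearson correlations of fold changes across perturbations and between
  HERVH units and their overlapping lncRNAs (expressed = mean control
  CPM > 1).
- **ChIP-peak enrichment** over a repeat class: A = fraction of peak base
  pairs on the merged feature set, B = fraction of the genome covered by it,
  score = log2(A/B), significance from a permutation null that re-places
  each peak uniformly on its own chromosome; plus peak assignment to
  full-length HERVH units within a 10-kb flank.
- **Insertion dating**: a full-length unit is LTR7–HERVH-int–LTR7 on one
  strand; its two LTRs were identical at insertion, so after global
  alignment, transition (P) and transversion (Q) proportions give the
  Kimura 2-parameter distance

      K = ½ ln[1/(1 − 2P − Q)] + ¼ ln[1/(1 − 2Q)]

  and the insertion age T = K / (2r) at r = 1.28e−8 substitutions per site
  per year (two post-insertion lineages). Expression-stratified groups
  (top-200 vs bottom-200) are compared with a Mann–Whitney U test.

A first-class synthetic-data module generates toy genomes, counts, peaks
and reads with every one of these signals planted at known strength, so the
whole pipeline is validated end to end by parameter recovery, with no
downloads.

## Worked example

```bash
ervkit demo --seed 7 --out-dir demo_out
```

runs the full synthetic pipeline and prints its self-checks (abridged):

```
[PASS] tss_recovery: recovered 5 of 5 planted TSSs (depth >= 30); 0 unassigned reads
[PASS] ks_hervh_signal: LTR7/HERVH D=0.867, p=2.59e-150 vs background
[PASS] cross_kd_inverse_correlation: R=-0.420, p=1.37e-35 over 800 ERV1 loci
[PASS] lncrna_hervh_correlation: R=0.476 within 95% sampling interval [0.278, 0.672]
       of planted rho=0.5, p=0.00016 over 58 pairs (56 expressed lncRNAs)
[PASS] ltr_enrichment: score=1.135 (A=0.497, B=0.226), perm_p=0.001
[PASS] unit_detection: found 60 of 60 planted full-length units
[PASS] k2p_recovery: mean K-hat=0.0594 vs planted mean 0.0600
[PASS] divergence_vs_expression: median T(top)=7.04e+05 < median T(bottom)=3.86e+06,
       p=2.99e-11 (mannwhitney, n=30+30)
```

Reading the numbers: TSS peaks planted at read depths 29/30/31 behave
exactly as the ≥ 30-read rule dictates; the planted +1 log2 shift on
LTR7/HERVH loci produces a dominant KS statistic against the unshifted
background; ChIP-like peaks placed with 5× density on LTR repeats give a
log2(A/B) enrichment score of 1.14 with permutation p = 0.001; all 60
planted full-length units are re-detected and their mean estimated K2P
distance (0.0594) recovers the planted mean (0.06) within 1%; and
highly-expressed (young, K = 0.02) units date significantly younger than
lowly-expressed (old, K = 0.10) ones. Per-unit output
(`demo_out/dating.tsv`) carries P, Q, K and T_years per LTR pair, e.g.
K = 0.1149 → T ≈ 4.49 My at r = 1.28e−8.

Library use mirrors the CLI:

```python
from ervkit.dating import date_pair
rec = date_pair(ltr5_seq, ltr3_seq)   # align, count P/Q, K2P-correct
rec.K, rec.T                          # distance, years since insertion
```

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the complete seeded pipeline from scratch (toy genome → TSS →
KS scan → correlations → enrichment → dating), prints the planted-parameter
self-checks, and writes the results JSON to `--out`. Intermediate reports
land next to it under `demo_reports/`.

## Layout

```
src/ervkit/
  intervals.py    0-based half-open interval engine (overlap, merge, coverage)
  io.py           FASTA / BED / GTF / FASTQ / chrom-sizes readers and writers
  simulate.py     synthetic genomes, K2P-evolved LTR pairs, NB counts, peaks, reads
  tss.py          demultiplex, trim, TSS clustering, annotation, promoters, motifs
  repeats.py      CountTable, CPM, log2FC, KS scan, correlations, lncRNA overlap
  enrichment.py   A/B ratios, log2 score, permutation null, HERVH association
  dating.py       full-length unit detection, alignment, P/Q, K2P, group tests
  config.py       validated pipeline thresholds
  demo.py         seeded end-to-end run with self-checks
  cli.py          `ervkit` command-line entry points
```
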