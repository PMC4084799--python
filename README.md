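# exoninclusion

Transcriptome-wide differential exon-inclusion analysis for small paired
designs, built around the question: *does a trans-acting perturbation (for
example a splicing-factor mutation carried by cases but not their sibling
controls) shift exon inclusion across the whole transcriptome, and which
exons does it hit?*

The measurement unit is the exon-array **probeset** (one exon-sized region)
with a gene-level **metaprobeset** summary. Per-sample inclusion of an exon
in its gene's transcripts is the log-ratio

```
I[p, s] = log2 X_probeset[p, s] − log2 X_metaprobeset[g(p), s]
```

computed after detection and cross-hybridization filtering. The analysis
stack on top of `I`:

- **Paired t-tests** per probeset on within-sibling-pair case − control
  differences (df = n_pairs − 1). Their null p-values are independent
  across probesets, so they feed **π0 estimation** (Storey's smoother:
  raw π0(λ) = #{p > λ}/(m(1−λ)) on λ = 0.05…0.95, cubic smoothing spline
  with 3 effective df, read off at λ = 0.95). 1 − π0 estimates the fraction
  of exons whose inclusion the perturbation changed.
- **Moderated t-tests** (empirical Bayes): probeset variances are shrunk
  toward a scaled-F prior s² ~ s0²·F(d, d0), hyperparameters fitted by
  method of moments on log variances; the moderated statistic uses the
  posterior variance and d0 + d degrees of freedom. These give the
  per-probeset calls and **q-values** (step-up with the π0 factor; π0 = 1
  is exactly Benjamini–Hochberg).
- **Exhaustive permutations**: every within-sibling-pair relabeling
  (2^n_pairs) and every unrestricted n-vs-n split (C(2n, n)), each with its
  own π0; the tie-inclusive empirical p-value and the correlation of π0
  with the number of properly paired sibling pairs test whether the
  observed labeling is genuinely special.
- **Directional enrichment**: among probesets below a p-value threshold,
  an exact binomial test of the proportion with t > 0 (higher inclusion in
  cases), plus the same proportion in p-value bins of width 0.05.
- **Structural characterization**: probesets mapped one-to-one onto exons,
  labelled Up/Down/background at moderated p ≤ 0.01, and compared on
  splice-site scores, exon and flanking-intron lengths, nucleotide
  content, gene length and 3′-end distance with Wilcoxon rank-sum tests
  (exact for pooled n ≤ 25) under BH or q-value correction; plus ESE
  hexamer prevalence (overlapping matches per bp) with motif masking.

A first-class synthetic-data generator (`exoninclusion.simulate`) emulates
the 4-sibling-pair design with known ground truth, so the whole pipeline is
testable end to end without any downloads.

## Worked example

The numbered scripts under `analysis/` run one fixed-seed synthetic study
(4 sibling pairs, ~40,000 probesets, 20% of probesets with a planted
inclusion shift, 80% of shifts positive) one stage at a time, writing
under `results/study/`:

```bash
python analysis/01_simulate.py
python analysis/02_inclusion.py
python analysis/03_differential_testing.py
python analysis/04_permutations.py
python analysis/05_exon_features.py
```

Output of the run committed to this configuration:

```
pi0 = 0.893 over 34790 probesets (simulated true value 0.8)
direction below p = 0.2: 5811 up vs 3685 down (binomial p = 2.65e-106)
within-sibling-pair swaps: 16 ordered labelings, observed pi0 = 0.893, empirical p = 0.1250
unrestricted 4-vs-4 splits: 70 ordered labelings, observed pi0 = 0.893, empirical p = 0.0286
  Up vs rest, exon_length: median 109 vs 142, BH-adjusted p = 1.54e-34
  Up vs rest, intron_up: median 2.1e+03 vs 1.32e+03, BH-adjusted p = 6.62e-51
short upstream introns (<250 bp): Down: 0.117, Up: 0.092, background: 0.228
```

Reading: the estimated null fraction (0.893) recovers most of the planted
0.8 (the exponential effect-size distribution leaves some shifts too small
to detect); the observed labeling gives the lowest π0 of all 16 restricted
relabelings (p = 2/16 = 0.125) and of all 70 unrestricted splits
(p = 2/70 ≈ 0.029); probesets below p = 0.2 are dominated by higher
inclusion in cases; and the Up exons are shorter, preceded by longer
introns, and depleted of short (<250 bp, intron-defined) upstream introns —
the planted exon-definition signature, recovered.

The same pipeline runs from the shell (`exoninclusion run --seed 1 --out
DIR`, or per stage: `simulate`, `include`, `difftest`, `permute`,
`characterize`), and on real data by pointing `--data` at TSVs in the
documented formats (expression, detection calls, design, annotation).

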