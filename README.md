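# mirsig

Differential-expression and signature analysis of miRNA-seq count data for
two-cohort designs, built around the question of lymphatic dissemination in
prostate cancer: given raw miRNA read counts for tumors with (N1) and
without (N0) regional lymph-node metastases, which miRNAs discriminate the
cohorts, and do they form a coherent per-sample expression signature?

It is intended for bioinformaticians analyzing small-RNA sequencing count
tables (e.g. miRge-style miRNA × sample matrices) together with a clinical
annotation table (node status, optional Gleason score).

## What it computes

1. **Normalization.** Per-sample factors by TMM (trimmed mean of M-values;
   trim 30% on M, 5% on A, inverse-variance weights, geometric mean 1), RLE
   (median ratio), upper quartile, or total count, and counts per million

   `CPM[m,s] = counts[m,s] / lib_size[s] × 10⁶ / factor[s]`,

   plus a concordance comparison across methods (divergence of total-count
   factors flags composition bias). Low-expression miRNAs are filtered by a
   configurable CPM threshold.

2. **Consensus differential expression.** Each miRNA is tested twice: a
   negative-binomial quasi-likelihood F-test (QLF) on raw counts with
   offsets for effective library size, and a two-sided Mann–Whitney U test
   on CPM. Both p-value families get Benjamini–Hochberg adjustment, and a
   miRNA is called **N1-miR** (up in N1) or **N0-miR** (down in N1) only if
   *both* FDRs < α (default 0.05) *and* |fold change| ≥ 1.5. Per-miRNA
   high/low relative-expression frequencies (beyond mean×1.5 / below
   mean÷1.5) are compared between cohorts with Fisher's exact test.

3. **Signature scoring.** With the N1-miR and N0-miR sets (from the
   consensus calls or supplied explicitly), every sample gets a
   *Δ avg. log2 FC* score — mean centered log2 CPM over N1-miRs minus that
   over N0-miRs. Negative scores define group G0, positive G1; the G×N
   contingency table is tested with Fisher's exact test, and the module
   structure is summarized by average pairwise Spearman correlations
   (within each module and across modules) and by per-miRNA correlations
   with node status and Gleason score.

4. **Synthetic data.** A seeded generator draws NB counts with log-normal
   library sizes and two anti-correlated signature modules driven by a
   group-linked latent factor, with known ground truth for recovery and
   calibration studies.

## Worked example

Simulate a study-sized dataset (24 N0 + 20 N1 samples, 300 miRNAs, 9 + 9
planted signature miRNAs at |log2 FC| = 1) and analyze it:

```sh
mirsig simulate --seed 7 --outdir demo/sim
mirsig run --counts demo/sim/counts.tsv \
           --annotations demo/sim/annotations.tsv \
           --outdir demo/out
```

prints

```
mirsig 0.1.0 run report
samples: 44 (N0=24, N1=20)
miRNAs: 300 input, 300 pass CPM filter
consensus calls: 8 N1-miRs, 9 N0-miRs, 283 not significant
signature contingency (rows G0,G1 x cols N0,N1): [[22, 1], [2, 19]]
Fisher exact p (G x N): 3.76e-09
avg Spearman r: within-N1 0.505, within-N0 0.530, cross -0.516
```

Reading this: 16 of the 18 planted miRNAs were recovered by the dual-test
consensus rule at FDR < 0.05, alongside one false call among the 282 null
miRNAs (planted effects sit near the power limit of this design, so
recovery varies considerably across seeds). The signature score splits the samples into G0/G1 groups
that track the true cohorts almost perfectly (41/44 concordant,
Fisher p ≈ 4 × 10⁻⁹), and the two modules are internally correlated
(r ≈ +0.5) and mutually anti-correlated (r ≈ −0.5) — the latent-factor
structure the generator plants and the analysis is designed to expose.
Full per-miRNA statistics land in `demo/out/de_results.tsv`, per-sample
scores in `signature_samples.tsv`, and every other intermediate (factors,
CPM, correlation matrix, normalization comparison) next to them.

The same stages are available as a library:

```python
from mirsig import (SyntheticSpec, generate_dataset, tmm_factors, cpm,
                    filter_by_cpm, run_differential_expression, evaluate_signature)

dataset, truth = generate_dataset(SyntheticSpec(seed=7))
factors = tmm_factors(dataset.counts)
expr = cpm(dataset.counts, factors)
expr = expr.subset_mirnas(filter_by_cpm(expr))
records = run_differential_expression(dataset.counts, expr, factors,
                                      dataset.node_status)
```

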