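# homingtrack

Tracking CNS-homing T cells in blood and brain from multimodal
single-cell data.

In multiple sclerosis, a small population of circulating CD4⁺ memory
T cells ("T09"-like cells) homes to the central nervous system. Blocking
the VLA-4 integrin (natalizumab, an anti-ITGA4 antibody) traps these
cells in the blood, which makes them measurable: their surface phenotype
(ITGA4⁺/ITGB1⁺ double-positivity) and their treatment-induced expression
signature together identify the homing population, and the same
signature can then be scored in other cohorts' blood and in spatial
transcriptomes of post-mortem brain tissue.

`homingtrack` is a tested, reusable implementation of that analysis
chain for cell × gene UMI matrices with antibody-derived-tag (ADT)
surface-marker counts:

1. **QC & normalization** — cell filters (500–15,000 RNA UMI, 300–5,000
   detected genes, 100–7,000 ADT UMI, ≤ 20% mitochondrial transcripts),
   gene detection filter (≥ 10 cells), log-CPM for RNA and centered
   log-ratio (CLR) for ADT.
2. **Gating & differential abundance** — ITGA4⁺/ITGB1⁺ double-positive
   gating on CLR values (mixture-midpoint auto-thresholds or manual),
   per-(sample, cluster) frequencies with the 20-cell/paired-drop and
   5-sample exclusion rules, paired t-tests with BH adjustment.
3. **Pseudobulk differential expression** — per-sample cluster matrices
   resampled with replacement to a fixed n = 1,558 cells, gene-wise
   aggregation, and a negative-binomial Wald GLM (`~ donor + group`,
   median-of-ratios size factors, trend-shrunk dispersions). Genes at
   FDR ≤ 0.1 (or p ≤ 0.05 for gene-set use) form a bidirectional
   **signature** (positive = up, negative = down).
4. **AUC-ratio enrichment** — the core statistic. For a profile (cell,
   pseudobulk or spatial spot) with genes ranked by expression, the
   recovery AUC of a gene set over the top-k ranks (k = ⌈top_frac·n⌉) is

   AUC = Σ_{r=1..k} y(r) / Σ_{r=1..k} y_ideal(r),

   where y(r) counts set genes at rank ≤ r and the ideal curve puts set
   genes at the very top. Enrichment of a signature is
   **AUC_pos / AUC_neg**. Group comparisons draw 150 cluster cells per
   sample (fewer ⇒ sample excluded) and t-test the per-sample means;
   matched-size random signatures give the negative control.
5. **Spatial enrichment** — the identical statistic per spot
   transcriptome, thresholded either at a carried-over cutoff (11.5 for
   the original signature) or, recommended, at a high percentile of
   control-section ratios.

A first-class synthetic-data module (`homingtrack.simdata`) generates
paired multi-donor cohorts and spatial sections with planted ground
truth (signature genes, double-positive shifts, infiltrate spots), so
every stage is testable without access to restricted cohort data.

## Worked example

`examples/` contains one narrative script per capability. From
`examples/02_qc_and_gating.py` (seed 1, default cohort):

```
retained 88335/95811 cells

gate thresholds (CLR scale): {'ITGA4': 0.182, 'ITGB1': 0.185}

per-cluster treated-minus-untreated double-positive shift:
cluster  n_pairs  mean_delta         t        p     padj
    T09        8    0.203061 14.649417 0.000002 0.000020
    C01        8    0.023695  2.684677 0.031326 0.159831
    C06        8    0.029374  2.517473 0.039958 0.159831
    ...
```

The homing cluster's double-positive fraction rises by ~0.2 under
treatment (the planted effect) with padj ≪ 0.05; all other clusters
stay above the 0.05 threshold after BH adjustment.
`examples/04_auc_enrichment.py` then shows the planted signature
separating treated from untreated samples (t = 31.2, p = 9.0·10⁻⁹)
while a matched-size random control stays non-significant (p = 0.72),
and `examples/05_spatial_sections.py` recovers the simulated
infiltrate spots at a 99.9th-percentile control cutoff (recall 1.00,
precision 0.95 in that run).

(Exact numbers vary with the seed; each script prints the values it
computed in that run.)

## Command line

The library is also exposed as a thin CLI:

```bash
homingtrack simulate --seed 1 --out cohort/
homingtrack qc --in cohort/ --out qcd/
homingtrack gate-freq --in qcd/ --out gated/
homingtrack dge --in qcd/ --cluster T09 --n-fixed 1558 --seed 1 --out dge/
homingtrack signature --from dge/dge.tsv --out sig.json
homingtrack score --in qcd/ --signature sig.json --out scored/
homingtrack run --config pipeline.yaml --out run/
```

Counts travel as MatrixMarket (+ TSV metadata), signatures as JSON or
TSV; every run writes a manifest with the config hash and seed.

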