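# sclc-taxonomy

Molecular subtyping of small cell lung cancer (SCLC) from bulk and
single-cell transcriptomes, as a reusable, tested Python pipeline.

SCLC has classically been split by dominant transcription factors
(ASCL1/NEUROD1/POU2F3/YAP1), but "triple-negative" tumors are heterogeneous:
part of them are *inflamed* (SCLC-I, immune-infiltrated) and part are
*mesenchymal* (SCLC-M, tumor-intrinsic EMT driven by YAP/TAZ), with
different microenvironments, developmental positions on the neuroendocrine
(NE) → non-NE axis, and clinical outcomes. This package implements the
full analysis that separates and characterises these subtypes:

- **Subtype discovery** — consensus non-negative matrix factorization
  (KL-divergence multiplicative updates) over random gene subsamples;
  cluster stability per rank K measured by the cophenetic correlation
  coefficient of the consensus matrix, compared against a
  gene-permutation null band; rank selected by the
  largest-supported-K-before-a-drop rule with argmax fallback.
- **Characterisation** — single-sample gene-set enrichment (ssGSEA,
  rank-weighted running sum), marker-mean abundances, EMT/immune/hypoxia
  signatures, and mutual-information regulons (equal-frequency-bin MI,
  permutation threshold, data-processing-inequality pruning) scored
  against subtype metagenes by Fisher's exact test.
- **Cross-cohort classification** — nearest-shrunken-centroid (PAM-style)
  classifier with cross-validated shrinkage.
- **Deconvolution** — four-cell-type (epithelial/fibroblast/endothelial/
  immune) fractions by non-negative least squares on a signature matrix;
  group-mode and per-sample epithelial purification; Welch-t differential
  expression between deconvoluted epithelial subtypes; tumor-intrinsic M
  and I scores and their differential.
- **Trajectory** — principal-curve pseudotime of human epithelial profiles
  and mouse single-cell time courses, NE scores, subtype occurrence along
  pseudotime, and the cross-species concordance matrix.
- **Clinic** — Kaplan–Meier/log-rank survival comparison, vimentin H-scores,
  CD8+ TIL scores, Mann–Whitney comparisons, and the IHC-based SCLC-M call
  (vimentin-positive / CD8-low).
- **Synthetic cohorts** — a first-class generator that plants all of the
  above structure (six subtype programs, cell-type mixing, a shared
  human/mouse NE→non-NE axis, subtype-dependent survival and IHC) with
  ground truth for recovery testing.

## Worked example

Discover the subtypes of a synthetic cohort and test their survival
separation:

```python
from sclc_taxonomy import synthetic as syn, nmf, clinical as clin
from sclc_taxonomy.preprocess import counts_to_log_tpm

counts, lengths, truth, clinical = syn.generate_cohort(syn.CohortConfig())
logtpm = counts_to_log_tpm(counts, lengths)

res = nmf.run_rank_scan(logtpm, k_min=2, k_max=10,
                        n_subsamples=50, n_perm=20, seed=1)
print("selected rank:", res.selected_rank)
print("stability:", {k: round(v, 3) for k, v in res.cophenetic.items()})

chi2, df, p = clin.logrank_test(clinical["os_time"], clinical["os_event"],
                                truth.subtype_labels)
print(f"log-rank chi2={chi2:.1f} (df={df}), p={p:.2e}")
```

prints

```
selected rank: 6
stability: {2: 0.999, 3: 0.99, 4: 0.989, 5: 0.999, 6: 1.0, 7: 0.999,
            8: 0.998, 9: 0.996, 10: 0.995}
log-rank chi2=13.5 (df=5), p=1.88e-02
```

The consensus is essentially perfectly reproducible only at the planted six
subtypes (cophenetic score 0.9999), so the rank scan selects K = 6; the
planted worse outcomes of the mesenchymal and hypoxic subtypes — minority
subtypes at this cohort size — give a significant six-group log-rank test.

The same steps are scriptable from the shell:

```bash
sclc-taxonomy simulate cohort --seed 7 --out data/
sclc-taxonomy discover --expr data/counts.tsv --kmin 2 --kmax 10 \
    --subsamples 50 --perms 20 --seed 1 --out discovery/
sclc-taxonomy run --config pipeline.yaml --out run/     # full pipeline
```

(`discover` expects log2-TPM input; the `run` pipeline handles
normalisation itself.)

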