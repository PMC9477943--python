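# targetmr

A drug-target Mendelian randomisation (MR) toolkit for estimating the
effect of a multi-target drug on disease outcomes from GWAS summary
statistics, exercised end-to-end on synthetic data with known ground truth.

The pipeline mirrors a full drug-target MR study design:

1. **Instrument selection** — per-gene eQTL instruments (lowest-p,
   LD-pruned at r² < 0.001), validated by approximate-Bayes-factor
   colocalisation between gene expression and the glycaemic biomarker
   (PP4 ≥ 0.70), with R²/F instrument-strength statistics and LD-proxy
   fallback (r² > 0.8) for variants missing from an outcome GWAS.
2. **Two-sample MR** — Wald ratio, fixed/random-effects IVW, MR-Egger,
   weighted median, weighted mode, Cochran's Q, and a single-variant /
   leave-one-out influence scan.
3. **Drug-level synthesis** — per-target estimates pooled by
   inverse-variance meta-analysis into the "general drug effect", with
   cross-target heterogeneity, OR scaling per 1 SD biomarker lowering,
   and Bonferroni multiplicity control.
4. **Candidate-gene MR** — per-gene Wald/IVW estimates of brain expression
   on each outcome with regional colocalisation verdicts.
5. **One-sample / factorial MR** — allele-score 2SLS and a 2×2
   median-split factorial contrast on individual-level cohorts, plus
   triangulation of estimates from different sources on a common scale.
6. **Synthetic data** — generators for two-sample GWAS, multi-trait LD
   regions (AR(1) LD), and individual-level cohorts, all reproducible
   bit-for-bit from one integer seed with truth records saved alongside.

## CLI

```bash
# generate a complete synthetic study (data + config + truth sidecar)
targetmr simulate --out-dir study --seed 7

# main analysis: per-target MR + pooled general effect
targetmr main --config study/config.yaml --out-dir out_main

# candidate-gene MR with coloc verdicts
targetmr genes --config study/config.yaml --out-dir out_genes

# estimator suite on biomarker-wide / filtered instrument sets
targetmr sensitivity --config study/config.yaml --out-dir out_sens

# one-sample and factorial MR on the cohort
targetmr onesample --config study/config.yaml --out-dir out_os
targetmr factorial --config study/config.yaml --out-dir out_fact

# compare estimates from different sources on a common scale
targetmr triangulate --input study/triangulation_inputs.tsv --out-dir out_tri
```

Exit code 0 on success, 2 on validation/configuration errors. Reports are
byte-identical across repeated runs with the same config and seed, and
every report carries a manifest (seed, input SHA-256 hashes, thresholds).

## File formats

Summary statistics are headered TSV with columns
`SNP CHR POS EA OA EAF BETA SE P N PHENO` (`#` comment lines allowed).
LD panels are a whitespace-delimited square correlation matrix plus a
one-column id file. Cohorts are TSV with `IID`, dosage columns `G1..Gm`,
`EXPOSURE`, `OUTCOME`. Run configuration is YAML (see the `config.yaml`
written by `targetmr simulate`).

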