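# mced

Multimodal cell-free DNA (cfDNA) multi-cancer early detection pipeline:

- **methylome** — CpG filtering, methylation-status classification, region
  construction, average methylation fraction (AMF) quantification, Welch-t
  differential region selection with Benjamini–Hochberg FDR control, and
  tissue/cfDNA directional-concordance marker refinement.
- **copynumber** — bin-level log2 copy ratios against a healthy reference
  panel, 2σ alteration calls, prevalence-rule (α/β) marker selection with a
  healthy-exclusion step that guards against clonal-hematopoiesis-like
  signal, and a marker-frequency cancer-signal score.
- **fragmentome** — per-window short/long fragment size ratio (FSR; short
  >80 and <150 bp, long >150 and <220 bp) and the global fragment size
  distribution (FSD; 5-bp bins over 80–220 bp), standardized on training
  samples only.
- **classifiers** — per-feature nine-class models (healthy + eight cancer
  types) with cross-validated candidate selection by macro one-vs-rest AUC,
  cancer-signal scores (1 − p(healthy)) and conditional tissue-of-origin
  probabilities.
- **ensemble** — a logistic meta-model over logit-normalized feature scores
  plus age and sex, with a threshold calibrated to a target specificity
  (default 95%) on training healthy samples; weighted tissue-of-origin
  aggregation with top-1/top-2 calls and a 0.07 "in between" ambiguity rule;
  evaluation metrics with Wilson confidence intervals.
- **simcohort** — a seeded synthetic cohort generator (healthy + eight
  cancer types, stages I–IV) with stage-dependent tumor-fraction mixing of
  methylation, copy-number and fragment-length signal, plus planted ground
  truth so every stage is testable without external data.
- **io / pipeline / cli** — TSV/BED/JSON/YAML formats, the sequencing-QC
  gate, stratified 6:4 splitting, a run manifest with checksums, and a
  train/test leakage audit.

## Tests

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (oracle equivalence
for AMF and BH-FDR, planted-marker recovery, the CNV exclusion invariant,
specificity calibration, signal monotonicity in tumor fraction, TOO sanity,
and null-cohort safety with a leakage audit).

## CLI

Everything runs end to end on a simulated cohort:

```bash
mced run --out runs/demo --seed 1
```

or stage by stage against a shared working directory:

```bash
mced simulate --out work --seed 1
mced qc --dir work
mced build-markers --dir work --fdr 0.05 --min-cov 3 --min-cpg 3 --pct 10
mced featurize-amf --dir work
mced featurize-cnv --dir work --alpha 5 --beta 20 --ksigma 2
mced featurize-frag --dir work --fsd-range 80:220 --fsd-width 5
mced train --dir work --seed 1
mced train-ensemble --dir work --target-specificity 0.95 --too-delta 0.07
mced predict --dir work
mced evaluate --dir work
```

Configuration is a single YAML file (see `configs/default.yaml`); every
module default is surfaced there. `mced split --dir work --ratio 0.6`
re-assigns the stratified train/test split.

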