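# molscreen

Ligand-based virtual screening as a reusable, tested pipeline: dataset
assembly under multiple activity thresholds, two-stage feature filtering,
correlation-based feature subset selection (CFS) with four search
strategies, classifier training/validation, and unanimous-consensus
screening of large compound libraries — exercised end-to-end on synthetic
feature tables with planted structure.

## What's inside

| Module | Purpose |
| --- | --- |
| `molscreen.synthetic` | Labeled training tables and screening libraries with planted informative / redundant / zero-variance / noise columns and simulated IC50s |
| `molscreen.preprocess` | IC50 binarization, min-max normalization, low-variance filter, Kendall tau-a high-correlation filter with audit report |
| `molscreen.cfs` | CFS merit scoring plus best-first, genetic, geometric-PSO, and subset-size forward-selection searches (and an exhaustive oracle) |
| `molscreen.classify` | Decision-tree / random-forest / mixed naive-Bayes training, grid search by cross-validated AUC, AUC + MCC validation |
| `molscreen.screening` | Chunked library screening, strict consensus voting, Tanimoto nearest-neighbor annotation of hits |
| `molscreen.io`, `molscreen.pipeline`, `molscreen.cli` | CSV dialect with kind sidecars, the end-to-end grid runner with manifest, and the command-line surface |

## CLI

```bash
molscreen simulate --out train.csv --library-size 10000 --seed 1
molscreen filter train.csv --out filtered.csv --cutoff-um 11.4
molscreen select filtered.csv --selector BF --out subset.csv
molscreen validate filtered.csv --classifier RF
molscreen screen train.library.csv filtered.csv --out hits.csv
molscreen run --config config.yaml --out results/
molscreen report results/
```

`molscreen run` executes the full threshold x selector x classifier grid
(default: 5 activity cutoffs x {BF, GS, PSO, SSFS, none} x {DT, RF, NB})
and writes a validation grid, per-stage filter reports, selected feature
subsets, and a `manifest.json` from which the run can be reproduced
bit-identically (`molscreen.pipeline.rerun_from_manifest`).

Exit codes: 0 success, 2 configuration error, 3 data error, 4 stage error.

## Notes on conventions

- Activity labels: `active` iff IC50 <= cutoff; decoy rows are always inactive.
- The correlation filter compares |tau-a| to the threshold and keeps the
  earlier column of an offending pair.
- CFS merit uses |Pearson| magnitudes for both feature-class and
  feature-feature terms; single-feature subsets have zero inter-correlation.
- Consensus hits require every model's active probability to be strictly
  greater than the cutoff (default 0.9).
- Tanimoto similarity is computed over binary (fingerprint-bit) columns only.
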