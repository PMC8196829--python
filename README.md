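# pharmacotype

Ex vivo organoid pharmacotyping pipeline: plate-reader luminescence →
percent viability → dose-response AUC → natural-breaks responder classes →
combination-regimen prediction → cohort evaluation.

## What it does

- **`plate_io`** — reads/validates long-format plate CSVs (two-signal
  cytotoxicity read-out: pre-lysis `s1`, post-lysis `s2`), drug-panel JSON
  (default: 10 log-spaced doses, 13 nM–50 µM) and regimen JSON (default:
  five standard-of-care regimens mapped to their screened component drugs).
- **`viability_auc`** — viability % = 100 × net drug signal / net control
  signal, replicate-averaged; trapezoidal AUC over log10(concentration);
  PDO × drug AUC matrix with explicit missingness.
- **`natural_breaks`** — exact Jenks natural breaks (Fisher optimal 1-D
  partition by dynamic programming, deterministic tie-breaking): k=3
  responder classes per drug (low AUC = high responder = score 1), k=2
  Ki-67 proliferation classes (or the fixed 45% cut-off).
- **`regimen_prediction`** — regimen score = mean of component drug
  scores; ≤ 2 ⇒ sensitive, > 2 ⇒ resistant. Alternative hard-margin
  linear SVM (non-separable data is an explicit error).
- **`cohort_stats`** — pharmacotyping efficacy, prediction accuracy vs
  RECIST tumor control, exact two-sided Fisher test (direct hypergeometric
  enumeration), exact/asymptotic Mann–Whitney, Kaplan–Meier product-limit
  curves and log-rank test, subtype concordance.
- **`synthetic_cohort`** — Hill-curve plate generator and outcome/survival
  cohort generator with known ground truth, plus a deterministic packaged
  54-sample fixture reproducing the published category counts.
- **`pipeline` / `cli`** — orchestration and the `pharmacotype` command.

## CLI

```sh
pharmacotype validate-plate plates.csv
pharmacotype auc plates.csv --out auc.tsv
pharmacotype classify auc.tsv --out-breaks breaks.tsv --out-calls calls.tsv
pharmacotype predict calls.tsv --out predictions.tsv
pharmacotype svm-train auc.tsv labels.json --regimen FOLFIRINOX --out model.json
pharmacotype svm-predict model.json auc.tsv
pharmacotype evaluate patients.tsv evaluations.tsv --out report.json
pharmacotype simulate --seed 7 --n-pdos 28 --out sim/
pharmacotype fixture --out fixture/
pharmacotype run --plates plates.csv --patients patients.tsv \
    --evaluations evaluations.tsv --out out/
```

`run` writes per-stage TSVs plus `report.json`, the single source for all
statistics (counts and exclusions included) and per-PDO classification
cards (per-drug AUC + responder category).

## Conventions

- Concentrations are molar internally; AUC integrates percent viability
  over log10(concentration) (unit-invariant), giving a 0–358.5 scale for
  curves ≤ 100% on the default panel.
- Viability is not capped at 100%; negative net signals clip to 0.
- Per-drug classification expects a library of n ≥ 25 (override available).
- Percentages are reported rounded half-up to one decimal.
- Fixture PFS days and Ki-67 values are synthetic placeholders — only the
  category counts are faithful.
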