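# xlapipe

Decision-tree knowledge discovery and a rule-based expert system for
severity assessment in X-linked agammaglobulinemia (XLA, Bruton's disease).

XLA is a rare primary immunodeficiency caused by mutations of Bruton's
tyrosine kinase (*BTK*): B-lymphocyte maturation is blocked, so patients
lack B cells and immunoglobulins and suffer recurrent, sometimes invasive,
infections from the first months of life. Clinicians grade both the
**disease course** (very severe / severe / less severe) and the **mutation**
(severe / less severe) from a small set of measurements: age of symptom
onset, immunoglobulin levels (IgG, IgA, IgM) expressed as a percentage of
the age-specific norm, B-cell counts, and Btk expression in B lymphocytes
and monocytes.

`xlapipe` implements the complete path from a raw patient table to a
forward-chaining expert system, for researchers who want to reproduce,
stress-test, or extend this kind of clinical rule-extraction workflow:

1. **Synthetic cohorts** (`xlapipe.cohort`) — seeded 51-patient cohorts in
   the original 37-attribute spreadsheet schema, matching the study
   population's label marginals (course 17/22/12, mutation 28/23), since the
   real patient-level data are not published.
2. **Preprocessing** (`xlapipe.preprocess`) — ages to months, laboratory
   values to percent-of-norm via an age-banded reference table, 21 past-
   disease flags folded into per-system counts: the 18-attribute modelling
   table.
3. **Tree induction** (`xlapipe.trees`) — CART classification trees with
   Gini impurity, `minsplit`/`maxdepth` control and stratified train/test
   partitioning.  A split sends `attribute < threshold` left; Gini impurity
   is `1 − Σ_k p_k²`, and the chosen split maximizes the weighted impurity
   decrease `Δ = i(t) − p_L i(t_L) − p_R i(t_R)` over all attributes and
   midpoints.
4. **Attribute importance** (`xlapipe.importance`) — random forests with
   bootstrap resampling and `mtry` attribute sampling; importance is the
   mean decrease in Gini per attribute across trees.
5. **Rule compilation** (`xlapipe.rules`) — one IF–THEN production rule per
   root-to-leaf path, with same-attribute conditions merged into intervals;
   compiled rule sets are verified mutually exclusive and exhaustive by
   interval arithmetic, and serialize to JSON and CLIPS-style `defrule`
   text.
6. **Inference** (`xlapipe.engine`) — a small forward-chaining production
   system (working memory, agenda, specificity-then-order conflict
   resolution) with full condition traces.
7. **Knowledge bases** (`xlapipe.kb`) — the two fully specified XLA rule
   sets (course from immunoglobulins + onset age; mutation from
   immunoglobulins), four partial prose-derived rule sets, the threshold
   catalog that grounds qualitative terms ("undetectable" < 20% of norm,
   "early" onset < 24 months, IgA bands at 20/50), and a verification
   harness with the published expected-result tables.

## Worked example

Generate a cohort, preprocess it, and train the course model:

```sh
xlapipe generate --n 51 --seed 1 --out cohort.csv
xlapipe preprocess --in cohort.csv --out processed.csv
xlapipe train --in processed.csv --target course \
    --attrs igm_pct,igg_pct,iga_pct,age_ob --minsplit 8 --maxdepth 5 --seed 1
```

which prints the grown tree and its held-out accuracy:

```
igm_pct < 10.1166?
  -> very severe  {'very severe': 11, 'severe': 0, 'less severe': 0}
igm_pct >= 10.1166?
  ...
test accuracy: 0.750 (35 train / 16 test rows)
```

The first split is the IgM percent-of-norm — undetectable IgM points to a
(very) severe course — and the 0.75 accuracy is measured on the 16 held-out
patients of the stratified 70/30 split.  Inference against the shipped
course knowledge base, with the rule trace:

```sh
xlapipe infer --kb kb1_course_ig --age-ob 19 --igm 12 --igg 19 --iga 17 --trace
```

```
rule kb1-r1: satisfied=True
  igm_pct lt 20.0 (value 12.0): True
  age_ob lt 24.0 (value 19.0): True
  igg_pct lt 20.0 (value 19.0): True
...
very severe
```

A 19-month onset with IgM, IgG and IgA all far below the age norm satisfies
the first rule only: the course is classified very severe.  The whole
pipeline (generate → preprocess → 7 tree experiments → importance →
compile → verify) runs as:

```sh
xlapipe run-all --seed 1 --out runs/r1
```

and reports `verification course 7/7, mutation 5/5`: the two expert systems
reproduce every row of their published expected-result tables.

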