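# Methods

This note documents the models, numeric conventions, and design choices
behind `xlapipe`, in the order the pipeline runs.

## The severity logic and its numeric grounding

The package's central artifact is a pair of expert systems for X-linked
agammaglobulinemia: one classifies the disease course (very severe / severe
/ less severe) from the onset age and the IgM/IgG/IgA percent-of-norm
values; the other classifies the mutation (severe / less severe) from the
immunoglobulins alone.  Both are binary threshold trees compiled to
production rules, one rule per root-to-leaf path.

The published rules are qualitative ("IgM% is undetectable", "the age of
onset is early", "IgA% is from the range (20, 50)").  The
`ThresholdCatalog` grounds them numerically:

| term | attribute | default | determined by the verification data |
|---|---|---|---|
| early onset | `age_ob` | < 24 months | any cut in (23, 47] months works |
| undetectable Ig | `igm_pct`, `igg_pct` | < 20 % of norm | any cut in (19, 36] works |
| reduced IgA | `iga_pct` | ≤ ~20 % | cut in [17, 46) |
| mid IgA band | `iga_pct` | (20, 50) | upper cut in [46, 76) |
| high IgM (mutation tree) | `igm_pct` | ≥ 60 % | cut in (41, 81] |
| low Btk expression | `btk_lib` | < 20 % | stated explicitly in the source narrative |
| absent B cells | `bcells_pct` | < 5 % of norm | not determined by printed data; package default |

The defaults sit comfortably inside each determined interval; 24 months
matches the "before the age of two" phrasing.  The test suite pins every
threshold against the verification tables from both directions: moving any
threshold outside its interval breaks at least one expected result, and
interior perturbations keep all twelve cases green.

Two reconstruction choices deserve a flag.  First, the printed first rule
concludes "extremely severe"; it is mapped to the label "very severe" used
everywhere else (and expected by the verification table).  Second, the
mutation tree is a *reconstruction*: the narrative fixes four splits (IgM
undetectable → severe; else IgG detectable → less severe; else IgA reduced →
severe; else a final IgM cut), giving five leaves; the final cut at 60% is
the package's choice inside the data-determined interval (41, 81].  The
narrative also quotes per-leaf training coverage percentages (43%, 30%, 8%)
that cannot be checked without the unpublished patient data; they are
recorded here and not tested.

## Boundary conventions

One convention is used everywhere: tree splits send `attribute < threshold`
left, so a record exactly at a threshold goes right; compiled rule
conditions are `<`, `≥`, or a closed-open interval `[low, high)`.  Under
this convention a compiled rule set tiles the attribute space exactly, which
makes `predict(tree, x) == infer(compile(tree), x)` an identity rather than
an approximation — the package's core oracle test.  No printed verification
value sits on a threshold, so the choice of side is unobservable in the
published cases.  Exhaustiveness and mutual exclusivity are verified
constructively: conditions are axis-aligned with finitely many thresholds,
so probing one representative point per cell of the threshold-refined grid
decides both properties exactly.

## Tree induction

`grow_tree` is a deterministic CART: exhaustive search over all attributes
and all midpoints between consecutive distinct sorted values, maximizing the
weighted Gini decrease; recursion stops at `maxdepth` (root depth 0), below
`minsplit` observations, on purity, or when no split has positive gain.
There is no cost-complexity pruning: the study tunes only
`minsplit`/`maxdepth`, so the complexity parameter is effectively zero
(a documented divergence from rpart defaults).  Tie-breaks are fixed for
reproducibility: equal gains resolve by attribute order then by the lower
threshold, and leaf-label ties resolve by severity order (very severe,
severe, less severe).  A small-table brute-force oracle and scikit-learn's
Gini CART serve as independent cross-checks in the tests; neither is used in
the implementation.

The train/test split is stratified with largest-remainder per-class
rounding, so each class is within one observation of the global fraction.
The study's text assigns 70% of the data to the *testing* set, the reverse
of convention and most likely a typo; the package defaults to a 70% training
share and offers `--split-as-printed` to honour the text as written.

## Random-forest importance

Forests grow deep, unpruned trees (`minsplit` 2, effectively unbounded
depth) on bootstrap resamples with `mtry = ⌊√p⌋` candidate attributes per
split — the conventional classification-forest defaults; `n_trees` defaults
to 500.  An attribute's importance is the sum over its splits of the
node-weighted impurity decrease `(n_node/n_root)·Δ`, averaged over trees, so
a single perfect root split scores exactly the root impurity.  Exact
importance values from the original analysis are not reproducible — they
depend on the unpublished data and on R's random stream — so only rank-order
structure is asserted: laboratory measurements (IgM percent-of-norm, Btk
expression in B cells) must outrank family history, the rheumatology count,
and an injected pure-noise column.  With n = 51, a random noise column can
genuinely chance-correlate with the labels, which is why the ranking
property is stated over repeated seeded cohorts rather than per cohort.

## The inference engine

A deliberately small forward-chaining production system: working memory
holds one fact per attribute; the agenda contains every rule whose
conditions all hold, ordered by specificity (condition count) then
declaration order; one rule fires per run, and conclusions are terminal (the
severity rules are one level deep, so no chaining is needed).  For compiled
rule sets the agenda provably has exactly one entry, making the conflict
strategy irrelevant there; it exists to make hand-written overlapping rule
sets predictable.  Missing facts raise an error naming the attributes; an
empty agenda returns conclusion `None` with a full per-condition diagnostic
trace.  The four partial, prose-derived knowledge bases (course from Btk/B
cells, course from combined attributes, mutation from Btk, mutation from
disease history) are flagged non-exhaustive and return `None` outside their
coverage.

## Preprocessing

Ages are converted to months (`12·years + months`).  Laboratory values
become percentages of an age-banded reference value; the bundled table
(bands 0–6, 6–12, 12–24, 24–72, 72+ months) uses midpoints of conventional
pediatric intervals and is an explicit placeholder — reference ranges are
assay- and laboratory-specific, and users should supply their own for real
data.  Whether the original analysis normalized against a lower limit or a
central value is not stated; the midpoint convention is this package's
choice.  The band is selected by the age at diagnosis, when the laboratory
panel is drawn.  The 21 disease flags fold into five organ-system counts
under a clinically conventional mapping (pulmonology, otorhinolaryngology,
gastroenterology, rheumatology, and general resistance/immunology — the two
names are treated as the same attribute) plus severe/less-severe counts,
where the severe set {sepsis, meningitis, encephalitis, pneumonia} follows
the clinical definition of severe invasive infection.  Both mappings ship as
editable YAML.  Missing numeric values are imputed with the column median
(robust, deterministic, order-independent); a fully missing column is an
error.  Re-processing an already processed table is rejected rather than
silently re-applied.

## The synthetic cohort generator

The real 51-patient database is not published at patient level, so the
generator *defines* the study conditions rather than estimating them.  What
it reproduces exactly: the cohort size (51), the raw 37-column schema, and
the label marginals (course 17/22/12, mutation 28/23) — for every seed.
Mutation labels are allocated by weighted sampling without replacement with
odds rising steeply with course severity, preserving the dependency the
combined-attribute tree exploits while keeping both marginals exact.

Features are generated conditionally on the labels.  Each patient is
assigned one of the seven course rules (consistent with their label;
within-course allocation uses fixed proportions so every rule region
receives enough patients to be carved out under `minsplit` 8), and the
onset age and Ig percentages are drawn from truncated normals pinned inside
that rule's region with a safety margin from every threshold.  Two
deliberate refinements keep the rule structure recoverable by *greedy* tree
induction at n = 51: the undetectable-IgM stratum is split into a
very-severe sub-band below the severe one, and detectable IgM is lower for
severe-course than for less-severe-course patients — both consistent with
the study's "the lower the immunoglobulin level, the more severe the
course".  Mutation-linked features follow the narrative: Btk expression in
B lymphocytes separates at the 20% cutoff (and additionally grades with
course), monocyte Btk tracks the mutation only weakly, and B-cell levels
tend low with severe mutations but overlap between classes.  Disease-flag
rates rise with course severity (severe infections) and with mutation
severity (overall disease burden).  Raw immunoglobulins are emitted in g/L
by inverting the percent-of-norm table at the diagnosis age, so
preprocessing is exercised end to end, and a 10% fraction of blanks is
injected into two numeric columns to mirror the original database's missing
values.

`noise_level` (default 0.15, a typical clinical-data misfit rate) is the
fraction of patients whose features are drawn from a rule with a *different*
conclusion; labels are never changed, so marginals stay exact.  At noise 0
every record satisfies its generating rule and inference recovers every
course label; at the default noise a tree grown with the study's controls
still roots on IgM and beats the majority rate out of sample.

What the generator does **not** emulate — and therefore what passing tests
do not show about real data: measurement error and assay variability,
within-patient correlation between immunoglobulin classes beyond the rule
structure, genotype structure (the exon/nucleotide/protein columns carry
placeholder text), longitudinal course, or any patient resembling an actual
individual from the study.  Tests on synthetic cohorts demonstrate that the
*pipeline* recovers the knowledge structure it was pointed at, not that the
published trees are clinically optimal.

## Problem sizes and determinism

All randomness flows through explicit integer seeds
(`numpy.random.default_rng`); identical configuration yields byte-identical
CSV exports and manifests.  The test suite and the acceptance script use
cohorts of 51 (the study size), 20-seed replications for the stochastic
properties, forests of 100–200 trees (500 is the CLI default), and 10,000
random probes plus a full threshold grid for the tree/rule equivalence
oracle — sizes chosen so the complete suite runs in well under a minute.

## Known limitations

- The published model accuracies (0.79, 0.64, 0.36, 0.93, 0.71, 0.86, 0.79)
  and the exact importance table are not reproducible without the original
  data; the pipeline reports its own accuracies on synthetic cohorts.
- The four partial knowledge bases are illustrative reconstructions of tree
  narratives, not transcriptions; only the two immunoglobulin-based systems
  have printed verification tables.
- Of the 33 verification tests the original work mentions, only 12 are
  printed; the remainder cannot be recovered.
- The CLIPS export is a syntax mapping for interoperability and the parser
  accepts only the subset the compiler emits; the inference semantics live
  in the package's own engine.
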