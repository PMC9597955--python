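# Methods

## The selection algorithm and its operationalization

The package implements the nine-step hierarchical procedure for choosing the
best-evidence systematic review (SR) among two or more discordant reviews of
the same question. The routing logic (A→B or C; C→D→E/F when the trial
rosters coincide; C→G→H/I when they differ) is fixed by the algorithm's
decision graph; what the original description leaves open is *how* the
decisive comparisons are made. Those choices are isolated in a `Ruleset`:

| parameter | default | meaning |
|---|---|---|
| `step_h_order` | `n_databases, grey_literature, duplicate_independent_screening, last_search_date` | lexicographic order of the step-H search-rigour criteria |
| `step_i_order` | `publication_status_scope, rct_quality_assessed, language_restriction, ipd_analysis` | lexicographic order of the step-I publication-hierarchy criteria |
| `criteria_similarity_threshold` | 0.8 | minimum pairwise PICO term overlap (mean Jaccard over P/I/C/O) for step G to answer "same criteria" when no human judgment is recorded |
| `quality_comparison_mode` | `within_tool_only` | quality ranks are never compared across instruments |

The defaults are *this package's* operationalization — one defensible
reading among several — which is precisely the point: the reproducibility
question the package studies is what happens when two assessors pick
different readings. Alternative operationalizations are first-class values,
not code changes.

Fixed design rules, applied everywhere:

- **Ties keep all maximal reviews.** A selection step returns every review
  attaining the lexicographic maximum; real assessors do choose two or three
  reviews when nothing separates them, and forcing a single winner would
  inject positional bias (the engine is permutation-equivariant, which the
  suite checks).
- **Unknown ranks strictly below any known value.** Rewarding unreported
  metadata would privilege poorly reported reviews.
- **Quality is ordinal within one instrument only.** AMSTAR uses the
  five-level scale `critically low < low < moderate < high < highest` as the
  corpus prints it, AMSTAR-2 the standard four levels, the Oxman–Guyatt
  score 1–7, and the risk-of-bias instrument the binary `high_risk <
  low_risk`. Comparing, say, an AMSTAR "high" against a "low risk" verdict
  raises an error instead of silently coercing; callers must supply ratings
  from a shared tool.
- **Trial identity** is a normalized `firstauthor-year` label (lowercased,
  punctuation collapsed, "et al." dropped); distinct raw labels that collide
  on the same identifier are an error, never a silent merge.

## Effect-direction classification

A pooled effect (RR, OR, MD or SMD with 95% CI and/or p-value, plus a
recorded benefit direction for the outcome) is classified as

- **null** if not significant,
- **favourable** if significant with the point estimate on the beneficial
  side of the null value (1 for ratios, 0 for differences),
- **unfavourable** if significant on the harmful side.

Significance uses the printed p-value when present (`p < alpha`, default
alpha 0.05) and otherwise strict exclusion of the null value from the CI.
The p-value takes precedence because printed intervals are rounded: the
corpus contains an estimate whose upper bound prints as −0.00 with p = 0.04,
which the CI rule alone would misclassify as null. The benefit direction is
always a recorded input (pain and complication outcomes: lower is better;
function and disease-control outcomes: higher is better); inferring it from
the data would make every significant effect "favourable" by construction.

A point estimate exactly at the null combined with a significant p-value is
rejected as inconsistent rather than guessed at.

## The replication corpus

`load_fixture_tables` ships a transcription of a 21-case published
replication study: per case the paired (original authors vs replication
team) final decision steps and chosen review sets, per-review quality /
Cochrane / risk-of-bias flags, and 27 pooled effect rows with their printed
favourable/null verdicts and agree/disagree direction calls. Statistics
computed on it (38% choice agreement; 6 same vs 7 different final steps
among the 13 disagreements; 86% overall and 77% among-disagreement direction
concordance; replication routing of 17 cases to step H and 4 to step I) are
reproduced exactly by the test suite.

Two caveats, detailed in `src/jadad_select/fixtures/NOTES.md`: trial
rosters and search profiles are *not* printed in the source tables, so the
loader substitutes synthetic pairwise-distinct rosters (the same-trials step
answers "no" on every case, as observed) and default search profiles —
consequently per-case step-H/I *selections* on the corpus are not
meaningful and are never asserted; and the per-case ease-of-use colour
assignments are synthetic within the printed marginal counts.

## The synthetic-case generator

`generate_cases(SimConfig)` emulates the corpus structure: per case a
question, 2–10 reviews (uniform; the corpus ranges 2–7 plus one case with
10), rosters drawn by independent inclusion of each trial of a per-case
universe (default size 30, inclusion probability 0.6; an empty draw is
replaced by one random trial so rosters are non-empty), AMSTAR quality
levels from a configurable distribution, and heterogeneous search profiles
(2–8 databases, grey literature 50%, duplicate screening 70%, search dates
2005–2020, no language restriction 70%, unpublished literature included 50%,
individual-patient-data analyses 0% — none occurred in the corpus). The
step-G judgment is drawn with probability 0.81 of "same criteria", the
corpus rate.

Effects: each case draws a true effect θ ~ Normal(0, τ) — on the log scale
for ratio measures, raw scale for differences (τ default 0.3) — and each
review an estimate ~ Normal(θ, se) with se uniform on (0.1, 0.5), CI =
estimate ± 1.96·se and a two-sided Wald p-value, exponentiated for RR/OR.
Under τ = 0 the p-values are exactly uniform, so the classifier's
significant-verdict rate must match the nominal alpha; the suite checks this
within three Monte-Carlo standard errors at 10,000 simulated reviews. The
measure mix (MD 0.55, RR 0.26, OR 0.15, SMD 0.04) follows the corpus row
shares.

What the generator deliberately does **not** emulate: trial-level data and
meta-analytic pooling (pooled estimates are drawn directly), correlated
rosters between reviews of the same case beyond the shared universe,
data-extraction error, and non-normal small-sample behaviour of pooled
estimates. Assessor disagreement is modelled *purely* as ruleset
perturbation, so simulation results isolate the rule-interpretation
mechanism; passing simulator tests therefore show that divergent
operationalizations alone suffice to break choice agreement, not that they
are the only cause in real corpora.

## Numerical and degenerate-input choices

- 1.96 is fixed for 95% intervals, matching the corpus reporting convention.
- Printed p-values of the form `<x` are parsed as `x`: for any alpha ≥ x the
  classification is identical to the unprinted exact value.
- Percentages are held at full precision and rounded to whole numbers only
  for display (the corpus prints integers).
- Median/IQR of assessment minutes are reported as absent when no timing
  data exist (the shipped corpus has none); a single observation yields a
  median but no IQR. Pilot assessments are excluded from timing by default.
- Degenerate cases: fewer than two reviews is a structural error; an empty
  trial roster at step C, cross-tool quality at step D/F, and a step-G
  evaluation with neither judgment nor PICO terms raise step-annotated
  errors rather than defaulting.

## Problem sizes

The engine-vs-brute-force equivalence property runs on 1,000 generated
small cases (2–5 reviews each), classifier calibration on 10,000 simulated
reviews, and agreement curves on grids of 4–5 replicates of 10–15 cases per
cell; these sizes give stable Monte-Carlo estimates (binomial SE ≤ 0.007 for
the calibration check) while keeping the full suite fast.

## Known limitations

- Step-G computed similarity is bag-of-terms Jaccard over curated PICO term
  lists; it does not attempt semantic matching, and with no term lists and
  no recorded judgment it errs rather than guessing.
- The step-E synthesis comparison encodes three ordinal sub-judgments
  (extraction rigour, heterogeneity assessed, synthesis appropriate); real
  corpora rarely reach step E (the replication corpus never did), so this
  encoding is the least exercised part of the engine.
- The shipped corpus inherits its source tables' internal inconsistencies
  (a step-I author tally of 13 rows against a stated 12; review-label
  mismatches between tables), which are preserved and documented rather
  than reconciled.
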