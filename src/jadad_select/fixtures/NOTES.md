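# Replication-corpus fixture notes

The three CSVs transcribe the published result tables of a 21-case
replication corpus of discordant-review assessments:

- `table1.csv` — one row per case: question labels, benefit direction of the
  primary outcome, number of competing systematic reviews (2–10), the
  step-G judgment recorded by the replication team (`same_criteria_judged`),
  and whether the case was one of the three pilot assessments.
- `table2.csv` — one row per (case, assessor): final decision step, chosen
  review labels (primary first, `;`-separated, with per-review quality,
  Cochrane and risk-of-bias flags `;`-matched to the labels), and the
  replication team's ease-of-use rating.
- `table3.csv` — one row per reported effect estimate (27 rows): measure
  type, pooled point estimate, 95% CI, p-value as printed (`<0.0001`, `NR`),
  the printed favourable/null/unfavourable verdict, and the per-case
  direction agree/disagree call.

## Transcription decisions

- **Label inconsistency between the assessment and effect tables.** The
  effect table heads the non-union block (Ouyang 2013 vs Heineman 2010)
  "Zhao 2015a" while the assessment table lists those reviews under
  Zhao 2015b. Rows are keyed by the *review* labels, so the block is filed
  under `zhao-2015b` (the humeral-fracture non-union case); the clavicle
  constant-score case `zhao-2015a` (identical choices, Lenza 2013) has no
  effect rows, like every other case with identical choice sets.
- **Ease ratings.** Only the 18 non-pilot assessments carry a rating. The
  source reports marginal counts (10 easy, 6 moderate, 1 "moderate/hard",
  1 hard; all easy ratings on step-H assessments; 3 of the 8 moderate-to-hard
  on step I). The rubric has exactly three levels, so the "moderate/hard"
  assessment is encoded `red`; the per-case assignment within those marginal
  counts is not printed and is therefore synthetic (consistent with every
  printed marginal). Do not treat individual ease cells as source data.
- **Minutes.** Per-assessment timings appear only in supplementary material
  that is not transcribed here; the `minutes` column is left empty and the
  timing summary is reported as absent.
- **Step-I author tally.** The source text says twelve author groups ended at
  Step I while the assessment table contains thirteen Step-I author rows;
  the transcription preserves the table and leaves the discrepancy
  unresolved.
- **p-values.** Printed as in the source; `<x` bounds are parsed as the
  bound (equivalent for any significance level at or above the bound) and
  `NR` as absent, in which case classification falls back to the CI rule.
- **Synthetic structure added by the loader.** Trial rosters, search
  profiles, and the unnamed filler reviews needed to reach each case's
  printed review count are not in the tables and are generated synthetically
  by `load_fixture_tables` (pairwise-distinct rosters so that the same-trials
  step answers "no" on every case, as observed). Per-case step-H/I
  *selections* therefore must not be asserted against these fixtures; only
  routing and the tabulated choices/effects are source data.
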