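# jadad-select

Clinicians, guideline developers and policy makers routinely find several
systematic reviews (SRs) with meta-analysis answering the *same* clinical
question — and disagreeing. The classic remedy is a 1997 hierarchical
decision algorithm (Jadad et al.) for picking the "best evidence" review:

- **A/B** — if a review does not address the question, drop it; with fewer
  than two candidates left, take the one closest to the question (terminal
  **B**);
- **C** — did the candidate reviews include the same randomized trials?
- if **yes**: **D** compares methodological quality; equal quality leads to a
  comparison of data extraction, heterogeneity and synthesis (terminal
  **E**), unequal quality selects the highest-quality review(s) (terminal
  **F**);
- if **no**: **G** asks whether the reviews applied the same selection
  criteria; if yes, search rigour decides (terminal **H**), otherwise a
  publication-status / trial-quality / language / individual-patient-data
  hierarchy decides (terminal **I**).

The algorithm's published description leaves the inner workings of the
decisive steps open, so independent assessors can reach different choices
from identical inputs. This package makes every such degree of freedom an
explicit, serializable parameter (`Ruleset`: the step-H and step-I criterion
orders and the step-G PICO-similarity threshold), implements the algorithm
deterministically with full decision traces, and provides:

- `jadad_select.models` / `io` — validated domain types (PICO frames, trial
  rosters, search profiles, tool-specific quality ratings, pooled effect
  estimates), JSON case files with a shipped schema, and a bundled 21-case
  replication corpus transcribed from a published discordant-review study
  (tables of paired author-vs-replicator assessments and 27 pooled effects);
- `jadad_select.engine` — steps A–I with lexicographic tie handling (ties
  keep *all* maximal reviews; unknown metadata ranks below any known value);
- `jadad_select.classify` — favourable / null / unfavourable classification
  of pooled effects (p-value precedence, else strict CI exclusion of the
  null, with the benefit direction a recorded per-outcome input);
- `jadad_select.stats` — choice-agreement, final-step, direction-concordance
  and ease/time summaries over paired assessments;
- `jadad_select.simulate` — a synthetic-case generator and paired simulated
  assessors with perturbed rulesets, to study quantitatively how divergent
  rule interpretations produce selection disagreement.

## Worked example

```python
import jadad_select as js

bundle = js.load_fixture_tables()          # 21 cases, 21 pairs, 27 effects
report = js.build_report(bundle.pairs, bundle.effect_index())
print(report.to_text())
```

prints

```
21 paired assessments
choice of review(s): 8 agreed (38%), 13 disagreed (62%)
final decision step among disagreements: 6 same, 7 different
direction of effect: 18/21 agreed overall (86%); 10 of the 13 choice disagreements still agreed in direction; 3 pointed different ways
original final steps: F: 1, H: 5, I: 13, not_reported: 2
replication final steps: H: 17, I: 4
ease ratings: green: 10, red: 2, yellow: 6 over 18 rated assessments
minutes per assessment: not recorded
```

In words: on the 21-case corpus the original authors and an independent
replication team chose the same review set only 8 times (38%) — the
algorithm is poorly reproducible between users — yet 18 of 21 assessments
(86%) still agreed in the *direction* of the pooled effect, because
overlapping reviews of the same question usually point the same way.

The same report is available from the shell:

```sh
jadad-select reproduce --out results/
jadad-select assess --case my_case.json --ruleset my_rules.json
jadad-select simulate --config sim.json --seed 1 --out sim_out/
```

To quantify the mechanism behind the disagreement, simulate two assessors
who differ only in how they ordered the step-H search criteria:

```python
cfg = js.SimConfig(seed=1, n_cases=50)
base = js.Ruleset()
curve = js.agreement_curve(
    cfg,
    [("identical", {}),
     ("reversed-h", {"step_h_order": tuple(reversed(base.step_h_order))})],
    n_replicates=10,
)
print(curve[["perturbation", "mean_choice_agreement", "mean_direction_agreement"]])
```

The identical-ruleset cell agrees on 100% of cases; reversing one criterion
order is enough to drop choice agreement far below 1 while direction
agreement stays high — the pattern observed on the real corpus.

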