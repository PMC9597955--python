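"""Synthetic discordant-review cases and paired simulated assessors.

The generator emulates the structure of the replication corpus: each case is
a clinical question with 2–10 overlapping systematic reviews, partially
overlapping trial rosters, tool-based quality ratings, heterogeneous search
profiles, and pooled effects scattered around a case-level true effect.
Effects are simulated on the log scale for ratio measures (RR/OR) and on the
raw scale for differences (MD/SMD); 95% CIs use the fixed 1.96 normal
quantile and p-values come from the two-sided Wald statistic, so the
classifier's CI/null-value semantics apply unchanged.

Assessor disagreement is modelled purely as *ruleset perturbation*: two
simulated assessors run the identical deterministic algorithm with different
operationalizations of the under-specified steps.  Data-extraction error is
deliberately not simulated, so any disagreement is attributable to the rules.
"""

from __future__ import annotations

from datetime import date, timedelta
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .engine import Ruleset, run_jadad
from .errors import ConfigError
from .stats import direction_concordance
from .models import (
    AssessmentPair,
    DiscordantCase,
    EffectEstimate,
    PicoElement,
    PicoFrame,
    QualityRating,
    SearchProfile,
    SRRecord,
    SynthesisProfile,
    TrialSet,
)

_Z95 = 1.96

_DATABASE_POOL = (
    "MEDLINE", "Embase", "CENTRAL", "Web of Science", "Scopus",
    "CINAHL", "PsycINFO", "CNKI", "Wanfang", "VIP",
)

_AMSTAR_LEVELS = ("Critically low", "Low", "Moderate", "High", "Highest")

_EXTRACTION_P = {"duplicate": 0.6, "single": 0.3, "unknown": 0.1}


class SimConfig(BaseModel):
    """Study conditions for the synthetic corpus.

    Defaults mirror the replication corpus where it pins a value (review
    counts 2–10; 81% of cases judged to share selection criteria; measure mix
    matching the effect table's row shares; no review with an individual
    patient data analysis) and plausible evidence-synthesis practice
    elsewhere.
    """

    model_config = ConfigDict(extra="forbid")

    n_cases: int = Field(default=21, ge=1)
    reviews_per_case: tuple[int, int] = (2, 10)
    trial_universe_size: int = Field(default=30, ge=1)
    trial_inclusion_probability: float = Field(default=0.6, ge=0.0, le=1.0)
    quality_level_distribution: dict[str, float] = Field(
        default_factory=lambda: {
            "Critically low": 0.1, "Low": 0.15, "Moderate": 0.3,
            "High": 0.35, "Highest": 0.1,
        }
    )
    databases_range: tuple[int, int] = (2, 8)
    grey_literature_probability: float = Field(default=0.5, ge=0.0, le=1.0)
    duplicate_screening_probability: float = Field(default=0.7, ge=0.0, le=1.0)
    search_window: tuple[date, date] = (date(2005, 1, 1), date(2020, 12, 31))
    language_none_probability: float = Field(default=0.7, ge=0.0, le=1.0)
    includes_unpublished_probability: float = Field(default=0.5, ge=0.0, le=1.0)
    rct_quality_assessed_probability: float = Field(default=0.7, ge=0.0, le=1.0)
    ipd_probability: float = Field(default=0.0, ge=0.0, le=1.0)
    same_criteria_probability: float = Field(default=0.81, ge=0.0, le=1.0)
    true_effect_sd: float = Field(default=0.3, ge=0.0)
    se_range: tuple[float, float] = (0.1, 0.5)
    measure_mix: dict[str, float] = Field(
        default_factory=lambda: {"MD": 0.55, "RR": 0.26, "OR": 0.15, "SMD": 0.04}
    )
    benefit_direction: str = "lower_better"
    seed: int

    @model_validator(mode="after")
    def _feasible(self) -> "SimConfig":
        lo, hi = self.reviews_per_case
        if not 2 <= lo <= hi:
            raise ConfigError("reviews_per_case must satisfy 2 <= lo <= hi")
        if self.databases_range[0] < 0 or self.databases_range[0] > self.databases_range[1]:
            raise ConfigError("databases_range must be a non-degenerate 0 <= lo <= hi")
        if self.databases_range[1] > len(_DATABASE_POOL):
            raise ConfigError(
                f"at most {len(_DATABASE_POOL)} distinct databases are available"
            )
        if not 0 < self.se_range[0] <= self.se_range[1]:
            raise ConfigError("se_range must satisfy 0 < lo <= hi")
        if self.search_window[0] > self.search_window[1]:
            raise ConfigError("search_window must be ordered")
        for name, mix in (("measure_mix", self.measure_mix),
                          ("quality_level_distribution", self.quality_level_distribution)):
            if not mix or any(v < 0 for v in mix.values()) or sum(mix.values()) <= 0:
                raise ConfigError(f"{name} must be a non-empty non-negative mixture")
        if set(self.measure_mix) - {"RR", "OR", "MD", "SMD"}:
            raise ConfigError("measure_mix keys must be RR/OR/MD/SMD")
        if set(self.quality_level_distribution) - set(_AMSTAR_LEVELS):
            raise ConfigError("quality levels must be AMSTAR levels")
        if self.benefit_direction not in ("lower_better", "higher_better"):
            raise ConfigError("benefit_direction must be lower_better or higher_better")
        return self


def _choice(rng: np.random.Generator, mix: Mapping[str, float]) -> str:
    keys = sorted(mix)
    p = np.array([mix[k] for k in keys], dtype=float)
    return str(rng.choice(keys, p=p / p.sum()))


def _simulate_effect(
    rng: np.random.Generator, theta: float, measure: str, cfg: SimConfig
) -> EffectEstimate:
    from scipy.stats import norm

    se = float(rng.uniform(*cfg.se_range))
    est = float(rng.normal(theta, se))
    lo, hi = est - _Z95 * se, est + _Z95 * se
    p = float(2.0 * norm.sf(abs(est) / se))
    if measure in ("RR", "OR"):
        est, lo, hi = float(np.exp(est)), float(np.exp(lo)), float(np.exp(hi))
    return EffectEstimate(
        measure=measure, point=est, ci_low=lo, ci_high=hi,
        p_value=min(p, 1.0), benefit_direction=cfg.benefit_direction,
    )


def _simulate_review(
    rng: np.random.Generator,
    case_idx: int,
    review_idx: int,
    theta: float,
    measure: str,
    pico: PicoFrame,
    cfg: SimConfig,
) -> SRRecord:
    universe = [f"trial-{j + 1}" for j in range(cfg.trial_universe_size)]
    mask = rng.random(len(universe)) < cfg.trial_inclusion_probability
    roster = [t for t, keep in zip(universe, mask) if keep]
    if not roster:  # a review always holds at least one trial
        roster = [universe[int(rng.integers(len(universe)))]]

    n_db = int(rng.integers(cfg.databases_range[0], cfg.databases_range[1] + 1))
    dbs = list(rng.choice(_DATABASE_POOL, size=n_db, replace=False)) if n_db else []
    window_days = (cfg.search_window[1] - cfg.search_window[0]).days
    search = SearchProfile(
        databases=[str(d) for d in dbs],
        grey_literature="yes" if rng.random() < cfg.grey_literature_probability else "no",
        last_search_date=cfg.search_window[0]
        + timedelta(days=int(rng.integers(window_days + 1))),
        duplicate_independent_screening="yes"
        if rng.random() < cfg.duplicate_screening_probability else "no",
        language_restriction="none"
        if rng.random() < cfg.language_none_probability else "restricted",
        publication_status_scope="includes_unpublished"
        if rng.random() < cfg.includes_unpublished_probability else "published_only",
        ipd_analysis="yes" if rng.random() < cfg.ipd_probability else "no",
    )
    quality = QualityRating.from_label(
        "AMSTAR",
        _choice(rng, cfg.quality_level_distribution),
        rct_quality_assessed="yes"
        if rng.random() < cfg.rct_quality_assessed_probability else "no",
    )
    synthesis = SynthesisProfile(
        extraction=_choice(rng, _EXTRACTION_P),
        heterogeneity_assessed="yes" if rng.random() < 0.7 else "no",
        synthesis_appropriate="yes" if rng.random() < 0.8 else "no",
    )
    return SRRecord(
        sr_id=f"sr-{review_idx + 1:02d}",
        label=f"Review {review_idx + 1} (case {case_idx + 1})",
        is_cochrane=bool(rng.random() < 0.15),
        pico=pico,
        trials=TrialSet(trial_ids=frozenset(roster)),
        search=search,
        quality=[quality],
        effect=_simulate_effect(rng, theta, measure, cfg),
        robis_verdict="low_risk" if rng.random() < 0.45 else "high_risk",
        synthesis=synthesis,
    )


def generate_cases(config: SimConfig) -> list[DiscordantCase]:
    """Generate a reproducible synthetic corpus of discordant cases.

    Each case draws a true effect from ``Normal(0, true_effect_sd)`` (log
    scale for ratio measures) and each review a pooled estimate
    ``Normal(theta, se)`` with its Wald 95% CI and p-value.
    """
    rng = np.random.default_rng(config.seed)
    cases = []
    for i in range(config.n_cases):
        lo, hi = config.reviews_per_case
        n_reviews = int(rng.integers(lo, hi + 1))
        measure = _choice(rng, config.measure_mix)
        theta = float(rng.normal(0.0, config.true_effect_sd))
        pico = PicoFrame(
            intervention=PicoElement(text=f"intervention {i + 1}", terms=[f"int-{i + 1}"]),
            outcome=PicoElement(text=f"outcome {i + 1}", terms=[f"out-{i + 1}"]),
        )
        reviews = [
            _simulate_review(rng, i, r, theta, measure, pico, config)
            for r in range(n_reviews)
        ]
        cases.append(
            DiscordantCase(
                case_id=f"case-{i + 1:04d}",
                question=pico,
                primary_outcome=f"outcome {i + 1}",
                primary_intervention=f"intervention {i + 1}",
                reviews=reviews,
                judged_same_criteria=bool(rng.random() < config.same_criteria_probability),
            )
        )
    return cases


def save_cases(cases: Sequence[DiscordantCase], directory: Union[str, Path]) -> None:
    """Write each case to ``<directory>/<case_id>.json`` in the case-file schema."""
    from .io import save_case

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for case in cases:
        save_case(case, directory / f"{case.case_id}.json")


def effect_index(cases: Sequence[DiscordantCase]) -> dict[tuple[str, str], EffectEstimate]:
    """Assessor-independent effect lookup ``(case_id, sr_id) -> estimate``."""
    return {
        (c.case_id, r.sr_id): r.effect
        for c in cases
        for r in c.reviews
        if r.effect is not None
    }


def perturb_ruleset(
    base: Ruleset, overrides: Mapping[str, object], ruleset_id: Optional[str] = None
) -> Ruleset:
    """A copy of ``base`` with the given fields replaced."""
    data = base.model_dump()
    data.update(overrides)
    if ruleset_id is not None:
        data["ruleset_id"] = ruleset_id
    return Ruleset.model_validate(data)


def simulate_assessor_pair(
    cases: Sequence[DiscordantCase], ruleset_a: Ruleset, ruleset_b: Ruleset
) -> list[AssessmentPair]:
    """Run the deterministic algorithm under two rulesets on every case."""
    pairs = []
    for case in cases:
        ta = run_jadad(case, ruleset_a)
        tb = run_jadad(case, ruleset_b)
        pairs.append(
            AssessmentPair(
                case_id=case.case_id,
                original_choice=tuple(ta.chosen),
                original_final_step=ta.terminal_step,
                replication_choice=tuple(tb.chosen),
                replication_final_step=tb.terminal_step,
            )
        )
    return pairs


def agreement_curve(
    config: SimConfig,
    perturbation_grid: Sequence[tuple[str, Mapping[str, object]]],
    n_replicates: int = 20,
    base_ruleset: Optional[Ruleset] = None,
) -> pd.DataFrame:
    """Monte-Carlo agreement rates between a reference assessor and a
    perturbed one, per perturbation cell.

    Returns one row per cell with the mean choice-agreement and
    direction-agreement rates, the replicate count and the seeds used.
    """
    if not perturbation_grid:
        raise ConfigError("perturbation_grid must be non-empty")
    base = base_ruleset or Ruleset()
    seed_rng = np.random.default_rng(config.seed)
    seeds = seed_rng.integers(0, 2**31, size=(len(perturbation_grid), n_replicates))
    rows = []
    for (name, overrides), cell_seeds in zip(perturbation_grid, seeds):
        other = perturb_ruleset(base, overrides, ruleset_id=name)
        choice_rates, dir_rates = [], []
        for s in cell_seeds:
            cfg = config.model_copy(update={"seed": int(s)})
            cases = generate_cases(cfg)
            pairs = simulate_assessor_pair(cases, base, other)
            n_agree = sum(p.choices_equal() for p in pairs)
            choice_rates.append(n_agree / len(pairs))
            overall, _, _ = direction_concordance(pairs, effect_index(cases))
            dir_rates.append(overall)
        rows.append(
            {
                "perturbation": name,
                "n_replicates": n_replicates,
                "n_cases": config.n_cases,
                "seeds": ";".join(str(int(s)) for s in cell_seeds),
                "mean_choice_agreement": float(np.mean(choice_rates)),
                "mean_direction_agreement": float(np.mean(dir_rates)),
            }
        )
    return pd.DataFrame(rows)
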