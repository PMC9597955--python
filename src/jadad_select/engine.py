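"""Deterministic implementation of the nine-step best-evidence selection
algorithm for discordant systematic reviews.

The algorithm (steps A–I) routes as follows: if some reviews do not address
the case's question they are dropped and, when fewer than two remain, the
single closest review is chosen at step B.  Otherwise step C asks whether all
candidate reviews included the same trials.  If yes, step D compares their
methodological quality: equal quality leads to a synthesis comparison
(terminal step E), unequal quality chooses the highest-quality review(s)
(terminal step F).  If the trial rosters differ, step G asks whether the
reviews applied the same selection criteria: if yes, search rigour decides
(terminal step H); if not, a publication/quality/language/IPD hierarchy
decides (terminal step I).

The published description of the algorithm leaves the inner ordering of the
step H and step I criteria open — different operationalizations are exactly
what makes independent assessors disagree — so the orderings and the step-G
similarity threshold are explicit, serializable parameters
(:class:`Ruleset`) rather than constants.  Ties select *all* maximal reviews.
"""

from __future__ import annotations

import itertools
import json
from pathlib import Path
from typing import Callable, Literal, Optional, Sequence, Union

from pydantic import BaseModel, ConfigDict, Field, field_validator

from .errors import IncomparableQualityError, StepError
from .models import DiscordantCase, JadadTrace, PicoFrame, SRRecord

StepHCriterion = Literal[
    "n_databases",
    "grey_literature",
    "duplicate_independent_screening",
    "last_search_date",
]
StepICriterion = Literal[
    "publication_status_scope",
    "rct_quality_assessed",
    "language_restriction",
    "ipd_analysis",
]

_H_CRITERIA = (
    "n_databases",
    "grey_literature",
    "duplicate_independent_screening",
    "last_search_date",
)
_I_CRITERIA = (
    "publication_status_scope",
    "rct_quality_assessed",
    "language_restriction",
    "ipd_analysis",
)


class Ruleset(BaseModel):
    """One operationalization of the under-specified steps.

    ``step_h_order`` and ``step_i_order`` are permutations of their criterion
    sets, applied lexicographically (first criterion most important).
    ``criteria_similarity_threshold`` is the minimum pairwise PICO term
    overlap (mean Jaccard over P/I/C/O) for step G to answer "same criteria"
    when no human judgment is recorded.  Quality ratings are compared only
    within a single tool's ordinal scale.
    """

    model_config = ConfigDict(extra="forbid")

    ruleset_id: str = "default"
    step_h_order: tuple[StepHCriterion, ...] = _H_CRITERIA
    step_i_order: tuple[StepICriterion, ...] = _I_CRITERIA
    criteria_similarity_threshold: float = Field(default=0.8, ge=0.0, le=1.0)
    quality_comparison_mode: Literal["within_tool_only"] = "within_tool_only"

    @field_validator("step_h_order")
    @classmethod
    def _h_permutation(cls, v):
        if sorted(v) != sorted(_H_CRITERIA):
            raise ValueError("step_h_order must be a permutation of the four criteria")
        return v

    @field_validator("step_i_order")
    @classmethod
    def _i_permutation(cls, v):
        if sorted(v) != sorted(_I_CRITERIA):
            raise ValueError("step_i_order must be a permutation of the four criteria")
        return v

    @classmethod
    def load(cls, path: Union[str, Path]) -> "Ruleset":
        return cls.model_validate_json(Path(path).read_text(encoding="utf-8"))

    def save(self, path: Union[str, Path]) -> None:
        Path(path).write_text(self.model_dump_json(indent=2) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# criterion orderings (larger key = preferred; unknown always ranks lowest)

_YNU = {"yes": 2, "no": 1, "unknown": 0}


def _key_n_databases(sr: SRRecord):
    return sr.search.n_databases


def _key_grey(sr: SRRecord):
    return _YNU[sr.search.grey_literature]


def _key_screening(sr: SRRecord):
    return _YNU[sr.search.duplicate_independent_screening]


def _key_search_date(sr: SRRecord):
    d = sr.search.last_search_date
    return (0, 0) if d is None else (1, d.toordinal())


def _key_pub_status(sr: SRRecord):
    return {"includes_unpublished": 2, "published_only": 1, "unknown": 0}[
        sr.search.publication_status_scope
    ]


def _key_rct_quality(sr: SRRecord):
    ranks = [_YNU[q.rct_quality_assessed] for q in sr.quality]
    return max(ranks, default=0)


def _key_language(sr: SRRecord):
    return {"none": 2, "restricted": 1, "unknown": 0}[sr.search.language_restriction]


def _key_ipd(sr: SRRecord):
    return 1 if sr.search.ipd_analysis == "yes" else 0


CRITERION_KEYS: dict[str, Callable[[SRRecord], object]] = {
    "n_databases": _key_n_databases,
    "grey_literature": _key_grey,
    "duplicate_independent_screening": _key_screening,
    "last_search_date": _key_search_date,
    "publication_status_scope": _key_pub_status,
    "rct_quality_assessed": _key_rct_quality,
    "language_restriction": _key_language,
    "ipd_analysis": _key_ipd,
}

_EXTRACTION = {"duplicate": 2, "single": 1, "unknown": 0}


def _synthesis_key(sr: SRRecord) -> tuple[int, int, int]:
    s = sr.synthesis
    if s is None:
        return (0, 0, 0)
    return (
        _EXTRACTION[s.extraction],
        _YNU[s.heterogeneity_assessed],
        _YNU[s.synthesis_appropriate],
    )


def lexicographic_select(
    candidates: Sequence[SRRecord], keys: Sequence[Callable[[SRRecord], object]]
) -> list[SRRecord]:
    """Keep, tier by tier, the candidates maximal under each key; survivors of
    all tiers are the chosen set (possibly several, on full ties)."""
    survivors = list(candidates)
    for key in keys:
        best = max(key(s) for s in survivors)
        survivors = [s for s in survivors if key(s) == best]
    return survivors


# ---------------------------------------------------------------------------
# individual steps


def step_question_match(case: DiscordantCase) -> tuple[list[SRRecord], Optional[SRRecord]]:
    """Step A/B: drop reviews judged off-question; when fewer than two remain
    the single closest review is the step-B choice (second return value)."""
    candidates = [r for r in case.reviews if case.same_question(r.sr_id)]
    if not candidates:
        raise StepError("B", "no review addresses the case question")
    if len(candidates) < 2:
        return candidates, candidates[0]
    return candidates, None


def step_same_trials(candidates: Sequence[SRRecord]) -> bool:
    """Step C: did all candidate reviews include the same trials?"""
    _require(len(candidates) >= 2, "C", "at least two candidates required")
    for sr in candidates:
        if not sr.trials.trial_ids:
            raise StepError("C", f"review {sr.sr_id!r} has an empty trial roster")
    first = candidates[0].trials.trial_ids
    return all(sr.trials.trial_ids == first for sr in candidates[1:])


def _shared_tool_ranks(candidates: Sequence[SRRecord], step: str) -> dict[str, int]:
    """Ordinal ranks on a tool shared by every candidate (quality is never
    compared across instruments)."""
    shared = set.intersection(*({q.tool for q in sr.quality} for sr in candidates))
    if not shared:
        raise IncomparableQualityError(
            "no quality instrument is shared by all candidate reviews; supply "
            "ratings from a common tool (e.g. fresh ROBIS verdicts)",
            step=step,
        )
    tool = sorted(shared)[0]
    ranks = {}
    for sr in candidates:
        ranks[sr.sr_id] = max(q.ordinal_rank for q in sr.quality if q.tool == tool)
    return ranks


def step_same_quality(candidates: Sequence[SRRecord]) -> bool:
    """Step D: are all candidates of the same quality / risk of bias?"""
    _require(len(candidates) >= 2, "D", "at least two candidates required")
    ranks = _shared_tool_ranks(candidates, "D")
    return len(set(ranks.values())) == 1


def step_choose_highest_quality(candidates: Sequence[SRRecord]) -> list[SRRecord]:
    """Terminal step F: all candidates attaining the maximal quality rank."""
    ranks = _shared_tool_ranks(candidates, "F")
    best = max(ranks.values())
    return [sr for sr in candidates if ranks[sr.sr_id] == best]


def step_compare_synthesis(candidates: Sequence[SRRecord]) -> list[SRRecord]:
    """Terminal step E: lexicographic preference over extraction rigour,
    heterogeneity assessment, and synthesis appropriateness (unknown worst)."""
    return lexicographic_select(candidates, [_synthesis_key])


def pico_similarity(a: PicoFrame, b: PicoFrame) -> float:
    """Mean Jaccard overlap of the four PICO term lists (two empty lists for
    the same element count as full overlap)."""
    total = 0.0
    for elem in ("population", "intervention", "comparator", "outcome"):
        sa = set(getattr(a, elem).terms)
        sb = set(getattr(b, elem).terms)
        total += 1.0 if not (sa | sb) else len(sa & sb) / len(sa | sb)
    return total / 4.0


def step_same_criteria(
    candidates: Sequence[SRRecord],
    ruleset: Ruleset,
    judged_same_criteria: Optional[bool] = None,
) -> bool:
    """Step G: same selection criteria?  A recorded human judgment takes
    precedence; otherwise all pairwise PICO similarities must reach the
    ruleset threshold."""
    if judged_same_criteria is not None:
        return judged_same_criteria
    if any(
        all(getattr(sr.pico, e).is_empty() for e in ("population", "intervention", "comparator", "outcome"))
        for sr in candidates
    ):
        raise StepError("G", "neither a criteria judgment nor PICO terms are available")
    return all(
        pico_similarity(a.pico, b.pico) >= ruleset.criteria_similarity_threshold
        for a, b in itertools.combinations(candidates, 2)
    )


def step_search_rigour(candidates: Sequence[SRRecord], ruleset: Ruleset) -> list[SRRecord]:
    """Terminal step H: lexicographic maximization over the ruleset's search
    criteria (databases searched, grey literature, duplicate screening,
    search recency by default)."""
    keys = [CRITERION_KEYS[c] for c in ruleset.step_h_order]
    return lexicographic_select(candidates, keys)


def step_publication_hierarchy(
    candidates: Sequence[SRRecord], ruleset: Ruleset
) -> list[SRRecord]:
    """Terminal step I: lexicographic maximization over publication status,
    trial-quality assessment, language restriction, and IPD analysis."""
    keys = [CRITERION_KEYS[c] for c in ruleset.step_i_order]
    return lexicographic_select(candidates, keys)


def _require(cond: bool, step: str, msg: str) -> None:
    if not cond:
        raise StepError(step, msg)


# ---------------------------------------------------------------------------
# full algorithm


def run_jadad(case: DiscordantCase, ruleset: Optional[Ruleset] = None) -> JadadTrace:
    """Run the full decision algorithm on a case, producing an ordered trace
    of step verdicts, the terminal step, and the chosen review set.

    Deterministic: identical (case, ruleset) inputs yield identical traces.
    """
    ruleset = ruleset or Ruleset()
    steps: list[tuple[str, str]] = []

    candidates, closest = step_question_match(case)
    excluded = [r.sr_id for r in case.reviews if not case.same_question(r.sr_id)]
    verdict_a = (
        "all reviews address the case question"
        if not excluded
        else f"excluded off-question reviews: {', '.join(sorted(excluded))}"
    )
    steps.append(("A", verdict_a))

    if closest is not None:
        steps.append(("B", f"chose the review closest to the question: {closest.sr_id}"))
        return JadadTrace(
            steps=steps, terminal_step="B", chosen=[closest.sr_id], ruleset_id=ruleset.ruleset_id
        )

    same_trials = step_same_trials(candidates)
    steps.append(("C", "same trials included" if same_trials else "different trials included"))

    if same_trials:
        same_quality = step_same_quality(candidates)
        steps.append(
            ("D", "same methodological quality" if same_quality else "quality differs")
        )
        if same_quality:
            chosen = step_compare_synthesis(candidates)
            steps.append(("E", "compared data extraction, heterogeneity and synthesis"))
            terminal = "E"
        else:
            chosen = step_choose_highest_quality(candidates)
            steps.append(("F", "chose the highest-quality review(s)"))
            terminal = "F"
    else:
        same_criteria = step_same_criteria(candidates, ruleset, case.judged_same_criteria)
        steps.append(
            ("G", "same selection criteria" if same_criteria else "different selection criteria")
        )
        if same_criteria:
            chosen = step_search_rigour(candidates, ruleset)
            steps.append(("H", "compared search strategies and criteria application"))
            terminal = "H"
        else:
            chosen = step_publication_hierarchy(candidates, ruleset)
            steps.append(
                ("I", "compared publication status, trial quality, language and IPD")
            )
            terminal = "I"

    return JadadTrace(
        steps=steps,
        terminal_step=terminal,
        chosen=sorted(sr.sr_id for sr in chosen),
        ruleset_id=ruleset.ruleset_id,
    )


def trace_to_json(trace: JadadTrace) -> str:
    return json.dumps(trace.model_dump(), indent=2)
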