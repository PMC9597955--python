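"""Domain model for discordant systematic reviews and their assessment.

A *discordant case* is a clinical question addressed by two or more
overlapping systematic reviews (SRs) with meta-analysis of randomized
controlled trials whose pooled results conflict.  The types here carry the
machine-readable metadata the selection algorithm consumes: the PICO frame,
the roster of included trials, the search profile, quality/risk-of-bias
ratings, and the pooled effect estimate for the case's primary outcome.
"""

from __future__ import annotations

import re
from datetime import date
from typing import Literal, Optional

from pydantic import (
    BaseModel,
    ConfigDict,
    Field,
    computed_field,
    field_validator,
    model_validator,
)

from .errors import CaseError

# ---------------------------------------------------------------------------
# vocabulary

YesNoUnknown = Literal["yes", "no", "unknown"]
YesNo = Literal["yes", "no"]
LanguageRestriction = Literal["none", "restricted", "unknown"]
PublicationStatusScope = Literal["published_only", "includes_unpublished", "unknown"]
MeasureType = Literal["RR", "OR", "MD", "SMD"]
BenefitDirection = Literal["lower_better", "higher_better"]
RobisVerdict = Literal["low_risk", "high_risk", "unknown"]
QualityTool = Literal["AMSTAR", "AMSTAR2", "OXMAN_GUYATT", "ROBIS"]
StepId = Literal["A", "B", "C", "D", "E", "F", "G", "H", "I"]
TerminalStep = Literal["B", "E", "F", "H", "I"]
EaseRating = Literal["green", "yellow", "red"]
ExtractionRigour = Literal["duplicate", "single", "unknown"]

#: Three-colour ease-of-use rubric for a selection step (exactly three levels).
EASE_RUBRIC: dict[str, str] = {
    "green": "easy — the step is accomplished easily, with low cognitive load "
    "or via a recognised method",
    "yellow": "moderate — the step demands a notable degree of cognitive load "
    "but can generally be accomplished with some effort",
    "red": "hard — the step is difficult or confusing; some assessors would "
    "likely fail or abandon it",
}

#: Per-tool ordered quality scales, worst to best (index = ordinal rank).
#: Ratings are only ever compared within a single tool's scale.
TOOL_SCALES: dict[str, tuple[str, ...]] = {
    "AMSTAR": (
        "critically low quality",
        "low quality",
        "moderate quality",
        "high quality",
        "highest quality",
    ),
    "AMSTAR2": (
        "critically low quality",
        "low quality",
        "moderate quality",
        "high quality",
    ),
    "OXMAN_GUYATT": ("1", "2", "3", "4", "5", "6", "7"),
    "ROBIS": ("high risk", "low risk"),
}

_ID_RE = re.compile(r"[^a-z0-9]+")
_ET_AL_RE = re.compile(r"\bet\s+al\b\.?", flags=re.IGNORECASE)


def normalize_trial_id(raw_label: str) -> str:
    """Normalize a study label to a canonical ``firstauthor-year`` identifier.

    Lowercases, drops "et al.", and collapses whitespace/punctuation runs to
    single hyphens.  Idempotent: ``normalize_trial_id(x)`` is a fixed point.

    >>> normalize_trial_id("FENG, 2015")
    'feng-2015'
    >>> normalize_trial_id("Dai et al. 2017")
    'dai-2017'
    """
    if not isinstance(raw_label, str) or not raw_label.strip():
        raise ValueError("trial label must be a non-empty string")
    s = _ET_AL_RE.sub(" ", raw_label.lower())
    s = _ID_RE.sub("-", s).strip("-")
    if not s:
        raise ValueError(f"label {raw_label!r} normalizes to an empty identifier")
    return s


# ---------------------------------------------------------------------------
# types


class PicoElement(BaseModel):
    """One PICO element: free text plus an optional controlled term list."""

    model_config = ConfigDict(extra="forbid")

    text: str = ""
    terms: list[str] = Field(default_factory=list)

    def is_empty(self) -> bool:
        return not self.text.strip() and not self.terms


class PicoFrame(BaseModel):
    """Population / Intervention / Comparator / Outcome question frame."""

    model_config = ConfigDict(extra="forbid")

    population: PicoElement = Field(default_factory=PicoElement)
    intervention: PicoElement
    comparator: PicoElement = Field(default_factory=PicoElement)
    outcome: PicoElement

    @model_validator(mode="after")
    def _require_i_and_o(self) -> "PicoFrame":
        if self.intervention.is_empty():
            raise ValueError("intervention must be non-empty")
        if self.outcome.is_empty():
            raise ValueError("outcome must be non-empty")
        return self


class TrialSet(BaseModel):
    """Set of normalized trial identifiers included in one review."""

    model_config = ConfigDict(extra="forbid")

    trial_ids: frozenset[str] = frozenset()

    @field_validator("trial_ids")
    @classmethod
    def _normalized(cls, v: frozenset[str]) -> frozenset[str]:
        for tid in v:
            if normalize_trial_id(tid) != tid:
                raise ValueError(f"trial id {tid!r} is not normalized")
        return v

    @classmethod
    def from_labels(cls, labels: list[str]) -> "TrialSet":
        """Build a roster from raw study labels.

        Two *distinct* raw labels that collide onto the same normalized
        identifier raise an error rather than merging silently.
        """
        seen: dict[str, str] = {}
        for raw in labels:
            tid = normalize_trial_id(raw)
            prev = seen.get(tid)
            if prev is not None and prev != raw:
                raise ValueError(
                    f"labels {prev!r} and {raw!r} collide on identifier {tid!r}"
                )
            seen[tid] = raw
        return cls(trial_ids=frozenset(seen))


class SearchProfile(BaseModel):
    """How a review searched and screened the literature.

    Unknown metadata is an explicit ``unknown`` value, never an empty string;
    the selection rules rank unknown strictly below any known value.
    """

    model_config = ConfigDict(extra="forbid")

    databases: list[str] = Field(default_factory=list)
    grey_literature: YesNoUnknown = "unknown"
    last_search_date: Optional[date] = None
    duplicate_independent_screening: YesNoUnknown = "unknown"
    language_restriction: LanguageRestriction = "unknown"
    publication_status_scope: PublicationStatusScope = "unknown"
    ipd_analysis: YesNo = "no"

    @computed_field  # type: ignore[prop-decorator]
    @property
    def n_databases(self) -> int:
        return len(self.databases)

    @model_validator(mode="before")
    @classmethod
    def _drop_derived(cls, data):
        # n_databases is derived; tolerate it on input but require consistency.
        if isinstance(data, dict) and "n_databases" in data:
            n = data.pop("n_databases")
            if n != len(data.get("databases", [])):
                raise ValueError("n_databases must equal len(databases)")
        return data


class QualityRating(BaseModel):
    """A methodological-quality or risk-of-bias rating from one instrument."""

    model_config = ConfigDict(extra="forbid")

    tool: QualityTool
    raw_level: str
    ordinal_rank: int
    rct_quality_assessed: YesNoUnknown = "unknown"

    @model_validator(mode="after")
    def _rank_on_scale(self) -> "QualityRating":
        scale = TOOL_SCALES[self.tool]
        if not 0 <= self.ordinal_rank < len(scale):
            raise ValueError(
                f"ordinal_rank {self.ordinal_rank} outside the {self.tool} scale"
            )
        canon = _canonical_level(self.tool, self.raw_level)
        if canon in scale and scale.index(canon) != self.ordinal_rank:
            raise ValueError(
                f"ordinal_rank {self.ordinal_rank} inconsistent with "
                f"{self.tool} level {self.raw_level!r}"
            )
        return self

    @classmethod
    def from_label(
        cls,
        tool: QualityTool,
        raw_level: str,
        rct_quality_assessed: YesNoUnknown = "unknown",
    ) -> "QualityRating":
        """Construct a rating from a printed level label (e.g. "High quality")."""
        canon = _canonical_level(tool, raw_level)
        scale = TOOL_SCALES[tool]
        if canon not in scale:
            raise ValueError(f"unknown {tool} level {raw_level!r}")
        return cls(
            tool=tool,
            raw_level=raw_level,
            ordinal_rank=scale.index(canon),
            rct_quality_assessed=rct_quality_assessed,
        )


def _canonical_level(tool: str, raw_level: str) -> str:
    s = " ".join(raw_level.lower().replace("-", " ").split())
    if tool in ("AMSTAR", "AMSTAR2") and not s.endswith("quality"):
        s = f"{s} quality"
    if tool == "ROBIS" and not s.endswith("risk"):
        s = f"{s} risk"
    return s


class EffectEstimate(BaseModel):
    """A pooled effect for the primary outcome, as printed by a review.

    The null value is determined solely by the measure type: 1 for ratio
    measures (RR, OR), 0 for difference measures (MD, SMD).  The benefit
    direction is a recorded per-outcome attribute, never inferred from data.
    """

    model_config = ConfigDict(extra="forbid")

    measure: MeasureType
    point: float
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None
    p_value: Optional[float] = Field(default=None, ge=0.0, le=1.0)
    benefit_direction: BenefitDirection

    @computed_field  # type: ignore[prop-decorator]
    @property
    def null_value(self) -> float:
        return 1.0 if self.measure in ("RR", "OR") else 0.0

    @model_validator(mode="before")
    @classmethod
    def _drop_derived(cls, data):
        if isinstance(data, dict):
            data.pop("null_value", None)
        return data

    @model_validator(mode="after")
    def _ordered_ci(self) -> "EffectEstimate":
        if self.ci_low is not None and self.ci_high is not None:
            if not (self.ci_low <= self.point <= self.ci_high):
                raise ValueError(
                    f"point {self.point} outside CI ({self.ci_low}, {self.ci_high})"
                )
        elif (self.ci_low is None) != (self.ci_high is None):
            raise ValueError("both CI bounds must be given, or neither")
        return self


class SynthesisProfile(BaseModel):
    """Recorded sub-judgments on a review's extraction and synthesis conduct."""

    model_config = ConfigDict(extra="forbid")

    extraction: ExtractionRigour = "unknown"
    heterogeneity_assessed: YesNoUnknown = "unknown"
    synthesis_appropriate: YesNoUnknown = "unknown"


class SRRecord(BaseModel):
    """One systematic review's machine-readable metadata."""

    model_config = ConfigDict(extra="forbid")

    sr_id: str
    label: str
    is_cochrane: bool = False
    pico: PicoFrame
    trials: TrialSet = Field(default_factory=TrialSet)
    search: SearchProfile = Field(default_factory=SearchProfile)
    quality: list[QualityRating] = Field(default_factory=list)
    effect: Optional[EffectEstimate] = None
    robis_verdict: RobisVerdict = "unknown"
    synthesis: Optional[SynthesisProfile] = None


class DiscordantCase(BaseModel):
    """A question plus its competing reviews and recorded human judgments."""

    model_config = ConfigDict(extra="forbid")

    case_id: str
    question: PicoFrame
    primary_outcome: str
    primary_intervention: str
    reviews: list[SRRecord] = Field(min_length=2)
    judged_same_question: dict[str, bool] = Field(default_factory=dict)
    judged_same_criteria: Optional[bool] = None

    @model_validator(mode="after")
    def _consistent_ids(self) -> "DiscordantCase":
        ids = [r.sr_id for r in self.reviews]
        if len(set(ids)) != len(ids):
            raise ValueError("sr_id values must be unique within a case")
        unknown = set(self.judged_same_question) - set(ids)
        if unknown:
            raise ValueError(f"judged_same_question refers to unknown ids {sorted(unknown)}")
        return self

    def sr_ids(self) -> list[str]:
        return [r.sr_id for r in self.reviews]

    def review(self, sr_id: str) -> SRRecord:
        for r in self.reviews:
            if r.sr_id == sr_id:
                return r
        raise KeyError(sr_id)

    def same_question(self, sr_id: str) -> bool:
        """Human judgment whether this review addresses the case question
        (defaults to yes when no judgment was recorded)."""
        return self.judged_same_question.get(sr_id, True)


_ALLOWED_PATHS: tuple[tuple[str, ...], ...] = (
    ("A", "B"),
    ("A", "C", "D", "E"),
    ("A", "C", "D", "F"),
    ("A", "C", "G", "H"),
    ("A", "C", "G", "I"),
)


class JadadTrace(BaseModel):
    """Ordered step verdicts ending in a terminal step and a chosen review set."""

    model_config = ConfigDict(extra="forbid")

    steps: list[tuple[StepId, str]]
    terminal_step: TerminalStep
    chosen: list[str] = Field(min_length=1)
    ruleset_id: str

    @model_validator(mode="after")
    def _valid_path(self) -> "JadadTrace":
        path = tuple(s for s, _ in self.steps)
        if path not in _ALLOWED_PATHS:
            raise ValueError(f"step sequence {path} does not follow the decision graph")
        if path[-1] != self.terminal_step:
            raise ValueError("terminal_step must be the last step of the trace")
        if sorted(self.chosen) != self.chosen:
            raise ValueError("chosen must be sorted for deterministic serialization")
        return self

    def as_text(self) -> str:
        """Human-readable rendering of the decision path."""
        lines = [f"ruleset: {self.ruleset_id}"]
        for step, verdict in self.steps:
            lines.append(f"Step {step}: {verdict}")
        lines.append(f"chosen: {', '.join(self.chosen)}")
        return "\n".join(lines)


NOT_REPORTED = "not_reported"
FinalStep = Literal["A", "B", "C", "D", "E", "F", "G", "H", "I", "not_reported"]


class AssessmentPair(BaseModel):
    """Two selections on the same case: the original authors' and a replication.

    Choices are ordered tuples with the primary review first (effect tables
    report one estimate per assessment even when several reviews are chosen).
    """

    model_config = ConfigDict(extra="forbid")

    case_id: str
    original_choice: tuple[str, ...] = Field(min_length=1)
    original_final_step: FinalStep = NOT_REPORTED
    replication_choice: tuple[str, ...] = Field(min_length=1)
    replication_final_step: FinalStep = NOT_REPORTED
    ease_rating: Optional[EaseRating] = None
    minutes: Optional[float] = None
    pilot: bool = False

    @property
    def original_primary(self) -> str:
        return self.original_choice[0]

    @property
    def replication_primary(self) -> str:
        return self.replication_choice[0]

    def choices_equal(self) -> bool:
        """Strict set equality of the two chosen review sets."""
        return set(self.original_choice) == set(self.replication_choice)


def make_case(**kwargs) -> DiscordantCase:
    """Validate and build a case, raising :class:`CaseError` when fewer than
    two reviews are supplied (the structural minimum for discordance)."""
    reviews = kwargs.get("reviews", [])
    if len(reviews) < 2:
        raise CaseError("a discordant case requires at least two systematic reviews")
    return DiscordantCase(**kwargs)
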