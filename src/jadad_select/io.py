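"""Reading and writing case files, and loading the bundled replication corpus.

Case files are JSON, one discordant case per file, with field names exactly
matching :mod:`jadad_select.models`; the corresponding JSON Schema is shipped
at ``schemas/discordant_case.schema.json``.  The replication corpus is three
CSV tables under ``fixtures/`` (see ``fixtures/NOTES.md`` for transcription
decisions and which parts of the loaded objects are synthetic scaffolding).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Optional, Union

import pandas as pd
from pydantic import ValidationError

from .errors import CaseError, FixtureIntegrityError
from .models import (
    AssessmentPair,
    DiscordantCase,
    EffectEstimate,
    PicoElement,
    PicoFrame,
    QualityRating,
    SRRecord,
    TrialSet,
    normalize_trial_id,
)

_MEASURES = {"RR", "OR", "MD", "SMD"}


def load_case(path: Union[str, Path]) -> DiscordantCase:
    """Load and validate a discordant case from a JSON file.

    Raises :class:`CaseError` when fewer than two reviews are present and
    pydantic's ``ValidationError`` (naming the offending field) on any other
    schema violation.
    """
    with open(path, encoding="utf-8") as fh:
        data = json.load(fh)
    reviews = data.get("reviews")
    if isinstance(reviews, list) and len(reviews) < 2:
        raise CaseError(
            f"{path}: a discordant case requires at least two systematic reviews"
        )
    return DiscordantCase.model_validate(data)


def save_case(case: DiscordantCase, path: Union[str, Path]) -> None:
    """Write a case as JSON; ``load_case`` of the result reproduces the case."""
    Path(path).write_text(
        case.model_dump_json(indent=2, exclude_none=True) + "\n", encoding="utf-8"
    )


def case_json_schema() -> dict:
    """JSON Schema of the case-file format (also shipped as a static file)."""
    return DiscordantCase.model_json_schema()


@dataclass(frozen=True)
class EffectRow:
    """One transcribed effect-table row: which assessment it belongs to,
    the review it reports on, and the printed verdict/direction cells."""

    case_id: str
    assessor: str  # "authors" | "replication"
    sr_id: str
    label: str
    effect: EffectEstimate
    printed_verdict: str  # favourable | null | unfavourable
    printed_direction: str  # agree | disagree


@dataclass(frozen=True)
class FixtureBundle:
    cases: list[DiscordantCase]
    pairs: list[AssessmentPair]
    effects: list[EffectRow]

    def case(self, case_id: str) -> DiscordantCase:
        for c in self.cases:
            if c.case_id == case_id:
                return c
        raise KeyError(case_id)

    def effect_index(self) -> dict[tuple[str, str, str], EffectEstimate]:
        """Mapping ``(case_id, assessor, sr_id) -> EffectEstimate``."""
        return {(r.case_id, r.assessor, r.sr_id): r.effect for r in self.effects}


def _fixture_dir() -> Path:
    return Path(str(resources.files("jadad_select").joinpath("fixtures")))


def _parse_p(raw: str) -> Optional[float]:
    s = str(raw).strip()
    if not s or s.upper() in {"NR", "NAN"}:
        return None
    if s.startswith("<"):
        # a bound below any conventional significance level classifies
        # identically to the (unprinted) exact value
        return float(s[1:])
    return float(s)


def _split(field, n: int, fill: str = "") -> list[str]:
    vals = [v.strip() for v in str(field).split(";")] if str(field).strip() else []
    vals += [fill] * (n - len(vals))
    return vals[:n]


def _synthetic_roster(case_id: str, index: int) -> TrialSet:
    # Rosters are not tabulated; give each review a distinct two-trial roster
    # so the same-trials step answers "no", as observed on every case.
    return TrialSet(
        trial_ids=frozenset({f"trial-{index + 1}", f"trial-{index + 2}"})
    )


def load_fixture_tables(directory: Union[str, Path, None] = None) -> FixtureBundle:
    """Load the bundled replication corpus (or a directory with the same
    three CSV tables) into validated domain objects.

    Returns 21 cases, 21 assessment pairs, and 27 effect rows; any deviation
    from the tables' internal structure raises
    :class:`FixtureIntegrityError`.
    """
    fdir = Path(directory) if directory is not None else _fixture_dir()
    try:
        # keep_default_na: the verdict cell "null" is data, not a missing value
        t1 = pd.read_csv(fdir / "table1.csv", dtype=str, keep_default_na=False)
        t2 = pd.read_csv(fdir / "table2.csv", dtype=str, keep_default_na=False)
        t3 = pd.read_csv(fdir / "table3.csv", dtype=str, keep_default_na=False)
    except FileNotFoundError as exc:
        raise FixtureIntegrityError(f"missing fixture table: {exc}") from exc

    case_meta = {row.case_id: row for row in t1.itertuples()}
    if len(case_meta) != len(t1):
        raise FixtureIntegrityError("duplicate case ids in the case table")

    # --- assessments -------------------------------------------------------
    by_case: dict[str, dict[str, pd.Series]] = {}
    for _, row in t2.iterrows():
        if row["assessor"] not in ("authors", "replication"):
            raise FixtureIntegrityError(f"unknown assessor {row['assessor']!r}")
        if row["case_id"] not in case_meta:
            raise FixtureIntegrityError(f"assessment row for unknown case {row['case_id']!r}")
        slot = by_case.setdefault(row["case_id"], {})
        if row["assessor"] in slot:
            raise FixtureIntegrityError(
                f"duplicate {row['assessor']} row for case {row['case_id']!r}"
            )
        slot[row["assessor"]] = row

    cases: list[DiscordantCase] = []
    pairs: list[AssessmentPair] = []
    for case_id, meta in case_meta.items():
        slot = by_case.get(case_id, {})
        if set(slot) != {"authors", "replication"}:
            raise FixtureIntegrityError(f"case {case_id!r} lacks a row for each assessor")

        # collect the reviews named by either assessor, primary first
        reviews: dict[str, SRRecord] = {}
        choices: dict[str, tuple[str, ...]] = {}
        for assessor, row in slot.items():
            labels = [s.strip() for s in row["chosen"].split(";") if s.strip()]
            if not labels:
                raise FixtureIntegrityError(f"{case_id}/{assessor}: empty choice set")
            n = len(labels)
            levels = _split(row["quality_levels"], n)
            cochrane = _split(row["cochrane"], n, fill="no")
            robis = _split(row["robis"], n, fill="unknown")
            ids = []
            for label, level, coch, rob in zip(labels, levels, cochrane, robis):
                sr_id = normalize_trial_id(label)
                ids.append(sr_id)
                quality = []
                if row["tool"] and level:
                    quality = [QualityRating.from_label(row["tool"], level)]
                rec = SRRecord(
                    sr_id=sr_id,
                    label=label,
                    is_cochrane=coch == "yes",
                    pico=_case_pico(meta),
                    quality=quality,
                    robis_verdict=rob if rob in ("low_risk", "high_risk") else "unknown",
                )
                prev = reviews.get(sr_id)
                if prev is None or (not prev.quality and quality):
                    reviews[sr_id] = rec
            choices[assessor] = tuple(ids)

        n_reviews = int(meta.n_reviews)
        if len(reviews) > n_reviews:
            raise FixtureIntegrityError(
                f"case {case_id!r}: more chosen reviews than its printed review count"
            )
        for k in range(n_reviews - len(reviews)):
            sr_id = f"unlisted-{k + 1}"
            reviews[sr_id] = SRRecord(
                sr_id=sr_id,
                label=f"Unlisted review {k + 1}",
                pico=_case_pico(meta),
            )
        ordered = [
            rec.model_copy(update={"trials": _synthetic_roster(case_id, i)})
            for i, rec in enumerate(reviews.values())
        ]
        cases.append(
            DiscordantCase(
                case_id=case_id,
                question=_case_pico(meta),
                primary_outcome=meta.primary_outcome,
                primary_intervention=meta.primary_intervention,
                reviews=ordered,
                judged_same_criteria=meta.same_criteria_judged == "yes",
            )
        )

        repl = slot["replication"]
        minutes = str(repl["minutes"]).strip()
        pairs.append(
            AssessmentPair(
                case_id=case_id,
                original_choice=choices["authors"],
                original_final_step=_step(slot["authors"]["final_step"]),
                replication_choice=choices["replication"],
                replication_final_step=_step(repl["final_step"]),
                ease_rating=repl["ease_rating"] or None,
                minutes=float(minutes) if minutes else None,
                pilot=meta.pilot == "yes",
            )
        )

    # --- effect rows -------------------------------------------------------
    case_ids = {c.case_id: c for c in cases}
    effects: list[EffectRow] = []
    for _, row in t3.iterrows():
        case = case_ids.get(row["case_id"])
        if case is None:
            raise FixtureIntegrityError(f"effect row for unknown case {row['case_id']!r}")
        if row["measure"] not in _MEASURES:
            raise FixtureIntegrityError(f"unknown measure {row['measure']!r}")
        sr_id = normalize_trial_id(row["review_label"])
        if sr_id not in case.sr_ids():
            raise FixtureIntegrityError(
                f"effect row review {row['review_label']!r} not in case {case.case_id!r}"
            )
        try:
            effect = EffectEstimate(
                measure=row["measure"],
                point=float(row["point"]),
                ci_low=float(row["ci_low"]),
                ci_high=float(row["ci_high"]),
                p_value=_parse_p(row["p_value"]),
                benefit_direction=case_meta[case.case_id].benefit_direction,
            )
        except (ValueError, ValidationError) as exc:
            raise FixtureIntegrityError(
                f"invalid effect row for {row['case_id']}/{row['review_label']}: {exc}"
            ) from exc
        effects.append(
            EffectRow(
                case_id=case.case_id,
                assessor=row["assessor"],
                sr_id=sr_id,
                label=row["review_label"],
                effect=effect,
                printed_verdict=row["verdict"],
                printed_direction=row["direction"],
            )
        )
        # attach the estimate to the review record when not already present
        rec = case.review(sr_id)
        if rec.effect is None:
            rec.effect = effect

    _check_counts(cases, pairs, effects)
    return FixtureBundle(cases=cases, pairs=pairs, effects=effects)


def _case_pico(meta) -> PicoFrame:
    return PicoFrame(
        intervention=PicoElement(text=meta.primary_intervention),
        outcome=PicoElement(text=meta.primary_outcome),
    )


def _step(raw: str) -> str:
    s = str(raw).strip().upper()
    if s in ("", "NR"):
        return "not_reported"
    if s not in set("ABCDEFGHI"):
        raise FixtureIntegrityError(f"unknown final step {raw!r}")
    return s


def _check_counts(cases, pairs, effects) -> None:
    if len(cases) != 21 or len(pairs) != 21:
        raise FixtureIntegrityError(
            f"expected 21 cases and 21 assessment pairs, got {len(cases)}/{len(pairs)}"
        )
    if len(effects) != 27:
        raise FixtureIntegrityError(f"expected 27 effect rows, got {len(effects)}")
    keys = {(r.case_id, r.assessor, r.sr_id) for r in effects}
    if len(keys) != len(effects):
        raise FixtureIntegrityError("duplicate effect rows")
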