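"""Agreement, routing, and ease/time statistics over paired assessments.

All statistics are descriptive (counts, percentages, median/IQR); choice
agreement uses strict set equality of the chosen review sets — an assessment
that picks a superset of the other's choice counts as a disagreement.
Percentages are carried at full precision and rounded to whole numbers only
for display.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import asdict, dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np

from .classify import direction_agreement
from .errors import JadadSelectError
from .models import NOT_REPORTED, AssessmentPair, JadadTrace


def choice_agreement(pairs: Sequence[AssessmentPair]) -> tuple[int, int, float, float]:
    """Counts and percentages of pairs whose two choice sets are set-equal."""
    for p in pairs:
        if not p.original_choice or not p.replication_choice:
            raise JadadSelectError(f"pair {p.case_id!r} has an empty choice set")
    n_agree = sum(p.choices_equal() for p in pairs)
    n = len(pairs)
    pct = 100.0 * n_agree / n if n else float("nan")
    return n_agree, n - n_agree, pct, 100.0 - pct if n else float("nan")


def step_agreement(
    pairs: Sequence[AssessmentPair], restrict_to_disagree: bool = False
) -> tuple[int, int, int]:
    """Among the selected pairs, count (same step, different step, any step
    not reported)."""
    subset = [p for p in pairs if not restrict_to_disagree or not p.choices_equal()]
    same = diff = nr = 0
    for p in subset:
        a, b = p.original_final_step, p.replication_final_step
        if NOT_REPORTED in (a, b):
            nr += 1
        elif a == b:
            same += 1
        else:
            diff += 1
    return same, diff, nr


def routing_tally(
    traces: Iterable[Union[JadadTrace, str]]
) -> dict[str, int]:
    """Terminal-step counts over traces (or bare step labels)."""
    steps = [t.terminal_step if isinstance(t, JadadTrace) else t for t in traces]
    return dict(Counter(steps))


def direction_concordance(
    pairs: Sequence[AssessmentPair],
    effects: Mapping,
    alpha: float = 0.05,
) -> tuple[float, float, int]:
    """(overall agreement fraction, fraction among choice-disagreeing pairs,
    number of direction disagreements).

    Pairs with identical choice sets agree by construction; the rest are
    compared through the effect classifier on each assessment's primary
    chosen review.
    """
    n_agree = 0
    disagree_pairs = []
    for p in pairs:
        if p.choices_equal():
            n_agree += 1
        else:
            disagree_pairs.append(p)
    n_dir_agree_among = sum(
        direction_agreement(p, effects, alpha=alpha) for p in disagree_pairs
    )
    n_overall = n_agree + n_dir_agree_among
    overall = n_overall / len(pairs) if pairs else float("nan")
    among = n_dir_agree_among / len(disagree_pairs) if disagree_pairs else float("nan")
    return overall, among, len(disagree_pairs) - n_dir_agree_among


def ease_time_summary(
    pairs: Sequence[AssessmentPair], include_pilot_minutes: bool = False
) -> dict:
    """Ease-rating distribution and median/IQR of assessment minutes.

    Pairs without a rating are excluded from the distribution but counted;
    pilot assessments are excluded from the timing summary by default.
    """
    rated = [p for p in pairs if p.ease_rating is not None]
    dist = dict(Counter(p.ease_rating for p in rated))
    minutes = [
        p.minutes
        for p in pairs
        if p.minutes is not None and (include_pilot_minutes or not p.pilot)
    ]
    if minutes:
        median = float(np.median(minutes))
        if len(minutes) > 1:
            q1, q3 = (float(q) for q in np.percentile(minutes, [25, 75]))
            iqr: Optional[tuple[float, float]] = (q1, q3)
        else:
            iqr = None
    else:
        median, iqr = None, None
    return {
        "n_rated": len(rated),
        "n_unrated": len(pairs) - len(rated),
        "distribution": dist,
        "n_timed": len(minutes),
        "minutes_median": median,
        "minutes_iqr": iqr,
    }


@dataclass
class AgreementReport:
    """Aggregate replication report over a collection of assessment pairs."""

    n_pairs: int
    n_choice_agree: int
    n_choice_disagree: int
    pct_choice_agree: float
    pct_choice_disagree: float
    n_same_final_step_among_disagree: int
    n_diff_final_step_among_disagree: int
    n_step_not_reported: int
    n_direction_agree_overall: int
    pct_direction_agree_overall: float
    n_direction_agree_among_disagree: int
    n_direction_disagree: int
    step_tally_original: dict[str, int] = field(default_factory=dict)
    step_tally_replication: dict[str, int] = field(default_factory=dict)
    ease_distribution: dict = field(default_factory=dict)
    minutes_summary: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    def to_text(self) -> str:
        """Plain-text report, percentages rounded as displayed."""
        r = self
        lines = [
            f"{r.n_pairs} paired assessments",
            f"choice of review(s): {r.n_choice_agree} agreed "
            f"({round(r.pct_choice_agree)}%), {r.n_choice_disagree} disagreed "
            f"({round(r.pct_choice_disagree)}%)",
            f"final decision step among disagreements: "
            f"{r.n_same_final_step_among_disagree} same, "
            f"{r.n_diff_final_step_among_disagree} different",
            f"direction of effect: {r.n_direction_agree_overall}/{r.n_pairs} "
            f"agreed overall ({round(r.pct_direction_agree_overall)}%); "
            f"{r.n_direction_agree_among_disagree} of the "
            f"{r.n_choice_disagree} choice disagreements still agreed in "
            f"direction; {r.n_direction_disagree} pointed different ways",
            f"original final steps: {_fmt_tally(r.step_tally_original)}",
            f"replication final steps: {_fmt_tally(r.step_tally_replication)}",
            f"ease ratings: {_fmt_tally(r.ease_distribution.get('distribution', {}))} "
            f"over {r.ease_distribution.get('n_rated', 0)} rated assessments",
        ]
        ms = r.minutes_summary
        if ms.get("minutes_median") is not None:
            iqr = ms.get("minutes_iqr")
            iqr_txt = f", IQR {iqr[0]:g}-{iqr[1]:g}" if iqr else ""
            lines.append(
                f"minutes per assessment: median {ms['minutes_median']:g}{iqr_txt} "
                f"(n={ms['n_timed']})"
            )
        else:
            lines.append("minutes per assessment: not recorded")
        return "\n".join(lines)


def _fmt_tally(tally: Mapping) -> str:
    if not tally:
        return "none"
    return ", ".join(f"{k}: {v}" for k, v in sorted(tally.items()))


def build_report(
    pairs: Sequence[AssessmentPair],
    effects: Mapping,
    alpha: float = 0.05,
) -> AgreementReport:
    """Compute the full agreement report from paired assessments and their
    effect estimates."""
    n = len(pairs)
    n_agree, n_disagree, pct_agree, pct_disagree = choice_agreement(pairs)
    same, diff, _ = step_agreement(pairs, restrict_to_disagree=True)
    _, _, nr_all = step_agreement(pairs, restrict_to_disagree=False)
    overall, among, n_dir_disagree = direction_concordance(pairs, effects, alpha=alpha)
    n_dir_overall = round(overall * n)
    ease = ease_time_summary(pairs)
    return AgreementReport(
        n_pairs=n,
        n_choice_agree=n_agree,
        n_choice_disagree=n_disagree,
        pct_choice_agree=pct_agree,
        pct_choice_disagree=pct_disagree,
        n_same_final_step_among_disagree=same,
        n_diff_final_step_among_disagree=diff,
        n_step_not_reported=nr_all,
        n_direction_agree_overall=n_dir_overall,
        pct_direction_agree_overall=100.0 * overall,
        n_direction_agree_among_disagree=n_disagree - n_dir_disagree,
        n_direction_disagree=n_dir_disagree,
        step_tally_original=dict(
            Counter(p.original_final_step for p in pairs)
        ),
        step_tally_replication=dict(
            Counter(p.replication_final_step for p in pairs)
        ),
        ease_distribution={k: ease[k] for k in ("n_rated", "n_unrated", "distribution")},
        minutes_summary={k: ease[k] for k in ("n_timed", "minutes_median", "minutes_iqr")},
    )
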