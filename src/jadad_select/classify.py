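"""Direction-of-effect classification for pooled estimates.

A pooled effect is *favourable* when it is statistically significant and the
point estimate lies on the beneficial side of the measure's null value
(1 for RR/OR, 0 for MD/SMD), *unfavourable* when significant on the harmful
side, and *null* otherwise.  Significance is judged by the printed p-value
when one is available (p < alpha), else by strict exclusion of the null value
from the confidence interval.  The p-value takes precedence because printed
intervals are rounded: a bound rounded to the null (e.g. an upper CI limit of
-0.00) would otherwise misclassify a significant result.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping, Optional

from .errors import EffectClassificationError
from .models import AssessmentPair, EffectEstimate

Verdict = Literal["favourable", "null", "unfavourable"]


@dataclass(frozen=True)
class EffectVerdict:
    verdict: Verdict
    significance_source: Literal["p_value", "ci", "none"]

    def __str__(self) -> str:  # convenient in reports
        return self.verdict


def classify_effect(effect: EffectEstimate, alpha: float = 0.05) -> EffectVerdict:
    """Classify a pooled effect as favourable / null / unfavourable.

    Raises :class:`EffectClassificationError` when neither a p-value nor a
    complete CI is available, or when significance is claimed for a point
    estimate sitting exactly at the null value.
    """
    if effect.p_value is not None:
        significant = effect.p_value < alpha
        source = "p_value"
    elif effect.ci_low is not None and effect.ci_high is not None:
        significant = effect.ci_low > effect.null_value or effect.ci_high < effect.null_value
        source = "ci"
    else:
        raise EffectClassificationError(
            "cannot classify: neither p-value nor confidence interval present"
        )

    if not significant:
        return EffectVerdict("null", source)
    if effect.point == effect.null_value:
        raise EffectClassificationError(
            "inconsistent estimate: significant but the point estimate equals the null value"
        )
    beneficial = (
        effect.point < effect.null_value
        if effect.benefit_direction == "lower_better"
        else effect.point > effect.null_value
    )
    return EffectVerdict("favourable" if beneficial else "unfavourable", source)


EffectKey = tuple  # (case_id, assessor, sr_id)


def _lookup(
    effects: Mapping, case_id: str, assessor: str, sr_id: str
) -> Optional[EffectEstimate]:
    e = effects.get((case_id, assessor, sr_id))
    if e is None:
        e = effects.get((case_id, sr_id))
    return e


def direction_agreement(
    pair: AssessmentPair,
    effects: Mapping,
    alpha: float = 0.05,
) -> bool:
    """Do the two assessments' primary chosen reviews point the same way?

    ``effects`` maps ``(case_id, assessor, sr_id)`` — or ``(case_id, sr_id)``
    when an estimate is assessor-independent — to an
    :class:`~jadad_select.models.EffectEstimate`.  Identical primary reviews
    trivially agree; symmetric in the two assessments.
    """
    if pair.original_primary == pair.replication_primary:
        return True
    verdicts = []
    for assessor, sr_id in (
        ("authors", pair.original_primary),
        ("replication", pair.replication_primary),
    ):
        effect = _lookup(effects, pair.case_id, assessor, sr_id)
        if effect is None:
            raise EffectClassificationError(
                f"no effect estimate for the {assessor} assessment of case "
                f"{pair.case_id!r} (review {sr_id!r})"
            )
        verdicts.append(classify_effect(effect, alpha=alpha).verdict)
    return verdicts[0] == verdicts[1]
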