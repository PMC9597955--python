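import pytest

from jadad_select import (
    DiscordantCase,
    EffectEstimate,
    PicoElement,
    PicoFrame,
    QualityRating,
    SearchProfile,
    SRRecord,
    SynthesisProfile,
    TrialSet,
    load_fixture_tables,
)


def make_pico(int_terms=("drug",), out_terms=("pain",)):
    return PicoFrame(
        intervention=PicoElement(text="intervention", terms=list(int_terms)),
        outcome=PicoElement(text="outcome", terms=list(out_terms)),
    )


def make_review(sr_id, trials=("smith-2001", "jones-2002"), **kwargs):
    defaults = dict(
        label=sr_id.replace("-", " ").title(),
        pico=make_pico(),
        trials=TrialSet(trial_ids=frozenset(trials)),
    )
    defaults.update(kwargs)
    return SRRecord(sr_id=sr_id, **defaults)


def make_case(reviews, case_id="case-1", **kwargs):
    return DiscordantCase(
        case_id=case_id,
        question=make_pico(),
        primary_outcome="outcome",
        primary_intervention="intervention",
        reviews=reviews,
        **kwargs,
    )


def amstar(level, rct="unknown"):
    return QualityRating.from_label("AMSTAR", level, rct_quality_assessed=rct)


def effect(point, lo, hi, p=None, measure="MD", direction="lower_better"):
    return EffectEstimate(
        measure=measure, point=point, ci_low=lo, ci_high=hi,
        p_value=p, benefit_direction=direction,
    )


@pytest.fixture(scope="session")
def bundle():
    """The bundled 21-case replication corpus."""
    return load_fixture_tables()


@pytest.fixture()
def two_reviews():
    return [make_review("sr-a"), make_review("sr-b", trials=("smith-2001", "lee-2003"))]


__all__ = [
    "make_pico",
    "make_review",
    "make_case",
    "amstar",
    "effect",
    "SearchProfile",
    "SynthesisProfile",
]
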