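"""Step semantics, routing, determinism and tie behaviour of the engine."""

from datetime import date

import pytest

from jadad_select import (
    IncomparableQualityError,
    QualityRating,
    Ruleset,
    StepError,
    run_jadad,
    step_choose_highest_quality,
    step_compare_synthesis,
    step_publication_hierarchy,
    step_question_match,
    step_same_criteria,
    step_same_quality,
    step_same_trials,
    step_search_rigour,
)
from jadad_select.engine import trace_to_json
from pydantic import ValidationError

from conftest import SearchProfile, SynthesisProfile, amstar, make_case, make_pico, make_review

# ---------------------------------------------------------------------------
# independent brute-force comparator for the lexicographic selections

_YNU = {"yes": 2, "no": 1, "unknown": 0}


def h_tuple(sr, order):
    vals = {
        "n_databases": len(sr.search.databases),
        "grey_literature": _YNU[sr.search.grey_literature],
        "duplicate_independent_screening": _YNU[sr.search.duplicate_independent_screening],
        "last_search_date": (0, 0)
        if sr.search.last_search_date is None
        else (1, sr.search.last_search_date.toordinal()),
    }
    return tuple(vals[c] for c in order)


def i_tuple(sr, order):
    vals = {
        "publication_status_scope": {"includes_unpublished": 2, "published_only": 1, "unknown": 0}[
            sr.search.publication_status_scope
        ],
        "rct_quality_assessed": max(
            (_YNU[q.rct_quality_assessed] for q in sr.quality), default=0
        ),
        "language_restriction": {"none": 2, "restricted": 1, "unknown": 0}[
            sr.search.language_restriction
        ],
        "ipd_analysis": 1 if sr.search.ipd_analysis == "yes" else 0,
    }
    return tuple(vals[c] for c in order)


def e_tuple(sr):
    if sr.synthesis is None:
        return (0, 0, 0)
    return (
        {"duplicate": 2, "single": 1, "unknown": 0}[sr.synthesis.extraction],
        _YNU[sr.synthesis.heterogeneity_assessed],
        _YNU[sr.synthesis.synthesis_appropriate],
    )


def brute_force(candidates, key):
    scores = {sr.sr_id: key(sr) for sr in candidates}
    best = max(scores.values())
    return {i for i, s in scores.items() if s == best}


# ---------------------------------------------------------------------------
# steps A/B


def test_all_on_question_proceeds(two_reviews):
    case = make_case(two_reviews)
    candidates, closest = step_question_match(case)
    assert len(candidates) == 2 and closest is None


def test_off_question_review_forces_step_b(two_reviews):
    case = make_case(two_reviews, judged_same_question={"sr-a": False})
    candidates, closest = step_question_match(case)
    assert closest is not None and closest.sr_id == "sr-b"
    trace = run_jadad(case)
    assert trace.terminal_step == "B" and trace.chosen == ["sr-b"]


def test_filtering_keeps_remaining_candidates():
    reviews = [make_review(f"sr-{c}", trials=(f"t-{c}",)) for c in "abc"]
    case = make_case(reviews, judged_same_question={"sr-c": False},
                     judged_same_criteria=True)
    candidates, closest = step_question_match(case)
    assert [r.sr_id for r in candidates] == ["sr-a", "sr-b"] and closest is None


# ---------------------------------------------------------------------------
# step C


def test_same_trials_is_set_equality():
    a = make_review("sr-a", trials=("x-1", "y-2"))
    b = make_review("sr-b", trials=("y-2", "x-1"))
    c = make_review("sr-c", trials=("x-1", "z-3"))
    assert step_same_trials([a, b]) is True
    assert step_same_trials([a, c]) is False


def test_empty_roster_is_a_step_error():
    a = make_review("sr-a", trials=())
    b = make_review("sr-b")
    with pytest.raises(StepError) as exc:
        step_same_trials([a, b])
    assert exc.value.step == "C"


# ---------------------------------------------------------------------------
# steps D/E/F


def test_same_quality_within_tool():
    a = make_review("sr-a", quality=[amstar("High")])
    b = make_review("sr-b", quality=[amstar("High")])
    c = make_review("sr-c", quality=[amstar("Moderate")])
    assert step_same_quality([a, b]) is True
    assert step_same_quality([a, c]) is False


def test_cross_tool_quality_is_incomparable():
    a = make_review("sr-a", quality=[amstar("High")])
    b = make_review("sr-b", quality=[QualityRating.from_label("ROBIS", "Low risk")])
    with pytest.raises(IncomparableQualityError):
        step_same_quality([a, b])
    with pytest.raises(IncomparableQualityError):
        step_choose_highest_quality([a, b])


def test_highest_quality_selection_and_ties():
    a = make_review("sr-a", quality=[amstar("Highest")])
    b = make_review("sr-b", quality=[amstar("High")])
    c = make_review("sr-c", quality=[amstar("High")])
    assert [sr.sr_id for sr in step_choose_highest_quality([a, b, c])] == ["sr-a"]
    both = step_choose_highest_quality([b, c])
    assert {sr.sr_id for sr in both} == {"sr-b", "sr-c"}


def test_synthesis_comparison_prefers_duplicate_extraction():
    a = make_review("sr-a", synthesis=SynthesisProfile(extraction="duplicate"))
    b = make_review("sr-b", synthesis=SynthesisProfile(extraction="single"))
    assert [sr.sr_id for sr in step_compare_synthesis([a, b])] == ["sr-a"]
    tie = step_compare_synthesis([a, a.model_copy(update={"sr_id": "sr-c"})])
    assert {sr.sr_id for sr in tie} == {"sr-a", "sr-c"}


# ---------------------------------------------------------------------------
# step G


def test_criteria_judgment_passthrough(two_reviews):
    assert step_same_criteria(two_reviews, Ruleset(), judged_same_criteria=True) is True
    assert step_same_criteria(two_reviews, Ruleset(), judged_same_criteria=False) is False


def test_criteria_similarity_identical_terms(two_reviews):
    assert step_same_criteria(two_reviews, Ruleset()) is True  # Jaccard 1.0


def test_criteria_similarity_disjoint_outcomes():
    # P and C empty on both sides (overlap 1 each), I identical (1),
    # O disjoint (0): mean Jaccard = 3/4 < 0.8
    a = make_review("sr-a", pico=make_pico(out_terms=("pain",)))
    b = make_review("sr-b", pico=make_pico(out_terms=("function",)))
    assert step_same_criteria([a, b], Ruleset(criteria_similarity_threshold=0.8)) is False
    assert step_same_criteria([a, b], Ruleset(criteria_similarity_threshold=0.75)) is True


# ---------------------------------------------------------------------------
# steps H/I


def test_search_rigour_tiers():
    many = make_review("sr-a", search=SearchProfile(databases=[f"d{i}" for i in range(8)]))
    few = make_review("sr-b", search=SearchProfile(databases=[f"d{i}" for i in range(4)]))
    assert [sr.sr_id for sr in step_search_rigour([many, few], Ruleset())] == ["sr-a"]

    grey = make_review("sr-c", search=SearchProfile(databases=["d1"], grey_literature="yes"))
    no_grey = make_review("sr-d", search=SearchProfile(databases=["d1"], grey_literature="no"))
    assert [sr.sr_id for sr in step_search_rigour([grey, no_grey], Ruleset())] == ["sr-c"]


def test_publication_hierarchy_tiers():
    unpub = make_review("sr-a", search=SearchProfile(publication_status_scope="includes_unpublished"))
    pub = make_review("sr-b", search=SearchProfile(publication_status_scope="published_only"))
    assert [sr.sr_id for sr in step_publication_hierarchy([unpub, pub], Ruleset())] == ["sr-a"]

    tied = [make_review("sr-a"), make_review("sr-b")]
    assert {sr.sr_id for sr in step_publication_hierarchy(tied, Ruleset())} == {"sr-a", "sr-b"}


def test_ipd_never_discriminates_when_absent():
    # reviews differing only in earlier unknowns but both without IPD
    a = make_review("sr-a", search=SearchProfile(ipd_analysis="no"))
    b = make_review("sr-b", search=SearchProfile(ipd_analysis="no"))
    chosen = step_publication_hierarchy([a, b], Ruleset())
    assert {sr.sr_id for sr in chosen} == {"sr-a", "sr-b"}


def test_ruleset_orders_must_be_permutations():
    with pytest.raises(ValidationError):
        Ruleset(step_h_order=("n_databases", "grey_literature"))
    with pytest.raises(ValidationError):
        Ruleset(step_i_order=("ipd_analysis",) * 4)


# ---------------------------------------------------------------------------
# full runs


def test_routing_same_criteria_to_h(two_reviews):
    case = make_case(two_reviews, judged_same_criteria=True)
    assert run_jadad(case).terminal_step == "H"


def test_routing_different_criteria_to_i(two_reviews):
    case = make_case(two_reviews, judged_same_criteria=False)
    assert run_jadad(case).terminal_step == "I"


def test_routing_same_trials_unequal_quality_to_f():
    a = make_review("sr-a", quality=[amstar("Highest")])
    b = make_review("sr-b", quality=[amstar("High")])
    trace = run_jadad(make_case([a, b]))
    assert [s for s, _ in trace.steps] == ["A", "C", "D", "F"]
    assert trace.chosen == ["sr-a"]


def test_identical_records_tie_everywhere_terminal_e():
    a = make_review("sr-a", quality=[amstar("High")],
                    synthesis=SynthesisProfile(extraction="duplicate"))
    b = a.model_copy(update={"sr_id": "sr-b"})
    trace = run_jadad(make_case([a, b]))
    assert trace.terminal_step == "E"
    assert trace.chosen == ["sr-a", "sr-b"]


def test_determinism_byte_identical_traces(two_reviews):
    case = make_case(two_reviews, judged_same_criteria=True)
    t1, t2 = run_jadad(case, Ruleset()), run_jadad(case, Ruleset())
    assert trace_to_json(t1) == trace_to_json(t2)


def test_permutation_equivariance():
    profiles = [
        SearchProfile(databases=["d1", "d2"], grey_literature="yes"),
        SearchProfile(databases=["d1", "d2"], grey_literature="yes"),
        SearchProfile(databases=["d1"], grey_literature="no"),
    ]
    reviews = [
        make_review(f"sr-{c}", trials=(f"t-{c}",), search=p)
        for c, p in zip("abc", profiles)
    ]
    case = make_case(reviews, judged_same_criteria=True)
    chosen = set(run_jadad(case).chosen)
    assert chosen == {"sr-a", "sr-b"}  # tie between the two rigorous reviews

    # reorder reviews: the chosen set is unchanged (no positional bias)
    reordered = make_case(list(reversed(reviews)), judged_same_criteria=True)
    assert set(run_jadad(reordered).chosen) == chosen

    # relabel reviews: the chosen set follows the relabeling
    mapping = {"sr-a": "sr-z", "sr-b": "sr-y", "sr-c": "sr-x"}
    relabeled = make_case(
        [r.model_copy(update={"sr_id": mapping[r.sr_id]}) for r in reviews],
        judged_same_criteria=True,
    )
    assert set(run_jadad(relabeled).chosen) == {mapping[i] for i in chosen}


def test_step_errors_name_the_failing_step(two_reviews):
    empty = [r.model_copy(update={"trials": type(r.trials)()}) for r in two_reviews]
    case = make_case(empty, judged_same_criteria=True)
    with pytest.raises(StepError) as exc:
        run_jadad(case)
    assert exc.value.step == "C"


def test_last_search_date_breaks_final_ties():
    recent = make_review("sr-a", search=SearchProfile(
        databases=["d1"], grey_literature="yes",
        duplicate_independent_screening="yes", last_search_date=date(2020, 5, 1)))
    older = make_review("sr-b", search=SearchProfile(
        databases=["d1"], grey_literature="yes",
        duplicate_independent_screening="yes", last_search_date=date(2015, 5, 1)))
    unknown = make_review("sr-c", search=SearchProfile(
        databases=["d1"], grey_literature="yes",
        duplicate_independent_screening="yes"))
    chosen = step_search_rigour([unknown, older, recent], Ruleset())
    assert [sr.sr_id for sr in chosen] == ["sr-a"]
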