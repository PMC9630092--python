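"""Matching semantics: reference-comparison verdicts, assay confirmation
rules and the partition invariant."""

import pytest

from fusionbench.core import (
    AssayModality,
    AssayOutcome,
    Caller,
    EventClass,
    FusionEvent,
    OrthogonalAssay,
    Panel,
    QCStatus,
    SampleRecord,
    Specimen,
)
from fusionbench.matching import (
    AssayCategory,
    MatchCategory,
    match_cohort_to_reference,
    match_events_to_assays,
    match_to_assays,
    match_to_reference,
)
from fusionbench.synthetic import generate_cohort, lung_config


def _sample(sid="S1", qc=QCStatus.PASS):
    return SampleRecord(sid, "P1", Panel.SARCOMA, Specimen.CNB, qc, 500000)


def _fusion(partners, caller=Caller.ARR, sid="S1"):
    return FusionEvent(sid, caller, tuple(partners))


class TestReferenceMatching:
    def test_confirmed_on_shared_pair(self):
        v = match_to_reference(
            [_fusion(["ETV6", "NTRK3"])], [_fusion(["NTRK3", "ETV6"], Caller.REF)], _sample()
        )
        assert v.category is MatchCategory.CONFIRMED
        assert v.matched_key.key == "ETV6--NTRK3"

    def test_different_when_no_pair_matches(self):
        v = match_to_reference(
            [_fusion(["SLC34A2", "ROS1"])], [_fusion(["EWSR1", "TFCP2"], Caller.REF)], _sample()
        )
        assert v.category is MatchCategory.DIFFERENT

    def test_missed_on_empty_subject(self):
        v = match_to_reference(
            [], [_fusion(["EWSR1", "FLI1"], Caller.REF)], _sample(), subject_caller=Caller.SFU
        )
        assert v.category is MatchCategory.MISSED
        assert v.subject_caller is Caller.SFU

    def test_additional_and_negative_concordant_on_reference_negative(self):
        assert (
            match_to_reference([_fusion(["A", "B"])], [], _sample()).category
            is MatchCategory.ADDITIONAL
        )
        assert (
            match_to_reference([], [], _sample(), subject_caller=Caller.ARR).category
            is MatchCategory.NEGATIVE_CONCORDANT
        )

    def test_complex_subject_call_contains_reference_pair(self):
        subject = _fusion(["EWSR1", "X1", "FLI1"])
        v = match_to_reference([subject], [_fusion(["EWSR1", "FLI1"], Caller.REF)], _sample())
        assert v.category is MatchCategory.CONFIRMED

    def test_not_evaluable_sample_screens_for_additional_calls(self):
        v = match_to_reference(
            [_fusion(["RREB1", "MKL2"])], [], _sample(qc=QCStatus.NOT_EVALUABLE)
        )
        assert v.category is MatchCategory.ADDITIONAL
        assert not v.qc_pass


class TestAssayMatching:
    def test_fusion_probe_confirms_exact_pair(self):
        event = _fusion(["ETV6", "NTRK3"], Caller.REF)
        assay = OrthogonalAssay(
            "S1", AssayModality.FISH_FUSION, ("ETV6", "NTRK3"), AssayOutcome.FUSION_CONFIRMED
        )
        assert match_to_assays(event, [assay]).category is AssayCategory.CONFIRMED

    def test_breakapart_on_either_partner_confirms(self):
        event = _fusion(["EWSR1", "PATZ1"], Caller.REF)
        assay = OrthogonalAssay(
            "S1", AssayModality.FISH_BREAKAPART, ("EWSR1",), AssayOutcome.TRANSLOCATED
        )
        assert match_to_assays(event, [assay]).category is AssayCategory.CONFIRMED

    def test_negative_breakapart_contradicts(self):
        event = _fusion(["SS18", "SSX1"], Caller.REF)
        assay = OrthogonalAssay(
            "S1", AssayModality.FISH_BREAKAPART, ("SS18",), AssayOutcome.NEGATIVE
        )
        assert match_to_assays(event, [assay]).category is AssayCategory.CONTRADICTED

    def test_intragenic_rearrangement_is_non_confirming(self):
        event = _fusion(["SS18", "SSX4"], Caller.REF)
        assay = OrthogonalAssay(
            "S1", AssayModality.FISH_BREAKAPART, ("SS18",), AssayOutcome.INTRAGENIC_REARRANGEMENT
        )
        assert match_to_assays(event, [assay]).category is AssayCategory.CONTRADICTED

    def test_not_assessable_is_uninformative(self):
        event = _fusion(["NAB2", "STAT6"], Caller.REF)
        assay = OrthogonalAssay(
            "S1", AssayModality.FISH_BREAKAPART, ("NAB2",), AssayOutcome.NOT_ASSESSABLE
        )
        assert match_to_assays(event, [assay]).category is AssayCategory.UNINFORMATIVE

    def test_unbalanced_pattern_reported(self):
        event = _fusion(["SLC34A2", "ROS1"], Caller.REF)
        assay = OrthogonalAssay(
            "S1", AssayModality.FISH_BREAKAPART, ("ROS1",), AssayOutcome.UNBALANCED
        )
        assert match_to_assays(event, [assay]).category is AssayCategory.UNBALANCED_PATTERN

    def test_ihc_alone_is_uninformative(self):
        event = _fusion(["ETV6", "NTRK3"], Caller.REF)
        assay = OrthogonalAssay("S1", AssayModality.IHC, ("NTRK3",), AssayOutcome.POSITIVE_STAIN)
        verdict = match_to_assays(event, [assay])
        assert verdict.category is AssayCategory.UNINFORMATIVE
        assert "IHC" in verdict.evidence


def test_sarcoma_fixture_fish_verdicts(sarcoma_cohort):
    """FISH confirms 7 of the 14 reference fusion calls and contradicts 3;
    FISH was attempted for 11 of the 14 fusion-positive samples."""
    verdicts = match_events_to_assays(sarcoma_cohort, Caller.REF)
    assert len(verdicts) == 14
    by_cat = {c: sum(1 for v in verdicts if v.category is c) for c in AssayCategory}
    assert by_cat[AssayCategory.CONFIRMED] == 7
    assert by_cat[AssayCategory.CONTRADICTED] == 3
    positive = {v.sample_id for v in verdicts}
    attempted = {
        a.sample_id
        for a in sarcoma_cohort.assays
        if a.sample_id in positive and a.performed
    }
    assert len(attempted) == 11


@pytest.mark.parametrize("seed", [0, 7, 23])
def test_verdict_partition_on_synthetic_cohorts(seed):
    """Every sample in scope receives exactly one verdict; positive samples
    land in {confirmed,different,missed}, negative ones in
    {additional,negative_concordant}."""
    cohort, _ = generate_cohort(lung_config(n_samples=60, seed=seed))
    skipping_only = {
        s.sample_id
        for s in cohort.samples
        if cohort.events_for(s.sample_id, Caller.REF)
        and all(
            e.event_class is not EventClass.FUSION
            for e in cohort.events_for(s.sample_id, Caller.REF)
        )
    }
    for caller in (Caller.ARR, Caller.SFU):
        verdicts = match_cohort_to_reference(cohort, caller)
        assert len(verdicts) == len(cohort.samples) - len(skipping_only)
        assert len({v.sample_id for v in verdicts}) == len(verdicts)
        for v in verdicts:
            if v.reference_positive:
                assert v.category in (
                    MatchCategory.CONFIRMED, MatchCategory.DIFFERENT, MatchCategory.MISSED
                )
            else:
                assert v.category in (
                    MatchCategory.ADDITIONAL, MatchCategory.NEGATIVE_CONCORDANT
                )


@pytest.mark.parametrize("seed", [1, 11])
def test_policy_monotonicity(seed):
    """Relaxing ordered matching to unordered never turns a confirmed verdict
    into different/missed."""
    cohort, _ = generate_cohort(lung_config(n_samples=50, seed=seed))
    for caller in (Caller.ARR, Caller.SFU):
        ordered = {v.sample_id: v.category for v in match_cohort_to_reference(cohort, caller, "ordered")}
        unordered = {v.sample_id: v.category for v in match_cohort_to_reference(cohort, caller, "unordered")}
        for sid, cat in ordered.items():
            if cat is MatchCategory.CONFIRMED:
                assert unordered[sid] is MatchCategory.CONFIRMED
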