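"""Metric aggregation: sensitivity/negative-concordance fractions, the two
PPV/NPV constructions, Venn partitions and the depth rank test."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fusionbench.concordance import (
    Fraction,
    PPVConstruction,
    detection_vs_reads,
    negative_concordance,
    ppv_npv,
    sensitivity_vs_reference,
    venn_partition,
)
from fusionbench.core import Caller, UndefinedMetricError, UndefinedTestError
from fusionbench.matching import MatchCategory, MatchVerdict
from fusionbench.core import make_pair_key


def _verdict(category, sid, n_events=1, positive=None, qc=True):
    positive = (
        positive
        if positive is not None
        else category in (MatchCategory.CONFIRMED, MatchCategory.DIFFERENT, MatchCategory.MISSED)
    )
    key = make_pair_key(["A", "B"]) if category is MatchCategory.CONFIRMED else None
    return MatchVerdict(
        sid, Caller.ARR, category, matched_key=key,
        n_subject_events=n_events if category in (MatchCategory.CONFIRMED, MatchCategory.DIFFERENT, MatchCategory.ADDITIONAL) else 0,
        reference_positive=positive, qc_pass=qc,
    )


def _verdict_set():
    # 3 confirmed, 1 additional, 2 negative-concordant, 1 missed
    return [
        _verdict(MatchCategory.CONFIRMED, "s1"),
        _verdict(MatchCategory.CONFIRMED, "s2"),
        _verdict(MatchCategory.CONFIRMED, "s3"),
        _verdict(MatchCategory.ADDITIONAL, "s4"),
        _verdict(MatchCategory.NEGATIVE_CONCORDANT, "s5"),
        _verdict(MatchCategory.NEGATIVE_CONCORDANT, "s6"),
        _verdict(MatchCategory.MISSED, "s7"),
    ]


def test_ppv_npv_event_level_hand_counted():
    ppv, npv = ppv_npv(_verdict_set(), PPVConstruction.EVENT_LEVEL)
    assert (ppv.numerator, ppv.denominator) == (3, 4)
    assert (npv.numerator, npv.denominator) == (2, 3)
    assert "event_level" in ppv.label and "event_level" in npv.label


def test_ppv_constructions_differ_on_multi_event_samples():
    verdicts = _verdict_set() + [_verdict(MatchCategory.ADDITIONAL, "s8", n_events=3)]
    ppv_event, _ = ppv_npv(verdicts, PPVConstruction.EVENT_LEVEL)
    ppv_sample, _ = ppv_npv(verdicts, PPVConstruction.SAMPLE_LEVEL)
    assert ppv_event.denominator == 3 + 1 + 3
    assert ppv_sample.denominator == 3 + 2


def test_perfect_caller_metrics():
    verdicts = [
        _verdict(MatchCategory.CONFIRMED, "s1"),
        _verdict(MatchCategory.NEGATIVE_CONCORDANT, "s2"),
    ]
    assert sensitivity_vs_reference(verdicts).value == 1.0
    assert negative_concordance(verdicts).value == 1.0
    ppv, npv = ppv_npv(verdicts)
    assert ppv.value == npv.value == 1.0


def test_sensitivity_partition_identity():
    """confirmed + different + missed fractions sum to 1 over positives."""
    verdicts = _verdict_set() + [_verdict(MatchCategory.DIFFERENT, "s9")]
    sens = sensitivity_vs_reference(verdicts)
    positives = [v for v in verdicts if v.reference_positive]
    others = sum(
        1 for v in positives if v.category in (MatchCategory.DIFFERENT, MatchCategory.MISSED)
    )
    assert sens.numerator + others == sens.denominator


def test_undefined_metrics_raise():
    with pytest.raises(UndefinedMetricError):
        sensitivity_vs_reference([_verdict(MatchCategory.NEGATIVE_CONCORDANT, "s1")])
    with pytest.raises(UndefinedMetricError):
        negative_concordance([_verdict(MatchCategory.CONFIRMED, "s1")])
    with pytest.raises(UndefinedMetricError):
        Fraction(0, 0, "x")


def test_negative_concordance_excludes_not_evaluable_samples():
    verdicts = [
        _verdict(MatchCategory.NEGATIVE_CONCORDANT, "s1"),
        _verdict(MatchCategory.NEGATIVE_CONCORDANT, "s2", qc=False),
        _verdict(MatchCategory.ADDITIONAL, "s3"),
    ]
    frac = negative_concordance(verdicts)
    assert (frac.numerator, frac.denominator) == (1, 2)


def test_venn_examples():
    same = {("s1", "k1"), ("s2", "k2")}
    assert venn_partition({"A": same, "B": set(same)}) == {
        ("A",): 0, ("B",): 0, ("A", "B"): 2
    }
    disjoint = venn_partition({"A": {("s1", "k1")}, "B": {("s2", "k2")}})
    assert disjoint[("A", "B")] == 0 and disjoint[("A",)] == disjoint[("B",)] == 1


@given(
    st.lists(st.tuples(st.sampled_from("stuvw"), st.sampled_from("klmno")), max_size=20),
    st.lists(st.tuples(st.sampled_from("stuvw"), st.sampled_from("klmno")), max_size=20),
    st.lists(st.tuples(st.sampled_from("stuvw"), st.sampled_from("klmno")), max_size=20),
)
@settings(max_examples=100, derandomize=True)
def test_venn_regions_sum_to_union(a, b, c):
    sets = {"A": set(a), "B": set(b), "C": set(c)}
    regions = venn_partition(sets)
    assert sum(regions.values()) == len(set(a) | set(b) | set(c))
    assert all(v >= 0 for v in regions.values())


def test_rank_sum_exact_enumeration():
    p, method = detection_vs_reads([1, 2, 3], [4, 5, 6], alternative="less")
    assert method == "exact"
    assert p == pytest.approx(1 / 20)


def test_rank_sum_identical_groups():
    p, _ = detection_vs_reads([5, 6, 7], [5, 6, 7], alternative="two-sided")
    assert p == pytest.approx(1.0)


def test_rank_sum_requires_two_groups():
    with pytest.raises(UndefinedTestError):
        detection_vs_reads([], [1, 2])


def test_rank_sum_null_uniformity():
    """Under exchangeability the p-value is approximately uniform."""
    from scipy import stats

    rng = np.random.default_rng(42)
    pvals = []
    for _ in range(500):
        pooled = rng.normal(size=60)
        p, _ = detection_vs_reads(pooled[:30], pooled[30:])
        pvals.append(p)
    assert stats.kstest(pvals, "uniform").pvalue > 0.01
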