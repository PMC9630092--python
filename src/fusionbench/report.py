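"""One-call summaries of a cohort: accuracy metrics, Venn partitions,
orthogonal-assay tallies and the depth rank test, in machine-readable form.
"""

from __future__ import annotations

from typing import Optional

from .concordance import (
    PPVConstruction,
    build_report,
    detection_vs_reads,
    negative_concordance,
    ppv_npv,
    sensitivity_vs_reference,
    venn_partition,
)
from .core import (
    AssayModality,
    AssayOutcome,
    Caller,
    Cohort,
    EventClass,
    Panel,
    QCStatus,
)
from .io import load_fixture_cohort
from .matching import (
    AssayCategory,
    MatchCategory,
    match_cohort_to_reference,
    match_events_to_assays,
)

_FISH_MODALITIES = (AssayModality.FISH_BREAKAPART, AssayModality.FISH_FUSION)


def reference_positive_samples(cohort: Cohort) -> list[str]:
    """Samples with at least one retained reference fusion-class call."""
    return sorted(
        {
            e.sample_id
            for e in cohort.events
            if e.caller is Caller.REF and e.event_class is EventClass.FUSION
        }
    )


def clean_negative_fish_count(cohort: Cohort) -> int:
    """Reference-fusion-negative samples with >=1 performed FISH assay and no
    non-negative informative FISH outcome."""
    positive = set(reference_positive_samples(cohort))
    count = 0
    for sample in cohort.samples:
        if sample.sample_id in positive:
            continue
        fish = [
            a
            for a in cohort.assays_for(sample.sample_id)
            if a.modality in _FISH_MODALITIES and a.performed
        ]
        if not fish:
            continue
        if all(not a.informative or a.outcome is AssayOutcome.NEGATIVE for a in fish):
            count += 1
    return count


def _caller_event_tally(cohort: Cohort, caller: Caller) -> dict:
    fusions = [
        e
        for e in cohort.events
        if e.caller is caller and e.event_class is EventClass.FUSION
    ]
    return {"fusions": len(fusions), "samples": len({e.sample_id for e in fusions})}


def _callsets(cohort: Cohort, policy: str = "unordered") -> dict:
    sets: dict[str, set] = {c.value: set() for c in Caller}
    for e in cohort.events:
        if e.event_class is EventClass.FUSION:
            sets[e.caller.value].add((e.sample_id, e.pair_key(policy).key))
    return sets


def cohort_report(
    cohort: Cohort,
    panel: Panel,
    construction: PPVConstruction = PPVConstruction.EVENT_LEVEL,
    policy: str = "unordered",
) -> dict:
    """Full metric summary of one panel cohort against the reference caller."""
    cohort = cohort.subset_panel(panel)
    positive = reference_positive_samples(cohort)
    n_negative = sum(
        1
        for s in cohort.samples
        if s.sample_id not in positive and s.qc_status is QCStatus.PASS
        # skipping-only samples are positive for the assay but outside the
        # fusion comparison; they are not negatives either
        and not cohort.events_for(s.sample_id, Caller.REF)
    )
    n_skip_events = sum(
        1
        for e in cohort.events
        if e.caller is Caller.REF and e.event_class is EventClass.EXON_SKIPPING
    )

    out: dict = {
        "panel": panel.value,
        "n_samples": len(cohort.samples),
        "n_not_evaluable": sum(
            1 for s in cohort.samples if s.qc_status is QCStatus.NOT_EVALUABLE
        ),
        "reference_positive_samples": len(positive),
        "reference_negative_samples": n_negative,
        "exon_skipping_events": n_skip_events,
        "callers": {},
    }

    assay_verdicts = match_events_to_assays(cohort, Caller.REF, policy)
    out["fish"] = {
        "reference_calls_assessed": len(assay_verdicts),
        "confirmed": sum(1 for v in assay_verdicts if v.category is AssayCategory.CONFIRMED),
        "contradicted": sum(1 for v in assay_verdicts if v.category is AssayCategory.CONTRADICTED),
        "uninformative": sum(1 for v in assay_verdicts if v.category is AssayCategory.UNINFORMATIVE),
        "clean_negative_samples": clean_negative_fish_count(cohort),
    }

    callsets = _callsets(cohort, policy)
    for caller in (Caller.ARR, Caller.SFU):
        verdicts = match_cohort_to_reference(cohort, caller, policy)
        report = build_report(verdicts, caller, panel, construction)
        entry = report.to_dict()
        entry["tally"] = _caller_event_tally(cohort, caller)
        entry["categories"] = {
            cat.value: sum(1 for v in verdicts if v.category is cat) for cat in MatchCategory
        }
        out["callers"][caller.value] = entry

    out["venn"] = {
        "+".join(k): v
        for k, v in venn_partition(
            {name: callsets[name] for name in ("REF", "ARR", "SFU")}
        ).items()
    }

    pos_reads = [cohort.sample(sid).total_reads for sid in positive]
    neg_reads = [
        s.total_reads
        for s in cohort.samples
        if s.sample_id not in positive and s.qc_status is QCStatus.PASS
    ]
    if pos_reads and neg_reads:
        p, method = detection_vs_reads(pos_reads, neg_reads)
        out["detection_vs_reads"] = {"p_value": p, "method": method}
    return out


def fixture_report(fixture_dir, construction=PPVConstruction.EVENT_LEVEL) -> dict:
    """Metric summary of both packaged panel fixtures."""
    out = {}
    for panel in (Panel.SARCOMA, Panel.LUNG):
        cohort = load_fixture_cohort(fixture_dir, panel)
        out[panel.value] = cohort_report(cohort, panel, construction)
    return out
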