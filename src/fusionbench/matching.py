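"""Categorical matching of caller calls against the reference caller and
against orthogonal assays (break-apart FISH, fusion-probe FISH, RT-PCR, IHC).

Reference comparison yields exactly one verdict per (sample, subject caller):
on reference-fusion-positive samples one of ``confirmed``/``different``/
``missed``; on reference-negative (or not-evaluable) samples one of
``additional``/``negative_concordant``.  Exon-skipping reference events are
outside the comparison because the compared callers cannot emit them.

Assay matching is gene-level.  A break-apart ``translocated`` result on
either partner confirms a fusion (the assay cannot see the partner), a
fusion-probe or RT-PCR result confirms only the exact pair, and an
``intragenic_rearrangement`` pattern is treated as non-confirming.  IHC is a
screening stain only: it never confirms on its own.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Optional, Sequence

from .core import (
    AssayModality,
    AssayOutcome,
    Caller,
    Cohort,
    ConfidenceTier,
    EventClass,
    FusionEvent,
    IntegrityError,
    OrthogonalAssay,
    PairKey,
    QCStatus,
    SampleRecord,
    make_pair_key,
)


class MatchCategory(str, enum.Enum):
    CONFIRMED = "confirmed"
    DIFFERENT = "different"
    MISSED = "missed"
    ADDITIONAL = "additional"
    NEGATIVE_CONCORDANT = "negative_concordant"


class AssayCategory(str, enum.Enum):
    CONFIRMED = "confirmed"
    CONTRADICTED = "contradicted"
    UNINFORMATIVE = "uninformative"
    UNBALANCED_PATTERN = "unbalanced_pattern"


@dataclass(frozen=True)
class MatchVerdict:
    sample_id: str
    subject_caller: Caller
    category: MatchCategory
    matched_key: Optional[PairKey] = None
    evidence: str = ""
    n_subject_events: int = 0
    reference_positive: bool = False
    qc_pass: bool = True

    def __post_init__(self) -> None:
        if self.category is MatchCategory.CONFIRMED and self.matched_key is None:
            raise ValueError("confirmed verdicts require a matched key")


@dataclass(frozen=True)
class AssayVerdict:
    sample_id: str
    event_key: PairKey
    category: AssayCategory
    modality: Optional[AssayModality] = None
    evidence: str = ""


def _retained_fusions(events: Sequence[FusionEvent]) -> list[FusionEvent]:
    return [
        e
        for e in events
        if e.confidence_tier is ConfidenceTier.RETAIN and e.event_class is EventClass.FUSION
    ]


def _keys_match(subject: FusionEvent, reference: FusionEvent, policy: str) -> bool:
    if subject.pair_key(policy) == reference.pair_key(policy):
        return True
    # a >2-partner (complex) subject call matches when it contains both
    # reference partners
    if len(subject.partners) > 2 and set(reference.partners) <= set(subject.partners):
        return True
    return False


def match_to_reference(
    subject_events: Sequence[FusionEvent],
    reference_events: Sequence[FusionEvent],
    sample: SampleRecord,
    policy: str = "unordered",
    subject_caller: Optional[Caller] = None,
) -> MatchVerdict:
    """Compare one caller's calls on one sample against the reference caller.

    ``subject_events``/``reference_events`` must already be restricted to the
    sample; retained fusion-class events only enter the comparison.
    ``subject_caller`` labels the verdict when the subject emitted nothing.
    """
    for e in (*subject_events, *reference_events):
        if e.sample_id != sample.sample_id:
            raise IntegrityError(
                f"event for {e.sample_id} passed with sample {sample.sample_id}"
            )
    subj = _retained_fusions(subject_events)
    ref = _retained_fusions(reference_events)
    caller = subject_caller or (
        subject_events[0].caller if subject_events else (subj[0].caller if subj else Caller.ARR)
    )
    qc_pass = sample.qc_status is QCStatus.PASS

    if ref and qc_pass:
        for r in ref:
            for s in subj:
                if _keys_match(s, r, policy):
                    return MatchVerdict(
                        sample.sample_id, s.caller, MatchCategory.CONFIRMED,
                        matched_key=r.pair_key(policy),
                        evidence="-".join(r.partners),
                        n_subject_events=len(subj),
                        reference_positive=True,
                    )
        if subj:
            return MatchVerdict(
                sample.sample_id, caller, MatchCategory.DIFFERENT,
                evidence="; ".join("-".join(s.partners) for s in subj),
                n_subject_events=len(subj),
                reference_positive=True,
            )
        return MatchVerdict(
            sample.sample_id, caller, MatchCategory.MISSED,
            n_subject_events=0, reference_positive=True,
        )

    # reference-negative or not-evaluable sample
    if subj:
        return MatchVerdict(
            sample.sample_id, caller, MatchCategory.ADDITIONAL,
            evidence="; ".join("-".join(s.partners) for s in subj),
            n_subject_events=len(subj),
            reference_positive=False,
            qc_pass=qc_pass,
        )
    return MatchVerdict(
        sample.sample_id, caller, MatchCategory.NEGATIVE_CONCORDANT,
        n_subject_events=0, reference_positive=False, qc_pass=qc_pass,
    )


def match_cohort_to_reference(
    cohort: Cohort, subject_caller: Caller, policy: str = "unordered"
) -> list[MatchVerdict]:
    """One verdict per sample for ``subject_caller`` vs the reference caller.

    Samples whose only reference events are exon skippings (undetectable by
    the compared callers) are excluded from the comparison entirely.
    """
    verdicts = []
    for sample in cohort.samples:
        ref = cohort.events_for(sample.sample_id, Caller.REF)
        if ref and not _retained_fusions(ref):
            continue  # skipping/deletion-only reference sample
        subj = cohort.events_for(sample.sample_id, subject_caller)
        verdicts.append(
            match_to_reference(subj, ref, sample, policy=policy, subject_caller=subject_caller)
        )
    return verdicts


_CONFIRMING = {
    AssayModality.FISH_FUSION: {AssayOutcome.FUSION_CONFIRMED},
    AssayModality.RTPCR: {AssayOutcome.FUSION_CONFIRMED},
    AssayModality.FISH_BREAKAPART: {AssayOutcome.TRANSLOCATED},
}
_NON_CONFIRMING = {AssayOutcome.NEGATIVE, AssayOutcome.INTRAGENIC_REARRANGEMENT}


def match_to_assays(
    event: FusionEvent, assays: Sequence[OrthogonalAssay], policy: str = "unordered"
) -> AssayVerdict:
    """Judge one retained call against the sample's orthogonal assays.

    Precedence: exact fusion-probe/RT-PCR confirmation outranks break-apart
    confirmation; an ``unbalanced`` break-apart pattern outranks negatives;
    a call whose partners are covered only by negative (or intragenic-
    rearrangement) results is ``contradicted``; anything else (no assay,
    ``not_done``/``not_assessable``, IHC only) is ``uninformative``.
    """
    key = event.pair_key(policy)
    partners = set(event.partners)
    covering = [
        a
        for a in assays
        if a.sample_id == event.sample_id
        and a.informative
        and partners & set(a.genes)
        and a.modality is not AssayModality.IHC
    ]

    # exact-pair probes first, then break-apart
    for a in covering:
        if a.modality in (AssayModality.FISH_FUSION, AssayModality.RTPCR):
            if set(a.genes) == partners and a.outcome in _CONFIRMING[a.modality]:
                return AssayVerdict(event.sample_id, key, AssayCategory.CONFIRMED, a.modality,
                                    evidence="-".join(a.genes))
    for a in covering:
        if a.modality is AssayModality.FISH_BREAKAPART and a.outcome is AssayOutcome.TRANSLOCATED:
            return AssayVerdict(event.sample_id, key, AssayCategory.CONFIRMED, a.modality,
                                evidence=a.genes[0])
    for a in covering:
        if a.outcome is AssayOutcome.UNBALANCED:
            return AssayVerdict(event.sample_id, key, AssayCategory.UNBALANCED_PATTERN,
                                a.modality, evidence=a.genes[0])
    if covering and all(a.outcome in _NON_CONFIRMING for a in covering):
        return AssayVerdict(event.sample_id, key, AssayCategory.CONTRADICTED,
                            covering[0].modality,
                            evidence="; ".join(a.genes[0] for a in covering))
    ihc = [
        a for a in assays
        if a.sample_id == event.sample_id and a.informative
        and a.modality is AssayModality.IHC and partners & set(a.genes)
    ]
    evidence = "IHC only" if ihc else ""
    return AssayVerdict(event.sample_id, key, AssayCategory.UNINFORMATIVE, evidence=evidence)


def match_events_to_assays(
    cohort: Cohort, caller: Caller = Caller.REF, policy: str = "unordered"
) -> list[AssayVerdict]:
    """Assay verdict for every retained fusion-class call of ``caller``."""
    verdicts = []
    for event in cohort.events:
        if event.caller is caller and event.event_class is EventClass.FUSION:
            verdicts.append(match_to_assays(event, cohort.assays_for(event.sample_id), policy))
    return verdicts


def write_verdicts(verdicts: Sequence[MatchVerdict], path) -> None:
    import csv

    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["sample_id", "caller", "category", "matched_key", "evidence"])
        for v in verdicts:
            writer.writerow([
                v.sample_id, v.subject_caller.value, v.category.value,
                v.matched_key.key if v.matched_key else "", v.evidence,
            ])
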