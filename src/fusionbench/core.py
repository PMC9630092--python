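"""Domain model for multi-caller fusion-transcript concordance analysis.

The central objects are per-sample metadata (:class:`SampleRecord`), retained
caller calls (:class:`FusionEvent`), orthogonal single-gene assay outcomes
(:class:`OrthogonalAssay`, e.g. break-apart FISH) and the canonical partner
key (:class:`PairKey`) used to decide whether two calls name the same fusion.

Gene-symbol handling is purely syntactic: symbols are upper-cased and
stripped of surrounding whitespace/markup, with no alias or HGNC resolution.
Callers are compared by the gene names they print, which is also all that an
orthogonal assay can resolve.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from typing import Optional, Sequence


class FusionbenchError(Exception):
    """Base class for all package errors."""


class InvalidSymbolError(FusionbenchError):
    """Raised when a gene symbol is empty or unusable after normalization."""


class ClassificationError(FusionbenchError):
    """Raised when a caller result string cannot be classified."""


class FormatError(FusionbenchError):
    """Raised when an input table lacks mandatory structure."""


class IntegrityError(FusionbenchError):
    """Raised on referential-integrity violations within a cohort."""


class UndefinedMetricError(FusionbenchError):
    """Raised when a metric's denominator is empty (never silently 0)."""


class UndefinedTestError(FusionbenchError):
    """Raised when a statistical test's preconditions are not met."""


class Panel(str, enum.Enum):
    SARCOMA = "sarcoma"
    LUNG = "lung"


class Specimen(str, enum.Enum):
    CNB = "CNB"
    SURGICAL = "surgical"
    CYTOLOGY = "cytology"


class QCStatus(str, enum.Enum):
    PASS = "pass"
    NOT_EVALUABLE = "not_evaluable"


class Caller(str, enum.Enum):
    """REF is the assay vendor's pipeline, treated as the reference method."""

    REF = "REF"
    ARR = "ARR"
    SFU = "SFU"


class EventClass(str, enum.Enum):
    FUSION = "fusion"
    EXON_SKIPPING = "exon_skipping"
    INTRAGENIC_DELETION = "intragenic_deletion"


class ConfidenceTier(str, enum.Enum):
    RETAIN = "retain"
    DISCARD = "discard"


class AssayModality(str, enum.Enum):
    FISH_BREAKAPART = "FISH_breakapart"
    FISH_FUSION = "FISH_fusion"
    IHC = "IHC"
    RTPCR = "RTPCR"


class AssayOutcome(str, enum.Enum):
    TRANSLOCATED = "translocated"
    FUSION_CONFIRMED = "fusion_confirmed"
    NEGATIVE = "negative"
    INTRAGENIC_REARRANGEMENT = "intragenic_rearrangement"
    UNBALANCED = "unbalanced"
    POSITIVE_STAIN = "positive_stain"
    NEGATIVE_STAIN = "negative_stain"
    NOT_DONE = "not_done"
    NOT_ASSESSABLE = "not_assessable"


#: Outcomes that carry no information for matching (assay absent or failed).
UNINFORMATIVE_OUTCOMES = frozenset({AssayOutcome.NOT_DONE, AssayOutcome.NOT_ASSESSABLE})

_MARKUP_CHARS = "*_`\"'"


def normalize_gene_symbol(raw: str) -> str:
    """Return the canonical form of a gene symbol.

    Upper-cases and strips surrounding whitespace and light text markup
    (asterisks, underscores, quotes).  Deterministic and idempotent; no alias
    resolution is attempted.

    Raises
    ------
    InvalidSymbolError
        If the input is empty or blank after stripping.
    """
    if raw is None:
        raise InvalidSymbolError("gene symbol is None")
    sym = raw.strip().strip(_MARKUP_CHARS).strip()
    if not sym:
        raise InvalidSymbolError(f"empty gene symbol: {raw!r}")
    return sym.upper()


@dataclass(frozen=True)
class PairKey:
    """Canonical identifier of a partner set.

    Under the default unordered policy the key is invariant to partner order
    (break-apart FISH cannot resolve 5'/3' orientation, and callers are
    compared by gene names only).  Single-partner events (exon skipping,
    intragenic deletion) key on the lone symbol plus the event class so they
    never collide with a fusion key.
    """

    key: str
    ordered: bool = False

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.key


def make_pair_key(
    partners: Sequence[str],
    policy: str = "unordered",
    event_class: EventClass = EventClass.FUSION,
) -> PairKey:
    """Build the canonical :class:`PairKey` for a partner list.

    ``policy`` is ``"unordered"`` (sort partners lexicographically; default)
    or ``"ordered"`` (preserve 5'->3' order).
    """
    if policy not in ("unordered", "ordered"):
        raise ValueError(f"unknown pair-key policy: {policy!r}")
    if not partners:
        raise InvalidSymbolError("pair key requires at least one partner")
    symbols = [normalize_gene_symbol(p) for p in partners]
    if len(symbols) == 1:
        return PairKey(key=f"{symbols[0]}[{event_class.value}]", ordered=policy == "ordered")
    if policy == "unordered":
        symbols = sorted(symbols)
    return PairKey(key="--".join(symbols), ordered=policy == "ordered")


@dataclass(frozen=True)
class ClassifiedResult:
    event_class: EventClass
    partners: tuple[str, ...]
    detail: str = ""


# "<GENE> deletion (<span>)", e.g. "ALK deletion (Δ2-18)"
_DELETION_RE = re.compile(r"^\s*(?P<gene>[^\s]+)\s+deletion\s*\(\s*(?P<detail>[^)]+?)\s*\)\s*$", re.IGNORECASE)
# "<GENE> exon[s] <span> skipping", tolerant of "exon5" and en-dash spans
_SKIPPING_RE = re.compile(
    r"^\s*(?P<gene>[^\s]+)\s+exons?\s*(?P<detail>\d+(?:\s*[–—-]\s*\d+)?)\s+skipping\s*$",
    re.IGNORECASE,
)


def classify_event(raw_result_label: str) -> ClassifiedResult:
    """Classify a harmonized caller result string.

    Three dialect forms are recognised:

    * hyphen-joined symbols (``"EWSR1-FLI1"``, possibly >2 partners) -> fusion
    * ``"<GENE> deletion (Δa-b)"`` -> intragenic deletion with the span as detail
    * ``"<GENE> exon[s] N[-M] skipping"`` -> exon skipping with the span as detail

    Raises
    ------
    ClassificationError
        If the label matches none of the dialect forms.
    """
    if raw_result_label is None or not str(raw_result_label).strip():
        raise ClassificationError("empty result label")
    label = str(raw_result_label).strip()

    m = _DELETION_RE.match(label)
    if m:
        gene = normalize_gene_symbol(m.group("gene"))
        return ClassifiedResult(EventClass.INTRAGENIC_DELETION, (gene,), m.group("detail"))

    m = _SKIPPING_RE.match(label)
    if m:
        gene = normalize_gene_symbol(m.group("gene"))
        detail = "exon " + re.sub(r"\s+", "", m.group("detail"))
        return ClassifiedResult(EventClass.EXON_SKIPPING, (gene,), detail)

    if "-" in label:
        parts = [p for p in label.split("-") if p.strip()]
        if len(parts) >= 2:
            try:
                partners = tuple(normalize_gene_symbol(p) for p in parts)
            except InvalidSymbolError as exc:
                raise ClassificationError(f"unparseable fusion label {label!r}: {exc}") from exc
            return ClassifiedResult(EventClass.FUSION, partners)

    raise ClassificationError(f"unclassifiable result label: {label!r}")


@dataclass(frozen=True)
class SampleRecord:
    """Per-sample panel, specimen, QC and read-depth metadata."""

    sample_id: str
    patient_id: str
    panel: Panel
    specimen: Specimen
    qc_status: QCStatus
    total_reads: int
    histology: str = ""

    def __post_init__(self) -> None:
        if self.total_reads < 0:
            raise ValueError(f"total_reads must be >= 0 (sample {self.sample_id})")


@dataclass(frozen=True)
class FusionEvent:
    """One retained (or explicitly discarded) caller call."""

    sample_id: str
    caller: Caller
    partners: tuple[str, ...]
    event_class: EventClass = EventClass.FUSION
    detail: str = ""
    confidence_tier: ConfidenceTier = ConfidenceTier.RETAIN
    junction_reads: Optional[int] = None
    spanning_reads: Optional[int] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "partners", tuple(normalize_gene_symbol(p) for p in self.partners))
        if self.event_class is EventClass.FUSION and len(self.partners) < 2:
            raise ValueError("fusion events require >= 2 partners")
        if self.event_class in (EventClass.EXON_SKIPPING, EventClass.INTRAGENIC_DELETION) and len(self.partners) != 1:
            raise ValueError(f"{self.event_class.value} events require exactly 1 partner")
        for reads in (self.junction_reads, self.spanning_reads):
            if reads is not None and reads < 0:
                raise ValueError("read support must be >= 0")

    def pair_key(self, policy: str = "unordered") -> PairKey:
        return make_pair_key(self.partners, policy=policy, event_class=self.event_class)


@dataclass(frozen=True)
class OrthogonalAssay:
    """One FISH/IHC/RT-PCR outcome for a gene or gene pair in a sample."""

    sample_id: str
    modality: AssayModality
    genes: tuple[str, ...]
    outcome: AssayOutcome

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", tuple(normalize_gene_symbol(g) for g in self.genes))
        n = len(self.genes)
        if self.modality in (AssayModality.FISH_FUSION, AssayModality.RTPCR) and n != 2:
            raise ValueError(f"{self.modality.value} requires exactly 2 genes, got {n}")
        if self.modality in (AssayModality.FISH_BREAKAPART, AssayModality.IHC) and n != 1:
            raise ValueError(f"{self.modality.value} requires exactly 1 gene, got {n}")

    @property
    def performed(self) -> bool:
        """Assay was attempted (``not_done`` means it never happened)."""
        return self.outcome is not AssayOutcome.NOT_DONE

    @property
    def informative(self) -> bool:
        """Outcome usable for matching (attempted and interpretable)."""
        return self.outcome not in UNINFORMATIVE_OUTCOMES


@dataclass
class Cohort:
    """A validated collection of samples, retained events and assays."""

    samples: list[SampleRecord] = field(default_factory=list)
    events: list[FusionEvent] = field(default_factory=list)
    assays: list[OrthogonalAssay] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def validate(self) -> "Cohort":
        ids = [s.sample_id for s in self.samples]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise IntegrityError(f"duplicate sample_ids: {dupes}")
        known = set(ids)
        orphans = sorted(
            {e.sample_id for e in self.events if e.sample_id not in known}
            | {a.sample_id for a in self.assays if a.sample_id not in known}
        )
        if orphans:
            raise IntegrityError(f"events/assays reference unknown samples: {orphans}")
        for s in self.samples:
            if s.qc_status is QCStatus.NOT_EVALUABLE and any(
                e.sample_id == s.sample_id and e.caller is Caller.REF for e in self.events
            ):
                raise IntegrityError(
                    f"not-evaluable sample {s.sample_id} carries reference-caller events"
                )
        return self

    def sample(self, sample_id: str) -> SampleRecord:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s
        raise IntegrityError(f"unknown sample: {sample_id}")

    def events_for(self, sample_id: str, caller: Optional[Caller] = None) -> list[FusionEvent]:
        return [
            e
            for e in self.events
            if e.sample_id == sample_id and (caller is None or e.caller is caller)
        ]

    def assays_for(self, sample_id: str) -> list[OrthogonalAssay]:
        return [a for a in self.assays if a.sample_id == sample_id]

    def subset_panel(self, panel: Panel) -> "Cohort":
        keep = {s.sample_id for s in self.samples if s.panel is panel}
        return Cohort(
            samples=[s for s in self.samples if s.sample_id in keep],
            events=[e for e in self.events if e.sample_id in keep],
            assays=[a for a in self.assays if a.sample_id in keep],
            provenance=dict(self.provenance),
        )
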