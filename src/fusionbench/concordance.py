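"""Accuracy metrics aggregated from match verdicts.

Sensitivity is confirmed reference-positive samples over all reference-
fusion-positive samples; negative concordance (reported where specificity
would be, since there is no event-level truth on negative samples) is the
fraction of QC-passing reference-negative samples on which the subject
caller is also silent.  PPV/NPV come in two constructions — event-level
(additional calls counted as events) and sample-level — and the construction
label travels with the numbers so they are never silently mixed.

All fractions are stored as integer numerator/denominator pairs; rounding to
display precision happens only at presentation.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from itertools import combinations
from typing import Dict, Mapping, Sequence, Set, Tuple

import numpy as np
from scipy import stats

from .core import Caller, Panel, UndefinedMetricError, UndefinedTestError
from .matching import MatchCategory, MatchVerdict


@dataclass(frozen=True)
class Fraction:
    numerator: int
    denominator: int
    label: str = ""

    def __post_init__(self) -> None:
        if self.denominator <= 0:
            raise UndefinedMetricError(f"{self.label or 'metric'}: empty denominator")
        if not 0 <= self.numerator <= self.denominator:
            raise ValueError(f"{self.label}: {self.numerator}/{self.denominator} out of range")

    @property
    def value(self) -> float:
        return self.numerator / self.denominator

    @property
    def percent(self) -> float:
        return 100.0 * self.value

    def __str__(self) -> str:
        return f"{self.numerator}/{self.denominator} ({self.percent:.1f}%)"


class PPVConstruction(str, enum.Enum):
    EVENT_LEVEL = "event_level"
    SAMPLE_LEVEL = "sample_level"


def _count(verdicts: Sequence[MatchVerdict], category: MatchCategory) -> int:
    return sum(1 for v in verdicts if v.category is category)


def sensitivity_vs_reference(verdicts: Sequence[MatchVerdict]) -> Fraction:
    """Confirmed / reference-fusion-positive samples."""
    positive = [v for v in verdicts if v.reference_positive]
    if not positive:
        raise UndefinedMetricError("sensitivity: no reference-positive samples in scope")
    return Fraction(_count(positive, MatchCategory.CONFIRMED), len(positive), "sensitivity")


def negative_concordance(verdicts: Sequence[MatchVerdict]) -> Fraction:
    """Silent-subject fraction of QC-passing reference-negative samples."""
    negative = [v for v in verdicts if not v.reference_positive and v.qc_pass]
    if not negative:
        raise UndefinedMetricError("negative concordance: no reference-negative samples")
    return Fraction(
        _count(negative, MatchCategory.NEGATIVE_CONCORDANT), len(negative), "negative_concordance"
    )


def ppv_npv(
    verdicts: Sequence[MatchVerdict],
    construction: PPVConstruction = PPVConstruction.EVENT_LEVEL,
) -> tuple[Fraction, Fraction]:
    """Positive and negative predictive value under one labelled construction.

    ``event_level``: PPV = confirmed events / (confirmed + additional
    events); ``sample_level``: the same with each sample counted once.  NPV
    is sample-level in both constructions (negative-concordant /
    (negative-concordant + missed)).
    """
    construction = PPVConstruction(construction)
    confirmed = _count(verdicts, MatchCategory.CONFIRMED)
    if construction is PPVConstruction.EVENT_LEVEL:
        additional = sum(
            v.n_subject_events for v in verdicts if v.category is MatchCategory.ADDITIONAL
        )
    else:
        additional = _count(verdicts, MatchCategory.ADDITIONAL)
    neg_conc = _count(verdicts, MatchCategory.NEGATIVE_CONCORDANT)
    missed = _count(verdicts, MatchCategory.MISSED)
    ppv = Fraction(confirmed, confirmed + additional, f"ppv[{construction.value}]")
    npv = Fraction(neg_conc, neg_conc + missed, f"npv[{construction.value}]")
    return ppv, npv


def venn_partition(
    callsets: Mapping[str, Set[Tuple[str, object]]]
) -> Dict[Tuple[str, ...], int]:
    """Disjoint membership-region counts for 2 or 3 call sets.

    Keys are sorted tuples of caller names belonging to the region; counts
    sum to the size of the union.
    """
    names = sorted(callsets)
    if not 2 <= len(names) <= 3:
        raise ValueError("venn_partition requires 2 or 3 callsets")
    regions: Dict[Tuple[str, ...], int] = {}
    for k in range(1, len(names) + 1):
        for members in combinations(names, k):
            inside = set.intersection(*(set(callsets[m]) for m in members))
            outside = set.union(
                set(), *(set(callsets[m]) for m in names if m not in members)
            )
            regions[members] = len(inside - outside)
    return regions


def detection_vs_reads(
    positive_reads: Sequence[int],
    negative_reads: Sequence[int],
    alternative: str = "two-sided",
) -> tuple[float, str]:
    """Wilcoxon rank-sum test of read depth between detection groups.

    Exact enumeration when the combined sample is small (n <= 20) and free of
    ties, the tie-corrected normal approximation otherwise.  Returns
    ``(p_value, method)``.
    """
    x, y = list(positive_reads), list(negative_reads)
    if not x or not y:
        raise UndefinedTestError("detection_vs_reads requires two nonempty groups")
    pooled = x + y
    exact = len(pooled) <= 20 and len(set(pooled)) == len(pooled)
    method = "exact" if exact else "asymptotic"
    result = stats.mannwhitneyu(x, y, alternative=alternative, method=method)
    return float(result.pvalue), method


@dataclass
class ConcordanceReport:
    caller: Caller
    panel: Panel
    sensitivity: Fraction
    negative_concordance: Fraction
    ppv: Fraction
    npv: Fraction
    venn: Dict[Tuple[str, ...], int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "caller": self.caller.value,
            "panel": self.panel.value,
            "sensitivity": {
                "numerator": self.sensitivity.numerator,
                "denominator": self.sensitivity.denominator,
                "percent": self.sensitivity.percent,
            },
            "negative_concordance": {
                "numerator": self.negative_concordance.numerator,
                "denominator": self.negative_concordance.denominator,
                "percent": self.negative_concordance.percent,
            },
            "ppv": {
                "numerator": self.ppv.numerator,
                "denominator": self.ppv.denominator,
                "percent": self.ppv.percent,
                "construction": self.ppv.label,
            },
            "npv": {
                "numerator": self.npv.numerator,
                "denominator": self.npv.denominator,
                "percent": self.npv.percent,
                "construction": self.npv.label,
            },
            "venn": {"+".join(k): v for k, v in self.venn.items()},
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    def to_tsv(self) -> str:
        """Human-readable flat form: one metric per line."""
        lines = ["metric\tnumerator\tdenominator\tpercent"]
        for name in ("sensitivity", "negative_concordance", "ppv", "npv"):
            frac: Fraction = getattr(self, name)
            lines.append(f"{name}\t{frac.numerator}\t{frac.denominator}\t{frac.percent:.1f}")
        for region, count in sorted(self.venn.items()):
            lines.append(f"venn:{'+'.join(region)}\t{count}\t\t")
        return "\n".join(lines) + "\n"


def build_report(
    verdicts: Sequence[MatchVerdict],
    caller: Caller,
    panel: Panel,
    construction: PPVConstruction = PPVConstruction.EVENT_LEVEL,
    venn: Dict[Tuple[str, ...], int] | None = None,
) -> ConcordanceReport:
    ppv, npv = ppv_npv(verdicts, construction)
    return ConcordanceReport(
        caller=caller,
        panel=panel,
        sensitivity=sensitivity_vs_reference(verdicts),
        negative_concordance=negative_concordance(verdicts),
        ppv=ppv,
        npv=npv,
        venn=venn or {},
    )
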