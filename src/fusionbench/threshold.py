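"""Recursive contingency analysis for a read-count reliability threshold.

Samples are labelled concordant/discordant (NGS result versus orthogonal
truth) and carry a total-read count.  Every midpoint between adjacent
distinct read counts is a candidate cut; each cut induces a 2x2 table
(below/above x discordant/concordant) tested with a one-tailed Fisher exact
(hypergeometric tail) test, by default in the direction "low-reads group
enriched for discordance".  The selected threshold is the candidate with the
globally minimal p (ties broken toward the smaller cut) when that minimum
reaches ``alpha``.

Because the minimum is taken over every candidate cut, the nominal p is
optimistically biased; :func:`permutation_adjust` reports a label-permutation
estimate of the family-wise p alongside it.

Exact tails are computed with log-gamma arithmetic; no continuity
corrections are applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.special import gammaln

#: read-count threshold printed in the assay manufacturer's instructions
MANUFACTURER_THRESHOLD = 5.0e5
#: lower reliability threshold derived in the source study's cohort
STUDY_DERIVED_THRESHOLD = 1.75e5


def _log_pmf(k: np.ndarray, N: int, K: int, n: int) -> np.ndarray:
    """log P(X = k) for X ~ Hypergeometric(N, K, n)."""
    k = np.asarray(k, dtype=float)
    return (
        gammaln(K + 1) - gammaln(k + 1) - gammaln(K - k + 1)
        + gammaln(N - K + 1) - gammaln(n - k + 1) - gammaln(N - K - n + k + 1)
        - (gammaln(N + 1) - gammaln(n + 1) - gammaln(N - n + 1))
    )


def _tail_profile(N: int, K: int, n: int) -> np.ndarray:
    """Upper-tail array ``sf`` with ``sf[a] = P(X >= a)`` for a in 0..min(n,K)."""
    lo, hi = max(0, n + K - N), min(n, K)
    support = np.arange(lo, hi + 1)
    probs = np.exp(_log_pmf(support, N, K, n))
    suffix = np.cumsum(probs[::-1])[::-1]  # suffix[j] = P(X >= lo + j)
    sf = np.ones(hi + 1)
    sf[lo:] = suffix
    return np.clip(sf, 0.0, 1.0)


def hypergeom_tail(a: int, b: int, c: int, d: int, direction: str = "greater") -> float:
    """One-tailed Fisher exact p for the 2x2 table ``[[a, b], [c, d]]``.

    Rows are below/above the cut, columns discordant/concordant.  With the
    default ``direction="greater"`` the tail is ``P(X >= a)`` for X
    hypergeometric with the table's margins — the low-reads row enriched for
    discordance.  ``direction="less"`` tests the opposite corner.
    """
    for cell in (a, b, c, d):
        if cell < 0:
            raise ValueError(f"negative cell in 2x2 table: {(a, b, c, d)}")
    if direction not in ("greater", "less"):
        raise ValueError(f"unknown direction: {direction!r}")
    N, K, n = a + b + c + d, a + c, a + b
    if N == 0:
        return 1.0
    sf = _tail_profile(N, K, n)
    if direction == "greater":
        return float(sf[a])
    # P(X <= a) = 1 - P(X >= a+1)
    return float(1.0 - (sf[a + 1] if a + 1 < len(sf) else 0.0))


@dataclass(frozen=True)
class ScanInput:
    """Per-sample read counts and concordance-with-truth labels."""

    total_reads: tuple[int, ...]
    concordant: tuple[bool, ...]

    def __post_init__(self) -> None:
        if len(self.total_reads) != len(self.concordant):
            raise ValueError("total_reads and concordant must have equal length")
        if len(self.total_reads) < 2:
            raise ValueError("a threshold scan needs at least 2 samples")

    @classmethod
    def from_arrays(cls, reads: Sequence[int], concordant: Sequence[bool]) -> "ScanInput":
        return cls(tuple(int(r) for r in reads), tuple(bool(c) for c in concordant))


@dataclass(frozen=True)
class ScanCandidate:
    cut: float
    a: int  # discordant below
    b: int  # concordant below
    c: int  # discordant above
    d: int  # concordant above
    p: float


@dataclass
class ThresholdScanResult:
    candidates: list[ScanCandidate]
    selected_threshold: Optional[float]
    min_p: float
    alpha: float
    min_group: int
    direction: str
    adjusted_min_p: Optional[float] = None
    reference_thresholds: dict = field(
        default_factory=lambda: {
            "manufacturer": MANUFACTURER_THRESHOLD,
            "study_derived": STUDY_DERIVED_THRESHOLD,
        }
    )

    def to_rows(self) -> list[tuple]:
        return [(c.cut, c.a, c.b, c.c, c.d, c.p) for c in self.candidates]

    def summary(self) -> dict:
        return {
            "selected_threshold": self.selected_threshold,
            "min_p": self.min_p,
            "adjusted_min_p": self.adjusted_min_p,
            "alpha": self.alpha,
            "min_group": self.min_group,
            "direction": self.direction,
            "n_candidates": len(self.candidates),
            "reference_thresholds": dict(self.reference_thresholds),
        }


def _scan_geometry(reads: np.ndarray, min_group: int):
    """Sort order, candidate boundary positions and cut values."""
    order = np.argsort(reads, kind="stable")
    sorted_reads = reads[order]
    n = len(reads)
    # boundary after position i (0-based) splits into i+1 below / n-i-1 above
    boundaries = np.array(
        [
            i
            for i in range(n - 1)
            if sorted_reads[i] != sorted_reads[i + 1]
            and (i + 1) >= min_group
            and (n - i - 1) >= min_group
        ],
        dtype=int,
    )
    cuts = (sorted_reads[boundaries] + sorted_reads[boundaries + 1]) / 2.0
    return order, boundaries, cuts


def scan_read_thresholds(
    scan_input: ScanInput,
    alpha: float = 0.05,
    min_group: int = 1,
    direction: str = "greater",
) -> ThresholdScanResult:
    """Scan every adjacent-value read-count cut with a one-tailed Fisher test.

    Ties in read counts cannot be split, so candidates are midpoints between
    adjacent *distinct* sorted values whose sides both hold at least
    ``min_group`` samples.  Returns the full p-profile plus the selected
    threshold (None when no cut reaches ``alpha``).
    """
    reads = np.asarray(scan_input.total_reads, dtype=float)
    conc = np.asarray(scan_input.concordant, dtype=bool)
    order, boundaries, cuts = _scan_geometry(reads, min_group)
    disc_sorted = (~conc[order]).astype(int)
    cum_disc = np.cumsum(disc_sorted)
    N, K = len(reads), int(disc_sorted.sum())

    candidates: list[ScanCandidate] = []
    for i, cut in zip(boundaries, cuts):
        n_below = i + 1
        a = int(cum_disc[i])
        b = n_below - a
        c = K - a
        d = (N - n_below) - c
        candidates.append(ScanCandidate(float(cut), a, b, c, d, hypergeom_tail(a, b, c, d, direction)))

    if not candidates or K == 0 or K == N:
        return ThresholdScanResult(candidates, None, 1.0, alpha, min_group, direction)

    min_p = min(c.p for c in candidates)
    # ties on p break toward the smaller cut; candidates are in cut order
    selected = next(c.cut for c in candidates if c.p <= min_p)
    return ThresholdScanResult(
        candidates,
        selected if min_p <= alpha else None,
        float(min_p),
        alpha,
        min_group,
        direction,
    )


def _min_p_machinery(scan_input: ScanInput, min_group: int, direction: str):
    """Precomputed per-candidate tail tables for fast repeated scans.

    Under label permutation the margins (N, per-candidate n, total discordant
    K) are fixed; only the below-cut discordant count varies, so each
    candidate's full tail profile can be tabulated once and then indexed.
    """
    reads = np.asarray(scan_input.total_reads, dtype=float)
    conc = np.asarray(scan_input.concordant, dtype=bool)
    order, boundaries, _ = _scan_geometry(reads, min_group)
    disc = (~conc[order]).astype(int)
    N, K = len(reads), int(disc.sum())
    if len(boundaries) == 0 or K == 0 or K == N:
        return None
    tables = np.ones((len(boundaries), K + 1))
    for j, i in enumerate(boundaries):
        n_below = i + 1
        sf = _tail_profile(N, K, n_below)
        if direction == "greater":
            tables[j, : len(sf)] = sf
            tables[j, len(sf):] = 0.0  # a beyond min(n, K) cannot occur
        else:
            cdf = 1.0 - np.append(sf[1:], 0.0)
            tables[j, : len(cdf)] = cdf
            tables[j, len(cdf):] = 1.0
    return disc, boundaries, tables


def _min_p_for_labels(disc_sorted: np.ndarray, boundaries: np.ndarray, tables: np.ndarray) -> float:
    a = np.cumsum(disc_sorted)[boundaries]
    return float(tables[np.arange(len(boundaries)), a].min())


def permutation_adjust(
    scan_input: ScanInput,
    B: int = 1000,
    seed: int = 0,
    min_group: int = 1,
    direction: str = "greater",
) -> float:
    """Permutation estimate of the family-wise minimum-p significance.

    Returns the add-one proportion of ``B`` label permutations whose scan
    minimum p is at or below the observed one.  Degenerate inputs (no
    candidate cuts, or all labels equal) return 1.0.
    """
    if B < 100:
        raise ValueError("B must be >= 100 for a stable permutation estimate")
    machinery = _min_p_machinery(scan_input, min_group, direction)
    if machinery is None:
        return 1.0
    disc, boundaries, tables = machinery
    observed = _min_p_for_labels(disc, boundaries, tables)

    rng = np.random.default_rng(seed)
    n = len(disc)
    # permute labels in blocks to keep memory flat
    hits = 0
    block = max(1, min(B, 200))
    done = 0
    while done < B:
        m = min(block, B - done)
        idx = rng.random((m, n)).argsort(axis=1)
        permuted = disc[idx]
        a = np.cumsum(permuted, axis=1)[:, boundaries]
        p = tables[np.arange(len(boundaries))[None, :], a]
        hits += int((p.min(axis=1) <= observed + 1e-12).sum())
        done += m
    return (1 + hits) / (B + 1)


def write_scan_tsv(result: ThresholdScanResult, path) -> None:
    import csv

    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["cut", "a", "b", "c", "d", "p"])
        for row in result.to_rows():
            writer.writerow(row)
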