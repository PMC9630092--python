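"""Seeded generator of synthetic panel cohorts with the statistical structure
the concordance analysis assumes.

The generative model, per sample: a log-normal total-read depth; a true
status (fusion with a partner pair drawn from the panel vocabulary, exon
skipping on the lung panel, or negative); per-caller detection of a true
event with probability ``s_max / (1 + exp(-k * (log10 r - log10 T)))`` — a
logistic step in log10 reads with midpoint ``T`` emulating the depth-
dependent reliability of the assay; per-caller Poisson false-positive novel
pairs; and, where FISH is available, a break-apart outcome (withheld-
negative for cryptic fusions, an unbalanced pattern at a configured rate).

The reference caller respects the QC flag (not-evaluable samples carry no
reference events); the comparison callers run on every sample.  Defaults are
calibrated to the two study panels: prevalence 0.45/0.18, median depths near
894,000 and 344,622 reads, and a detection midpoint at 1.75e5 reads.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from math import log10
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .core import (
    AssayModality,
    AssayOutcome,
    Caller,
    Cohort,
    EventClass,
    FusionEvent,
    OrthogonalAssay,
    Panel,
    QCStatus,
    SampleRecord,
    Specimen,
)
from .io import write_assays, write_harmonized_calls, write_manifest
from .threshold import STUDY_DERIVED_THRESHOLD, ScanInput

SARCOMA_PANEL_GENES = [
    "ALK", "CAMTA1", "CCNB3", "CIC", "EPC1", "EWSR1", "FOXO1", "FUS", "GLI1",
    "HMGA2", "JAZF1", "MEAF6", "MKL2", "NCOA2", "NTRK3", "PDGFB", "PLAG1",
    "ROS1", "SS18", "STAT6", "TAF15", "TCF12", "TFE3", "TFG", "USP6", "YWHAE",
]
LUNG_PANEL_GENES = [
    "ALK", "BRAF", "EGFR", "FGFR1", "FGFR2", "FGFR3", "KRAS", "MET", "NRG1",
    "NTRK1", "NTRK2", "NTRK3", "RET", "ROS1",
]
_PARTNER_GENES = [
    "EML4", "KIF5B", "TPM3", "TPR", "ETV6", "NCOA4", "TACC3", "CCDC6",
    "SDC4", "SLC34A2", "TFG", "KIF5C", "RELCH", "NAB2", "FLI1", "SSX1",
]


@dataclass(frozen=True)
class CallerModel:
    """Depth-dependent detection and false-positive behaviour of one caller."""

    s_max: float = 0.9          # asymptotic sensitivity at saturating depth
    slope_k: float = 6.0        # logistic slope per log10 read
    midpoint_reads: float = STUDY_DERIVED_THRESHOLD  # T, reads
    fp_rate: float = 0.0        # expected false-positive calls per sample

    def detection_prob(self, total_reads: float) -> float:
        if total_reads <= 0:
            return 0.0
        x = self.slope_k * (log10(total_reads) - log10(self.midpoint_reads))
        return self.s_max / (1.0 + np.exp(-x))

    def validate(self) -> None:
        if not 0.0 <= self.s_max <= 1.0:
            raise ValueError(f"s_max must be in [0,1], got {self.s_max}")
        if self.slope_k <= 0:
            raise ValueError("logistic slope must be > 0")
        if self.midpoint_reads <= 0:
            raise ValueError("detection midpoint must be > 0 reads")
        if self.fp_rate < 0:
            raise ValueError("false-positive rate must be >= 0")


@dataclass(frozen=True)
class CohortConfig:
    n_samples: int = 162
    panel: Panel = Panel.LUNG
    prevalence: float = 0.18            # true-positive fraction
    exon_skipping_share: float = 8 / 29  # share of positives that are skippings (lung)
    read_depth_log10_mean: float = log10(344622)
    read_depth_log10_sd: float = 0.45
    callers: dict = field(default_factory=dict)
    gene_vocabulary: tuple[str, ...] = tuple(LUNG_PANEL_GENES)
    partner_vocabulary: tuple[str, ...] = tuple(_PARTNER_GENES)
    fish_availability: float = 0.35
    cryptic_fraction: float = 0.2       # true fusions invisible to break-apart FISH
    unbalanced_rate: float = 0.02       # negative samples with an unbalanced pattern
    not_evaluable_rate: float = 0.07
    seed: int = 0

    def caller_models(self) -> dict[Caller, CallerModel]:
        models = {
            Caller.REF: CallerModel(s_max=0.95, fp_rate=0.0),
            Caller.ARR: CallerModel(s_max=0.86, fp_rate=0.27),
            Caller.SFU: CallerModel(s_max=0.33, fp_rate=0.14),
        }
        models.update({Caller(k): v for k, v in self.callers.items()})
        return models

    def validate(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        for name, p in (
            ("prevalence", self.prevalence),
            ("exon_skipping_share", self.exon_skipping_share),
            ("fish_availability", self.fish_availability),
            ("cryptic_fraction", self.cryptic_fraction),
            ("unbalanced_rate", self.unbalanced_rate),
            ("not_evaluable_rate", self.not_evaluable_rate),
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be a probability, got {p}")
        if self.read_depth_log10_sd <= 0:
            raise ValueError("read-depth spread must be > 0")
        for model in self.caller_models().values():
            model.validate()


def config_from_yaml(path, panel: Panel | None = None, **overrides) -> CohortConfig:
    """Load a cohort configuration from a YAML key-value file.

    Top-level keys mirror :class:`CohortConfig` field names; an optional
    ``callers`` mapping holds per-caller ``s_max``/``slope_k``/
    ``midpoint_reads``/``fp_rate``.  Keyword ``overrides`` (e.g. a CLI seed)
    win over file values.
    """
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    callers = {
        Caller(name): CallerModel(**params)
        for name, params in (raw.pop("callers", None) or {}).items()
    }
    if "panel" in raw:
        raw["panel"] = Panel(raw["panel"])
    raw.update(overrides)
    factory = sarcoma_config if (panel or raw.get("panel")) is Panel.SARCOMA else lung_config
    if callers:
        raw["callers"] = callers
    return factory(**raw)


def sarcoma_config(**overrides) -> CohortConfig:
    """Study-calibrated sarcoma-panel conditions (31 samples, 45% prevalence,
    median depth near 894,000 reads, no exon skipping)."""
    base = CohortConfig(
        n_samples=31,
        panel=Panel.SARCOMA,
        prevalence=0.45,
        exon_skipping_share=0.0,
        read_depth_log10_mean=log10(894000),
        read_depth_log10_sd=0.33,
        gene_vocabulary=tuple(SARCOMA_PANEL_GENES),
        fish_availability=0.75,
        not_evaluable_rate=3 / 31,
        callers={
            Caller.REF: CallerModel(s_max=0.95, fp_rate=0.0),
            Caller.ARR: CallerModel(s_max=0.57, fp_rate=0.29),
            Caller.SFU: CallerModel(s_max=0.07, fp_rate=0.47),
        },
    )
    return replace(base, **overrides)


def lung_config(**overrides) -> CohortConfig:
    """Study-calibrated lung-panel conditions (162 samples, 18% positive of
    which ~28% exon skippings, median depth near 344,622 reads)."""
    return replace(CohortConfig(), **overrides)


@dataclass
class TruthRecord:
    sample_id: str
    status: str                   # fusion | exon_skipping | negative
    partners: tuple[str, ...]
    total_reads: int
    qc_pass: bool
    cryptic: bool
    detected: dict                # Caller -> bool (true event detected)


def _draw_pair(rng: np.random.Generator, config: CohortConfig) -> tuple[str, str]:
    driver = config.gene_vocabulary[rng.integers(len(config.gene_vocabulary))]
    partner = driver
    while partner == driver:
        partner = config.partner_vocabulary[rng.integers(len(config.partner_vocabulary))]
    return partner, driver  # 5' partner first, panel driver 3'


def _draw_fp_pair(rng: np.random.Generator, config: CohortConfig, true_pair: frozenset) -> tuple[str, str]:
    vocab = list(config.gene_vocabulary) + list(config.partner_vocabulary)
    while True:
        i, j = rng.integers(len(vocab), size=2)
        if i != j and frozenset((vocab[i], vocab[j])) != true_pair:
            return vocab[i], vocab[j]


def generate_cohort(config: CohortConfig) -> tuple[Cohort, pd.DataFrame]:
    """Generate a cohort plus its ground-truth table.

    Returns ``(cohort, truth)`` where ``truth`` has one row per sample with
    the true status, true partners, depth and per-caller detection flags.
    Fully deterministic given ``config`` (including its seed).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    models = config.caller_models()
    prefix = "Y" if config.panel is Panel.LUNG else "X"

    samples, events, assays, truth_rows = [], [], [], []
    for i in range(config.n_samples):
        sid = f"{prefix}{i:04d}"
        reads = int(round(10 ** rng.normal(config.read_depth_log10_mean, config.read_depth_log10_sd)))
        qc_pass = rng.random() >= config.not_evaluable_rate
        positive = rng.random() < config.prevalence
        skipping = (
            positive
            and config.panel is Panel.LUNG
            and rng.random() < config.exon_skipping_share
        )
        partners: tuple[str, ...] = ()
        status = "negative"
        if positive and skipping:
            status = "exon_skipping"
            partners = (config.gene_vocabulary[rng.integers(len(config.gene_vocabulary))],)
        elif positive:
            status = "fusion"
            partners = _draw_pair(rng, config)
        cryptic = status == "fusion" and rng.random() < config.cryptic_fraction

        samples.append(
            SampleRecord(
                sample_id=sid,
                patient_id=f"P{sid}",
                panel=config.panel,
                specimen=Specimen.CNB,
                qc_status=QCStatus.PASS if qc_pass else QCStatus.NOT_EVALUABLE,
                total_reads=reads,
                histology="synthetic",
            )
        )

        detected = {}
        true_pair = frozenset(partners) if status == "fusion" else frozenset()
        for caller, model in models.items():
            hit = False
            if status == "fusion" or (status == "exon_skipping" and caller is Caller.REF):
                hit = rng.random() < model.detection_prob(reads)
            # exon skipping is invisible to the comparison callers by design
            detected[caller] = bool(hit)
            if caller is Caller.REF and not qc_pass:
                detected[caller] = False
                continue
            if detected[caller]:
                if status == "fusion":
                    events.append(
                        FusionEvent(
                            sample_id=sid, caller=caller, partners=partners,
                            junction_reads=int(rng.integers(5, 80)),
                            spanning_reads=int(rng.integers(2, 40)),
                        )
                    )
                else:
                    events.append(
                        FusionEvent(
                            sample_id=sid, caller=caller, partners=partners,
                            event_class=EventClass.EXON_SKIPPING, detail="exon 14",
                            junction_reads=int(rng.integers(5, 80)),
                        )
                    )
            n_fp = rng.poisson(model.fp_rate)
            for _ in range(n_fp):
                events.append(
                    FusionEvent(
                        sample_id=sid, caller=caller,
                        partners=_draw_fp_pair(rng, config, true_pair),
                        junction_reads=int(rng.integers(3, 20)),
                        spanning_reads=int(rng.integers(1, 10)),
                    )
                )

        if rng.random() < config.fish_availability:
            if status == "fusion":
                probe = partners[1]  # panel driver gene carries the break-apart probe
                outcome = AssayOutcome.NEGATIVE if cryptic else AssayOutcome.TRANSLOCATED
                assays.append(OrthogonalAssay(sid, AssayModality.FISH_BREAKAPART, (probe,), outcome))
            elif status == "negative":
                probe = config.gene_vocabulary[rng.integers(len(config.gene_vocabulary))]
                outcome = (
                    AssayOutcome.UNBALANCED
                    if rng.random() < config.unbalanced_rate
                    else AssayOutcome.NEGATIVE
                )
                assays.append(OrthogonalAssay(sid, AssayModality.FISH_BREAKAPART, (probe,), outcome))
            else:
                assays.append(
                    OrthogonalAssay(
                        sid, AssayModality.FISH_BREAKAPART, (partners[0],),
                        AssayOutcome.NOT_ASSESSABLE,
                    )
                )

        truth_rows.append(
            TruthRecord(sid, status, partners, reads, qc_pass, cryptic, detected)
        )

    truth = pd.DataFrame(
        {
            "sample_id": [t.sample_id for t in truth_rows],
            "status": [t.status for t in truth_rows],
            "partners": ["-".join(t.partners) for t in truth_rows],
            "total_reads": [t.total_reads for t in truth_rows],
            "qc_pass": [t.qc_pass for t in truth_rows],
            "cryptic": [t.cryptic for t in truth_rows],
            **{
                f"detected_{c.value}": [t.detected[c] for t in truth_rows]
                for c in models
            },
        }
    )
    cohort = Cohort(
        samples=samples,
        events=events,
        assays=assays,
        provenance={"generator": "synthetic", "seed": config.seed, "panel": config.panel.value},
    ).validate()
    return cohort, truth


def scan_input_from_truth(truth: pd.DataFrame, caller: Caller = Caller.REF) -> ScanInput:
    """Concordance-with-truth labels for the threshold scan.

    A sample is concordant when the caller's detection flag equals its true
    positivity (detected a real event, or stayed silent on a negative).
    """
    is_positive = truth["status"] != "negative"
    concordant = truth[f"detected_{caller.value}"] == is_positive
    return ScanInput.from_arrays(truth["total_reads"].tolist(), concordant.tolist())


# ---------------------------------------------------------------------------
# On-disk caller dialects
# ---------------------------------------------------------------------------

ARRIBA_COLUMNS = [
    "#gene1", "gene2", "strand1(gene/fusion)", "strand2(gene/fusion)",
    "breakpoint1", "breakpoint2", "site1", "site2", "type",
    "split_reads1", "split_reads2", "discordant_mates", "confidence",
]
STAR_FUSION_COLUMNS = [
    "#FusionName", "JunctionReadCount", "SpanningFragCount", "SpliceType",
    "LeftGene", "LeftBreakpoint", "RightGene", "RightBreakpoint",
    "LargeAnchorSupport",
]


def _decoy_seed(sample_id: str) -> int:
    return zlib.crc32(sample_id.encode())


def _write_tsv(path, header, rows) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def write_arriba_file(events, sample_id: str, path) -> None:
    """Write one sample's Arriba-style TSV: retained calls at ``high``
    confidence plus deterministic low/medium decoy rows that exercise the
    reader's confidence filter."""
    rng = np.random.default_rng(_decoy_seed(sample_id))
    rows = []
    for e in events:
        rows.append([
            e.partners[0], e.partners[1], "+/+", "-/-",
            "1:1000", "2:2000", "splice-site", "splice-site", "translocation",
            (e.junction_reads or 0) // 2, (e.junction_reads or 0) - (e.junction_reads or 0) // 2,
            e.spanning_reads or 0, "high",
        ])
    for conf in ("medium", "low"):
        g1, g2 = f"DECOY{rng.integers(100):02d}A", f"DECOY{rng.integers(100):02d}B"
        rows.append([g1, g2, "+/+", "+/+", "3:300", "4:400",
                     "exon", "exon", "deletion/read-through", 1, 1, 0, conf])
    _write_tsv(path, ARRIBA_COLUMNS, rows)


def write_star_fusion_file(events, sample_id: str, path) -> None:
    """Write one sample's STAR-Fusion abridged TSV: retained calls with the
    affirmative large-anchor label plus deterministic ``NO_LDAS`` decoys."""
    rng = np.random.default_rng(_decoy_seed(sample_id) + 1)
    rows = []
    for e in events:
        rows.append([
            "--".join(e.partners), e.junction_reads or 0, e.spanning_reads or 0,
            "ONLY_REF_SPLICE", e.partners[0], "chr1:1000:+",
            e.partners[-1], "chr2:2000:-", "YES_LDAS",
        ])
    g1, g2 = f"DECOY{rng.integers(100):02d}C", f"DECOY{rng.integers(100):02d}D"
    rows.append([f"{g1}--{g2}", 2, 1, "INCL_NON_REF_SPLICE",
                 g1, "chr3:300:+", g2, "chr4:400:-", "NO_LDAS"])
    _write_tsv(path, STAR_FUSION_COLUMNS, rows)


def write_caller_files(cohort: Cohort, outdir) -> dict[str, Path]:
    """Serialize a cohort in the on-disk dialects the readers consume.

    Per sample: ``<sid>.arriba.tsv`` (ARR fusion calls) and
    ``<sid>.star-fusion.tsv`` (SFU fusion calls), each salted with
    non-retained decoy rows; cohort-wide: ``manifest.tsv``,
    ``reference_calls.csv`` (all REF events) and ``assays.csv``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    for sample in cohort.samples:
        sid = sample.sample_id
        arr = [
            e for e in cohort.events_for(sid, Caller.ARR)
            if e.event_class is EventClass.FUSION
        ]
        sfu = [
            e for e in cohort.events_for(sid, Caller.SFU)
            if e.event_class is EventClass.FUSION
        ]
        paths[f"{sid}.arriba"] = outdir / f"{sid}.arriba.tsv"
        paths[f"{sid}.star-fusion"] = outdir / f"{sid}.star-fusion.tsv"
        write_arriba_file(arr, sid, paths[f"{sid}.arriba"])
        write_star_fusion_file(sfu, sid, paths[f"{sid}.star-fusion"])

    ref_events = [e for e in cohort.events if e.caller is Caller.REF]
    paths["manifest"] = outdir / "manifest.tsv"
    paths["reference_calls"] = outdir / "reference_calls.csv"
    paths["assays"] = outdir / "assays.csv"
    write_manifest(cohort.samples, paths["manifest"])
    write_harmonized_calls(ref_events, paths["reference_calls"])
    write_assays(cohort.assays, paths["assays"])
    return paths
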