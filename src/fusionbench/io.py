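"""Readers and writers for caller outputs, sample manifests and assay tables.

Three tabular dialects are supported:

* Arriba-style TSV (``#``-prefixed header allowed) with ``gene1``/``gene2``,
  split/discordant read counts and a ``confidence`` column (low/medium/high);
* STAR-Fusion abridged TSV with a ``FusionName`` column joining partners with
  a double hyphen (``LEFT--RIGHT``), junction/spanning counts and a
  ``LargeAnchorSupport`` column;
* a harmonized-calls CSV (``sample_id,caller,result,confidence,
  junction_reads,spanning_reads``) used as the canonical interchange form for
  reference-caller exports and pre-digested comparison tables.

``build_fixtures`` writes the transcribed two-panel study cohorts in these
dialects so the whole pipeline can be exercised without any external data.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from . import _tables as T
from .core import (
    AssayModality,
    AssayOutcome,
    Caller,
    Cohort,
    ConfidenceTier,
    EventClass,
    FormatError,
    FusionEvent,
    OrthogonalAssay,
    Panel,
    QCStatus,
    SampleRecord,
    Specimen,
    classify_event,
)

ARRIBA_RETAIN_DEFAULT = frozenset({"high"})
STAR_FUSION_RETAIN_DEFAULT = frozenset({"YES_LDAS"})
#: harmonized-CSV confidence values retained per caller
HARMONIZED_RETAIN_DEFAULT = {
    Caller.REF: frozenset({"high"}),
    Caller.ARR: frozenset({"high"}),
    Caller.SFU: frozenset({"large"}),
}


def _read_table(path, sep: str) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    except OSError as exc:
        raise FormatError(f"cannot read {path}: {exc}") from exc
    df.columns = [c.lstrip("#").strip() for c in df.columns]
    return df


def _require(df: pd.DataFrame, columns: Iterable[str], path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing mandatory column(s) {missing}")


def _first_symbol(raw: str) -> str:
    # multi-candidate fields ("A,B") resolve to the first listed symbol;
    # Arriba's read-through "A(12345)" style annotations are stripped too
    sym = raw.split(",")[0]
    return sym.split("(")[0]


def _opt_int(value: str) -> Optional[int]:
    value = str(value).strip()
    return int(float(value)) if value not in ("", "NA", ".") else None


def infer_sample_id(path) -> str:
    """Sample id convention for per-sample caller files: the stem up to the
    first dot (``S01.arriba.tsv`` -> ``S01``)."""
    return Path(path).name.split(".")[0]


def read_arriba(
    path,
    retention: Iterable[str] = ARRIBA_RETAIN_DEFAULT,
    sample_id: Optional[str] = None,
    provenance: Optional[dict] = None,
) -> list[FusionEvent]:
    """Read an Arriba-style fusions TSV, keeping retained confidence levels.

    By default only ``high``-confidence rows are kept; discarded-row counts
    are recorded in ``provenance`` when a dict is supplied.
    """
    retention = {str(r).lower() for r in retention}
    sample_id = sample_id or infer_sample_id(path)
    df = _read_table(path, sep="\t")
    _require(df, ["gene1", "gene2", "confidence"], path)
    events, discarded = [], 0
    for _, row in df.iterrows():
        if str(row["confidence"]).strip().lower() not in retention:
            discarded += 1
            continue
        junction = None
        if "split_reads1" in df.columns and "split_reads2" in df.columns:
            junction = (_opt_int(row["split_reads1"]) or 0) + (_opt_int(row["split_reads2"]) or 0)
        spanning = _opt_int(row["discordant_mates"]) if "discordant_mates" in df.columns else None
        events.append(
            FusionEvent(
                sample_id=sample_id,
                caller=Caller.ARR,
                partners=(_first_symbol(row["gene1"]), _first_symbol(row["gene2"])),
                junction_reads=junction,
                spanning_reads=spanning,
            )
        )
    if provenance is not None:
        provenance.setdefault("arriba_discarded", 0)
        provenance["arriba_discarded"] += discarded
        provenance.setdefault("files", []).append(str(path))
    return events


def read_star_fusion(
    path,
    retention: Iterable[str] = STAR_FUSION_RETAIN_DEFAULT,
    sample_id: Optional[str] = None,
    provenance: Optional[dict] = None,
) -> list[FusionEvent]:
    """Read a STAR-Fusion abridged predictions TSV.

    Rows are kept when their large-anchor-support label is in ``retention``
    (default: the affirmative ``YES_LDAS``).  Partners are split on the
    double hyphen so hyphenated locus names survive intact.
    """
    retention = {str(r) for r in retention}
    sample_id = sample_id or infer_sample_id(path)
    df = _read_table(path, sep="\t")
    _require(df, ["FusionName", "JunctionReadCount", "SpanningFragCount", "LargeAnchorSupport"], path)
    events, discarded = [], 0
    for _, row in df.iterrows():
        if str(row["LargeAnchorSupport"]).strip() not in retention:
            discarded += 1
            continue
        partners = tuple(p for p in str(row["FusionName"]).split("--") if p)
        if len(partners) < 2:
            raise FormatError(f"{path}: FusionName {row['FusionName']!r} lacks a '--' separator")
        events.append(
            FusionEvent(
                sample_id=sample_id,
                caller=Caller.SFU,
                partners=partners,
                junction_reads=_opt_int(row["JunctionReadCount"]),
                spanning_reads=_opt_int(row["SpanningFragCount"]),
            )
        )
    if provenance is not None:
        provenance.setdefault("star_fusion_discarded", 0)
        provenance["star_fusion_discarded"] += discarded
        provenance.setdefault("files", []).append(str(path))
    return events


def read_harmonized_calls(
    path,
    retention: Optional[dict] = None,
    provenance: Optional[dict] = None,
) -> list[FusionEvent]:
    """Read the harmonized-calls CSV; one event per retained row.

    Result strings go through :func:`~fusionbench.core.classify_event`, so a
    row may describe a fusion, an exon skipping or an intragenic deletion.
    Retention is per caller on the (case-insensitive) confidence value.
    """
    keep = dict(HARMONIZED_RETAIN_DEFAULT)
    if retention:
        keep.update({Caller(k): frozenset(v) for k, v in retention.items()})
    df = _read_table(path, sep=",")
    _require(df, ["sample_id", "caller", "result", "confidence"], path)
    events, discarded = [], 0
    for idx, row in df.iterrows():
        caller = Caller(str(row["caller"]).strip())
        if str(row["confidence"]).strip().lower() not in {c.lower() for c in keep[caller]}:
            discarded += 1
            continue
        try:
            cls = classify_event(row["result"])
        except Exception as exc:
            raise FormatError(f"{path} row {idx + 2}: {exc}") from exc
        events.append(
            FusionEvent(
                sample_id=str(row["sample_id"]).strip(),
                caller=caller,
                partners=cls.partners,
                event_class=cls.event_class,
                detail=cls.detail,
                junction_reads=_opt_int(row.get("junction_reads", "")),
                spanning_reads=_opt_int(row.get("spanning_reads", "")),
            )
        )
    if provenance is not None:
        provenance.setdefault("harmonized_discarded", 0)
        provenance["harmonized_discarded"] += discarded
        provenance.setdefault("files", []).append(str(path))
    return events


MANIFEST_COLUMNS = ["sample_id", "patient_id", "panel", "specimen", "qc_status", "total_reads", "histology"]
ASSAY_COLUMNS = ["sample_id", "modality", "genes", "outcome"]
CALLS_COLUMNS = ["sample_id", "caller", "result", "confidence", "junction_reads", "spanning_reads"]


def read_manifest(path) -> list[SampleRecord]:
    df = _read_table(path, sep="\t")
    _require(df, MANIFEST_COLUMNS[:-1], path)
    return [
        SampleRecord(
            sample_id=row["sample_id"],
            patient_id=row["patient_id"],
            panel=Panel(row["panel"]),
            specimen=Specimen(row["specimen"]),
            qc_status=QCStatus(row["qc_status"]),
            total_reads=int(row["total_reads"]),
            histology=row.get("histology", ""),
        )
        for _, row in df.iterrows()
    ]


def read_assays(path) -> list[OrthogonalAssay]:
    df = _read_table(path, sep=",")
    _require(df, ASSAY_COLUMNS, path)
    return [
        OrthogonalAssay(
            sample_id=row["sample_id"],
            modality=AssayModality(row["modality"]),
            genes=tuple(g for g in row["genes"].split(";") if g),
            outcome=AssayOutcome(row["outcome"]),
        )
        for _, row in df.iterrows()
    ]


def read_cohort(manifest_path, calls_paths: Sequence, assays_path=None) -> Cohort:
    """Assemble and validate a :class:`Cohort` from on-disk tables.

    ``calls_paths`` are harmonized-calls CSVs; referential-integrity
    violations (events or assays naming unknown samples) are hard errors.
    """
    provenance: dict = {"manifest": str(manifest_path)}
    samples = read_manifest(manifest_path)
    events: list[FusionEvent] = []
    for p in calls_paths:
        events.extend(read_harmonized_calls(p, provenance=provenance))
    assays = read_assays(assays_path) if assays_path else []
    return Cohort(samples=samples, events=events, assays=assays, provenance=provenance).validate()


# ---------------------------------------------------------------------------
# Serialization helpers (stable column order, Unix newlines)
# ---------------------------------------------------------------------------

def _write_rows(path, header: Sequence[str], rows: Iterable[Sequence], sep: str) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter=sep, lineterminator="\n")
        writer.writerow(header)
        writer.writerows(rows)


def write_manifest(samples: Sequence[SampleRecord], path) -> None:
    _write_rows(
        path,
        MANIFEST_COLUMNS,
        [
            (s.sample_id, s.patient_id, s.panel.value, s.specimen.value,
             s.qc_status.value, s.total_reads, s.histology)
            for s in samples
        ],
        sep="\t",
    )


def write_assays(assays: Sequence[OrthogonalAssay], path) -> None:
    _write_rows(
        path,
        ASSAY_COLUMNS,
        [(a.sample_id, a.modality.value, ";".join(a.genes), a.outcome.value) for a in assays],
        sep=",",
    )


def _event_result_string(event: FusionEvent) -> str:
    if event.event_class is EventClass.FUSION:
        return "-".join(event.partners)
    if event.event_class is EventClass.INTRAGENIC_DELETION:
        return f"{event.partners[0]} deletion ({event.detail})"
    span = event.detail.removeprefix("exon ")
    return f"{event.partners[0]} exon {span} skipping"


def write_harmonized_calls(events: Sequence[FusionEvent], path) -> None:
    """Write events in the harmonized-calls CSV dialect (retained confidence
    labels per caller, so a round trip through the default reader keeps all
    of them)."""
    conf = {Caller.REF: "high", Caller.ARR: "high", Caller.SFU: "large"}
    _write_rows(
        path,
        CALLS_COLUMNS,
        [
            (e.sample_id, e.caller.value, _event_result_string(e), conf[e.caller],
             "" if e.junction_reads is None else e.junction_reads,
             "" if e.spanning_reads is None else e.spanning_reads)
            for e in events
        ],
        sep=",",
    )


# ---------------------------------------------------------------------------
# Study fixtures
# ---------------------------------------------------------------------------

def _sarcoma_samples() -> list[SampleRecord]:
    samples = []
    for n, histology, qc, _res, _fish in T.SARCOMA_ROWS:
        samples.append(
            SampleRecord(
                sample_id=T.sarcoma_sample_id(n),
                patient_id=f"SP{n:02d}",
                panel=Panel.SARCOMA,
                specimen=Specimen.SURGICAL if n % 2 == 0 else Specimen.CNB,
                qc_status=QCStatus(qc),
                total_reads=T.SARCOMA_READS[n],
                histology=histology,
            )
        )
    return samples


def _lung_samples() -> list[SampleRecord]:
    samples = []
    positive = {n: (h, res) for n, h, res, _ in T.LUNG_POSITIVE_ROWS}
    for n in [*positive, *T.LUNG_NEGATIVE_NUMBERS, *T.LUNG_NOT_EVALUABLE_NUMBERS]:
        histology = positive[n][0] if n in positive else "Lung adenocarcinoma"
        qc = QCStatus.NOT_EVALUABLE if n in T.LUNG_NOT_EVALUABLE_NUMBERS else QCStatus.PASS
        patient_n = T.LUNG_SHARED_PATIENT.get(n, n)
        samples.append(
            SampleRecord(
                sample_id=T.lung_sample_id(n),
                patient_id=f"LP{patient_n:03d}",
                panel=Panel.LUNG,
                specimen=Specimen.CNB if n % 3 else Specimen.SURGICAL,
                qc_status=qc,
                total_reads=T.LUNG_READS[n],
                histology=histology,
            )
        )
    return samples


def _events_from_results(sample_id: str, caller: Caller, results: Iterable[str]) -> list[FusionEvent]:
    events = []
    for j, res in enumerate(results):
        cls = classify_event(res)
        events.append(
            FusionEvent(
                sample_id=sample_id,
                caller=caller,
                partners=cls.partners,
                event_class=cls.event_class,
                detail=cls.detail,
                junction_reads=12 + 3 * j,
                spanning_reads=5 + 2 * j,
            )
        )
    return events


def _sarcoma_tables():
    ref, comparison, assays = [], [], []
    for n, _h, qc, results, fish in T.SARCOMA_ROWS:
        sid = T.sarcoma_sample_id(n)
        if qc == "pass":
            ref.extend(_events_from_results(sid, Caller.REF, results))
        for modality, genes, outcome in fish:
            assays.append(
                OrthogonalAssay(sid, AssayModality(modality), tuple(genes), AssayOutcome(outcome))
            )
    for n in sorted(T.SARCOMA_ARR):
        comparison.extend(_events_from_results(T.sarcoma_sample_id(n), Caller.ARR, T.SARCOMA_ARR[n]))
    for n in sorted(T.SARCOMA_SFU):
        comparison.extend(_events_from_results(T.sarcoma_sample_id(n), Caller.SFU, T.SARCOMA_SFU[n]))
    return ref, comparison, assays


def _lung_tables():
    ref, comparison, assays = [], [], []
    for n, _h, results, fish in T.LUNG_POSITIVE_ROWS:
        sid = T.lung_sample_id(n)
        ref.extend(_events_from_results(sid, Caller.REF, results))
        for modality, genes, outcome in fish:
            assays.append(
                OrthogonalAssay(sid, AssayModality(modality), tuple(genes), AssayOutcome(outcome))
            )
    for n, fish in sorted(T.LUNG_NEGATIVE_FISH.items()):
        sid = T.lung_sample_id(n)
        for modality, genes, outcome in fish:
            assays.append(
                OrthogonalAssay(sid, AssayModality(modality), tuple(genes), AssayOutcome(outcome))
            )
    for table, caller in (
        (T.LUNG_ARR_POSITIVE, Caller.ARR),
        (T.LUNG_ARR_NEGATIVE, Caller.ARR),
        (T.LUNG_SFU_POSITIVE, Caller.SFU),
        (T.LUNG_SFU_NEGATIVE, Caller.SFU),
    ):
        for n in sorted(table):
            comparison.extend(_events_from_results(T.lung_sample_id(n), caller, table[n]))
    return ref, comparison, assays


def build_fixtures(outdir) -> dict[str, Path]:
    """Write the transcribed two-panel study cohorts under ``outdir``.

    Emits, per panel, a manifest TSV, a reference-caller harmonized CSV, an
    ARR/SFU comparison harmonized CSV and an assay CSV.  Output is
    deterministic: re-running produces byte-identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    for panel, samples, (ref, comparison, assays) in (
        ("sarcoma", _sarcoma_samples(), _sarcoma_tables()),
        ("lung", _lung_samples(), _lung_tables()),
    ):
        paths[f"{panel}_manifest"] = outdir / f"{panel}_manifest.tsv"
        paths[f"{panel}_reference"] = outdir / f"{panel}_reference_calls.csv"
        paths[f"{panel}_comparison"] = outdir / f"{panel}_comparison_calls.csv"
        paths[f"{panel}_assays"] = outdir / f"{panel}_assays.csv"
        write_manifest(samples, paths[f"{panel}_manifest"])
        write_harmonized_calls(ref, paths[f"{panel}_reference"])
        write_harmonized_calls(comparison, paths[f"{panel}_comparison"])
        write_assays(assays, paths[f"{panel}_assays"])
    return paths


def load_fixture_cohort(fixture_dir, panel: Panel) -> Cohort:
    """Read one panel's fixture files back into a validated :class:`Cohort`."""
    d = Path(fixture_dir)
    name = panel.value
    return read_cohort(
        d / f"{name}_manifest.tsv",
        [d / f"{name}_reference_calls.csv", d / f"{name}_comparison_calls.csv"],
        d / f"{name}_assays.csv",
    )
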