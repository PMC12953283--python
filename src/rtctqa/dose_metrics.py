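"""Dose-report parsing and CT dose descriptors.

A dose report collects the irradiation events of one planning-CT study:
the topogram(s) used to set the scan range and the volumetric scan(s)
that deliver the bulk of the imaging dose.  Per volumetric event the
scanner reports CTDIvol (mGy, normalized to a 16 or 32 cm phantom), the
scanning length (mm) and the dose-length product DLP (mGy*cm).  The
effective dose E (mSv) is estimated as DLP times a body-region-specific
k-factor.

Input records use a documented JSON dialect whose field names mirror the
DICOM radiation-dose structured-report concept names (``CTDIvol``,
``DLP``, ``ScanningLength``); one report per line in a JSON-lines file.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd

from .sop_registry import KFactorTable, ProtocolMap

__all__ = [
    "DoseEvent",
    "DoseReport",
    "EffectiveDose",
    "DoseParseError",
    "parse_dose_report",
    "serialize_dose_report",
    "read_dose_reports",
    "write_dose_reports",
    "effective_dose",
    "dlp_consistency",
    "report_dlp",
    "dose_table",
]

TOPOGRAM = "topogram"
VOLUMETRIC = "volumetric"

#: default relative tolerance for the DLP ~= CTDIvol * length cross-check;
#: with tube-current modulation the reported CTDIvol is a mean over the
#: scan, so exact equality is not expected.
DLP_REL_TOL = 0.10


class DoseParseError(ValueError):
    """A dose-report record violated the documented schema."""


@dataclass(frozen=True)
class DoseEvent:
    """One irradiation event (topogram or volumetric scan)."""

    event_kind: str
    ctdi_vol: float  # mGy
    dlp: float  # mGy*cm
    scan_length_mm: float | None = None
    phantom_diameter_cm: int = 32
    kvp: float = 120.0
    timestamp: str | None = None

    def __post_init__(self) -> None:
        if self.event_kind not in (TOPOGRAM, VOLUMETRIC):
            raise DoseParseError(f"invalid event kind {self.event_kind!r}")
        if self.ctdi_vol < 0:
            raise DoseParseError("CTDIvol must be >= 0")
        if self.dlp < 0:
            raise DoseParseError("DLP must be >= 0")
        if self.event_kind == VOLUMETRIC:
            if self.scan_length_mm is None or not self.scan_length_mm > 0:
                raise DoseParseError(
                    "volumetric events require ScanningLength > 0"
                )
        if self.phantom_diameter_cm not in (16, 32):
            raise DoseParseError(
                f"phantom diameter must be 16 or 32 cm, got "
                f"{self.phantom_diameter_cm}"
            )


@dataclass(frozen=True)
class DoseReport:
    """All irradiation events of one study, with protocol resolution."""

    patient_pseudo_id: str
    protocol_name: str
    group: str
    modality: str
    study_date: str  # ISO date
    events: tuple[DoseEvent, ...]
    extras: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.events:
            raise DoseParseError("a dose report must contain >= 1 event")

    @property
    def volumetric_events(self) -> tuple[DoseEvent, ...]:
        return tuple(e for e in self.events if e.event_kind == VOLUMETRIC)


@dataclass(frozen=True)
class EffectiveDose:
    """DLP-derived effective-dose estimate for one body region."""

    value_msv: float
    k_used: float
    region: str


_KNOWN_REPORT_FIELDS = {
    "PatientPseudoID",
    "ProtocolName",
    "StudyDate",
    "Events",
}
_EVENT_FIELDS = {
    "EventKind": "event_kind",
    "CTDIvol": "ctdi_vol",
    "DLP": "dlp",
    "ScanningLength": "scan_length_mm",
    "PhantomDiameter": "phantom_diameter_cm",
    "KVP": "kvp",
    "Timestamp": "timestamp",
}


def parse_dose_report(record: Mapping | str, protocol_map: ProtocolMap) -> DoseReport:
    """Parse one JSON dose-report record into a validated :class:`DoseReport`.

    Unknown top-level fields are preserved in the report's ``extras`` bag.

    Raises
    ------
    DoseParseError
        On schema violations, naming the offending field.
    KeyError
        When the protocol name resolves to no body-region group.
    """
    if isinstance(record, str):
        record = json.loads(record)
    for fieldname in ("PatientPseudoID", "ProtocolName", "StudyDate", "Events"):
        if fieldname not in record:
            raise DoseParseError(f"missing field {fieldname!r}")
    events = []
    for i, ev in enumerate(record["Events"]):
        kwargs = {}
        for src, dst in _EVENT_FIELDS.items():
            if src in ev:
                kwargs[dst] = ev[src]
        try:
            events.append(DoseEvent(**kwargs))
        except (DoseParseError, TypeError) as exc:
            raise DoseParseError(f"Events[{i}]: {exc}") from None
    group, modality = protocol_map.resolve(str(record["ProtocolName"]))
    extras = {k: v for k, v in record.items() if k not in _KNOWN_REPORT_FIELDS}
    return DoseReport(
        patient_pseudo_id=str(record["PatientPseudoID"]),
        protocol_name=str(record["ProtocolName"]),
        group=group,
        modality=modality,
        study_date=str(record["StudyDate"]),
        events=tuple(events),
        extras=extras,
    )


def serialize_dose_report(report: DoseReport) -> dict:
    """Inverse of :func:`parse_dose_report` (extras are written back)."""
    events = []
    for ev in report.events:
        out = {
            "EventKind": ev.event_kind,
            "CTDIvol": ev.ctdi_vol,
            "DLP": ev.dlp,
            "PhantomDiameter": ev.phantom_diameter_cm,
            "KVP": ev.kvp,
        }
        if ev.scan_length_mm is not None:
            out["ScanningLength"] = ev.scan_length_mm
        if ev.timestamp is not None:
            out["Timestamp"] = ev.timestamp
        events.append(out)
    doc = {
        "PatientPseudoID": report.patient_pseudo_id,
        "ProtocolName": report.protocol_name,
        "StudyDate": report.study_date,
        "Events": events,
    }
    doc.update(report.extras)
    return doc


def read_dose_reports(
    path: str | Path, protocol_map: ProtocolMap
) -> Iterator[DoseReport]:
    """Iterate dose reports from a JSON-lines file."""
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                yield parse_dose_report(json.loads(line), protocol_map)


def write_dose_reports(reports: Iterable[DoseReport], path: str | Path) -> None:
    with open(path, "w") as fh:
        for report in reports:
            fh.write(json.dumps(serialize_dose_report(report)) + "\n")


def effective_dose(dlp: float, region: str, k: KFactorTable) -> EffectiveDose:
    """Estimate effective dose E = DLP * k(region).

    Parameters
    ----------
    dlp : float
        Dose-length product in mGy*cm.
    region : str
        Body region; must be present in the k-factor table.
    """
    factor = k.k(region)
    return EffectiveDose(value_msv=dlp * factor, k_used=factor, region=region)


def dlp_consistency(event: DoseEvent, rel_tol: float = DLP_REL_TOL) -> "QAFinding":
    """Cross-check DLP against CTDIvol * scan length.

    DLP should equal CTDIvol (mGy) times the irradiated length (cm).
    With tube-current modulation the reported CTDIvol is a scan mean, so
    deviations up to ``rel_tol`` are tolerated.  Topogram events are not
    applicable.
    """
    from .qa_battery import QAFinding  # local import to avoid a cycle

    if event.event_kind != VOLUMETRIC:
        return QAFinding(
            check_id="dlp_consistency",
            status="not_applicable",
            details={"reason": "topogram event"},
            message="DLP consistency applies to volumetric events only",
        )
    expected = event.ctdi_vol * event.scan_length_mm / 10.0
    denom = max(event.dlp, 1e-9)
    rel_dev = abs(event.dlp - expected) / denom
    status = "flag" if rel_dev > rel_tol else "pass"
    return QAFinding(
        check_id="dlp_consistency",
        status=status,
        details={
            "dlp": event.dlp,
            "expected_dlp": expected,
            "relative_deviation": rel_dev,
            "rel_tol": rel_tol,
        },
        message=(
            f"DLP {event.dlp:.1f} vs CTDIvol*L {expected:.1f} mGy*cm "
            f"({100 * rel_dev:.1f}% deviation)"
        ),
    )


def report_dlp(report: DoseReport) -> float:
    """Total DLP of a report: volumetric events only (topograms excluded)."""
    return float(sum(e.dlp for e in report.volumetric_events))


def dose_table(
    reports: Iterable[DoseReport], kfactors: KFactorTable
) -> pd.DataFrame:
    """Per-volumetric-event dose descriptor table.

    Columns: pseudo_id, date, group, modality, protocol, ctdi_vol,
    scan_length_mm, dlp, effective_dose_msv.  One row per volumetric
    event; aggregation across events is left to the trend layer.
    """
    rows = []
    for report in reports:
        for ev in report.volumetric_events:
            rows.append(
                {
                    "pseudo_id": report.patient_pseudo_id,
                    "date": report.study_date,
                    "group": report.group,
                    "modality": report.modality,
                    "protocol": report.protocol_name,
                    "ctdi_vol": ev.ctdi_vol,
                    "scan_length_mm": ev.scan_length_mm,
                    "dlp": ev.dlp,
                    "effective_dose_msv": effective_dose(
                        ev.dlp, report.group, kfactors
                    ).value_msv,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "pseudo_id",
            "date",
            "group",
            "modality",
            "protocol",
            "ctdi_vol",
            "scan_length_mm",
            "dlp",
            "effective_dose_msv",
        ],
    )
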