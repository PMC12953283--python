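"""Rule-based protocol-adherence checks.

Each check is a pure function of its inputs and emits a
:class:`QAFinding` with status ``pass``, ``flag`` or ``not_applicable``
plus machine-readable details.  The battery covers:

* contrast-agent application (volume extraction; cohort rates are
  aggregated downstream),
* metal detection by HU thresholding (> 4000 HU) versus use of iterative
  metal-artifact reduction (iMAR) in the reconstruction,
* topogram length versus volumetric scan length,
* the institutional 399-slice limit imposed by an image-guidance system,
* breathing-phase plausibility via lung volumes across scans,
* bladder filling classification (empty < 200 mL, partially filled
  200-400 mL, full > 400 mL) against the protocol's expectation,
* misapplication of the thorax protocol to abdominal anatomy (cranial
  end > 10 cm too low AND caudal end > 10 cm too long),
* field-of-view truncation at the upper reconstruction-circle edge, with
  detection of extended-FOV (HDFoV) reconstructions.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .landmark_engine import DeltaResult, LabelMap

__all__ = [
    "ScanRecord",
    "QAFinding",
    "check_contrast",
    "check_metal_imar",
    "check_topogram",
    "check_slice_count",
    "check_breathing_phase",
    "check_bladder_filling",
    "check_misapplied_thorax",
    "check_fov_truncation",
    "lung_volume_ml",
    "bladder_volume_ml",
    "run_battery",
]

HU_METAL_THRESHOLD = 4000.0
SLICE_LIMIT = 399
BLADDER_EMPTY_ML = 200.0
BLADDER_FULL_ML = 400.0
MISAPPLIED_THORAX_MM = 100.0
AIR_HU = -500.0
HDFOV_PAD_HU = -1024.0  # padding sentinel outside the reconstruction circle
IMAR_TOKEN = "imar"

#: breathing-phase plausibility ranks: higher rank must show larger lungs
BREATHING_RANK = {"expiration": 0, "free": 1, "inspiration": 2, "DIBH": 2}

#: expected bladder state by protocol family (substring on protocol name)
BLADDER_EXPECTATIONS = {
    "bladder": "empty",
    "blase": "empty",
    "prostat": "filled",
    "rect": "filled",
    "rekt": "filled",
    "anal": "filled",
    "cervix": "filled",
    "zervix": "filled",
}


@dataclass(frozen=True)
class QAFinding:
    """Outcome of one QA check."""

    check_id: str
    status: str  # pass | flag | not_applicable | error
    details: Mapping[str, object] = field(default_factory=dict)
    message: str = ""

    def __post_init__(self) -> None:
        if self.status not in ("pass", "flag", "not_applicable", "error"):
            raise ValueError(f"invalid finding status {self.status!r}")
        if self.status == "not_applicable" and "reason" not in self.details:
            raise ValueError("not_applicable findings must state a reason")


@dataclass
class ScanRecord:
    """Per-scan metadata consumed by the QA battery."""

    pseudo_id: str
    group: str
    protocol_name: str
    study_date: str
    slice_count: int
    slice_thickness_mm: float
    volumetric_length_mm: float
    topogram_length_mm: float | None = None
    contrast_volume_ml: float | None = None
    recon_description: str = ""
    breathing_label: str | None = None  # free | inspiration | expiration | DIBH
    fov: str = "standard"  # standard | HDFoV
    fov_radius_mm: float | None = None
    label_map: LabelMap | None = None
    image: np.ndarray | None = None  # HU volume, same grid as label_map
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.slice_count < 1:
            raise ValueError("slice_count must be >= 1")
        if not self.volumetric_length_mm > 0:
            raise ValueError("volumetric length must be > 0")
        if self.topogram_length_mm is not None and not self.topogram_length_mm > 0:
            raise ValueError("topogram length must be > 0 when present")


def _na(check_id: str, reason: str) -> QAFinding:
    return QAFinding(
        check_id=check_id,
        status="not_applicable",
        details={"reason": reason},
        message=reason,
    )


def check_contrast(rec: ScanRecord) -> QAFinding:
    """Record whether and how much contrast agent was applied."""
    volume = rec.contrast_volume_ml
    if volume is not None and volume < 0:
        return QAFinding(
            check_id="contrast",
            status="flag",
            details={"applied": True, "volume_ml": volume},
            message=f"negative contrast volume {volume} mL",
        )
    applied = volume is not None
    return QAFinding(
        check_id="contrast",
        status="pass",
        details={"applied": applied, "volume_ml": volume},
        message=(
            f"contrast applied: {volume} mL" if applied else "no contrast recorded"
        ),
    )


def check_metal_imar(
    image: np.ndarray | None,
    rec: ScanRecord,
    hu_threshold: float = HU_METAL_THRESHOLD,
) -> QAFinding:
    """Flag scans containing metal (HU > threshold) reconstructed without iMAR."""
    if image is None:
        return _na("metal_imar", "no image volume available")
    metal = bool(np.any(np.asarray(image) > hu_threshold))
    imar = IMAR_TOKEN in rec.recon_description.lower()
    status = "flag" if metal and not imar else "pass"
    return QAFinding(
        check_id="metal_imar",
        status=status,
        details={"metal": metal, "imar": imar, "hu_threshold": hu_threshold},
        message=(
            "metal present without iMAR reconstruction"
            if status == "flag"
            else f"metal={metal}, imar={imar}"
        ),
    )


def check_topogram(rec: ScanRecord) -> QAFinding:
    """Flag volumetric scans extending beyond the planning topogram."""
    if rec.topogram_length_mm is None:
        return _na("topogram", "no topogram recorded")
    short = rec.topogram_length_mm < rec.volumetric_length_mm
    return QAFinding(
        check_id="topogram",
        status="flag" if short else "pass",
        details={
            "topogram_length_mm": rec.topogram_length_mm,
            "volumetric_length_mm": rec.volumetric_length_mm,
        },
        message=(
            "volumetric scan exceeds topogram length"
            if short
            else "topogram covers the volumetric scan"
        ),
    )


def check_slice_count(rec: ScanRecord, limit: int = SLICE_LIMIT) -> QAFinding:
    """Enforce the institutional slice-count limit (compliant iff <= limit)."""
    over = rec.slice_count > limit
    return QAFinding(
        check_id="slice_count",
        status="flag" if over else "pass",
        details={"slice_count": rec.slice_count, "limit": limit},
        message=(
            f"{rec.slice_count} slices exceed the {limit}-slice limit"
            if over
            else f"{rec.slice_count} slices within the {limit}-slice limit"
        ),
    )


def lung_volume_ml(label_map: LabelMap, lung_structures: Sequence[str]) -> float:
    """Total lung volume (mL) = labelled voxel count x voxel volume."""
    name_to_id = {v: k for k, v in label_map.label_names.items()}
    ids = [name_to_id[s] for s in lung_structures if s in name_to_id]
    if not ids:
        return 0.0
    voxel_ml = abs(float(np.linalg.det(label_map.affine[:3, :3]))) / 1000.0
    count = int(np.isin(label_map.grid, ids).sum())
    return count * voxel_ml


def check_breathing_phase(
    scans: Sequence[tuple[ScanRecord, float]], min_ratio: float = 0.0
) -> QAFinding:
    """Check lung-volume plausibility across breathing phases.

    Requires at least two scans with distinct breathing labels.  The
    expected ordering is inspiration/DIBH > free > expiration; a pair
    violating it by more than ``min_ratio`` (relative to the larger
    volume) is flagged.
    """
    labelled = [
        (rec, vol)
        for rec, vol in scans
        if rec.breathing_label in BREATHING_RANK and vol > 0
    ]
    distinct = {rec.breathing_label for rec, _ in labelled}
    if len(distinct) < 2:
        return _na(
            "breathing_phase",
            "requires >= 2 scans in different breathing modes",
        )
    violations = []
    for i, (rec_a, vol_a) in enumerate(labelled):
        for rec_b, vol_b in labelled[i + 1 :]:
            rank_a = BREATHING_RANK[rec_a.breathing_label]
            rank_b = BREATHING_RANK[rec_b.breathing_label]
            if rank_a == rank_b:
                continue
            hi, lo = ((vol_a, vol_b) if rank_a > rank_b else (vol_b, vol_a))
            if (lo - hi) / max(lo, hi) > min_ratio:
                violations.append(
                    {
                        "labels": sorted(
                            [rec_a.breathing_label, rec_b.breathing_label]
                        ),
                        "volumes_ml": [vol_a, vol_b],
                    }
                )
    return QAFinding(
        check_id="breathing_phase",
        status="flag" if violations else "pass",
        details={"n_scans": len(labelled), "violations": violations},
        message=(
            f"{len(violations)} breathing-phase ordering violation(s)"
            if violations
            else "lung volumes consistent with breathing labels"
        ),
    )


def bladder_volume_ml(label_map: LabelMap) -> float | None:
    """Urinary-bladder volume in mL, or None when not segmented."""
    name_to_id = {v: k for k, v in label_map.label_names.items()}
    if "urinary_bladder" not in name_to_id:
        return None
    voxel_ml = abs(float(np.linalg.det(label_map.affine[:3, :3]))) / 1000.0
    count = int((label_map.grid == name_to_id["urinary_bladder"]).sum())
    vol = count * voxel_ml
    return vol if count > 0 else None


def classify_bladder(volume_ml: float, low: float = BLADDER_EMPTY_ML,
                     high: float = BLADDER_FULL_ML) -> str:
    """Filling state: empty < low, full > high, else partially filled."""
    if volume_ml < low:
        return "empty"
    if volume_ml > high:
        return "full"
    return "partially_filled"


def check_bladder_filling(
    label_map: LabelMap | None,
    rec: ScanRecord,
    low: float = BLADDER_EMPTY_ML,
    high: float = BLADDER_FULL_ML,
    expectations: Mapping[str, str] = BLADDER_EXPECTATIONS,
) -> QAFinding:
    """Classify bladder filling and compare with the protocol expectation.

    Bladder protocols expect an empty bladder; other pelvic protocols
    (prostate, rectum, anal, cervix) expect a non-empty one.  Protocols
    without an expectation, or scans without a segmented bladder, are
    not applicable.
    """
    lowered = rec.protocol_name.lower()
    expected = next(
        (state for token, state in expectations.items() if token in lowered), None
    )
    if expected is None:
        return _na("bladder_filling", "protocol has no bladder expectation")
    if label_map is None:
        return _na("bladder_filling", "no label map available")
    volume = bladder_volume_ml(label_map)
    if volume is None:
        return _na("bladder_filling", "bladder not segmented")
    state = classify_bladder(volume, low, high)
    if expected == "empty":
        ok = state == "empty"
    else:  # filled: partially filled counts as acceptable
        ok = state != "empty"
    return QAFinding(
        check_id="bladder_filling",
        status="pass" if ok else "flag",
        details={
            "volume_ml": volume,
            "state": state,
            "expected": expected,
            "low_ml": low,
            "high_ml": high,
        },
        message=f"bladder {state} ({volume:.0f} mL), expected {expected}",
    )


def check_misapplied_thorax(
    delta: DeltaResult, threshold_mm: float = MISAPPLIED_THORAX_MM
) -> QAFinding:
    """Detect the thorax protocol applied to abdominal anatomy.

    Flagged when the cranial end is more than ``threshold_mm`` below the
    intended thorax coverage (delta_top < -threshold) AND the caudal end
    more than ``threshold_mm`` beyond it (delta_bot > +threshold); both
    conditions are strict inequalities and both are required.
    """
    if delta.delta_top is None or delta.delta_bot is None:
        return _na("misapplied_thorax", "scan-range deltas unavailable")
    flagged = delta.delta_top < -threshold_mm and delta.delta_bot > threshold_mm
    return QAFinding(
        check_id="misapplied_thorax",
        status="flag" if flagged else "pass",
        details={
            "delta_top_mm": delta.delta_top,
            "delta_bot_mm": delta.delta_bot,
            "threshold_mm": threshold_mm,
        },
        message=(
            "scan range suggests thorax protocol applied to abdomen"
            if flagged
            else "scan range consistent with intended coverage"
        ),
    )


def check_fov_truncation(
    image: np.ndarray | None,
    rec: ScanRecord,
    air_hu: float = AIR_HU,
    pad_hu: float = HDFOV_PAD_HU,
    n_angles: int = 90,
) -> QAFinding:
    """Detect anatomy truncated at the reconstruction-circle edge.

    Samples voxels just inside the upper half of the standard
    reconstruction circle on every slice; any HU above ``air_hu`` there
    means the patient's skin reaches the field-of-view edge.  The four
    corner regions outside the circle are probed for non-padding values
    to detect an extended-FOV (HDFoV) reconstruction; truncation without
    HDFoV is flagged.

    The image grid must match ``rec.label_map``'s geometry (axes ordered
    x, y, z with in-plane spacing from the affine).
    """
    if image is None or rec.fov_radius_mm is None or rec.label_map is None:
        return _na("fov_truncation", "image volume or FOV geometry missing")
    image = np.asarray(image)
    affine = rec.label_map.affine
    nx, ny, nz = image.shape
    dx = abs(float(affine[0, 0])) or 1.0
    dy = abs(float(affine[1, 1])) or 1.0
    cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0
    # sample a ring one voxel inside the circle, upper (anterior) half
    r_vox_x = rec.fov_radius_mm / dx - 1.0
    r_vox_y = rec.fov_radius_mm / dy - 1.0
    angles = np.linspace(0.0, np.pi, n_angles)
    ix = np.clip(np.round(cx + r_vox_x * np.cos(angles)), 0, nx - 1).astype(int)
    iy = np.clip(np.round(cy + r_vox_y * np.sin(angles)), 0, ny - 1).astype(int)
    edge_samples = image[ix, iy, :]
    truncation = bool(np.any(edge_samples > air_hu))

    # corner probes strictly outside the standard reconstruction circle
    corner = max(1, int(round(0.05 * min(nx, ny))))
    corners = np.concatenate(
        [
            image[:corner, :corner, :].ravel(),
            image[:corner, -corner:, :].ravel(),
            image[-corner:, :corner, :].ravel(),
            image[-corner:, -corner:, :].ravel(),
        ]
    )
    hdfov_used = bool(np.any(corners > pad_hu + 0.5))

    status = "flag" if truncation and not hdfov_used else "pass"
    return QAFinding(
        check_id="fov_truncation",
        status=status,
        details={
            "truncation": truncation,
            "hdfov_used": hdfov_used,
            "air_hu": air_hu,
            "fov_radius_mm": rec.fov_radius_mm,
        },
        message=(
            "anatomy truncated at the FOV edge without HDFoV"
            if status == "flag"
            else f"truncation={truncation}, hdfov_used={hdfov_used}"
        ),
    )


def run_battery(
    rec: ScanRecord,
    delta: DeltaResult | None = None,
    dose_event=None,
    options: Mapping[str, object] | None = None,
) -> list[QAFinding]:
    """Run all per-scan checks in a deterministic order.

    A failing check never aborts the battery; its exception is converted
    into an ``error``-status finding.  The cohort-level breathing-phase
    check is run separately (it needs several scans).
    """
    options = dict(options or {})
    checks = [
        ("contrast", lambda: check_contrast(rec)),
        (
            "metal_imar",
            lambda: check_metal_imar(
                rec.image, rec, options.get("hu_threshold", HU_METAL_THRESHOLD)
            ),
        ),
        ("topogram", lambda: check_topogram(rec)),
        (
            "slice_count",
            lambda: check_slice_count(rec, options.get("slice_limit", SLICE_LIMIT)),
        ),
        (
            "bladder_filling",
            lambda: check_bladder_filling(
                rec.label_map,
                rec,
                options.get("bladder_low_ml", BLADDER_EMPTY_ML),
                options.get("bladder_high_ml", BLADDER_FULL_ML),
            ),
        ),
        (
            "misapplied_thorax",
            lambda: (
                check_misapplied_thorax(
                    delta, options.get("misapplied_mm", MISAPPLIED_THORAX_MM)
                )
                if delta is not None and rec.group == "Thorax"
                else _na(
                    "misapplied_thorax",
                    "requires deltas against the thorax SOP",
                )
            ),
        ),
        (
            "fov_truncation",
            lambda: check_fov_truncation(
                rec.image, rec, options.get("air_hu", AIR_HU)
            ),
        ),
    ]
    if dose_event is not None:
        from .dose_metrics import dlp_consistency

        checks.append(("dlp_consistency", lambda: dlp_consistency(dose_event)))

    findings = []
    for check_id, fn in checks:
        try:
            findings.append(fn())
        except Exception as exc:  # noqa: BLE001 - battery must not abort
            findings.append(
                QAFinding(
                    check_id=check_id,
                    status="error",
                    details={"exception": repr(exc)},
                    message=f"check raised {type(exc).__name__}",
                )
            )
    return findings
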