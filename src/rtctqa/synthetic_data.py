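"""Stylized voxel phantoms with known ground truth.

The generator builds a cranio-caudal stack of simple solids — skull,
the full vertebral column C1-L5 with per-segment lengths (defaulting to
the VB-LUT reference values, optionally jittered to emulate anatomical
variability), lungs, liver, urinary bladder and hips — plus a matching
HU image (soft tissue 40, lung -800, bone 700, air -1000, metal 8000)
and the scan metadata/dose report a clinical study would carry.

The scan range is chosen so that the true cranial/caudal deviations
from the body region's SOP boundaries equal the requested
over-coverage: the caudal scan face sits exactly at the requested
boundary and the cranial face absorbs the (sub-slice) quantization of
the slice grid.  Everything the QA pipeline later measures — deltas,
bladder class, lung volume, metal, DLP — is therefore known exactly at
generation time and returned as :class:`GroundTruth`.

Anatomy is deliberately stylized (stacked slabs and ellipsoids): the QA
logic consumes only extents, volumes and HU ranges, so geometric realism
is unnecessary.  Soft organs are tied to (jittered) vertebral levels so
the SOP fallback chains stay anatomically consistent:

* lung: T1 cranial end .. T10 caudal end,
* liver: T10 cranial end .. L2 caudal end,
* hip: L3 caudal end, extending 180 mm caudally,
* bladder: sphere just caudal of L5.
"""
from __future__ import annotations

import csv
import gzip
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, NamedTuple, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from .dose_metrics import DoseEvent, DoseReport, serialize_dose_report
from .landmark_engine import LabelMap
from .qa_battery import ScanRecord, classify_bladder
from .sop_registry import Registry, default_registry

__all__ = [
    "PhantomSpec",
    "GroundTruth",
    "PhantomData",
    "generate_phantom",
    "generate_cohort",
    "DEFAULT_PROTOCOLS",
    "DEFAULT_MIX",
]

SKULL_TOP_Z = 900.0  # construction origin (mm); arbitrary but fixed

HU_AIR = -1000.0
HU_SOFT = 40.0
HU_LUNG = -800.0
HU_BONE = 700.0
HU_METAL = 8000.0
HU_PAD = -1024.0  # outside the standard reconstruction circle

BONE_COLUMN = (
    ["skull"]
    + [f"vertebrae_C{i}" for i in range(1, 8)]
    + [f"vertebrae_T{i}" for i in range(1, 13)]
    + [f"vertebrae_L{i}" for i in range(1, 6)]
)
SOFT_STRUCTURES = [
    "lung_upper_lobe_left",
    "lung_lower_lobe_left",
    "lung_upper_lobe_right",
    "lung_lower_lobe_right",
    "liver",
    "urinary_bladder",
    "hip_left",
    "hip_right",
    "body",
]
#: stable structure -> label ID assignment
LABEL_IDS = {name: i + 1 for i, name in enumerate(BONE_COLUMN + SOFT_STRUCTURES)}

#: representative protocol names per body-region group (resolve through
#: the default protocol map)
DEFAULT_PROTOCOLS = {
    "Brain": ["Brain_3D", "Brain_STX"],
    "H&N": ["HN_3D"],
    "Thorax": ["Thorax_Lunge_3D", "Thorax_Mamma_3D"],
    "4D": ["Lunge_4D"],
    "Upper abdomen": ["Oberbauch_3D", "Leber_3D"],
    "Abdomen": ["Abdomen_3D", "Abdomen_Bladder_3D"],
    "Pelvis": ["Pelvis_Prostate_3D", "Pelvis_Rectum_3D", "Pelvis_Cervix_3D"],
    "Spine": ["Spine_3D"],
}

#: typical scanner-reported CTDIvol per group (mGy)
DEFAULT_CTDI = {
    "Brain": 73.0,
    "H&N": 56.0,
    "Thorax": 8.0,
    "4D": 25.0,
    "Upper abdomen": 10.0,
    "Abdomen": 13.0,
    "Pelvis": 14.0,
    "Spine": 60.0,
}

DEFAULT_MIX = {
    "Brain": 0.15,
    "H&N": 0.10,
    "Thorax": 0.20,
    "4D": 0.10,
    "Upper abdomen": 0.10,
    "Abdomen": 0.10,
    "Pelvis": 0.15,
    "Spine": 0.10,
}


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of one synthetic planning-CT acquisition."""

    group: str
    seed: int = 0
    slice_thickness_mm: float = 3.0
    structure_lengths: Mapping[str, float] | None = None  # default: VB-LUT
    length_jitter: float = 0.0  # uniform +/- fraction on segment lengths
    intended_overcoverage: tuple[float, float] = (20.0, 20.0)  # (top, bot) mm
    truncate: frozenset[str] = frozenset()  # structures omitted from labels
    bladder_volume_ml: float | None = 150.0
    metal: bool = False
    imar: bool = False
    breathing_scale: float = 1.0
    breathing_label: str | None = None
    ctdi_vol: float | None = None  # default: group-typical value
    in_plane_mm: float = 4.0
    grid_n: int = 64
    body_radius_mm: float = 110.0
    fov_radius_mm: float = 125.0
    hdfov: bool = False
    topogram_margin_mm: float | None = 20.0  # None -> no topogram
    protocol_name: str | None = None
    pseudo_id: str = "PSEUDO-0000"
    study_date: str = "2023-06-15"

    def __post_init__(self) -> None:
        if not self.slice_thickness_mm > 0:
            raise ValueError("slice_thickness_mm must be > 0")
        if self.structure_lengths is not None:
            for name, length in self.structure_lengths.items():
                if not length > 0:
                    raise ValueError(f"length for {name!r} must be > 0")
        if not 0 <= self.length_jitter < 0.5:
            raise ValueError("length_jitter must be in [0, 0.5)")


@dataclass(frozen=True)
class GroundTruth:
    """Planted quantities, exact by construction."""

    true_delta_top: float
    true_delta_bot: float
    true_bladder_class: str | None
    true_bladder_volume_ml: float | None
    true_metal: bool
    true_lung_volume_ml: float
    true_dlp: float
    sop_top_z: float
    sop_bot_z: float


class PhantomData(NamedTuple):
    label_map: LabelMap
    image: np.ndarray
    scan_record: ScanRecord
    dose_report: DoseReport
    ground_truth: GroundTruth


def _segment_lengths(spec: PhantomSpec, registry: Registry) -> dict[str, float]:
    lengths = {s: registry.vblut.length(s) for s in BONE_COLUMN}
    if spec.structure_lengths:
        lengths.update(spec.structure_lengths)
    if spec.length_jitter > 0:
        rng = np.random.default_rng(spec.seed + 101)
        for name in BONE_COLUMN:
            lengths[name] *= 1.0 + rng.uniform(-spec.length_jitter, spec.length_jitter)
    return lengths


def _stack_layout(lengths: Mapping[str, float]) -> dict[str, tuple[float, float]]:
    """(z_cranial, z_caudal) of every structure in construction space."""
    layout: dict[str, tuple[float, float]] = {}
    z = SKULL_TOP_Z
    for name in BONE_COLUMN:
        layout[name] = (z, z - lengths[name])
        z -= lengths[name]
    # soft organs anchored at the vertebral levels the SOP chains assume
    c7_top = layout["vertebrae_C7"][0]
    t10_top = layout["vertebrae_T10"][0]
    t12_bot = layout["vertebrae_T12"][1]
    l2_bot = layout["vertebrae_L2"][1]
    l3_bot = layout["vertebrae_L3"][1]
    l5_bot = layout["vertebrae_L5"][1]
    layout["lung"] = (c7_top, t12_bot)
    layout["liver"] = (t10_top, l2_bot)
    layout["hip"] = (l3_bot, l3_bot - 180.0)
    layout["bladder_top"] = (l5_bot - 10.0, l5_bot - 10.0)
    return layout


def _sop_boundaries(
    group: str, layout: Mapping[str, tuple[float, float]]
) -> tuple[float, float]:
    """True (z_top, z_bot) of the group's SOP anatomical FOV."""
    skull_top = layout["skull"][0]
    targets = {
        "Brain": (skull_top + 10.0, layout["vertebrae_C4"][1]),
        "H&N": (skull_top + 10.0, layout["lung"][1]),
        "Thorax": (layout["vertebrae_C1"][0], layout["liver"][1]),
        "4D": (layout["lung"][0], layout["lung"][1]),
        "Upper abdomen": (layout["vertebrae_T4"][0], layout["hip"][0]),
        "Abdomen": (layout["liver"][0] + 30.0, layout["hip"][1]),
        "Pelvis": (layout["liver"][0], layout["hip"][1] - 100.0),
        "Spine": (layout["vertebrae_C1"][0], layout["hip"][0]),
    }
    if group not in targets:
        raise ValueError(f"no phantom layout for group {group!r}")
    return targets[group]


def _disk(xx: np.ndarray, yy: np.ndarray, cx: float, cy: float, r: float) -> np.ndarray:
    return (xx - cx) ** 2 + (yy - cy) ** 2 <= r**2


def generate_phantom(
    spec: PhantomSpec, registry: Registry | None = None
) -> PhantomData:
    """Build one phantom acquisition with exact ground truth.

    Raises
    ------
    ValueError
        When the requested coverage falls outside the constructible
        anatomy stack, or the group is unknown.
    """
    registry = registry or default_registry()
    if spec.group not in registry.sops:
        raise ValueError(f"group {spec.group!r} not in SOP registry")
    lengths = _segment_lengths(spec, registry)
    layout = _stack_layout(lengths)
    sop_top, sop_bot = _sop_boundaries(spec.group, layout)

    over_top, over_bot = spec.intended_overcoverage
    t = spec.slice_thickness_mm
    z_bot = sop_bot - over_bot  # exact caudal face
    z_top_requested = sop_top + over_top
    n_slices = max(1, int(round((z_top_requested - z_bot) / t)))
    z_top = z_bot + n_slices * t

    body_bot = layout["hip"][1] - 250.0
    body_top = layout["skull"][0]
    if z_bot < body_bot or z_top > body_top + 300.0:
        raise ValueError("requested coverage lies outside the constructible stack")

    # --- in-plane geometry -------------------------------------------------
    n = spec.grid_n
    dxy = spec.in_plane_mm
    coords = (np.arange(n) - (n - 1) / 2.0) * dxy
    xx, yy = np.meshgrid(coords, coords, indexing="ij")
    body_mask = _disk(xx, yy, 0, 0, spec.body_radius_mm)
    lung_r = 32.0 * np.sqrt(spec.breathing_scale)
    lung_left = _disk(xx, yy, -52, -30, lung_r) & body_mask
    lung_right = _disk(xx, yy, 52, -30, lung_r) & body_mask
    liver_mask = _disk(xx, yy, 40, 45, 38.0) & body_mask & ~(lung_left | lung_right)
    bone_mask = _disk(xx, yy, 0, 0, 16.0)
    skull_mask = _disk(xx, yy, 0, 0, 75.0) & ~_disk(xx, yy, 0, 0, 55.0)
    hip_left_mask = _disk(xx, yy, -60, 10, 20.0)
    hip_right_mask = _disk(xx, yy, 60, 10, 20.0)
    fov_mask = _disk(xx, yy, 0, 0, spec.fov_radius_mm)

    bladder_r = None
    if spec.bladder_volume_ml is not None:
        bladder_r = (3.0 * spec.bladder_volume_ml * 1000.0 / (4.0 * np.pi)) ** (1 / 3)

    grid = np.zeros((n, n, n_slices), dtype=np.int16)
    image = np.full((n, n, n_slices), HU_AIR, dtype=np.float32)
    centers = z_bot + t / 2.0 + t * np.arange(n_slices)

    lung_mid = (layout["lung"][0] + layout["lung"][1]) / 2.0
    bladder_top = layout["bladder_top"][0]
    bladder_c = bladder_top - (bladder_r if bladder_r else 0.0)

    omit = spec.truncate

    def paint(k: int, mask: np.ndarray, name: str, hu: float) -> None:
        if name in omit:
            return
        grid[:, :, k][mask] = LABEL_IDS[name]
        image[:, :, k][mask] = hu

    for k, zc in enumerate(centers):
        if body_bot <= zc <= body_top:
            image[:, :, k][body_mask] = HU_SOFT
            grid[:, :, k][body_mask] = LABEL_IDS["body"]
        # lungs: upper/lower lobes split at mid-lung level
        if layout["lung"][1] <= zc < layout["lung"][0]:
            upper = zc >= lung_mid
            paint(k, lung_left, f"lung_{'upper' if upper else 'lower'}_lobe_left", HU_LUNG)
            paint(k, lung_right, f"lung_{'upper' if upper else 'lower'}_lobe_right", HU_LUNG)
        if layout["liver"][1] <= zc < layout["liver"][0]:
            paint(k, liver_mask, "liver", HU_SOFT)
        for name in BONE_COLUMN:
            hi, lo = layout[name]
            if lo <= zc < hi:
                paint(k, skull_mask if name == "skull" else bone_mask, name, HU_BONE)
                break
        if layout["hip"][1] <= zc < layout["hip"][0]:
            paint(k, hip_left_mask, "hip_left", HU_BONE)
            paint(k, hip_right_mask, "hip_right", HU_BONE)
        if bladder_r is not None:
            dz = zc - bladder_c
            if abs(dz) < bladder_r:
                r_slice = float(np.sqrt(bladder_r**2 - dz**2))
                paint(k, _disk(xx, yy, 0, 55, r_slice) & body_mask,
                      "urinary_bladder", HU_SOFT)

    if spec.metal:
        k0 = n_slices // 2
        i0 = int(n / 2 + 30.0 / dxy)
        j0 = int(n / 2 - 35.0 / dxy)
        image[i0 : i0 + 2, j0 : j0 + 2, k0 : k0 + 2] = HU_METAL

    # reconstruction circle: standard recon pads outside the FOV radius
    if not spec.hdfov:
        image[~fov_mask, :] = HU_PAD

    affine = np.diag([dxy, dxy, t, 1.0])
    affine[0, 3] = coords[0]
    affine[1, 3] = coords[0]
    affine[2, 3] = float(centers[0])
    label_names = {v: k for k, v in LABEL_IDS.items()}
    label_map = LabelMap(grid=grid, affine=affine, label_names=label_names)

    # --- ground truth ------------------------------------------------------
    voxel_ml = dxy * dxy * t / 1000.0
    lung_ids = [
        LABEL_IDS[s]
        for s in ("lung_upper_lobe_left", "lung_lower_lobe_left",
                  "lung_upper_lobe_right", "lung_lower_lobe_right")
    ]
    lung_volume = float(np.isin(grid, lung_ids).sum()) * voxel_ml
    bladder_volume = None
    bladder_class = None
    n_bladder = int((grid == LABEL_IDS["urinary_bladder"]).sum())
    if n_bladder > 0:
        bladder_volume = n_bladder * voxel_ml
        bladder_class = classify_bladder(bladder_volume)

    scan_length = z_top - z_bot
    ctdi = spec.ctdi_vol if spec.ctdi_vol is not None else DEFAULT_CTDI[spec.group]
    dlp = ctdi * scan_length / 10.0
    truth = GroundTruth(
        true_delta_top=z_top - sop_top,
        true_delta_bot=sop_bot - z_bot,
        true_bladder_class=bladder_class,
        true_bladder_volume_ml=bladder_volume,
        true_metal=spec.metal,
        true_lung_volume_ml=lung_volume,
        true_dlp=dlp,
        sop_top_z=sop_top,
        sop_bot_z=sop_bot,
    )

    # --- metadata ----------------------------------------------------------
    protocol = spec.protocol_name or DEFAULT_PROTOCOLS[spec.group][0]
    recon = "Br40s iMAR" if spec.imar else "Br40s"
    topo = (
        None
        if spec.topogram_margin_mm is None
        else scan_length + spec.topogram_margin_mm
    )
    record = ScanRecord(
        pseudo_id=spec.pseudo_id,
        group=spec.group,
        protocol_name=protocol,
        study_date=spec.study_date,
        slice_count=n_slices,
        slice_thickness_mm=t,
        volumetric_length_mm=scan_length,
        topogram_length_mm=topo,
        contrast_volume_ml=None,
        recon_description=recon,
        breathing_label=spec.breathing_label,
        fov="HDFoV" if spec.hdfov else "standard",
        fov_radius_mm=spec.fov_radius_mm,
        label_map=label_map,
        image=image,
    )
    events = []
    if topo is not None:
        events.append(
            DoseEvent(event_kind="topogram", ctdi_vol=0.1, dlp=0.5)
        )
    events.append(
        DoseEvent(
            event_kind="volumetric",
            ctdi_vol=ctdi,
            dlp=dlp,
            scan_length_mm=scan_length,
        )
    )
    report = DoseReport(
        patient_pseudo_id=spec.pseudo_id,
        protocol_name=protocol,
        group=spec.group,
        modality="EBRT",
        study_date=spec.study_date,
        events=tuple(events),
    )
    return PhantomData(label_map, image, record, report, truth)


# --------------------------------------------------------------------------
# cohort generation
# --------------------------------------------------------------------------

DEFECT_KINDS = (
    "truncation",
    "metal_no_imar",
    "short_topogram",
    "wrong_breathing",
    "misapplied_thorax",
)


def _write_nifti_gz(array: np.ndarray, affine: np.ndarray, path: Path) -> None:
    """Deterministic .nii.gz (gzip mtime pinned to 0)."""
    img = nib.Nifti1Image(np.asarray(array), affine)
    raw = img.to_bytes()
    path.write_bytes(gzip.compress(raw, mtime=0))


def generate_cohort(
    n: int,
    out_dir: str | Path,
    protocol_mix: Mapping[str, float] | None = None,
    defect_rates: Mapping[str, float] | None = None,
    date_range: tuple[str, str] = ("2021-04-01", "2024-12-31"),
    seed: int = 0,
    registry: Registry | None = None,
    length_jitter: float = 0.10,
    write_volumes: bool = True,
) -> pd.DataFrame:
    """Generate a synthetic cohort on disk with planted defects.

    Layout: ``<out>/<case id>/labels.nii.gz``, ``image.nii.gz`` and
    ``meta.json`` per case, plus cohort-level ``dose_reports.jsonl`` and
    ``ground_truth.csv``.  All randomness derives from ``seed``; two
    runs with the same arguments produce byte-identical outputs.

    Defects are planted independently per scan at the configured rates:
    truncated caudal coverage, metal without iMAR, topograms shorter
    than the volumetric scan, breathing-phase pairs in the wrong order
    (4D cases, which emit two scans) and the thorax protocol applied to
    abdominal coverage (Thorax cases only).

    Returns the ground-truth table.
    """
    registry = registry or default_registry()
    mix = dict(protocol_mix or DEFAULT_MIX)
    if n < 1:
        raise ValueError("n must be >= 1")
    total = sum(mix.values())
    if abs(total - 1.0) > 1e-6 or any(f < 0 for f in mix.values()):
        raise ValueError("protocol mix fractions must be >= 0 and sum to 1")
    unknown = [g for g in mix if g not in registry.sops]
    if unknown:
        raise ValueError(f"protocol mix contains unknown groups: {unknown}")
    rates = {k: 0.0 for k in DEFECT_KINDS}
    rates.update(defect_rates or {})
    bad = [k for k in rates if k not in DEFECT_KINDS]
    if bad:
        raise ValueError(f"unknown defect kinds: {bad}")

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    groups = sorted(mix)
    probs = np.array([mix[g] for g in groups])
    probs = probs / probs.sum()
    t0 = np.datetime64(date_range[0])
    t1 = np.datetime64(date_range[1])
    span_days = int((t1 - t0) / np.timedelta64(1, "D"))

    rows = []
    reports = []
    case_index = 0
    for case in range(n):
        group = str(rng.choice(groups, p=probs))
        names = DEFAULT_PROTOCOLS.get(group, [f"{group}_3D"])
        protocol = names[int(rng.integers(len(names)))]
        date = str(t0 + int(rng.integers(span_days + 1)))
        pseudo = f"PSEUDO-{case:05d}"
        planted = {
            kind: bool(rng.random() < rates[kind]) for kind in DEFECT_KINDS
        }
        planted["misapplied_thorax"] &= group == "Thorax"
        planted["wrong_breathing"] &= group == "4D"

        over_top = float(rng.uniform(6.0, 45.0))
        over_bot = float(rng.uniform(6.0, 45.0))
        if planted["truncation"]:
            over_bot = -float(rng.uniform(30.0, 60.0))
        if planted["misapplied_thorax"]:
            over_top = -115.0
            over_bot = float(rng.uniform(110.0, 150.0))

        # bladder: empty for bladder protocols, filled for other pelvic ones
        if "Bladder" in protocol:
            bladder = float(rng.uniform(80.0, 180.0))
        elif group == "Pelvis":
            bladder = float(rng.uniform(250.0, 550.0))
        else:
            bladder = float(rng.uniform(100.0, 300.0))

        metal = bool(rng.random() < 0.3) or planted["metal_no_imar"]
        imar = metal and not planted["metal_no_imar"]
        topo_margin = (
            -30.0 if planted["short_topogram"] else float(rng.uniform(10.0, 40.0))
        )
        ctdi = DEFAULT_CTDI[group] * float(rng.uniform(0.9, 1.1))

        base = PhantomSpec(
            group=group,
            seed=int(rng.integers(2**31 - 1)),
            length_jitter=length_jitter,
            intended_overcoverage=(over_top, over_bot),
            bladder_volume_ml=bladder,
            metal=metal,
            imar=imar,
            ctdi_vol=ctdi,
            topogram_margin_mm=topo_margin,
            protocol_name=protocol,
            pseudo_id=pseudo,
            study_date=date,
        )
        if group == "4D":
            # breathing pair: inspiration should show the larger lungs
            scales = (1.4, 0.8)
            if planted["wrong_breathing"]:
                scales = (0.8, 1.4)
            specs = [
                replace(base, breathing_label="inspiration", breathing_scale=scales[0]),
                replace(
                    base,
                    breathing_label="expiration",
                    breathing_scale=scales[1],
                    seed=base.seed + 1,
                ),
            ]
        else:
            specs = [base]

        for spec in specs:
            data = generate_phantom(spec, registry)
            case_id = f"case_{case_index:05d}"
            case_index += 1
            if write_volumes:
                case_dir = out / case_id
                case_dir.mkdir(exist_ok=True)
                _write_nifti_gz(data.label_map.grid, data.label_map.affine,
                                case_dir / "labels.nii.gz")
                _write_nifti_gz(data.image, data.label_map.affine,
                                case_dir / "image.nii.gz")
                meta = {
                    "pseudo_id": spec.pseudo_id,
                    "group": group,
                    "protocol_name": spec.protocol_name,
                    "study_date": spec.study_date,
                    "slice_count": data.scan_record.slice_count,
                    "slice_thickness_mm": data.scan_record.slice_thickness_mm,
                    "volumetric_length_mm": data.scan_record.volumetric_length_mm,
                    "topogram_length_mm": data.scan_record.topogram_length_mm,
                    "contrast_volume_ml": data.scan_record.contrast_volume_ml,
                    "recon_description": data.scan_record.recon_description,
                    "breathing_label": spec.breathing_label,
                    "fov": data.scan_record.fov,
                    "fov_radius_mm": spec.fov_radius_mm,
                    "label_names": {
                        str(k): v for k, v in data.label_map.label_names.items()
                    },
                }
                (case_dir / "meta.json").write_text(
                    json.dumps(meta, indent=1, sort_keys=True)
                )
            reports.append(data.dose_report)
            truth = data.ground_truth
            rows.append(
                {
                    "case_id": case_id,
                    "pseudo_id": spec.pseudo_id,
                    "group": group,
                    "protocol": spec.protocol_name,
                    "date": spec.study_date,
                    "breathing_label": spec.breathing_label or "",
                    "true_delta_top_mm": truth.true_delta_top,
                    "true_delta_bot_mm": truth.true_delta_bot,
                    "true_bladder_class": truth.true_bladder_class or "",
                    "true_bladder_volume_ml": truth.true_bladder_volume_ml,
                    "true_metal": truth.true_metal,
                    "imar": spec.imar,
                    "true_lung_volume_ml": truth.true_lung_volume_ml,
                    "true_dlp": truth.true_dlp,
                    **{f"planted_{k}": planted[k] for k in DEFECT_KINDS},
                }
            )

    with open(out / "dose_reports.jsonl", "w") as fh:
        for report in reports:
            fh.write(json.dumps(serialize_dose_report(report)) + "\n")
    table = pd.DataFrame(rows)
    table.to_csv(out / "ground_truth.csv", index=False)
    return table
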