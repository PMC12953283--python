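"""Anatomical scan-range audit from organ label maps.

Given an organ label map (TotalSegmentator-style segmentation) and a
body-region SOP definition, this module measures how far the actual scan
boundaries deviate from the SOP-required anatomical field of view:

* ``delta_top``: signed cranial-boundary deviation in mm,
* ``delta_bot``: signed caudal-boundary deviation in mm,

with positive values meaning over-coverage and negative values meaning
under-coverage on either end.

All geometry is evaluated in patient-space millimetres derived from the
NIfTI affine after reorientation to a canonical RAS-like frame, so the
cranial direction is +z.  Structure extents are reported as outer slice
faces (voxel centre +/- half a slice thickness): an organ filling 11
slices of 3 mm has a 33 mm extent.  Scan boundaries likewise use the
outer faces of the first and last slice.

When a landmark structure is missing from a truncated scan (or cut at
the scan border, which makes its extent unreliable), the boundary is
estimated by anchoring on the first fully visible vertebral level of the
SOP fallback chain and bridging the missing levels with VB-LUT reference
lengths.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import nibabel as nib
import numpy as np

from .sop_registry import CAUDAL, CRANIAL, SOPDefinition, VBLUT, chain_gap

__all__ = [
    "LabelMap",
    "LandmarkSet",
    "ScanExtent",
    "DeltaResult",
    "LabelMapError",
    "load_label_map",
    "extract_extents",
    "resolve_boundary",
    "estimate_missing_boundary",
    "compute_deltas",
]

GUIDELINE_MM = 50.0  # recommended |delta| threshold from national guidance

DIRECT = "direct"
LUT_ESTIMATED = "lut-estimated"
UNAVAILABLE = "unavailable"


class LabelMapError(ValueError):
    """Raised for unusable label maps."""


@dataclass
class LabelMap:
    """A 3-D integer label volume in a known patient-space frame.

    ``grid`` holds label IDs, ``affine`` maps voxel indices to patient
    mm, and ``label_names`` maps each nonzero ID to a structure name.
    The z (cranio-caudal) axis must be voxel-axis aligned, which holds
    for canonical-orientation NIfTI volumes.
    """

    grid: np.ndarray
    affine: np.ndarray
    label_names: Mapping[int, str]

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.grid.ndim != 3:
            raise LabelMapError("label grid must be 3-D")
        if self.affine.shape != (4, 4) or abs(np.linalg.det(self.affine[:3, :3])) < 1e-9:
            raise LabelMapError("affine must be an invertible 4x4 transform")
        zrow = self.affine[2, :3]
        self._z_axis = int(np.argmax(np.abs(zrow)))
        off_axis = np.abs(np.delete(zrow, self._z_axis))
        if np.any(off_axis > 1e-3 * max(np.abs(zrow[self._z_axis]), 1e-9)):
            raise LabelMapError(
                "patient z must align with one voxel axis; reorient the "
                "volume to a canonical frame first"
            )

    @property
    def z_axis(self) -> int:
        return self._z_axis

    @property
    def slice_thickness(self) -> float:
        return float(abs(self.affine[2, self._z_axis]))

    def slice_z(self, k: np.ndarray | int) -> np.ndarray:
        """Patient z (mm) of slice-centre ``k`` along the z axis."""
        return self.affine[2, self._z_axis] * np.asarray(k) + self.affine[2, 3]

    def n_slices(self) -> int:
        return self.grid.shape[self._z_axis]


@dataclass(frozen=True)
class LandmarkSet:
    """Per-structure cranio-caudal extents plus scan-border contact flags."""

    extents: Mapping[str, tuple[float, float]]  # name -> (z_cranial, z_caudal)
    touches_top: frozenset[str]
    touches_bottom: frozenset[str]

    def extent(self, structure: str, side: str) -> float | None:
        if structure not in self.extents:
            return None
        z_cranial, z_caudal = self.extents[structure]
        return z_cranial if side == CRANIAL else z_caudal

    def usable(self, structure: str, side: str) -> bool:
        """Present, and its ``side`` extent is not cut at the scan border."""
        if structure not in self.extents:
            return False
        touched = self.touches_top if side == CRANIAL else self.touches_bottom
        return structure not in touched


@dataclass(frozen=True)
class ScanExtent:
    """Scanned z range: outer faces of the most cranial/caudal slices."""

    z_top: float
    z_bot: float
    slice_thickness: float
    n_slices: int

    def __post_init__(self) -> None:
        if not self.z_top > self.z_bot:
            raise LabelMapError("scan z_top must exceed z_bot")
        if self.n_slices < 1:
            raise LabelMapError("scan must contain >= 1 slice")
        if abs((self.z_top - self.z_bot) - self.n_slices * self.slice_thickness) > (
            self.slice_thickness + 1e-6
        ):
            raise LabelMapError("scan extent inconsistent with slice count")

    @classmethod
    def from_label_map(cls, label_map: LabelMap) -> "ScanExtent":
        n = label_map.n_slices()
        centers = label_map.slice_z(np.arange(n))
        half = label_map.slice_thickness / 2.0
        return cls(
            z_top=float(centers.max() + half),
            z_bot=float(centers.min() - half),
            slice_thickness=label_map.slice_thickness,
            n_slices=n,
        )

    @property
    def length_mm(self) -> float:
        return self.z_top - self.z_bot


@dataclass(frozen=True)
class DeltaResult:
    """Signed scan-range deviations from the SOP anatomical FOV.

    Positive = over-coverage, negative = under-coverage, on both ends.
    ``*_method`` records whether the SOP boundary was located directly
    from a segmented landmark or estimated via the VB-LUT chain; a delta
    is ``None`` (never 0) when neither was possible.
    """

    delta_top: float | None
    delta_bot: float | None
    top_method: str
    bot_method: str
    guideline_flag_top: bool
    guideline_flag_bot: bool
    guideline_mm: float = GUIDELINE_MM


def load_label_map(
    nifti_path: str | Path, mapping: str | Path | Mapping[int, str]
) -> LabelMap:
    """Load a NIfTI label volume plus a ``{label_id: structure}`` mapping.

    The volume is reoriented to the closest canonical (RAS) frame so the
    cranial direction is +z.
    """
    img = nib.as_closest_canonical(nib.load(str(nifti_path)))
    if not isinstance(mapping, Mapping):
        mapping = json.loads(Path(mapping).read_text())
    label_names = {int(k): str(v) for k, v in mapping.items()}
    grid = np.asanyarray(img.dataobj).astype(np.int32)
    return LabelMap(grid=grid, affine=img.affine, label_names=label_names)


def extract_extents(
    label_map: LabelMap, aliases: Mapping[str, tuple[str, ...]] | None = None
) -> LandmarkSet:
    """Measure per-structure cranio-caudal extents in patient mm.

    Alias structures (e.g. ``lung`` as the union of the lobe classes,
    ``hip`` as left+right) are added whenever at least one member is
    present; an alias touches a scan border if any member does.

    Raises
    ------
    LabelMapError
        For an all-zero map or a label ID absent from ``label_names``.
    """
    grid = label_map.grid
    if not np.any(grid):
        raise LabelMapError("label map contains no labelled voxels")
    present = np.unique(grid)
    present = present[present != 0]
    unknown = [int(i) for i in present if int(i) not in label_map.label_names]
    if unknown:
        raise LabelMapError(f"label IDs without a structure name: {unknown}")

    zax = label_map.z_axis
    other_axes = tuple(a for a in range(3) if a != zax)
    n = label_map.n_slices()
    centers = label_map.slice_z(np.arange(n))
    half = label_map.slice_thickness / 2.0
    k_top = int(np.argmax(centers))
    k_bot = int(np.argmin(centers))

    extents: dict[str, tuple[float, float]] = {}
    touches_top: set[str] = set()
    touches_bottom: set[str] = set()
    for label_id in present:
        name = label_map.label_names[int(label_id)]
        in_slice = np.any(grid == label_id, axis=other_axes)
        ks = np.nonzero(in_slice)[0]
        zs = centers[ks]
        extents[name] = (float(zs.max() + half), float(zs.min() - half))
        if in_slice[k_top]:
            touches_top.add(name)
        if in_slice[k_bot]:
            touches_bottom.add(name)

    for alias, members in (aliases or {}).items():
        member_exts = [extents[m] for m in members if m in extents]
        if not member_exts or alias in extents:
            continue
        extents[alias] = (
            max(e[0] for e in member_exts),
            min(e[1] for e in member_exts),
        )
        if any(m in touches_top for m in members):
            touches_top.add(alias)
        if any(m in touches_bottom for m in members):
            touches_bottom.add(alias)

    return LandmarkSet(
        extents=extents,
        touches_top=frozenset(touches_top),
        touches_bottom=frozenset(touches_bottom),
    )


def resolve_boundary(
    sop: SOPDefinition, landmarks: LandmarkSet, end: str
) -> tuple[float, str] | None:
    """Locate one SOP boundary directly from a segmented landmark.

    The primary structure is used when present and not cut at the scan
    border on the side whose extent defines the landmark; otherwise the
    equivalent height-level organ is tried.  Returns ``(z_mm, "direct")``
    or ``None`` when neither is usable.
    """
    spec = sop.landmark(end)
    candidates = [(spec.structure, spec.side)]
    if spec.equivalent_structure is not None:
        candidates.append(
            (spec.equivalent_structure, spec.effective_equivalent_side)
        )
    for structure, side in candidates:
        if landmarks.usable(structure, side):
            z = landmarks.extent(structure, side)
            return z + spec.offset_mm, DIRECT
    return None


def estimate_missing_boundary(
    sop: SOPDefinition, landmarks: LandmarkSet, lut: VBLUT, end: str
) -> tuple[float, str] | None:
    """Estimate a missing SOP boundary via the VB-LUT fallback chain.

    The chain starts at the vertebral level equivalent to the landmark
    and proceeds toward the scan interior.  The first chain element that
    is segmented and not cut at the relevant border anchors the
    estimate; the reference lengths of the skipped levels are added
    (cranial end) or subtracted (caudal end), then the SOP offset is
    applied.  Returns ``None`` when no chain element qualifies.
    """
    spec = sop.landmark(end)
    chain = sop.chain(end)
    side = CRANIAL if end == "top" else CAUDAL
    for index, structure in enumerate(chain):
        if landmarks.usable(structure, side):
            anchor = landmarks.extent(structure, side)
            gap = chain_gap(lut, chain, 0, index)
            z = anchor + gap if end == "top" else anchor - gap
            return z + spec.offset_mm, LUT_ESTIMATED
    return None


def _boundary(
    sop: SOPDefinition, landmarks: LandmarkSet, lut: VBLUT, end: str
) -> tuple[float | None, str]:
    located = resolve_boundary(sop, landmarks, end)
    if located is None:
        located = estimate_missing_boundary(sop, landmarks, lut, end)
    if located is None:
        return None, UNAVAILABLE
    return located[0], located[1]


def compute_deltas(
    scan: ScanExtent,
    sop: SOPDefinition,
    landmarks: LandmarkSet,
    lut: VBLUT,
    guideline_mm: float = GUIDELINE_MM,
) -> DeltaResult:
    """Compute ``delta_top``/``delta_bot`` against a body-region SOP.

    ``delta_top = scan.z_top - z_sop_top`` and
    ``delta_bot = z_sop_bot - scan.z_bot``, so over-coverage is positive
    on both ends.  Guideline flags mark ``|delta| > guideline_mm``
    (default 50 mm).
    """
    z_top, top_method = _boundary(sop, landmarks, lut, "top")
    z_bot, bot_method = _boundary(sop, landmarks, lut, "bot")
    delta_top = None if z_top is None else scan.z_top - z_top
    delta_bot = None if z_bot is None else z_bot - scan.z_bot
    return DeltaResult(
        delta_top=delta_top,
        delta_bot=delta_bot,
        top_method=top_method,
        bot_method=bot_method,
        guideline_flag_top=delta_top is not None and abs(delta_top) > guideline_mm,
        guideline_flag_bot=delta_bot is not None and abs(delta_bot) > guideline_mm,
        guideline_mm=guideline_mm,
    )
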