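"""SOP registry: anatomical FOV definitions, VB-LUT, k-factors, protocol map.

The registry bundles everything the audit needs to know about the
institution's scanning rules:

* per body-region group, the standard-operating-procedure (SOP) anatomical
  field of view — a cranial and a caudal landmark, each given as a
  segmentable structure extent plus a signed offset in mm, optionally with
  an equivalent height-level organ for landmarks the segmentation does not
  provide directly (e.g. the mastoid resolved via the cranial end of C1);
* per group, ordered fallback chains of vertebral levels used to estimate
  a boundary when the landmark itself is missing from a truncated scan;
* the vertebral-body lookup table (VB-LUT) of reference segment lengths
  used to bridge the missing levels;
* effective-dose k-factors (mSv per mGy*cm) per body region;
* ordered protocol-name → group resolution rules.

Everything is loadable from a single YAML/JSON config; the shipped default
encodes the institutional SOP table and VB-LUT.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import yaml

__all__ = [
    "LandmarkSpec",
    "SOPDefinition",
    "VBLUT",
    "KFactorTable",
    "ProtocolMap",
    "Registry",
    "RegistryError",
    "load_registry",
    "default_registry",
    "vblut_length",
    "chain_gap",
]

CRANIAL = "cranial"
CAUDAL = "caudal"

#: vertebral levels every VB-LUT must cover, plus the skull
REQUIRED_LUT_STRUCTURES = (
    ["skull"]
    + [f"vertebrae_C{i}" for i in range(1, 8)]
    + [f"vertebrae_T{i}" for i in range(1, 13)]
    + [f"vertebrae_L{i}" for i in range(1, 6)]
)


class RegistryError(ValueError):
    """Raised for invalid registry configuration."""


@dataclass(frozen=True)
class LandmarkSpec:
    """One SOP boundary: a structure extent plus a signed cranial offset.

    ``offset_mm`` is positive toward the cranial direction.  When the
    primary ``structure`` cannot be segmented (or is cut at the scan
    border), ``equivalent_structure``/``equivalent_side`` name the
    height-level organ that stands in for it.
    """

    structure: str
    side: str  # "cranial" or "caudal" extent of the structure
    offset_mm: float = 0.0
    equivalent_structure: str | None = None
    equivalent_side: str | None = None

    def __post_init__(self) -> None:
        if not self.structure:
            raise RegistryError("landmark structure must be non-empty")
        if self.side not in (CRANIAL, CAUDAL):
            raise RegistryError(f"invalid landmark side {self.side!r}")
        if not (self.offset_mm == self.offset_mm and abs(self.offset_mm) < 1e6):
            raise RegistryError("landmark offset must be finite")
        if self.equivalent_structure == self.structure:
            raise RegistryError(
                "equivalent structure must differ from the primary structure"
            )
        if self.equivalent_side is not None and self.equivalent_side not in (
            CRANIAL,
            CAUDAL,
        ):
            raise RegistryError(f"invalid equivalent side {self.equivalent_side!r}")

    @property
    def effective_equivalent_side(self) -> str:
        return self.equivalent_side if self.equivalent_side is not None else self.side


@dataclass(frozen=True)
class SOPDefinition:
    """A body-region group's SOP anatomical FOV and fallback chains.

    Chains are ordered starting at the vertebral level equivalent to the
    landmark and proceeding toward the scan interior, so that in a
    truncated scan the first chain element still fully visible anchors a
    lookup-table estimate of the missing boundary.
    """

    group: str
    top: LandmarkSpec
    bot: LandmarkSpec
    top_chain: tuple[str, ...] = ()
    bot_chain: tuple[str, ...] = ()
    organ_characteristic: Mapping[str, str] = field(default_factory=dict)

    def landmark(self, end: str) -> LandmarkSpec:
        if end == "top":
            return self.top
        if end == "bot":
            return self.bot
        raise ValueError(f"end must be 'top' or 'bot', got {end!r}")

    def chain(self, end: str) -> tuple[str, ...]:
        return self.top_chain if end == "top" else self.bot_chain


@dataclass(frozen=True)
class VBLUT:
    """Vertebral-body lookup table: reference segment lengths in mm."""

    lengths: Mapping[str, float]

    def __post_init__(self) -> None:
        for name, length in self.lengths.items():
            if not length > 0:
                raise RegistryError(f"VB-LUT length for {name!r} must be > 0")
        missing = [s for s in REQUIRED_LUT_STRUCTURES if s not in self.lengths]
        if missing:
            raise RegistryError(f"VB-LUT missing required entries: {missing}")

    def __contains__(self, structure: str) -> bool:
        return structure in self.lengths

    def length(self, structure: str) -> float:
        try:
            return float(self.lengths[structure])
        except KeyError:
            raise KeyError(f"structure {structure!r} not in VB-LUT") from None


@dataclass(frozen=True)
class KFactorTable:
    """Effective-dose conversion coefficients per body region (mSv/(mGy*cm))."""

    factors: Mapping[str, float]

    def __post_init__(self) -> None:
        for region, k in self.factors.items():
            if not k > 0:
                raise RegistryError(f"k-factor for {region!r} must be > 0")

    def k(self, region: str) -> float:
        try:
            return float(self.factors[region])
        except KeyError:
            raise KeyError(f"region {region!r} not in k-factor table") from None


@dataclass(frozen=True)
class ProtocolMap:
    """Ordered protocol-name resolution rules.

    Matching is case-insensitive substring search; the first matching rule
    wins.  Each rule carries the target body-region group and a modality
    tag (EBRT or brachy).
    """

    rules: tuple[tuple[str, str, str], ...]  # (pattern, group, modality)

    def resolve(self, protocol_name: str) -> tuple[str, str]:
        """Return ``(group, modality)`` for a protocol name.

        Raises
        ------
        KeyError
            If no rule matches.
        """
        lowered = protocol_name.lower()
        for pattern, group, modality in self.rules:
            if pattern.lower() in lowered:
                return group, modality
        raise KeyError(f"protocol name {protocol_name!r} matches no mapping rule")


@dataclass(frozen=True)
class Registry:
    """The full QA configuration: SOPs, VB-LUT, k-factors, protocol map."""

    sops: Mapping[str, SOPDefinition]
    vblut: VBLUT
    kfactors: KFactorTable
    protocol_map: ProtocolMap
    aliases: Mapping[str, tuple[str, ...]] = field(default_factory=dict)

    def sop(self, group: str) -> SOPDefinition:
        try:
            return self.sops[group]
        except KeyError:
            raise KeyError(f"no SOP definition for group {group!r}") from None

    def to_dict(self) -> dict:
        """Serialize back to the config-document structure."""
        doc: dict = {"aliases": {k: list(v) for k, v in self.aliases.items()}}
        sops = {}
        for group, sop in self.sops.items():
            entry: dict = {
                "top": _landmark_to_dict(sop.top),
                "bot": _landmark_to_dict(sop.bot),
                "top_chain": list(sop.top_chain),
                "bot_chain": list(sop.bot_chain),
            }
            if sop.organ_characteristic:
                entry["organ_characteristic"] = dict(sop.organ_characteristic)
            sops[group] = entry
        doc["sops"] = sops
        doc["vblut"] = {k: float(v) for k, v in self.vblut.lengths.items()}
        doc["kfactors"] = {k: float(v) for k, v in self.kfactors.factors.items()}
        doc["protocol_map"] = [
            {"pattern": p, "group": g, "modality": m}
            for p, g, m in self.protocol_map.rules
        ]
        return doc

    def save(self, path: str | Path) -> None:
        path = Path(path)
        with open(path, "w") as fh:
            if path.suffix == ".json":
                json.dump(self.to_dict(), fh, indent=2)
            else:
                yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def _landmark_to_dict(spec: LandmarkSpec) -> dict:
    out: dict = {
        "structure": spec.structure,
        "side": spec.side,
        "offset_mm": float(spec.offset_mm),
    }
    if spec.equivalent_structure is not None:
        out["equivalent_structure"] = spec.equivalent_structure
    if spec.equivalent_side is not None:
        out["equivalent_side"] = spec.equivalent_side
    return out


def _parse_landmark(doc: Mapping, where: str) -> LandmarkSpec:
    try:
        return LandmarkSpec(
            structure=doc["structure"],
            side=doc["side"],
            offset_mm=float(doc.get("offset_mm", 0.0)),
            equivalent_structure=doc.get("equivalent_structure"),
            equivalent_side=doc.get("equivalent_side"),
        )
    except KeyError as exc:
        raise RegistryError(f"{where}: missing landmark field {exc}") from None


def _load_document(config_path: str | Path) -> Mapping:
    path = Path(config_path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text()
    if path.suffix == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def load_registry(config_path: str | Path) -> Registry:
    """Load and validate a registry from a YAML or JSON config file."""
    return registry_from_dict(_load_document(config_path))


def registry_from_dict(doc: Mapping) -> Registry:
    """Build a validated :class:`Registry` from a parsed config document."""
    for section in ("sops", "vblut", "kfactors", "protocol_map"):
        if section not in doc:
            raise RegistryError(f"config missing section {section!r}")

    vblut = VBLUT(lengths={str(k): float(v) for k, v in doc["vblut"].items()})
    kfactors = KFactorTable(
        factors={str(k): float(v) for k, v in doc["kfactors"].items()}
    )
    aliases = {
        str(k): tuple(str(s) for s in v)
        for k, v in (doc.get("aliases") or {}).items()
    }

    sops: dict[str, SOPDefinition] = {}
    for group, entry in doc["sops"].items():
        sop = SOPDefinition(
            group=str(group),
            top=_parse_landmark(entry["top"], f"sops[{group}].top"),
            bot=_parse_landmark(entry["bot"], f"sops[{group}].bot"),
            top_chain=tuple(entry.get("top_chain") or ()),
            bot_chain=tuple(entry.get("bot_chain") or ()),
            organ_characteristic=dict(entry.get("organ_characteristic") or {}),
        )
        for chain_name in ("top_chain", "bot_chain"):
            for structure in getattr(sop, chain_name):
                if structure not in vblut:
                    raise RegistryError(
                        f"sops[{group}].{chain_name}: {structure!r} has no "
                        "VB-LUT entry"
                    )
        sops[str(group)] = sop

    rules = []
    for rule in doc["protocol_map"]:
        pattern = str(rule["pattern"])
        group = str(rule["group"])
        modality = str(rule.get("modality", "EBRT"))
        if group not in sops:
            raise RegistryError(
                f"protocol_map rule {pattern!r} targets unknown group {group!r}"
            )
        rules.append((pattern, group, modality))

    return Registry(
        sops=sops,
        vblut=vblut,
        kfactors=kfactors,
        protocol_map=ProtocolMap(rules=tuple(rules)),
        aliases=aliases,
    )


def default_registry() -> Registry:
    """The shipped default registry (institutional SOP table and VB-LUT)."""
    ref = resources.files("rtctqa.data") / "default_registry.yaml"
    return registry_from_dict(yaml.safe_load(ref.read_text()))


def vblut_length(lut: VBLUT, structure: str) -> float:
    """Reference length (mm) of one skull/vertebral segment."""
    return lut.length(structure)


def chain_gap(
    lut: VBLUT, chain: Sequence[str], from_index: int, to_index: int
) -> float:
    """Summed reference length (mm) of chain elements in ``[from_index, to_index)``.

    This is the anatomical distance bridged when the first ``to_index``
    chain levels are missing from a truncated scan and the estimate is
    anchored on element ``to_index``.
    """
    if not 0 <= from_index <= to_index <= len(chain):
        raise IndexError(
            f"invalid chain span [{from_index}, {to_index}) for chain of "
            f"length {len(chain)}"
        )
    return float(sum(lut.length(s) for s in chain[from_index:to_index]))
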