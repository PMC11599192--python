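"""Family evidence catalog: the machine-readable definitions of the nine
canonical CD28-family members plus the chondrichthyan co-ortholog class.

The built-in catalog ships as package data (``data/catalog.yaml``); a custom
catalog following the same schema can be supplied instead.  Each profile
carries compiled motif requirements (with the structural region they are
evaluated in and a REQUIRED/SUPPORTING weight), its conserved-synteny marker
genes, and architecture flags.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from .errors import CatalogError, MotifParseError
from .motif import MotifPattern, compile_pattern

#: structural regions a motif requirement may be evaluated in
REGIONS = (
    "CDR3_NEIGHBORHOOD",
    "G_STRAND",
    "E_STRAND",
    "TM",
    "CYTOPLASMIC",
    "CTERM",
)

#: regions that lie inside the IgV domain; suppressed for divergent IgV
IGV_REGIONS = frozenset({"CDR3_NEIGHBORHOOD", "G_STRAND", "E_STRAND"})

WEIGHTS = ("REQUIRED", "SUPPORTING")

#: the ten profile names the catalog must contain, in canonical order
CANONICAL_FAMILIES = (
    "CD28",
    "CTLA4",
    "ICOS",
    "CD28H",
    "CD28HL1",
    "CD28HL2",
    "CD28HL3",
    "CD28X",
    "PD1",
    "CD28_CTLA4_CO_ORTHOLOG",
)

#: the nine canonical family labels (co-ortholog class excluded)
CANONICAL_LABELS = CANONICAL_FAMILIES[:9]

#: profiles belonging to the ancestral three-gene cassette locus
CASSETTE_FAMILIES = frozenset({"CD28", "CTLA4", "ICOS", "CD28_CTLA4_CO_ORTHOLOG"})


@dataclass(frozen=True)
class MotifRequirement:
    pattern: MotifPattern
    region: str
    weight: str
    lineage_note: str = ""
    cassette_position: Optional[int] = None

    def __post_init__(self):
        if self.region not in REGIONS:
            raise CatalogError(f"unknown region {self.region!r}")
        if self.weight not in WEIGHTS:
            raise CatalogError(f"unknown weight {self.weight!r}")


@dataclass(frozen=True)
class FamilyProfile:
    name: str
    motif_requirements: tuple
    synteny_markers: frozenset
    allow_divergent_igv: bool = False
    notes: str = ""

    def __post_init__(self):
        if self.name not in CANONICAL_FAMILIES:
            raise CatalogError(f"unknown family name {self.name!r}")
        required = [m for m in self.motif_requirements if m.weight == "REQUIRED"]
        if not required and not (self.allow_divergent_igv and self.synteny_markers):
            raise CatalogError(
                f"profile {self.name}: needs >=1 REQUIRED motif, or "
                "allow_divergent_igv with a non-empty marker set"
            )

    def required_motifs(self) -> list[MotifRequirement]:
        return [m for m in self.motif_requirements if m.weight == "REQUIRED"]


def _parse_profile(entry: dict) -> FamilyProfile:
    name = entry.get("name", "<unnamed>")
    motifs = []
    for m in entry.get("motifs", []):
        try:
            pattern = compile_pattern(m["notation"])
        except (MotifParseError, KeyError) as exc:
            raise CatalogError(f"profile {name}: uncompilable motif {m!r}: {exc}") from exc
        motifs.append(
            MotifRequirement(
                pattern=pattern,
                region=m.get("region", ""),
                weight=m.get("weight", ""),
                lineage_note=str(m.get("lineage_note", "")).strip(),
                cassette_position=m.get("cassette_position"),
            )
        )
    markers = [str(x).lower() for x in entry.get("markers", [])]
    if len(markers) != len(set(markers)):
        raise CatalogError(f"profile {name}: duplicate synteny markers")
    try:
        return FamilyProfile(
            name=name,
            motif_requirements=tuple(motifs),
            synteny_markers=frozenset(markers),
            allow_divergent_igv=bool(entry.get("allow_divergent_igv", False)),
            notes=str(entry.get("notes", "")).strip(),
        )
    except CatalogError:
        raise
    except Exception as exc:  # schema violations surface with the profile name
        raise CatalogError(f"profile {name}: {exc}") from exc


def load_catalog(config_path: Optional[str | Path] = None) -> list[FamilyProfile]:
    """Load and validate the family catalog.

    With no argument the built-in catalog is returned.  Profiles are returned
    in canonical catalog order; exactly the ten expected profiles must be
    present and every pattern must compile.
    """
    if config_path is None:
        text = (
            importlib.resources.files("cd28fam").joinpath("data/catalog.yaml").read_text()
        )
    else:
        text = Path(config_path).read_text()
    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise CatalogError(f"catalog is not valid YAML: {exc}") from exc
    if not isinstance(doc, dict) or "families" not in doc:
        raise CatalogError("catalog must be a mapping with a 'families' list")
    profiles = [_parse_profile(e) for e in doc["families"]]
    names = [p.name for p in profiles]
    if sorted(names) != sorted(CANONICAL_FAMILIES):
        missing = set(CANONICAL_FAMILIES) - set(names)
        extra = set(names) - set(CANONICAL_FAMILIES)
        raise CatalogError(f"catalog families mismatch: missing={missing}, extra={extra}")
    profiles.sort(key=lambda p: CANONICAL_FAMILIES.index(p.name))
    return profiles


def get_profile(profiles: list[FamilyProfile], name: str) -> FamilyProfile:
    for p in profiles:
        if p.name == name:
            return p
    raise CatalogError(f"no profile named {name!r}")


def dump_catalog(profiles: list[FamilyProfile]) -> str:
    """Serialize a catalog back to its YAML config format (round-trip safe)."""
    families = []
    for p in profiles:
        motifs = []
        for m in p.motif_requirements:
            entry = {
                "notation": m.pattern.notation,
                "region": m.region,
                "weight": m.weight,
            }
            if m.cassette_position is not None:
                entry["cassette_position"] = m.cassette_position
            if m.lineage_note:
                entry["lineage_note"] = m.lineage_note
            motifs.append(entry)
        families.append(
            {
                "name": p.name,
                "allow_divergent_igv": p.allow_divergent_igv,
                "markers": sorted(p.synteny_markers),
                "notes": p.notes,
                "motifs": motifs,
            }
        )
    return yaml.safe_dump({"version": 1, "families": families}, sort_keys=False)
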