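"""Family assignment: combining architecture, motif and synteny evidence.

The decision rule mirrors the two acceptance criteria used for membership in
the CD28 family: (1) the protein has the conserved IgV-TM-cytoplasmic domain
structure with the family's diagnostic motifs in the CDR3 neighborhood and
the cytoplasmic region, and (2) the gene lies in a region with conserved
synteny markers.  Criterion (2) is enforced whenever a genomic context is
supplied and waived otherwise (transcript-only evidence is still
classifiable).

Scoring convention: REQUIRED motifs matched in their region score 2 points,
SUPPORTING motifs 1; a synteny hit sharing >= 2 markers with the profile
scores 2, exactly 1 shared marker scores 1.  The point weights are an
artifact convention — the literature ranks motif evidence only qualitatively.
A candidate is labelled with the top-scoring profile when its score reaches
the acceptance threshold and leads the runner-up by the acceptance margin;
two cassette-locus profiles (CD28/CTLA4/ICOS/co-ortholog) within the margin
of each other yield the unresolved co-ortholog outcome, anything else below
threshold or margin is UNCLASSIFIED.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .architecture import ArchitectureCall, ProteinRecord, motif_windows, segment
from .catalog import CASSETTE_FAMILIES, IGV_REGIONS, FamilyProfile, load_catalog
from .errors import SegmentationError
from .motif import scan
from .synteny import GeneOrderTable, SyntenyHit, marker_support

UNCLASSIFIED = "UNCLASSIFIED"

#: smallest values under which every zero-divergence exemplar is accepted and
#: the chondrichthyan hybrid evidence pattern resolves to the co-ortholog
#: outcome; tunable via classify(..., score_threshold=, margin=)
SCORE_THRESHOLD = 4
MARGIN = 2

REQUIRED_POINTS = 2
SUPPORTING_POINTS = 1


@dataclass(frozen=True)
class Evidence:
    source: str  # MOTIF | ARCHITECTURE | SYNTENY
    detail: str  # pattern notation or marker name
    region: str = ""
    weight_points: int = 1

    def __post_init__(self):
        if self.weight_points not in (1, 2):
            raise ValueError("weight_points must be 1 or 2")


@dataclass(frozen=True)
class FamilyAssignment:
    label: str
    score: int
    runner_up_label: Optional[str]
    runner_up_score: int
    evidence: tuple
    architecture_pass: bool
    missing_required: tuple = ()
    note: str = ""


def score_profile(
    record: ProteinRecord,
    arch: ArchitectureCall,
    profile: FamilyProfile,
    synteny_hit: Optional[SyntenyHit] = None,
) -> tuple[int, list[Evidence], list[str]]:
    """Score one profile against a segmented record.

    Returns ``(score, evidence, missing_required)``.  REQUIRED motifs that do
    not match subtract nothing but are reported as missing.  When the IgV is
    divergent, IgV-internal motif regions are not evaluated unless the
    profile tolerates a divergent V domain.
    """
    windows = motif_windows(arch, len(record.sequence))
    score = 0
    evidence: list[Evidence] = []
    missing: list[str] = []
    for req in profile.motif_requirements:
        if (
            arch.igv_divergent
            and req.region in IGV_REGIONS
            and not profile.allow_divergent_igv
        ):
            if req.weight == "REQUIRED":
                missing.append(req.pattern.notation)
            continue
        window = windows.get(req.region)
        matched = bool(window and scan(record.sequence, req.pattern, window=window))
        if matched:
            points = REQUIRED_POINTS if req.weight == "REQUIRED" else SUPPORTING_POINTS
            score += points
            evidence.append(
                Evidence(
                    source="MOTIF",
                    detail=req.pattern.notation,
                    region=req.region,
                    weight_points=points,
                )
            )
        elif req.weight == "REQUIRED":
            missing.append(req.pattern.notation)
    if synteny_hit is not None and synteny_hit.shared_count > 0:
        points = 2 if synteny_hit.shared_count >= 2 else 1
        score += points
        evidence.append(
            Evidence(
                source="SYNTENY",
                detail=",".join(sorted(synteny_hit.shared_markers)),
                region="",
                weight_points=points,
            )
        )
    return score, evidence, missing


def classify(
    record: ProteinRecord,
    genome_context: Optional[tuple[GeneOrderTable, str]] = None,
    profiles: Optional[list[FamilyProfile]] = None,
    score_threshold: int = SCORE_THRESHOLD,
    margin: int = MARGIN,
    synteny_k: int = 10,
) -> FamilyAssignment:
    """Assign a family label to a protein record.

    *genome_context*, when given, is ``(gene_order_table, gene_name)`` for
    the record's gene; a canonical label then additionally requires synteny
    evidence for the winning profile.  Deterministic; exact ties between
    profiles are broken by catalog order.
    """
    if profiles is None:
        profiles = load_catalog()
    try:
        arch = segment(record)
    except SegmentationError as exc:
        return FamilyAssignment(
            label=UNCLASSIFIED,
            score=0,
            runner_up_label=None,
            runner_up_score=0,
            evidence=(),
            architecture_pass=False,
            note=str(exc),
        )

    scored = []
    for profile in profiles:
        hit = None
        if genome_context is not None:
            table, gene_name = genome_context
            hit = marker_support(table, gene_name, profile.synteny_markers, k=synteny_k)
        s, ev, missing = score_profile(record, arch, profile, synteny_hit=hit)
        scored.append((s, profile, ev, missing))
    # stable sort: catalog order breaks exact ties
    scored.sort(key=lambda t: -t[0])
    top_score, top_profile, top_ev, top_missing = scored[0]
    runner_score, runner_profile = scored[1][0], scored[1][1]

    architecture_pass = arch.has_single_igv or (
        arch.igv_divergent and top_profile.allow_divergent_igv
    )

    label = UNCLASSIFIED
    note = ""
    if not architecture_pass:
        note = "architecture check failed (no single IgV domain)"
    elif top_score < score_threshold:
        note = f"score {top_score} below threshold {score_threshold}"
    elif top_score - runner_score < margin:
        if (
            top_profile.name in CASSETTE_FAMILIES
            and runner_profile.name in CASSETTE_FAMILIES
        ):
            label = "CD28_CTLA4_CO_ORTHOLOG"
            note = (
                f"cassette-locus profiles {top_profile.name}/{runner_profile.name} "
                f"within margin {margin}: unresolved co-ortholog"
            )
        else:
            note = f"margin {top_score - runner_score} below {margin}"
    else:
        if genome_context is not None and not any(
            e.source == "SYNTENY" for e in top_ev
        ):
            note = "genomic context supplied but no conserved-synteny evidence"
        else:
            label = top_profile.name

    return FamilyAssignment(
        label=label,
        score=top_score,
        runner_up_label=runner_profile.name,
        runner_up_score=runner_score,
        evidence=tuple(top_ev),
        architecture_pass=architecture_pass,
        missing_required=tuple(top_missing),
        note=note,
    )
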