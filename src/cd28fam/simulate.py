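"""Synthetic receptor sequences and genomes with full truth tables.

The generators emulate the two kinds of evidence the classifier consumes:

* :func:`simulate_family_protein` — a single-IgV type-I membrane protein for
  one catalog family: hydrophobic leader, IgV scaffold with the framework
  C/W/C triple at canonical spacings (or a degenerate framework for the
  divergent bony-fish PD-1 V domain), the family's diagnostic motifs planted
  in their structural regions, a hydrophobic TM (with the YxxxxT dimerization
  motif when the profile lists one) and a cytoplasmic tail with the family's
  signaling motifs.  Per-site substitutions are then applied at a controlled
  divergence.

* :func:`simulate_genome` — gene-order tables carrying the per-family marker
  neighborhoods (including the ancestral three-gene cassette), subjected to
  whole-genome duplications, gene loss and local rearrangement.

Scaffold residues are drawn from a hydrophilic alphabet chosen so that no
diagnostic motif and no membrane-like hydrophobic stretch can arise by
chance; motif insertion overwrites scaffold positions.  Substitutions draw
the replacement uniformly from the 19 alternatives — divergence is a stress
parameter here, not an evolutionary model.

Every emitted record has exactly one truth entry recording the planted
regions, motif positions and (for genomes) block ancestry and surviving copy
counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .architecture import ProteinRecord
from .catalog import (
    CASSETTE_FAMILIES,
    FamilyProfile,
    get_profile,
    load_catalog,
)
from .errors import Cd28FamError
from .motif import ElementKind, MotifPattern
from .synteny import Gene, GeneOrderTable

#: hydrophilic scaffold alphabet.  G is deliberately excluded: scaffold
#: glycines would create chance GxG G-strand matches at a rate that corrupts
#: family assignment; Y, C and W are excluded so no chance framework triples
#: or tyrosine motifs arise.
SCAFFOLD_ALPHABET = "STNQDEA"
#: juxtamembrane flanks avoid A (the one mildly hydrophobic scaffold residue)
#: so the planted TM boundaries are sharp: a Ser/Thr/acidic stalk end and a
#: charged cytoplasmic juxtamembrane, as in real type-I receptors
FLANK_ALPHABET = "STNQDE"
LEADER_ALPHABET = "LVAF"
TM_ALPHABET = "LIVF"
AA20 = "ACDEFGHIKLMNPQRSTVWY"

LEADER_LEN = 18
IGV_BEFORE_CYS1 = 22  # canonical C23 numbering: 22 residues precede cys1
CYS1_TO_TRP = 18  # within the [10, 25] framework spacing window
CYS1_TO_CYS2 = 65  # within the [50, 85] framework spacing window
IGV_AFTER_CYS2 = 13
TM_LEN = 21
#: concrete length substituted for an unbounded (X)_n spacer when planting
PLANT_GAP_LEN = 8


@dataclass(frozen=True)
class SimProteinConfig:
    family: str
    divergence: float = 0.0
    protect_motifs: bool = True
    seed: int = 0
    #: (min, max) scaffold lengths for the stalk and the cytoplasmic tail
    scaffold_length_bounds: dict = field(
        default_factory=lambda: {"stalk": (10, 14), "cyt": (36, 44)}
    )
    #: None = divergent IgV iff the family allows it (PD-1 bony-fish case)
    divergent_igv: Optional[bool] = None
    #: separate stream for substitutions, so several mutated descendants of
    #: one scaffold (same seed) can be drawn; None = reuse the main stream
    mutation_seed: Optional[int] = None

    def __post_init__(self):
        if not (0.0 <= self.divergence < 1.0):
            raise Cd28FamError("divergence must be in [0, 1)")


@dataclass(frozen=True)
class SimProteinTruth:
    family: str
    regions: dict  # region name -> (start, end), 1-based inclusive
    motif_positions: dict  # motif notation -> (start, end)
    framework: Optional[tuple]  # (cys1, trp, cys2) or None
    divergent_igv: bool
    protected: frozenset  # 1-based positions exempt from substitution
    n_substitutions: int = 0


def _instantiate(pattern: MotifPattern, in_tm: bool = False) -> tuple[str, int]:
    """Concrete exemplar string for a pattern (canonical consensus choice:
    first class residue alphabetically, minimal spacer lengths, S wildcards —
    L inside the TM).  Returns (string, length)."""
    fill = "L" if in_tm else "S"
    out = []
    for el in pattern.elements:
        if el.kind is ElementKind.FIXED:
            out.append(next(iter(el.residues)))
        elif el.kind is ElementKind.CLASS:
            out.append(sorted(el.residues)[0])
        elif el.kind is ElementKind.WILDCARD:
            out.append(fill * el.min_len)
        else:  # GAP
            length = el.min_len if el.max_len is not None else PLANT_GAP_LEN
            out.append(fill * length)
    s = "".join(out)
    return s, len(s)


def simulate_family_protein(
    config: SimProteinConfig,
    profiles: Optional[list[FamilyProfile]] = None,
) -> tuple[ProteinRecord, SimProteinTruth]:
    """Generate one synthetic receptor for *config.family* with its truth
    entry.  Reproducible per seed."""
    if profiles is None:
        profiles = load_catalog()
    profile = get_profile(profiles, config.family)
    rng = np.random.default_rng(config.seed)

    divergent = config.divergent_igv
    if divergent is None:
        divergent = profile.allow_divergent_igv
    if divergent and not profile.allow_divergent_igv:
        raise Cd28FamError(f"family {profile.name} does not allow a divergent IgV")

    stalk_lo, stalk_hi = config.scaffold_length_bounds["stalk"]
    cyt_lo, cyt_hi = config.scaffold_length_bounds["cyt"]
    stalk_len = int(rng.integers(stalk_lo, stalk_hi + 1))
    cyt_len = int(rng.integers(cyt_lo, cyt_hi + 1))

    # --- backbone coordinates (1-based) ---
    leader = (1, LEADER_LEN)
    igv_start = LEADER_LEN + 1
    cys1 = igv_start + IGV_BEFORE_CYS1
    trp = cys1 + CYS1_TO_TRP
    cys2 = cys1 + CYS1_TO_CYS2
    igv_end = cys2 + IGV_AFTER_CYS2
    tm_start = igv_end + stalk_len + 1
    tm_end = tm_start + TM_LEN - 1
    seq_len = tm_end + cyt_len

    seq = list(rng.choice(list(SCAFFOLD_ALPHABET), size=seq_len))
    seq[0] = "M"
    for i in range(1, LEADER_LEN):
        seq[i] = str(rng.choice(list(LEADER_ALPHABET)))
    for i in range(tm_start - 1, tm_end):
        seq[i] = str(rng.choice(list(TM_ALPHABET)))
    # whole stalk plus 9-residue cytoplasmic juxtamembrane (0-based indices)
    for i in list(range(igv_end, tm_start - 1)) + list(
        range(tm_end, min(seq_len, tm_end + 9))
    ):
        seq[i] = str(rng.choice(list(FLANK_ALPHABET)))

    framework = None
    if not divergent:
        seq[cys1 - 1] = "C"
        seq[trp - 1] = "W"
        seq[cys2 - 1] = "C"
        framework = (cys1, trp, cys2)

    # --- plant the family's motifs ---
    motif_positions: dict[str, tuple[int, int]] = {}

    def plant(notation: str, exemplar: str, start: int) -> None:
        end = start + len(exemplar) - 1
        if end > seq_len:
            raise Cd28FamError(f"motif {notation!r} does not fit (needs {end} residues)")
        seq[start - 1 : end] = list(exemplar)
        motif_positions[notation] = (start, end)

    cdr3_cursor = cys2 + 3
    cyt_cursor = tm_end + 10  # clear of the hydrophobic juxtamembrane window
    for req in profile.motif_requirements:
        if req.region in ("CDR3_NEIGHBORHOOD", "G_STRAND", "E_STRAND") and divergent:
            continue  # a degenerate V domain carries no IgV motifs
        exemplar, length = _instantiate(req.pattern, in_tm=(req.region == "TM"))
        notation = req.pattern.notation
        if req.region == "CDR3_NEIGHBORHOOD":
            elements = req.pattern.elements
            anchored = (
                len(elements) > 2
                and elements[2].kind is ElementKind.FIXED
                and "C" in elements[2].residues
            )
            if anchored:
                # the motif's own Cys is the second framework cysteine
                plant(notation, exemplar, cys2 - 2)
            else:
                plant(notation, exemplar, cdr3_cursor)
                cdr3_cursor += length + 1
        elif req.region == "G_STRAND":
            plant(notation, exemplar, cys2 + 9)
        elif req.region == "E_STRAND":
            plant(notation, exemplar, cys1 + 35)
        elif req.region == "TM":
            plant(notation, exemplar, tm_start + 7)
        elif req.region == "CYTOPLASMIC":
            plant(notation, exemplar, cyt_cursor)
            cyt_cursor += length + 3
        elif req.region == "CTERM":
            plant(notation, exemplar, seq_len - 8)

    # --- per-site substitutions ---
    protected: set[int] = set()
    if config.protect_motifs:
        for s, e in motif_positions.values():
            protected.update(range(s, e + 1))
        if framework:
            protected.update(framework)
    n_subs = 0
    if config.divergence > 0:
        if config.mutation_seed is not None:
            rng = np.random.default_rng(config.mutation_seed)
        for pos in range(1, seq_len + 1):
            if pos in protected:
                continue
            if rng.random() < config.divergence:
                current = seq[pos - 1]
                alternatives = [a for a in AA20 if a != current]
                seq[pos - 1] = str(rng.choice(alternatives))
                n_subs += 1

    regions = {
        "leader": leader,
        "IgV": (igv_start, igv_end),
        "TM": (tm_start, tm_end),
        "cytoplasmic": (tm_end + 1, seq_len),
    }
    if stalk_len > 0:
        regions["stalk"] = (igv_end + 1, tm_start - 1)

    record = ProteinRecord(
        id=f"{profile.name}_seed{config.seed}",
        sequence="".join(seq),
    )
    truth = SimProteinTruth(
        family=profile.name,
        regions=regions,
        motif_positions=motif_positions,
        framework=framework,
        divergent_igv=divergent,
        protected=frozenset(protected),
        n_substitutions=n_subs,
    )
    return record, truth


# --------------------------------------------------------------------------
# genomes
# --------------------------------------------------------------------------

#: shared marker panel of the ancestral CD28/CTLA4/ICOS cassette locus
CASSETTE_MARKERS = ("raph1", "abi2", "wdr12", "cyp20a1")


@dataclass(frozen=True)
class SimGenomeConfig:
    families_placed: tuple = ()
    include_cassette: bool = True
    n_markers_per_block: int = 4
    wgd_events: int = 0
    loss_probability: float = 0.0
    #: 'all' loses any gene; 'family' restricts loss to receptor genes
    loss_scope: str = "all"
    #: indices of post-WGD copies loss applies to (None = every copy)
    loss_copies: Optional[tuple] = None
    rearrangement_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.loss_probability <= 1.0):
            raise Cd28FamError("loss_probability must be in [0, 1]")
        if self.wgd_events < 0:
            raise Cd28FamError("wgd_events must be >= 0")
        if self.loss_scope not in ("all", "family"):
            raise Cd28FamError("loss_scope must be 'all' or 'family'")


@dataclass(frozen=True)
class SimGenomeTruth:
    block_of_gene: dict  # gene name -> block id
    family_genes: frozenset  # receptor gene names
    block_markers: dict  # block id -> tuple of marker names
    surviving_copies: dict  # block id -> number of copies retaining >=2 markers
    family_surviving: dict  # block id -> number of copies retaining >=1 family gene
    n_copies: int


def _ancestral_blocks(config: SimGenomeConfig, profiles) -> list[tuple[str, list[tuple[str, bool]]]]:
    """Blocks as (block_id, [(gene name, is_family_gene), ...])."""
    blocks = []
    if config.include_cassette:
        genes = [(CASSETTE_MARKERS[0], False), (CASSETTE_MARKERS[1], False)]
        genes += [(f"cd28ctla4_{i}", True) for i in (1, 2, 3)]
        genes += [(m, False) for m in CASSETTE_MARKERS[2:]]
        blocks.append(("cassette", genes))
    for fam in config.families_placed:
        if fam in CASSETTE_FAMILIES:
            continue  # cassette families live in the cassette block
        profile = get_profile(profiles, fam)
        markers = sorted(profile.synteny_markers)[: config.n_markers_per_block]
        half = max(1, len(markers) // 2)
        genes = [(m, False) for m in markers[:half]]
        genes.append((fam.lower(), True))
        genes += [(m, False) for m in markers[half:]]
        blocks.append((fam, genes))
    if not blocks:
        raise Cd28FamError("nothing to place: no cassette and no families")
    return blocks


def simulate_genome(
    config: SimGenomeConfig,
    profiles: Optional[list[FamilyProfile]] = None,
    species: str = "synthetic",
) -> tuple[list[GeneOrderTable], SimGenomeTruth]:
    """Simulate gene-order tables for one species.

    An ancestral chromosome of marker blocks (with the three-gene cassette
    when requested) undergoes ``wgd_events`` full duplications — each copy
    moving to a new chromosome — followed by per-gene loss and local
    rearrangement.  Reproducible per seed.
    """
    if profiles is None:
        profiles = load_catalog()
    rng = np.random.default_rng(config.seed)
    blocks = _ancestral_blocks(config, profiles)

    block_of_gene: dict[str, str] = {}
    family_genes: set[str] = set()
    block_markers: dict[str, tuple] = {}
    ancestral: list[str] = []  # gene names in order, blocks separated by filler
    filler_i = 0
    for block_id, genes in blocks:
        if ancestral:
            for _ in range(3):
                name = f"flnk{filler_i}"
                filler_i += 1
                ancestral.append(name)
                block_of_gene[name] = "filler"
        markers = []
        for name, is_family in genes:
            ancestral.append(name)
            block_of_gene[name] = block_id
            if is_family:
                family_genes.add(name)
            else:
                markers.append(name)
        block_markers[block_id] = tuple(markers)

    # --- WGD rounds ---
    copies: list[list[str]] = [list(ancestral)]
    for _ in range(config.wgd_events):
        copies = [list(c) for c in copies for _ in (0, 1)]

    # --- loss ---
    if config.loss_probability > 0:
        eligible_copies = (
            set(range(len(copies))) if config.loss_copies is None else set(config.loss_copies)
        )
        for ci, copy in enumerate(copies):
            if ci not in eligible_copies:
                continue
            kept = []
            for name in copy:
                eligible = config.loss_scope == "all" or name in family_genes
                if eligible and rng.random() < config.loss_probability:
                    continue
                kept.append(name)
            copies[ci] = kept

    # --- rearrangement: random adjacent transpositions ---
    if config.rearrangement_rate > 0:
        for copy in copies:
            n_swaps = int(round(config.rearrangement_rate * len(copy)))
            for _ in range(n_swaps):
                if len(copy) < 2:
                    break
                i = int(rng.integers(0, len(copy) - 1))
                copy[i], copy[i + 1] = copy[i + 1], copy[i]

    tables = []
    for ci, copy in enumerate(copies):
        genes = tuple(
            Gene(
                name=name,
                start=i * 10_000 + 1,
                end=i * 10_000 + 4_001,
                strand="+" if rng.random() < 0.5 else "-",
            )
            for i, name in enumerate(copy)
        )
        tables.append(
            GeneOrderTable(species=species, chromosome=f"chr{ci + 1}", genes=genes)
        )

    surviving = {}
    family_surviving = {}
    for block_id, markers in block_markers.items():
        block_family = {
            g for g in family_genes if block_of_gene.get(g) == block_id
        }
        n = n_fam = 0
        for copy in copies:
            present = {m for m in markers if m in copy}
            if len(present) >= 2:
                n += 1
            if block_family & set(copy):
                n_fam += 1
        surviving[block_id] = n
        family_surviving[block_id] = n_fam

    truth = SimGenomeTruth(
        block_of_gene=block_of_gene,
        family_genes=frozenset(family_genes),
        block_markers=block_markers,
        surviving_copies=surviving,
        family_surviving=family_surviving,
        n_copies=len(copies),
    )
    return tables, truth


def marker_context_table(
    family: str,
    candidate_gene: str = "cand",
    profiles: Optional[list[FamilyProfile]] = None,
) -> GeneOrderTable:
    """A minimal gene-order table placing *candidate_gene* amid the marker
    neighborhood of *family* — the synteny context a curated locus provides."""
    if profiles is None:
        profiles = load_catalog()
    profile = get_profile(profiles, family)
    markers = sorted(profile.synteny_markers)
    half = max(1, len(markers) // 2)
    names = markers[:half] + [candidate_gene] + markers[half:]
    genes = tuple(
        Gene(name=n, start=i * 10_000 + 1, end=i * 10_000 + 4_001, strand="+")
        for i, n in enumerate(names)
    )
    return GeneOrderTable(species="synthetic", chromosome="ctx", genes=genes)
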