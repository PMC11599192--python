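"""Conserved-synteny scoring, cassette detection and WGD copy counting.

Orthology of a receptor gene is supported independently of sequence by the
marker genes of its neighborhood.  Operations work on :class:`GeneOrderTable`
objects (the ordered genes of one chromosome) and are deliberately
rank-based: curated synteny panels show only conserved markers, so distances
are measured in gene ranks, not base pairs.

Gene-name matching is case-insensitive and tolerant of lineage suffixes
(teleost/salmonid ohnolog naming such as ``tacc3.1`` or ``prkab1b``): a
trailing ``.N``/``-N`` suffix is stripped, and a short trailing ``[0-9ab]``
run may distinguish two ohnologs of the same marker.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Optional

from .errors import TableError

_SUFFIX_RE = re.compile(r"[.\-][0-9ab]+$")
_OHNOLOG_TAIL_RE = re.compile(r"[0-9ab]{1,2}$")


@dataclass(frozen=True)
class Gene:
    name: str
    start: int
    end: int
    strand: str

    def __post_init__(self):
        if not self.name:
            raise TableError("gene with empty name")
        if self.start > self.end:
            raise TableError(f"gene {self.name}: start > end")
        if self.strand not in ("+", "-"):
            raise TableError(f"gene {self.name}: invalid strand {self.strand!r}")


@dataclass(frozen=True)
class GeneOrderTable:
    """Ordered genes on one chromosome of one species."""

    species: str
    chromosome: str
    genes: tuple

    def __post_init__(self):
        starts = [g.start for g in self.genes]
        for i in range(1, len(starts)):
            if starts[i] <= starts[i - 1]:
                raise TableError(
                    f"{self.species}/{self.chromosome}: gene starts not strictly "
                    f"increasing at {self.genes[i].name!r}"
                )

    def names(self) -> list[str]:
        return [g.name for g in self.genes]

    def index_of(self, gene_name: str) -> int:
        for i, g in enumerate(self.genes):
            if names_equal(g.name, gene_name):
                return i
        raise TableError(
            f"{self.species}/{self.chromosome}: gene {gene_name!r} not found"
        )


@dataclass(frozen=True)
class SyntenyHit:
    candidate_gene: str
    shared_markers: frozenset
    shared_count: int
    window_interval: tuple[int, int]  # gene-rank interval searched, 0-based


@dataclass(frozen=True)
class CassetteCall:
    member_genes: tuple
    size: int
    flanking_markers: frozenset


def normalize_name(name: str) -> str:
    """Lower-case a gene symbol and strip a trailing lineage suffix."""
    return _SUFFIX_RE.sub("", name.strip().lower())


def names_equal(a: str, b: str) -> bool:
    """Case-insensitive, ohnolog-suffix-tolerant gene-symbol comparison."""
    na, nb = normalize_name(a), normalize_name(b)
    if na == nb:
        return True
    for short, long in ((na, nb), (nb, na)):
        if long.startswith(short):
            tail = long[len(short):]
            if _OHNOLOG_TAIL_RE.fullmatch(tail):
                return True
    return False


def _match_marker(gene_name: str, marker_set: Iterable[str]) -> Optional[str]:
    for marker in marker_set:
        if names_equal(gene_name, marker):
            return marker.lower()
    return None


def marker_support(
    table: GeneOrderTable,
    candidate_gene: str,
    marker_set: Iterable[str],
    k: int = 10,
) -> SyntenyHit:
    """Score conserved-marker support for *candidate_gene*.

    The *k* genes on each side of the candidate (rank window, orientation-
    and strand-insensitive) are intersected with *marker_set*.
    """
    if k < 1:
        raise TableError("window half-width k must be >= 1")
    idx = table.index_of(candidate_gene)
    lo = max(0, idx - k)
    hi = min(len(table.genes) - 1, idx + k)
    shared = set()
    for i in range(lo, hi + 1):
        if i == idx:
            continue
        m = _match_marker(table.genes[i].name, marker_set)
        if m is not None:
            shared.add(m)
    return SyntenyHit(
        candidate_gene=candidate_gene,
        shared_markers=frozenset(shared),
        shared_count=len(shared),
        window_interval=(lo, hi),
    )


def detect_cassette(
    table: GeneOrderTable,
    family_gene_names: Iterable[str],
    max_gap: int = 1,
) -> list[CassetteCall]:
    """Find maximal runs of family genes separated by <= *max_gap*
    interleaving non-family genes.  Runs of size 1 are not reported.
    """
    if max_gap < 0:
        raise TableError("max_gap must be >= 0")
    family = list(family_gene_names)
    is_member = [
        any(names_equal(g.name, f) for f in family) for g in table.genes
    ]
    member_idx = [i for i, m in enumerate(is_member) if m]
    calls: list[CassetteCall] = []
    run: list[int] = []
    for i in member_idx:
        if run and i - run[-1] - 1 > max_gap:
            calls.append(_emit_run(table, run))
            run = []
        run.append(i)
    if run:
        calls.append(_emit_run(table, run))
    return [c for c in calls if c is not None and c.size >= 2]


def _emit_run(table: GeneOrderTable, run: list[int]) -> Optional[CassetteCall]:
    if len(run) < 2:
        return None
    members = tuple(table.genes[i].name for i in run)
    flanks = set()
    if run[0] > 0:
        flanks.add(table.genes[run[0] - 1].name)
    if run[-1] < len(table.genes) - 1:
        flanks.add(table.genes[run[-1] + 1].name)
    return CassetteCall(member_genes=members, size=len(members), flanking_markers=frozenset(flanks))


#: two marker windows on one chromosome further apart than this many gene
#: ranks count as distinct paralogous regions
REGION_SPLIT_GAP = 50


def count_paralogous_regions(
    tables: Iterable[GeneOrderTable],
    marker_set: Iterable[str],
    min_shared: int = 2,
) -> int:
    """Count distinct chromosomal regions carrying >= *min_shared* markers.

    At most one region per chromosome is counted unless two marker windows on
    one chromosome are separated by more than 50 genes — the situation that
    arises when a rearrangement fuses two WGD-derived copies.
    """
    if min_shared < 2:
        raise TableError("min_shared must be >= 2")
    markers = list(marker_set)
    count = 0
    for table in tables:
        hits = []  # (gene rank, matched marker)
        for i, g in enumerate(table.genes):
            m = _match_marker(g.name, markers)
            if m is not None:
                hits.append((i, m))
        # cluster hits by rank gap
        clusters: list[list[tuple[int, str]]] = []
        for i, m in hits:
            if clusters and i - clusters[-1][-1][0] <= REGION_SPLIT_GAP:
                clusters[-1].append((i, m))
            else:
                clusters.append([(i, m)])
        for cluster in clusters:
            if len({m for _, m in cluster}) >= min_shared:
                count += 1
    return count


def reverse_table(table: GeneOrderTable) -> GeneOrderTable:
    """Reverse gene order (and flip strands), renumbering coordinates so that
    starts stay strictly increasing.  Used to assert orientation invariance."""
    flipped = []
    span = max(g.end for g in table.genes) + 1
    for g in reversed(table.genes):
        flipped.append(
            Gene(
                name=g.name,
                start=span - g.end,
                end=span - g.start,
                strand="-" if g.strand == "+" else "+",
            )
        )
    return GeneOrderTable(species=table.species, chromosome=table.chromosome, genes=tuple(flipped))
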