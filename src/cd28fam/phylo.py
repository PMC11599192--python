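"""Clustering support: pairwise global alignment, similarity matrices,
neighbor-joining trees with bootstrap support, and clade-membership tests.

This layer deliberately uses distance methods (NJ on Poisson-corrected
distances) rather than maximum likelihood: it provides the topology/recovery
properties needed to ask "does this candidate cluster with that reference
set", not likelihood values.

* :func:`align_global` — affine-gap Needleman-Wunsch (BLOSUM62, -11/-1 by
  default) via ``Bio.Align.PairwiseAligner``, with percent identity computed
  over non-terminal-gap columns.
* :func:`nj_tree` — canonical neighbor joining, deterministic tie-breaking by
  lowest label pair, negative branch lengths clamped to zero with the deficit
  transferred to the sibling edge.  Exact on additive matrices.
* :func:`bootstrap_support` — column resampling of a multiple alignment,
  Poisson-corrected distances (d = -ln(1 - p)), NJ per replicate, support =
  percentage of replicates containing each original internal bipartition.
* :func:`clade_membership` — does a candidate fall inside the smallest
  cluster (unrooted bipartition side) containing a reference set?

The multiple alignment for bootstrapping is produced by center-star
progressive alignment over :func:`align_global` — adequate at the scale of a
per-species receptor repertoire.
"""

from __future__ import annotations

import io as _io
import warnings
from dataclasses import dataclass

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from skbio import TreeNode

from .errors import PhyloError

DEFAULT_MATRIX = "BLOSUM62"
DEFAULT_GAP_OPEN = -11.0
DEFAULT_GAP_EXTEND = -1.0
#: Poisson-corrected distance assigned when the mismatch fraction reaches 1
DISTANCE_CAP = 10.0


@dataclass(frozen=True)
class AlignmentResult:
    aligned_a: str
    aligned_b: str
    score: float
    percent_identity: float


@dataclass(frozen=True)
class DistanceMatrix:
    labels: tuple
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1] or v.shape[0] != len(self.labels):
            raise PhyloError("distance matrix shape does not match labels")
        if not np.allclose(v, v.T, atol=1e-12):
            raise PhyloError("distance matrix is not symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-12):
            raise PhyloError("distance matrix diagonal is not zero")
        if not np.all(np.isfinite(v)):
            raise PhyloError("distance matrix has non-finite entries")


@dataclass(frozen=True)
class SupportedTree:
    newick: str
    support: dict  # frozenset of tip names (smaller side) -> percentage

    def tree(self) -> TreeNode:
        return TreeNode.read(_io.StringIO(self.newick), convert_underscores=False)


def _make_aligner(substitution_matrix: str, gap_open: float, gap_extend: float):
    if not (gap_open <= gap_extend <= 0):
        raise PhyloError("expected gap_open <= gap_extend <= 0")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(substitution_matrix)
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


def percent_identity(aligned_a: str, aligned_b: str) -> float:
    """Percent identity over aligned columns, terminal gap columns excluded."""
    if len(aligned_a) != len(aligned_b):
        raise PhyloError("aligned strings differ in length")
    cols = len(aligned_a)
    lo, hi = 0, cols
    while lo < cols and (aligned_a[lo] == "-" or aligned_b[lo] == "-"):
        lo += 1
    while hi > lo and (aligned_a[hi - 1] == "-" or aligned_b[hi - 1] == "-"):
        hi -= 1
    n = hi - lo
    if n == 0:
        return 0.0
    matches = sum(1 for i in range(lo, hi) if aligned_a[i] == aligned_b[i])
    return 100.0 * matches / n


def align_global(
    a: str,
    b: str,
    substitution_matrix: str = DEFAULT_MATRIX,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> AlignmentResult:
    """Optimal affine-gap global alignment of two protein sequences.

    A gap of length k scores ``gap_open + (k - 1) * gap_extend``.  The
    traceback is deterministic (the aligner's canonical first path).
    """
    if not a or not b:
        raise PhyloError("sequences must be non-empty")
    aligner = _make_aligner(substitution_matrix, gap_open, gap_extend)
    try:
        alignment = aligner.align(a, b)[0]
    except ValueError as exc:
        raise PhyloError(f"alignment failed: {exc}") from exc
    aligned_a, aligned_b = str(alignment[0]), str(alignment[1])
    return AlignmentResult(
        aligned_a=aligned_a,
        aligned_b=aligned_b,
        score=float(alignment.score),
        percent_identity=percent_identity(aligned_a, aligned_b),
    )


def similarity_matrix(records) -> "pd.DataFrame":
    """Symmetric percent-identity matrix (diagonal 100) for >= 2 records.

    *records* is a sequence of objects with ``id`` and ``sequence``
    attributes, or ``(id, sequence)`` pairs.
    """
    import pandas as pd

    pairs = [
        (r.id, r.sequence) if hasattr(r, "id") else (r[0], r[1]) for r in records
    ]
    if len(pairs) < 2:
        raise PhyloError("similarity matrix requires >= 2 records")
    labels = [p[0] for p in pairs]
    n = len(pairs)
    m = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            pid = align_global(pairs[i][1], pairs[j][1]).percent_identity
            m[i, j] = m[j, i] = pid
    return pd.DataFrame(m, index=labels, columns=labels)


# --------------------------------------------------------------------------
# neighbor joining
# --------------------------------------------------------------------------

def nj_tree(d: DistanceMatrix) -> TreeNode:
    """Canonical neighbor joining on a distance matrix (>= 3 taxa).

    Ties in the Q criterion are broken by the lexicographically lowest label
    pair.  Negative branch lengths are clamped to zero with the deficit
    transferred to the sibling edge, preserving the path length between the
    joined pair.
    """
    labels = list(d.labels)
    if len(labels) < 3:
        raise PhyloError("neighbor joining requires >= 3 taxa")
    dm = {a: {b: float(d.values[i, j]) for j, b in enumerate(labels)} for i, a in enumerate(labels)}
    # newick fragment per active node
    frag = {a: a for a in labels}
    active = list(labels)
    counter = 0
    while len(active) > 3:
        n = len(active)
        totals = {a: sum(dm[a][b] for b in active if b != a) for a in active}
        best = None
        for i, a in enumerate(active):
            for b in active[i + 1 :]:
                q = (n - 2) * dm[a][b] - totals[a] - totals[b]
                key = tuple(sorted((str(a), str(b))))
                if best is None or q < best[0] - 1e-12 or (abs(q - best[0]) <= 1e-12 and key < best[1]):
                    best = (q, key, a, b)
        _, _, a, b = best
        dab = dm[a][b]
        la = 0.5 * dab + (totals[a] - totals[b]) / (2 * (n - 2))
        lb = dab - la
        # clamp negatives, transferring the deficit to the sibling edge
        if la < 0:
            lb += la
            la = 0.0
        if lb < 0:
            la += lb
            lb = 0.0
        la, lb = max(la, 0.0), max(lb, 0.0)
        new = f"_nj{counter}"
        counter += 1
        frag[new] = f"({frag[a]}:{la:.17g},{frag[b]}:{lb:.17g})"
        dm[new] = {}
        for c in active:
            if c in (a, b):
                continue
            dm[new][c] = dm[c][new] = 0.5 * (dm[a][c] + dm[b][c] - dab)
        dm[new][new] = 0.0
        active = [c for c in active if c not in (a, b)] + [new]
    # final three-taxon join (three-point formulas)
    a, b, c = active
    la = 0.5 * (dm[a][b] + dm[a][c] - dm[b][c])
    lb = 0.5 * (dm[a][b] + dm[b][c] - dm[a][c])
    lc = 0.5 * (dm[a][c] + dm[b][c] - dm[a][b])
    la, lb, lc = (max(x, 0.0) for x in (la, lb, lc))
    newick = f"({frag[a]}:{la:.17g},{frag[b]}:{lb:.17g},{frag[c]}:{lc:.17g});"
    return TreeNode.read(_io.StringIO(newick), convert_underscores=False)


# --------------------------------------------------------------------------
# bootstrap
# --------------------------------------------------------------------------

def poisson_distance_matrix(labels, rows) -> DistanceMatrix:
    """Poisson-corrected distances d = -ln(1 - p) from gapped alignment rows.

    p is the per-pair mismatch fraction over shared non-gap columns.  Pairs
    with p >= 1 (or no shared columns) get the documented cap with a warning.
    """
    n = len(labels)
    arr = np.array([list(r) for r in rows])
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            shared = (arr[i] != "-") & (arr[j] != "-")
            total = int(shared.sum())
            if total == 0:
                warnings.warn(f"no shared columns for {labels[i]}/{labels[j]}; distance capped")
                dist = DISTANCE_CAP
            else:
                p = float((arr[i][shared] != arr[j][shared]).sum()) / total
                if p >= 1.0:
                    warnings.warn(
                        f"saturated mismatch fraction for {labels[i]}/{labels[j]}; distance capped"
                    )
                    dist = DISTANCE_CAP
                else:
                    dist = -np.log(1.0 - p)
            values[i, j] = values[j, i] = dist
    return DistanceMatrix(labels=tuple(labels), values=values)


def tree_bipartitions(tree: TreeNode) -> set:
    """Non-trivial bipartitions of an (unrooted) tree as canonical frozensets.

    Each internal edge yields the frozenset of the smaller side (ties broken
    lexicographically) of the induced leaf split.
    """
    taxa = frozenset(t.name for t in tree.tips())
    bips = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if len(side) < 2 or len(side) > len(taxa) - 2:
            continue
        bips.add(_canonical_side(side, taxa))
    return bips


def _canonical_side(side: frozenset, taxa: frozenset) -> frozenset:
    comp = taxa - side
    if len(side) < len(comp):
        return side
    if len(comp) < len(side):
        return comp
    return side if tuple(sorted(side)) < tuple(sorted(comp)) else comp


def bootstrap_support(alignment_rows, n_reps: int, seed: int) -> SupportedTree:
    """Bootstrap NJ supports from a multiple alignment.

    *alignment_rows* is a sequence of ``(label, gapped_sequence)`` pairs of
    equal length.  Columns are resampled with replacement per replicate in a
    canonical order (one draw of ``n_columns`` indices per replicate from a
    single seeded generator), so supports are invariant to taxon order.
    """
    rows = [(str(l), str(s)) for l, s in alignment_rows]
    if n_reps < 1:
        raise PhyloError("n_reps must be >= 1")
    if len(rows) < 3:
        raise PhyloError("bootstrap requires >= 3 taxa")
    lengths = {len(s) for _, s in rows}
    if len(lengths) != 1:
        raise PhyloError("alignment rows differ in length")
    # canonical taxon order for resampling and distance computation
    order = sorted(range(len(rows)), key=lambda i: rows[i][0])
    labels = [rows[i][0] for i in order]
    seqs = [rows[i][1] for i in order]
    n_cols = len(seqs[0])

    base = nj_tree(poisson_distance_matrix(labels, seqs))
    taxa = frozenset(labels)
    original = tree_bipartitions(base)
    counts = {b: 0 for b in original}

    rng = np.random.default_rng(seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for _ in range(n_reps):
            idx = rng.integers(0, n_cols, size=n_cols)
            resampled = ["".join(s[i] for i in idx) for s in seqs]
            rep = nj_tree(poisson_distance_matrix(labels, resampled))
            for b in tree_bipartitions(rep):
                if b in counts:
                    counts[b] += 1

    support = {b: 100.0 * c / n_reps for b, c in counts.items()}
    # annotate internal nodes with supports
    for node in base.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if len(side) < 2 or len(side) > len(taxa) - 2:
            continue
        key = _canonical_side(side, taxa)
        if key in support:
            node.name = f"{support[key]:.0f}"
    buf = _io.StringIO()
    base.write(buf)
    return SupportedTree(newick=buf.getvalue().strip(), support=support)


def clade_membership(tree, candidate_label: str, reference_labels) -> bool:
    """True iff *candidate_label* falls inside the smallest cluster
    (non-trivial unrooted bipartition side) containing all references.

    A star tree (no internal edges) yields False for any proper subset.
    Missing labels raise :class:`PhyloError`.
    """
    if isinstance(tree, str):
        tree = TreeNode.read(_io.StringIO(tree), convert_underscores=False)
    taxa = frozenset(t.name for t in tree.tips())
    refs = frozenset(reference_labels)
    missing = ({candidate_label} | refs) - taxa
    if missing:
        raise PhyloError(f"labels not in tree: {sorted(missing)}")
    sides = []
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if 2 <= len(side) <= len(taxa) - 2:
            sides.append(side)
            sides.append(taxa - side)
    containing = [s for s in sides if refs <= s]
    if not containing:
        return False
    smallest = min(containing, key=lambda s: (len(s), tuple(sorted(s))))
    return candidate_label in smallest


# --------------------------------------------------------------------------
# center-star progressive multiple alignment
# --------------------------------------------------------------------------

def progressive_msa(records, **align_kwargs) -> list[tuple[str, str]]:
    """Center-star multiple alignment built from pairwise global alignments.

    The center is the sequence maximizing the summed pairwise score; every
    other sequence is aligned to it and the pairwise alignments are merged
    under the once-a-gap-always-a-gap rule.
    """
    pairs = [
        (r.id, r.sequence) if hasattr(r, "id") else (r[0], r[1]) for r in records
    ]
    if len(pairs) < 2:
        raise PhyloError("progressive alignment requires >= 2 sequences")
    n = len(pairs)
    scores = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            s = align_global(pairs[i][1], pairs[j][1], **align_kwargs).score
            scores[i, j] = scores[j, i] = s
    center = int(np.argmax(scores.sum(axis=1)))
    center_seq = pairs[center][1]
    m = len(center_seq)
    # per-alignment gap profiles: gaps inserted into the center before each
    # center residue (index 0..m, m = trailing)
    alignments = {}
    gap_profile = np.zeros(m + 1, dtype=int)
    for i in range(n):
        if i == center:
            continue
        res = align_global(center_seq, pairs[i][1], **align_kwargs)
        gaps = np.zeros(m + 1, dtype=int)
        pos = 0
        run = 0
        for c in res.aligned_a:
            if c == "-":
                run += 1
            else:
                gaps[pos] = run
                run = 0
                pos += 1
        gaps[m] = run
        alignments[i] = (res.aligned_a, res.aligned_b, gaps)
        gap_profile = np.maximum(gap_profile, gaps)

    def project(aligned_center: str, aligned_other: str, gaps: np.ndarray) -> str:
        out = []
        pos = 0  # center residue index
        k = 0  # column index in this pairwise alignment
        cols = len(aligned_center)
        while pos <= m:
            run = gaps[pos]
            extra = gap_profile[pos] - run
            # columns where this pairwise alignment gaps the center
            taken = 0
            while k < cols and aligned_center[k] == "-":
                out.append(aligned_other[k])
                k += 1
                taken += 1
            out.extend("-" * extra)
            if pos < m:
                out.append(aligned_other[k])
                k += 1
            pos += 1
        return "".join(out)

    merged: list[tuple[str, str]] = []
    center_row = []
    for pos in range(m + 1):
        center_row.extend("-" * gap_profile[pos])
        if pos < m:
            center_row.append(center_seq[pos])
    merged.append((pairs[center][0], "".join(center_row)))
    for i in range(n):
        if i == center:
            continue
        ca, co, gaps = alignments[i]
        merged.append((pairs[i][0], project(ca, co, gaps)))
    width = len(merged[0][1])
    assert all(len(s) == width for _, s in merged)
    # restore input order
    by_id = dict(merged)
    return [(pid, by_id[pid]) for pid, _ in pairs]
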