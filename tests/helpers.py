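"""Independent reference implementations (oracles) used by the test suite.

These deliberately avoid the code paths they check: the motif oracle
enumerates variable-length assignments with itertools, the alignment oracle
enumerates alignments recursively, the clade oracle uses dendropy
bipartitions, and additive matrices come from dendropy-simulated trees.
"""

from __future__ import annotations

import itertools
import math
import random

import dendropy
import numpy as np
from Bio.Align import substitution_matrices

from cd28fam.motif import ElementKind, MotifPattern, UNBOUNDED_GAP_CAP

AA20 = "ACDEFGHIKLMNPQRSTVWY"


# ---------------------------------------------------------------------------
# motif matching oracle
# ---------------------------------------------------------------------------

def oracle_matches(sequence: str, pattern: MotifPattern) -> list:
    """All (start, end) matches, 1-based inclusive, by trying every start and
    every assignment of variable element lengths."""
    n = len(sequence)
    ranges = []
    for el in pattern.elements:
        hi = el.max_len if el.max_len is not None else UNBOUNDED_GAP_CAP
        ranges.append(range(el.min_len, hi + 1))
    found = set()
    for start in range(n):
        for lengths in itertools.product(*ranges):
            i = start
            ok = True
            for el, length in zip(pattern.elements, lengths):
                if i + length > n:
                    ok = False
                    break
                if el.kind in (ElementKind.FIXED, ElementKind.CLASS):
                    if sequence[i] not in el.residues:
                        ok = False
                        break
                i += length
            if ok:
                found.add((start + 1, i))
    if any(el.max_len is None for el in pattern.elements):
        by_start = {}
        for s, e in sorted(found):
            by_start.setdefault(s, e)
        found = set(by_start.items())
    return sorted(found)


def random_notation(rng: np.random.Generator, n_elements: int) -> str:
    """A random consensus string in the supported dialect (bounded only)."""
    tokens = []
    for _ in range(n_elements):
        kind = rng.integers(0, 4)
        if kind == 0:
            tokens.append(str(rng.choice(list(AA20))))
        elif kind == 1:
            k = int(rng.integers(2, 4))
            letters = rng.choice(list(AA20), size=k, replace=False)
            tokens.append("[" + "/".join(letters) + "]")
        elif kind == 2:
            n = int(rng.integers(1, 4))
            tokens.append("x" if n == 1 else f"x_{n}")
        else:
            lo = int(rng.integers(0, 3))
            hi = lo + int(rng.integers(1, 3))
            tokens.append(f"x_{lo}/{hi}")
    return "-".join(tokens)


def random_sequence(rng: np.random.Generator, max_len: int, alphabet: str = AA20) -> str:
    n = int(rng.integers(0, max_len + 1))
    return "".join(rng.choice(list(alphabet), size=n)) if n else ""


# ---------------------------------------------------------------------------
# affine-gap global alignment oracle
# ---------------------------------------------------------------------------

def oracle_alignment_score(
    a: str, b: str, matrix_name: str = "BLOSUM62", gap_open: float = -11.0, gap_extend: float = -1.0
) -> float:
    """Best global alignment score by exhaustive recursion over all
    alignments, with affine gaps (a gap of k costs open + (k-1) * extend)."""
    sub = substitution_matrices.load(matrix_name)
    best = -math.inf

    def rec(i: int, j: int, score: float, prev: str) -> None:
        nonlocal best
        if i == len(a) and j == len(b):
            best = max(best, score)
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, score + sub[a[i], b[j]], "M")
        if i < len(a):
            rec(i + 1, j, score + (gap_extend if prev == "D" else gap_open), "D")
        if j < len(b):
            rec(i, j + 1, score + (gap_extend if prev == "I" else gap_open), "I")

    rec(0, 0, 0.0, "")
    return best


# ---------------------------------------------------------------------------
# clade membership oracle (dendropy bipartitions)
# ---------------------------------------------------------------------------

def oracle_clade_membership(newick: str, candidate: str, references) -> bool:
    tree = dendropy.Tree.get(data=newick, schema="newick")
    taxa = frozenset(t.label for t in tree.taxon_namespace)
    refs = frozenset(references)
    tree.encode_bipartitions()
    sides = []
    for bp in tree.bipartition_encoding:
        side = frozenset(
            t.label for t in tree.taxon_namespace.bitmask_taxa_list(bp.leafset_bitmask)
        )
        if 2 <= len(side) <= len(taxa) - 2:
            sides.append(side)
            sides.append(taxa - side)
    containing = [s for s in sides if refs <= s]
    if not containing:
        return False
    smallest = min(containing, key=lambda s: (len(s), tuple(sorted(s))))
    return candidate in smallest


# ---------------------------------------------------------------------------
# random additive distance matrices from simulated trees
# ---------------------------------------------------------------------------

def random_additive_matrix(n_taxa: int, seed: int):
    """(labels, matrix, newick) for a random binary tree with positive branch
    lengths; the matrix is exactly additive on that tree."""
    taxa = [f"t{i}" for i in range(n_taxa)]
    tns = dendropy.TaxonNamespace(taxa)
    tree = dendropy.simulate.treesim.birth_death_tree(
        birth_rate=1.0,
        death_rate=0.0,
        num_extant_tips=n_taxa,
        taxon_namespace=tns,
        rng=random.Random(seed),
    )
    rng = random.Random(seed + 1)
    for edge in tree.edges():
        if edge.length is None or edge.length <= 0:
            edge.length = rng.uniform(0.05, 1.0)
    pdm = tree.phylogenetic_distance_matrix()
    m = np.zeros((n_taxa, n_taxa))
    for i, ta in enumerate(tns):
        for j, tb in enumerate(tns):
            if i != j:
                m[i, j] = pdm.patristic_distance(ta, tb)
    return tuple(t.label for t in tns), m, tree.as_string(schema="newick")


def random_resolved_newick(n_taxa: int, seed: int) -> str:
    """Random binary tree in newick form (unit branch lengths)."""
    return random_additive_matrix(n_taxa, seed)[2]
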