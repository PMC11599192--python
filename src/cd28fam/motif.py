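"""Degenerate consensus-motif patterns: parsing and scanning.

The CD28-family literature writes diagnostic motifs in a compact consensus
dialect, e.g. ``[M/L/I]-[Y/F]-P-P-P-Y`` (a residue class followed by fixed
residues), ``YxCx_6_PPPx_4/5_GxG`` (wildcards with subscripted run lengths,
including a bounded 4-to-5 run), or ``[I,V]xYxxL (X)_n VTYxxV`` (an ITIM and
ITSM joined by an unbounded spacer).  This module compiles that dialect into
:class:`MotifPattern` objects and finds all occurrences in protein sequences.

Grammar accepted by :func:`compile_pattern`:

* ``A`` — a single upper-case standard amino-acid letter (FIXED element);
* ``[A/B/C]`` or ``[A,B,C]`` — a residue class of >= 2 letters (CLASS);
* ``x`` — one wildcard position;
* ``x_N`` — N wildcard positions;
* ``x_N/M`` — an N-to-M residue bounded spacer;
* ``(X)_n`` — an unbounded spacer (bounded at 60 residues for matching);
* ``-`` and whitespace — cosmetic separators, ignored.

Coordinates are 1-based inclusive throughout, matching the residue-numbering
style used for IgV framework positions (e.g. C23, W41).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional, Sequence

from .errors import MotifParseError, SequenceError

AA20 = frozenset("ACDEFGHIKLMNPQRSTVWY")
#: residues accepted in scanned sequences; X is an assembly-gap ambiguity code
SEQUENCE_ALPHABET = AA20 | {"X"}

#: matching bound substituted for an unbounded ``(X)_n`` spacer.  60 residues
#: covers any plausible ITIM-to-ITSM spacing within a cytoplasmic tail.
UNBOUNDED_GAP_CAP = 60


class ElementKind(str, Enum):
    FIXED = "FIXED"
    CLASS = "CLASS"
    WILDCARD = "WILDCARD"
    GAP = "GAP"


@dataclass(frozen=True)
class PatternElement:
    """One token of a compiled consensus pattern."""

    kind: ElementKind
    residues: frozenset = frozenset()
    min_len: int = 1
    max_len: Optional[int] = 1  # None = unbounded (GAP only)

    def __post_init__(self):
        if self.kind is ElementKind.FIXED and len(self.residues) != 1:
            raise MotifParseError("FIXED element requires exactly one residue")
        if self.kind is ElementKind.CLASS:
            if len(self.residues) < 2 or not self.residues <= AA20:
                raise MotifParseError("CLASS element requires >=2 standard residues")
        if self.kind is ElementKind.WILDCARD:
            if self.min_len != self.max_len or self.min_len < 1:
                raise MotifParseError("WILDCARD element requires min_len == max_len >= 1")
        if self.kind is ElementKind.GAP:
            if self.max_len is not None and self.min_len > self.max_len:
                raise MotifParseError("GAP element requires min_len <= max_len")


@dataclass(frozen=True)
class MotifPattern:
    """A compiled degenerate consensus, with residue-span bounds."""

    name: str
    elements: tuple
    min_span: int = field(default=0)
    max_span: Optional[int] = field(default=0)  # None if any GAP is unbounded
    notation: str = ""

    @property
    def has_unbounded_gap(self) -> bool:
        return any(e.max_len is None for e in self.elements)


@dataclass(frozen=True)
class MotifMatch:
    """One occurrence of a pattern; coordinates 1-based inclusive."""

    pattern_name: str
    start: int
    end: int
    matched_span: str


def _spans(elements: Sequence[PatternElement]):
    min_span = sum(e.min_len for e in elements)
    if any(e.max_len is None for e in elements):
        return min_span, None
    return min_span, sum(e.max_len for e in elements)


def compile_pattern(notation: str, name: Optional[str] = None) -> MotifPattern:
    """Compile consensus notation into a :class:`MotifPattern`.

    Raises :class:`MotifParseError` naming the offending token and position
    (0-based index into the notation string) on malformed input.
    """
    elements: list[PatternElement] = []
    i, n = 0, len(notation)
    while i < n:
        c = notation[i]
        if c in "- \t\n":
            i += 1
        elif c == "[":
            j = notation.find("]", i)
            if j < 0:
                raise MotifParseError(
                    f"unterminated class at position {i}", token=notation[i:], position=i
                )
            body = notation[i + 1 : j]
            letters = [t.strip() for t in body.replace(",", "/").split("/") if t.strip()]
            if not letters:
                raise MotifParseError(f"empty class at position {i}", token=notation[i : j + 1], position=i)
            for t in letters:
                if len(t) != 1 or t not in AA20:
                    raise MotifParseError(
                        f"invalid class member {t!r} at position {i}",
                        token=t,
                        position=i,
                    )
            residues = frozenset(letters)
            if len(residues) < 2:
                raise MotifParseError(
                    f"class with fewer than two distinct residues at position {i}",
                    token=notation[i : j + 1],
                    position=i,
                )
            elements.append(PatternElement(ElementKind.CLASS, residues))
            i = j + 1
        elif c == "(":
            # unbounded spacer written (X)_n, optional trailing underscore
            for form in ("(X)_n_", "(X)_n"):
                if notation.startswith(form, i):
                    elements.append(PatternElement(ElementKind.GAP, min_len=0, max_len=None))
                    i += len(form)
                    break
            else:
                raise MotifParseError(
                    f"malformed spacer at position {i}", token=notation[i : i + 6], position=i
                )
        elif c == "x":
            i += 1
            if i < n and notation[i] == "_":
                i += 1
                j = i
                while j < n and notation[j].isdigit():
                    j += 1
                if j == i:
                    raise MotifParseError(
                        f"missing run length after 'x_' at position {i}",
                        token=notation[i - 2 : i + 1],
                        position=i,
                    )
                lo = int(notation[i:j])
                i = j
                if i < n and notation[i] == "/":
                    i += 1
                    j = i
                    while j < n and notation[j].isdigit():
                        j += 1
                    if j == i:
                        raise MotifParseError(
                            f"missing upper bound after '/' at position {i}",
                            token=notation[i - 1 : i + 1],
                            position=i,
                        )
                    hi = int(notation[i:j])
                    i = j
                    elements.append(PatternElement(ElementKind.GAP, min_len=lo, max_len=hi))
                else:
                    if lo < 1:
                        raise MotifParseError(
                            f"wildcard run length must be >= 1 at position {i}",
                            token=str(lo),
                            position=i,
                        )
                    elements.append(PatternElement(ElementKind.WILDCARD, min_len=lo, max_len=lo))
                if i < n and notation[i] == "_":  # closing subscript underscore
                    i += 1
            else:
                elements.append(PatternElement(ElementKind.WILDCARD, min_len=1, max_len=1))
        elif c in AA20:
            elements.append(PatternElement(ElementKind.FIXED, frozenset(c)))
            i += 1
        else:
            raise MotifParseError(
                f"unexpected token {c!r} at position {i}", token=c, position=i
            )
    if not elements:
        raise MotifParseError("empty pattern", token=notation, position=0)
    min_span, max_span = _spans(elements)
    return MotifPattern(
        name=name or notation,
        elements=tuple(elements),
        min_span=min_span,
        max_span=max_span,
        notation=notation,
    )


def _validate_sequence(sequence: str) -> None:
    for pos, c in enumerate(sequence, start=1):
        if c not in SEQUENCE_ALPHABET:
            raise SequenceError(f"invalid residue {c!r} at position {pos}")


def _match_ends(seq: str, i: int, elements: tuple, j: int, limit: int) -> Iterable[int]:
    """Yield 0-based exclusive end indices of matches of elements[j:] at i."""
    if j == len(elements):
        yield i
        return
    el = elements[j]
    if el.kind in (ElementKind.FIXED, ElementKind.CLASS):
        # X never satisfies a FIXED/CLASS position (conservative for
        # gap-filled gene models); el.residues never contains X.
        if i < limit and seq[i] in el.residues:
            yield from _match_ends(seq, i + 1, elements, j + 1, limit)
    else:  # WILDCARD or GAP: any valid residue, including X
        hi = el.max_len if el.max_len is not None else UNBOUNDED_GAP_CAP
        hi = min(hi, limit - i)
        for length in range(el.min_len, hi + 1):
            yield from _match_ends(seq, i + length, elements, j + 1, limit)


def scan(
    sequence: str,
    pattern: MotifPattern,
    window: Optional[tuple[int, int]] = None,
) -> list[MotifMatch]:
    """Find all occurrences of *pattern* in *sequence*.

    All overlapping matches are reported, sorted by start then end.  For
    patterns containing an unbounded spacer only the minimal match (shortest
    end) per start is reported.  When *window* (1-based closed interval) is
    given, matches are restricted to lie entirely inside it.
    """
    _validate_sequence(sequence)
    n = len(sequence)
    if window is None:
        lo, hi = 1, n
    else:
        lo, hi = window
        if lo < 1 or hi > n or lo > hi:
            if n == 0 or lo > hi:
                return []
            raise SequenceError(f"window {window} outside sequence bounds [1, {n}]")
    out: list[MotifMatch] = []
    for start0 in range(lo - 1, hi):  # 0-based start
        ends = sorted(set(_match_ends(sequence, start0, pattern.elements, 0, hi)))
        if not ends:
            continue
        if pattern.has_unbounded_gap:
            ends = ends[:1]
        for end0 in ends:
            out.append(
                MotifMatch(
                    pattern_name=pattern.name,
                    start=start0 + 1,
                    end=end0,
                    matched_span=sequence[start0:end0],
                )
            )
    out.sort(key=lambda m: (m.start, m.end))
    return out


def brute_force_scan(
    sequence: str,
    pattern: MotifPattern,
) -> list[tuple[int, int]]:
    """Exhaustive reference matcher: tries every start and every assignment
    of variable element lengths.  Quadratic-ish; for testing only."""
    _validate_sequence(sequence)
    n = len(sequence)
    var_ranges = []
    for el in pattern.elements:
        hi = el.max_len if el.max_len is not None else UNBOUNDED_GAP_CAP
        var_ranges.append(range(el.min_len, hi + 1))
    found = set()
    for start0 in range(n):
        for lengths in itertools.product(*var_ranges):
            i = start0
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
                found.add((start0 + 1, i))
    if pattern.has_unbounded_gap:
        minimal = {}
        for s, e in sorted(found):
            minimal.setdefault(s, e)
        found = {(s, e) for s, e in minimal.items()}
    return sorted(found)


def matches_to_tsv(matches_by_sequence: dict[str, list[MotifMatch]]) -> str:
    """Render matches as TSV: sequence_id, pattern_name, start, end, span."""
    lines = ["sequence_id\tpattern_name\tstart\tend\tspan"]
    for seq_id, matches in matches_by_sequence.items():
        for m in matches:
            lines.append(f"{seq_id}\t{m.pattern_name}\t{m.start}\t{m.end}\t{m.matched_span}")
    return "\n".join(lines) + "\n"
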