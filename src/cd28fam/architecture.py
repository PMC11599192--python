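"""Type-I membrane protein segmentation and IgV framework diagnostics.

CD28-family receptors share a leader / single IgV ectodomain / stalk / TM /
cytoplasmic-tail architecture.  This module infers that segmentation from the
sequence alone:

* transmembrane segments from Kyte-Doolittle hydropathy (window 19, mean
  threshold 1.6, ends trimmed back to hydrophobic residues);
* the IgV domain from its framework triple — a cysteine pair forming the
  intradomain disulfide plus the conserved tryptophan (canonical C23/W41
  numbering), with spacing windows C->W in [10, 25] and C->C in [50, 85];
* the leader peptide from hydrophobicity of the N-terminal residues.

From the segmentation, motif-evaluation windows (CDR3 neighborhood, G strand,
E strand, TM, cytoplasmic, C terminus) are derived for the classifier.

All coordinates are 1-based inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from Bio.SeqUtils.ProtParamData import kd as KYTE_DOOLITTLE

from .errors import SegmentationError, SequenceError
from .motif import SEQUENCE_ALPHABET

TM_WINDOW = 19
TM_THRESHOLD = 1.6
TM_MIN_LEN = 15
LEADER_THRESHOLD = 1.0
LEADER_LEN = 18  # typical signal-peptide length used when a leader is called
#: trim hydropathy-window overhang back to residues at least this hydrophobic
TM_TRIM_THRESHOLD = 1.0

# IgV framework spacing windows (residues), bracketing canonical C23/W41/C104
CW_SPACING = (10, 25)
CC_SPACING = (50, 85)
# IgV interval relative to the framework cysteines: the first framework
# cysteine sits 22 residues into the domain (C23 numbering) and the G strand
# ends ~13 residues after the second cysteine.
IGV_BEFORE_CYS1 = 22
IGV_AFTER_CYS2 = 13
# size range of a candidate (possibly divergent) IgV-sized span before the TM
IGV_SPAN_RANGE = (55, 130)

CTERM_LEN = 20  # C-terminal window for "closer to the C terminus" motifs


def _hydropathy(residue: str) -> float:
    return KYTE_DOOLITTLE.get(residue, 0.0)


@dataclass(frozen=True)
class ProteinRecord:
    id: str
    sequence: str
    provided_regions: tuple = ()  # of (region_name, start, end)

    def __post_init__(self):
        if not self.sequence:
            raise SequenceError(f"record {self.id!r}: empty sequence")
        for pos, c in enumerate(self.sequence, start=1):
            if c not in SEQUENCE_ALPHABET:
                raise SequenceError(
                    f"record {self.id!r}: invalid residue {c!r} at position {pos}"
                )
        n = len(self.sequence)
        seen: list[tuple[int, int]] = []
        for name, start, end in self.provided_regions:
            if not (1 <= start <= end <= n):
                raise SequenceError(
                    f"record {self.id!r}: region {name} interval ({start},{end}) out of bounds"
                )
            for s, e in seen:
                if start <= e and s <= end:
                    raise SequenceError(f"record {self.id!r}: overlapping provided regions")
            seen.append((start, end))


@dataclass(frozen=True)
class ArchitectureCall:
    """Segmentation of a receptor into its canonical regions."""

    regions: dict  # region name -> (start, end), 1-based inclusive
    has_single_igv: bool
    igv_cys1: Optional[int] = None
    igv_cys2: Optional[int] = None
    igv_trp: Optional[int] = None
    tm_interval: Optional[tuple[int, int]] = None
    cyt_length: int = 0
    igv_divergent: bool = False


def detect_tm(sequence: str) -> list[tuple[int, int]]:
    """Detect candidate transmembrane segments.

    Maximal unions of 19-residue windows with mean Kyte-Doolittle hydropathy
    >= 1.6, merged when overlapping, with window overhang trimmed back to
    hydrophobic end residues; intervals shorter than 15 residues are dropped.
    Sequences shorter than the window yield an empty list.
    """
    n = len(sequence)
    if n < TM_WINDOW:
        return []
    values = [_hydropathy(c) for c in sequence]
    running = sum(values[:TM_WINDOW])
    hits = []
    for i in range(n - TM_WINDOW + 1):  # 0-based window start
        if i > 0:
            running += values[i + TM_WINDOW - 1] - values[i - 1]
        if running / TM_WINDOW >= TM_THRESHOLD:
            hits.append((i, i + TM_WINDOW - 1))
    if not hits:
        return []
    merged = [list(hits[0])]
    for s, e in hits[1:]:
        if s <= merged[-1][1] + 1:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    out = []
    for s, e in merged:
        while s < e and values[s] < TM_TRIM_THRESHOLD:
            s += 1
        while e > s and values[e] < TM_TRIM_THRESHOLD:
            e -= 1
        if e - s + 1 >= TM_MIN_LEN:
            out.append((s + 1, e + 1))
    return out


def check_igv(
    sequence: str, search_interval: tuple[int, int]
) -> tuple[bool, Optional[int], Optional[int], Optional[int], bool]:
    """Look for the IgV framework C/W/C triple inside *search_interval*.

    Returns ``(has_igv, cys1, cys2, trp, divergent_flag)``.  When several
    candidate triples exist the leftmost first cysteine, then the smallest
    second cysteine, then the smallest tryptophan is reported.  The divergent
    flag is set when no triple exists but the searched span is large enough to
    hold an IgV-sized domain.
    """
    lo, hi = search_interval
    n = len(sequence)
    if not (1 <= lo <= hi <= n):
        raise SequenceError(f"search interval ({lo},{hi}) outside bounds [1,{n}]")
    segment = sequence[lo - 1 : hi]
    cys = [lo + i for i, c in enumerate(segment) if c == "C"]
    trp = [lo + i for i, c in enumerate(segment) if c == "W"]
    for p1 in cys:
        for p3 in cys:
            if not (CC_SPACING[0] <= p3 - p1 <= CC_SPACING[1]):
                continue
            for p2 in trp:
                if CW_SPACING[0] <= p2 - p1 <= CW_SPACING[1]:
                    return True, p1, p3, p2, False
    divergent = (hi - lo + 1) >= IGV_SPAN_RANGE[0]
    return False, None, None, None, divergent


def segment(record: ProteinRecord) -> ArchitectureCall:
    """Segment a record into leader/IgV/stalk/TM/cytoplasmic regions.

    ``provided_regions`` take precedence over inference; inference fills in
    the remaining regions around them.  Raises :class:`SegmentationError`
    when no TM segment is detected and none is provided.
    """
    seq = record.sequence
    n = len(seq)
    provided = {name: (s, e) for name, s, e in record.provided_regions}
    regions: dict[str, tuple[int, int]] = {}

    # --- membrane anchor ---
    if "TM" in provided:
        tm = provided["TM"]
    else:
        candidates = detect_tm(seq)
        # the last TM before the C terminus that leaves >= 8 downstream
        # residues is taken as the membrane anchor
        candidates = [c for c in candidates if n - c[1] >= 8]
        if not candidates:
            raise SegmentationError(
                f"record {record.id!r}: not a candidate type-I membrane protein"
            )
        tm = candidates[-1]
    regions["TM"] = tm

    # --- leader ---
    if "leader" in provided:
        leader_end = provided["leader"][1]
        regions["leader"] = provided["leader"]
    elif n >= 16 and sum(_hydropathy(c) for c in seq[1:16]) / 15 >= LEADER_THRESHOLD:
        leader_end = min(LEADER_LEN, tm[0] - 1)
        regions["leader"] = (1, leader_end)
    else:
        leader_end = 0

    # --- IgV ---
    igv_divergent = False
    cys1 = cys2 = trp = None
    has_igv = False
    if "IgV" in provided:
        regions["IgV"] = provided["IgV"]
        has_igv = True
        igv_lo, igv_hi = provided["IgV"]
        found, cys1, cys2, trp, _ = check_igv(seq, (igv_lo, igv_hi))
        has_single_igv = True
    else:
        search_lo = leader_end + 1
        search_hi = tm[0] - 1
        has_single_igv = False
        if search_hi - search_lo >= 0 and search_hi >= search_lo:
            has_igv, cys1, cys2, trp, igv_divergent = check_igv(seq, (search_lo, search_hi))
            if has_igv:
                igv_lo = max(search_lo, cys1 - IGV_BEFORE_CYS1)
                igv_hi = min(search_hi, cys2 + IGV_AFTER_CYS2)
                regions["IgV"] = (igv_lo, igv_hi)
                # a second disjoint framework triple before the TM means the
                # record is not a single-IgV receptor
                second = False
                if cys2 + 1 <= search_hi:
                    second, *_ = check_igv(seq, (cys2 + 1, search_hi))
                has_single_igv = not second
        else:
            igv_divergent = False

    # --- stalk & cytoplasmic ---
    if "IgV" in regions and regions["IgV"][1] + 1 <= tm[0] - 1:
        regions["stalk"] = (regions["IgV"][1] + 1, tm[0] - 1)
    cyt_length = n - tm[1]
    if cyt_length > 0:
        regions["cytoplasmic"] = (tm[1] + 1, n)

    return ArchitectureCall(
        regions=regions,
        has_single_igv=has_single_igv,
        igv_cys1=cys1,
        igv_cys2=cys2,
        igv_trp=trp,
        tm_interval=tm,
        cyt_length=cyt_length,
        igv_divergent=igv_divergent,
    )


def motif_windows(arch: ArchitectureCall, sequence_length: int) -> dict:
    """Derive the motif-evaluation windows from a segmentation.

    CDR3 neighborhood = [cys2 - 5, cys2 + 30] (the CDR3 loop follows the
    second framework cysteine); G strand = last 15 residues of the IgV
    interval; E strand = [cys1 + 30, cys1 + 50]; TM and cytoplasmic as
    segmented; C terminus = last 20 residues.  Windows are clipped to the
    sequence; regions without the prerequisites are absent from the result.
    """
    n = sequence_length

    def clip(lo: int, hi: int) -> Optional[tuple[int, int]]:
        lo, hi = max(1, lo), min(n, hi)
        return (lo, hi) if lo <= hi else None

    windows: dict[str, tuple[int, int]] = {}
    if arch.igv_cys2 is not None:
        w = clip(arch.igv_cys2 - 5, arch.igv_cys2 + 30)
        if w:
            windows["CDR3_NEIGHBORHOOD"] = w
    if "IgV" in arch.regions:
        lo, hi = arch.regions["IgV"]
        w = clip(hi - 14, hi)
        if w:
            windows["G_STRAND"] = w
    if arch.igv_cys1 is not None:
        w = clip(arch.igv_cys1 + 30, arch.igv_cys1 + 50)
        if w:
            windows["E_STRAND"] = w
    if arch.tm_interval is not None:
        windows["TM"] = arch.tm_interval
    if "cytoplasmic" in arch.regions:
        windows["CYTOPLASMIC"] = arch.regions["cytoplasmic"]
    w = clip(n - CTERM_LEN + 1, n)
    if w:
        windows["CTERM"] = w
    return windows
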