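"""Readers, writers and run configuration.

Conventions: FASTA via Biopython with ids taken up to the first whitespace
and 60-column wrapping on write; gene-order tables as 6-column TSV
(species, chromosome, gene, start, end, strand; coordinates 1-based
inclusive) or BED6 (chrom, start, end, name, score, strand; 0-based
half-open — each dialect follows its own standard, converted centrally
here).  Reports are TSV with a ``#`` header echoing the run configuration
and seed.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Iterable, Optional

import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .architecture import ProteinRecord
from .errors import SequenceError, TableError
from .synteny import Gene, GeneOrderTable


@dataclass
class RunConfig:
    catalog_path: Optional[str] = None
    score_threshold: int = 4
    margin: int = 2
    synteny_k: int = 10
    max_gap: int = 1
    min_shared: int = 2
    substitution_matrix: str = "BLOSUM62"
    gap_open: float = -11.0
    gap_extend: float = -1.0
    n_reps: int = 100
    seed: int = 0

    def __post_init__(self):
        for name in ("score_threshold", "margin", "synteny_k", "min_shared"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)

    def header_lines(self) -> list[str]:
        return [f"# {k}={v}" for k, v in asdict(self).items()]


# --------------------------------------------------------------------------
# FASTA
# --------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[ProteinRecord]:
    records = []
    seen = set()
    duplicates = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            duplicates.append(rec.id)
        seen.add(rec.id)
        records.append(ProteinRecord(id=rec.id, sequence=str(rec.seq).upper()))
    if duplicates:
        raise SequenceError(f"duplicate ids in {path}: {sorted(set(duplicates))}")
    if not records:
        raise SequenceError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records
    ]
    with open(path, "w") as fh:
        SeqIO.write(seq_records, fh, "fasta")  # Biopython wraps at 60 columns


# --------------------------------------------------------------------------
# gene-order tables
# --------------------------------------------------------------------------

TSV_COLUMNS = ("species", "chromosome", "gene", "start", "end", "strand")


def read_gene_table(path: str | Path, dialect: Optional[str] = None) -> GeneOrderTable:
    """Read one gene-order table from TSV (1-based inclusive) or BED6
    (0-based half-open).  The dialect is inferred from the extension when not
    given (``.bed`` -> BED)."""
    path = Path(path)
    if dialect is None:
        dialect = "bed" if path.suffix.lower() == ".bed" else "tsv"
    rows = []
    for ln, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.rstrip("\r")
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if dialect == "tsv" and parts[: len(TSV_COLUMNS)] == list(TSV_COLUMNS):
            continue  # header row
        if len(parts) < 6:
            raise TableError(f"{path}:{ln}: expected 6 columns, got {len(parts)}")
        rows.append((ln, parts))
    if not rows:
        raise TableError(f"{path}: empty gene table")
    genes = []
    species = chromosome = None
    for ln, parts in rows:
        if dialect == "tsv":
            sp, chrom, name, start, end, strand = parts[:6]
            start_i, end_i = int(start), int(end)
        else:  # BED6: chrom, start, end, name, score, strand
            chrom, start, end, name, _score, strand = parts[:6]
            sp = path.stem
            start_i, end_i = int(start) + 1, int(end)  # to 1-based inclusive
        if species is None:
            species, chromosome = sp, chrom
        genes.append(Gene(name=name, start=start_i, end=end_i, strand=strand))
    for i in range(1, len(genes)):
        if genes[i].start <= genes[i - 1].start:
            raise TableError(
                f"{path}: unsorted coordinates at gene {genes[i].name!r} "
                f"(start {genes[i].start} after {genes[i - 1].start})"
            )
    return GeneOrderTable(species=species, chromosome=chromosome, genes=tuple(genes))


def write_gene_table(table: GeneOrderTable, path: str | Path) -> None:
    lines = ["\t".join(TSV_COLUMNS)]
    for g in table.genes:
        lines.append(
            f"{table.species}\t{table.chromosome}\t{g.name}\t{g.start}\t{g.end}\t{g.strand}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


# --------------------------------------------------------------------------
# reports
# --------------------------------------------------------------------------

ASSIGNMENT_COLUMNS = (
    "sequence_id",
    "label",
    "score",
    "runner_up_label",
    "runner_up_score",
    "architecture_pass",
    "evidence",
    "missing_required",
    "note",
)


def write_assignments(assignments: dict, path: str | Path, config: Optional[RunConfig] = None) -> None:
    """Write ``{sequence_id: FamilyAssignment}`` as TSV."""
    lines = list(config.header_lines()) if config else []
    lines.append("\t".join(ASSIGNMENT_COLUMNS))
    for seq_id, a in assignments.items():
        ev = ";".join(
            f"{e.source}:{e.detail}@{e.region or '-'}:{e.weight_points}" for e in a.evidence
        )
        lines.append(
            "\t".join(
                [
                    seq_id,
                    a.label,
                    str(a.score),
                    str(a.runner_up_label),
                    str(a.runner_up_score),
                    str(a.architecture_pass),
                    ev,
                    ";".join(a.missing_required),
                    a.note,
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_assignments(path: str | Path) -> "pd.DataFrame":
    import pandas as pd

    return pd.read_csv(path, sep="\t", comment="#")


def write_matrix(df, path: str | Path, config: Optional[RunConfig] = None) -> None:
    header = "".join(line + "\n" for line in (config.header_lines() if config else []))
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, sep="\t")


def write_newick(newick: str, path: str | Path) -> None:
    Path(path).write_text(newick.strip() + "\n")
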