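"""On-disk formats: oligos primer files, FASTA, taxonomy, result tables.

Conventions
-----------
* FASTA record ids are the first whitespace-delimited header token, so they
  line up with taxonomy-file identifiers.
* The taxonomy file for ``db.fasta`` is ``db.tax`` unless given explicitly.
* Written files use 1-based inclusive coordinates; everything in memory is
  0-based half-open.
* Gzip-compressed FASTA/taxonomy (``.gz``) is read transparently.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, TextIO, Union

from Bio import SeqIO

from .match_engine import IUPAC_CODES

logger = logging.getLogger(__name__)

__all__ = [
    "OligosParseError",
    "PrimerRecord",
    "TargetRecord",
    "Lineage",
    "parse_oligos",
    "read_oligos",
    "serialize_oligos",
    "read_fasta",
    "read_taxonomy",
    "locate_taxonomy",
    "write_coverage_table",
    "write_per_group_table",
    "write_amplicon_fasta",
]

_ROLES = ("forward", "reverse", "pair", "unknown")


class OligosParseError(ValueError):
    """Raised for malformed or invalid oligos input, with a line number."""


def _check_iupac(seq: str, lineno: Optional[int] = None) -> str:
    seq = seq.upper()
    for ch in seq:
        if ch not in IUPAC_CODES:
            where = f" on line {lineno}" if lineno is not None else ""
            raise OligosParseError(
                f"non-IUPAC character {ch!r} in sequence {seq!r}{where}"
            )
    if not seq:
        raise OligosParseError(f"empty sequence on line {lineno}")
    return seq


def _is_iupac(tok: str) -> bool:
    return bool(tok) and all(c in IUPAC_CODES for c in tok.upper())


@dataclass(frozen=True)
class PrimerRecord:
    """One oligos entry: a single primer or a forward/reverse pair."""

    name: str
    role: str
    sequence: Optional[str] = None
    fwd_sequence: Optional[str] = None
    rev_sequence: Optional[str] = None

    def __post_init__(self) -> None:
        if self.role not in _ROLES:
            raise ValueError(f"unknown primer role: {self.role!r}")
        if self.role == "pair":
            if not (self.fwd_sequence and self.rev_sequence) or self.sequence:
                raise ValueError("pair records need exactly fwd and rev sequences")
        else:
            if not self.sequence or self.fwd_sequence or self.rev_sequence:
                raise ValueError(f"{self.role} records need exactly one sequence")

    @property
    def is_pair(self) -> bool:
        return self.role == "pair"


@dataclass(frozen=True)
class TargetRecord:
    """One database sequence, optionally carrying its lineage."""

    id: str
    sequence: str
    lineage: Optional["Lineage"] = None


@dataclass(frozen=True)
class Lineage:
    """An ordered (level_name, taxon) classification for one sequence."""

    levels: tuple

    @property
    def level_names(self) -> tuple:
        return tuple(name for name, _ in self.levels)

    @property
    def taxa(self) -> tuple:
        return tuple(taxon for _, taxon in self.levels)

    def prefix_key(self, depth: int) -> str:
        """Join the first ``depth`` taxon names with ';' (a clade key)."""
        return ";".join(self.taxa[:depth])


def parse_oligos(text: str) -> list:
    """Parse oligos-format text into :class:`PrimerRecord` objects.

    Recognised keywords: ``forward SEQ [NAME]``, ``reverse SEQ [NAME]``,
    ``primer FWD REV [NAME]``. ``barcode`` lines are skipped with a warning.
    A line whose leading token is not a keyword is accepted as an
    unknown-role primer when it carries a valid IUPAC sequence (either as
    its first or second field). Blank lines and ``#`` comments are skipped.
    Records missing a name get ``primer_<k>`` (k = 1-based record index).
    """
    records: list = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        tokens = line.split()
        keyword = tokens[0].lower()
        k = len(records) + 1

        if keyword in ("forward", "reverse"):
            if len(tokens) not in (2, 3):
                raise OligosParseError(
                    f"line {lineno}: expected '{keyword} SEQ [NAME]', got "
                    f"{len(tokens)} fields"
                )
            seq = _check_iupac(tokens[1], lineno)
            name = tokens[2] if len(tokens) == 3 else f"primer_{k}"
            records.append(PrimerRecord(name=name, role=keyword, sequence=seq))
        elif keyword == "primer":
            if len(tokens) not in (3, 4):
                raise OligosParseError(
                    f"line {lineno}: expected 'primer FWD REV [NAME]', got "
                    f"{len(tokens)} fields"
                )
            fwd = _check_iupac(tokens[1], lineno)
            rev = _check_iupac(tokens[2], lineno)
            name = tokens[3] if len(tokens) == 4 else f"primer_{k}"
            records.append(
                PrimerRecord(name=name, role="pair", fwd_sequence=fwd, rev_sequence=rev)
            )
        elif keyword == "barcode":
            logger.warning("line %d: barcode entries are not analysed, skipped", lineno)
        elif _is_iupac(tokens[0]) and len(tokens) <= 2:
            # bare sequence line -> unknown-role primer
            seq = _check_iupac(tokens[0], lineno)
            name = tokens[1] if len(tokens) == 2 else f"primer_{k}"
            records.append(PrimerRecord(name=name, role="unknown", sequence=seq))
        elif len(tokens) >= 2 and _is_iupac(tokens[1]):
            # unrecognised keyword but a valid sequence in field 2
            if len(tokens) > 3:
                raise OligosParseError(
                    f"line {lineno}: too many fields for a primer entry"
                )
            seq = _check_iupac(tokens[1], lineno)
            name = tokens[2] if len(tokens) == 3 else f"primer_{k}"
            records.append(PrimerRecord(name=name, role="unknown", sequence=seq))
        else:
            raise OligosParseError(
                f"line {lineno}: unrecognised keyword {tokens[0]!r} and no valid "
                "IUPAC sequence found"
            )
    return records


def read_oligos(path: Union[str, Path]) -> list:
    """Read and parse an oligos file from disk."""
    return parse_oligos(Path(path).read_text())


def serialize_oligos(records: Iterable[PrimerRecord]) -> str:
    """Emit canonical oligos lines; ``parse_oligos`` round-trips the result."""
    lines = []
    for rec in records:
        if rec.role == "pair":
            lines.append(f"primer {rec.fwd_sequence} {rec.rev_sequence} {rec.name}")
        elif rec.role == "unknown":
            lines.append(f"{rec.sequence} {rec.name}")
        else:
            lines.append(f"{rec.role} {rec.sequence} {rec.name}")
    return "\n".join(lines) + ("\n" if lines else "")


def _open_text(path: Union[str, Path]) -> TextIO:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_fasta(path: Union[str, Path]) -> list:
    """Read a (possibly gzipped) FASTA file into :class:`TargetRecord` list.

    Ids are the first header token; sequences are uppercased with internal
    whitespace removed. Duplicate ids and empty files are errors.
    """
    records: list = []
    seen: dict = {}
    with _open_text(path) as handle:
        for seq_rec in SeqIO.parse(handle, "fasta"):
            rid = seq_rec.id
            seen[rid] = seen.get(rid, 0) + 1
            records.append(TargetRecord(id=rid, sequence=str(seq_rec.seq).upper()))
    dupes = sorted(rid for rid, n in seen.items() if n > 1)
    if dupes:
        raise ValueError(f"duplicate FASTA ids in {path}: {', '.join(dupes)}")
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def locate_taxonomy(fasta_path: Union[str, Path]) -> Path:
    """Default taxonomy location: the FASTA path with its extension -> .tax."""
    p = Path(fasta_path)
    if p.suffix == ".gz":
        p = p.with_suffix("")
    return p.with_suffix(".tax")


def read_taxonomy(path: Union[str, Path], level_names: Sequence[str]) -> dict:
    """Read ``id TAB lineage`` rows; lineages are semicolon-separated.

    Every line must carry exactly ``len(level_names)`` taxon fields after
    empty trailing fields are dropped (a trailing ';' is tolerated). Returns
    a mapping of sequence id to :class:`Lineage`.
    """
    expected = len(level_names)
    out: dict = {}
    with _open_text(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if "\t" not in line:
                raise ValueError(
                    f"{path}, line {lineno}: expected 'id<TAB>lineage'"
                )
            rid, lineage_str = line.split("\t", 1)
            fields = [f.strip() for f in lineage_str.split(";")]
            while fields and fields[-1] == "":
                fields.pop()
            if len(fields) != expected:
                raise ValueError(
                    f"{path}, line {lineno}: lineage depth {len(fields)} != "
                    f"expected {expected} levels ({', '.join(level_names)})"
                )
            if any(f == "" for f in fields):
                raise ValueError(
                    f"{path}, line {lineno}: empty taxon name in lineage"
                )
            out[rid.strip()] = Lineage(tuple(zip(level_names, fields)))
    return out


def _fmt(value, nd: int = 2) -> str:
    return "" if value is None else f"{value:.{nd}f}"


COVERAGE_HEADER = (
    "primer_name",
    "n_groups",
    "n_covered",
    "coverage_pct",
    "mean_start",
    "mean_end",
    "mean_amplicon_length",
)


def write_coverage_table(rows: Iterable, path: Union[str, Path]) -> None:
    """Write one tab-separated coverage table (2-decimal floats).

    ``rows`` are objects with the attributes named in ``COVERAGE_HEADER``;
    absent means (uncovered primers, or amplicon length for single primers)
    are written as empty fields.
    """
    with open(path, "wt") as out:
        out.write("\t".join(COVERAGE_HEADER) + "\n")
        for r in rows:
            fields = (
                r.primer_name,
                str(r.n_groups),
                str(r.n_covered),
                _fmt(r.coverage_pct),
                _fmt(r.mean_start),
                _fmt(r.mean_end),
                _fmt(r.mean_amplicon_length),
            )
            out.write("\t".join(fields) + "\n")


def write_per_group_table(
    per_group: Mapping[str, float],
    group_sizes: Mapping[str, int],
    path: Union[str, Path],
) -> None:
    """Write the optional per-group coverage table (group, size, pct)."""
    with open(path, "wt") as out:
        out.write("group_key\tn_members\tpct_covered\n")
        for key in per_group:
            out.write(f"{key}\t{group_sizes[key]}\t{per_group[key]:.2f}\n")


def write_amplicon_fasta(hits: Iterable, path: Union[str, Path]) -> None:
    """Write matched subsequences / amplicons as FASTA.

    Each hit is a ``(source_id, start, end, sequence)`` tuple whose
    coordinates are already in the run's output convention (1-based
    inclusive); headers read ``>id|start-end``. Input order is preserved;
    no hits yields an empty file.
    """
    with open(path, "wt") as out:
        for source_id, start, end, seq in hits:
            out.write(f">{source_id}|{start}-{end}\n{seq}\n")
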