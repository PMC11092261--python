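"""Sequence quality control: flag non-ACGT characters, apply keep/drop policy."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, Tuple, Union

from .oligo_io import TargetRecord

logger = logging.getLogger(__name__)

__all__ = ["QCError", "QCReport", "scan_sequence", "scan_database", "apply_policy", "run_qc", "write_qc_report"]

_STANDARD = frozenset("ACGT")
POLICIES = ("keep", "drop")


class QCError(ValueError):
    pass


@dataclass
class QCReport:
    """Per-sequence flags plus summary counts of offending characters."""

    flags: dict = field(default_factory=dict)  # id -> [(pos, char), ...]
    policy: str = "keep"

    @property
    def flagged_ids(self) -> list:
        return [rid for rid, fl in self.flags.items() if fl]

    @property
    def char_counts(self) -> dict:
        counts: dict = {}
        for fl in self.flags.values():
            for _, ch in fl:
                counts[ch] = counts.get(ch, 0) + 1
        return counts


def scan_sequence(record: TargetRecord) -> list:
    """List (0-based position, character) for every non-A/C/G/T character."""
    return [
        (i, ch) for i, ch in enumerate(record.sequence) if ch not in _STANDARD
    ]


def scan_database(records: Iterable[TargetRecord]) -> QCReport:
    report = QCReport()
    for rec in records:
        report.flags[rec.id] = scan_sequence(rec)
    return report


def apply_policy(
    records: Sequence[TargetRecord],
    report: QCReport,
    policy: str = "keep",
) -> Tuple[list, list]:
    """Apply the keep/drop policy; returns (kept records, log lines).

    ``keep`` retains everything and warns per flagged sequence; ``drop``
    removes any sequence with at least one flag. Dropping every sequence is
    an error.
    """
    if policy not in POLICIES:
        raise QCError(f"unknown QC policy {policy!r}; choose from {POLICIES}")
    report.policy = policy
    log_lines: list = []
    flagged = set(report.flagged_ids)
    if policy == "keep":
        for rid in report.flagged_ids:
            n = len(report.flags[rid])
            line = f"QC warning: sequence {rid} has {n} non-standard character(s)"
            log_lines.append(line)
            logger.warning(line)
        return list(records), log_lines

    kept = [r for r in records if r.id not in flagged]
    if flagged:
        line = (
            f"QC: dropped {len(flagged)} of {len(records)} sequence(s) with "
            "non-standard characters"
        )
        log_lines.append(line)
        logger.info(line)
    if not kept:
        raise QCError("no sequences remain after QC")
    return kept, log_lines


def run_qc(
    records: Sequence[TargetRecord], policy: str = "keep"
) -> Tuple[list, QCReport, list]:
    """Scan then apply policy in one call."""
    report = scan_database(records)
    kept, log_lines = apply_policy(records, report, policy)
    return kept, report, log_lines


def write_qc_report(report: QCReport, path: Union[str, Path]) -> None:
    """Tab-separated flag listing: id, 1-based position, character."""
    with open(path, "wt") as out:
        out.write("id\tposition\tcharacter\n")
        for rid, fl in report.flags.items():
            for pos, ch in fl:
                out.write(f"{rid}\t{pos + 1}\t{ch}\n")
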