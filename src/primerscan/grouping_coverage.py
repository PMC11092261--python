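"""Form analysis groups (per-sequence / per-taxon / per-clade) and score coverage.

Group keys for taxonomic modes are full semicolon-joined lineage prefixes
(e.g. ``Bacteria;Firmicutes``), never bare taxon names, so homonymous taxa
at different positions in the hierarchy cannot merge. Clade mode enumerates
every distinct non-empty lineage prefix of any depth; a clade's members are
all sequences whose lineage extends that prefix, so clades nest.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Tuple

from .oligo_io import Lineage, TargetRecord

logger = logging.getLogger(__name__)

__all__ = [
    "CLADES",
    "Group",
    "CoverageRow",
    "make_groups",
    "coverage_percent",
    "per_group_coverage",
    "position_summary",
]

#: Sentinel mode string selecting all-clades grouping.
CLADES = "clades"


@dataclass(frozen=True)
class Group:
    key: str
    member_ids: frozenset

    def __post_init__(self) -> None:
        if not self.member_ids:
            raise ValueError(f"group {self.key!r} has no members")


@dataclass
class CoverageRow:
    """Per-primer(-pair) coverage result."""

    primer_name: str
    n_groups: int
    n_covered: int
    coverage_pct: float
    mean_start: Optional[float] = None
    mean_end: Optional[float] = None
    mean_amplicon_length: Optional[float] = None
    per_group_pct: Optional[dict] = None


def make_groups(
    records: Sequence[TargetRecord],
    lineages: Optional[Mapping[str, Lineage]] = None,
    mode: Optional[str] = None,
    level_names: Optional[Sequence[str]] = None,
) -> list:
    """Build the analysis groups for one run.

    mode=None        one group per sequence (key = sequence id)
    mode=<level>     one group per distinct lineage prefix up to that level
    mode="clades"    one group per distinct non-empty lineage prefix, any depth

    Taxonomic modes require a lineage for every analysed record; records
    without one are excluded with a logged count. Group order is input order
    for per-sequence mode, sorted by key otherwise.
    """
    if mode is None:
        return [Group(key=r.id, member_ids=frozenset([r.id])) for r in records]

    lineages = lineages or {}
    with_tax = [r for r in records if r.id in lineages]
    n_missing = len(records) - len(with_tax)
    if n_missing:
        logger.info(
            "excluded %d sequence(s) without taxonomy from grouping", n_missing
        )
    if not with_tax:
        raise ValueError("no sequences have taxonomy; cannot group by " + mode)

    members: dict = {}
    if mode == CLADES:
        for r in with_tax:
            lin = lineages[r.id]
            for depth in range(1, len(lin.taxa) + 1):
                members.setdefault(lin.prefix_key(depth), set()).add(r.id)
    else:
        if level_names is None:
            level_names = lineages[with_tax[0].id].level_names
        if mode not in level_names:
            raise ValueError(
                f"unknown taxonomic level {mode!r}; valid levels: "
                + ", ".join(level_names)
            )
        depth = list(level_names).index(mode) + 1
        for r in with_tax:
            members.setdefault(lineages[r.id].prefix_key(depth), set()).add(r.id)

    return [
        Group(key=key, member_ids=frozenset(members[key]))
        for key in sorted(members)
    ]


def coverage_percent(groups: Sequence[Group], covered_ids: Iterable[str]) -> Tuple[int, int, float]:
    """(n_groups, n_covered, pct): a group counts as covered if any member is."""
    if not groups:
        raise ValueError("cannot compute coverage over zero groups")
    covered = set(covered_ids)
    n_covered = sum(1 for g in groups if g.member_ids & covered)
    return len(groups), n_covered, 100.0 * n_covered / len(groups)


def per_group_coverage(groups: Sequence[Group], covered_ids: Iterable[str]) -> dict:
    """Per-group percentage of member sequences covered (unrounded)."""
    covered = set(covered_ids)
    return {
        g.key: 100.0 * len(g.member_ids & covered) / len(g.member_ids)
        for g in groups
    }


def position_summary(representative_hits: Sequence) -> Tuple[Optional[float], Optional[float], Optional[float]]:
    """Mean 1-based start, 1-based inclusive end, and amplicon length.

    Takes one representative hit per covered sequence — either
    :class:`~primerscan.match_engine.MatchHit` (length mean is ``None``) or
    :class:`~primerscan.match_engine.AmpliconHit`. Empty input yields all
    ``None`` (absent, not an error).
    """
    if not representative_hits:
        return None, None, None
    starts, ends, lengths = [], [], []
    for h in representative_hits:
        if hasattr(h, "amp_start"):
            starts.append(h.amp_start + 1)
            ends.append(h.amp_end)  # 0-based exclusive == 1-based inclusive
            lengths.append(h.length)
        else:
            starts.append(h.start + 1)
            ends.append(h.end)
    mean_start = sum(starts) / len(starts)
    mean_end = sum(ends) / len(ends)
    mean_length = sum(lengths) / len(lengths) if lengths else None
    return mean_start, mean_end, mean_length
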