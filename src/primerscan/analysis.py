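"""Orchestration: single-primer and pair analyses, domain calls, case study.

The analysis pipeline is: quality control -> grouping -> primer search ->
coverage metrics. ``analyze_ip`` scores single primers (unknown-role primers
are searched in both orientations and a hit by either counts);
``analyze_pp`` scores pairs, where a sequence counts as covered only when at
least one valid amplicon exists. ``run_case_study`` chains species-level
single-primer runs on two databases, classifies each primer's domain from
its coverages, builds all forward-by-reverse combinations of primers above
an eligibility threshold per domain, and re-evaluates the pairs.

Everything is deterministic: rerunning with identical inputs and settings
produces byte-identical output files.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Optional, Sequence, Tuple

from . import qc as qc_mod
from .grouping_coverage import (
    CLADES,
    CoverageRow,
    coverage_percent,
    make_groups,
    per_group_coverage,
    position_summary,
)
from .match_engine import find_amplicons, find_primer_hits, reverse_complement
from .oligo_io import (
    PrimerRecord,
    TargetRecord,
    read_fasta,
    read_oligos,
    read_taxonomy,
    write_amplicon_fasta,
    write_coverage_table,
    write_per_group_table,
)

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_LEVEL_NAMES",
    "RunConfig",
    "DomainCall",
    "CaseStudyResult",
    "analyze_ip",
    "analyze_pp",
    "classify_domains",
    "build_candidate_pairs",
    "run_case_study",
]

DEFAULT_LEVEL_NAMES = (
    "domain",
    "phylum",
    "class",
    "order",
    "family",
    "genus",
    "species",
)


@dataclass
class RunConfig:
    """Resolved settings for one analysis run."""

    max_mismatches: int = 0
    mode: Optional[str] = None  # None | level name | "clades"
    min_len: Optional[int] = None
    max_len: Optional[int] = None
    rc_reverse: bool = False
    qc_policy: str = "keep"
    out_dir: Optional[Path] = None
    level_names: Sequence[str] = DEFAULT_LEVEL_NAMES
    write_per_group: bool = False

    def __post_init__(self) -> None:
        if self.max_mismatches < 0:
            raise ValueError("max_mismatches must be >= 0")
        if (
            self.min_len is not None
            and self.max_len is not None
            and self.min_len > self.max_len
        ):
            raise ValueError("min_len must be <= max_len")
        if self.mode not in (None, CLADES) and self.mode not in self.level_names:
            raise ValueError(
                f"unknown taxonomic level {self.mode!r}; valid levels: "
                + ", ".join(self.level_names)
            )
        if self.out_dir is not None:
            self.out_dir = Path(self.out_dir)

    def to_json(self) -> str:
        d = asdict(self)
        d["out_dir"] = str(d["out_dir"]) if d["out_dir"] else None
        d["level_names"] = list(d["level_names"])
        return json.dumps(d, indent=2, sort_keys=True) + "\n"


@dataclass(frozen=True)
class DomainCall:
    primer_name: str
    call: str  # bacteria | archaea | universal | none
    bacterial_cov_pct: float
    archaeal_cov_pct: float


def _safe_name(name: str) -> str:
    return re.sub(r"[^A-Za-z0-9._-]+", "_", name)


def _prepare(records, lineages, config):
    kept, report, log_lines = qc_mod.run_qc(records, config.qc_policy)
    groups = make_groups(kept, lineages, config.mode, config.level_names)
    analysed_ids = {rid for g in groups for rid in g.member_ids}
    return kept, groups, analysed_ids, report, log_lines


def _single_primer_reps(primer, records, analysed_ids, max_mismatches):
    """Representative hit per covered sequence, ascending (start, end)."""
    reps = {}
    search_seqs = [primer.sequence]
    if primer.role == "unknown":
        search_seqs.append(reverse_complement(primer.sequence))
    for rec in records:
        if rec.id not in analysed_ids:
            continue
        hits = []
        for s in search_seqs:
            hits.extend(find_primer_hits(s, rec.sequence, max_mismatches, rec.id))
        if hits:
            hits.sort(key=lambda h: (h.start, h.end))
            reps[rec.id] = hits[0]
    return reps


def _row_from_reps(name, groups, reps, is_pair):
    n_groups, n_covered, pct = coverage_percent(groups, reps.keys())
    # one representative per covered sequence, in stable id order
    ordered = [reps[rid] for rid in sorted(reps)]
    mean_start, mean_end, mean_len = position_summary(ordered)
    return CoverageRow(
        primer_name=name,
        n_groups=n_groups,
        n_covered=n_covered,
        coverage_pct=pct,
        mean_start=mean_start,
        mean_end=mean_end,
        mean_amplicon_length=mean_len if is_pair else None,
        per_group_pct=per_group_coverage(groups, reps.keys()),
    )


def _hit_tuples(records, reps, use_amplicon):
    """1-based inclusive output tuples for write_amplicon_fasta, input order."""
    out = []
    for rec in records:
        h = reps.get(rec.id)
        if h is None:
            continue
        if use_amplicon:
            out.append((rec.id, h.amp_start + 1, h.amp_end, h.amplicon_seq))
        else:
            out.append((rec.id, h.start + 1, h.end, h.matched_seq))
    return out


def _write_outputs(rows, records, all_reps, config, kind, group_sizes):
    out_dir = config.out_dir
    if out_dir is None:
        return
    out_dir.mkdir(parents=True, exist_ok=True)
    write_coverage_table(rows, out_dir / f"coverage_{kind}.tsv")
    use_amp = kind == "pp"
    suffix = "amplicons" if use_amp else "hits"
    for row in rows:
        reps = all_reps[row.primer_name]
        write_amplicon_fasta(
            _hit_tuples(records, reps, use_amp),
            out_dir / f"{_safe_name(row.primer_name)}_{suffix}.fasta",
        )
        if config.write_per_group and row.per_group_pct is not None:
            write_per_group_table(
                row.per_group_pct,
                group_sizes,
                out_dir / f"{_safe_name(row.primer_name)}_groups.tsv",
            )


def analyze_ip(
    primers: Sequence[PrimerRecord],
    records: Sequence[TargetRecord],
    config: RunConfig,
    lineages: Optional[Mapping] = None,
) -> list:
    """Evaluate single primers against a database; one CoverageRow each.

    When ``config.out_dir`` is set, writes ``coverage_ip.tsv`` plus one
    matched-subsequence FASTA per primer.
    """
    singles = [p for p in primers if not p.is_pair]
    if not singles:
        raise ValueError("no single-primer records to analyse")
    if not records:
        raise ValueError("empty sequence database")
    kept, groups, analysed_ids, _report, _log = _prepare(records, lineages, config)
    group_sizes = {g.key: len(g.member_ids) for g in groups}

    rows, all_reps = [], {}
    for primer in singles:
        reps = _single_primer_reps(primer, kept, analysed_ids, config.max_mismatches)
        rows.append(_row_from_reps(primer.name, groups, reps, is_pair=False))
        all_reps[primer.name] = reps
    _write_outputs(rows, kept, all_reps, config, "ip", group_sizes)
    return rows


def analyze_pp(
    pairs: Sequence[PrimerRecord],
    records: Sequence[TargetRecord],
    config: RunConfig,
    lineages: Optional[Mapping] = None,
) -> list:
    """Evaluate primer pairs; a sequence is covered iff a valid amplicon exists.

    Amplicon spans include both primer footprints and must satisfy
    ``config.min_len``/``max_len`` when set. The representative amplicon per
    sequence is the leftmost-start, then shortest one.
    """
    pair_recs = [p for p in pairs if p.is_pair]
    if not pair_recs:
        raise ValueError("no primer-pair records to analyse")
    if not records:
        raise ValueError("empty sequence database")
    kept, groups, analysed_ids, _report, _log = _prepare(records, lineages, config)
    group_sizes = {g.key: len(g.member_ids) for g in groups}

    rows, all_reps = [], {}
    for pair in pair_recs:
        reps = {}
        for rec in kept:
            if rec.id not in analysed_ids:
                continue
            amps = find_amplicons(
                pair.fwd_sequence,
                pair.rev_sequence,
                rec.sequence,
                max_mismatches=config.max_mismatches,
                min_len=config.min_len,
                max_len=config.max_len,
                rc_reverse=config.rc_reverse,
                target_id=rec.id,
            )
            if amps:
                reps[rec.id] = amps[0]
        rows.append(_row_from_reps(pair.name, groups, reps, is_pair=True))
        all_reps[pair.name] = reps
    _write_outputs(rows, kept, all_reps, config, "pp", group_sizes)
    return rows


def classify_domains(
    bacterial_rows: Sequence[CoverageRow],
    archaeal_rows: Sequence[CoverageRow],
    min_cov: float = 0.0,
) -> list:
    """Call each primer bacteria / archaea / universal / none from coverages.

    A primer "covers" a domain when its coverage there exceeds ``min_cov``
    (strictly; default 0). Both row lists must contain the same primer names.
    """
    bact = {r.primer_name: r.coverage_pct for r in bacterial_rows}
    arch = {r.primer_name: r.coverage_pct for r in archaeal_rows}
    missing = sorted(set(bact) ^ set(arch))
    if missing:
        raise ValueError(
            "primers present in only one domain's results: " + ", ".join(missing)
        )
    calls = []
    for name in bact:
        b, a = bact[name], arch[name]
        covers_b, covers_a = b > min_cov, a > min_cov
        if covers_b and covers_a:
            call = "universal"
        elif covers_b:
            call = "bacteria"
        elif covers_a:
            call = "archaea"
        else:
            call = "none"
        calls.append(DomainCall(name, call, b, a))
    return calls


def build_candidate_pairs(
    primers: Sequence[PrimerRecord],
    rows: Sequence[CoverageRow],
    threshold_pct: float = 75.0,
) -> list:
    """Cross all eligible forward x reverse primers into pair records.

    Eligible = single-primer coverage >= ``threshold_pct`` (unrounded).
    Unknown-role primers are eligible on both sides. Pair names are
    ``<fwd>-<rev>``. Returns [] with a warning when either side is empty.
    """
    cov = {r.primer_name: r.coverage_pct for r in rows}
    eligible = [
        p for p in primers if not p.is_pair and cov.get(p.name, 0.0) >= threshold_pct
    ]
    fwd = [p for p in eligible if p.role in ("forward", "unknown")]
    rev = [p for p in eligible if p.role in ("reverse", "unknown")]
    if not fwd or not rev:
        logger.warning(
            "no eligible %s primers at threshold %.2f%%; no pairs built",
            "forward" if not fwd else "reverse",
            threshold_pct,
        )
        return []
    return [
        PrimerRecord(
            name=f"{f.name}-{r.name}",
            role="pair",
            fwd_sequence=f.sequence,
            rev_sequence=r.sequence,
        )
        for f in fwd
        for r in rev
    ]


def _rank_pairs(rows: Sequence[CoverageRow]) -> list:
    return sorted(
        rows,
        key=lambda r: (
            -r.coverage_pct,
            r.mean_amplicon_length if r.mean_amplicon_length is not None else float("inf"),
            r.primer_name,
        ),
    )


@dataclass
class CaseStudyResult:
    domain_calls: list
    counts: dict  # call -> number of primers
    bacterial_rows: list
    archaeal_rows: list
    bacterial_pair_rows: list  # ranked
    archaeal_pair_rows: list  # ranked
    n_candidate_pairs: int = 0


def run_case_study(
    primer_file,
    bact_db,
    arch_db,
    config: RunConfig,
    threshold_pct: float = 75.0,
    domain_min_cov: float = 0.0,
    bact_tax=None,
    arch_tax=None,
) -> CaseStudyResult:
    """Full case-study procedure over two databases.

    1. species-level (``config.mode``) single-primer runs on both databases;
    2. domain classification of every primer from the two coverages;
    3. per-domain candidate pairs from primers at/above ``threshold_pct``;
    4. pair re-evaluation on the matching database, ranked by coverage
       (descending), mean amplicon length (ascending), then name.

    Inputs may be paths (read with the package's readers) or pre-loaded
    objects. Output files land under ``config.out_dir`` in ``bacterial/``
    and ``archaeal/`` subdirectories plus top-level summary tables.
    """
    primers = (
        read_oligos(primer_file)
        if isinstance(primer_file, (str, Path))
        else list(primer_file)
    )
    singles = [p for p in primers if not p.is_pair]
    if not singles:
        raise ValueError("primer file contains no single primers")

    def _load(db, tax):
        recs = read_fasta(db) if isinstance(db, (str, Path)) else list(db)
        if tax is None:
            return recs, None
        lin = (
            read_taxonomy(tax, config.level_names)
            if isinstance(tax, (str, Path))
            else tax
        )
        return recs, lin

    bact_recs, bact_lin = _load(bact_db, bact_tax)
    arch_recs, arch_lin = _load(arch_db, arch_tax)

    def _sub(config, sub):
        d = None if config.out_dir is None else config.out_dir / sub
        return RunConfig(
            max_mismatches=config.max_mismatches,
            mode=config.mode,
            min_len=config.min_len,
            max_len=config.max_len,
            rc_reverse=config.rc_reverse,
            qc_policy=config.qc_policy,
            out_dir=d,
            level_names=config.level_names,
            write_per_group=config.write_per_group,
        )

    bact_rows = analyze_ip(singles, bact_recs, _sub(config, "bacterial"), bact_lin)
    arch_rows = analyze_ip(singles, arch_recs, _sub(config, "archaeal"), arch_lin)

    calls = classify_domains(bact_rows, arch_rows, domain_min_cov)
    counts = {"bacteria": 0, "archaea": 0, "universal": 0, "none": 0}
    for c in calls:
        counts[c.call] += 1

    bact_pairs = build_candidate_pairs(singles, bact_rows, threshold_pct)
    arch_pairs = build_candidate_pairs(singles, arch_rows, threshold_pct)

    bact_pair_rows: list = []
    arch_pair_rows: list = []
    if bact_pairs:
        bact_pair_rows = _rank_pairs(
            analyze_pp(bact_pairs, bact_recs, _sub(config, "bacterial_pairs"), bact_lin)
        )
    if arch_pairs:
        arch_pair_rows = _rank_pairs(
            analyze_pp(arch_pairs, arch_recs, _sub(config, "archaeal_pairs"), arch_lin)
        )

    result = CaseStudyResult(
        domain_calls=calls,
        counts=counts,
        bacterial_rows=bact_rows,
        archaeal_rows=arch_rows,
        bacterial_pair_rows=bact_pair_rows,
        archaeal_pair_rows=arch_pair_rows,
        n_candidate_pairs=len(bact_pairs) + len(arch_pairs),
    )

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "domain_calls.tsv", "wt") as fh:
            fh.write("primer_name\tcall\tbacterial_cov_pct\tarchaeal_cov_pct\n")
            for c in calls:
                fh.write(
                    f"{c.primer_name}\t{c.call}\t{c.bacterial_cov_pct:.2f}\t"
                    f"{c.archaeal_cov_pct:.2f}\n"
                )
        with open(out / "domain_counts.tsv", "wt") as fh:
            fh.write("bacteria\tarchaea\tuniversal\tnone\n")
            fh.write(
                f"{counts['bacteria']}\t{counts['archaea']}\t"
                f"{counts['universal']}\t{counts['none']}\n"
            )
        write_coverage_table(bact_pair_rows, out / "ranked_pairs_bacterial.tsv")
        write_coverage_table(arch_pair_rows, out / "ranked_pairs_archaeal.tsv")
        (out / "run_config.json").write_text(config.to_json())
    return result
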