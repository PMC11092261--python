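"""Synthetic oligos/FASTA/taxonomy fixtures with planted sites and exact truth.

The generator plants concrete primer binding sites (optionally with an exact
number of injected mismatches) into random background sequences organised
under a small taxonomy tree. Backgrounds are screened with a naive scanner:
any accidental match of a planted primer — within the screening mismatch
budget, in either orientation that the analysis would probe — triggers a
re-roll of that sequence, so the recorded ground truth is exact rather than
probabilistic. Everything is fully determined by the seed.

Ground-truth expectations (coverage per grouping mode, mean positions, mean
amplicon length) are computed here by direct enumeration over the planted
design, independently of the analysis pipeline they validate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "PlantSpec",
    "FixtureSpec",
    "Fixture",
    "GroundTruth",
    "FixtureError",
    "mutate_site",
    "generate_fixture",
    "mini_oral",
]

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_RC = {
    "A": "T", "C": "G", "G": "C", "T": "A", "R": "Y", "Y": "R", "S": "S",
    "W": "W", "K": "M", "M": "K", "B": "V", "V": "B", "D": "H", "H": "D",
    "N": "N",
}


class FixtureError(ValueError):
    pass


def _rc(seq: str) -> str:
    return "".join(_RC[c] for c in reversed(seq))


def _naive_offsets(primer: str, target: str, budget: int) -> list:
    """Brute-force sliding-window scan; independent of the match engine."""
    m, out = len(primer), []
    for i in range(len(target) - m + 1):
        mm = 0
        for j in range(m):
            if target[i + j] not in _IUPAC[primer[j]]:
                mm += 1
                if mm > budget:
                    break
        else:
            out.append(i)
    return out


def mutate_site(site_seq: str, k_substitutions: int, seed: int) -> str:
    """Substitute exactly ``k`` positions for a different base (Hamming k)."""
    if k_substitutions > len(site_seq):
        raise FixtureError(
            f"cannot make {k_substitutions} substitutions in a "
            f"{len(site_seq)}-base site"
        )
    rng = np.random.default_rng(seed)
    chars = list(site_seq)
    positions = rng.choice(len(chars), size=k_substitutions, replace=False)
    for pos in positions:
        alternatives = [b for b in "ACGT" if b != chars[pos]]
        chars[pos] = alternatives[rng.integers(len(alternatives))]
    return "".join(chars)


@dataclass(frozen=True)
class PlantSpec:
    """One primer (or pair) planted into every sequence of some leaf taxa."""

    name: str
    role: str = "forward"  # forward | reverse | unknown | pair
    sequence: Optional[str] = None
    fwd_sequence: Optional[str] = None
    rev_sequence: Optional[str] = None
    target_taxa: Tuple[str, ...] = ()  # leaf taxon names; () plants nowhere
    offset: Optional[int] = None  # fixed 0-based offset; None -> random
    gap: int = 20  # insert length between pair footprints
    inject_mismatches: int = 0

    @property
    def is_pair(self) -> bool:
        return self.role == "pair"

    @property
    def footprint(self) -> int:
        if self.is_pair:
            return len(self.fwd_sequence) + self.gap + len(self.rev_sequence)
        return len(self.sequence)


@dataclass(frozen=True)
class FixtureSpec:
    level_names: Tuple[str, ...] = ("phylum", "species")
    n_taxa_per_level: Tuple[int, ...] = (2, 4)
    seqs_per_taxon: int = 3
    seq_length: int = 150
    gc: float = 0.5
    plants: Tuple[PlantSpec, ...] = ()
    seed: int = 0
    screen_mismatches: int = 3
    max_rerolls: int = 200

    def __post_init__(self) -> None:
        if len(self.level_names) != len(self.n_taxa_per_level):
            raise FixtureError("level_names and n_taxa_per_level length mismatch")
        if any(
            a > b for a, b in zip(self.n_taxa_per_level, self.n_taxa_per_level[1:])
        ):
            raise FixtureError("taxon counts must be non-decreasing with depth")
        for p in self.plants:
            if p.inject_mismatches > self.screen_mismatches:
                raise FixtureError(
                    f"plant {p.name}: injected mismatches exceed screening budget"
                )
            if p.footprint > self.seq_length:
                raise FixtureError(
                    f"plant {p.name}: planted site longer than sequence"
                )


class GroundTruth:
    """Exact expected hits and coverage for one generated fixture."""

    def __init__(self, level_names: Sequence[str]):
        self.level_names = tuple(level_names)
        self.lineages: dict = {}  # seq_id -> tuple of taxa
        self.primer_hits: dict = {}  # name -> {seq_id: hit dict}
        self.primer_is_pair: dict = {}
        self.injected_mm: dict = {}

    def covered_ids(self, name: str, max_mismatches: int = 0) -> set:
        if self.injected_mm[name] > max_mismatches:
            return set()
        return set(self.primer_hits[name])

    def _group_keys(self, seq_ids, mode):
        """Distinct group keys among seq_ids, enumerated directly."""
        keys = set()
        for sid in seq_ids:
            taxa = self.lineages[sid]
            if mode is None:
                keys.add(sid)
            elif mode == "clades":
                for d in range(1, len(taxa) + 1):
                    keys.add(";".join(taxa[:d]))
            else:
                depth = self.level_names.index(mode) + 1
                keys.add(";".join(taxa[:depth]))
        return keys

    def expected_coverage(self, name: str, mode=None, max_mismatches: int = 0):
        """(n_groups, n_covered, pct) by brute-force key enumeration."""
        all_keys = self._group_keys(self.lineages.keys(), mode)
        covered_keys = self._group_keys(
            self.covered_ids(name, max_mismatches), mode
        )
        n_groups = len(all_keys)
        n_covered = len(covered_keys & all_keys)
        return n_groups, n_covered, 100.0 * n_covered / n_groups

    def expected_means(self, name: str, max_mismatches: int = 0):
        """(mean_start, mean_end, mean_length) on the 1-based output scale."""
        ids = sorted(self.covered_ids(name, max_mismatches))
        if not ids:
            return None, None, None
        hits = [self.primer_hits[name][sid] for sid in ids]
        mean_start = sum(h["start"] + 1 for h in hits) / len(hits)
        mean_end = sum(h["end"] for h in hits) / len(hits)
        if self.primer_is_pair[name]:
            mean_len = sum(h["end"] - h["start"] for h in hits) / len(hits)
        else:
            mean_len = None
        return mean_start, mean_end, mean_len

    def to_json(self) -> str:
        return json.dumps(
            {
                "level_names": list(self.level_names),
                "lineages": {k: list(v) for k, v in self.lineages.items()},
                "primer_hits": self.primer_hits,
                "primer_is_pair": self.primer_is_pair,
                "injected_mm": self.injected_mm,
            },
            indent=2,
            sort_keys=True,
        )


@dataclass
class Fixture:
    oligos_text: str
    fasta_text: str
    tax_text: str
    ground_truth: GroundTruth
    spec: FixtureSpec

    def write(self, directory, stem: str = "fixture") -> dict:
        """Write <stem>.oligos/.fasta/.tax plus ground_truth.json; return paths."""
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        paths = {
            "oligos": d / f"{stem}.oligos",
            "fasta": d / f"{stem}.fasta",
            "tax": d / f"{stem}.tax",
            "ground_truth": d / "ground_truth.json",
        }
        paths["oligos"].write_text(self.oligos_text)
        paths["fasta"].write_text(self.fasta_text)
        paths["tax"].write_text(self.tax_text)
        paths["ground_truth"].write_text(self.ground_truth.to_json())
        return paths


def _taxon_name(level_name: str, index: int) -> str:
    return f"{level_name.capitalize()}{index + 1}"


def _leaf_lineage(spec: FixtureSpec, leaf_idx: int) -> tuple:
    """Ancestor chain for one leaf; contiguous-block parent assignment."""
    counts = spec.n_taxa_per_level
    idx = leaf_idx
    chain = [idx]
    for i in range(len(counts) - 1, 0, -1):
        idx = idx * counts[i - 1] // counts[i]
        chain.append(idx)
    chain.reverse()
    return tuple(
        _taxon_name(spec.level_names[i], chain[i]) for i in range(len(counts))
    )


def _realize(primer_seq: str, rng) -> str:
    """Pick one concrete ACGT realisation of a degenerate primer."""
    return "".join(
        _IUPAC[c][rng.integers(len(_IUPAC[c]))] if len(_IUPAC[c]) > 1 else c
        for c in primer_seq
    )


def _inject_outside_class(primer_seq: str, site: str, k: int, rng) -> str:
    """Mutate k site positions to bases outside the primer's class there."""
    if k == 0:
        return site
    chars = list(site)
    eligible = [i for i, c in enumerate(primer_seq) if len(_IUPAC[c]) < 4]
    if len(eligible) < k:
        raise FixtureError(
            "cannot inject mismatches: too many fully degenerate (N) positions"
        )
    positions = rng.choice(len(eligible), size=k, replace=False)
    for p in positions:
        i = eligible[p]
        outside = [b for b in "ACGT" if b not in _IUPAC[primer_seq[i]]]
        chars[i] = outside[rng.integers(len(outside))]
    return "".join(chars)


def _probes_for(plant: PlantSpec) -> list:
    """(probe sequence, which planted segment it must hit) per orientation."""
    if plant.is_pair:
        return [(plant.fwd_sequence, "fwd"), (plant.rev_sequence, "rev")]
    probes = [(plant.sequence, "single")]
    if plant.role == "unknown":
        probes.append((_rc(plant.sequence), None))  # must hit nowhere
    return probes


def generate_fixture(spec: FixtureSpec) -> Fixture:
    """Generate one fixture; deterministic in ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    base_probs = [(1 - spec.gc) / 2, spec.gc / 2, spec.gc / 2, (1 - spec.gc) / 2]
    bases = np.array(list("ACGT"))

    n_leaves = spec.n_taxa_per_level[-1]
    leaf_names = [
        _taxon_name(spec.level_names[-1], i) for i in range(n_leaves)
    ]
    for p in spec.plants:
        unknown = set(p.target_taxa) - set(leaf_names)
        if unknown:
            raise FixtureError(
                f"plant {p.name}: unknown leaf taxa {sorted(unknown)}"
            )

    gt = GroundTruth(spec.level_names)
    for p in spec.plants:
        gt.primer_hits[p.name] = {}
        gt.primer_is_pair[p.name] = p.is_pair
        gt.injected_mm[p.name] = p.inject_mismatches

    fasta_lines: list = []
    tax_lines: list = []
    seq_counter = 0
    for leaf_idx in range(n_leaves):
        lineage = _leaf_lineage(spec, leaf_idx)
        plants_here = [
            p for p in spec.plants if leaf_names[leaf_idx] in p.target_taxa
        ]
        for _ in range(spec.seqs_per_taxon):
            seq_counter += 1
            sid = f"seq_{seq_counter:04d}"
            seq, placements = _build_sequence(
                spec, plants_here, rng, base_probs, bases, sid
            )
            fasta_lines.append(f">{sid}\n{seq}")
            tax_lines.append(f"{sid}\t" + ";".join(lineage) + ";")
            gt.lineages[sid] = lineage
            for plant, start, end in placements:
                gt.primer_hits[plant.name][sid] = {
                    "start": start,
                    "end": end,
                    "mismatches": plant.inject_mismatches,
                }

    oligos_lines = []
    for p in spec.plants:
        if p.is_pair:
            oligos_lines.append(f"primer {p.fwd_sequence} {p.rev_sequence} {p.name}")
        elif p.role == "unknown":
            oligos_lines.append(f"{p.sequence} {p.name}")
        else:
            oligos_lines.append(f"{p.role} {p.sequence} {p.name}")

    return Fixture(
        oligos_text="\n".join(oligos_lines) + "\n",
        fasta_text="\n".join(fasta_lines) + "\n",
        tax_text="\n".join(tax_lines) + "\n",
        ground_truth=gt,
        spec=spec,
    )


def _place_plants(spec: FixtureSpec, plants, rng):
    """Choose non-overlapping intervals for every planted site in a sequence."""
    placements = []  # (plant, start)
    taken: list = []
    # fixed-offset sites claim their interval first; random sites then
    # dodge everything already taken
    ordered = sorted(plants, key=lambda p: p.offset is None)
    for plant in ordered:
        size = plant.footprint
        if plant.offset is not None:
            start = plant.offset
            if start + size > spec.seq_length:
                raise FixtureError(
                    f"plant {plant.name}: fixed offset {start} overruns sequence"
                )
            if any(start < e and s < start + size for s, e in taken):
                raise FixtureError(
                    f"plant {plant.name}: fixed offset overlaps another site"
                )
        else:
            for _ in range(100):
                start = int(rng.integers(0, spec.seq_length - size + 1))
                if not any(start < e and s < start + size for s, e in taken):
                    break
            else:
                raise FixtureError(
                    f"plant {plant.name}: could not place site without overlap"
                )
        taken.append((start, start + size))
        placements.append((plant, start))
    return placements


def _build_sequence(spec, plants, rng, base_probs, bases, sid):
    """Background + planted sites, re-rolled until screening passes."""
    all_probes = [
        (probe, plant, segment)
        for plant in spec.plants
        for probe, segment in _probes_for(plant)
    ]
    for _attempt in range(spec.max_rerolls):
        chars = rng.choice(bases, size=spec.seq_length, p=base_probs)
        placements = _place_plants(spec, plants, rng)
        spans = []  # (plant, seg_starts)
        for plant, start in placements:
            if plant.is_pair:
                f_site = _realize(plant.fwd_sequence, rng)
                r_site = _realize(plant.rev_sequence, rng)
                f_site = _inject_outside_class(
                    plant.fwd_sequence, f_site, plant.inject_mismatches, rng
                )
                r_site = _inject_outside_class(
                    plant.rev_sequence, r_site, plant.inject_mismatches, rng
                )
                r_start = start + len(f_site) + plant.gap
                chars[start : start + len(f_site)] = list(f_site)
                chars[r_start : r_start + len(r_site)] = list(r_site)
                spans.append(
                    (plant, {"fwd": start, "rev": r_start}, start, r_start + len(r_site))
                )
            else:
                site = _realize(plant.sequence, rng)
                site = _inject_outside_class(
                    plant.sequence, site, plant.inject_mismatches, rng
                )
                chars[start : start + len(site)] = list(site)
                spans.append((plant, {"single": start}, start, start + len(site)))
        seq = "".join(chars)

        if _screening_ok(spec, seq, all_probes, spans):
            placements_out = [
                (plant, s, e) for plant, _seg, s, e in spans
            ]
            return seq, placements_out
    raise FixtureError(
        f"sequence {sid}: screening failed after {spec.max_rerolls} re-rolls; "
        "use longer primers or shorter sequences"
    )


def _screening_ok(spec, seq, all_probes, spans) -> bool:
    """Every probe must hit exactly its planted offsets, nothing else."""
    planted_by_probe: dict = {}
    for plant, seg_starts, _s, _e in spans:
        for seg, off in seg_starts.items():
            planted_by_probe.setdefault((plant.name, seg), set()).add(off)
    for probe, plant, segment in all_probes:
        expected = (
            planted_by_probe.get((plant.name, segment), set())
            if segment is not None
            else set()
        )
        found = set(_naive_offsets(probe, seq, spec.screen_mismatches))
        if found != expected:
            return False
    return True


def mini_oral(seed: int = 20240514) -> Fixture:
    """Canned small fixture: 3 phyla / 8 species / 40 sequences, 5 single
    primers (forward, reverse, and unknown roles) and 2 pairs with planted
    sites of known per-species coverage. Used for docs and smoke tests.
    """
    plants = (
        PlantSpec(
            name="bact_fwd_broad",
            role="forward",
            sequence="ACGGTCCAGACTCCTACG",
            target_taxa=("Species1", "Species2", "Species3", "Species4", "Species5", "Species6"),
            offset=10,
        ),
        PlantSpec(
            name="bact_rev_broad",
            role="reverse",
            sequence="GGACTACHVGGGTWTCTAAT"[:18],
            target_taxa=("Species1", "Species2", "Species3", "Species4", "Species5", "Species6"),
            offset=160,
        ),
        PlantSpec(
            name="arch_fwd",
            role="forward",
            sequence="TTCCGGTTGATCCYGCCGGA",
            target_taxa=("Species7", "Species8"),
        ),
        PlantSpec(
            name="narrow_unknown",
            role="unknown",
            sequence="CCTACGGGAGGCAGCAG",
            target_taxa=("Species1",),
        ),
        PlantSpec(
            name="dead_primer",
            role="forward",
            sequence="TGCATGCATGCATGCA",
            target_taxa=(),
        ),
        PlantSpec(
            name="pair_broad",
            role="pair",
            fwd_sequence="GTGCCAGCMGCCGCGGTAA",
            rev_sequence="CCGTCAATTCMTTTRAGTTT",
            target_taxa=("Species2", "Species3", "Species4", "Species5"),
            offset=60,
            gap=40,
        ),
        PlantSpec(
            name="pair_narrow",
            role="pair",
            fwd_sequence="AGAGTTTGATCMTGGCTCAG",
            rev_sequence="TACGGYTACCTTGTTACGACTT"[:20],
            target_taxa=("Species7",),
            gap=25,
        ),
    )
    spec = FixtureSpec(
        level_names=("phylum", "species"),
        n_taxa_per_level=(3, 8),
        seqs_per_taxon=5,
        seq_length=260,
        plants=plants,
        seed=seed,
        screen_mismatches=2,
    )
    return generate_fixture(spec)
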