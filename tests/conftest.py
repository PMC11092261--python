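"""Shared test fixtures and the independent brute-force matching oracle."""

from __future__ import annotations

import numpy as np
import pytest

from primerscan.fixtures import FixtureSpec, PlantSpec, generate_fixture, mini_oral

# Independent IUPAC table for the oracle -- deliberately not imported from
# the package under test.
ORACLE_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def oracle_hits(primer: str, target: str, max_mismatches: int):
    """Naive O(n*m) double-loop Hamming scanner over every window."""
    primer, target = primer.upper(), target.upper()
    m = len(primer)
    hits = []
    for i in range(len(target) - m + 1):
        mm = sum(
            1 for j in range(m) if target[i + j] not in ORACLE_IUPAC[primer[j]]
        )
        if mm <= max_mismatches:
            hits.append((i, i + m, mm))
    return hits


def random_primer(rng: np.random.Generator, length: int, degen_frac: float) -> str:
    degenerate_codes = list("RYSWKMBDHVN")
    chars = [
        "ACGT"[rng.integers(4)] for _ in range(length)
    ]
    n_degen = int(round(degen_frac * length))
    if n_degen:
        for pos in rng.choice(length, size=n_degen, replace=False):
            chars[pos] = degenerate_codes[rng.integers(len(degenerate_codes))]
    return "".join(chars)


def random_target(rng: np.random.Generator, length: int) -> str:
    return "".join("ACGT"[rng.integers(4)] for _ in range(length))


@pytest.fixture(scope="session")
def mini_fixture():
    return mini_oral()


@pytest.fixture(scope="session")
def mini_paths(mini_fixture, tmp_path_factory):
    d = tmp_path_factory.mktemp("mini_oral")
    return mini_fixture.write(d, "mini")


def small_planted_spec(seed: int) -> FixtureSpec:
    """A compact fixture with single primers (0/1/2 injected mismatches,
    mixed roles) plus a pair, used across the planted-recovery tests."""
    plants = (
        PlantSpec(
            name="fwd_exact",
            role="forward",
            sequence="ACGTTGCATCGGAATTCG",
            target_taxa=("Species1", "Species2"),
            offset=5,
        ),
        PlantSpec(
            name="unk_mm1",
            role="unknown",
            sequence="GGATCCTTAAGCGTACGA",
            target_taxa=("Species3",),
            inject_mismatches=1,
        ),
        PlantSpec(
            name="rev_mm2",
            role="reverse",
            sequence="TTGACCGGTATCCAGAGC",
            target_taxa=("Species2", "Species4"),
            inject_mismatches=2,
        ),
        PlantSpec(
            name="pair_planted",
            role="pair",
            fwd_sequence="CATGGCTAGCTAACTGAC",
            rev_sequence="GTTCAAGCGGCCGATATC",
            target_taxa=("Species1", "Species3"),
            gap=15,
            offset=40,
        ),
    )
    return FixtureSpec(
        level_names=("phylum", "species"),
        n_taxa_per_level=(2, 4),
        seqs_per_taxon=2,
        seq_length=130,
        plants=plants,
        seed=seed,
        screen_mismatches=3,
    )


@pytest.fixture
def small_fixture():
    return generate_fixture(small_planted_spec(seed=7))
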