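# primerscan

In-silico evaluation of PCR primers and primer pairs against any sequence
database. `primerscan` locates primers with IUPAC-degenerate,
mismatch-tolerant matching, extracts amplicons with optional length bounds,
and reports coverage — the percentage of analysis groups (individual
sequences, taxa at a chosen taxonomic level, or all lineage-prefix clades)
with at least one matched/amplified sequence — along with mean start/end
positions and mean amplicon length.

## Features

- **Oligos input** in the Mothur-style keyword format (`forward SEQ [name]`,
  `reverse SEQ [name]`, `primer FWD REV [name]`; bare-sequence lines are
  accepted as unknown-role primers and searched in both orientations).
- **Mismatch budget** (substitution-only; default 0) on top of IUPAC
  degenerate-base classes. A degenerate character in the *target* never
  matches by set-intersection — it must literally belong to the primer
  position's class — and quality control flags all non-ACGT characters with
  a user-selected `keep`/`drop` policy.
- **Grouping modes**: per sequence (default), per taxon at a named level, or
  all possible clades (every distinct lineage prefix). Taxonomy is a
  tab-separated `id<TAB>lineage;...;` file sharing the FASTA basename.
- **Primer pairs**: all forward×reverse hit combinations are enumerated; the
  amplicon span includes both primer footprints and can be bounded with
  `--min-len`/`--max-len`. Reverse primers are searched as written
  (amplification orientation); `--rc-reverse` reverse-complements them first.
- **Case-study pipeline**: species-level runs on two databases → per-primer
  domain classification (bacteria/archaea/universal/none) → all
  forward×reverse combinations of primers at/above a coverage threshold
  (default 75%) → ranked pair re-evaluation.
- **NCBI download module** with batched retrieval, retries and an injected
  transport (fully offline-testable).
- **Synthetic fixtures** (`primerscan.fixtures`) that plant primer sites
  with exact, collision-screened ground truth for testing.

## CLI

```sh
# single primers, species-level coverage
primerscan analyze-ip --oligos primers.oligos --fasta db.fasta \
    --levels domain,phylum,class,order,family,genus,species \
    --level species --mismatches 1 --out results/ip

# primer pairs with amplicon length bounds, clade coverage
primerscan analyze-pp --oligos pairs.oligos --fasta db.fasta \
    --levels domain,phylum,class,order,family,genus,species --clades \
    --min-len 200 --max-len 600 --out results/pp

# two-database case study
primerscan case-study --oligos primers.oligos \
    --bacteria bact.fasta --archaea arch.fasta \
    --threshold 75 --out results/cs

# batched NCBI download (requires network + contact e-mail)
primerscan download --ids accessions.txt --out genomes.fasta --tax \
    --batch-size 100 --email you@example.org
```

Each analysis run writes a `run_config.json` echoing resolved settings, a
`run.log`, a tab-separated coverage table (`coverage_ip.tsv` /
`coverage_pp.tsv`), and one FASTA of matched subsequences or representative
amplicons per primer (headers `>id|start-end`, 1-based inclusive). Reruns
with identical inputs are byte-identical.

A small worked example lives in `examples/mini_oral/` (3 phyla, 8 species,
40 sequences, 5 single primers, 2 pairs, with its exact ground truth in
`ground_truth.json`); it is regenerated deterministically by
`primerscan.fixtures.mini_oral()`.

## Library use

```python
from primerscan import (RunConfig, analyze_ip, find_primer_hits,
                        read_fasta, read_oligos, read_taxonomy)

primers = read_oligos("primers.oligos")
records = read_fasta("db.fasta")
levels = ["domain", "phylum", "class", "order", "family", "genus", "species"]
lineages = read_taxonomy("db.tax", levels)
rows = analyze_ip(primers, records,
                  RunConfig(mode="species", level_names=levels), lineages)
```

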