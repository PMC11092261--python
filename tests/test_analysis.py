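import pytest

from primerscan.analysis import (
    RunConfig,
    analyze_ip,
    analyze_pp,
    build_candidate_pairs,
    classify_domains,
    run_case_study,
)
from primerscan.grouping_coverage import CoverageRow
from primerscan.oligo_io import Lineage, PrimerRecord, TargetRecord, parse_oligos


def _rec(rid, seq):
    return TargetRecord(id=rid, sequence=seq)


def _lineage(taxa, level_names=("phylum", "species")):
    return Lineage(tuple(zip(level_names, taxa)))


def _row(name, pct):
    return CoverageRow(
        primer_name=name, n_groups=10, n_covered=int(pct / 10), coverage_pct=pct
    )


BACKGROUND = "TGCCTGAGTCCTAGTCGGACTTGACCCATAGTTTGGACTTGACC"


class TestAnalyzeIp:
    def test_sequence_level_coverage(self):
        primer = PrimerRecord(name="p1", role="forward", sequence="ACGTACGT")
        records = [
            _rec("s1", BACKGROUND[:12] + "ACGTACGT" + BACKGROUND[12:]),
            _rec("s2", "ACGTACGT" + BACKGROUND),
            _rec("s3", BACKGROUND),
            _rec("s4", BACKGROUND[::-1]),
        ]
        rows = analyze_ip([primer], records, RunConfig())
        assert rows[0].n_groups == 4
        assert rows[0].n_covered == 2
        assert rows[0].coverage_pct == 50.0
        # representative hits: s1 at 0-based 12, s2 at 0 -> 1-based starts 13, 1
        assert rows[0].mean_start == 7.0
        assert rows[0].mean_end == pytest.approx((20 + 8) / 2)
        assert rows[0].mean_amplicon_length is None

    def test_species_level_recomputed_by_hand(self):
        # 2 hit sequences are the only members of 1 of 3 species -> 33.33%
        primer = PrimerRecord(name="p1", role="forward", sequence="ACGTACGT")
        records = [
            _rec("s1", "ACGTACGT" + BACKGROUND),
            _rec("s2", BACKGROUND + "ACGTACGT"),
            _rec("s3", BACKGROUND),
            _rec("s4", BACKGROUND[::-1]),
        ]
        lineages = {
            "s1": _lineage(("P1", "SpA")),
            "s2": _lineage(("P1", "SpA")),
            "s3": _lineage(("P1", "SpB")),
            "s4": _lineage(("P2", "SpC")),
        }
        cfg = RunConfig(mode="species", level_names=("phylum", "species"))
        rows = analyze_ip([primer], records, cfg, lineages)
        assert rows[0].n_groups == 3
        assert rows[0].n_covered == 1
        assert rows[0].coverage_pct == pytest.approx(100 / 3)

    def test_absent_primer_zero_and_empty_fasta(self, tmp_path):
        primer = PrimerRecord(name="ghost", role="forward", sequence="ACGTACGTACGT")
        records = [_rec("s1", BACKGROUND)]
        cfg = RunConfig(out_dir=tmp_path)
        rows = analyze_ip([primer], records, cfg)
        assert rows[0].coverage_pct == 0.0
        assert rows[0].mean_start is None
        assert (tmp_path / "ghost_hits.fasta").read_text() == ""

    def test_unknown_role_hits_in_either_orientation(self):
        primer = PrimerRecord(name="u", role="unknown", sequence="AACCCA")
        # target contains only the reverse complement TGGGTT
        records = [_rec("s1", BACKGROUND[:10] + "TGGGTT" + BACKGROUND[10:])]
        rows = analyze_ip([primer], records, RunConfig())
        assert rows[0].coverage_pct == 100.0
        forward_only = PrimerRecord(name="f", role="forward", sequence="AACCCA")
        assert analyze_ip([forward_only], records, RunConfig())[0].coverage_pct == 0.0

    def test_empty_inputs_error(self):
        primer = PrimerRecord(name="p", role="forward", sequence="ACGT")
        with pytest.raises(ValueError):
            analyze_ip([], [_rec("s1", "ACGT")], RunConfig())
        with pytest.raises(ValueError):
            analyze_ip([primer], [], RunConfig())

    def test_pair_records_rejected_by_ip(self):
        pair = PrimerRecord(name="pp", role="pair", fwd_sequence="AA", rev_sequence="TT")
        with pytest.raises(ValueError):
            analyze_ip([pair], [_rec("s1", "ACGT")], RunConfig())

    def test_output_files_written(self, tmp_path):
        primer = PrimerRecord(name="p1", role="forward", sequence="ACGTACGT")
        records = [_rec("s1", "ACGTACGT" + BACKGROUND)]
        cfg = RunConfig(out_dir=tmp_path)
        analyze_ip([primer], records, cfg)
        table = (tmp_path / "coverage_ip.tsv").read_text().splitlines()
        assert table[1].startswith("p1\t1\t1\t100.00")
        fasta = (tmp_path / "p1_hits.fasta").read_text()
        assert fasta == ">s1|1-8\nACGTACGT\n"


class TestAnalyzePp:
    def _db(self):
        fwd, rev = "CATGGCTAGC", "GTTCAAGCGG"
        insert = "A" * 80
        present = BACKGROUND[:10] + fwd + insert + rev + BACKGROUND[10:20]
        absent = BACKGROUND + BACKGROUND[:20]
        pair = PrimerRecord(name="pA", role="pair", fwd_sequence=fwd, rev_sequence=rev)
        records = [
            _rec("s1", present),
            _rec("s2", present),
            _rec("s3", present),
            _rec("s4", absent),
            _rec("s5", absent),
        ]
        return pair, records

    def test_planted_pair_coverage_and_length(self):
        pair, records = self._db()
        cfg = RunConfig(min_len=50, max_len=200)
        rows = analyze_pp([pair], records, cfg)
        assert rows[0].coverage_pct == 60.0
        assert rows[0].mean_amplicon_length == 100.0

    def test_max_len_excludes_all(self):
        pair, records = self._db()
        rows = analyze_pp([pair], records, RunConfig(max_len=80))
        assert rows[0].coverage_pct == 0.0

    def test_unset_bounds_equal_loose_bounds(self):
        pair, records = self._db()
        loose = analyze_pp([pair], records, RunConfig(min_len=0, max_len=10 ** 9))
        unset = analyze_pp([pair], records, RunConfig())
        assert [r.coverage_pct for r in loose] == [r.coverage_pct for r in unset]

    def test_amplicon_fasta_contains_representatives(self, tmp_path):
        pair, records = self._db()
        cfg = RunConfig(out_dir=tmp_path)
        analyze_pp([pair], records, cfg)
        text = (tmp_path / "pA_amplicons.fasta").read_text()
        assert text.count(">") == 3
        first_header, first_seq = text.splitlines()[:2]
        assert first_header == ">s1|11-110"
        assert len(first_seq) == 100

    def test_single_records_rejected_by_pp(self):
        single = PrimerRecord(name="f", role="forward", sequence="ACGT")
        with pytest.raises(ValueError):
            analyze_pp([single], [_rec("s1", "ACGT")], RunConfig())


class TestClassifyDomains:
    def test_calls(self):
        bact = [_row("a", 30.0), _row("b", 12.5), _row("c", 0.0), _row("d", 0.0)]
        arch = [_row("a", 0.0), _row("b", 80.0), _row("c", 50.0), _row("d", 0.0)]
        calls = {c.primer_name: c.call for c in classify_domains(bact, arch)}
        assert calls == {"a": "bacteria", "b": "universal", "c": "archaea", "d": "none"}

    def test_counts_sum_to_input(self):
        bact = [_row(f"p{i}", 10.0 * (i % 2)) for i in range(10)]
        arch = [_row(f"p{i}", 10.0 * (i % 3 == 0)) for i in range(10)]
        calls = classify_domains(bact, arch)
        assert len(calls) == 10

    def test_missing_primer_errors(self):
        with pytest.raises(ValueError, match="b"):
            classify_domains([_row("a", 1.0), _row("b", 1.0)], [_row("a", 1.0)])

    def test_min_cov_threshold(self):
        bact, arch = [_row("a", 5.0)], [_row("a", 0.0)]
        assert classify_domains(bact, arch, min_cov=0.0)[0].call == "bacteria"
        assert classify_domains(bact, arch, min_cov=5.0)[0].call == "none"


class TestBuildCandidatePairs:
    def _primers(self):
        return [
            PrimerRecord(name=f"f{i}", role="forward", sequence="ACGTACGT")
            for i in range(3)
        ] + [
            PrimerRecord(name=f"r{i}", role="reverse", sequence="TTGGCCAA")
            for i in range(2)
        ]

    def test_cross_product(self):
        primers = self._primers()
        rows = [_row(p.name, 90.0) for p in primers]
        pairs = build_candidate_pairs(primers, rows)
        assert len(pairs) == 6
        assert {p.name for p in pairs} == {
            f"f{i}-r{j}" for i in range(3) for j in range(2)
        }

    def test_threshold_is_ge_on_unrounded_value(self):
        primers = [
            PrimerRecord(name="f", role="forward", sequence="ACGT"),
            PrimerRecord(name="r1", role="reverse", sequence="ACGT"),
            PrimerRecord(name="r2", role="reverse", sequence="ACGT"),
        ]
        rows = [_row("f", 80.0), _row("r1", 74.99), _row("r2", 75.0)]
        pairs = build_candidate_pairs(primers, rows, threshold_pct=75.0)
        assert [p.name for p in pairs] == ["f-r2"]

    def test_no_eligible_reverse_empty(self, caplog):
        primers = self._primers()
        rows = [_row(p.name, 90.0 if p.role == "forward" else 10.0) for p in primers]
        with caplog.at_level("WARNING"):
            assert build_candidate_pairs(primers, rows) == []
        assert "no eligible" in caplog.text

    def test_unknown_role_eligible_both_sides(self):
        primers = [
            PrimerRecord(name="u1", role="unknown", sequence="ACGT"),
            PrimerRecord(name="u2", role="unknown", sequence="GGCC"),
        ]
        rows = [_row("u1", 90.0), _row("u2", 90.0)]
        pairs = build_candidate_pairs(primers, rows)
        assert {p.name for p in pairs} == {"u1-u1", "u1-u2", "u2-u1", "u2-u2"}


class TestRunCaseStudy:
    def _setup(self):
        """Planted design: 2 bacteria-only, 1 archaea-only, 1 universal,
        1 dead primer, over two 4-species databases."""
        site_b1 = "ACGGTCCAGACTCCTACG"
        site_b2 = "GGATCCTTAAGCGTACGA"
        site_a1 = "TTGACCGGTATCCAGAGC"
        site_u1 = "CATGGCTAGCTAACTGAC"
        dead = "GTGTGTGTGTACACACAC"
        primers = [
            PrimerRecord(name="b1", role="forward", sequence=site_b1),
            PrimerRecord(name="b2", role="reverse", sequence=site_b2),
            PrimerRecord(name="a1", role="forward", sequence=site_a1),
            PrimerRecord(name="u1", role="reverse", sequence=site_u1),
            PrimerRecord(name="dead", role="forward", sequence=dead),
        ]
        pad1 = "TTCAATCTGTCCTGAGTCCTAGTCGGACTTGCAATCTG"
        pad2 = "CCTTGAGTGCAGAGTCCTAGAAGGACTTGACCCATAGG"

        def db(sites_by_species):
            records, lineages = [], {}
            for sp, sites in sites_by_species.items():
                for k in range(2):
                    sid = f"{sp}_{k}"
                    seq = pad1 + "".join(sites) + pad2
                    records.append(_rec(sid, seq))
                    lineages[sid] = _lineage(("P1", sp))
            return records, lineages

        bact_records, bact_lin = db(
            {
                "SpA": [site_b1, site_u1],
                "SpB": [site_b1, site_b2, site_u1],
                "SpC": [site_b2],
                "SpD": [pad1],
            }
        )
        arch_records, arch_lin = db(
            {
                "SpE": [site_a1, site_u1],
                "SpF": [site_a1],
                "SpG": [site_u1],
                "SpH": [pad2],
            }
        )
        return primers, (bact_records, bact_lin), (arch_records, arch_lin)

    def test_table1_style_counts(self):
        primers, (brec, blin), (arec, alin) = self._setup()
        cfg = RunConfig(mode="species", level_names=("phylum", "species"))
        result = run_case_study(
            primers, brec, arec, cfg, bact_tax=blin, arch_tax=alin
        )
        assert result.counts == {
            "bacteria": 2,
            "archaea": 1,
            "universal": 1,
            "none": 1,
        }
        assert sum(result.counts.values()) == len(primers)

    def test_pair_table_ranked(self):
        primers, (brec, blin), (arec, alin) = self._setup()
        cfg = RunConfig(mode="species", level_names=("phylum", "species"))
        result = run_case_study(
            primers, brec, arec, cfg, threshold_pct=50.0,
            bact_tax=blin, arch_tax=alin,
        )
        assert result.n_candidate_pairs > 0
        covs = [r.coverage_pct for r in result.bacterial_pair_rows]
        assert covs == sorted(covs, reverse=True)

    def test_no_primer_reaches_threshold_empty_pairs(self):
        primers, (brec, blin), (arec, alin) = self._setup()
        cfg = RunConfig(mode="species", level_names=("phylum", "species"))
        result = run_case_study(
            primers, brec, arec, cfg, threshold_pct=100.1,
            bact_tax=blin, arch_tax=alin,
        )
        assert result.bacterial_pair_rows == []
        assert result.archaeal_pair_rows == []

    def test_pair_coverage_bounded_by_singles(self):
        primers, (brec, blin), (arec, alin) = self._setup()
        cfg = RunConfig(mode="species", level_names=("phylum", "species"))
        result = run_case_study(
            primers, brec, arec, cfg, threshold_pct=25.0,
            bact_tax=blin, arch_tax=alin,
        )
        singles = {r.primer_name: r.coverage_pct for r in result.bacterial_rows}
        for row in result.bacterial_pair_rows:
            fwd_name, _, rev_name = row.primer_name.partition("-")
            assert row.coverage_pct <= min(singles[fwd_name], singles[rev_name]) + 1e-9


class TestRunConfig:
    def test_len_bounds_validated(self):
        with pytest.raises(ValueError):
            RunConfig(min_len=10, max_len=5)

    def test_level_must_be_known(self):
        with pytest.raises(ValueError, match="species"):
            RunConfig(mode="variant")

    def test_clades_mode_always_valid(self):
        assert RunConfig(mode="clades").mode == "clades"

    def test_json_echo_roundtrip(self):
        import json

        cfg = RunConfig(max_mismatches=2, mode="species", min_len=50)
        data = json.loads(cfg.to_json())
        assert data["max_mismatches"] == 2
        assert data["mode"] == "species"
        assert data["min_len"] == 50
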