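import numpy as np
import pytest
import yaml

from tewick.errors import ConfigError, InputError
from tewick.evidence import (
    dump_rules,
    format_record,
    infer_domain_role,
    load_rules,
    parse_blast_tabular,
    parse_domtbl,
    parse_subject_category,
    read_fasta,
    write_output,
)
from tewick.model import ClassificationRecord, Order, Status


def _blast_line(qid, sid, sstart, send, slen):
    return "\t".join(map(str, [qid, sid, 85.0, abs(send - sstart) + 1, 3, 0,
                               1, 600, sstart, send, "1e-50", 200.0, slen]))


class TestReadFasta:
    def test_two_records_order_and_lengths(self, tmp_path):
        p = tmp_path / "in.fa"
        p.write_text(">a desc\nACGTACGT\n>b\nACG\nTAC\n")
        recs = read_fasta(p)
        assert [(r.id, r.length) for r in recs] == [("a", 8), ("b", 6)]

    def test_soft_masked_residues_uppercased(self, tmp_path):
        p = tmp_path / "in.fa"
        p.write_text(">a\nacgtRyacgt\n")
        (rec,) = read_fasta(p)
        assert rec.sequence == "ACGTNNACGT"

    def test_crlf_equals_lf(self, tmp_path):
        lf = tmp_path / "lf.fa"
        crlf = tmp_path / "crlf.fa"
        lf.write_text(">a\nACGT\nACGT\n")
        crlf.write_bytes(b">a\r\nACGT\r\nACGT\r\n")
        assert read_fasta(lf) == read_fasta(crlf)

    def test_duplicate_ids_strict_vs_uniquify(self, tmp_path):
        p = tmp_path / "in.fa"
        p.write_text(">a\nACGT\n>a\nACGG\n")
        with pytest.raises(InputError):
            read_fasta(p)
        recs = read_fasta(p, on_duplicate="uniquify")
        assert [r.id for r in recs] == ["a", "a.1"]

    def test_empty_file_empty_list(self, tmp_path):
        p = tmp_path / "in.fa"
        p.write_text("")
        assert read_fasta(p) == []


class TestParseBlastTabular:
    def test_coverage_at_exactly_five_percent_dropped(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text(_blast_line("q", "s#LTR/Gypsy", 1, 50, 1000) + "\n")
        assert parse_blast_tabular(p, "TE_bank", "blastx") == []

    def test_reversed_subject_span_is_orientation_agnostic(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text(_blast_line("q", "s#LTR/Gypsy", 100, 1, 200) + "\n")
        (hit,) = parse_blast_tabular(p, "TE_bank", "blastx")
        assert hit.subject_coverage == pytest.approx(50.0)
        assert hit.strand == -1

    def test_retained_set_matches_filter_oracle(self, tmp_path):
        rng = np.random.default_rng(7)
        rows = []
        for i in range(20):
            slen = int(rng.integers(100, 2000))
            s_start = int(rng.integers(1, slen))
            s_end = int(rng.integers(1, slen))
            rows.append(("q%d" % i, "s%d#LINE/L1" % i, s_start, s_end, slen))
        p = tmp_path / "hits.tsv"
        p.write_text("".join(_blast_line(*r) + "\n" for r in rows))
        got = {h.subject_id for h in parse_blast_tabular(p, "TE_bank", "blastx")}
        expected = {sid for _, sid, s0, s1, slen in rows
                    if 100.0 * (abs(s1 - s0) + 1) / slen > 5.0}
        assert got == expected

    def test_filter_is_idempotent(self, tmp_path):
        rng = np.random.default_rng(70)
        rows = [("q", "s%d#DNA/hAT" % i, 1, int(rng.integers(1, 900)), 900)
                for i in range(10)]
        p = tmp_path / "a.tsv"
        p.write_text("".join(_blast_line(*r) + "\n" for r in rows))
        first = parse_blast_tabular(p, "TE_bank", "tblastx")
        p2 = tmp_path / "b.tsv"
        p2.write_text("".join(
            _blast_line(h.query_id, h.subject_id, h.s_start, h.s_end, h.subject_length) + "\n"
            for h in first))
        second = parse_blast_tabular(p2, "TE_bank", "tblastx")
        assert [(h.subject_id, h.subject_coverage) for h in first] == \
               [(h.subject_id, h.subject_coverage) for h in second]

    def test_missing_subject_length_names_subject(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text("\t".join(map(str, ["q", "mystery", 90.0, 100, 1, 0,
                                         1, 100, 1, 100, "1e-10", 50.0])) + "\n")
        with pytest.raises(InputError, match="mystery"):
            parse_blast_tabular(p, "TE_bank", "blastx")
        (hit,) = parse_blast_tabular(p, "TE_bank", "blastx",
                                     subject_lengths={"mystery": 400})
        assert hit.subject_coverage == pytest.approx(25.0)

    def test_non_te_banks_keep_subthreshold_hits(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text(_blast_line("q", "geneX#Gene", 1, 20, 1000) + "\n")
        (hit,) = parse_blast_tabular(p, "hostgene_bank", "blastn")
        assert hit.subject_coverage == pytest.approx(2.0)


class TestSubjectCategory:
    @pytest.mark.parametrize("header,order", [
        ("X#LTR/Gypsy", Order.LTR),
        ("X#DNA/hAT", Order.TIR),
        ("X#RC/Helitron", Order.HELITRON),
        ("X#Penelope", Order.PLE),
        ("X#MITE/Tourist", Order.MITE),
        ("plainname", Order.UNKNOWN),
        ("X#Martian/Thing", Order.UNKNOWN),
    ])
    def test_repbase_style_headers(self, header, order):
        assert parse_subject_category(header).order is order

    def test_override_map_wins(self):
        assert parse_subject_category("oddname", {"oddname": "Crypton"}).order is Order.CRYPTON


def _domtbl_line(profile, tlen, query, hmm_from, hmm_to):
    fields = [profile, "-", tlen, query, "-", 500, "1e-40", 150.0, 0.1,
              1, 1, "1e-40", "1e-40", 150.0, 0.1, hmm_from, hmm_to,
              10, 60, 10, 60, 0.9, "desc"]
    return " ".join(map(str, fields))


class TestParseDomtbl:
    def test_coverage_at_exactly_twenty_percent_dropped(self, tmp_path):
        p = tmp_path / "d.tbl"
        p.write_text(_domtbl_line("RVT_1", 250, "q_fr+1", 1, 50) + "\n")
        assert parse_domtbl(p) == []

    def test_full_profile_span_retained(self, tmp_path):
        p = tmp_path / "d.tbl"
        p.write_text(_domtbl_line("RVT_1", 250, "q_fr-2", 1, 250) + "\n")
        (hit,) = parse_domtbl(p)
        assert hit.profile_coverage == pytest.approx(100.0)
        assert (hit.query_id, hit.frame, hit.domain_role) == ("q", -2, "RT")

    def test_threshold_straddle_matches_recomputation(self, tmp_path):
        rng = np.random.default_rng(9)
        rows = []
        for i in range(10):
            tlen = 200
            hmm_to = int(rng.integers(20, 200))
            rows.append(("GAG_%d" % i, tlen, "q_fr+1", 1, hmm_to))
        p = tmp_path / "d.tbl"
        p.write_text("".join(_domtbl_line(*r) + "\n" for r in rows))
        got = {h.profile_name for h in parse_domtbl(p)}
        expected = {name for name, tlen, _, lo, hi in rows
                    if 100.0 * (hi - lo + 1) / tlen > 20.0}
        assert got == expected

    def test_malformed_frame_suffix_is_input_error(self, tmp_path):
        p = tmp_path / "d.tbl"
        p.write_text(_domtbl_line("RVT_1", 250, "q_frX", 1, 250) + "\n")
        with pytest.raises(InputError):
            parse_domtbl(p)

    @pytest.mark.parametrize("name,role", [
        ("RVT_1", "RT"), ("rve", "INT"), ("GAG_pre", "GAG"), ("Prot_AP", "AP"),
        ("RNaseH", "RH"), ("ENV_2", "ENV"), ("Endo_EN", "EN"), ("Tase_DDE", "Tase"),
        ("YR_crypt", "YR"), ("HEL_c", "HEL"), ("RPA_like", "RPA"),
        ("PolB_2", "PolB"), ("ATPase_AAA", "ATPase"), ("unremarkable", "other"),
    ])
    def test_role_inference(self, name, role):
        assert infer_domain_role(name) == role


class TestRules:
    def test_default_config_round_trips(self, tmp_path, ruleset):
        out = tmp_path / "rules.yaml"
        dump_rules(ruleset, out)
        again = load_rules(out)
        assert again.raw == ruleset.raw
        assert {k: v.max_raw for k, v in again.categories.items()} == \
               {k: v.max_raw for k, v in ruleset.categories.items()}

    def test_user_override_merges(self, tmp_path):
        p = tmp_path / "user.yaml"
        p.write_text("thresholds:\n  blast_cov_min: 10\n")
        rs = load_rules(p)
        assert rs.thresholds["blast_cov_min"] == 10
        assert rs.thresholds["profile_cov_min"] == 20  # default kept

    def test_unknown_condition_keyword_rejected(self, tmp_path):
        p = tmp_path / "user.yaml"
        p.write_text(yaml.safe_dump({"categories": {"LTR": {"max_raw": "auto", "rules": [
            {"name": "bad", "add": 1, "when": {"has_tsd": True}}]}}}))
        with pytest.raises(ConfigError, match="has_tsd"):
            load_rules(p)

    def test_max_raw_below_attainable_rejected(self, tmp_path):
        p = tmp_path / "user.yaml"
        p.write_text(yaml.safe_dump({"categories": {"TIR": {"max_raw": 1, "rules": [
            {"name": "a", "add": 2, "when": {"terminal_repeat": "inverted"}}]}}}))
        with pytest.raises(ConfigError, match="max_raw"):
            load_rules(p)

    def test_auto_max_raw_is_sum_of_positive_increments(self, ruleset):
        for name, cat in ruleset.categories.items():
            attainable = sum(r.add for r in cat.rules if r.add > 0)
            assert cat.max_raw >= attainable
            if name != "LTR":
                assert cat.max_raw == attainable


class TestWriteOutput:
    def _record(self, **kw):
        defaults = dict(te_id="te1", length=5366, orientation="+", status=Status.OK,
                        te_class="I", order="LTR", completeness="complete",
                        confidence=100, evidence_summary=["coding(TE_BLRx: x 60.00%)"])
        defaults.update(kw)
        return ClassificationRecord(**defaults)

    def test_pipe_joined_candidates(self, tmp_path):
        rec = self._record(order="Helitron|LARD", te_class="II|I",
                           status=Status.POTENTIAL_CHIMERIC, confidence=70)
        line = format_record(rec)
        assert "Helitron|LARD" in line
        assert "PotentialChimeric" in line

    def test_confidence_printed_as_integer(self):
        assert format_record(self._record(confidence=100)).split("\t")[7] == "100"

    def test_column_order_fixed(self, tmp_path):
        out = tmp_path / "out.tsv"
        write_output([self._record()], out)
        header, row = out.read_text().splitlines()
        assert header == "#te_id\tlength\torientation\tstatus\tclass\torder\tcompleteness\tconfidence\tevidence"
        assert row.split("\t")[:4] == ["te1", "5366", "+", "OK"]
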