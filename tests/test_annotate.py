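"""BTOP grammar, annotation TSV ingestion, naive V/J calls, primer trimming."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dumparts.annotate import (
    BtopEvent,
    btop_counts,
    btop_mutations,
    naive_vdj_assign,
    parse_annotation_tsv,
    parse_btop,
    serialize_btop,
    trim_primer_regions,
)
from dumparts.simulate import mutate_substitutions


class TestParseBtop:
    def test_pure_match_run(self):
        events = parse_btop("120")
        assert events == [BtopEvent("match", 120)]
        assert btop_counts(events) == (120, 0, 0)

    def test_runs_with_substitutions(self):
        events = parse_btop("25AG10CT100")
        assert btop_counts(events) == (137, 2, 0)
        subs = [e for e in events if e.op == "sub"]
        assert [(e.q, e.s) for e in subs] == [("A", "G"), ("C", "T")]

    def test_gap_tokens(self):
        # 'A-': read base over a gap (insertion); '-A': gap over germline base
        events = parse_btop("10A-5")
        assert [e.op for e in events] == ["match", "ins", "match"]
        events = parse_btop("10-A5")
        assert [e.op for e in events] == ["match", "del", "match"]

    def test_malformed_token_reports_offset(self):
        with pytest.raises(ValueError, match="offset"):
            parse_btop("10A")

    def test_mutation_positions(self):
        muts = btop_mutations(parse_btop("25AG10CT100"), germ_start=0, read_start=0)
        assert [(m.read_pos, m.germ_pos) for m in muts] == [(25, 25), (36, 36)]
        assert [(m.germ_base, m.read_base) for m in muts] == [("G", "A"), ("T", "C")]


@st.composite
def btop_events(draw):
    """Random event lists whose serialization is canonical (no adjacent runs,
    no zero-length runs), so serialize -> parse is an exact round trip."""
    n = draw(st.integers(1, 12))
    events, last_was_run = [], False
    bases = "ACGT"
    for _ in range(n):
        if last_was_run:
            op = draw(st.sampled_from(["sub", "ins", "del"]))
        else:
            op = draw(st.sampled_from(["match", "sub", "ins", "del"]))
        if op == "match":
            events.append(BtopEvent("match", draw(st.integers(1, 500))))
            last_was_run = True
        else:
            q = draw(st.sampled_from(bases))
            s = draw(st.sampled_from(bases))
            if op == "sub":
                events.append(BtopEvent("sub", 1, q, s))
            elif op == "ins":
                events.append(BtopEvent("ins", 1, q, None))
            else:
                events.append(BtopEvent("del", 1, None, s))
            last_was_run = False
    return events


class TestBtopRoundTrip:
    @given(btop_events())
    @settings(max_examples=200, deadline=None)
    def test_serialize_then_parse_is_identity(self, events):
        assert parse_btop(serialize_btop(events)) == events


TSV_HEADER = "sequence_id\tv_call\tj_call\tcdr3\tv_alignment_length\tmismatches\tgaps\tbtop\n"


class TestParseAnnotationTsv:
    def test_well_formed_rows(self, tmp_path):
        p = tmp_path / "ann.tsv"
        p.write_text(
            TSV_HEADER
            + "s1\tIGHV1-1*01\tIGHJ1*01\tACGT\t100\t0\t0\t100\n"
            + "s2\tIGHV1-2*01\tIGHJ2*01\tACGA\t137\t2\t0\t25AG10CT100\n"
            + "s3\tIGHV2-1*01\tIGHJ1*01\tAC\t16\t0\t1\t10A-5\n"
        )
        rows = parse_annotation_tsv(p)
        assert len(rows) == 3
        assert rows[1].mismatches == 2
        assert rows[0].v_gene == "IGHV1-1"  # allele suffix stripped

    def test_btop_inconsistent_with_counts_rejected(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text(TSV_HEADER + "s1\tV\tJ\tACGT\t137\t5\t0\t25AG10CT100\n")
        with pytest.raises(ValueError, match="line 2"):
            parse_annotation_tsv(p)

    def test_empty_file_with_header(self, tmp_path):
        p = tmp_path / "empty.tsv"
        p.write_text(TSV_HEADER)
        assert parse_annotation_tsv(p) == []

    def test_missing_column_named(self, tmp_path):
        p = tmp_path / "cols.tsv"
        p.write_text("sequence_id\tv_call\n" + "s1\tV\n")
        with pytest.raises(ValueError, match="btop"):
            parse_annotation_tsv(p)


class TestNaiveVdjAssign:
    def test_error_free_round_trip(self, germlines):
        v = germlines.v_genes[3]
        j = germlines.j_genes[1]
        junction = "ACGTACGTACGTAGG"
        read = v.sequence + junction + j.sequence + germlines.constant_stub
        row = naive_vdj_assign(read, "r1", germlines)
        assert (row.v_call, row.j_call) == (v.gene_id, j.gene_id)
        assert row.mismatches == 0
        expected_cdr3 = read[v.anchor : len(v.sequence) + len(junction) + j.anchor]
        assert row.cdr3_nt == expected_cdr3

    def test_substitutions_counted_and_traced(self, germlines):
        v = germlines.v_genes[0]
        j = germlines.j_genes[0]
        rng = np.random.default_rng(2)
        v_mut = mutate_substitutions(v.sequence, 2, rng)
        read = v_mut + "AAAACCCC" + j.sequence + germlines.constant_stub
        row = naive_vdj_assign(read, "r1", germlines)
        assert row.v_call == v.gene_id
        assert row.mismatches == 2
        assert btop_counts(parse_btop(row.btop))[1] == 2
        # mismatch count equals the Hamming distance of the gap-free columns
        assert row.mismatches == sum(a != b for a, b in zip(v_mut, v.sequence))

    def test_random_sequence_gets_null_calls(self, germlines):
        rng = np.random.default_rng(3)
        junk = "".join("ACGT"[i] for i in rng.integers(0, 4, 350))
        row = naive_vdj_assign(junk, "r1", germlines)
        assert row.v_call is None and row.j_call is None

    def test_error_free_simulated_reads_fully_recovered(self, germlines):
        from dumparts.simulate import SimConfig, make_repertoire

        cfg = SimConfig(n_samples=1, templates_per_sample=25, seed=9)
        for t in make_repertoire(cfg, germlines):
            row = naive_vdj_assign(t.sequence, t.template_id, germlines)
            assert (row.v_call, row.j_call) == (t.v_id, t.j_id)
            assert row.cdr3_nt == t.cdr3


class TestTrimPrimerRegions:
    def _row(self, germlines, mut_positions):
        v = germlines.v_genes[0]
        rng = np.random.default_rng(4)
        seq = list(v.sequence + "AAAACCCC" + germlines.j_genes[0].sequence + germlines.constant_stub)
        for p in mut_positions:
            seq[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[seq[p]]
        return naive_vdj_assign("".join(seq), "r", germlines)

    def test_mutation_in_lead_window_excluded(self, germlines):
        row = self._row(germlines, [10])
        assert len(row.mutations) == 1
        trimmed = trim_primer_regions(row, lead=25, tail=8)
        assert trimmed.mutations == []

    def test_mutation_past_lead_retained(self, germlines):
        row = self._row(germlines, [30])
        trimmed = trim_primer_regions(row, lead=25, tail=8)
        assert len(trimmed.mutations) == 1 and trimmed.mutations[0].read_pos == 30

    def test_zero_trim_is_identity(self, germlines):
        row = self._row(germlines, [10, 30])
        trimmed = trim_primer_regions(row, lead=0, tail=0)
        assert trimmed.mutations == row.mutations

    def test_too_short_alignment_flagged(self, germlines):
        row = self._row(germlines, [])
        short = trim_primer_regions(row, lead=200, tail=200)
        assert short.shm_valid is False and short.mutations == []
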