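"""Clonotyping, SHM, profiles/patterns, replacement, similarity indices."""

import numpy as np
import pytest
from scipy.stats import entropy

from dumparts.annotate import AnnotationRow, Mutation
from dumparts.consensus import ConsensusRecord
from dumparts.stats import (
    define_clones,
    jsd_top_clones,
    morisita_horn,
    mutation_pattern,
    mutation_profile,
    shared_clones,
    shm_stats,
    unique_seq_fold_change,
    vj_replacement,
)


def _row(sid, v="IGHV1-1*01", j="IGHJ1*01", cdr3="ACGT", v_aln=220, muts=()):
    return AnnotationRow(
        sequence_id=sid,
        v_call=v,
        j_call=j,
        cdr3_nt=cdr3,
        v_alignment_length=v_aln,
        mismatches=len(muts),
        gaps=0,
        identity=1.0,
        btop=str(v_aln),
        v_end=v_aln,
        mutations=list(muts),
    )


class TestDefineClones:
    def test_same_key_groups_into_one_clone(self):
        df = define_clones([_row("a"), _row("b")])
        assert len(df) == 1 and df.iloc[0]["size"] == 2

    def test_short_v_alignment_excluded(self):
        df = define_clones([_row("a"), _row("b", v_aln=150)])
        assert df["size"].sum() == 1

    def test_different_j_different_clone(self):
        df = define_clones([_row("a"), _row("b", j="IGHJ2*01")])
        assert len(df) == 2

    def test_allele_level_calls_collapse_to_gene(self):
        df = define_clones([_row("a", v="IGHV1-1*01"), _row("b", v="IGHV1-1*02")])
        assert len(df) == 1


class TestShm:
    def test_clone_mean_is_arithmetic_mean(self):
        rows = [
            _row("a", muts=()),
            _row("b", muts=(Mutation(30, 30, "A", "G"),)),
            _row("c", muts=(Mutation(30, 30, "A", "G"), Mutation(40, 40, "C", "T"))),
        ]
        df = define_clones(rows)
        assert df.iloc[0]["mean_shm"] == pytest.approx(1.0)

    def test_segment_rate_from_btop(self):
        from dumparts.annotate import btop_mutations, parse_btop

        muts = btop_mutations(parse_btop("25AG10CT100"))
        df = shm_stats([_row("a", v_aln=137, muts=muts)])
        assert df.iloc[0]["rate"] == pytest.approx(2 / 137)

    def test_error_free_repertoire_all_zero(self):
        df = shm_stats([_row(f"r{i}") for i in range(10)])
        assert (df["n_mutations"] == 0).all()


class TestMutationProfile:
    def test_error_free_profile_is_zero(self):
        rows = [_row(f"r{i}") for i in range(10)]
        prof = mutation_profile(rows, "IGHV1-1*01", germline_length=240)
        covered = prof["coverage"] > 0
        assert (prof.loc[covered, "frequency"] == 0).all()

    def test_frequency_counts_sequences_not_events(self):
        mut = (Mutation(57, 57, "A", "G"),)
        rows = [_row(f"m{i}", muts=mut) for i in range(4)] + [_row(f"c{i}") for i in range(6)]
        prof = mutation_profile(rows, "IGHV1-1*01", germline_length=240)
        assert prof.loc[prof["position"] == 58, "frequency"].item() == pytest.approx(0.4)

    def test_uncovered_positions_masked_not_zero(self):
        rows = [_row("a", v_aln=100)]
        prof = mutation_profile(rows, "IGHV1-1*01", germline_length=240)
        assert np.isnan(prof["frequency"].iloc[200])


class TestMutationPattern:
    def test_tally_percentages(self):
        rows = [
            _row("a", muts=tuple(Mutation(i, i, "A", "G") for i in range(3))),
            _row("b", muts=(Mutation(5, 5, "C", "T"),)),
        ]
        mat = mutation_pattern(rows)
        assert mat.loc["A", "G"] == pytest.approx(75.0)
        assert mat.loc["C", "T"] == pytest.approx(25.0)

    def test_single_event_is_hundred_percent(self):
        mat = mutation_pattern([_row("a", muts=(Mutation(1, 1, "G", "A"),))])
        assert mat.loc["G", "A"] == pytest.approx(100.0)

    def test_off_diagonal_sums_to_hundred(self):
        rng = np.random.default_rng(0)
        rows = []
        for i in range(20):
            g, o = rng.choice(list("ACGT"), 2, replace=False)
            rows.append(_row(f"r{i}", muts=(Mutation(i, i, g, o),)))
        mat = mutation_pattern(rows)
        assert np.asarray(mat).sum() == pytest.approx(100.0)
        assert all(mat.loc[n, n] == 0 for n in "ACGT")

    def test_no_substitutions_raises(self):
        with pytest.raises(ValueError):
            mutation_pattern([_row("a")])


class TestVjReplacement:
    def test_hand_example(self):
        rows = [
            _row("a", v="IGHV1-1*01", cdr3="X"),
            _row("b", v="IGHV1-2*01", cdr3="X"),
            _row("c", v="IGHV1-1*01", cdr3="Y"),
        ]
        rep = vj_replacement(rows)
        assert rep["v_replacement"] == pytest.approx(0.5)
        assert rep["j_replacement"] == 0.0

    def test_all_single_v_is_zero(self):
        rows = [_row(chr(97 + i), cdr3=f"C{i}") for i in range(5)]
        assert vj_replacement(rows)["v_replacement"] == 0.0


class TestJsd:
    def test_identical_repertoires_zero(self):
        rep = {("V", "J", "A"): 10, ("V", "J", "B"): 5}
        assert jsd_top_clones(rep, dict(rep)) == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_top_clones_maximal(self):
        a = {("V", "J", "A"): 10}
        b = {("V", "J", "B"): 10}
        assert jsd_top_clones(a, b) == pytest.approx(1.0)

    def test_closed_form_entropy_oracle(self):
        a = {("V", "J", "A"): 5, ("V", "J", "B"): 5}
        b = {("V", "J", "A"): 10}
        p, q = np.array([0.5, 0.5]), np.array([1.0, 0.0])
        m = (p + q) / 2
        expected = np.sqrt(entropy(m, base=2) - 0.5 * (entropy(p, base=2) + entropy(q, base=2)))
        assert jsd_top_clones(a, b) == pytest.approx(float(expected), abs=1e-12)

    def test_symmetry(self):
        rng = np.random.default_rng(1)
        a = {("V", "J", f"C{i}"): int(rng.integers(1, 50)) for i in range(15)}
        b = {("V", "J", f"C{i}"): int(rng.integers(1, 50)) for i in range(5, 20)}
        assert jsd_top_clones(a, b) == pytest.approx(jsd_top_clones(b, a), abs=1e-12)


class TestMorisitaHorn:
    def test_identical_vectors(self):
        assert morisita_horn([3, 2, 1], [3, 2, 1]) == pytest.approx(1.0)

    def test_disjoint_supports(self):
        assert morisita_horn([1, 0], [0, 1]) == pytest.approx(0.0)

    def test_hand_evaluated_example(self):
        # x=(2,1), y=(1,2): C = 2*(2+2) / ((5/9 + 5/9) * 3 * 3) = 8/10
        assert morisita_horn([2, 1], [1, 2]) == pytest.approx(0.8)

    def test_all_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            morisita_horn([0, 0], [1, 2])

    def test_oracle_and_symmetry_on_random_vectors(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            x = rng.integers(0, 40, size=12).astype(float)
            y = rng.integers(0, 40, size=12).astype(float)
            if x.sum() == 0 or y.sum() == 0:
                continue
            X, Y = x.sum(), y.sum()
            direct = 2 * np.dot(x, y) / ((np.dot(x, x) / X**2 + np.dot(y, y) / Y**2) * X * Y)
            assert morisita_horn(x, y) == pytest.approx(direct, abs=1e-12)
            assert morisita_horn(x, y) == pytest.approx(morisita_horn(y, x), abs=1e-12)
            assert -1e-12 <= morisita_horn(x, y) <= 1 + 1e-9


class TestFoldChange:
    def _cons(self, seq, n):
        return [
            ConsensusRecord("S1", f"U{i}", f"V{i}", "C", seq, support=2) for i in range(n)
        ]

    def _reads(self, seq, n, n_pairs):
        return [(seq, ("S1", f"U{i % n_pairs}", f"V{i % n_pairs}")) for i in range(n)]

    def test_forty_reads_over_two_pairs_is_fold_twenty(self):
        df, lost = unique_seq_fold_change(self._reads("AAA", 40, 2), self._cons("AAA", 2))
        assert df.iloc[0]["fold"] == pytest.approx(20.0)
        assert lost == []

    def test_unit_fold(self):
        df, _ = unique_seq_fold_change(self._reads("AAA", 1, 1), self._cons("AAA", 1))
        assert df.iloc[0]["fold"] == pytest.approx(1.0)

    def test_lost_sequences_reported_not_divided(self):
        reads = self._reads("AAA", 2, 1) + [("CCC", ("S1", "X", "Y"))]
        df, lost = unique_seq_fold_change(reads, self._cons("AAA", 1))
        assert lost == ["CCC"] and len(df) == 1

    def test_folds_never_below_one(self):
        # reads whose error copies land in retained pairs still give fold >= 1
        reads = self._reads("AAA", 5, 2) + self._reads("AAT", 1, 1)
        df, _ = unique_seq_fold_change(reads, self._cons("AAA", 2))
        assert (df["fold"] >= 1).all()


class TestSharedClones:
    def test_identical(self):
        rep = {("V", "J", "A"): 3, ("V", "J", "B"): 1}
        s = shared_clones(rep, dict(rep))
        assert s["proportion_a"] == 1.0 and s["singleton_fraction_a"] == 0.5

    def test_disjoint(self):
        assert shared_clones({("V", "J", "A"): 1}, {("V", "J", "B"): 1})["n_shared"] == 0

    def test_constructed_overlap(self):
        a = {("V", "J", f"A{i}"): 2 for i in range(95)}
        b = {("V", "J", f"B{i}"): 2 for i in range(95)}
        for i in range(5):
            a[("V", "J", f"S{i}")] = 1
            b[("V", "J", f"S{i}")] = 4
        s = shared_clones(a, b)
        assert s["proportion_a"] == pytest.approx(0.05)
        assert s["proportion_b"] == pytest.approx(0.05)
        assert s["singleton_fraction_a"] == 1.0 and s["singleton_fraction_b"] == 0.0
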