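"""Simulator unit and property tests: construction, labelling, amplification."""

import dataclasses

import numpy as np
import pytest

from dumparts.simulate import (
    GermlineGene,
    GermlineSet,
    Molecule,
    SimConfig,
    Template,
    attach_labels,
    chimera_read_fraction,
    count_umi_collisions,
    make_repertoire,
    mutate_substitutions,
    pcr_amplify,
    sequence_reads,
)


def small_config(**kw):
    defaults = dict(n_samples=2, templates_per_sample=10, molecules_per_sample=30, seed=7)
    defaults.update(kw)
    return SimConfig(**defaults)


class TestMakeRepertoire:
    def test_templates_distinct_cdr3s(self, germlines):
        cfg = small_config(templates_per_sample=100, n_samples=1, seed=7)
        templates = make_repertoire(cfg, germlines)
        assert len(templates) == 100
        assert len({t.cdr3 for t in templates}) == 100

    def test_deterministic_under_fixed_seed(self, germlines):
        cfg = small_config(seed=7)
        a = make_repertoire(cfg, germlines)
        b = make_repertoire(small_config(seed=7), germlines)
        assert a == b

    def test_zero_junction_is_pure_concatenation(self):
        g = GermlineSet(
            (GermlineGene("V1", "ACGTACGTACGTACGT", 10),),
            (GermlineGene("J1", "TTTTCCCC", 4),),
            "GGGG",
        )
        cfg = small_config(n_samples=1, templates_per_sample=1, junction_length=(0, 0))
        (t,) = make_repertoire(cfg, g)
        assert t.sequence == "ACGTACGTACGTACGT" + "TTTTCCCC" + "GGGG"
        assert t.cdr3 == t.sequence[10 : len("ACGTACGTACGTACGT") + 4]

    def test_empty_germline_set_rejected(self):
        with pytest.raises(ValueError):
            make_repertoire(small_config(), GermlineSet((), (), ""))


class TestTemplateInvariants:
    def test_bad_cdr3_offsets_rejected(self):
        with pytest.raises(ValueError):
            Template("t", "S1", "ACGT", "V", "J", 2, 10, 1.0, 0.9)

    def test_bad_efficiency_rejected(self):
        with pytest.raises(ValueError):
            Template("t", "S1", "ACGT", "V", "J", 0, 2, 1.0, 1.5)

    def test_molecule_origin_switch_consistency(self):
        with pytest.raises(ValueError):
            Molecule("ACGT", "S1", "b", "b", "u", "u", "T1", "T2", "S1", 0.9, switch_pos=None)


class TestAttachLabels:
    def test_umi_pairs_nearly_all_distinct(self, germlines):
        # birthday bound: 1000 pairs over 4^24 keys -> expected collisions
        # ~ 1000^2 / (2 * 4^24) ~ 1.8e-9; assert at most 1
        cfg = small_config(n_samples=1, templates_per_sample=10, molecules_per_sample=1000)
        mols = attach_labels(make_repertoire(cfg, germlines), cfg)
        assert len(mols) == 1000
        assert count_umi_collisions(mols) <= 1

    def test_short_umi_rejected(self, germlines):
        with pytest.raises(ValueError):
            cfg = small_config()
            cfg.umi_length = 0
            attach_labels(make_repertoire(small_config(), germlines), cfg)

    def test_samples_never_carry_foreign_barcodes(self, germlines):
        cfg = small_config(n_samples=2)
        sheet = cfg.resolved_sheet()
        mols = attach_labels(make_repertoire(cfg, germlines), cfg)
        for m in mols:
            row = sheet.row(m.sample_id)
            assert m.barcode5 == row.barcode5 and m.barcode3 == row.barcode3


def _uniform_molecules(n, efficiency, seq_len=120, rng=None):
    rng = rng or np.random.default_rng(0)
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, seq_len))
    return [
        Molecule(seq, "S1", "b5", "b3", f"u5{i}", f"u3{i}", "T1", "T1", "S1", efficiency)
        for i in range(n)
    ]


class TestPcrAmplify:
    def test_pure_doubling(self):
        cfg = small_config(n_cycles=5, p_switch=0.0, e_pcr=0.0, pool_capacity=10**9)
        mols = _uniform_molecules(4, efficiency=1.0)
        pool = pcr_amplify(mols, cfg)
        assert sum(m.multiplicity for m in pool) == 4 * 2**5
        assert all(m.sequence == mols[0].sequence for m in pool)

    def test_branching_process_expectation(self):
        # supercritical branching process: E[Z_c] = n * (1 + eff)^c,
        # Var[Z_c] from the standard Galton-Watson variance formula
        eff, cycles, n0 = 0.9, 10, 50
        m = 1 + eff
        var1 = eff * (1 - eff)
        var_c = var1 * m ** (cycles - 1) * (m**cycles - 1) / (m - 1)
        finals = []
        for seed in range(5):
            cfg = small_config(n_cycles=cycles, p_switch=0.0, e_pcr=0.0, pool_capacity=10**9, seed=seed)
            pool = pcr_amplify(_uniform_molecules(n0, eff), cfg, np.random.default_rng(seed))
            finals.append(sum(mm.multiplicity for mm in pool))
        expected = n0 * m**cycles
        sd = np.sqrt(n0 * var_c)
        assert abs(np.mean(finals) - expected) < 3 * sd

    def test_pooled_samples_produce_mispaired_barcodes(self, germlines):
        cfg = small_config(n_samples=2, n_cycles=12, p_switch=0.05, molecules_per_sample=60)
        rng = np.random.default_rng(3)
        mols = attach_labels(make_repertoire(cfg, germlines, rng), cfg, rng)
        pool = pcr_amplify(mols, cfg, rng)
        assert any(m.is_inter_chimera for m in pool)

    def test_chimeras_are_late_biased(self, default_run):
        # chimeras arise preferentially in late cycles, so their final copy
        # number is below that of genuine molecules
        _, _, sim_stats = default_run
        assert sim_stats["mean_copies_chimeric"] < sim_stats["mean_copies_genuine"]

    def test_homology_dependence(self, germlines):
        # two template families at ~95% vs ~60% pairwise identity: the
        # similar pool forms chimeras at a higher rate at equal p_switch
        rng = np.random.default_rng(5)
        base = "".join("ACGT"[i] for i in rng.integers(0, 4, 300))
        fracs = {}
        for name, div in (("similar", 0.05), ("dissimilar", 0.40)):
            rates = []
            for seed in range(3):
                r = np.random.default_rng(100 + seed)
                mols = []
                for i in range(40):
                    seq = mutate_substitutions(base, int(round(300 * div)), r)
                    mols.append(
                        Molecule(seq, "S1", "b", "b", f"u{i}", f"v{i}", f"T{i}", f"T{i}", "S1", 0.9)
                    )
                cfg = small_config(n_cycles=8, p_switch=0.05, e_pcr=0.0, pool_capacity=10**6, seed=100 + seed)
                pool = pcr_amplify(mols, cfg, r)
                rates.append(chimera_read_fraction(pool))
            fracs[name] = np.mean(rates)
        assert fracs["similar"] > fracs["dissimilar"]


class TestSequenceReads:
    def test_error_free_reads_equal_molecules(self, germlines):
        cfg = small_config(e_seq=0.0, depth=50, randomize_orientation=False)
        mols = attach_labels(make_repertoire(cfg, germlines), cfg)
        reads, truth = sequence_reads(mols, cfg)
        from dumparts.simulate import assemble_amplicon

        sheet = cfg.resolved_sheet()
        by_umi = {(m.umi5, m.umi3): m for m in mols}
        for r, t in zip(reads, truth):
            assert r.sequence == assemble_amplicon(by_umi[(t.umi5, t.umi3)], sheet)

    def test_sequencing_error_rate_matches_binomial_expectation(self):
        cfg = small_config(e_seq=0.01, depth=2000, randomize_orientation=False)
        row = cfg.resolved_sheet().row("S1")
        mols = _uniform_molecules(5, efficiency=1.0, seq_len=350)
        mols = [
            dataclasses.replace(m, barcode5=row.barcode5, barcode3=row.barcode3) for m in mols
        ]
        # count n_errors from the truth table
        reads, truth = sequence_reads(mols, cfg)
        L = len(reads[0].sequence)
        mean_err = np.mean([t.n_errors for t in truth])
        expect = L * 0.01
        sd = np.sqrt(L * 0.01 * 0.99 / len(truth))
        assert abs(mean_err - expect) < 5 * sd

    def test_truth_rows_match_fastq_records(self, default_run):
        result, truth, _ = default_run
        assert len(truth) == result.report["demux"]["n_reads"]

    def test_full_determinism(self, germlines):
        from dumparts.simulate import simulate_library

        cfg = small_config(depth=500, n_cycles=6)
        r1 = simulate_library(cfg, germlines)
        r2 = simulate_library(small_config(depth=500, n_cycles=6), germlines)
        assert [x.sequence for x in r1[0]] == [x.sequence for x in r2[0]]
        assert r1[1] == r2[1]


class TestChimeraMonotonicity:
    def test_fraction_nondecreasing_in_p_switch(self, germlines):
        fracs = []
        for ps in (0.0, 0.01, 0.05):
            per_seed = []
            for seed in range(5):
                cfg = small_config(n_cycles=10, p_switch=ps, molecules_per_sample=40, seed=seed)
                rng = np.random.default_rng(seed)
                mols = attach_labels(make_repertoire(cfg, germlines, rng), cfg, rng)
                per_seed.append(chimera_read_fraction(pcr_amplify(mols, cfg, rng)))
            fracs.append(np.mean(per_seed))
        assert fracs[0] == 0.0
        assert fracs[0] <= fracs[1] <= fracs[2]
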