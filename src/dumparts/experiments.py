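"""Canned study-condition experiments used for validation and benchmarking.

Each function simulates a library under fixed conditions, runs the relevant
pipeline stages, and returns the summary quantities of interest. They are
the computational counterparts of the wet-lab validation experiments:
within-UMI-group read homogeneity, recovery of a known injected
inter-sample chimera fraction, the cycle-number dependence of chimera
formation, RPUP separation of genuine molecules from chimeras, consensus
accuracy, stepwise mutation reduction, replicate reproducibility, and
breakpoint-area validity on known amplicons.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from dumparts import stats as dstats
from dumparts.breakpoints import (
    ReferenceSet,
    call_breakpoints,
    breakpoint_frequency_profile,
    make_reference_set,
)
from dumparts.consensus import consensus_for_group
from dumparts.demux import ReadRecord, demux_reads
from dumparts.pipeline import PipelineResult, run_pipeline, simulate_and_run
from dumparts.sheet import edit_distance
from dumparts.simulate import (
    GermlineSet,
    SimConfig,
    _acceptor_site,
    _seq_to_arr,
    attach_labels,
    chimera_read_fraction,
    inject_inter_chimeras,
    make_repertoire,
    mutate_substitutions,
    pcr_amplify,
    redraw_efficiencies,
    sequence_reads,
    synthetic_germlines,
)
from dumparts.umi_filter import UmiGroup


def default_conditions(seed: int) -> SimConfig:
    """The standard 4-sample pooled library used for end-to-end validation.

    18,000 reads over 600 labelled molecules gives a genuine-molecule mean
    RPUP of 30; the pool capacity is sized so amplification saturates
    mid-run, the regime in which template switching concentrates.
    """
    return SimConfig(
        seed=seed,
        n_samples=4,
        templates_per_sample=30,
        molecules_per_sample=150,
        depth=18000,
        pool_capacity=60000,
    )


def _rand_seq(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


def _noisy_read(template: str, error: float, rng: np.random.Generator) -> str:
    return mutate_substitutions(template, int(rng.binomial(len(template), error)), rng)


def umi_group_homogeneity(
    seed: int,
    n_groups: int = 200,
    read_length: int = 350,
    reads_range: tuple[int, int] = (10, 50),
    error: float = 0.005,
) -> dict:
    """Max Levenshtein-distance / read-length ratio within single-template
    UMI groups (each read compared to the group's most abundant sequence)."""
    rng = np.random.default_rng(seed)
    max_ratio = 0.0
    n_reads = 0
    for _ in range(n_groups):
        template = _rand_seq(rng, read_length)
        reads = [
            _noisy_read(template, error, rng)
            for _ in range(int(rng.integers(reads_range[0], reads_range[1] + 1)))
        ]
        n_reads += len(reads)
        uniq: dict[str, int] = {}
        for r in reads:
            uniq[r] = uniq.get(r, 0) + 1
        top = min(uniq, key=lambda s: (-uniq[s], s))
        for r in reads:
            ratio = edit_distance(r, top) / len(r)
            max_ratio = max(max_ratio, ratio)
    return {"max_ratio": max_ratio, "n_reads": n_reads}


def inter_chimera_recovery(
    seed: int,
    fraction: float,
    n_seeds: int = 5,
    depth: int = 4000,
    germlines: GermlineSet | None = None,
) -> dict:
    """Inject a known inter-sample chimera fraction; pool the demux estimate
    and the truth read fraction over seeds."""
    germlines = germlines or synthetic_germlines()
    est_inter = est_total = 0
    truth_inter = truth_total = 0
    for k in range(n_seeds):
        cfg = SimConfig(
            seed=seed + 1000 * k,
            n_samples=4,
            templates_per_sample=20,
            molecules_per_sample=80,
            depth=depth,
        )
        rng = np.random.default_rng(cfg.seed)
        mols = attach_labels(make_repertoire(cfg, germlines, rng), cfg, rng)
        mols = inject_inter_chimeras(mols, fraction, cfg, rng)
        reads, truth = sequence_reads(mols, cfg, rng)
        _, report = demux_reads(reads, cfg.resolved_sheet())
        c = report["status_counts"]
        est_inter += c["inter_sample_chimera"]
        est_total += c["assigned"] + c["inter_sample_chimera"]
        truth_inter += sum(t.is_inter_chimera for t in truth)
        truth_total += len(truth)
    return {
        "target": fraction,
        "estimate": est_inter / est_total,
        "truth": truth_inter / truth_total,
        "n": est_total,
    }


def cycle_dependence(
    seed: int,
    cycles: Sequence[int] = (18, 24, 30),
    n_seeds: int = 5,
    germlines: GermlineSet | None = None,
) -> list[float]:
    """Mean chimeric copy fraction at several amplification cycle counts."""
    germlines = germlines or synthetic_germlines()
    out = []
    for c in cycles:
        fracs = []
        for k in range(n_seeds):
            cfg = SimConfig(
                seed=seed + k,
                n_samples=2,
                templates_per_sample=15,
                molecules_per_sample=80,
                n_cycles=c,
                pool_capacity=20000,
            )
            rng = np.random.default_rng(cfg.seed)
            mols = attach_labels(make_repertoire(cfg, germlines, rng), cfg, rng)
            fracs.append(chimera_read_fraction(pcr_amplify(mols, cfg, rng)))
        out.append(float(np.mean(fracs)))
    return out


def consensus_accuracy(
    seed: int,
    n_groups: int = 300,
    read_length: int = 350,
    support_range: tuple[int, int] = (10, 30),
    error: float = 0.005,
) -> dict:
    """Fraction of consensus sequences equal to their template, and the
    residual per-base error of the consensus set."""
    rng = np.random.default_rng(seed)
    exact = total = 0
    err_bases = tot_bases = 0
    for gi in range(n_groups):
        template = _rand_seq(rng, read_length)
        cdr3 = template[150:180]
        n = int(rng.integers(support_range[0], support_range[1] + 1))
        g = UmiGroup("S1", f"U{gi}", f"V{gi}")
        ann = {}
        for ri in range(n):
            read = _noisy_read(template, error, rng)
            rid = f"g{gi}_r{ri}"
            g.reads.append(
                ReadRecord(rid, read, b5_id="b", b3_id="b", umi5=g.umi5, umi3=g.umi3,
                           sample_id="S1", status="assigned", insert=read)
            )
            ann[rid] = read[150:180]  # annotator-style CDR3 call, errors included
        # the dominant CDR3 subgroup is the one matching the template call
        recs = consensus_for_group(g, ann)
        recs = [r for r in recs if r.cdr3_nt == cdr3]
        if not recs:
            continue
        total += 1
        cons = recs[0].sequence
        if cons == template:
            exact += 1
        err_bases += sum(a != b for a, b in zip(cons, template))
        tot_bases += len(template)
    return {
        "exact_fraction": exact / total,
        "residual_error_rate": err_bases / tot_bases,
        "n_consensus": total,
    }


def shm_stepwise(result: PipelineResult, truth) -> dict:
    """Mean mutation counts of all reads / non-chimeric reads / consensus."""
    tmap = {t.read_id: t for t in truth}

    def mean_mut(rows):
        vals = [len(r.mutations) for r in rows if r.shm_valid and r.v_call]
        return float(np.mean(vals))

    all_rows = list(result.annotations.values())
    nonchim = [
        r
        for rid, r in result.annotations.items()
        if rid in tmap and not (tmap[rid].is_intra_chimera or tmap[rid].is_inter_chimera)
    ]
    return {
        "all_reads": mean_mut(all_rows),
        "non_chimeric": mean_mut(nonchim),
        "consensus": mean_mut(result.consensus_annotations),
        "n": len(all_rows),
    }


def replicate_reproducibility(
    seed: int,
    n_replicates: int = 3,
    k: int = 10,
    germlines: GermlineSet | None = None,
) -> dict:
    """Top-k clone JSD / Morisita-Horn across replicates, before vs after
    correction.

    One repertoire of templates is amplified and sequenced ``n_replicates``
    times with per-reaction efficiency redraws (amplification bias is a
    property of the reaction). "Before" clone tables come from raw assigned
    reads; "after" from consensus sequences.
    """
    germlines = germlines or synthetic_germlines()
    cfg = SimConfig(
        seed=seed,
        n_samples=2,
        templates_per_sample=40,
        molecules_per_sample=400,
        depth=12000,
        pool_capacity=40000,
    )
    templates = make_repertoire(cfg, germlines)
    sheet = cfg.resolved_sheet()
    before, after = [], []
    for rep in range(n_replicates):
        rng = np.random.default_rng(seed + 7919 * (rep + 1))
        tpl = redraw_efficiencies(templates, cfg, rng)
        mols = attach_labels(tpl, cfg, rng)
        pool = pcr_amplify(mols, cfg, rng)
        reads, _ = sequence_reads(pool, cfg, rng)
        result = run_pipeline(reads, sheet, germlines)
        sample = sheet.sample_ids()[0]
        raw_rows = [
            result.annotations[r.read_id]
            for r in result.assigned
            if r.sample_id == sample and r.read_id in result.annotations
        ]
        cons_rows = [
            row
            for c, row in zip(result.consensus, result.consensus_annotations)
            if c.sample_id == sample
        ]
        before.append(dstats.define_clones(raw_rows))
        after.append(dstats.define_clones(cons_rows))

    def pairwise(tables, fn):
        vals = [
            fn(tables[i], tables[j])
            for i in range(len(tables))
            for j in range(i + 1, len(tables))
        ]
        return float(np.mean(vals))

    return {
        "jsd_before": pairwise(before, lambda a, b: dstats.jsd_top_clones(a, b, k)),
        "jsd_after": pairwise(after, lambda a, b: dstats.jsd_top_clones(a, b, k)),
        "mh_before": pairwise(before, lambda a, b: dstats.morisita_horn_clones(a, b, k)),
        "mh_after": pairwise(after, lambda a, b: dstats.morisita_horn_clones(a, b, k)),
        "n_replicates": n_replicates,
    }


def simulate_reference_chimeras(
    refs: ReferenceSet,
    n_chimeras: int,
    seed: int,
    homology_k: int = 10,
    h_min: float = 0.8,
) -> tuple[list[tuple[str, str]], dict[str, int]]:
    """Error-free first-order chimeras between known reference amplicons.

    Donor truncation is uniform; the acceptor site uses the same
    homology-weighted model as the PCR simulator. Returns (reads, truth)
    where truth maps read_id -> true switch position (read coordinates).
    """
    rng = np.random.default_rng(seed)
    arrs = {r.reference_id: _seq_to_arr(r.sequence) for r in refs.references}
    reads, truth = [], {}
    made = attempts = 0
    while made < n_chimeras and attempts < n_chimeras * 50:
        attempts += 1
        i, j = rng.choice(len(refs.references), 2, replace=False)
        a, b = refs.references[int(i)], refs.references[int(j)]
        t = int(rng.integers(homology_k, len(a.sequence) - 1))
        site = _acceptor_site(arrs[a.reference_id][t - homology_k : t], arrs[b.reference_id], h_min, rng)
        if site is None:
            continue
        rid = f"chim_{made}"
        reads.append((rid, a.sequence[:t] + b.sequence[site:]))
        truth[rid] = t
        made += 1
    return reads, truth


def breakpoint_validation(seed: int, n_references: int = 20, n_chimeras: int = 200) -> dict:
    """Containment of true switch positions and the regional profile on
    error-free chimeras of known reference amplicons."""
    refs = make_reference_set(n_references, seed=seed)
    reads, truth = simulate_reference_chimeras(refs, n_chimeras, seed)
    calls, report = call_breakpoints(reads, refs)
    contained = sum(c.contains(truth[c.read_id]) for c in calls)
    freq, regions = breakpoint_frequency_profile(calls, refs)
    return {
        "n_calls": len(calls),
        "containment_fraction": contained / len(calls) if calls else float("nan"),
        "frequency_sum": float(freq.sum()),
        "region_total_sum": float(sum(r["total"] for r in regions.values())),
        "regions": regions,
        "report": report,
        "calls": calls,
        "refs": refs,
        "frequencies": freq,
    }


def fold_change_summary(result: PipelineResult) -> dict:
    raw = [
        (r.insert, (r.sample_id, r.umi5, r.umi3))
        for r in result.assigned
        if r.insert
    ]
    df, lost = dstats.unique_seq_fold_change(raw, result.consensus)
    kept = df[df["umi_pairs_after"] > 0]
    return {
        "n_unique_before": len(df) + len(lost),
        "n_unique_after": len({c.sequence for c in result.consensus}),
        "median_fold": float(kept["fold"].median()) if len(kept) else float("nan"),
        "min_fold": float(kept["fold"].min()) if len(kept) else float("nan"),
        "table": df,
        "lost": lost,
    }


def run_default_study(seed: int, germlines: GermlineSet | None = None):
    """Default-conditions end-to-end run with truth evaluation."""
    germlines = germlines or synthetic_germlines()
    return simulate_and_run(default_conditions(seed), germlines)
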