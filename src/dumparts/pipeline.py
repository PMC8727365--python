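"""End-to-end pipeline: demux -> RPUP filter -> annotation -> consensus -> stats.

The stages mirror the library's processing order: inter-sample chimeras are
removed with barcode pairs during sample splitting, intra-sample chimeras
with the first low ebb of the RPUP distribution, then CDR3-subclustered
consensus building corrects base errors and amplification bias. The run
report carries per-stage counts sufficient to reproduce the headline
proportions (inter-sample chimera fraction, ebb threshold, removed-read
fraction, consensus count) and, in truth-aware mode, confusion matrices
against the simulator's ground truth.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from dumparts.annotate import AnnotationRow, naive_vdj_assign, trim_primer_regions
from dumparts.consensus import ConsensusRecord, build_all_consensus
from dumparts.demux import ReadRecord, demux_reads
from dumparts.sheet import SampleSheet
from dumparts.simulate import FastqRead, GermlineSet, TruthRecord, simulate_library, SimConfig
from dumparts.umi_filter import (
    RpupHistogram,
    UmiGroup,
    filter_intra_chimeras,
    find_first_low_ebb,
    group_by_umi_pair,
)


@dataclass
class PipelineResult:
    records: list[ReadRecord]
    kept_groups: list[UmiGroup]
    removed_groups: list[UmiGroup]
    histogram: RpupHistogram
    annotations: dict[str, AnnotationRow]
    consensus: list[ConsensusRecord]
    consensus_annotations: list[AnnotationRow]
    report: dict

    @property
    def assigned(self) -> list[ReadRecord]:
        return [r for r in self.records if r.status == "assigned"]


def annotate_reads(
    records: Sequence[ReadRecord],
    germlines: GermlineSet,
    trim_lead: int = 25,
    trim_tail: int = 8,
) -> dict[str, AnnotationRow]:
    """Naive V/J annotation (primer-trimmed) for every assigned read."""
    out: dict[str, AnnotationRow] = {}
    for r in records:
        if r.status != "assigned" or not r.insert:
            continue
        row = naive_vdj_assign(r.insert, r.read_id, germlines)
        out[r.read_id] = trim_primer_regions(row, trim_lead, trim_tail)
    return out


def run_pipeline(
    reads: Sequence[FastqRead],
    sheet: SampleSheet,
    germlines: GermlineSet,
    truth: Sequence[TruthRecord] | None = None,
    ebb_override: int | None = None,
    smooth_window: int = 1,
    min_fraction: float = 0.30,
    min_reads: int = 2,
    trim_lead: int = 25,
    trim_tail: int = 8,
) -> PipelineResult:
    """Run demux, RPUP filtering, annotation, and consensus building."""
    records, demux_report = demux_reads(reads, sheet)
    assigned = [r for r in records if r.status == "assigned"]
    groups = group_by_umi_pair(assigned)
    hist = RpupHistogram.from_groups(groups)
    threshold = ebb_override if ebb_override is not None else find_first_low_ebb(hist, smooth_window)
    hist.threshold = threshold
    kept, removed, filter_report = filter_intra_chimeras(groups, threshold)

    annotations = annotate_reads(records, germlines, trim_lead, trim_tail)
    cdr3_by_read = {rid: row.cdr3_nt for rid, row in annotations.items()}
    consensus, cons_report = build_all_consensus(kept, cdr3_by_read, min_fraction, min_reads)
    consensus_annotations = [
        trim_primer_regions(
            naive_vdj_assign(c.sequence, f"{c.sample_id}|{c.umi5}|{c.umi3}", germlines),
            trim_lead,
            trim_tail,
        )
        for c in consensus
    ]

    report = {
        "demux": demux_report,
        "rpup": filter_report,
        "consensus": cons_report,
        "histogram": {int(k): int(v) for k, v in sorted(hist.counts.items())},
    }
    # conservation checks, asserted on every run
    counts = demux_report["status_counts"]
    assert sum(counts.values()) == demux_report["n_reads"]
    assert len(kept) + len(removed) == len(groups)
    assert sum(c.support for c in consensus) <= sum(g.rpup for g in kept)
    if truth is not None:
        report["truth"] = _truth_evaluation(records, kept, removed, truth)
    return PipelineResult(
        records, kept, removed, hist, annotations, consensus, consensus_annotations, report
    )


def _truth_evaluation(
    records: Sequence[ReadRecord],
    kept: Sequence[UmiGroup],
    removed: Sequence[UmiGroup],
    truth: Sequence[TruthRecord],
) -> dict:
    """Confusion matrices for inter- and intra-sample chimera detection."""
    tmap = {t.read_id: t for t in truth}
    inter = {"tp": 0, "fp": 0, "fn": 0, "tn": 0}
    for r in records:
        t = tmap.get(r.read_id)
        if t is None or r.status in ("merge_failed", "unmatched_adapter"):
            continue
        called = r.status == "inter_sample_chimera"
        if t.is_inter_chimera:
            inter["tp" if called else "fn"] += 1
        else:
            inter["fp" if called else "tn"] += 1

    def group_class(g: UmiGroup) -> str:
        """genuine / chimeric / umi_artifact (sequencing error inside a UMI).

        A group is only a molecule's group if its observed key matches the
        reads' true UMI pair; corrupted-UMI singletons are artifacts of
        sequencing error, not genuine molecules, and are scored separately.
        """
        truths = [tmap[r.read_id] for r in g.reads if r.read_id in tmap]
        if not truths:
            return "umi_artifact"
        key_ok = np.mean([(t.umi5, t.umi3) == (g.umi5, g.umi3) for t in truths]) > 0.5
        if not key_ok:
            return "umi_artifact"
        chim = np.mean([t.is_intra_chimera or t.is_inter_chimera for t in truths]) > 0.5
        return "chimeric" if chim else "genuine"

    tallies = {"kept": {"genuine": 0, "chimeric": 0, "umi_artifact": 0},
               "removed": {"genuine": 0, "chimeric": 0, "umi_artifact": 0}}
    for g in removed:
        tallies["removed"][group_class(g)] += 1
    for g in kept:
        tallies["kept"][group_class(g)] += 1
    n_genuine = tallies["kept"]["genuine"] + tallies["removed"]["genuine"]
    n_chim = tallies["kept"]["chimeric"] + tallies["removed"]["chimeric"]

    def rates(c):
        prec = c["tp"] / (c["tp"] + c["fp"]) if c["tp"] + c["fp"] else float("nan")
        rec = c["tp"] / (c["tp"] + c["fn"]) if c["tp"] + c["fn"] else float("nan")
        return {"counts": c, "precision": prec, "recall": rec}

    return {
        "inter_sample": rates(inter),
        "intra_sample_groups": {
            "tallies": tallies,
            "genuine_retention": tallies["kept"]["genuine"] / n_genuine if n_genuine else float("nan"),
            "chimeric_removal": tallies["removed"]["chimeric"] / n_chim if n_chim else float("nan"),
        },
    }


def simulate_and_run(
    config: SimConfig,
    germlines: GermlineSet | None = None,
    **pipeline_kwargs,
) -> tuple[PipelineResult, list[TruthRecord], dict]:
    """Simulate a library under ``config`` and run the full pipeline on it."""
    from dumparts.simulate import synthetic_germlines

    if germlines is None:
        germlines = synthetic_germlines()
    reads, truth, _templates, sim_stats = simulate_library(config, germlines)
    result = run_pipeline(reads, config.resolved_sheet(), germlines, truth=truth, **pipeline_kwargs)
    return result, truth, sim_stats


def write_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True, default=float) + "\n")
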