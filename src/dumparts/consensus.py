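"""Consensus building within retained UMI-pair groups.

Rarely, two distinct molecules draw the same UMI pair; within each UMI
group, reads are therefore sub-clustered by exact CDR3 nucleotide sequence
first. A subgroup survives only if it holds at least 30% of the group's
reads and at least 2 reads; its reads are then restricted to the length of
the most abundant unique sequence, and a position-wise plurality consensus
is taken. A tie at any position discards the whole consensus (an ambiguous
base would propagate an invented nucleotide into the repertoire).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from dumparts.demux import ReadRecord
from dumparts.umi_filter import UmiGroup


@dataclass
class Cdr3Subgroup:
    parent_key: tuple[str, str, str]
    cdr3_nt: str
    reads: list[ReadRecord]
    fraction: float  # of the parent group's total assigned reads


@dataclass(frozen=True)
class ConsensusRecord:
    sample_id: str
    umi5: str
    umi3: str
    cdr3_nt: str
    sequence: str
    support: int

    @property
    def key(self) -> tuple[str, str, str, str]:
        return (self.sample_id, self.umi5, self.umi3, self.cdr3_nt)

    @property
    def length(self) -> int:
        return len(self.sequence)


def subcluster_by_cdr3(
    group: UmiGroup, annotations: Mapping[str, str | None]
) -> tuple[list[Cdr3Subgroup], int]:
    """Partition a UMI group's reads by exact CDR3; returns (subgroups, n_dropped).

    ``annotations`` maps read_id -> CDR3 nt (None/missing = no call). Reads
    without a CDR3 call are excluded from every subgroup but still count in
    the denominator of the subgroup fractions (the fraction is of all reads
    in the UMI pair).
    """
    buckets: dict[str, list[ReadRecord]] = {}
    dropped = 0
    for r in group.reads:
        cdr3 = annotations.get(r.read_id)
        if not cdr3:
            dropped += 1
            continue
        buckets.setdefault(cdr3, []).append(r)
    total = group.rpup
    return (
        [
            Cdr3Subgroup(group.key, cdr3, reads, len(reads) / total)
            for cdr3, reads in sorted(buckets.items())
        ],
        dropped,
    )


def filter_subgroups(
    subgroups: Sequence[Cdr3Subgroup], min_fraction: float = 0.30, min_reads: int = 2
) -> list[Cdr3Subgroup]:
    """Keep subgroups with fraction >= 30% (inclusive) and >= 2 reads."""
    return [s for s in subgroups if s.fraction >= min_fraction and len(s.reads) >= min_reads]


def length_filter(subgroup: Cdr3Subgroup) -> list[ReadRecord]:
    """Keep only reads matching the modal unique sequence's length.

    The most abundant unique sequence defines the target length; ties
    between unique sequences break lexicographically (deterministic).
    """
    seqs = [r.insert for r in subgroup.reads]
    counts = Counter(seqs)
    best = min(counts, key=lambda s: (-counts[s], s))
    target = len(best)
    return [r for r in subgroup.reads if len(r.insert) == target]


def build_consensus(sequences: Sequence[str]) -> str | None:
    """Position-wise plurality consensus of equal-length sequences.

    Returns None (discarded) if any position's plurality is tied. Requires
    at least 2 sequences, all of one length.
    """
    if len(sequences) < 2:
        raise ValueError("consensus requires at least 2 reads")
    if len({len(s) for s in sequences}) != 1:
        raise ValueError("consensus requires equal-length sequences")
    mat = np.frombuffer("".join(sequences).encode(), dtype=np.uint8).reshape(
        len(sequences), len(sequences[0])
    )
    out = bytearray(mat.shape[1])
    for j in range(mat.shape[1]):
        vals, counts = np.unique(mat[:, j], return_counts=True)
        top = counts.max()
        if (counts == top).sum() > 1:
            return None
        out[j] = int(vals[counts.argmax()])
    return out.decode()


def consensus_for_group(
    group: UmiGroup,
    annotations: Mapping[str, str | None],
    min_fraction: float = 0.30,
    min_reads: int = 2,
    report: dict | None = None,
) -> list[ConsensusRecord]:
    """Full per-group pipeline: subcluster, filter, length-filter, consensus."""
    if report is None:
        report = {}
    report.setdefault("reads_without_cdr3", 0)
    report.setdefault("discarded_ambiguous", 0)
    subs, dropped = subcluster_by_cdr3(group, annotations)
    report["reads_without_cdr3"] += dropped
    out: list[ConsensusRecord] = []
    for sub in filter_subgroups(subs, min_fraction, min_reads):
        reads = length_filter(sub)
        if len(reads) < 2:
            continue
        cons = build_consensus([r.insert for r in reads])
        if cons is None:
            report["discarded_ambiguous"] += 1
            continue
        out.append(
            ConsensusRecord(
                sample_id=group.sample_id,
                umi5=group.umi5,
                umi3=group.umi3,
                cdr3_nt=sub.cdr3_nt,
                sequence=cons,
                support=len(reads),
            )
        )
    return out


def build_all_consensus(
    groups: Sequence[UmiGroup],
    annotations: Mapping[str, str | None],
    min_fraction: float = 0.30,
    min_reads: int = 2,
) -> tuple[list[ConsensusRecord], dict]:
    report: dict = {}
    records: list[ConsensusRecord] = []
    for g in groups:
        records.extend(consensus_for_group(g, annotations, min_fraction, min_reads, report))
    report["n_consensus"] = len(records)
    return records, report
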