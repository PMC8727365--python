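"""Intra-sample chimera removal via the reads-per-UMI-pair (RPUP) distribution.

Genuine molecules are labelled before amplification and accumulate copies
through every cycle; chimeras arise predominantly in late cycles with a
fresh (donor-UMI5, acceptor-UMI3) pair and therefore few descendant reads.
The RPUP count histogram is consequently bimodal: a low-copy chimera mode
and a high-copy genuine mode. The *first low ebb* — the first local minimum
of the histogram — is used as the cutoff: UMI groups with RPUP strictly
below it are discarded as intra-sample chimeras.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from dumparts.demux import ReadRecord


@dataclass
class UmiGroup:
    sample_id: str
    umi5: str
    umi3: str
    reads: list[ReadRecord] = field(default_factory=list)

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.sample_id, self.umi5, self.umi3)

    @property
    def rpup(self) -> int:
        return len(self.reads)


@dataclass
class RpupHistogram:
    """Counts of UMI groups per RPUP value, plus the chosen threshold."""

    counts: dict[int, int]
    threshold: int | None = None

    def __post_init__(self):
        if any(r < 1 or c < 0 for r, c in self.counts.items()):
            raise ValueError("RPUP values must be >= 1 and counts >= 0")

    @classmethod
    def from_groups(cls, groups: Iterable[UmiGroup]) -> "RpupHistogram":
        counts: dict[int, int] = defaultdict(int)
        for g in groups:
            counts[g.rpup] += 1
        return cls(dict(counts))

    def dense(self) -> np.ndarray:
        """counts as an array indexed by r = 1..r_max (index 0 unused)."""
        r_max = max(self.counts)
        arr = np.zeros(r_max + 1, dtype=float)
        for r, c in self.counts.items():
            arr[r] = c
        return arr


def group_by_umi_pair(records: Sequence[ReadRecord]) -> list[UmiGroup]:
    """Exact-match grouping of assigned reads on (sample, UMI5, UMI3)."""
    groups: dict[tuple[str, str, str], UmiGroup] = {}
    for rec in records:
        if rec.status != "assigned":
            raise ValueError(f"read {rec.read_id} has status {rec.status!r}, expected assigned")
        key = (rec.sample_id, rec.umi5, rec.umi3)
        if key not in groups:
            groups[key] = UmiGroup(*key)
        groups[key].reads.append(rec)
    return list(groups.values())


def find_first_low_ebb(hist: RpupHistogram, smooth_window: int = 1) -> int:
    """First local minimum of the RPUP histogram; fallback 2 if none.

    After optional moving-average smoothing, the threshold is the smallest
    r in [2, r_max - 1] with counts[r] <= both neighbours and strictly
    below at least one; a plateau collapses to its smallest r provided the
    next differing value rebounds upward. A monotone non-increasing
    histogram (no rebound) yields the singleton-removal fallback of 2.
    """
    if not hist.counts:
        raise ValueError("empty RPUP histogram")
    arr = hist.dense()
    if smooth_window > 1:
        kernel = np.ones(smooth_window) / smooth_window
        body = np.convolve(arr[1:], kernel, mode="same")
        arr = np.concatenate([[0.0], body])
    r_max = len(arr) - 1
    r = 2
    while r <= r_max - 1:
        if arr[r] > arr[r - 1]:
            r += 1
            continue
        # plateau [r, j] of equal (smoothed) counts
        j = r
        while j + 1 <= r_max and arr[j + 1] == arr[r]:
            j += 1
        if j + 1 <= r_max and arr[j + 1] > arr[r] and (arr[r] < arr[r - 1] or arr[j + 1] > arr[r]):
            hist.threshold = r
            return r
        r = j + 1
    hist.threshold = 2
    return 2


def filter_intra_chimeras(
    groups: Sequence[UmiGroup], threshold: int
) -> tuple[list[UmiGroup], list[UmiGroup], dict]:
    """Partition groups into kept (rpup >= threshold) and removed.

    Groups at exactly the threshold are kept ("less than the threshold"
    defines a chimera). Returns (kept, removed, report) where the report
    carries the removed-read fraction.
    """
    if threshold < 2:
        raise ValueError("threshold must be >= 2")
    kept = [g for g in groups if g.rpup >= threshold]
    removed = [g for g in groups if g.rpup < threshold]
    n_reads = sum(g.rpup for g in groups)
    n_removed = sum(g.rpup for g in removed)
    report = {
        "threshold": threshold,
        "n_groups": len(groups),
        "n_kept_groups": len(kept),
        "n_removed_groups": len(removed),
        "removed_read_fraction": n_removed / n_reads if n_reads else 0.0,
    }
    return kept, removed, report
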