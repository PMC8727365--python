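"""Demultiplexing: read merging, fuzzy barcode/primer location, UMI extraction.

Inter-sample chimeras are called here: a read whose two ends carry barcodes
of different samples is a bona fide chimera formed in the pooled library and
is removed before any UMI-level processing. Barcodes and primers are matched
with a Levenshtein-distance threshold of 1 (the distance-3 spacing enforced
by the sample sheet makes that unambiguous); reads whose adapters exceed the
threshold are discarded as unmatched.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import edlib

from dumparts.sheet import SampleSheet
from dumparts.simulate import FastqRead, revcomp

STATUSES = ("assigned", "inter_sample_chimera", "unmatched_adapter", "merge_failed")


@dataclass
class ReadRecord:
    read_id: str
    merged_sequence: str | None
    b5_id: str | None = None  # matched barcode5 sequence (sheet identity)
    b3_id: str | None = None
    umi5: str | None = None
    umi3: str | None = None
    sample_id: str | None = None
    status: str = "unmatched_adapter"
    insert: str | None = None  # variable region between the two primers

    def __post_init__(self):
        if self.status not in STATUSES:
            raise ValueError(f"unknown status {self.status!r}")


def merge_read_pairs(r1: str, r2: str, min_overlap: int = 20, max_mismatch_frac: float = 0.1) -> str | None:
    """Merge a read pair by overlap; return the merged sequence or None.

    Mate 2 is reverse-complemented and slid along mate 1; the offset with
    the most matching overlap bases wins, provided the overlap spans at
    least ``min_overlap`` bases with a mismatch fraction <= 0.1.
    Disagreeing overlap bases resolve toward mate 1 (qualities in this
    pipeline are placeholders).
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    r2rc = revcomp(r2)
    best = None  # (matches, overlap_len, offset)
    for off in range(0, len(r1) - min_overlap + 1):
        ov = min(len(r1) - off, len(r2rc))
        if ov < min_overlap:
            break
        a = r1[off : off + ov]
        b = r2rc[:ov]
        matches = sum(x == y for x, y in zip(a, b))
        if (ov - matches) / ov > max_mismatch_frac:
            continue
        cand = (matches, ov, -off)
        if best is None or cand > best:
            best = cand
    if best is None:
        return None
    off = -best[2]
    return r1 + r2rc[len(r1) - off :]


@dataclass(frozen=True)
class _EndMatch:
    barcode: str
    umi: str
    barcode_dist: int
    primer_dist: int
    end_offset: int  # offset past the primer, from the anchored terminus

    @property
    def total_dist(self) -> int:
        return self.barcode_dist + self.primer_dist


def _locate_end(
    seq: str,
    barcodes: Sequence[str],
    primer_for: dict[str, str],
    umi_len_for: dict[str, int],
    edit_max: int = 1,
    pos_slack: int = 2,
    umi_slack: int = 1,
) -> _EndMatch | None:
    """Locate (barcode, UMI, primer) anchored at the start of ``seq``.

    The 3' end is handled by calling this on reversed strings. Returns the
    unique best-scoring match, or None if no barcode/primer is within the
    edit threshold or the best score is tied between two barcodes.
    """
    candidates: list[_EndMatch] = []
    for bc in barcodes:
        win = seq[: len(bc) + edit_max + pos_slack]
        res = edlib.align(bc, win, mode="HW", task="locations")
        if res["editDistance"] < 0 or res["editDistance"] > edit_max:
            continue
        loc = next(((s, e) for s, e in res["locations"] if (s or 0) <= pos_slack), None)
        if loc is None:
            continue
        b_end = loc[1] + 1
        primer = primer_for[bc]
        umi_len = umi_len_for[bc]
        pwin_stop = b_end + umi_len + umi_slack + len(primer) + edit_max
        pwin = seq[b_end:pwin_stop]
        pres = edlib.align(primer, pwin, mode="HW", task="locations")
        if pres["editDistance"] < 0 or pres["editDistance"] > edit_max:
            continue
        ploc = next(
            ((s, e) for s, e in pres["locations"] if abs((s or 0) - umi_len) <= umi_slack), None
        )
        if ploc is None:
            continue
        umi = seq[b_end : b_end + ploc[0]]
        candidates.append(
            _EndMatch(
                barcode=bc,
                umi=umi,
                barcode_dist=res["editDistance"],
                primer_dist=pres["editDistance"],
                end_offset=b_end + ploc[1] + 1,
            )
        )
    if not candidates:
        return None
    candidates.sort(key=lambda c: c.total_dist)
    if len(candidates) > 1 and candidates[0].total_dist == candidates[1].total_dist:
        return None  # ambiguous: two barcodes tie — discard conservatively
    return candidates[0]


def locate_adapters(
    seq: str,
    sheet: SampleSheet,
    edit_max: int = 1,
    pos_slack: int = 2,
    umi_slack: int = 1,
) -> tuple[str | None, str | None, str | None, str | None, str | None]:
    """Locate both adapter blocks, trying both read orientations.

    Returns ``(b5, umi5, b3, umi3, insert)`` where the barcode fields are
    the matched sheet barcode sequences (None for an unmatched end) and
    ``insert`` is the variable region between the two primers in the
    orientation that matched best (None unless both ends matched).
    """
    b5_codes = sorted(sheet.barcodes5())
    b3_codes = sorted(sheet.barcodes3())
    p5_for = {r.barcode5: r.primer5 for r in sheet.rows}
    p3_for = {r.barcode3: r.primer3 for r in sheet.rows}
    u5_for = {r.barcode5: r.umi5_len for r in sheet.rows}
    u3_for = {r.barcode3: r.umi3_len for r in sheet.rows}
    p3_for_rev = {bc[::-1]: p3_for[bc][::-1] for bc in b3_codes}
    u3_for_rev = {bc[::-1]: u3_for[bc] for bc in b3_codes}
    b3_rev_codes = [bc[::-1] for bc in b3_codes]

    def score(oriented: str):
        m5 = _locate_end(oriented, b5_codes, p5_for, u5_for, edit_max, pos_slack, umi_slack)
        m3 = _locate_end(
            oriented[::-1], b3_rev_codes, p3_for_rev, u3_for_rev, edit_max, pos_slack, umi_slack
        )
        n_matched = (m5 is not None) + (m3 is not None)
        dist = (m5.total_dist if m5 else 0) + (m3.total_dist if m3 else 0)
        return (-n_matched, dist), m5, m3

    key_f, m5, m3 = score(seq)
    oriented = seq
    key_r, m5r, m3r = score(revcomp(seq))
    if key_r < key_f:
        m5, m3, oriented = m5r, m3r, revcomp(seq)
    b5 = m5.barcode if m5 else None
    umi5 = m5.umi if m5 else None
    b3 = m3.barcode[::-1] if m3 else None
    umi3 = m3.umi[::-1] if m3 else None
    insert = None
    if m5 and m3:
        lo, hi = m5.end_offset, len(oriented) - m3.end_offset
        if lo < hi:
            insert = oriented[lo:hi]
    return b5, umi5, b3, umi3, insert


def assign_sample(rec: ReadRecord, sheet: SampleSheet) -> ReadRecord:
    """Classify a located read: assigned / inter_sample_chimera / unmatched."""
    if rec.status == "merge_failed":
        return rec
    if rec.b5_id is None or rec.b3_id is None:
        rec.status = "unmatched_adapter"
        rec.sample_id = None
        return rec
    sample = sheet.sample_for_pair(rec.b5_id, rec.b3_id)
    if sample is None:
        rec.status = "inter_sample_chimera"
        rec.sample_id = None
    else:
        if rec.umi5 is None or rec.umi3 is None:  # pragma: no cover - guarded upstream
            rec.status = "unmatched_adapter"
        else:
            rec.status = "assigned"
            rec.sample_id = sample
    return rec


def demux_reads(
    reads: Iterable[FastqRead | tuple[str, str]],
    sheet: SampleSheet,
    edit_max: int = 1,
) -> tuple[list[ReadRecord], dict]:
    """Demultiplex merged reads; returns records plus a status-count report."""
    records: list[ReadRecord] = []
    counts = {s: 0 for s in STATUSES}
    for r in reads:
        rid, seq = (r.read_id, r.sequence) if isinstance(r, FastqRead) else (r[0], r[1])
        if seq is None:
            rec = ReadRecord(read_id=rid, merged_sequence=None, status="merge_failed")
        else:
            b5, umi5, b3, umi3, insert = locate_adapters(seq, sheet, edit_max)
            rec = ReadRecord(
                read_id=rid,
                merged_sequence=seq,
                b5_id=b5,
                b3_id=b3,
                umi5=umi5,
                umi3=umi3,
                insert=insert,
            )
            assign_sample(rec, sheet)
        counts[rec.status] += 1
        records.append(rec)
    n_bc = counts["assigned"] + counts["inter_sample_chimera"]
    report = {
        "n_reads": len(records),
        "status_counts": counts,
        "inter_sample_chimera_fraction": counts["inter_sample_chimera"] / n_bc if n_bc else 0.0,
    }
    return records, report
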