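"""VDJ annotation: AIRR/IgBLAST-style TSV ingestion, BTOP parsing, a naive
edit-distance V/J assigner for synthetic data, and primer-region trimming.

The external aligner (IgBLAST) is treated as an adapter: its tabular output
is parsed and validated, and mutation-level detail is recovered from the
BTOP (BLAST trace-back operations) string. For simulated fixtures the
built-in :func:`naive_vdj_assign` provides equivalent rows from free-end
edit-distance alignments against the synthetic germline set.

BTOP grammar: an alternation of match-run lengths and two-character
operation codes; a code is (query base, subject base) for a substitution,
(base, '-') for an insertion in the query, and ('-', base) for a deletion.
Here the query is the read and the subject the germline.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import edlib
import pandas as pd

from dumparts.simulate import GermlineSet


class BtopEvent(NamedTuple):
    op: str  # "match" | "sub" | "ins" | "del"
    length: int  # match-run length; 1 for the others
    q: str | None = None  # read base (None for match runs / deletions)
    s: str | None = None  # germline base (None for match runs / insertions)


class Mutation(NamedTuple):
    read_pos: int  # 0-based position on the aligned read segment
    germ_pos: int  # 0-based position on the germline
    germ_base: str
    read_base: str


_BTOP_TOKEN = re.compile(r"(\d+)|([A-Za-z-]{2})")


def parse_btop(btop: str) -> list[BtopEvent]:
    """Parse a BTOP string into an ordered event list.

    Raises ``ValueError`` with the byte offset of the first malformed token.
    """
    events: list[BtopEvent] = []
    pos = 0
    for m in _BTOP_TOKEN.finditer(btop):
        if m.start() != pos:
            raise ValueError(f"malformed BTOP at offset {pos}: {btop[pos:pos+4]!r}")
        num, pair = m.groups()
        if num is not None:
            events.append(BtopEvent("match", int(num)))
        else:
            q, s = pair[0].upper(), pair[1].upper()
            if q == "-" and s == "-":
                raise ValueError(f"malformed BTOP at offset {m.start()}: double gap")
            if q == "-":
                events.append(BtopEvent("del", 1, None, s))
            elif s == "-":
                events.append(BtopEvent("ins", 1, q, None))
            else:
                events.append(BtopEvent("sub", 1, q, s))
        pos = m.end()
    if pos != len(btop):
        raise ValueError(f"malformed BTOP at offset {pos}: {btop[pos:pos+4]!r}")
    return events


def serialize_btop(events: Iterable[BtopEvent]) -> str:
    out: list[str] = []
    for e in events:
        if e.op == "match":
            out.append(str(e.length))
        elif e.op == "sub":
            out.append(e.q + e.s)
        elif e.op == "ins":
            out.append(e.q + "-")
        elif e.op == "del":
            out.append("-" + e.s)
        else:  # pragma: no cover
            raise ValueError(f"unknown event {e.op!r}")
    return "".join(out)


def btop_counts(events: Sequence[BtopEvent]) -> tuple[int, int, int]:
    """(aligned_columns, mismatches, gap_columns) implied by the events."""
    cols = sum(e.length for e in events)
    mism = sum(1 for e in events if e.op == "sub")
    gaps = sum(1 for e in events if e.op in ("ins", "del"))
    return cols, mism, gaps


def btop_mutations(events: Sequence[BtopEvent], germ_start: int = 0, read_start: int = 0) -> list[Mutation]:
    """Substitution events with read and germline coordinates (gaps skipped)."""
    muts: list[Mutation] = []
    rp, gp = read_start, germ_start
    for e in events:
        if e.op == "match":
            rp += e.length
            gp += e.length
        elif e.op == "sub":
            muts.append(Mutation(rp, gp, e.s, e.q))
            rp += 1
            gp += 1
        elif e.op == "ins":
            rp += 1
        else:  # del
            gp += 1
    return muts


@dataclass
class AnnotationRow:
    sequence_id: str
    v_call: str | None
    j_call: str | None
    cdr3_nt: str | None
    v_alignment_length: int
    mismatches: int
    gaps: int
    identity: float
    btop: str
    v_start: int = 0  # V alignment extent on the read, 0-based half-open
    v_end: int = 0
    j_end: int | None = None  # end of the J alignment on the read
    v_germ_start: int = 0
    d_call: str | None = None
    shm_valid: bool = True  # False once trimming leaves no usable window
    mutations: list[Mutation] = field(default_factory=list)

    @property
    def v_gene(self) -> str | None:
        """Gene-level call: allele suffix stripped at the first '*'."""
        return self.v_call.split("*")[0] if self.v_call else None

    @property
    def j_gene(self) -> str | None:
        return self.j_call.split("*")[0] if self.j_call else None


REQUIRED_COLUMNS = (
    "sequence_id",
    "v_call",
    "j_call",
    "cdr3",
    "v_alignment_length",
    "mismatches",
    "gaps",
    "btop",
)


def parse_annotation_tsv(path: str | Path) -> list[AnnotationRow]:
    """Ingest an IgBLAST/AIRR-style tabular annotation file.

    Unknown columns are ignored. Rows whose BTOP is malformed or whose
    stated mismatch/gap counts disagree with a recount from the BTOP are
    rejected with their line number.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(REQUIRED_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"annotation TSV missing required columns: {sorted(missing)}")
    rows: list[AnnotationRow] = []
    errors: list[str] = []
    for i, rec in enumerate(df.to_dict("records")):
        line = i + 2  # 1-based, after the header
        try:
            events = parse_btop(rec["btop"])
            _, mism, gaps = btop_counts(events)
            if mism != int(rec["mismatches"]) or gaps != int(rec["gaps"]):
                raise ValueError(
                    f"BTOP implies {mism} mismatches / {gaps} gaps, row states "
                    f"{rec['mismatches']} / {rec['gaps']}"
                )
            v_aln = int(rec["v_alignment_length"])
            if v_aln < 0:
                raise ValueError("negative v_alignment_length")
            germ_start = int(rec.get("v_germline_start", "1") or "1") - 1
            v_start = int(rec.get("v_sequence_start", "1") or "1") - 1
            rows.append(
                AnnotationRow(
                    sequence_id=rec["sequence_id"],
                    v_call=rec["v_call"] or None,
                    j_call=rec["j_call"] or None,
                    cdr3_nt=rec["cdr3"] or None,
                    v_alignment_length=v_aln,
                    mismatches=mism,
                    gaps=gaps,
                    identity=float(rec.get("identity", "") or (1 - mism / v_aln if v_aln else 0)),
                    btop=rec["btop"],
                    v_start=v_start,
                    v_end=v_start + v_aln,
                    v_germ_start=germ_start,
                    d_call=rec.get("d_call") or None,
                    mutations=btop_mutations(events, germ_start, v_start),
                )
            )
        except (ValueError, KeyError) as exc:
            errors.append(f"line {line}: {exc}")
    if errors:
        raise ValueError("rejected annotation rows:\n" + "\n".join(errors))
    return rows


def write_annotation_tsv(rows: Sequence[AnnotationRow], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "sequence_id": r.sequence_id,
                "v_call": r.v_call or "",
                "j_call": r.j_call or "",
                "d_call": r.d_call or "",
                "cdr3": r.cdr3_nt or "",
                "v_alignment_length": r.v_alignment_length,
                "mismatches": r.mismatches,
                "gaps": r.gaps,
                "identity": round(r.identity, 6),
                "btop": r.btop,
                "v_sequence_start": r.v_start + 1,
                "v_germline_start": r.v_germ_start + 1,
            }
            for r in rows
        ]
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# naive V/J assignment for synthetic data
# ---------------------------------------------------------------------------


def _cigar_events(cigar: str, query: str, target: str, t_start: int) -> list[BtopEvent]:
    """Convert an edlib extended CIGAR (query=germline, target=read) into
    BTOP events in read-as-query convention."""
    events: list[BtopEvent] = []
    qp, tp = 0, t_start
    for m in re.finditer(r"(\d+)([=XIDM])", cigar):
        n, op = int(m.group(1)), m.group(2)
        if op in "=M":
            events.append(BtopEvent("match", n))
            qp += n
            tp += n
        elif op == "X":
            for _ in range(n):
                events.append(BtopEvent("sub", 1, target[tp], query[qp]))
                qp += 1
                tp += 1
        elif op == "I":  # base in germline absent from read -> deletion in read
            for _ in range(n):
                events.append(BtopEvent("del", 1, None, query[qp]))
                qp += 1
        else:  # "D": base in read absent from germline -> insertion in read
            for _ in range(n):
                events.append(BtopEvent("ins", 1, target[tp], None))
                tp += 1
    return events


def _germ_to_read(events: Sequence[BtopEvent], read_start: int, germ_offset: int) -> int:
    """Map a germline offset (within the aligned germline span) to a read position."""
    rp, gp = read_start, 0
    for e in events:
        if e.op == "match" or e.op == "sub":
            if gp + e.length > germ_offset:
                return rp + (germ_offset - gp)
            rp += e.length
            gp += e.length
        elif e.op == "ins":
            rp += 1
        else:
            if gp + 1 > germ_offset:
                return rp
            gp += 1
    return rp


def naive_vdj_assign(
    sequence: str,
    sequence_id: str,
    germlines: GermlineSet,
    identity_floor: float = 0.8,
) -> AnnotationRow:
    """Assign V and J by best free-end edit-distance alignment; extract CDR3.

    Every germline V (then J) is aligned as a full query against the read
    (edlib infix mode); the lowest edit distance wins, ties breaking by
    germline identifier order. The CDR3 is the read substring between the
    mapped V and J anchors. Calls whose identity falls below
    ``identity_floor`` are null.
    """
    best_v = None  # (dist, gene, result)
    for g in sorted(germlines.v_genes, key=lambda g: g.gene_id):
        res = edlib.align(g.sequence, sequence, mode="HW", task="path")
        if best_v is None or res["editDistance"] < best_v[0]:
            best_v = (res["editDistance"], g, res)
    null = AnnotationRow(sequence_id, None, None, None, 0, 0, 0, 0.0, "")
    if best_v is None:
        return null
    v_dist, v_gene, v_res = best_v
    v_ident = 1.0 - v_dist / len(v_gene.sequence)
    if v_ident < identity_floor:
        return null
    v_start, v_end_inc = v_res["locations"][0]
    v_start = v_start or 0
    v_end = v_end_inc + 1
    events = _cigar_events(v_res["cigar"], v_gene.sequence, sequence, v_start)
    cols, mism, gaps = btop_counts(events)

    best_j = None
    tail = sequence[v_end:]
    for g in sorted(germlines.j_genes, key=lambda g: g.gene_id):
        if len(tail) < len(g.sequence) // 2:
            continue
        res = edlib.align(g.sequence, tail, mode="HW", task="path")
        if best_j is None or res["editDistance"] < best_j[0]:
            best_j = (res["editDistance"], g, res)
    j_call = None
    j_end = None
    cdr3 = None
    if best_j is not None:
        j_dist, j_gene, j_res = best_j
        if 1.0 - j_dist / len(j_gene.sequence) >= identity_floor:
            j_call = j_gene.gene_id
            j_start_inc, j_end_inc = j_res["locations"][0]
            j_start = v_end + (j_start_inc or 0)
            j_end = v_end + j_end_inc + 1
            j_events = _cigar_events(j_res["cigar"], j_gene.sequence, tail, j_start_inc or 0)
            cdr3_start = _germ_to_read(events, v_start, v_gene.anchor)
            cdr3_end = v_end + _germ_to_read(j_events, j_start_inc or 0, j_gene.anchor)
            if cdr3_start < cdr3_end <= len(sequence):
                cdr3 = sequence[cdr3_start:cdr3_end]
    return AnnotationRow(
        sequence_id=sequence_id,
        v_call=v_gene.gene_id,
        j_call=j_call,
        cdr3_nt=cdr3,
        v_alignment_length=cols,
        mismatches=mism,
        gaps=gaps,
        identity=1.0 - (mism + gaps) / cols if cols else 0.0,
        btop=serialize_btop(events),
        v_start=v_start,
        v_end=v_end,
        j_end=j_end,
        v_germ_start=0,
        mutations=btop_mutations(events, 0, v_start),
    )


def trim_primer_regions(row: AnnotationRow, lead: int = 25, tail: int = 8) -> AnnotationRow:
    """Exclude primer-landing windows from downstream mutation statistics.

    Mutations within the first ``lead`` bases of the aligned read region
    (primer-seeded FR1 start) and within the last ``tail`` bases before the
    J alignment end (FR4 end) are dropped, and the effective V alignment
    length shrinks accordingly. Rows whose alignment is shorter than
    ``lead + tail`` are flagged invalid for SHM statistics.
    """
    end = row.j_end if row.j_end is not None else row.v_end
    lo = row.v_start + lead
    hi = end - tail
    if hi - lo <= 0:
        return replace(row, shm_valid=False, mutations=[])
    kept = [m for m in row.mutations if lo <= m.read_pos < hi]
    eff_len = max(0, min(row.v_end, hi) - lo)
    return replace(
        row,
        mutations=kept,
        mismatches=len(kept),
        v_alignment_length=eff_len,
    )
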