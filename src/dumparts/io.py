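"""File I/O helpers: FASTQ/FASTA via Biopython, TSV tables via pandas."""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from dumparts.simulate import FastqRead, Template, TruthRecord


def write_fastq(reads: Iterable[FastqRead], path: str | Path) -> None:
    records = []
    for r in reads:
        rec = SeqRecord(Seq(r.sequence), id=r.read_id, description="")
        rec.letter_annotations["phred_quality"] = [ord(c) - 33 for c in r.quality]
        records.append(rec)
    SeqIO.write(records, str(path), "fastq")


def read_fastq(path: str | Path) -> list[FastqRead]:
    out = []
    for rec in SeqIO.parse(str(path), "fastq"):
        qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
        out.append(FastqRead(rec.id, str(rec.seq), qual))
    return out


def write_templates_fasta(templates: Sequence[Template], path: str | Path) -> None:
    SeqIO.write(
        [
            SeqRecord(
                Seq(t.sequence),
                id=t.template_id,
                description=f"v={t.v_id} j={t.j_id} cdr3={t.cdr3_start}-{t.cdr3_end}",
            )
            for t in templates
        ],
        str(path),
        "fasta",
    )


def write_truth_tsv(truth: Sequence[TruthRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "read_id": t.read_id,
                "sample_id": t.sample_id,
                "template5": t.template5,
                "template3": t.template3,
                "is_inter_chimera": t.is_inter_chimera,
                "is_intra_chimera": t.is_intra_chimera,
                "switch_pos": "" if t.switch_pos is None else t.switch_pos,
                "umi5": t.umi5,
                "umi3": t.umi3,
                "n_errors": t.n_errors,
            }
            for t in truth
        ]
    ).to_csv(path, sep="\t", index=False)


def read_truth_tsv(path: str | Path) -> list[TruthRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"switch_pos": "Int64"})
    out = []
    for r in df.itertuples(index=False):
        out.append(
            TruthRecord(
                read_id=str(r.read_id),
                sample_id=str(r.sample_id),
                template5=str(r.template5),
                template3=str(r.template3),
                is_inter_chimera=bool(r.is_inter_chimera),
                is_intra_chimera=bool(r.is_intra_chimera),
                switch_pos=None if pd.isna(r.switch_pos) else int(r.switch_pos),
                umi5=str(r.umi5),
                umi3=str(r.umi3),
                n_errors=int(r.n_errors),
            )
        )
    return out
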