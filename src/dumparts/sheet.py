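"""Sample sheets: per-sample dual barcodes, primers, and UMI lengths.

A sample sheet row describes the fixed layout of one sample's merged
amplicon in forward orientation::

    barcode5 . UMI5 . primer5 . variable region . primer3 . UMI3 . barcode3

``barcode3``/``primer3`` are stored as the literal strings occurring at the
3' end of the forward-oriented merged read (not their reverse complements).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import edlib
import numpy as np
import pandas as pd

_NUC = "ACGT"


def edit_distance(a: str, b: str) -> int:
    """Levenshtein distance between two sequences."""
    if not a:
        return len(b)
    if not b:
        return len(a)
    return edlib.align(a, b, mode="NW")["editDistance"]


@dataclass(frozen=True)
class SampleRow:
    sample_id: str
    barcode5: str
    barcode3: str
    primer5: str
    primer3: str
    umi5_len: int = 12
    umi3_len: int = 12


class SampleSheet:
    """Collection of :class:`SampleRow` with barcode-uniqueness validation.

    Raises ``ValueError`` if two samples share a (barcode5, barcode3) pair or
    if two distinct barcodes at the same end are within edit distance 2 of
    each other (which would defeat unambiguous distance-1 matching).
    """

    def __init__(self, rows: Iterable[SampleRow]):
        self.rows = list(rows)
        if not self.rows:
            raise ValueError("sample sheet is empty")
        pairs = [(r.barcode5, r.barcode3) for r in self.rows]
        if len(set(pairs)) != len(pairs):
            raise ValueError("duplicate (barcode5, barcode3) pair in sample sheet")
        for end in ("barcode5", "barcode3"):
            codes = sorted({getattr(r, end) for r in self.rows})
            for i, a in enumerate(codes):
                for b in codes[i + 1 :]:
                    if edit_distance(a, b) <= 2:
                        raise ValueError(
                            f"{end} barcodes {a!r} and {b!r} are within edit distance 2"
                        )
        self._pair_to_sample = {(r.barcode5, r.barcode3): r.sample_id for r in self.rows}
        self._by_sample = {r.sample_id: r for r in self.rows}
        if len(self._by_sample) != len(self.rows):
            raise ValueError("duplicate sample_id in sample sheet")

    def __len__(self) -> int:
        return len(self.rows)

    def __iter__(self):
        return iter(self.rows)

    def sample_ids(self) -> list[str]:
        return [r.sample_id for r in self.rows]

    def row(self, sample_id: str) -> SampleRow:
        return self._by_sample[sample_id]

    def barcodes5(self) -> dict[str, list[str]]:
        """Map barcode5 sequence -> sample_ids carrying it."""
        out: dict[str, list[str]] = {}
        for r in self.rows:
            out.setdefault(r.barcode5, []).append(r.sample_id)
        return out

    def barcodes3(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for r in self.rows:
            out.setdefault(r.barcode3, []).append(r.sample_id)
        return out

    def sample_for_pair(self, b5: str, b3: str) -> str | None:
        return self._pair_to_sample.get((b5, b3))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.__dict__ for r in self.rows])

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SampleSheet":
        df = pd.read_csv(path, sep="\t", dtype=str)
        required = {"sample_id", "barcode5", "barcode3", "primer5", "primer3"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"sample sheet missing required columns: {sorted(missing)}")
        rows = []
        for _, r in df.iterrows():
            rows.append(
                SampleRow(
                    sample_id=str(r["sample_id"]),
                    barcode5=str(r["barcode5"]),
                    barcode3=str(r["barcode3"]),
                    primer5=str(r["primer5"]),
                    primer3=str(r["primer3"]),
                    umi5_len=int(r.get("umi5_len", 12)),
                    umi3_len=int(r.get("umi3_len", 12)),
                )
            )
        return cls(rows)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_NUC[i] for i in rng.integers(0, 4, size=n))


def _spaced_barcodes(rng: np.random.Generator, n: int, length: int, min_dist: int = 3) -> list[str]:
    codes: list[str] = []
    attempts = 0
    while len(codes) < n:
        cand = _random_seq(rng, length)
        attempts += 1
        if attempts > 10000:
            raise RuntimeError("could not generate spaced barcode set")
        if all(edit_distance(cand, c) >= min_dist for c in codes):
            codes.append(cand)
    return codes


def make_default_sheet(
    n_samples: int = 4,
    barcode_length: int = 8,
    umi_length: int = 12,
    seed: int = 20210929,
) -> SampleSheet:
    """Deterministically generate a sheet with well-separated barcodes.

    All samples share one universal primer pair (the library design uses
    universal outer primers); barcodes are unique per sample at both ends
    with pairwise edit distance >= 3.
    """
    rng = np.random.default_rng(seed)
    primer5 = _random_seq(rng, 20)
    primer3 = _random_seq(rng, 20)
    b5s = _spaced_barcodes(rng, n_samples, barcode_length)
    b3s = _spaced_barcodes(rng, n_samples, barcode_length)
    rows = [
        SampleRow(
            sample_id=f"S{i+1}",
            barcode5=b5s[i],
            barcode3=b3s[i],
            primer5=primer5,
            primer3=primer3,
            umi5_len=umi_length,
            umi3_len=umi_length,
        )
        for i in range(n_samples)
    ]
    return SampleSheet(rows)
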