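"""Repertoire statistics: clonotyping, SHM, mutation profiles and patterns,
V/J replacement, reproducibility indices, fold change, shared clones.

A clone is the standard gene-level clonotype: identical V gene, J gene, and
CDR3 nucleotide sequence. SHM is counted as substitutions only (recovered
from BTOP traces after primer-region trimming); gap events are recorded
upstream but excluded from mutation counts.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.spatial.distance import jensenshannon

from dumparts.annotate import AnnotationRow
from dumparts.consensus import ConsensusRecord

CloneKey = tuple[str, str, str]  # (v_gene, j_gene, cdr3_nt)


# ---------------------------------------------------------------------------
# clonotyping and SHM
# ---------------------------------------------------------------------------


def define_clones(rows: Sequence[AnnotationRow], min_v_aln: int = 200) -> pd.DataFrame:
    """Group annotated sequences into clones.

    Sequences lacking a V/J/CDR3 call or with fewer than ``min_v_aln``
    bases aligned to the V gene are excluded. Returns a DataFrame with
    columns v_gene, j_gene, cdr3_nt, size, mean_shm sorted by size.
    """
    buckets: dict[CloneKey, list[AnnotationRow]] = defaultdict(list)
    for r in rows:
        if r.v_gene is None or r.j_gene is None or not r.cdr3_nt:
            continue
        if r.v_alignment_length < min_v_aln:
            continue
        buckets[(r.v_gene, r.j_gene, r.cdr3_nt)].append(r)
    recs = [
        {
            "v_gene": k[0],
            "j_gene": k[1],
            "cdr3_nt": k[2],
            "size": len(members),
            "mean_shm": float(np.mean([len(m.mutations) for m in members])),
        }
        for k, members in buckets.items()
    ]
    df = pd.DataFrame(recs, columns=["v_gene", "j_gene", "cdr3_nt", "size", "mean_shm"])
    return df.sort_values(["size", "v_gene", "j_gene", "cdr3_nt"], ascending=[False, True, True, True]).reset_index(
        drop=True
    )


def shm_stats(rows: Sequence[AnnotationRow]) -> pd.DataFrame:
    """Per-read mutation counts and per-V-segment rates.

    Rate = substitutions / (effective) V alignment length; rows flagged
    invalid after trimming are excluded.
    """
    recs = [
        {
            "sequence_id": r.sequence_id,
            "v_call": r.v_call,
            "n_mutations": len(r.mutations),
            "v_alignment_length": r.v_alignment_length,
            "rate": len(r.mutations) / r.v_alignment_length if r.v_alignment_length else np.nan,
        }
        for r in rows
        if r.shm_valid and r.v_call is not None
    ]
    return pd.DataFrame(recs, columns=["sequence_id", "v_call", "n_mutations", "v_alignment_length", "rate"])


def mutation_profile(
    rows: Sequence[AnnotationRow],
    allele: str,
    germline_length: int,
    smoothing_sigma: float = 2.0,
) -> pd.DataFrame:
    """Per-position mutation frequency on one V allele in germline coordinates.

    frequency[p] = sequences mutated at p / sequences covering p; positions
    with zero coverage are NaN (undefined, not 0). A Gaussian-smoothed copy
    (sigma 2, display only) is returned alongside the raw frequencies.
    """
    cov = np.zeros(germline_length, dtype=float)
    mut = np.zeros(germline_length, dtype=float)
    n = 0
    for r in rows:
        if r.v_call != allele or not r.shm_valid:
            continue
        n += 1
        lo = r.v_germ_start
        hi = min(germline_length, r.v_germ_start + (r.v_end - r.v_start))
        cov[lo:hi] += 1
        for m in r.mutations:
            if 0 <= m.germ_pos < germline_length:
                mut[m.germ_pos] += 1
    if n == 0:
        raise ValueError(f"no rows assigned to allele {allele!r}")
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(cov > 0, mut / np.maximum(cov, 1), np.nan)
    smooth = gaussian_filter1d(np.nan_to_num(freq), smoothing_sigma)
    return pd.DataFrame(
        {
            "position": np.arange(1, germline_length + 1),  # 1-based for humans
            "coverage": cov,
            "frequency": freq,
            "frequency_smoothed": smooth,
        }
    )


def mutation_pattern(rows: Sequence[AnnotationRow]) -> pd.DataFrame:
    """4x4 germline->observed substitution matrix, percent of all mutations.

    Off-diagonal entries sum to 100; the diagonal is identically 0. Raises
    on zero substitutions (an empty pattern is flagged, not silently 0/0).
    """
    nucs = ["A", "C", "G", "T"]
    counts = Counter()
    for r in rows:
        for m in r.mutations:
            if m.germ_base in nucs and m.read_base in nucs:
                counts[(m.germ_base, m.read_base)] += 1
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no substitutions observed; mutation pattern undefined")
    mat = pd.DataFrame(0.0, index=nucs, columns=nucs)
    for (g, o), c in counts.items():
        mat.loc[g, o] = 100.0 * c / total
    return mat


def vj_replacement(rows: Sequence[AnnotationRow]) -> dict:
    """Fraction of CDR3 groups carrying >= 2 distinct V (resp. J) genes.

    Operates on unique sequences with both gene calls and a CDR3; one CDR3
    shared by multiple V genes is evidence of chimeric recombination (real
    repertoires show near-zero replacement in naive B cells).
    """
    v_by_cdr3: dict[str, set[str]] = defaultdict(set)
    j_by_cdr3: dict[str, set[str]] = defaultdict(set)
    for r in rows:
        if r.v_gene and r.j_gene and r.cdr3_nt:
            v_by_cdr3[r.cdr3_nt].add(r.v_gene)
            j_by_cdr3[r.cdr3_nt].add(r.j_gene)
    n = len(v_by_cdr3)
    if n == 0:
        return {"n_cdr3_groups": 0, "v_replacement": 0.0, "j_replacement": 0.0}
    return {
        "n_cdr3_groups": n,
        "v_replacement": sum(1 for s in v_by_cdr3.values() if len(s) >= 2) / n,
        "j_replacement": sum(1 for s in j_by_cdr3.values() if len(s) >= 2) / n,
    }


# ---------------------------------------------------------------------------
# reproducibility
# ---------------------------------------------------------------------------


def _clone_sizes(rep) -> dict[CloneKey, float]:
    if isinstance(rep, pd.DataFrame):
        return {
            (r.v_gene, r.j_gene, r.cdr3_nt): float(r.size) for r in rep.itertuples(index=False)
        }
    return dict(rep)


def _top_keys(sizes: Mapping[CloneKey, float], k: int) -> list[CloneKey]:
    return sorted(sizes, key=lambda key: (-sizes[key], key))[:k]


def jsd_top_clones(rep_a, rep_b, k: int = 10) -> float:
    """Jensen-Shannon distance (base 2, in [0, 1]) of top-k clone compositions.

    The union of each repertoire's top-k clones (by size, ties by key)
    defines the support; each repertoire's frequency vector over that
    support is renormalized to sum 1, with absent clones at 0.
    """
    a, b = _clone_sizes(rep_a), _clone_sizes(rep_b)
    if not a or not b:
        raise ValueError("both repertoires need at least one clone")
    union = sorted(set(_top_keys(a, k)) | set(_top_keys(b, k)))
    p = np.array([a.get(key, 0.0) for key in union], dtype=float)
    q = np.array([b.get(key, 0.0) for key in union], dtype=float)
    return float(jensenshannon(p / p.sum(), q / q.sum(), base=2))


def morisita_horn(x: Sequence[float], y: Sequence[float]) -> float:
    """Morisita-Horn similarity C = 2*sum(x*y) / ((sum(x^2)/X^2 + sum(y^2)/Y^2) * X * Y)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("count vectors must share the clone-key union support")
    X, Y = x.sum(), y.sum()
    if X == 0 or Y == 0:
        raise ValueError("Morisita-Horn undefined for an all-zero vector")
    return float(2.0 * (x * y).sum() / (((x * x).sum() / X**2 + (y * y).sum() / Y**2) * X * Y))


def morisita_horn_clones(rep_a, rep_b, k: int | None = 10) -> float:
    """Morisita-Horn on (top-k) clone-size vectors over the union of keys."""
    a, b = _clone_sizes(rep_a), _clone_sizes(rep_b)
    if k is not None:
        union = sorted(set(_top_keys(a, k)) | set(_top_keys(b, k)))
    else:
        union = sorted(set(a) | set(b))
    return morisita_horn(
        [a.get(key, 0.0) for key in union], [b.get(key, 0.0) for key in union]
    )


# ---------------------------------------------------------------------------
# fold change and shared clones
# ---------------------------------------------------------------------------


def unique_seq_fold_change(
    raw_reads: Iterable[tuple[str, tuple]],
    consensus_records: Sequence[ConsensusRecord],
) -> tuple[pd.DataFrame, list[str]]:
    """Per-unique-sequence amplification fold change.

    ``raw_reads`` are ``(variable_region_sequence, umi_pair_key)`` pairs,
    one per read, with keys ``(sample, umi5, umi3)``. For each unique
    variable-region sequence, the size before correction is its raw read
    count and the size after correction is the number of retained UMI pairs
    (pairs with a consensus) in which it occurs; fold = before / after.
    Every retained pair contributes at least one read, so folds are >= 1.
    Sequences occurring in no retained pair are reported separately (never
    divided by zero).
    """
    kept_keys = {(c.sample_id, c.umi5, c.umi3) for c in consensus_records}
    before: Counter[str] = Counter()
    pairs: dict[str, set] = defaultdict(set)
    for seq, key in raw_reads:
        before[seq] += 1
        if key in kept_keys:
            pairs[seq].add(key)
    rows = []
    lost = []
    for seq, n_raw in before.items():
        n_after = len(pairs.get(seq, ()))
        if n_after == 0:
            lost.append(seq)
        else:
            rows.append(
                {"sequence": seq, "reads_before": n_raw, "umi_pairs_after": n_after, "fold": n_raw / n_after}
            )
    df = pd.DataFrame(rows, columns=["sequence", "reads_before", "umi_pairs_after", "fold"])
    return df, lost


def shared_clones(rep_a, rep_b) -> dict:
    """Shared-clone statistics between two repertoires.

    proportion_a = |shared| / |clones in A| (and symmetrically for B);
    singleton fractions are the fraction of shared clones supported by a
    single read in the respective repertoire.
    """
    a, b = _clone_sizes(rep_a), _clone_sizes(rep_b)
    shared = set(a) & set(b)
    return {
        "n_shared": len(shared),
        "proportion_a": len(shared) / len(a) if a else 0.0,
        "proportion_b": len(shared) / len(b) if b else 0.0,
        "singleton_fraction_a": (
            sum(1 for key in shared if a[key] == 1) / len(shared) if shared else 0.0
        ),
        "singleton_fraction_b": (
            sum(1 for key in shared if b[key] == 1) / len(shared) if shared else 0.0
        ),
    }
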