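"""Ground-truth simulator: repertoire synthesis, chimera-forming PCR, sequencing.

The simulator emulates the library it is meant to debug: molecules of a
multi-sample pool are labelled with sample barcode pairs and fresh dual UMIs
*before* amplification, then amplified through a branching-process PCR in
which each copy event may (a) introduce substitution errors and (b) switch
template mid-synthesis, producing a chimera that inherits its 5' labels from
the donor molecule and its 3' labels from the acceptor. Reads are finally
drawn from the amplified pool with per-base sequencing error, and every read
carries a TruthRecord naming its parents and chimera status.

Mechanistic choices (the phenomena, not the mechanism, are empirically
established):

* Template switching: the nascent strand truncates at a uniform position t
  and re-anneals on a different molecule at a site whose trailing
  ``homology_k``-mer identity to the donor's 3' terminus is at least
  ``h_min``; among admissible sites the acceptor position is sampled with
  probability proportional to window identity. The per-copy switch
  probability is ``p_switch`` scaled by pool saturation
  (``population / pool_capacity``, capped at 1): switching requires the
  nascent strand to re-anneal on another template, which competes with
  primer annealing and so grows with template concentration. This keeps
  early-cycle chimeras a trace and makes formation explosive as the
  reaction saturates, and it is the simplest model under which chimera
  yield grows with cycle number and with pool sequence similarity.
* Amplification bias: each template draws a per-cycle duplication
  probability (efficiency) from Beta(20, 2).
* Reagent exhaustion: the per-cycle duplication probability is damped by
  ``max(0, 1 - population/pool_capacity)``, giving the familiar logistic
  plateau of real PCR and keeping late-cycle simulations tractable.
* Only substitutions are simulated; downstream edit-distance machinery is
  still indel-tolerant for real data.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import yaml
from numpy.lib.stride_tricks import sliding_window_view

from dumparts.sheet import SampleSheet, make_default_sheet

_NUC = np.frombuffer(b"ACGT", dtype=np.uint8)

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


def _rand_seq(rng: np.random.Generator, n: int) -> str:
    return rng.integers(0, 4, size=n, dtype=np.uint8).astype(np.uint8).tobytes().translate(
        bytes.maketrans(bytes(range(4)), b"ACGT")
    ).decode()


def _seq_to_arr(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


def mutate_substitutions(seq: str, n: int, rng: np.random.Generator) -> str:
    """Place exactly n substitutions at distinct random positions."""
    if n <= 0:
        return seq
    arr = _seq_to_arr(seq).copy()
    pos = rng.choice(len(arr), size=min(n, len(arr)), replace=False)
    for p in pos:
        choices = _NUC[_NUC != arr[p]]
        arr[p] = choices[rng.integers(0, 3)]
    return arr.tobytes().decode()


# ---------------------------------------------------------------------------
# germlines and templates
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GermlineGene:
    gene_id: str
    sequence: str
    anchor: int  # V: CDR3 start offset within the gene; J: CDR3 end offset


@dataclass(frozen=True)
class GermlineSet:
    v_genes: tuple[GermlineGene, ...]
    j_genes: tuple[GermlineGene, ...]
    constant_stub: str

    def v(self, gene_id: str) -> GermlineGene:
        return next(g for g in self.v_genes if g.gene_id == gene_id)

    def j(self, gene_id: str) -> GermlineGene:
        return next(g for g in self.j_genes if g.gene_id == gene_id)


def synthetic_germlines(
    n_v: int = 8,
    n_j: int = 4,
    v_length: int = 240,
    j_length: int = 48,
    n_families: int = 2,
    within_family_divergence: float = 0.06,
    constant_stub_length: int = 30,
    seed: int = 104,
) -> GermlineSet:
    """Generate a deterministic synthetic germline reference set.

    V genes come in families derived from a shared family ancestor with
    ``within_family_divergence`` substitutions per base, reproducing the
    high within-family similarity of real IGHV segments that drives
    homology-dependent chimera formation. Anchors (CDR3 boundaries) sit 6 nt
    from the V 3' end and 6 nt into each J.
    """
    rng = np.random.default_rng(seed)
    v_genes = []
    fam_seqs = [_rand_seq(rng, v_length) for _ in range(n_families)]
    for i in range(n_v):
        fam = i % n_families
        n_mut = rng.binomial(v_length, within_family_divergence)
        seq = mutate_substitutions(fam_seqs[fam], int(n_mut), rng)
        v_genes.append(GermlineGene(f"IGHV{fam+1}-{i//n_families+1}*01", seq, v_length - 6))
    j_genes = [
        GermlineGene(f"IGHJ{i+1}*01", _rand_seq(rng, j_length), 6) for i in range(n_j)
    ]
    return GermlineSet(tuple(v_genes), tuple(j_genes), _rand_seq(rng, constant_stub_length))


@dataclass(frozen=True)
class Template:
    """One input molecule species: V + junction + J + constant-region stub."""

    template_id: str
    sample_id: str
    sequence: str
    v_id: str
    j_id: str
    cdr3_start: int
    cdr3_end: int
    abundance_weight: float
    efficiency: float

    def __post_init__(self):
        if not (0 <= self.cdr3_start <= self.cdr3_end <= len(self.sequence)):
            raise ValueError("cdr3 offsets outside sequence bounds")
        if self.abundance_weight <= 0:
            raise ValueError("abundance_weight must be positive")
        if not (0.0 <= self.efficiency <= 1.0):
            raise ValueError("efficiency must be in [0, 1]")

    @property
    def cdr3(self) -> str:
        return self.sequence[self.cdr3_start : self.cdr3_end]


@dataclass
class Molecule:
    """One physical molecule lineage in the amplification pool.

    ``sequence`` is the insert (variable region + constant stub) without
    adapters; barcodes/UMIs are carried as labels and assembled into the
    full amplicon only at sequencing time. ``multiplicity`` counts
    error-free copies of this exact molecule, which keeps late-cycle pools
    tractable without altering the branching process.
    """

    sequence: str
    sample_id: str
    barcode5: str
    barcode3: str
    umi5: str
    umi3: str
    origin: str
    origin3: str
    sample_id3: str
    efficiency: float
    switch_pos: int | None = None
    n_pcr_errors: int = 0
    multiplicity: int = 1
    birth_cycle: int = 0

    def __post_init__(self):
        if (self.origin3 == self.origin) != (self.switch_pos is None):
            raise ValueError("origin3 == origin must hold exactly when switch_pos is null")

    @property
    def is_chimera(self) -> bool:
        return self.switch_pos is not None

    @property
    def is_inter_chimera(self) -> bool:
        return self.is_chimera and self.sample_id3 != self.sample_id

    @property
    def is_intra_chimera(self) -> bool:
        return self.is_chimera and self.sample_id3 == self.sample_id


@dataclass
class SimConfig:
    """Study conditions for one simulated library."""

    n_samples: int = 4
    templates_per_sample: int = 50
    molecules_per_sample: int = 200
    umi_length: int = 12
    n_cycles: int = 24
    p_switch: float = 0.25
    homology_k: int = 10
    h_min: float = 0.8
    e_pcr: float = 1e-4
    e_seq: float = 0.005
    depth: int = 40000
    seed: int = 0
    efficiency_alpha: float = 20.0
    efficiency_beta: float = 2.0
    pool_capacity: int = 150_000
    plateau_residual: float = 0.02
    junction_length: tuple[int, int] = (12, 30)
    read_quality: int = 30
    randomize_orientation: bool = True
    sheet: SampleSheet | None = None

    def __post_init__(self):
        for name in ("p_switch", "h_min", "e_pcr", "e_seq"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")

    def resolved_sheet(self) -> SampleSheet:
        if self.sheet is None:
            self.sheet = make_default_sheet(self.n_samples, umi_length=self.umi_length)
        return self.sheet

    def to_yaml(self) -> str:
        d = dataclasses.asdict(self)
        d["sheet"] = None if self.sheet is None else [r.__dict__ for r in self.sheet.rows]
        d["junction_length"] = list(self.junction_length)
        return yaml.safe_dump(d, sort_keys=False)


@dataclass(frozen=True)
class TruthRecord:
    read_id: str
    sample_id: str
    template5: str
    template3: str
    is_inter_chimera: bool
    is_intra_chimera: bool
    switch_pos: int | None
    umi5: str
    umi3: str
    n_errors: int


# ---------------------------------------------------------------------------
# repertoire and labelling
# ---------------------------------------------------------------------------


def make_repertoire(
    config: SimConfig,
    germlines: GermlineSet,
    rng: np.random.Generator | None = None,
) -> list[Template]:
    """Draw a repertoire of templates with distinct CDR3s for every sample.

    Each template is V + random junction + J + constant stub; abundance
    weights are lognormal(0, 1) (clone sizes in real repertoires are
    heavy-tailed) and amplification efficiencies Beta(alpha, beta).
    """
    if not germlines.v_genes or not germlines.j_genes:
        raise ValueError("germline set must contain at least one V and one J gene")
    if config.templates_per_sample < 1:
        raise ValueError("templates_per_sample must be >= 1")
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    sheet = config.resolved_sheet()
    templates: list[Template] = []
    seen_cdr3: set[str] = set()
    lo, hi = config.junction_length
    for sample_id in sheet.sample_ids():
        for t in range(config.templates_per_sample):
            for _ in range(200):
                v = germlines.v_genes[rng.integers(0, len(germlines.v_genes))]
                j = germlines.j_genes[rng.integers(0, len(germlines.j_genes))]
                junction = _rand_seq(rng, int(rng.integers(lo, hi + 1))) if hi > 0 else ""
                seq = v.sequence + junction + j.sequence + germlines.constant_stub
                cdr3_start = v.anchor
                cdr3_end = len(v.sequence) + len(junction) + j.anchor
                cdr3 = seq[cdr3_start:cdr3_end]
                if cdr3 not in seen_cdr3:
                    seen_cdr3.add(cdr3)
                    break
            else:  # pragma: no cover - needs adversarial junction ranges
                raise RuntimeError("could not draw a unique CDR3; widen junction_length")
            templates.append(
                Template(
                    template_id=f"{sample_id}_T{t+1}",
                    sample_id=sample_id,
                    sequence=seq,
                    v_id=v.gene_id,
                    j_id=j.gene_id,
                    cdr3_start=cdr3_start,
                    cdr3_end=cdr3_end,
                    abundance_weight=float(rng.lognormal(0.0, 1.0)),
                    efficiency=float(rng.beta(config.efficiency_alpha, config.efficiency_beta)),
                )
            )
    return templates


def redraw_efficiencies(
    templates: Sequence[Template],
    config: SimConfig,
    rng: np.random.Generator,
) -> list[Template]:
    """Fresh Beta-distributed amplification efficiencies for a new reaction.

    Amplification bias is a property of one PCR reaction, not of the
    molecule; biological replicates of the same repertoire redraw it.
    """
    return [
        dataclasses.replace(
            t, efficiency=float(rng.beta(config.efficiency_alpha, config.efficiency_beta))
        )
        for t in templates
    ]


def attach_labels(
    templates: Sequence[Template],
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> list[Molecule]:
    """Attach sample barcodes and fresh dual UMIs to the initial molecules.

    Per sample, ``molecules_per_sample`` molecules are distributed over that
    sample's templates multinomially by abundance weight; every molecule
    receives an independent random UMI pair. UMI-pair collisions (two
    molecules drawing the same pair) are possible but astronomically rare at
    the default UMI length; the observed count is exposed via
    :func:`count_umi_collisions`.
    """
    if config.umi_length < 6:
        raise ValueError("umi_length must be >= 6 for unique molecular labelling")
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    sheet = config.resolved_sheet()
    molecules: list[Molecule] = []
    for sample_id in sheet.sample_ids():
        row = sheet.row(sample_id)
        mine = [t for t in templates if t.sample_id == sample_id]
        if not mine:
            continue
        w = np.array([t.abundance_weight for t in mine], dtype=float)
        counts = rng.multinomial(config.molecules_per_sample, w / w.sum())
        for t, n in zip(mine, counts):
            for _ in range(int(n)):
                molecules.append(
                    Molecule(
                        sequence=t.sequence,
                        sample_id=sample_id,
                        barcode5=row.barcode5,
                        barcode3=row.barcode3,
                        umi5=_rand_seq(rng, row.umi5_len),
                        umi3=_rand_seq(rng, row.umi3_len),
                        origin=t.template_id,
                        origin3=t.template_id,
                        sample_id3=sample_id,
                        efficiency=t.efficiency,
                    )
                )
    return molecules


def count_umi_collisions(molecules: Iterable[Molecule]) -> int:
    """Number of molecules whose (sample, UMI5, UMI3) repeats an earlier one."""
    seen: set[tuple[str, str, str]] = set()
    n = 0
    for m in molecules:
        key = (m.sample_id, m.umi5, m.umi3)
        if key in seen:
            n += 1
        seen.add(key)
    return n


# ---------------------------------------------------------------------------
# PCR amplification with template switching
# ---------------------------------------------------------------------------


def _acceptor_site(
    donor_tail: np.ndarray,
    acceptor_arr: np.ndarray,
    h_min: float,
    rng: np.random.Generator,
) -> int | None:
    """Best re-annealing site on the acceptor: window identity >= h_min,
    sampled with probability proportional to identity. Returns the position
    at which synthesis resumes (index into acceptor), or None."""
    k = len(donor_tail)
    if len(acceptor_arr) < k + 1:
        return None
    windows = sliding_window_view(acceptor_arr, k)  # window i = acceptor[i:i+k]
    ident = (windows == donor_tail).mean(axis=1)
    # resume position a means acceptor[a-k:a] anneals to the donor tail; a in [k, L-1]
    ok = np.nonzero(ident[: len(acceptor_arr) - k] >= h_min)[0]
    if ok.size == 0:
        return None
    w = ident[ok]
    a = int(rng.choice(ok, p=w / w.sum())) + k
    return a


def pcr_amplify(
    molecules: Sequence[Molecule],
    config: SimConfig,
    rng: np.random.Generator | None = None,
    stats: dict | None = None,
) -> list[Molecule]:
    """Amplify the pool for ``config.n_cycles`` branching-process cycles.

    Per cycle each physical copy duplicates with probability
    ``efficiency * max(0, 1 - population / pool_capacity)``. A duplication
    becomes a template switch with probability
    ``p_switch * min(1, population / pool_capacity)`` (the chimeric product
    inherits barcode5/UMI5 from the donor and barcode3/UMI3 from the
    acceptor) and otherwise acquires substitutions at ``e_pcr`` per base.
    Switch attempts without an admissible homologous acceptor site are
    abandoned and counted.
    """
    if config.n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    pool: list[Molecule] = [dataclasses.replace(m) for m in molecules]
    arrs: list[np.ndarray] = [_seq_to_arr(m.sequence) for m in pool]
    if stats is None:
        stats = {}
    stats.setdefault("aborted_switches", 0)
    stats.setdefault("switch_events", 0)
    k = config.homology_k

    for cycle in range(1, config.n_cycles + 1):
        pop = sum(m.multiplicity for m in pool)
        saturation = min(1.0, pop / config.pool_capacity)
        # the plateau is not perfectly flat: a small residual duplication
        # rate persists at saturation, where switching is most likely
        damp = max(config.plateau_residual, 1.0 - pop / config.pool_capacity)
        p_switch_eff = config.p_switch * saturation
        n_before = len(pool)
        cum = np.cumsum([m.multiplicity for m in pool[:n_before]], dtype=float)
        total = cum[-1]
        new_mols: list[Molecule] = []
        new_arrs: list[np.ndarray] = []
        for idx in range(n_before):
            m = pool[idx]
            p_dup = m.efficiency * damp
            ndup = int(rng.binomial(m.multiplicity, p_dup)) if p_dup > 0 else 0
            if ndup == 0:
                continue
            nsw = int(rng.binomial(ndup, p_switch_eff)) if p_switch_eff > 0 else 0
            L = len(m.sequence)
            p_any_err = 1.0 - (1.0 - config.e_pcr) ** L if config.e_pcr > 0 else 0.0
            nerr = int(rng.binomial(ndup - nsw, p_any_err)) if p_any_err > 0 else 0
            m.multiplicity += ndup - nsw - nerr
            for _ in range(nerr):
                # number of substitutions conditioned on >= 1
                n_mut = 0
                while n_mut < 1:
                    n_mut = int(rng.binomial(L, config.e_pcr))
                seq2 = mutate_substitutions(m.sequence, n_mut, rng)
                child = dataclasses.replace(
                    m,
                    sequence=seq2,
                    n_pcr_errors=m.n_pcr_errors + n_mut,
                    multiplicity=1,
                    birth_cycle=cycle,
                )
                new_mols.append(child)
                new_arrs.append(_seq_to_arr(seq2))
            for _ in range(nsw):
                if L <= k + 1:
                    stats["aborted_switches"] += 1
                    continue
                t = int(rng.integers(k, L))  # truncation position of the nascent strand
                donor_tail = arrs[idx][t - k : t]
                # sample acceptor molecules (by multiplicity) until one offers
                # a homologous site; a few tries model the kinetic search
                acc_idx = None
                site = None
                for _try in range(8):
                    j = int(np.searchsorted(cum, rng.random() * total, side="right"))
                    j = min(j, n_before - 1)
                    cand = pool[j]
                    if j == idx or cand.origin3 == m.origin:
                        continue
                    site = _acceptor_site(donor_tail, arrs[j], config.h_min, rng)
                    if site is not None:
                        acc_idx = j
                        break
                if acc_idx is None or site is None:
                    stats["aborted_switches"] += 1
                    continue
                acc = pool[acc_idx]
                chim_seq = m.sequence[:t] + acc.sequence[site:]
                n_mut = int(rng.binomial(len(chim_seq), config.e_pcr)) if config.e_pcr > 0 else 0
                if n_mut:
                    chim_seq = mutate_substitutions(chim_seq, n_mut, rng)
                child = Molecule(
                    sequence=chim_seq,
                    sample_id=m.sample_id,
                    barcode5=m.barcode5,
                    barcode3=acc.barcode3,
                    umi5=m.umi5,
                    umi3=acc.umi3,
                    origin=m.origin,
                    origin3=acc.origin3,
                    sample_id3=acc.sample_id3,
                    efficiency=m.efficiency,
                    switch_pos=t,
                    n_pcr_errors=m.n_pcr_errors + n_mut,
                    multiplicity=1,
                    birth_cycle=cycle,
                )
                new_mols.append(child)
                new_arrs.append(_seq_to_arr(chim_seq))
                stats["switch_events"] += 1
        pool.extend(new_mols)
        arrs.extend(new_arrs)
    stats["final_population"] = sum(m.multiplicity for m in pool)
    stats["distinct_molecules"] = len(pool)
    return pool


def chimera_read_fraction(pool: Sequence[Molecule]) -> float:
    """Fraction of physical copies in the pool that are chimeric."""
    tot = sum(m.multiplicity for m in pool)
    chim = sum(m.multiplicity for m in pool if m.is_chimera)
    return chim / tot if tot else 0.0


def inject_inter_chimeras(
    molecules: Sequence[Molecule],
    fraction: float,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> list[Molecule]:
    """Add barcode-mispaired chimeras so they form ``fraction`` of all copies.

    Each injected chimera joins the 5' part of a molecule from one sample to
    the 3' part of a molecule from a different sample at a uniform position,
    inheriting labels accordingly. Used to create libraries with a known
    inter-sample chimera rate without running the full branching process.
    """
    if not (0.0 <= fraction < 1.0):
        raise ValueError("fraction must be in [0, 1)")
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    pool = [dataclasses.replace(m) for m in molecules]
    total = sum(m.multiplicity for m in pool)
    target = int(round(total * fraction / (1.0 - fraction)))
    donors = [m for m in pool if not m.is_chimera]
    out = list(pool)
    made = 0
    while made < target:
        a, b = rng.choice(len(donors), size=2, replace=True)
        ma, mb = donors[int(a)], donors[int(b)]
        if ma.sample_id == mb.sample_id or ma.origin == mb.origin3:
            continue
        t = int(rng.integers(1, min(len(ma.sequence), len(mb.sequence))))
        out.append(
            Molecule(
                sequence=ma.sequence[:t] + mb.sequence[t:],
                sample_id=ma.sample_id,
                barcode5=ma.barcode5,
                barcode3=mb.barcode3,
                umi5=ma.umi5,
                umi3=mb.umi3,
                origin=ma.origin,
                origin3=mb.origin3,
                sample_id3=mb.sample_id3,
                efficiency=ma.efficiency,
                switch_pos=t,
            )
        )
        made += 1
    return out


# ---------------------------------------------------------------------------
# sequencing
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FastqRead:
    read_id: str
    sequence: str
    quality: str


def assemble_amplicon(m: Molecule, sheet: SampleSheet) -> str:
    """Full merged-read sequence: b5 . umi5 . p5 . insert . p3 . umi3 . b3.

    Primers are universal in the default design; for generality the primer
    of the sample owning each end's barcode is used.
    """
    row5 = next(r for r in sheet.rows if r.barcode5 == m.barcode5)
    row3 = next(r for r in sheet.rows if r.barcode3 == m.barcode3)
    return m.barcode5 + m.umi5 + row5.primer5 + m.sequence + row3.primer3 + m.umi3 + m.barcode3


def sequence_reads(
    molecules: Sequence[Molecule],
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[list[FastqRead], list[TruthRecord]]:
    """Sample ``config.depth`` reads proportional to molecule multiplicity.

    Per-base substitution at ``e_seq``; constant placeholder qualities; half
    of the reads are emitted reverse-complemented when
    ``randomize_orientation`` is set (merged real reads arrive in both
    orientations).
    """
    if not molecules:
        raise ValueError("no molecules to sequence")
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    sheet = config.resolved_sheet()
    mult = np.array([m.multiplicity for m in molecules], dtype=float)
    idx = rng.choice(len(molecules), size=config.depth, replace=True, p=mult / mult.sum())
    reads: list[FastqRead] = []
    truth: list[TruthRecord] = []
    for i, mi in enumerate(idx):
        m = molecules[int(mi)]
        seq = assemble_amplicon(m, sheet)
        n_seq_err = int(rng.binomial(len(seq), config.e_seq)) if config.e_seq > 0 else 0
        if n_seq_err:
            seq = mutate_substitutions(seq, n_seq_err, rng)
        if config.randomize_orientation and rng.random() < 0.5:
            seq = revcomp(seq)
        rid = f"read_{i+1}"
        reads.append(FastqRead(rid, seq, chr(33 + config.read_quality) * len(seq)))
        truth.append(
            TruthRecord(
                read_id=rid,
                sample_id=m.sample_id,
                template5=m.origin,
                template3=m.origin3,
                is_inter_chimera=m.is_inter_chimera,
                is_intra_chimera=m.is_intra_chimera,
                switch_pos=m.switch_pos,
                umi5=m.umi5,
                umi3=m.umi3,
                n_errors=m.n_pcr_errors + n_seq_err,
            )
        )
    return reads, truth


def simulate_library(
    config: SimConfig,
    germlines: GermlineSet | None = None,
) -> tuple[list[FastqRead], list[TruthRecord], list[Template], dict]:
    """Convenience end-to-end run: repertoire -> labels -> PCR -> reads."""
    rng = np.random.default_rng(config.seed)
    if germlines is None:
        germlines = synthetic_germlines()
    templates = make_repertoire(config, germlines, rng)
    molecules = attach_labels(templates, config, rng)
    stats: dict = {}
    pool = pcr_amplify(molecules, config, rng, stats)
    reads, truth = sequence_reads(pool, config, rng)
    stats["chimera_copy_fraction"] = chimera_read_fraction(pool)
    chim = [m.multiplicity for m in pool if m.is_chimera]
    genuine = [m.multiplicity for m in pool if not m.is_chimera]
    stats["mean_copies_chimeric"] = float(np.mean(chim)) if chim else 0.0
    stats["mean_copies_genuine"] = float(np.mean(genuine)) if genuine else 0.0
    return reads, truth, templates, stats
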