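# Methods

## Library model

A merged read is laid out, in forward orientation, as

    barcode5 · UMI5 · primer5 · variable region · primer3 · UMI3 · barcode3

with `barcode3`/`primer3` stored in the sample sheet as the literal strings
at the 3' end of the forward read. Sample sheets are validated so that all
(barcode5, barcode3) pairs are unique and no two barcodes at the same end
are within edit distance 2 — this guarantees that matching at Levenshtein
distance ≤ 1 is unambiguous. The default generated design uses 8-mer
barcodes with pairwise edit distance ≥ 3, one universal 20-mer primer pair,
and 12-mer UMIs at both ends.

## Demultiplexing

Read pairs are merged by exhaustive overlap scan (minimum overlap 20,
mismatch fraction ≤ 0.1, disagreements resolved toward mate 1 — qualities
in this pipeline are placeholders). Both read orientations are tried and
the one with lower total adapter edit distance is kept. Barcodes are
anchored at the read termini with a positional slack of ±2; the primer is
then sought after the expected UMI length ± 1 (absorbing an isolated indel
in the UMI); candidate barcodes tie-breaking at equal total edit distance
are treated as ambiguous and the end is left unmatched — conservative, so
that chimera statistics are not polluted by guessed assignments. Matched
barcode pairs present in the sheet assign the read to a sample; matched
but absent pairs are inter-sample chimeras; anything else is unmatched.

## RPUP filter (first low ebb)

Assigned reads are grouped by exact (sample, UMI5, UMI3). On the RPUP
count histogram (optionally smoothed by a centred moving average; default
off, window 3 offered because real tails are noisy), the threshold is the
smallest r in [2, r_max − 1] with counts[r] ≤ both neighbours and strictly
below at least one; a plateau collapses to its smallest r provided the
next differing count rebounds upward; a monotone non-increasing histogram
falls back to threshold 2 (singleton removal). Groups with RPUP strictly
below the threshold are discarded ("less than the threshold" defines the
chimera side; groups at the threshold are kept). The threshold is
overridable for expert use.

Two distinct populations end up below the ebb: genuine late-cycle
chimeras, and singleton groups minted by a sequencing error inside a UMI
(at 0.5% per-base error and 24 UMI bases, ~11% of reads). Both are
artifacts; the truth-aware evaluation keeps them apart by classifying a
group as genuine/chimeric only when its observed key matches its reads'
true UMI pair, and as a UMI artifact otherwise.

## Consensus

Within each kept group, reads are partitioned by exact CDR3 nucleotide
call; reads lacking a call are excluded from subgroups but remain in the
fraction denominator (the fraction is of all reads in the UMI pair).
Subgroups need ≥ 30% of the group's reads (inclusive) and ≥ 2 reads; reads
are then restricted to the length of the most abundant unique sequence
(ties broken lexicographically — deterministic), and a position-wise
plurality consensus is taken. A tied column discards the whole consensus
rather than emitting an ambiguity code — an invented base would propagate
into clonotype keys. No indel-aware multiple alignment is attempted before
the column vote; the length filter makes surviving indels rare, and this
is a known limitation for indel-heavy real data.

## Annotation

External IgBLAST-style TSVs are ingested with validation: the BTOP string
is re-parsed and must reproduce the stated mismatch and gap counts
exactly; malformed rows are rejected with line numbers. BTOP convention:
match-run lengths alternate with two-character codes, (read base, germline
base) for substitutions, a `-` marking the gapped side. SHM counts
substitutions only; gap events are recorded but excluded.

The built-in assigner for synthetic data aligns every germline V (then J)
as a full query against the read with free-end (infix) edit-distance
alignment (edlib); lowest distance wins, ties break by germline identifier
order, and calls below an identity floor (default 0.8) are null. Edit
distance rather than a scored local alignment keeps pipeline-scale
annotation (tens of thousands of reads × every germline) fast and exactly
reproducible; on substitution-dominated synthetic data the two give the
same calls. CDR3 boundaries come from anchor offsets carried in the
germline FASTA headers (`anchor=<offset>`; the Cys-equivalent position for
V, the end-of-CDR3 position for J), mapped through the alignment.

Primer-landing windows — the first 25 bp of the aligned read and the last
8 bp before the J alignment end — are excluded from all mutation
statistics, and the effective V alignment length shrinks accordingly; rows
left without a usable window are flagged and dropped from SHM statistics.
Clonotypes use gene-level calls (allele suffix stripped at the first `*`)
and require ≥ 200 bp aligned to the V gene.

## Repertoire statistics

Jensen–Shannon distance uses base-2 logarithms on the union of both
repertoires' top-k clones (k = 10), each frequency vector renormalized
over that union, so values live in [0, 1]; the Morisita–Horn index is the
standard count-vector formula over the same union. Both choices (base,
union-of-top-k support, renormalization) are ours; the statistic is
otherwise underdetermined. Mutation profiles report per-position
frequencies in germline coordinates, defined only where coverage > 0
(masked, not zero); a Gaussian-smoothed copy (σ = 2) is emitted for
display alongside, never in place of, the raw frequencies. Fold change per
unique variable-region sequence is its raw read count divided by the
number of retained UMI pairs in which it occurs — every retained pair
contributes at least one read, so folds are ≥ 1 by construction;
sequences occurring in no retained pair are reported separately.

## Breakpoint inference

For known-amplicon libraries, the (B5, B3) embedded barcodes identify each
chimera's parents; the switch position is bounded by direct first-mismatch
scans — from the 5' end against the 5' parent (bound_hi) and from the 3'
end against the 3' parent (bound_lo). Both bounds are feasible switch
boundaries, so containment checks use the closed interval; the positional
profile increments the half-open [bound_lo, bound_hi) area of each valid
call and normalizes to sum 1. Direct scans are preferred over alignment
columns because a global alignment, optimizing total cost, will trade away
suffix exactness when the opposite half of the read is mismatch-rich; a
direct scan is exact for substitution-only data and an isolated indel only
terminates a scan early, widening one bound inward. Calls with crossed
bounds (a sequencing error upstream of the true switch) are counted and
excluded, as are reads whose best-matching reference contradicts both
barcode-implied parents (candidate higher-order chimeras). The synthetic
reference set conserves its FR3 analogue across references (as real IGHV
families do), which concentrates homologous switch sites there.

## Simulator

Templates are V + random junction (12–30 nt) + J + constant stub, with
CDR3 spanning the last 6 V bases through the first 6 J bases; CDR3
uniqueness is enforced by redrawing junctions. Abundance weights are
lognormal(0, 1) (clone sizes are heavy-tailed); per-template, per-reaction
amplification efficiency is Beta(20, 2) (mean 0.91). Initial molecules
are allotted multinomially by weight and each receives a fresh random UMI
pair.

Amplification is a per-cycle branching process. Each copy duplicates with
probability `efficiency · max(plateau_residual, 1 − N/K)` where N is the
current population and K the pool capacity — the logistic factor is the
reagent-exhaustion plateau of real PCR, and the small residual (0.02)
reflects that plateaus are not perfectly flat. A duplication becomes a
template switch with probability `p_switch · min(1, N/K)`: switching
requires the nascent strand to re-anneal on another template, which
competes with primer annealing and therefore scales with template
concentration. This makes early-cycle chimeras a trace and late-cycle
formation explosive, matching the established phenomenology; a chimera
formed at the plateau inherits barcode5/UMI5 from its donor and
barcode3/UMI3 from its acceptor and accumulates few copies — the physical
basis of the RPUP separation. The donor truncation point is uniform; the
acceptor site must show ≥ 80% identity over a trailing 10-mer window and
is sampled with probability proportional to window identity (acceptors
carrying the donor's own template are excluded so that parentage truth
stays well defined). Switch attempts with no admissible acceptor are
abandoned and counted. Non-switch duplications acquire substitutions at
`e_pcr` (default 1e-4/base/cycle); sequencing adds `e_seq` (default
0.5%/base) and emits half the reads reverse-complemented. Only
substitutions are simulated; the demux and consensus machinery remain
indel-tolerant for real data. Copy counting uses a multiplicity field for
identical error-free siblings, which leaves the branching process exact
while keeping 30-cycle simulations tractable.

`p_switch` defaults to 0.25. No per-cycle switch rate is established in
the literature; the default was calibrated once so that the standard
4-sample study conditions yield the artifact levels reported for real
dual-barcode libraries (≈ 14% inter-sample chimeric reads, ≈ 18% of
assigned reads removed at the ebb), and was then left alone.

### What the simulator does not emulate

Quality-score structure (qualities are constant placeholders; no stage
uses them), indels and homopolymer errors, PCR stutter, adapter
read-through, index hopping between libraries, primer-site mutation
effects, and annealing-temperature dependence (subsumed into `p_switch`).
Passing tests therefore demonstrate correctness of the *computational*
pipeline under a substitution-error, homology-driven-switching model —
not robustness to every failure mode of real sequencers.

## Study conditions and problem sizes

The standard end-to-end run uses 4 samples × 30 templates × 150 labelled
molecules, 24 cycles into a 60,000-copy capacity, and 18,000 reads —
a mean of 30 reads per genuine UMI pair, the ≥ 20× regime the RPUP filter
is designed for. Replicate-reproducibility runs use 2 samples × 40
templates × 400 molecules × 12,000 reads × 3 replicates with per-reaction
efficiency redraws; cycle-dependence runs use 2 × 15 × 80 molecules into a
20,000 capacity at 18/24/30 cycles × 5 seeds; consensus accuracy uses 300
groups of 10–30 reads at 0.5%/base error; breakpoint validation uses 20
references × 200 error-free chimeras. These sizes reproduce the paper-scale
phenomena at desktop cost; all are parameters, not constants.

## Numerical and degenerate-input choices

Deterministic tie-breaks throughout: lexicographic for modal sequences and
clone ordering, germline-id order for equal alignment scores, smallest-r
for RPUP plateaus, forward orientation at equal adapter distance.
Ambiguities that cannot be broken honestly (equal-distance barcode
matches, tied consensus columns) discard the observation and count it.
Empty inputs raise errors rather than returning empty results where a
threshold would otherwise be fabricated (empty RPUP histogram, zero
substitutions for a mutation pattern, all-zero Morisita–Horn vectors).
Seeded `numpy.random.Generator` objects thread through every stochastic
step; a fixed seed reproduces FASTQ, truth table, and reports
byte-for-byte.
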