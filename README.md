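# dumparts

Artifact removal for dual-barcode, dual-UMI bulk antibody repertoire
sequencing (Rep-seq), with a ground-truth PCR/chimera simulator.

## The problem

PCR amplification of an antibody library creates three classes of artifact
that corrupt downstream repertoire analysis:

* **Inter-sample chimeras** — template-switch products joining molecules of
  two pooled samples. They carry mispaired sample barcodes, masquerade as
  "public" clones shared between donors, and inflate shared-clone counts.
* **Intra-sample chimeras** — switch products within one sample. They look
  like novel rearrangements with extra mutations, inflating clone counts,
  apparent somatic hypermutation (SHM), and V/J replacement rates.
* **Base errors and amplification bias** — substitutions from the
  polymerase and the sequencer, and uneven per-template amplification that
  distorts clone quantification.

When each *sample* is labelled with a dual barcode pair (B5, B3) and each
*molecule* with a dual UMI pair attached before amplification, all three
can be removed computationally:

1. **Demultiplexing** — barcodes and primers are located at the read
   termini with a Levenshtein-distance threshold of 1; a read whose two
   barcodes belong to different samples is an inter-sample chimera and is
   removed during sample splitting.
2. **RPUP filtering** — reads are grouped by exact UMI pair and the
   reads-per-UMI-pair (RPUP) count histogram is formed. Genuine molecules
   are labelled before amplification and accumulate copies through every
   cycle; chimeras arise predominantly late, with a fresh
   (donor-UMI5, acceptor-UMI3) pair, and stay low-copy. The histogram is
   therefore bimodal and its **first low ebb** (first local minimum) is
   the cutoff: groups with RPUP below it are intra-sample chimeras.
3. **Consensus building** — within each retained UMI pair, reads are
   sub-clustered by exact CDR3 nucleotide sequence (guarding against UMI
   collisions); subgroups holding ≥ 30% of the group's reads (and ≥ 2
   reads) are kept, restricted to the modal sequence length, and reduced
   to a position-wise plurality consensus (any tied column discards the
   consensus). One consensus ≈ one input molecule, which also removes
   amplification bias from clone counts.

Downstream statistics operate on annotated sequences (IgBLAST-style TSV
with BTOP trace-backs, or the built-in edit-distance V/J assigner for
synthetic data): clonotypes keyed by (V gene, J gene, CDR3 nt), per-read
SHM from BTOP substitutions with primer-landing windows (first 25 bp /
last 8 bp) excluded, per-position mutation profiles and 4×4 mutation
patterns, V/J replacement rates, top-*k*-clone Jensen–Shannon distance
(base 2) and Morisita–Horn similarity between replicates,
C = 2Σxᵢyᵢ / ((Σxᵢ²/X² + Σyᵢ²/Y²)·X·Y), and per-sequence fold change
(reads before correction / retained UMI pairs containing the sequence).

For libraries built from *known* reference amplicons with embedded unique
barcode pairs, the `breakpoints` module identifies chimera parents from
the barcodes, bounds each template-switch position by first-mismatch scans
against both parents, and accumulates a positional / per-region (FR/CDR)
chimera-formation frequency profile.

The `simulate` module provides the ground truth for all of this: a
branching-process PCR with per-template Beta(20, 2) amplification
efficiencies, a logistic reagent plateau, saturation-scaled
homology-weighted template switching, per-cycle substitution errors, and
per-read sequencing errors — emitting FASTQ plus a truth table (parents,
chimera class, switch position, UMI pair, error count per read).

## Worked example

```python
from dumparts.experiments import run_default_study

result, truth, sim_stats = run_default_study(seed=1)
print(result.report["demux"]["status_counts"])
print(result.report["rpup"])
print("consensus sequences:", len(result.consensus))
```

Output:

```
{'assigned': 15185, 'inter_sample_chimera': 2628, 'unmatched_adapter': 187, 'merge_failed': 0}
{'threshold': 5, 'n_groups': 3176, 'n_kept_groups': 589, 'n_removed_groups': 2587, 'removed_read_fraction': 0.1837}
consensus sequences: 582
```

Reading this: of 18,000 simulated reads from a 4-sample pool of 600
labelled molecules, 14.8% carried mispaired barcodes (inter-sample
chimeras) and were removed at splitting. The RPUP histogram's first low
ebb sat at 5 reads; groups below it — late-arising chimeras plus
singleton groups created by sequencing errors inside a UMI — held 18.4%
of the assigned reads. The 589 retained UMI pairs yielded 582 consensus
sequences, close to the 600 molecules actually labelled. Against the
simulator's truth table this run retained 98.2% of genuine molecules'
groups and removed 100% of chimeric groups.

The same pipeline is available from the shell:

```bash
dumparts run-all --seed 1 --n-samples 4 --depth 18000 --out out/
dumparts simulate --seed 1 --out sim/           # FASTQ + truth.tsv + sheet
dumparts demux  --fastq sim/reads.fastq --sheet sim/sample_sheet.tsv --out dm/
dumparts filter --assignments dm/assignments.tsv --out flt/
```

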