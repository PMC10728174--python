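# imutseq

Analysis toolkit for **multiplexed amplicon deep sequencing of DNA
double-strand break (DSB) repair outcomes** — the experimental design in
which a panel of genomic loci around endonuclease-induced DSBs (e.g.
AsiSI sites in DIvA cells) is amplified in one multiplexed PCR and
sequenced to very high depth, so that substitutions, deletions,
insertions and translocations induced by DSB repair can be quantified at
single-nucleotide resolution, down to frequencies of roughly one event
in 200,000 reads.

The package covers the full computational path around such an assay:

- **Amplicon catalog** (`imutseq.amplicon_catalog`) — the multiplexed
  primer pool: per-locus primers, reference sequence, cut-site offset and
  repair-class label (HR-prone, NHEJ-prone, uncut control), with strict
  validation (primer/reference consistency, collision-free primers) and
  TSV/FASTA serialization. A synthetic 25-locus default panel
  (10 HR / 10 NHEJ / 5 uncut, 250–290 bp amplicons, central `GCGATCGC`
  cut motif, ≥100 bp primer-free flanks) ships with the package.
- **Synthetic sequencing** (`imutseq.synthetic_sequencing`) — a seeded
  generator of paired 150-base FASTQ reads and of samtools-dialect pileup
  text under a parameterized mutation spectrum (cut-peaked substitutions
  with ~20 bp exponential decay, break-adjacent deletions in three size
  classes, distant 1-bp slippage deletions at homopolymers, MMEJ
  deletions with 2–7 bp junction microhomology, rare insertions,
  translocation chimeras, uniform sequencing error), with a complete
  machine-readable truth table.
- **Translocation capture** (`imutseq.translocapture`) — alignment-free
  classification of read pairs by primer identity into *cis* (both
  primers from one locus), *trans* (primers from two loci: a
  translocation) or unmatched; emits a locus×locus translocation matrix
  and splits cis/trans pairs into separate FASTQ files. Also marker-based
  read partitioning (e.g. the corrected-eGFP sequence of a
  traffic-light-reporter HR assay).
- **Mutation caller** (`imutseq.mutation_caller`) — a symbol-exact parser
  for samtools-dialect pileup text producing per-position *mprofiles*
  (12 directional substitution counts, insertion events, deletion
  coverage, deletion events by size class) plus per-event deletion
  annotations: size class (1 bp / 2–5 bp / >5 bp), break adjacency,
  junction microhomology, MMEJ and slippage flags.
- **Mutation analysis** (`imutseq.mutation_analysis`) — per-nucleotide
  damaged−undamaged deltas, chained treatment−control deltas, cut-aligned
  metagene profiles, per-locus "per DSB" summaries, 6-class pyrimidine
  substitution signatures and translocation class-pair summaries.
- **Aligner tuner** (`imutseq.aligner_tuner`) — a seeded genetic
  algorithm (tournament selection, uniform crossover, domain-respecting
  mutation, elitism) over short-read aligner parameter spaces, with a
  pluggable alignment-efficiency fitness; the packaged default genome
  renders the tuned bowtie2 parameter string used for heavily mutated
  amplicon reads.
- **Pipeline** (`imutseq.pipeline`, `imutseq` CLI) — YAML-configured
  orchestration: transloc-filter → call → analyze, with provenance
  (config hash, seed) and per-stage counts.

## Worked example

```python
import imutseq as iq

pool = iq.default_pool()                       # 25-locus packaged panel
spec = iq.MutationSpectrum()                   # defaults: DSB-like rates

# simulate a damaged and an undamaged sample as pileups, depth 20,000
plus_lines, _ = iq.simulate_pileup(pool, spec, depth=20_000, seed=1)
minus_lines, _ = iq.simulate_pileup(pool, iq.MutationSpectrum.null(1e-3),
                                    depth=20_000, seed=2)

plus, anns = iq.pileup_to_profile(plus_lines, pool)
minus, _ = iq.pileup_to_profile(minus_lines, pool)

delta = iq.delta_profiles(plus, minus, min_depth=100)
hr = iq.metagene_profile(delta, pool, "HR", window=100)
print(round(hr["mean"].loc[0], 4), round(hr["mean"].loc[-90:-80].mean(), 4))
```

prints (seed-exact):

```
0.024 0.0044
```

i.e. the mean substitution delta across HR-prone loci is ~0.024 % per
read at the cut itself (the injected peak is 0.025 %, decaying with a
20 bp length scale) and close to zero 80–90 bp away — the cut-peaked
profile the simulation injects, recovered through the caller and the
damaged−undamaged delta. Translocations are classified directly
from FASTQ:

```python
r1, r2, truth = iq.simulate_sample(pool, iq.MutationSpectrum(transloc_rate=0.05),
                                   5_000, seed=3,
                                   r1_path="s.r1.fastq", r2_path="s.r2.fastq")
matrix, report = iq.scan_fastq("s.r1.fastq", "s.r2.fastq", pool)
print(report)
```

```
{'total': 5000, 'cis': 4748, 'trans': 250, 'unmatched': 2}
```

250/4998 classified pairs are trans — matching the injected 5 %
translocation propensity (the truth table records exactly 250 chimeric
pairs for this seed). The same operations are exposed on the
command line: `imutseq simulate | transloc | call | analyze | tune | run`.

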