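# Methods

## The assay this package models

A multiplexed genomic PCR amplifies a panel of loci centred on
endonuclease-induced double-strand breaks (DSBs); the pool of 250–290 bp
amplicons is sequenced paired-end 150 to very high depth. Because every
read pair carries its two amplification primers as 5' prefixes, two
orthogonal analyses follow without any special-purpose chemistry:

1. **Translocation capture.** A pair whose forward and reverse primers
   come from the same locus is a correctly repaired (cis) molecule; a
   pair whose primers come from two different loci can only arise from
   ligation of two distinct DSB ends — a translocation. Primer identity
   is decided by Hamming comparison of the read prefix against each
   primer (default tolerance 1 mismatch), so classification needs no
   alignment and is exact under the pool's collision-freeness invariant.
2. **Per-nucleotide mutation profiling.** After removing trans pairs,
   reads are aligned to the amplicon references and summarized as
   per-position pileup columns; the caller decodes these into counts of
   each substitution direction, insertion events, deletion events
   (anchored at their first deleted base) and deletion coverage. Every
   mutation rate is the percentage of reads at the position where the
   mutation occurs. Background (genomic SNVs, PCR and sequencing error)
   is removed by the per-nucleotide damaged−undamaged delta, and
   treatment effects by the chained delta
   (treat⁺ − treat⁻) − (ctrl⁺ − ctrl⁻). Deltas may be negative and are
   never floored.

The alignment and pileup generation steps themselves are wrapped external
engines, not reimplemented; everything upstream and downstream of them is
this package, and the pileup simulator provides an aligner-free path for
testing the calling and analysis chain end to end.

## The packaged amplicon panel

The default panel is synthetic (sequences are generated, not genomic) but
obeys the assay's design constraints: 25 loci — 10 HR-prone, 10
NHEJ-prone, 5 uncut controls — each 250–290 bp; cut loci carry a single
central AsiSI recognition site (GCGATCGC; the cut-site coordinate is the
midpoint of the motif, and the enzyme's 2-nt "TA" overhang is treated as
a repair-chemistry detail, not a coordinate offset); at least 100 bp of
primer-free sequence flanks the cut on both sides, so cut-relative
positions −100..+100 are always profiled; 20-mer primers are pairwise ≥6
Hamming mismatches apart, far beyond the classification radius. Each cut
locus additionally carries planted homopolymer runs (A₅ at −45, T₄ at
+40) so that distant-slippage modelling has guaranteed substrate. The
panel is built deterministically from a fixed seed and shipped as a TSV;
`imutseq._fixture.build_default_pool()` regenerates it byte-identically.

## The mutation spectrum (synthetic data generator)

`MutationSpectrum` parameterizes a generative model of DSB repair
outcomes. Defaults were chosen once to emulate the order of magnitude of
observed per-DSB mutation rates in this assay class (~1 % substitutions,
~0.27 % deletions, ~0.05 % insertions, ~0.01 % translocations per DSB)
and the qualitative spatial structure of the profiles:

| parameter | default | meaning |
|---|---|---|
| `sub_rate_peak` | 2.5×10⁻⁴ | per-read, per-position substitution probability at the cut |
| `sub_decay_bp` | 20 bp | exponential decay length of substitutions from the cut |
| `sub_floor` | 0 | optional distant substitution floor |
| `sub_signature` | C>T 0.35, C>G 0.20, C>A 0.15, T>C 0.12, T>G 0.10, T>A 0.08 | 6-class pyrimidine-collapsed change weights (C>T-dominant) |
| `del_small/mid/large_rate` | 8×10⁻⁴ / 9.4×10⁻⁴ / 1.7×10⁻³ | per-read probability of break-adjacent 1 bp / 2–5 bp / 6–20 bp deletions |
| `distant_slip_rate` | 1.4×10⁻³ | per-read 1-bp deletion at a homopolymer run (≥3) further than `adjacency_bp` from the cut |
| `mmej_rate` | 6.8×10⁻⁴ | per-read large deletion spanning the cut whose junction carries 2–7 bp microhomology (≤70 bp) |
| `ins_rate` | 5×10⁻⁴ | per-read insertion (1–3 bp at the cut) |
| `transloc_rate` | 10⁻⁴ | per-pair chimeric (trans) emission probability |
| `seq_error_rate` | 10⁻³ | per-base uniform substitution error |

Translocation partner pairs are drawn from an unordered locus-pair weight
table; the default table weights HR–HR pairs 15×, HR–NHEJ 2× and
NHEJ–NHEJ 1× (uncut loci excluded), reflecting the strong HR-locus bias
of observed translocation maps. Reads are fixed at 150 bases with
constant Q30 qualities; at most one repair event is injected per cis
pair, which keeps truth-table diffing unambiguous. Substitution events
are placed with probability proportional to the exponential profile and
their alternate base drawn from the signature, purine references handled
by reverse-complement collapse.

The FASTQ generator is read-level; the pileup generator is count-level —
alternate counts at each position are drawn binomially from the
spectrum-implied probabilities, deletion events are drawn per
anchor/length and re-encoded as `-N<seq>` plus `*` coverage exactly as
the samtools dialect prescribes. Both are deterministic given (pool,
spectrum, size, seed).

**What the generator does not model:** PCR duplicates and chimeras other
than translocation chimeras, base-quality-dependent error, strand bias,
enzyme re-cutting, sister-chromatid effects and cell-cycle structure.
Passing recovery tests therefore demonstrate correctness of the
classification/calling/delta arithmetic under a faithful dialect, not
robustness to every real-data artifact; in a real experiment those
artifacts are exactly what the ±DSB delta is designed to cancel.

## Numerical and design choices

- **Coordinates.** 0-based, half-open everywhere internally; the pileup
  parser converts from the dialect's 1-based positions at its boundary.
- **Deletion rate vs events.** The per-position deletion *rate* uses
  deletion coverage (`*` symbols), matching the per-position percentage
  convention; size-class quantification uses anchored events so each
  deletion counts once. Both are emitted.
- **Microhomology.** For a deletion `[s, e)` the junction microhomology
  is the largest k ≤ min(e−s, len(ref)−e) with `ref[s:s+k] == ref[e:e+k]`.
  The cap at the deletion length matters: homology that survives the
  deletion on both flanks cannot exceed what was deleted. MMEJ is flagged
  for large-class deletions with microhomology ≥2 (the observed 2–7 bp
  band is reported but not enforced as a ceiling, to avoid excluding
  longer accidental homologies from inspection); slippage is flagged for
  ≤2 bp deletions inside homopolymer runs ≥3.
- **Adjacency.** "Break-adjacent" defaults to |cut-relative distance|
  ≤ 10 bp (configurable); the literature contrasts adjacent and distant
  events without a printed threshold, and 10 bp separates the deletion
  anchor zone from the slippage zone cleanly in this model.
- **Rate emission.** Positions with depth < `min_depth` (default 100)
  are reported as missing rather than as noisy rates; missingness
  propagates through deltas.
- **Translocation rate denominator.** trans(i,j) counts divided by total
  classified (cis+trans) pairs, reported per unordered pair by summing
  (i,j)+(j,i). This denominator is self-normalizing and monotone in the
  underlying propensity; per-locus and per-total-read alternatives can be
  derived from the emitted counts matrix.
- **Pairs with two forward (or two reverse) primers** have no valid
  amplicon structure and are counted unmatched, not trans.
- **"Per DSB" totals** are sums of per-position percent rates over the
  ±100 bp window (uncut controls: the primer-free interior) — the only
  reading that makes per-DSB totals commensurate across mutation types;
  a per-position mean is available via `aggregate="mean"`. Metagene means
  are unweighted across loci.
- **GA defaults.** Population 24, 30 generations, tournament 3, crossover
  0.7, per-gene mutation 0.1, 2 elites, seed mandatory. Real-valued genes
  mutate by Gaussian steps with σ = 10 % of the domain, clipped; integer
  genes take discrete Gaussian steps of at least 1; categorical and flag
  genes resample. Elitism guarantees a monotone best-so-far trajectory.
  The alignment-efficiency fitness (concordant-pair fraction parsed from
  the aligner summary) requires the external aligner and is optional;
  the optimizer itself is exercised with synthetic fitness functions.

## Problem sizes used in the automated checks

The shipped test suite and acceptance script run at desk scale, chosen as
the smallest sizes at which the statistical assertions have comfortable
power: sensitivity-floor recovery pools 50 replicates at per-position
depth 5×10⁶ (≈1,250 expected events, so the pooled estimate has ≈2.8 %
relative standard error against a ±10 % acceptance band); end-to-end
±DSB parameter recovery uses a 6-locus slice of the panel at depth 10⁵
per position over 10 seeds with 99 % binomial intervals; translocation
spike-in recovery uses 2×10⁵ read pairs. Headline biological rates from
real deposited data are not reproduction targets: they depend on cutting
efficiency, cell-state structure and PCR amplification that the generator
deliberately does not model.

## Known limitations

- Primer matching is prefix-anchored; primers truncated by severe
  adapter read-through would be missed (such pairs become unmatched).
- The caller ignores base qualities and strand (strand is collapsed into
  one count); strand-bias diagnostics are out of scope.
- Breakpoint-resolution junction mapping inside trans reads, inversions
  and same-locus rearrangements are not attempted — trans evidence is
  primer identity only.
- The pileup parser accepts the six-column samtools dialect including
  `^X $ +N -N * < >`; extended columns (mapping-quality field lists) are
  ignored beyond column six.
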