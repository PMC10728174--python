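"""Deterministic construction of the packaged default amplicon panel.

The shipped ``data/default_pool.tsv`` is the output of
:func:`build_default_pool` and is synthetic: the sequences are generated,
not taken from a genome, but the panel obeys every design constraint of
the assay — 25 loci (10 HR-prone, 10 NHEJ-prone, 5 uncut controls),
amplicons of 250-290 bp, a central AsiSI recognition site (GCGATCGC) at
cut loci whose midpoint has at least 100 bp of primer-free sequence on
both sides, guaranteed homopolymer runs in the flanks (slippage substrate),
and 20-mer primers that are pairwise far apart in Hamming distance.
"""

from __future__ import annotations

import numpy as np

from .amplicon_catalog import AmpliconLocus, PrimerPool
from .dna import ASISI_SITE, hamming, revcomp

_BASES = np.array(list("ACGT"))
_FIXTURE_SEED = 411259  # fixed: the panel is part of the package, not a dial
_PRIMER_LEN = 20
_MIN_PRIMER_DIST = 6  # >> 2*max_mismatch+1; classification stays unambiguous


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, n)])


def _build_locus_seq(rng: np.random.Generator, length: int, cut: bool) -> tuple[str, int | None]:
    """One amplicon sequence; returns (seq, cut_offset or None)."""
    while True:
        seq = _random_seq(rng, length)
        if cut:
            # centre the AsiSI site; cut_offset = midpoint of the 8-mer
            motif_start = length // 2 - len(ASISI_SITE) // 2
            seq = seq[:motif_start] + ASISI_SITE + seq[motif_start + len(ASISI_SITE) :]
            cut_offset = motif_start + len(ASISI_SITE) // 2
            # guaranteed distant homopolymer runs for slippage modelling
            for rel, run in ((-45, "AAAAA"), (40, "TTTT")):
                p = cut_offset + rel
                seq = seq[:p] + run + seq[p + len(run) :]
            if seq.count(ASISI_SITE) != 1:
                continue
            if cut_offset - _PRIMER_LEN < 100 or length - _PRIMER_LEN - cut_offset < 100:
                continue
            return seq, cut_offset
        if ASISI_SITE in seq:
            continue
        return seq, None


def build_default_pool(seed: int = _FIXTURE_SEED) -> PrimerPool:
    """Construct the default 25-locus panel deterministically."""
    rng = np.random.default_rng(seed)
    plan = [("HR", 10), ("NHEJ", 10), ("UNCUT", 5)]
    loci: list[AmpliconLocus] = []
    primers: list[str] = []
    chrom_cycle = [f"chr{c}" for c in (1, 2, 5, 6, 9, 13, 17, 18, 20, 21, 22, "X")]
    counter = 0
    for repair_class, n in plan:
        for i in range(n):
            while True:
                length = int(rng.integers(250, 291))
                seq, cut_offset = _build_locus_seq(rng, length, repair_class != "UNCUT")
                fwd = seq[:_PRIMER_LEN]
                rev = revcomp(seq[-_PRIMER_LEN:])
                if any(hamming(p, q) < _MIN_PRIMER_DIST for q in primers for p in (fwd, rev)):
                    continue
                if hamming(fwd, rev) < _MIN_PRIMER_DIST:
                    continue
                break
            primers.extend([fwd, rev])
            start = 1_000_000 + 50_000 * counter
            loci.append(
                AmpliconLocus(
                    locus_id=f"{repair_class}{i + 1:02d}",
                    repair_class=repair_class,
                    chrom=chrom_cycle[counter % len(chrom_cycle)],
                    start=start,
                    end=start + length,
                    cut_offset=cut_offset,
                    fwd_primer=fwd,
                    rev_primer=rev,
                    ref_seq=seq,
                )
            )
            counter += 1
    return PrimerPool(loci, max_mismatch=1)
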