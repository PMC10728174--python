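"""Sensitivity-floor recovery: how low a mutation rate the caller resolves.

The assay's detection floor is depth-limited: at a per-position depth of
several million reads, individual substitutions occurring in 1 of 200,000
reads are still recovered.  :func:`recover_floor_frequency` simulates
exactly that regime — binomial alternate counts at a fixed true
frequency, emitted as pileup text and recovered through the mutation
caller — and reports the pooled recovered frequency as "1 in N" reads.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .amplicon_catalog import PrimerPool, default_pool
from .mutation_caller import SUB_DIRECTIONS, pileup_to_profile

FLOOR_ONE_IN = 200_000  # detection floor: one event per this many reads


def recover_floor_frequency(
    seed: int,
    true_one_in: int = FLOOR_ONE_IN,
    depth: int = 5_000_000,
    n_replicates: int = 50,
    pool: Optional[PrimerPool] = None,
) -> dict:
    """Recover a substitution frequency at the detection floor.

    For each seeded replicate, draws a binomial alternate count at the
    given per-position depth and true frequency ``1/true_one_in``, writes
    one samtools-dialect pileup column, runs the mutation caller on it,
    and pools the recovered alternate counts over replicates.

    Returns a dict with the depth-weighted recovered frequency, its
    "1 in N" form, and the pooled counts.
    """
    pool = pool or default_pool()
    locus = pool.cut_loci[0]
    x = locus.cut_offset  # any interior position works; the cut is central
    ref_base = locus.ref_seq[x]
    alt = {"A": "T", "C": "A", "G": "C", "T": "G"}[ref_base]
    p_true = 1.0 / true_one_in

    rng = np.random.default_rng(seed)
    total_alt = 0
    total_depth = 0
    sub_cols = [f"sub_{c}" for c in SUB_DIRECTIONS]
    for _ in range(n_replicates):
        k = int(rng.binomial(depth, p_true))
        bases = "." * (depth - k) + alt * k
        line = f"{locus.locus_id}\t{x + 1}\t{ref_base}\t{depth}\t{bases}\t{'I' * depth}"
        profile, _ = pileup_to_profile([line], pool)
        row = profile.counts.loc[(locus.locus_id, x)]
        total_alt += int(sum(row[c] for c in SUB_DIRECTIONS))
        total_depth += int(row["depth"])

    recovered_p = total_alt / total_depth if total_depth else 0.0
    return {
        "recovered_frequency": recovered_p,
        "one_in_n": (1.0 / recovered_p) if recovered_p > 0 else float("inf"),
        "total_alt": total_alt,
        "total_depth": total_depth,
        "true_one_in": true_one_in,
    }
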