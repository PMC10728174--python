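"""Primer-identity classification of read pairs: cis, trans, unmatched.

In a multiplexed amplicon experiment every read pair was created by one
forward and one reverse primer.  A pair whose two primers belong to the
same locus is a correctly repaired (cis) amplicon; a pair whose primers
belong to two different loci evidences a ligation of two distinct DSB
ends — a translocation.  Classification needs no alignment: the primer
sequence is the 5' prefix of each mate.

:func:`scan_fastq` streams synchronized FASTQ mates, fills a
locus-by-locus :class:`TranslocationMatrix` (diagonal = cis) and writes
cis and trans pairs to separate FASTQ files so translocated molecules can
be removed before alignment.  :func:`partition_by_marker` splits pairs on
the presence of a marker subsequence (e.g. a repair-template-corrected
eGFP sequence), used to separate HR-repaired reads in reporter assays.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Optional

import numpy as np
import pandas as pd
import pysam

from .amplicon_catalog import PrimerPool
from .dna import revcomp
from .errors import DomainError, FormatError, PoolConsistencyError


@dataclass(frozen=True)
class ReadOrigin:
    """Classification of one read pair by primer identity."""

    status: str  # "cis" | "trans" | "unmatched"
    locus_fwd: Optional[str] = None
    locus_rev: Optional[str] = None

    def __post_init__(self) -> None:
        if self.status == "cis":
            assert self.locus_fwd is not None and self.locus_fwd == self.locus_rev
        elif self.status == "trans":
            assert self.locus_fwd is not None and self.locus_rev is not None
            assert self.locus_fwd != self.locus_rev
        elif self.status == "unmatched":
            assert self.locus_fwd is None or self.locus_rev is None
        else:
            raise DomainError(f"unknown status {self.status!r}")


_PREFIX_CACHE: dict = {}


def _prefix_index(pool: PrimerPool) -> dict:
    """Exact-prefix lookup tables, one per distinct effective primer length."""
    key = id(pool)
    cached = _PREFIX_CACHE.get(key)
    if cached is None:
        tables: dict[int, dict[str, tuple[str, str]]] = {}
        for locus_id, side, primer in pool.primers():
            n = len(primer) if pool.match_len is None else min(pool.match_len, len(primer))
            tables.setdefault(n, {})[primer[:n]] = (locus_id, side)
        _PREFIX_CACHE[key] = cached = tables
    return cached


def match_primer(
    seq: str, pool: PrimerPool, max_mismatch: Optional[int] = None
) -> Optional[tuple[str, str]]:
    """Match the 5' prefix of ``seq`` against every primer in the pool.

    Returns the unique ``(locus_id, side)`` whose primer matches with at
    most ``max_mismatch`` Hamming mismatches (side in {"fwd", "rev"}), or
    None if nothing matches.  Two simultaneous matches indicate a pool
    whose collision invariant is broken and raise
    :class:`PoolConsistencyError`.
    """
    if max_mismatch is None:
        max_mismatch = pool.max_mismatch
    seq = seq.upper()
    # fast path: an exact prefix hit is unique for a validated pool (any
    # second primer within max_mismatch of the read would collide with it)
    for n, index in _prefix_index(pool).items():
        hit = index.get(seq[:n])
        if hit is not None:
            return hit
    hits = []
    for locus_id, side, primer in pool.primers():
        n = len(primer) if pool.match_len is None else min(pool.match_len, len(primer))
        if len(seq) < n:
            continue
        prefix = seq[:n]
        mism = 0
        for a, b in zip(prefix, primer[:n]):
            if a != b:
                mism += 1
                if mism > max_mismatch:
                    break
        if mism <= max_mismatch:
            hits.append((locus_id, side))
    if not hits:
        return None
    if len(hits) > 1:
        raise PoolConsistencyError(
            f"read prefix matched multiple primers within {max_mismatch} mismatches: {hits}"
        )
    return hits[0]


def classify_read_pair(
    r1_seq: str, r2_seq: str, pool: PrimerPool, max_mismatch: Optional[int] = None
) -> ReadOrigin:
    """Classify one pair; tries (fwd on R1, rev on R2), then swapped.

    Pairs matching two forward or two reverse primers have no valid
    amplicon structure (primer-dimer-like artifacts) and are counted
    unmatched, not trans.
    """
    m1 = match_primer(r1_seq, pool, max_mismatch)
    m2 = match_primer(r2_seq, pool, max_mismatch)
    if m1 is None or m2 is None:
        return ReadOrigin("unmatched", m1 and m1[0], m2 and m2[0])
    (id1, side1), (id2, side2) = m1, m2
    if side1 == "fwd" and side2 == "rev":
        fwd_id, rev_id = id1, id2
    elif side1 == "rev" and side2 == "fwd":
        fwd_id, rev_id = id2, id1
    else:
        return ReadOrigin("unmatched", None, None)
    if fwd_id == rev_id:
        return ReadOrigin("cis", fwd_id, rev_id)
    return ReadOrigin("trans", fwd_id, rev_id)


@dataclass
class TranslocationMatrix:
    """Locus-by-locus read-pair counts; the diagonal holds cis pairs."""

    locus_ids: list[str]
    counts: np.ndarray  # square, ordered (fwd locus, rev locus)

    @classmethod
    def zeros(cls, locus_ids: list[str]) -> "TranslocationMatrix":
        n = len(locus_ids)
        return cls(list(locus_ids), np.zeros((n, n), dtype=np.int64))

    @property
    def total_classified(self) -> int:
        return int(self.counts.sum())

    @property
    def rates(self) -> np.ndarray:
        """Counts normalized by total classified (cis + trans) pairs."""
        total = self.total_classified
        if total == 0:
            return np.zeros_like(self.counts, dtype=float)
        return self.counts / total

    def add(self, fwd_id: str, rev_id: str, n: int = 1) -> None:
        i = self.locus_ids.index(fwd_id)
        j = self.locus_ids.index(rev_id)
        self.counts[i, j] += n

    def trans_total(self) -> int:
        return int(self.counts.sum() - np.trace(self.counts))

    def unordered_pair_rates(self) -> pd.DataFrame:
        """Per unordered locus pair: counts (i,j)+(j,i) over total classified."""
        total = self.total_classified
        rows = []
        for i, a in enumerate(self.locus_ids):
            for j in range(i + 1, len(self.locus_ids)):
                b = self.locus_ids[j]
                c = int(self.counts[i, j] + self.counts[j, i])
                rows.append((a, b, c, c / total if total else 0.0))
        return pd.DataFrame(rows, columns=["locus_a", "locus_b", "count", "rate"])

    def counts_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.locus_ids, columns=self.locus_ids)

    def rates_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rates, index=self.locus_ids, columns=self.locus_ids)

    def to_csv(self, counts_path: str | Path, rates_path: Optional[str | Path] = None) -> None:
        self.counts_frame().to_csv(counts_path)
        if rates_path is not None:
            self.rates_frame().to_csv(rates_path)

    @classmethod
    def from_csv(cls, counts_path: str | Path) -> "TranslocationMatrix":
        df = pd.read_csv(counts_path, index_col=0)
        return cls(list(df.index), df.to_numpy(dtype=np.int64))


def _fastq_pairs(r1_path: str | Path, r2_path: str | Path) -> Iterator[tuple]:
    """Yield synchronized mate records, raising FormatError on desync."""
    with pysam.FastxFile(str(r1_path)) as f1, pysam.FastxFile(str(r2_path)) as f2:
        idx = 0
        it1, it2 = iter(f1), iter(f2)
        while True:
            rec1 = next(it1, None)
            rec2 = next(it2, None)
            if rec1 is None and rec2 is None:
                return
            if rec1 is None or rec2 is None:
                raise FormatError(f"FASTQ mates desynchronized: record {idx} missing in one file")
            n1 = rec1.name.split("/")[0]
            n2 = rec2.name.split("/")[0]
            if n1 != n2:
                raise FormatError(
                    f"FASTQ mates desynchronized at record {idx}: {n1!r} != {n2!r}"
                )
            yield rec1, rec2
            idx += 1


def _open_out(path: Optional[str | Path]):
    if path is None:
        return None
    path = Path(path)
    return gzip.open(path, "wt") if path.suffix == ".gz" else open(path, "w")


def scan_fastq(
    r1_path: str | Path,
    r2_path: str | Path,
    pool: PrimerPool,
    max_mismatch: Optional[int] = None,
    out_prefix: Optional[str | Path] = None,
) -> tuple[TranslocationMatrix, dict]:
    """Stream paired FASTQ files, classify every pair exactly once.

    Returns the translocation matrix and a report dict with per-status
    totals.  With ``out_prefix``, cis pairs go to ``<prefix>.cis.r1/r2.fastq``
    and trans pairs to ``<prefix>.trans.r1/r2.fastq``.  Memory is bounded:
    pairs are processed one at a time.
    """
    matrix = TranslocationMatrix.zeros(pool.locus_ids)
    report = {"total": 0, "cis": 0, "trans": 0, "unmatched": 0}
    outs = {}
    if out_prefix is not None:
        prefix = str(out_prefix)
        outs = {
            ("cis", 1): _open_out(f"{prefix}.cis.r1.fastq"),
            ("cis", 2): _open_out(f"{prefix}.cis.r2.fastq"),
            ("trans", 1): _open_out(f"{prefix}.trans.r1.fastq"),
            ("trans", 2): _open_out(f"{prefix}.trans.r2.fastq"),
        }
    try:
        for rec1, rec2 in _fastq_pairs(r1_path, r2_path):
            origin = classify_read_pair(rec1.sequence, rec2.sequence, pool, max_mismatch)
            report["total"] += 1
            report[origin.status] += 1
            if origin.status in ("cis", "trans"):
                matrix.add(origin.locus_fwd, origin.locus_rev)
                if outs:
                    for mate, rec in ((1, rec1), (2, rec2)):
                        fh = outs[(origin.status, mate)]
                        qual = rec.quality or "I" * len(rec.sequence)
                        fh.write(f"@{rec.name}\n{rec.sequence}\n+\n{qual}\n")
    finally:
        for fh in outs.values():
            if fh is not None:
                fh.close()
    return matrix, report


def partition_by_marker(
    r1_path: str | Path,
    r2_path: str | Path,
    marker: str,
    out_prefix: Optional[str | Path] = None,
) -> dict:
    """Split read pairs on presence of a marker subsequence.

    A pair is positive iff either mate contains ``marker`` or its reverse
    complement as an exact substring.  With ``out_prefix``, positive pairs
    are written to ``<prefix>.pos.r1/r2.fastq`` and negatives to
    ``<prefix>.neg.r1/r2.fastq``.  Returns counts.
    """
    if not marker:
        raise DomainError("marker must be non-empty")
    marker = marker.upper()
    rc = revcomp(marker)
    counts = {"total": 0, "positive": 0, "negative": 0}
    outs = {}
    if out_prefix is not None:
        prefix = str(out_prefix)
        outs = {
            ("positive", 1): _open_out(f"{prefix}.pos.r1.fastq"),
            ("positive", 2): _open_out(f"{prefix}.pos.r2.fastq"),
            ("negative", 1): _open_out(f"{prefix}.neg.r1.fastq"),
            ("negative", 2): _open_out(f"{prefix}.neg.r2.fastq"),
        }
    try:
        for rec1, rec2 in _fastq_pairs(r1_path, r2_path):
            s1, s2 = rec1.sequence.upper(), rec2.sequence.upper()
            pos = any(m in s for m in (marker, rc) for s in (s1, s2))
            status = "positive" if pos else "negative"
            counts["total"] += 1
            counts[status] += 1
            if outs:
                for mate, rec in ((1, rec1), (2, rec2)):
                    qual = rec.quality or "I" * len(rec.sequence)
                    outs[(status, mate)].write(
                        f"@{rec.name}\n{rec.sequence}\n+\n{qual}\n"
                    )
    finally:
        for fh in outs.values():
            if fh is not None:
                fh.close()
    return counts
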