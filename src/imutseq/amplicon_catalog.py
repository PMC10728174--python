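"""The multiplexed primer pool: amplicon loci, validation, and serialization.

An iMUT-seq style experiment amplifies a panel of genomic loci around
endonuclease-induced double-strand breaks (DSBs) in a single multiplexed
PCR.  Each :class:`AmpliconLocus` records the two amplification primers,
the full amplicon reference sequence, and — for cut loci — the offset of
the cut midpoint, so downstream profiles can be expressed in cut-relative
coordinates.  The packaged default panel has 25 loci: 10 HR-prone,
10 NHEJ-prone and 5 uncut controls, each ~250-290 bp with the cut site
central enough that at least 100 bp of primer-free sequence flanks it on
both sides.

Internal coordinates are 0-based, half-open throughout the package; the
pileup parser converts from the 1-based pileup convention at its boundary.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional

from .dna import hamming, revcomp
from .errors import DomainError, FormatError, PoolValidationError

POOL_COLUMNS = [
    "locus_id",
    "repair_class",
    "chrom",
    "start",
    "end",
    "cut_offset",
    "fwd_primer",
    "rev_primer",
    "ref_seq",
]

REPAIR_CLASSES = ("HR", "NHEJ", "UNCUT")


@dataclass(frozen=True)
class AmpliconLocus:
    """One multiplexed PCR target.

    ``cut_offset`` is the 0-based offset, from the amplicon start, of the
    first base 3' of the cut midpoint; it is ``None`` for uncut controls.
    ``rev_primer`` is given 5'->3' on the opposite strand, so the amplicon
    ends with its reverse complement.
    """

    locus_id: str
    repair_class: str
    chrom: str
    start: int
    end: int
    fwd_primer: str
    rev_primer: str
    ref_seq: str
    cut_offset: Optional[int] = None

    def __post_init__(self) -> None:
        if self.repair_class not in REPAIR_CLASSES:
            raise PoolValidationError(
                f"{self.locus_id}: repair_class {self.repair_class!r} not in {REPAIR_CLASSES}"
            )
        if len(self.ref_seq) != self.end - self.start:
            raise PoolValidationError(
                f"{self.locus_id}: len(ref_seq)={len(self.ref_seq)} != end-start={self.end - self.start}"
            )
        if not self.ref_seq.startswith(self.fwd_primer):
            raise PoolValidationError(
                f"{self.locus_id}: ref_seq does not start with fwd_primer"
            )
        if not self.ref_seq.endswith(revcomp(self.rev_primer)):
            raise PoolValidationError(
                f"{self.locus_id}: ref_seq does not end with reverse-complement(rev_primer)"
            )
        if (self.repair_class == "UNCUT") != (self.cut_offset is None):
            raise PoolValidationError(
                f"{self.locus_id}: cut_offset must be absent iff repair_class is UNCUT"
            )
        if self.cut_offset is not None and not (0 <= self.cut_offset < len(self.ref_seq)):
            raise PoolValidationError(
                f"{self.locus_id}: cut_offset {self.cut_offset} outside amplicon"
            )

    def __len__(self) -> int:
        return len(self.ref_seq)

    @property
    def is_cut(self) -> bool:
        return self.cut_offset is not None

    def to_cut_relative(self, abs_pos: int) -> int:
        """Signed position relative to the cut midpoint.

        Negative = upstream of the cut; 0 = first base 3' of the cut
        midpoint.  Raises :class:`DomainError` for uncut control loci.
        """
        if self.cut_offset is None:
            raise DomainError(f"{self.locus_id}: UNCUT locus has no cut-relative frame")
        if not (0 <= abs_pos < len(self.ref_seq)):
            raise DomainError(
                f"{self.locus_id}: position {abs_pos} outside amplicon [0,{len(self.ref_seq)})"
            )
        return abs_pos - self.cut_offset

    def interior(self) -> tuple[int, int]:
        """[start, end) of the primer-free interior of the amplicon."""
        return len(self.fwd_primer), len(self.ref_seq) - len(self.rev_primer)


def to_cut_relative(locus: AmpliconLocus, abs_pos: int) -> int:
    """Module-level alias for :meth:`AmpliconLocus.to_cut_relative`."""
    return locus.to_cut_relative(abs_pos)


@dataclass
class PrimerPool:
    """An ordered, collision-free collection of amplicon loci.

    ``max_mismatch`` is the number of mismatches tolerated when matching a
    read prefix against a primer (default 1: one sequencing error).  Pool
    validation requires that no two primers are within ``max_mismatch``
    Hamming mismatches of each other over ``match_len`` bases, so primer
    classification is unambiguous.
    """

    loci: list[AmpliconLocus]
    match_len: Optional[int] = None  # None = full primer length
    max_mismatch: int = 1
    _index: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.validate()
        self._index = {loc.locus_id: loc for loc in self.loci}

    def __len__(self) -> int:
        return len(self.loci)

    def __iter__(self) -> Iterator[AmpliconLocus]:
        return iter(self.loci)

    def __getitem__(self, locus_id: str) -> AmpliconLocus:
        return self._index[locus_id]

    def __contains__(self, locus_id: str) -> bool:
        return locus_id in self._index

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PrimerPool):
            return NotImplemented
        return (
            self.loci == other.loci
            and self.match_len == other.match_len
            and self.max_mismatch == other.max_mismatch
        )

    @property
    def locus_ids(self) -> list[str]:
        return [loc.locus_id for loc in self.loci]

    def by_class(self, repair_class: str) -> list[AmpliconLocus]:
        return [loc for loc in self.loci if loc.repair_class == repair_class]

    @property
    def cut_loci(self) -> list[AmpliconLocus]:
        return [loc for loc in self.loci if loc.is_cut]

    def primers(self) -> list[tuple[str, str, str]]:
        """All (locus_id, side, primer) triples, pool order, fwd before rev."""
        out = []
        for loc in self.loci:
            out.append((loc.locus_id, "fwd", loc.fwd_primer))
            out.append((loc.locus_id, "rev", loc.rev_primer))
        return out

    def primer_collisions(self) -> list[tuple[str, str, str, str, int]]:
        """All-pairs primer comparison over ``match_len`` bases.

        Returns (locus_a, side_a, locus_b, side_b, distance) for every pair
        whose truncated primers are within ``max_mismatch`` of each other.
        """
        prims = self.primers()
        bad = []
        for i in range(len(prims)):
            for j in range(i + 1, len(prims)):
                ida, sa, pa = prims[i]
                idb, sb, pb = prims[j]
                n = min(len(pa), len(pb))
                if self.match_len is not None:
                    n = min(n, self.match_len)
                d = hamming(pa[:n], pb[:n])
                if d <= self.max_mismatch:
                    bad.append((ida, sa, idb, sb, d))
        return bad

    def validate(self) -> None:
        ids = [loc.locus_id for loc in self.loci]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise PoolValidationError(f"duplicate locus_id(s): {sorted(dupes)}")
        collisions = self.primer_collisions()
        if collisions:
            a, sa, b, sb, d = collisions[0]
            raise PoolValidationError(
                f"primer collision: {a}/{sa} within {d} mismatches of {b}/{sb} "
                f"(max_mismatch={self.max_mismatch})"
            )


def load_primer_pool(
    path: str | Path, match_len: Optional[int] = None, max_mismatch: int = 1
) -> PrimerPool:
    """Load and validate a primer-pool TSV.

    The TSV must carry exactly the header columns ``locus_id, repair_class,
    chrom, start, end, cut_offset, fwd_primer, rev_primer, ref_seq``;
    ``cut_offset`` is empty for UNCUT control loci.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header_line = fh.readline().rstrip("\n")
        if not header_line:
            raise FormatError(f"{path}: empty file, expected a header line")
        header = header_line.split("\t")
        missing = [c for c in POOL_COLUMNS if c not in header]
        if missing:
            raise FormatError(f"{path}: missing column(s) {missing}")
        col = {c: header.index(c) for c in POOL_COLUMNS}
        loci = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != len(header):
                raise FormatError(f"{path}:{lineno}: expected {len(header)} fields, got {len(fields)}")
            raw_cut = fields[col["cut_offset"]]
            loci.append(
                AmpliconLocus(
                    locus_id=fields[col["locus_id"]],
                    repair_class=fields[col["repair_class"]],
                    chrom=fields[col["chrom"]],
                    start=int(fields[col["start"]]),
                    end=int(fields[col["end"]]),
                    cut_offset=int(raw_cut) if raw_cut != "" else None,
                    fwd_primer=fields[col["fwd_primer"]],
                    rev_primer=fields[col["rev_primer"]],
                    ref_seq=fields[col["ref_seq"]],
                )
            )
    return PrimerPool(loci, match_len=match_len, max_mismatch=max_mismatch)


def write_primer_pool(pool: PrimerPool, path: str | Path) -> None:
    """Serialize a pool back to the TSV format read by :func:`load_primer_pool`."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(POOL_COLUMNS) + "\n")
        for loc in pool:
            cut = "" if loc.cut_offset is None else str(loc.cut_offset)
            fh.write(
                "\t".join(
                    [
                        loc.locus_id,
                        loc.repair_class,
                        loc.chrom,
                        str(loc.start),
                        str(loc.end),
                        cut,
                        loc.fwd_primer,
                        loc.rev_primer,
                        loc.ref_seq,
                    ]
                )
                + "\n"
            )


def write_reference_fasta(pool: PrimerPool, path: str | Path, width: int = 80) -> None:
    """Write one FASTA record per locus (header = locus_id, 80-col wrapping)."""
    with open(path, "w", encoding="utf-8") as fh:
        for loc in pool:
            fh.write(f">{loc.locus_id}\n")
            for i in range(0, len(loc.ref_seq), width):
                fh.write(loc.ref_seq[i : i + width] + "\n")


def default_pool_path() -> Path:
    """Path of the packaged 25-locus default panel TSV."""
    return Path(importlib.resources.files("imutseq") / "data" / "default_pool.tsv")


def default_pool(max_mismatch: int = 1) -> PrimerPool:
    """Load the packaged default 25-locus panel (10 HR / 10 NHEJ / 5 UNCUT).

    The panel is synthetic: sequences are generated, not genomic, but obey
    the design constraints of the assay (250-290 bp amplicons, central
    AsiSI site GCGATCGC at cut loci, >= 100 bp primer-free flank on each
    side of the cut, collision-free 20-mer primers).
    """
    return load_primer_pool(default_pool_path(), max_mismatch=max_mismatch)


def subset_pool(pool: PrimerPool, locus_ids: Iterable[str]) -> PrimerPool:
    """A new pool containing only the named loci, in pool order."""
    wanted = set(locus_ids)
    unknown = wanted - set(pool.locus_ids)
    if unknown:
        raise DomainError(f"unknown locus id(s): {sorted(unknown)}")
    return PrimerPool(
        [loc for loc in pool if loc.locus_id in wanted],
        match_len=pool.match_len,
        max_mismatch=pool.max_mismatch,
    )
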