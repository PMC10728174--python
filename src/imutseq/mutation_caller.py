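"""Pileup parsing and per-nucleotide mutation profiling.

Parses samtools-dialect pileup text into an :class:`MProfile` — per
(locus, position) depth, 12 directional substitution counts, insertion
event counts, deletion coverage (``*`` symbols) and deletion events by
size class — and annotates each distinct deletion with its size class,
break adjacency and junction microhomology.

Rates follow the per-position convention: every mutation is expressed as
a percentage of the reads covering the position at which it occurs.  The
per-position deletion *rate* uses deletion coverage (a 3-bp deletion
contributes to three positions), while event-level classification uses
the ``-N`` anchor (each deletion counted once).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Optional, Union

import numpy as np
import pandas as pd

from .amplicon_catalog import AmpliconLocus, PrimerPool
from .dna import in_homopolymer
from .errors import DomainError, FormatError, PoolValidationError

SUB_DIRECTIONS = [
    f"{r}to{a}" for r in "ACGT" for a in "ACGT" if r != a
]  # 12 directional substitution columns

_INDEL_RE = re.compile(r"([+-])(\d+)")
_CARET_RE = re.compile(r"\^.", re.DOTALL)
_PLAIN = set(".,ACGTNacgtn*<>")


@dataclass(frozen=True)
class PileupRecord:
    """One decoded pileup line (position converted to 0-based)."""

    ref_name: str
    pos: int
    ref_base: str
    depth: int
    sub_counts: dict  # alt base (upper) -> count, strand-collapsed
    ins_events: list  # inserted sequences (upper), one entry per event
    del_events: list  # (length, deleted seq upper), anchored at this position
    del_cov: int  # '*' symbols: reads deleted at this position
    ref_count: int


def parse_pileup_record(line: str) -> PileupRecord:
    """Decode one samtools-dialect pileup line.

    Handles ``. ,`` (reference match), ``ACGTacgt`` (substitution),
    ``*`` (deletion coverage), ``+N<seq>`` / ``-N<seq>`` (indel events
    attached to the preceding read base), ``^X`` (read start; the mapping
    quality character is consumed), ``$`` (read end) and ``< >``
    (reference skips, depth-consuming but mutation-free).  Raises
    :class:`FormatError` if the decoded symbol count disagrees with the
    depth field or an unknown byte is met.
    """
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 6:
        raise FormatError(f"pileup line has {len(fields)} fields, expected 6")
    ref_name, pos_s, ref_base, depth_s = fields[0], fields[1], fields[2], fields[3]
    bases = fields[4]
    try:
        pos = int(pos_s)
        depth = int(depth_s)
    except ValueError as exc:
        raise FormatError(f"non-integer pos/depth in pileup line: {exc}") from exc

    # fast paths matter: columns can be millions of reads deep
    s = _CARET_RE.sub("", bases) if "^" in bases else bases
    if "$" in s:
        s = s.replace("$", "")

    ins_events: list[str] = []
    del_events: list[tuple[int, str]] = []
    if "+" not in s and "-" not in s:
        core = s
        return _finish_record(ref_name, pos, ref_base, depth, core, ins_events, del_events)
    pieces = []
    last = 0
    for m in _INDEL_RE.finditer(s):
        if m.start() < last:
            continue  # digits that belonged to a previous indel's sequence (impossible for ACGTN seqs)
        n = int(m.group(2))
        seq = s[m.end() : m.end() + n]
        if len(seq) < n or not set(seq) <= set("ACGTNacgtn"):
            raise FormatError(
                f"{ref_name}:{pos_s}: dangling {m.group(1)}{n} indel (sequence {seq!r})"
            )
        if m.group(1) == "+":
            ins_events.append(seq.upper())
        else:
            del_events.append((n, seq.upper()))
        pieces.append(s[last : m.start()])
        last = m.end() + n
    pieces.append(s[last:])
    core = "".join(pieces)
    return _finish_record(ref_name, pos, ref_base, depth, core, ins_events, del_events)


def _finish_record(
    ref_name: str,
    pos: int,
    ref_base: str,
    depth: int,
    core: str,
    ins_events: list,
    del_events: list,
) -> PileupRecord:
    unknown = set(core) - _PLAIN
    if unknown:
        bad = sorted(unknown)[0]
        raise FormatError(f"{ref_name}:{pos}: unknown pileup symbol {bad!r} (0x{ord(bad):02x})")
    if len(core) != depth:
        raise FormatError(
            f"{ref_name}:{pos}: decoded {len(core)} read symbols but depth is {depth}"
        )

    ref_upper = ref_base.upper()
    sub_counts = {}
    for alt in "ACGT":
        if alt == ref_upper:
            continue
        c = core.count(alt) + core.count(alt.lower())
        if c:
            sub_counts[alt] = c
    ref_count = core.count(".") + core.count(",")
    # a read base equal to the reference letter is also a reference match
    ref_count += core.count(ref_upper) + core.count(ref_upper.lower())
    del_cov = core.count("*")

    return PileupRecord(
        ref_name=ref_name,
        pos=pos - 1,
        ref_base=ref_upper,
        depth=depth,
        sub_counts=sub_counts,
        ins_events=ins_events,
        del_events=del_events,
        del_cov=del_cov,
        ref_count=ref_count,
    )


def classify_deletion_length(length: int) -> str:
    """Size class of a deletion: 1 bp = small, 2-5 bp = mid, >5 bp = large."""
    if length < 1:
        raise DomainError(f"deletion length must be >= 1, got {length}")
    if length == 1:
        return "small"
    if length <= 5:
        return "mid"
    return "large"


def compute_microhomology(ref: str, del_start: int, del_end: int) -> int:
    """Junction ambiguity length of the deletion ``ref[del_start:del_end]``.

    The largest ``k <= min(del_end - del_start, len(ref) - del_end)`` with
    ``ref[del_start : del_start + k] == ref[del_end : del_end + k]`` — the
    microhomology shared by the two junction flanks.
    """
    if not (0 <= del_start < del_end <= len(ref)):
        raise DomainError(
            f"invalid deletion interval [{del_start},{del_end}) for length-{len(ref)} ref"
        )
    k_max = min(del_end - del_start, len(ref) - del_end)
    best = 0
    for k in range(1, k_max + 1):
        if ref[del_start : del_start + k] == ref[del_end : del_end + k]:
            best = k
        else:
            break
    return best


@dataclass(frozen=True)
class DeletionAnnotation:
    """One deletion event with its repair-mechanism annotations."""

    locus_id: str
    start: int  # 0-based first deleted base
    length: int
    size_class: str
    rel_dist: Optional[int]  # signed cut-relative distance of nearest deleted base
    adjacency: str  # "adjacent" | "distant"
    microhomology_len: int
    mmej: bool
    slippage: bool
    count: int = 1  # supporting reads


def annotate_deletion(
    locus: AmpliconLocus,
    start: int,
    length: int,
    adjacency_bp: int = 10,
    count: int = 1,
) -> DeletionAnnotation:
    """Annotate one deletion event within the amplicon interior.

    ``rel_dist`` is the signed cut-relative position of the deleted base
    nearest the cut (None for uncut loci, which are always "distant");
    ``mmej`` requires large size class and junction microhomology >= 2;
    ``slippage`` requires length <= 2 inside a homopolymer run >= 3.
    """
    a, b = locus.interior()
    if not (a <= start and start + length <= b):
        raise DomainError(
            f"{locus.locus_id}: deletion [{start},{start + length}) outside interior [{a},{b})"
        )
    size_class = classify_deletion_length(length)
    if locus.is_cut:
        rels = [locus.to_cut_relative(x) for x in range(start, start + length)]
        rel_dist = min(rels, key=abs)
        adjacency = "adjacent" if abs(rel_dist) <= adjacency_bp else "distant"
    else:
        rel_dist = None
        adjacency = "distant"
    mh = compute_microhomology(locus.ref_seq, start, start + length)
    mmej = size_class == "large" and mh >= 2
    slippage = length <= 2 and in_homopolymer(locus.ref_seq, start, start + length, 3)
    return DeletionAnnotation(
        locus_id=locus.locus_id,
        start=start,
        length=length,
        size_class=size_class,
        rel_dist=rel_dist,
        adjacency=adjacency,
        microhomology_len=mh,
        mmej=mmej,
        slippage=slippage,
        count=count,
    )


class MProfile:
    """Per-locus, per-position mutation counts with derived percent rates.

    Backed by a tidy DataFrame indexed by (locus_id, pos) with columns:
    ``ref_base, depth, ref_count``, the 12 directional substitution counts
    (``AtoC`` ...), ``ins_events``, ``del_cov`` and anchored deletion-event
    counts by size class (``del_small, del_mid, del_large``).
    """

    COUNT_COLUMNS = SUB_DIRECTIONS + [
        "ins_events",
        "del_cov",
        "del_small",
        "del_mid",
        "del_large",
    ]

    def __init__(self, counts: pd.DataFrame, pool: Optional[PrimerPool] = None):
        self.counts = counts
        self.pool = pool

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MProfile):
            return NotImplemented
        return self.counts.equals(other.counts)

    def rates(self, min_depth: int = 100) -> pd.DataFrame:
        """Percent rates (100*count/depth); NaN where depth < min_depth.

        Adds ``sub_total`` (sum of the 12 directional rates) and
        ``del_cov_rate``/``ins_rate`` columns; keeps ref_base and depth.
        """
        df = self.counts.copy()
        depth = df["depth"].to_numpy(dtype=float)
        ok = depth >= max(min_depth, 1)
        denom = np.where(ok, depth, np.nan)
        out = df[["ref_base", "depth"]].copy()
        if "rel_pos" in df.columns:
            out["rel_pos"] = df["rel_pos"]
        for c in SUB_DIRECTIONS:
            out[f"sub_{c}"] = 100.0 * df[c].to_numpy() / denom
        out["sub_total"] = out[[f"sub_{c}" for c in SUB_DIRECTIONS]].sum(
            axis=1, skipna=False
        )
        out["ins_rate"] = 100.0 * df["ins_events"].to_numpy() / denom
        out["del_cov_rate"] = 100.0 * df["del_cov"].to_numpy() / denom
        for c in ("del_small", "del_mid", "del_large"):
            out[f"{c}_rate"] = 100.0 * df[c].to_numpy() / denom
        return out

    def to_tsv(self, path: str | Path, min_depth: int = 100) -> None:
        self.rates(min_depth).to_csv(path, sep="\t", float_format="%.6g")

    @property
    def locus_ids(self) -> list[str]:
        return list(self.counts.index.get_level_values("locus_id").unique())


def _iter_lines(pileup: Union[str, Path, Iterable[str]]) -> Iterator[str]:
    if isinstance(pileup, (str, Path)) and "\t" not in str(pileup):
        with open(pileup) as fh:
            yield from fh
    elif isinstance(pileup, str):
        yield from pileup.splitlines()
    else:
        yield from pileup


def pileup_to_profile(
    pileup: Union[str, Path, Iterable[str]],
    pool: PrimerPool,
    adjacency_bp: int = 10,
) -> tuple[MProfile, list[DeletionAnnotation]]:
    """Aggregate pileup text into an MProfile plus deletion annotations.

    ``pileup`` may be a file path, a multi-line string, or an iterable of
    lines.  Reference names must be pool locus ids and positions must lie
    inside the amplicon.  Deletion events increment the anchored event
    class counts at their first deleted base; their spanned positions are
    covered by the ``*`` symbols the dialect itself emits.
    """
    arrays: dict[str, dict[str, np.ndarray]] = {}
    ref_bases: dict[str, list] = {}
    del_counter: dict[tuple[str, int, int], int] = {}

    def _locus_arrays(locus_id: str) -> dict[str, np.ndarray]:
        if locus_id not in arrays:
            if locus_id not in pool:
                raise PoolValidationError(f"pileup ref name {locus_id!r} not in pool")
            L = len(pool[locus_id].ref_seq)
            arrays[locus_id] = {
                c: np.zeros(L, dtype=np.int64)
                for c in ["depth", "ref_count"] + MProfile.COUNT_COLUMNS
            }
            ref_bases[locus_id] = [""] * L
        return arrays[locus_id]

    for line in _iter_lines(pileup):
        if not line.strip():
            continue
        rec = parse_pileup_record(line)
        cols = _locus_arrays(rec.ref_name)
        L = len(pool[rec.ref_name].ref_seq)
        if not (0 <= rec.pos < L):
            raise PoolValidationError(
                f"{rec.ref_name}: pileup position {rec.pos + 1} outside amplicon of length {L}"
            )
        x = rec.pos
        cols["depth"][x] += rec.depth
        cols["ref_count"][x] += rec.ref_count
        ref_bases[rec.ref_name][x] = rec.ref_base
        for alt, c in rec.sub_counts.items():
            if rec.ref_base in "ACGT" and alt != rec.ref_base:
                cols[f"{rec.ref_base}to{alt}"][x] += c
        cols["ins_events"][x] += len(rec.ins_events)
        cols["del_cov"][x] += rec.del_cov
        for length, _seq in rec.del_events:
            cls = classify_deletion_length(length)
            cols[f"del_{cls}"][x] += 1
            key = (rec.ref_name, x + 1, length)  # first deleted base
            del_counter[key] = del_counter.get(key, 0) + 1

    frames = []
    for locus_id, cols in arrays.items():
        L = len(pool[locus_id].ref_seq)
        locus = pool[locus_id]
        df = pd.DataFrame(cols)
        df.insert(0, "ref_base", ref_bases[locus_id])
        df.insert(0, "pos", np.arange(L))
        df.insert(0, "locus_id", locus_id)
        if locus.is_cut:
            df["rel_pos"] = df["pos"] - locus.cut_offset
        else:
            df["rel_pos"] = np.nan
        frames.append(df)
    if frames:
        counts = pd.concat(frames).set_index(["locus_id", "pos"])
    else:
        counts = pd.DataFrame(
            columns=["ref_base", "rel_pos", "depth", "ref_count"] + MProfile.COUNT_COLUMNS
        )

    annotations = [
        annotate_deletion(pool[lid], start, length, adjacency_bp=adjacency_bp, count=n)
        for (lid, start, length), n in sorted(del_counter.items())
    ]
    return MProfile(counts, pool), annotations


def annotations_to_frame(annotations: list[DeletionAnnotation]) -> pd.DataFrame:
    """Deletion annotations as a tidy DataFrame (TSV-ready)."""
    return pd.DataFrame(
        [
            {
                "locus_id": a.locus_id,
                "start": a.start,
                "length": a.length,
                "class": a.size_class,
                "rel_dist": a.rel_dist,
                "adjacency": a.adjacency,
                "microhomology": a.microhomology_len,
                "mmej": a.mmej,
                "slippage": a.slippage,
                "count": a.count,
            }
            for a in annotations
        ],
        columns=[
            "locus_id",
            "start",
            "length",
            "class",
            "rel_dist",
            "adjacency",
            "microhomology",
            "mmej",
            "slippage",
            "count",
        ],
    )
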