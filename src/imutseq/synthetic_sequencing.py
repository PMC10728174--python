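"""Synthetic amplicon sequencing around induced double-strand breaks.

Two generators share one parameterisation (:class:`MutationSpectrum`):

* :func:`simulate_sample` emits paired 150-base FASTQ reads, including
  chimeric (translocated) pairs whose two primers come from different
  loci, together with a machine-readable truth table.
* :func:`simulate_pileup` emits samtools-dialect pileup text directly,
  bypassing alignment, with per-position alternate counts drawn
  binomially from the spectrum-implied probabilities.  This gives an
  aligner-free path into the mutation caller with exact truth counts.

The spectrum models the phenomenology of DSB repair outcomes: base
substitutions peaked at the cut and decaying exponentially (~20 bp scale),
break-adjacent deletions of three size classes, distant 1-bp slippage
deletions at homopolymer runs, large MMEJ deletions whose junctions carry
2-7 bp of microhomology, rare insertions, uniform sequencing error, and a
per-pair translocation propensity.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np
import pandas as pd

from .amplicon_catalog import AmpliconLocus, PrimerPool
from .dna import homopolymer_runs, revcomp
from .errors import DomainError

READ_LEN = 150
_QUAL_CHAR = "?"  # constant Q30
_BASES = "ACGT"

TRUTH_COLUMNS = ["read_id", "locus_id", "kind", "rel_pos", "length", "detail"]


@dataclass(frozen=True)
class Event:
    """One mutation applied to an amplicon reference.

    kinds: ``sub`` (detail = alt base), ``ins`` (inserted after position
    ``start``; detail = inserted sequence), ``del`` (``start`` = first
    deleted base, ``length`` bases removed).
    """

    kind: str
    start: int
    length: int = 1
    detail: str = ""

    def span(self) -> tuple[int, int]:
        if self.kind == "del":
            return self.start, self.start + self.length
        if self.kind == "sub":
            return self.start, self.start + 1
        return self.start, self.start  # insertion occupies no reference bases


def apply_events(ref_seq: str, events: Sequence[Event]) -> str:
    """Apply ordered, non-overlapping events to a reference sequence.

    Events must be sorted by position; they are applied right-to-left so
    earlier anchors stay valid.  Result length is
    ``len(ref) + sum(ins lengths) - sum(del lengths)``.
    """
    prev_end = -1
    for ev in events:
        s, e = ev.span()
        if not (0 <= s and e <= len(ref_seq)):
            raise DomainError(f"event {ev} outside sequence of length {len(ref_seq)}")
        if s < prev_end:
            raise DomainError(f"overlapping/unsorted events at {s} (previous end {prev_end})")
        prev_end = max(e, s)
    out = ref_seq
    for ev in reversed(events):
        if ev.kind == "sub":
            out = out[: ev.start] + ev.detail + out[ev.start + 1 :]
        elif ev.kind == "del":
            out = out[: ev.start] + out[ev.start + ev.length :]
        elif ev.kind == "ins":
            out = out[: ev.start + 1] + ev.detail + out[ev.start + 1 :]
        else:
            raise DomainError(f"unknown event kind {ev.kind!r}")
    return out


@dataclass
class MutationSpectrum:
    """Generative parameters of a simulated sample.

    Rates are per read (or per read pair for ``transloc_rate``), except
    ``seq_error_rate`` which is per base.  ``sub_rate_peak`` is the
    per-read, per-position substitution probability at the cut itself;
    it decays exponentially with ``sub_decay_bp`` away from the cut.
    Defaults emulate the order of magnitude of DSB-induced mutation rates
    in the assay this package models (~1% substitutions, ~0.27% deletions,
    ~0.05% insertions, ~0.01% translocations per DSB).
    """

    sub_rate_peak: float = 2.5e-4
    sub_decay_bp: float = 20.0
    sub_floor: float = 0.0
    sub_signature: dict = field(
        default_factory=lambda: {
            "C>A": 0.15,
            "C>G": 0.20,
            "C>T": 0.35,
            "T>A": 0.08,
            "T>C": 0.12,
            "T>G": 0.10,
        }
    )
    del_small_rate: float = 8e-4
    del_mid_rate: float = 9.4e-4
    del_large_rate: float = 1.7e-3
    distant_slip_rate: float = 1.4e-3
    mmej_rate: float = 6.8e-4
    ins_rate: float = 5e-4
    transloc_rate: float = 1e-4
    transloc_weights: Optional[dict] = None  # (locus_i, locus_j) -> weight
    seq_error_rate: float = 1e-3
    adjacency_bp: int = 10
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        rates = [
            self.sub_rate_peak,
            self.sub_floor,
            self.del_small_rate,
            self.del_mid_rate,
            self.del_large_rate,
            self.distant_slip_rate,
            self.mmej_rate,
            self.ins_rate,
            self.transloc_rate,
            self.seq_error_rate,
        ]
        if any(not (0.0 <= r <= 1.0) for r in rates):
            raise DomainError("all spectrum rates must lie in [0, 1]")
        total = sum(self.sub_signature.values())
        if abs(total - 1.0) > 1e-9:
            raise DomainError(f"sub_signature weights must sum to 1 (got {total})")
        if self.sub_decay_bp <= 0:
            raise DomainError("sub_decay_bp must be > 0")

    @classmethod
    def null(cls, seq_error_rate: float = 0.0) -> "MutationSpectrum":
        """Spectrum with every event rate zero (an undamaged sample)."""
        return cls(
            sub_rate_peak=0.0,
            del_small_rate=0.0,
            del_mid_rate=0.0,
            del_large_rate=0.0,
            distant_slip_rate=0.0,
            mmej_rate=0.0,
            ins_rate=0.0,
            transloc_rate=0.0,
            seq_error_rate=seq_error_rate,
        )


_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}
_SIG_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")


def _alt_base_for(ref_base: str, rng: np.random.Generator, signature: dict) -> str:
    """Draw an alternate base for ``ref_base`` from a 6-class signature.

    Purine references are handled by reverse-complement collapse: a G>A
    change is drawn as C>T on the opposite strand.
    """
    if ref_base in "CT":
        pyr, flip = ref_base, False
    elif ref_base in "AG":
        pyr, flip = _COMP[ref_base], True
    else:  # N or unexpected: fall back to uniform
        choices = [b for b in _BASES if b != ref_base]
        return choices[rng.integers(0, len(choices))]
    classes = [c for c in _SIG_CLASSES if c[0] == pyr]
    weights = np.array([signature.get(c, 0.0) for c in classes])
    if weights.sum() <= 0:
        weights = np.ones(len(classes))
    weights = weights / weights.sum()
    alt_pyr = classes[rng.choice(len(classes), p=weights)][2]
    return _COMP[alt_pyr] if flip else alt_pyr


# --- per-locus event-placement machinery -----------------------------------


def _sub_profile(locus: AmpliconLocus, spectrum: MutationSpectrum) -> np.ndarray:
    """Per-position, per-read DSB substitution probability over the amplicon."""
    L = len(locus.ref_seq)
    p = np.zeros(L)
    if locus.is_cut:
        a, b = locus.interior()
        rel = np.arange(a, b) - locus.cut_offset
        p[a:b] = spectrum.sub_rate_peak * np.exp(-np.abs(rel) / spectrum.sub_decay_bp)
        p[a:b] += spectrum.sub_floor
    return p


def _slippage_sites(locus: AmpliconLocus, adjacency_bp: int) -> list[int]:
    """Starts of 1-bp deletion sites inside distant homopolymer runs (>=3)."""
    if not locus.is_cut:
        return []
    a, b = locus.interior()
    sites = []
    for rs, re_ in homopolymer_runs(locus.ref_seq, 3):
        if rs < a or re_ > b:
            continue
        rel = min(abs(x - locus.cut_offset) for x in range(rs, re_))
        if rel > adjacency_bp:
            sites.append(rs)
    return sites


def _mmej_candidates(locus: AmpliconLocus, max_del: int = 70) -> list[tuple[int, int, int]]:
    """Deletions spanning the cut whose junction carries 2-7 bp microhomology.

    Returns (start, length, microhomology_len) triples; deletions are
    large-class (>5 bp), confined to the primer-free interior.
    """
    if not locus.is_cut:
        return []
    from .mutation_caller import compute_microhomology  # local import: no cycle at module load

    ref, cut = locus.ref_seq, locus.cut_offset
    a, b = locus.interior()
    out = []
    for start in range(max(a, cut - 60), cut - 2):
        for end in range(cut + 1, min(b, start + max_del + 1)):
            length = end - start
            if length <= 5:
                continue
            mh = compute_microhomology(ref, start, end)
            if 2 <= mh <= 7:
                out.append((start, length, mh))
    return out


class _LocusModel:
    """Cached per-locus event-placement tables."""

    def __init__(self, locus: AmpliconLocus, spectrum: MutationSpectrum):
        self.locus = locus
        self.sub_p = _sub_profile(locus, spectrum)
        self.sub_p_total = float(self.sub_p.sum())
        if self.sub_p_total > 0:
            self.sub_weights = self.sub_p / self.sub_p_total
        else:
            self.sub_weights = None
        self.slip_sites = _slippage_sites(locus, spectrum.adjacency_bp)
        self.mmej = _mmej_candidates(locus) if spectrum.mmej_rate > 0 else []
        a, b = locus.interior()
        cut = locus.cut_offset
        if locus.is_cut:
            self.adj_anchors = [p for p in range(cut - 5, cut + 5) if a <= p < b]
        else:
            self.adj_anchors = []


def _draw_event(
    model: _LocusModel, spectrum: MutationSpectrum, rng: np.random.Generator
) -> Optional[Event]:
    """Draw at most one DSB-induced event for a single read of this locus."""
    locus = model.locus
    if not locus.is_cut:
        return None
    ref = locus.ref_seq
    a, b = locus.interior()
    probs = [
        ("mmej", spectrum.mmej_rate if model.mmej else 0.0),
        ("del_large", spectrum.del_large_rate),
        ("del_mid", spectrum.del_mid_rate),
        ("del_small", spectrum.del_small_rate),
        ("slip", spectrum.distant_slip_rate if model.slip_sites else 0.0),
        ("ins", spectrum.ins_rate),
        ("sub", model.sub_p_total),
    ]
    u = rng.random()
    acc = 0.0
    kind = None
    for name, p in probs:
        acc += p
        if u < acc:
            kind = name
            break
    if kind is None:
        return None
    cut = locus.cut_offset
    if kind == "sub":
        pos = int(rng.choice(len(ref), p=model.sub_weights))
        alt = _alt_base_for(ref[pos], rng, spectrum.sub_signature)
        return Event("sub", pos, 1, alt)
    if kind == "ins":
        n = int(rng.integers(1, 4))
        seq = "".join(_BASES[rng.integers(0, 4)] for _ in range(n))
        return Event("ins", cut - 1, n, seq)
    if kind == "del_small":
        start = int(model.adj_anchors[rng.integers(0, len(model.adj_anchors))])
        return Event("del", start, 1)
    if kind == "del_mid":
        length = int(rng.integers(2, 6))
        start = int(np.clip(cut + rng.integers(-length, 4), a, b - length))
        return Event("del", start, length)
    if kind == "del_large":
        length = int(rng.integers(6, 21))
        start = int(np.clip(cut + rng.integers(-length, 4), a, b - length))
        return Event("del", start, length)
    if kind == "slip":
        start = int(model.slip_sites[rng.integers(0, len(model.slip_sites))])
        return Event("del", start, 1, "slippage")
    if kind == "mmej":
        start, length, mh = model.mmej[rng.integers(0, len(model.mmej))]
        return Event("del", start, length, f"mmej:{mh}")
    raise AssertionError(kind)


def _default_transloc_weights(pool: PrimerPool) -> dict:
    """Unordered locus-pair weights: HR-HR pairs dominate, uncut loci excluded."""
    weights: dict = {}
    cut = pool.cut_loci
    for i, li in enumerate(cut):
        for lj in cut[i + 1 :]:
            classes = {li.repair_class, lj.repair_class}
            if classes == {"HR"}:
                w = 15.0
            elif classes == {"HR", "NHEJ"}:
                w = 2.0
            else:
                w = 1.0
            weights[(li.locus_id, lj.locus_id)] = w
    return weights


def _seq_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Inject uniform per-base substitution errors into a read."""
    if rate <= 0:
        return seq
    n_err = rng.binomial(len(seq), rate)
    if n_err == 0:
        return seq
    chars = list(seq)
    for pos in rng.choice(len(seq), size=n_err, replace=False):
        base = chars[pos]
        alts = [b for b in _BASES if b != base]
        chars[pos] = alts[rng.integers(0, 3)]
    return "".join(chars)


def simulate_sample(
    pool: PrimerPool,
    spectrum: MutationSpectrum,
    n_pairs: int,
    seed: Optional[int] = None,
    r1_path: Optional[str | Path] = None,
    r2_path: Optional[str | Path] = None,
    truth_path: Optional[str | Path] = None,
):
    """Simulate ``n_pairs`` paired 150-base reads from the amplicon pool.

    Cis pairs draw one locus uniformly; with probability ``transloc_rate``
    a chimeric pair is emitted instead, its (fwd, rev) loci drawn from the
    spectrum's unordered locus-pair weight table.  At most one DSB-induced
    event is injected per cis pair; sequencing errors are added per mate.

    Returns ``(r1_records, r2_records, truth)`` where records are
    ``(read_id, sequence, quality)`` triples and ``truth`` is a DataFrame
    with one row per pair (columns ``read_id, locus_id, kind, rel_pos,
    length, detail``).  If paths are given the FASTQ/truth files are also
    written; identical inputs and seed give byte-identical outputs.
    """
    if n_pairs < 0:
        raise DomainError("n_pairs must be >= 0")
    if seed is None:
        seed = spectrum.seed
    rng = np.random.default_rng(seed)
    models = {loc.locus_id: _LocusModel(loc, spectrum) for loc in pool}
    weights = spectrum.transloc_weights or _default_transloc_weights(pool)
    pair_ids = list(weights)
    pair_w = np.array([weights[p] for p in pair_ids], dtype=float)
    if pair_w.sum() > 0:
        pair_w = pair_w / pair_w.sum()
    locus_list = list(pool)

    r1_records, r2_records, truth_rows = [], [], []
    for i in range(n_pairs):
        read_id = f"pair{i:06d}"
        if pair_ids and rng.random() < spectrum.transloc_rate:
            li_id, lj_id = pair_ids[rng.choice(len(pair_ids), p=pair_w)]
            if rng.random() < 0.5:  # unordered pair, random amplification orientation
                li_id, lj_id = lj_id, li_id
            li, lj = pool[li_id], pool[lj_id]
            r1 = li.ref_seq[:READ_LEN]
            r2 = revcomp(lj.ref_seq)[:READ_LEN]
            truth_rows.append((read_id, f"{li_id}|{lj_id}", "transloc", "", 0, ""))
        else:
            locus = locus_list[rng.integers(0, len(locus_list))]
            model = models[locus.locus_id]
            ev = _draw_event(model, spectrum, rng)
            if ev is None:
                mutated = locus.ref_seq
                truth_rows.append((read_id, locus.locus_id, "none", "", 0, ""))
            else:
                mutated = apply_events(locus.ref_seq, [ev])
                rel = locus.to_cut_relative(ev.start)
                truth_rows.append(
                    (read_id, locus.locus_id, ev.kind, rel, ev.length, ev.detail)
                )
            r1 = mutated[:READ_LEN]
            r2 = revcomp(mutated)[:READ_LEN]
        r1 = _seq_errors(r1, spectrum.seq_error_rate, rng)
        r2 = _seq_errors(r2, spectrum.seq_error_rate, rng)
        r1_records.append((read_id, r1, _QUAL_CHAR * len(r1)))
        r2_records.append((read_id, r2, _QUAL_CHAR * len(r2)))

    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    if r1_path is not None:
        write_fastq(r1_records, r1_path)
    if r2_path is not None:
        write_fastq(r2_records, r2_path)
    if truth_path is not None:
        truth.to_csv(truth_path, sep="\t", index=False)
    return r1_records, r2_records, truth


def write_fastq(records: Iterable[tuple[str, str, str]], path: str | Path) -> None:
    """Write (id, seq, qual) records as 4-line FASTQ; gzip if path ends .gz."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        for rid, seq, qual in records:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


# --- pileup-level simulation -------------------------------------------------


def simulate_pileup(
    pool: PrimerPool,
    spectrum: MutationSpectrum,
    depth: int,
    seed: Optional[int] = None,
    path: Optional[str | Path] = None,
):
    """Simulate samtools-dialect pileup text at constant per-position depth.

    Alternate-read counts are drawn binomially from the spectrum-implied
    per-position probabilities; deletion events are encoded as ``-N<seq>``
    on the anchor base (the base before the first deleted position) and as
    ``*`` over every deleted position, insertions as ``+N<seq>``.

    Returns ``(lines, truth)``: ``lines`` is a lazy iterator of pileup
    lines (or the output path if ``path`` is given), and ``truth`` is a
    dict of DataFrames — ``positions`` with exact per-position drawn
    counts (``sub_A..sub_T``, ``ins_events``, ``del_cov``) and
    ``deletions`` with per-event (start, length, count) rows.
    """
    if depth < 0:
        raise DomainError("depth must be >= 0")
    if seed is None:
        seed = spectrum.seed
    rng = np.random.default_rng(seed)

    pos_rows = []
    del_rows = []
    locus_columns: dict[str, list] = {}

    for locus in pool:
        model = _LocusModel(locus, spectrum)
        ref = locus.ref_seq
        L = len(ref)
        a, b = locus.interior()
        cut = locus.cut_offset

        sub_counts = np.zeros((L, 4), dtype=np.int64)  # alt A/C/G/T
        p_sub = model.sub_p
        if depth > 0:
            k_dsb = rng.binomial(depth, np.clip(p_sub, 0, 1))
            for x in np.nonzero(k_dsb)[0]:
                for _ in range(int(k_dsb[x])):
                    alt = _alt_base_for(ref[x], rng, spectrum.sub_signature)
                    sub_counts[x, _BASES.index(alt)] += 1
            if spectrum.seq_error_rate > 0:
                k_err = rng.binomial(depth, spectrum.seq_error_rate, size=L)
                for x in np.nonzero(k_err)[0]:
                    alts = [bi for bi in range(4) if _BASES[bi] != ref[x]]
                    draws = rng.integers(0, 3, size=int(k_err[x]))
                    for d in draws:
                        sub_counts[x, alts[d]] += 1

        ins_counts = np.zeros(L, dtype=np.int64)
        ins_details: dict[int, list[str]] = {}
        if locus.is_cut and depth > 0 and spectrum.ins_rate > 0:
            k_ins = rng.binomial(depth, spectrum.ins_rate)
            if k_ins:
                p = cut - 1
                ins_counts[p] = k_ins
                seqs = []
                for _ in range(int(k_ins)):
                    n = int(rng.integers(1, 4))
                    seqs.append("".join(_BASES[rng.integers(0, 4)] for _ in range(n)))
                ins_details[p] = seqs

        del_events: dict[tuple[int, int], int] = {}

        def _add_del(start: int, length: int, count: int) -> None:
            if count > 0:
                key = (int(start), int(length))
                del_events[key] = del_events.get(key, 0) + int(count)

        if locus.is_cut and depth > 0:
            anchors = model.adj_anchors
            if anchors and spectrum.del_small_rate > 0:
                per = spectrum.del_small_rate / len(anchors)
                for p in anchors:
                    _add_del(p, 1, rng.binomial(depth, per))
            for rate, lo, hi in (
                (spectrum.del_mid_rate, 2, 5),
                (spectrum.del_large_rate, 6, 20),
            ):
                if rate > 0:
                    k = rng.binomial(depth, rate)
                    for _ in range(int(k)):
                        length = int(rng.integers(lo, hi + 1))
                        start = int(np.clip(cut + rng.integers(-length, 4), a + 1, b - length))
                        _add_del(start, length, 1)
            if model.slip_sites and spectrum.distant_slip_rate > 0:
                k = rng.binomial(depth, spectrum.distant_slip_rate)
                for _ in range(int(k)):
                    _add_del(model.slip_sites[rng.integers(0, len(model.slip_sites))], 1, 1)
            if model.mmej and spectrum.mmej_rate > 0:
                k = rng.binomial(depth, spectrum.mmej_rate)
                for _ in range(int(k)):
                    start, length, _mh = model.mmej[rng.integers(0, len(model.mmej))]
                    _add_del(start, length, 1)

        del_cov = np.zeros(L, dtype=np.int64)
        del_anchor: dict[int, list[tuple[int, int]]] = {}
        for (start, length), count in sorted(del_events.items()):
            del_cov[start : start + length] += count
            del_anchor.setdefault(start - 1, []).append((length, count))
            del_rows.append((locus.locus_id, start, length, count))

        # consistency: non-reference symbols can never exceed depth
        consumed = sub_counts.sum(axis=1) + del_cov
        if depth > 0 and consumed.max(initial=0) > depth:
            raise DomainError(
                "event rates too high for requested depth: column overflow"
            )

        for x in range(L):
            row = {
                "locus_id": locus.locus_id,
                "pos": x,
                "ref_base": ref[x],
                "depth": depth,
                "true_sub_p": p_sub[x] + spectrum.seq_error_rate,
                "sub_A": int(sub_counts[x, 0]),
                "sub_C": int(sub_counts[x, 1]),
                "sub_G": int(sub_counts[x, 2]),
                "sub_T": int(sub_counts[x, 3]),
                "ins_events": int(ins_counts[x]),
                "del_cov": int(del_cov[x]),
            }
            pos_rows.append(row)

        locus_columns[locus.locus_id] = (ref, sub_counts, del_cov, del_anchor, ins_details)

    truth = {
        "positions": pd.DataFrame(pos_rows),
        "deletions": pd.DataFrame(
            del_rows, columns=["locus_id", "start", "length", "count"]
        ),
    }

    def _lines() -> Iterator[str]:
        for locus in pool:
            ref, sub_counts, del_cov, del_anchor, ins_details = locus_columns[locus.locus_id]
            for x in range(len(ref)):
                parts = []
                n_used = 0
                for (length, count) in del_anchor.get(x, []):
                    deleted = ref[x + 1 : x + 1 + length]
                    parts.append(f".-{length}{deleted}" * count)
                    n_used += count
                for seq in ins_details.get(x, []):
                    parts.append(f".+{len(seq)}{seq}")
                    n_used += 1
                for bi, base in enumerate(_BASES):
                    c = int(sub_counts[x, bi])
                    if c:
                        parts.append(base * c)
                        n_used += c
                stars = int(del_cov[x])
                if stars:
                    parts.append("*" * stars)
                    n_used += stars
                parts.insert(0, "." * (depth - n_used))
                bases = "".join(parts)
                qual = "I" * depth
                yield f"{locus.locus_id}\t{x + 1}\t{ref[x]}\t{depth}\t{bases}\t{qual}"

    if path is not None:
        with open(path, "w") as fh:
            for line in _lines():
                fh.write(line + "\n")
        return path, truth
    return _lines(), truth
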