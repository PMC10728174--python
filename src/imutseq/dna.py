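"""Small DNA sequence helpers used throughout the package."""

from __future__ import annotations

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: AsiSI recognition site; the enzyme cuts between positions 5 and 6 on the
#: top strand (GCGAT^CGC), leaving a 2-nt "TA" 3' overhang.
ASISI_SITE = "GCGATCGC"


def revcomp(seq: str) -> str:
    """Reverse-complement of a DNA string (preserves case, keeps N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def hamming(a: str, b: str) -> int:
    """Hamming distance between two equal-length strings."""
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal-length strings")
    return sum(x != y for x, y in zip(a, b))


def homopolymer_runs(seq: str, min_len: int = 3) -> list[tuple[int, int]]:
    """Return [start, end) intervals of homopolymer runs of length >= min_len."""
    runs: list[tuple[int, int]] = []
    i, n = 0, len(seq)
    while i < n:
        j = i + 1
        while j < n and seq[j] == seq[i]:
            j += 1
        if j - i >= min_len:
            runs.append((i, j))
        i = j
    return runs


def in_homopolymer(seq: str, start: int, end: int, min_len: int = 3) -> bool:
    """True if seq[start:end] lies entirely inside a homopolymer run >= min_len."""
    for rs, re_ in homopolymer_runs(seq, min_len):
        if rs <= start and end <= re_:
            return True
    return False
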