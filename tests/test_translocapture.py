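"""Primer matching, pair classification, FASTQ scanning, marker partition."""

import numpy as np
import pytest

from imutseq import (
    MutationSpectrum,
    classify_read_pair,
    match_primer,
    partition_by_marker,
    scan_fastq,
    simulate_sample,
)
from imutseq.amplicon_catalog import AmpliconLocus, PrimerPool
from imutseq.dna import revcomp
from imutseq.synthetic_sequencing import write_fastq
from imutseq.errors import FormatError


def _toy_pool():
    """Two tiny loci with hand-checkable 10-mer primers."""
    loci = []
    for lid, fwd, tail in [
        ("A", "ACGTACGTAC", "GGATCCGGAA"),
        ("B", "TTGGCCAATT", "CCGGTTAACC"),
    ]:
        seq = fwd + "ACACACACAC" * 3 + tail
        loci.append(
            AmpliconLocus(
                locus_id=lid, repair_class="UNCUT", chrom="c", start=0, end=len(seq),
                fwd_primer=fwd, rev_primer=revcomp(tail), ref_seq=seq,
            )
        )
    return PrimerPool(loci, max_mismatch=1)


class TestMatchPrimer:
    def test_exact_prefix_match(self):
        pool = _toy_pool()
        assert match_primer("ACGTACGTACGGTAA", pool, 0) == ("A", "fwd")

    def test_all_n_read_matches_nothing(self):
        pool = _toy_pool()
        assert match_primer("N" * 15, pool, 1) is None

    def test_single_mismatch_tolerance(self):
        pool = _toy_pool()
        read = "ACGTACGAACGGTAA"  # one mismatch at position 7
        assert match_primer(read, pool, 1) == ("A", "fwd")
        assert match_primer(read, pool, 0) is None


class TestClassifyReadPair:
    def test_cis_trans_unmatched(self):
        pool = _toy_pool()
        a, b = pool["A"], pool["B"]
        cis = classify_read_pair(a.ref_seq, revcomp(a.ref_seq), pool)
        assert (cis.status, cis.locus_fwd, cis.locus_rev) == ("cis", "A", "A")
        trans = classify_read_pair(a.ref_seq, revcomp(b.ref_seq), pool)
        assert (trans.status, trans.locus_fwd, trans.locus_rev) == ("trans", "A", "B")
        un = classify_read_pair(a.ref_seq, "G" * 20, pool)
        assert un.status == "unmatched"

    def test_swapped_orientation_recovered(self):
        pool = _toy_pool()
        a = pool["A"]
        origin = classify_read_pair(revcomp(a.ref_seq), a.ref_seq, pool)
        assert origin.status == "cis" and origin.locus_fwd == "A"

    def test_two_forward_primers_are_unmatched(self):
        pool = _toy_pool()
        a, b = pool["A"], pool["B"]
        origin = classify_read_pair(a.ref_seq, b.ref_seq, pool)
        assert origin.status == "unmatched"


class TestScanFastq:
    def _write_pairs(self, tmp_path, pairs):
        r1 = [(f"p{i}", s1, "I" * len(s1)) for i, (s1, _) in enumerate(pairs)]
        r2 = [(f"p{i}", s2, "I" * len(s2)) for i, (_, s2) in enumerate(pairs)]
        write_fastq(r1, tmp_path / "r1.fastq")
        write_fastq(r2, tmp_path / "r2.fastq")
        return tmp_path / "r1.fastq", tmp_path / "r2.fastq"

    def test_hand_counted_example(self, tmp_path):
        pool = _toy_pool()
        a, b = pool["A"], pool["B"]
        pairs = [(a.ref_seq, revcomp(a.ref_seq))] * 8
        pairs += [(a.ref_seq, revcomp(b.ref_seq))]
        pairs += [("G" * 40, "G" * 40)]
        r1p, r2p = self._write_pairs(tmp_path, pairs)
        matrix, report = scan_fastq(r1p, r2p, pool)
        assert report == {"total": 10, "cis": 8, "trans": 1, "unmatched": 1}
        assert matrix.counts_frame().loc["A", "A"] == 8
        assert matrix.counts_frame().loc["A", "B"] == 1
        assert matrix.total_classified == 9
        assert matrix.rates_frame().loc["A", "B"] == pytest.approx(1 / 9)

    def test_empty_inputs(self, tmp_path):
        pool = _toy_pool()
        r1p, r2p = self._write_pairs(tmp_path, [])
        matrix, report = scan_fastq(r1p, r2p, pool)
        assert report["total"] == 0 and matrix.counts.sum() == 0

    def test_desynchronized_mates_raise(self, tmp_path):
        pool = _toy_pool()
        write_fastq([("x", "ACGT", "IIII")], tmp_path / "r1.fastq")
        write_fastq([], tmp_path / "r2.fastq")
        with pytest.raises(FormatError, match="desynchronized"):
            scan_fastq(tmp_path / "r1.fastq", tmp_path / "r2.fastq", pool)

    def test_split_outputs_consistent_with_matrix(self, pool, tmp_path):
        spec = MutationSpectrum(transloc_rate=0.05)
        r1p, r2p = tmp_path / "s.r1.fastq", tmp_path / "s.r2.fastq"
        simulate_sample(pool, spec, 500, seed=21, r1_path=r1p, r2_path=r2p)
        matrix, report = scan_fastq(r1p, r2p, pool, out_prefix=tmp_path / "out")
        n_cis = (tmp_path / "out.cis.r1.fastq").read_text().count("\n") // 4
        n_trans = (tmp_path / "out.trans.r1.fastq").read_text().count("\n") // 4
        assert n_cis == report["cis"] == int(np.trace(matrix.counts))
        assert n_trans == report["trans"] == matrix.trans_total()

    def test_brute_force_oracle_equivalence(self, pool, tmp_path):
        """Streaming scan equals an exhaustive every-primer-vs-every-end classifier."""
        from imutseq.dna import hamming

        spec = MutationSpectrum(transloc_rate=0.1, seq_error_rate=0.005)
        r1p, r2p = tmp_path / "o.r1.fastq", tmp_path / "o.r2.fastq"
        r1, r2, _ = simulate_sample(pool, spec, 200, seed=33, r1_path=r1p, r2_path=r2p)

        def brute_match(seq):
            hits = [
                (lid, side)
                for lid, side, primer in pool.primers()
                if len(seq) >= len(primer) and hamming(seq[: len(primer)], primer) <= 1
            ]
            return hits[0] if len(hits) == 1 else None

        expected = {"cis": 0, "trans": 0, "unmatched": 0}
        for (_, s1, _), (_, s2, _) in zip(r1, r2):
            m1, m2 = brute_match(s1), brute_match(s2)
            if m1 is None or m2 is None or {m1[1], m2[1]} != {"fwd", "rev"}:
                expected["unmatched"] += 1
            elif m1[0] == m2[0]:
                expected["cis"] += 1
            else:
                expected["trans"] += 1
        _, report = scan_fastq(r1p, r2p, pool)
        assert {k: report[k] for k in expected} == expected

    def test_partition_property_total(self, pool, tmp_path):
        spec = MutationSpectrum(transloc_rate=0.02, seq_error_rate=0.01)
        r1p, r2p = tmp_path / "p.r1.fastq", tmp_path / "p.r2.fastq"
        simulate_sample(pool, spec, 300, seed=5, r1_path=r1p, r2_path=r2p)
        _, report = scan_fastq(r1p, r2p, pool)
        assert report["cis"] + report["trans"] + report["unmatched"] == report["total"]


class TestSpikeInRecovery:
    def test_transloc_rate_recovered_within_99ci(self, pool, tmp_path):
        """Aggregate trans rate over 10 seeds matches the injected propensity."""
        t = 1e-3
        spec = MutationSpectrum(transloc_rate=t)
        trans = total = 0
        for seed in range(10):
            r1p = tmp_path / f"t{seed}.r1.fastq"
            r2p = tmp_path / f"t{seed}.r2.fastq"
            simulate_sample(pool, spec, 5000, seed=seed, r1_path=r1p, r2_path=r2p)
            _, report = scan_fastq(r1p, r2p, pool)
            trans += report["trans"]
            total += report["cis"] + report["trans"]
        est = trans / total
        se = np.sqrt(t * (1 - t) / total)
        assert abs(est - t) < 2.576 * se + 1e-12


class TestMarkerPartition:
    MARKER = "GAGGGCGAGGGCGATGC"  # corrected eGFP marker

    def _pairs(self, tmp_path, pairs, tag=""):
        write_fastq(
            [(f"m{i}", s1, "I" * len(s1)) for i, (s1, _) in enumerate(pairs)],
            tmp_path / f"m{tag}.r1.fastq",
        )
        write_fastq(
            [(f"m{i}", s2, "I" * len(s2)) for i, (_, s2) in enumerate(pairs)],
            tmp_path / f"m{tag}.r2.fastq",
        )
        return tmp_path / f"m{tag}.r1.fastq", tmp_path / f"m{tag}.r2.fastq"

    def test_marker_and_revcomp_positive(self, tmp_path):
        pairs = [
            ("AAA" + self.MARKER + "TTT", "A" * 30),       # marker on R1
            ("A" * 30, "CC" + revcomp(self.MARKER) + "GG"),  # revcomp on R2
            ("A" * 30, "A" * 30),                           # negative
        ]
        r1p, r2p = self._pairs(tmp_path, pairs)
        counts = partition_by_marker(r1p, r2p, self.MARKER)
        assert counts == {"total": 3, "positive": 2, "negative": 1}

    def test_invariant_under_mate_swap_and_revcomp(self, tmp_path):
        pairs = [
            ("AAA" + self.MARKER + "TTT", "C" * 30),
            ("C" * 30, "T" * 30),
        ]
        variants = [
            pairs,
            [(b, a) for a, b in pairs],                       # mate swap
            [(revcomp(a), revcomp(b)) for a, b in pairs],     # reverse complement
        ]
        results = []
        for i, ps in enumerate(variants):
            r1p, r2p = self._pairs(tmp_path, ps, tag=str(i))
            counts = partition_by_marker(r1p, r2p, self.MARKER)
            results.append((counts["positive"], counts["negative"]))
        assert results[0] == results[1] == results[2]
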