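"""Pileup decoding, rate computation, deletion classing and microhomology."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from imutseq import (
    MutationSpectrum,
    annotate_deletion,
    classify_deletion_length,
    compute_microhomology,
    parse_pileup_record,
    pileup_to_profile,
    simulate_pileup,
)
from imutseq.mutation_caller import SUB_DIRECTIONS, annotations_to_frame
from imutseq.errors import DomainError, FormatError, PoolValidationError


class TestParsePileupRecord:
    def test_substitutions_counted_strand_collapsed(self):
        rec = parse_pileup_record("ampA\t101\tA\t5\t.,Tt.\tIIIII")
        assert rec.depth == 5 and rec.pos == 100
        assert rec.sub_counts == {"T": 2}

    def test_insertion_decoded(self):
        rec = parse_pileup_record("ampA\t50\tG\t4\t.+2TA.,.\tIIII")
        assert rec.ins_events == ["TA"]
        assert rec.sub_counts == {}
        assert rec.depth == 4

    def test_deletion_event_anchored(self):
        rec = parse_pileup_record("ampA\t60\tC\t6\t..-2AT..,,\tIIIIII")
        assert rec.del_events == [(2, "AT")]
        assert rec.del_cov == 0

    def test_read_start_marker_consumed(self):
        rec = parse_pileup_record("ampA\t10\tT\t2\t.^],\tII")
        assert rec.depth == 2
        assert rec.sub_counts == {} and rec.ins_events == [] and rec.del_events == []

    def test_star_counts_deletion_coverage(self):
        rec = parse_pileup_record("ampA\t61\tA\t6\t..*..,\tIIIIII")
        assert rec.del_cov == 1

    def test_symbol_count_mismatch_raises(self):
        with pytest.raises(FormatError, match="depth"):
            parse_pileup_record("ampA\t10\tT\t5\t...\tIIIII")

    def test_dangling_indel_raises(self):
        with pytest.raises(FormatError, match="indel"):
            parse_pileup_record("ampA\t10\tT\t3\t..+5AT\tIII")

    def test_unknown_symbol_named(self):
        with pytest.raises(FormatError, match="'!'"):
            parse_pileup_record("ampA\t10\tT\t3\t..!\tIII")

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(
        n_ref=st.integers(0, 50),
        subs=st.lists(st.sampled_from("CGTcgt"), max_size=10),
        stars=st.integers(0, 5),
        ins=st.lists(st.text("ACGT", min_size=1, max_size=6), max_size=3),
        dels=st.lists(st.text("ACGT", min_size=1, max_size=6), max_size=3),
        starts=st.integers(0, 3),
    )
    def test_composed_column_round_trips(self, n_ref, subs, stars, ins, dels, starts):
        """Any column composed from known symbol counts decodes back exactly."""
        parts = ["^I." for _ in range(starts)]
        parts += ["." for _ in range(n_ref)]
        parts += list(subs)
        parts += ["*" for _ in range(stars)]
        parts += [f".+{len(s)}{s}" for s in ins]
        parts += [f".-{len(s)}{s}" for s in dels]
        depth = starts + n_ref + len(subs) + stars + len(ins) + len(dels)
        line = f"amp\t5\tA\t{depth}\t{''.join(parts)}\t{'I' * depth}"
        rec = parse_pileup_record(line)
        assert rec.depth == depth
        assert sum(rec.sub_counts.values()) == sum(1 for c in subs if c.upper() != "A")
        assert rec.del_cov == stars
        assert rec.ins_events == [s.upper() for s in ins]
        assert rec.del_events == [(len(s), s.upper()) for s in dels]


class TestPileupToProfile:
    def test_sensitivity_floor_rate(self, pool):
        """2 alternate reads at depth 400,000 give a 0.0005% rate (1 in 200,000)."""
        locus = pool.cut_loci[0]
        x = locus.cut_offset
        ref = locus.ref_seq[x]
        alt = "T" if ref != "T" else "A"
        depth = 400_000
        line = f"{locus.locus_id}\t{x + 1}\t{ref}\t{depth}\t" + \
               "." * (depth - 2) + alt * 2 + "\t" + "I" * depth
        profile, _ = pileup_to_profile([line], pool)
        rates = profile.rates(min_depth=100)
        assert rates.loc[(locus.locus_id, x), "sub_total"] == pytest.approx(0.0005)

    def test_all_reference_pileup_zero_rates(self, small_pool):
        lines, _ = simulate_pileup(small_pool, MutationSpectrum.null(), 200, seed=1)
        profile, anns = pileup_to_profile(lines, small_pool)
        rates = profile.rates(min_depth=100)
        assert (rates["sub_total"] == 0).all()
        assert (rates["del_cov_rate"] == 0).all()
        assert anns == []

    def test_deletion_semantics_by_hand(self, pool):
        """A length-3 deletion anchored at p: '*' at p+1..p+3, one mid event."""
        locus = pool.cut_loci[0]
        p = locus.cut_offset  # anchor (0-based); deleted bases p+1..p+3
        ref = locus.ref_seq
        deleted = ref[p + 1 : p + 4]
        lines = []
        for x in range(len(ref)):
            if x == p:
                bases = "...." + f".-3{deleted}"
            elif p + 1 <= x <= p + 3:
                bases = "....*"
            else:
                bases = "....."
            lines.append(f"{locus.locus_id}\t{x + 1}\t{ref[x]}\t5\t{bases}\t IIIII".replace(" ", ""))
        profile, anns = pileup_to_profile(lines, pool)
        cnt = profile.counts.loc[locus.locus_id]
        assert cnt.loc[p, "del_mid"] == 1
        for x in range(p + 1, p + 4):
            assert cnt.loc[x, "del_cov"] == 1
        assert len(anns) == 1
        ann = anns[0]
        assert (ann.start, ann.length, ann.size_class) == (p + 1, 3, "mid")

    def test_unknown_ref_name_rejected(self, pool):
        with pytest.raises(PoolValidationError, match="nosuch"):
            pileup_to_profile(["nosuch\t1\tA\t1\t.\tI"], pool)

    def test_position_out_of_range_rejected(self, pool):
        lid = pool.locus_ids[0]
        with pytest.raises(PoolValidationError, match="outside"):
            pileup_to_profile([f"{lid}\t100000\tA\t1\t.\tI"], pool)

    def test_exact_truth_recovery_on_simulated_pileup(self, small_pool):
        """Caller counts equal simulator truth exactly (error-free dialect)."""
        spec = MutationSpectrum()
        lines, truth = simulate_pileup(small_pool, spec, 3000, seed=17)
        profile, anns = pileup_to_profile(lines, small_pool)
        tp = truth["positions"].set_index(["locus_id", "pos"])
        called = profile.counts
        assert np.array_equal(
            tp[["sub_A", "sub_C", "sub_G", "sub_T"]].sum(axis=1).loc[called.index],
            called[SUB_DIRECTIONS].sum(axis=1),
        )
        assert np.array_equal(tp["del_cov"].loc[called.index], called["del_cov"])
        assert np.array_equal(tp["ins_events"].loc[called.index], called["ins_events"])
        af = annotations_to_frame(anns)
        td = truth["deletions"]
        merged = td.merge(af, on=["locus_id", "start", "length"], how="outer")
        assert (merged["count_x"].fillna(0) == merged["count_y"].fillna(0)).all()

    def test_depth_halving_at_most_doubles_relative_se(self, pool):
        """Binomial noise scaling: rel. SE grows at most ~sqrt(2) when depth halves."""
        from imutseq import subset_pool

        one = subset_pool(pool, ["HR01"])
        locus = one.cut_loci[0]
        spec = MutationSpectrum.null()
        spec.sub_rate_peak = 0.02
        rel_se = {}
        for depth in (4000, 2000):
            vals = []
            for seed in range(12):
                lines, _ = simulate_pileup(one, spec, depth, seed=seed)
                profile, _ = pileup_to_profile(lines, one)
                rate = profile.rates(min_depth=10).loc[
                    (locus.locus_id, locus.cut_offset), "sub_total"
                ]
                vals.append(rate)
            rel_se[depth] = np.std(vals) / np.mean(vals)
        assert rel_se[2000] <= 2 * rel_se[4000]


class TestDeletionClassing:
    @pytest.mark.parametrize(
        "length,expected",
        [(1, "small"), (2, "mid"), (5, "mid"), (6, "large"), (70, "large")],
    )
    def test_size_classes(self, length, expected):
        assert classify_deletion_length(length) == expected

    def test_zero_length_rejected(self):
        with pytest.raises(DomainError):
            classify_deletion_length(0)


class TestMicrohomology:
    def _brute(self, ref, s, e):
        """Independent oracle: exhaustive scan over all k under the length cap."""
        best = 0
        for k in range(1, min(e - s, len(ref) - e) + 1):
            if ref[s : s + k] == ref[e : e + k]:
                best = max(best, k)
        return best

    @pytest.mark.parametrize(
        "ref,s,e,expected",
        [
            ("ATCACGTACGTTT", 3, 7, 4),   # "ACGT" repeats across the junction
            ("AAAATTTT", 2, 4, 0),        # first junction comparison fails
            ("CCAAAAACC", 2, 3, 1),       # 1-bp deletion: homology capped by length
        ],
    )
    def test_examples_match_brute_force(self, ref, s, e, expected):
        assert self._brute(ref, s, e) == expected
        assert compute_microhomology(ref, s, e) == expected

    def test_equals_brute_force_on_random_instances(self):
        rng = np.random.default_rng(2024)
        bases = np.array(list("ACGT"))
        for _ in range(1000):
            n = int(rng.integers(10, 60))
            ref = "".join(bases[rng.integers(0, 4, n)])
            s = int(rng.integers(0, n - 1))
            e = int(rng.integers(s + 1, n + 1))
            assert compute_microhomology(ref, s, e) == self._brute(ref, s, e)

    def test_invalid_interval_rejected(self):
        with pytest.raises(DomainError):
            compute_microhomology("ACGT", 3, 2)


class TestAnnotateDeletion:
    def test_slippage_small_distant(self, pool):
        locus = pool.cut_loci[0]
        # the fixture plants an A5 run 45 bp upstream of every cut
        start = locus.cut_offset - 45
        assert locus.ref_seq[start : start + 5] == "AAAAA"
        ann = annotate_deletion(locus, start + 1, 1)
        assert ann.size_class == "small"
        assert ann.adjacency == "distant"
        assert ann.slippage is True
        assert ann.mmej is False

    def test_large_adjacent_mmej(self, pool):
        """A constructed 12-bp deletion over the cut with junction homology >= 2."""
        from imutseq.synthetic_sequencing import _mmej_candidates

        locus = pool.cut_loci[0]
        cands = [c for c in _mmej_candidates(locus) if c[1] >= 10]
        start, length, mh = cands[0]
        ann = annotate_deletion(locus, start, length)
        assert ann.size_class == "large"
        assert ann.adjacency == "adjacent"
        assert ann.mmej is True
        assert ann.microhomology_len == mh >= 2

    def test_mid_at_cut_not_mmej(self, pool):
        locus = pool.cut_loci[0]
        ann = annotate_deletion(locus, locus.cut_offset, 2)
        assert ann.size_class == "mid"
        assert ann.adjacency == "adjacent"
        assert ann.mmej is False

    def test_uncut_locus_is_distant(self, pool):
        locus = pool.by_class("UNCUT")[0]
        a, _ = locus.interior()
        ann = annotate_deletion(locus, a + 5, 3)
        assert ann.rel_dist is None and ann.adjacency == "distant"

    def test_primer_region_rejected(self, pool):
        locus = pool.cut_loci[0]
        with pytest.raises(DomainError):
            annotate_deletion(locus, 0, 2)

    def test_event_totals_partition_by_class(self, small_pool):
        """Sum of class-wise deletion totals equals the total event count."""
        spec = MutationSpectrum()
        lines, _ = simulate_pileup(small_pool, spec, 4000, seed=23)
        profile, anns = pileup_to_profile(lines, small_pool)
        total = sum(a.count for a in anns)
        by_class = profile.counts[["del_small", "del_mid", "del_large"]].sum().sum()
        assert total == by_class
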