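"""Microhomology scanner: flank extraction, left alignment, and the
scan itself, checked against brute-force oracles and structural
properties."""

import numpy as np
import pytest

from mhsig.mh import (
    extract_flanks,
    left_align_deletion,
    mh_oracle,
    reverse_complement,
    scan_deletion,
    scan_microhomology,
)
from mhsig.types import FlankContext, GenomicInterval, MHCall, ScanConfig

from conftest import BASES, random_context


def brute_force_left_align(ref: str, interval: GenomicInterval) -> GenomicInterval:
    """Leftmost same-length interval whose removal yields the same
    derived sequence — direct definition, O(n^2)."""
    length = interval.length
    derived = ref[: interval.start] + ref[interval.end:]
    for s in range(0, interval.start + 1):
        if ref[:s] + ref[s + length:] == derived:
            return GenomicInterval(interval.chrom, s, s + length)
    raise AssertionError("unreachable: the interval itself always matches")


class TestLeftAlign:
    def test_repeat_context_shifts_left(self):
        # deleting any A of the run is the same deletion; normal form is leftmost
        assert left_align_deletion("CAAAT", GenomicInterval("x", 3, 4)) == \
            GenomicInterval("x", 1, 2)

    def test_non_repetitive_context_unchanged(self):
        iv = GenomicInterval("x", 5, 8)
        assert left_align_deletion("ACGTGACTGACGT", iv) == iv

    def test_out_of_bounds_rejected(self):
        with pytest.raises(IndexError):
            left_align_deletion("ACGT", GenomicInterval("x", 2, 6))

    def test_matches_brute_force_and_idempotent(self):
        rng = np.random.default_rng(7)
        for _ in range(2000):
            n = int(rng.integers(2, 40))
            ref = "".join(BASES[i] for i in rng.integers(4, size=n))
            s = int(rng.integers(0, n - 1))
            e = int(rng.integers(s + 1, n + 1))
            iv = GenomicInterval("x", s, e)
            aligned = left_align_deletion(ref, iv)
            assert aligned == brute_force_left_align(ref, iv)
            assert left_align_deletion(ref, aligned) == aligned


class TestExtractFlanks:
    def test_boundary_truncation(self):
        ref = "".join("ACGT"[i % 4] for i in range(100))
        ctx = extract_flanks(ref, GenomicInterval("x", 5, 8))
        assert len(ctx.left_flank) == 5  # truncated at the sequence start
        assert len(ctx.right_flank) == 20

    def test_interior_deletion_full_windows(self):
        ref = "".join("ACGT"[i % 4] for i in range(100))
        ctx = extract_flanks(ref, GenomicInterval("x", 40, 50))
        assert len(ctx.left_flank) == len(ctx.right_flank) == 20

    def test_concatenation_is_reference_slice(self):
        rng = np.random.default_rng(11)
        for _ in range(500):
            n = int(rng.integers(2, 120))
            ref = "".join(BASES[i] for i in rng.integers(4, size=n))
            s = int(rng.integers(0, n - 1))
            e = int(rng.integers(s + 1, n + 1))
            ctx = extract_flanks(ref, GenomicInterval("x", s, e))
            joined = ctx.left_flank + ctx.deleted_seq + ctx.right_flank
            assert joined in ref
            assert ctx.deleted_seq == ref[s:e]


class TestScan:
    def test_planted_right_side_mh(self):
        ref = "TTTACGTGGGACGTAAA"
        ctx = extract_flanks(ref, GenomicInterval("x", 3, 10))
        call = scan_microhomology(ctx)
        assert call == MHCall(k=4, m=0, side="right", mh_seq="ACGT")

    def test_no_homology_returns_zero_call(self):
        ctx = FlankContext(left_flank="CCCCCC", deleted_seq="AT",
                           right_flank="GGGGGG")
        call = scan_microhomology(ctx)
        assert call.k == 0 and call.side == "none"

    def test_single_internal_mismatch_tolerated(self):
        # ACGTAG vs ACGTCG: mismatch at the 5th position, terminal G anchors
        ctx = FlankContext(left_flank="CCCCCC", deleted_seq="ACGTAGTTTTT",
                           right_flank="ACGTCGCCCC")
        call = scan_microhomology(ctx)
        assert (call.k, call.m, call.effective_length) == (6, 1, 5)

    def test_mismatch_requires_minimum_length(self):
        # a 3 bp near-match with 1 mismatch must not be upgraded
        ctx = FlankContext(left_flank="CCCCCC", deleted_seq="AGATTTTT",
                           right_flank="ATACCCCC")
        call = scan_microhomology(ctx, ScanConfig(min_k_for_mismatch=4))
        assert call.m == 0 and call.effective_length <= 1

    def test_mismatch_disabled_by_config(self):
        ctx = FlankContext(left_flank="CCCCCC", deleted_seq="ACGTAGTTTTT",
                           right_flank="ACGTCGCCCC")
        call = scan_microhomology(ctx, ScanConfig(allow_mismatch=False))
        assert call.m == 0 and call.k == 4

    def test_n_bases_never_match(self):
        ctx = FlankContext(left_flank="CCCCCC", deleted_seq="NNNNN",
                           right_flank="NNNNN")
        assert scan_microhomology(ctx).k == 0

    def test_k_capped_by_flank_window(self):
        w = 20
        seq = "A" * 30
        ctx = FlankContext(left_flank="C" * 20, deleted_seq=seq,
                           right_flank="A" * 20)
        call = scan_microhomology(ctx)
        assert call.k == w

    def test_oracle_equivalence_random_contexts(self, config):
        rng = np.random.default_rng(1234)
        off = ScanConfig(allow_mismatch=False)
        for _ in range(3000):
            ctx = random_context(rng)
            assert scan_microhomology(ctx, config) == mh_oracle(ctx, config)
            assert scan_microhomology(ctx, off) == mh_oracle(ctx, off)

    def test_monotone_in_planted_extension(self):
        # prepending the same base to the deleted prefix and the right
        # flank can only improve (or keep) the best effective length
        rng = np.random.default_rng(99)
        for _ in range(500):
            ctx = random_context(rng, max_del=30)
            base = BASES[int(rng.integers(4))]
            grown = FlankContext(
                left_flank=ctx.left_flank,
                deleted_seq=base + ctx.deleted_seq,
                right_flank=base + ctx.right_flank,
            )
            assert (
                scan_microhomology(grown).effective_length
                >= scan_microhomology(ctx).effective_length
            )

    def test_reverse_complement_symmetry(self):
        rng = np.random.default_rng(4321)
        for _ in range(500):
            n = int(rng.integers(5, 80))
            ref = "".join(BASES[i] for i in rng.integers(4, size=n))
            s = int(rng.integers(0, n - 1))
            e = int(rng.integers(s + 1, n + 1))
            fwd = scan_microhomology(extract_flanks(ref, GenomicInterval("x", s, e)))
            rc = reverse_complement(ref)
            rc_iv = GenomicInterval("x", n - e, n - s)
            rev = scan_microhomology(extract_flanks(rc, rc_iv))
            assert fwd.effective_length == rev.effective_length


def test_scan_deletion_invariant_under_representation(config):
    """Equivalent deletion representations in a repeat get one answer."""
    ref = "TTTACGTGGGACGTAAA"
    a1, c1 = scan_deletion(ref, GenomicInterval("x", 3, 10), config)
    # the equivalent representation starting inside the repeat
    a2, c2 = scan_deletion(ref, left_align_deletion(ref, GenomicInterval("x", 3, 10)), config)
    assert a1 == a2 and c1 == c2
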