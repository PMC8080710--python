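"""Microhomology scanning at deletion breakpoints.

The MMEJ repair model predicts that a double-strand break between two
short identical sequences (microhomologies, MHs) is resolved by
annealing the two copies, deleting one copy plus the intervening
sequence.  The surviving junction therefore carries a deletion whose
*deleted sequence* shares a prefix with the right flank (the retained
downstream MH copy) or a suffix with the left flank.  This module
extracts flanks, left-aligns deletions so that equivalent coordinate
representations scan identically, and finds the best-supported MH.

Mismatch rule: a single internal mismatch is tolerated, but only for
raw match lengths >= ``min_k_for_mismatch`` and only when the first and
last compared bases match exactly (a mismatch at a terminus would just
be a shorter exact match).  Classification uses the *effective* length
``k - m``.  Any comparison involving an ``N`` base counts as a mismatch.
"""

from __future__ import annotations

from .types import NO_MH, DEFAULT_CONFIG, FlankContext, GenomicInterval, MHCall, ScanConfig


_RC = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_RC)[::-1]


def left_align_deletion(ref: str, interval: GenomicInterval) -> GenomicInterval:
    """Shift a deletion to its leftmost equivalent representation.

    Two same-length deletions are equivalent when removing either yields
    the same derived sequence; the leftmost one is the normal form
    (VCF-style left alignment).
    """
    start, end = interval.start, interval.end
    if start < 0 or end > len(ref):
        raise IndexError(
            f"interval {interval.start}-{interval.end} out of bounds for "
            f"reference of length {len(ref)}"
        )
    while start > 0 and ref[start - 1] == ref[end - 1]:
        start -= 1
        end -= 1
    return GenomicInterval(interval.chrom, start, end)


def extract_flanks(
    ref: str, interval: GenomicInterval, config: ScanConfig = DEFAULT_CONFIG
) -> FlankContext:
    """Cut the deletion and its <= W bp flanks out of the reference.

    Flanks are truncated at sequence boundaries, never padded.
    """
    if interval.start < 0 or interval.end > len(ref):
        raise IndexError(
            f"interval {interval.start}-{interval.end} out of bounds for "
            f"reference of length {len(ref)}"
        )
    w = config.flank_window
    return FlankContext(
        left_flank=ref[max(0, interval.start - w): interval.start].upper(),
        deleted_seq=ref[interval.start: interval.end].upper(),
        right_flank=ref[interval.end: interval.end + w].upper(),
    )


def _mismatch_positions(a: str, b: str) -> list[int]:
    # N never matches anything, including N
    return [i for i, (x, y) in enumerate(zip(a, b)) if x != y or x == "N" or y == "N"]


def _candidate(a: str, b: str, k: int, config: ScanConfig) -> int | None:
    """Mismatch count of the k-length comparison of a vs b, or None if
    the comparison is not an admissible MH candidate."""
    mm = _mismatch_positions(a, b)
    if not mm:
        return 0
    if (
        len(mm) == 1
        and config.allow_mismatch
        and k >= config.min_k_for_mismatch
        and 0 < mm[0] < k - 1
    ):
        return 1
    return None


def scan_microhomology(
    ctx: FlankContext, config: ScanConfig = DEFAULT_CONFIG
) -> MHCall:
    """Find the best microhomology explaining a deletion.

    Right-side candidates compare the first k deleted bases with the
    first k bases of the right flank; left-side candidates compare the
    last k deleted bases with the last k bases of the left flank.  The
    call maximizes effective length ``k - m``; ties prefer fewer
    mismatches, then the right side.  A ``k = 0`` call is returned when
    no candidate reaches effective length 1.
    """
    d = ctx.deleted_seq
    L = len(d)
    best: tuple[int, int, int, str, str] | None = None  # (eff, -m_pref, side_pref, ...)

    for side, flank in (("right", ctx.right_flank), ("left", ctx.left_flank)):
        kmax = min(L, config.flank_window, len(flank))
        for k in range(1, kmax + 1):
            if side == "right":
                a, b = d[:k], flank[:k]
            else:
                a, b = d[L - k:], flank[len(flank) - k:]
            m = _candidate(a, b, k, config)
            if m is None:
                continue
            eff = k - m
            if eff < 1:
                continue
            rank = (eff, -m, 1 if side == "right" else 0)
            if best is None or rank > best[:3]:
                best = (*rank, side, b)
    if best is None:
        return NO_MH
    eff, neg_m, _, side, mh_seq = best
    m = -neg_m
    return MHCall(k=eff + m, m=m, side=side, mh_seq=mh_seq)


def mh_oracle(ctx: FlankContext, config: ScanConfig = DEFAULT_CONFIG) -> MHCall:
    """Exhaustive reference scanner (test support).

    Enumerates every (side, k, mismatch placement) explicitly and keeps
    the best under the same objective as :func:`scan_microhomology`;
    kept deliberately naive so the two implementations can check each
    other.
    """
    d = ctx.deleted_seq
    L = len(d)
    candidates: list[tuple[tuple[int, int, int], str, str, int, int]] = []
    for side, flank in (("left", ctx.left_flank), ("right", ctx.right_flank)):
        for k in range(1, min(L, config.flank_window, len(flank)) + 1):
            if side == "right":
                a, b = d[:k], flank[:k]
            else:
                a, b = d[L - k:], flank[len(flank) - k:]
            for m in (0, 1):
                if m == 1 and not (config.allow_mismatch and k >= config.min_k_for_mismatch):
                    continue
                mm = _mismatch_positions(a, b)
                if m == 0 and mm:
                    continue
                if m == 1 and not (len(mm) == 1 and 0 < mm[0] < k - 1):
                    continue
                if k - m < 1:
                    continue
                rank = (k - m, -m, 1 if side == "right" else 0)
                candidates.append((rank, side, b, k, m))
    if not candidates:
        return NO_MH
    rank, side, mh_seq, k, m = max(candidates, key=lambda c: c[0])
    return MHCall(k=k, m=m, side=side, mh_seq=mh_seq)


def scan_deletion(
    ref: str, interval: GenomicInterval, config: ScanConfig = DEFAULT_CONFIG
) -> tuple[GenomicInterval, MHCall]:
    """Left-align, extract flanks and scan in one step."""
    aligned = left_align_deletion(ref, interval)
    return aligned, scan_microhomology(extract_flanks(ref, aligned, config), config)
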