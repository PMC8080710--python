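"""Prediction of MMEJ deletion products from a double-strand-break site.

Given a sequence and a cut position, every pair of identical k-mers
(microhomology copies) straddling the cut defines a candidate repair
product: annealing at the two copies deletes one copy plus the sequence
between them.  Which products actually dominate depends on the break
position relative to the MH pair, which is why sequential cuts along a
locus produce different deletion spectra.
"""

from __future__ import annotations

from dataclasses import dataclass

from .types import GenomicInterval


@dataclass(frozen=True)
class CutSite:
    """A sequence with a DSB at gap position ``cut`` (0-based, between
    ``seq[cut-1]`` and ``seq[cut]``)."""

    seq: str
    cut: int

    def __post_init__(self) -> None:
        if not 0 <= self.cut <= len(self.seq):
            raise IndexError(
                f"cut {self.cut} outside sequence of length {len(self.seq)}"
            )


@dataclass(frozen=True)
class MMEJProduct:
    """One predicted deletion allele: MH copies at [i, i+k) and
    [j, j+k); repair deletes [i, j), retaining the downstream copy."""

    i: int
    j: int
    k: int
    seq_name: str = "seq"

    @property
    def left_mh(self) -> GenomicInterval:
        return GenomicInterval(self.seq_name, self.i, self.i + self.k)

    @property
    def right_mh(self) -> GenomicInterval:
        return GenomicInterval(self.seq_name, self.j, self.j + self.k)

    @property
    def deletion(self) -> GenomicInterval:
        return GenomicInterval(self.seq_name, self.i, self.j)

    @property
    def deletion_length(self) -> int:
        return self.j - self.i

    def product_seq(self, seq: str) -> str:
        return seq[: self.i] + seq[self.j:]


def _admissible(i: int, j: int, k: int, cut: int, search_window: int) -> bool:
    return (
        i + k <= cut <= j
        and cut - i <= search_window
        and j + k - cut <= search_window
    )


def enumerate_mh_pairs(
    site: CutSite,
    k_min: int = 2,
    k_max: int = 25,
    search_window: int = 60,
) -> list[MMEJProduct]:
    """Enumerate candidate MMEJ products for a cut.

    A pair (i, j, k) is reported when seq[i:i+k] == seq[j:j+k] exactly,
    k_min <= k <= k_max, the cut lies between the copies
    (i + k <= cut <= j) and both copies lie within ``search_window`` bp
    of the cut.  For each (i, j) only the maximal k is kept, and a pair
    whose match interval is contained in a longer reported pair on the
    same diagonal (same deletion length) is suppressed.  Ranking is
    (k descending, deletion length ascending, i ascending).
    """
    seq = site.seq.upper()
    cut = site.cut
    n = len(seq)
    lo = max(0, cut - search_window)
    hi = min(n, cut + search_window)

    # best k per (i, j): scan diagonals d = j - i, find runs of matching
    # positions p: seq[p] == seq[p + d]
    best: dict[tuple[int, int], int] = {}
    for d in range(1, hi - lo):
        p = lo
        while p + d < hi:
            if seq[p] != seq[p + d] or seq[p] == "N":
                p += 1
                continue
            run_start = p
            while p + d < hi and seq[p] == seq[p + d] and seq[p] != "N":
                p += 1
            run_len = p - run_start
            # place (i, k) within the run subject to the cut constraints
            for i in range(run_start, run_start + run_len):
                j = i + d
                k_cap = min(run_len - (i - run_start), k_max, d)
                for k in range(k_cap, k_min - 1, -1):
                    if _admissible(i, j, k, cut, search_window):
                        if best.get((i, j), 0) < k:
                            best[(i, j)] = k
                        break
    # suppress sub-matches: same diagonal, match interval contained in a
    # longer kept pair
    kept = []
    items = sorted(best.items(), key=lambda kv: -kv[1])
    for (i, j), k in items:
        contained = any(
            (j2 - i2) == (j - i) and i2 <= i and i2 + k2 >= i + k and (i2, j2, k2) != (i, j, k)
            for (i2, j2), k2 in best.items()
        )
        if not contained:
            kept.append(MMEJProduct(i=i, j=j, k=k))
    kept.sort(key=lambda p: (-p.k, p.deletion_length, p.i))
    return kept


def predict_for_guides(
    ref: str,
    cut_positions: list[int],
    target: GenomicInterval | None = None,
    k_min: int = 2,
    k_max: int = 25,
    search_window: int = 60,
) -> dict[int, tuple[list[MMEJProduct], bool]]:
    """Predict products for several cut positions along one locus.

    Returns, per cut, the ranked product list and a flag telling whether
    a designated target deletion interval is among the products.
    """
    out: dict[int, tuple[list[MMEJProduct], bool]] = {}
    for cut in cut_positions:
        products = enumerate_mh_pairs(
            CutSite(ref, cut), k_min=k_min, k_max=k_max, search_window=search_window
        )
        hit = target is not None and any(
            p.i == target.start and p.j == target.end for p in products
        )
        out[cut] = (products, hit)
    return out
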