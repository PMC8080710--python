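"""Signature classification and cohort summaries.

The three-way deletion signature: long (>=5 bp) deletions flanked by
microhomology of effective length >= 2 bp (MH_DEL, the MMEJ hallmark),
long deletions without such flanks (LONG_NO_MH_DEL) and short (<5 bp)
deletions (SHORT_DEL, the c-NHEJ-associated class).
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Callable, Sequence

from .types import (
    DEFAULT_CONFIG,
    DeletionRecord,
    MHCall,
    ScanConfig,
    SignatureClass,
    TruncationClass,
)

DELETION_CLASSES = (
    SignatureClass.MH_DEL,
    SignatureClass.LONG_NO_MH_DEL,
    SignatureClass.SHORT_DEL,
)


def classify_deletion(
    length: int, mh: MHCall, config: ScanConfig = DEFAULT_CONFIG
) -> SignatureClass:
    """Assign one of the three deletion classes.

    Mismatch tolerance is honoured through the *effective* MH length
    (k - m): a 3 bp match using one mismatch counts as 2 bp.
    """
    if length <= 0:
        raise ValueError(f"deletion length must be positive, got {length}")
    if length < config.long_del_threshold:
        return SignatureClass.SHORT_DEL
    if mh.effective_length >= config.mh_class_threshold:
        return SignatureClass.MH_DEL
    return SignatureClass.LONG_NO_MH_DEL


def classify_truncating(
    variant_type: str,
    deletion_length: int | None = None,
    mh: MHCall | None = None,
    config: ScanConfig = DEFAULT_CONFIG,
) -> TruncationClass:
    """Classify a protein-truncating variant.

    ``variant_type`` is one of ``nonsense``, ``insertion`` or
    ``deletion`` (frameshifting); deletions are subclassified by the
    deletion signature.  Non-truncating input is rejected.
    """
    if variant_type == "nonsense":
        return TruncationClass.NONSENSE
    if variant_type == "insertion":
        return TruncationClass.FS_INSERTION
    if variant_type == "deletion":
        if deletion_length is None or mh is None:
            raise ValueError("deletion truncations need a length and an MH call")
        sig = classify_deletion(deletion_length, mh, config)
        return {
            SignatureClass.SHORT_DEL: TruncationClass.FS_DEL_SHORT,
            SignatureClass.MH_DEL: TruncationClass.FS_DEL_LONG_MH,
            SignatureClass.LONG_NO_MH_DEL: TruncationClass.FS_DEL_LONG_NO_MH,
        }[sig]
    raise ValueError(f"not a truncating variant type: {variant_type!r}")


@dataclass
class RecurrentDeletion:
    gene: str
    mutation_cds: str
    signature: SignatureClass
    sample_count: int


@dataclass
class CohortSummary:
    """Per-deletion recurrence counts plus per-class totals.

    ``recurrent`` lists unique deletions with at least
    ``recurrence_min_samples`` unique carriers, ordered by sample count
    descending then key; ``class_totals`` counts every retained record.
    """

    recurrent: list[RecurrentDeletion]
    all_deletions: list[RecurrentDeletion]
    class_totals: dict[SignatureClass, int] = field(default_factory=dict)

    @property
    def total_records(self) -> int:
        return sum(self.class_totals.values())


def summarize_cohort(
    assigned: Sequence[tuple[DeletionRecord, SignatureClass]],
    config: ScanConfig = DEFAULT_CONFIG,
) -> CohortSummary:
    """Group records by (gene, canonical CDS name) and count carriers.

    ``sample_count`` counts unique sample ids per deletion.  The
    per-class totals count records, so they sum to the number of
    retained records (conservation).
    """
    samples: dict[tuple[str, str], set[str]] = defaultdict(set)
    sigs: dict[tuple[str, str], SignatureClass] = {}
    totals: Counter[SignatureClass] = Counter()
    for rec, sig in assigned:
        key = (rec.gene, rec.mutation_cds)
        samples[key].add(rec.sample_id)
        sigs[key] = sig
        totals[sig] += 1
    rows = [
        RecurrentDeletion(gene=g, mutation_cds=c, signature=sigs[(g, c)],
                          sample_count=len(s))
        for (g, c), s in samples.items()
    ]
    rows.sort(key=lambda r: (-r.sample_count, r.gene, r.mutation_cds))
    recurrent = [r for r in rows if r.sample_count >= config.recurrence_min_samples]
    return CohortSummary(
        recurrent=recurrent,
        all_deletions=rows,
        class_totals={c: totals.get(c, 0) for c in DELETION_CLASSES},
    )


def contingency_by_group(
    assigned: Sequence[tuple[DeletionRecord, SignatureClass]],
    grouping: Callable[[DeletionRecord], str],
    group_order: Sequence[str] | None = None,
) -> list[list[int]]:
    """Build the 2x2 table of MH_DEL vs other deletions by group.

    Rows are the two groups (in ``group_order`` or sorted order),
    columns are (MH_DEL, other deletion).  Cell counts sum to the total
    number of deletion records.
    """
    counts: dict[str, list[int]] = defaultdict(lambda: [0, 0])
    for rec, sig in assigned:
        if sig not in DELETION_CLASSES:
            continue
        g = grouping(rec)
        counts[g][0 if sig is SignatureClass.MH_DEL else 1] += 1
    groups = list(group_order) if group_order else sorted(counts)
    if len(groups) != 2 or any(g not in counts for g in groups):
        raise ValueError(
            f"need exactly two non-empty groups, got {sorted(counts)}"
        )
    return [counts[groups[0]], counts[groups[1]]]
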