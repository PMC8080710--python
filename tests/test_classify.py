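import numpy as np
import pytest

from mhsig.classify import (
    classify_deletion,
    classify_truncating,
    contingency_by_group,
    summarize_cohort,
)
from mhsig.types import (
    DeletionRecord,
    GenomicInterval,
    MHCall,
    NO_MH,
    ScanConfig,
    SignatureClass,
    TruncationClass,
)


def _mh(eff):
    return MHCall(k=eff, m=0, side="right", mh_seq="A" * eff) if eff else NO_MH


@pytest.mark.parametrize(
    "length,eff,expected",
    [
        (3, 4, SignatureClass.SHORT_DEL),      # short wins regardless of MH
        (4, 0, SignatureClass.SHORT_DEL),
        (5, 2, SignatureClass.MH_DEL),
        (23, 4, SignatureClass.MH_DEL),        # the recurrent-deletion geometry
        (7, 1, SignatureClass.LONG_NO_MH_DEL),
        (5, 0, SignatureClass.LONG_NO_MH_DEL),
    ],
)
def test_three_way_partition(length, eff, expected):
    assert classify_deletion(length, _mh(eff)) == expected


def test_mismatch_counts_via_effective_length():
    # raw 3 bp with one mismatch = effective 2 bp -> reaches the MH bar
    call = MHCall(k=3, m=1, side="right", mh_seq="AAA")
    assert classify_deletion(10, call) == SignatureClass.MH_DEL
    # raw 2 bp with one mismatch would be 50% identity; the scanner never
    # emits it, and effective length 1 would not classify as MH anyway
    assert classify_deletion(10, MHCall(k=2, m=0, side="left", mh_seq="AA")) \
        == SignatureClass.MH_DEL


def test_nonpositive_length_rejected():
    with pytest.raises(ValueError):
        classify_deletion(0, NO_MH)


class TestTruncating:
    def test_nonsense_passthrough(self):
        assert classify_truncating("nonsense") == TruncationClass.NONSENSE

    def test_insertion_passthrough(self):
        assert classify_truncating("insertion") == TruncationClass.FS_INSERTION

    def test_deletion_subclassified_by_signature(self):
        assert classify_truncating("deletion", 23, _mh(4)) \
            == TruncationClass.FS_DEL_LONG_MH
        assert classify_truncating("deletion", 2, NO_MH) \
            == TruncationClass.FS_DEL_SHORT
        assert classify_truncating("deletion", 8, _mh(1)) \
            == TruncationClass.FS_DEL_LONG_NO_MH

    def test_non_truncating_rejected(self):
        with pytest.raises(ValueError):
            classify_truncating("missense")


def _record(sample, gene="G", cds="c.1_5del5", site="x", start=0, end=5):
    return DeletionRecord(
        sample_id=sample, gene=gene, mutation_cds=cds,
        interval=GenomicInterval("chr1", start, end), primary_site=site,
    )


class TestSummarize:
    def test_recurrence_threshold(self):
        assigned = [(_record(f"s{i}"), SignatureClass.MH_DEL) for i in range(12)]
        assigned += [
            (_record(f"t{i}", cds="c.9_13del5", start=8, end=13),
             SignatureClass.LONG_NO_MH_DEL)
            for i in range(9)
        ]
        s = summarize_cohort(assigned)
        assert [r.sample_count for r in s.recurrent] == [12]
        assert {r.mutation_cds for r in s.all_deletions} == {"c.1_5del5", "c.9_13del5"}
        # below-threshold deletion still counted in totals
        assert s.class_totals[SignatureClass.LONG_NO_MH_DEL] == 9
        assert s.total_records == 21

    def test_sample_count_is_unique_samples(self):
        assigned = [(_record("dup"), SignatureClass.MH_DEL)] * 3
        s = summarize_cohort(assigned)
        assert s.all_deletions[0].sample_count == 1
        assert s.class_totals[SignatureClass.MH_DEL] == 3

    def test_partition_conservation_random(self):
        rng = np.random.default_rng(0)
        classes = list(SignatureClass)[:3]
        assigned = [
            (_record(f"s{i}", cds=f"c.{i}_{i+4}del5", start=i, end=i + 5),
             classes[int(rng.integers(3))])
            for i in range(200)
        ]
        s = summarize_cohort(assigned)
        assert sum(s.class_totals.values()) == 200

    def test_deterministic_ordering(self):
        assigned = [(_record(f"s{i}"), SignatureClass.MH_DEL) for i in range(10)]
        assigned += [(_record(f"s{i}", gene="A", cds="c.2_6del5", start=1, end=6),
                      SignatureClass.MH_DEL) for i in range(10)]
        s = summarize_cohort(assigned, ScanConfig(recurrence_min_samples=10))
        # equal counts: ordered by key
        assert [r.gene for r in s.recurrent] == ["A", "G"]


class TestContingency:
    def test_printed_cohort_table(self):
        assigned = []
        for n, sig, site in [
            (153, SignatureClass.MH_DEL, "heme"),
            (223, SignatureClass.SHORT_DEL, "heme"),
            (4, SignatureClass.MH_DEL, "solid"),
            (99, SignatureClass.LONG_NO_MH_DEL, "solid"),
        ]:
            assigned += [
                (_record(f"{site}{sig.value}{i}", site=site), sig) for i in range(n)
            ]
        table = contingency_by_group(
            assigned, lambda r: r.primary_site, group_order=("heme", "solid")
        )
        assert table == [[153, 223], [4, 99]]
        assert sum(map(sum, table)) == len(assigned)

    def test_single_group_is_degenerate(self):
        assigned = [(_record("s1"), SignatureClass.MH_DEL)]
        with pytest.raises(ValueError):
            contingency_by_group(assigned, lambda r: "only")

    def test_margins_equal_group_sizes(self):
        rng = np.random.default_rng(5)
        classes = list(SignatureClass)[:3]
        assigned = [
            (_record(f"s{i}", site="A" if rng.random() < 0.6 else "B"),
             classes[int(rng.integers(3))])
            for i in range(300)
        ]
        table = contingency_by_group(assigned, lambda r: r.primary_site,
                                     group_order=("A", "B"))
        sizes = {"A": 0, "B": 0}
        for rec, _ in assigned:
            sizes[rec.primary_site] += 1
        assert [sum(row) for row in table] == [sizes["A"], sizes["B"]]
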