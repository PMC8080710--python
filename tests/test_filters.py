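import pytest

from mhsig.filters import (
    apply_chain,
    dedup_samples,
    filter_adjacent_snps,
    filter_maf,
    filter_myeloid,
    filter_publications,
    filter_regions,
    merge_isoforms,
)
from mhsig.simulate import simulate_deletion_cohort
from mhsig.types import DeletionRecord, GenomicInterval, ScanConfig


def _rec(sample="s1", gene="G", cds="c.1_5del5", start=100, end=105,
         site="haematopoietic_and_lymphoid_tissue",
         hist="haematopoietic_neoplasm", region="exonic",
         pubs=("p1", "p2"), maf=None):
    return DeletionRecord(
        sample_id=sample, gene=gene, mutation_cds=cds,
        interval=GenomicInterval("chr1", start, end),
        primary_site=site, primary_histology=hist, region_class=region,
        pubmed_ids=frozenset(pubs), maf=maf or {},
    )


class TestDedup:
    def test_identical_rows_collapse(self):
        assert len(dedup_samples([_rec(), _rec()])) == 1

    def test_distinct_deletions_same_sample_kept(self):
        out = dedup_samples([_rec(), _rec(cds="c.9_13del5", start=108, end=113)])
        assert len(out) == 2

    def test_idempotent(self):
        rs = [_rec(), _rec(), _rec(sample="s2")]
        once = dedup_samples(rs)
        assert dedup_samples(once) == once


class TestMergeIsoforms:
    def test_shared_interval_gets_majority_name(self):
        rs = [
            _rec(sample="a", cds="c.1900_1922del23"),
            _rec(sample="b", cds="c.1900_1922del23"),
            _rec(sample="c", cds="c.1888_1910del23"),
        ]
        merged = merge_isoforms(rs)
        assert {r.mutation_cds for r in merged} == {"c.1900_1922del23"}

    def test_tie_broken_lexicographically(self):
        rs = [_rec(sample="a", cds="c.2_6del5"), _rec(sample="b", cds="c.1_5del5")]
        assert {r.mutation_cds for r in merge_isoforms(rs)} == {"c.1_5del5"}

    def test_distinct_intervals_untouched(self):
        rs = [_rec(), _rec(cds="c.9_13del5", start=200, end=205)]
        assert merge_isoforms(rs) == rs

    def test_unique_sample_counts_preserved(self):
        rs = [
            _rec(sample=f"s{i}", cds=f"c.{1 + (i % 2)}_x")  # two isoform names
            for i in range(10)
        ]
        assert len({r.sample_id for r in merge_isoforms(rs)}) == 10


class TestMaf:
    def test_at_threshold_removed(self):
        assert filter_maf([_rec(maf={"ExAC_ALL": 0.001})]) == []
        assert filter_maf([_rec(maf={"AF": 0.0001})]) == []

    def test_all_missing_retained(self):
        rs = [_rec(maf={})]
        assert filter_maf(rs) == rs

    def test_below_threshold_retained(self):
        rs = [_rec(maf={k: 0.00005 for k in ("AF", "ExAC_ALL", "Kaviar_AF",
                                             "ExAC_nonpsych_ALL", "AF_popmax")})]
        assert filter_maf(rs) == rs

    def test_missing_distinct_from_zero(self):
        # explicit 0.0 is data below threshold; missing is no data: both kept,
        # but only because both are below the bar, not by coercion
        rs = [_rec(maf={"AF": 0.0}), _rec(sample="s2", maf={})]
        assert filter_maf(rs) == rs


class TestRegionsAndTissue:
    def test_intronic_intergenic_removed_unknown_kept(self):
        rs = [_rec(region="intronic"), _rec(sample="b", region="intergenic"),
              _rec(sample="c", region="exonic"), _rec(sample="d", region="unknown")]
        assert [r.sample_id for r in filter_regions(rs)] == ["c", "d"]

    def test_lymphoid_histology_removed(self):
        assert filter_myeloid([_rec(hist="lymphoid_neoplasm")]) == []

    def test_myeloid_histology_kept(self):
        rs = [_rec(hist="haematopoietic_neoplasm")]
        assert filter_myeloid(rs) == rs

    def test_non_heme_site_removed(self):
        assert filter_myeloid([_rec(site="lung")]) == []

    def test_site_matching_separator_insensitive(self):
        rs = [_rec(site="Haematopoietic and lymphoid tissue")]
        assert filter_myeloid(rs) == rs


class TestPublications:
    def test_single_publication_removed(self):
        assert filter_publications([_rec(pubs=("p1",))]) == []

    def test_three_publications_kept(self):
        rs = [_rec(pubs=("p1", "p2", "p3"))]
        assert filter_publications(rs) == rs

    def test_empty_set_counts_as_single(self):
        assert filter_publications([_rec(pubs=())]) == []

    def test_union_across_samples(self):
        rs = [_rec(sample="a", pubs=("p1",)), _rec(sample="b", pubs=("p2",))]
        assert filter_publications(rs) == rs


class TestAdjacentSnps:
    def test_snp_in_flank_window_removes(self):
        rs = [_rec(start=100, end=105)]
        assert filter_adjacent_snps(rs, [("chr1", 110)]) == []  # 5 bp downstream

    def test_far_snp_kept(self):
        rs = [_rec(start=100, end=105)]
        assert filter_adjacent_snps(rs, [("chr1", 155)]) == rs  # 50 bp away

    def test_empty_snp_set_is_identity(self):
        rs = [_rec()]
        assert filter_adjacent_snps(rs, []) == rs

    def test_window_follows_config(self):
        rs = [_rec(start=100, end=105)]
        narrow = ScanConfig(flank_window=3)
        assert filter_adjacent_snps(rs, [("chr1", 110)], narrow) == rs


class TestChain:
    def test_report_reconciles_and_filters_idempotent(self):
        rs = [
            _rec(), _rec(),                             # duplicate
            _rec(sample="b", hist="lymphoid_neoplasm"),
            _rec(sample="c", region="intronic"),
            _rec(sample="d", maf={"AF": 0.01}),
            _rec(sample="e", cds="c.50_54del5", start=149, end=154, pubs=("only",)),
            _rec(sample="f"),
        ]
        kept, report = apply_chain(rs)
        assert {r.sample_id for r in kept} == {"s1", "f"}
        for prev, nxt in zip(report.steps, report.steps[1:]):
            assert prev.retained == nxt.input_count
        assert report.steps[0].input_count == len(rs)
        assert report.steps[-1].retained == len(kept)
        # running the chain again removes nothing
        kept2, report2 = apply_chain(kept)
        assert kept2 == kept
        assert all(s.removed == 0 for s in report2.steps)

    def test_contaminant_recovery_against_manifest(self):
        records, _, manifest = simulate_deletion_cohort(
            seed=17, n_records=400, snp_rate=0.1, lymphoid_rate=0.1,
            single_pub_rate=0.1,
        )
        kept, _ = apply_chain(records)
        kept_ids = {r.sample_id for r in kept}
        for truth in manifest["records"]:
            if truth["contaminant"] is None:
                assert truth["sample_id"] in kept_ids
            else:
                assert truth["sample_id"] not in kept_ids
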