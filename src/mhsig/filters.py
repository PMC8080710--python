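"""The record-curation stack applied to public cohort tables before
signature counting: dedup, isoform merging, tissue selection, region and
germline filters.

Each step is a pure function ``records -> records``; :func:`apply_chain`
runs them in a fixed order and keeps an auditable per-step report.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

from .types import DEFAULT_CONFIG, DeletionRecord, GenomicInterval, ScanConfig


@dataclass
class FilterStep:
    name: str
    input_count: int
    removed: int

    @property
    def retained(self) -> int:
        return self.input_count - self.removed


@dataclass
class FilterReport:
    steps: list[FilterStep] = field(default_factory=list)

    def add(self, name: str, before: int, after: int) -> None:
        self.steps.append(FilterStep(name, before, before - after))

    def as_dict(self) -> dict:
        return {
            "steps": [
                {"name": s.name, "input": s.input_count,
                 "removed": s.removed, "retained": s.retained}
                for s in self.steps
            ]
        }


def dedup_samples(records: Sequence[DeletionRecord]) -> list[DeletionRecord]:
    """Keep one record per (sample, gene, CDS name); first wins."""
    seen: set[tuple[str, str, str]] = set()
    out = []
    for r in records:
        key = (r.sample_id, r.gene, r.mutation_cds)
        if key not in seen:
            seen.add(key)
            out.append(r)
    return out


def merge_isoforms(records: Sequence[DeletionRecord]) -> list[DeletionRecord]:
    """Give records sharing a genomic interval one canonical CDS name.

    The same genomic deletion may carry several HGVS c. names because
    transcripts differ; the canonical name is the most frequent one
    among the merged records, ties broken lexicographically.
    """
    by_interval: dict[tuple[str, GenomicInterval], Counter[str]] = defaultdict(Counter)
    for r in records:
        by_interval[(r.gene, r.interval)][r.mutation_cds] += 1
    canonical = {
        key: min(names.items(), key=lambda kv: (-kv[1], kv[0]))[0]
        for key, names in by_interval.items()
    }
    out = []
    for r in records:
        name = canonical[(r.gene, r.interval)]
        if name != r.mutation_cds:
            r = DeletionRecord(
                sample_id=r.sample_id, gene=r.gene, interval=r.interval,
                mutation_cds=name, deleted_seq=r.deleted_seq,
                primary_site=r.primary_site, primary_histology=r.primary_histology,
                region_class=r.region_class, pubmed_ids=r.pubmed_ids, maf=dict(r.maf),
            )
        out.append(r)
    return out


def _norm(text: str) -> str:
    return "".join(ch if ch.isalnum() else "_" for ch in text.lower())


def filter_myeloid(records: Sequence[DeletionRecord]) -> list[DeletionRecord]:
    """Keep myeloid records: haematopoietic/lymphoid primary site whose
    histology does not contain 'lymph' (case- and separator-insensitive)."""
    out = []
    for r in records:
        site_ok = "haematopoietic_and_lymphoid" in _norm(r.primary_site)
        histology_ok = "lymph" not in r.primary_histology.lower()
        if site_ok and histology_ok:
            out.append(r)
    return out


def filter_regions(records: Sequence[DeletionRecord]) -> list[DeletionRecord]:
    """Drop intronic and intergenic records; exonic and unknown stay."""
    return [r for r in records if r.region_class not in ("intronic", "intergenic")]


def filter_adjacent_snps(
    records: Sequence[DeletionRecord],
    snp_positions: Iterable[tuple[str, int]],
    config: ScanConfig = DEFAULT_CONFIG,
) -> list[DeletionRecord]:
    """Drop deletions with a common SNP inside the deletion or its
    flank window (the same W bp used for MH scanning).

    ``snp_positions`` are (chrom, 0-based position) pairs.
    """
    by_chrom: dict[str, list[int]] = defaultdict(list)
    for chrom, pos in snp_positions:
        by_chrom[chrom].append(pos)
    w = config.flank_window
    out = []
    for r in records:
        lo = r.interval.start - w
        hi = r.interval.end + w
        if any(lo <= p < hi for p in by_chrom.get(r.interval.chrom, ())):
            continue
        out.append(r)
    return out


def filter_maf(
    records: Sequence[DeletionRecord], config: ScanConfig = DEFAULT_CONFIG
) -> list[DeletionRecord]:
    """Drop likely germline variants: any population MAF at or above the
    threshold (default 1e-4) in any dataset.  Records with no MAF data in
    any dataset are retained."""
    out = []
    for r in records:
        for value in r.maf.values():
            if value < 0:
                raise ValueError(f"negative MAF on {r.mutation_cds!r}")
        if any(v >= config.maf_threshold for v in r.maf.values()):
            continue
        out.append(r)
    return out


def filter_publications(records: Sequence[DeletionRecord]) -> list[DeletionRecord]:
    """Drop unique deletions reported by at most one publication.

    PubMed ids are unioned across all samples carrying the deletion; an
    empty set counts as single-publication (conservative removal).
    """
    pubs: dict[tuple[str, str], set[str]] = defaultdict(set)
    for r in records:
        pubs[(r.gene, r.mutation_cds)] |= r.pubmed_ids
    return [r for r in records if len(pubs[(r.gene, r.mutation_cds)]) > 1]


def apply_chain(
    records: Sequence[DeletionRecord],
    snp_positions: Iterable[tuple[str, int]] = (),
    config: ScanConfig = DEFAULT_CONFIG,
    skip: Sequence[str] = (),
) -> tuple[list[DeletionRecord], FilterReport]:
    """Run the full curation chain in its canonical order:

    dedup -> merge_isoforms -> myeloid -> regions -> adjacent_snps
    -> maf -> publications

    ``skip`` names steps to omit (e.g. ``("myeloid", "publications")``
    for cohorts that are already tissue-restricted).
    """
    snp_positions = list(snp_positions)
    steps: list[tuple[str, Callable[[list[DeletionRecord]], list[DeletionRecord]]]] = [
        ("dedup", dedup_samples),
        ("merge_isoforms", merge_isoforms),
        ("myeloid", filter_myeloid),
        ("regions", filter_regions),
        ("adjacent_snps", lambda rs: filter_adjacent_snps(rs, snp_positions, config)),
        ("maf", lambda rs: filter_maf(rs, config)),
        ("publications", filter_publications),
    ]
    report = FilterReport()
    current = list(records)
    for name, fn in steps:
        if name in skip:
            continue
        before = len(current)
        current = fn(current)
        report.add(name, before, len(current))
    return current, report
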