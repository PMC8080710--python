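"""Readers and writers for the external formats the pipeline touches:
FASTA references, COSMIC-style cohort tables, BED intervals, amplicon
VCFs and the classified-deletion output table.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pysam
from Bio import SeqIO

from .types import DeletionRecord, GenomicInterval, IndelAllele, MHCall, SignatureClass

_IUPAC = set("ACGTUNRYSWKMBDHV")

MAF_DATASETS = ("AF", "ExAC_ALL", "Kaviar_AF", "ExAC_nonpsych_ALL", "AF_popmax")


class FormatError(ValueError):
    pass


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into {name: upper-case sequence}.

    Names are the first whitespace-delimited token of each header.
    Non-IUPAC characters raise a :class:`FormatError` naming the line.
    """
    path = Path(path)
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        bad = set(seq) - _IUPAC
        if bad:
            # locate the offending line for the error message
            with open(path) as fh:
                for lineno, line in enumerate(fh, 1):
                    if not line.startswith(">") and set(line.strip().upper()) - _IUPAC:
                        raise FormatError(
                            f"{path}:{lineno}: non-IUPAC characters {sorted(bad)}"
                        )
            raise FormatError(f"{path}: non-IUPAC characters {sorted(bad)}")
        seqs[rec.id] = seq
    return seqs


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 70) -> None:
    """Write sequences in deterministic (insertion) order."""
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i: i + width] + "\n")


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED3+ intervals (0-based half-open, as BED is defined)."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: fewer than 3 BED columns")
            out.append(GenomicInterval(parts[0], int(parts[1]), int(parts[2])))
    return out


@dataclass
class CohortDialect:
    """Column mapping for one cohort table flavour.

    Cohorts differ in column naming (COSMIC vs supplementary tables), so
    the mapping is configuration.  ``position`` must name a column with
    1-based inclusive coordinates formatted ``chrom:start-end``, or
    ``chrom_col``/``start_col``/``end_col`` may be given separately.
    """

    sample_col: str = "ID_sample"
    gene_col: str = "Gene_name"
    cds_col: str = "Mutation_CDS"
    position_col: str | None = "Mutation_genome_position"
    chrom_col: str | None = None
    start_col: str | None = None
    end_col: str | None = None
    site_col: str = "Primary_site"
    histology_col: str = "Primary_histology"
    region_col: str | None = "Region_class"
    pubmed_col: str | None = "Pubmed_PMID"
    maf_cols: Sequence[str] = MAF_DATASETS
    delimiter: str = "\t"


@dataclass
class CohortReadResult:
    records: list[DeletionRecord]
    dropped_no_coordinates: int = 0


def _parse_position(text: str) -> tuple[str, int, int] | None:
    text = text.strip()
    if not text:
        return None
    try:
        chrom, span = text.split(":")
        s, e = span.replace("..", "-").split("-")
        return chrom, int(s), int(e)
    except ValueError:
        return None


def read_cohort_table(
    path: str | Path, dialect: CohortDialect | None = None
) -> CohortReadResult:
    """Read a somatic-deletion cohort table.

    Rows without usable genomic coordinates are dropped and counted.
    1-based inclusive input coordinates are converted to the internal
    0-based half-open convention.  Empty MAF cells stay *missing* — they
    are never coerced to 0.
    """
    dialect = dialect or CohortDialect()
    records: list[DeletionRecord] = []
    dropped = 0
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter=dialect.delimiter)
        cols = reader.fieldnames or []
        mandatory = [dialect.sample_col, dialect.gene_col, dialect.cds_col]
        missing = [c for c in mandatory if c not in cols]
        if missing:
            raise FormatError(f"{path}: missing mandatory column(s) {missing}")
        for row in reader:
            if dialect.position_col:
                pos = _parse_position(row.get(dialect.position_col, ""))
            else:
                try:
                    pos = (
                        row[dialect.chrom_col].strip(),
                        int(row[dialect.start_col]),
                        int(row[dialect.end_col]),
                    )
                except (KeyError, ValueError, AttributeError):
                    pos = None
            if pos is None:
                dropped += 1
                continue
            chrom, start1, end1 = pos
            maf: dict[str, float] = {}
            for name in dialect.maf_cols:
                cell = (row.get(name) or "").strip()
                if cell not in ("", ".", "NA", "nan"):
                    maf[name] = float(cell)
            pubmed: frozenset[str] = frozenset()
            if dialect.pubmed_col and row.get(dialect.pubmed_col):
                pubmed = frozenset(
                    p.strip() for p in row[dialect.pubmed_col].split(";") if p.strip()
                )
            records.append(
                DeletionRecord(
                    sample_id=row[dialect.sample_col],
                    gene=row[dialect.gene_col],
                    interval=GenomicInterval.from_one_based(chrom, start1, end1),
                    mutation_cds=row[dialect.cds_col],
                    primary_site=row.get(dialect.site_col, "") or "",
                    primary_histology=row.get(dialect.histology_col, "") or "",
                    region_class=(row.get(dialect.region_col or "", "") or "unknown"),
                    pubmed_ids=pubmed,
                    maf=maf,
                )
            )
    return CohortReadResult(records=records, dropped_no_coordinates=dropped)


def read_vcf_indels(
    path: str | Path,
    alt_count_field: str = "AD",
    depth_field: str = "DP",
) -> list[IndelAllele]:
    """Read an amplicon VCF into per-allele modified-read counts.

    ``alt_count_field`` may be an AD-style FORMAT field (ref,alt counts)
    or a plain integer FORMAT/INFO field holding the alt-supporting read
    count.  Substitution records are retained (their ``kind`` property
    flags them); the caller decides whether to keep them.
    """
    alleles: list[IndelAllele] = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            sample = rec.samples[0] if rec.samples else None

            def _get(fieldname):
                if sample is not None and fieldname in sample:
                    return sample[fieldname]
                if fieldname in rec.info:
                    return rec.info[fieldname]
                return None

            depth = _get(depth_field)
            counts = _get(alt_count_field)
            if depth is None or counts is None:
                raise FormatError(
                    f"{path}: record {rec.chrom}:{rec.pos} lacks "
                    f"{alt_count_field}/{depth_field}"
                )
            if isinstance(depth, tuple):
                depth = depth[0]
            for i, alt in enumerate(rec.alts or ()):
                if isinstance(counts, tuple):
                    count = counts[i + 1] if len(counts) > 1 else counts[0]
                else:
                    count = counts
                alleles.append(
                    IndelAllele(
                        pos=rec.pos - 1,
                        ref=rec.ref,
                        alt=alt,
                        modified_read_count=int(count),
                        depth=int(depth),
                    )
                )
    return alleles


CLASSIFIED_COLUMNS = (
    "sample", "gene", "mutation_cds", "chrom", "start", "end",
    "length", "mh_length", "mh_mismatches", "signature_class",
)


def write_classified_table(
    rows: Iterable[tuple[DeletionRecord, MHCall, SignatureClass]],
    path: str | Path,
) -> None:
    """Write the classified-deletion TSV with a stable column order.

    Output is deterministic given the input order, so write→read→write
    is byte-identical.
    """
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(CLASSIFIED_COLUMNS)
        for rec, mh, sig in rows:
            w.writerow([
                rec.sample_id, rec.gene, rec.mutation_cds,
                rec.interval.chrom, rec.interval.start, rec.interval.end,
                rec.interval.length, mh.k, mh.m, sig.value,
            ])


def read_classified_table(path: str | Path) -> list[dict[str, str]]:
    with open(path, newline="") as fh:
        return list(csv.DictReader(fh, delimiter="\t"))
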