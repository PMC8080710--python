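"""Core domain types shared across the pipeline.

Coordinate convention: all internal intervals are 0-based half-open
(``[start, end)``), the convention used by BED and by Python slicing.
COSMIC-style cohort tables use 1-based inclusive coordinates and are
converted on input (see :mod:`mhsig.io`).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field


class SignatureClass(enum.Enum):
    """Deletion-signature classes, plus INSERTION for editing outcomes.

    Deletions partition into exactly one of MH_DEL (long, >=5 bp, flanked
    by microhomology of effective length >=2 bp), LONG_NO_MH_DEL (long but
    with 0-1 bp microhomology) and SHORT_DEL (<5 bp).
    """

    MH_DEL = "MH_DEL"
    LONG_NO_MH_DEL = "LONG_NO_MH_DEL"
    SHORT_DEL = "SHORT_DEL"
    INSERTION = "INSERTION"


class TruncationClass(enum.Enum):
    """Classes of protein-truncating variants."""

    NONSENSE = "nonsense"
    FS_INSERTION = "fs_insertion"
    FS_DEL_SHORT = "fs_del_short"
    FS_DEL_LONG_MH = "fs_del_long_mh"
    FS_DEL_LONG_NO_MH = "fs_del_long_no_mh"


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open interval on a named sequence."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    @classmethod
    def from_one_based(cls, chrom: str, start1: int, end1: int) -> "GenomicInterval":
        """Build from 1-based inclusive coordinates (COSMIC/HGVS style)."""
        return cls(chrom, start1 - 1, end1)

    def to_one_based(self) -> tuple[int, int]:
        """Return (start, end) in 1-based inclusive coordinates."""
        return self.start + 1, self.end


_MISSING = object()


@dataclass
class DeletionRecord:
    """One somatic deletion with its cohort metadata.

    ``maf`` maps population-database names (AF, ExAC_ALL, Kaviar_AF,
    ExAC_nonpsych_ALL, AF_popmax) to allele fractions; a dataset with no
    data is *absent from the map*, never stored as 0.0.
    """

    sample_id: str
    gene: str
    interval: GenomicInterval
    mutation_cds: str = ""
    deleted_seq: str = ""
    primary_site: str = ""
    primary_histology: str = ""
    region_class: str = "unknown"  # exonic | intronic | intergenic | unknown
    pubmed_ids: frozenset[str] = field(default_factory=frozenset)
    maf: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.deleted_seq and len(self.deleted_seq) != self.interval.length:
            raise ValueError(
                f"deleted_seq length {len(self.deleted_seq)} != interval "
                f"length {self.interval.length} for {self.mutation_cds!r}"
            )
        for name, value in self.maf.items():
            if value < 0:
                raise ValueError(f"negative MAF {value} in dataset {name!r}")
            if value > 1:
                raise ValueError(f"MAF {value} > 1 in dataset {name!r}")


@dataclass(frozen=True)
class CdsDeletion:
    """A coding-DNA deletion span parsed from HGVS c. notation."""

    cds_start: int
    cds_end: int

    def __post_init__(self) -> None:
        if self.cds_start < 1 or self.cds_end < self.cds_start:
            raise ValueError(f"invalid CDS span {self.cds_start}_{self.cds_end}")

    @property
    def length(self) -> int:
        return self.cds_end - self.cds_start + 1


@dataclass(frozen=True)
class ProteinTruncation:
    """A protein truncation parsed from HGVS p. notation.

    ``last_intact_aa`` is the position of the last unchanged residue of
    the truncated protein.
    """

    kind: str  # nonsense | frameshift
    changed_residue: int
    fs_stop_offset: int | None
    last_intact_aa: int


@dataclass(frozen=True)
class FlankContext:
    """A deletion with its reference flanks.

    ``left_flank + deleted_seq + right_flank`` is a contiguous substring
    of the reference; flanks are truncated (never padded) at sequence
    boundaries.
    """

    left_flank: str
    deleted_seq: str
    right_flank: str

    def __post_init__(self) -> None:
        if not self.deleted_seq:
            raise ValueError("deleted_seq must be non-empty")


@dataclass(frozen=True)
class MHCall:
    """Result of a microhomology scan at a deletion junction.

    ``k`` is the raw matched length, ``m`` the number of mismatches used
    (0 or 1), ``effective_length = k - m`` is what classification uses.
    ``mh_seq`` is taken from the retained copy (the flank).
    """

    k: int
    m: int
    side: str  # left | right | none
    mh_seq: str

    def __post_init__(self) -> None:
        if self.k == 0 and (self.m != 0 or self.side != "none"):
            raise ValueError("k=0 call must have m=0 and side='none'")
        if self.m not in (0, 1):
            raise ValueError("at most one mismatch is supported")

    @property
    def effective_length(self) -> int:
        return self.k - self.m


NO_MH = MHCall(k=0, m=0, side="none", mh_seq="")


@dataclass(frozen=True)
class ScanConfig:
    """All numeric thresholds of the signature analysis.

    flank_window
        bp of reference taken on each side of a deletion (default 20).
    allow_mismatch
        whether a single internal mismatch is tolerated in an MH.
    min_k_for_mismatch
        minimum raw match length before a mismatch may be used.
    long_del_threshold
        deletions >= this length (bp) are "long" (default 5).
    mh_class_threshold
        minimum effective MH length for the MH class (default 2).
    recurrence_min_samples
        unique-sample count for the recurrent-deletion view (default 10).
    maf_threshold
        population allele-frequency at or above which a variant is
        treated as a germline polymorphism (default 1e-4).
    """

    flank_window: int = 20
    allow_mismatch: bool = True
    min_k_for_mismatch: int = 4
    long_del_threshold: int = 5
    mh_class_threshold: int = 2
    recurrence_min_samples: int = 10
    maf_threshold: float = 1e-4

    def __post_init__(self) -> None:
        if min(self.flank_window, self.min_k_for_mismatch,
               self.long_del_threshold, self.mh_class_threshold,
               self.recurrence_min_samples) <= 0 or self.maf_threshold <= 0:
            raise ValueError("all thresholds must be positive")
        if self.mh_class_threshold > self.long_del_threshold:
            raise ValueError("mh_class_threshold must not exceed long_del_threshold")


DEFAULT_CONFIG = ScanConfig()


@dataclass(frozen=True)
class IndelAllele:
    """One editing outcome from an amplicon variant-call table.

    ``pos`` is the 0-based position of the first REF base; ``ref``/``alt``
    are VCF-style alleles (anchor base included for indels).
    """

    pos: int
    ref: str
    alt: str
    modified_read_count: int
    depth: int

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if not 0 <= self.modified_read_count <= self.depth:
            raise ValueError("modified_read_count must be in [0, depth]")

    @property
    def key(self) -> tuple[int, str, str]:
        return (self.pos, self.ref, self.alt)

    @property
    def kind(self) -> str:
        if len(self.ref) > len(self.alt):
            return "deletion"
        if len(self.ref) < len(self.alt):
            return "insertion"
        return "substitution"

    @property
    def indel_length(self) -> int:
        return abs(len(self.ref) - len(self.alt))
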