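"""Quantification of CRISPR/Cas9 editing outcomes from amplicon
variant-call tables.

Two summary numbers per experiment: the *allele percent* of each
outcome (its modified-read count over the sum of all modified reads)
and the *overall modification frequency* (sum of modified reads over
the mean depth).  Variants shared with the unedited control are
background and are excluded before either is computed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from .classify import classify_deletion
from .mh import left_align_deletion, extract_flanks, scan_microhomology
from .types import (
    DEFAULT_CONFIG,
    GenomicInterval,
    IndelAllele,
    ScanConfig,
    SignatureClass,
)


@dataclass
class QuantResult:
    """Per-allele percents plus the experiment-level summary."""

    allele_percent: dict[tuple[int, str, str], float]
    overall_modification_frequency: float
    mean_depth: float
    total_modified_reads: int


@dataclass(frozen=True)
class ReplicateStat:
    mean: float
    sem: float
    n: int


@dataclass
class TaggedAllele:
    allele: IndelAllele
    signature: SignatureClass | None
    is_recurrent: bool = False
    deletion: GenomicInterval | None = None


def subtract_controls(
    edited: Sequence[IndelAllele], control: Sequence[IndelAllele]
) -> list[IndelAllele]:
    """Drop edited alleles whose (pos, ref, alt) key appears in the
    unedited control — sequencing/PCR background, not Cas9 products."""
    background = {a.key for a in control}
    return [a for a in edited if a.key not in background]


def allele_percent(
    alleles: Sequence[IndelAllele], include_substitutions: bool = False
) -> dict[tuple[int, str, str], float]:
    """Allele percent per outcome: 100 * count_i / sum(counts).

    By default only indel alleles enter the denominator; zero total
    modified reads yields an empty result rather than an error.
    """
    kept = [
        a for a in alleles
        if include_substitutions or a.kind != "substitution"
    ]
    total = sum(a.modified_read_count for a in kept)
    if total == 0:
        return {}
    return {a.key: 100.0 * a.modified_read_count / total for a in kept}


def modification_frequency(
    alleles: Sequence[IndelAllele],
    mean_depth: float | None = None,
    include_substitutions: bool = False,
) -> float:
    """Overall modification frequency: 100 * sum(counts) / mean depth.

    When ``mean_depth`` is not supplied it is the arithmetic mean of the
    per-allele depths.
    """
    kept = [
        a for a in alleles
        if include_substitutions or a.kind != "substitution"
    ]
    if mean_depth is None:
        if not kept:
            return 0.0
        mean_depth = sum(a.depth for a in kept) / len(kept)
    if mean_depth <= 0:
        raise ValueError(f"mean depth must be positive, got {mean_depth}")
    return 100.0 * sum(a.modified_read_count for a in kept) / mean_depth


def quantify(
    edited: Sequence[IndelAllele],
    control: Sequence[IndelAllele] = (),
    mean_depth: float | None = None,
    include_substitutions: bool = False,
) -> QuantResult:
    """Control subtraction, allele percents and modification frequency."""
    kept = subtract_controls(edited, control)
    pct = allele_percent(kept, include_substitutions)
    indels = [a for a in kept if include_substitutions or a.kind != "substitution"]
    if mean_depth is None:
        mean_depth = (
            sum(a.depth for a in indels) / len(indels) if indels else 0.0
        )
    freq = (
        modification_frequency(indels, mean_depth, include_substitutions)
        if mean_depth > 0 else 0.0
    )
    return QuantResult(
        allele_percent=pct,
        overall_modification_frequency=freq,
        mean_depth=mean_depth,
        total_modified_reads=sum(a.modified_read_count for a in indels),
    )


def aggregate_replicates(values: Sequence[float]) -> ReplicateStat:
    """Mean and SEM (sample sd / sqrt(n), ddof 1) over replicates."""
    n = len(values)
    if n < 2:
        raise ValueError("need at least 2 replicates")
    mean = sum(values) / n
    var = sum((v - mean) ** 2 for v in values) / (n - 1)
    return ReplicateStat(mean=mean, sem=math.sqrt(var) / math.sqrt(n), n=n)


def tag_signatures(
    alleles: Sequence[IndelAllele],
    ref: str,
    recurrent_interval: GenomicInterval | None = None,
    config: ScanConfig = DEFAULT_CONFIG,
    seq_name: str = "amplicon",
) -> list[TaggedAllele]:
    """Assign each editing outcome its signature class.

    Deletion alleles are converted to genomic intervals (VCF anchor base
    excluded), left-aligned and routed through the MH scanner and the
    deletion classifier; insertions are tagged INSERTION; substitutions
    keep no signature.  A designated recurrent-deletion interval is
    flagged separately (the experimentally tracked MMEJ product).
    """
    out: list[TaggedAllele] = []
    for a in alleles:
        if a.kind == "substitution":
            out.append(TaggedAllele(a, None))
            continue
        if a.kind == "insertion":
            out.append(TaggedAllele(a, SignatureClass.INSERTION))
            continue
        # deletion: REF anchor base at a.pos, deleted bases follow it
        start = a.pos + len(a.alt)
        end = a.pos + len(a.ref)
        if end > len(ref):
            raise IndexError(
                f"deletion {a.key} extends past the amplicon (length {len(ref)})"
            )
        aligned = left_align_deletion(ref, GenomicInterval(seq_name, start, end))
        mh = scan_microhomology(extract_flanks(ref, aligned, config), config)
        sig = classify_deletion(aligned.length, mh, config)
        recurrent = (
            recurrent_interval is not None
            and aligned.start == recurrent_interval.start
            and aligned.end == recurrent_interval.end
        )
        out.append(TaggedAllele(a, sig, is_recurrent=recurrent, deletion=aligned))
    return out


def class_fractions(
    tagged: Sequence[TaggedAllele],
) -> dict[str, float]:
    """Percent of modified indel reads per signature class (plus the
    recurrent-deletion share), the per-panel readout of editing runs."""
    totals: dict[str, int] = {}
    grand = 0
    for t in tagged:
        if t.signature is None:
            continue
        grand += t.allele.modified_read_count
        totals[t.signature.value] = (
            totals.get(t.signature.value, 0) + t.allele.modified_read_count
        )
        if t.is_recurrent:
            totals["RECURRENT"] = (
                totals.get("RECURRENT", 0) + t.allele.modified_read_count
            )
    if grand == 0:
        return {}
    return {k: 100.0 * v / grand for k, v in sorted(totals.items())}
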