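"""Seeded generators for every input the pipeline consumes, with
ground-truth manifests.

Each generator is a pure function of (seed, parameters): the same call
reproduces identical sequences, tables and VCF bytes.  Planted
structure (microhomology pairs, class labels, allele fractions, subset
correlations) is verified at generation time with the exhaustive
scanners, so downstream recovery tests can read truth from the manifest
alone.

The generators model the *statistical shape* of the real inputs —
deletion cohorts as a mixture of the three signature classes with
germline/tissue/publication contaminants, amplicon variant tables with
multinomial read sampling at fixed depth, expression matrices with a
subset-restricted correlated gene pair.  They do not model sequencing
error profiles or read-level data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .mh import extract_flanks, left_align_deletion, mh_oracle
from .predict import CutSite, enumerate_mh_pairs
from .types import DEFAULT_CONFIG, DeletionRecord, GenomicInterval, IndelAllele, ScanConfig

_BASES = np.array(list("ACGT"))


class GenerationError(RuntimeError):
    """Raised when rejection sampling cannot satisfy the no-leakage
    invariant within the attempt budget."""


def _random_seq(rng: np.random.Generator, n: int, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(_BASES[rng.choice(4, size=n, p=p)])


def _random_over(rng: np.random.Generator, n: int, alphabet: str) -> str:
    return "".join(alphabet[i] for i in rng.integers(len(alphabet), size=n))


@dataclass
class PlantedLocus:
    """Ground truth for one reference locus with a planted MH pair."""

    name: str
    seq: str
    k: int
    spacer: int
    mh_seq: str
    del_start: int  # left MH start; deleting [del_start, del_end) is the MMEJ product
    del_end: int    # right MH start
    cut: int        # midpoint gap position between the copies

    @property
    def deletion(self) -> GenomicInterval:
        return GenomicInterval(self.name, self.del_start, self.del_end)

    @property
    def deletion_length(self) -> int:
        return self.del_end - self.del_start


def _plant_locus(
    rng: np.random.Generator,
    name: str,
    k: int,
    spacer: int,
    gc: float,
    pad: int = 30,
    max_attempts: int = 1000,
    config: ScanConfig = DEFAULT_CONFIG,
) -> PlantedLocus:
    """Embed exactly one MH pair (k-mer, spacer, same k-mer) such that
    the pair is the unique best candidate for both the scanner and the
    predictor.

    The background is built over disjoint two-letter alphabets on the
    two sides of the cut ({A,C} upstream, {G,T} downstream), so no
    unplanned repeat can straddle the break; the exhaustive scanner and
    the enumerating predictor then verify the construction, rejecting
    the rare residual coincidences (at alphabet boundaries or inside
    the MH k-mer itself).  ``gc`` is accepted for signature
    compatibility; the split construction is balanced by design.
    """
    del gc  # split-alphabet construction fixes base composition
    i = pad
    for _ in range(max_attempts):
        mh = _random_seq(rng, k)
        j = pad + k + spacer
        cut_gap = (i + k + j) // 2  # midpoint between the copies
        left_pad = _random_over(rng, pad, "AC")
        s1_len = cut_gap - (i + k)
        sp = _random_over(rng, s1_len, "AC") + _random_over(rng, spacer - s1_len, "GT")
        right_pad = _random_over(rng, pad, "GT")
        seq = left_pad + mh + sp + mh + right_pad
        # deletion [i, j) must already be left-aligned so coordinates in
        # the manifest are canonical
        interval = GenomicInterval(name, i, j)
        if left_align_deletion(seq, interval) != interval:
            continue
        # scanner truth: effective MH length equals planted k
        call = mh_oracle(extract_flanks(seq, interval, config), config)
        if call.effective_length != k or call.m != 0:
            continue
        # predictor truth: planted product is rank 1 at the midpoint cut
        cut = (i + k + j) // 2
        products = enumerate_mh_pairs(CutSite(seq, cut))
        if not products or (products[0].i, products[0].j, products[0].k) != (i, j, k):
            continue
        if sum(1 for p in products if p.k >= k) != 1:
            continue
        return PlantedLocus(
            name=name, seq=seq, k=k, spacer=spacer, mh_seq=mh,
            del_start=i, del_end=j, cut=cut,
        )
    raise GenerationError(
        f"could not plant an unambiguous {k}-bp MH pair (spacer {spacer}) "
        f"in {max_attempts} attempts"
    )


def _plant_cohort_mh(
    rng: np.random.Generator,
    name: str,
    k: int,
    spacer: int,
    gc: float,
    pad: int = 30,
    max_attempts: int = 1000,
    config: ScanConfig = DEFAULT_CONFIG,
) -> tuple[str, GenomicInterval, str]:
    """Plant an MH pair in fully random background for cohort records.

    Only the scanner truth matters here (the deletion's flanking MH has
    effective length exactly k and the interval is left-aligned); the
    predictor-uniqueness guarantee of :func:`_plant_locus` is not
    needed, so the background stays natural.
    """
    for _ in range(max_attempts):
        mh = _random_seq(rng, k, gc)
        seq = (
            _random_seq(rng, pad, gc) + mh + _random_seq(rng, spacer, gc)
            + mh + _random_seq(rng, pad, gc)
        )
        interval = GenomicInterval(name, pad, pad + k + spacer)
        if left_align_deletion(seq, interval) != interval:
            continue
        call = mh_oracle(extract_flanks(seq, interval, config), config)
        if call.effective_length == k:
            return seq, interval, mh
    raise GenerationError(
        f"could not plant a cohort {k}-bp MH deletion in {max_attempts} attempts"
    )


def make_reference_with_mh(
    seed: int,
    n_loci: int,
    mh_len_range: tuple[int, int] = (2, 8),
    spacer_range: tuple[int, int] = (1, 48),
    gc: float = 0.5,
    out_dir: str | Path | None = None,
) -> tuple[dict[str, str], dict]:
    """Generate loci each carrying exactly one planted MH pair.

    Returns ({name: sequence}, manifest); when ``out_dir`` is given,
    writes ``reference.fa`` and ``manifest.json`` there.
    """
    if not (1 <= mh_len_range[0] <= mh_len_range[1]):
        raise ValueError(f"invalid mh_len_range {mh_len_range}")
    if not (1 <= spacer_range[0] <= spacer_range[1]):
        raise ValueError(f"invalid spacer_range {spacer_range}")
    rng = np.random.default_rng(seed)
    seqs: dict[str, str] = {}
    loci = []
    for idx in range(n_loci):
        k = int(rng.integers(mh_len_range[0], mh_len_range[1] + 1))
        spacer = int(rng.integers(spacer_range[0], spacer_range[1] + 1))
        locus = _plant_locus(rng, f"locus_{idx:05d}", k, spacer, gc)
        seqs[locus.name] = locus.seq
        loci.append({
            "name": locus.name, "k": locus.k, "spacer": locus.spacer,
            "mh_seq": locus.mh_seq, "del_start": locus.del_start,
            "del_end": locus.del_end, "cut": locus.cut,
            "deletion_length": locus.deletion_length,
        })
    manifest = {
        "seed": seed,
        "params": {
            "n_loci": n_loci, "mh_len_range": list(mh_len_range),
            "spacer_range": list(spacer_range), "gc": gc,
        },
        "loci": loci,
    }
    if out_dir is not None:
        from .io import write_fasta

        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_fasta(seqs, out_dir / "reference.fa")
        _write_json(manifest, out_dir / "manifest.json")
    return seqs, manifest


def _write_json(obj: dict, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True)
        fh.write("\n")


def random_flank_context(
    rng: np.random.Generator, max_del: int = 60
) -> "FlankContext":
    """A random flank context for scanner stress-testing.

    Half the draws plant a shared prefix between the deleted sequence
    and the right flank (sometimes with one internal mismatch), and a
    third plant a shared suffix with the left flank, so the scanner's
    interesting code paths are exercised rather than only the no-MH
    path of fully random sequence.
    """
    from .types import FlankContext

    L = int(rng.integers(1, max_del + 1))
    deleted = _random_seq(rng, L)
    left = _random_seq(rng, int(rng.integers(0, 21)))
    right = _random_seq(rng, int(rng.integers(0, 21)))
    if rng.random() < 0.5 and right:
        k = int(rng.integers(1, min(L, len(right)) + 1))
        right = deleted[:k] + right[k:]
        if rng.random() < 0.3 and k >= 3:
            p = int(rng.integers(1, k - 1))
            alt = "ACGT"[("ACGT".index(right[p]) + 1) % 4]
            right = right[:p] + alt + right[p + 1:]
    if rng.random() < 0.3 and left:
        k = int(rng.integers(1, min(L, len(left)) + 1))
        left = left[: len(left) - k] + deleted[L - k:]
    return FlankContext(left_flank=left, deleted_seq=deleted, right_flank=right)


# ---------------------------------------------------------------------------
# deletion cohorts


_MAF_DATASETS = ("AF", "ExAC_ALL", "Kaviar_AF", "ExAC_nonpsych_ALL", "AF_popmax")


def _exact_counts(n: int, mixture: Sequence[float]) -> list[int]:
    """Largest-remainder apportionment so class counts are exact."""
    raw = [n * p for p in mixture]
    counts = [int(x) for x in raw]
    rem = n - sum(counts)
    order = sorted(range(len(raw)), key=lambda i: raw[i] - counts[i], reverse=True)
    for i in order[:rem]:
        counts[i] += 1
    return counts


def simulate_deletion_cohort(
    seed: int,
    n_records: int,
    class_mixture: tuple[float, float, float] = (0.6, 0.25, 0.15),
    snp_rate: float = 0.0,
    lymphoid_rate: float = 0.0,
    single_pub_rate: float = 0.0,
    gc: float = 0.5,
    out_dir: str | Path | None = None,
) -> tuple[list[DeletionRecord], dict[str, str], dict]:
    """Simulate a somatic-deletion cohort with known class labels.

    ``class_mixture`` is (p_mh, p_long_no_mh, p_short); counts per class
    are exact (largest-remainder rounding of n*p), so a perfect
    classifier recovers them exactly.  Contaminant flags are mutually
    exclusive Bernoulli draws per record: a germline-like record carries
    a population MAF >= 1e-4, a lymphoid record a 'lymph' histology, a
    single-publication record exactly one PubMed id.  Clean records have
    no MAF data, myeloid metadata and two or three publications.

    Returns (records, {chrom: sequence}, manifest).
    """
    if abs(sum(class_mixture) - 1.0) > 1e-9 or min(class_mixture) < 0:
        raise ValueError(f"class mixture must be a distribution, got {class_mixture}")
    if snp_rate + lymphoid_rate + single_pub_rate > 1:
        raise ValueError("contaminant rates must sum to <= 1")
    rng = np.random.default_rng(seed)
    counts = _exact_counts(n_records, class_mixture)
    labels = (
        ["MH_DEL"] * counts[0]
        + ["LONG_NO_MH_DEL"] * counts[1]
        + ["SHORT_DEL"] * counts[2]
    )
    rng.shuffle(labels)

    records: list[DeletionRecord] = []
    seqs: dict[str, str] = {}
    truth = []
    for idx, label in enumerate(labels):
        chrom = f"locus_{idx:05d}"
        if label == "MH_DEL":
            k = int(rng.integers(2, 9))
            spacer = int(rng.integers(max(1, 5 - k), 30))
            seq, interval, _mh = _plant_cohort_mh(rng, chrom, k, spacer, gc)
            planted_k = k
        elif label == "LONG_NO_MH_DEL":
            seq, interval = _plant_no_mh_deletion(
                rng, chrom, length=int(rng.integers(5, 30)), gc=gc
            )
            planted_k = 0
        else:  # SHORT_DEL: any context, length < 5
            length = int(rng.integers(1, 5))
            seq = _random_seq(rng, 60 + length, gc)
            start = 30
            interval = left_align_deletion(
                seq, GenomicInterval(chrom, start, start + length)
            )
            planted_k = -1  # not controlled for short deletions
        seqs[chrom] = seq

        u = rng.random()
        contaminant = None
        maf: dict[str, float] = {}
        histology = "haematopoietic_neoplasm"
        n_pubs = int(rng.integers(2, 4))
        if u < snp_rate:
            contaminant = "snp"
            dataset = _MAF_DATASETS[int(rng.integers(len(_MAF_DATASETS)))]
            maf[dataset] = float(rng.uniform(1e-4, 0.05))
        elif u < snp_rate + lymphoid_rate:
            contaminant = "lymphoid"
            histology = "lymphoid_neoplasm"
        elif u < snp_rate + lymphoid_rate + single_pub_rate:
            contaminant = "single_pub"
            n_pubs = 1
        pubs = frozenset(f"PMID{idx:05d}_{p}" for p in range(n_pubs))
        s1, e1 = interval.to_one_based()
        rec = DeletionRecord(
            sample_id=f"S{idx:06d}",
            gene=f"GENE_{idx:05d}",
            interval=interval,
            mutation_cds=f"c.{s1}_{e1}del{interval.length}"
            if interval.length > 1 else f"c.{s1}del",
            deleted_seq=seq[interval.start: interval.end],
            primary_site="haematopoietic_and_lymphoid_tissue",
            primary_histology=histology,
            region_class="exonic",
            pubmed_ids=pubs,
            maf=maf,
        )
        records.append(rec)
        truth.append({
            "sample_id": rec.sample_id, "gene": rec.gene, "chrom": chrom,
            "true_class": label, "planted_mh_length": planted_k,
            "contaminant": contaminant,
            "start": interval.start, "end": interval.end,
        })
    manifest = {
        "seed": seed,
        "params": {
            "n_records": n_records, "class_mixture": list(class_mixture),
            "snp_rate": snp_rate, "lymphoid_rate": lymphoid_rate,
            "single_pub_rate": single_pub_rate, "gc": gc,
        },
        "class_counts": dict(zip(("MH_DEL", "LONG_NO_MH_DEL", "SHORT_DEL"), counts)),
        "records": truth,
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        _write_cohort_tsv(records, out_dir / "cohort.tsv")
        from .io import write_fasta

        write_fasta(seqs, out_dir / "reference.fa")
        _write_json(manifest, out_dir / "manifest.json")
    return records, seqs, manifest


def _plant_no_mh_deletion(
    rng: np.random.Generator,
    chrom: str,
    length: int,
    gc: float,
    max_attempts: int = 1000,
    config: ScanConfig = DEFAULT_CONFIG,
) -> tuple[str, GenomicInterval]:
    """A long deletion whose flanks carry at most 1 bp of effective MH."""
    for _ in range(max_attempts):
        seq = _random_seq(rng, 60 + length, gc)
        interval = left_align_deletion(seq, GenomicInterval(chrom, 30, 30 + length))
        call = mh_oracle(extract_flanks(seq, interval, config), config)
        if call.effective_length <= 1:
            return seq, interval
    raise GenerationError(
        f"could not place a {length}-bp deletion without flanking MH "
        f"in {max_attempts} attempts"
    )


def _write_cohort_tsv(records: Sequence[DeletionRecord], path: Path) -> None:
    import csv

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow([
            "ID_sample", "Gene_name", "Mutation_CDS", "Mutation_genome_position",
            "Primary_site", "Primary_histology", "Region_class", "Pubmed_PMID",
            *_MAF_DATASETS,
        ])
        for r in records:
            s1, e1 = r.interval.to_one_based()
            w.writerow([
                r.sample_id, r.gene, r.mutation_cds,
                f"{r.interval.chrom}:{s1}-{e1}",
                r.primary_site, r.primary_histology, r.region_class,
                ";".join(sorted(r.pubmed_ids)),
                *[("" if d not in r.maf else repr(r.maf[d])) for d in _MAF_DATASETS],
            ])


# ---------------------------------------------------------------------------
# CRISPR amplicon variant calls


@dataclass
class CrisprTruth:
    amplicon: str
    recurrent: GenomicInterval
    outcome_keys: list[tuple[int, str, str]]
    true_fractions: list[float]
    counts: list[int]
    total_modified: int
    depth: int
    editing_rate: float


def _vcf_text(
    contig: str,
    contig_len: int,
    rows: Sequence[tuple[int, str, str, int, int]],
) -> str:
    """Minimal deterministic single-sample VCF (DP + AD format fields).

    rows: (pos0, ref, alt, alt_count, depth).
    """
    lines = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID={contig},length={contig_len}>",
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tsample",
    ]
    for pos0, ref, alt, count, depth in sorted(rows):
        lines.append(
            f"{contig}\t{pos0 + 1}\t.\t{ref}\t{alt}\t.\tPASS\t.\t"
            f"DP:AD\t{depth}:{depth - count},{count}"
        )
    return "\n".join(lines) + "\n"


def simulate_crispr_calls(
    seed: int,
    true_fractions: Sequence[float] = (0.5, 0.3, 0.2),
    editing_rate: float = 0.4,
    depth: int = 5000,
    mh_len: int = 4,
    recurrent_del_len: int = 23,
    amplicon_seed: int | None = None,
    out_dir: str | Path | None = None,
) -> tuple[list[IndelAllele], list[IndelAllele], dict[str, str], dict]:
    """Simulate an edited/control amplicon variant-table pair.

    Three editing outcomes are planted, matched positionally to
    ``true_fractions``: the recurrent MH-flanked deletion (MMEJ
    product), a 2-bp deletion at the cut and a 1-bp insertion at the
    cut.  The number of modified reads is Binomial(depth, editing_rate)
    and is split across outcomes multinomially.  Both tables share two
    background variants (a substitution and a 1-bp indel away from the
    cut) for control-subtraction testing.

    Replicates of one experiment share a locus: pass the same
    ``amplicon_seed`` (defaults to ``seed``) with different ``seed``
    values to redraw only the read sampling on an identical amplicon.

    Returns (edited alleles, control alleles, {amplicon: seq}, manifest);
    with ``out_dir``, writes ``edited.vcf``, ``control.vcf``,
    ``amplicon.fa`` and ``manifest.json``.
    """
    fr = list(true_fractions)
    if abs(sum(fr) - 1.0) > 1e-9 or min(fr) < 0 or len(fr) != 3:
        raise ValueError(f"true_fractions must be 3 non-negative values summing to 1")
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if not 0 <= editing_rate <= 1:
        raise ValueError("editing_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    rng_seq = np.random.default_rng(seed if amplicon_seed is None else amplicon_seed)
    spacer = recurrent_del_len - mh_len
    if spacer < 1:
        raise ValueError("recurrent_del_len must exceed mh_len")
    locus = _plant_locus(rng_seq, "amplicon", mh_len, spacer, gc=0.5, pad=60)
    seq = locus.seq
    i, j = locus.del_start, locus.del_end
    cut = locus.cut

    # planted outcomes as VCF-style (pos0 of anchor, ref, alt)
    recurrent = (i - 1, seq[i - 1: j], seq[i - 1])
    short_del = (cut - 1, seq[cut - 1: cut + 2], seq[cut - 1])
    insertion = (cut - 1, seq[cut - 1], seq[cut - 1] + "A")
    outcomes = [recurrent, short_del, insertion]

    total_modified = int(rng.binomial(depth, editing_rate))
    counts = [int(c) for c in rng.multinomial(total_modified, fr)]

    # shared background (amplicon property): one substitution, one 1-bp
    # deletion, far from the cut; per-run read counts vary with `seed`
    sub_pos = 5
    sub = (sub_pos, seq[sub_pos], "A" if seq[sub_pos] != "A" else "G")
    bg_del_pos = len(seq) - 10
    bg_del = (bg_del_pos - 1, seq[bg_del_pos - 1: bg_del_pos + 1], seq[bg_del_pos - 1])
    bg_counts = [int(rng.integers(3, 12)), int(rng.integers(3, 12))]

    edited_rows = [
        (*outcomes[n], counts[n], depth) for n in range(3)
    ] + [(*sub, bg_counts[0], depth), (*bg_del, bg_counts[1], depth)]
    control_rows = [(*sub, bg_counts[0], depth), (*bg_del, bg_counts[1], depth)]

    def _alleles(rows):
        return [
            IndelAllele(pos=p, ref=r, alt=a, modified_read_count=c, depth=d)
            for p, r, a, c, d in sorted(rows)
        ]

    manifest = {
        "seed": seed,
        "params": {
            "true_fractions": fr, "editing_rate": editing_rate, "depth": depth,
            "mh_len": mh_len, "recurrent_del_len": recurrent_del_len,
            "amplicon_seed": seed if amplicon_seed is None else amplicon_seed,
        },
        "amplicon_length": len(seq),
        "recurrent_interval": {"start": i, "end": j},
        "cut": cut,
        "outcome_keys": [list(o) for o in outcomes],
        "outcome_classes": ["MH_DEL", "SHORT_DEL", "INSERTION"],
        "counts": counts,
        "total_modified": total_modified,
        "background_keys": [list(sub), list(bg_del)],
    }
    seqs = {"amplicon": seq}
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "edited.vcf").write_text(_vcf_text("amplicon", len(seq), edited_rows))
        (out_dir / "control.vcf").write_text(_vcf_text("amplicon", len(seq), control_rows))
        from .io import write_fasta

        write_fasta(seqs, out_dir / "amplicon.fa")
        _write_json(manifest, out_dir / "manifest.json")
    return _alleles(edited_rows), _alleles(control_rows), seqs, manifest


# ---------------------------------------------------------------------------
# metacell expression


def simulate_metacell_expression(
    seed: int,
    n_genes: int = 20,
    n_metacells: int = 2000,
    subset_fraction: float = 0.025,
    anchor_gene: str = "anchor",
    planted_gene: str = "gene_00001",
    r_subset: float = 0.8,
    out_dir: str | Path | None = None,
):
    """Simulate a genes x metacells expression matrix with one gene
    correlated with the anchor *only inside* a metacell subset.

    The anchor/planted pair is bivariate normal with correlation
    ``r_subset`` within the subset and independent outside; every other
    gene is independent noise.  Values are shifted to be non-negative
    (Pearson correlation is shift-invariant).  Returns
    (DataFrame, subset mask, manifest).
    """
    import pandas as pd

    if not 0 < subset_fraction < 1:
        raise ValueError("subset_fraction must be in (0, 1)")
    if not abs(r_subset) < 1:
        raise ValueError("|r_subset| must be < 1")
    rng = np.random.default_rng(seed)
    n_subset = max(2, round(subset_fraction * n_metacells))
    mask = np.zeros(n_metacells, dtype=bool)
    mask[rng.choice(n_metacells, size=n_subset, replace=False)] = True

    genes = [anchor_gene, planted_gene] + [
        f"gene_{i:05d}" for i in range(2, n_genes)
    ]
    X = rng.standard_normal((n_genes, n_metacells))
    anchor = X[0]
    noise = rng.standard_normal(n_metacells)
    planted = X[1].copy()
    planted[mask] = r_subset * anchor[mask] + np.sqrt(1 - r_subset**2) * noise[mask]
    X[1] = planted
    X = X - X.min()  # non-negative, correlation-preserving
    frame = pd.DataFrame(X, index=genes)
    manifest = {
        "seed": seed,
        "params": {
            "n_genes": n_genes, "n_metacells": n_metacells,
            "subset_fraction": subset_fraction, "r_subset": r_subset,
            "anchor_gene": anchor_gene, "planted_gene": planted_gene,
        },
        "subset_indices": [int(ix) for ix in np.flatnonzero(mask)],
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        frame.to_csv(out_dir / "expression.tsv", sep="\t", float_format="%.6g")
        _write_json(manifest, out_dir / "manifest.json")
    return frame, mask, manifest
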