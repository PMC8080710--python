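"""End-to-end orchestration: the cohort signature analysis and the
CRISPR quantification analysis, each a deterministic function from a
run configuration to output files plus in-memory results."""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import yaml

from . import __version__
from .classify import CohortSummary, classify_deletion, summarize_cohort
from .crispr import aggregate_replicates, class_fractions, quantify, tag_signatures
from .filters import apply_chain
from .io import (
    CohortDialect,
    read_bed,
    read_cohort_table,
    read_fasta,
    read_vcf_indels,
    write_classified_table,
)
from .mh import scan_deletion
from .stats import t_test_unpaired
from .types import GenomicInterval, ScanConfig

log = logging.getLogger("mhsig")


@dataclass
class RunConfig:
    """Serializable configuration of one pipeline run."""

    scan: ScanConfig = field(default_factory=ScanConfig)
    filter_skip: tuple[str, ...] = ()
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "version": __version__,
            "scan": dataclasses.asdict(self.scan),
            "filter_skip": list(self.filter_skip),
            "seed": self.seed,
        }

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(
            scan=ScanConfig(**data.get("scan", {})),
            filter_skip=tuple(data.get("filter_skip", ())),
            seed=int(data.get("seed", 0)),
        )


def _echo_config(config: RunConfig, out_dir: Path) -> None:
    with open(out_dir / "run_config.yaml", "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)


def run_cohort_analysis(
    cohort_path: str | Path,
    fasta_path: str | Path,
    out_dir: str | Path,
    config: RunConfig | None = None,
    dialect: CohortDialect | None = None,
    snp_bed: str | Path | None = None,
) -> CohortSummary:
    """Filter, scan and classify a cohort table end to end.

    Stages: curation chain -> left-alignment -> flank extraction -> MH
    scan -> signature classification -> recurrence summary.  Writes the
    classified TSV, the summary JSON, the filter report and the echoed
    config into ``out_dir``.
    """
    config = config or RunConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    try:
        ref = read_fasta(fasta_path)
    except Exception as exc:
        raise RuntimeError(f"[stage reference] {exc}") from exc
    try:
        loaded = read_cohort_table(cohort_path, dialect)
    except Exception as exc:
        raise RuntimeError(f"[stage cohort-input] {exc}") from exc
    log.info("read %d records (%d dropped for missing coordinates)",
             len(loaded.records), loaded.dropped_no_coordinates)
    snps: list[tuple[str, int]] = []
    if snp_bed is not None:
        snps = [(iv.chrom, p) for iv in read_bed(snp_bed)
                for p in range(iv.start, iv.end)]
    try:
        records, report = apply_chain(
            loaded.records, snp_positions=snps, config=config.scan,
            skip=config.filter_skip,
        )
    except Exception as exc:
        raise RuntimeError(f"[stage filters] {exc}") from exc
    for step in report.steps:
        log.info("filter %-14s in=%d removed=%d", step.name,
                 step.input_count, step.removed)

    classified = []
    try:
        for rec in records:
            if rec.interval.chrom not in ref:
                raise KeyError(f"no reference sequence {rec.interval.chrom!r}")
            aligned, mh = scan_deletion(
                ref[rec.interval.chrom], rec.interval, config.scan
            )
            sig = classify_deletion(aligned.length, mh, config.scan)
            classified.append((rec, mh, sig))
    except Exception as exc:
        raise RuntimeError(f"[stage scan] {exc}") from exc

    summary = summarize_cohort([(r, s) for r, _, s in classified], config.scan)
    write_classified_table(classified, out_dir / "classified.tsv")
    with open(out_dir / "summary.json", "w") as fh:
        json.dump(
            {
                "class_totals": {c.value: n for c, n in summary.class_totals.items()},
                "n_recurrent": len(summary.recurrent),
                "recurrent": [
                    {"gene": r.gene, "mutation_cds": r.mutation_cds,
                     "signature": r.signature.value, "samples": r.sample_count}
                    for r in summary.recurrent
                ],
            },
            fh, indent=1, sort_keys=True,
        )
        fh.write("\n")
    with open(out_dir / "filter_report.json", "w") as fh:
        json.dump(report.as_dict(), fh, indent=1, sort_keys=True)
        fh.write("\n")
    _echo_config(config, out_dir)
    return summary


def run_crispr_analysis(
    experiments: Sequence[dict],
    fasta_path: str | Path,
    out_dir: str | Path,
    config: RunConfig | None = None,
    recurrent_interval: tuple[int, int] | None = None,
    min_allele_percent: float = 0.0,
) -> dict:
    """Quantify a set of replicate CRISPR experiments.

    ``experiments`` is a list of manifest entries
    ``{"name", "condition", "edited", "control"}`` (VCF paths).  Per
    experiment: control subtraction -> signature tagging -> allele
    percents -> modification frequency; per condition: mean +/- SEM over
    replicates; between conditions: unpaired two-tailed t-tests on the
    recurrent-deletion share.  ``min_allele_percent`` filters the
    *written* per-allele table only, never the statistics.
    """
    if not experiments:
        raise ValueError("empty experiment manifest")
    config = config or RunConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ref = read_fasta(fasta_path)
    (amplicon_name, amplicon), = ref.items()
    target = (
        GenomicInterval(amplicon_name, *recurrent_interval)
        if recurrent_interval else None
    )

    per_exp = []
    by_condition: dict[str, list[float]] = {}
    for exp in experiments:
        for key in ("name", "condition", "edited", "control"):
            if key not in exp:
                raise ValueError(f"experiment entry missing {key!r}: {exp}")
        edited = read_vcf_indels(exp["edited"])
        control = read_vcf_indels(exp["control"])
        from .crispr import subtract_controls

        kept = subtract_controls(edited, control)
        quant = quantify(kept)
        tagged = tag_signatures(kept, amplicon, target, config.scan,
                                seq_name=amplicon_name)
        fractions = class_fractions(tagged)
        per_exp.append({
            "name": exp["name"], "condition": exp["condition"],
            "modification_frequency": quant.overall_modification_frequency,
            "class_fractions": fractions,
            "allele_percent": {
                f"{k[0]}:{k[1]}>{k[2]}": v
                for k, v in quant.allele_percent.items()
                if v >= min_allele_percent
            },
        })
        by_condition.setdefault(exp["condition"], []).append(
            fractions.get("RECURRENT", 0.0)
        )

    replicate_stats = {
        cond: dataclasses.asdict(aggregate_replicates(vals))
        for cond, vals in by_condition.items() if len(vals) >= 2
    }
    conditions = sorted(by_condition)
    tests = {}
    for a_idx in range(len(conditions)):
        for b_idx in range(a_idx + 1, len(conditions)):
            a, b = conditions[a_idx], conditions[b_idx]
            if len(by_condition[a]) >= 2 and len(by_condition[b]) >= 2:
                res = t_test_unpaired(by_condition[a], by_condition[b])
                tests[f"{a}_vs_{b}"] = {
                    "statistic": res.statistic, "p_value": res.p_value,
                    "df": res.df,
                }
    result = {
        "experiments": per_exp,
        "recurrent_percent_by_condition": by_condition,
        "replicate_stats": replicate_stats,
        "t_tests": tests,
    }
    with open(out_dir / "crispr_results.json", "w") as fh:
        json.dump(result, fh, indent=1, sort_keys=True)
        fh.write("\n")
    _echo_config(config, out_dir)
    return result


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        stream=sys.stderr, level=getattr(logging, level.upper()),
        format="%(levelname)s %(name)s: %(message)s",
    )
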