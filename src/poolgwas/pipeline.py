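"""End-to-end orchestration of the two-phase study.

Discovery: calibrate intensities -> PAF matrix -> bead filter -> PCA QC
-> variance-modelled chi-square scan -> sliding-window prioritisation ->
top-k candidate list.  Validation: per-cohort genetic-model tests on
individual genotypes for the candidates, replication in cohort 2, and a
merged-cohort analysis, with a BKY FDR batch per analysis.

Every stage appends one JSON line to ``log.jsonl`` (stage name + record
counts) so downstream tooling and tests can assert stage arithmetic; all
outputs are plain TSV/JSON under the configured output directory, listed
in ``manifest.json``.  The pipeline is a pure function of (inputs,
config): re-running it never changes an output byte.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .phenotype import read_phenotypes
from .pooled_array import PafMatrix, read_intensity_tsv
from .pooled_scan import PooledScan, PooledScanResults
from .validation_stats import (
    GenotypeTable,
    TwoStageValidation,
    ValidationResults,
    read_genotype_tsv,
    read_genotype_vcf,
)

__all__ = [
    "PipelineConfig",
    "QCFailure",
    "InputFormatError",
    "run_discovery",
    "run_validation",
    "run_all",
]


class QCFailure(RuntimeError):
    """Replicate-clustering QC failed (exit code 2 at the CLI)."""


class InputFormatError(ValueError):
    """Malformed or missing input (exit code 3 at the CLI)."""


@dataclass
class PipelineConfig:
    """Paths and analysis parameters for the full pipeline."""

    out_dir: str
    intensity_tsv: str | None = None
    genotypes: dict[str, str] = field(default_factory=dict)   # cohort -> path
    phenotypes: dict[str, str] = field(default_factory=dict)  # cohort -> csv
    n_cases: int = 98
    n_controls: int = 100
    window: int = 10
    top_k: int = 5
    min_beads: int = 4
    fdr_q: float = 0.05
    significance_threshold: float | None = None
    or_style: str = "sample"
    force: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.window < 1 or self.top_k < 1:
            raise ValueError("window and top_k must be >= 1")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - names
        if unknown:
            raise InputFormatError(f"unknown pipeline config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict) or "pipeline" not in data:
            raise InputFormatError("config file must contain a 'pipeline' section")
        return cls.from_dict(data["pipeline"])


class _StageLog:
    def __init__(self, path: Path) -> None:
        self.path = path
        self.entries: list[dict] = []
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text("")

    def log(self, stage: str, **counts) -> None:
        entry = {"stage": stage, **counts}
        self.entries.append(entry)
        with open(self.path, "a") as fh:
            fh.write(json.dumps(entry, sort_keys=True) + "\n")


def _write_manifest(out: Path, files: list[Path]) -> None:
    manifest = {
        f.name: {"bytes": f.stat().st_size}
        for f in sorted(files)
        if f.exists() and f.name != "manifest.json"
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))


def run_discovery(config: PipelineConfig) -> PooledScanResults:
    """Calibrate, filter, QC and scan; write all intermediate tables."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = _StageLog(out / "log.jsonl")

    if not config.intensity_tsv:
        raise InputFormatError("discovery requires intensity_tsv")
    try:
        records = read_intensity_tsv(config.intensity_tsv)
    except (OSError, ValueError) as exc:
        raise InputFormatError(str(exc)) from exc
    log.log("read_intensities", records=len(records),
            snps=records["snp_id"].nunique(), samples=records["sample_id"].nunique())

    matrix = PafMatrix.from_intensities(records)
    log.log("calibrate", snps=matrix.n_snps, missing_excluded=len(matrix.exclusions))

    filtered, report = matrix.filter_beads(config.min_beads)
    log.log("bead_filter", snps=filtered.n_snps, dropped=report.n_dropped,
            fraction_dropped=round(report.fraction_dropped, 6))
    exclusions = pd.concat(
        [matrix.exclusions, report.dropped[["snp_id", "reason"]]], ignore_index=True
    )
    exclusions.to_csv(out / "exclusions.tsv", sep="\t", index=False)
    filtered.to_tsv(out / "paf_matrix.tsv")

    qc = filtered.pca_qc()
    log.log("pca_qc", verdict=qc.verdict,
            max_within=qc.max_within, min_between=qc.min_between,
            explained=[round(float(x), 4) for x in qc.explained_variance_ratio])
    qc.coords.assign(group=filtered.groups.reindex(qc.coords.index)).to_csv(
        out / "pca_coords.tsv", sep="\t", index_label="sample_id"
    )
    if not qc.passed and not config.force:
        raise QCFailure(
            f"replicate clustering QC failed (max within-group distance "
            f"{qc.max_within:.4g} >= min between-group {qc.min_between:.4g})"
        )

    results = PooledScan(filtered, config.n_cases, config.n_controls).fit(
        window=config.window
    )
    results.to_tsv(out / "scan.tsv")
    results.to_bedgraph(out / "window_score.bedgraph")
    top = results.top(config.top_k)
    top.to_csv(out / "top_candidates.tsv", sep="\t", index=False)
    log.log("scan", tested=results.m, unstable=len(results.unstable),
            top_k=len(top))
    (out / "summary_discovery.txt").write_text(results.summary(config.top_k) + "\n")

    _write_manifest(out, list(out.iterdir()))
    return results


def _load_cohort(config: PipelineConfig, name: str) -> GenotypeTable:
    path = config.genotypes[name]
    try:
        if str(path).endswith(".vcf"):
            table = read_genotype_vcf(path)
        else:
            table = read_genotype_tsv(path)
    except (OSError, ValueError) as exc:
        raise InputFormatError(f"cohort {name}: {exc}") from exc
    pheno = config.phenotypes.get(name)
    if pheno:
        subjects = read_phenotypes(pheno)
        status = pd.Series({s.id: s.ir_status.value for s in subjects})
        table = GenotypeTable(table.codes, status.reindex(table.codes.index))
    return table


def run_validation(
    config: PipelineConfig, snp_list: list[str]
) -> ValidationResults | None:
    """Genetic-model tests on candidates, per cohort and merged."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = _StageLog(out / "log_validation.jsonl")

    if not snp_list:
        (out / "validation.tsv").write_text(
            "batch\tsnp_id\tmodel\tp\tq\tsignificant\n"
        )
        log.log("validation", snps=0, batches=0)
        _write_manifest(out, list(out.iterdir()))
        return None
    if not config.genotypes:
        raise InputFormatError("validation requires genotype inputs")

    cohorts = {}
    for name in config.genotypes:
        table = _load_cohort(config, name)
        present = [s for s in snp_list if s in table.snp_ids]
        cohorts[name] = GenotypeTable(
            table.codes[present], table.status, table.snps
        )
        log.log("load_cohort", cohort=name, subjects=len(table.codes),
                snps_requested=len(snp_list), snps_present=len(present))

    model = TwoStageValidation(cohorts)
    results = model.fit(
        q=config.fdr_q,
        significance_threshold=config.significance_threshold,
    )
    results.to_tsv(out / "validation.tsv")
    (out / "summary_validation.txt").write_text(results.summary() + "\n")
    log.log("validation", snps=len(snp_list),
            batches=results.table["batch"].nunique(),
            significant=int(results.table["significant"].sum()))
    _write_manifest(out, list(out.iterdir()))
    return results


def run_all(config: PipelineConfig) -> tuple[PooledScanResults, ValidationResults | None]:
    """Discovery followed by validation of the discovered candidates."""
    scan = run_discovery(config)
    candidates = list(scan.top(config.top_k)["snp_id"])
    validation = run_validation(config, candidates)
    return scan, validation
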