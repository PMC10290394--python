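"""Pipeline orchestration: configuration, run, and report writing.

The WGS pipeline chains: load VCF -> high-quality-SNP ladder -> missing
policy -> prune uninformative loci -> condition on the focal sample ->
exact combination counts -> elevated-set detection -> divergence chain,
plus the clustering/PCA baselines when requested. The GRAS-Di pipeline
chains: load VCF -> GRAS-Di ladder -> combination counts with grove
labels. All outputs are byte-stable given config + seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from . import genotypes as gt
from .filters import FilterReport, apply_grasdi_filters, apply_wgs_ladder
from .inheritance import AltLocusClassification, classify_alt_loci
from .intersections import (
    CombinationTable,
    ElevatedSet,
    combination_counts,
    condition_on_focal,
    detect_elevated,
    prune_uninformative,
)
from .matrix import GenotypeMatrix
from .pedigree import (
    Dendrogram,
    DivergenceChain,
    bootstrap_cluster,
    encode_numeric,
    infer_divergence_chain,
    pca_scores,
)
from .render import plot_upset, render_upset_text
from .vcfio import load_vcf

__all__ = ["PipelineConfig", "RunReport", "run_pipeline", "write_outputs",
           "load_metadata", "load_ref_control"]


@dataclass
class PipelineConfig:
    """Everything a run needs; round-trips losslessly through JSON."""

    vcf: str
    mode: str = "wgs"  # "wgs" | "grasdi"
    metadata: str | None = None  # TSV: sample<TAB>label (region or grove)
    ref_control: str | None = None  # TSV: scaffold<TAB>position
    focal: str | None = None
    min_degree: int = 2
    z_cut: float = 3.5
    missing: str = "drop"  # "drop" | "as-ref"
    filter2_literal: bool = False
    grove_rule: str = "whole-groves"
    nboot: int = 0  # bootstrap resamples for the clustering baseline
    plot: bool = False
    out: str = "clonehet_out"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("wgs", "grasdi"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.missing not in ("drop", "as-ref"):
            raise ValueError(f"unknown missing policy {self.missing!r}")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        return cls(**json.loads(text))

    def digest(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]


@dataclass
class RunReport:
    """Self-contained result of one pipeline run."""

    config: PipelineConfig
    filter_report: FilterReport
    matrix: GenotypeMatrix
    prune_report: dict | None = None
    tables: dict[str, CombinationTable] = field(default_factory=dict)
    elevated: list[ElevatedSet] = field(default_factory=list)
    chain: DivergenceChain | None = None
    alt_classification: AltLocusClassification | None = None
    dendrogram: Dendrogram | None = None
    pca: pd.DataFrame | None = None
    pca_variance: list[float] | None = None
    stage_log: list[str] = field(default_factory=list)

    def provenance(self) -> dict:
        return {
            "clonehet_version": __version__,
            "config": dataclasses.asdict(self.config),
            "config_digest": self.config.digest(),
        }


def load_metadata(path) -> dict[str, str]:
    """Read a sample -> label TSV (two columns, no header required)."""
    frame = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    return dict(zip(frame[0], frame[1]))


def load_ref_control(path) -> frozenset[tuple[str, int]]:
    """Read a scaffold <TAB> position TSV of reference-read control loci."""
    frame = pd.read_csv(path, sep="\t", header=None, comment="#")
    return frozenset((str(s), int(p)) for s, p in zip(frame[0], frame[1]))


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute the configured pipeline end to end."""
    log: list[str] = [f"config: {config.to_json()}"]
    records, _ = load_vcf(config.vcf)
    log.append(f"loaded {len(records)} records from {config.vcf}")
    metadata = load_metadata(config.metadata) if config.metadata else {}

    if config.mode == "wgs":
        ref_control = (
            load_ref_control(config.ref_control) if config.ref_control else frozenset()
        )
        survivors, freport = apply_wgs_ladder(records, ref_control)
    else:
        if not metadata:
            raise ValueError("grasdi mode requires a sample -> grove metadata table")
        survivors, freport = apply_grasdi_filters(
            records, metadata,
            filter2_literal=config.filter2_literal,
            grove_rule=config.grove_rule,
        )
    for name, n_in, n_out in freport.counts():
        log.append(f"filter stage {name}: {n_in} -> {n_out}")

    matrix = GenotypeMatrix.from_records(survivors, metadata)
    report = RunReport(config, freport, matrix, stage_log=log)
    if matrix.n_loci == 0:
        log.append("no loci survive filtering; empty report")
        return report

    if config.missing == "drop":
        work = matrix.drop_missing_loci()
    else:
        work = matrix.missing_as_ref()
    log.append(f"missing policy {config.missing}: {matrix.n_loci} -> {work.n_loci} loci")

    if config.mode == "grasdi":
        report.tables["HET"] = combination_counts(work, gt.HET)
        log.append(f"HET combinations: {len(report.tables['HET'].rows)} rows")
        return report

    work, prune = prune_uninformative(work)
    report.prune_report = prune
    log.append(f"pruned {prune['monomorphic']} monomorphic + "
               f"{prune['singleton']} singleton; {prune['kept']} kept")
    report.alt_classification = classify_alt_loci(matrix)

    if config.focal is not None:
        work = condition_on_focal(work, config.focal)
        log.append(f"focal-HET conditioning on {config.focal}: {work.n_loci} loci")

    report.tables["HET"] = combination_counts(work, gt.HET)
    report.tables["ALT"] = combination_counts(work, gt.ALT)
    report.elevated = detect_elevated(
        report.tables["HET"], min_degree=config.min_degree, z_cut=config.z_cut
    )
    log.append(f"{len(report.elevated)} elevated combinations "
               f"(min_degree={config.min_degree}, z_cut={config.z_cut})")
    if config.focal is not None:
        report.chain = infer_divergence_chain(report.elevated, config.focal)
        log.append(f"divergence chain length {len(report.chain.sets)}")

    if work.n_loci >= 2 and work.n_samples >= 3:
        try:
            numeric = encode_numeric(work)
            report.dendrogram = bootstrap_cluster(
                numeric, nboot=config.nboot, seed=config.seed
            )
            scores, var = pca_scores(numeric)
            report.pca = scores
            report.pca_variance = [float(v) for v in var]
        except ValueError as exc:
            log.append(f"baselines skipped: {exc}")
    return report


def write_outputs(report: RunReport, out_dir) -> list[Path]:
    """Write the report to ``out_dir``; returns the files written.

    Emits the genotype-class matrix (TSV), the filter report (TSV), one
    combination table per class (TSV, degree-then-cardinality order), the
    elevated sets and divergence chain (JSON), a text UpSet rendering,
    the run report JSON (provenance + stage log), and optionally a
    graphical UpSet.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(name: str, text: str) -> None:
        p = out / name
        p.write_text(text)
        written.append(p)

    report.matrix.to_tsv(out / "genotype_matrix.tsv")
    written.append(out / "genotype_matrix.tsv")

    frows = report.filter_report.to_rows()
    emit(
        "filter_report.tsv",
        "stage\tloci_in\tloci_out\tremoved\treasons\n"
        + "".join(
            f"{r['stage']}\t{r['loci_in']}\t{r['loci_out']}\t{r['removed']}\t"
            f"{json.dumps(r['reasons'], sort_keys=True)}\n"
            for r in frows
        ),
    )

    for cls, table in sorted(report.tables.items()):
        emit(
            f"combinations_{cls}.tsv",
            "samples\tdegree\tcount\n"
            + "".join(
                f"{row['samples']}\t{row['degree']}\t{row['count']}\n"
                for row in table.to_rows()
            ),
        )
        emit(f"upset_{cls}.txt", render_upset_text(table))
        if report.config.plot:
            plot_upset(table, out / f"upset_{cls}.png")
            written.append(out / f"upset_{cls}.png")

    emit(
        "elevated_sets.json",
        json.dumps(
            [
                {
                    "samples": list(e.samples),
                    "degree": e.degree,
                    "count": e.count,
                    "zscore": e.zscore if e.zscore != float("inf") else "inf",
                    "z_cut": e.z_cut,
                    "degree_median": e.degree_median,
                    "degree_mad": e.degree_mad,
                    "n_combinations": e.n_combinations,
                    "zeros_included": e.zeros_included,
                }
                for e in report.elevated
            ],
            indent=2,
        ),
    )

    if report.chain is not None:
        emit("divergence_chain.json", json.dumps(report.chain.to_dict(), indent=2))
    elif report.config.mode == "wgs":
        emit("divergence_chain.json", json.dumps({"chain": None,
                                                  "note": "no elevated sets"}, indent=2))

    body = {
        "provenance": report.provenance(),
        "filter_report": frows,
        "prune_report": report.prune_report,
        "alt_classification": (
            dataclasses.asdict(report.alt_classification)
            if report.alt_classification
            else None
        ),
        "pca_variance_explained_percent": report.pca_variance,
        "stage_log": report.stage_log,
    }
    emit("run_report.json", json.dumps(body, indent=2))
    return written
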