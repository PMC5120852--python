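"""End-to-end pipeline: ingest -> filter -> aggregate -> test -> read-level.

PipelineConfig gathers every analysis threshold in one place with the
standard defaults (>=5 reads per CpG, >=5 CpGs per promoter/ICR, >=5 CpGs
per read, >=20 reads per region, 5-percentage-point effect gate, alpha 0.05,
60% high-read cutoff).  ``run_pipeline`` executes the stages, writes every
stage output as TSV plus a JSON run manifest (config echo, package/library
versions, input checksums, per-stage record counts), and is deterministic
for fixed inputs and seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import diffmeth, epiallele, methcalls, regions

logger = logging.getLogger("epihet")


class ConfigError(Exception):
    """Invalid or incomplete pipeline configuration."""


class DataError(Exception):
    """Malformed or inconsistent input data."""


@dataclass
class PipelineConfig:
    calls: dict[str, str] = field(default_factory=dict)  # sample -> coverage path
    reads: dict[str, str] = field(default_factory=dict)  # sample -> reads path
    annotation: str = ""
    sample_sheet: str = ""
    out_dir: str = "epihet_out"
    min_reads: int = 5
    min_cpgs_region: int = 5
    min_cpgs_read: int = 5
    min_reads_region: int = 20
    delta_min: float = 0.05
    alpha: float = 0.05
    high_read_cutoff: float = 0.6
    tau_high: float = 0.05
    tau_mid: float = 0.05
    cluster_method: str = "average"
    cluster_metric: str = "euclidean"
    reference_group: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "min_reads",
            "min_cpgs_region",
            "min_cpgs_read",
            "min_reads_region",
        ):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be a positive integer")
        for name in ("delta_min", "alpha", "high_read_cutoff", "tau_high", "tau_mid"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ConfigError(f"{name} must be in (0, 1], got {v}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"{path}: unknown config keys {sorted(unknown)}")
        try:
            return cls(**raw)
        except TypeError as exc:
            raise ConfigError(str(exc)) from None

    def validate_paths(self) -> None:
        for field_name in ("annotation", "sample_sheet"):
            p = getattr(self, field_name)
            if not p:
                raise ConfigError(f"config field '{field_name}' is required")
            if not Path(p).exists():
                raise ConfigError(f"config field '{field_name}': no such file {p}")
        for label, mapping in (("calls", self.calls), ("reads", self.reads)):
            if not mapping:
                raise ConfigError(f"config field '{label}' is required")
            for sample, p in mapping.items():
                if not Path(p).exists():
                    raise ConfigError(f"{label}[{sample}]: no such file {p}")


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Execute every stage; returns the manifest dict (also written to disk)."""
    config.validate_paths()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    stream = logging.StreamHandler(sys.stderr)
    fmt = logging.Formatter("%(levelname)s %(message)s")
    for h in (handler, stream):
        h.setFormatter(fmt)
        logger.addHandler(h)
    logger.setLevel(logging.INFO)

    manifest: dict[str, Any] = {
        "config": asdict(config),
        "versions": {
            "epihet": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "python": sys.version.split()[0],
        },
        "inputs": {},
        "stages": {},
    }
    try:
        sheet = methcalls.SampleSheet.from_csv(config.sample_sheet)
        manifest["inputs"]["sample_sheet"] = _sha256(config.sample_sheet)
        manifest["inputs"]["annotation"] = _sha256(config.annotation)
        missing = [s for s in sheet.samples if s not in config.calls]
        if missing:
            raise DataError(f"samples in sheet without coverage files: {missing}")

        # stage: ingest + coverage filter
        calls = {}
        for sample in sheet.samples:
            calls[sample] = methcalls.read_coverage_file(config.calls[sample])
            manifest["inputs"][f"calls:{sample}"] = _sha256(config.calls[sample])
        filtered = methcalls.filter_by_coverage(
            calls, min_reads=config.min_reads, require_all_samples=True
        )
        n_covered = len(next(iter(filtered.values())))
        logger.info(
            "ingest: %d samples, %d CpGs covered >=%dx in all samples",
            len(calls),
            n_covered,
            config.min_reads,
        )
        manifest["stages"]["ingest"] = {
            "n_samples": len(calls),
            "n_groups": len(sheet.groups),
            "group_sizes": sheet.group_sizes,
            "n_covered_cpgs": n_covered,
        }

        # stage: annotation + aggregation
        features = regions.read_bed(config.annotation)
        assignment = regions.assign_sites(
            next(iter(filtered.values()))[["chrom", "pos"]], features
        )
        class_means = regions.class_mean_table(filtered, assignment)
        class_summary = regions.group_summary(class_means, sheet)
        prom_like = [
            f
            for f in features
            if f.feature_class == "promoter" or f.feature_class.startswith("ICR")
        ]
        matrix = regions.region_matrix(
            filtered, prom_like, min_cpgs=config.min_cpgs_region
        )
        logger.info(
            "aggregate: %d feature classes, %d promoter/ICR regions (%d with values)",
            class_means.shape[0],
            matrix.shape[0],
            int(matrix.notna().all(axis=1).sum()),
        )
        manifest["stages"]["aggregate"] = {
            "n_features": len(features),
            "n_classes": int(class_means.shape[0]),
            "n_regions_tested_pool": int(matrix.shape[0]),
        }
        class_means.to_csv(out / "class_means.tsv", sep="\t")
        _write_group_summary(class_summary, out / "class_group_summary.tsv")
        matrix.to_csv(out / "region_matrix.tsv", sep="\t")

        # stage: differential methylation
        diff = diffmeth.call_differential(
            matrix,
            sheet,
            delta_min=config.delta_min,
            alpha=config.alpha,
        )
        diff_regions = list(diff.index[diff["differential"]])
        logger.info(
            "diffmeth: %d testable, %d differential regions",
            int(diff["testable"].sum()),
            len(diff_regions),
        )
        clusters = pd.Series(dtype=object)
        excluded: list[str] = []
        if len(diff_regions) >= 2:
            clusters, excluded = diffmeth.cluster_differential(
                matrix,
                diff_regions,
                sheet,
                reference_group=config.reference_group,
                method=config.cluster_method,
                metric=config.cluster_metric,
            )
        diff["cluster"] = clusters.reindex(diff.index).fillna("")
        diff.to_csv(out / "diffmeth.tsv", sep="\t")
        clusters.rename("cluster").to_csv(out / "clusters.tsv", sep="\t")
        manifest["stages"]["diffmeth"] = {
            "n_testable": int(diff["testable"].sum()),
            "n_differential": len(diff_regions),
            "clusters": {
                str(kk): int(vv) for kk, vv in clusters.value_counts().items()
            },
            "n_excluded_flat": len(excluded),
        }

        # stage: read-level epiallele analysis on differential regions
        reads_by_sample = {}
        for sample in sheet.samples:
            if sample not in config.reads:
                raise DataError(f"sample {sample} has no reads file")
            reads_by_sample[sample] = methcalls.read_readfile(config.reads[sample])
            manifest["inputs"][f"reads:{sample}"] = _sha256(config.reads[sample])
        target_regions = diff_regions if diff_regions else None
        profiles, calls_tbl, filt = epiallele.profile_table(
            reads_by_sample,
            regions=target_regions,
            min_cpgs=config.min_cpgs_read,
            min_reads=config.min_reads_region,
            tau_high=config.tau_high,
            tau_mid=config.tau_mid,
            cutoff=config.high_read_cutoff,
        )
        profiles.to_csv(out / "bin_profiles.tsv", sep="\t", index=False)
        calls_tbl.to_csv(out / "pattern_calls.tsv", sep="\t", index=False)
        filt.to_csv(out / "filtered_methylation.tsv", sep="\t", index=False)
        logger.info(
            "epiallele: %d region x sample profiles, %d pattern-I calls",
            len(profiles),
            int((calls_tbl["call"] == "pattern_I").sum()) if len(calls_tbl) else 0,
        )
        manifest["stages"]["epiallele"] = {
            "n_profiles": int(len(profiles)),
            "n_pattern_I": int((calls_tbl["call"] == "pattern_I").sum())
            if len(calls_tbl)
            else 0,
            "n_pattern_II": int((calls_tbl["call"] == "pattern_II").sum())
            if len(calls_tbl)
            else 0,
        }

        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        return manifest
    finally:
        logger.removeHandler(handler)
        logger.removeHandler(stream)
        handler.close()


def _write_group_summary(summary: pd.DataFrame, path: Path) -> None:
    flat = summary.copy()
    flat.columns = [f"{g}_{stat}" for g, stat in summary.columns]
    flat.to_csv(path, sep="\t")
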