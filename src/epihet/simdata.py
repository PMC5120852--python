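"""Synthetic RRBS generator with read-level epiallele structure.

Generates per-sample CpG call tables, per-read methylation records, a BED
feature annotation and a sample sheet, with the statistical structure the
downstream analysis assumes:

* three age groups (default sizes 7, 3 and 7 samples);
* hypomethylated promoters and imprinting control regions (ICRs) carrying a
  small admixed fully-methylated epiallele fraction in the youngest group
  only;
* highly methylated retrotransposon classes with a small monotone increase
  across groups;
* incomplete bisulfite-conversion noise (<1% failure by default).

Two read-level generators are mean-matched by construction.  In *mixture*
mode a read is drawn whole from a fully-methylated epiallele class (per-CpG
Bernoulli(p_high)) with probability rho, otherwise from the unmethylated
class (Bernoulli(p_low)); this produces the bimodal read-level distribution
in which individual molecules are either mostly methylated or mostly not.  In
*uniform* mode every CpG of every read is Bernoulli(rho*p_high +
(1-rho)*p_low), so the pooled per-CpG mean is identical but no read stands
out.  Mean-level statistics cannot tell the two apart; read-level statistics
can, which is the point of the epiallele module.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from .methcalls import ReadRecord, SampleSheet, reads_to_site_counts, write_coverage_file, write_readfile
from .regions import GenomicFeature, write_bed

DEFAULT_P_HIGH = 0.95
DEFAULT_P_LOW = 0.02


@dataclass(frozen=True)
class EpialleleMixtureParams:
    """Two-class epiallele mixture for one region in one group.

    rho is the fraction of molecules from the fully-methylated class; p_high
    and p_low are the per-CpG methylation probabilities of the two classes.
    The pooled per-CpG mean is rho*p_high + (1-rho)*p_low regardless of
    pattern mode.
    """

    rho: float
    p_high: float = DEFAULT_P_HIGH
    p_low: float = DEFAULT_P_LOW

    def __post_init__(self) -> None:
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError(f"rho must be in [0,1], got {self.rho}")
        if not 0.0 <= self.p_low < self.p_high <= 1.0:
            raise ValueError(
                f"need 0 <= p_low < p_high <= 1, got ({self.p_low}, {self.p_high})"
            )

    @property
    def mean_level(self) -> float:
        return self.rho * self.p_high + (1.0 - self.rho) * self.p_low


def mixture_for_mean(
    mean: float, p_high: float = DEFAULT_P_HIGH, p_low: float = DEFAULT_P_LOW
) -> EpialleleMixtureParams:
    """Mixture parameters whose pooled per-CpG mean equals ``mean``."""
    if not p_low <= mean <= p_high:
        raise ValueError(f"mean {mean} outside [{p_low}, {p_high}]")
    rho = (mean - p_low) / (p_high - p_low)
    return EpialleleMixtureParams(rho=rho, p_high=p_high, p_low=p_low)


@dataclass(frozen=True)
class ConversionNoiseParams:
    """Bisulfite conversion error model.

    fail_rate: probability an unmethylated C escapes conversion and is read
    as methylated (conversion rates >99% in good libraries, so < 0.01).
    over_rate: probability a methylated C is read as unmethylated.
    """

    fail_rate: float = 0.005
    over_rate: float = 0.0

    def __post_init__(self) -> None:
        for name, v in (("fail_rate", self.fail_rate), ("over_rate", self.over_rate)):
            if not 0.0 <= v <= 0.05:
                raise ValueError(f"{name} must be in [0, 0.05], got {v}")


@dataclass(frozen=True)
class RegionSpec:
    """Template for one simulated region.

    group_mixture maps group label -> EpialleleMixtureParams; pattern is
    "mixture" or "uniform" (a single string applies to all groups, or a
    mapping gives one mode per group).
    """

    name: str
    feature_class: str
    chrom: str
    start: int  # 0-based position of the first CpG
    n_cpg: int
    spacing: int = 10
    group_mixture: Mapping[str, EpialleleMixtureParams] = field(default_factory=dict)
    pattern: str | Mapping[str, str] = "mixture"

    def cpg_positions(self) -> np.ndarray:
        return self.start + self.spacing * np.arange(self.n_cpg)

    @property
    def end(self) -> int:
        """0-based half-open end covering the last CpG."""
        return int(self.start + self.spacing * (self.n_cpg - 1) + 2)

    def pattern_for(self, group: str) -> str:
        p = self.pattern if isinstance(self.pattern, str) else self.pattern[group]
        if p not in ("mixture", "uniform"):
            raise ValueError(f"pattern must be 'mixture' or 'uniform', got {p!r}")
        return p


@dataclass(frozen=True)
class SimulationDesign:
    """Full study design: groups, region templates, depth and noise."""

    groups: tuple[tuple[str, int], ...]
    regions: tuple[RegionSpec, ...]
    mean_coverage: float = 30.0  # target per-CpG read coverage
    cpgs_per_read: tuple[int, int] = (5, 10)  # inclusive uniform support
    noise: ConversionNoiseParams = ConversionNoiseParams()
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 1 for _, n in self.groups):
            raise ValueError("group sizes must be positive")
        if self.cpgs_per_read[0] < 1 or self.cpgs_per_read[0] > self.cpgs_per_read[1]:
            raise ValueError(f"bad cpgs_per_read support {self.cpgs_per_read}")
        labels = [g for g, _ in self.groups]
        for spec in self.regions:
            missing = [g for g in labels if g not in spec.group_mixture]
            if missing:
                raise ValueError(
                    f"region {spec.name}: no mixture parameters for groups {missing}"
                )

    @property
    def sample_sheet(self) -> SampleSheet:
        entries = []
        for label, n in self.groups:
            for i in range(1, n + 1):
                entries.append((f"{label}_{i:02d}", label))
        return SampleSheet(entries)


# ---------------------------------------------------------------------------
# Read-level generator
# ---------------------------------------------------------------------------


def simulate_read(
    mix: EpialleleMixtureParams,
    noise: ConversionNoiseParams,
    n_cpg: int,
    pattern: str,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw one read's binary methylation vector.

    mixture: the epiallele class is drawn once per read — with probability rho
    all CpGs are Bernoulli(p_high), otherwise Bernoulli(p_low).  uniform:
    every CpG is Bernoulli(rho*p_high + (1-rho)*p_low).  Conversion noise then
    flips 0->1 with fail_rate and 1->0 with over_rate.  Expected per-CpG
    methylation is identical between the two modes.
    """
    if n_cpg < 1:
        raise ValueError(f"n_cpg must be >= 1, got {n_cpg}")
    if pattern == "mixture":
        p = mix.p_high if rng.random() < mix.rho else mix.p_low
    elif pattern == "uniform":
        p = mix.mean_level
    else:
        raise ValueError(f"pattern must be 'mixture' or 'uniform', got {pattern!r}")
    v = (rng.random(n_cpg) < p).astype(np.int8)
    if noise.fail_rate > 0 or noise.over_rate > 0:
        v = _apply_noise(v, noise, rng)
    return v


def _apply_noise(
    v: np.ndarray, noise: ConversionNoiseParams, rng: np.random.Generator
) -> np.ndarray:
    u = rng.random(v.shape)
    out = v.copy()
    out[(v == 0) & (u < noise.fail_rate)] = 1
    out[(v == 1) & (u < noise.over_rate)] = 0
    return out


def simulate_region_reads(
    spec: RegionSpec,
    group: str,
    noise: ConversionNoiseParams,
    n_reads: int,
    cpgs_per_read: tuple[int, int],
    rng: np.random.Generator,
    sample_id: str = "s",
) -> list[ReadRecord]:
    """Draw reads for one region in one sample.

    Each read covers a contiguous window of the region's CpGs; window length
    is uniform on the cpgs_per_read support (clipped to the region's CpG
    count) and the window start is uniform over valid offsets.
    """
    mix = spec.group_mixture[group]
    pattern = spec.pattern_for(group)
    positions = spec.cpg_positions()
    lo, hi = cpgs_per_read
    reads: list[ReadRecord] = []
    for i in range(n_reads):
        k = min(int(rng.integers(lo, hi + 1)), spec.n_cpg)
        off = int(rng.integers(0, spec.n_cpg - k + 1))
        vec = simulate_read(mix, noise, k, pattern, rng)
        reads.append(
            ReadRecord(
                read_id=f"{sample_id}:{spec.name}:{i}",
                chrom=spec.chrom,
                region_id=spec.name,
                cpg_positions=tuple(int(p) for p in positions[off : off + k]),
                meth_vector=tuple(int(x) for x in vec),
            )
        )
    return reads


def _reads_per_region(design: SimulationDesign, spec: RegionSpec) -> int:
    mean_len = 0.5 * (design.cpgs_per_read[0] + design.cpgs_per_read[1])
    return max(1, int(np.ceil(design.mean_coverage * spec.n_cpg / mean_len)))


# ---------------------------------------------------------------------------
# Dataset assembly
# ---------------------------------------------------------------------------


def simulate_sample_reads(
    design: SimulationDesign, sample_index: int
) -> list[ReadRecord]:
    """All reads for one sample; RNG streams keyed by (seed, sample, region)."""
    sheet = design.sample_sheet
    sample_id, group = sheet.entries[sample_index]
    reads: list[ReadRecord] = []
    for ri, spec in enumerate(design.regions):
        rng = np.random.default_rng([design.seed, sample_index, ri])
        n_reads = _reads_per_region(design, spec)
        reads.extend(
            simulate_region_reads(
                spec, group, design.noise, n_reads, design.cpgs_per_read, rng, sample_id
            )
        )
    return reads


def design_features(design: SimulationDesign) -> list[GenomicFeature]:
    return [
        GenomicFeature(
            chrom=spec.chrom,
            start=spec.start,
            end=spec.end,
            strand="+",
            feature_class=spec.feature_class,
            name=spec.name,
        )
        for spec in design.regions
    ]


def simulate_dataset(design: SimulationDesign, out_dir: str | Path) -> dict:
    """Generate and write the full dataset; returns a manifest of paths.

    Per sample: ``<sample>.cov.tsv`` (Bismark-coverage dialect, aggregated
    exactly from the emitted reads so counts conserve observations) and
    ``<sample>.reads.tsv``.  Plus ``annotation.bed`` and ``samples.csv``.
    Deterministic given the design seed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sheet = design.sample_sheet
    cov_paths: dict[str, Path] = {}
    read_paths: dict[str, Path] = {}
    for si, (sample_id, _group) in enumerate(sheet.entries):
        reads = simulate_sample_reads(design, si)
        sites = reads_to_site_counts(reads)
        cov_paths[sample_id] = out / f"{sample_id}.cov.tsv"
        read_paths[sample_id] = out / f"{sample_id}.reads.tsv"
        write_coverage_file(sites, cov_paths[sample_id])
        write_readfile(reads, read_paths[sample_id])
    ann_path = out / "annotation.bed"
    write_bed(design_features(design), ann_path)
    sheet_path = out / "samples.csv"
    sheet.to_csv(sheet_path)
    return {
        "coverage": {s: str(p) for s, p in cov_paths.items()},
        "reads": {s: str(p) for s, p in read_paths.items()},
        "annotation": str(ann_path),
        "sample_sheet": str(sheet_path),
        "samples": sheet.samples,
    }


# ---------------------------------------------------------------------------
# Default study-like design
# ---------------------------------------------------------------------------

GROUPS_DEFAULT: tuple[tuple[str, int], ...] = (("8w", 7), ("18w", 3), ("17m", 7))


def _flat(mean: float) -> dict[str, EpialleleMixtureParams]:
    m = mixture_for_mean(mean)
    return {g: m for g, _ in GROUPS_DEFAULT}


def default_design(seed: int = 0) -> SimulationDesign:
    """A compact design emulating the study's structure.

    Three age groups of 7/3/7 samples.  Promoters and ICRs are hypomethylated
    (per-CpG ~2%) with a rho=0.10 fully-methylated epiallele admixture in the
    8w group only (mixture mode) — the read-level signature is 5-15% of reads
    >80% methylated with the rest <20%.  A second promoter set is lower in 8w
    than in the older groups with uniform (pattern-II-like) reads.
    Retrotransposon classes are highly methylated with a small monotone age
    trend (LINE ~80/82/83%).  Coverage ~30x per CpG; reads carry 5-10 CpGs;
    0.5% conversion failure.
    """
    regions: list[RegionSpec] = []
    chrom = "chr1"
    cursor = 10_000

    def add(name, fclass, n_cpg, mixtures, pattern, spacing=10):
        nonlocal cursor
        regions.append(
            RegionSpec(
                name=name,
                feature_class=fclass,
                chrom=chrom,
                start=cursor,
                n_cpg=n_cpg,
                spacing=spacing,
                group_mixture=mixtures,
                pattern=pattern,
            )
        )
        cursor += spacing * n_cpg + 2_000

    low = EpialleleMixtureParams(rho=0.0)
    admixed = EpialleleMixtureParams(rho=0.10)

    # stable hypomethylated promoters (no group effect)
    for i in range(40):
        add(f"prom_null_{i:03d}", "promoter", 12, _flat(DEFAULT_P_LOW), "mixture")
    # cluster-I-like promoters: epiallele admixture in 8w only
    for i in range(12):
        add(
            f"prom_cI_{i:03d}",
            "promoter",
            12,
            {"8w": admixed, "18w": low, "17m": low},
            "mixture",
        )
    # cluster-II-like promoters: lower in 8w, uniform partial methylation
    for i in range(6):
        add(
            f"prom_cII_{i:03d}",
            "promoter",
            12,
            {"8w": low, "18w": admixed, "17m": admixed},
            "uniform",
        )
    # maternally methylated ICRs behave like cluster I in sperm
    for name in ("Gnas", "Plagl1", "Mest"):
        add(f"ICR_{name}", f"ICR:{name}", 12, {"8w": admixed, "18w": low, "17m": low}, "mixture")

    def trend(m8, m18, m17):
        return {
            "8w": mixture_for_mean(m8),
            "18w": mixture_for_mean(m18),
            "17m": mixture_for_mean(m17),
        }

    for i in range(3):
        add(f"LINE_{i}", "LINE", 40, trend(0.800, 0.820, 0.831), "uniform")
    for i in range(2):
        add(f"LTR_{i}", "LTR", 40, trend(0.672, 0.684, 0.688), "uniform")
    for i in range(2):
        add(f"SINE_{i}", "SINE", 40, trend(0.693, 0.717, 0.714), "uniform")
    # one L1 subfamily large enough to pass the >=500-CpG class gate
    add("L1MdT_0", "L1:L1MdT", 520, trend(0.872, 0.888, 0.902), "uniform")
    for i in range(2):
        add(f"exon_{i}", "exon", 30, trend(0.143, 0.144, 0.143), "uniform")
    for i in range(2):
        add(f"intron_{i}", "intron", 30, trend(0.219, 0.229, 0.228), "uniform")
    for i in range(2):
        add(f"intergenic_{i}", "intergenic", 30, trend(0.374, 0.385, 0.385), "uniform")

    return SimulationDesign(
        groups=GROUPS_DEFAULT,
        regions=tuple(regions),
        mean_coverage=30.0,
        cpgs_per_read=(5, 10),
        noise=ConversionNoiseParams(fail_rate=0.005, over_rate=0.0),
        seed=seed,
    )
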