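"""Read-level epiallele heterogeneity analysis.

Two regions with the same mean methylation can carry very different molecule
populations: a bimodal mixture of fully methylated and unmethylated
epialleles (pattern I), or uniform partial methylation on every molecule
(pattern II).  Mean-level statistics cannot distinguish them; the per-read
methylation level r = (# methylated CpGs) / (# CpGs on the read) can.

This module filters reads (>=5 CpGs per read, >=20 reads per region),
histograms r into five bins ([0,0.2), [0.2,0.4), [0.4,0.6), [0.6,0.8),
[0.8,1]), calls pattern I vs II from the bin shape, estimates the
fully-methylated epiallele fraction with a Wilson interval, and recomputes
region methylation after excluding >=60%-methylated reads — the
contamination-sensitivity analysis: if the high reads come from admixed
fully-methylated molecules (e.g. somatic contamination), removing them
should equalise the group means.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .methcalls import ReadRecord

BIN_EDGES = (0.0, 0.2, 0.4, 0.6, 0.8)  # left edges; last bin is [0.8, 1.0]
BIN_NAMES = ("B1", "B2", "B3", "B4", "B5")
MIN_CPGS_PER_READ = 5
MIN_READS_PER_REGION = 20
HIGH_READ_CUTOFF = 0.6


@dataclass(frozen=True)
class ReadBinProfile:
    """Per region x sample counts of reads in the five methylation bins."""

    region_id: str
    sample_id: str
    counts: tuple[int, int, int, int, int]

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.counts):
            raise ValueError("negative bin count")

    @property
    def n_reads(self) -> int:
        return sum(self.counts)

    @property
    def fractions(self) -> tuple[float, ...]:
        n = self.n_reads
        return tuple(c / n for c in self.counts)

    @property
    def frac_high(self) -> float:
        """Fraction of reads in the top bin (r >= 0.8)."""
        return self.counts[4] / self.n_reads

    @property
    def frac_low(self) -> float:
        """Fraction of reads in the bottom bin (r < 0.2)."""
        return self.counts[0] / self.n_reads

    @property
    def frac_mid(self) -> float:
        return sum(self.counts[1:4]) / self.n_reads


@dataclass(frozen=True)
class PatternCall:
    region_id: str
    sample_id: str
    frac_high: float
    frac_low: float
    frac_mid: float
    call: str  # pattern_I | pattern_II | indeterminate
    tau_high: float
    tau_mid: float


@dataclass(frozen=True)
class FilteredRegionMethylation:
    """Region methylation recomputed after dropping high-methylation reads."""

    region_id: str
    sample_id: str
    mean_level: float  # NaN when no read survives
    n_reads_kept: int
    n_reads_removed: int


def filter_reads(
    reads: Iterable[ReadRecord], min_cpgs: int = MIN_CPGS_PER_READ
) -> list[ReadRecord]:
    """Keep reads covering at least ``min_cpgs`` CpGs (inclusive); idempotent."""
    return [r for r in reads if r.n_cpgs >= min_cpgs]


def read_bin(level: float) -> int:
    """Index of the five-bin histogram bin containing read level ``level``.

    Bins are left-closed, [0,0.2) ... [0.6,0.8), with the last bin closed
    [0.8,1], so r = 0.6 falls in B4 and r = 1.0 in B5.
    """
    return min(int(level * 5), 4)


def bin_reads(
    reads: Sequence[ReadRecord],
    region_id: str,
    sample_id: str,
    min_reads: int = MIN_READS_PER_REGION,
) -> ReadBinProfile | None:
    """Five-bin read-level profile; None when fewer than ``min_reads`` reads.

    Reads must already be CpG-filtered; only reads assigned to ``region_id``
    are counted.
    """
    counts = [0, 0, 0, 0, 0]
    n = 0
    for r in reads:
        if r.region_id != region_id:
            continue
        counts[read_bin(r.level)] += 1
        n += 1
    if n < min_reads:
        return None
    return ReadBinProfile(region_id, sample_id, tuple(counts))


def call_pattern(
    profile: ReadBinProfile, tau_high: float = 0.05, tau_mid: float = 0.05
) -> PatternCall:
    """Classify a bin profile as pattern I, pattern II or indeterminate.

    pattern I: a distinct fully-methylated subpopulation — the top-bin
    fraction is at least tau_high while the middle bins stay at or below
    tau_mid.  pattern II: no high reads (top bin below tau_high) but mass in
    the middle bins above tau_mid.  Anything else is indeterminate.
    """
    fh, fm = profile.frac_high, profile.frac_mid
    if fh >= tau_high and fm <= tau_mid:
        call = "pattern_I"
    elif fh < tau_high and fm > tau_mid:
        call = "pattern_II"
    else:
        call = "indeterminate"
    return PatternCall(
        profile.region_id,
        profile.sample_id,
        fh,
        profile.frac_low,
        fm,
        call,
        tau_high,
        tau_mid,
    )


def wilson_interval(k: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion."""
    if n == 0:
        return (0.0, 1.0)
    from scipy import stats

    z = stats.norm.ppf(0.5 + conf / 2.0)
    phat = k / n
    denom = 1.0 + z**2 / n
    center = (phat + z**2 / (2 * n)) / denom
    half = z * np.sqrt(phat * (1 - phat) / n + z**2 / (4 * n**2)) / denom
    return (max(0.0, center - half), min(1.0, center + half))


def estimate_epiallele_fraction(
    profile: ReadBinProfile, conf: float = 0.95
) -> tuple[float, tuple[float, float]]:
    """Point estimate and Wilson CI for the fully-methylated read fraction.

    The estimator is the top-bin fraction (reads with r >= 0.8).  With short
    reads it slightly underestimates the molecular epiallele fraction because
    a fully-methylated molecule's read can drop below the bin edge by
    sampling only a few CpGs (attenuation).
    """
    k = profile.counts[4]
    n = profile.n_reads
    return k / n, wilson_interval(k, n, conf)


def recompute_without_high_reads(
    reads: Sequence[ReadRecord],
    region_id: str,
    sample_id: str,
    cutoff: float = HIGH_READ_CUTOFF,
) -> FilteredRegionMethylation:
    """Region methylation after excluding reads with r >= cutoff (inclusive).

    The recomputed level is the pooled per-CpG mean over the surviving reads
    (methylated CpG observations / total CpG observations), matching the
    site-level definition of methylation.  Removing high reads can only
    lower the pooled mean.
    """
    kept_meth = 0
    kept_total = 0
    n_kept = 0
    n_removed = 0
    for r in reads:
        if r.region_id != region_id:
            continue
        if r.level >= cutoff:
            n_removed += 1
            continue
        n_kept += 1
        kept_meth += sum(r.meth_vector)
        kept_total += r.n_cpgs
    mean = kept_meth / kept_total if kept_total else float("nan")
    return FilteredRegionMethylation(region_id, sample_id, mean, n_kept, n_removed)


# ---------------------------------------------------------------------------
# Tabular drivers over many regions / samples
# ---------------------------------------------------------------------------


def profile_table(
    reads_by_sample: Mapping[str, Sequence[ReadRecord]],
    regions: Sequence[str] | None = None,
    min_cpgs: int = MIN_CPGS_PER_READ,
    min_reads: int = MIN_READS_PER_REGION,
    tau_high: float = 0.05,
    tau_mid: float = 0.05,
    cutoff: float = HIGH_READ_CUTOFF,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Run the read-level analysis over every (region, sample) pair.

    Returns (bin profiles, pattern calls, filtered methylation) tables.
    ``regions=None`` analyses every region seen in the reads.
    """
    profiles = []
    calls = []
    filtered = []
    for sample, reads in reads_by_sample.items():
        good = filter_reads(reads, min_cpgs=min_cpgs)
        by_region: dict[str, list[ReadRecord]] = {}
        for r in good:
            by_region.setdefault(r.region_id, []).append(r)
        todo = regions if regions is not None else sorted(by_region)
        for region in todo:
            sub = by_region.get(region, [])
            prof = bin_reads(sub, region, sample, min_reads=min_reads)
            if prof is None:
                continue
            est, (lo, hi) = estimate_epiallele_fraction(prof)
            profiles.append(
                {
                    "region": region,
                    "sample": sample,
                    **dict(zip(BIN_NAMES, prof.counts)),
                    "n_reads": prof.n_reads,
                    "frac_high": prof.frac_high,
                    "epiallele_fraction": est,
                    "ci_low": lo,
                    "ci_high": hi,
                }
            )
            pc = call_pattern(prof, tau_high=tau_high, tau_mid=tau_mid)
            calls.append(
                {
                    "region": region,
                    "sample": sample,
                    "frac_high": pc.frac_high,
                    "frac_low": pc.frac_low,
                    "frac_mid": pc.frac_mid,
                    "call": pc.call,
                    "tau_high": tau_high,
                    "tau_mid": tau_mid,
                }
            )
            fm = recompute_without_high_reads(sub, region, sample, cutoff=cutoff)
            filtered.append(
                {
                    "region": region,
                    "sample": sample,
                    "mean_level": fm.mean_level,
                    "n_reads_kept": fm.n_reads_kept,
                    "n_reads_removed": fm.n_reads_removed,
                }
            )
    return (
        pd.DataFrame(profiles),
        pd.DataFrame(calls),
        pd.DataFrame(filtered),
    )
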