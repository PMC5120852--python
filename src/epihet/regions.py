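"""Feature annotation, CpG-to-feature assignment and methylation aggregation.

Features are 0-based half-open intervals with a feature class (promoter,
exon, intron, intergenic, LINE/LTR/SINE, ``L1:<subfamily>`` or
``ICR:<name>``).  A CpG belongs to a feature iff ``start <= pos < end``; a
site may belong to several overlapping features and contributes to every
class it overlaps.

Aggregation follows the "methylation level of each cytosine" convention:
per-site levels are averaged unweighted (not coverage-weighted), first within
a sample, then summarised as mean +/- SE across the samples of an age group.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .methcalls import SampleSheet, site_levels

PROMOTER_FLANK = 500  # promoters span TSS-500 .. TSS+500


@dataclass(frozen=True)
class GenomicFeature:
    """An annotated interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str
    feature_class: str
    name: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"{self.name}: empty interval [{self.start}, {self.end})")

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


def read_bed(path: str | Path) -> list[GenomicFeature]:
    """Read a BED6 annotation; the name field encodes ``class:subname``.

    A name like ``promoter:prom_01`` yields feature_class "promoter" and name
    "prom_01"; classes that are themselves qualified use two colons worth of
    name, e.g. ``ICR:Gnas:ICR_Gnas`` -> class "ICR:Gnas", name "ICR_Gnas".
    A bare name with no colon is both class and name.
    """
    feats: list[GenomicFeature] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ValueError(f"{path}:{lineno}: need 6 BED columns, got {len(parts)}")
            chrom, start, end, name_field, _score, strand = parts[:6]
            pieces = name_field.split(":")
            if len(pieces) == 1:
                fclass, name = name_field, name_field
            else:
                fclass, name = ":".join(pieces[:-1]), pieces[-1]
            feats.append(
                GenomicFeature(chrom, int(start), int(end), strand, fclass, name)
            )
    return feats


def write_bed(features: Sequence[GenomicFeature], path: str | Path) -> None:
    with open(path, "w") as fh:
        for f in features:
            fh.write(
                f"{f.chrom}\t{f.start}\t{f.end}\t{f.feature_class}:{f.name}\t0\t{f.strand}\n"
            )


def derive_promoters(tss_table: pd.DataFrame, flank: int = PROMOTER_FLANK) -> list[GenomicFeature]:
    """Promoter features [TSS-flank, TSS+flank) from a TSS table.

    The table needs columns chrom, tss (0-based), strand, name.  The interval
    is taken around the TSS regardless of strand (strand is recorded for the
    metaplot); intervals are clipped at the chromosome start.  Transcripts
    sharing a TSS yield distinct features with identical intervals.
    """
    required = {"chrom", "tss", "strand", "name"}
    missing = required - set(tss_table.columns)
    if missing:
        raise ValueError(f"TSS table lacks columns: {sorted(missing)}")
    if tss_table["strand"].isna().any() or (~tss_table["strand"].isin(["+", "-"])).any():
        raise ValueError("every TSS needs a strand of '+' or '-'")
    feats = []
    for r in tss_table.itertuples(index=False):
        start = max(0, int(r.tss) - flank)
        feats.append(
            GenomicFeature(
                chrom=r.chrom,
                start=start,
                end=int(r.tss) + flank,
                strand=r.strand,
                feature_class="promoter",
                name=str(r.name),
            )
        )
    return feats


# ---------------------------------------------------------------------------
# Site -> feature assignment
# ---------------------------------------------------------------------------


def assign_sites(
    sites: pd.DataFrame, features: Sequence[GenomicFeature]
) -> pd.DataFrame:
    """Map each CpG site to every feature whose interval contains it.

    Returns a DataFrame with columns chrom, pos, feature_name, feature_class,
    sorted by (chrom, pos, feature_name).  Membership is half-open:
    ``start <= pos < end``.
    """
    out_chrom: list[str] = []
    out_pos: list[int] = []
    out_name: list[str] = []
    out_class: list[str] = []
    by_chrom: dict[str, np.ndarray] = {}
    for chrom, sub in sites.groupby("chrom", sort=False):
        by_chrom[chrom] = np.sort(sub["pos"].to_numpy())
    for f in features:
        pos = by_chrom.get(f.chrom)
        if pos is None:
            continue
        lo = np.searchsorted(pos, f.start, side="left")
        hi = np.searchsorted(pos, f.end, side="left")
        if hi > lo:
            hits = pos[lo:hi]
            out_chrom.extend([f.chrom] * len(hits))
            out_pos.extend(int(p) for p in hits)
            out_name.extend([f.name] * len(hits))
            out_class.extend([f.feature_class] * len(hits))
    df = pd.DataFrame(
        {
            "chrom": out_chrom,
            "pos": out_pos,
            "feature_name": out_name,
            "feature_class": out_class,
        }
    )
    return df.sort_values(
        ["chrom", "pos", "feature_name"], kind="stable"
    ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------

MIN_CPGS_L1 = 500  # an L1 subfamily is reported only with >=500 qualifying CpGs


def feature_class_mean(
    sites: pd.DataFrame,
    assignment: pd.DataFrame,
    feature_class: str,
    min_cpgs: int = 1,
) -> float:
    """Unweighted mean of per-site levels over all sites in a feature class.

    Returns NaN when fewer than ``min_cpgs`` assigned sites have calls — an
    empty or under-covered class is undefined, never zero.
    """
    members = assignment[assignment["feature_class"] == feature_class]
    if members.empty:
        return float("nan")
    keyed = sites.set_index(["chrom", "pos"])
    idx = pd.MultiIndex.from_frame(members[["chrom", "pos"]]).drop_duplicates()
    idx = idx.intersection(pd.MultiIndex.from_frame(sites[["chrom", "pos"]]))
    if len(idx) < min_cpgs:
        return float("nan")
    sub = keyed.loc[idx]
    levels = sub["n_meth"] / (sub["n_meth"] + sub["n_unmeth"])
    return float(levels.mean())


def class_mean_table(
    calls_by_sample: Mapping[str, pd.DataFrame],
    assignment: pd.DataFrame,
    min_cpgs_l1: int = MIN_CPGS_L1,
) -> pd.DataFrame:
    """Feature-class x sample matrix of per-sample pooled-CpG mean levels.

    L1 subfamilies (classes named ``L1:<subfamily>``) are reported only when
    they carry at least ``min_cpgs_l1`` qualifying CpGs.
    """
    classes = sorted(assignment["feature_class"].unique())
    rows = {}
    for fclass in classes:
        gate = min_cpgs_l1 if fclass.startswith("L1:") else 1
        rows[fclass] = {
            s: feature_class_mean(df, assignment, fclass, min_cpgs=gate)
            for s, df in calls_by_sample.items()
        }
    out = pd.DataFrame(rows).T
    out.index.name = "feature_class"
    return out.dropna(how="all")


def region_mean(
    sites: pd.DataFrame,
    feature: GenomicFeature,
    min_cpgs: int = 5,
) -> tuple[float, int]:
    """(mean level, n CpGs used) for one feature; NaN when under the CpG gate."""
    sub = sites[
        (sites["chrom"] == feature.chrom)
        & (sites["pos"] >= feature.start)
        & (sites["pos"] < feature.end)
    ]
    n = len(sub)
    if n < min_cpgs:
        return float("nan"), n
    return float(site_levels(sub).mean()), n


def region_matrix(
    calls_by_sample: Mapping[str, pd.DataFrame],
    features: Sequence[GenomicFeature],
    min_cpgs: int = 5,
) -> pd.DataFrame:
    """Feature x sample matrix of region mean levels (NaN below the CpG gate)."""
    data = {}
    for sample, sites in calls_by_sample.items():
        col = {}
        for f in features:
            m, _n = region_mean(sites, f, min_cpgs=min_cpgs)
            col[f.name] = m
        data[sample] = col
    out = pd.DataFrame(data)
    out = out.loc[[f.name for f in features]]
    out.index.name = "region"
    return out


def group_summary(values: pd.DataFrame, sheet: SampleSheet) -> pd.DataFrame:
    """Per-group mean and standard error across samples.

    ``values`` is any row-entity x sample matrix (regions or feature
    classes).  SE is the sample standard deviation (ddof=1) over the group's
    samples divided by sqrt(n_g); groups of one sample get SE 0.
    """
    out = {}
    for g in sheet.groups:
        cols = [s for s in sheet.samples_in(g) if s in values.columns]
        sub = values[cols]
        n = sub.notna().sum(axis=1)
        mean = sub.mean(axis=1)
        sd = sub.std(axis=1, ddof=1)
        se = sd / np.sqrt(n)
        se = se.where(n > 1, 0.0)
        out[(g, "mean")] = mean
        out[(g, "se")] = se
        out[(g, "n")] = n
    df = pd.DataFrame(out)
    df.columns = pd.MultiIndex.from_tuples(df.columns, names=["group", "stat"])
    return df


# ---------------------------------------------------------------------------
# TSS / gene-body / TES metaplot
# ---------------------------------------------------------------------------


def metaplot(
    sites_by_sample: Mapping[str, pd.DataFrame],
    genes: pd.DataFrame,
    flank_bp: int = 2000,
    n_body_bins: int = 40,
    n_flank_bins: int = 20,
) -> tuple[pd.DataFrame, int]:
    """Average methylation profile over upstream flank, scaled gene body and
    downstream flank.

    ``genes`` needs columns chrom, tx_start, tx_end (0-based half-open),
    strand, name.  Minus-strand genes are orientation-flipped so bin 0 is
    always the 5' end.  Per gene, a bin's value is the mean of site levels
    falling in it; bins are then averaged across genes (NaN where no gene has
    data) and reported per sample.  Genes with a body shorter than
    n_body_bins bases are skipped; the skip count is returned.
    """
    required = {"chrom", "tx_start", "tx_end", "strand", "name"}
    missing = required - set(genes.columns)
    if missing:
        raise ValueError(f"gene table lacks columns: {sorted(missing)}")
    total_bins = 2 * n_flank_bins + n_body_bins
    flank_w = flank_bp / n_flank_bins
    n_skipped = 0
    usable = []
    for g in genes.itertuples(index=False):
        if g.tx_end - g.tx_start < n_body_bins:
            n_skipped += 1
            continue
        usable.append(g)
    profiles = {}
    for sample, sites in sites_by_sample.items():
        acc = np.zeros(total_bins)
        cnt = np.zeros(total_bins, dtype=int)
        for g in usable:
            sub = sites[
                (sites["chrom"] == g.chrom)
                & (sites["pos"] >= g.tx_start - flank_bp)
                & (sites["pos"] < g.tx_end + flank_bp)
            ]
            if sub.empty:
                continue
            pos = sub["pos"].to_numpy()
            lev = (sub["n_meth"] / (sub["n_meth"] + sub["n_unmeth"])).to_numpy()
            body_len = g.tx_end - g.tx_start
            rel = pos - g.tx_start
            bins = np.empty(len(pos), dtype=int)
            up = rel < 0
            body = (rel >= 0) & (rel < body_len)
            down = rel >= body_len
            bins[up] = np.floor((rel[up] + flank_bp) / flank_w).astype(int)
            bins[body] = n_flank_bins + np.floor(
                rel[body] / body_len * n_body_bins
            ).astype(int)
            bins[down] = (
                n_flank_bins
                + n_body_bins
                + np.floor((rel[down] - body_len) / flank_w).astype(int)
            )
            bins = np.clip(bins, 0, total_bins - 1)
            if g.strand == "-":
                bins = total_bins - 1 - bins
            gene_sum = np.zeros(total_bins)
            gene_cnt = np.zeros(total_bins, dtype=int)
            np.add.at(gene_sum, bins, lev)
            np.add.at(gene_cnt, bins, 1)
            has = gene_cnt > 0
            acc[has] += gene_sum[has] / gene_cnt[has]
            cnt[has] += 1
        with np.errstate(invalid="ignore"):
            profiles[sample] = np.where(cnt > 0, acc / np.maximum(cnt, 1), np.nan)
    idx = (
        [f"up_{i}" for i in range(n_flank_bins)]
        + [f"body_{i}" for i in range(n_body_bins)]
        + [f"down_{i}" for i in range(n_flank_bins)]
    )
    return pd.DataFrame(profiles, index=idx), n_skipped
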