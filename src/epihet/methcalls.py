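"""Per-CpG methylation calls and per-read records: data model, I/O, coverage filter.

The package works downstream of a bisulfite aligner: its inputs are per-CpG
methylation count tables in the Bismark-coverage dialect (one row per cytosine,
1-based positions, methylated/unmethylated read counts) and a simple per-read
TSV carrying each read's binary CpG methylation vector.

Internally every position is 0-based; conversion to/from the 1-based coverage
dialect happens only at the I/O boundary.  Bulk collections of site calls are
held as pandas DataFrames with columns ``chrom, pos, n_meth, n_unmeth`` sorted
by (chrom, pos); single records use the dataclasses below.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

SITE_COLUMNS = ["chrom", "pos", "n_meth", "n_unmeth"]


@dataclass(frozen=True)
class CpGSiteCall:
    """One CpG site in one sample: counts of (un)methylated observations."""

    chrom: str
    pos: int  # 0-based position of the C on the plus strand
    n_meth: int
    n_unmeth: int

    def __post_init__(self) -> None:
        if self.n_meth < 0 or self.n_unmeth < 0:
            raise ValueError(f"negative counts at {self.chrom}:{self.pos}")
        if self.n_meth + self.n_unmeth < 1:
            raise ValueError(f"zero coverage at {self.chrom}:{self.pos}")

    @property
    def coverage(self) -> int:
        return self.n_meth + self.n_unmeth

    @property
    def level(self) -> float:
        """Methylation level m = n_meth / (n_meth + n_unmeth), in [0, 1]."""
        return self.n_meth / self.coverage


@dataclass(frozen=True)
class ReadRecord:
    """One sequenced read's binary methylation vector over the CpGs it covers."""

    read_id: str
    chrom: str
    region_id: str
    cpg_positions: tuple[int, ...]  # 0-based, ascending
    meth_vector: tuple[int, ...]  # aligned to cpg_positions, values in {0, 1}

    def __post_init__(self) -> None:
        if len(self.cpg_positions) != len(self.meth_vector):
            raise ValueError(
                f"read {self.read_id}: {len(self.cpg_positions)} positions "
                f"but {len(self.meth_vector)} methylation states"
            )
        if any(v not in (0, 1) for v in self.meth_vector):
            raise ValueError(f"read {self.read_id}: non-binary methylation state")

    @property
    def n_cpgs(self) -> int:
        return len(self.cpg_positions)

    @property
    def level(self) -> float:
        """Read-level methylation r = (# methylated CpGs) / (# CpGs)."""
        return sum(self.meth_vector) / len(self.meth_vector)


@dataclass
class SampleSheet:
    """Ordered sample -> age-group assignment.

    Group order follows first appearance in the sheet; the first group is
    treated as the reference (youngest) group by downstream cluster labelling.
    """

    entries: list[tuple[str, str]] = field(default_factory=list)

    @classmethod
    def from_csv(cls, path: str | Path) -> "SampleSheet":
        df = pd.read_csv(path, dtype=str)
        cols = {c.lower(): c for c in df.columns}
        if "sample_id" not in cols or "group" not in cols:
            raise ValueError(
                f"{path}: sample sheet needs 'sample_id' and 'group' columns, "
                f"found {list(df.columns)}"
            )
        return cls(list(zip(df[cols["sample_id"]], df[cols["group"]])))

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.entries, columns=["sample_id", "group"]).to_csv(
            path, index=False
        )

    @property
    def samples(self) -> list[str]:
        return [s for s, _ in self.entries]

    @property
    def groups(self) -> list[str]:
        seen: list[str] = []
        for _, g in self.entries:
            if g not in seen:
                seen.append(g)
        return seen

    @property
    def group_sizes(self) -> dict[str, int]:
        sizes: dict[str, int] = {}
        for _, g in self.entries:
            sizes[g] = sizes.get(g, 0) + 1
        return sizes

    def samples_in(self, group: str) -> list[str]:
        return [s for s, g in self.entries if g == group]

    def group_of(self, sample: str) -> str:
        for s, g in self.entries:
            if s == sample:
                return g
        raise KeyError(sample)


# ---------------------------------------------------------------------------
# Coverage-table I/O (Bismark coverage dialect)
# ---------------------------------------------------------------------------


def read_coverage_file(
    path: str | Path, dialect: str = "bismark_cov", collapse_strands: bool = False
) -> pd.DataFrame:
    """Read a Bismark-coverage-style TSV into a site-call table.

    The dialect has columns ``chrom, start, end, methylation%, n_meth,
    n_unmeth`` with 1-based inclusive positions.  Positions are shifted to the
    internal 0-based convention; counts are preserved exactly.

    With ``collapse_strands=True``, calls at adjacent positions ``pos`` and
    ``pos + 1`` (the two strands of a symmetric CpG dyad) are merged into one
    site at the lower position by summing counts.  Off by default, matching
    raw Bismark coverage output.
    """
    if dialect != "bismark_cov":
        raise ValueError(f"unknown coverage dialect: {dialect!r}")
    path = Path(path)
    rows: list[tuple[str, int, int, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 6:
                raise ValueError(
                    f"{path}:{lineno}: expected 6 tab-separated fields, "
                    f"got {len(parts)}"
                )
            chrom, start, _end, _pct, n_meth, n_unmeth = parts
            try:
                pos1 = int(start)
                nm = int(n_meth)
                nu = int(n_unmeth)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
            if pos1 < 1:
                raise ValueError(f"{path}:{lineno}: position {pos1} is not positive")
            if nm < 0 or nu < 0:
                raise ValueError(f"{path}:{lineno}: negative count")
            if nm + nu < 1:
                raise ValueError(f"{path}:{lineno}: zero coverage")
            rows.append((chrom, pos1 - 1, nm, nu))
    df = pd.DataFrame(rows, columns=SITE_COLUMNS)
    df = df.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
    if collapse_strands:
        df = _collapse_strands(df)
    return df


def _collapse_strands(df: pd.DataFrame) -> pd.DataFrame:
    """Merge pos/pos+1 call pairs of a CpG dyad by summing counts."""
    out: list[tuple[str, int, int, int]] = []
    i = 0
    recs = df.itertuples(index=False)
    rows = list(recs)
    while i < len(rows):
        r = rows[i]
        if (
            i + 1 < len(rows)
            and rows[i + 1].chrom == r.chrom
            and rows[i + 1].pos == r.pos + 1
        ):
            nxt = rows[i + 1]
            out.append((r.chrom, r.pos, r.n_meth + nxt.n_meth, r.n_unmeth + nxt.n_unmeth))
            i += 2
        else:
            out.append((r.chrom, r.pos, r.n_meth, r.n_unmeth))
            i += 1
    return pd.DataFrame(out, columns=SITE_COLUMNS)


def write_coverage_file(sites: pd.DataFrame, path: str | Path) -> None:
    """Write a site-call table in the Bismark coverage dialect (1-based)."""
    buf = io.StringIO()
    for r in sites.itertuples(index=False):
        cov = r.n_meth + r.n_unmeth
        pct = 100.0 * r.n_meth / cov
        buf.write(f"{r.chrom}\t{r.pos + 1}\t{r.pos + 1}\t{pct:g}\t{r.n_meth}\t{r.n_unmeth}\n")
    Path(path).write_text(buf.getvalue())


def site_levels(sites: pd.DataFrame) -> pd.Series:
    """Per-site methylation level m = n_meth / (n_meth + n_unmeth)."""
    return sites["n_meth"] / (sites["n_meth"] + sites["n_unmeth"])


# ---------------------------------------------------------------------------
# Coverage filter
# ---------------------------------------------------------------------------


def filter_by_coverage(
    calls: Mapping[str, pd.DataFrame] | pd.DataFrame,
    min_reads: int = 5,
    require_all_samples: bool = True,
) -> Mapping[str, pd.DataFrame] | pd.DataFrame:
    """Restrict calls to CpGs covered by at least ``min_reads`` observations.

    With a mapping of per-sample tables and ``require_all_samples=True`` a
    site is kept only if it passes the coverage threshold in *every* sample
    (the analyzable CpG universe is the all-sample intersection).  Output
    tables are sorted by (chrom, pos).
    """
    if min_reads < 1:
        raise ValueError(f"min_reads must be >= 1, got {min_reads}")
    if isinstance(calls, pd.DataFrame):
        cov = calls["n_meth"] + calls["n_unmeth"]
        return (
            calls[cov >= min_reads]
            .sort_values(["chrom", "pos"], kind="stable")
            .reset_index(drop=True)
        )
    filtered = {
        s: df[(df["n_meth"] + df["n_unmeth"]) >= min_reads] for s, df in calls.items()
    }
    if not require_all_samples:
        return {
            s: df.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
            for s, df in filtered.items()
        }
    keys = None
    for df in filtered.values():
        idx = pd.MultiIndex.from_frame(df[["chrom", "pos"]])
        keys = idx if keys is None else keys.intersection(idx)
    if keys is None:
        raise ValueError("no samples given")
    keys = keys.sortlevel([0, 1])[0]
    out = {}
    for s, df in filtered.items():
        d = df.set_index(["chrom", "pos"]).loc[keys].reset_index()
        out[s] = d[SITE_COLUMNS].reset_index(drop=True)
    return out


def covered_sites(calls: Mapping[str, pd.DataFrame]) -> pd.MultiIndex:
    """The (chrom, pos) index common to all per-sample tables."""
    keys = None
    for df in calls.values():
        idx = pd.MultiIndex.from_frame(df[["chrom", "pos"]])
        keys = idx if keys is None else keys.intersection(idx)
    if keys is None:
        raise ValueError("no samples given")
    return keys.sortlevel([0, 1])[0]


# ---------------------------------------------------------------------------
# Per-read record I/O
# ---------------------------------------------------------------------------


def read_readfile(path: str | Path) -> list[ReadRecord]:
    """Read the per-read TSV dialect.

    Columns: read_id, chrom, region_id, comma-separated 1-based CpG positions,
    binary methylation string — e.g. ``r1  chr1  reg1  11,21,31  101``.
    """
    path = Path(path)
    reads: list[ReadRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 5:
                raise ValueError(
                    f"{path}:{lineno}: expected 5 tab-separated fields, got {len(parts)}"
                )
            read_id, chrom, region_id, pos_str, meth_str = parts
            try:
                positions = tuple(int(p) - 1 for p in pos_str.split(","))
                vector = tuple(int(c) for c in meth_str)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
            try:
                reads.append(ReadRecord(read_id, chrom, region_id, positions, vector))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
    return reads


def write_readfile(reads: Sequence[ReadRecord], path: str | Path) -> None:
    buf = io.StringIO()
    for r in reads:
        pos = ",".join(str(p + 1) for p in r.cpg_positions)
        vec = "".join(str(v) for v in r.meth_vector)
        buf.write(f"{r.read_id}\t{r.chrom}\t{r.region_id}\t{pos}\t{vec}\n")
    Path(path).write_text(buf.getvalue())


def reads_to_site_counts(reads: Sequence[ReadRecord]) -> pd.DataFrame:
    """Aggregate read-level observations into a per-CpG site-call table.

    The result is exactly the column sums of the reads at each covered
    position, so a coverage table derived this way conserves observations.
    """
    counts: dict[tuple[str, int], list[int]] = {}
    for r in reads:
        for pos, v in zip(r.cpg_positions, r.meth_vector):
            c = counts.setdefault((r.chrom, pos), [0, 0])
            if v:
                c[0] += 1
            else:
                c[1] += 1
    rows = [(chrom, pos, nm, nu) for (chrom, pos), (nm, nu) in counts.items()]
    df = pd.DataFrame(rows, columns=SITE_COLUMNS)
    return df.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
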