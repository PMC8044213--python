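"""Per-CpG count table and interval I/O.

The substrate of every downstream stage is a :class:`MethylomeTrack`: an
ordered table of cytosines, each carrying the number of reads reporting
protection from bisulfite conversion (``meth``) and the total read count
(``total``).  Tracks are read from methcounts-style text (six whitespace
separated columns: chrom, position, strand, context, methylation level,
coverage), in which the level is a ratio — counts are reconstructed as
``round(level * coverage)`` with round-half-to-even.

All coordinates are 0-based; intervals are half-open ``[start, end)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SITE_COLUMNS = ["chrom", "pos", "strand", "context", "meth", "total"]

_CONTEXTS = frozenset({"CpG", "CHH", "CHG"})


class MethcountsParseError(ValueError):
    """Raised for malformed methcounts input, naming the offending line."""


@dataclass
class ConversionStats:
    """Bisulfite conversion rate: the fraction of unmethylated cytosines
    read as thymidine, estimated from non-CpG cytosines (assumed to be
    essentially unmethylated in mammalian genomes)."""

    conversion_rate: float
    n_sites_used: int


@dataclass
class MethylomeTrack:
    """Ordered per-cytosine methylation counts for one sample.

    Parameters
    ----------
    sample_id
        Free-text label for the sample.
    sites
        DataFrame with columns ``chrom, pos, strand, context, meth, total``,
        sorted by (chrom, pos).  ``meth <= total`` at every site.
    """

    sample_id: str
    sites: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        missing = [c for c in SITE_COLUMNS if c not in self.sites.columns]
        if missing:
            raise ValueError(f"track missing columns: {missing}")
        s = self.sites
        if len(s):
            if (s["meth"] > s["total"]).any():
                raise ValueError("meth count exceeds total count")
            if (s["total"] < 0).any():
                raise ValueError("negative coverage")
        self.sites = s.sort_values(["chrom", "pos"], kind="mergesort").reset_index(
            drop=True
        )

    def __len__(self) -> int:
        return len(self.sites)

    @property
    def levels(self) -> np.ndarray:
        """Per-site methylation level meth/total; NaN where total == 0."""
        total = self.sites["total"].to_numpy(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(total > 0, self.sites["meth"].to_numpy(float) / total, np.nan)

    def subset(self, context: str) -> "MethylomeTrack":
        return MethylomeTrack(
            self.sample_id, self.sites[self.sites["context"] == context].copy()
        )


def read_methcounts(path, context_filter: str | None = "CpG") -> MethylomeTrack:
    """Read a methcounts-style table into a :class:`MethylomeTrack`.

    Counts are reconstructed from the stored (level, coverage) pair as
    ``round(level * coverage)`` using round-half-to-even.  Lines whose
    context does not match ``context_filter`` are dropped; pass ``None``
    to keep every context (needed for conversion-rate estimation).
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 6:
                raise MethcountsParseError(
                    f"line {lineno}: expected 6 fields, got {len(parts)}"
                )
            chrom, pos_s, strand, context, level_s, cov_s = parts
            try:
                pos = int(pos_s)
                level = float(level_s)
                cov = int(cov_s)
            except ValueError as exc:
                raise MethcountsParseError(f"line {lineno}: {exc}") from None
            if cov < 0:
                raise MethcountsParseError(f"line {lineno}: negative coverage {cov}")
            if not (0.0 <= level <= 1.0) and cov > 0:
                raise MethcountsParseError(
                    f"line {lineno}: level {level} outside [0, 1]"
                )
            if context_filter is not None and context != context_filter:
                continue
            meth = int(np.rint(level * cov))  # np.rint rounds half to even
            rows.append((chrom, pos, strand, context, meth, cov))
    sites = pd.DataFrame(rows, columns=SITE_COLUMNS)
    if not len(sites):
        sites = _empty_sites()
    import os

    sample_id = os.path.splitext(os.path.basename(str(path)))[0]
    return MethylomeTrack(sample_id, sites)


def _empty_sites() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": pd.Series(dtype=str),
            "pos": pd.Series(dtype=np.int64),
            "strand": pd.Series(dtype=str),
            "context": pd.Series(dtype=str),
            "meth": pd.Series(dtype=np.int64),
            "total": pd.Series(dtype=np.int64),
        }
    )


def write_methcounts(track: MethylomeTrack, path) -> None:
    """Write a track back to methcounts-style text (level + coverage).

    The level is written with enough digits that ``read_methcounts``
    reconstructs every count exactly (round-trip lossless).
    """
    s = track.sites
    total = s["total"].to_numpy(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        level = np.where(total > 0, s["meth"].to_numpy(float) / total, 0.0)
    out = pd.DataFrame(
        {
            "chrom": s["chrom"],
            "pos": s["pos"],
            "strand": s["strand"],
            "context": s["context"],
            "level": [format(x, ".10g") for x in level],
            "total": s["total"],
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def merge_symmetric_cpgs(track: MethylomeTrack) -> MethylomeTrack:
    """Merge symmetric CpG dyads into single plus-strand records.

    A minus-strand CpG at position ``p`` pairs with a plus-strand CpG at
    ``p - 1``; the merged record carries the summed counts at the
    plus-strand C.  Unpaired sites are kept unchanged, so the operation
    is idempotent and conserves total counts.  Non-CpG sites pass through
    untouched.
    """
    s = track.sites
    cpg = s[s["context"] == "CpG"]
    other = s[s["context"] != "CpG"]
    if not len(cpg):
        return MethylomeTrack(track.sample_id, s.copy())

    plus = cpg[cpg["strand"] == "+"]
    minus = cpg[cpg["strand"] == "-"]

    plus_keys = set(zip(plus["chrom"], plus["pos"]))
    minus_partner = minus["pos"].to_numpy() - 1
    paired_mask = [
        (c, p) in plus_keys for c, p in zip(minus["chrom"], minus_partner)
    ]
    paired_mask = np.asarray(paired_mask, dtype=bool)
    minus_paired = minus[paired_mask]
    minus_lone = minus[~paired_mask]

    add = pd.DataFrame(
        {
            "chrom": minus_paired["chrom"].to_numpy(),
            "pos": minus_paired["pos"].to_numpy() - 1,
            "meth": minus_paired["meth"].to_numpy(),
            "total": minus_paired["total"].to_numpy(),
        }
    )
    merged = plus[["chrom", "pos", "meth", "total"]].copy()
    merged = (
        pd.concat([merged, add], ignore_index=True)
        .groupby(["chrom", "pos"], as_index=False, sort=False)[["meth", "total"]]
        .sum()
    )
    merged["strand"] = "+"
    merged["context"] = "CpG"
    out = pd.concat(
        [merged[SITE_COLUMNS], minus_lone[SITE_COLUMNS], other[SITE_COLUMNS]],
        ignore_index=True,
    )
    return MethylomeTrack(track.sample_id, out)


def estimate_conversion_rate(track: MethylomeTrack) -> ConversionStats:
    """Estimate the bisulfite conversion rate from non-CpG cytosines.

    Non-CpG (CHH/CHG) cytosines are assumed unmethylated, so any read
    still reporting C there reflects failed conversion:
    ``rate = (reads converted) / (total non-CpG reads)``.
    """
    s = track.sites
    non_cpg = s[s["context"].isin(["CHH", "CHG"])]
    total = int(non_cpg["total"].sum())
    if total == 0:
        raise ValueError("no covered non-CpG cytosines; cannot estimate conversion")
    protected = int(non_cpg["meth"].sum())
    n_used = int((non_cpg["total"] > 0).sum())
    return ConversionStats(conversion_rate=(total - protected) / total, n_sites_used=n_used)


def global_methylation_summary(track: MethylomeTrack) -> dict[str, float]:
    """Coverage-weighted modified fraction per cytosine context."""
    s = track.sites
    if not len(s):
        raise ValueError("empty track")
    out: dict[str, float] = {}
    for context, grp in s.groupby("context"):
        total = int(grp["total"].sum())
        out[str(context)] = float(grp["meth"].sum()) / total if total else float("nan")
    return out


# ---------------------------------------------------------------------------
# BED / bedGraph


def read_bed(path) -> pd.DataFrame:
    """Read BED3+ into a DataFrame (chrom, start, end[, name, score, strand]).

    Coordinates are 0-based half-open.  ``start >= end`` is rejected.
    """
    names = ["chrom", "start", "end", "name", "score", "strand"]
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    if df.shape[1] < 3:
        raise ValueError("BED file needs at least 3 columns")
    df = df.iloc[:, :6]
    df.columns = names[: df.shape[1]]
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    bad = df["start"] >= df["end"]
    if bad.any():
        i = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValueError(
            f"invalid interval at record {i}: start {df['start'].iloc[i]} >= end {df['end'].iloc[i]}"
        )
    return df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(
        drop=True
    )


def write_bed(intervals: pd.DataFrame, path) -> None:
    """Write intervals as BED; keeps chrom/start/end plus any extra columns."""
    cols = ["chrom", "start", "end"] + [
        c for c in intervals.columns if c not in ("chrom", "start", "end")
    ]
    intervals[cols].to_csv(path, sep="\t", header=False, index=False)


def write_bedgraph(track: MethylomeTrack, path) -> None:
    """Write per-CpG methylation levels as bedGraph (chrom, start, end, level).

    Zero-coverage sites are omitted (their level is undefined).
    """
    s = track.sites[track.sites["total"] > 0]
    level = s["meth"].to_numpy(float) / s["total"].to_numpy(float)
    out = pd.DataFrame(
        {
            "chrom": s["chrom"],
            "start": s["pos"],
            "end": s["pos"].to_numpy() + 1,
            "level": [format(x, ".6g") for x in level],
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)
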