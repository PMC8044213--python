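"""Genomic interval set statistics and annotation.

Intervals are pandas DataFrames with at least ``chrom, start, end``
(0-based half-open).  The low-level set operations (merge, subtract,
intersection length) work on sorted coordinate arrays per chromosome and
are shared with the differential module, where interval subtraction
defines DMR candidate fragments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


# ---------------------------------------------------------------------------
# primitive set operations


def _per_chrom(df: pd.DataFrame):
    for chrom, grp in df.groupby("chrom", sort=True):
        yield chrom, grp.sort_values("start")


def _merge_arrays(starts: np.ndarray, ends: np.ndarray, slack: int = 0):
    """Union-merge sorted intervals; intervals closer than ``slack`` join."""
    if len(starts) == 0:
        return starts, ends
    order = np.argsort(starts, kind="mergesort")
    starts, ends = starts[order], ends[order]
    out_s, out_e = [starts[0]], [ends[0]]
    for s, e in zip(starts[1:], ends[1:]):
        if s <= out_e[-1] + slack:
            out_e[-1] = max(out_e[-1], e)
        else:
            out_s.append(s)
            out_e.append(e)
    return np.asarray(out_s), np.asarray(out_e)


def merge_intervals(df: pd.DataFrame, slack: int = 0) -> pd.DataFrame:
    """Union-merge overlapping (or within ``slack`` bp) intervals per chrom."""
    rows = []
    for chrom, grp in _per_chrom(df):
        s, e = _merge_arrays(grp["start"].to_numpy(), grp["end"].to_numpy(), slack)
        rows.append(pd.DataFrame({"chrom": chrom, "start": s, "end": e}))
    if not rows:
        return pd.DataFrame(columns=["chrom", "start", "end"])
    return pd.concat(rows, ignore_index=True)


def subtract_intervals(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    """Parts of intervals in ``a`` not covered by any interval of ``b``.

    Each output fragment remembers which ``a`` record it came from
    (column ``source_index``, index into ``a``).
    """
    b_by_chrom = {
        chrom: _merge_arrays(grp["start"].to_numpy(), grp["end"].to_numpy())
        for chrom, grp in _per_chrom(b)
    }
    rows = []
    for idx, rec in a.iterrows():
        chrom, s, e = rec["chrom"], int(rec["start"]), int(rec["end"])
        bs, be = b_by_chrom.get(chrom, (np.array([], int), np.array([], int)))
        cur = s
        for os_, oe in zip(bs, be):
            if oe <= cur or os_ >= e:
                continue
            if os_ > cur:
                rows.append((chrom, cur, os_, idx))
            cur = max(cur, oe)
            if cur >= e:
                break
        if cur < e:
            rows.append((chrom, cur, e, idx))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "source_index"])


def total_length(df: pd.DataFrame) -> int:
    m = merge_intervals(df)
    return int((m["end"] - m["start"]).sum()) if len(m) else 0


def _intersection_length(a: pd.DataFrame, b: pd.DataFrame) -> int:
    total = 0
    b_by_chrom = {
        chrom: _merge_arrays(grp["start"].to_numpy(), grp["end"].to_numpy())
        for chrom, grp in _per_chrom(b)
    }
    am = merge_intervals(a)
    for chrom, grp in _per_chrom(am):
        bs, be = b_by_chrom.get(chrom, (np.array([], int), np.array([], int)))
        for s, e in zip(grp["start"], grp["end"]):
            lo = np.maximum(bs, s)
            hi = np.minimum(be, e)
            total += int(np.clip(hi - lo, 0, None).sum())
    return total


# ---------------------------------------------------------------------------
# set comparison statistics


def jaccard(set_a: pd.DataFrame, set_b: pd.DataFrame) -> float:
    """Base-pair Jaccard statistic between two interval sets.

    intersection bp / union bp, after union-merging each set; ranges from
    0 (no overlap) to 1 (identical coverage).
    """
    la, lb = total_length(set_a), total_length(set_b)
    if la == 0 and lb == 0:
        raise ValueError("both interval sets are empty")
    inter = _intersection_length(set_a, set_b)
    union = la + lb - inter
    return inter / union


def reciprocal_overlap(
    dmrs_a: pd.DataFrame,
    dmrs_b: pd.DataFrame,
    min_frac: float = 0.5,
    either_side: bool = False,
) -> dict:
    """Pairs of intervals overlapping by more than ``min_frac`` of each.

    The overlap must exceed ``min_frac`` of BOTH intervals' lengths
    (reciprocal; strictly greater-than).  With ``either_side=True`` the
    fraction test only needs to pass for one of the two intervals.

    Returns a dict with the pair table and the number of intervals of
    each set involved in at least one qualifying pair.
    """
    if not (0 < min_frac <= 1):
        raise ValueError("min_frac must be in (0, 1]")
    pairs = []
    b_groups = {chrom: grp for chrom, grp in _per_chrom(dmrs_b)}
    for chrom, grp_a in _per_chrom(dmrs_a):
        grp_b = b_groups.get(chrom)
        if grp_b is None:
            continue
        bs = grp_b["start"].to_numpy()
        be = grp_b["end"].to_numpy()
        for ia, rec in grp_a.iterrows():
            s, e = int(rec["start"]), int(rec["end"])
            ov = np.minimum(be, e) - np.maximum(bs, s)
            cand = np.flatnonzero(ov > 0)
            for j in cand:
                o = int(ov[j])
                frac_a = o / (e - s)
                frac_b = o / int(be[j] - bs[j])
                ok = (
                    (frac_a > min_frac or frac_b > min_frac)
                    if either_side
                    else (frac_a > min_frac and frac_b > min_frac)
                )
                if ok:
                    pairs.append((ia, grp_b.index[j], o))
    pair_df = pd.DataFrame(pairs, columns=["index_a", "index_b", "overlap_bp"])
    return {
        "pairs": pair_df,
        "n_a_overlapping": pair_df["index_a"].nunique(),
        "n_b_overlapping": pair_df["index_b"].nunique(),
    }


def nearest_tss(intervals: pd.DataFrame, tss_set: pd.DataFrame) -> pd.DataFrame:
    """Signed distance from each interval midpoint to the closest TSS.

    ``tss_set`` needs columns ``chrom, pos, strand`` and optionally
    ``gene``.  The sign follows the TSS strand: negative means the
    midpoint lies upstream of the gene, positive downstream (3') of the
    TSS.  A midpoint exactly at a TSS gives 0.
    """
    if not len(tss_set):
        raise ValueError("empty TSS set")
    tss_by_chrom = {
        chrom: grp.reset_index(drop=True) for chrom, grp in tss_set.groupby("chrom")
    }
    rows = []
    for idx, rec in intervals.iterrows():
        mid = (int(rec["start"]) + int(rec["end"])) // 2
        grp = tss_by_chrom.get(rec["chrom"])
        if grp is None:
            rows.append((idx, np.nan, None))
            continue
        pos = grp["pos"].to_numpy()
        j = int(np.argmin(np.abs(pos - mid)))
        delta = mid - int(pos[j])  # + means 3' of a plus-strand TSS
        if grp["strand"].iloc[j] == "-":
            delta = -delta
        gene = grp["gene"].iloc[j] if "gene" in grp.columns else None
        rows.append((idx, delta, gene))
    return pd.DataFrame(rows, columns=["index", "tss_distance", "nearest_gene"]).set_index(
        "index"
    )


# ---------------------------------------------------------------------------
# genomic feature annotation

FEATURE_PRECEDENCE = ["promoter", "TTS", "5UTR", "3UTR", "exon", "intron", "intergenic"]


def _gene_model_features(
    gene_model: pd.DataFrame, promoter_window: int, tts_window: int
) -> dict[str, list[tuple[int, int, str]]]:
    """Explode a transcript table into labeled feature spans per chrom.

    The transcript table needs columns ``chrom, strand, tx_start, tx_end,
    cds_start, cds_end, exon_starts, exon_ends`` (exon columns are
    comma-separated coordinate lists, BED12-style).
    """
    needed = [
        "chrom",
        "strand",
        "tx_start",
        "tx_end",
        "cds_start",
        "cds_end",
        "exon_starts",
        "exon_ends",
    ]
    missing = [c for c in needed if c not in gene_model.columns]
    if missing:
        raise ValueError(f"gene model missing columns: {missing}")
    feats: dict[str, list[tuple[int, int, str]]] = {}
    for _, t in gene_model.iterrows():
        chrom = t["chrom"]
        strand = t["strand"]
        txs, txe = int(t["tx_start"]), int(t["tx_end"])
        cs, ce = int(t["cds_start"]), int(t["cds_end"])
        if txs >= txe or cs > ce or cs < txs or ce > txe:
            raise ValueError(f"malformed transcript span in gene model: {t.to_dict()}")
        ex_s = [int(x) for x in str(t["exon_starts"]).rstrip(",").split(",") if x != ""]
        ex_e = [int(x) for x in str(t["exon_ends"]).rstrip(",").split(",") if x != ""]
        if len(ex_s) != len(ex_e) or any(s >= e for s, e in zip(ex_s, ex_e)):
            raise ValueError("malformed exon lists in gene model")
        bucket = feats.setdefault(chrom, [])
        tss = txs if strand == "+" else txe
        tts = txe if strand == "+" else txs
        bucket.append((tss - promoter_window, tss + promoter_window, "promoter"))
        bucket.append((tts - tts_window, tts + tts_window, "TTS"))
        for s, e in zip(ex_s, ex_e):
            # exon portions outside the CDS are UTR
            if s < cs:
                lo, hi = s, min(e, cs)
                label = "5UTR" if strand == "+" else "3UTR"
                bucket.append((lo, hi, label))
            if e > ce:
                lo, hi = max(s, ce), e
                label = "3UTR" if strand == "+" else "5UTR"
                bucket.append((lo, hi, label))
            lo, hi = max(s, cs), min(e, ce)
            if lo < hi:
                bucket.append((lo, hi, "exon"))
        for (s_prev, e_next) in zip(ex_e[:-1], ex_s[1:]):
            if s_prev < e_next:
                bucket.append((s_prev, e_next, "intron"))
    return feats


def annotate_features(
    intervals: pd.DataFrame,
    gene_model: pd.DataFrame,
    tss_set: pd.DataFrame | None = None,
    promoter_window: int = 1000,
    tts_window: int = 100,
) -> pd.DataFrame:
    """Assign one genomic feature label per interval.

    An interval gets the highest-precedence feature it overlaps:
    promoter > TTS > 5'UTR > 3'UTR > exon > intron > intergenic, with
    promoter = TSS +/- ``promoter_window``.  If ``tss_set`` is given,
    nearest-gene and signed TSS distance are included.
    """
    feats = _gene_model_features(gene_model, promoter_window, tts_window)
    rank = {f: i for i, f in enumerate(FEATURE_PRECEDENCE)}
    labels = []
    for _, rec in intervals.iterrows():
        s, e = int(rec["start"]), int(rec["end"])
        best = "intergenic"
        for fs, fe, label in feats.get(rec["chrom"], []):
            if fs < e and fe > s and rank[label] < rank[best]:
                best = label
        labels.append(best)
    out = intervals[["chrom", "start", "end"]].copy()
    out["feature"] = labels
    if tss_set is not None and len(tss_set):
        near = nearest_tss(intervals, tss_set)
        out["nearest_gene"] = near["nearest_gene"].to_numpy()
        out["tss_distance"] = near["tss_distance"].to_numpy()
    return out


# ---------------------------------------------------------------------------
# gene-set overlap


def gene_set_overlap_test(set_a, set_b, background) -> tuple[float, float]:
    """Two-sided Fisher's exact test on the overlap of two gene sets.

    Both sets must be subsets of ``background`` (e.g. all expressed
    genes).  Returns (odds ratio, p-value) from the 2x2 membership table.
    """
    bg = set(background)
    a, b = set(set_a), set(set_b)
    if not a <= bg or not b <= bg:
        raise ValueError("gene sets must be subsets of the background")
    n11 = len(a & b)
    n10 = len(a - b)
    n01 = len(b - a)
    n00 = len(bg) - n11 - n10 - n01
    odds, p = sps.fisher_exact([[n11, n10], [n01, n00]], alternative="two-sided")
    return float(odds), float(p)


# ---------------------------------------------------------------------------
# meta-profiles


@dataclass
class SignalMatrix:
    """Interval x bin matrix of binned signal for meta-profiles.

    ``matrix`` holds one row per interval; NaN marks bins without any
    covered CpG (excluded from column means rather than zero-filled, so
    low-coverage data do not drag profiles toward zero).
    """

    matrix: np.ndarray
    bin_bp: int
    flank_bp: int
    scaled: bool
    body_bins: int = 0

    @property
    def column_means(self) -> np.ndarray:
        import warnings

        with warnings.catch_warnings():
            # a column with no covered CpG anywhere is legitimately NaN
            warnings.simplefilter("ignore", category=RuntimeWarning)
            return np.nanmean(self.matrix, axis=0)


def _track_arrays(track):
    s = track.sites[track.sites["total"] > 0]
    return {
        chrom: (
            grp["pos"].to_numpy(),
            grp["meth"].to_numpy(float),
            grp["total"].to_numpy(float),
        )
        for chrom, grp in s.groupby("chrom")
    }


def _bin_mean(pos, meth, total, lo, hi, nbins):
    """Coverage-weighted mean level in nbins equal bins spanning [lo, hi)."""
    out = np.full(nbins, np.nan)
    if hi <= lo:
        return out
    sel = (pos >= lo) & (pos < hi)
    if not sel.any():
        return out
    idx = ((pos[sel] - lo) * nbins // (hi - lo)).astype(int)
    idx = np.clip(idx, 0, nbins - 1)
    m = np.bincount(idx, weights=meth[sel], minlength=nbins)
    t = np.bincount(idx, weights=total[sel], minlength=nbins)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(t > 0, m / t, np.nan)
    return out


def bin_signal(
    track,
    intervals: pd.DataFrame,
    mode: str = "center",
    flank_bp: int = 2000,
    bin_bp: int = 100,
    body_bins: int = 0,
) -> SignalMatrix:
    """Binned methylation meta-profile over a set of intervals.

    ``center`` mode tiles ``2 * flank_bp / bin_bp`` bins around each
    interval midpoint; ``scaled`` mode resamples each interval body to
    ``body_bins`` bins flanked by fixed-width flank bins, so intervals of
    different lengths align.
    """
    if bin_bp <= 0:
        raise ValueError("bin_bp must be positive")
    if flank_bp % bin_bp:
        raise ValueError("bin_bp must divide flank_bp")
    if mode not in ("center", "scaled"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "scaled" and body_bins <= 0:
        raise ValueError("scaled mode needs body_bins > 0")
    arrays = _track_arrays(track)
    n_flank = flank_bp // bin_bp
    ncols = 2 * n_flank + (body_bins if mode == "scaled" else 0)
    mat = np.full((len(intervals), ncols), np.nan)
    for i, (_, rec) in enumerate(intervals.iterrows()):
        chrom, s, e = rec["chrom"], int(rec["start"]), int(rec["end"])
        if chrom not in arrays:
            continue
        pos, meth, total = arrays[chrom]
        if mode == "center":
            mid = (s + e) // 2
            mat[i] = _bin_mean(
                pos, meth, total, mid - flank_bp, mid + flank_bp, ncols
            )
        else:
            left = _bin_mean(pos, meth, total, s - flank_bp, s, n_flank)
            body = _bin_mean(pos, meth, total, s, e, body_bins)
            right = _bin_mean(pos, meth, total, e, e + flank_bp, n_flank)
            mat[i] = np.concatenate([left, body, right])
    return SignalMatrix(
        matrix=mat,
        bin_bp=bin_bp,
        flank_bp=flank_bp,
        scaled=(mode == "scaled"),
        body_bins=body_bins if mode == "scaled" else 0,
    )


def correlate_over_intervals(values_x, values_y, method: str = "spearman") -> float:
    """Correlation between paired per-interval values.

    Spearman (average ranks for ties) by default; Pearson behind the
    ``method`` flag.  Returns NaN when either side is constant.
    """
    x = np.asarray(values_x, float)
    y = np.asarray(values_y, float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need at least 3 paired values")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if x.size < 3 or np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan")
    if method == "spearman":
        return float(sps.spearmanr(x, y).statistic)
    if method == "pearson":
        return float(sps.pearsonr(x, y).statistic)
    raise ValueError(f"unknown method {method!r}")
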