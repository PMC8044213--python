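"""Differential methylation: per-CpG scores, DMRs, and three-condition
DNMT3A-dependent DMRs (DDMRs).

The per-CpG differential score is the posterior probability that the
methylation level in track A exceeds that in track B, with independent
Beta(meth+1, unmeth+1) posteriors on each level (uniform prior).  It is
evaluated by an exact finite sum over the integer posterior parameters,
not by sampling or approximation.

DMR candidates are the parts of one sample's HMRs not covered by the
other sample's HMRs: a DMR is a place where an HMR exists in one
methylome but not at the same location in the other.  A candidate
fragment is retained only if it spans at least ``min_cpgs`` covered CpGs
of which at least ``min_sig`` are significantly differential in the
concordant direction — the "at least 10 CpGs, at least 5 significant"
filter by default.

DDMRs generalize this to the (proB, wild-type mature, knockout mature)
triplet of one lineage: the three pairwise DMR sets are union-merged and
each merged interval is annotated with its per-condition mean
methylation vector, the input to pattern classification.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import betaln, logsumexp

from methdyn.io import MethylomeTrack
from methdyn.intervals import merge_intervals, subtract_intervals


def beta_diff_prob(meth_a, total_a, meth_b, total_b) -> np.ndarray:
    """Exact P(p_a > p_b) under independent Beta posteriors.

    With p_a ~ Beta(meth_a + 1, unmeth_a + 1) and likewise for b, the
    probability has a closed-form finite sum over the (integer) second
    sample's alpha parameter:

        P(p_a > p_b) = sum_{j=0}^{a2-1} B(a1+j, b1+b2)
                       / [ (b2+j) B(1+j, b2) B(a1, b1) ]

    evaluated in log space for numerical stability.  Vectorized over
    site arrays.
    """
    meth_a = np.atleast_1d(np.asarray(meth_a, int))
    total_a = np.atleast_1d(np.asarray(total_a, int))
    meth_b = np.atleast_1d(np.asarray(meth_b, int))
    total_b = np.atleast_1d(np.asarray(total_b, int))
    if (total_a <= 0).any() or (total_b <= 0).any():
        raise ValueError("both sides need positive coverage")
    if (meth_a > total_a).any() or (meth_b > total_b).any() or (meth_a < 0).any() or (meth_b < 0).any():
        raise ValueError("invalid counts")
    # The finite sum below evaluates P(p_2 > p_1); exchanging the roles of
    # the two samples turns it into the wanted P(p_a > p_b).
    a1 = meth_b + 1.0
    b1 = total_b - meth_b + 1.0
    a2 = meth_a + 1.0
    b2 = total_a - meth_a + 1.0
    jmax = int(a2.max())  # a2 is integer-valued
    j = np.arange(jmax)[:, None].astype(float)
    with np.errstate(divide="ignore"):
        log_terms = (
            betaln(a1[None, :] + j, b1[None, :] + b2[None, :])
            - np.log(b2[None, :] + j)
            - betaln(1.0 + j, b2[None, :])
            - betaln(a1, b1)[None, :]
        )
    mask = j < a2[None, :]
    log_terms = np.where(mask, log_terms, -np.inf)
    out = np.exp(logsumexp(log_terms, axis=0))
    return np.clip(out, 0.0, 1.0)


def diff_scores(track_a: MethylomeTrack, track_b: MethylomeTrack) -> pd.DataFrame:
    """Per-CpG differential methylation scores on jointly covered CpGs.

    Sites covered in only one track are skipped; the number skipped is
    available as ``df.attrs['n_skipped']``.

    Returns chrom, pos, meth_a, total_a, meth_b, total_b, score where
    score = P(level_a > level_b).
    """
    a = track_a.sites
    b = track_b.sites
    a = a[(a["context"] == "CpG")]
    b = b[(b["context"] == "CpG")]
    joined = a.merge(
        b, on=["chrom", "pos"], suffixes=("_a", "_b"), how="outer", indicator=True
    )
    both = joined[joined["_merge"] == "both"]
    covered = both[(both["total_a"] > 0) & (both["total_b"] > 0)].copy()
    n_skipped = len(joined) - len(covered)
    if len(covered):
        covered["score"] = beta_diff_prob(
            covered["meth_a"].to_numpy(int),
            covered["total_a"].to_numpy(int),
            covered["meth_b"].to_numpy(int),
            covered["total_b"].to_numpy(int),
        )
    else:
        covered["score"] = pd.Series(dtype=float)
    out = covered[
        ["chrom", "pos", "meth_a", "total_a", "meth_b", "total_b", "score"]
    ].sort_values(["chrom", "pos"]).reset_index(drop=True)
    for c in ("meth_a", "total_a", "meth_b", "total_b"):
        out[c] = out[c].astype(np.int64)
    out.attrs["n_skipped"] = int(n_skipped)
    return out


def _fragment_stats(fragments: pd.DataFrame, scores: pd.DataFrame):
    """Per-fragment covered-CpG count, significant counts and mean levels."""
    stats = []
    by_chrom = {chrom: grp for chrom, grp in scores.groupby("chrom")}
    for _, frag in fragments.iterrows():
        grp = by_chrom.get(frag["chrom"])
        if grp is None:
            stats.append((0, np.empty(0), np.empty((0, 4))))
            continue
        sel = grp[(grp["pos"] >= frag["start"]) & (grp["pos"] < frag["end"])]
        stats.append(
            (
                len(sel),
                sel["score"].to_numpy(),
                sel[["meth_a", "total_a", "meth_b", "total_b"]].to_numpy(float),
            )
        )
    return stats


def call_dmrs(
    hmrs_a: pd.DataFrame,
    hmrs_b: pd.DataFrame,
    scores: pd.DataFrame,
    min_cpgs: int = 10,
    min_sig: int = 5,
    sig_level: float = 0.95,
) -> pd.DataFrame:
    """Assemble DMRs from two HMR sets and per-CpG differential scores.

    Candidates in the hypo-in-A direction are the parts of A's HMRs not
    covered by B's HMRs, and vice versa.  A hypo-in-A fragment needs
    ``min_sig`` CpGs with P(level_a > level_b) <= 1 - sig_level (A
    confidently lower); hypo-in-B needs scores >= sig_level.  Fragments
    also need at least ``min_cpgs`` jointly covered CpGs.

    Returns chrom, start, end, direction, n_cpgs, n_sig, mean_a, mean_b.
    """
    rows = []
    for direction, frags in (
        ("hypo-in-A", subtract_intervals(hmrs_a, hmrs_b)),
        ("hypo-in-B", subtract_intervals(hmrs_b, hmrs_a)),
    ):
        for (_, frag), (n_cpg, s, counts) in zip(
            frags.iterrows(), _fragment_stats(frags, scores)
        ):
            if n_cpg < min_cpgs:
                continue
            if direction == "hypo-in-A":
                n_sig = int((s <= 1 - sig_level).sum())
            else:
                n_sig = int((s >= sig_level).sum())
            if n_sig < min_sig:
                continue
            mean_a = counts[:, 0].sum() / counts[:, 1].sum()
            mean_b = counts[:, 2].sum() / counts[:, 3].sum()
            rows.append(
                (
                    frag["chrom"],
                    int(frag["start"]),
                    int(frag["end"]),
                    direction,
                    n_cpg,
                    n_sig,
                    mean_a,
                    mean_b,
                )
            )
    df = pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "direction", "n_cpgs", "n_sig", "mean_a", "mean_b"],
    )
    return df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)


def region_meth_stat(track: MethylomeTrack, intervals: pd.DataFrame) -> pd.DataFrame:
    """Coverage-weighted mean methylation per interval.

    mean = sum(meth) / sum(total) over covered CpGs inside the half-open
    interval; an interval with no covered CpG gets NaN (missing), never 0.
    """
    s = track.sites
    s = s[(s["context"] == "CpG") & (s["total"] > 0)]
    by_chrom = {chrom: grp for chrom, grp in s.groupby("chrom")}
    means, counts = [], []
    for _, rec in intervals.iterrows():
        grp = by_chrom.get(rec["chrom"])
        if grp is None:
            means.append(np.nan)
            counts.append(0)
            continue
        sel = grp[(grp["pos"] >= rec["start"]) & (grp["pos"] < rec["end"])]
        total = sel["total"].sum()
        means.append(sel["meth"].sum() / total if total else np.nan)
        counts.append(len(sel))
    out = intervals[["chrom", "start", "end"]].copy()
    out["mean_meth"] = means
    out["n_cpgs"] = counts
    return out


def construct_ddmrs(
    tracks: dict[str, MethylomeTrack],
    hmr_sets: dict[str, pd.DataFrame],
    conditions: tuple[str, str, str] = ("proB", "WT", "KO"),
    sig_level: float = 0.95,
    min_cpgs: int = 10,
    min_sig: int = 5,
    min_support: int = 1,
) -> pd.DataFrame:
    """Three-condition DNMT3A-dependent DMRs for one lineage.

    Pairwise DMRs are computed for (proB, WT), (proB, KO) and (WT, KO);
    all retained intervals are union-merged (0 bp slack) and each merged
    interval is annotated with its mean methylation in the three
    conditions.  ``min_support`` is the number of distinct pairwise
    comparisons that must contribute a DMR to a merged interval
    (default 1: any single comparison suffices).

    Returns chrom, start, end, mean_<condition> x3, support, n_cpgs
    (CpGs covered in all three tracks is not required; each mean uses
    that track's own coverage).
    """
    missing = [c for c in conditions if c not in tracks or c not in hmr_sets]
    if missing:
        raise ValueError(f"missing condition(s): {missing}")
    pairs = [
        (conditions[0], conditions[1]),
        (conditions[0], conditions[2]),
        (conditions[1], conditions[2]),
    ]
    all_dmrs = []
    for ca, cb in pairs:
        scores = diff_scores(tracks[ca], tracks[cb])
        dmrs = call_dmrs(
            hmr_sets[ca],
            hmr_sets[cb],
            scores,
            min_cpgs=min_cpgs,
            min_sig=min_sig,
            sig_level=sig_level,
        )
        dmrs["comparison"] = f"{ca}-vs-{cb}"
        all_dmrs.append(dmrs)
    all_dmrs = pd.concat(all_dmrs, ignore_index=True)
    if not len(all_dmrs):
        cols = ["chrom", "start", "end"] + [f"mean_{c}" for c in conditions]
        return pd.DataFrame(columns=cols + ["support", "n_cpgs"])
    merged = merge_intervals(all_dmrs[["chrom", "start", "end"]])
    # count contributing comparisons per merged interval
    support = []
    for _, rec in merged.iterrows():
        sel = all_dmrs[
            (all_dmrs["chrom"] == rec["chrom"])
            & (all_dmrs["start"] < rec["end"])
            & (all_dmrs["end"] > rec["start"])
        ]
        support.append(sel["comparison"].nunique())
    merged["support"] = support
    merged = merged[merged["support"] >= min_support].reset_index(drop=True)
    out = merged[["chrom", "start", "end"]].copy()
    n_cpgs = None
    for cond in conditions:
        stat = region_meth_stat(tracks[cond], merged)
        out[f"mean_{cond}"] = stat["mean_meth"].to_numpy()
        if n_cpgs is None:
            n_cpgs = stat["n_cpgs"].to_numpy()
    out["support"] = merged["support"].to_numpy()
    out["n_cpgs"] = n_cpgs
    return out
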