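"""Joint (unmethylated, 5mC, 5hmC) estimation from paired WGBS/TAB-Seq.

Standard bisulfite sequencing cannot tell 5-methylcytosine from
5-hydroxymethylcytosine: both read as C (protected).  TET-assisted
bisulfite sequencing (TAB-Seq) first glucosyl-protects 5hmC, then
oxidizes 5mC with recombinant TET so it converts like an unmethylated
base — ideally only 5hmC reads as C.  Real efficiencies are below 1 and
are estimated from spike-in controls synthesized entirely with 5hmC or
5mC, plus the sample's own non-CpG-derived conversion rate.

Forward model for the probability that a read reports C (protection),
with f = TET oxidation efficiency, g = glucosylation protection
efficiency, c = bisulfite conversion rate and (u, m, h) the per-CpG
cytosine-state fractions:

    WGBS:    p_w = (m + h) + u (1 - c)
    TAB-Seq: p_t = h [g + (1-g)(1-c)] + m [(1-f) + f (1-c)] + u (1 - c)

(unprotected 5hmC and oxidized 5mC convert at rate c, unoxidized 5mC is
always protected).  Both equations are linear in (m, h) with
u = 1 - m - h, so each CpG is a 2x2 linear solve; solutions outside the
probability simplex are replaced by the residual-minimizing point of the
simplex (an exact, closed-form 2-variable constrained least squares).

In the ideal limit f = g = c = 1 the estimator reduces exactly to the
naive subtraction h = p_t, m = p_w - p_t.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from methdyn.io import MethylomeTrack


@dataclass
class TabSeqEfficiencies:
    """Spike-in-derived TAB-Seq efficiencies, each in [0, 1].

    f_ox: TET oxidation efficiency of 5mC; g_protect: glucosylation
    protection efficiency of 5hmC; c_conv: bisulfite conversion rate of
    unprotected cytosines.
    """

    f_ox: float
    g_protect: float
    c_conv: float

    def __post_init__(self) -> None:
        for name in ("f_ox", "g_protect", "c_conv"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")


def _protected_fraction(track: MethylomeTrack, min_reads: int) -> float:
    total = int(track.sites["total"].sum())
    if total < min_reads:
        raise ValueError(
            f"spike-in aggregate coverage {total} below required {min_reads}"
        )
    return float(track.sites["meth"].sum()) / total


def estimate_efficiencies(
    spike_5hmc_track: MethylomeTrack,
    spike_5mc_track: MethylomeTrack,
    spike_unmeth_track: MethylomeTrack,
    min_reads: int = 100,
) -> TabSeqEfficiencies:
    """Estimate (f_ox, g_protect, c_conv) from the three spike-in controls.

    c_conv is the converted fraction of the fully unmethylated control;
    g_protect solves p_h = g + (1-g)(1-c) on the pure-5hmC control;
    f_ox solves p_m = (1-f) + f (1-c) on the pure-5mC control.  Rates
    solved outside [0, 1] are clamped with a warning.
    """
    import warnings

    p_h = _protected_fraction(spike_5hmc_track, min_reads)
    p_m = _protected_fraction(spike_5mc_track, min_reads)
    p_u = _protected_fraction(spike_unmeth_track, min_reads)
    c = 1.0 - p_u
    if c <= 0:
        raise ValueError("unmethylated control fully protected; conversion rate is 0")
    g = (p_h - (1.0 - c)) / c
    f = (1.0 - p_m) / c
    out = {}
    for name, v in (("f_ox", f), ("g_protect", g), ("c_conv", c)):
        if not (0.0 <= v <= 1.0):
            warnings.warn(f"{name} solved to {v:.4f}; clamped to [0, 1]")
            v = float(np.clip(v, 0.0, 1.0))
        out[name] = float(v)
    return TabSeqEfficiencies(**out)


def _solve_mh(p_w, p_t, eff: TabSeqEfficiencies):
    """Unconstrained per-CpG solve for (m, h) from protected fractions."""
    c, f, g = eff.c_conv, eff.f_ox, eff.g_protect
    if abs(g - (1.0 - f)) < 1e-9:
        raise ValueError(
            "degenerate system: g_protect equals 1 - f_ox, so 5mC and 5hmC "
            "are indistinguishable in the TAB-Seq channel (identifiability failure)"
        )
    if c <= 0:
        raise ValueError("conversion rate must be positive")
    M = (np.asarray(p_w, float) - (1.0 - c)) / c  # = m + h
    T = (np.asarray(p_t, float) - (1.0 - c)) / c  # = h g + m (1 - f)
    h = (T - (1.0 - f) * M) / (g - (1.0 - f))
    m = M - h
    return m, h


def _residual(m, h, p_w, p_t, eff: TabSeqEfficiencies):
    c, f, g = eff.c_conv, eff.f_ox, eff.g_protect
    u = 1.0 - m - h
    r1 = (m + h) + u * (1 - c) - p_w
    r2 = h * (g + (1 - g) * (1 - c)) + m * ((1 - f) + f * (1 - c)) + u * (1 - c) - p_t
    return r1 * r1 + r2 * r2


def _simplex_constrain(m, h, p_w, p_t, eff: TabSeqEfficiencies):
    """Residual-minimizing (m, h) subject to m, h >= 0, m + h <= 1.

    The feasible region is a triangle; the unconstrained optimum either
    lies inside (returned as-is) or the constrained optimum sits on one
    of the three edges / corners, each a closed-form 1-D least squares.
    """
    if m >= 0 and h >= 0 and m + h <= 1:
        return float(m), float(h)
    candidates = []
    c, f, g = eff.c_conv, eff.f_ox, eff.g_protect
    # coefficient vectors of (m, h) in the two model equations
    a_m = np.array([c, c * (1 - f)])
    a_h = np.array([c, c * g])
    b = np.array([p_w - (1 - c), p_t - (1 - c)])

    def clamp01(x):
        return min(max(x, 0.0), 1.0)

    # edge m = 0: minimize ||a_h h - b||
    denom = float(a_h @ a_h)
    if denom > 0:
        candidates.append((0.0, clamp01(float(a_h @ b) / denom)))
    # edge h = 0
    denom = float(a_m @ a_m)
    if denom > 0:
        candidates.append((clamp01(float(a_m @ b) / denom), 0.0))
    # edge m + h = 1: substitute m = 1 - h
    d = a_h - a_m
    r = b - a_m
    denom = float(d @ d)
    if denom > 0:
        hh = clamp01(float(d @ r) / denom)
        candidates.append((1.0 - hh, hh))
    candidates.extend([(0.0, 0.0), (1.0, 0.0), (0.0, 1.0)])
    best = min(candidates, key=lambda mh: _residual(mh[0], mh[1], p_w, p_t, eff))
    return float(best[0]), float(best[1])


def estimate_5hmc(
    wgbs_site,
    tabseq_site,
    eff: TabSeqEfficiencies,
    return_raw: bool = False,
):
    """Estimate the (u, m, h) cytosine-state simplex at one CpG.

    ``wgbs_site`` and ``tabseq_site`` are (meth_count, total_count)
    pairs from the two assays at the same CpG.  Returns a dict with keys
    u, m, h (and raw_m, raw_h when ``return_raw``); u + m + h = 1 and
    all components are non-negative after the simplex constraint.
    """
    k_w, n_w = wgbs_site
    k_t, n_t = tabseq_site
    if n_w <= 0 or n_t <= 0:
        raise ValueError("both assays must cover the CpG")
    p_w = k_w / n_w
    p_t = k_t / n_t
    m_raw, h_raw = _solve_mh(p_w, p_t, eff)
    m, h = _simplex_constrain(float(m_raw), float(h_raw), p_w, p_t, eff)
    out = {"u": 1.0 - m - h, "m": m, "h": h}
    if return_raw:
        out["raw_m"] = float(m_raw)
        out["raw_h"] = float(h_raw)
    return out


def estimate_5hmc_regions(
    wgbs: MethylomeTrack,
    tabseq: MethylomeTrack,
    intervals: pd.DataFrame,
    eff: TabSeqEfficiencies,
) -> pd.DataFrame:
    """Region-level (u, m, h): counts aggregated across each interval
    before solving, which stabilizes the estimate at low coverage."""
    rows = []
    w = wgbs.sites[wgbs.sites["context"] == "CpG"]
    t = tabseq.sites[tabseq.sites["context"] == "CpG"]
    w_by = {c: g for c, g in w.groupby("chrom")}
    t_by = {c: g for c, g in t.groupby("chrom")}
    for _, rec in intervals.iterrows():
        gw = w_by.get(rec["chrom"])
        gt = t_by.get(rec["chrom"])
        if gw is None or gt is None:
            rows.append((np.nan, np.nan, np.nan, 0, 0))
            continue
        sw = gw[(gw["pos"] >= rec["start"]) & (gw["pos"] < rec["end"])]
        st = gt[(gt["pos"] >= rec["start"]) & (gt["pos"] < rec["end"])]
        n_w, n_t = int(sw["total"].sum()), int(st["total"].sum())
        if n_w == 0 or n_t == 0:
            rows.append((np.nan, np.nan, np.nan, n_w, n_t))
            continue
        est = estimate_5hmc(
            (int(sw["meth"].sum()), n_w), (int(st["meth"].sum()), n_t), eff
        )
        rows.append((est["u"], est["m"], est["h"], n_w, n_t))
    out = intervals[["chrom", "start", "end"]].copy()
    out[["u", "m", "h", "coverage_wgbs", "coverage_tab"]] = pd.DataFrame(
        rows, index=out.index
    )
    return out


def estimate_5hmc_sites(
    wgbs: MethylomeTrack, tabseq: MethylomeTrack, eff: TabSeqEfficiencies
) -> pd.DataFrame:
    """Per-CpG (u, m, h) on CpGs covered in both assays."""
    w = wgbs.sites[(wgbs.sites["context"] == "CpG") & (wgbs.sites["total"] > 0)]
    t = tabseq.sites[(tabseq.sites["context"] == "CpG") & (tabseq.sites["total"] > 0)]
    j = w.merge(t, on=["chrom", "pos"], suffixes=("_w", "_t"))
    p_w = j["meth_w"].to_numpy(float) / j["total_w"].to_numpy(float)
    p_t = j["meth_t"].to_numpy(float) / j["total_t"].to_numpy(float)
    m_raw, h_raw = _solve_mh(p_w, p_t, eff)
    m = np.empty_like(m_raw)
    h = np.empty_like(h_raw)
    for i in range(len(m_raw)):
        m[i], h[i] = _simplex_constrain(
            float(m_raw[i]), float(h_raw[i]), float(p_w[i]), float(p_t[i]), eff
        )
    out = j[["chrom", "pos"]].copy()
    out["u"] = 1.0 - m - h
    out["m"] = m
    out["h"] = h
    out["coverage_wgbs"] = j["total_w"].to_numpy()
    out["coverage_tab"] = j["total_t"].to_numpy()
    return out


def hmc_boundary_profile(
    hmrs: pd.DataFrame,
    hmc_estimates: pd.DataFrame,
    flank_bp: int = 2000,
    bin_bp: int = 100,
) -> pd.DataFrame:
    """Mean 5hmC fraction by signed distance from HMR edges.

    Each CpG within ``flank_bp`` of an HMR start or end contributes at
    the signed distance d = pos - edge for starts and d = edge - pos for
    ends, so positive distances point into the HMR interior on both
    sides (strand-agnostic).  Returns one row per bin with the bin
    center, mean h and CpG count; bin count = 2 * flank_bp / bin_bp.
    """
    if bin_bp <= 0 or flank_bp % bin_bp:
        raise ValueError("bin_bp must be positive and divide flank_bp")
    nbins = 2 * flank_bp // bin_bp
    sums = np.zeros(nbins)
    counts = np.zeros(nbins, int)
    by_chrom = {c: g for c, g in hmc_estimates.groupby("chrom")}
    for _, rec in hmrs.iterrows():
        g = by_chrom.get(rec["chrom"])
        if g is None:
            continue
        pos = g["pos"].to_numpy()
        hval = g["h"].to_numpy(float)
        for edge, sign in ((int(rec["start"]), +1), (int(rec["end"]), -1)):
            d = sign * (pos - edge)
            sel = (d >= -flank_bp) & (d < flank_bp)
            idx = ((d[sel] + flank_bp) // bin_bp).astype(int)
            np.add.at(sums, idx, hval[sel])
            np.add.at(counts, idx, 1)
    centers = -flank_bp + bin_bp * (np.arange(nbins) + 0.5)
    with np.errstate(invalid="ignore"):
        mean_h = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return pd.DataFrame(
        {"distance": centers, "mean_h": mean_h, "n_cpgs": counts}
    )
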