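"""Hypomethylated-region segmentation with a two-state beta-binomial HMM.

The genome-wide background of a mammalian methylome is hypermethylated;
regulatory elements sit in contiguous runs of lowly methylated CpGs
(hypomethylated regions, HMRs).  Segmentation models the ordered per-CpG
counts with a two-state hidden Markov chain — state 0 "hypo", state 1
"hyper" — whose emissions are beta-binomial: at a CpG with coverage n the
methylated read count k is Binomial(n, p) with p itself Beta-distributed
per state.  The beta-binomial absorbs the overdispersion of low-coverage
bisulfite data relative to a plain binomial (a binomial emission is
available as a configuration fallback).

Fitting is Baum-Welch EM (monotone log-likelihood); decoding is by
posterior state marginals.  Maximal runs of hypo-decoded CpGs become
HMRs; runs are split at inter-CpG gaps larger than ``gap_limit`` so that
CpG deserts never bridge two distant hypomethylated loci.  HMRs of
3.5 kb or longer are classified as methylation canyons.

The model follows the statsmodels idiom: :class:`BetaBinomialHMM` is
constructed from a track, ``fit()`` returns a
:class:`SegmentationResult` carrying the estimates, the log-likelihood
trace and the HMR caller.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps
from scipy.special import betaln, gammaln, logsumexp

from methdyn.io import MethylomeTrack


@dataclass
class HmmParams:
    """Parameters of the two-state (hypo, hyper) methylation HMM.

    Emissions are beta-binomial with per-state shape (alpha, beta); the
    state mean is alpha/(alpha+beta).  State 0 is hypo: its mean must be
    below state 1's.  ``trans`` is row-stochastic; ``start`` is the
    initial state distribution.
    """

    trans: np.ndarray
    start: np.ndarray
    alpha: np.ndarray  # shape (2,), per-state alpha
    beta: np.ndarray  # shape (2,), per-state beta
    emission: str = "betabinom"  # or "binom" (alpha/(alpha+beta) used as p)

    def __post_init__(self) -> None:
        self.trans = np.asarray(self.trans, float)
        self.start = np.asarray(self.start, float)
        self.alpha = np.asarray(self.alpha, float)
        self.beta = np.asarray(self.beta, float)
        if self.trans.shape != (2, 2) or not np.allclose(self.trans.sum(axis=1), 1.0):
            raise ValueError("trans must be 2x2 row-stochastic")
        if not np.allclose(self.start.sum(), 1.0):
            raise ValueError("start must sum to 1")
        if (self.alpha <= 0).any() or (self.beta <= 0).any():
            raise ValueError("alpha and beta must be positive")
        if self.means[0] >= self.means[1]:
            raise ValueError("hypo state mean must be below hyper state mean")

    @property
    def means(self) -> np.ndarray:
        return self.alpha / (self.alpha + self.beta)


def default_init(seed: int | None = None, jitter: float = 0.0) -> HmmParams:
    """Default EM starting point: hypo mean 0.1, hyper mean 0.8,
    self-transition 0.99, concentration 10; optional seeded jitter for
    EM restarts."""
    rng = np.random.default_rng(seed)
    mu = np.array([0.1, 0.8])
    if jitter:
        mu = np.clip(mu + rng.uniform(-jitter, jitter, 2), 0.02, 0.98)
        mu.sort()
    s = 10.0
    return HmmParams(
        trans=np.array([[0.99, 0.01], [0.01, 0.99]]),
        start=np.array([0.5, 0.5]),
        alpha=mu * s,
        beta=(1 - mu) * s,
    )


def _emission_logp(k: np.ndarray, n: np.ndarray, params: HmmParams) -> np.ndarray:
    """log P(k | n, state) for every site; shape (len(k), 2)."""
    k = np.asarray(k, float)[:, None]
    n = np.asarray(n, float)[:, None]
    comb = gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
    if params.emission == "betabinom":
        a = params.alpha[None, :]
        b = params.beta[None, :]
        return comb + betaln(k + a, n - k + b) - betaln(a, b)
    if params.emission == "binom":
        p = params.means[None, :]
        return comb + k * np.log(p) + (n - k) * np.log1p(-p)
    raise ValueError(f"unknown emission family {params.emission!r}")


def _chains(track: MethylomeTrack, gap_limit: int):
    """Covered CpGs split per chromosome and at gaps > gap_limit.

    Yields (chrom, pos, k, n) arrays; zero-coverage sites are skipped,
    not imputed.
    """
    s = track.sites
    s = s[(s["context"] == "CpG") & (s["total"] > 0)]
    for chrom, grp in s.groupby("chrom", sort=True):
        pos = grp["pos"].to_numpy()
        k = grp["meth"].to_numpy()
        n = grp["total"].to_numpy()
        if len(pos) == 0:
            continue
        breaks = np.flatnonzero(np.diff(pos) > gap_limit) + 1
        for piece in np.split(np.arange(len(pos)), breaks):
            yield chrom, pos[piece], k[piece], n[piece]


def _forward_backward(logB: np.ndarray, params: HmmParams):
    """Scaled forward-backward.

    Returns (gamma, xi_sum, loglik): posterior state marginals, summed
    pairwise posteriors, and the chain log-likelihood.
    """
    T = logB.shape[0]
    B = np.exp(logB - logB.max(axis=1, keepdims=True))
    corr = logB.max(axis=1)  # re-added to the log-likelihood
    A = params.trans
    alpha = np.empty((T, 2))
    c = np.empty(T)
    alpha[0] = params.start * B[0]
    c[0] = alpha[0].sum()
    alpha[0] /= c[0]
    for t in range(1, T):
        alpha[t] = (alpha[t - 1] @ A) * B[t]
        c[t] = alpha[t].sum()
        alpha[t] /= c[t]
    beta = np.empty((T, 2))
    beta[-1] = 1.0
    for t in range(T - 2, -1, -1):
        beta[t] = (A @ (B[t + 1] * beta[t + 1])) / c[t + 1]
    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)
    xi_sum = np.zeros((2, 2))
    for t in range(T - 1):
        xi = (alpha[t][:, None] * A) * (B[t + 1] * beta[t + 1])[None, :] / c[t + 1]
        xi_sum += xi
    loglik = float(np.log(c).sum() + corr.sum())
    return gamma, xi_sum, loglik


def posterior_marginals(k, n, params: HmmParams) -> np.ndarray:
    """Posterior P(state | data) per site for a single chain."""
    logB = _emission_logp(np.asarray(k), np.asarray(n), params)
    gamma, _, _ = _forward_backward(logB, params)
    return gamma


def enumerate_posteriors(k, n, params: HmmParams) -> np.ndarray:
    """Brute-force posterior marginals by exhaustive path enumeration.

    Sums over all 2**T state paths; only feasible for short chains.
    Serves as an independent oracle for the forward-backward recursion.
    """
    k = np.asarray(k)
    n = np.asarray(n)
    T = len(k)
    if T > 20:
        raise ValueError("enumeration oracle limited to 20 sites")
    logB = _emission_logp(k, n, params)
    logA = np.log(params.trans)
    log_start = np.log(params.start)
    path_logp = []
    paths = []
    for mask in range(2**T):
        states = [(mask >> t) & 1 for t in range(T)]
        lp = log_start[states[0]] + logB[0, states[0]]
        for t in range(1, T):
            lp += logA[states[t - 1], states[t]] + logB[t, states[t]]
        path_logp.append(lp)
        paths.append(states)
    path_logp = np.asarray(path_logp)
    total = logsumexp(path_logp)
    gamma = np.zeros((T, 2))
    w = np.exp(path_logp - total)
    for weight, states in zip(w, paths):
        for t, st in enumerate(states):
            gamma[t, st] += weight
    return gamma


# ---------------------------------------------------------------------------
# fitting


def _weighted_betabinom_nll(theta, k, n, w):
    """Negative weighted beta-binomial log-likelihood; theta = (logit mu, log s)."""
    mu = 1.0 / (1.0 + np.exp(-theta[0]))
    s = np.exp(theta[1])
    a, b = mu * s, (1 - mu) * s
    ll = betaln(k + a, n - k + b) - betaln(a, b)
    return -float(np.dot(w, ll))


def _mstep_emission(k, n, gamma, params: HmmParams) -> tuple[np.ndarray, np.ndarray]:
    """Numerically maximize the expected emission log-likelihood per state.

    Optimizes (mean, concentration) from the current values; a solution
    is only accepted if it does not decrease the objective, which keeps
    the EM log-likelihood monotone.
    """
    alpha = params.alpha.copy()
    beta = params.beta.copy()
    for st in (0, 1):
        w = gamma[:, st]
        if w.sum() < 1e-8:
            continue
        mu0 = params.means[st]
        s0 = params.alpha[st] + params.beta[st]
        theta0 = np.array([np.log(mu0 / (1 - mu0)), np.log(s0)])
        res = optimize.minimize(
            _weighted_betabinom_nll,
            theta0,
            args=(k, n, w),
            method="L-BFGS-B",
            bounds=[(-7, 7), (np.log(0.5), np.log(5000.0))],
        )
        if res.success or res.fun < _weighted_betabinom_nll(theta0, k, n, w):
            if res.fun <= _weighted_betabinom_nll(theta0, k, n, w) + 1e-12:
                mu = 1.0 / (1.0 + np.exp(-res.x[0]))
                s = np.exp(res.x[1])
                alpha[st], beta[st] = mu * s, (1 - mu) * s
    return alpha, beta


@dataclass
class SegmentationResult:
    """Fitted segmentation model: parameter estimates, log-likelihood
    trace, and HMR/canyon callers bound to the fitted parameters."""

    model: "BetaBinomialHMM"
    params: HmmParams
    loglik_trace: list[float] = field(default_factory=list)
    converged: bool = False
    n_iter: int = 0

    @property
    def loglik(self) -> float:
        return self.loglik_trace[-1]

    def call_hmrs(self, track: MethylomeTrack | None = None, min_cpgs: int | None = None) -> pd.DataFrame:
        track = track if track is not None else self.model.track
        min_cpgs = min_cpgs if min_cpgs is not None else self.model.min_cpgs
        return call_hmrs(
            track, self.params, gap_limit=self.model.gap_limit, min_cpgs=min_cpgs
        )

    def summary(self) -> str:
        p = self.params
        lines = [
            "Two-state beta-binomial HMM segmentation",
            "=" * 44,
            f"observations (covered CpGs): {self.model.n_obs}",
            f"log-likelihood: {self.loglik:.3f}   iterations: {self.n_iter}"
            f"   converged: {self.converged}",
            "",
            f"{'state':<8}{'mean':>8}{'alpha':>10}{'beta':>10}{'self-trans':>12}",
            f"{'hypo':<8}{p.means[0]:>8.4f}{p.alpha[0]:>10.3f}{p.beta[0]:>10.3f}"
            f"{p.trans[0, 0]:>12.5f}",
            f"{'hyper':<8}{p.means[1]:>8.4f}{p.alpha[1]:>10.3f}{p.beta[1]:>10.3f}"
            f"{p.trans[1, 1]:>12.5f}",
        ]
        return "\n".join(lines)


class BetaBinomialHMM:
    """Two-state HMM over per-CpG methylation counts.

    Parameters
    ----------
    track
        CpG-context :class:`~methdyn.io.MethylomeTrack`.
    gap_limit
        Decoding and fitting treat CpGs separated by more than this many
        bp as belonging to independent chains (default 1000 bp), so CpG
        deserts cannot be spanned by a single HMR.
    min_cpgs
        Minimum covered CpGs for a called HMR (default 1).
    emission
        "betabinom" (default) or "binom".
    """

    def __init__(
        self,
        track: MethylomeTrack,
        gap_limit: int = 1000,
        min_cpgs: int = 1,
        emission: str = "betabinom",
    ):
        self.track = track
        self.gap_limit = gap_limit
        self.min_cpgs = min_cpgs
        self.emission = emission
        self._chain_data = [
            (k, n) for _, _, k, n in _chains(track, gap_limit)
        ]
        self.n_obs = int(sum(len(k) for k, _ in self._chain_data))
        if self.n_obs < 2:
            raise ValueError("track needs at least 2 covered CpGs")

    def loglik(self, params: HmmParams) -> float:
        total = 0.0
        for k, n in self._chain_data:
            logB = _emission_logp(k, n, params)
            _, _, ll = _forward_backward(logB, params)
            total += ll
        return total

    def fit(
        self,
        init: HmmParams | None = None,
        tol: float = 1e-3,
        max_iter: int = 100,
        seed: int | None = None,
    ) -> SegmentationResult:
        """Baum-Welch EM.

        Stops when the log-likelihood improves by less than ``tol`` or
        after ``max_iter`` iterations.  The log-likelihood trace is
        non-decreasing.  ``seed`` controls the jitter of the default
        initialization only.
        """
        params = init if init is not None else default_init(seed=seed)
        params = replace(params, emission=self.emission)
        trace: list[float] = []
        converged = False
        it = 0
        all_k = np.concatenate([k for k, _ in self._chain_data])
        all_n = np.concatenate([n for _, n in self._chain_data])
        for it in range(1, max_iter + 1):
            # E-step over all chains
            gammas = []
            xi_total = np.zeros((2, 2))
            start_total = np.zeros(2)
            ll = 0.0
            for k, n in self._chain_data:
                logB = _emission_logp(k, n, params)
                gamma, xi, chain_ll = _forward_backward(logB, params)
                gammas.append(gamma)
                xi_total += xi
                start_total += gamma[0]
                ll += chain_ll
            trace.append(ll)
            if not np.isfinite(tol):
                # degenerate tolerance: any improvement is below tol, so the
                # starting parameters are returned after a single E-step
                converged = True
                break
            if len(trace) > 1 and abs(trace[-1] - trace[-2]) < tol:
                converged = True
                break
            # M-step
            gamma_all = np.concatenate(gammas, axis=0)
            trans = xi_total / np.clip(xi_total.sum(axis=1, keepdims=True), 1e-300, None)
            start = start_total / start_total.sum()
            if params.emission == "betabinom":
                alpha, beta = _mstep_emission(all_k, all_n, gamma_all, params)
            else:
                w = gamma_all
                mu = (w * all_k[:, None]).sum(axis=0) / np.clip(
                    (w * all_n[:, None]).sum(axis=0), 1e-12, None
                )
                mu = np.clip(mu, 1e-4, 1 - 1e-4)
                s = params.alpha + params.beta
                alpha, beta = mu * s, (1 - mu) * s
            if alpha[0] / (alpha[0] + beta[0]) >= alpha[1] / (alpha[1] + beta[1]):
                # keep state identity: hypo stays the low-mean state
                alpha, beta = alpha[::-1].copy(), beta[::-1].copy()
                trans = trans[::-1, ::-1].copy()
                start = start[::-1].copy()
            params = HmmParams(
                trans=trans, start=start, alpha=alpha, beta=beta, emission=params.emission
            )
        return SegmentationResult(
            model=self,
            params=params,
            loglik_trace=trace,
            converged=converged,
            n_iter=it,
        )


def fit_hmm(
    track: MethylomeTrack,
    init: HmmParams | None = None,
    tol: float = 1e-3,
    max_iter: int = 100,
    seed: int | None = None,
    gap_limit: int = 1000,
) -> tuple[HmmParams, list[float]]:
    """Functional wrapper: fit the two-state HMM, return (params, trace)."""
    res = BetaBinomialHMM(track, gap_limit=gap_limit).fit(
        init=init, tol=tol, max_iter=max_iter, seed=seed
    )
    return res.params, res.loglik_trace


def call_hmrs(
    track: MethylomeTrack,
    params: HmmParams,
    gap_limit: int = 1000,
    min_cpgs: int = 1,
) -> pd.DataFrame:
    """Posterior-decode the track and emit hypomethylated regions.

    Each covered CpG is labeled hypo/hyper by its posterior marginal;
    maximal runs of hypo CpGs become HMRs spanning first CpG position to
    last CpG position + 2 (covering the CpG dyad).  Runs never cross
    inter-CpG gaps larger than ``gap_limit``.

    Returns a DataFrame with chrom, start, end, n_cpgs, mean_meth.
    """
    rows = []
    for chrom, pos, k, n in _chains(track, gap_limit):
        gamma = posterior_marginals(k, n, params)
        hypo = gamma[:, 0] > 0.5
        if not hypo.any():
            continue
        # maximal runs of hypo
        edges = np.flatnonzero(np.diff(np.concatenate([[0], hypo.view(np.int8), [0]])))
        for lo, hi in zip(edges[::2], edges[1::2]):
            if hi - lo < min_cpgs:
                continue
            rows.append(
                (
                    chrom,
                    int(pos[lo]),
                    int(pos[hi - 1]) + 2,
                    int(hi - lo),
                    float(k[lo:hi].sum() / n[lo:hi].sum()),
                )
            )
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "n_cpgs", "mean_meth"])
    return df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)


def call_canyons(hmrs: pd.DataFrame, min_length: int = 3500) -> pd.DataFrame:
    """Methylation canyons: HMRs of length >= ``min_length`` bp (3.5 kb
    or longer by default); a pure threshold filter, order preserved."""
    if min_length < 0:
        raise ValueError("min_length must be non-negative")
    lengths = hmrs["end"] - hmrs["start"]
    return hmrs[lengths >= min_length].copy()


def hmr_length_stats(hmrs: pd.DataFrame, genome_size: int | None = None) -> dict:
    """Order statistics of an HMR set: median length, count, and (when
    ``genome_size`` is given) the fraction of the genome covered."""
    if not len(hmrs):
        raise ValueError("empty HMR set")
    lengths = (hmrs["end"] - hmrs["start"]).to_numpy()
    out = {
        "count": int(len(lengths)),
        "median_length": float(np.median(lengths)),
        "total_bp": int(lengths.sum()),
    }
    if genome_size is not None:
        out["genome_fraction"] = float(lengths.sum() / genome_size)
    return out


def ks_statistic(lengths_a, lengths_b) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov comparison of HMR length sets.

    Returns (statistic, p-value); the statistic is the supremum of the
    absolute ECDF difference.
    """
    res = sps.ks_2samp(np.asarray(lengths_a, float), np.asarray(lengths_b, float))
    return float(res.statistic), float(res.pvalue)
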