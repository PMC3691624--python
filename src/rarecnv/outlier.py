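"""Windowed mean-distance outlier statistic and its Beta null.

The screen slides a window of k consecutive probes (default k=7) along the
genome. Within a window each sample is a point in the unit hypercube
(0,1)^k of pseudo-ranks; its statistic mu is the mean L_d distance (default
Manhattan, d=1) to the k-mers of all cohort samples, the zero self-distance
included in the mean:

    mu_d(s) = (1/|S|) * sum_{j in S} ( sum_{l in Q} |R_ls - R_lj|^d )^(1/d)

A rare CNV carrier sits near a corner of the hypercube over the aberrant
probes and maximises this mean distance. Per window, the cohort's mu values
are rescaled to their observed [min, max] span and a Beta(alpha, beta) null
is fitted by the method of moments; samples in the upper 1% tail of the fit
are flagged as rare-CNV markers.

For k=1 the statistic has an explicit large-cohort limit: a sample at
pseudo-rank z has mu -> integral_0^1 |t-z| dt = (z^2 + (1-z)^2) / 2, i.e.
half the summed squared Euclidean distance to the two extreme hypercube
corners 0 and 1. Under column independence the k>1 null is the sum of k
such independent one-dimensional terms; ``simulate_independence_null``
samples it by Monte Carlo.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy.special import betaincc

from .data import ProbeIndex
from .ranks import PseudoRankMatrix

__all__ = [
    "WindowSpec",
    "MuMatrix",
    "BetaNullFit",
    "MarkerSet",
    "make_windows",
    "mu_statistic",
    "mu_matrix",
    "mu_limit_k1",
    "simulate_independence_null",
    "fit_null_beta",
    "marker_pvalues",
    "call_markers",
]

DEFAULT_K = 7
DEFAULT_P_THRESHOLD = 0.01


@dataclass(frozen=True)
class WindowSpec:
    """Sliding windows of k consecutive probes, never spanning a chromosome
    boundary. ``starts`` holds each window's genome-order start position; the
    window covers probes [q, q+k)."""

    k: int
    step: int
    starts: np.ndarray

    def __len__(self) -> int:
        return len(self.starts)


def make_windows(probe_index: ProbeIndex, k: int = DEFAULT_K, step: int = 1) -> WindowSpec:
    """All maximal step-s windows of k consecutive probes per chromosome.

    Chromosomes with fewer than k probes contribute no window.
    """
    if k < 2:
        raise ValueError("window size k must be >= 2")
    if step < 1:
        raise ValueError("step must be >= 1")
    starts = []
    for lo, hi in probe_index.chrom_blocks().values():
        starts.extend(range(lo, hi - k + 1, step))
    return WindowSpec(k=k, step=step, starts=np.asarray(starts, dtype=np.int64))


@dataclass
class MuMatrix:
    """Per-window, per-sample mu values (windows x samples); NaN marks samples
    excluded from a window because of missing cells."""

    values: np.ndarray
    windows: WindowSpec
    d: float = 1.0


def _mu_window(W: np.ndarray, d: float) -> np.ndarray:
    """mu for one window: W is samples x k pseudo-ranks. Samples with any
    missing cell are excluded (NaN in the output) and do not enter the mean
    of the remaining samples; the divisor is the included count."""
    n = W.shape[0]
    out = np.full(n, np.nan)
    inc = ~np.isnan(W).any(axis=1)
    m = int(inc.sum())
    if m == 0:
        warnings.warn("window with no fully observed sample skipped", stacklevel=3)
        return out
    sub = W[inc]
    diff = np.abs(sub[:, None, :] - sub[None, :, :])
    if np.isinf(d):
        dist = diff.max(axis=2)
    elif d == 1.0:
        dist = diff.sum(axis=2)
    else:
        dist = (diff**d).sum(axis=2) ** (1.0 / d)
    out[inc] = dist.sum(axis=1) / m
    return out


def mu_statistic(R: PseudoRankMatrix | np.ndarray, window, d: float = 1.0) -> np.ndarray:
    """Mean L_d distance of each sample's k-mer to all samples' k-mers in one
    window.

    ``window`` is (start, k) in genome-order probe positions. Returns a
    vector of length n with NaN for samples excluded due to missingness.
    """
    values = R.values if isinstance(R, PseudoRankMatrix) else np.asarray(R, float)
    q, k = window
    return _mu_window(values[:, q : q + k], d)


def mu_matrix(R: PseudoRankMatrix, windows: WindowSpec, d: float = 1.0) -> MuMatrix:
    """mu for every window (windows x samples matrix).

    For the default Manhattan distance the double sum over samples and probes
    separates per probe, so fully observed windows are computed from
    per-probe pairwise distance sums with sliding-window totals (O(n p log n)
    overall); windows touching missing cells fall back to the direct
    per-window computation with sample exclusion.
    """
    X = R.values
    n, p = X.shape
    k = windows.k
    out = np.full((len(windows), n), np.nan)
    col_ok = ~np.isnan(X).any(axis=0)
    if d == 1.0 and len(windows):
        C = _column_pairwise_abs_sums(X)  # n x p, NaN-safe
        # sliding sums over every possible start; index the ones we need
        sums = sliding_window_view(C, k, axis=1).sum(axis=2)  # n x (p-k+1)
        win_ok = sliding_window_view(col_ok, k).all(axis=1)
        for w, q in enumerate(windows.starts):
            if win_ok[q]:
                out[w] = sums[:, q] / n
            else:
                out[w] = _mu_window(X[:, q : q + k], d)
    else:
        for w, q in enumerate(windows.starts):
            out[w] = _mu_window(X[:, q : q + k], d)
    return MuMatrix(out, windows, d)


def _column_pairwise_abs_sums(X: np.ndarray) -> np.ndarray:
    """C[s, q] = sum_j |X[s,q] - X[j,q]| over observed j, via per-column
    sorting and prefix sums; NaN where X is NaN."""
    n, p = X.shape
    order = np.argsort(X, axis=0)  # NaNs sort last
    S = np.take_along_axis(X, order, axis=0)
    m = np.sum(~np.isnan(X), axis=0)  # observed count per column
    Z = np.where(np.isnan(S), 0.0, S)
    P = np.cumsum(Z, axis=0)  # prefix sums over observed values
    total = P[np.maximum(m - 1, 0), np.arange(p)]
    i = np.arange(1, n + 1)[:, None].astype(float)
    C_sorted = (2 * i - m[None, :]) * S - 2 * P + total[None, :]
    C = np.empty_like(X)
    np.put_along_axis(C, order, C_sorted, axis=0)
    C[np.isnan(X)] = np.nan
    return C


def mu_limit_k1(z: float) -> float:
    """Large-cohort limit of mu at k=1, d=1 for a sample at pseudo-rank z.

    Equals the mean absolute deviation of Uniform(0,1) from z:
    integral_0^1 |t - z| dt = (z^2 + (1-z)^2) / 2 — half the summed squared
    distance to the two extreme corners of the unit interval. Minimised at
    z = 1/2 (value 1/4), maximised at the edges (value 1/2).
    """
    z = np.asarray(z, dtype=float)
    if np.any((z < 0) | (z > 1)):
        raise ValueError("pseudo-rank z must lie in [0, 1]")
    out = 0.5 * (z**2 + (1.0 - z) ** 2)
    return float(out) if out.ndim == 0 else out


def simulate_independence_null(
    k: int, n: int, reps: int, d: float = 1.0, seed: int | None = None
) -> np.ndarray:
    """Monte-Carlo sample of the independence null of mu.

    Draws ``reps`` realisations of mu_d for one sample in a cohort of n where
    all k window columns are independent rank columns (i.e. the pseudo-rank
    matrix of iid data). For d=1 the statistic separates per column and only
    the tracked sample's rank in each column matters, so each draw is
    computed exactly from k uniform rank positions; for general d full
    per-column rank permutations are simulated.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if k < 1 or n < 2:
        raise ValueError("require k >= 1 and n >= 2")
    rng = np.random.default_rng(seed)
    if d == 1.0:
        i = rng.integers(1, n + 1, size=(reps, k)).astype(float)
        # sum_j |i - j| / (n+1) over j = 1..n, exact for a full rank column
        colsum = (i * (i - 1) / 2 + (n - i) * (n - i + 1) / 2) / (n + 1.0)
        return colsum.sum(axis=1) / n
    out = np.empty(reps)
    for r in range(reps):
        ranks = (np.argsort(rng.random((k, n)), axis=1).argsort(axis=1) + 1) / (n + 1.0)
        z = ranks[:, 0][:, None]
        diff = np.abs(z - ranks)
        if np.isinf(d):
            dist = diff.max(axis=0)
        else:
            dist = (diff**d).sum(axis=0) ** (1.0 / d)
        out[r] = dist.mean()
    return out


@dataclass
class BetaNullFit:
    """Beta(alpha, beta) null for one window's mu values, shifted to the
    observed interval [lo, hi]. ``ok`` is False when the window is degenerate
    (no spread or undefined moments); callers must then emit no marker."""

    window: int
    alpha: float | None
    beta: float | None
    lo: float
    hi: float
    method: str = "moments"
    ok: bool = True


def fit_null_beta(
    mu: np.ndarray, lo: float | None = None, hi: float | None = None, window: int = -1
) -> BetaNullFit:
    """Method-of-moments Beta fit to mu values rescaled to [lo, hi]
    (defaults: observed min/max, as the screen uses per window).

    Boundary values are nudged inward by eps = 1/(2m) before computing
    moments, since the rescaled min/max sit exactly on the Beta support
    boundary. Degenerate inputs (hi <= lo, zero variance, or moments outside
    the Beta-feasible region) yield a no-fit result.
    """
    mu = np.asarray(mu, dtype=float)
    obs = mu[~np.isnan(mu)]
    m = len(obs)
    if m < 8:
        raise ValueError("Beta null fit requires at least 8 observed values")
    lo = float(np.min(obs)) if lo is None else float(lo)
    hi = float(np.max(obs)) if hi is None else float(hi)
    if not hi > lo:
        return BetaNullFit(window, None, None, lo, hi, ok=False)
    eps = 1.0 / (2.0 * m)
    x = np.clip((obs - lo) / (hi - lo), eps, 1.0 - eps)
    mean = float(np.mean(x))
    var = float(np.var(x, ddof=1))
    if var <= 0:
        return BetaNullFit(window, None, None, lo, hi, ok=False)
    common = mean * (1.0 - mean) / var - 1.0
    if common <= 0:
        return BetaNullFit(window, None, None, lo, hi, ok=False)
    return BetaNullFit(window, mean * common, (1.0 - mean) * common, lo, hi)


def marker_pvalues(mu: np.ndarray, fit: BetaNullFit) -> np.ndarray:
    """Upper-tail p-value of each mu under the fitted Beta null.

    p = 1 - BetaCDF((mu - lo)/(hi - lo)); rescaled values are clipped to
    [0, 1], so mu at the fitted maximum gets p = 0 and at the minimum p = 1.
    Outliers have *large* mean distance, hence upper tail only. A no-fit
    window returns p = 1 everywhere; NaN mu (excluded samples) stays NaN.
    """
    mu = np.asarray(mu, dtype=float)
    nan = np.isnan(mu)
    if not fit.ok:
        p = np.ones_like(mu)
    else:
        x = np.clip((mu - fit.lo) / (fit.hi - fit.lo), 0.0, 1.0)
        with np.errstate(invalid="ignore"):
            p = betaincc(fit.alpha, fit.beta, x)
        p = np.clip(p, 0.0, 1.0)
    p[nan] = np.nan
    return p


def fit_null_beta_rows(M: np.ndarray) -> tuple[list[BetaNullFit], np.ndarray]:
    """Fit the Beta null for every row of a windows x samples mu matrix and
    return the fits together with the matching upper-tail p-value matrix.

    Row-vectorised version of :func:`fit_null_beta` + :func:`marker_pvalues`
    (same moments, nudging and tail conventions); no-fit rows get p = 1 and
    NaN entries (excluded samples) stay NaN.
    """
    M = np.asarray(M, dtype=float)
    nw = M.shape[0]
    obs = ~np.isnan(M)
    m = obs.sum(axis=1).astype(float)
    if np.any(m < 8):
        raise ValueError("Beta null fit requires at least 8 observed values per window")
    with np.errstate(all="ignore"):
        lo = np.nanmin(M, axis=1)
        hi = np.nanmax(M, axis=1)
        span = hi - lo
        eps = 1.0 / (2.0 * m)
        x = np.clip((M - lo[:, None]) / span[:, None], eps[:, None], 1.0 - eps[:, None])
        mean = np.nanmean(x, axis=1)
        var = np.nanvar(x, axis=1, ddof=1)
        common = mean * (1.0 - mean) / var - 1.0
        ok = (span > 0) & (var > 0) & (common > 0)
        a = np.where(ok, mean * common, np.nan)
        b = np.where(ok, (1.0 - mean) * common, np.nan)
        xr = np.clip((M - lo[:, None]) / np.where(span > 0, span, 1.0)[:, None], 0.0, 1.0)
        P = np.where(
            ok[:, None], betaincc(a[:, None], b[:, None], xr), 1.0
        )
    P = np.clip(P, 0.0, 1.0)
    P[~obs] = np.nan
    fits = [
        BetaNullFit(
            w,
            float(a[w]) if ok[w] else None,
            float(b[w]) if ok[w] else None,
            float(lo[w]),
            float(hi[w]),
            ok=bool(ok[w]),
        )
        for w in range(nw)
    ]
    return fits, P


@dataclass
class MarkerSet:
    """Flagged (sample, window) pairs with their p-values.

    ``records`` columns: sample, window (genome-order start position of the
    flagged k-probe window), pvalue. Every stored p-value is strictly below
    ``p_threshold``.
    """

    records: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["sample", "window", "pvalue"])
    )
    k: int = DEFAULT_K
    p_threshold: float = DEFAULT_P_THRESHOLD

    def __post_init__(self):
        if len(self.records) and not (self.records["pvalue"] < self.p_threshold).all():
            raise ValueError("marker set contains p-values at or above the threshold")

    def __len__(self) -> int:
        return len(self.records)

    def pairs(self) -> set[tuple[str, int]]:
        return set(zip(self.records["sample"], self.records["window"].astype(int)))


def call_markers(
    pvals: np.ndarray,
    windows: WindowSpec,
    sample_ids: list[str],
    threshold: float = DEFAULT_P_THRESHOLD,
) -> MarkerSet:
    """Select (sample, window) pairs with p strictly below the threshold.

    The 1% default mirrors the frequency that defines a rare CNV: flagged
    pairs are those in the upper 1% tail of the window's null.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    P = np.asarray(pvals, dtype=float)
    with np.errstate(invalid="ignore"):
        w_idx, s_idx = np.nonzero(P < threshold)
    df = pd.DataFrame(
        {
            "sample": [sample_ids[s] for s in s_idx],
            "window": windows.starts[w_idx],
            "pvalue": P[w_idx, s_idx],
        }
    )
    return MarkerSet(df, k=windows.k, p_threshold=threshold)
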