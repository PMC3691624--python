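"""Segment scoring by marker coverage density, candidate selection, the
segmentation-free marker-clustering mode, and a minimal built-in segmenter.

The density score of a segment is the percentage of its probes covered by the
union of that sample's flagged marker windows; segments with no marker inside
are sieved out, and candidates require a score strictly above 50% together
with an absolute segment mean logratio strictly above 0.1.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .data import LogratioMatrix, ProbeIndex, Segmentation, SEGMENTATION_COLUMNS
from .outlier import MarkerSet, WindowSpec

__all__ = [
    "density_score",
    "select_candidates",
    "cluster_markers",
    "simple_segment",
    "SCORED_COLUMNS",
]

SCORED_COLUMNS = SEGMENTATION_COLUMNS + ["marker_probes", "density_score"]

DEFAULT_MIN_SCORE = 50.0
DEFAULT_MIN_ABS_MEAN = 0.1


def _marker_coverage(markers: MarkerSet, n_probes: int) -> dict[str, np.ndarray]:
    """Per sample, boolean vector of probes covered by >= 1 flagged window."""
    cov: dict[str, np.ndarray] = {}
    k = markers.k
    for rec in markers.records.itertuples(index=False):
        vec = cov.get(rec.sample)
        if vec is None:
            vec = cov[rec.sample] = np.zeros(n_probes, dtype=bool)
        q = int(rec.window)
        vec[q : q + k] = True
    return cov


def density_score(
    seg: Segmentation, markers: MarkerSet, window_spec: WindowSpec, n_probes: int | None = None
) -> pd.DataFrame:
    """Score every segment by marker coverage and sieve out unmarked ones.

    A probe of a segment counts as covered when it lies inside at least one
    flagged window of the same sample; the score is 100 * covered / n_probes.
    Segments without any covered probe are removed from the output.
    """
    if n_probes is None:
        seg_end = int(seg.records["end_pos"].max()) if len(seg) else 0
        mark_end = (
            int(markers.records["window"].max()) + markers.k if len(markers) else 0
        )
        n_probes = max(seg_end, mark_end)
    cov = _marker_coverage(markers, n_probes)
    rows = []
    for rec in seg.records.itertuples(index=False):
        vec = cov.get(rec.sample)
        covered = int(vec[int(rec.start_pos) : int(rec.end_pos)].sum()) if vec is not None else 0
        if covered == 0:
            continue
        rows.append(
            {
                "sample": rec.sample,
                "chrom": rec.chrom,
                "start_pos": int(rec.start_pos),
                "end_pos": int(rec.end_pos),
                "n_probes": int(rec.n_probes),
                "seg_mean": float(rec.seg_mean),
                "marker_probes": covered,
                "density_score": 100.0 * covered / int(rec.n_probes),
            }
        )
    return pd.DataFrame(rows, columns=SCORED_COLUMNS)


def select_candidates(
    scored: pd.DataFrame,
    min_score: float = DEFAULT_MIN_SCORE,
    min_abs_mean: float = DEFAULT_MIN_ABS_MEAN,
) -> pd.DataFrame:
    """Keep segments with density score strictly above ``min_score`` and
    |seg_mean| strictly above ``min_abs_mean``, sorted by descending score
    (stable for ties)."""
    keep = (scored["density_score"] > min_score) & (
        scored["seg_mean"].abs() > min_abs_mean
    )
    out = scored.loc[keep]
    return out.sort_values(
        "density_score", ascending=False, kind="stable"
    ).reset_index(drop=True)


def cluster_markers(
    markers: MarkerSet,
    probe_index: ProbeIndex,
    L: LogratioMatrix | None = None,
    max_gap_probes: int = 0,
) -> Segmentation:
    """Segmentation-free mode: per sample, merge flagged windows along the
    genome into segments.

    Overlapping or near-by window intervals (separated by at most
    ``max_gap_probes`` unmarked probes, same chromosome) are unioned; the
    segment mean is recomputed from the logratio matrix when available.
    """
    k = markers.k
    chrom_of = probe_index.chrom
    rows = []
    for sample, sub in markers.records.groupby("sample", sort=True):
        qs = np.sort(sub["window"].to_numpy(dtype=np.int64))
        cur_s, cur_e = int(qs[0]), int(qs[0]) + k
        for q in qs[1:]:
            q = int(q)
            same_chrom = chrom_of[q] == chrom_of[cur_s]
            if same_chrom and q - cur_e <= max_gap_probes:
                cur_e = max(cur_e, q + k)
            else:
                rows.append((sample, cur_s, cur_e))
                cur_s, cur_e = q, q + k
        rows.append((sample, cur_s, cur_e))
    recs = []
    for sample, s, e in rows:
        if L is not None:
            i = L.sample_ids.index(sample)
            mean = float(np.nanmean(L.values[i, s:e]))
        else:
            mean = float("nan")
        recs.append(
            {
                "sample": sample,
                "chrom": chrom_of[s],
                "start_pos": s,
                "end_pos": e,
                "n_probes": e - s,
                "seg_mean": mean,
            }
        )
    return Segmentation(pd.DataFrame(recs, columns=SEGMENTATION_COLUMNS))


# ---------------------------------------------------------------------------
# minimal built-in segmenter (plumbing; any external SEG file takes precedence)


_SPLIT_GRID_CACHE: dict[tuple[int, int], tuple[np.ndarray, int]] = {}


def _split_grid(m: int, min_probes: int) -> tuple[np.ndarray, int]:
    """Weight grid m/(n1*n0) over candidate pairs (i, j), zero where a part
    would fall below min_probes; cached per (region length, min_probes)."""
    key = (m, min_probes)
    hit = _SPLIT_GRID_CACHE.get(key)
    if hit is None:
        idx = np.arange(m + 1)
        n1 = (idx[None, :] - idx[:, None]).astype(float)
        n0 = m - n1
        valid = (n1 >= min_probes) & (n0 >= min_probes)
        with np.errstate(divide="ignore", invalid="ignore"):
            w = np.where(valid, m / (n1 * n0), 0.0)
        if len(_SPLIT_GRID_CACHE) > 64:
            _SPLIT_GRID_CACHE.clear()
        hit = _SPLIT_GRID_CACHE[key] = (w, int(valid.sum()))
    return hit


def _best_interior_split(x: np.ndarray, min_probes: int):
    """Best interior segment [i, j) maximising the pooled t statistic between
    the inside mean and the outside mean (the circular-split test of CBS —
    a single left/right breakpoint cannot detect a short CNV buried in a
    long region). Returns ((i, j), Bonferroni-adjusted p-value) or
    (None, 1.0). Memory is O(m^2) in the region length.

    Maximising t^2 is equivalent to maximising the between-group sum of
    squares B = (sum1 - n1*mean)^2 * m/(n1*n0), since the total centered sum
    of squares is fixed; only the best pair's t^2 is formed explicitly.
    """
    m = len(x)
    if m < 2 * min_probes:
        return None, 1.0
    w, n_valid = _split_grid(m, min_probes)
    if n_valid == 0:
        return None, 1.0
    S = np.concatenate([[0.0], np.cumsum(x)])
    ybar = S[m] / m
    G = S - np.arange(m + 1) * ybar  # A(i,j) = G[j] - G[i] = sum1 - n1*ybar
    B = (G[None, :] - G[:, None]) ** 2 * w
    flat = int(np.argmax(B))
    bi, bj = divmod(flat, m + 1)
    best_b = B[bi, bj]
    ss_c = float(np.sum(x**2)) - m * ybar**2
    if best_b <= 0:
        return None, 1.0
    resid = ss_c - best_b
    if resid <= 1e-12 * max(ss_c, 1.0):  # perfect split (noise-free step)
        return (int(bi), int(bj)), 0.0
    df = max(m - 2, 1)
    t2 = best_b * df / resid
    p_pt = float(2.0 * stats.t.sf(np.sqrt(t2), df))
    return (int(bi), int(bj)), min(1.0, p_pt * n_valid)


def _segment_1d(x: np.ndarray, offset: int, min_probes: int, alpha: float, out: list):
    split, pval = _best_interior_split(x, min_probes)
    if split is not None and pval < alpha:
        i, j = split
        for s, e in ((0, i), (i, j), (j, len(x))):
            if e > s:
                _segment_1d(x[s:e], offset + s, min_probes, alpha, out)
    else:
        out.append((offset, offset + len(x), float(np.mean(x))))


def simple_segment(
    L: LogratioMatrix, min_probes: int = 10, alpha: float = 0.01
) -> Segmentation:
    """Recursive binary segmentation of each sample per chromosome.

    At each step the interior segment maximising the two-sample t statistic
    between its mean and the rest of the region is taken (the circular-split
    test of CBS; boundary splits are the special case of one breakpoint);
    splitting continues while the Bonferroni-adjusted p-value over candidate
    splits is below ``alpha`` and every part keeps at least ``min_probes``
    probes. Deliberately minimal plumbing — the screen accepts any external
    segmentation (e.g. DNAcopy output) in its place.
    """
    blocks = L.probe_index.chrom_blocks()
    rows = []
    for i, sample in enumerate(L.sample_ids):
        for chrom, (lo, hi) in blocks.items():
            x = L.values[i, lo:hi]
            x = np.where(np.isnan(x), np.nanmean(x) if np.any(~np.isnan(x)) else 0.0, x)
            pieces: list[tuple[int, int, float]] = []
            _segment_1d(x, lo, min_probes, alpha, pieces)
            for s, e, mean in pieces:
                rows.append(
                    {
                        "sample": sample,
                        "chrom": chrom,
                        "start_pos": s,
                        "end_pos": e,
                        "n_probes": e - s,
                        "seg_mean": mean,
                    }
                )
    return Segmentation(pd.DataFrame(rows, columns=SEGMENTATION_COLUMNS))
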