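"""Candidate annotation against interval databases and the enrichment curve.

Candidates are intersected with three tracks playing fixed roles: a
pathogenic-variant track ("isca"), a disease-association track ("gad") and a
benign/population-variant track ("dgv"). A candidate with a significant DGV
presence (>= 3 overlapping records by default) is labelled a common variant;
otherwise any ISCA or GAD support marks it a rare candidate, and no support
leaves it unsupported. Any BED file can be registered under any role — the
logic, not the download, is what matters here.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data import IntervalDB, ProbeIndex

__all__ = [
    "overlap_counts",
    "classify_segment",
    "annotate_segments",
    "enrichment_curve",
]

LABEL_COMMON = "common_dgv"
LABEL_RARE = "rare_candidate"
LABEL_UNSUPPORTED = "unsupported"

DEFAULT_DGV_MIN = 3


def overlap_counts(
    segment: tuple[str, int, int], db: IntervalDB, min_reciprocal: float = 0.0
) -> int:
    """Number of database intervals overlapping a bp segment.

    Default: any overlap of >= 1 bp counts. With ``min_reciprocal`` set, the
    overlap must cover at least that fraction of *both* the segment and the
    database interval (reciprocal-overlap rule).
    """
    chrom, start, end = segment
    hits = db.tree(chrom).overlap(start, end)
    if min_reciprocal <= 0.0:
        return len(hits)
    n = 0
    seg_len = end - start
    for iv in hits:
        ov = min(end, iv.end) - max(start, iv.begin)
        if ov >= min_reciprocal * seg_len and ov >= min_reciprocal * (iv.end - iv.begin):
            n += 1
    return n


def classify_segment(db_counts: dict[str, int], dgv_min: int = DEFAULT_DGV_MIN) -> str:
    """Label from database hit counts; the DGV commonness rule takes
    precedence over pathogenic/association support."""
    if db_counts.get("dgv", 0) >= dgv_min:
        return LABEL_COMMON
    if db_counts.get("isca", 0) > 0 or db_counts.get("gad", 0) > 0:
        return LABEL_RARE
    return LABEL_UNSUPPORTED


def annotate_segments(
    scored: pd.DataFrame,
    probe_index: ProbeIndex,
    dbs: dict[str, IntervalDB],
    dgv_min: int = DEFAULT_DGV_MIN,
    min_reciprocal: float = 0.0,
) -> pd.DataFrame:
    """Add bp coordinates, per-database overlap counts and a class label to a
    scored-segment table."""
    out = scored.copy()
    if len(out):
        out["start_bp"] = probe_index.start[out["start_pos"].to_numpy(int)]
        out["end_bp"] = probe_index.end[out["end_pos"].to_numpy(int) - 1]
    else:
        out["start_bp"] = pd.Series(dtype=np.int64)
        out["end_bp"] = pd.Series(dtype=np.int64)
    counts = {name: [] for name in dbs}
    labels = []
    for rec in out.itertuples(index=False):
        seg = (rec.chrom, int(rec.start_bp), int(rec.end_bp))
        c = {
            name: overlap_counts(seg, db, min_reciprocal=min_reciprocal)
            for name, db in dbs.items()
        }
        for name in dbs:
            counts[name].append(c[name])
        labels.append(classify_segment(c, dgv_min=dgv_min))
    for name in dbs:
        out[f"n_{name}"] = counts[name]
    out["label"] = labels
    return out


def enrichment_curve(
    scored: pd.DataFrame | list, positive_labels: list[bool] | np.ndarray
) -> np.ndarray:
    """Cumulative enrichment of positives along the score ranking.

    Input is already sorted by descending density score; the curve walks down
    that ranking and records (fraction of segments screened, fraction of all
    positives recovered), starting at (0, 0) and ending at (1, 1) whenever
    any positive exists. Under a random ordering the curve follows the
    diagonal in expectation; a perfect ranking reaches 1 at the prevalence.
    """
    pos = np.asarray(positive_labels, dtype=bool)
    N = len(pos)
    if N != (len(scored) if scored is not None else N):
        raise ValueError("labels and scored list must be aligned")
    if N == 0:
        return np.array([[0.0, 0.0]])
    P = pos.sum()
    frac_screened = np.arange(N + 1) / N
    cum = np.concatenate([[0], np.cumsum(pos)])
    frac_found = cum / P if P > 0 else np.zeros(N + 1)
    return np.column_stack([frac_screened, frac_found])
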