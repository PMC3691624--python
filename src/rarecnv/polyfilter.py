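"""Cohort polymorphic profile and marker filtering.

The windowed outlier statistic flags rare-CNV carriers, but also samples in
highly polymorphic regions, where many cohort members deviate and the null is
misspecified. The remedy is an in-cohort profile: the segmentation is mapped
onto probes (each probe inherits the mean logratio of its sample's containing
segment), a probe is "aberrant" in a sample when that signal exceeds 0.07 in
absolute value (log10 units; the conservative 0.24 log2 aberration threshold),
and a probe is polymorphic when strictly more than 1% of the cohort is
aberrant there (strictly more than 3 samples at the reference cohort size of
366). Markers falling in k-probe runs of polymorphic probes are removed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import ProbeIndex, Segmentation
from .outlier import MarkerSet, WindowSpec

__all__ = [
    "PolymorphicProfile",
    "DEFAULT_SIGNAL_THRESHOLD",
    "log2_ratio_to_log10",
    "segmentation_to_probe_signal",
    "build_polymorphic_profile",
    "polymorphic_windows",
    "filter_markers",
]

#: |log10 ratio| above which a probe's segment signal counts as aberrant;
#: equals the conservative log2 threshold 0.24 expressed in log10 units.
DEFAULT_SIGNAL_THRESHOLD = 0.07
DEFAULT_FREQUENCY = 0.01


def log2_ratio_to_log10(x: float) -> float:
    """Convert a log2 ratio threshold to the log10 scale of the matrix."""
    return float(x) * float(np.log10(2.0))


@dataclass
class PolymorphicProfile:
    """Per-probe binary cohort vector: 1 where the region is polymorphic."""

    profile: np.ndarray
    signal_threshold: float = DEFAULT_SIGNAL_THRESHOLD
    count_threshold: int = 1

    def __post_init__(self):
        self.profile = np.asarray(self.profile, dtype=np.int8)
        if self.count_threshold < 1:
            raise ValueError("count_threshold must be >= 1")
        if not np.isin(self.profile, (0, 1)).all():
            raise ValueError("profile values must be 0/1")


def segmentation_to_probe_signal(
    seg: Segmentation, probe_index: ProbeIndex, sample_ids: list[str]
) -> np.ndarray:
    """Map the segmentation into probes: cell (s, q) carries the mean logratio
    of sample s's segment containing probe q, and 0 for probes outside every
    segment (segmentation-free probes carry no aberration evidence)."""
    n, p = len(sample_ids), len(probe_index)
    signal = np.zeros((n, p))
    row = {s: i for i, s in enumerate(sample_ids)}
    for rec in seg.records.itertuples(index=False):
        i = row.get(rec.sample)
        if i is None:
            continue
        signal[i, int(rec.start_pos) : int(rec.end_pos)] = rec.seg_mean
    return signal


def build_polymorphic_profile(
    probe_signal: np.ndarray,
    signal_threshold: float = DEFAULT_SIGNAL_THRESHOLD,
    frequency: float = DEFAULT_FREQUENCY,
) -> PolymorphicProfile:
    """Per-probe polymorphism calls from the probe-mapped segment signal.

    A sample is aberrant at a probe when |signal| strictly exceeds
    ``signal_threshold``; the probe is polymorphic when the aberrant count
    strictly exceeds floor(frequency * n) — "more than 1% of the cohort",
    i.e. more than 3 of 366. Both comparisons are strict.
    """
    signal = np.asarray(probe_signal, dtype=float)
    n = signal.shape[0]
    if n < 1:
        raise ValueError("probe signal must contain at least one sample")
    count_threshold = max(int(np.floor(frequency * n)), 1)
    counts = (np.abs(signal) > signal_threshold).sum(axis=0)
    return PolymorphicProfile(
        (counts > count_threshold).astype(np.int8),
        signal_threshold=signal_threshold,
        count_threshold=count_threshold,
    )


def polymorphic_windows(profile: PolymorphicProfile, windows: WindowSpec) -> set[int]:
    """Start positions of marker windows whose k probes are all polymorphic."""
    prof = profile.profile
    k = windows.k
    return {
        int(q) for q in windows.starts if q + k <= len(prof) and prof[q : q + k].all()
    }


def filter_markers(
    markers: MarkerSet, poly_windows: set[int], mode: str = "intersect"
) -> MarkerSet:
    """Remove markers lying in polymorphic regions.

    mode="intersect": drop a marker only when its window is itself a fully
    polymorphic k-mer (exact window-set intersection). mode="overlap": drop a
    marker when its window shares at least one probe with any polymorphic
    window.
    """
    if mode not in ("intersect", "overlap"):
        raise ValueError(f"unknown filter mode {mode!r}")
    if len(markers) == 0 or not poly_windows:
        return MarkerSet(markers.records.copy(), k=markers.k, p_threshold=markers.p_threshold)
    w = markers.records["window"].to_numpy(dtype=np.int64)
    if mode == "intersect":
        drop = np.isin(w, list(poly_windows))
    else:
        poly = np.sort(np.fromiter(poly_windows, dtype=np.int64))
        k = markers.k
        # windows [q, q+k) and [p, p+k) share a probe iff |q - p| < k
        left = np.searchsorted(poly, w - k, side="right")
        right = np.searchsorted(poly, w + k, side="left")
        drop = right > left
    kept = markers.records.loc[~drop].reset_index(drop=True)
    return MarkerSet(kept, k=markers.k, p_threshold=markers.p_threshold)
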