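"""Model-style front end: `RareCNVScreen` holds a cohort and configuration;
`fit()` runs the three-phase screen (segmentation, rank-based marker calling
with polymorphism filtering, segment scoring/annotation) and returns a
`RareCNVResults` with the markers, scored segments, candidates, per-stage
counts, a text summary and plotting helpers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import annotate as _annotate
from . import polyfilter as _poly
from . import segscore as _segscore
from .data import (
    IntervalDB,
    LogratioMatrix,
    Segmentation,
    read_interval_db,
    read_logratio_table,
    read_segmentation,
)
from .outlier import (
    MarkerSet,
    MuMatrix,
    call_markers,
    fit_null_beta_rows,
    make_windows,
    mu_matrix,
)
from .ranks import pseudo_rank

__all__ = ["RareCNVScreen", "RareCNVResults"]


class RareCNVScreen:
    """Multi-sample rare-CNV screen over a cohort logratio matrix.

    Parameters
    ----------
    logratio
        Cohort matrix (samples x probes, log10 units, NaN for missing).
    segmentation
        Pre-computed per-sample segmentation (e.g. CBS output read via
        :func:`rarecnv.data.read_segmentation`). Required for
        ``segmenter="external"``.
    databases
        Optional mapping of role name ("isca"/"dgv"/"gad") to interval
        databases for candidate annotation.
    k, d, p_threshold, step
        Window size (probes), distance exponent, marker tail probability and
        window stride.
    signal_threshold, frequency, filter_mode
        Polymorphic-profile parameters: |log10| segment-signal cutoff, cohort
        frequency defining "polymorphic", and marker exclusion semantics
        ("intersect" or "overlap").
    min_score, min_abs_mean
        Candidate thresholds: density score (percent, strict) and absolute
        segment mean logratio (strict).
    segmenter
        "external" (use the supplied segmentation), "simple" (built-in
        recursive splitter) or "cluster" (segmentation-free marker
        clustering).
    """

    def __init__(
        self,
        logratio: LogratioMatrix,
        segmentation: Optional[Segmentation] = None,
        databases: Optional[dict[str, IntervalDB]] = None,
        *,
        k: int = 7,
        d: float = 1.0,
        p_threshold: float = 0.01,
        step: int = 1,
        signal_threshold: float = _poly.DEFAULT_SIGNAL_THRESHOLD,
        frequency: float = _poly.DEFAULT_FREQUENCY,
        filter_mode: str = "intersect",
        min_score: float = _segscore.DEFAULT_MIN_SCORE,
        min_abs_mean: float = _segscore.DEFAULT_MIN_ABS_MEAN,
        max_gap_probes: int = 0,
        segmenter: str = "external",
        seg_min_probes: int = 10,
        seg_alpha: float = 0.01,
        dgv_min: int = _annotate.DEFAULT_DGV_MIN,
        min_reciprocal: float = 0.0,
    ):
        if segmenter not in ("external", "simple", "cluster"):
            raise ValueError(f"unknown segmenter {segmenter!r}")
        if segmenter == "external" and segmentation is None:
            raise ValueError("segmenter='external' requires a segmentation")
        self.logratio = logratio
        self.segmentation = segmentation
        self.databases = databases or {}
        self.k = k
        self.d = d
        self.p_threshold = p_threshold
        self.step = step
        self.signal_threshold = signal_threshold
        self.frequency = frequency
        self.filter_mode = filter_mode
        self.min_score = min_score
        self.min_abs_mean = min_abs_mean
        self.max_gap_probes = max_gap_probes
        self.segmenter = segmenter
        self.seg_min_probes = seg_min_probes
        self.seg_alpha = seg_alpha
        self.dgv_min = dgv_min
        self.min_reciprocal = min_reciprocal

    @classmethod
    def from_files(
        cls,
        logratio_path,
        segmentation_path=None,
        db_paths: Optional[dict[str, str]] = None,
        **kwargs,
    ) -> "RareCNVScreen":
        probe_index, L = read_logratio_table(logratio_path)
        seg = (
            read_segmentation(segmentation_path, probe_index)
            if segmentation_path is not None
            else None
        )
        dbs = {
            name: read_interval_db(path, name)
            for name, path in (db_paths or {}).items()
        }
        return cls(L, segmentation=seg, databases=dbs, **kwargs)

    def fit(self) -> "RareCNVResults":
        L = self.logratio
        probe_index = L.probe_index
        counts: dict[str, int] = {"n_samples": L.n_samples, "n_probes": L.n_probes}

        R = pseudo_rank(L)
        windows = make_windows(probe_index, k=self.k, step=self.step)
        counts["n_windows"] = len(windows)
        mu = mu_matrix(R, windows, d=self.d)

        fits, P = fit_null_beta_rows(mu.values)
        counts["n_windows_no_fit"] = sum(not f.ok for f in fits)

        markers_raw = call_markers(P, windows, L.sample_ids, threshold=self.p_threshold)
        counts["markers_called"] = len(markers_raw)

        if self.segmenter == "simple" or (
            self.segmenter == "external" and self.segmentation is None
        ):
            seg = _segscore.simple_segment(
                L, min_probes=self.seg_min_probes, alpha=self.seg_alpha
            )
        elif self.segmenter == "cluster":
            seg = _segscore.cluster_markers(
                markers_raw, probe_index, L=L, max_gap_probes=self.max_gap_probes
            )
        else:
            seg = self.segmentation
        counts["segments_in"] = len(seg)

        signal = _poly.segmentation_to_probe_signal(seg, probe_index, L.sample_ids)
        profile = _poly.build_polymorphic_profile(
            signal, signal_threshold=self.signal_threshold, frequency=self.frequency
        )
        counts["polymorphic_probes"] = int(profile.profile.sum())
        poly_windows = _poly.polymorphic_windows(profile, windows)
        counts["polymorphic_windows"] = len(poly_windows)
        markers = _poly.filter_markers(markers_raw, poly_windows, mode=self.filter_mode)
        counts["markers_after_filter"] = len(markers)

        scored = _segscore.density_score(seg, markers, windows, n_probes=L.n_probes)
        counts["segments_scored"] = len(scored)
        candidates = _segscore.select_candidates(
            scored, min_score=self.min_score, min_abs_mean=self.min_abs_mean
        )
        counts["candidates"] = len(candidates)

        annotated = _annotate.annotate_segments(
            candidates,
            probe_index,
            self.databases,
            dgv_min=self.dgv_min,
            min_reciprocal=self.min_reciprocal,
        )
        return RareCNVResults(
            model=self,
            windows=windows,
            mu=mu,
            null_fits=fits,
            pvalues=P,
            markers_raw=markers_raw,
            poly_profile=profile,
            markers=markers,
            segmentation_used=seg,
            scored=scored,
            candidates=candidates,
            annotated=annotated,
            stage_counts=counts,
        )


@dataclass
class RareCNVResults:
    """Everything the screen produced, with per-stage counts."""

    model: RareCNVScreen
    windows: object
    mu: MuMatrix
    null_fits: list
    pvalues: np.ndarray
    markers_raw: MarkerSet
    poly_profile: object
    markers: MarkerSet
    segmentation_used: Segmentation
    scored: pd.DataFrame
    candidates: pd.DataFrame
    annotated: pd.DataFrame
    stage_counts: dict = field(default_factory=dict)

    def summary(self) -> str:
        m = self.model
        lines = [
            "Rare-CNV multi-sample screen",
            "=" * 40,
            f"samples: {self.stage_counts['n_samples']}   "
            f"probes: {self.stage_counts['n_probes']}",
            f"window k={m.k} d={m.d} step={m.step}  "
            f"p<{m.p_threshold} (upper tail, Beta null)",
            f"windows: {self.stage_counts['n_windows']} "
            f"(no-fit: {self.stage_counts['n_windows_no_fit']})",
            f"markers called: {self.stage_counts['markers_called']}",
            f"polymorphic probes: {self.stage_counts['polymorphic_probes']}  "
            f"polymorphic windows: {self.stage_counts['polymorphic_windows']} "
            f"(|signal|>{m.signal_threshold}, freq>{m.frequency})",
            f"markers after polymorphism filter: "
            f"{self.stage_counts['markers_after_filter']}",
            f"segments in ({m.segmenter}): {self.stage_counts['segments_in']}  "
            f"with markers: {self.stage_counts['segments_scored']}",
            f"candidates (score>{m.min_score}%, |mean|>{m.min_abs_mean}): "
            f"{self.stage_counts['candidates']}",
        ]
        if len(self.annotated) and "label" in self.annotated:
            vc = self.annotated["label"].value_counts()
            lines.append(
                "labels: " + ", ".join(f"{lab}={int(cnt)}" for lab, cnt in vc.items())
            )
        return "\n".join(lines)

    # -- plotting -----------------------------------------------------------

    def plot_window_null(self, window: int, ax=None):
        """Histogram of one window's mu values with the fitted Beta density."""
        import matplotlib.pyplot as plt
        from scipy.stats import beta as beta_dist

        if ax is None:
            _, ax = plt.subplots()
        vals = self.mu.values[window]
        vals = vals[~np.isnan(vals)]
        ax.hist(vals, bins=30, density=True, alpha=0.6, label="observed mu")
        f = self.null_fits[window]
        if f.ok:
            x = np.linspace(f.lo, f.hi, 200)
            ax.plot(
                x,
                beta_dist.pdf((x - f.lo) / (f.hi - f.lo), f.alpha, f.beta)
                / (f.hi - f.lo),
                label=f"Beta({f.alpha:.2f},{f.beta:.2f})",
            )
        ax.set_xlabel("mean Manhattan distance mu")
        ax.legend()
        return ax

    def plot_enrichment(self, positive_labels, ax=None):
        """Enrichment of positives along the density-score ranking of the
        scored segments, against the random-selection diagonal."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ranked = self.scored.sort_values(
            "density_score", ascending=False, kind="stable"
        )
        curve = _annotate.enrichment_curve(ranked, positive_labels)
        ax.plot(curve[:, 0], curve[:, 1], label="density score")
        ax.plot([0, 1], [0, 1], "--", color="grey", label="random")
        ax.set_xlabel("fraction of segments screened")
        ax.set_ylabel("fraction of positives found")
        ax.legend()
        return ax
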