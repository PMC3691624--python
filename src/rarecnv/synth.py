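"""Synthetic aCGH cohort generator with ground truth, and call evaluation.

The generator emulates the statistical structure the screen assumes in a real
exon-targeted cohort: per-probe Gaussian noise on the log10 scale, a
genome-position-correlated sinusoidal "wave" whose pattern is partially
shared across samples, batch-specific offsets on a subset of disrupted
probes (experimenter bias), probes with inflated variance, and planted CNVs —
rare ones carried by at most 1% of samples and polymorphic ones carried by
more. Everything is deterministic under the config seed.

Default condition: 100 samples, two chromosomes of 600 probes, noise sd 0.1,
one rare single-carrier deletion of 30 probes at amplitude -0.3 (log10 of a
one-copy loss with signal compression) and one 5%-carrier polymorphic
deletion of the same size.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .data import LogratioMatrix, ProbeIndex

__all__ = [
    "WaveConfig",
    "BatchConfig",
    "CnvSpec",
    "PolyCnvSpec",
    "SimConfig",
    "TruthTable",
    "simulate_cohort",
    "evaluate_calls",
    "make_probe_index",
]


@dataclass(frozen=True)
class WaveConfig:
    # default amplitude sits below the 0.07 aberration threshold even after
    # half-period segment averaging (2A/pi ~ 0.02), matching the description
    # of 0.07 as a conservative cutoff that wave artifacts do not reach
    amplitude: float = 0.03        # log10 units
    period_probes: int = 150
    per_sample_phase_sd: float = 0.5   # radians
    shared_fraction: float = 0.5   # 1.0 => identical wave in every sample


@dataclass(frozen=True)
class BatchConfig:
    count: int = 2
    disrupted_probe_fraction: float = 0.01
    offset_sd: float = 0.2         # log10 units, per (batch, disrupted probe)


@dataclass(frozen=True)
class CnvSpec:
    n_carriers: int = 1
    length_probes: int = 30
    amplitude: float = -0.3


@dataclass(frozen=True)
class PolyCnvSpec:
    carrier_fraction: float = 0.05
    length_probes: int = 30
    amplitude: float = -0.3


@dataclass(frozen=True)
class SimConfig:
    n_samples: int = 100
    chrom_layout: tuple[tuple[str, int], ...] = (("chr1", 600), ("chr2", 600))
    noise_sd: float = 0.1
    wave: WaveConfig = field(default_factory=WaveConfig)
    batches: BatchConfig = field(default_factory=BatchConfig)
    rare_cnvs: tuple[CnvSpec, ...] = (CnvSpec(),)
    poly_cnvs: tuple[PolyCnvSpec, ...] = (PolyCnvSpec(),)
    disrupted_probe_fraction: float = 0.01   # probes with inflated variance
    variance_inflation: float = 3.0
    seed: int = 0

    def validate(self):
        n = self.n_samples
        for c in self.rare_cnvs:
            if c.n_carriers > 0.01 * n:
                raise ValueError(
                    f"rare CNV with {c.n_carriers} carriers exceeds 1% of {n} samples"
                )
            if c.length_probes < 1:
                raise ValueError("CNV length must be >= 1 probe")
        for c in self.poly_cnvs:
            if not 0.0 <= c.carrier_fraction <= 1.0:
                raise ValueError("carrier_fraction must lie in [0, 1]")
            if c.carrier_fraction <= 0.01:
                raise ValueError("polymorphic CNV requires carrier_fraction > 1%")


@dataclass
class TruthTable:
    """Planted CNVs: one record per carrier sample and probe range."""

    records: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["sample", "chrom", "start_pos", "end_pos", "kind", "amplitude"]
        )
    )

    def __len__(self) -> int:
        return len(self.records)

    def rare(self) -> pd.DataFrame:
        return self.records[self.records["kind"] == "rare"]


def make_probe_index(chrom_layout, spacing_bp: int = 1000, probe_bp: int = 60) -> ProbeIndex:
    """Regularly spaced probe grid per chromosome (bp values are nominal; all
    statistics operate on probe order)."""
    ids, chroms, starts, ends = [], [], [], []
    for chrom, count in chrom_layout:
        for i in range(count):
            ids.append(f"{chrom}_p{i}")
            chroms.append(chrom)
            starts.append(i * spacing_bp)
            ends.append(i * spacing_bp + probe_bp)
    return ProbeIndex(
        probe_id=np.array(ids, dtype=object),
        chrom=np.array(chroms, dtype=object),
        start=np.array(starts, dtype=np.int64),
        end=np.array(ends, dtype=np.int64),
    )


def _place_interval(rng, blocks, length, occupied, max_tries=1000):
    chroms = list(blocks)
    for _ in range(max_tries):
        chrom = chroms[rng.integers(len(chroms))]
        lo, hi = blocks[chrom]
        if hi - lo < length:
            continue
        s = int(rng.integers(lo, hi - length + 1))
        if not occupied[s : s + length].any():
            occupied[s : s + length] = True
            return chrom, s
    raise RuntimeError("could not place a CNV without overlap; layout too crowded")


def simulate_cohort(config: SimConfig) -> tuple[ProbeIndex, LogratioMatrix, TruthTable]:
    """Draw a cohort logratio matrix with planted truth.

    The random stream is consumed in a fixed order (noise, wave phases, batch
    structure, CNV placement), so two configs differing only in an amplitude
    produce matrices differing only in that component's contribution.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    probe_index = make_probe_index(config.chrom_layout)
    n, p = config.n_samples, len(probe_index)
    blocks = probe_index.chrom_blocks()

    L = rng.normal(0.0, config.noise_sd, size=(n, p))
    n_noisy = int(round(config.disrupted_probe_fraction * p))
    noisy = rng.choice(p, size=n_noisy, replace=False) if n_noisy else np.array([], int)
    if n_noisy:
        L[:, noisy] *= config.variance_inflation

    # wave: phases are drawn regardless of amplitude so that amplitude-only
    # config changes leave the rest of the stream untouched
    w = config.wave
    phase0 = rng.uniform(0.0, 2.0 * np.pi)
    jitter = rng.normal(0.0, w.per_sample_phase_sd, size=n) * (1.0 - w.shared_fraction)
    q = np.arange(p)
    L += w.amplitude * np.sin(
        2.0 * np.pi * q[None, :] / w.period_probes + phase0 + jitter[:, None]
    )

    b = config.batches
    batch_of = rng.integers(0, max(b.count, 1), size=n)
    n_disr = int(round(b.disrupted_probe_fraction * p))
    disrupted = rng.choice(p, size=n_disr, replace=False) if n_disr else np.array([], int)
    offsets = rng.normal(0.0, b.offset_sd, size=(max(b.count, 1), n_disr))
    if n_disr:
        L[:, disrupted] += offsets[batch_of]

    occupied = np.zeros(p, dtype=bool)
    truth_rows = []
    for spec in config.rare_cnvs:
        chrom, s = _place_interval(rng, blocks, spec.length_probes, occupied)
        carriers = rng.choice(n, size=spec.n_carriers, replace=False)
        for c in carriers:
            L[c, s : s + spec.length_probes] += spec.amplitude
            truth_rows.append(
                {
                    "sample": f"S{c:03d}",
                    "chrom": chrom,
                    "start_pos": s,
                    "end_pos": s + spec.length_probes,
                    "kind": "rare",
                    "amplitude": spec.amplitude,
                }
            )
    for spec in config.poly_cnvs:
        n_car = max(int(round(spec.carrier_fraction * n)), 1)
        chrom, s = _place_interval(rng, blocks, spec.length_probes, occupied)
        carriers = rng.choice(n, size=n_car, replace=False)
        for c in carriers:
            L[c, s : s + spec.length_probes] += spec.amplitude
            truth_rows.append(
                {
                    "sample": f"S{c:03d}",
                    "chrom": chrom,
                    "start_pos": s,
                    "end_pos": s + spec.length_probes,
                    "kind": "polymorphic",
                    "amplitude": spec.amplitude,
                }
            )
    sample_ids = [f"S{i:03d}" for i in range(n)]
    truth = TruthTable(
        pd.DataFrame(
            truth_rows,
            columns=["sample", "chrom", "start_pos", "end_pos", "kind", "amplitude"],
        )
    )
    return probe_index, LogratioMatrix(L, sample_ids, probe_index), truth


def _overlap(a_s, a_e, b_s, b_e) -> int:
    return max(0, min(a_e, b_e) - max(a_s, b_s))


def evaluate_calls(
    candidates: pd.DataFrame,
    truth: TruthTable,
    sample_ids: list[str] | None = None,
    min_overlap: float = 0.5,
) -> dict:
    """Score candidate segments against the planted truth.

    A rare truth record is detected when a candidate of the same sample
    covers at least ``min_overlap`` of its probes. A candidate is a false
    positive when it overlaps no rare truth record of its sample at all.
    Specificity is measured over (rare region x non-carrier sample) trials: a
    trial fails when that sample has a candidate covering >= min_overlap of
    the region.
    """
    rare = truth.rare()
    cand_by_sample: dict[str, list[tuple[int, int]]] = {}
    if candidates is not None and len(candidates):
        for rec in candidates.itertuples(index=False):
            cand_by_sample.setdefault(rec.sample, []).append(
                (int(rec.start_pos), int(rec.end_pos))
            )
    detected = 0
    for rec in rare.itertuples(index=False):
        length = rec.end_pos - rec.start_pos
        for s, e in cand_by_sample.get(rec.sample, []):
            if _overlap(s, e, rec.start_pos, rec.end_pos) >= min_overlap * length:
                detected += 1
                break
    n_rare = len(rare)
    n_candidates = sum(len(v) for v in cand_by_sample.values())
    fp = 0
    for sample, segs in cand_by_sample.items():
        truth_here = rare[rare["sample"] == sample]
        for s, e in segs:
            if not any(
                _overlap(s, e, r.start_pos, r.end_pos) > 0
                for r in truth_here.itertuples(index=False)
            ):
                fp += 1
    trials = called = 0
    if sample_ids:
        regions = rare.drop_duplicates(["chrom", "start_pos", "end_pos"])
        for reg in regions.itertuples(index=False):
            carriers = set(rare[rare["start_pos"] == reg.start_pos]["sample"])
            length = reg.end_pos - reg.start_pos
            for sid in sample_ids:
                if sid in carriers:
                    continue
                trials += 1
                if any(
                    _overlap(s, e, reg.start_pos, reg.end_pos) >= min_overlap * length
                    for s, e in cand_by_sample.get(sid, [])
                ):
                    called += 1
    return {
        "n_rare_truth": n_rare,
        "n_detected": detected,
        "sensitivity": detected / n_rare if n_rare else float("nan"),
        "n_candidates": n_candidates,
        "n_false_positives": fp,
        "specificity": 1.0 - called / trials if trials else float("nan"),
    }
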