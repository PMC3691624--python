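"""Core containers and file I/O for the rare-CNV screen.

Internal coordinate convention: every statistic works in *genome-order probe
positions* — integers ``0..p-1`` assigned after sorting probes by
``(chromosome, start)``. Probe ranges are half-open ``[start_pos, end_pos)``.
Base-pair coordinates appear only at the file boundary: BED-style 0-based
half-open on output, SEG input interpreted as 1-based inclusive (the common
DNAcopy dialect).
"""

from __future__ import annotations

import os
import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

__all__ = [
    "ProbeIndex",
    "LogratioMatrix",
    "Segmentation",
    "IntervalDB",
    "read_logratio_table",
    "read_segmentation",
    "read_interval_db",
    "write_logratio_table",
    "write_segmentation",
    "write_markers_bed",
    "write_scored_table",
    "read_scored_table",
    "write_outputs",
]

SEG_COLUMNS = ["ID", "chrom", "loc.start", "loc.end", "num.mark", "seg.mean"]


def _chrom_sort_key(chrom: str):
    """Natural chromosome order: chr2 before chr10, autosomes before X/Y."""
    body = chrom[3:] if chrom.lower().startswith("chr") else chrom
    if body.isdigit():
        return (0, int(body), "")
    special = {"X": 100, "Y": 101, "M": 102, "MT": 102}
    if body.upper() in special:
        return (0, special[body.upper()], "")
    return (1, 0, body)


@dataclass(frozen=True)
class ProbeIndex:
    """Genome-ordered probe annotation.

    The array index *is* the genome-order position: probes are sorted by
    (chromosome, start) and positions run 0..p-1.
    """

    probe_id: np.ndarray
    chrom: np.ndarray
    start: np.ndarray
    end: np.ndarray

    def __post_init__(self):
        p = len(self.probe_id)
        if not (len(self.chrom) == len(self.start) == len(self.end) == p):
            raise ValueError("probe annotation arrays must have equal length")
        if len(set(self.probe_id.tolist())) != p:
            raise ValueError("duplicate probe_id in probe index")
        if np.any(self.end <= self.start):
            raise ValueError("every probe must satisfy end > start")
        for lo, hi in self.chrom_blocks().values():
            if np.any(np.diff(self.start[lo:hi]) <= 0):
                raise ValueError("probe starts must be strictly increasing per chromosome")

    def __len__(self) -> int:
        return len(self.probe_id)

    @property
    def n_probes(self) -> int:
        return len(self)

    def chrom_blocks(self) -> dict[str, tuple[int, int]]:
        """Contiguous position range [lo, hi) occupied by each chromosome."""
        blocks: dict[str, tuple[int, int]] = {}
        chroms = self.chrom
        lo = 0
        for i in range(1, len(chroms) + 1):
            if i == len(chroms) or chroms[i] != chroms[lo]:
                if chroms[lo] in blocks:
                    raise ValueError(f"chromosome {chroms[lo]} is not contiguous")
                blocks[str(chroms[lo])] = (lo, i)
                lo = i
        return blocks

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ProbeIndex":
        """Build from a frame with chrom/start/end/probe_id columns, sorting
        rows into genome order."""
        key = df["chrom"].map(_chrom_sort_key)
        order = pd.DataFrame({"k": key, "s": df["start"]}).sort_values(
            ["k", "s"], kind="stable"
        ).index
        df = df.loc[order]
        return cls(
            probe_id=df["probe_id"].to_numpy(dtype=object),
            chrom=df["chrom"].to_numpy(dtype=object),
            start=df["start"].to_numpy(dtype=np.int64),
            end=df["end"].to_numpy(dtype=np.int64),
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": self.chrom,
                "start": self.start,
                "end": self.end,
                "probe_id": self.probe_id,
            }
        )


@dataclass
class LogratioMatrix:
    """Cohort matrix of per-probe log10(test/reference) ratios.

    ``values`` is samples x probes; missing measurements are NaN.
    """

    values: np.ndarray
    sample_ids: list[str]
    probe_index: ProbeIndex

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("logratio values must be a 2-D matrix")
        n, p = self.values.shape
        if n != len(self.sample_ids):
            raise ValueError("row count must equal number of sample ids")
        if p != len(self.probe_index):
            raise ValueError("column count must equal probe index length")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_probes(self) -> int:
        return self.values.shape[1]


#: columns of the internal segmentation frame (probe coordinates)
SEGMENTATION_COLUMNS = ["sample", "chrom", "start_pos", "end_pos", "n_probes", "seg_mean"]


@dataclass
class Segmentation:
    """Per-sample partition of the probe sequence into constant-mean intervals.

    Backed by a DataFrame with columns sample, chrom, start_pos, end_pos
    (half-open genome-order probe range), n_probes, seg_mean.
    """

    records: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=SEGMENTATION_COLUMNS)
    )

    def __post_init__(self):
        missing = [c for c in SEGMENTATION_COLUMNS if c not in self.records.columns]
        if missing:
            raise ValueError(f"segmentation frame missing columns: {missing}")
        self.records = self.records.reset_index(drop=True)
        self.validate()

    def validate(self):
        df = self.records
        if len(df) == 0:
            return
        if np.any(df["end_pos"].to_numpy() - df["start_pos"].to_numpy() < 1):
            raise ValueError("segments must span at least one probe")
        if np.any(
            df["n_probes"].to_numpy() != df["end_pos"].to_numpy() - df["start_pos"].to_numpy()
        ):
            raise ValueError("n_probes must equal end_pos - start_pos")
        for sample, sub in df.groupby("sample", sort=False):
            sub = sub.sort_values("start_pos")
            s = sub["start_pos"].to_numpy()
            e = sub["end_pos"].to_numpy()
            if np.any(s[1:] < e[:-1]):
                raise ValueError(f"overlapping segments for sample {sample!r}")

    def __len__(self) -> int:
        return len(self.records)

    def for_sample(self, sample_id: str) -> pd.DataFrame:
        return self.records[self.records["sample"] == sample_id]

    @property
    def samples(self) -> list[str]:
        return list(dict.fromkeys(self.records["sample"]))


@dataclass
class IntervalDB:
    """A named track of genomic intervals (ISCA/DGV/GAD-style roles)."""

    name: str
    intervals: pd.DataFrame  # chrom, start, end, record_id

    def __post_init__(self):
        if len(self.intervals) and np.any(
            self.intervals["start"].to_numpy() >= self.intervals["end"].to_numpy()
        ):
            raise ValueError("interval database requires start < end")
        self._trees: dict[str, IntervalTree] | None = None

    def __len__(self) -> int:
        return len(self.intervals)

    def tree(self, chrom: str) -> IntervalTree:
        if self._trees is None:
            trees: dict[str, IntervalTree] = {}
            for c, sub in self.intervals.groupby("chrom", sort=False):
                trees[str(c)] = IntervalTree.from_tuples(
                    zip(sub["start"], sub["end"], sub["record_id"])
                )
            self._trees = trees
        return self._trees.get(chrom, IntervalTree())


# ---------------------------------------------------------------------------
# readers


def read_logratio_table(path) -> tuple[ProbeIndex, LogratioMatrix]:
    """Read the cohort logratio TSV (chrom, start, end, probe_id, one column
    per sample; probe rows in any order).

    Rows are re-sorted to genome order and the matrix is transposed to
    samples x probes. Empty cells become NaN; any other non-numeric cell is an
    error naming the offending row and column.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str}, keep_default_na=False)
    required = ["chrom", "start", "end", "probe_id"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"logratio table missing required column(s): {missing}")
    if df["probe_id"].duplicated().any():
        dup = df["probe_id"][df["probe_id"].duplicated()].iloc[0]
        raise ValueError(f"duplicate probe_id {dup!r} in logratio table")
    sample_cols = [c for c in df.columns if c not in required]
    if not sample_cols:
        raise ValueError("logratio table contains no sample columns")
    for col in sample_cols:
        raw = df[col].astype(str).str.strip()
        numeric = pd.to_numeric(raw.replace({"": None, "NA": None, "nan": None}),
                                errors="coerce")
        bad = numeric.isna() & ~raw.isin(["", "NA", "nan"])
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"non-numeric logratio {raw.iloc[row]!r} at row {row} column {col!r}"
            )
        df[col] = numeric
    df["start"] = pd.to_numeric(df["start"]).astype(np.int64)
    df["end"] = pd.to_numeric(df["end"]).astype(np.int64)
    probe_index = ProbeIndex.from_dataframe(df[required])
    # reorder sample columns to the sorted probe order
    key = df["chrom"].map(_chrom_sort_key)
    order = pd.DataFrame({"k": key, "s": df["start"]}).sort_values(
        ["k", "s"], kind="stable"
    ).index
    values = df.loc[order, sample_cols].to_numpy(dtype=float).T
    return probe_index, LogratioMatrix(values, list(sample_cols), probe_index)


def write_logratio_table(path, L: LogratioMatrix):
    df = L.probe_index.to_dataframe()
    for i, s in enumerate(L.sample_ids):
        df[s] = L.values[i]
    df.to_csv(path, sep="\t", index=False, float_format="%.6f", na_rep="")


def read_segmentation(path, probe_index: ProbeIndex) -> Segmentation:
    """Read a SEG-style TSV (ID, chrom, loc.start, loc.end, num.mark, seg.mean;
    bp 1-based inclusive) and map each segment to its genome-order probe range.

    A probe belongs to a segment when its start bp lies in
    ``[loc.start-1, loc.end)``. Segments matching no probe are dropped with a
    warning; n_probes is recomputed from the mapping.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in SEG_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"segmentation file missing required column(s): {missing}")
    df = df[SEG_COLUMNS]
    blocks = probe_index.chrom_blocks()
    out = []
    n_dropped = 0
    for rec in df.itertuples(index=False):
        chrom = getattr(rec, "chrom")
        if chrom not in blocks:
            n_dropped += 1
            continue
        lo, hi = blocks[chrom]
        starts = probe_index.start[lo:hi]
        s_bp = int(getattr(rec, "_2"))  # loc.start
        e_bp = int(getattr(rec, "_3"))  # loc.end
        start_pos = lo + int(np.searchsorted(starts, s_bp - 1, side="left"))
        end_pos = lo + int(np.searchsorted(starts, e_bp, side="left"))
        if end_pos <= start_pos:
            n_dropped += 1
            continue
        out.append(
            {
                "sample": str(getattr(rec, "ID")),
                "chrom": chrom,
                "start_pos": start_pos,
                "end_pos": end_pos,
                "n_probes": end_pos - start_pos,
                "seg_mean": float(getattr(rec, "_5")),
            }
        )
    if n_dropped:
        warnings.warn(
            f"{n_dropped} segment(s) matched no probe and were dropped", stacklevel=2
        )
    return Segmentation(pd.DataFrame(out, columns=SEGMENTATION_COLUMNS))


def write_segmentation(path, seg: Segmentation, probe_index: ProbeIndex):
    """Write the internal segmentation back out in the SEG dialect
    (bp, 1-based inclusive)."""
    df = seg.records
    rows = pd.DataFrame(
        {
            "ID": df["sample"],
            "chrom": df["chrom"],
            "loc.start": probe_index.start[df["start_pos"].to_numpy(int)] + 1
            if len(df)
            else pd.Series(dtype=np.int64),
            "loc.end": probe_index.end[df["end_pos"].to_numpy(int) - 1]
            if len(df)
            else pd.Series(dtype=np.int64),
            "num.mark": df["n_probes"],
            "seg.mean": df["seg_mean"],
        }
    )
    rows.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_interval_db(path, name: str) -> IntervalDB:
    """Read a BED3+ file (0-based half-open) into an interval database.

    Lines with start >= end are skipped and counted in a warning; a fourth
    column, when present, supplies the record id.
    """
    rows = []
    n_skipped = 0
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = re.split(r"\t|\s+", line)
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if start >= end:
                n_skipped += 1
                continue
            record_id = parts[3] if len(parts) > 3 else f"{name}_{i}"
            rows.append({"chrom": chrom, "start": start, "end": end, "record_id": record_id})
    if n_skipped:
        warnings.warn(f"{n_skipped} malformed BED line(s) skipped in {name}", stacklevel=2)
    return IntervalDB(
        name,
        pd.DataFrame(rows, columns=["chrom", "start", "end", "record_id"]),
    )


# ---------------------------------------------------------------------------
# pipeline outputs

MARKER_HEADER = "#chrom\tstart\tend\tsample\tpvalue"


def write_markers_bed(path, markers, probe_index: ProbeIndex):
    """Write rare-CNV markers as BED-like lines: the bp span of each flagged
    window plus the sample and the marker p-value."""
    k = markers.k
    with open(path, "w") as fh:
        fh.write(MARKER_HEADER + "\n")
        df = markers.records.sort_values(["window", "sample"], kind="stable")
        for rec in df.itertuples(index=False):
            q = int(rec.window)
            fh.write(
                f"{probe_index.chrom[q]}\t{probe_index.start[q]}\t"
                f"{probe_index.end[q + k - 1]}\t{rec.sample}\t{rec.pvalue:.6g}\n"
            )


def write_scored_table(path, scored: pd.DataFrame):
    scored.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_scored_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str, "sample": str})


def write_outputs(markers, scored: pd.DataFrame, probe_index: ProbeIndex, out_dir):
    """Write the standard result pair: the BED-like marker file and the
    scored-segment TSV, into ``out_dir``."""
    ensure_dir(out_dir)
    write_markers_bed(os.path.join(out_dir, "markers.bed"), markers, probe_index)
    write_scored_table(os.path.join(out_dir, "scored.tsv"), scored)


def ensure_dir(path):
    os.makedirs(path, exist_ok=True)
    if not os.access(path, os.W_OK):
        raise OSError(f"output directory {path!r} is not writable")
    return path
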