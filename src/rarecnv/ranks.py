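"""Column-wise pseudo-rank transform of the cohort logratio matrix.

For every probe (column) the n sample logratios are replaced by their rank
among the samples, divided by (m+1) where m is the column's observed count.
The resulting pseudo-ranks live strictly inside (0, 1) and are invariant under
any strictly increasing per-column transformation of the raw logratios — in
particular under additive genome-position-correlated "wave" artifacts and
per-probe experimenter bias shared across samples, which this transform is
designed to neutralise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .data import LogratioMatrix, ProbeIndex

__all__ = ["PseudoRankMatrix", "pseudo_rank"]


@dataclass
class PseudoRankMatrix:
    """Samples x probes matrix of pseudo-ranks in (0, 1); NaN where the
    logratio was missing. Ties receive midranks, which conserves the column
    rank sum (a fully observed column sums to exactly m/2)."""

    values: np.ndarray
    sample_ids: list[str]
    probe_index: ProbeIndex
    tie_policy: str = "midrank"

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_probes(self) -> int:
        return self.values.shape[1]


def pseudo_rank(L: LogratioMatrix) -> PseudoRankMatrix:
    """Rank every column of the logratio matrix and divide by (m+1).

    m is the per-column count of non-missing entries, so observed marginals
    are uniform on {1/(m+1), ..., m/(m+1)} regardless of missingness. Columns
    with fewer than two observed values carry no ranking information and are
    flagged entirely missing (with a warning).
    """
    if L.n_samples < 2:
        raise ValueError("pseudo-rank transform requires at least 2 samples")
    X = L.values
    m = np.sum(~np.isnan(X), axis=0).astype(float)
    ranks = rankdata(X, method="average", axis=0, nan_policy="omit")
    with np.errstate(invalid="ignore"):
        R = ranks / (m + 1.0)[None, :]
    thin = m < 2
    if np.any(thin):
        R[:, thin] = np.nan
        warnings.warn(
            f"{int(thin.sum())} column(s) with fewer than 2 observed values "
            "were flagged missing",
            stacklevel=2,
        )
    return PseudoRankMatrix(R, list(L.sample_ids), L.probe_index)
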