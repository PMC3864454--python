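"""Replicate pooling, quantile normalization and the raw-count filter.

The analysis order mirrors the experimental pipeline: raw replicate counts
are pooled by summation into one column per (circadian time, day), the
pooled 12-point series are quantile normalized across timepoints, and the
expression filter operates on the *raw* pooled counts while the amplitude
filter (see :mod:`trapcycle.cycling_calls`) uses normalized values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ContractError
from .io_tables import CountMatrix, SampleMeta

__all__ = [
    "FilterThresholds",
    "pool_replicates",
    "quantile_normalize",
    "mean_count_filter",
]


@dataclass(frozen=True)
class FilterThresholds:
    """Cutoffs applied when combining detector output into cycling calls.

    min_mean_raw_count : mean raw pooled count across timepoints, inclusive.
    min_rel_amplitude  : ½(max−min)/median of the normalized series, inclusive.
    p_harmonic, p_rank : per-detector significance cutoffs, strict (<).
    """

    min_mean_raw_count: float = 20.0
    min_rel_amplitude: float = 0.5
    p_harmonic: float = 0.021
    p_rank: float = 0.015

    def __post_init__(self) -> None:
        if self.min_mean_raw_count <= 0 or self.min_rel_amplitude <= 0:
            raise ContractError("count/amplitude thresholds must be positive")
        for name in ("p_harmonic", "p_rank"):
            p = getattr(self, name)
            if not (0.0 < p < 1.0):
                raise ContractError(f"{name}={p} must lie in (0, 1)")


def pool_replicates(
    m: CountMatrix, meta: list[SampleMeta], strategy: str = "sum"
) -> tuple[CountMatrix, list[SampleMeta]]:
    """Sum raw replicate counts into one column per (ct, day).

    Returns the pooled raw matrix (columns ordered by absolute time) together
    with its synthesized one-replicate sample metadata.  Total reads per gene
    are conserved.
    """
    if m.normalized:
        raise ContractError("pool_replicates requires a raw count matrix")
    if strategy != "sum":
        raise ContractError(f"unknown pooling strategy {strategy!r}")
    by_id = {s.sample_id: s for s in meta}
    missing = [sid for sid in m.sample_ids if sid not in by_id]
    if missing:
        raise ContractError(f"samples absent from metadata: {missing[:5]}")
    groups: dict[tuple[float, int], list[str]] = {}
    for sid in m.sample_ids:
        groups.setdefault(by_id[sid].timepoint, []).append(sid)
    ordered = sorted(groups, key=lambda tp: 24.0 * (tp[1] - 1) + tp[0])
    pooled_cols = {}
    pooled_meta = []
    for ct, day in ordered:
        cols = groups[(ct, day)]
        name = f"d{day}_ct{ct:g}"
        pooled_cols[name] = m.values[cols].sum(axis=1)
        pooled_meta.append(SampleMeta(sample_id=name, ct=ct, day=day, replicate="pooled"))
    pooled = pd.DataFrame(pooled_cols, index=m.values.index)
    return CountMatrix(values=pooled, normalized=False), pooled_meta


def quantile_normalize(m: CountMatrix) -> CountMatrix:
    """Force every sample to the same value distribution.

    The value at rank k in each sample becomes the across-sample mean of the
    rank-k values; ties within a sample receive the mean of the normalized
    values over the ranks they occupy.  This is the classic rank-mean
    quantile normalization used for expression matrices.
    """
    if m.shape[1] < 2:
        raise ContractError("quantile normalization needs at least 2 samples")
    arr = m.values.to_numpy(dtype=float)
    n_genes, n_samples = arr.shape
    order = np.argsort(arr, axis=0, kind="stable")
    sorted_vals = np.take_along_axis(arr, order, axis=0)
    ref = sorted_vals.mean(axis=1)  # mean of rank-k values across samples
    out = np.empty_like(arr)
    for j in range(n_samples):
        col_sorted = sorted_vals[:, j]
        # Assign ref by rank, then average ref over runs of tied input values.
        assigned = ref.copy()
        start = 0
        for end in range(1, n_genes + 1):
            if end == n_genes or col_sorted[end] != col_sorted[start]:
                if end - start > 1:
                    assigned[start:end] = assigned[start:end].mean()
                start = end
        out[order[:, j], j] = assigned
    values = pd.DataFrame(out, index=m.values.index, columns=m.values.columns)
    return CountMatrix(values=values, normalized=True)


def mean_count_filter(m: CountMatrix, thresholds: FilterThresholds) -> pd.Series:
    """Boolean mask: gene passes iff its mean raw pooled count across all
    timepoint columns is at least ``min_mean_raw_count`` (inclusive)."""
    if m.normalized:
        raise ContractError("mean_count_filter requires raw pooled counts")
    return m.values.mean(axis=1) >= thresholds.min_mean_raw_count
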