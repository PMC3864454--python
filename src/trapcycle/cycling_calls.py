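"""Combine the two detectors and the expression/amplitude filters into final calls.

A gene is finally called cycling iff (a) at least one detector is
significant at its cutoff (strict <), (b) its mean raw pooled count across
the 12 timepoints is at least the count threshold (inclusive ≥), and (c) its
relative cycling amplitude — ½(max−min)/median of the normalized series —
is at least the amplitude threshold (inclusive ≥).  The union/intersection
accounting of the two detectors and the expected-false-positive arithmetic
q × n_called are reported alongside.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .detect_harmonic import HarmonicTestResult
from .detect_rank import RankTestResult
from .errors import ContractError
from .io_tables import CountMatrix
from .preprocess import FilterThresholds

__all__ = [
    "CyclingCall",
    "OverlapSummary",
    "rel_amplitude",
    "call_cyclers",
    "overlap_summary",
    "expected_false_positives",
    "calls_to_frame",
]


@dataclass(frozen=True)
class CyclingCall:
    gene_id: str
    mean_raw_count: float
    rel_amplitude: float
    p_rank: float
    p_harmonic: float
    called_by: frozenset[str]  # subset of {"rank", "harmonic"}
    final_call: bool
    phase: float  # peak CT hours of the calling detector (harmonic preferred)


@dataclass(frozen=True)
class OverlapSummary:
    n_rank_only: int
    n_harmonic_only: int
    n_both: int

    @property
    def n_union(self) -> int:
        return self.n_rank_only + self.n_harmonic_only + self.n_both


def rel_amplitude(values: np.ndarray | list[float]) -> float:
    """Relative cycling amplitude ½(max − min)/median of a series.

    A positive swing over a zero median is reported as +inf (maximally
    relatively variable); an all-zero series has amplitude 0.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ContractError("rel_amplitude: empty series")
    spread = 0.5 * (float(v.max()) - float(v.min()))
    med = float(np.median(v))
    if spread == 0.0:
        return 0.0
    if med == 0.0:
        return math.inf
    return spread / med


def call_cyclers(
    rank: list[RankTestResult],
    harmonic: list[HarmonicTestResult],
    raw: CountMatrix,
    norm: CountMatrix,
    thresholds: FilterThresholds,
) -> list[CyclingCall]:
    """Apply detector cutoffs and both filters over a common gene set.

    All four inputs must cover exactly the same genes.  The reported phase
    comes from the harmonic fit when that detector calls the gene, else from
    the rank test.
    """
    rank_by = {r.gene_id: r for r in rank}
    harm_by = {r.gene_id: r for r in harmonic}
    genes = raw.gene_ids
    for name, ids in (
        ("rank results", set(rank_by)),
        ("harmonic results", set(harm_by)),
        ("normalized matrix", set(norm.gene_ids)),
    ):
        if ids != set(genes):
            raise ContractError(f"gene set mismatch between raw matrix and {name}")
    calls = []
    for g in genes:
        rr, hr = rank_by[g], harm_by[g]
        mean_raw = float(raw.values.loc[g].mean())
        amp = rel_amplitude(norm.values.loc[g].to_numpy(dtype=float))
        called = set()
        if rr.p < thresholds.p_rank:
            called.add("rank")
        if hr.p < thresholds.p_harmonic:
            called.add("harmonic")
        final = (
            bool(called)
            and mean_raw >= thresholds.min_mean_raw_count
            and amp >= thresholds.min_rel_amplitude
        )
        phase = hr.phase if "harmonic" in called else rr.best_phase
        calls.append(
            CyclingCall(
                gene_id=g,
                mean_raw_count=mean_raw,
                rel_amplitude=amp,
                p_rank=rr.p,
                p_harmonic=hr.p,
                called_by=frozenset(called),
                final_call=final,
                phase=float(phase) if not math.isnan(phase) else 0.0,
            )
        )
    return calls


def overlap_summary(calls: list[CyclingCall]) -> OverlapSummary:
    """Partition finally-called genes by which detector(s) found them."""
    n_rank = n_harm = n_both = 0
    for c in calls:
        if not c.final_call:
            continue
        if c.called_by == {"rank"}:
            n_rank += 1
        elif c.called_by == {"harmonic"}:
            n_harm += 1
        elif c.called_by == {"rank", "harmonic"}:
            n_both += 1
    return OverlapSummary(n_rank_only=n_rank, n_harmonic_only=n_harm, n_both=n_both)


def expected_false_positives(q_at_cutoff: float, n_called: int) -> int:
    """Expected number of false positives among the calls: round(q × n).

    E.g. an FDR of 0.148 over 1,255 calls corresponds to about 186 expected
    false positives.
    """
    if not (0.0 <= q_at_cutoff <= 1.0):
        raise ContractError("q must lie in [0, 1]")
    return int(round(q_at_cutoff * n_called))


def calls_to_frame(calls: list[CyclingCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": [c.gene_id for c in calls],
            "mean_raw_count": [c.mean_raw_count for c in calls],
            "rel_amplitude": [c.rel_amplitude for c in calls],
            "p_rank": [c.p_rank for c in calls],
            "p_harmonic": [c.p_harmonic for c in calls],
            "called_by": ["+".join(sorted(c.called_by)) for c in calls],
            "final_call": [c.final_call for c in calls],
            "phase": [c.phase for c in calls],
        }
    )
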