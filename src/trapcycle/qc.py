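"""Dataset quality control and the ΔΔCt helper.

Two QC layers are implemented.  Replicate agreement computes one Pearson r
per timepoint between the two biological replicates across all genes; a
well-behaved experiment shows r > 0.9 throughout.  The "best cosine
correlation" screen scores each single-day 6-point series of a control gene
against a bank of phase-shifted 24-h cosine curves (48 curves at 0.5-h
steps) and takes the best r; a day-dataset in which known transcriptional
cyclers fail this screen is dropped from analysis.

``ddct_relative_abundance`` implements the standard ΔΔCt quantification used
for qPCR validation series: one PCR cycle equals a two-fold abundance change,
relative to a reference transcript (e.g. Rp49) and a chosen baseline
timepoint.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ContractError, ValidationError
from .io_tables import CountMatrix, SampleMeta

__all__ = [
    "ReplicatePair",
    "CosineQCResult",
    "replicate_correlation",
    "reference_bank",
    "best_cosine_correlation",
    "control_gene_qc",
    "ddct_relative_abundance",
]


@dataclass(frozen=True)
class ReplicatePair:
    """Pearson correlation between the two replicates at one timepoint."""

    timepoint: tuple[float, int]  # (ct, day)
    r: float
    n_genes: int


@dataclass(frozen=True)
class CosineQCResult:
    """Best correlation of a series against the phase-shifted cosine bank.

    ``undefined`` is set for zero-variance (constant) series, where a
    correlation coefficient does not exist; ``best_r`` is then NaN.
    """

    gene_id: str
    best_r: float
    best_phase: float
    undefined: bool = False


def replicate_correlation(m: CountMatrix, meta: list[SampleMeta]) -> list[ReplicatePair]:
    """One product-moment correlation per timepoint across all genes.

    Requires exactly two replicates at every (ct, day).
    """
    by_id = {s.sample_id: s for s in meta}
    groups: dict[tuple[float, int], list[str]] = {}
    for sid in m.sample_ids:
        if sid not in by_id:
            raise ContractError(f"sample {sid!r} absent from metadata")
        groups.setdefault(by_id[sid].timepoint, []).append(sid)
    out = []
    for tp in sorted(groups, key=lambda t: 24.0 * (t[1] - 1) + t[0]):
        cols = groups[tp]
        if len(cols) != 2:
            raise ContractError(
                f"timepoint (ct={tp[0]}, day={tp[1]}) has {len(cols)} replicates, expected 2"
            )
        a = m.values[cols[0]].to_numpy(dtype=float)
        b = m.values[cols[1]].to_numpy(dtype=float)
        if len(a) < 3:
            raise ContractError("replicate correlation needs at least 3 genes")
        r = float(np.corrcoef(a, b)[0, 1])
        out.append(ReplicatePair(timepoint=tp, r=r, n_genes=len(a)))
    return out


def reference_bank(
    period: float, phase_step: float, times: np.ndarray | list[float]
) -> tuple[np.ndarray, np.ndarray]:
    """Bank of cosine reference curves cos(2π(t−φ)/period), φ on a phase grid.

    Returns ``(phases, curves)`` with ``curves[i, j] = cos(2π(t_j − φ_i)/period)``.
    ``phase_step`` must divide the period exactly; period 24 h at 0.5-h steps
    gives the canonical 48-curve bank.
    """
    n = period / phase_step
    if abs(n - round(n)) > 1e-9:
        raise ContractError(f"phase_step {phase_step} does not divide period {period}")
    phases = np.arange(round(n)) * phase_step
    t = np.asarray(times, dtype=float)
    curves = np.cos(2.0 * np.pi * (t[None, :] - phases[:, None]) / period)
    return phases, curves


def best_cosine_correlation(
    series: np.ndarray | list[float],
    times: np.ndarray | list[float],
    period: float = 24.0,
    phase_step: float = 0.5,
    gene_id: str = "",
) -> CosineQCResult:
    """Best Pearson r of a series against the phase-shifted cosine bank.

    Scans every curve in the bank, returns the highest r and the phase that
    attains it (smallest phase on ties).  A constant series has no defined
    correlation and is returned with the ``undefined`` flag.
    """
    y = np.asarray(series, dtype=float)
    t = np.asarray(times, dtype=float)
    if len(y) != len(t):
        raise ContractError("series and times must have equal length")
    if len(y) < 3:
        raise ContractError("best cosine correlation needs at least 3 timepoints")
    if np.ptp(y) == 0.0:
        return CosineQCResult(gene_id=gene_id, best_r=math.nan, best_phase=0.0, undefined=True)
    phases, curves = reference_bank(period, phase_step, t)
    yc = y - y.mean()
    cc = curves - curves.mean(axis=1, keepdims=True)
    denom = np.sqrt((yc**2).sum() * (cc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        rs = (cc @ yc) / denom
    rs = np.where(np.isfinite(rs), rs, -np.inf)  # degenerate curve sampling
    best = int(np.argmax(rs))  # argmax returns the first (smallest) phase on ties
    return CosineQCResult(
        gene_id=gene_id, best_r=float(rs[best]), best_phase=float(phases[best])
    )


def control_gene_qc(
    m: CountMatrix,
    times: np.ndarray | list[float],
    controls: list[str],
    min_best_r: float = 0.8,
    period: float = 24.0,
    phase_step: float = 0.5,
) -> tuple[bool, list[CosineQCResult]]:
    """Screen one day-dataset using known cycling control genes.

    Computes the best cosine correlation for each control gene over the
    within-day series and passes the dataset iff the median best r is at
    least ``min_best_r``.  An undefined (constant-series) r counts as −1 in
    the median: a flat control gene is evidence against dataset quality.
    """
    if not controls:
        raise ContractError("control gene list is empty")
    missing = [g for g in controls if g not in m.values.index]
    if missing:
        raise ValidationError(f"control genes absent from matrix: {missing}")
    results = [
        best_cosine_correlation(
            m.values.loc[g].to_numpy(dtype=float), times, period, phase_step, gene_id=g
        )
        for g in controls
    ]
    rs = [(-1.0 if res.undefined else res.best_r) for res in results]
    passed = bool(np.median(rs) >= min_best_r)
    return passed, results


def ddct_relative_abundance(
    ct_target: list[float], ct_reference: list[float], baseline_index: int
) -> np.ndarray:
    """Relative abundance 2^(−ΔΔCt) from qPCR threshold cycles.

    ΔCt_i = Ct(target)_i − Ct(reference)_i, ΔΔCt_i = ΔCt_i − ΔCt_baseline;
    the baseline point has relative abundance 1 and each cycle below the
    baseline doubles the value.
    """
    a = np.asarray(ct_target, dtype=float)
    b = np.asarray(ct_reference, dtype=float)
    if a.shape != b.shape:
        raise ContractError("target and reference Ct lists must have equal length")
    if not (0 <= baseline_index < len(a)):
        raise ContractError(f"baseline_index {baseline_index} out of range")
    dct = a - b
    return np.power(2.0, -(dct - dct[baseline_index]))
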