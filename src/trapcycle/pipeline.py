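"""End-to-end orchestration: QC → pool → normalize → detect → call → phases.

Every stage writes its TSV product into the output directory, and a JSON
run log records the config hash, the seed, and gene counts entering and
leaving each filter, so the union/intersection accounting of the final
calls can be reconstructed from the log alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io_tables, preprocess, qc
from .config import PipelineConfig
from .cycling_calls import call_cyclers, calls_to_frame, expected_false_positives, overlap_summary
from .detect_harmonic import harmonic_test_experiment
from .detect_rank import rank_test
from .errors import TrapcycleError
from .io_tables import CountMatrix, SampleMeta, write_results
from .phase_analysis import order_by_phase, summarize_phases
from .synthetic_data import generate

logger = logging.getLogger("trapcycle")

__all__ = ["run_pipeline", "analyze_counts"]


def analyze_counts(counts: CountMatrix, meta: list[SampleMeta], config: PipelineConfig | None = None):
    """In-memory analysis: pool → normalize → both detectors → cycling calls.

    Returns a dict with keys ``calls``, ``rank``, ``harmonic``, ``pooled``,
    ``norm`` and ``times``.  This is the computational core of
    :func:`run_pipeline` without any file I/O.
    """
    from .config import PipelineConfig as _PC

    config = config or _PC()
    pooled, pooled_meta = preprocess.pool_replicates(counts, meta)
    norm = preprocess.quantile_normalize(pooled)
    times = np.array([m.absolute_time for m in pooled_meta])
    vals = norm.values.to_numpy(dtype=float)
    genes = norm.gene_ids
    rank_results = [
        rank_test(vals[i], times, period=config.rank.period,
                  phase_step=config.rank.phase_step, gene_id=genes[i])
        for i in range(len(genes))
    ]
    harm_results = harmonic_test_experiment(
        vals, times, genes,
        order=config.harmonic.order,
        period_range=tuple(config.harmonic.period_range),
        methods=tuple(config.harmonic.methods),
    )
    calls = call_cyclers(rank_results, harm_results, pooled, norm, config.filters)
    return {
        "calls": calls,
        "rank": rank_results,
        "harmonic": harm_results,
        "pooled": pooled,
        "norm": norm,
        "times": times,
    }


def _zscore_rows(df: pd.DataFrame) -> pd.DataFrame:
    arr = df.to_numpy(dtype=float)
    mu = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return pd.DataFrame((arr - mu) / sd, index=df.index, columns=df.columns)


def run_pipeline(
    config: PipelineConfig,
    outdir: str | Path,
    seed: int | None = None,
    counts: CountMatrix | None = None,
    meta: list[SampleMeta] | None = None,
    simulate: bool = False,
) -> dict:
    """Execute the full analysis and write all products under ``outdir``.

    Either pass a raw count matrix + sample sheet, or set ``simulate`` to
    draw them from the config's simulation spec.  Returns the run log as a
    dict (also written to ``run_log.json``).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: dict = {"config_hash": config.config_hash(), "stages": {}}

    sim = config.simulate
    if seed is not None:
        sim = dataclasses.replace(sim, seed=seed)
    log["seed"] = sim.seed

    if simulate:
        logger.info("simulating %d genes", sim.n_genes)
        counts, meta, truth = generate(sim)
        io_tables.write_counts(counts, outdir / "counts.tsv")
        io_tables.write_sample_sheet(meta, outdir / "sample_sheet.tsv")
        write_results(truth.table, outdir / "truth.tsv")
        log["stages"]["simulate"] = {"n_genes": sim.n_genes, "n_samples": len(meta)}
    if counts is None or meta is None:
        raise TrapcycleError("run_pipeline needs input tables or simulate=True")
    io_tables.validate_counts_against_meta(counts, meta)

    # --- QC: replicate agreement (when the design has exactly 2 replicates)
    n_reps = len({m.replicate for m in meta})
    if n_reps == 2:
        pairs = qc.replicate_correlation(counts, meta)
        write_results(
            pd.DataFrame(
                {
                    "ct": [p.timepoint[0] for p in pairs],
                    "day": [p.timepoint[1] for p in pairs],
                    "r": [p.r for p in pairs],
                    "n_genes": [p.n_genes for p in pairs],
                }
            ),
            outdir / "qc_replicates.tsv",
        )
        worst = min(p.r for p in pairs)
        log["stages"]["qc_replicates"] = {"min_r": worst, "threshold": config.qc.min_replicate_r}
        if worst < config.qc.min_replicate_r:
            logger.warning("replicate correlation %.3f below %.2f", worst, config.qc.min_replicate_r)

    # --- pooling + normalization
    pooled, pooled_meta = preprocess.pool_replicates(counts, meta)
    io_tables.write_counts(pooled, outdir / "counts_pooled.tsv")
    norm = preprocess.quantile_normalize(pooled)
    io_tables.write_counts(norm, outdir / "counts_normalized.tsv")
    log["stages"]["preprocess"] = {
        "n_genes": pooled.shape[0],
        "n_timepoints": pooled.shape[1],
    }

    # --- optional control-gene cosine QC, per day
    if config.qc.controls:
        qc_rows = []
        for day in sorted({m.day for m in pooled_meta}):
            day_meta = [m for m in pooled_meta if m.day == day]
            cols = [m.sample_id for m in day_meta]
            cts = [m.ct for m in day_meta]
            sub = CountMatrix(pooled.values[cols], normalized=False)
            passed, results = qc.control_gene_qc(
                sub, cts, list(config.qc.controls), config.qc.min_best_r,
                config.qc.period, config.qc.phase_step,
            )
            for r in results:
                qc_rows.append(
                    {"day": day, "gene_id": r.gene_id, "best_r": r.best_r,
                     "best_phase": r.best_phase, "undefined": r.undefined}
                )
            qc_rows.append({"day": day, "gene_id": "_summary", "best_r": np.nan,
                            "best_phase": np.nan, "undefined": not passed})
            log["stages"].setdefault("qc_controls", {})[f"day{day}"] = bool(passed)
        write_results(pd.DataFrame(qc_rows), outdir / "qc_controls.tsv")

    # --- detection on quantile-normalized pooled series
    times = np.array([m.absolute_time for m in pooled_meta])
    vals = norm.values.to_numpy(dtype=float)
    genes = norm.gene_ids
    rank_results = [
        rank_test(vals[i], times, period=config.rank.period,
                  phase_step=config.rank.phase_step, gene_id=genes[i])
        for i in range(len(genes))
    ]
    harm_results = harmonic_test_experiment(
        vals, times, genes,
        order=config.harmonic.order,
        period_range=tuple(config.harmonic.period_range),
        methods=tuple(config.harmonic.methods),
    )
    write_results(
        pd.DataFrame(
            {"gene_id": genes,
             "method": "rank",
             "p": [r.p for r in rank_results],
             "best_phase": [r.best_phase for r in rank_results],
             "tau": [r.tau for r in rank_results]}
        ),
        outdir / "detect_rank.tsv",
    )
    write_results(
        pd.DataFrame(
            {"gene_id": genes, "method": "harmonic",
             "p": [r.p for r in harm_results], "q": [r.q for r in harm_results],
             "period": [r.period for r in harm_results],
             "phase": [r.phase for r in harm_results],
             "amplitude": [r.amplitude for r in harm_results],
             "F": [r.f_statistic for r in harm_results]}
        ),
        outdir / "detect_harmonic.tsv",
    )

    # --- calls
    calls = call_cyclers(rank_results, harm_results, pooled, norm, config.filters)
    write_results(calls_to_frame(calls), outdir / "cycling_calls.tsv")
    ov = overlap_summary(calls)
    called_ids = {c.gene_id for c in calls if c.final_call}
    q_at_cutoff = max(
        (r.q for r in harm_results
         if r.gene_id in called_ids and r.p < config.filters.p_harmonic),
        default=0.0,
    )
    efp = expected_false_positives(min(q_at_cutoff, 1.0), ov.n_union)
    summary = pd.DataFrame(
        [{"n_rank_only": ov.n_rank_only, "n_harmonic_only": ov.n_harmonic_only,
          "n_both": ov.n_both, "n_union": ov.n_union,
          "q_at_cutoff": q_at_cutoff, "expected_false_positives": efp}]
    )
    write_results(summary, outdir / "call_summary.tsv")
    log["stages"]["calls"] = {
        "n_genes": len(calls),
        "n_pass_count_filter": int(sum(
            c.mean_raw_count >= config.filters.min_mean_raw_count for c in calls)),
        "n_pass_amplitude_filter": int(sum(
            c.rel_amplitude >= config.filters.min_rel_amplitude for c in calls)),
        "n_rank_only": ov.n_rank_only, "n_harmonic_only": ov.n_harmonic_only,
        "n_both": ov.n_both, "n_union": ov.n_union,
        "expected_false_positives": efp,
    }

    # --- phase analysis
    phase_summary = summarize_phases(calls)
    write_results(
        pd.DataFrame(
            {"bin_left": phase_summary.bin_edges[:-1],
             "bin_right": phase_summary.bin_edges[1:],
             "count": phase_summary.bin_counts}
        ),
        outdir / "phase_histogram.tsv",
    )
    modes = phase_summary.mode_estimates or (np.nan, np.nan)
    write_results(
        pd.DataFrame(
            [{"n_day": phase_summary.n_day, "n_night": phase_summary.n_night,
              "bimodality_r": phase_summary.bimodality_r,
              "mode_1": modes[0], "mode_2": modes[1]}]
        ),
        outdir / "phase_summary.tsv",
    )
    ordered = order_by_phase(calls)
    if ordered:
        heat = _zscore_rows(norm.values.loc[[c.gene_id for c in ordered]])
        heat.insert(0, "phase", [c.phase for c in ordered])
        heat.to_csv(outdir / "heatmap_matrix.tsv", sep="\t",
                    index_label="gene_id", float_format="%.6g")
    log["stages"]["phases"] = {
        "n_day": phase_summary.n_day, "n_night": phase_summary.n_night,
        "bimodality_r": phase_summary.bimodality_r,
        "modes": list(modes),
    }

    with open(outdir / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2, default=float)
    return log
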