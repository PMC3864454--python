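"""Tabular I/O: count matrices, sample sheets, category maps, result tables.

All artifacts are plain tab-separated text with a header row, '.' decimal
separator and no quoting.  Gene order is preserved from input everywhere;
nothing is silently re-sorted.  Missing values are not permitted in count
matrices — a blank or non-numeric cell is an error, not NaN.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import TableFormatError, ValidationError

__all__ = [
    "SampleMeta",
    "CountMatrix",
    "read_counts",
    "write_counts",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_category_map",
    "write_results",
    "validate_counts_against_meta",
]


@dataclass(frozen=True)
class SampleMeta:
    """One sequencing sample: a (circadian time, day, replicate) cell of the design.

    ``ct`` is circadian time in hours, in [0, 24).  ``day`` is 1-based.
    ``absolute_time`` places the sample on a single free-running time axis:
    24·(day−1) + ct.
    """

    sample_id: str
    ct: float
    day: int
    replicate: str

    @property
    def absolute_time(self) -> float:
        return 24.0 * (self.day - 1) + self.ct

    @property
    def timepoint(self) -> tuple[float, int]:
        return (self.ct, self.day)


@dataclass
class CountMatrix:
    """Genes × samples expression matrix.

    ``values`` is a DataFrame indexed by gene ID with one column per sample.
    ``normalized`` distinguishes raw integer read counts from
    quantile-normalized real values; raw matrices must be integral and
    nonnegative.
    """

    values: pd.DataFrame
    normalized: bool = False

    def __post_init__(self) -> None:
        v = self.values
        if v.index.has_duplicates:
            dups = v.index[v.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene IDs: {dups[:5]}")
        if v.columns.has_duplicates:
            dups = v.columns[v.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample IDs: {dups[:5]}")
        arr = v.to_numpy()
        if arr.size and not np.isfinite(arr).all():
            raise ValidationError("count matrix contains non-finite values")
        if arr.size and (arr < 0).any():
            raise ValidationError("count matrix contains negative values")
        if not self.normalized and arr.size:
            if not np.allclose(arr, np.round(arr)):
                raise ValidationError("raw count matrix contains non-integer values")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def _split_tsv_line(line: str) -> list[str]:
    return line.rstrip("\n").rstrip("\r").split("\t")


def read_counts(path: str | Path, normalized: bool = False) -> CountMatrix:
    """Read a TSV count matrix (first column gene IDs, header of sample IDs).

    Raises :class:`TableFormatError` naming the offending 1-based line for a
    row with the wrong number of fields or a non-numeric cell, and
    :class:`ValidationError` for duplicate gene IDs or negative values.
    """
    path = Path(path)
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise TableFormatError(f"{path}: empty file")
    header = _split_tsv_line(lines[0])
    if len(header) < 2:
        raise TableFormatError(f"{path}: header has no sample columns")
    sample_ids = header[1:]
    n_cols = len(header)
    gene_ids: list[str] = []
    rows: list[list[float]] = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = _split_tsv_line(line)
        if len(fields) != n_cols:
            raise TableFormatError(
                f"{path}: line {lineno} has {len(fields)} fields, expected {n_cols}"
            )
        gene_ids.append(fields[0])
        try:
            rows.append([float(x) for x in fields[1:]])
        except ValueError as exc:
            raise TableFormatError(f"{path}: line {lineno}: non-numeric cell ({exc})") from None
    values = pd.DataFrame(
        np.asarray(rows, dtype=float).reshape(len(gene_ids), len(sample_ids)),
        index=pd.Index(gene_ids, name="gene_id"),
        columns=sample_ids,
    )
    return CountMatrix(values=values, normalized=normalized)


def write_counts(m: CountMatrix, path: str | Path) -> None:
    """Write a count matrix as TSV; raw counts render as integers."""
    df = m.values
    if not m.normalized:
        df = df.astype(np.int64)
        df.to_csv(path, sep="\t", index_label="gene_id")
    else:
        df.to_csv(path, sep="\t", index_label="gene_id", float_format="%.10g")


_SHEET_COLUMNS = ("sample_id", "ct", "day", "replicate")


def read_sample_sheet(path: str | Path) -> list[SampleMeta]:
    """Read the sample sheet (columns sample_id, ct, day, replicate).

    Enforces: unique sample IDs, ct in [0, 24), positive integer day, unique
    absolute time per replicate, and an identical (ct, day) design across
    replicates.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "replicate": str})
    except Exception as exc:
        raise TableFormatError(f"{path}: cannot parse sample sheet: {exc}") from None
    missing = [c for c in _SHEET_COLUMNS if c not in df.columns]
    if missing:
        raise TableFormatError(f"{path}: missing columns {missing}")
    metas = [
        SampleMeta(
            sample_id=str(r.sample_id), ct=float(r.ct), day=int(r.day), replicate=str(r.replicate)
        )
        for r in df.itertuples()
    ]
    validate_sample_meta(metas)
    return metas


def validate_sample_meta(metas: Sequence[SampleMeta]) -> None:
    ids = [m.sample_id for m in metas]
    if len(set(ids)) != len(ids):
        dups = sorted({i for i in ids if ids.count(i) > 1})
        raise ValidationError(f"duplicate sample_id: {dups}")
    for m in metas:
        if not (0.0 <= m.ct < 24.0):
            raise ValidationError(f"sample {m.sample_id}: ct={m.ct} outside [0, 24)")
        if m.day < 1:
            raise ValidationError(f"sample {m.sample_id}: day={m.day} must be >= 1")
    by_rep: dict[str, set[tuple[float, int]]] = {}
    for m in metas:
        tps = by_rep.setdefault(m.replicate, set())
        if m.timepoint in tps:
            raise ValidationError(
                f"replicate {m.replicate}: duplicate timepoint (ct={m.ct}, day={m.day})"
            )
        tps.add(m.timepoint)
    designs = {rep: frozenset(tps) for rep, tps in by_rep.items()}
    if len(set(designs.values())) > 1:
        reps = sorted(designs)
        ref = designs[reps[0]]
        for rep in reps[1:]:
            diff = ref.symmetric_difference(designs[rep])
            if diff:
                raise ValidationError(
                    f"replicates {reps[0]!r} and {rep!r} disagree on timepoints: {sorted(diff)}"
                )


def write_sample_sheet(metas: Sequence[SampleMeta], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "sample_id": [m.sample_id for m in metas],
            "ct": [m.ct for m in metas],
            "day": [m.day for m in metas],
            "replicate": [m.replicate for m in metas],
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_category_map(path: str | Path) -> dict[str, str]:
    """Read a gene → functional-category TSV (columns gene_id, category)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("gene_id", "category"):
        if col not in df.columns:
            raise TableFormatError(f"{path}: missing column {col!r}")
    if df["gene_id"].duplicated().any():
        dups = df.loc[df["gene_id"].duplicated(), "gene_id"].unique().tolist()
        raise ValidationError(f"duplicate gene_id in category map: {dups[:5]}")
    if (df["category"].fillna("") == "").any():
        raise ValidationError("empty category label in category map")
    return dict(zip(df["gene_id"], df["category"]))


def write_results(records: pd.DataFrame | Iterable[dict], path: str | Path) -> None:
    """Write any result table as TSV with floats at 6 significant digits.

    An empty table still gets its header row if a DataFrame with columns is
    passed.
    """
    if not isinstance(records, pd.DataFrame):
        records = pd.DataFrame(list(records))
    records.to_csv(path, sep="\t", index=False, float_format="%.6g")


def validate_counts_against_meta(m: CountMatrix, metas: Sequence[SampleMeta]) -> None:
    """Require the matrix's sample IDs to be a permutation of the sheet's."""
    mat = set(m.sample_ids)
    sheet = {s.sample_id for s in metas}
    if mat != sheet:
        extra = sorted(mat - sheet)
        missing = sorted(sheet - mat)
        raise ValidationError(
            f"count matrix and sample sheet disagree: matrix-only={extra[:5]}, "
            f"sheet-only={missing[:5]}"
        )
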