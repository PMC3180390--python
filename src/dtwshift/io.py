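"""Reading expression matrices and writing result tables.

Input format: an expression matrix (rows = genes, columns = samples,
log2 scale, TSV or CSV by extension) plus a sample-metadata table with
columns ``sample``, ``group`` and ``age``.  Both require a header row,
UTF-8 encoding and '.' as the decimal separator.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .aligner import ShiftProfile
from .trajectory import AgeTransform, RawSeries, transform_ages

__all__ = ["load_dataset", "write_shifts_table", "read_shifts_table"]

_FLOAT_FMT = "%.10g"


def _sep(path: str) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def load_dataset(
    expr_path: str,
    meta_path: str,
    age_offset: float | None = None,
    groups: tuple[str, str] | None = None,
) -> dict[str, dict[str, RawSeries]]:
    """Load per-gene, per-group series from an expression matrix + metadata.

    ``age_offset`` switches on the log2 age axis: ages become
    log2(age + offset) at ingestion and every downstream shift is computed
    on that scale.  ``groups`` restricts (and orders) the groups kept.
    """
    expr = pd.read_csv(expr_path, sep=_sep(expr_path), index_col=0)
    meta = pd.read_csv(meta_path, sep=_sep(meta_path))
    required = {"sample", "group", "age"}
    if not required.issubset(meta.columns):
        raise ValueError(f"metadata must have columns {sorted(required)}")
    meta = meta.set_index("sample")
    missing = [s for s in meta.index if s not in expr.columns]
    if missing:
        raise ValueError(f"samples missing from expression matrix: {missing}")
    if groups is not None:
        meta = meta[meta["group"].isin(groups)]
    tr = AgeTransform(age_offset) if age_offset is not None else None
    dataset: dict[str, dict[str, RawSeries]] = {}
    for gene, row in expr.iterrows():
        per_group: dict[str, RawSeries] = {}
        for grp, sub in meta.groupby("group", sort=True):
            ages = sub["age"].to_numpy(dtype=float)
            if tr is not None:
                ages = transform_ages(ages, tr)
            values = row[sub.index].to_numpy(dtype=float)
            keep = np.isfinite(values)
            per_group[str(grp)] = RawSeries(str(gene), str(grp), ages[keep], values[keep])
        dataset[str(gene)] = per_group
    return dataset


def write_shifts_table(profiles: list[ShiftProfile], path: str) -> None:
    """Long-format TSV: gene_id, query_time, shift, reporting_shift, cost."""
    rows = []
    for p in profiles:
        rep = p.reporting_shifts
        for idx in range(p.N):
            rows.append(
                {
                    "gene_id": p.gene_id,
                    "query_time": p.query_times[idx],
                    "shift": p.shifts[idx],
                    "reporting_shift": rep[idx] if rep is not None else np.nan,
                    "cost": p.cost,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_shifts_table(path: str) -> dict[str, pd.DataFrame]:
    """Inverse of :func:`write_shifts_table`, grouped by gene."""
    df = pd.read_csv(path, sep="\t")
    return {str(g): sub.reset_index(drop=True) for g, sub in df.groupby("gene_id", sort=True)}
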