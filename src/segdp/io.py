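"""Reading signals and writing segmentations.

Internal coordinates are 1-based inclusive, matching the changepoint
convention (segment j covers indices ``tau_{j-1}+1 .. tau_j``); BED output
is the single place 0-based half-open coordinates appear.
"""

from __future__ import annotations

import json
import math

import numpy as np
import pandas as pd

from .costs import CostModel, GaussianMeanCost, TimeSeries

__all__ = [
    "read_series",
    "segment_table",
    "write_segmentation",
    "internal_to_bed",
    "bed_to_internal",
]


def internal_to_bed(start: int, end: int) -> tuple[int, int]:
    """1-based inclusive segment -> 0-based half-open BED interval."""
    return start - 1, end


def bed_to_internal(start0: int, end: int) -> tuple[int, int]:
    """0-based half-open BED interval -> 1-based inclusive segment."""
    return start0 + 1, end


def _parse_float(token: str, lineno: int, path) -> float:
    try:
        val = float(token)
    except ValueError:
        raise ValueError(
            f"{path}: line {lineno}: could not parse value {token!r}") from None
    if math.isnan(val):
        raise ValueError(f"{path}: line {lineno}: NaN value not allowed")
    return val


def read_series(path, format: str = "plain", column=0, chrom: str | None = None):
    """Read an ordered signal from disk.

    Parameters
    ----------
    format : {"plain", "csv_column", "bedgraph"}
        ``plain`` is one numeric value per line; ``csv_column`` takes the
        given column (name or position) of a CSV file; ``bedgraph`` reads
        4-column (chrom, start, end, value) rows in file order, the value
        column being the signal.
    chrom : str, optional
        Required to disambiguate a bedGraph containing several chromosomes.

    Returns
    -------
    (TimeSeries, coords)
        ``coords`` is a list of ``(chrom, start, end)`` tuples for
        bedGraph input and None otherwise.
    """
    if format == "plain":
        values = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                tok = line.strip()
                if not tok or tok.startswith("#"):
                    continue
                values.append(_parse_float(tok, lineno, path))
        if not values:
            raise ValueError(f"{path}: empty signal file")
        return TimeSeries.from_values(values), None

    if format == "csv_column":
        df = pd.read_csv(path, comment="#")
        if df.empty:
            raise ValueError(f"{path}: empty signal file")
        col = df.columns[column] if isinstance(column, int) else column
        if col not in df.columns:
            raise ValueError(f"{path}: no column named {col!r}")
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.index[vals.isna()]
        if len(bad):
            raise ValueError(
                f"{path}: non-numeric or missing values in column {col!r} at "
                f"rows {list(bad[:5])}")
        return TimeSeries.from_values(vals.to_numpy()), None

    if format == "bedgraph":
        values, coords, seen = [], [], []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                stripped = line.strip()
                if (not stripped or stripped.startswith("#")
                        or stripped.startswith(("track", "browser"))):
                    continue
                fields = stripped.split()
                if len(fields) < 4:
                    raise ValueError(
                        f"{path}: line {lineno}: expected 4 bedGraph columns, "
                        f"got {len(fields)}")
                c, s, e, v = fields[:4]
                if c not in seen:
                    seen.append(c)
                if chrom is not None and c != chrom:
                    continue
                values.append(_parse_float(v, lineno, path))
                coords.append((c, int(s), int(e)))
        if chrom is None and len(seen) > 1:
            raise ValueError(
                f"{path}: multiple chromosomes {seen}; pass a chrom filter")
        if not values:
            raise ValueError(f"{path}: no rows" +
                             (f" for chromosome {chrom!r}" if chrom else ""))
        return TimeSeries.from_values(values), coords

    raise ValueError(f"unknown input format {format!r}")


def segment_table(series: TimeSeries, changepoints, model: CostModel | None = None,
                  ) -> pd.DataFrame:
    """Tabulate a segmentation: one row per segment with its fitted mean and
    cost.  Segments tile 1..n; the end of segment j is changepoint tau_j."""
    if model is None:
        model = GaussianMeanCost()
    cps = np.asarray(changepoints, dtype=int)
    n = series.n
    if cps.size and (np.any(np.diff(cps) <= 0) or cps[0] < 1 or cps[-1] > n - 1):
        raise ValueError("changepoints must be strictly increasing in 1..n-1")
    bounds = np.concatenate([[0], cps, [n]])
    rows = []
    for j, (s, t) in enumerate(zip(bounds[:-1], bounds[1:]), start=1):
        seg = series.values[s:t]
        rows.append({
            "segment": j,
            "start": int(s) + 1,
            "end": int(t),
            "mean": float(seg.mean()),
            "cost": float(model.segment_cost(series, int(s), int(t))),
        })
    return pd.DataFrame(rows)


def write_segmentation(series: TimeSeries, changepoints, path,
                       format: str = "csv", model: CostModel | None = None,
                       metadata: dict | None = None,
                       coords=None, chrom: str = "signal") -> pd.DataFrame:
    """Write a segmentation as CSV (segment, start, end, mean, cost) or BED.

    Metadata key/value pairs are recorded as ``#`` header comments.  BED
    rows are 0-based half-open; when bedGraph coordinates are supplied the
    genomic positions of the segment boundaries are used, otherwise the
    internal indices are converted directly.
    """
    table = segment_table(series, changepoints, model)
    with open(path, "w") as fh:
        for key, value in (metadata or {}).items():
            fh.write(f"# {key}: {value}\n")
        if format == "csv":
            table.to_csv(fh, index=False)
        elif format == "bed":
            for _, row in table.iterrows():
                start, end = int(row["start"]), int(row["end"])
                if coords is not None:
                    name = coords[start - 1][0]
                    bed_start = coords[start - 1][1]
                    bed_end = coords[end - 1][2]
                else:
                    name = chrom
                    bed_start, bed_end = internal_to_bed(start, end)
                fh.write(f"{name}\t{bed_start}\t{bed_end}\t"
                         f"seg{int(row['segment'])}\t{row['mean']:.6g}\n")
        else:
            raise ValueError(f"unknown output format {format!r}")
    return table


def write_metadata_sidecar(path, metadata: dict) -> None:
    """Write a JSON run-metadata sidecar next to an output file."""
    with open(str(path) + ".meta.json", "w") as fh:
        json.dump(metadata, fh, indent=2, default=str)
        fh.write("\n")
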