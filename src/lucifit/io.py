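"""Readers and writers for the package's plain-text formats.

Three tabular formats are supported, all CSV with UTF-8 and a decimal
point:

* **long format** — ``sample_id,time_h,cps``; one row per reading.
* **wide plate format** — one row per well, first column the well id,
  remaining columns successive readings at a fixed interval (the shape a
  TopCount-style plate reader exports).
* **metadata** — ``sample_id,genotype,tissue,temperature_c`` plus optional
  ``ld_schedule`` and ``dd_onset_h`` columns.

Times are hours as floating point, 0-based from the recording start.
Missing values are empty cells and are dropped, not interpolated: the
fitting stage uses actual sample times, so gaps are harmless.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import SampleMetadata, TimeSeries
from .exceptions import ParseError, ValidationError

__all__ = [
    "read_long_csv",
    "write_long_csv",
    "read_plate_wide_csv",
    "write_plate_wide_csv",
    "read_metadata_csv",
    "write_metadata_csv",
    "join_metadata",
    "fits_to_frame",
    "write_fits_csv",
    "read_fits_csv",
]

logger = logging.getLogger(__name__)

LONG_COLUMNS = ["sample_id", "time_h", "cps"]
METADATA_COLUMNS = ["sample_id", "genotype", "tissue", "temperature_c"]

#: Columns of the Table-1-style report CSV produced by the summarize stage.
REPORT_COLUMNS = [
    "genotype",
    "tissue",
    "temperature_c",
    "n",
    "tau_mean_h",
    "tau_sem_h",
    "error_mean",
    "error_sem",
    "cps_mean",
    "cps_sem",
    "q10",
]


def read_long_csv(path: str | Path) -> list[TimeSeries]:
    """Read a long-format CSV into one :class:`TimeSeries` per sample.

    Rows are sorted by time within each sample; duplicate
    ``(sample_id, time_h)`` rows and negative counts are rejected.
    Samples appear in order of first appearance in the file.
    """
    df = pd.read_csv(path)
    missing = [c for c in LONG_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {missing}; header must "
                         f"contain {LONG_COLUMNS}")
    if df.empty:
        logger.warning("%s: empty data section, returning no samples", path)
        return []
    for col in ("time_h", "cps"):
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[numeric.isna() & df[col].notna()]
        if len(bad):
            # +2: 1-based line numbers plus the header line
            raise ParseError(
                f"{path}: non-numeric {col!r} value {df.loc[bad[0], col]!r} "
                f"at line {bad[0] + 2}"
            )
        df[col] = numeric
    df = df.dropna(subset=["time_h", "cps"])
    if (df["cps"] < 0).any():
        line = df.index[df["cps"] < 0][0] + 2
        raise ParseError(f"{path}: negative cps at line {line}")
    dup = df.duplicated(subset=["sample_id", "time_h"], keep=False)
    if dup.any():
        line = df.index[dup][0] + 2
        raise ParseError(
            f"{path}: duplicate (sample_id, time_h) row at line {line}"
        )

    out: list[TimeSeries] = []
    for sid, grp in df.groupby("sample_id", sort=False):
        grp = grp.sort_values("time_h")
        times = grp["time_h"].to_numpy(float)
        out.append(
            TimeSeries(
                sample_id=str(sid),
                times_h=times,
                counts_cps=grp["cps"].to_numpy(float),
                dd_onset_h=times[0],
            )
        )
    return out


def write_long_csv(series: Iterable[TimeSeries], path: str | Path) -> None:
    """Write a collection of series to the long CSV format."""
    frames = [
        pd.DataFrame(
            {"sample_id": ts.sample_id, "time_h": ts.times_h, "cps": ts.counts_cps}
        )
        for ts in series
    ]
    df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=LONG_COLUMNS
    )
    df.to_csv(path, index=False)


def read_plate_wide_csv(
    path: str | Path, interval_h: float, start_h: float = 0.0
) -> list[TimeSeries]:
    """Read a wide plate-reader export: one row per well.

    Times are reconstructed as ``start_h + k * interval_h`` for the k-th
    reading column. Blank cells are dropped (the corresponding time point
    is simply missing from that well's series). Ragged rows are an error.
    """
    import csv

    if interval_h <= 0:
        raise ValidationError("interval_h must be > 0")
    with open(path, newline="", encoding="utf-8") as fh:
        rows = [(i + 1, row) for i, row in enumerate(csv.reader(fh)) if row]
    if not rows:
        logger.warning("%s: empty plate file, returning no samples", path)
        return []
    n_cols = len(rows[0][1])
    ragged = [line for line, row in rows if len(row) != n_cols]
    if ragged:
        raise ParseError(
            f"{path}: ragged row at line {ragged[0]} "
            f"(expected {n_cols} fields)"
        )
    times = start_h + interval_h * np.arange(n_cols - 1, dtype=float)
    out: list[TimeSeries] = []
    for line, row in rows:
        well = row[0].strip()
        if not well:
            raise ParseError(f"{path}: missing well id at line {line}")
        values = np.full(n_cols - 1, np.nan)
        for k, cell in enumerate(row[1:]):
            cell = cell.strip()
            if not cell:
                continue  # blank cell: missing reading, dropped below
            try:
                values[k] = float(cell)
            except ValueError:
                raise ParseError(
                    f"{path}: non-numeric reading {cell!r} at line {line}"
                ) from None
        if np.any(values < 0):
            raise ParseError(f"{path}: negative reading at line {line}")
        keep = ~np.isnan(values)
        if not keep.any():
            logger.warning("%s: well %s has no readings, skipped", path, well)
            continue
        out.append(
            TimeSeries(
                sample_id=well, times_h=times[keep], counts_cps=values[keep]
            )
        )
    return out


def write_plate_wide_csv(series: Sequence[TimeSeries], path: str | Path) -> None:
    """Write regularly sampled series as a wide plate CSV (lossless only
    when every series shares the same time grid)."""
    if not series:
        Path(path).write_text("")
        return
    grid = series[0].times_h
    rows = {}
    for ts in series:
        if len(ts.times_h) != len(grid) or not np.allclose(ts.times_h, grid):
            raise ValidationError(
                f"sample {ts.sample_id!r} is not on the shared time grid"
            )
        rows[ts.sample_id] = ts.counts_cps
    pd.DataFrame(rows).T.to_csv(path, header=False)


def read_metadata_csv(path: str | Path) -> list[SampleMetadata]:
    """Read a sample-metadata CSV; sample ids must be unique."""
    df = pd.read_csv(path)
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing metadata column(s) {missing}")
    if df["sample_id"].duplicated().any():
        dup_id = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ParseError(f"{path}: duplicate sample_id {dup_id!r}")
    known = set(METADATA_COLUMNS) | {"ld_schedule", "dd_onset_h"}
    out = []
    for _, row in df.iterrows():
        extra = {k: str(row[k]) for k in df.columns if k not in known}
        out.append(
            SampleMetadata(
                sample_id=str(row["sample_id"]),
                genotype=str(row["genotype"]),
                tissue=str(row["tissue"]),
                temperature_c=float(row["temperature_c"]),
                ld_schedule=str(row.get("ld_schedule", "LD 12:12")),
                dd_onset_h=(
                    float(row["dd_onset_h"])
                    if "dd_onset_h" in df.columns and pd.notna(row["dd_onset_h"])
                    else None
                ),
                extra=extra,
            )
        )
    return out


def write_metadata_csv(metadata: Iterable[SampleMetadata], path: str | Path) -> None:
    rows = []
    for m in metadata:
        row = {
            "sample_id": m.sample_id,
            "genotype": m.genotype,
            "tissue": m.tissue,
            "temperature_c": m.temperature_c,
            "ld_schedule": m.ld_schedule,
            "dd_onset_h": m.dd_onset_h,
        }
        row.update(m.extra)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def join_metadata(
    series: Sequence[TimeSeries],
    metadata: Sequence[SampleMetadata],
    strict: bool = True,
) -> list[TimeSeries]:
    """Attach genotype/tissue/temperature annotations to each series.

    Under ``strict`` every sample must have metadata; otherwise unmatched
    series are dropped with a warning.
    """
    by_id = {m.sample_id: m for m in metadata}
    unmatched = [ts.sample_id for ts in series if ts.sample_id not in by_id]
    if unmatched and strict:
        raise ValidationError(
            f"samples without metadata: {', '.join(sorted(unmatched))}"
        )
    if unmatched:
        logger.warning("dropping %d unmatched sample(s): %s",
                       len(unmatched), ", ".join(sorted(unmatched)))
    out = []
    for ts in series:
        m = by_id.get(ts.sample_id)
        if m is None:
            continue
        ann = dict(ts.annotations)
        ann.update(
            genotype=m.genotype, tissue=m.tissue, ld_schedule=m.ld_schedule
        )
        ann.update({k: str(v) for k, v in m.extra.items()})
        out.append(
            ts.with_values(
                temperature_c=m.temperature_c,
                dd_onset_h=m.dd_onset_h if m.dd_onset_h is not None else ts.dd_onset_h,
                annotations=ann,
            )
        )
    return out


# ---------------------------------------------------------------------------
# fit-result tables

def fits_to_frame(fits) -> pd.DataFrame:
    """Convert an iterable of :class:`~lucifit.fitting.FitResult` to a frame."""
    rows = []
    for f in fits:
        rows.append(
            {
                "sample_id": f.sample_id,
                "tau_h": f.tau_h,
                "amplitude_cps": f.amplitude_cps,
                "damping_per_h": f.damping_per_h,
                "phase_h": f.phase_h,
                "offset_cps": f.offset_cps,
                "error": f.error,
                "mean_cps": f.mean_cps,
                "converged": f.converged,
                "n_points": f.n_points,
                "genotype": f.annotations.get("genotype", ""),
                "tissue": f.annotations.get("tissue", ""),
                "temperature_c": f.temperature_c,
            }
        )
    return pd.DataFrame(rows)


def write_fits_csv(fits, path: str | Path) -> None:
    fits_to_frame(fits).to_csv(path, index=False)


def read_fits_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"sample_id", "tau_h", "error"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing fit column(s) {sorted(missing)}")
    return df
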