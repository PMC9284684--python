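"""Readers and writers for the pipeline's plain-text formats.

All tabular artifacts are TSV/CSV.  Writes are atomic (temp file + rename)
so an interrupted run never leaves a truncated table, and every written
artifact gets a JSON sidecar (``<name>.meta.json``) recording the tool
version, the resolved configuration digest and the seed.
"""

from __future__ import annotations

import hashlib
import json
import os
import tempfile
from pathlib import Path
from typing import Callable, Mapping, Optional

import numpy as np
import pandas as pd

from . import __version__
from .diversity import TdNCDMatrix
from .timeseries import ROITimeSeries


def atomic_write(path: str | Path, writer: Callable[[Path], None]) -> None:
    """Write via a temp file in the target directory, then rename."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    os.close(fd)
    tmp = Path(tmp)
    try:
        writer(tmp)
        os.replace(tmp, path)
    finally:
        tmp.unlink(missing_ok=True)


def _stringify_keys(obj):
    if isinstance(obj, Mapping):
        return {str(k): _stringify_keys(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_stringify_keys(v) for v in obj]
    return obj


def config_digest(config: Mapping) -> str:
    """Stable short digest of a resolved configuration mapping."""
    blob = json.dumps(
        _stringify_keys(config), sort_keys=True, default=str
    ).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_sidecar(
    path: str | Path, config: Optional[Mapping] = None, seed: Optional[int] = None
) -> None:
    """Provenance sidecar next to an output file."""
    meta = {
        "tool": "tdncd",
        "version": __version__,
        "config_digest": config_digest(config or {}),
        "seed": seed,
    }
    side = Path(str(path) + ".meta.json")

    def _w(tmp: Path) -> None:
        tmp.write_text(json.dumps(meta, indent=2) + "\n")

    atomic_write(side, _w)


# -- time series ----------------------------------------------------------


def read_timeseries_file(
    path: str | Path,
    subject_id: str = "",
    site_id: str = "",
    diagnosis: str = "NC",
    mmse: Optional[float] = None,
    tr_seconds: float = 2.0,
    transposed: bool = False,
) -> ROITimeSeries:
    """Read one subject's tab-separated time-series file.

    The file has one header row of ROI labels and one row per frame.  A file
    stored ROIs x frames can be read with ``transposed=True``.  NaN, inf,
    non-numeric cells and ragged rows are rejected with the offending
    location.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, sep="\t", header=0)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty file") from None
    if df.shape[0] == 0 or df.shape[1] < 2:
        raise ValueError(f"{path}: expected a header row plus data rows")
    values = df.to_numpy()
    if values.dtype == object or not np.issubdtype(values.dtype, np.number):
        for j, col in enumerate(df.columns):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = np.flatnonzero(coerced.isna().to_numpy() & df[col].notna().to_numpy())
            if bad.size:
                raise ValueError(
                    f"{path}: non-numeric cell at line {bad[0] + 2}, "
                    f"column {j + 1}"
                )
        values = df.apply(pd.to_numeric, errors="coerce").to_numpy()
    if np.isnan(values).any():
        i, j = np.argwhere(np.isnan(values))[0]
        raise ValueError(f"{path}: missing/NaN cell at line {i + 2}, column {j + 1}")
    if not np.all(np.isfinite(values)):
        i, j = np.argwhere(~np.isfinite(values))[0]
        raise ValueError(f"{path}: non-finite cell at line {i + 2}, column {j + 1}")
    labels = list(df.columns)
    if transposed:
        values = values.T
        labels = None
    return ROITimeSeries(
        subject_id=subject_id or path.stem,
        site_id=site_id,
        diagnosis=diagnosis,
        mmse=mmse,
        tr_seconds=tr_seconds,
        values=values.astype(float),
        roi_labels=labels,
    )


def write_timeseries_file(ts: ROITimeSeries, path: str | Path) -> None:
    """Write a frames x ROIs TSV with an ROI-label header row."""
    labels = ts.roi_labels or [f"roi{i:04d}" for i in range(ts.n_rois)]
    df = pd.DataFrame(ts.values, columns=labels)

    def _w(tmp: Path) -> None:
        df.to_csv(tmp, sep="\t", index=False, float_format="%.17g")

    atomic_write(path, _w)


# -- manifest -------------------------------------------------------------

MANIFEST_COLUMNS = ["subject_id", "site_id", "diagnosis", "mmse", "path"]


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a cohort manifest CSV and validate its columns."""
    df = pd.read_csv(path)
    missing = [c for c in MANIFEST_COLUMNS[:3] if c not in df.columns]
    if missing:
        raise ValueError(f"manifest {path} lacks columns {missing}")
    if "mmse" not in df.columns:
        df["mmse"] = np.nan
    return df


def load_cohort_timeseries(
    manifest: pd.DataFrame, base_dir: str | Path, tr_seconds: float = 2.0
) -> dict[str, ROITimeSeries]:
    """Read every subject's series referenced by a manifest."""
    base = Path(base_dir)
    out = {}
    for row in manifest.itertuples(index=False):
        out[row.subject_id] = read_timeseries_file(
            base / row.path,
            subject_id=row.subject_id,
            site_id=row.site_id,
            diagnosis=row.diagnosis,
            mmse=getattr(row, "mmse", None),
            tr_seconds=tr_seconds,
        )
    return out


# -- analysis artifacts ---------------------------------------------------


def write_tdncd_tsv(matrix: TdNCDMatrix, path: str | Path) -> None:
    """ROI x time-distance table; column headers are distances in seconds."""

    def _w(tmp: Path) -> None:
        matrix.to_frame().to_csv(tmp, sep="\t", index_label="roi")

    atomic_write(path, _w)


def read_tdncd_tsv(path: str | Path, step_seconds: float = 10.0) -> TdNCDMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return TdNCDMatrix(
        matrix=df.to_numpy(dtype=float),
        step_seconds=step_seconds,
        roi_labels=list(df.index),
    )


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    """Atomic TSV dump of any result table."""

    def _w(tmp: Path) -> None:
        df.to_csv(tmp, sep="\t", index=index)

    atomic_write(path, _w)
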