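"""Static and sliding-window (dynamic) functional connectivity.

Functional connectivity is the Pearson correlation between regional time
series.  The static variant (sFC) correlates over the whole scan; the dynamic
variant (dFC) recomputes the correlation inside successive rectangular
windows, giving a windows x ROI x ROI tensor whose fluctuation across windows
is the raw material for the reconfiguration statistics in
:mod:`tdncd.diversity`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .timeseries import ROITimeSeries, WindowConfig


@dataclass
class SFCMatrix:
    """Static functional connectivity: full-scan Pearson correlation matrix."""

    matrix: np.ndarray
    roi_labels: Optional[Sequence[str]] = None

    @property
    def n_rois(self) -> int:
        return self.matrix.shape[0]


@dataclass
class DFCStack:
    """Dynamic functional connectivity tensor.

    ``tensor[w]`` is the ROI x ROI correlation matrix computed inside window
    ``w``, which covers frames ``[window_starts[w], window_starts[w] +
    window_frames)``.
    """

    tensor: np.ndarray
    window_starts: np.ndarray
    window_frames: int
    step_frames: int
    tr_seconds: float
    roi_labels: Optional[Sequence[str]] = None

    @property
    def n_windows(self) -> int:
        return self.tensor.shape[0]

    @property
    def n_rois(self) -> int:
        return self.tensor.shape[1]

    @property
    def step_seconds(self) -> float:
        return self.step_frames * self.tr_seconds


def _pearson_matrix(segment: np.ndarray) -> np.ndarray:
    """Pairwise Pearson correlation of the columns of ``segment``."""
    corr = np.corrcoef(segment, rowvar=False)
    corr = np.clip(corr, -1.0, 1.0)
    corr = (corr + corr.T) / 2.0
    np.fill_diagonal(corr, 1.0)
    return corr


def _check_variance(segment: np.ndarray, context: str) -> None:
    std = segment.std(axis=0)
    flat = np.flatnonzero(std == 0.0)
    if flat.size:
        raise ValueError(f"ROI {flat[0]} is constant {context}")


def compute_sfc(ts: ROITimeSeries) -> SFCMatrix:
    """Static functional connectivity over the full scan.

    Entry (m, n) is the Pearson correlation of ROI columns m and n over all
    frames.  A zero-variance ROI is an error: preprocessed data should never
    contain constant signals, and silently propagating NaN hides bugs.
    """
    if ts.n_frames < 3:
        raise ValueError("need at least 3 frames for a static FC matrix")
    _check_variance(ts.values, "over the full series")
    return SFCMatrix(matrix=_pearson_matrix(ts.values), roi_labels=ts.roi_labels)


def compute_dfc(ts: ROITimeSeries, cfg: WindowConfig = WindowConfig()) -> DFCStack:
    """Sliding-window dynamic functional connectivity.

    Windows start at frame 0 and advance by ``step_frames``; trailing frames
    that do not fill a complete window are dropped, so the number of windows is
    ``floor((n_frames - window_frames) / step_frames) + 1``.  With the default
    geometry (100 s window, 10 s step) on a 170-frame, TR = 2 s series this
    yields 25 windows.

    Raises
    ------
    ValueError
        If the window is longer than the series, or an ROI is constant inside
        some window (the error names the window and the ROI).
    """
    window_frames, step_frames = cfg.frames(ts.tr_seconds)
    n_frames = ts.n_frames
    if window_frames > n_frames:
        raise ValueError(
            f"window of {window_frames} frames exceeds series length {n_frames}"
        )
    starts = np.arange(0, n_frames - window_frames + 1, step_frames)
    slices = np.empty((starts.size, ts.n_rois, ts.n_rois))
    for w, start in enumerate(starts):
        segment = ts.values[start : start + window_frames]
        std = segment.std(axis=0)
        flat = np.flatnonzero(std == 0.0)
        if flat.size:
            raise ValueError(f"ROI {flat[0]} is constant within window {w}")
        slices[w] = _pearson_matrix(segment)
    return DFCStack(
        tensor=slices,
        window_starts=starts,
        window_frames=window_frames,
        step_frames=step_frames,
        tr_seconds=ts.tr_seconds,
        roi_labels=ts.roi_labels,
    )
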