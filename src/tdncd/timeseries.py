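"""Containers for preprocessed ROI time series and sliding-window settings.

A subject enters the pipeline as a ``ROITimeSeries``: a frames x ROIs matrix of
already-preprocessed regional BOLD signals together with acquisition metadata
(repetition time, site, diagnosis, MMSE).  ``WindowConfig`` holds the sliding
window geometry in seconds and converts it to frames for a given repetition
time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

#: Recognised diagnostic groups: normal control, mild cognitive impairment,
#: Alzheimer's disease.
DIAGNOSES = ("NC", "MCI", "AD")


def usable_frames(scan_seconds: float, tr_seconds: float, n_discard: int = 10) -> int:
    """Number of frames retained from a scan after dropping dummy volumes.

    A scan of ``scan_seconds`` at repetition time ``tr_seconds`` yields
    ``scan_seconds / tr_seconds`` volumes; the first ``n_discard`` are
    discarded to allow magnetisation equilibrium.  With a 360 s acquisition at
    TR = 2 s and 10 dummies this gives the canonical 170 analysed frames.
    """
    if scan_seconds <= 0 or tr_seconds <= 0:
        raise ValueError("scan_seconds and tr_seconds must be positive")
    total = int(round(scan_seconds / tr_seconds))
    retained = total - int(n_discard)
    if retained < 2:
        raise ValueError(
            f"only {retained} frames would remain after discarding {n_discard}"
        )
    return retained


@dataclass
class ROITimeSeries:
    """One subject's preprocessed regional time series.

    Parameters
    ----------
    subject_id, site_id : str
        Identifiers linking the series to the cohort manifest.
    diagnosis : str
        One of ``NC``, ``MCI``, ``AD``.
    tr_seconds : float
        Repetition time (seconds per frame).
    values : ndarray, shape (n_frames, n_rois)
        Signal matrix, rows are time points.
    mmse : float or None
        Mini-Mental State Exam score in [0, 30]; ``None`` when missing.
    roi_labels : sequence of str, optional
        Per-ROI labels (e.g. network names); length must equal ``n_rois``.
    """

    subject_id: str
    site_id: str
    diagnosis: str
    tr_seconds: float
    values: np.ndarray
    mmse: Optional[float] = None
    roi_labels: Optional[Sequence[str]] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D frames x ROIs matrix")
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"non-finite value at frame {bad[0]}, ROI {bad[1]} "
                f"for subject {self.subject_id!r}"
            )
        t, r = self.values.shape
        if r < 2:
            raise ValueError("need at least 2 ROIs")
        if t < 2:
            raise ValueError("need at least 2 frames")
        if self.diagnosis not in DIAGNOSES:
            raise ValueError(f"unknown diagnosis {self.diagnosis!r}")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if self.mmse is not None:
            if np.isnan(self.mmse):
                self.mmse = None
            elif not 0 <= self.mmse <= 30:
                raise ValueError(f"MMSE {self.mmse} outside [0, 30]")
        if self.roi_labels is not None:
            self.roi_labels = list(self.roi_labels)
            if len(self.roi_labels) != r:
                raise ValueError(
                    f"{len(self.roi_labels)} ROI labels for {r} ROIs"
                )

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_rois(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class WindowConfig:
    """Rectangular sliding-window geometry in seconds.

    Defaults follow the standard protocol for this method: 100 s windows
    advanced in 10 s steps.  Frame counts are obtained by dividing by the
    repetition time and rounding to the nearest integer; at TR = 2 s the
    defaults convert exactly to 50-frame windows with a 5-frame step.
    """

    window_seconds: float = 100.0
    step_seconds: float = 10.0

    def __post_init__(self) -> None:
        if self.window_seconds <= 0 or self.step_seconds <= 0:
            raise ValueError("window and step durations must be positive")

    def frames(self, tr_seconds: float) -> tuple[int, int]:
        """Return ``(window_frames, step_frames)`` for a repetition time."""
        if tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        window_frames = int(round(self.window_seconds / tr_seconds))
        step_frames = int(round(self.step_seconds / tr_seconds))
        if window_frames < 3:
            raise ValueError(
                f"window of {window_frames} frames is too short for a "
                "meaningful correlation (minimum 3)"
            )
        if step_frames < 1:
            raise ValueError("step shorter than one frame")
        return window_frames, step_frames

    def n_windows(self, n_frames: int, tr_seconds: float) -> int:
        """Number of complete windows that fit into ``n_frames``."""
        window_frames, step_frames = self.frames(tr_seconds)
        if window_frames > n_frames:
            raise ValueError(
                f"window of {window_frames} frames exceeds series length "
                f"{n_frames}"
            )
        return (n_frames - window_frames) // step_frames + 1
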