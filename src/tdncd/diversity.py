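"""Nodal connectivity diversity across window pairs and time distances.

The nodal connectivity diversity (NCD) between two connectivity matrices is,
for node n,

    NCD(i, j; n) = 1 - | corr( FC_i[n, :], FC_j[n, :] ) |

i.e. one minus the absolute Pearson correlation between the node's
connectivity profiles in the two conditions, after removing the trivial
self-connection entry from both profiles.  Applied to two windows of a dFC
stack this is the dynamic NCD (dNCD); averaging the dNCD over every window
pair separated by a fixed lag d gives the time-distance NCD

    tdNCD(n, d) = mean_{i} dNCD(i, i + d; n),   d = 1 .. T - 1,

one reconfiguration-intensity curve per node over T - 1 lags (T = number of
windows).  Because of the absolute value, a profile that flips sign exactly
counts as no reconfiguration; that is a deliberate property of the statistic,
kept as defined.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .dfc import DFCStack


@dataclass
class TdNCDMatrix:
    """Per-ROI reconfiguration profile over time distances.

    ``matrix`` has shape (n_rois, n_distances) with entries in [0, 1];
    column d-1 holds the mean dNCD over all window pairs at lag d, which
    corresponds to ``d * step_seconds`` seconds.
    """

    matrix: np.ndarray
    step_seconds: float
    roi_labels: Optional[Sequence[str]] = None

    @property
    def n_rois(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_distances(self) -> int:
        return self.matrix.shape[1]

    @property
    def distance_seconds(self) -> np.ndarray:
        return (np.arange(self.n_distances) + 1) * self.step_seconds

    def to_frame(self) -> pd.DataFrame:
        """Tabular view: rows = ROI labels, columns = distance in seconds."""
        labels = (
            list(self.roi_labels)
            if self.roi_labels is not None
            else [f"roi{i:04d}" for i in range(self.n_rois)]
        )
        cols = [f"{s:g}" for s in self.distance_seconds]
        return pd.DataFrame(self.matrix, index=labels, columns=cols)


def _profile_rows(matrix_i: np.ndarray, matrix_j: np.ndarray, roi: int) -> tuple[np.ndarray, np.ndarray]:
    keep = np.arange(matrix_i.shape[0]) != roi
    return matrix_i[roi, keep], matrix_j[roi, keep]


def _row_distance(row_a: np.ndarray, row_b: np.ndarray, context: str) -> float:
    if row_a.std() == 0.0 or row_b.std() == 0.0:
        raise ValueError(f"constant connectivity profile {context}")
    r = np.corrcoef(row_a, row_b)[0, 1]
    return float(np.clip(1.0 - abs(r), 0.0, 1.0))


def ncd(matrix_i: np.ndarray, matrix_j: np.ndarray, roi: int) -> float:
    """Nodal connectivity diversity between two static FC matrices at one node.

    The self-connection entry (roi, roi) is removed from both profiles before
    correlating.  Returns a value in [0, 1]: 0 means the node's connectivity
    profile is (up to sign) perfectly preserved, 1 means it is uncorrelated.
    """
    row_a, row_b = _profile_rows(np.asarray(matrix_i), np.asarray(matrix_j), roi)
    return _row_distance(row_a, row_b, f"for ROI {roi}")


def dncd_profile_distance(stack: DFCStack, window_i: int, window_j: int, roi_n: int) -> float:
    """Dynamic NCD between two windows of a dFC stack for one ROI.

    Returns ``1 - |corr|`` between ROI ``roi_n``'s connectivity rows in
    windows ``window_i`` and ``window_j`` (self-connection removed).
    """
    t = stack.n_windows
    if not (0 <= window_i < t and 0 <= window_j < t):
        raise IndexError(f"window index out of range (0..{t - 1})")
    if not 0 <= roi_n < stack.n_rois:
        raise IndexError(f"ROI index out of range (0..{stack.n_rois - 1})")
    row_a, row_b = _profile_rows(stack.tensor[window_i], stack.tensor[window_j], roi_n)
    return _row_distance(
        row_a, row_b, f"for ROI {roi_n} (windows {window_i}, {window_j})"
    )


def compute_tdncd(stack: DFCStack) -> TdNCDMatrix:
    """Time-distance NCD profile for every ROI of a dFC stack.

    Entry (n, d-1) is the mean of ``dncd_profile_distance(stack, i, i+d, n)``
    over the T - d admissible window pairs; in particular the last column is
    the single pair (first window, last window).  Runs in
    O(R * T^2 * R) via one T x T profile-correlation matrix per ROI.
    """
    t = stack.n_windows
    if t < 2:
        raise ValueError("need at least 2 windows to measure reconfiguration")
    r = stack.n_rois
    out = np.empty((r, t - 1))
    for n in range(r):
        keep = np.arange(r) != n
        profiles = stack.tensor[:, n, keep]  # T x (R-1)
        std = profiles.std(axis=1)
        flat = np.flatnonzero(std == 0.0)
        if flat.size:
            raise ValueError(
                f"constant connectivity profile for ROI {n} in window {flat[0]}"
            )
        corr = np.clip(np.corrcoef(profiles), -1.0, 1.0)
        diversity = 1.0 - np.abs(corr)
        for d in range(1, t):
            out[n, d - 1] = np.mean(np.diagonal(diversity, offset=d))
    np.clip(out, 0.0, 1.0, out=out)
    return TdNCDMatrix(
        matrix=out, step_seconds=stack.step_seconds, roi_labels=stack.roi_labels
    )
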