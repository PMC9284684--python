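"""Subject x feature tables built from connectivity matrices.

Three feature kinds are supported:

``sfc_edge``
    Upper-triangle entries of the static FC matrix: R(R-1)/2 columns.
``tdncd_roi_distance``
    Entries of the tdNCD matrix: R x D columns (ROI by time distance).
``dfc_window_edge``
    Upper-triangle entries of every window of the dFC stack:
    n_windows x R(R-1)/2 columns.

Column ordering is deterministic: lexicographic by kind name, then by
ROI/edge/window/distance index, so two runs over the same cohort produce
byte-identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .dfc import DFCStack, SFCMatrix
from .diversity import TdNCDMatrix

FEATURE_KINDS = ("dfc_window_edge", "sfc_edge", "tdncd_roi_distance")


@dataclass
class FeatureTable:
    """Aligned subject x feature matrix with per-column provenance.

    Attributes
    ----------
    X : DataFrame
        Rows indexed by subject id, columns by feature id.
    kinds : Series
        Feature id -> feature kind.
    meta : DataFrame
        Feature id -> structural coordinates (roi / roi_a / roi_b /
        distance_seconds / window, whichever apply to the kind).
    """

    X: pd.DataFrame
    kinds: pd.Series
    meta: pd.DataFrame

    @property
    def n_subjects(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]


def _edge_index(n_rois: int) -> tuple[np.ndarray, np.ndarray]:
    return np.triu_indices(n_rois, k=1)


def sfc_feature_block(sfc_by_subject: Mapping[str, SFCMatrix]) -> FeatureTable:
    """Flatten static FC matrices into one row of upper-triangle edges each."""
    subjects = list(sfc_by_subject)
    n_rois = sfc_by_subject[subjects[0]].n_rois
    rows_idx, cols_idx = _edge_index(n_rois)
    ids = [f"sfc_edge:{a:04d}-{b:04d}" for a, b in zip(rows_idx, cols_idx)]
    data = np.empty((len(subjects), len(ids)))
    for i, sid in enumerate(subjects):
        m = sfc_by_subject[sid].matrix
        if m.shape[0] != n_rois:
            raise ValueError(
                f"subject {sid!r} has {m.shape[0]} ROIs, expected {n_rois}"
            )
        data[i] = m[rows_idx, cols_idx]
    X = pd.DataFrame(data, index=subjects, columns=ids)
    meta = pd.DataFrame(
        {"roi_a": rows_idx, "roi_b": cols_idx}, index=ids, dtype="Int64"
    )
    kinds = pd.Series("sfc_edge", index=ids)
    return FeatureTable(X=X, kinds=kinds, meta=meta)


def tdncd_feature_block(tdncd_by_subject: Mapping[str, TdNCDMatrix]) -> FeatureTable:
    """Flatten tdNCD matrices into ROI x distance columns."""
    subjects = list(tdncd_by_subject)
    first = tdncd_by_subject[subjects[0]]
    n_rois, n_dist = first.n_rois, first.n_distances
    step = first.step_seconds
    ids = [
        f"tdncd_roi_distance:r{n:04d}-d{d:03d}"
        for n in range(n_rois)
        for d in range(1, n_dist + 1)
    ]
    data = np.empty((len(subjects), len(ids)))
    for i, sid in enumerate(subjects):
        m = tdncd_by_subject[sid].matrix
        if m.shape != (n_rois, n_dist):
            raise ValueError(
                f"subject {sid!r} has tdNCD shape {m.shape}, "
                f"expected {(n_rois, n_dist)}"
            )
        data[i] = m.ravel()
    X = pd.DataFrame(data, index=subjects, columns=ids)
    roi = np.repeat(np.arange(n_rois), n_dist)
    dist = np.tile(np.arange(1, n_dist + 1), n_rois)
    meta = pd.DataFrame(
        {"roi": roi, "distance_steps": dist, "distance_seconds": dist * step},
        index=ids,
    )
    kinds = pd.Series("tdncd_roi_distance", index=ids)
    return FeatureTable(X=X, kinds=kinds, meta=meta)


def dfc_feature_block(dfc_by_subject: Mapping[str, DFCStack]) -> FeatureTable:
    """Flatten every window of the dFC stack into edge columns."""
    subjects = list(dfc_by_subject)
    first = dfc_by_subject[subjects[0]]
    n_rois, n_windows = first.n_rois, first.n_windows
    rows_idx, cols_idx = _edge_index(n_rois)
    ids = [
        f"dfc_window_edge:w{w:03d}-{a:04d}-{b:04d}"
        for w in range(n_windows)
        for a, b in zip(rows_idx, cols_idx)
    ]
    data = np.empty((len(subjects), len(ids)))
    for i, sid in enumerate(subjects):
        stack = dfc_by_subject[sid]
        if stack.tensor.shape != first.tensor.shape:
            raise ValueError(
                f"subject {sid!r} has dFC shape {stack.tensor.shape}, "
                f"expected {first.tensor.shape}"
            )
        data[i] = stack.tensor[:, rows_idx, cols_idx].ravel()
    X = pd.DataFrame(data, index=subjects, columns=ids)
    meta = pd.DataFrame(
        {
            "window": np.repeat(np.arange(n_windows), rows_idx.size),
            "roi_a": np.tile(rows_idx, n_windows),
            "roi_b": np.tile(cols_idx, n_windows),
        },
        index=ids,
    )
    kinds = pd.Series("dfc_window_edge", index=ids)
    return FeatureTable(X=X, kinds=kinds, meta=meta)


def build_feature_table(
    matrices_by_subject: Mapping[str, Mapping[str, object]],
    kinds: Iterable[str],
) -> FeatureTable:
    """Assemble one aligned feature table from per-subject matrices.

    Parameters
    ----------
    matrices_by_subject : mapping
        ``subject_id -> {"sfc": SFCMatrix, "tdncd": TdNCDMatrix,
        "dfc": DFCStack}`` (only the keys needed by ``kinds`` are required).
    kinds : iterable of str
        Subset of :data:`FEATURE_KINDS`.
    """
    kinds = sorted(set(kinds))
    if not kinds:
        raise ValueError("empty feature-kind request")
    unknown = [k for k in kinds if k not in FEATURE_KINDS]
    if unknown:
        raise ValueError(f"unknown feature kinds: {unknown}")
    key_for = {
        "sfc_edge": "sfc",
        "tdncd_roi_distance": "tdncd",
        "dfc_window_edge": "dfc",
    }
    builder_for = {
        "sfc_edge": sfc_feature_block,
        "tdncd_roi_distance": tdncd_feature_block,
        "dfc_window_edge": dfc_feature_block,
    }
    blocks = []
    for kind in kinds:  # already lexicographic
        per_subject = {
            sid: mats[key_for[kind]] for sid, mats in matrices_by_subject.items()
        }
        blocks.append(builder_for[kind](per_subject))
    X = pd.concat([b.X for b in blocks], axis=1)
    if X.isna().any().any():
        raise ValueError("missing values after feature assembly")
    kinds_series = pd.concat([b.kinds for b in blocks])
    meta = pd.concat([b.meta for b in blocks])
    return FeatureTable(X=X, kinds=kinds_series, meta=meta)
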