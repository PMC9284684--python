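"""Multi-site group comparison: per-site t-tests plus Liptak-Stouffer pooling.

Each acquisition site contributes an independent two-sample two-sided t-test
per feature (tdNCD entry or FC edge).  Site p-values are pooled with the
weighted Stouffer method: each p_i is mapped to a signed z-score

    z_i = sign(t_i) * Phi^{-1}(1 - p_i / 2),

the combined score is z = sum(w_i z_i) / sqrt(sum(w_i^2)) with w_i the square
root of the site's sample size, and the combined two-sided p-value is
2 * (1 - Phi(|z|)).  Significance is declared under a Bonferroni family:
the 24 time distances of a tdNCD profile (threshold alpha/24) or the 264
ROIs of the FC comparison (threshold alpha/264, the convention of the
original analysis even though the FC family counts edges).

The module exposes both the individual operations and a statsmodels-style
``MetaAnalysis`` model whose ``fit()`` returns a ``MetaAnalysisResults``
object with a ``summary()`` table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

#: Bonferroni family sizes: the 24 time distances of a tdNCD profile and the
#: 264 ROIs of the static-FC comparison.
FAMILY_SIZES = {"tdncd_24": 24, "fc_264": 264}


def bonferroni_threshold(alpha: float = 0.05, family: str | int = "tdncd_24") -> float:
    """Per-test significance threshold alpha / N for a named or integer family."""
    n = FAMILY_SIZES[family] if isinstance(family, str) else int(family)
    if n < 1:
        raise ValueError("family size must be positive")
    return alpha / n


def sitewise_ttest(
    X: pd.DataFrame,
    manifest: pd.DataFrame,
    group_a: str = "NC",
    group_b: str = "AD",
    equal_var: bool = True,
) -> pd.DataFrame:
    """Two-sample two-sided t-tests per (site, feature).

    Parameters
    ----------
    X : DataFrame
        Subjects x features, indexed by subject id.
    manifest : DataFrame
        Cohort table with columns ``subject_id``, ``site_id``, ``diagnosis``.
    group_a, group_b : str
        Diagnoses being contrasted; the t statistic is (mean_a - mean_b)
        scaled, so a positive sign means group_a exceeds group_b.
    equal_var : bool
        Student's pooled-variance test when True (the default); Welch
        otherwise.

    Returns
    -------
    DataFrame
        Long table with columns ``site_id``, ``feature_id``, ``t_stat``,
        ``p_two_sided``, ``effect_sign``, ``n_group_a``, ``n_group_b``,
        ``n_total``.  Sites with fewer than 2 subjects in either group are
        skipped with a warning and appear in no row.
    """
    man = manifest.set_index("subject_id")
    frames = []
    for site, site_man in man.groupby("site_id", sort=True):
        ids_a = site_man.index[site_man["diagnosis"] == group_a]
        ids_b = site_man.index[site_man["diagnosis"] == group_b]
        if len(ids_a) < 2 or len(ids_b) < 2:
            warnings.warn(
                f"site {site!r} has <2 subjects in {group_a} or {group_b}; "
                "excluded from the combination",
                stacklevel=2,
            )
            continue
        a = X.loc[ids_a].to_numpy()
        b = X.loc[ids_b].to_numpy()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            t, p = stats.ttest_ind(a, b, axis=0, equal_var=equal_var)
        t = np.asarray(t, dtype=float)
        p = np.asarray(p, dtype=float)
        # zero-variance features: identical group means are a perfect null
        # (t = 0, p = 1); scipy leaves NaN there
        degenerate = np.isnan(t) & np.isclose(a.mean(axis=0), b.mean(axis=0))
        t = np.where(degenerate, 0.0, t)
        p = np.where(degenerate, 1.0, p)
        sign = np.where(t < 0, -1, 1)
        frames.append(
            pd.DataFrame(
                {
                    "site_id": site,
                    "feature_id": X.columns,
                    "t_stat": t,
                    "p_two_sided": p,
                    "effect_sign": sign,
                    "n_group_a": len(ids_a),
                    "n_group_b": len(ids_b),
                    "n_total": len(ids_a) + len(ids_b),
                }
            )
        )
    if not frames:
        raise ValueError("no site had enough subjects in both groups")
    return pd.concat(frames, ignore_index=True)


def stouffer_combine(site_results: pd.DataFrame) -> pd.DataFrame:
    """Weighted Stouffer combination of per-site p-values, per feature.

    Weights are sqrt(site sample size).  Returns a DataFrame indexed by
    feature id with ``combined_z``, ``combined_p`` and ``n_sites_used``.
    Zero p-values (where the normal quantile diverges) are clamped to the
    smallest positive float with a warning.
    """
    p = site_results["p_two_sided"].to_numpy(dtype=float)
    if np.any(p <= 0.0):
        warnings.warn(
            "p-values of 0 clamped to the smallest positive float", stacklevel=2
        )
        p = np.maximum(p, np.finfo(float).tiny)
    if np.any(p > 1.0):
        raise ValueError("p-values above 1")
    z_site = site_results["effect_sign"].to_numpy() * stats.norm.isf(p / 2.0)
    w = np.sqrt(site_results["n_total"].to_numpy(dtype=float))
    df = pd.DataFrame(
        {
            "feature_id": site_results["feature_id"].to_numpy(),
            "wz": w * z_site,
            "w2": w**2,
        }
    )
    grouped = df.groupby("feature_id", sort=False).agg(
        wz=("wz", "sum"), w2=("w2", "sum"), n_sites_used=("wz", "size")
    )
    z = grouped["wz"] / np.sqrt(grouped["w2"])
    combined_p = 2.0 * stats.norm.sf(np.abs(z))
    out = pd.DataFrame(
        {
            "combined_z": z,
            "combined_p": np.clip(combined_p, np.finfo(float).tiny, 1.0),
            "n_sites_used": grouped["n_sites_used"].astype(int),
        }
    )
    out.index.name = "feature_id"
    return out


def meta_significance(
    meta: pd.DataFrame,
    feature_meta: pd.DataFrame,
    family: str,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Bonferroni significance flags plus a per-ROI summary.

    Parameters
    ----------
    meta : DataFrame
        Output of :func:`stouffer_combine` (indexed by feature id).
    feature_meta : DataFrame
        Feature coordinates: ``roi`` (+ ``distance_seconds``) for the tdNCD
        family, ``roi_a``/``roi_b`` for the FC edge family.
    family : {"tdncd_24", "fc_264"}
        Bonferroni family; the per-test threshold is ``alpha / 24`` or
        ``alpha / 264`` respectively.

    Returns
    -------
    (features, roi_summary)
        ``features`` is ``meta`` joined with coordinates and a boolean
        ``significant`` column.  ``roi_summary`` has one row per ROI with a
        ``flagged`` boolean: for tdNCD an ROI is flagged when any of its
        distances is significant; for FC edges the summary also carries
        ``n_significant_edges`` (incident significant edges) and the ROI is
        flagged when that count is positive.
    """
    if family not in FAMILY_SIZES:
        raise ValueError(
            f"unknown family {family!r}; expected one of {sorted(FAMILY_SIZES)}"
        )
    threshold = bonferroni_threshold(alpha, family)
    features = meta.join(feature_meta, how="left")
    features["significant"] = features["combined_p"] < threshold

    if family == "tdncd_24":
        if "roi" not in features:
            raise ValueError("tdncd family needs a 'roi' column in feature_meta")
        roi_summary = (
            features.groupby("roi")["significant"]
            .agg(n_significant="sum", flagged="any")
            .reset_index()
        )
    else:
        if not {"roi_a", "roi_b"} <= set(features.columns):
            raise ValueError("fc family needs 'roi_a'/'roi_b' columns")
        sig = features[features["significant"]]
        rois = pd.unique(
            np.concatenate(
                [features["roi_a"].to_numpy(), features["roi_b"].to_numpy()]
            )
        )
        counts = pd.Series(0, index=np.sort(rois))
        incident = pd.concat([sig["roi_a"], sig["roi_b"]])
        counts = counts.add(incident.value_counts(), fill_value=0).astype(int)
        roi_summary = pd.DataFrame(
            {
                "roi": counts.index,
                "n_significant_edges": counts.to_numpy(),
                "flagged": counts.to_numpy() > 0,
            }
        )
    return features, roi_summary


class MetaAnalysis:
    """Multi-site group-difference meta-analysis model.

    Parameters
    ----------
    X : DataFrame
        Subjects x features (tdNCD entries or FC edges), indexed by subject.
    manifest : DataFrame
        Cohort table (``subject_id``, ``site_id``, ``diagnosis``).
    feature_meta : DataFrame
        Per-feature coordinates, as produced by :mod:`tdncd.features`.
    group_a, group_b : str
        Contrasted diagnoses (defaults NC vs AD).
    family : {"tdncd_24", "fc_264"}
    alpha : float
    equal_var : bool
        Pooled-variance t-test when True; Welch otherwise.
    """

    def __init__(
        self,
        X: pd.DataFrame,
        manifest: pd.DataFrame,
        feature_meta: pd.DataFrame,
        group_a: str = "NC",
        group_b: str = "AD",
        family: str = "tdncd_24",
        alpha: float = 0.05,
        equal_var: bool = True,
    ) -> None:
        if family not in FAMILY_SIZES:
            raise ValueError(f"unknown family {family!r}")
        self.X = X
        self.manifest = manifest
        self.feature_meta = feature_meta
        self.group_a = group_a
        self.group_b = group_b
        self.family = family
        self.alpha = alpha
        self.equal_var = equal_var

    def fit(self) -> "MetaAnalysisResults":
        site_results = sitewise_ttest(
            self.X,
            self.manifest,
            group_a=self.group_a,
            group_b=self.group_b,
            equal_var=self.equal_var,
        )
        combined = stouffer_combine(site_results)
        features, roi_summary = meta_significance(
            combined, self.feature_meta, self.family, self.alpha
        )
        return MetaAnalysisResults(
            model=self,
            site_results=site_results,
            table=features,
            roi_summary=roi_summary,
        )


@dataclass
class MetaAnalysisResults:
    """Fitted meta-analysis: per-feature combined statistics and ROI flags."""

    model: MetaAnalysis
    site_results: pd.DataFrame
    table: pd.DataFrame
    roi_summary: pd.DataFrame

    @property
    def threshold(self) -> float:
        return bonferroni_threshold(self.model.alpha, self.model.family)

    @property
    def n_significant(self) -> int:
        return int(self.table["significant"].sum())

    def summary(self, top: int = 10) -> str:
        """Human-readable fit summary with the strongest features."""
        m = self.model
        lines = [
            "Multi-site group-difference meta-analysis",
            f"  contrast:   {m.group_a} vs {m.group_b}",
            f"  sites used: {self.site_results['site_id'].nunique()}",
            f"  features:   {len(self.table)}",
            f"  family:     {m.family} (per-test threshold "
            f"{self.threshold:.4g})",
            f"  significant features: {self.n_significant}",
            f"  flagged ROIs:         {int(self.roi_summary['flagged'].sum())}",
            "",
            f"  top {top} features by |combined z|:",
        ]
        ordered = self.table.reindex(
            self.table["combined_z"].abs().sort_values(ascending=False).index
        )
        head = ordered.head(top)[["combined_z", "combined_p", "significant"]]
        lines.append(head.to_string())
        return "\n".join(lines)
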