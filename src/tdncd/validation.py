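"""End-to-end validation experiments on synthetic cohorts.

These routines exercise the whole pipeline -- generator, windowed FC, tdNCD,
meta-analysis, classification -- under controlled ground truth, and are used
both by the test suite and by the reproduction script.

Because the features of one cohort are mutually correlated (all ROIs of a
subject share the same latent factors and window grid), single-cohort
empirical rates have an effective sample size far below the feature count.
The calibration experiment therefore simulates independent replicate
cohorts: the Monte-Carlo standard error of the false-positive rate is taken
across replicates, and the Kolmogorov-Smirnov check uses an effective sample
size estimated from the replicate dispersion rather than the raw feature
count.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .classify import ClassificationResults, ClassifierSpec, LosoClassifier
from .dfc import compute_dfc, compute_sfc
from .diversity import compute_tdncd
from .features import FeatureTable, build_feature_table, tdncd_feature_block
from .group_stats import MetaAnalysis
from .synthetic import SyntheticSpec, simulate_cohort, uniform_group_sizes

#: Planted ROIs used by the recovery experiments: 3 raised, 2 lowered.
DEFAULT_AFFECTED = {0: 1, 8: 1, 16: 1, 24: -1, 32: -1}


def derive_seeds(seed: int, n: int) -> list[int]:
    """Well-separated child seeds (31-bit) for replicate experiments."""
    state = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint64)
    return [int(s % (2**31)) for s in state]


def null_spec(seed: int, per_group: int = 50, n_sites: int = 7, n_rois: int = 40) -> SyntheticSpec:
    """Stationary zero-effect cohort: one latent state, no planted ROIs."""
    return SyntheticSpec.desk_scale(
        n_rois=n_rois,
        seed=seed,
        n_states=1,
        dwell={"NC": 1.0, "MCI": 1.0, "AD": 1.0},
        group_sizes=uniform_group_sizes(n_sites, per_group, ("NC", "AD")),
        effect_delta={"NC": 0.0, "MCI": 0.0, "AD": 0.0},
    )


def planted_spec(
    seed: int,
    effect_delta: float = 1.0,
    per_group: int = 25,
    n_sites: int = 7,
    n_rois: int = 40,
    affected: Optional[Mapping[int, int]] = None,
) -> SyntheticSpec:
    """Cohort with a known reconfiguration effect in 5 of 40 ROIs."""
    return SyntheticSpec.desk_scale(
        n_rois=n_rois,
        seed=seed,
        group_sizes=uniform_group_sizes(n_sites, per_group, ("NC", "AD")),
        affected_rois=dict(affected or DEFAULT_AFFECTED),
        effect_delta={"NC": 0.0, "MCI": effect_delta / 2, "AD": effect_delta},
    )


def cohort_tdncd_meta(spec: SyntheticSpec) -> "MetaResultBundle":
    """Simulate a cohort and run the tdNCD meta-analysis end to end."""
    manifest, series = simulate_cohort(spec)
    profiles = {
        sid: compute_tdncd(compute_dfc(ts)) for sid, ts in series.items()
    }
    block = tdncd_feature_block(profiles)
    results = MetaAnalysis(
        block.X, manifest, block.meta, family="tdncd_24"
    ).fit()
    return MetaResultBundle(
        manifest=manifest, series=series, block=block, results=results
    )


@dataclass
class MetaResultBundle:
    manifest: pd.DataFrame
    series: dict
    block: FeatureTable
    results: object


@dataclass
class NullCalibration:
    """Summary of the zero-effect calibration experiment."""

    rates: np.ndarray           # per-replicate p < alpha rate
    pooled_p: np.ndarray        # all combined p-values
    alpha: float

    @property
    def mean_rate(self) -> float:
        return float(self.rates.mean())

    @property
    def mc_se(self) -> float:
        """Monte-Carlo SE of the mean rate across independent replicates,
        floored at the pooled binomial SE."""
        binom = np.sqrt(self.alpha * (1 - self.alpha) / self.pooled_p.size)
        if len(self.rates) < 2:
            return float(binom)
        rep = self.rates.std(ddof=1) / np.sqrt(len(self.rates))
        return float(max(rep, binom))

    @property
    def n_effective(self) -> float:
        """Effective number of independent tests implied by the replicate
        dispersion of the rate."""
        var = self.rates.var(ddof=1) if len(self.rates) > 1 else 0.0
        if var <= 0:
            return float(self.pooled_p.size)
        per_rep = self.alpha * (1 - self.alpha) / var
        return float(min(per_rep * len(self.rates), self.pooled_p.size))

    @property
    def ks_statistic(self) -> float:
        return float(stats.kstest(self.pooled_p, "uniform").statistic)

    @property
    def ks_critical_1pct(self) -> float:
        return float(1.628 / np.sqrt(self.n_effective))

    def rate_within_band(self) -> bool:
        return abs(self.mean_rate - self.alpha) <= 2 * self.mc_se

    def ks_passes(self) -> bool:
        return self.ks_statistic < self.ks_critical_1pct


def null_calibration(
    seed: int, n_replicates: int = 6, per_group: int = 50,
    n_sites: int = 7, n_rois: int = 40, alpha: float = 0.05,
) -> NullCalibration:
    """Zero-effect calibration: combined p-values should be uniform."""
    rates, pools = [], []
    for rep_seed in derive_seeds(seed, n_replicates):
        bundle = cohort_tdncd_meta(
            null_spec(rep_seed, per_group, n_sites, n_rois)
        )
        p = bundle.results.table["combined_p"].to_numpy()
        rates.append((p < alpha).mean())
        pools.append(p)
    return NullCalibration(
        rates=np.asarray(rates), pooled_p=np.concatenate(pools), alpha=alpha
    )


def detection_auc(bundle: MetaResultBundle, affected: Mapping[int, int]) -> float:
    """Ranking quality of planted-ROI recovery: ROIs are scored by their
    strongest meta-analytic |z| over time distances and compared with the
    ground-truth labels via the area under the ROC curve."""
    from sklearn.metrics import roc_auc_score

    z = bundle.results.table.groupby("roi")["combined_z"].apply(
        lambda s: s.abs().max()
    )
    y = np.array([1 if r in affected else 0 for r in z.index])
    return float(roc_auc_score(y, z.to_numpy()))


def recovery_experiment(
    seed: int, n_seeds: int = 10, effect_delta: float = 1.0,
    per_group: int = 25, n_sites: int = 7,
) -> dict:
    """Detection AUC of the planted effect across independent cohorts."""
    aucs = []
    for rep_seed in derive_seeds(seed, n_seeds):
        bundle = cohort_tdncd_meta(
            planted_spec(rep_seed, effect_delta, per_group, n_sites)
        )
        aucs.append(detection_auc(bundle, DEFAULT_AFFECTED))
    return {"aucs": aucs, "mean_auc": float(np.mean(aucs))}


def loso_on_cohort(
    spec: SyntheticSpec, model: str = "lr", seed: int = 0,
    kinds=("sfc_edge", "tdncd_roi_distance"),
) -> ClassificationResults:
    """Full feature pipeline plus nested LOSO classification on one cohort."""
    manifest, series = simulate_cohort(spec)
    mats = {}
    for sid, ts in series.items():
        entry = {}
        stack = None
        if "sfc_edge" in kinds:
            entry["sfc"] = compute_sfc(ts)
        if "tdncd_roi_distance" in kinds:
            stack = compute_dfc(ts)
            entry["tdncd"] = compute_tdncd(stack)
        mats[sid] = entry
    table = build_feature_table(mats, list(kinds))
    return LosoClassifier(
        table, manifest, ClassifierSpec(model=model, seed=seed), task="nc_vs_ad"
    ).fit()


def planted_vs_null_loso(seed: int, effect_delta: float = 1.0) -> dict:
    """Positive-control vs null-control classification experiment."""
    planted = loso_on_cohort(planted_spec(seed, effect_delta), seed=seed)
    null = loso_on_cohort(planted_spec(seed, 0.0), seed=seed)
    n = int(planted.ok_folds["n_test"].sum())
    correct = int(round(planted.pooled_accuracy() / 100.0 * n))
    binom_p = float(
        stats.binomtest(correct, n, 0.5, alternative="greater").pvalue
    )
    return {
        "planted_accuracy": planted.pooled_accuracy(),
        "null_accuracy": null.pooled_accuracy(),
        "n_test": n,
        "binomial_p": binom_p,
    }


def leakage_canary(seed: int, n_sites: int = 5, per_group: int = 10) -> dict:
    """A feature equal to the subject's site indicator must not lift LOSO
    accuracy above chance on label-balanced data: feature selection and
    standardisation are fitted strictly inside each training split."""
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_sites):
        for diag in ("NC", "AD"):
            for j in range(per_group):
                rows.append(
                    {
                        "subject_id": f"s{s}_{diag}_{j}",
                        "site_id": f"site{s}",
                        "diagnosis": diag,
                        "mmse": 25.0,
                    }
                )
    manifest = pd.DataFrame(rows)
    n = len(manifest)
    cols = {
        f"tdncd_roi_distance:noise{j:03d}": rng.standard_normal(n)
        for j in range(40)
    }
    for s in range(n_sites):
        cols[f"tdncd_roi_distance:site{s}"] = (
            (manifest["site_id"] == f"site{s}").astype(float).to_numpy()
        )
    X = pd.DataFrame(cols, index=manifest["subject_id"])
    table = FeatureTable(
        X=X,
        kinds=pd.Series("tdncd_roi_distance", index=X.columns),
        meta=pd.DataFrame(index=X.columns),
    )
    res = LosoClassifier(
        table, manifest, ClassifierSpec(model="lr", seed=seed),
        task="nc_vs_ad", thresholds={"tdncd_roi_distance": 1.0},
    ).fit()
    acc = res.pooled_accuracy() / 100.0
    n_test = int(res.ok_folds["n_test"].sum())
    return {
        "accuracy": 100.0 * acc,
        "n_test": n_test,
        "chance_band_se": 100.0 * np.sqrt(0.25 / n_test),
    }
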