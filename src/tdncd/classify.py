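"""Diagnosis classification with nested leave-one-site-out cross-validation.

The evaluation protocol treats each acquisition site as one fold: the outer
loop holds out a site as the test set; the inner loop rotates each remaining
site as a validation set to choose hyperparameters by mean validation
accuracy; the winning setting is refit on all non-test sites and scored on
the held-out site.  Feature selection (two-sample t-test per column against
per-kind p thresholds) and feature standardisation are refit inside every
training split, so no statistic of the held-out site ever reaches the model.

Five model families are supported: ``fcnet`` (a 4-layer fully connected
network -- input, hidden 64, hidden 32, softmax output -- trained with Adam,
whose two searched hyperparameters are the number of passes over the data and
the Adam learning rate), plus linear-kernel SVM, k-nearest neighbours,
L2 logistic regression and linear discriminant analysis baselines.

The decision score of a subject is the predicted probability of the AD class
(for margin models, a logistic link of the margin); pooled over held-out
sites it supports the decision-score vs MMSE correlation analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import product
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.linear_model import LogisticRegression
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .features import FeatureTable

#: Per-kind feature-selection p thresholds.
DEFAULT_THRESHOLDS = {
    "sfc_edge": 0.001,
    "dfc_window_edge": 0.00001,
    "tdncd_roi_distance": 0.05,
}

#: Default hyperparameter grid for the fully connected network: Adam learning
#: rate x passes over the training data.  Ordered ascending so ties in the
#: inner loop resolve toward the smaller learning rate, then fewer passes.
FCNET_GRID = [
    {"learning_rate": lr, "n_passes": n}
    for lr, n in product((1e-4, 1e-3, 1e-2), (50, 100, 200))
]

TASK_CLASSES = {"nc_vs_ad": ("NC", "AD"), "nc_mci_ad": ("NC", "MCI", "AD")}

MODEL_NAMES = ("fcnet", "svm", "knn", "lr", "lda")


@dataclass
class ClassifierSpec:
    """A model family, its hyperparameter grid and the run seed."""

    model: str = "fcnet"
    grid: Optional[Sequence[Mapping[str, float]]] = None
    seed: int = 0
    params: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.model not in MODEL_NAMES:
            raise ValueError(f"unknown model {self.model!r}")
        if self.grid is None:
            self.grid = FCNET_GRID if self.model == "fcnet" else [{}]
        if self.model == "fcnet" and not self.grid:
            raise ValueError("fcnet requires a non-empty hyperparameter grid")
        self.grid = [dict(g) for g in self.grid]


def make_estimator(spec: ClassifierSpec, setting: Mapping[str, float]):
    """Instantiate the sklearn estimator for one hyperparameter setting."""
    if spec.model == "fcnet":
        return MLPClassifier(
            hidden_layer_sizes=(64, 32),
            activation="relu",
            solver="adam",
            learning_rate_init=float(setting.get("learning_rate", 1e-3)),
            max_iter=int(setting.get("n_passes", 100)),
            random_state=spec.seed,
            **spec.params,
        )
    if spec.model == "svm":
        return SVC(kernel="linear", C=1.0, random_state=spec.seed, **spec.params)
    if spec.model == "knn":
        return KNeighborsClassifier(n_neighbors=5, **spec.params)
    if spec.model == "lr":
        return LogisticRegression(
            C=1.0, max_iter=2000, random_state=spec.seed, **spec.params
        )
    if spec.model == "lda":
        return LinearDiscriminantAnalysis(**spec.params)
    raise ValueError(spec.model)


def select_features(
    X: pd.DataFrame,
    labels: pd.Series,
    kinds: pd.Series,
    thresholds: Mapping[str, float] = DEFAULT_THRESHOLDS,
    contrast: tuple[str, str] = ("NC", "AD"),
) -> pd.Index:
    """Keep columns whose two-sample t-test p beats the kind's threshold.

    The test contrasts the two diagnoses in ``contrast`` among the supplied
    (training!) subjects; for the three-class task the contrast stays
    NC vs AD.  Raises when nothing survives, advising threshold relaxation.
    """
    a = X.loc[labels == contrast[0]].to_numpy()
    b = X.loc[labels == contrast[1]].to_numpy()
    if len(a) < 2 or len(b) < 2:
        raise ValueError(
            f"need at least 2 subjects per group for selection "
            f"({contrast[0]}: {len(a)}, {contrast[1]}: {len(b)})"
        )
    _, p = stats.ttest_ind(a, b, axis=0, equal_var=True)
    p = np.where(np.isnan(p), 1.0, p)
    cut = np.array([thresholds[k] for k in kinds.loc[X.columns]])
    keep = X.columns[p < cut]
    if len(keep) == 0:
        raise ValueError(
            "feature selection kept zero columns; relax the per-kind "
            "p thresholds"
        )
    return keep


def _ad_score(estimator, X: np.ndarray, classes: Sequence[str]) -> np.ndarray:
    """Probability-like score for the AD class, in [0, 1]."""
    if hasattr(estimator, "predict_proba"):
        proba = estimator.predict_proba(X)
        col = list(estimator.classes_).index("AD")
        return proba[:, col]
    margin = estimator.decision_function(X)
    if margin.ndim == 1:  # binary: positive margin favours classes_[1]
        score = 1.0 / (1.0 + np.exp(-margin))
        if list(estimator.classes_)[1] != "AD":
            score = 1.0 - score
        return score
    # multiclass one-vs-rest margins -> softmax, take the AD component
    e = np.exp(margin - margin.max(axis=1, keepdims=True))
    proba = e / e.sum(axis=1, keepdims=True)
    col = list(estimator.classes_).index("AD")
    return proba[:, col]


@dataclass
class _FittedPipeline:
    columns: pd.Index
    scaler: StandardScaler
    estimator: object

    def transform(self, X: pd.DataFrame) -> np.ndarray:
        return self.scaler.transform(X[self.columns].to_numpy())

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return self.estimator.predict(self.transform(X))

    def score_ad(self, X: pd.DataFrame) -> np.ndarray:
        return _ad_score(self.estimator, self.transform(X), None)


def _fit_pipeline(
    X: pd.DataFrame,
    labels: pd.Series,
    kinds: pd.Series,
    thresholds: Mapping[str, float],
    spec: ClassifierSpec,
    setting: Mapping[str, float],
) -> _FittedPipeline:
    keep = select_features(X, labels, kinds, thresholds)
    scaler = StandardScaler().fit(X[keep].to_numpy())
    est = make_estimator(spec, setting)
    with warnings.catch_warnings():
        from sklearn.exceptions import ConvergenceWarning

        warnings.simplefilter("ignore", ConvergenceWarning)
        est.fit(scaler.transform(X[keep].to_numpy()), labels.to_numpy())
    return _FittedPipeline(columns=keep, scaler=scaler, estimator=est)


def compute_metrics(
    truth: Sequence[str], predicted: Sequence[str], positive_class: str = "AD"
) -> dict[str, float]:
    """ACC / SEN / SPE / F1 in percent.

    ``positive_class="AD"`` gives the two-class convention: sensitivity is
    the recall of AD, specificity the recall of everything else pooled, F1
    has AD positive.  ``positive_class="macro"`` gives unweighted macro
    averages of the per-class one-vs-rest sensitivity, specificity and F1;
    a class absent from the truth is excluded from the macro mean with a
    warning.
    """
    truth = np.asarray(truth)
    predicted = np.asarray(predicted)
    if truth.size == 0 or truth.size != predicted.size:
        raise ValueError("truth and prediction must be equal-length, non-empty")
    acc = 100.0 * np.mean(truth == predicted)

    def one_vs_rest(cls: str) -> tuple[float, float, float]:
        tp = np.sum((truth == cls) & (predicted == cls))
        fn = np.sum((truth == cls) & (predicted != cls))
        fp = np.sum((truth != cls) & (predicted == cls))
        tn = np.sum((truth != cls) & (predicted != cls))
        sen = tp / (tp + fn) if tp + fn else np.nan
        spe = tn / (tn + fp) if tn + fp else np.nan
        f1 = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else 0.0
        return sen, spe, f1

    if positive_class == "macro":
        classes = sorted(set(truth) | set(predicted))
        rows = []
        for cls in classes:
            if cls not in truth:
                warnings.warn(
                    f"class {cls!r} absent from truth; excluded from the "
                    "macro average",
                    stacklevel=2,
                )
                continue
            rows.append(one_vs_rest(cls))
        sen, spe, f1 = (100.0 * np.nanmean([r[i] for r in rows]) for i in range(3))
    else:
        sen, spe, f1 = (100.0 * v for v in one_vs_rest(positive_class))
    return {"acc": acc, "sen": sen, "spe": spe, "f1": f1}


class LosoClassifier:
    """Nested leave-one-site-out classification model.

    Parameters
    ----------
    table : FeatureTable
        Aligned subject x feature matrix (see :mod:`tdncd.features`).
    manifest : DataFrame
        Cohort table with ``subject_id``, ``site_id``, ``diagnosis``,
        ``mmse``.
    spec : ClassifierSpec
        Model family, hyperparameter grid, seed.
    task : {"nc_vs_ad", "nc_mci_ad"}
    thresholds : mapping
        Per-kind selection p cutoffs (defaults 0.001 sFC / 1e-5 dFC /
        0.05 tdNCD).
    """

    def __init__(
        self,
        table: FeatureTable,
        manifest: pd.DataFrame,
        spec: ClassifierSpec,
        task: str = "nc_vs_ad",
        thresholds: Mapping[str, float] = DEFAULT_THRESHOLDS,
    ) -> None:
        if task not in TASK_CLASSES:
            raise ValueError(f"unknown task {task!r}")
        self.table = table
        self.manifest = manifest.set_index("subject_id", drop=False)
        self.spec = spec
        self.task = task
        self.thresholds = dict(thresholds)
        self.sites = sorted(self.manifest["site_id"].unique())
        if len(self.sites) < 3:
            raise ValueError("leave-one-site-out needs at least 3 sites")

    # -- split helpers -----------------------------------------------------
    def _subjects(self, sites: Sequence[str], diagnoses: Sequence[str]) -> pd.Index:
        man = self.manifest
        mask = man["site_id"].isin(sites) & man["diagnosis"].isin(diagnoses)
        return man.index[mask]

    def _choose_setting(self, train_sites: list[str], classes) -> Mapping[str, float]:
        if len(self.spec.grid) == 1:
            return self.spec.grid[0]
        best_setting, best_score = None, -np.inf
        for setting in self.spec.grid:
            accs = []
            for val_site in train_sites:
                inner_sites = [s for s in train_sites if s != val_site]
                fit_ids = self._subjects(inner_sites, classes)
                val_ids = self._subjects([val_site], classes)
                if len(val_ids) == 0:
                    continue
                pipe = _fit_pipeline(
                    self.table.X.loc[fit_ids],
                    self.manifest.loc[fit_ids, "diagnosis"],
                    self.table.kinds,
                    self.thresholds,
                    self.spec,
                    setting,
                )
                pred = pipe.predict(self.table.X.loc[val_ids])
                accs.append(
                    np.mean(pred == self.manifest.loc[val_ids, "diagnosis"])
                )
            score = float(np.mean(accs)) if accs else -np.inf
            if score > best_score:  # strict: first (smallest) setting wins ties
                best_setting, best_score = setting, score
        return best_setting

    def fit(self) -> "ClassificationResults":
        """Run the nested leave-one-site-out evaluation."""
        classes = TASK_CLASSES[self.task]
        positive = "AD" if self.task == "nc_vs_ad" else "macro"
        fold_rows, score_rows = [], []
        for test_site in self.sites:
            train_sites = [s for s in self.sites if s != test_site]
            test_ids = self._subjects([test_site], classes)
            test_diag = set(self.manifest.loc[test_ids, "diagnosis"])
            if not set(classes) <= test_diag:
                warnings.warn(
                    f"site {test_site!r} is missing a required class; fold "
                    "reported as missing",
                    stacklevel=2,
                )
                fold_rows.append(
                    {"site_id": test_site, "status": "missing", "n_test": len(test_ids)}
                )
                continue
            setting = self._choose_setting(train_sites, classes)
            train_ids = self._subjects(train_sites, classes)
            pipe = _fit_pipeline(
                self.table.X.loc[train_ids],
                self.manifest.loc[train_ids, "diagnosis"],
                self.table.kinds,
                self.thresholds,
                self.spec,
                setting,
            )
            pred = pipe.predict(self.table.X.loc[test_ids])
            truth = self.manifest.loc[test_ids, "diagnosis"].to_numpy()
            metrics = compute_metrics(truth, pred, positive_class=positive)
            fold_rows.append(
                {
                    "site_id": test_site,
                    "status": "ok",
                    "n_test": len(test_ids),
                    **metrics,
                    "n_selected": len(pipe.columns),
                    **{f"hp_{k}": v for k, v in setting.items()},
                }
            )
            scored_ids = list(test_ids)
            if self.task == "nc_vs_ad":
                # score the held-out site's MCI subjects with the fold model
                # so their decision scores support the MMSE correlation
                mci_ids = self._subjects([test_site], ["MCI"])
                scored_ids += list(mci_ids)
            scores = pipe.score_ad(self.table.X.loc[scored_ids])
            for sid, s in zip(scored_ids, scores):
                row = self.manifest.loc[sid]
                score_rows.append(
                    {
                        "subject_id": sid,
                        "site_id": row["site_id"],
                        "diagnosis": row["diagnosis"],
                        "mmse": row.get("mmse", np.nan),
                        "score": float(s),
                    }
                )
        folds = pd.DataFrame(fold_rows)
        scores = pd.DataFrame(
            score_rows,
            columns=["subject_id", "site_id", "diagnosis", "mmse", "score"],
        )
        return ClassificationResults(
            model=self, folds=folds, scores=scores, seed=self.spec.seed
        )


# Backwards-compatible functional entry point.
def nested_loso_evaluate(
    table: FeatureTable,
    manifest: pd.DataFrame,
    spec: ClassifierSpec,
    task: str = "nc_vs_ad",
    thresholds: Mapping[str, float] = DEFAULT_THRESHOLDS,
) -> "ClassificationResults":
    """Run :class:`LosoClassifier` and return its results."""
    return LosoClassifier(table, manifest, spec, task, thresholds).fit()


@dataclass
class ClassificationResults:
    """Per-fold metrics and pooled held-out decision scores."""

    model: LosoClassifier
    folds: pd.DataFrame
    scores: pd.DataFrame
    seed: int

    METRICS = ("acc", "sen", "spe", "f1")

    @property
    def ok_folds(self) -> pd.DataFrame:
        return self.folds[self.folds["status"] == "ok"]

    def mean_metrics(self) -> dict[str, float]:
        """Unweighted mean of each metric over completed folds (percent)."""
        return {m: float(self.ok_folds[m].mean()) for m in self.METRICS}

    def pooled_accuracy(self) -> float:
        """Accuracy pooled over all held-out task subjects (percent)."""
        ok = self.ok_folds
        return float(
            np.sum(ok["acc"] * ok["n_test"]) / np.sum(ok["n_test"])
        )

    def mmse_correlation(self) -> dict[str, float]:
        """Decision-score vs MMSE Pearson correlation in AD + MCI subjects."""
        return decision_mmse_correlation(self.scores)

    def summary(self) -> str:
        mm = self.mean_metrics()
        lines = [
            f"Leave-one-site-out classification ({self.model.task}, "
            f"model={self.model.spec.model}, seed={self.seed})",
            f"  folds: {len(self.folds)} sites "
            f"({len(self.ok_folds)} completed)",
            "  mean metrics over folds (%): "
            + ", ".join(f"{k.upper()}={v:.1f}" for k, v in mm.items()),
        ]
        corr = self.mmse_correlation()
        if not np.isnan(corr["r"]):
            lines.append(
                f"  decision-score vs MMSE (AD+MCI): R={corr['r']:.3f}, "
                f"p={corr['p']:.2g}, n={corr['n']:.0f}"
            )
        lines.append("")
        lines.append(self.folds.to_string(index=False))
        return "\n".join(lines)


def decision_mmse_correlation(scores: pd.DataFrame) -> dict[str, float]:
    """Pearson correlation between decision score and MMSE in AD+MCI subjects.

    Returns ``{"r", "p", "n"}``; ``r``/``p`` are NaN when fewer than 3
    usable subjects remain or the scores are constant.
    """
    sub = scores[scores["diagnosis"].isin(["AD", "MCI"])].dropna(subset=["mmse"])
    if len(sub) < 3:
        warnings.warn("fewer than 3 AD/MCI subjects with MMSE", stacklevel=2)
        return {"r": np.nan, "p": np.nan, "n": float(len(sub))}
    if np.std(sub["score"]) == 0 or np.std(sub["mmse"]) == 0:
        warnings.warn("constant scores or MMSE; correlation undefined", stacklevel=2)
        return {"r": np.nan, "p": np.nan, "n": float(len(sub))}
    r, p = stats.pearsonr(sub["score"], sub["mmse"])
    return {"r": float(r), "p": float(p), "n": float(len(sub))}


def compare_models_paired_t(
    results_a: ClassificationResults, results_b: ClassificationResults
) -> pd.DataFrame:
    """Paired two-sided t-test across per-fold metrics of two runs.

    Both runs must share the identical fold structure (same sites, same
    completion pattern).  A constant non-zero difference makes the paired t
    degenerate (zero variance); that is reported as p = 0 with the
    ``degenerate`` flag set rather than a spurious finite p.
    """
    a, b = results_a.ok_folds, results_b.ok_folds
    if list(a["site_id"]) != list(b["site_id"]):
        raise ValueError("fold structure differs between the two reports")
    rows = []
    for metric in ClassificationResults.METRICS:
        diff = a[metric].to_numpy() - b[metric].to_numpy()
        degenerate = False
        if np.allclose(diff, 0.0):
            t, p = 0.0, 1.0
        elif np.std(diff, ddof=1) == 0.0:
            t = np.inf if diff[0] > 0 else -np.inf
            p, degenerate = 0.0, True
        else:
            t, p = stats.ttest_rel(a[metric], b[metric])
        rows.append(
            {
                "metric": metric,
                "t_stat": float(t),
                "p_two_sided": float(p),
                "mean_diff": float(diff.mean()),
                "degenerate": degenerate,
            }
        )
    return pd.DataFrame(rows)
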