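"""Synthetic multi-site cohorts with controllable connectivity reconfiguration.

The generator produces ROI time series whose dynamic-reconfiguration ground
truth is known, so every pipeline stage (windowed FC, tdNCD, meta-analysis,
classification) can be exercised without access to clinical data.

Generative model
----------------
Each subject's regional signal follows a first-order Markov chain over
``n_states`` latent connectivity states.  Connectivity is generated by a
network-factor model: every ROI belongs to a primary network whose latent
factor it loads on with share ``primary_loading``; the factors of the
networks are coupled through a state-specific network covariance (so network
coupling reconfigures from state to state); and each ROI additionally loads,
with share ``state_contrast``, on a *secondary* network whose identity is
redrawn per state.  The secondary loadings are what make an individual
node's connectivity profile rotate between states.  Because the covariance
is implied by a generative factor model it is positive definite by
construction.  At each frame the chain stays in its current state with the
group's dwell probability, otherwise jumps uniformly to another state, and
the frame is drawn from the current state's model.  Site effects are a
global gain and additive white noise with site-specific standard deviation.
An MMSE score is drawn per subject from the group's normal model and clipped
to [0, 30].

Planting effects
----------------
Each ROI's secondary loading is split between a fixed network and a
state-varying network; the fraction assigned to the varying one (the
``profile_rotation``) controls how strongly the node's connectivity profile
re-points between states.  The group effect scales that rotating fraction by
``1 + direction * effect_delta`` for affected ROIs in the patient groups: a
positive direction makes the profile rotate more (raising tdNCD), a negative
direction pins it to the fixed network (``direction = -1`` with
``effect_delta = 1`` removes the state-dependent component entirely).  The
variance shares themselves are identical for every ROI and group, so the
profile signal-to-noise ratio -- and with it mean connectivity strength --
is untouched: reconfiguration (tdNCD) and level (sFC) effects stay
separately controllable.  Reconfiguration *rate* is controlled independently
through the per-group dwell probability.

Randomness
----------
One master seed drives everything.  State covariances are cohort-level
(derived from the master seed alone); each subject gets an independent
stream keyed by (site index, diagnosis, subject index), so adding subjects
or sites never perturbs other subjects' data.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .timeseries import DIAGNOSES, ROITimeSeries

log = logging.getLogger("tdncd.synthetic")

#: MMSE mean/SD per group, matching a large multi-site AD cohort.
MMSE_MODEL = {"NC": (28.52, 1.64), "MCI": (25.14, 3.39), "AD": (16.56, 6.02)}

#: Per-site (noise SD, gain) pairs emulating scanner heterogeneity.
DEFAULT_SITE_PARAMS = (
    (0.40, 1.00),
    (0.55, 1.10),
    (0.45, 0.90),
    (0.60, 1.05),
    (0.50, 0.95),
    (0.65, 1.15),
    (0.35, 1.00),
)

#: Diagnosis totals of the full-size default cohort (N = 809 over 7 sites).
FULL_COHORT_TOTALS = {"AD": 295, "MCI": 257, "NC": 257}


def _spread(total: int, n_sites: int) -> list[int]:
    """Split a group total as evenly as possible across sites."""
    base, extra = divmod(total, n_sites)
    return [base + (1 if i < extra else 0) for i in range(n_sites)]


def default_group_sizes(
    n_sites: int = 7, totals: Mapping[str, int] = FULL_COHORT_TOTALS
) -> dict[tuple[str, str], int]:
    """Full-size allocation: each diagnosis spread evenly over the sites."""
    sizes: dict[tuple[str, str], int] = {}
    for diag, total in totals.items():
        for i, n in enumerate(_spread(total, n_sites)):
            sizes[(f"site{i + 1}", diag)] = n
    return sizes


def uniform_group_sizes(
    n_sites: int, per_group: int, diagnoses: Sequence[str] = DIAGNOSES
) -> dict[tuple[str, str], int]:
    """Desk-scale allocation: the same count per (site, diagnosis) cell."""
    return {
        (f"site{i + 1}", d): per_group
        for i in range(n_sites)
        for d in diagnoses
    }


def _default_networks(n_rois: int) -> list[int]:
    """Assign ROIs to contiguous, roughly equal network blocks."""
    n_networks = 13 if n_rois >= 100 else max(2, n_rois // 8)
    edges = np.linspace(0, n_rois, n_networks + 1).astype(int)
    labels = np.empty(n_rois, dtype=int)
    for k in range(n_networks):
        labels[edges[k] : edges[k + 1]] = k
    return labels.tolist()


def _default_affected(n_rois: int) -> dict[int, int]:
    """Evenly spaced affected ROIs; ~60% raised, the rest lowered."""
    n_affected = max(2, round(n_rois / 8))
    rois = np.linspace(0, n_rois - 1, n_affected).astype(int)
    n_up = int(np.ceil(0.6 * n_affected))
    return {int(r): (1 if i < n_up else -1) for i, r in enumerate(rois)}


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic multi-site cohort.

    Defaults describe the full-size study: 264 ROIs, 170 frames at TR = 2 s,
    7 sites, 809 subjects.  :meth:`desk_scale` returns a 40-ROI variant
    suitable for fast validation experiments.
    """

    n_rois: int = 264
    networks: Optional[Sequence[int]] = None
    n_states: int = 3
    dwell: Mapping[str, float] = field(
        default_factory=lambda: {"NC": 0.97, "MCI": 0.97, "AD": 0.97}
    )
    effect_delta: Mapping[str, float] = field(
        default_factory=lambda: {"NC": 0.0, "MCI": 0.5, "AD": 1.0}
    )
    affected_rois: Optional[Mapping[int, int]] = None
    site_params: Sequence[tuple[float, float]] = DEFAULT_SITE_PARAMS
    group_sizes: Optional[Mapping[tuple[str, str], int]] = None
    tr_seconds: float = 2.0
    t_frames: int = 170
    primary_loading: float = 0.30
    state_contrast: float = 0.35
    profile_rotation: float = 0.25
    coupling_drift: float = 0.15
    mmse_model: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(MMSE_MODEL)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rois < 2:
            raise ValueError("need at least 2 ROIs")
        if self.n_states < 1:
            raise ValueError("need at least 1 state")
        for g, p in self.dwell.items():
            if not 0.0 < p < 1.0:
                if not (self.n_states == 1 and p == 1.0):
                    raise ValueError(f"dwell probability for {g} not in (0, 1)")
        if self.networks is None:
            self.networks = _default_networks(self.n_rois)
        if len(self.networks) != self.n_rois:
            raise ValueError("networks must label every ROI")
        if self.affected_rois is None:
            self.affected_rois = _default_affected(self.n_rois)
        bad = [r for r in self.affected_rois if not 0 <= r < self.n_rois]
        if bad:
            raise ValueError(f"affected ROIs out of range: {bad}")
        if self.group_sizes is None:
            self.group_sizes = default_group_sizes(len(self.site_params))
        if any(n < 0 for n in self.group_sizes.values()):
            raise ValueError("group sizes must be non-negative")

    @classmethod
    def desk_scale(cls, per_group: int = 25, n_sites: int = 7, **kwargs) -> "SyntheticSpec":
        """Small, fast configuration: 40 ROIs, uniform group sizes."""
        kwargs.setdefault("n_rois", 40)
        kwargs.setdefault(
            "group_sizes", uniform_group_sizes(n_sites, per_group)
        )
        kwargs.setdefault(
            "site_params", DEFAULT_SITE_PARAMS[:n_sites]
        )
        return cls(**kwargs)

    @property
    def sites(self) -> list[str]:
        return sorted({s for s, _ in self.group_sizes})


def _ensure_positive_definite(cov: np.ndarray) -> np.ndarray:
    """Diagonal loading until the smallest eigenvalue clears a margin."""
    eigmin = np.linalg.eigvalsh(cov)[0]
    if eigmin > 1e-6:
        return cov
    log.warning(
        "state covariance not positive definite (min eigenvalue %.3g); "
        "applying diagonal loading",
        eigmin,
    )
    loaded = cov + (abs(eigmin) + 1e-3) * np.eye(cov.shape[0])
    if np.linalg.eigvalsh(loaded)[0] <= 0:
        raise ValueError("covariance not positive definite even after loading")
    return loaded


@dataclass
class _StateModel:
    """Cohort-level factor-model parameters for one diagnosis group."""

    primary_share: float        # variance share on the primary network factor
    secondary_share: float      # variance share on the secondary component
    idio_share: float           # idiosyncratic-noise share
    rotation: np.ndarray        # per-ROI rotating fraction of the secondary
    net: np.ndarray             # primary network index per ROI
    fix: np.ndarray             # fixed secondary network per ROI
    var: np.ndarray             # (n_states, n_rois) state-varying secondary
    g_chol: list[np.ndarray]    # per-state network-factor Cholesky
    g: np.ndarray               # (n_states, n_net, n_net) network covariances


def _cov_fingerprint(spec: SyntheticSpec, diagnosis: str) -> tuple:
    return (
        spec.seed,
        spec.n_rois,
        spec.n_states,
        spec.primary_loading,
        spec.state_contrast,
        spec.profile_rotation,
        spec.coupling_drift,
        tuple(spec.networks),
        tuple(sorted(spec.affected_rois.items())),
        float(spec.effect_delta.get(diagnosis, 0.0)),
    )


_MODEL_CACHE: dict[tuple, _StateModel] = {}


def _group_state_model(spec: SyntheticSpec, diagnosis: str) -> _StateModel:
    key = _cov_fingerprint(spec, diagnosis)
    cached = _MODEL_CACHE.get(key)
    if cached is not None:
        return cached
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 7919]))
    net = np.asarray(spec.networks, dtype=int)
    n_net = int(net.max()) + 1
    r, s = spec.n_rois, spec.n_states
    # network coupling: a stable base correlation structure shared by all
    # states plus a modest state-specific drift (convex combination of
    # random correlation matrices stays a correlation matrix)
    def _random_corr() -> np.ndarray:
        w = rng.standard_normal((n_net, n_net + 3))
        cov = w @ w.T
        d = np.sqrt(np.diag(cov))
        return cov / np.outer(d, d)

    # shrink the base coupling toward identity so network factors are never
    # near-collinear: rotating a loading between collinear factors would be
    # a no-op and make the planted effect structure-dependent
    base_g = 0.5 * np.eye(n_net) + 0.5 * _random_corr()
    gamma = spec.coupling_drift
    g = np.empty((s, n_net, n_net))
    g_chol = []
    for k in range(s):
        g[k] = (1.0 - gamma) * base_g + gamma * _random_corr()
        g_chol.append(np.linalg.cholesky(g[k] + 1e-10 * np.eye(n_net)))
    # secondary structure per ROI: one fixed network plus one state-varying
    # network, both different from the primary; the varying one is distinct
    # across states whenever enough networks exist, so a rotating ROI's
    # profile is guaranteed to re-point between states
    if n_net > 1:
        fix = np.empty(r, dtype=int)
        var = np.empty((s, r), dtype=int)
        for i in range(r):
            others = np.delete(np.arange(n_net), net[i])
            fix[i] = rng.choice(others)
            pool = others[others != fix[i]] if len(others) > 1 else others
            if len(pool) >= s:
                var[:, i] = rng.permutation(pool)[:s]
            else:
                var[:, i] = pool[rng.integers(0, len(pool), size=s)]
    else:
        fix = net.copy()
        var = np.tile(net, (s, 1))
    # the rotating fraction of the secondary share carries the group effect;
    # the variance shares themselves are identical for all ROIs and groups so
    # profile signal-to-noise is untouched
    delta = float(spec.effect_delta.get(diagnosis, 0.0))
    rho = np.full(r, spec.profile_rotation)
    for roi, direction in spec.affected_rois.items():
        rho[roi] = np.clip(
            spec.profile_rotation * (1.0 + direction * delta), 0.0, 1.0
        )
    a, b = spec.primary_loading, spec.state_contrast
    idio = 1.0 - a - b
    if idio < 0.05:
        raise ValueError(
            "primary_loading + state_contrast leave less than 5% "
            "idiosyncratic variance"
        )
    model = _StateModel(
        primary_share=a,
        secondary_share=b,
        idio_share=idio,
        rotation=rho,
        net=net,
        fix=fix,
        var=var,
        g_chol=g_chol,
        g=g,
    )
    if len(_MODEL_CACHE) > 64:
        _MODEL_CACHE.clear()
    _MODEL_CACHE[key] = model
    return model


def state_covariances(spec: SyntheticSpec, diagnosis: str) -> np.ndarray:
    """The group's implied latent-state covariances (n_states x R x R).

    Cohort-level: depends only on the spec (master seed), never on the
    subject, so all subjects of a group share the same states.  The factor
    construction makes each covariance positive definite; the diagonal-
    loading guard is belt-and-braces for numerically degenerate parameter
    choices.
    """
    m = _group_state_model(spec, diagnosis)
    r = spec.n_rois
    covs = np.empty((spec.n_states, r, r))
    idx = np.arange(r)
    for k in range(spec.n_states):
        loadings = np.zeros((r, m.g.shape[1]))
        loadings[idx, m.net] += np.sqrt(m.primary_share)
        loadings[idx, m.fix] += np.sqrt(m.secondary_share * (1.0 - m.rotation))
        loadings[idx, m.var[k]] += np.sqrt(m.secondary_share * m.rotation)
        cov = loadings @ m.g[k] @ loadings.T + m.idio_share * np.eye(r)
        covs[k] = _ensure_positive_definite(cov)
    return covs


def _markov_states(
    n_frames: int, n_states: int, dwell: float, rng: np.random.Generator
) -> np.ndarray:
    states = np.zeros(n_frames, dtype=int)
    states[0] = rng.integers(n_states)
    if n_states == 1:
        return states
    u = rng.random(n_frames - 1)
    jumps = rng.integers(1, n_states, size=n_frames - 1)
    for t in range(1, n_frames):
        if u[t - 1] < dwell:
            states[t] = states[t - 1]
        else:
            states[t] = (states[t - 1] + jumps[t - 1]) % n_states
    return states


def subject_rng(spec: SyntheticSpec, site_index: int, diagnosis: str, subject_index: int) -> np.random.Generator:
    """Independent per-subject stream keyed by (site, diagnosis, subject)."""
    diag_code = DIAGNOSES.index(diagnosis)
    return np.random.default_rng(
        np.random.SeedSequence([spec.seed, site_index, diag_code, subject_index])
    )


def simulate_subject(
    spec: SyntheticSpec,
    site_id: str,
    diagnosis: str,
    rng: np.random.Generator,
    subject_id: str = "sub",
) -> ROITimeSeries:
    """Draw one subject's ROI time series from the state-switching model."""
    if diagnosis not in DIAGNOSES:
        raise ValueError(f"unknown diagnosis {diagnosis!r}")
    site_index = spec.sites.index(site_id)
    noise_sd, gain = spec.site_params[site_index]
    model = _group_state_model(spec, diagnosis)
    dwell = spec.dwell.get(diagnosis, 0.97) if spec.n_states > 1 else 1.0
    states = _markov_states(spec.t_frames, spec.n_states, dwell, rng)
    n_net = model.g.shape[1]
    factor_innov = rng.standard_normal((spec.t_frames, n_net))
    idio = rng.standard_normal((spec.t_frames, spec.n_rois))
    values = np.empty((spec.t_frames, spec.n_rois))
    sqrt_a = np.sqrt(model.primary_share)
    sqrt_fix = np.sqrt(model.secondary_share * (1.0 - model.rotation))
    sqrt_var = np.sqrt(model.secondary_share * model.rotation)
    sqrt_e = np.sqrt(model.idio_share)
    for k in range(spec.n_states):
        mask = states == k
        if not mask.any():
            continue
        factors = factor_innov[mask] @ model.g_chol[k].T
        values[mask] = (
            sqrt_a * factors[:, model.net]
            + sqrt_fix[None, :] * factors[:, model.fix]
            + sqrt_var[None, :] * factors[:, model.var[k]]
            + sqrt_e * idio[mask]
        )
    values = gain * values + noise_sd * rng.standard_normal(values.shape)
    mu, sd = spec.mmse_model[diagnosis]
    mmse = float(np.clip(np.round(rng.normal(mu, sd)), 0.0, 30.0))
    labels = [f"net{spec.networks[i]:02d}_roi{i:04d}" for i in range(spec.n_rois)]
    return ROITimeSeries(
        subject_id=subject_id,
        site_id=site_id,
        diagnosis=diagnosis,
        tr_seconds=spec.tr_seconds,
        values=values,
        mmse=mmse,
        roi_labels=labels,
    )


def cohort_manifest(spec: SyntheticSpec) -> pd.DataFrame:
    """Manifest of the cohort the spec describes, without simulating data.

    Rows carry ``subject_id``, ``site_id``, ``diagnosis``; MMSE and file path
    are filled in by :func:`simulate_cohort` / :func:`generate_cohort`.
    """
    rows = []
    for site_index, site in enumerate(spec.sites):
        for diag in DIAGNOSES:
            n = spec.group_sizes.get((site, diag), 0)
            for j in range(n):
                rows.append(
                    {
                        "subject_id": f"{site}_{diag}_{j:03d}",
                        "site_id": site,
                        "diagnosis": diag,
                        "site_index": site_index,
                        "subject_index": j,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=["subject_id", "site_id", "diagnosis", "site_index", "subject_index"],
    )


def simulate_cohort(
    spec: SyntheticSpec,
) -> tuple[pd.DataFrame, dict[str, ROITimeSeries]]:
    """Simulate every subject in memory.

    Returns the manifest (with MMSE filled in) and a dict mapping subject id
    to its :class:`ROITimeSeries`.
    """
    manifest = cohort_manifest(spec)
    series: dict[str, ROITimeSeries] = {}
    mmse_col = []
    for row in manifest.itertuples(index=False):
        rng = subject_rng(spec, row.site_index, row.diagnosis, row.subject_index)
        ts = simulate_subject(
            spec, row.site_id, row.diagnosis, rng, subject_id=row.subject_id
        )
        series[row.subject_id] = ts
        mmse_col.append(ts.mmse)
    manifest = manifest.drop(columns=["site_index", "subject_index"])
    manifest["mmse"] = mmse_col
    return manifest, series


def ground_truth(spec: SyntheticSpec) -> dict:
    """Sidecar describing the planted effect; never read by the pipeline."""
    return {
        "seed": spec.seed,
        "n_rois": spec.n_rois,
        "n_states": spec.n_states,
        "affected_rois": {str(k): int(v) for k, v in spec.affected_rois.items()},
        "effect_delta": dict(spec.effect_delta),
        "dwell": dict(spec.dwell),
        "state_contrast": spec.state_contrast,
        "profile_rotation": spec.profile_rotation,
        "coupling_drift": spec.coupling_drift,
    }


def generate_cohort(
    spec: SyntheticSpec, out_dir: str | Path, overwrite: bool = False
) -> pd.DataFrame:
    """Write one time-series TSV per subject plus manifest and ground truth.

    Refuses to write into an existing non-empty directory unless
    ``overwrite`` is set.  Fully reproducible: the same spec and seed yield
    byte-identical files.
    """
    from .io import write_timeseries_file  # local import to avoid a cycle

    out_dir = Path(out_dir)
    if out_dir.exists() and any(out_dir.iterdir()) and not overwrite:
        raise FileExistsError(
            f"output directory {out_dir} is not empty (pass overwrite=True)"
        )
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest, series = simulate_cohort(spec)
    paths = []
    for sid in manifest["subject_id"]:
        path = out_dir / f"{sid}.tsv"
        write_timeseries_file(series[sid], path)
        paths.append(path.name)
    manifest = manifest.assign(path=paths)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    with open(out_dir / "ground_truth.json", "w") as fh:
        json.dump(ground_truth(spec), fh, indent=2)
    return manifest
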