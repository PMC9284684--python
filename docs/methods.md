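# Methods

## The statistic

Functional connectivity (FC) between two brain regions is the Pearson
correlation of their BOLD time series. Static FC (sFC) uses the whole scan;
dynamic FC (dFC) recomputes the correlation inside a rectangular window of
length `W` slid in steps of `S`:

    dFC_w[m, n] = corr( x_m[t_w : t_w + W], x_n[t_w : t_w + W] )

With the standard acquisition used throughout (170 frames at TR = 2 s,
`W` = 100 s, `S` = 10 s) a scan yields 25 windows. Windows start at frame 0;
trailing frames that cannot fill a complete window are dropped, so
`n_windows = floor((T − W_frames)/S_frames) + 1`. Window and step lengths in
seconds are converted to frames by rounding to the nearest integer; at
TR = 2 s the defaults convert exactly (50 and 5 frames).

The nodal connectivity diversity (NCD) of node `n` between two connectivity
matrices is one minus the absolute correlation of its connectivity profiles:

    NCD(i, j; n) = 1 − | corr( FC_i[n, :], FC_j[n, :] ) |

The self-connection entry `(n, n)` — identically 1 — is removed from both
profiles before correlating; a constant shared element only distorts the
correlation. Applied to two windows of the dFC stack this is the dynamic NCD
(dNCD). Averaging over all window pairs at a fixed lag `d` gives the
time-distance NCD:

    tdNCD(n, d) = mean_{i = 1..T−d} dNCD(i, i+d; n),   d = 1 .. T−1,

one reconfiguration-intensity curve per node over `T − 1` lags (24 under the
defaults, i.e. 10 s–240 s). The lag-`d` column averages exactly `T − d`
pairs; the last column is the single (first window, last window) pair and is
correspondingly noisy — a known property of the statistic, mitigated in
group analysis by averaging over subjects.

Two deliberate consequences of the definition are preserved as such:

* **Absolute value.** A profile that flips sign exactly counts as *no*
  reconfiguration. It also means the statistic *folds*: pushing a profile
  past orthogonality (toward anticorrelation) lowers tdNCD again. The
  maximum of `E[1 − |r|]` sits near profile decorrelation, not beyond it.
* **Estimation noise floor.** With 50-frame windows the profile correlation
  between two windows is bounded away from 1 by sampling error, so tdNCD is
  positive even for a perfectly stationary process, and neighbouring
  windows (which share frames) are more similar than distant ones.

## Multi-site group comparison

Each site contributes an independent two-sample two-sided t-test per feature
(Student's pooled-variance by default; Welch behind `equal_var=False`). A
site needs at least 2 subjects per group, otherwise it is skipped with a
warning and the number of combined sites reflects that. Per-feature site
p-values are pooled with the weighted (Liptak–)Stouffer method:

    z_i = sign(t_i) · Φ⁻¹(1 − p_i / 2),
    z   = Σ w_i z_i / sqrt(Σ w_i²),   w_i = sqrt(n_i),
    p   = 2 (1 − Φ(|z|)),

the standard directional form: the sign is carried from the t statistic so
that sites with opposite effects cancel, and the combined p is two-sided.
A p of exactly 0 is clamped to the smallest positive float (the quantile
diverges) with a warning.

Significance uses Bonferroni families fixed by convention: the 24 time
distances of a tdNCD profile (per-test threshold 0.05/24 ≈ 0.0021; an ROI is
flagged when any distance is significant) and 264 for the FC-edge
comparison, the convention of the original analysis even though the edge
family counts pairs rather than ROIs — kept verbatim and noted here. For FC
edges the ROI summary counts incident significant edges and flags ROIs with
a positive count.

A useful caution: the unqualified claim "adding an agreeing site never
weakens the combined evidence" is false for the weighted statistic — a
near-null agreeing site inflates the weight denominator more than the
numerator. The provable monotonicity, which the test suite checks, requires
the added site's own z to be at least the current combined z (then
`W + w' ≥ sqrt(W² + w'²)` gives the bound).

## Classification

Features are flattened matrices: upper-triangle sFC edges (R(R−1)/2
columns), tdNCD entries (R × D), and optionally per-window dFC edges.
Columns are ordered deterministically (kind, then index). Feature selection
keeps columns whose two-sample t-test p (NC vs AD, computed on training
subjects only; the same contrast in the three-class task) beats a per-kind
threshold: 0.001 (sFC), 1e−5 (dFC), 0.05 (tdNCD). Selected columns are
z-scored with training-split statistics — required for the margin- and
distance-based models, harmless for the rest.

Evaluation is nested leave-one-site-out: the outer loop holds out one site
as the test set; the inner loop rotates each remaining site as validation to
pick hyperparameters by mean validation accuracy (ties resolve toward the
smaller learning rate, then fewer passes); the winner is refit on all
non-test sites. Selection and scaling are refit inside every split — a
leakage canary in the test suite feeds site-indicator features and verifies
chance-level accuracy.

Model families:

* **fcnet** — a 4-layer fully connected network (input → 64 → 32 → softmax
  output) trained with Adam; the two searched hyperparameters are the
  number of passes over the data {50, 100, 200} and the Adam learning rate
  {1e−4, 1e−3, 1e−2}. Hidden widths are fixed design choices: small enough
  to be stable at a few hundred training subjects. Implemented with
  scikit-learn's `MLPClassifier` (binary output collapses to one logistic
  unit, the standard equivalent parameterisation).
* **svm** (linear kernel, C = 1), **knn** (k = 5), **lr** (L2 logistic
  regression), **lda** — all overridable through `ClassifierSpec.params`.

Metrics are reported in percent: two-class sensitivity/specificity/F1 take
AD as positive; the three-class task reports unweighted macro averages of
per-class one-vs-rest values (whether macro or micro averaging was intended
is unstated in the source analysis; macro is implemented and documented).
A subject's decision score is the predicted AD-class probability (for
margin models, a logistic link of the margin; for the three-class model the
AD component of the softmax). In the two-class task the fold model also
scores the held-out site's MCI subjects, so the pooled decision-score vs
MMSE Pearson correlation can be computed over AD + MCI subjects, all scored
by models that never saw them. Model comparison is a paired two-sided t-test
across per-fold metrics; an exactly constant non-zero difference has zero
variance and is reported as p = 0 with a `degenerate` flag instead of a
spurious finite p.

## The synthetic cohort generator

No clinical data ships with the package; the generator manufactures
multi-site cohorts whose reconfiguration ground truth is known, so that
recovery, calibration and leakage are all testable. It emulates: multi-site
acquisition (per-site gain and noise SD), three diagnostic groups with MMSE
drawn from group models (NC 28.52 ± 1.64, MCI 25.14 ± 3.39, AD 16.56 ± 6.02,
clipped to [0, 30]), and a full-size default of 809 subjects (295 AD /
257 MCI / 257 NC) spread as evenly as possible over 7 sites. The desk-scale
configuration (40 ROIs) is used for all validation experiments.

Signal model per subject: a first-order Markov chain over `n_states = 3`
latent connectivity states (stay probability `dwell = 0.97` per frame, i.e.
mean state duration ≈ 66 s, commensurate with the 100 s window; jumps are
uniform over the other states). Connectivity is a network-factor model:

    x_i(t) = sqrt(a) f_net(i) + sqrt(b(1−ρ_i)) f_fix(i) + sqrt(b ρ_i) f_var(i,s) + sqrt(1−a−b) ε_i

with `a = 0.30` (primary-network share), `b = 0.35` (secondary share),
baseline rotation `ρ = 0.25`. Network factors `f` are correlated through a
state-specific coupling `G_s = (1−γ) G₀ + γ P_s` (`γ = 0.15`), where `G₀`
and `P_s` are random correlation matrices and `G₀` is shrunk 50% toward the
identity — near-collinear factors would make loading rotation a structural
no-op. Each ROI's state-varying secondary network is distinct across states
whenever enough networks exist. Frames are drawn independently given the
state; site effects are applied afterwards. Covariances are positive
definite by construction (generative factor model); a diagonal-loading
guard remains for degenerate parameter choices.

**Effect planting.** Affected ROIs have their rotating fraction scaled:
`ρ_i = ρ · (1 + direction · δ)`, clipped to [0, 1]. Variance shares are
identical for every ROI and group, so profile signal-to-noise — and with it
sFC levels and t-test validity — is untouched: the group difference lives
purely in how strongly the node's profile re-points between states.
`direction = +1` raises tdNCD, `−1` lowers it (δ = 1 pins the profile
entirely). The scale constants above define the operating meaning of
δ = 1: a clearly detectable plant (meta-analytic detection AUC ≈ 0.94 at
25 subjects/group/site over 7 sites). Because of the fold of `1 − |corr|`,
the baseline rotation is deliberately placed on the steep side of the
response, below the decorrelation peak.

**Randomness.** One master seed drives everything; cohort-level structure
uses a stream derived from the seed alone, and each subject gets an
independent stream keyed by (site, diagnosis, subject index), so enlarging
the cohort never perturbs existing subjects (tested byte-for-byte).

**What the generator does not emulate:** hemodynamics, spatial maps,
realistic fMRI noise spectra (1/f, motion), temporal autocorrelation within
states, diagnosis-correlated head motion, or site differences beyond gain
and white-noise level. Passing tests therefore demonstrate the statistical
machinery and its calibration on plausibly structured Gaussian dynamics,
not performance on real scanner data.

## Validation experiments and their design

* **Null calibration.** Features of one cohort are strongly
  cross-correlated (all ROIs share latent factors and the window grid), so
  the effective number of independent ROI × distance tests is in the tens,
  not 960; single-cohort false-positive rates have SD ≈ 0.027 around 0.05.
  The calibration experiment therefore simulates 6 independent zero-effect
  cohorts (one latent state, equal groups, 50 subjects/group/site, 7 sites,
  40 ROIs), takes the Monte-Carlo SE of the rate across replicates, and
  evaluates the Kolmogorov–Smirnov statistic of the pooled p-values against
  the 1% critical value at the effective sample size implied by the
  replicate dispersion. The statistical machinery itself is additionally
  checked on 5000 *independent* simulated features, where the raw 1% KS
  critical value applies. 50 subjects/group/site is used because Student's
  t on bounded, skewed per-subject features is visibly conservative at the
  shortest distances at n = 25 — a finite-sample property of the t-test,
  not of the pooling.
* **Recovery.** 5 of 40 ROIs planted at δ = 1.0 (three raised, two
  lowered), 25 subjects/group/site, 7 sites; ROIs ranked by their largest
  meta-analytic |z| over distances; detection AUC averaged over 10
  independent cohorts. Note that a "null" ROI's profile contains edges to
  planted ROIs, so profile-based statistics exhibit mild spillover at large
  N — intrinsic to the statistic, which is why recovery is assessed by
  ranking.
* **Classification control.** LOSO logistic regression (sFC + tdNCD
  features) on the planted cohort vs its δ = 0 twin; pooled accuracy is
  compared to chance by a binomial test, and the null control must stay
  within binomial noise of 50%.
* **Leakage canary.** Label-balanced cohort whose features are site
  indicators plus noise; LOSO accuracy at chance certifies split hygiene.

Experiment sizes were chosen so the entire validation battery (test suite
plus reproduction script) completes in a few minutes on one CPU;
`tdncd.validation` exposes each experiment for reuse at other scales.

## Numerical and degenerate-input choices

* Correlations are clipped to [−1, 1] and matrices symmetrised against
  floating-point drift; tdNCD entries clipped to [0, 1].
* Zero-variance ROIs (globally or within a window) and constant
  connectivity profiles are hard errors naming the ROI/window — silence
  would hide preprocessing bugs; simulated data never produces them.
* Identical groups with zero variance yield t = 0, p = 1 (a perfect null)
  rather than NaN.
* Time-series TSVs are written at full float precision (`%.17g`); a
  write–read round trip is exact to 1e−12.
* All writes are atomic (temp file + rename) with provenance sidecars
  (tool version, configuration digest, seed).

## Known limitations

* The FC-edge Bonferroni family of 264 understates the number of edge tests;
  it is kept for fidelity to the established convention and flagged here.
* tdNCD columns at long distances average few window pairs and are noisy at
  the single-subject level.
* The generator's effect-size scale is a design convention; δ values are
  not comparable to any physiological effect size.
* Three-class macro averaging is one of two defensible readings of the
  summary metrics; micro averages would differ on imbalanced sites.
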