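# Methods

## Pipeline model

The analysis treats each subject as a T×R matrix of group-ICA component
time courses (defaults T = 145, R = 48, TR = 2 s; ICA itself is upstream
and out of scope). Connectivity is the Pearson correlation between
component time courses, computed two ways:

* **static (sFNC)** — one correlation over the full series per pair;
* **dynamic (dFNC)** — a taper-weighted correlation in stride-1 sliding
  windows. The taper is the full convolution of a 15-TR rectangle with a
  Gaussian of σ = 3 TR truncated at ±3σ, normalized to sum 1. Its
  support is therefore 15 + 2·9 = 33 TR: the *nominal* window size names
  the rectangle, but the support determines the window count
  W = T − 33 + 1 = 113. Weighted means and covariances define the
  correlation; zero-variance columns yield 0 with a logged warning
  rather than NaN.

Before windowing, every column is band-pass filtered with a fifth-order
Butterworth on [0.01, 0.15] Hz. The filter is applied forward–backward
(zero phase, odd-symmetric padding), so "order 5" names the design order
of the prototype and the effective two-pass attenuation is doubled.
Single-pass application is available via `scipy` directly but the
pipeline always uses the zero-phase form to avoid shifting windows in
time.

## States

All subjects' window vectors (N ≈ 10 848 × P = 1128) are pooled and
clustered with squared-Euclidean k-means (k-means++ init, 10 restarts,
seeded; an L1/k-medians variant is a config switch). The number of
states is chosen over k = 2..9 by an elbow rule on the validity index

    V(k) = mean_i ||x_i − c_{label(i)}|| / mean_{a<b} ||c_a − c_b||,

selecting the k with the largest discrete second difference
V(k−1) − 2V(k) + V(k+1), ties to the smaller k. Two guards make the rule
robust: candidate ks must not have V(k) above V(k_min) (an "elbow" on a
curve that has risen past its start is noise — this is what makes the
rule return 2 on two-cluster data, via the fallback), and if no candidate
has positive curvature the smallest k is returned with a warning. k can
also be pinned in replication runs.

Subject representative state matrices are plain means of the subject's
windows assigned to the state; occupancy is the global label frequency;
subjects never entering a state are absent from its roster. No Fisher-z
transform is applied before clustering by default (plain correlations are
clustered); arctanh is a config switch.

## Group statistics

Within each state, each of the 1128 pairs gets a pooled-variance
two-sample t (patient − control sign convention) over the state's roster;
BH-FDR at α = 0.05 is applied *within* the state's 1128-test family, not
pooled across states. States with fewer than 2 subjects per group are
reported untested. Fisher's exact test (two-sided, point-probability
convention) handles sex tables; pooled-t recomputation from printed
summary rows is exposed separately so published demographic tables can be
checked to their printed precision. Covariate regression is OLS of a
pair's connectivity on intercept + sex + age + edu + WTAR with
per-coefficient t-tests; an intercept is included by design, and rank
deficiency fails loudly naming the collinear columns.

## LS-SVM and cross-validation

The classifier is the standard equality-constrained least-squares SVM
with linear kernel: minimize ½‖w‖² + (C/2)Σe², y_i(w·x_i + b) = 1 − e_i,
C = 0.1. This is exactly ridge regression of ±1 labels with penalty 1/C
on ‖w‖² and an unpenalized intercept; the dual is one (n+1) linear
system with ridge 1/C on the kernel diagonal. Because C weighs the
*total* squared slack, duplicating the training set is equivalent to
halving C; the decision function is invariant under that paired scaling,
which is the documented C convention. Following common LS-SVM practice,
every cross-validation wrapper standardizes features to training-fold
z-scores (the bare solver does not).

AUC is the Mann–Whitney statistic (ties ½) on *pooled* leave-one-out
decision values — per-fold AUC is undefined when each fold holds a single
subject. The nested procedure, per left-out subject: candidates are all
(state visited by the subject, τ ∈ {0, .25, .5, .75, 1, 2}); each is
scored by an inner LOOCV over the outer training roster, where
feature-selection t-values are recomputed within every inner training
subset (strict no-leakage; a config switch computes them once per outer
training set for sensitivity analysis); τ = 0 keeps all features by
definition. The best inner AUC wins, ties resolved toward larger τ (fewer
features) then lower state index, and the winner retrains on the full
outer training roster to score the left-out subject. The sFNC baseline is
the identical machinery with a single all-subject "state". The bootstrap
comparison resamples subjects with replacement, stratified by class,
from each classifier's pooled scores (B = 10 000 each) and applies a
pooled two-sample t to the AUC samples (df = 2B − 2); the resampling unit
is the subject's held-out score.

## Synthetic cohort

The generator emulates the study cohort so every stage is testable
against ground truth: 48 patients + 48 controls, R = 48 components in six
named network groups of eight (subcortical, cerebellum, auditory,
sensorimotor, visual, default-mode), T = 145, TR = 2 s, K = 4 latent
states. Each state's correlation matrix elevates within-group correlation
(0.60) on two rotating groups over a 0.05 baseline (0.15 within other
groups), making states mutually well separated. Patients additionally get
+0.3 on six *component-disjoint* cerebellum×sensorimotor pairs in one
state; disjoint pairs keep the perturbation's spectral norm at 0.3, so
the matrices stay positive definite without repair (a concentrated block
of shared components at the same δ is genuinely infeasible and is
rejected by the PD-repair tolerance of 0.01).

Latent states follow per-subject first-order Markov chains with
self-transition 1 − 1/dwell_mean. The default dwell of 80 TR (160 s)
mirrors the long-dwelling pattern of real scans — many subjects spend
most of a 5-minute scan in one or two states — and gives each visited
state enough windows that the windowed estimator's sampling noise does
not swamp the injected effect: with the 33-TR taper, shorter dwells put a
large fraction of windows across state transitions and attenuate the
measured group difference by ~30%. Non-dominant states (indices ≥ 2) are
each skipped entirely by a subject with probability 0.3, reproducing
"not all subjects visit all states" (rosters of ~36–63 of 96). Emissions
are white Gaussian given the state (row t ~ N(0, C_state)); a
moving-average smoothing of innovations is available but off by default,
since white emissions are exactly what the windowed-correlation estimator
assumes and keep recovery tests interpretable. Phenotypes are drawn
independently of the time series with a ~5-point WTAR group gap and
matched age/sex/education.

What the generator does *not* emulate: hemodynamics, motion or scanner
artifacts, between-subject variation in the state matrices themselves
(all patients share one set of matrices, so between-subject feature
variance is purely sampling noise), temporal autocorrelation within
state, or group differences in occupancy. Passing tests therefore show
that the pipeline recovers known structure from data obeying its own
assumptions — not that it is robust to real-fMRI nuisance structure.

## Numerical choices and degenerate inputs

* Correlation values are clipped to [−1, 1] only to absorb rounding
  (< 1e−10 overshoot); zero-variance columns are detected relative to the
  column's power (var ≤ 1e−13 × power).
* PD repair: eigenvalue clip at 1e−6 with diagonal renormalization,
  iterated; any requested entry moved by > 0.01 aborts generation naming
  the entry.
* Empty k-means clusters are re-seeded (sklearn's relocation); the
  k-medians variant re-seeds from the farthest point.
* Mass-univariate t with zero pooled variance returns t = 0, p = 1
  (logged) so maps stay finite; the scalar `two_sample_t` raises instead.
* Inner-CV candidates that select no feature, or whose scored labels are
  single-class, are dropped from the nested optimization; a subject with
  no usable candidate (or visiting no state) is excluded with a warning.
* All randomness flows through explicit integer seeds; reruns are
  byte-identical.

## Known limitations

* Pooled-LOOCV AUC at roster sizes of ~40–60 subjects has a standard
  deviation near 0.10 (plus a small LOOCV-induced downward bias), so
  per-state AUCs of *null* states scatter widely around chance on any
  single cohort draw; probes with i.i.d. features show this spread is
  irreducible at these sample sizes regardless of feature covariance.
  Conclusions should rest on contrasts (effect state vs others, dFNC vs
  sFNC bootstrap), not on a single state's AUC.
* The validity index is one reasonable dispersion ratio; other indices
  may place the elbow differently on weakly separated data.
* Problem sizes in the test suite and acceptance script follow the
  emulated study (96 subjects, 48 components, 145 timepoints, k-range
  2..9, B = 10 000), with small synthetic problems for solver-level
  oracle checks.
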