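"""State-aware LS-SVM classification with nested leave-one-out selection.

A linear least-squares SVM (squared slacks, solved as one linear system)
classifies subjects from their per-state representative connectivity
vectors.  Three layers are provided:

* per-state LOOCV using all R(R-1)/2 features, giving one AUC per state;
* the nested LOOCV: for every left-out subject, an inner LOOCV over the
  outer training set evaluates every candidate (state visited by the
  left-out subject, |t|-threshold in {0, .25, .5, .75, 1, 2}) and the best
  inner AUC picks the model that scores the left-out subject;
* a stratified subject bootstrap comparing two classifiers' pooled
  leave-one-out scores via a two-sample t-test on bootstrap AUC samples.

LS-SVM convention: minimize ``(1/2)·||w||^2 + (C/2)·sum_i e_i^2`` with
equality constraints ``y_i (w·x_i + b) = 1 - e_i`` (the standard
equality-constrained LS-SVM with regularization constant gamma = C),
equivalent to the primal ridge problem on +/-1 targets with penalty 1/C
on ``||w||^2``; the dual is an (n+1) linear system with ridge ``1/C`` on
the kernel diagonal.  Because C weights the *total* squared slack,
duplicating every training point is equivalent to halving C; the decision
function is invariant under that paired scaling.

Following common LS-SVM practice, every cross-validation wrapper
standardizes features to training-set z-scores before training and applies
the same transform to held-out subjects (``standardize=False`` disables
it); the bare solver :func:`lssvm_train` works on features as given.
Strict no-leakage: held-out subjects never enter inner t-tests, feature
selection, standardization, or training.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .stats import pooled_t_vector

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLDS = (0.0, 0.25, 0.50, 0.75, 1.0, 2.0)
DEFAULT_C = 0.1


@dataclass
class LSSVMModel:
    """Trained linear least-squares SVM restricted to selected features."""

    weights: np.ndarray
    bias: float
    C: float
    #: indices of the features the model was trained on
    feature_index: np.ndarray

    def decision_values(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(x)
        return x[:, self.feature_index] @ self.weights + self.bias


@dataclass
class CVReport:
    """Cross-validation outcome: scores, AUCs, and model-selection record."""

    per_state_auc: dict[int, float]
    overall_auc: float
    #: one entry per classified subject: id, chosen state, threshold, n_features
    per_fold_choice: list[dict]
    #: (state, threshold) -> times chosen
    selection_histogram: dict[tuple[int, float], int]
    #: subject_id -> (decision score, true label)
    pooled_scores: dict[str, tuple[float, int]]
    #: state -> mean full-length weight vector over folds choosing the state
    mean_weights: dict[int, np.ndarray] = field(default_factory=dict)
    #: subjects that visited no state and could not be classified
    excluded: list[str] = field(default_factory=list)
    thresholds: tuple = DEFAULT_THRESHOLDS

    @property
    def scores_and_labels(self) -> tuple[np.ndarray, np.ndarray]:
        s = np.array([v[0] for v in self.pooled_scores.values()])
        y = np.array([v[1] for v in self.pooled_scores.values()])
        return s, y


def _dual_solve(kernel: np.ndarray, y: np.ndarray, C: float) -> tuple[np.ndarray, float]:
    """Solve the LS-SVM dual: [[K + (1/C) I, 1], [1', 0]] [alpha; b] = [y; 0]."""
    n = len(y)
    a = np.empty((n + 1, n + 1))
    a[:n, :n] = kernel + (1.0 / C) * np.eye(n)
    a[:n, n] = 1.0
    a[n, :n] = 1.0
    a[n, n] = 0.0
    rhs = np.append(y, 0.0)
    sol = np.linalg.solve(a, rhs)
    return sol[:n], float(sol[n])


def lssvm_train(
    x: np.ndarray,
    y: np.ndarray,
    C: float = DEFAULT_C,
    feature_index: np.ndarray | None = None,
) -> LSSVMModel:
    """Train the linear LS-SVM on features ``x`` and labels ``y`` in {-1, +1}."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape[0] < 2:
        raise ValueError("need at least 2 training subjects")
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    if feature_index is None:
        feature_index = np.arange(x.shape[1])
    xs = x[:, feature_index]
    alpha, b = _dual_solve(xs @ xs.T, y, C)
    return LSSVMModel(weights=xs.T @ alpha, bias=b, C=C, feature_index=feature_index)


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC as the Mann-Whitney U statistic / (n+ * n-), ties counted 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == 1
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both classes")
    ranks = sps.rankdata(scores)
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def _train_scaler(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Training-fold feature mean and sd (sd 1 for constant features)."""
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    sd[sd <= 0] = 1.0
    return mean, sd


def loocv_state_auc(
    state_features: np.ndarray,
    labels: np.ndarray,
    C: float = DEFAULT_C,
    standardize: bool = True,
) -> tuple[float, np.ndarray]:
    """Leave-one-out AUC within one state using all features.

    Each subject in the state roster is scored by a model trained on the
    remaining roster; the AUC is computed on the pooled held-out decision
    values and the weight vector (on the standardized scale) is averaged
    over folds.
    """
    x = np.asarray(state_features, dtype=float)
    y = np.asarray(labels, dtype=float)
    n = len(y)
    if n < 4 or len(np.unique(y)) < 2:
        raise ValueError("state roster too small for LOOCV")
    scores = np.empty(n)
    weights = np.zeros(x.shape[1])
    for i in range(n):
        keep = np.arange(n) != i
        x_tr, x_te = x[keep], x[i]
        if standardize:
            mean, sd = _train_scaler(x_tr)
            x_tr = (x_tr - mean) / sd
            x_te = (x_te - mean) / sd
        model = lssvm_train(x_tr, y[keep], C=C)
        scores[i] = model.decision_values(x_te)[0]
        weights += model.weights
    return roc_auc(scores, y), weights / n


# ---------------------------------------------------------------------------
# nested LOOCV with joint (state, threshold) selection


def _loo_group_stats(x: np.ndarray, y: np.ndarray):
    """Per-class feature sums/sums-of-squares for fast leave-one-out t-values."""
    stats = {}
    for cls in (-1.0, 1.0):
        rows = x[y == cls]
        stats[cls] = (rows.sum(axis=0), (rows**2).sum(axis=0), len(rows))
    return stats


def _loo_t_values(stats, x_out: np.ndarray, y_out: float) -> np.ndarray:
    """Pooled t-values with one subject removed, from cached class sums."""
    out = {}
    for cls, (s, q, n) in stats.items():
        if cls == y_out:
            s, q, n = s - x_out, q - x_out**2, n - 1
        if n < 2:  # degenerate class: no usable t-values
            return np.zeros_like(s)
        mean = s / n
        var = np.maximum(q - n * mean**2, 0.0) / (n - 1)
        out[cls] = (mean, var, n)
    (m0, v0, n0), (m1, v1, n1) = out[-1.0], out[1.0]
    df = n0 + n1 - 2
    sp2 = ((n0 - 1) * v0 + (n1 - 1) * v1) / df
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m0) / np.sqrt(sp2 * (1.0 / n0 + 1.0 / n1))
    return np.nan_to_num(t, nan=0.0, posinf=0.0, neginf=0.0)


def _masked_kernel(
    xs: np.ndarray,
    xo: np.ndarray,
    gram: np.ndarray,
    kx_full: np.ndarray,
    mask: np.ndarray,
):
    """Kernel over the training rows and cross-kernel to the held-out subject
    on masked features, using whichever of the selected / excluded feature
    sets is smaller (building directly, or subtracting the excluded
    features' contribution from the full-feature Gram)."""
    n_sel = int(mask.sum())
    n_feat = mask.shape[0]
    if n_sel == n_feat:
        return gram, kx_full
    if n_sel <= n_feat - n_sel:
        xm = xs[:, mask]
        return xm @ xm.T, xm @ xo[mask]
    exc = ~mask
    xe = xs[:, exc]
    return gram - xe @ xe.T, kx_full - xe @ xo[exc]


def _inner_candidate_aucs(
    x: np.ndarray,
    y: np.ndarray,
    thresholds,
    C: float,
    t_mode: str,
    standardize: bool = True,
) -> dict[float, float]:
    """Inner-LOOCV AUC for every threshold within one outer-training state."""
    n = len(y)
    stats = _loo_group_stats(x, y)
    if t_mode == "outer":
        t_fixed = _loo_t_values(stats, np.zeros(x.shape[1]), 0.0)  # no removal
    scores: dict[float, list] = {tau: [] for tau in thresholds}
    idx = np.arange(n)
    for j in range(n):
        rows = idx[idx != j]
        if len(np.unique(y[rows])) < 2:
            continue
        t = t_fixed if t_mode == "outer" else _loo_t_values(stats, x[j], y[j])
        abs_t = np.abs(t)
        xs, xo = x[rows], x[j]
        if standardize:
            # inner-training mean/sd from the cached class sums
            s_tot = stats[-1.0][0] + stats[1.0][0] - x[j]
            q_tot = stats[-1.0][1] + stats[1.0][1] - x[j] ** 2
            mean = s_tot / (n - 1)
            var = np.maximum(q_tot - (n - 1) * mean**2, 0.0) / (n - 2)
            sd = np.sqrt(var)
            sd[sd <= 0] = 1.0
            xs = (xs - mean) / sd
            xo = (xo - mean) / sd
        gram = xs @ xs.T
        kx_full = xs @ xo
        for tau in thresholds:
            # tau = 0 keeps the full feature set by definition
            mask = abs_t > tau if tau > 0 else np.ones_like(abs_t, dtype=bool)
            if not mask.any():
                continue
            kernel, kx = _masked_kernel(xs, xo, gram, kx_full, mask)
            alpha, b = _dual_solve(kernel, y[rows], C)
            scores[tau].append((float(alpha @ kx + b), y[j]))
    aucs = {}
    for tau, sl in scores.items():
        if not sl:
            continue
        s = np.array([v[0] for v in sl])
        lab = np.array([v[1] for v in sl])
        if len(np.unique(lab)) < 2:
            continue
        aucs[tau] = roc_auc(s, lab)
    return aucs


def nested_loocv(
    state_features: dict[int, tuple[list[str], np.ndarray]],
    labels: dict[str, int],
    thresholds=DEFAULT_THRESHOLDS,
    C: float = DEFAULT_C,
    t_mode: str = "inner",
    standardize: bool = True,
) -> CVReport:
    """Outer LOOCV over subjects with nested (state, t-threshold) selection.

    Parameters
    ----------
    state_features
        state -> (roster subject ids, roster x P feature matrix).
    labels
        subject_id -> label in {-1, +1} (+1 = patient).
    thresholds
        |t| cutoffs for feature selection, evaluated in the inner loop.
    t_mode
        "inner" recomputes feature-selection t-values within every inner
        training subset (strict no-leakage, default); "outer" computes
        them once per outer training set.

    For each left-out subject, only states the subject visited are
    candidates.  Every (state, threshold) candidate is scored by an inner
    LOOCV over the outer training roster; the best inner AUC (ties: larger
    threshold, then lower state index) retrains on the full outer training
    roster and scores the left-out subject.  The overall AUC pools the
    outer held-out scores.
    """
    rosters = {s: list(ids) for s, (ids, _) in state_features.items()}
    all_subjects = sorted(labels)
    classified = [sid for sid in all_subjects if any(sid in r for r in rosters.values())]
    excluded = [sid for sid in all_subjects if sid not in classified]
    for sid in excluded:
        logger.warning("subject %s visited no state; cannot be classified", sid)

    per_fold = []
    pooled: dict[str, tuple[float, int]] = {}
    histogram: Counter = Counter()
    weight_sums: dict[int, np.ndarray] = {}
    weight_counts: Counter = Counter()

    for sid in classified:
        candidates = []
        for s, (ids, x) in state_features.items():
            if sid not in ids:
                continue
            pos = ids.index(sid)
            keep = np.arange(len(ids)) != pos
            x_tr = x[keep]
            y_tr = np.array([labels[i] for i in ids], dtype=float)[keep]
            if len(y_tr) < 3 or len(np.unique(y_tr)) < 2:
                continue
            aucs = _inner_candidate_aucs(
                x_tr, y_tr, thresholds, C, t_mode, standardize=standardize
            )
            for tau, auc in aucs.items():
                candidates.append((auc, tau, -s, s, x_tr, y_tr, x[pos]))
        if not candidates:
            logger.warning("subject %s: no usable candidate model", sid)
            excluded.append(sid)
            continue
        auc, tau, _, s, x_tr, y_tr, x_out = max(candidates, key=lambda c: c[:3])
        # final model: features from the full outer-training roster of state s
        t_final, _ = pooled_t_vector(x_tr[y_tr == -1], x_tr[y_tr == 1])
        mask = np.abs(t_final) > tau if tau > 0 else np.ones(x_tr.shape[1], bool)
        if not mask.any():
            mask = np.ones_like(mask)
        if standardize:
            mean, sd = _train_scaler(x_tr)
            x_tr = (x_tr - mean) / sd
            x_out = (x_out - mean) / sd
        model = lssvm_train(x_tr, y_tr, C=C, feature_index=np.flatnonzero(mask))
        score = float(model.decision_values(x_out)[0])
        pooled[sid] = (score, labels[sid])
        histogram[(s, tau)] += 1
        per_fold.append(
            {
                "subject_id": sid,
                "state": s,
                "threshold": tau,
                "n_features": int(mask.sum()),
                "inner_auc": auc,
                "n_candidates": len(candidates),
            }
        )
        full_w = np.zeros(x_tr.shape[1])
        full_w[model.feature_index] = model.weights
        weight_sums[s] = weight_sums.get(s, 0.0) + full_w
        weight_counts[s] += 1

    scores = np.array([pooled[sid][0] for sid in pooled])
    ys = np.array([pooled[sid][1] for sid in pooled])
    overall = roc_auc(scores, ys) if len(np.unique(ys)) == 2 else float("nan")

    per_state_auc = {}
    for s, (ids, x) in state_features.items():
        y = np.array([labels[i] for i in ids], dtype=float)
        try:
            per_state_auc[s], _ = loocv_state_auc(x, y, C=C, standardize=standardize)
        except ValueError:
            logger.warning("state %d roster too small for per-state LOOCV", s)
    return CVReport(
        per_state_auc=per_state_auc,
        overall_auc=overall,
        per_fold_choice=per_fold,
        selection_histogram=dict(histogram),
        pooled_scores=pooled,
        mean_weights={s: w / weight_counts[s] for s, w in weight_sums.items()},
        excluded=sorted(set(excluded)),
        thresholds=tuple(thresholds),
    )


def sfnc_nested_loocv(
    sfnc_table: np.ndarray,
    subject_ids: list[str],
    labels: dict[str, int],
    thresholds=DEFAULT_THRESHOLDS,
    C: float = DEFAULT_C,
    t_mode: str = "inner",
    standardize: bool = True,
) -> CVReport:
    """Nested LOOCV on static connectivity: one "state" holding all subjects,
    so the nested selection runs over thresholds only."""
    return nested_loocv(
        {0: (list(subject_ids), np.asarray(sfnc_table, dtype=float))},
        labels,
        thresholds=thresholds,
        C=C,
        t_mode=t_mode,
        standardize=standardize,
    )


def bootstrap_compare(
    report_a: CVReport,
    report_b: CVReport,
    n_boot: int = 10_000,
    seed: int = 0,
) -> dict:
    """Compare two classifiers by bootstrapping their pooled LOOCV scores.

    Subjects are resampled with replacement, stratified by class, within
    each report's pooled (score, label) pairs; each resample yields one
    AUC.  The two AUC samples are compared with a pooled two-sample t-test
    (df = 2*n_boot - 2).
    """
    rng = np.random.default_rng(seed)
    samples = []
    for rep in (report_a, report_b):
        s, y = rep.scores_and_labels
        pos, neg = np.flatnonzero(y == 1), np.flatnonzero(y != 1)
        if len(pos) == 0 or len(neg) == 0:
            raise ValueError("pooled scores must contain both classes")
        aucs = np.empty(n_boot)
        for b in range(n_boot):
            while True:
                ip = pos[rng.integers(len(pos), size=len(pos))]
                ineg = neg[rng.integers(len(neg), size=len(neg))]
                idx = np.concatenate([ip, ineg])
                if len(np.unique(y[idx])) == 2:
                    break
                logger.warning("single-class bootstrap resample; redrawing")
            aucs[b] = roc_auc(s[idx], y[idx])
        samples.append(aucs)
    a, b = samples
    df = 2 * n_boot - 2
    sp2 = ((n_boot - 1) * a.var(ddof=1) + (n_boot - 1) * b.var(ddof=1)) / df
    t = (a.mean() - b.mean()) / np.sqrt(sp2 * (2.0 / n_boot))
    p = 2.0 * sps.t.sf(abs(t), df)
    return {
        "auc_samples_a": a,
        "auc_samples_b": b,
        "t": float(t),
        "df": int(df),
        "p": float(p),
    }
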