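"""Synthetic state-switching component-time-course cohort.

Emulates a resting-state fMRI study cohort at the level the pipeline
consumes: per-subject matrices of T timepoints x R independent-component
time courses (TR-spaced), whose instantaneous covariance switches among K
latent connectivity "states" according to a per-subject first-order Markov
chain.  One state can carry a group difference (patients vs controls)
concentrated on a configurable set of component pairs, emulating a
cerebellum-sensorimotor connectivity increase.  A matching phenotype table
(sex, age, education, WTAR) is produced alongside ground-truth latent
labels so that state recovery, effect localization and classification can
be scored against the truth.

The emission model is conditionally independent Gaussian given the latent
state: row ``t`` is drawn from a zero-mean multivariate normal with the
correlation matrix of the active state.  An optional moving-average
smoothing of the innovations is available (off by default) to mimic the
temporal autocorrelation that band-pass filtering induces in real
component time courses.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: canonical network-group names used to partition components into blocks
NETWORK_GROUPS = (
    "subcortical",
    "cerebellum",
    "auditory",
    "sensorimotor",
    "visual",
    "default_mode",
)

GROUPS = ("control", "patient")


def component_partition(
    n_components: int, group_names: Sequence[str] = NETWORK_GROUPS
) -> dict[str, np.ndarray]:
    """Split ``0..n_components-1`` into contiguous, near-equal network groups."""
    if n_components < 2:
        raise ValueError("need at least 2 components")
    n_groups = min(len(group_names), n_components)
    chunks = np.array_split(np.arange(n_components), n_groups)
    return {group_names[g]: chunks[g] for g in range(n_groups)}


def default_state_block_spec(
    n_states: int, partition: dict[str, np.ndarray]
) -> list[dict]:
    """Per-state block correlation levels.

    Each state elevates within-group correlation on two network groups
    (rotating with the state index) so that states are mutually well
    separated in connectivity space; the remaining groups keep a weak
    within-group correlation over a low common baseline.
    """
    names = list(partition)
    n_groups = len(names)
    spec = []
    for k in range(n_states):
        strong = {names[k % n_groups], names[(k + 2) % n_groups]}
        spec.append(
            {
                "baseline": 0.05,
                "within": {nm: (0.60 if nm in strong else 0.15) for nm in names},
                "between": {},
            }
        )
    return spec


def default_phenotype_params() -> dict:
    """Group phenotype distributions (means/sds echo a matched mTBI cohort)."""
    return {
        "sex_male_frac": 23 / 48,
        "age": {"control": (27.40, 8.96), "patient": (27.79, 9.18)},
        "edu": {"control": (13.92, 2.13), "patient": (13.13, 2.25)},
        "wtar": {"control": (55.50, 7.40), "patient": (50.10, 8.74)},
    }


@dataclass
class CohortConfig:
    """Configuration of the synthetic cohort.

    Defaults reproduce the study conditions this generator emulates:
    48 patients and 48 matched controls, 48 components, 145 timepoints at
    TR = 2 s, four latent connectivity states, and a patient-only
    correlation increase of ``effect_delta`` on cerebellum x sensorimotor
    pairs in ``effect_state``.
    """

    n_per_group: int = 48
    n_components: int = 48
    n_timepoints: int = 145
    tr_seconds: float = 2.0
    n_states: int = 4
    #: mean dwell time of the latent chain, in timepoints
    dwell_mean: float = 80.0
    state_block_spec: list | None = None
    effect_state: int = 1
    effect_pairs: tuple | None = None
    effect_delta: float = 0.3
    #: probability a subject never enters a given non-dominant state
    state_visit_sparsity: float = 0.3
    #: states every subject may visit (never dropped by the sparsity draw)
    always_visited_states: tuple = (0, 1)
    #: moving-average length for innovation smoothing; 1 = white emissions
    smooth_len: int = 1
    phenotype_params: dict | None = None
    #: max allowed |change| of a requested entry during PD repair
    repair_tol: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_components < 2:
            raise ValueError("n_components must be >= 2")
        if self.n_states < 1:
            raise ValueError("n_states must be >= 1")
        if self.dwell_mean < 1:
            raise ValueError("dwell_mean must be >= 1 timepoint")
        if not 0 <= self.state_visit_sparsity < 1:
            raise ValueError("state_visit_sparsity must be in [0, 1)")
        if self.n_states > 1 and not (0 <= self.effect_state < self.n_states):
            raise ValueError("effect_state out of range")

    @property
    def partition(self) -> dict[str, np.ndarray]:
        return component_partition(self.n_components)

    def resolved_block_spec(self) -> list[dict]:
        if self.state_block_spec is not None:
            return self.state_block_spec
        return default_state_block_spec(self.n_states, self.partition)

    def resolved_effect_pairs(self) -> list[tuple[int, int]]:
        """Component pairs carrying the group effect (i < j).

        Default: component-disjoint cerebellum x sensorimotor pairs
        (cer[i], sen[i]).  Disjoint pairs keep the spectral norm of the
        group-difference perturbation at |effect_delta|, so the patient
        matrices stay positive definite without repair.
        """
        if self.effect_pairs is not None:
            return [tuple(sorted(p)) for p in self.effect_pairs]
        part = self.partition
        if "cerebellum" not in part or "sensorimotor" not in part:
            raise ValueError(
                "too few components for default effect pairs; set effect_pairs"
            )
        cer, sen = part["cerebellum"], part["sensorimotor"]
        n_pairs = min(len(cer), len(sen), 6)
        return [
            tuple(sorted((int(cer[i]), int(sen[i])))) for i in range(n_pairs)
        ]

    def resolved_phenotype_params(self) -> dict:
        return self.phenotype_params or default_phenotype_params()


@dataclass
class SubjectRecord:
    """One simulated participant: phenotypes plus the T x R time-course matrix."""

    subject_id: str
    group: str  # "control" or "patient"
    sex: str  # "M"/"F"
    age: float
    edu: float
    wtar: float
    timecourses: np.ndarray


@dataclass
class GroundTruth:
    """Latent quantities recorded for parameter-recovery scoring."""

    #: subject_id -> length-T array of latent state indices (0-based)
    labels: dict[str, np.ndarray]
    #: group -> list of K true correlation matrices
    state_correlations: dict[str, list[np.ndarray]]
    #: subject_id -> sorted tuple of states the subject's chain may enter
    allowed_states: dict[str, tuple[int, ...]]


# ---------------------------------------------------------------------------
# correlation-matrix construction


def nearest_pd_correlation(
    mat: np.ndarray, eig_floor: float = 1e-6, max_iter: int = 100
) -> np.ndarray:
    """Project a symmetric matrix to a positive-definite correlation matrix.

    Alternates an eigenvalue clip at ``eig_floor`` with re-normalization of
    the diagonal to 1 until the minimum eigenvalue clears the floor.
    """
    out = (mat + mat.T) / 2.0
    for _ in range(max_iter):
        vals, vecs = np.linalg.eigh(out)
        if vals.min() > eig_floor:
            break
        vals = np.clip(vals, eig_floor, None)
        out = (vecs * vals) @ vecs.T
        d = np.sqrt(np.diag(out))
        out = out / np.outer(d, d)
        out = (out + out.T) / 2.0
    np.fill_diagonal(out, 1.0)
    return out


def _block_matrix(n: int, partition: dict[str, np.ndarray], spec: dict) -> np.ndarray:
    mat = np.full((n, n), float(spec.get("baseline", 0.0)))
    for name, level in spec.get("within", {}).items():
        idx = partition[name]
        mat[np.ix_(idx, idx)] = level
    for (na, nb), level in spec.get("between", {}).items():
        ia, ib = partition[na], partition[nb]
        mat[np.ix_(ia, ib)] = level
        mat[np.ix_(ib, ia)] = level
    np.fill_diagonal(mat, 1.0)
    return mat


def build_state_correlations(config: CohortConfig) -> dict[str, list[np.ndarray]]:
    """True per-state correlation matrices for each group.

    Patient matrices differ from control matrices only at the configured
    effect pairs in the effect state, by ``+effect_delta`` (applied on the
    correlation scale before positive-definiteness repair).  Raises if the
    block specification is infeasible, i.e. PD repair moves a requested
    entry by more than ``config.repair_tol``.
    """
    part = config.partition
    spec = config.resolved_block_spec()
    if len(spec) != config.n_states:
        raise ValueError("state_block_spec length must equal n_states")
    out: dict[str, list[np.ndarray]] = {g: [] for g in GROUPS}
    pairs = config.resolved_effect_pairs() if config.effect_delta != 0 else []
    for k in range(config.n_states):
        base = _block_matrix(config.n_components, part, spec[k])
        targets = {"control": base}
        pat = base.copy()
        if k == config.effect_state:
            for i, j in pairs:
                pat[i, j] += config.effect_delta
                pat[j, i] += config.effect_delta
        targets["patient"] = pat
        for g, target in targets.items():
            if np.abs(target[~np.eye(config.n_components, dtype=bool)]).max() >= 1:
                raise ValueError(
                    f"state {k} ({g}): requested off-diagonal level outside (-1, 1)"
                )
            repaired = nearest_pd_correlation(target)
            delta = np.abs(repaired - target)
            if delta.max() > config.repair_tol:
                i, j = np.unravel_index(np.argmax(delta), delta.shape)
                raise ValueError(
                    f"infeasible block spec: state {k} ({g}) entry ({i},{j}) "
                    f"moved by {delta[i, j]:.4f} > {config.repair_tol} during PD repair"
                )
            out[g].append(repaired)
    return out


# ---------------------------------------------------------------------------
# latent chain and emission


def simulate_state_sequence(
    config: CohortConfig,
    n_timepoints: int,
    rng: np.random.Generator,
    allowed_states: Sequence[int] | None = None,
) -> np.ndarray:
    """Length-T latent state labels from a first-order Markov chain.

    Self-transition probability is ``1 - 1/dwell_mean``; leaving moves
    uniformly to one of the other allowed states.  States not in
    ``allowed_states`` never appear.
    """
    allowed = sorted(set(range(config.n_states) if allowed_states is None else allowed_states))
    if not allowed:
        raise ValueError("no allowed states for this subject")
    if any(s < 0 or s >= config.n_states for s in allowed):
        raise ValueError("allowed state out of range")
    labels = np.empty(n_timepoints, dtype=np.int64)
    p_stay = 1.0 - 1.0 / config.dwell_mean
    state = int(rng.choice(allowed))
    for t in range(n_timepoints):
        labels[t] = state
        if len(allowed) > 1 and rng.random() >= p_stay:
            others = [s for s in allowed if s != state]
            state = int(others[rng.integers(len(others))])
    return labels


def simulate_subject(
    config: CohortConfig,
    group: str,
    state_corrs: Sequence[np.ndarray],
    labels: np.ndarray,
    rng: np.random.Generator,
    subject_id: str = "sub-000",
    phenotypes: dict | None = None,
) -> SubjectRecord:
    """Draw one subject's T x R series given its latent label path.

    Row ``t`` is N(0, C_{labels[t]}); rows are independent given the labels
    (unless ``smooth_len > 1``, which moving-averages the innovations with
    variance renormalized to 1 before the state transform is applied).
    """
    n_t = len(labels)
    n_r = config.n_components
    z = rng.standard_normal((n_t, n_r))
    if config.smooth_len > 1:
        kern = np.ones(config.smooth_len) / np.sqrt(config.smooth_len)
        z = np.apply_along_axis(lambda c: np.convolve(c, kern, mode="same"), 0, z)
    x = np.empty_like(z)
    chols = {int(s): np.linalg.cholesky(state_corrs[int(s)]) for s in np.unique(labels)}
    for s, chol in chols.items():
        rows = labels == s
        x[rows] = z[rows] @ chol.T
    phen = phenotypes or {"sex": "F", "age": 0.0, "edu": 0.0, "wtar": 0.0}
    return SubjectRecord(
        subject_id=subject_id,
        group=group,
        sex=phen["sex"],
        age=float(phen["age"]),
        edu=float(phen["edu"]),
        wtar=float(phen["wtar"]),
        timecourses=x,
    )


def _draw_allowed_states(config: CohortConfig, rng: np.random.Generator) -> tuple[int, ...]:
    always = {s for s in config.always_visited_states if s < config.n_states}
    if not always:
        always = {0}
    allowed = []
    for s in range(config.n_states):
        if s in always or rng.random() >= config.state_visit_sparsity:
            allowed.append(s)
    return tuple(allowed)


def generate_cohort(
    config: CohortConfig,
) -> tuple[list[SubjectRecord], pd.DataFrame, GroundTruth]:
    """Generate the full cohort: subjects, phenotype table, and ground truth.

    Pure function of the config (all randomness comes from ``config.seed``);
    regenerating with the same config is bit-identical.
    """
    rng = np.random.default_rng(config.seed)
    corrs = build_state_correlations(config)
    params = config.resolved_phenotype_params()
    subjects: list[SubjectRecord] = []
    truth = GroundTruth(labels={}, state_correlations=corrs, allowed_states={})
    rows = []
    idx = 0
    for group in GROUPS:
        n = config.n_per_group
        n_males = int(round(params["sex_male_frac"] * n))
        for i in range(n):
            idx += 1
            sid = f"sub-{idx:03d}"
            phen = {
                "sex": "M" if i < n_males else "F",
                "age": rng.normal(*params["age"][group]),
                "edu": rng.normal(*params["edu"][group]),
                "wtar": rng.normal(*params["wtar"][group]),
            }
            allowed = _draw_allowed_states(config, rng)
            labels = simulate_state_sequence(
                config, config.n_timepoints, rng, allowed_states=allowed
            )
            subj = simulate_subject(
                config, group, corrs[group], labels, rng, subject_id=sid, phenotypes=phen
            )
            subjects.append(subj)
            truth.labels[sid] = labels
            truth.allowed_states[sid] = allowed
            rows.append(
                {
                    "subject_id": sid,
                    "group": group,
                    "sex": phen["sex"],
                    "age": phen["age"],
                    "edu": phen["edu"],
                    "wtar": phen["wtar"],
                }
            )
    phenotypes = pd.DataFrame(rows)
    return subjects, phenotypes, truth


def config_to_dict(config: CohortConfig) -> dict:
    """JSON/YAML-serializable echo of the configuration."""
    d = dataclasses.asdict(config)
    for key in ("effect_pairs", "always_visited_states"):
        if d[key] is not None:
            d[key] = [list(p) if isinstance(p, (tuple, list)) else p for p in d[key]]
    return d
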